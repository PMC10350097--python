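"""Train the desk-scale model and segment held-out phantoms.

Trains the depth-2, width-8 encoder-decoder on eight two-tract
phantoms with 6–12-measurement subset augmentation (a few minutes on
one CPU), then segments two held-out phantoms with a 4-member subset
ensemble and reports Dice scores and surface distances.
"""

from dwiseg import (
    ModelConfig,
    b0_normalize,
    binarize,
    build_model,
    ensemble_predict,
    evaluate_segmentation,
    make_training_sampler,
    random_crossing_spec,
    simulate_dwi,
    train,
)


def make_case(seed, snr=20.0):
    dwi, labels = simulate_dwi(random_crossing_spec(seed, grid=32, snr=snr))
    return b0_normalize(dwi), labels


train_cases = [make_case(s) for s in range(8)]
val_cases = [make_case(100 + s) for s in range(2)]

config = ModelConfig(patch_shape=(32, 32, 32), out_labels=2, depth=2,
                     base_width=8, learning_rate=1e-3, epochs=5,
                     iters_per_epoch=60, seed=0)
model = build_model(config)
sampler = make_training_sampler(train_cases[0][0].gtab, 6, 12, rng_seed=7)
model, log = train(model, train_cases, val_cases, config, sampler)
print(log.to_string(index=False))
# train/val soft-Dice loss should fall steadily toward ~0.2

for seed in (200, 201):
    dwi, labels = make_case(seed)
    ens = ensemble_predict(model, dwi, config, k=6, n=4, rng_seed=11)
    report = evaluate_segmentation(binarize(ens.mean), labels)
    print(f"\nheld-out phantom {seed}: mean DSC {report.mean_dsc:.3f}, "
          f"HD95 {report.mean_hd95:.2f} mm, ASSD {report.mean_assd:.2f} mm")
# DSC well above 0.9 shows the direct SH-input model recovers the
# tracts from only 6 of the 30 measurements per ensemble member
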