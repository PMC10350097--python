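# dwiseg

Direct segmentation of white-matter tracts from diffusion MRI — no
tractography, no fiber-orientation estimation in between.

Most tract-segmentation pipelines first reconstruct a tractogram or a
fiber-orientation distribution and segment that; every intermediate
step adds estimation error and often demands dense multi-shell
acquisitions that clinical scans lack. `dwiseg` instead feeds the
diffusion data itself to a 3D fully convolutional network, via a
representation that makes the model independent of the acquisition
scheme:

1. b0-normalize the diffusion-weighted volumes (divide by the mean b=0
   volume);
2. project the normalized signals x(q_i) onto the even real spherical
   harmonics of order 2 — **6 coefficient channels regardless of how
   many gradient directions were measured**;
3. at every training iteration, use a random well-spread subset of
   6–12 measurements (q-space subset augmentation);
4. at inference, predict with n different measurement subsets and
   average the probability maps voxel-wise:
   ȳ = (1/n) Σ_k y_k;
5. quantify the ensemble disagreement per tract with an unfolded
   earth-mover's distance,

   u = (1/n) Σ_k EMD(y_k, ȳ),

   where each probability map is downsampled ×4, normalized to unit
   mass, serpentine-unfolded to 1D and compared by the distance between
   cumulative sums (the exact 1D Wasserstein distance along the
   unfolded path). Tracts with u > 0.30 are flagged as
   likely-inaccurate segmentations.

The package is aimed at researchers who want to study or extend this
direct-segmentation recipe: it ships the full pipeline (gradient-table
IO, SH projection, subset selection, a self-contained NumPy 3D U-Net
with Dice-loss training, ensembling, uncertainty, DSC/HD95/ASSD
metrics) plus a multi-tensor phantom simulator so everything runs and
is testable at desk scale on a laptop CPU, with no external data.

## A worked example

```python
import numpy as np
from dwiseg import (b0_normalize, binarize, build_model, dice,
                    ensemble_predict, make_training_sampler, ModelConfig,
                    random_crossing_spec, simulate_dwi, train,
                    uncertainty_report)

def case(seed, snr=20.0):
    dwi, labels = simulate_dwi(random_crossing_spec(seed, grid=32, snr=snr))
    return b0_normalize(dwi), labels

config = ModelConfig(patch_shape=(32, 32, 32), out_labels=2, depth=2,
                     base_width=8, learning_rate=1e-3, epochs=5,
                     iters_per_epoch=60, seed=0)
model = build_model(config)
train_cases = [case(s) for s in range(8)]
sampler = make_training_sampler(train_cases[0][0].gtab, 6, 12, rng_seed=7)
model, log = train(model, train_cases, [case(100), case(101)], config, sampler)

dwi, labels = case(200)
ens = ensemble_predict(model, dwi, config, k=6, n=4, rng_seed=11)
mask = binarize(ens.mean)
print([round(dice(mask[..., l], labels[..., l]), 3) for l in range(2)])
report = uncertainty_report(ens, threshold=0.30)
print({l: round(u, 3) for l, u in report.u.items()})
```

On one CPU this trains in ≈ 3 minutes and prints (seeds as above):

```
[0.978, 0.991]
{0: 0.246, 1: 0.361}
```

meaning both held-out tracts are recovered with Dice ≈ 0.98 from
6-measurement subsets of a 30-direction scan, with ensemble
disagreement u of 0.25 and 0.36 — around the 0.30 flagging threshold
at this moderate SNR of 20. The contrast that makes u useful is with
scan quality: on the same geometries the median u is ≈ 0.24 at SNR 40
but ≈ 1.8 at SNR 5 (see `scripts/acceptance.py`), so unreliable noisy
scans stand out clearly. The
scripts in `examples/` walk through each capability — phantom
simulation, SH projection and subsets, training/segmentation, and
uncertainty flagging — and print what the numbers mean.

There is also a thin CLI over the same functions:

```bash
dwiseg simulate --seed 1 --grid 32 --out-dir work/p1
dwiseg train --train-dir work/p1 ... --val-dir work/p9 --out-dir work/model
dwiseg predict --model work/model/model.npz --data-dir work/p1 --out-dir work/pred
dwiseg uncertainty --prediction-dir work/pred --out-dir work/unc
dwiseg evaluate --prediction work/pred/segmentation.nii.gz \
                --truth work/p1/labels.nii.gz --out-dir work/eval
```

Every command writes a `manifest.json` with the resolved configuration
and seeds, so runs are reproducible bit for bit.

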