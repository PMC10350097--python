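# Methods

## Problem and approach

White-matter tracts are usually segmented from diffusion MRI through
intermediate reconstructions — tractograms or fiber-orientation
distributions — whose own estimation errors propagate into the final
segmentation, and which often demand dense multi-shell acquisitions that
clinical scans do not have. `dwiseg` implements the alternative: segment
tracts *directly* from single-shell, DTI-style data (b ≈ 750–1200 s/mm²)
with a fully convolutional network, made acquisition-independent by a
fixed low-order spherical-harmonics input representation and made robust
(and self-auditing) by q-space subset ensembling.

The pipeline is:

1. **b0 normalization.** Diffusion-weighted volumes are divided
   voxel-wise by the mean of the b=0 volumes. Measurements with
   b ≤ 50 s/mm² count as b=0 (the field has no universal cutoff; 50
   accommodates the small nonzero "b=0" values some scanners record).
   Averaging multiple b=0 volumes, rather than picking one, is the
   lower-variance choice. The normalized signal is clipped to [0, 2]:
   physical attenuation is ≤ 1, and values above 1 can only be noise;
   clipping keeps the downstream least-squares fit from chasing
   outliers.
2. **SH projection.** The normalized signals x(q_i) on unit directions
   q_i are fit with the even real spherical-harmonics basis of order 2
   (6 functions), by (optionally Laplace–Beltrami-regularized) least
   squares. Six or more well-spread directions determine the fit, so the
   network input is always 6 channels regardless of how many
   measurements a scan has — this is what lets one model serve scans
   with different gradient tables.
3. **Subset augmentation.** Each training iteration uses a random subset
   of 6–12 measurements (size uniform, selection below), giving the
   model a different view of the same scan every iteration. At test time
   n subsets (default 10; the studies here use 4) are predicted
   separately and averaged voxel-wise.
4. **Segmentation network.** A plain 3D U-Net-style encoder–decoder
   (two convolution + instance-norm + ReLU blocks per level, max-pool
   down, nearest-neighbour up with skip concatenation) with a
   multi-label sigmoid head — sigmoid, not softmax, because tracts
   overlap where they cross. Trained with Adam on the soft Dice loss,
   batch size 1, halving the learning rate when the validation loss
   plateaus.
5. **Uncertainty.** The disagreement u between ensemble members and
   their mean, measured by an unfolded earth-mover's distance, flags
   likely-inaccurate segmentations (u > 0.30 by default).

## SH basis convention

We use the real, symmetric (even-degree) basis with the orthonormal
complex harmonics Y_l^m combined as

    Y_{l,m} = √2 (−1)^m Im(Y_l^{|m|})  (m < 0),   Y_{l,0} = Y_l^0,
    Y_{l,m} = √2 (−1)^m Re(Y_l^m)      (m > 0),

ordered l = 0 then l = 2, m = −2…2 (`basis_name = "real_symmetric"`).
Several sign/ordering conventions circulate in dMRI software; any fixed
one works as long as training and inference share it, so the name is
recorded in every coefficient volume's sidecar and model checkpoint.
Coefficients are computed in the scanner frame of the bvecs, with no
reorientation to world axes, matching common dMRI practice.

## Subset selection

The selection must be simultaneously *random* (different draws must
differ, or augmentation is pointless) and *well spread* in q-space (a
clumped subset carries little angular information). We use randomized
farthest-point sampling with local refinement: a uniformly random
non-b0 start, greedy growth maximizing the minimum pairwise angular
distance (antipodal metric, min(θ, π−θ), since the diffusion signal
cannot tell q from −q), then single-point swap hill-climbing on the
minimum pairwise angle, best of 8 random restarts. Plain greedy growth
is a 2-approximation of the max-min dispersion optimum and in practice
can land ~25% below it; the swap refinement with restarts keeps the
selected spread within ~80% of the exhaustive optimum on every random
10-direction table we test, while the random starts preserve draw-to-
draw diversity. Disjoint test-time subsets (for reproducibility studies)
restrict each selection to the still-unused indices.

## The phantom generator

Phantoms stand in for research-grade single-shell scans. Each is a cubic
grid (default desk scale: 32³ voxels, 1 mm isotropic) containing 2–4
tubes around smooth polyline centerlines that cross near the volume
center; radii 3–4.5 mm. Signals follow a cylindrically symmetric
diffusion tensor per tract compartment — axial diffusivity 1.7e-3,
radial 0.3e-3 mm²/s, typical of coherent white matter — with the
principal axis along the local centerline tangent; crossing voxels
average compartment signals with equal fractions; the background is
isotropic with ADC 1.0e-3 mm²/s. Acquisition: 30 quasi-uniform
(Fibonacci-hemisphere) directions at b = 1000 s/mm² plus 3 b=0 volumes,
matching a common DTI protocol. Rician noise is applied as the
magnitude of the complex signal plus two Gaussian channels of
σ = s0/SNR; default SNR 20, a mid-range value for b=1000 brain dMRI.

What the phantom does **not** emulate: realistic tract geometry and
tract-to-tract contrast, partial-volume and T2 effects, distortion,
motion, spatially varying noise. Passing the desk-scale tests therefore
shows the pipeline's machinery is correct and that direct SH-input
segmentation works when the signal model holds — it does not certify
accuracy on real brains.

## The network and training at desk scale

The architecture is configuration, not contract: depth (number of
poolings), base width and patch size are free, with the constraint that
patch sides be divisible by 2^depth. The implementation is a NumPy
encoder–decoder with explicit forward/backward passes (convolutions as
a single GEMM over an im2col view, recomputed in backward to bound
memory) and an Adam optimizer; it is deliberately sized for CPU-scale
experiments and is verified against finite-difference gradients in
double precision. Full-scale defaults (96³ patches, 41 labels, lr 1e-4)
mirror a production run; the desk-scale studies in the tests and the
acceptance script use depth 2, base width 8, 32³ patches, lr 1e-3 and
5 epochs × 60 iterations (≈ 3 minutes on one CPU), which is enough for
the two-tract phantoms — held-out Dice is typically ≥ 0.95.

Patch sampling centers half the patches on a random foreground voxel
and draws the rest uniformly — standard practice for sparse labels.
The validation loss that drives the halve-on-plateau schedule is the
mean soft Dice loss over full validation volumes, each with one subset
fixed across epochs so the series is comparable epoch to epoch.

## Unfolded EMD and the statistic u

Exact Wasserstein distances between 3D probability maps are
impractical, so the maps are compared along a serpentine unfolding:
slices in ascending z, rows alternating direction by z-parity, voxels
within a row alternating by (y+z)-parity. Consecutive unfolded elements
are always grid-adjacent, so one step of the unfolded sequence
corresponds to one coarse-voxel move. With P, Q the cumulative sums of
the unfolded unit-mass maps, EMD(p, q) = Σ_t |P(t) − Q(t)| — exactly
the 1D Wasserstein distance along the unfolded path (the tests verify
this against an LP transport oracle). For scalar cumulative values the
ℓ2 pairing distance reduces to the absolute difference; a
root-sum-of-squares alternative is available via `mode="l2"`.

Maps are first downsampled by 4 per axis with cubic interpolation
(odd-reflection padding keeps the spline exact at the edges for locally
linear data; results are clipped to [0, 1] because cubic interpolation
overshoots), then normalized to unit mass. u is computed per tract as
the mean EMD between each member and the ensemble mean, in units of one
coarse-voxel step; u > 0.30 flags the tract. A member (or mean) with
zero mass has no defined EMD; it is recorded as NaN and the label is
flagged. u is computed per tract rather than jointly over channels —
the accuracy-vs-u relationship of interest is per segmentation.

## Metrics

DSC is 2|A∩B|/(|A|+|B|), defined as 1 when both masks are empty and 0
when exactly one is. Boundaries are mask minus 6-connected erosion
(array-edge voxels count as boundary); distances are voxel-center to
voxel-center, scaled per axis by the voxel size. HD95 is the maximum of
the two directed 95th percentiles (linear interpolation); ASSD is the
mean of the pooled symmetric distance set. Distance metrics for an
empty mask are undefined and reported as NaN, never 0. Per-label
metrics are aggregated by unweighted mean over labels present in the
ground truth.

## Numerical and design choices

- All network arithmetic is float32; SH fits and EMD are float64.
- The SH fit solves the normal equations; at order 2 with ≥ 6 spread
  directions the system is well conditioned, and reg_lambda defaults to
  0 (Laplace–Beltrami weights l²(l+1)² available for robustness).
- Sliding-window inference tiles with 50% overlap and averages
  overlapping patches; volumes smaller than the patch are padded
  reflectively and cropped back.
- Max-pool gradient splits ties equally; ties are measure-zero for
  float activations.
- Every stochastic component (phantom noise, subset draws, patch
  sampling, initialization) is driven by an explicit seed, and the CLI
  records all seeds in a manifest; identical seeds give bit-identical
  runs.

## Known limitations

- No GPU path; the NumPy network is not intended for 96³ × 41-label
  production training.
- The phantom's simplicity means desk-scale accuracy numbers do not
  transfer to real data; on real scans the 72→41-style merged tract
  label set and its reference segmentations must be supplied by the
  user.
- The unfolded EMD is an upper-bound-style surrogate of true 3D EMD:
  exact along the unfolded path, but path-dependent for genuinely 3D
  displacements; the traversal used is recorded in every report.
- The u = 0.30 flagging threshold is a default calibrated on the
  original study's data, not re-calibrated here.
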