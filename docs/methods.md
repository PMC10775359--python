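# Methods

This note documents the models, procedures and numerical choices behind
`fodshift`. The package studies, entirely on synthetic data, how a
deep-learning estimator of white-matter fiber orientation distributions
(FODs) from six diffusion directions degrades under cross-site and
cross-age domain shift, and how two remedies — Method-of-Moments (MoM)
signal harmonization and fine-tuning on few target subjects — recover
performance.

## Spherical-harmonic substrate

All spherical functions use the real, symmetric (even-order), orthonormal
SH basis ordered l-major with m from −l to +l (the MRtrix ordering); a
field up to even order `lmax` has `(lmax+1)(lmax+2)/2` coefficients.
Signals enter at order 2 (six coefficients — exactly determined by six
measurements) and FODs live at order 8 (45 coefficients). Associated
Legendre values are computed by stable upward recurrences, identical to
`scipy.special.lpmv` to ~1e-10 but an order of magnitude faster on the
million-point batches used in peak refinement.

Peak extraction finds strict local maxima of the FOD on a cached
724-point antipodally symmetric Fibonacci grid (neighbor graph of 8
nearest points under antipodal identification), refines each candidate by
a four-stage local cap search (radii 4°, 1.5°, 0.5°, 0.15°; ~0.04° final
resolution), discards peaks below 0.1 of the voxel's largest amplitude,
merges peaks closer than 15° keeping the larger, and returns at most
three. A constant (isotropic) FOD has no strict local maximum and yields
zero peaks. Candidates are capped at six per voxel before refinement;
only the strongest few can survive thresholding and merging, and noisy
near-flat fields would otherwise spend refinement effort on dozens of
ripples. Ties are broken by canonical-hemisphere lexicographic order so
extraction is deterministic.

## Synthetic cohorts

Each subject is a 24³ phantom (nominal 1.5 mm isotropic) whose interior
box is white matter (the study configurations leave a 4-voxel background
margin). The WM box is
partitioned into contiguous single-, double- and triple-fiber strata
(default shares 0.4/0.4/0.2, matched exactly by largest-remainder
allocation), each stratum further split into 32 sub-regions that draw
independent base directions; crossing angles are uniform in [45°, 90°]
and a smooth sinusoidal wobble (±6°) rotates all fibers of a voxel
coherently. The sub-regioning matters: with only a handful of distinct
fiber directions per subject, a trained estimator cannot interpolate
across direction space, and cross-subject generalization collapses.

Signals follow a multi-tensor forward model: each population is an
axially symmetric tensor with fixed axial diffusivity 1.7e-3 mm²/s;
the unassigned volume fraction is isotropic free water (MD 3.0e-3 mm²/s).
Two acquisition schemes are emulated with deterministic well-spread
hemisphere direction sets: a newborn-cohort-like multi-shell scheme
(b ∈ {0, 400, 1000, 2600} s/mm², 6+112 volumes) and a baby-cohort-like
scheme (b ∈ {0, 500, …, 3000} s/mm², 6+96 volumes).

White-matter maturation follows an arctan growth curve
`FA(t) = a·arctan(b·(t − t0)) + d` with defaults (0.07, 0.35, 0, 0.20)
— FA ≈ 0.15 at late-preterm ages rising toward ≈ 0.31 by five years —
and ages are postnatal months throughout (post-menstrual weeks convert
as `(weeks − 40)/4.345`). A subject's radial diffusivity solves the
single-tensor FA closed form for its age, so the DTI-refit FA of
noiseless single-fiber voxels reproduces the curve to 1e-3 by
construction.

Site effects are a smooth multiplicative gain field `1 + g·bump`, a
smooth additive offset `o·S0·(0.5 + 0.5·bump)` (bump: centered Gaussian),
and Rician noise `sqrt((S+ε₁)² + ε₂²)` with σ relative to the mean b=0
signal. The additive offset is the effective shift: a pure gain cancels
in b=0 normalization, while an offset compresses the normalized
attenuation nonlinearly and survives it.

Ground-truth FODs are sums of apodized band-limited deltas: coefficient
vectors `f·w_l·Y_lm(u)` with Gaussian taper `w_l = exp(−0.03·l(l+1))`,
chosen so the order-0 weight is 1 (total apparent fiber density equals
the fraction sum exactly) and peaks of 45°-separated crossings are
recovered within 2°.

## Reference FODs (CSD) and gold-standard consistency

Reference FODs come from single-tissue constrained spherical
deconvolution. The response function is estimated from known
single-fiber voxels per shell as a zonal SH fit of the b0-normalized
signal against the angle to the tensor principal eigenvector. On the
sphere, convolution with the zonal kernel is diagonal:
`s_lm(b) = sqrt(4π/(2l+1)) · r_l(b) · f_lm`. Only diffusion-weighted
rows enter the deconvolution (b=0 is used for normalization), the usual
single-tissue convention; it also makes total AFD proportional to fiber
density for partial-volume voxels whose remainder is invisible at b>0.

Non-negativity is enforced exactly on a 724-point symmetric grid: the
inequality-constrained least-squares problem is whitened through a
Cholesky factor of the normal matrix (with a light Laplace–Beltrami
damping of weakly determined high orders, scale 1e-4 of the data term)
and solved as a least-distance program via the Lawson–Hanson NNLS
transformation. Residual negativity at grid points is at machine level;
the 300-point grid sometimes suggested for this purpose leaves ~3%
between-point dips at order 8, which is why the constraint grid matches
the dense evaluation grid here. Infeasible voxels (not observed in
practice) fall back to their isotropic projection and are counted.

Gold-standard (GS) consistency splits the non-b0 measurements into two
interleaved halves per shell (deterministic alternation; b=0 shared),
reconstructs each half with CSD and compares the two fields with the
full metric suite. Noiselessly the two halves agree perfectly in peak
count on single-fiber phantoms; their residual AFD discrepancy reflects
the disjoint direction subsets (the halves do not carry identical
information) and shrinks with protocol density.

## The six-direction estimator

The six input measurements are the subset of the b = 1000 s/mm² shell
(the shell both protocols share) minimizing the condition number of the
order-2 SH design — exhaustively when C(n,6) ≤ 50,000, otherwise by
farthest-point seeding plus best-improvement exchange. Inputs are
normalized by the voxelwise mean b=0 signal and projected to order 2 by
an exact 6×6 solve.

The regressor maps each voxel's order-2 coefficients, stacked over a
3×3×3 neighborhood (162 features), to the 45 order-8 FOD coefficients
through a multilayer perceptron (two hidden layers, 128 units, ReLU,
dropout 0.1). Features are standardized by the training set's per-feature
mean and standard deviation; the statistics travel with the model, so at
test time a site shift reaches the network as a mis-standardized input
distribution — which is precisely the failure mode under study.
Optimization is Adam with decoupled weight decay 1e-3, learning rate
5e-5, batches of 35 voxel samples, and model selection at the epoch of
lowest validation MSE over WM voxels. Fine-tuning adapts both halves of
the model the way practitioners adapt batch-normalized networks: it
re-estimates the input statistics on the target subjects (their accuracy
improves as roughly 1/sqrt(n), which is where the diminishing returns
from additional target subjects come from) and continues optimizing the
weights from the selected parameters at learning rate 5e-6 with batches
of 10 for 100 epochs, holding out one target subject for epoch selection
when two or more are available (with a single subject the last epoch is
kept). Harmonization arms, by contrast, never touch the model: the
source model keeps its source statistics and the target signals are
moved instead. Desk-scale defaults
train 150 epochs on up to 1500 deterministically subsampled WM voxels
per subject (drawn from 16³ patches with ≥ 30% WM coverage); the
full-scale recipe of 1000 epochs remains configurable. Because the
network is voxelwise over its context window, sliding-window patch
inference with uniform overlap averaging is exactly one pass over all
voxels.

## Harmonization and evaluation

MoM computes per-voxel spherical moments — mean and population (1/n)
variance of the six selected-direction signals — per subject, takes
voxelwise medians across subjects, smooths with a Gaussian (σ = 1 voxel),
and derives `α = sqrt(var_ref/max(var_src, floor))`,
`β = mean_ref − α·mean_src` (α clipped to [0.1, 10]). One (α, β) pair per
voxel is applied to all six directions and, with the same pair, to the
b=0 volumes used for normalization — without the latter the target
site's shifted b=0 would leak back through the normalization. Since
α > 0, within-voxel signal rankings (the directional content) are
preserved exactly.

Metrics mirror the standard suite: Agreement Rate (AR) is the percentage
of WM voxels in a ground-truth fiber-count stratum (k ∈ {1,2,3}) whose
prediction has the same peak count; Angular Error (AE) averages matched
peak-pair angles pooled across a stratum's voxels, with matching solved
as the optimal one-to-one assignment under a 45° cap (maximize matched
pairs, then minimize total angle); total AFD is the FOD's sphere
integral `c₀₀·2√π` and ΔAFD its mean absolute error over WM. Three-fiber
rows are computed but excluded from headline comparisons. Arm-level
numbers are unweighted means over test subjects.

## Study designs

Intra-site: young/old age-group cohorts (12 subjects each, split 8/2/2,
mirroring the 40/10/10 design), baselines for every train→test direction
and fine-tuned arms with 5 target-age subjects.

Inter-site: 20 subjects per site (14/3/3, mirroring 70/15/15); per
direction, the target-trained self-test (upper bound), raw cross-test,
MoM(n) and FT(n) for n ∈ {1, 2, 5, 10} nested target training subsets,
and a from-scratch ablation on the 10-subject subset (8/2 split).
MoM arms never touch model parameters and FT arms never touch test
signals; both invariants are asserted by digest at run time, as is
train/test subject disjointness.

Two study conditions exist. The default emulates the full two-cohort
setting: the sites differ in scheme, smooth gain (amplitude 0.1),
additive offset (0.6·S0), Rician noise (0.02 vs 0.03) *and* age
structure (−2.5–1 vs 1.5–60 postnatal months).
`ExperimentConfig.site_shift_only` keeps the age distributions identical
so the measured gap isolates the scanner/protocol shift; this is the
configuration the acceptance experiment runs. The distinction matters
scientifically: no signal-level linear map can compensate a difference
in tissue maturation, so moment matching addresses scanner effects, not
physiology, and only the isolated-shift setting measures what
harmonization can in principle repair.

## What the phantoms do and do not show

The generator reproduces the features the pipeline is sensitive to —
multi-shell attenuation, crossing geometry, age-dependent anisotropy,
affine scanner shifts, Rician noise — but not anatomy (no gyri, tracts
or partial-volume cortex), no multi-tissue T2 contrast, no distortion or
motion, and subjects share a template grid so no registration error
exists. Passing results therefore demonstrate the internal consistency
and the qualitative domain-shift behavior of the methods, not absolute
performance on real cohorts.

## Determinism

Every stage derives its randomness from one master seed through
`numpy.random.SeedSequence` fan-out (cohorts, initialization, sample
order, dropout, noise). Reports are bit-reproducible for a fixed config
and seed in single-threaded execution.
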