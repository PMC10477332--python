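# Methods

This note documents the models, estimators, numerical choices and known
limitations of `miqfs`. It describes what the package computes and why the
defaults are what they are; every number quoted here is produced by the test
suite or the acceptance script.

## Band decomposition

Each epoch channel is decomposed with a 6-level discrete wavelet transform
(`mode="periodization"`), and one band-limited series is reconstructed per
clinical band by inverting a masked coefficient set. At fs = 256 Hz the
dyadic mapping is delta ← A6+D6 (<4 Hz), theta ← D5 (4–8), alpha ← D4
(8–16), beta ← D3 (16–32), gamma ← D2+D1 (≥32). Including the level-1
detail D1 in gamma makes the five bands a partition of the coefficient
space, so the band series sum back to the epoch exactly (checked to 1e-8
relative error); without D1 the 64–128 Hz residual would be silently
discarded. The band edges are nominal for fs = 256 and scale with fs.

The default mother wavelet is **db8**. Shorter filters have too shallow a
transition band for the stated band selectivity: a pure 10 Hz tone puts
93.4 % of its reconstruction energy into the alpha series under db8 but only
82 % under db4. Longer wavelets (db16+) are sharper still at higher cost;
db8 is the smallest Daubechies filter that clears 90 % capture. The wavelet
is configurable everywhere it is used.

Six levels require ≥ 64 samples; shorter epochs raise an error naming that
minimum. For filters longer than db2 the usual "max useful level" heuristic
would suggest fewer levels at short lengths; PyWavelets then warns about
boundary effects but the transform remains exactly invertible, which is the
property the pipeline relies on. At the default 10 s × 256 Hz epochs no
warning occurs.

## Feature families

Per channel × band, in canonical column order CO, ApEn, FD, Hjorth, PSD
(family-major, then channel, then band), named `<channel>.<band>.<family>`.
With 19 channels: 95 columns per scalar family, 285 for Hjorth, 665 fused.

- **C0 complexity**: DFT bins with power ≤ the mean bin power are zeroed,
  the kept spectrum inverted, and the residual energy fraction
  Σ|x−y|²/Σ|x|² returned; in [0, 1] by Parseval, 0 for pure tones and
  constants, strictly inside (0, 1) for white noise.
- **Approximate entropy** ApEn(m, r): Chebyshev template matching with
  self-matches included, natural-log averaging over the N−m+1 templates at
  both embeddings (the standard normalization; a count divisor printed
  elsewhere as N−m−1 is treated as a typo). Defaults m = 2, r = 0.2·SD(x)
  (the standard Pincus choice), both configurable. A constant series has
  ApEn 0 for any explicit r > 0; the default r is then degenerate and raises.
- **Higuchi fractal dimension**: mean normalized curve length L(T) over the
  T decimated subseries for T = 1..kmax, slope of ln L(T) vs ln(1/T). The
  curve-length formula is implemented in its standard sign-corrected form.
  Default kmax = 8 (a common choice giving ≥ 3 decades of scales at 2560
  samples); requires n ≥ 10·kmax. Calibration: 1.00 on a line, 2.00 on
  white noise, scale-invariant.
- **Hjorth parameters**: activity = population variance; mobility =
  sqrt(var(Δx)/var(x)) with Δ the first difference (length n−1);
  complexity = mobility(Δx)/mobility(x). All variances are mean-centered
  population (1/N) variances, applied uniformly to the signal and its
  differences. A constant signal raises a degenerate-signal error for
  mobility; a signal with constant first difference (a ramp) has mobility 0
  and complexity defined as 0 by convention.
- **Mean PSD**: (1/N)·Σ|DFT(x)|² with the unnormalized DFT, equal to Σx²
  by Parseval.

Degenerate-epoch policy during extraction is configurable: `raise`
(default) or `zero` (fill 0 with a warning).

## MIC estimation

MIC is the maximum over X×Y grids, with cell budget X·Y < B = ⌊n^0.6⌋, of
grid mutual information normalized by log₂ min(X, Y); logs are base 2 so
values live in [0, 1]. The strict budget would exclude even a 2×2 grid for
n ≤ 14, leaving MIC undefined at tiny n, so the effective budget is
max(⌊n^0.6⌋, 5): the 2×2 grid is always admissible.

The search follows the characteristic-matrix approximation: for each row
count q, the y-axis is equipartitioned into q rows (greedy run-packing;
tied values are never split, and a q that cannot produce q nonempty rows is
skipped as a duplicate of a smaller q), then the x-axis partition is
optimized exactly by dynamic programming over *clumps* — maximal runs of
x-sorted points sharing a row, with equal-x points atomic. The additive DP
objective is Σ_cols [−n_c log₂ n_c + Σ_rows n_cr log₂ n_cr], which recovers
H(P) − H(P,Q) after division by n, so grid MI = H(rows) + S/n. Both axis
orientations are searched and the maximum taken, making the estimator
symmetric by construction. When the clump count exceeds
`clump_factor × l_max` (default factor 15, the customary choice), clumps
are merged into near-equal-mass superclumps — a speed/exactness trade that
rarely triggers below a few hundred points. The DP core is numba-compiled.

Ties and determinism: partition boundaries fall only between distinct
values; identical inputs give bit-identical outputs. MIC is invariant under
strictly *increasing* transforms of either variable (identical grid counts).
A *decreasing* transform reverses the sort order, and the greedy
equipartition can then pick a slightly different row split when n is not a
multiple of q, so bitwise invariance is only guaranteed for order-preserving
maps.

An exhaustive oracle (`mic_exhaustive`, n ≤ 14) enumerates every cut-point
subset on both axes for every admissible shape. The DP estimator never
exceeds it (it searches a subset of grids) and matches it exactly on
monotone functional data, where the equipartition assumption is exact; both
properties are asserted in tests.

## Filter stage

Step 1 removes features with label-MIC < 0.2 (strict); Step 2 removes the
less relevant member of every surviving pair with pairwise MIC > 0.8
(strict). Thresholds follow the convention that MIC > 0.8 indicates strong
and MIC < 0.2 weak dependence. Pairwise removal is order-dependent for
redundancy chains (a~b, b~c, a≁c), so the sweep is greedy in descending
relevance: each accepted feature eliminates all not-yet-accepted features
too similar to it. This keeps the most relevant representative of each
redundant group, guarantees no kept pair exceeds the threshold, and is
deterministic (exact relevance ties keep the lower column index). Pairwise
MICs are computed lazily against accepted features only.

## QPSO

Position-only swarm dynamics with per-(particle, dimension) random draws
φ, u, r ~ U(0,1): attractor P = φ·pbest + (1−φ)·gbest, well width
α·|mbest − x| with mbest the mean personal best, displacement ln(1/u) with
u clamped to (1e-12, 1), sign negative when r ≥ 0.5. The
contraction–expansion coefficient α = 0.5 + 0.5·(Tmax−T)/Tmax decays
linearly from 1.0 to 0.5. Out-of-bounds positions are clamped to the box
(the update rule itself is unconstrained). The optimizer minimizes
natively — personal/global bests replace on strict improvement — and a
`sense="maximize"` flag negates the objective, keeping the best-update
rules literal. Non-finite objective values become +inf with a warning.
Defaults N = 200, Tmax = 200; the test suite uses reduced budgets
(N = 30, Tmax = 60 for selection problems of ~20 features, where
convergence is reached well before the budget).

## Wrapper stage

Mask threshold 0.5, with the boundary counting as selected (interval
[0.5, 1)). SVM evaluation is a scikit-learn RBF SVC with gamma = 1/(2σ²),
inner stratified k-fold CV (default k = 3), features standardized per fold
on the training portion only so σ acts on a common scale. The fold seed is
fixed per selection run, making fitness a deterministic function of the
particle. DR = 1 − selected/candidates (the candidate set entering the
wrapper), commensurate with CA on [0, 1]. d in φ(d) defaults to the
original pre-filter dimension and is configurable. C, σ bounds default to
[0.01, 100] with a linear particle mapping; an optional log10 mapping is
available (the linear default keeps the particle box literal). An empty
mask scores fitness 0 rather than raising inside the optimizer.

Numerical note: φ(d) is mathematically strictly decreasing with infimum
0.9, but in float64 it saturates to exactly 0.9 near d ≈ 3900 (e^(−d/100)
falls below the rounding threshold of 9); tests assert strict decrease
above the floor and non-increase overall.

## Outer evaluation harness

Outer stratified 5-fold CV with inner 3-fold CV during fitness evaluation.
Both selection stages are re-fit per outer fold on the training portion
only; held-out accuracy is measured once per fold with the selected mask
and SVM parameters (standardization fit on the outer-train fold). A
`prefilter_per_fold=False` compatibility flag fits the filter once on all
data instead, for comparison with protocols that pre-filter globally; the
leak-free per-fold behaviour is the default. Reports are plain dicts
serialized to sorted-key JSON and are byte-identical under fixed seeds.
The reported weighted value applies the fitness combination to outer-fold
CA and DR with d = the original dimension.

## Synthetic generators

Both generators are pure functions of (spec, seed).

**Planted tables** (defaults: 300 samples, 5 relevant, 3 redundant, 12
irrelevant, class gap 2.0 SD, balanced labels): relevant columns are
class-conditional Gaussians; redundant columns are strictly increasing
transforms (cube, scaled exp, x + tanh x) of a relevant parent plus noise,
re-calibrated at generation until the clone–parent MIC exceeds 0.8 (the
noiseless transform has MIC 1, so calibration terminates); irrelevant
columns are independent Gaussians re-drawn until their label-MIC is below
0.2. A redundant clone carries the same class information as its parent, so
selection-quality metrics count a selected clone as recovering its parent.

**EEG epoch sets** (defaults: 58 subjects × 240 s at 256 Hz, 19 channels
with 10–20 names, 10 s non-overlapping epochs → 1392 epochs, subjects split
29/29 into control/patient): each channel-epoch is a sum of five
band-centered sinusoids (2/6/10/20/40 Hz) with a 1/f-like amplitude profile
(4/3/2.5/1.5/0.8 signal units), phases randomized per epoch and channel (so
no trivial phase artifact separates the classes), plus unit-SD Gaussian
noise. The patient class multiplies the alpha amplitude by 1.5 by default;
any per-band multiplier map is accepted.

What passing on these fixtures does **not** show: the generators contain no
1/f broadband background, no artifacts (EMG/EOG/line noise), no
inter-channel correlation or volume conduction, no nonstationarity, and
class effects are homogeneous across subjects. Results on them validate the
algorithmic machinery (estimators, thresholds, optimization, leak-free
harness), not clinical performance on real recordings.

## Problem sizes used in validation

Tests exercise the pipeline at 150–300 samples × 8–20 features with swarm
budgets N = 10–30, Tmax = 6–60, and the EEG layout checks extract the full
665-column table from a small number of epochs of the default 1392-epoch
fixture — sizes at which every stage's behaviour (thresholding, recovery,
determinism) is already fully expressed and the whole suite runs in
minutes on one core.

## Known limitations

- Pairwise MIC in the filter is O(m²) MIC evaluations; for fused 665-column
  tables this is the dominant cost (the superclump cap bounds each
  evaluation, but the quadratic pair count remains).
- The MIC estimator is an approximation; absolute values on noisy data can
  differ slightly from other estimators of the same statistic, though the
  [0,1] range, symmetry and monotone-invariance guarantees hold exactly.
- The wrapper evaluates one SVM per particle per iteration; its cost scales
  linearly with N × Tmax × inner folds.
- Tables 6/10-style weighted values from external studies are not directly
  comparable unless their DR definition matches the one used here
  (selected/candidates), which is stated in the report.
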