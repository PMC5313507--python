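# Methods

## The metric

The banded DTW distance treats two z-scored BOLD series as elastically
matchable: sample `i` of one series may be matched to sample `j` of the
other whenever `|i − j| ≤ w`, matchings are monotone and gapless, the local
cost is the squared difference, and the distance is the square root of the
minimal accumulated cost. `w` — the Sakoe–Chiba warping window — is the
longest time lag the metric will absorb. It is specified in seconds and
converted to samples by the repetition time with round-half-away-from-zero
(the conversion rule and the backtracking tie-break, diagonal over vertical
over horizontal, are package conventions chosen for reproducibility; nothing
in the method depends on them).

Window sizing follows the expected lag structure: 20 s suffices for
positively coupled regions; anticorrelation-type couplings ride on delays of
up to half a period of the slowest retained fluctuation (50 s at 0.01 Hz),
so 100 s is the default for whole-brain analyses. An unnecessarily long
window costs sensitivity as well as time: independent pairs also warp closer
together, so the null tightens around smaller distances.

Distances are interpreted against an *empirical null*: the distance
distribution over independent band-limited surrogate pairs of the same
length, with the 5th percentile as the significance threshold (small
distance = strong coupling). Correlation metrics use the 5th/95th
percentiles two-sided. For maps and matrices the distances are transformed
to similarities, `s_i = mean(d) − d_i`, an order-reversing affine map whose
null is centered on zero; the demeaning unit is the analysis unit (one seed
map, or one matrix's 4005 pairs) and raw distances are retained alongside.

Properties worth knowing:

- **Boundary cost.** The warping path is pinned to both corners, so a
  constant k-sample lag costs the transition at the edges even when the
  band absorbs it: measured 10–25 % of the unwarped distance for
  band-limited signals. A claimed ≤10 % bound does not hold in general.
- **Null shape.** The null distance at a 100 s window is right-skewed
  (skew ≈ 0.8): it is a minimum over warping paths, not a sum of
  independent terms. A histogram is visually Gaussian, but a formal
  normality test (Shapiro at n = 500) rejects. Parametric t statistics on
  similarities remain serviceable — the t-test is robust to this level of
  skew at map scale — but exact normality should not be asserted.
- **Sign blindness.** DTW absorbs delays, not sign flips. A narrowband
  anti-phase signal looks like a half-period delay and is absorbed; a
  broadband sign flip is not. "Anticorrelated" couplings are therefore
  modeled as delays in the synthetic data.

## Signal conditioning

Order is fixed: nuisance regression first, band-pass second, z-scoring
last. Filtering before regression would re-introduce the out-of-band part of
each confound's projection. Confounds: six motion parameters, mean WM and
CSF signals, the first five temporal principal components of the WM and of
the CSF voxel blocks (computed on demeaned voxel series, ordered by
explained variance), and optionally the global (brain-mean) signal.

The band-pass is a regression high-pass on a discrete-cosine basis of order
9 plus a separate constant term, followed by a 12th-order Butterworth
low-pass at 0.08 Hz applied forward–backward (zero phase; the effective
magnitude order doubles). The DCT order is fixed at 9 per run regardless of
run length; over a 600 s run this removes fluctuations below
9/(2·600) ≈ 0.0075 Hz. The conventional "0.009 Hz" label for this high-pass
overstates the cutoff slightly; the module exposes the order, not the
frequency. Z-scoring uses the population (1/N) standard deviation so that
correlation is exactly the mean product of z-scores.

## Surrogate studies

**Transient interactions.** Surrogates are white Gaussian noise passed
through the same band-pass and z-scored. A transient interaction copies the
first L seconds of one surrogate into an independent surrogate at delay D
(overwrite, then re-z-score; with unit-variance segments the expected
zero-lag correlation at D = 0 is ≈ L/T). The experiment grid — delays
0–100 s in 4 s steps, lengths 60–600 s in 60 s steps, total 600 s at
TR 2 s — covers the regime where correlation works (D ≈ 0, r from ~0.2 to
0.5 as L grows) and the regime only a long-window DTW detects (D up to
~100 s for long L). Cells are flagged significant when the median metric
over the cell's repetitions crosses the null threshold. Defaults: 1000 null
pairs and 10 repetitions per cell; the test suite and the acceptance script
run a scaled version (200 null pairs, 5 repetitions) that reproduces the
same qualitative structure in seconds.

**Common noise.** Two opposite-phase 0.08 Hz sinusoids receive independent
band-limited noise whose amplitude is calibrated by bisection (tolerance
0.005 on the mean correlation of a fixed 40-pair batch) to a target
correlation of −0.86. A shared band-limited "global" signal is then mixed
in: `z((1−α)·x + α·c)` for α up to 0.5. Correlation decays toward zero and
loses significance at high α; the DTW distance stays below its
5th-percentile threshold throughout. The window for this experiment
defaults to 10 s: the only lag to absorb is the anti-phase half-period
(6.25 s), and at 100 s the null tightens enough that the calibrated pair
sits at its ~5th percentile — the detection margin then vanishes by
construction, not because of the noise.

## Synthetic fMRI fixtures

`synth_fmri` generates a small 4-D volume: gray-matter networks driven by
lagged, signed, strength-weighted copies of a shared band-limited source
plus white voxel noise; background gray-matter voxels with independent
sources; WM and CSF slabs with their own latent signals (so CompCor-style
confound extraction has something real to find); and an additive global
signal, modeled in gray matter only so that WM/CSF confounds do not
implicitly remove it. Everything is seed-deterministic and writable as
NIfTI + TSV + JSON. What it does **not** emulate: haemodynamic response
convolution, spatial autocorrelation/smoothing, motion, scanner drift
beyond the band, or physiological noise spectra — so passing tests show the
statistical machinery behaves as designed under the assumed signal model,
not that the pipeline is validated on real acquisitions.

The GSReg-sensitivity experiment (`run_gsr_sensitivity`) instantiates the
regime the sensitivity analysis is about: a seed network; a weak zero-lag
anti-phase network whose anticorrelation is masked by the global signal
(coupling 0.45 against a mean squared global weight of ≈0.44 — visible only
after GSReg); and a stronger anti-phase network at a 4 s lag that
maximal-lag cross-correlation can still find without GSReg (the global
signal's autocorrelation leaves the lagged peak less masked, and the
coupling, 0.9, dominates). The global weight is drawn per run from
0.45–0.85, as physiological noise levels vary between runs. Ten runs are
conditioned with and without GSReg, seed maps are computed for all three
metrics, fixed-effect t maps (FDR q = 0.05) are compared across pipelines,
and pipeline-unstable voxels are counted: for correlation metrics, voxels
significantly negative with GSReg but not significant without; for DTW,
voxels significantly *positive* (connected) under exactly one pipeline.
Under these conditions the counts order DTW < cross-correlation <
correlation in ≥8 of 10 fixture draws.

## Classifier

LASSO regression, objective `(1/N)‖y − Xθ − b‖² + λ‖θ‖₁` with unpenalized
intercept, minimized by cyclic coordinate descent on per-feature
standardized columns (soft-threshold updates; convergence when the largest
coefficient change in a full sweep is < 1e−6, cap 10⁴ sweeps; between full
sweeps the iteration restricts to the active set). Labels are predicted by
thresholding the regression output at 0.5. The hyper-parameter λ is chosen
per outer fold by an inner leave-one-subject-out loop over 25 log-spaced
values in [0.0005, 0.5], ties toward the sparser model; standardization
parameters come from training rows only.

Chance calibration has two levels. The coin-flip threshold (95th percentile
of iid Bernoulli(½) guessing accuracy) equals the Binomial(N, ½) quantile —
56.9 % at N = 130. But it understates the spread of *cross-validated* null
accuracy: predictions are correlated within subject (all runs of a held-out
subject move together), and under balanced leave-subject-out the
intercept-only model systematically predicts the majority class of the
training set, which is the opposite of the held-out subject's class — so
null CV accuracy is left-shifted and wide. Subject-level label permutation
reproduces exactly this distribution and is the appropriate strict
threshold; the suite checks the upper tail (null data beats the coin-flip
threshold only at chance rate) rather than asserting the coin-flip band
two-sided.

## Problem sizes and numerical conventions

Tests and the acceptance script use 300-sample series at TR 2 s (600 s
runs), 200–500-pair nulls, 6×6×3 to 8×8×4 fixture grids, 10-run fixture
batches, and a 20-subject × 5-run × 300-feature classification design (5
informative features at class separation 2 sd) — sizes chosen so every
study runs in seconds to a few minutes while preserving its qualitative
outcome. Degenerate inputs (constant series, empty masks, rank-deficient
confounds, single-class folds) raise typed errors or warn and degrade as
documented per operation. Unequal-length DTW requires `w ≥ |l1 − l2|`;
infeasible bands raise rather than return partial results.

## Known limitations

- The banded DTW is exact but quadratic-in-window; voxel-wise full
  connectomes are out of scope.
- The null must be rebuilt per series length and window; distances are not
  comparable across lengths without the length normalization option.
- The LASSO path's active set is not strictly monotone in λ (coefficients
  can re-enter); sparsity claims are trends, not invariants.
- Real-data acquisition effects (HRF shape variability, motion artifacts,
  spatial smoothing) are outside the synthetic model; conclusions about
  real scans require real scans.
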