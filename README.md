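# dtwconn

Dynamic-time-warping (DTW) functional connectivity for resting-state fMRI.

Classical seed-based connectivity analysis scores the coupling of two BOLD
time series with their zero-lag Pearson correlation, which assumes the
coupling is stationary and synchronous. Resting-state interactions are
neither: couplings switch on and off and carry time lags from a few seconds
(haemodynamic variability) up to 30–100 s (the delays that manifest as
"anticorrelations" between the default-mode and task-positive networks).
`dtwconn` scores coupling with the banded DTW distance instead: samples
`x1(i)` and `x2(j)` may be matched whenever `|i − j| ≤ w` (the Sakoe–Chiba
warping window, specified in seconds and converted by the repetition time),
and the distance is

    DTW(i,j) = (x1(i) − x2(j))² + min{ DTW(i−1,j), DTW(i,j−1), DTW(i−1,j−1) }
    d(x1,x2) = sqrt( DTW(l1,l2) )

computed over z-scored series. Small distances mean strong coupling at *any*
lag profile the band allows. For map- and matrix-level statistics the
distances are negated and demeaned ("DTW similarity"), so unconnected pairs
scatter around zero and the usual one-sample t machinery applies.

The package implements the full surrounding workflow:

- `core_dtw` — banded cost matrix, distance, optimal warping path, per-step
  lag profile (path diagnostics).
- `signal_prep` — nuisance regression (motion, mean WM/CSF and their first
  five principal components, optional global-signal regression), DCT
  high-pass + bidirectional Butterworth low-pass (0.009–0.08 Hz),
  z-normalization.
- `conn_metrics` — zero-lag correlation, maximal-lag cross-correlation
  (signed value of largest magnitude over lags), DTW distance, and the
  distance→similarity transform.
- `simulate` — band-limited surrogates, empirical null calibration,
  transient-interaction grids, common-noise (global signal) robustness
  sweeps, a synthetic 4-D fMRI fixture generator, and a planted-signal
  classification-dataset generator.
- `mapping` — seed-based voxel maps and ROI×ROI connectivity matrices with
  upper-triangle feature vectors (90 ROIs → 4005 features).
- `group_stats` — fixed-effect one-sample t maps with Benjamini–Hochberg
  FDR, paired-t stability matrices, and the global-signal-regression
  sensitivity ("dubious voxel") analysis.
- `classify` — LASSO regression by cyclic coordinate descent with nested
  leave-one-subject-out cross-validation, coin-flip and label-permutation
  chance thresholds.

## Worked example

Score an anti-phase pair under increasing common noise — the situation where
zero-lag correlation famously fails and DTW does not:

```python
import numpy as np
from dtwconn import (MetricSpec, anticorr_pair, build_null, common_noise_sweep)
from dtwconn.simulate import DEFAULT_NOISE_SWEEP_WINDOW_S

rng = np.random.default_rng(0)
null_r = build_null(MetricSpec("corr"), n_pairs=400, seed=rng)
null_d = build_null(MetricSpec("dtw", DEFAULT_NOISE_SWEEP_WINDOW_S), n_pairs=400, seed=rng)

pair = anticorr_pair(freq_hz=0.08, target_r=-0.86, seed=rng)  # r calibrated
sweep = common_noise_sweep(pair, null_r, null_d, w=5, tr=2.0, seed=rng)
for a, r, d, rs, ds in zip(sweep.alphas, sweep.corr, sweep.dtw,
                           sweep.corr_sig, sweep.dtw_sig):
    print(f"alpha={a:.2f}  r={r:+.2f} {'sig' if rs else 'ns '}   "
          f"dtw={d:.2f} {'sig' if ds else 'ns'}")
```

```
alpha=0.00  r=-0.90 sig   dtw=8.18 sig
alpha=0.05  r=-0.89 sig   dtw=8.32 sig
...
alpha=0.40  r=-0.32 sig   dtw=10.78 sig
alpha=0.45  r=-0.14 ns    dtw=10.93 sig
alpha=0.50  r=+0.05 ns    dtw=10.82 sig
```

At 50 % common-noise weight the correlation has collapsed to ≈0 and lost
significance, while the DTW distance stays below its 5th-percentile null
threshold (11.91 here) across the whole range: the anti-phase coupling is
still detected.

The same experiments are available from the shell:

```sh
dtwconn simulate-noise --seed 0 --out out/noise
dtwconn simulate-interaction --seed 0 --out out/grid
dtwconn make-fixture --seed 0 --out out/fixture --global-weight 0.4
dtwconn seed-map --data out/fixture/bold.nii.gz --mask out/fixture/gm_mask.nii.gz \
    --seed-voxel 0,0,0 --metric dtw --window-s 100 --seed 0 --out out/map
```

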