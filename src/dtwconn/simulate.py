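"""Surrogate simulations and synthetic fMRI fixtures.

Two simulation studies characterize the metrics:

* **Transient interactions** — pairs of band-limited (0.009–0.08 Hz)
  surrogate signals share a copied segment, inserted with a time delay.
  Zero-lag correlation detects the interaction only when the delay is
  (near) zero, while DTW with a sufficiently long warping window detects it
  at any delay the band allows, provided the shared segment is long enough.
* **Common noise** — two anti-phase sinusoids, calibrated with independent
  noise to a target correlation (e.g. -0.86), are mixed with a shared
  band-limited "global" signal.  Correlation is pulled toward zero as the
  common-noise weight grows; the DTW distance stays below its significance
  threshold across the whole 0–50 % range.

Significance is calibrated empirically: metric values over many independent
surrogate pairs form the null, with the 5th/95th percentiles as two-sided
thresholds for (cross-)correlation and the 5th percentile of the distance
for DTW (small distance = strong connection).

The module also provides a seed-deterministic synthetic 4-D fMRI generator
(networks of voxels driven by lagged copies of a band-limited source, plus
voxel noise and an additive global signal) used to exercise the mapping and
group-statistics layers, and a planted-signal classification-dataset
generator for the classifier layer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core_dtw import WarpWindow, dtw_distance, window_to_samples
from .conn_metrics import max_lag_xcorr, pearson, to_similarity
from .signal_prep import FilterSpec, bandpass, zscore

__all__ = [
    "MetricSpec",
    "NullDistribution",
    "InteractionGrid",
    "NoiseSweep",
    "SynthFmriConfig",
    "SynthFmri",
    "gen_surrogate",
    "build_null",
    "transient_pair",
    "run_interaction_grid",
    "calibrate_anticorr_noise",
    "anticorr_pair",
    "common_noise_sweep",
    "synth_fmri",
    "write_fixture",
    "gen_classification_dataset",
    "DEFAULT_DELAYS_S",
    "DEFAULT_LENGTHS_S",
]

#: Transient-interaction grid defaults: delays 0-100 s in 4 s steps and
#: shared-segment lengths 60-600 s in 60 s steps cover both the short-delay
#: regime where correlation works and the long-delay regime where only a
#: long-window DTW detects the interaction.
DEFAULT_DELAYS_S = tuple(range(0, 104, 4))
DEFAULT_LENGTHS_S = tuple(range(60, 660, 60))

#: Warping window (s) for the common-noise robustness experiment.  The
#: window should exceed the longest expected lag: for the anti-phase 0.08 Hz
#: pair that lag is the half-period, 6.25 s, so 10 s suffices.  An
#: unnecessarily long window also loosens the null (independent pairs warp
#: closer together), costing sensitivity.
DEFAULT_NOISE_SWEEP_WINDOW_S = 10.0


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class MetricSpec:
    """A metric with its parameters, resolvable against a TR.

    ``window_s`` applies to DTW (warping window) and to xcorr (maximal lag).
    """

    name: str  # 'corr' | 'xcorr' | 'dtw'
    window_s: float | None = None

    @property
    def label(self) -> str:
        if self.window_s is None:
            return self.name
        return f"{self.name}_w{self.window_s:g}s"

    def window_samples(self, tr: float) -> int | None:
        if self.window_s is None:
            return None
        return window_to_samples(self.window_s, tr)

    def evaluate(self, x1, x2, tr: float) -> float:
        if self.name == "corr":
            return pearson(x1, x2).value
        if self.name == "xcorr":
            return max_lag_xcorr(x1, x2, self.window_samples(tr), tr=tr).value
        if self.name == "dtw":
            return dtw_distance(x1, x2, self.window_samples(tr))
        raise ValueError(f"unknown metric {self.name!r}")


def gen_surrogate(n_samples: int, tr: float = 2.0, seed=0, spec: FilterSpec | None = None) -> np.ndarray:
    """Band-limited unit-variance surrogate: band-passed white Gaussian noise.

    Deterministic for a given integer seed; a Generator may be passed to
    draw several surrogates from one stream.
    """
    if n_samples < 50:
        raise ValueError("surrogates shorter than 50 samples are not supported")
    rng = _rng(seed)
    white = rng.standard_normal(n_samples)
    return zscore(bandpass(white, tr, spec))


@dataclass(frozen=True)
class NullDistribution:
    """Empirical metric distribution over independent surrogate pairs."""

    metric: str
    values: np.ndarray
    thresholds: dict

    @classmethod
    def from_values(cls, metric: str, values) -> "NullDistribution":
        values = np.asarray(values, dtype=float)
        if metric == "dtw":
            thr = {"q05": float(np.percentile(values, 5))}
        else:
            thr = {
                "q05": float(np.percentile(values, 5)),
                "q95": float(np.percentile(values, 95)),
            }
        return cls(metric=metric, values=values, thresholds=thr)

    def is_significant(self, value: float) -> bool:
        if self.metric == "dtw":
            return value < self.thresholds["q05"]
        return value < self.thresholds["q05"] or value > self.thresholds["q95"]


def build_null(
    spec: MetricSpec,
    n_pairs: int = 1000,
    n_samples: int = 300,
    tr: float = 2.0,
    seed=0,
) -> NullDistribution:
    """Metric null from ``n_pairs`` independent surrogate pairs."""
    if n_pairs < 100:
        raise ValueError("need at least 100 pairs for stable percentile thresholds")
    rng = _rng(seed)
    vals = np.empty(n_pairs)
    for k in range(n_pairs):
        x1 = gen_surrogate(n_samples, tr, rng)
        x2 = gen_surrogate(n_samples, tr, rng)
        vals[k] = spec.evaluate(x1, x2, tr)
    return NullDistribution.from_values(spec.name, vals)


def transient_pair(
    total_s: float, shared_s: float, delay_s: float, tr: float = 2.0, seed=0
) -> tuple[np.ndarray, np.ndarray]:
    """Two surrogates sharing a copied segment with a given delay.

    ``x2``'s samples in ``[delay, delay + shared)`` are overwritten with
    ``x1``'s first ``shared`` seconds; both series are re-z-scored.  With
    unit-variance segments the expected zero-lag correlation at zero delay
    is approximately ``shared / total``.
    """
    rng = _rng(seed)
    n = window_to_samples(total_s, tr)
    n_shared = window_to_samples(shared_s, tr)
    n_delay = window_to_samples(delay_s, tr)
    if n_shared + n_delay > n:
        raise ValueError(
            f"shared ({shared_s}s) + delay ({delay_s}s) exceeds total ({total_s}s)"
        )
    x1 = gen_surrogate(n, tr, rng)
    x2 = gen_surrogate(n, tr, rng)
    x2 = x2.copy()
    x2[n_delay : n_delay + n_shared] = x1[:n_shared]
    return zscore(x1), zscore(x2)


@dataclass(frozen=True)
class InteractionGrid:
    """Per-(delay, length) median metric values and significance flags."""

    delays_s: np.ndarray
    lengths_s: np.ndarray
    feasible: np.ndarray  # (n_delays, n_lengths) bool
    median: dict  # label -> (n_delays, n_lengths) float
    significant: dict  # label -> (n_delays, n_lengths) bool
    n_reps: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for a, d in enumerate(self.delays_s):
            for b, L in enumerate(self.lengths_s):
                row = {"delay_s": d, "length_s": L, "feasible": bool(self.feasible[a, b])}
                for label in self.median:
                    row[f"median_{label}"] = self.median[label][a, b]
                    row[f"sig_{label}"] = bool(self.significant[label][a, b])
                rows.append(row)
        return pd.DataFrame(rows)


def run_interaction_grid(
    specs: list[MetricSpec],
    nulls: dict[str, NullDistribution],
    delays_s=DEFAULT_DELAYS_S,
    lengths_s=DEFAULT_LENGTHS_S,
    total_s: float = 600.0,
    tr: float = 2.0,
    n_reps: int = 10,
    seed=0,
) -> InteractionGrid:
    """Transient-interaction significance grid.

    For every feasible cell (delay + length <= total), ``n_reps``
    independent transient pairs are generated, every metric is evaluated on
    the same pairs, and the cell is flagged significant when the median
    metric value crosses its null threshold.  ``nulls`` maps each spec's
    ``label`` to its :class:`NullDistribution`.
    """
    rng = _rng(seed)
    delays = np.asarray(delays_s, dtype=float)
    lengths = np.asarray(lengths_s, dtype=float)
    feasible = np.zeros((delays.size, lengths.size), dtype=bool)
    median = {s.label: np.full((delays.size, lengths.size), np.nan) for s in specs}
    signif = {s.label: np.zeros((delays.size, lengths.size), dtype=bool) for s in specs}
    for a, d in enumerate(delays):
        for b, L in enumerate(lengths):
            if window_to_samples(L, tr) + window_to_samples(d, tr) > window_to_samples(total_s, tr):
                continue
            feasible[a, b] = True
            vals = {s.label: np.empty(n_reps) for s in specs}
            for rep in range(n_reps):
                x1, x2 = transient_pair(total_s, L, d, tr, rng)
                for s in specs:
                    vals[s.label][rep] = s.evaluate(x1, x2, tr)
            for s in specs:
                med = float(np.median(vals[s.label]))
                median[s.label][a, b] = med
                signif[s.label][a, b] = nulls[s.label].is_significant(med)
    return InteractionGrid(
        delays_s=delays,
        lengths_s=lengths,
        feasible=feasible,
        median=median,
        significant=signif,
        n_reps=n_reps,
    )


def _anticorr_components(freq_hz, n_samples, tr, rng, spec=None):
    t = np.arange(n_samples) * tr
    phase = rng.uniform(0.0, 2.0 * np.pi)
    s = np.sqrt(2.0) * np.sin(2.0 * np.pi * freq_hz * t + phase)  # unit variance
    n1 = gen_surrogate(n_samples, tr, rng, spec)
    n2 = gen_surrogate(n_samples, tr, rng, spec)
    return s, n1, n2


def calibrate_anticorr_noise(
    freq_hz: float,
    target_r: float,
    n_samples: int = 300,
    tr: float = 2.0,
    seed=0,
    tol: float = 0.005,
    n_calib: int = 40,
    max_iter: int = 60,
) -> float:
    """Noise amplitude making two anti-phase sinusoids correlate at ``target_r``.

    Bisection on the noise amplitude against the mean realized correlation
    over a fixed calibration batch of ``n_calib`` sinusoid+noise pairs;
    converges to within ``tol`` of the target.
    """
    if not -1.0 < target_r < 0.0:
        raise ValueError("target_r must lie in (-1, 0)")
    rng = _rng(seed)
    batch = [_anticorr_components(freq_hz, n_samples, tr, rng) for _ in range(n_calib)]

    def realized(a: float) -> float:
        rs = [
            pearson(zscore(s + a * n1), zscore(-s + a * n2)).value
            for s, n1, n2 in batch
        ]
        return float(np.mean(rs))

    lo, hi = 0.0, 1.0
    while realized(hi) < target_r:
        hi *= 2.0
        if hi > 64.0:
            raise RuntimeError(f"calibration failure: target {target_r} unreachable")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        r = realized(mid)
        if abs(r - target_r) <= tol:
            return mid
        if r < target_r:  # too anticorrelated -> more noise
            lo = mid
        else:
            hi = mid
    raise RuntimeError("calibration failure: bisection did not converge")


def anticorr_pair(
    freq_hz: float = 0.08,
    target_r: float = -0.86,
    n_samples: int = 300,
    tr: float = 2.0,
    seed=0,
    noise_amplitude: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """A perfectly anti-phase sinusoid pair degraded by independent noise.

    The noise amplitude is calibrated (see :func:`calibrate_anticorr_noise`)
    so that the expected correlation matches ``target_r``; pass
    ``noise_amplitude`` to reuse a previous calibration.
    """
    rng = _rng(seed)
    if noise_amplitude is None:
        if target_r == -1.0:
            noise_amplitude = 0.0
        else:
            noise_amplitude = calibrate_anticorr_noise(
                freq_hz, target_r, n_samples, tr, seed=rng
            )
    s, n1, n2 = _anticorr_components(freq_hz, n_samples, tr, rng)
    return zscore(s + noise_amplitude * n1), zscore(-s + noise_amplitude * n2)


@dataclass(frozen=True)
class NoiseSweep:
    """Metrics of one pair under increasing common-noise mixing weight."""

    alphas: np.ndarray
    corr: np.ndarray
    dtw: np.ndarray
    corr_sig: np.ndarray
    dtw_sig: np.ndarray


def common_noise_sweep(
    pair: tuple[np.ndarray, np.ndarray],
    null_r: NullDistribution,
    null_dtw: NullDistribution,
    alphas=None,
    w=None,
    tr: float = 2.0,
    seed=0,
) -> NoiseSweep:
    """Mix a shared band-limited noise into both series and re-measure.

    ``mixed_i = zscore((1 - alpha) * x_i + alpha * common)`` with the common
    signal drawn once; ``alpha`` is the common-noise weight (0-50 %).
    """
    if alphas is None:
        alphas = np.arange(0.0, 0.55, 0.05)
    alphas = np.asarray(alphas, dtype=float)
    if alphas.min() < 0 or alphas.max() > 0.5:
        raise ValueError("alphas must lie in [0, 0.5]")
    x1, x2 = (np.asarray(v, dtype=float) for v in pair)
    rng = _rng(seed)
    common = gen_surrogate(x1.size, tr, rng)
    if isinstance(w, WarpWindow):
        w = w.samples
    corr = np.empty(alphas.size)
    dtw = np.empty(alphas.size)
    for k, a in enumerate(alphas):
        m1 = zscore((1 - a) * x1 + a * common) if a > 0 else zscore(x1)
        m2 = zscore((1 - a) * x2 + a * common) if a > 0 else zscore(x2)
        corr[k] = pearson(m1, m2).value
        dtw[k] = dtw_distance(m1, m2, w)
    return NoiseSweep(
        alphas=alphas,
        corr=corr,
        dtw=dtw,
        corr_sig=np.array([null_r.is_significant(v) for v in corr]),
        dtw_sig=np.array([null_dtw.is_significant(v) for v in dtw]),
    )


# ---------------------------------------------------------------------------
# Synthetic 4-D fMRI fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SynthFmriConfig:
    """Geometry and signal model of the synthetic fMRI fixture.

    Each network k is driven by ``sign_k * (strength_k * roll(base, lag_k)
    + sqrt(1 - strength_k**2) * own)`` where ``base`` and ``own`` are
    independent band-limited unit-variance sources; member voxels add white
    noise (``noise_sd``) and, in gray matter, the shared global signal
    (``global_weight``).
    The last z-slab is split into WM and CSF compartments with their own
    latent sources; remaining gray-matter voxels carry independent
    band-limited signals.
    """

    shape: tuple = (8, 8, 4)
    n_networks: int = 2
    voxels_per_network: int = 8
    n_timepoints: int = 300
    tr: float = 2.0
    coupling_lags_s: tuple = (0.0, 30.0)
    coupling_signs: tuple | None = None
    coupling_strengths: tuple | None = None
    global_weight: float = 0.0
    noise_sd: float = 0.3
    seed: int = 0

    def resolved_signs(self) -> tuple:
        return self.coupling_signs or (1.0,) * self.n_networks

    def resolved_strengths(self) -> tuple:
        return self.coupling_strengths or (1.0,) * self.n_networks


@dataclass(frozen=True)
class SynthFmri:
    data: np.ndarray  # (x, y, z, t)
    gm_mask: np.ndarray
    wm_mask: np.ndarray
    csf_mask: np.ndarray
    brain_mask: np.ndarray
    atlas: np.ndarray  # int labels, 1..n_networks on member voxels
    truth: pd.DataFrame
    config: SynthFmriConfig
    base_source: np.ndarray = field(repr=False, default=None)


def synth_fmri(config: SynthFmriConfig) -> SynthFmri:
    """Generate one synthetic resting-state run (seed-deterministic)."""
    cfg = config
    nx, ny, nz = cfg.shape
    if nz < 2:
        raise ValueError("need at least 2 z-slabs (GM + WM/CSF)")
    nt, tr = cfg.n_timepoints, cfg.tr
    rng = _rng(cfg.seed)
    signs = cfg.resolved_signs()
    strengths = cfg.resolved_strengths()
    if not (len(cfg.coupling_lags_s) == len(signs) == len(strengths) == cfg.n_networks):
        raise ValueError("coupling parameter lengths must equal n_networks")

    gm_mask = np.zeros(cfg.shape, dtype=bool)
    gm_mask[:, :, : nz - 1] = True
    wm_mask = np.zeros(cfg.shape, dtype=bool)
    wm_mask[: nx // 2, :, nz - 1] = True
    csf_mask = np.zeros(cfg.shape, dtype=bool)
    csf_mask[nx // 2 :, :, nz - 1] = True
    brain_mask = gm_mask | wm_mask | csf_mask

    gm_idx = np.argwhere(gm_mask)
    needed = cfg.n_networks * cfg.voxels_per_network
    if needed > gm_idx.shape[0]:
        raise ValueError("grid too small for the requested networks")

    base = gen_surrogate(nt, tr, rng)
    g = gen_surrogate(nt, tr, rng)
    sources = []
    for k in range(cfg.n_networks):
        lag = window_to_samples(abs(cfg.coupling_lags_s[k]), tr)
        lag = int(np.sign(cfg.coupling_lags_s[k])) * lag
        beta = float(strengths[k])
        src = beta * np.roll(base, lag)
        if beta < 1.0:
            src = src + np.sqrt(1.0 - beta**2) * gen_surrogate(nt, tr, rng)
        sources.append(float(signs[k]) * src)

    data = np.zeros((*cfg.shape, nt))
    atlas = np.zeros(cfg.shape, dtype=np.int16)
    rows = []
    pos = 0
    for k in range(cfg.n_networks):
        for _ in range(cfg.voxels_per_network):
            x, y, z = gm_idx[pos]
            series = sources[k] + cfg.noise_sd * rng.standard_normal(nt)
            data[x, y, z] = series
            atlas[x, y, z] = k + 1
            rows.append(
                {
                    "x": x, "y": y, "z": z, "network": k + 1,
                    "lag_s": cfg.coupling_lags_s[k],
                    "sign": signs[k], "strength": strengths[k],
                }
            )
            pos += 1
    for idx in range(pos, gm_idx.shape[0]):
        x, y, z = gm_idx[idx]
        data[x, y, z] = gen_surrogate(nt, tr, rng) + cfg.noise_sd * rng.standard_normal(nt)
        rows.append({"x": x, "y": y, "z": z, "network": 0,
                     "lag_s": np.nan, "sign": np.nan, "strength": np.nan})

    for mask, scale in ((wm_mask, 0.7), (csf_mask, 0.7)):
        latent = gen_surrogate(nt, tr, rng)
        for x, y, z in np.argwhere(mask):
            data[x, y, z] = scale * latent + max(cfg.noise_sd, 0.05) * rng.standard_normal(nt)

    # the global (physiological) signal is modeled in gray matter only, so
    # that the WM/CSF nuisance compartments do not implicitly remove it
    if cfg.global_weight:
        data[gm_mask] += cfg.global_weight * g

    return SynthFmri(
        data=data,
        gm_mask=gm_mask,
        wm_mask=wm_mask,
        csf_mask=csf_mask,
        brain_mask=brain_mask,
        atlas=atlas,
        truth=pd.DataFrame(rows),
        config=cfg,
        base_source=base,
    )


def write_fixture(sf: SynthFmri, outdir) -> dict:
    """Write the fixture as NIfTI images + ground-truth TSV + config JSON."""
    import os

    import nibabel as nib

    os.makedirs(outdir, exist_ok=True)
    affine = np.eye(4)
    paths = {}

    def save(name, arr, dtype):
        p = os.path.join(outdir, name)
        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=dtype), affine), p)
        paths[name] = p

    save("bold.nii.gz", sf.data, np.float32)
    save("gm_mask.nii.gz", sf.gm_mask, np.uint8)
    save("wm_mask.nii.gz", sf.wm_mask, np.uint8)
    save("csf_mask.nii.gz", sf.csf_mask, np.uint8)
    save("brain_mask.nii.gz", sf.brain_mask, np.uint8)
    save("atlas.nii.gz", sf.atlas, np.int16)
    truth_path = os.path.join(outdir, "truth.tsv")
    sf.truth.to_csv(truth_path, sep="\t", index=False)
    paths["truth.tsv"] = truth_path
    cfg_path = os.path.join(outdir, "config.json")
    with open(cfg_path, "w") as fh:
        json.dump(asdict(sf.config), fh, indent=2, default=list)
    paths["config.json"] = cfg_path
    return paths


def gen_classification_dataset(
    n_subjects: int = 20,
    n_runs: int = 5,
    n_features: int = 300,
    n_informative: int = 5,
    effect: float = 2.0,
    seed=0,
):
    """Planted-signal dataset for classifier recovery/calibration checks.

    Half the subjects get label 1; the first ``n_informative`` features are
    shifted by ``+-effect/2`` per class on top of unit-variance noise
    (``effect`` is the class-mean separation in noise-sd units).  All runs of
    a subject share its label.
    """
    from .classify import ClassificationDataset

    rng = _rng(seed)
    labels_per_subject = np.zeros(n_subjects, dtype=int)
    labels_per_subject[n_subjects // 2 :] = 1
    subjects = np.repeat(np.arange(n_subjects), n_runs)
    y = labels_per_subject[subjects]
    X = rng.standard_normal((n_subjects * n_runs, n_features))
    if n_informative:
        X[:, :n_informative] += (y[:, None] - 0.5) * effect
    return ClassificationDataset(X=X, y=y, subjects=subjects)
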