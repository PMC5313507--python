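"""Surrogates, empirical nulls, transient pairs, and the fMRI fixture generator."""

import numpy as np
import pytest
from scipy import signal as sps

from dtwconn.conn_metrics import pearson, to_similarity
from dtwconn.simulate import (
    MetricSpec,
    SynthFmriConfig,
    anticorr_pair,
    build_null,
    calibrate_anticorr_noise,
    common_noise_sweep,
    gen_classification_dataset,
    gen_surrogate,
    run_interaction_grid,
    synth_fmri,
    transient_pair,
    write_fixture,
)

TR = 2.0


class TestSurrogate:
    def test_seed_determinism(self):
        a = gen_surrogate(300, TR, seed=42)
        b = gen_surrogate(300, TR, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_unit_moments(self):
        x = gen_surrogate(300, TR, seed=1)
        assert abs(x.mean()) < 1e-12
        assert x.std() == pytest.approx(1.0)

    def test_power_concentrated_in_band(self):
        rng = np.random.default_rng(3)
        fracs = []
        for _ in range(50):
            x = gen_surrogate(300, TR, rng)
            f, p = sps.periodogram(x, fs=1.0 / TR)
            inside = (f >= 0.009 * 0.8) & (f <= 0.08 * 1.2)
            fracs.append(p[~inside].sum() / p.sum())
        assert np.mean(fracs) < 0.15

    def test_minimum_length_enforced(self):
        with pytest.raises(ValueError):
            gen_surrogate(10, TR, seed=0)


class TestNull:
    def test_correlation_null_symmetric_about_zero(self):
        null = build_null(MetricSpec("corr"), n_pairs=1000, seed=11)
        assert abs(null.values.mean()) < 0.02
        assert abs(null.thresholds["q95"] + null.thresholds["q05"]) < 0.03

    def test_dtw_null_similarities_centered(self):
        null = build_null(MetricSpec("dtw", 100.0), n_pairs=150, seed=5)
        sims = to_similarity(null.values).similarities
        assert abs(sims.mean()) < 1e-10
        assert null.is_significant(null.thresholds["q05"] - 0.1)
        assert not null.is_significant(null.values.mean())

    def test_threshold_converges_with_pair_count(self):
        small = build_null(MetricSpec("dtw", 100.0), n_pairs=1000, seed=2)
        large = build_null(MetricSpec("dtw", 100.0), n_pairs=4000, seed=3)
        q_small, q_large = small.thresholds["q05"], large.thresholds["q05"]
        assert abs(q_small - q_large) / q_large < 0.05

    def test_minimum_pair_count(self):
        with pytest.raises(ValueError):
            build_null(MetricSpec("corr"), n_pairs=50, seed=0)


class TestTransientPair:
    def test_full_overlap_is_identity(self):
        x1, x2 = transient_pair(600, 600, 0, TR, seed=0)
        assert pearson(x1, x2).value == pytest.approx(1.0)

    def test_expected_correlation_is_shared_fraction(self):
        rs = [
            pearson(*transient_pair(600, 300, 0, TR, seed=s)).value
            for s in range(200)
        ]
        assert np.mean(rs) == pytest.approx(0.5, abs=0.07)

    def test_delayed_segment_invisible_to_zero_lag_correlation(self):
        # a 60 s delayed shared segment behaves like the no-connection null
        # for zero-lag correlation: significance at roughly the nominal 10%
        # two-sided rate, not above it
        null = build_null(MetricSpec("corr"), n_pairs=400, seed=9)
        hits = sum(
            null.is_significant(pearson(*transient_pair(600, 120, 60, TR, seed=s)).value)
            for s in range(100)
        )
        assert hits <= 18

    def test_infeasible_geometry_rejected(self):
        with pytest.raises(ValueError):
            transient_pair(600, 500, 200, TR, seed=0)


class TestInteractionGrid:
    def test_grid_shapes_flags_and_feasibility(self):
        specs = [MetricSpec("corr"), MetricSpec("dtw", 100.0)]
        nulls = {s.label: build_null(s, n_pairs=100, seed=1) for s in specs}
        grid = run_interaction_grid(
            specs, nulls, delays_s=(0, 100), lengths_s=(120, 600), n_reps=3, seed=2
        )
        assert grid.feasible[0, 1] and grid.feasible[1, 0]
        assert not grid.feasible[1, 1]  # 100 s delay + 600 s segment > 600 s
        assert np.isnan(grid.median["corr"][1, 1])
        # full-overlap cell is significant for both metrics
        assert grid.significant["corr"][0, 1]
        assert grid.significant["dtw_w100s"][0, 1]
        frame = grid.to_frame()
        assert len(frame) == 4 and "sig_corr" in frame.columns


class TestAnticorrPair:
    def test_zero_noise_is_perfect_anticorrelation(self):
        x1, x2 = anticorr_pair(target_r=-0.9, seed=0, noise_amplitude=0.0)
        assert pearson(x1, x2).value == pytest.approx(-1.0)

    def test_calibration_hits_target(self):
        amp = calibrate_anticorr_noise(0.08, -0.86, seed=1)
        rs = [
            pearson(*anticorr_pair(seed=100 + s, noise_amplitude=amp)).value
            for s in range(100)
        ]
        assert -0.89 <= np.mean(rs) <= -0.83

    def test_more_noise_weakens_anticorrelation(self):
        rng = np.random.default_rng(4)
        from dtwconn.simulate import _anticorr_components
        from dtwconn.signal_prep import zscore

        batch = [_anticorr_components(0.08, 300, TR, rng) for _ in range(30)]
        means = []
        for amp in (0.0, 0.3, 0.6, 1.0):
            means.append(
                np.mean(
                    [
                        pearson(zscore(s + amp * n1), zscore(-s + amp * n2)).value
                        for s, n1, n2 in batch
                    ]
                )
            )
        assert all(a < b for a, b in zip(means, means[1:]))  # toward zero

    def test_target_must_be_negative(self):
        with pytest.raises(ValueError):
            calibrate_anticorr_noise(0.08, 0.5, seed=0)


class TestCommonNoiseSweep:
    def test_alpha_zero_matches_clean_pair(self):
        null_r = build_null(MetricSpec("corr"), n_pairs=100, seed=1)
        null_d = build_null(MetricSpec("dtw", 10.0), n_pairs=100, seed=2)
        pair = anticorr_pair(seed=5, noise_amplitude=0.4)
        sweep = common_noise_sweep(pair, null_r, null_d, alphas=[0.0, 0.25], w=5, seed=3)
        from dtwconn.core_dtw import dtw_distance

        assert sweep.corr[0] == pytest.approx(pearson(*pair).value)
        assert sweep.dtw[0] == pytest.approx(dtw_distance(pair[0], pair[1], 5))

    def test_alphas_must_stay_below_half(self):
        null = build_null(MetricSpec("corr"), n_pairs=100, seed=1)
        with pytest.raises(ValueError):
            common_noise_sweep((np.zeros(60), np.zeros(60)), null, null, alphas=[0.7])


class TestSynthFmri:
    def test_noiseless_single_network_perfectly_coherent(self):
        cfg = SynthFmriConfig(
            n_networks=1, coupling_lags_s=(0.0,), noise_sd=0.0, global_weight=0.0, seed=3
        )
        sf = synth_fmri(cfg)
        vox = sf.data[sf.atlas == 1]
        for k in range(1, vox.shape[0]):
            assert pearson(vox[0], vox[k]).value == pytest.approx(1.0)

    def test_seed_determinism(self):
        cfg = SynthFmriConfig(seed=7)
        np.testing.assert_array_equal(synth_fmri(cfg).data, synth_fmri(cfg).data)

    def test_delayed_network_seen_by_dtw_not_by_correlation(self):
        null_r = build_null(MetricSpec("corr"), n_pairs=200, seed=1)
        null_d = build_null(MetricSpec("dtw", 100.0), n_pairs=200, seed=2)
        from dtwconn.core_dtw import dtw_distance
        from dtwconn.signal_prep import zscore

        hits_dtw = hits_r = 0
        for s in range(10):
            cfg = SynthFmriConfig(
                coupling_lags_s=(0.0, 30.0), noise_sd=0.1, global_weight=0.0, seed=50 + s
            )
            sf = synth_fmri(cfg)
            a = zscore(sf.data[tuple(np.argwhere(sf.atlas == 1)[0])])
            b = zscore(sf.data[tuple(np.argwhere(sf.atlas == 2)[0])])
            hits_dtw += null_d.is_significant(dtw_distance(a, b, 50))
            hits_r += null_r.is_significant(pearson(a, b).value)
        assert hits_dtw >= 8
        assert hits_r <= 3

    def test_global_signal_inflates_pairwise_correlation(self):
        def mean_r(weight, seed):
            # compare background voxels, which are mutually independent sources
            cfg = SynthFmriConfig(
                n_networks=1, coupling_lags_s=(0.0,), voxels_per_network=4,
                noise_sd=0.3, global_weight=weight, seed=seed,
            )
            sf = synth_fmri(cfg)
            bg = sf.data[sf.gm_mask & (sf.atlas == 0)][:12]
            rs = [
                pearson(bg[i], bg[j]).value
                for i in range(len(bg))
                for j in range(i + 1, len(bg))
            ]
            return np.mean(rs)

        assert mean_r(0.4, 13) > mean_r(0.0, 13) + 0.05

    def test_fixture_roundtrip_to_nifti(self, tmp_path):
        import nibabel as nib

        sf = synth_fmri(SynthFmriConfig(shape=(4, 4, 2), voxels_per_network=4, seed=1))
        paths = write_fixture(sf, tmp_path)
        img = nib.load(paths["bold.nii.gz"])
        np.testing.assert_allclose(np.asarray(img.dataobj), sf.data, atol=1e-6)
        atlas = nib.load(paths["atlas.nii.gz"])
        np.testing.assert_array_equal(np.asarray(atlas.dataobj), sf.atlas)


def test_classification_dataset_generator():
    ds = gen_classification_dataset(26, 5, 40, 3, 1.5, seed=0)
    assert ds.n_instances == 130
    assert ds.n_features == 40
    # runs of one subject share the label; classes balanced at subject level
    for s in np.unique(ds.subjects):
        assert np.unique(ds.y[ds.subjects == s]).size == 1
    assert ds.y.mean() == pytest.approx(0.5)
    # informative features separate the classes
    gap = ds.X[ds.y == 1, 0].mean() - ds.X[ds.y == 0, 0].mean()
    assert gap == pytest.approx(1.5, abs=0.5)
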