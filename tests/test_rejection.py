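"""Rejection criteria against brute-force oracles and their invariants."""

import numpy as np
import pytest
from scipy import stats

from oddballeeg import (
    baseline_correct,
    combine_masks,
    reject_cells,
    reject_channels_kurtosis,
    reject_threshold,
    reject_trendline,
    rejection_topography,
    retention_curve,
    simulate_study,
    simulate_subject,
    traditional_reject,
)
from oddballeeg.containers import CleanMask, EpochedRecording, ValidationError
from oddballeeg.rejection import trendline_fit
from oddballeeg.simulate import subject_rng

from conftest import tiny_config


def _recording(data, fs=1000.0, pre_ms=200.0, **kw):
    C, E, T = data.shape
    return EpochedRecording(
        data=data,
        fs=fs,
        pre_stim_ms=pre_ms,
        labels=np.array(
            ["deviant" if i % 7 == 0 else "standard" for i in range(E)], dtype=object
        ),
        block_of=kw.pop("block_of", np.zeros(E, dtype=int)),
        channels=[f"E{i+1}" for i in range(C)],
        **kw,
    )


class TestBaseline:
    def test_constant_epoch_becomes_zero(self):
        rec = _recording(np.full((2, 3, 100), 5.0), fs=250.0)
        out = baseline_correct(rec)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_matches_direct_prestim_mean(self, rng):
        rec = _recording(rng.standard_normal((3, 4, 300)), fs=250.0)
        out = baseline_correct(rec)
        pre = rec.pre_samples
        assert pre == 50
        for c in range(3):
            for e in range(4):
                m = rec.data[c, e, :pre].mean()
                np.testing.assert_allclose(out.data[c, e], rec.data[c, e] - m,
                                           atol=1e-12)
        # post-condition: pre-stim mean is zero everywhere
        np.testing.assert_allclose(out.data[:, :, :pre].mean(axis=2), 0.0,
                                   atol=1e-9)

    def test_zero_prestim_rejected(self, rng):
        rec = _recording(rng.standard_normal((1, 2, 50)), pre_ms=0.0)
        with pytest.raises(ValidationError):
            baseline_correct(rec)


class TestThreshold:
    def test_null_signal_all_kept(self):
        mask = reject_threshold(_recording(np.zeros((4, 6, 50))), 100.0)
        assert mask.keep.all() and mask.n_rejected == 0

    def test_single_offending_sample_rejects_exactly_that_cell(self):
        data = np.zeros((6, 10, 50))
        data[3, 7, 20] = 100.5
        mask = reject_threshold(_recording(data), 100.0)
        assert not mask.keep[3, 7]
        assert mask.n_rejected == 1
        assert mask.criteria_log()[3, 7] == "threshold"

    def test_sample_exactly_at_bound_is_kept(self):
        data = np.zeros((1, 1, 10))
        data[0, 0, 3] = 100.0
        assert reject_threshold(_recording(data), 100.0).keep.all()

    def test_exhaustive_scan_oracle(self, rng):
        data = rng.standard_normal((5, 8, 40)) * 60
        mask = reject_threshold(_recording(data), 100.0)
        for c in range(5):
            for e in range(8):
                expected = any(abs(v) > 100.0 for v in data[c, e])
                assert mask.keep[c, e] == (not expected)


class TestTrendline:
    def test_flat_epoch_kept(self):
        assert reject_trendline(_recording(np.zeros((2, 3, 100)))).keep.all()

    def test_exact_line_rising_60_rejected(self):
        data = np.tile(np.linspace(0.0, 60.0, 100), (1, 1, 1))
        mask = reject_trendline(_recording(data), 50.0, 0.3)
        slope, r2 = trendline_fit(data)
        np.testing.assert_allclose(slope[0, 0], 60.0, atol=1e-9)
        np.testing.assert_allclose(r2[0, 0], 1.0, atol=1e-12)
        assert not mask.keep[0, 0]

    def test_noisy_ramps_against_normal_equations_oracle(self):
        rng = np.random.default_rng(42)
        T = 200
        slopes = [30.0, 49.0, 51.0, 80.0]
        data = np.stack(
            [np.linspace(0, s, T) + rng.standard_normal(T) * 1.0 for s in slopes]
        )[:, None, :]
        rec = _recording(data)
        mask = reject_trendline(rec, 50.0, 0.3)
        assert list(mask.keep[:, 0]) == [True, True, False, False]
        slope, r2 = trendline_fit(data)
        u = np.arange(T) / (T - 1)
        for c in range(4):
            b, a = np.polyfit(u, data[c, 0], 1)
            resid = data[c, 0] - (a + b * u)
            ss_tot = ((data[c, 0] - data[c, 0].mean()) ** 2).sum()
            np.testing.assert_allclose(slope[c, 0], b, atol=1e-9)
            np.testing.assert_allclose(r2[c, 0], 1 - (resid**2).sum() / ss_tot,
                                       atol=1e-9)

    def test_negative_slope_also_rejected(self):
        data = np.tile(np.linspace(0.0, -70.0, 100), (1, 1, 1))
        assert not reject_trendline(_recording(data)).keep[0, 0]


class TestCombine:
    def test_all_keep_is_identity(self, rng):
        keep = rng.random((4, 6)) > 0.3
        a = CleanMask(keep)
        out = combine_masks(a, CleanMask.all_keep((4, 6)))
        np.testing.assert_array_equal(out.keep, a.keep)

    def test_idempotent(self, rng):
        a = CleanMask(rng.random((4, 6)) > 0.3)
        np.testing.assert_array_equal(combine_masks(a, a).keep, a.keep)

    def test_cellwise_and_oracle(self, rng):
        a = CleanMask(rng.random((5, 9)) > 0.4)
        b = CleanMask(rng.random((5, 9)) > 0.4)
        out = combine_masks(a, b)
        for c in range(5):
            for e in range(9):
                assert out.keep[c, e] == (a.keep[c, e] and b.keep[c, e])

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValidationError):
            combine_masks(CleanMask.all_keep((2, 3)), CleanMask.all_keep((3, 2)))


class TestKurtosisScreen:
    def test_homogeneous_gaussian_no_rejections(self, rng):
        rec = _recording(rng.standard_normal((16, 20, 50)))
        assert reject_channels_kurtosis(rec, 5.0) == {0: set()}

    def test_spiky_channel_flagged(self, rng):
        data = rng.standard_normal((32, 20, 50))
        data[11, ::2, 10] += 40.0  # heavy spike contamination
        rec = _recording(data)
        k = stats.kurtosis(data.reshape(32, -1), axis=1)
        z = (k - k.mean()) / k.std()
        assert abs(z[11]) > 5  # construction check for the oracle
        assert reject_channels_kurtosis(rec, 5.0)[0] == {"E12"}

    def test_identical_channels_warn_and_keep(self):
        data = np.tile(np.sin(np.arange(50.0)), (2, 3, 1))
        with pytest.warns(UserWarning, match="kurtosis"):
            out = reject_channels_kurtosis(_recording(data), 5.0)
        assert out == {0: set()}


class TestTraditional:
    def test_null_signal_keeps_all_epochs(self):
        kept = traditional_reject(_recording(np.zeros((4, 6, 20))), 100.0)
        assert kept.all()

    def test_one_bad_channel_per_epoch_rejects_everything(self, rng):
        data = rng.standard_normal((8, 10, 30))
        bad_channels = rng.integers(0, 8, size=10)
        for e, c in enumerate(bad_channels):
            data[c, e, 5] = 300.0
        rec = _recording(data)
        kept = traditional_reject(rec, 100.0)
        assert not kept.any()
        # channel-by-epoch rejection still retains the clean cells
        mask = reject_threshold(rec, 100.0)
        assert mask.keep.sum() >= 8 * 10 - 10

    def test_column_conjunction_oracle(self, rng):
        data = rng.standard_normal((6, 12, 25)) * 70
        rec = _recording(data)
        kept = traditional_reject(rec, 100.0)
        mask = reject_threshold(rec, 100.0)
        np.testing.assert_array_equal(kept, mask.keep.all(axis=0))

    def test_blacklisted_channels_ignored(self, rng):
        data = np.zeros((3, 5, 10))
        data[0, :, 2] = 500.0  # blacklisted channel is always bad
        rec = _recording(data)
        assert not traditional_reject(rec, 100.0).any()
        assert traditional_reject(rec, 100.0, {"E1"}).all()


class TestRetention:
    def test_clean_recording_full_retention(self):
        curve = retention_curve(_recording(np.zeros((3, 8, 20))), [100, 500])
        assert (curve["median"] == 1.0).all()

    def test_monotone_and_dominant(self):
        cfg = tiny_config(n_channels=10, epochs_per_block=80, noise_sd=40.0)
        rec, _ = simulate_subject(cfg, "TD", subject_rng(2, 0))
        rec = baseline_correct(rec)
        thresholds = [60, 100, 200, 400, 800]
        curve = retention_curve(rec, thresholds)
        for method in ("channel_by_epoch", "traditional"):
            med = curve[curve.method == method].sort_values("threshold")["median"]
            assert (np.diff(med) >= 0).all()
        cell = curve[curve.method == "channel_by_epoch"].set_index("threshold")
        trad = curve[curve.method == "traditional"].set_index("threshold")
        assert (cell["median"] >= trad["median"]).all()

    def test_mask_monotone_in_threshold(self, rng):
        rec = _recording(rng.standard_normal((6, 15, 40)) * 80)
        kept_lo = reject_threshold(rec, 100.0).keep
        kept_hi = reject_threshold(rec, 200.0).keep
        assert np.all(kept_hi[kept_lo])  # kept at 100 => kept at 200


class TestTopography:
    def test_identical_masks_give_p_one(self, tiny_study):
        study, _ = tiny_study
        masks = [CleanMask.all_keep(r.data.shape[:2]) for r in study.recordings]
        report = rejection_topography(study, masks)
        assert (report.periocular["p_value"] == 1.0).all()

    def test_group_blink_difference_shows_frontally(self):
        cfg = tiny_config(
            n_asd=5, n_td=5, n_channels=16, epochs_per_block=150,
            blink_rate_asd=0.4, blink_rate_td=0.05, blink_amplitude=150.0,
            seed=13,
        )
        study, _ = simulate_study(cfg)
        masks = [reject_cells(baseline_correct(r)) for r in study.recordings]
        report = rejection_topography(study, masks)
        med_asd = report.periocular["median_ASD"]
        med_td = report.periocular["median_TD"]
        assert (med_asd > med_td).mean() > 0.8

    def test_rank_statistic_matches_hand_computation(self, rng):
        # 2 vs 3 subjects, one periocular channel: Kruskal-Wallis H by hand
        cfg = tiny_config(n_asd=2, n_td=3, n_channels=4, epochs_per_block=10,
                          n_periocular=1, deviant_fraction=0.1, min_gap=1)
        study, _ = simulate_study(cfg)
        props = [0.8, 0.6, 0.5, 0.3, 0.1]  # rejection proportions per subject
        masks = []
        for r, p in zip(study.recordings, props):
            keep = np.ones((4, 10), dtype=bool)
            perioc = r.periocular_idx[0]
            keep[perioc, : int(round(p * 10))] = False
            masks.append(CleanMask(keep))
        report = rejection_topography(study, masks)
        ranks = stats.rankdata(props)
        n = 5
        h = 12 / (n * (n + 1)) * (
            ranks[:2].sum() ** 2 / 2 + ranks[2:].sum() ** 2 / 3
        ) - 3 * (n + 1)
        p_hand = stats.chi2.sf(h, df=1)
        np.testing.assert_allclose(report.periocular["p_value"][0], p_hand,
                                   atol=1e-9)

    def test_single_group_study_rejected(self, rng):
        study, _ = simulate_study(tiny_config(n_asd=0, n_td=2, n_channels=4))
        masks = [CleanMask.all_keep(r.data.shape[:2]) for r in study.recordings]
        with pytest.raises(ValidationError):
            rejection_topography(study, masks)
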