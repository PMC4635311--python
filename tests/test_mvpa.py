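"""Decoding pipeline: t-map selection, preprocessing, SVM, d', permutation null."""

import math
import warnings

import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.special import erf

from cuefuse import mvpa
from cuefuse.observer_models import Condition
from cuefuse.synthetic_fmri import (
    HEMODYNAMIC_SHIFT,
    EncodingModel,
    ScanDesign,
    generate_experiment,
    generate_run,
)


class TestTmapAndSelection:
    def test_responsive_voxel_gets_large_t(self, small_scan_design):
        w = np.zeros(20)
        model = EncodingModel(
            w_disparity=w, w_motion=w, w_fused=w, noise_sd=0.5,
            w_stimulus=np.r_[np.full(5, 10.0), np.zeros(15)],
        )
        ds = generate_experiment(model, small_scan_design, seed=0)
        t = mvpa.compute_tmap(ds)
        assert t[:5].min() > 10 * np.abs(t[5:]).max()

    def test_null_voxels_within_t_band(self, small_scan_design):
        w = np.zeros(200)
        model = EncodingModel(w_disparity=w, w_motion=w, w_fused=w, noise_sd=1.0)
        ds = generate_experiment(model, small_scan_design, seed=1)
        t = mvpa.compute_tmap(ds)
        # ~95% of null t values inside the two-sided 5% critical band
        assert (np.abs(t) < 1.96).mean() > 0.85

    def test_constant_voxel_zeroed_with_warning(self, small_scan_design):
        w = np.zeros(4)
        model = EncodingModel(w_disparity=w, w_motion=w, w_fused=w, noise_sd=0.0)
        ds = generate_experiment(model, small_scan_design, seed=2)
        with pytest.warns(UserWarning, match="zero-variance"):
            t = mvpa.compute_tmap(ds)
        assert np.all(t == 0)

    def test_top_n_selection_order_statistic(self):
        rng = np.random.default_rng(0)
        t = rng.normal(size=1000)
        sel = mvpa.select_voxels(t, 400)
        assert len(sel) == 400
        assert t[sel].min() >= np.delete(t, sel).max()

    def test_oversized_request_returns_all_with_warning(self):
        with pytest.warns(UserWarning, match="returning all"):
            sel = mvpa.select_voxels(np.arange(10.0), 20)
        assert len(sel) == 10

    def test_tie_break_deterministic(self):
        t = np.array([1.0, 2.0, 2.0, 2.0, 0.5])
        a = mvpa.select_voxels(t, 2)
        b = mvpa.select_voxels(t, 2)
        assert np.array_equal(a, b)
        assert np.array_equal(a, [1, 2])  # ascending index among tied t = 2


class TestPreprocessing:
    def test_zscore_definition(self):
        rng = np.random.default_rng(3)
        run = rng.normal(5, 2, size=(10, 50))
        z = mvpa.preprocess_run(run)
        assert np.allclose(z.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(z.std(axis=1), 1, atol=1e-12)

    def test_constant_voxel_flagged(self):
        run = np.vstack([np.ones(30), np.random.default_rng(0).normal(size=30)])
        with pytest.warns(UserWarning, match="constant"):
            z = mvpa.preprocess_run(run)
        assert np.all(z[0] == 0)

    def test_block_window_shifted_two_volumes(self, small_scan_design):
        """A noiseless signal placed at onset+2 is recovered exactly by extraction."""
        w = np.zeros(6)
        model = EncodingModel(
            w_disparity=np.r_[1.0, np.zeros(5)], w_motion=w[:6] * 0, w_fused=w[:6] * 0,
            noise_sd=0.0, w_stimulus=np.full(6, 0.5),
        )
        sig, tab = generate_run(model, small_scan_design, 0, seed=4)
        onset = int(tab.onset_volume.iloc[0])
        # signal occupies [onset+2, onset+10): before the shift window it is baseline
        assert np.all(sig[0, onset : onset + HEMODYNAMIC_SHIFT] == 100.0)
        assert not np.all(sig[0, onset + HEMODYNAMIC_SHIFT : onset + 10] == 100.0)

    def test_patterns_mean_centered_and_counted(self, independence_dataset):
        patterns = mvpa.extract_block_patterns(independence_dataset)
        assert np.allclose(patterns.X.sum(axis=1), 0, atol=1e-9)
        counts = patterns.meta.groupby(["condition", "depth"]).size()
        assert (counts == 18).all()  # 3 blocks x 6 runs per condition x depth

    def test_uniform_block_signal_vanishes_after_centering(self, small_scan_design):
        n = 8
        model = EncodingModel(
            w_disparity=np.zeros(n), w_motion=np.zeros(n), w_fused=np.zeros(n),
            noise_sd=0.0, w_stimulus=np.ones(n),
        )
        ds = generate_experiment(model, small_scan_design, seed=5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # flat off-block variance
            patterns = mvpa.extract_block_patterns(ds)
        assert np.allclose(patterns.X, 0, atol=1e-9)


class TestDprime:
    def test_printed_formula_fixed_points(self):
        assert mvpa.accuracy_to_dprime(0.5) == 0.0
        assert mvpa.accuracy_to_dprime(0.75) == pytest.approx(0.9539, abs=1e-4)

    def test_antisymmetry(self):
        for a in np.linspace(0.05, 0.95, 19):
            assert mvpa.accuracy_to_dprime(float(a)) == pytest.approx(
                -mvpa.accuracy_to_dprime(float(1 - a)), abs=1e-12
            )

    def test_matches_bisection_inverse_of_erf(self):
        """2*erfinv(2a-1) checked against a brentq inversion of erf."""
        for a in np.linspace(0.02, 0.98, 97):
            target = 2 * a - 1
            x = brentq(lambda z: erf(z) - target, -10, 10, xtol=1e-14)
            assert mvpa.accuracy_to_dprime(float(a), clip=1e-6) == pytest.approx(
                2 * x, abs=1e-10
            )

    def test_clipping_bounds_extremes(self):
        hi = mvpa.accuracy_to_dprime(1.0)
        assert math.isfinite(hi)
        assert hi == mvpa.accuracy_to_dprime(1.0 - 1.0 / 72.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            mvpa.accuracy_to_dprime(1.2)


class TestDecoding:
    def test_fold_structure(self, independence_dataset):
        patterns = mvpa.extract_block_patterns(independence_dataset)
        res = mvpa.decode_condition(patterns.for_condition(Condition.DM))
        assert len(res.fold_accuracies) == 6
        assert res.n_train == 30 and res.n_test == 6
        assert res.accuracy == pytest.approx(np.mean(res.fold_accuracies))

    def test_separable_classes_hit_ceiling(self, small_scan_design):
        model = EncodingModel.random(n_voxels=40, seed=6, fused_gain=0.0, noise_sd=0.5)
        ds = generate_experiment(model, small_scan_design, seed=7)
        patterns = mvpa.extract_block_patterns(ds)
        res = mvpa.decode_condition(patterns.for_condition(Condition.D))
        assert res.accuracy == 1.0
        assert res.dprime == mvpa.accuracy_to_dprime(1.0)

    def test_unbalanced_labels_rejected(self, independence_dataset):
        patterns = mvpa.extract_block_patterns(independence_dataset)
        dm = patterns.for_condition(Condition.DM)
        bad = dm.meta.copy()
        bad.loc[bad.index[0], "depth"] = "far"
        with pytest.raises(ValueError, match="unbalanced"):
            mvpa.decode_condition(mvpa.BlockPatterns(dm.X, bad))

    def test_voxel_order_invariance(self, independence_dataset):
        patterns = mvpa.extract_block_patterns(independence_dataset)
        dm = patterns.for_condition(Condition.DM)
        rng = np.random.default_rng(8)
        perm = rng.permutation(dm.X.shape[1])
        shuffled = mvpa.BlockPatterns(dm.X[:, perm], dm.meta)
        a = mvpa.decode_condition(dm)
        b = mvpa.decode_condition(shuffled)
        assert a.accuracy == pytest.approx(b.accuracy)

    def test_integration_index_arithmetic(self):
        def mk(cond, acc):
            return mvpa.DecodingResult(cond, acc, mvpa.accuracy_to_dprime(acc), (acc,) * 6, 30, 6)

        dp = {c: mvpa.accuracy_to_dprime(a) for c, a in
              zip(["D", "M", "DM", "DconflictM"], [0.7, 0.65, 0.9, 0.8])}
        results = {
            "D": mk("D", 0.7), "M": mk("M", 0.65),
            "DM": mk("DM", 0.9), "DconflictM": mk("DconflictM", 0.8),
        }
        i1, i2 = mvpa.decoding_integration_indices(results)
        assert i1 == pytest.approx(dp["DM"] - dp["DconflictM"])
        assert i2 == pytest.approx(dp["DM"] - math.hypot(dp["D"], dp["M"]))

    def test_missing_condition_rejected(self, independence_dataset):
        patterns = mvpa.extract_block_patterns(independence_dataset)
        res = {"DM": mvpa.decode_condition(patterns.for_condition(Condition.DM))}
        with pytest.raises(ValueError, match="missing"):
            mvpa.decoding_integration_indices(res)


@pytest.fixture(scope="module")
def null_result(independence_dataset):
    patterns = mvpa.extract_block_patterns(independence_dataset)
    dm = patterns.for_condition(Condition.DM)
    return mvpa.permutation_null(dm, n_perm=200, seed=0)


class TestPermutationNull:

    def test_null_centered_at_chance(self, null_result):
        se = null_result.null_accuracies.std(ddof=1) / math.sqrt(200)
        assert abs(null_result.null_accuracies.mean() - 0.5) < 3 * max(se, 1e-3)

    def test_upper_bound_above_chance(self, null_result):
        assert null_result.upper_bound_97_5 > 0.5

    def test_strong_signal_beats_null_bound(self, fusion_dataset, null_result):
        tmap = mvpa.compute_tmap(fusion_dataset)
        sel = mvpa.select_voxels(tmap, 60)
        patterns = mvpa.extract_block_patterns(fusion_dataset, sel)
        res = mvpa.decode_condition(patterns.for_condition(Condition.DM))
        assert res.accuracy > null_result.upper_bound_97_5


class TestSearchlight:
    def test_fused_signal_localized(self):
        """The conflict-cost index (DM - DconflictM) peaks where the fused
        channel lives."""
        n = 64  # 4x4x4 grid
        wd = np.random.default_rng(0).normal(size=n)
        wm = np.random.default_rng(1).normal(size=n)
        wf = np.zeros(n)
        wf[:8] = 2.0  # fused cluster in one corner of the lattice
        model = EncodingModel(
            w_disparity=wd, w_motion=wm, w_fused=wf, fused_gain=1.5,
            noise_sd=8.0, w_stimulus=np.abs(wd),
        )
        ds = generate_experiment(model, ScanDesign(), seed=9)
        sl = mvpa.searchlight_map(ds, radius_voxels=1.5)
        in_cluster = np.nanmean(sl.index1[:8])
        outside = np.nanmean(sl.index1[32:])
        assert in_cluster > outside + 0.3

    def test_tiny_radius_masks_everything(self, independence_dataset):
        sl = mvpa.searchlight_map(independence_dataset, radius_voxels=1.0)
        # radius 1 on a compact lattice still finds neighbors; radius < 1 rejected
        with pytest.raises(ValueError):
            mvpa.searchlight_map(independence_dataset, radius_voxels=0.5)
        assert sl.mask.any()

    def test_mm_conversion(self):
        assert mvpa.mm_to_voxel_radius(8.0, 2.3) == 3
        assert mvpa.mm_to_voxel_radius(1.0, 2.3) == 1
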