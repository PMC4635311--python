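"""Cumulative-Gaussian fitting, exclusion rules, indices, and the age curve."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cuefuse.observer_models import Condition
from cuefuse.psychometrics import (
    DEFAULT_AGE_BINS,
    ExclusionRules,
    IntegrationIndices,
    PsychometricFit,
    SensitivitySet,
    apply_exclusions,
    fit_cumulative_gaussian,
    fit_developmental_curve,
    group_criteria_tests,
    integration_indices,
    quadratic_sum,
    sensitivity_standard_error,
)


def binomial_trials(levels, mu, sigma, n_per_level, seed, standard=1.0):
    """2AFC responses drawn from Phi((x - mu)/sigma)."""
    rng = np.random.default_rng(seed)
    rows = []
    for x in levels:
        p = stats.norm.cdf((x - mu) / sigma)
        chose = rng.random(n_per_level) < p
        for c in chose:
            rows.append(
                {"comparison_level": x, "chose_comparison": bool(c), "standard_level": standard}
            )
    return pd.DataFrame(rows)


LEVELS = np.linspace(-4, 4, 6)


class TestCumulativeGaussianFit:
    def test_parameter_recovery_large_n(self):
        trials = binomial_trials(LEVELS, mu=0.0, sigma=2.0, n_per_level=10_000, seed=0)
        fit = fit_cumulative_gaussian(trials)
        assert fit.converged
        assert 1.9 <= fit.sigma <= 2.1
        assert abs(fit.mu) < 0.1
        assert fit.r_squared > 0.99

    def test_shifted_pse_recovered(self):
        trials = binomial_trials(LEVELS, mu=0.5, sigma=1.5, n_per_level=10_000, seed=1)
        fit = fit_cumulative_gaussian(trials)
        se_mu = 3 * fit.sigma / math.sqrt(len(trials))  # generous SE bound
        assert abs(fit.mu - 0.5) < 3 * max(se_mu, 0.05)

    def test_exactly_flat_data_flagged_not_raised(self):
        # responses exactly 50% at every level: sigma runs to its bound
        rows = []
        for x in LEVELS:
            rows += [{"comparison_level": x, "chose_comparison": c, "standard_level": 1.0}
                     for c in [True, False] * 25]
        fit = fit_cumulative_gaussian(pd.DataFrame(rows))
        assert not fit.converged
        assert fit.sensitivity < 1e-2
        assert fit.r_squared < 0.1

    def test_decreasing_data_fit_with_mirrored_curve(self):
        trials = binomial_trials(LEVELS, mu=0.0, sigma=1.5, n_per_level=2000, seed=4)
        trials["chose_comparison"] = ~trials["chose_comparison"]
        fit = fit_cumulative_gaussian(trials)
        assert fit.slope_sign == -1
        assert 1.3 <= fit.sigma <= 1.7

    def test_too_few_levels_rejected(self):
        trials = binomial_trials([0.0], mu=0.0, sigma=1.0, n_per_level=50, seed=5)
        with pytest.raises(ValueError):
            fit_cumulative_gaussian(trials)

    def test_trial_order_invariance(self):
        trials = binomial_trials(LEVELS, mu=0.0, sigma=2.0, n_per_level=100, seed=6)
        shuffled = trials.sample(frac=1.0, random_state=1).reset_index(drop=True)
        f1 = fit_cumulative_gaussian(trials)
        f2 = fit_cumulative_gaussian(shuffled)
        assert f1.sigma == pytest.approx(f2.sigma, rel=1e-6)
        assert f1.mu == pytest.approx(f2.mu, abs=1e-6)

    def test_standard_error_shrinks_with_pooling(self):
        one = binomial_trials(LEVELS, 0.0, 2.0, 500, seed=7)
        two = pd.concat([one, binomial_trials(LEVELS, 0.0, 2.0, 500, seed=8)])
        se1 = sensitivity_standard_error(fit_cumulative_gaussian(one), one)
        se2 = sensitivity_standard_error(fit_cumulative_gaussian(two), two)
        assert se2 < se1
        assert se2 == pytest.approx(se1 / math.sqrt(2), rel=0.25)


class TestIntegrationIndices:
    def test_independence_prediction_is_zero(self):
        s = SensitivitySet(3.0, 4.0, 5.0, 5.0)
        idx = integration_indices(s)
        assert idx.index1 == pytest.approx(0.0)
        assert idx.index2 == pytest.approx(0.0)

    def test_arithmetic(self):
        idx = integration_indices(SensitivitySet(3.0, 4.0, 7.0, 2.0))
        assert idx.index1 == pytest.approx(5.0)
        assert idx.index2 == pytest.approx(2.0)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            integration_indices(SensitivitySet(3.0, float("nan"), 5.0, 5.0))


def _fit(r2=0.9, mu=1.0, sigma=0.3, standard=1.0):
    return PsychometricFit(
        mu=mu, sigma=sigma, r_squared=r2, n_trials=90, converged=True, standard=standard
    )


def _subject(r2=0.9, mu=1.0, i1=0.0, i2=0.0, sid="s"):
    fits = {c: _fit(r2=r2, mu=mu) for c in Condition}
    return fits, IntegrationIndices(index1=i1, index2=i2, subject_id=sid)


class TestExclusions:
    def make_cohort(self, n=12, seed=0):
        rng = np.random.default_rng(seed)
        fits, indices = {}, {}
        for i in range(n):
            sid = f"s{i:02d}"
            f, idx = _subject(
                i1=float(rng.normal(0, 0.1)), i2=float(rng.normal(0, 0.1)), sid=sid
            )
            fits[sid], indices[sid] = f, idx
        return fits, indices

    def test_clean_cohort_untouched(self):
        fits, indices = self.make_cohort()
        included, log = apply_exclusions(fits, indices)
        assert len(included) == len(fits)
        assert log.empty

    def test_poor_fit_excluded_with_rule(self):
        fits, indices = self.make_cohort()
        fits["s03"][Condition.M] = _fit(r2=0.69)
        included, log = apply_exclusions(fits, indices)
        assert "s03" not in included
        fired = log[log.subject_id == "s03"]
        assert list(fired.rule) == ["r_squared"]
        assert list(fired.condition) == [Condition.M.value]

    def test_large_bias_excluded_after_arcmin_conversion(self):
        fits, indices = self.make_cohort()
        # mu 1.5 units above the standard = 4 arcmin at 8 arcmin/unit
        fits["s05"][Condition.D] = _fit(mu=2.5)
        included, log = apply_exclusions(fits, indices)
        assert "s05" not in included
        assert (log[log.subject_id == "s05"].rule == "bias").all()

    def test_planted_index_outlier_excluded(self):
        # a lone outlier can reach at most (n-1)/sqrt(n) SDs of the
        # contaminated cohort, so the 5-SD rule needs n > 26 to ever fire
        fits, indices = self.make_cohort(n=40)
        vals = np.array([indices[s].index1 for s in indices])
        planted = float(vals.mean() + 1000 * vals.std(ddof=1))
        indices["s07"] = IntegrationIndices(index1=planted, index2=0.0, subject_id="s07")
        included, log = apply_exclusions(fits, indices)
        assert "s07" not in included
        assert "index_outlier" in set(log[log.subject_id == "s07"].rule)
        assert len(included) == 39

    def test_relaxed_thresholds_configurable(self):
        fits, indices = self.make_cohort()
        fits["s03"][Condition.M] = _fit(r2=0.69)
        rules = ExclusionRules(min_r_squared=0.65)
        included, _ = apply_exclusions(fits, indices, rules)
        assert "s03" in included

    def test_single_subject_rejected(self):
        fits, indices = self.make_cohort(n=1)
        with pytest.raises(ValueError):
            apply_exclusions(fits, indices)


class TestGroupCriteria:
    def cohort(self, n_per_bin, effect, seed=0):
        rng = np.random.default_rng(seed)
        out = []
        for (lo, hi), n in zip(DEFAULT_AGE_BINS, n_per_bin):
            for _ in range(n):
                age = rng.uniform(lo, hi)
                s_d, s_m = 3.0, 2.0
                qs = quadratic_sum(s_d, s_m)
                bump = effect if age >= 10.5 else 0.0
                out.append(
                    SensitivitySet(
                        s_D=s_d + rng.normal(0, 0.2),
                        s_M=s_m + rng.normal(0, 0.2),
                        s_DM=qs + bump + rng.normal(0, 0.2),
                        s_DconflictM=qs - bump + rng.normal(0, 0.2),
                        subject_id="x",
                        age_years=age,
                    )
                )
        return out

    def test_fusion_bin_significant(self):
        sens = self.cohort((10, 10, 12), effect=1.0)
        table = group_criteria_tests(sens)
        old = table[(table.bin == "10.5-12.0")]
        assert (old.p < 0.05).all() and (old.mean_diff > 0).all()

    def test_null_bins_not_significant(self):
        sens = self.cohort((10, 10, 12), effect=0.0, seed=3)
        table = group_criteria_tests(sens)
        bins = table[table.bin != "all"]
        assert (bins.p > 0.05).sum() >= 4  # at most stray marginal results

    def test_small_bin_skipped_with_warning(self):
        sens = self.cohort((2, 10, 10), effect=0.0)
        with pytest.warns(UserWarning, match="skipped"):
            table = group_criteria_tests(sens)
        assert "6.0-8.5" not in set(table.bin)


class TestDevelopmentalCurve:
    def test_exponential_recovery(self):
        rng = np.random.default_rng(0)
        ages = rng.uniform(6, 12, 120)
        a, b, c = 0.05, 0.8, -0.1
        y = a * np.exp(b * (ages - 6)) + c + rng.normal(0, 0.2, ages.size)
        fit = fit_developmental_curve(ages, y)
        assert fit.model_form == "exponential"
        assert fit.params["b"] == pytest.approx(b, abs=0.3)
        true_crossing = 6 + math.log(-c / a) / b
        assert fit.zero_crossing_age == pytest.approx(true_crossing, abs=1.0)

    def test_null_data_prefers_constant(self):
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            ages = rng.uniform(6, 12, 60)
            y = rng.normal(0, 0.3, 60)
            if fit_developmental_curve(ages, y).model_form == "constant":
                wins += 1
        assert wins >= 6

    def test_noiseless_linear_not_worse_than_exponential(self):
        ages = np.linspace(6, 12, 30)
        y = 0.2 * (ages - 6) - 0.3
        fit = fit_developmental_curve(ages, y)
        assert fit.aic_per_model["linear"] <= fit.aic_per_model.get("exponential", np.inf) + 2

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fit_developmental_curve(np.linspace(6, 7, 20), np.zeros(20))
        with pytest.raises(ValueError):
            fit_developmental_curve(np.linspace(6, 12, 5), np.zeros(5))
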