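"""Psychometric fitting, exclusion rules, integration criteria, and the
developmental curve for two-cue depth discrimination.

The central quantity is the sensitivity 1/sigma of a cumulative Gaussian
fitted to a subject's 2AFC responses in each of the four cue conditions
(D, M, DM, DconflictM).  Two criteria diagnose sensory fusion:

    index1 = S_DM - S_DconflictM          (conflict costs a fusion mechanism)
    index2 = S_DM - sqrt(S_D^2 + S_M^2)   (DM beats the quadratic-sum bound)

Both are identically zero for an observer reading out the cues
independently, and strictly positive for a fusion observer.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .observer_models import Condition, CueCalibration

__all__ = [
    "PsychometricFit",
    "SensitivitySet",
    "IntegrationIndices",
    "DevelopmentalFit",
    "ExclusionRules",
    "fit_cumulative_gaussian",
    "fit_subject_conditions",
    "integration_indices",
    "quadratic_sum",
    "apply_exclusions",
    "group_criteria_tests",
    "fit_developmental_curve",
    "DEFAULT_AGE_BINS",
]

SIGMA_FLOOR = 1e-6
SIGMA_CEIL = 1e3  # sigma pinned here => sensitivity ~0; fit flagged non-converged


@dataclass(frozen=True)
class PsychometricFit:
    """Cumulative-Gaussian fit of P(chose comparison) over comparison level.

    ``slope_sign`` is +1 for the standard increasing curve and -1 when the
    data are better described by the mirrored (decreasing) curve; ``sigma``
    is always positive and 1/sigma measures discriminability magnitude.
    ``r_squared`` is computed on the 6 level-wise response proportions
    against the fitted curve.
    """

    mu: float
    sigma: float
    r_squared: float
    n_trials: int
    converged: bool
    slope_sign: int = 1
    log_likelihood: float = float("nan")
    standard: float = float("nan")

    @property
    def sensitivity(self) -> float:
        return 1.0 / self.sigma

    @property
    def bias(self) -> float:
        """PSE shift relative to the condition standard (normalized units)."""
        return self.mu - self.standard

    def bias_arcmin(self, calibration: CueCalibration) -> float:
        """Bias on the common depth axis expressed in arcmin-equivalents."""
        if not math.isfinite(self.standard):
            return 0.0
        return float(calibration.units_to_arcmin(self.bias))


@dataclass(frozen=True)
class SensitivitySet:
    """Per-condition sensitivities (1/sigma) for one subject."""

    s_D: float
    s_M: float
    s_DM: float
    s_DconflictM: float
    subject_id: str = ""
    age_years: float = float("nan")


@dataclass(frozen=True)
class IntegrationIndices:
    index1: float  # S_DM - S_DconflictM
    index2: float  # S_DM - sqrt(S_D^2 + S_M^2)
    subject_id: str = ""
    age_years: float = float("nan")


def quadratic_sum(s_d: float, s_m: float) -> float:
    return math.hypot(s_d, s_m)


def integration_indices(s: SensitivitySet) -> IntegrationIndices:
    """Compute both fusion criteria from a subject's four sensitivities."""
    for v in (s.s_D, s.s_M, s.s_DM, s.s_DconflictM):
        if not math.isfinite(v):
            raise ValueError("all four sensitivities must be finite")
    return IntegrationIndices(
        index1=s.s_DM - s.s_DconflictM,
        index2=s.s_DM - quadratic_sum(s.s_D, s.s_M),
        subject_id=s.subject_id,
        age_years=s.age_years,
    )


def _aggregate_levels(trials: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    g = trials.groupby("comparison_level")["chose_comparison"]
    levels = np.array(sorted(g.groups))
    n = g.count().loc[levels].to_numpy(dtype=float)
    k = g.sum().loc[levels].to_numpy(dtype=float)
    return levels, k, n


def _nll(params: np.ndarray, x: np.ndarray, k: np.ndarray, n: np.ndarray) -> float:
    mu, log_sigma = params
    p = stats.norm.cdf((x - mu) / math.exp(log_sigma))
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-(k * np.log(p) + (n - k) * np.log(1 - p)).sum())


def fit_cumulative_gaussian(trials: pd.DataFrame) -> PsychometricFit:
    """Maximum-likelihood cumulative-Gaussian fit to one subject x condition.

    Fits P(chose_comparison) = Phi((x - mu)/sigma) over comparison level x by
    trial-wise (binomial) maximum likelihood; no lapse parameter, so sigma
    absorbs lapses.  Both slope orientations are tried and the better
    likelihood kept.  Degenerate data (flat or all-identical responses) pin
    sigma at a bound and flag the fit non-converged instead of raising.
    """
    if len(trials) < 20:
        raise ValueError("need at least 20 trials to fit a psychometric function")
    x, k, n = _aggregate_levels(trials)
    if len(x) < 2:
        raise ValueError("need responses at >= 2 distinct comparison levels")

    span = float(x.max() - x.min())
    best: tuple[float, float, float, int] | None = None  # (nll, mu, sigma, sign)
    for sign in (1, -1):
        kk = k if sign == 1 else n - k
        x0 = np.array([float(np.median(x)), math.log(max(span / 4.0, 1e-3))])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = optimize.minimize(
                _nll,
                x0,
                args=(x, kk, n),
                method="L-BFGS-B",
                bounds=[
                    (x.min() - 10 * span, x.max() + 10 * span),
                    (math.log(SIGMA_FLOOR), math.log(SIGMA_CEIL)),
                ],
            )
        cand = (float(res.fun), float(res.x[0]), math.exp(float(res.x[1])), sign)
        if best is None or cand[0] < best[0]:
            best = cand
    nll, mu, sigma, sign = best

    p_obs = k / n
    p_fit = stats.norm.cdf(sign * (x - mu) / sigma)
    ss_res = float(((p_obs - p_fit) ** 2).sum())
    ss_tot = float(((p_obs - p_obs.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0

    at_bound = sigma >= SIGMA_CEIL * 0.99 or sigma <= SIGMA_FLOOR * 1.01
    standard = (
        float(trials["standard_level"].iloc[0])
        if "standard_level" in trials.columns
        else float("nan")
    )
    return PsychometricFit(
        mu=mu,
        sigma=sigma,
        r_squared=r2,
        n_trials=int(n.sum()),
        converged=not at_bound,
        slope_sign=sign,
        log_likelihood=-nll,
        standard=standard,
    )


def sensitivity_standard_error(fit: PsychometricFit, trials: pd.DataFrame) -> float:
    """Delta-method SE of the fitted sensitivity 1/sigma.

    Uses the observed information of the binomial likelihood in the
    (mu, log sigma) parameterization, where d(1/sigma)/d(log sigma) =
    -1/sigma, so SE(1/sigma) = SE(log sigma) / sigma.
    """
    x, k, n = _aggregate_levels(trials)
    if fit.slope_sign < 0:
        k = n - k
    theta = np.array([fit.mu, math.log(fit.sigma)])
    h = np.array([1e-4 * max(1.0, abs(fit.mu)), 1e-4])
    H = np.zeros((2, 2))
    for i in range(2):
        for j in range(2):
            ei = np.zeros(2); ei[i] = h[i]
            ej = np.zeros(2); ej[j] = h[j]
            H[i, j] = (
                _nll(theta + ei + ej, x, k, n)
                - _nll(theta + ei - ej, x, k, n)
                - _nll(theta - ei + ej, x, k, n)
                + _nll(theta - ei - ej, x, k, n)
            ) / (4.0 * h[i] * h[j])
    try:
        cov = np.linalg.inv(H)
        var_log_sigma = float(cov[1, 1])
    except np.linalg.LinAlgError:
        return float("inf")
    if var_log_sigma <= 0:
        return float("inf")
    return math.sqrt(var_log_sigma) / fit.sigma


def fit_subject_conditions(trials: pd.DataFrame) -> dict[Condition, PsychometricFit]:
    """Fit each condition present in one subject's trial table."""
    out: dict[Condition, PsychometricFit] = {}
    for cond, sub in trials.groupby("condition"):
        out[Condition(cond)] = fit_cumulative_gaussian(sub)
    return out


def sensitivity_set(
    fits: dict[Condition, PsychometricFit],
    subject_id: str = "",
    age_years: float = float("nan"),
) -> SensitivitySet:
    return SensitivitySet(
        s_D=fits[Condition.D].sensitivity,
        s_M=fits[Condition.M].sensitivity,
        s_DM=fits[Condition.DM].sensitivity,
        s_DconflictM=fits[Condition.D_CONFLICT_M].sensitivity,
        subject_id=subject_id,
        age_years=age_years,
    )


@dataclass(frozen=True)
class ExclusionRules:
    """Subject-level exclusion thresholds.

    A subject is excluded when any condition's fit has R^2 below
    ``min_r_squared``, when any condition's bias |mu| exceeds
    ``max_bias_arcmin`` after conversion of the condition axis to
    arcmin-equivalents, or when either integration index deviates more than
    ``index_sd_limit`` SDs from the cohort mean (single pass on the
    pre-exclusion cohort).
    """

    min_r_squared: float = 0.7
    max_bias_arcmin: float = 3.0
    index_sd_limit: float = 5.0
    calibration: CueCalibration = field(default_factory=CueCalibration)


def apply_exclusions(
    fits_by_subject: dict[str, dict[Condition, PsychometricFit]],
    indices_by_subject: dict[str, IntegrationIndices],
    rules: ExclusionRules | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Apply the cohort exclusion rules; returns (included ids, exclusion log).

    The log has one row per (subject, rule, condition) fired, with columns
    subject_id / rule / condition / value.  The outlier rule uses the mean
    and SD of the full pre-exclusion cohort, in a single pass.
    """
    if rules is None:
        rules = ExclusionRules()
    if len(fits_by_subject) < 2:
        raise ValueError("exclusion rules require a cohort of >= 2 subjects")

    ids = list(fits_by_subject)
    i1 = np.array([indices_by_subject[s].index1 for s in ids])
    i2 = np.array([indices_by_subject[s].index2 for s in ids])
    mean1, sd1 = i1.mean(), i1.std(ddof=1)
    mean2, sd2 = i2.mean(), i2.std(ddof=1)

    records: list[dict] = []
    included: list[str] = []
    for sid in ids:
        fired = False
        for cond, fit in fits_by_subject[sid].items():
            if fit.r_squared < rules.min_r_squared:
                records.append(
                    {"subject_id": sid, "rule": "r_squared", "condition": cond.value,
                     "value": fit.r_squared}
                )
                fired = True
        for cond, fit in fits_by_subject[sid].items():
            if abs(fit.bias_arcmin(rules.calibration)) > rules.max_bias_arcmin:
                records.append(
                    {"subject_id": sid, "rule": "bias", "condition": cond.value,
                     "value": fit.bias_arcmin(rules.calibration)}
                )
                fired = True
        idx = indices_by_subject[sid]
        if sd1 > 0 and abs(idx.index1 - mean1) > rules.index_sd_limit * sd1:
            records.append(
                {"subject_id": sid, "rule": "index_outlier", "condition": "index1",
                 "value": idx.index1}
            )
            fired = True
        if sd2 > 0 and abs(idx.index2 - mean2) > rules.index_sd_limit * sd2:
            records.append(
                {"subject_id": sid, "rule": "index_outlier", "condition": "index2",
                 "value": idx.index2}
            )
            fired = True
        if not fired:
            included.append(sid)
    log = pd.DataFrame(records, columns=["subject_id", "rule", "condition", "value"])
    return included, log


DEFAULT_AGE_BINS: tuple[tuple[float, float], ...] = (
    (6.0, 8.5),
    (8.5, 10.5),
    (10.5, 12.0),
)


def group_criteria_tests(
    sensitivities: list[SensitivitySet],
    age_bins: tuple[tuple[float, float], ...] = DEFAULT_AGE_BINS,
    min_bin_size: int = 3,
) -> pd.DataFrame:
    """Paired t tests of both fusion criteria within each age bin.

    Per bin: S_DM vs S_DconflictM (criterion 1) and S_DM vs
    sqrt(S_D^2 + S_M^2) (criterion 2).  Subjects exactly at a bin edge go to
    the older bin; the last bin includes its upper edge.  Bins with fewer
    than ``min_bin_size`` subjects are skipped with a warning.  Also returns
    cohort-wide Pearson correlations of each index with age as rows with
    bin = 'all'.
    """
    rows: list[dict] = []
    ages = np.array([s.age_years for s in sensitivities])
    for lo, hi in age_bins:
        last = (lo, hi) == age_bins[-1]
        mask = (ages >= lo) & ((ages <= hi) if last else (ages < hi))
        members = [s for s, m in zip(sensitivities, mask) if m]
        if len(members) < min_bin_size:
            warnings.warn(
                f"age bin [{lo}, {hi}) has {len(members)} subjects; skipped",
                stacklevel=2,
            )
            continue
        dm = np.array([s.s_DM for s in members])
        dcm = np.array([s.s_DconflictM for s in members])
        qs = np.array([quadratic_sum(s.s_D, s.s_M) for s in members])
        t1 = stats.ttest_rel(dm, dcm)
        t2 = stats.ttest_rel(dm, qs)
        for name, res, diff in (
            ("criterion1", t1, dm - dcm),
            ("criterion2", t2, dm - qs),
        ):
            rows.append(
                {
                    "bin": f"{lo}-{hi}",
                    "test": name,
                    "n": len(members),
                    "mean_diff": float(diff.mean()),
                    "t": float(res.statistic),
                    "p": float(res.pvalue),
                }
            )
    idx1 = np.array([s.s_DM - s.s_DconflictM for s in sensitivities])
    idx2 = np.array([s.s_DM - quadratic_sum(s.s_D, s.s_M) for s in sensitivities])
    if len(sensitivities) >= 3 and np.ptp(ages) > 0:
        for name, vals in (("criterion1", idx1), ("criterion2", idx2)):
            r, p = stats.pearsonr(ages, vals)
            rows.append(
                {"bin": "all", "test": f"age_correlation_{name}", "n": len(ages),
                 "mean_diff": float(vals.mean()), "t": float(r), "p": float(p)}
            )
    return pd.DataFrame(rows, columns=["bin", "test", "n", "mean_diff", "t", "p"])


@dataclass(frozen=True)
class DevelopmentalFit:
    """Best AIC model of integration index vs age.

    The exponential form is I(age) = a * exp(b * (age - 6)) + c, anchored at
    the cohort minimum age for identifiability.  ``zero_crossing_age`` is
    reported only when the selected curve crosses zero inside [6, 12].
    """

    model_form: str  # constant | linear | exponential
    params: dict[str, float]
    aic_per_model: dict[str, float]
    zero_crossing_age: float | None
    fallback: bool = False

    @property
    def half_rise_age(self) -> float | None:
        """Age where the selected exponential reaches half of its total
        (age 6 to age 12) rise above its age-6 level.

        The transition midpoint of the developmental curve — a summary that,
        unlike the zero crossing, is defined whenever the curve grows and is
        insensitive to small vertical offsets of the early plateau.  Only
        defined for a growing exponential inside [6, 12].
        """
        if self.model_form != "exponential":
            return None
        a, b = self.params["a"], self.params["b"]
        if a <= 0 or b <= 0:
            return None
        age = 6.0 + math.log1p(0.5 * (math.exp(6.0 * b) - 1.0)) / b
        return age if 6.0 <= age <= 12.0 else None

    def predict(self, age: np.ndarray) -> np.ndarray:
        age = np.asarray(age, dtype=float)
        p = self.params
        if self.model_form == "constant":
            return np.full_like(age, p["c"])
        if self.model_form == "linear":
            return p["a"] * (age - 6.0) + p["c"]
        return p["a"] * np.exp(p["b"] * (age - 6.0)) + p["c"]


def _aic(rss: float, n: int, k: int) -> float:
    rss = max(rss, 1e-300)
    return n * math.log(rss / n) + 2 * k


def fit_developmental_curve(
    ages: np.ndarray, index_values: np.ndarray
) -> DevelopmentalFit:
    """Least-squares fit of constant, linear, and exponential age trends,
    selected by AIC."""
    ages = np.asarray(ages, dtype=float)
    y = np.asarray(index_values, dtype=float)
    if len(ages) < 10:
        raise ValueError("need >= 10 subjects for the developmental fit")
    if np.ptp(ages) < 3.0:
        raise ValueError("ages must span at least 3 years")
    t = ages - 6.0
    n = len(y)

    aics: dict[str, float] = {}
    fits: dict[str, dict[str, float]] = {}

    c0 = float(y.mean())
    aics["constant"] = _aic(float(((y - c0) ** 2).sum()), n, 1)
    fits["constant"] = {"c": c0}

    A = np.column_stack([t, np.ones_like(t)])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    rss_lin = float(((y - A @ coef) ** 2).sum())
    aics["linear"] = _aic(rss_lin, n, 2)
    fits["linear"] = {"a": float(coef[0]), "c": float(coef[1])}

    def expo(tt, a, b, c):
        return a * np.exp(np.clip(b * tt, -50, 50)) + c

    exp_ok = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = optimize.curve_fit(
                expo,
                t,
                y,
                p0=[max(abs(y).max() * 0.05, 1e-3), 0.5, float(y.min())],
                maxfev=20000,
            )
        resid = y - expo(t, *popt)
        aics["exponential"] = _aic(float((resid**2).sum()), n, 3)
        fits["exponential"] = {"a": float(popt[0]), "b": float(popt[1]), "c": float(popt[2])}
        exp_ok = np.all(np.isfinite(popt))
    except (RuntimeError, ValueError):
        exp_ok = False

    candidates = {k: v for k, v in aics.items() if k != "exponential" or exp_ok}
    best = min(candidates, key=candidates.get)

    zero_crossing = None
    p = fits[best]
    if best == "linear" and p["a"] != 0:
        age0 = 6.0 - p["c"] / p["a"]
        if 6.0 <= age0 <= 12.0:
            zero_crossing = float(age0)
    elif best == "exponential":
        a, b, c = p["a"], p["b"], p["c"]
        if a != 0 and b != 0 and -c / a > 0:
            age0 = 6.0 + math.log(-c / a) / b
            if 6.0 <= age0 <= 12.0:
                zero_crossing = float(age0)

    return DevelopmentalFit(
        model_form=best,
        params=fits[best],
        aic_per_model=aics,
        zero_crossing_age=zero_crossing,
        fallback=not exp_ok,
    )
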