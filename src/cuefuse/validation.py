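"""Study-condition validation routines.

Each function re-runs one of the package's core claims from scratch at a
given seed — oracle agreement, mechanism signatures, the decoding-level
quadratic-sum identity, permutation-null calibration, exclusion-rule
fidelity, and end-to-end developmental recovery — and returns the measured
quantities.  The test suite asserts on these; the acceptance script reports
them.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import mvpa
from .observer_models import (
    CONDITIONS,
    Condition,
    Mechanism,
    ObserverParams,
    SessionDesign,
    analytic_sensitivity,
    simulate_session,
)
from .pipeline import CohortSpec, behavioral_summary, simulate_cohort
from .psychometrics import (
    IntegrationIndices,
    PsychometricFit,
    apply_exclusions,
    fit_cumulative_gaussian,
    fit_developmental_curve,
    sensitivity_standard_error,
)
from .synthetic_fmri import EncodingModel, ScanDesign, generate_experiment

SIGMA_GRID = (0.6, 1.0, 1.5)


def oracle_agreement(
    seed: int,
    trials_per_level: int = 10_000,
    sigma_grid: tuple[float, ...] = SIGMA_GRID,
) -> list[dict]:
    """Monte-Carlo vs closed-form sensitivity for both mechanisms over a
    grid of channel noise levels.

    Returns one record per (mechanism, sigma_d, sigma_m, condition) with the
    fitted sensitivity, the analytic value, the delta-method Monte-Carlo SE,
    and the z score of their disagreement.
    """
    design = SessionDesign()
    rng = np.random.default_rng(seed)
    records = []
    for mechanism in (Mechanism.FUSION, Mechanism.INDEPENDENCE):
        for sd in sigma_grid:
            for sm in sigma_grid:
                obs = ObserverParams(sd, sm, mechanism)
                trials = simulate_session(
                    obs, design, seed=int(rng.integers(2**31 - 1)),
                    trials_per_level=trials_per_level,
                )
                for cond in CONDITIONS:
                    sub = trials[trials.condition == cond.value]
                    fit = fit_cumulative_gaussian(sub)
                    se = sensitivity_standard_error(fit, sub)
                    expected = analytic_sensitivity(obs, cond, design)
                    records.append(
                        {
                            "mechanism": mechanism.value,
                            "sigma_d": sd,
                            "sigma_m": sm,
                            "condition": cond.value,
                            "fitted": fit.sensitivity,
                            "analytic": expected,
                            "se": se,
                            "z": (fit.sensitivity - expected) / se,
                        }
                    )
    return records


@dataclass(frozen=True)
class MechanismSignature:
    mean_index1: float
    mean_index2: float
    sem_index1: float
    sem_index2: float
    expected_index1: float
    expected_index2: float
    n_observers: int


def _session_indices(obs: ObserverParams, design: SessionDesign, seed: int, n: int):
    trials = simulate_session(obs, design, seed=seed, trials_per_level=n)
    s = {}
    for cond in CONDITIONS:
        s[cond] = fit_cumulative_gaussian(trials[trials.condition == cond.value]).sensitivity
    i1 = s[Condition.DM] - s[Condition.D_CONFLICT_M]
    i2 = s[Condition.DM] - math.hypot(s[Condition.D], s[Condition.M])
    return i1, i2


def mechanism_signature(
    mechanism: Mechanism,
    seed: int,
    n_observers: int = 8,
    trials_per_level: int = 10_000,
    sigma: float = 1.0,
) -> MechanismSignature:
    """Mean fitted integration indices over replicate observers of one
    mechanism with sigma_d = sigma_m = sigma.

    Expected values: (0, 0) for independence; (S_DM, S_DM * (1 - 1/sqrt(2)))
    for equal-reliability fusion, whose conflict sensitivity is exactly zero.
    """
    design = SessionDesign()
    obs = ObserverParams(sigma, sigma, mechanism)
    rng = np.random.default_rng(seed)
    i1s, i2s = [], []
    for _ in range(n_observers):
        i1, i2 = _session_indices(obs, design, int(rng.integers(2**31 - 1)), trials_per_level)
        i1s.append(i1)
        i2s.append(i2)
    s_dm = analytic_sensitivity(obs, Condition.DM, design)
    if mechanism is Mechanism.FUSION:
        exp1, exp2 = s_dm, s_dm * (1.0 - 1.0 / math.sqrt(2.0))
    else:
        exp1, exp2 = 0.0, 0.0
    return MechanismSignature(
        mean_index1=float(np.mean(i1s)),
        mean_index2=float(np.mean(i2s)),
        sem_index1=float(np.std(i1s, ddof=1) / math.sqrt(n_observers)),
        sem_index2=float(np.std(i2s, ddof=1) / math.sqrt(n_observers)),
        expected_index1=exp1,
        expected_index2=exp2,
        n_observers=n_observers,
    )


def dprime_vs_bisection(n_points: int = 1000) -> float:
    """Max |d'(a) - 2x| over an accuracy grid, with x from brentq inversion
    of erf(x) = 2a - 1 (the independent numeric oracle)."""
    from scipy.optimize import brentq
    from scipy.special import erf

    grid = np.linspace(0.01, 0.99, n_points)
    worst = 0.0
    for a in grid:
        target = 2.0 * a - 1.0
        x = brentq(lambda z: erf(z) - target, -10, 10, xtol=1e-15, rtol=8.9e-16)
        worst = max(worst, abs(mvpa.accuracy_to_dprime(float(a), clip=1e-9) - 2.0 * x))
    return worst


def _decode_dataset(model: EncodingModel, scan: ScanDesign, seed: int,
                    n_select: int = 120) -> dict[str, float]:
    dataset = generate_experiment(model, scan, seed=seed)
    voxels = mvpa.select_voxels(mvpa.compute_tmap(dataset), n=n_select)
    patterns = mvpa.extract_block_patterns(dataset, voxel_indices=voxels)
    return {c: r.dprime for c, r in mvpa.decode_all_conditions(patterns).items()}


def decoding_identity(
    seed: int,
    n_seeds: int = 30,
    fused_gain: float = 1.5,
    n_voxels: int = 300,
    noise_sd: float = 25.0,
) -> dict:
    """Quadratic-sum identity at the decoding level.

    With no fused channel, mean d'_DM should match both sqrt(d'_D^2 + d'_M^2)
    and d'_DconflictM; a positive fused gain should push d'_DM above both in
    (nearly) every seed.  Returns the measured gaps, their SEMs, and sign-test
    p-values for the fused regime.
    """
    rng = np.random.default_rng(seed)
    scan = ScanDesign()
    gaps_qs, gaps_conf, fused_i1, fused_i2 = [], [], [], []
    for _ in range(n_seeds):
        mseed, dseed = (int(x) for x in rng.integers(2**31 - 1, size=2))
        base = EncodingModel.random(n_voxels=n_voxels, seed=mseed, fused_gain=0.0,
                                    noise_sd=noise_sd)
        d0 = _decode_dataset(base, scan, dseed)
        gaps_qs.append(d0["DM"] - math.hypot(d0["D"], d0["M"]))
        gaps_conf.append(d0["DM"] - d0["DconflictM"])
        fused = EncodingModel.random(n_voxels=n_voxels, seed=mseed, fused_gain=fused_gain,
                                     noise_sd=noise_sd)
        d1 = _decode_dataset(fused, scan, dseed)
        fused_i1.append(d1["DM"] - d1["DconflictM"])
        fused_i2.append(d1["DM"] - math.hypot(d1["D"], d1["M"]))
    sign_p1 = stats.binomtest(int(np.sum(np.array(fused_i1) > 0)), n_seeds, 0.5,
                              alternative="greater").pvalue
    sign_p2 = stats.binomtest(int(np.sum(np.array(fused_i2) > 0)), n_seeds, 0.5,
                              alternative="greater").pvalue
    root_n = math.sqrt(n_seeds)
    return {
        "mean_gap_dm_vs_qsum": float(np.mean(gaps_qs)),
        "sem_gap_dm_vs_qsum": float(np.std(gaps_qs, ddof=1) / root_n),
        "mean_gap_dm_vs_conflict": float(np.mean(gaps_conf)),
        "sem_gap_dm_vs_conflict": float(np.std(gaps_conf, ddof=1) / root_n),
        "fused_mean_index1": float(np.mean(fused_i1)),
        "fused_mean_index2": float(np.mean(fused_i2)),
        "fused_sign_p_index1": float(sign_p1),
        "fused_sign_p_index2": float(sign_p2),
        "n_seeds": n_seeds,
    }


def permutation_calibration(
    seed: int,
    n_shuffles: int = 200,
    n_perm: int = 200,
    n_voxels: int = 100,
) -> dict:
    """Label-shuffled decoding vs the explicit permutation null.

    Decodes one condition of a signal-bearing dataset under independently
    shuffled labels ``n_shuffles`` times and compares that accuracy
    distribution with the ``permutation_null`` distribution by a two-sample
    KS test.  Also measures the searchlight false-positive rate on a
    no-signal dataset against the 97.5% permutation bound.
    """
    rng = np.random.default_rng(seed)
    scan = ScanDesign()
    model = EncodingModel.random(n_voxels=n_voxels, seed=int(rng.integers(2**31 - 1)),
                                 fused_gain=0.0, noise_sd=25.0)
    dataset = generate_experiment(model, scan, seed=int(rng.integers(2**31 - 1)))
    patterns = mvpa.extract_block_patterns(dataset).for_condition(Condition.DM)

    null = mvpa.permutation_null(patterns, n_perm=n_perm, seed=int(rng.integers(2**31 - 1)))
    y = (patterns.meta["depth"] == "far").to_numpy().astype(int)
    runs = patterns.meta["run"].to_numpy()
    shuffled_accs = np.empty(n_shuffles)
    for i in range(n_shuffles):
        perm = y.copy()
        for r in np.unique(runs):
            idx = np.flatnonzero(runs == r)
            perm[idx] = y[idx][rng.permutation(len(idx))]
        shuffled_accs[i] = mvpa.decode_condition(patterns, labels=perm).accuracy
    ks = stats.ks_2samp(shuffled_accs, null.null_accuracies)

    # global-null searchlight: no signal anywhere, 4x4x4 lattice
    zeros = np.zeros(64)
    null_model = EncodingModel(w_disparity=zeros, w_motion=zeros, w_fused=zeros,
                               noise_sd=10.0, w_stimulus=np.abs(
                                   np.random.default_rng(seed + 1).normal(size=64)))
    exceed = 0
    total = 0
    for _ in range(2):
        nds = generate_experiment(null_model, scan, seed=int(rng.integers(2**31 - 1)))
        npat = mvpa.extract_block_patterns(nds)
        center = npat.for_condition(Condition.DM)
        bound = mvpa.permutation_null(
            mvpa.BlockPatterns(center.X[:, :13], center.meta),
            n_perm=n_perm, seed=int(rng.integers(2**31 - 1)),
        ).upper_bound_97_5
        sl = mvpa.searchlight_map(nds, radius_voxels=1.5)
        accs = sl.dprimes["DM"]
        dm_acc_bound = mvpa.accuracy_to_dprime(bound)
        exceed += int(np.nansum(accs > dm_acc_bound))
        total += int(np.sum(~np.isnan(accs)))
    return {
        "ks_statistic": float(ks.statistic),
        "ks_p": float(ks.pvalue),
        "null_mean_accuracy": float(null.null_accuracies.mean()),
        "searchlight_fp_rate": exceed / total,
        "n_searchlight_voxels": total,
    }


def exclusion_fidelity() -> dict:
    """Planted single-rule violations each fire exactly the right rule.

    Builds a clean 40-subject cohort of well-fit, unbiased, index-typical
    subjects, then plants one fit-quality violator (R^2 = 0.69), one bias
    violator (PSE 4 arcmin from the standard), and one 1000-SD index
    outlier.  Deterministic by construction.
    """
    rng = np.random.default_rng(12345)

    def fit(r2=0.9, mu=1.0):
        return PsychometricFit(mu=mu, sigma=0.3, r_squared=r2, n_trials=90,
                               converged=True, standard=1.0)

    fits, indices = {}, {}
    for i in range(40):
        sid = f"c{i:02d}"
        fits[sid] = {c: fit() for c in Condition}
        indices[sid] = IntegrationIndices(
            index1=float(rng.normal(0, 0.1)), index2=float(rng.normal(0, 0.1)),
            subject_id=sid,
        )
    fits["p_r2"] = {c: fit() for c in Condition}
    fits["p_r2"][Condition.M] = fit(r2=0.69)
    indices["p_r2"] = IntegrationIndices(0.0, 0.0, subject_id="p_r2")

    fits["p_bias"] = {c: fit() for c in Condition}
    fits["p_bias"][Condition.D] = fit(mu=1.5)  # 0.5 units = 4 arcmin
    indices["p_bias"] = IntegrationIndices(0.0, 0.0, subject_id="p_bias")

    fits["p_out"] = {c: fit() for c in Condition}
    sd = np.std([indices[s].index1 for s in indices if s.startswith("c")], ddof=1)
    indices["p_out"] = IntegrationIndices(float(1000 * sd), 0.0, subject_id="p_out")

    included, log = apply_exclusions(fits, indices)
    rules = {sid: sorted(set(log[log.subject_id == sid].rule)) for sid in
             ("p_r2", "p_bias", "p_out")}
    clean_kept = all(f"c{i:02d}" in included for i in range(40))
    correct = (
        clean_kept
        and rules["p_r2"] == ["r_squared"]
        and rules["p_bias"] == ["bias"]
        and rules["p_out"] == ["index_outlier"]
        and not any(s in included for s in ("p_r2", "p_bias", "p_out"))
    )
    return {"all_rules_correct": bool(correct), "rules_fired": rules,
            "n_clean_kept": sum(f"c{i:02d}" in included for i in range(40))}


def developmental_recovery(seed: int, n_seeds: int = 50) -> dict:
    """End-to-end mechanism recovery on cohorts switching readout at 10.5 y.

    A recovery succeeds when the oldest bin meets both fusion criteria
    (paired t, p < 0.05, positive mean), neither younger bin meets both, the
    exponential age model is selected for the conflict-cost index, and its
    half-rise age falls within [9, 12] around the switch.
    """
    rng = np.random.default_rng(seed)
    successes = 0
    half_rises = []
    for _ in range(n_seeds):
        spec = CohortSpec(master_seed=int(rng.integers(2**31 - 1)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = behavioral_summary(simulate_cohort(spec))
        bt = report.tables["bin_tests"]

        def meets(bin_name: str) -> bool:
            sub = bt[bt.bin == bin_name]
            return bool(len(sub) == 2 and (sub.p < 0.05).all() and (sub.mean_diff > 0).all())

        inc = report.tables["included_sensitivities"]
        curve = fit_developmental_curve(inc.age_years.to_numpy(), inc.index1.to_numpy())
        hr = curve.half_rise_age
        if hr is not None:
            half_rises.append(hr)
        ok = (
            meets("10.5-12.0")
            and not meets("6.0-8.5")
            and not meets("8.5-10.5")
            and curve.model_form == "exponential"
            and hr is not None
            and 9.0 <= hr <= 12.0
        )
        successes += ok
    return {
        "recovery_rate": successes / n_seeds,
        "n_seeds": n_seeds,
        "median_half_rise_age": float(np.median(half_rises)) if half_rises else None,
    }
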