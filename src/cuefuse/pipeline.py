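"""End-to-end behavioral and fMRI analyses over synthetic cohorts.

A cohort is a set of simulated child observers aged 6-12 whose readout
mechanism switches with age: below the switch age (default 10.5 years)
observers read their depth cues out independently (fMRI encoding:
``fused_gain = 0``); above it they fuse them.  The behavioral pipeline
simulates the sessions, fits psychometric functions, applies the exclusion
rules, computes both integration criteria per subject, runs the age-bin
tests and the developmental curve.  The fMRI pipeline generates scan
sessions per subject, decodes near/far per condition, and compares the
decoding-level indices between age groups.

All randomness flows from a single master seed; identical configurations
reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from scipy import stats

from . import mvpa, psychometrics as psy
from .observer_models import (
    CueCalibration,
    Mechanism,
    ObserverParams,
    SessionDesign,
    simulate_session,
    write_trials,
)
from .synthetic_fmri import EncodingModel, ScanDesign, generate_experiment

__all__ = [
    "CohortSpec",
    "RunReport",
    "simulate_cohort",
    "run_behavioral_pipeline",
    "run_fmri_pipeline",
    "load_config",
    "ConfigError",
]


class ConfigError(ValueError):
    """Invalid or unknown configuration key/value."""


@dataclass(frozen=True)
class CohortSpec:
    """Synthetic cohort definition.

    Observers below ``switch_age`` use the independence mechanism (and
    ``fused_gain = 0`` in their fMRI encoding); observers at or above it use
    fusion (``fused_gain``).  Ages are drawn from the three standard bins
    (6-8.5, 8.5-switch, switch-12) with ``age_bin_weights``, defaulting to a
    recruitment skew toward older children, as developmental cohorts
    targeting a late transition typically are.
    Per-subject disparity noise SDs are drawn log-uniformly from
    ``sigma_d_range`` (normalized depth units) and motion noise as
    ``motion_noise_ratio`` times the disparity noise.  Every subject's seeds
    derive deterministically from ``master_seed``.
    """

    n_subjects: int = 140
    age_min: float = 6.0
    age_max: float = 12.0
    switch_age: float = 10.5
    age_bin_weights: tuple[float, float, float] = (0.20, 0.38, 0.42)
    sigma_d_range: tuple[float, float] = (0.2, 0.3)
    motion_noise_ratio: tuple[float, float] = (1.4, 1.7)
    fused_gain: float = 1.0
    lapse_rate: float = 0.02
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not self.age_min <= self.switch_age <= self.age_max:
            raise ConfigError("switch_age must lie inside the age range")
        if self.sigma_d_range[0] <= 0 or self.sigma_d_range[1] < self.sigma_d_range[0]:
            raise ConfigError("sigma_d_range must be positive and ordered")
        if self.motion_noise_ratio[0] <= 0 or self.motion_noise_ratio[1] < self.motion_noise_ratio[0]:
            raise ConfigError("motion_noise_ratio must be positive and ordered")
        if not self.age_min < 8.5 < self.switch_age:
            raise ConfigError("age bins require age_min < 8.5 < switch_age")

    def subjects(self) -> pd.DataFrame:
        """Deterministic per-subject table: id, age, sigmas, mechanism, seed.

        The motion channel is made systematically noisier than disparity
        (``motion_noise_ratio``); unequal reliabilities keep a fusion
        observer's conflict-condition discriminability away from zero, as
        real integrating observers show, instead of the degenerate flat
        psychometric function of an exactly equal-weight averager.
        """
        rng = np.random.default_rng(self.master_seed)
        edges = np.array([self.age_min, 8.5, self.switch_age, self.age_max])
        weights = np.asarray(self.age_bin_weights, dtype=float)
        bins = rng.choice(3, size=self.n_subjects, p=weights / weights.sum())
        ages = np.sort(rng.uniform(edges[bins], edges[bins + 1]))
        lo, hi = self.sigma_d_range
        sig_d = np.exp(rng.uniform(np.log(lo), np.log(hi), self.n_subjects))
        rlo, rhi = self.motion_noise_ratio
        sig_m = sig_d * rng.uniform(rlo, rhi, self.n_subjects)
        seeds = rng.integers(0, 2**31 - 1, self.n_subjects)
        rows = []
        for i in range(self.n_subjects):
            fused = ages[i] >= self.switch_age
            rows.append(
                {
                    "subject_id": f"S{i:03d}",
                    "age_years": float(ages[i]),
                    "sigma_d": float(sig_d[i]),
                    "sigma_m": float(sig_m[i]),
                    "mechanism": Mechanism.FUSION.value if fused else Mechanism.INDEPENDENCE.value,
                    "fused_gain": self.fused_gain if fused else 0.0,
                    "seed": int(seeds[i]),
                }
            )
        return pd.DataFrame(rows)


def simulate_cohort(
    spec: CohortSpec, design: SessionDesign | None = None
) -> pd.DataFrame:
    """Simulate behavioral sessions for a full cohort; one row per trial."""
    if design is None:
        design = SessionDesign()
    frames = []
    for sub in spec.subjects().itertuples(index=False):
        observer = ObserverParams(
            sigma_d=sub.sigma_d,
            sigma_m=sub.sigma_m,
            mechanism=Mechanism(sub.mechanism),
            lapse_rate=spec.lapse_rate,
        )
        frames.append(
            simulate_session(
                observer,
                design,
                seed=sub.seed,
                subject_id=sub.subject_id,
                age_years=sub.age_years,
            )
        )
    return pd.concat(frames, ignore_index=True)


@dataclass
class RunReport:
    """Config echo + stage outputs of one pipeline run."""

    config: dict[str, Any]
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    summary: dict[str, Any] = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, table in self.tables.items():
            table.to_csv(out / f"{name}.tsv", sep="\t", index=False)
        payload = {"config": self.config, "summary": self.summary}
        (out / "report.json").write_text(json.dumps(payload, indent=2, default=_json_default))


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def behavioral_summary(
    trials: pd.DataFrame,
    calibration: CueCalibration | None = None,
    rules: psy.ExclusionRules | None = None,
) -> RunReport:
    """Fit, exclude, index, test, and model one behavioral cohort table."""
    if calibration is None:
        calibration = CueCalibration()
    if rules is None:
        rules = psy.ExclusionRules(calibration=calibration)

    fits_by_subject: dict[str, dict] = {}
    indices_by_subject: dict[str, psy.IntegrationIndices] = {}
    sens_rows = []
    for sid, sub in trials.groupby("subject_id"):
        fits = psy.fit_subject_conditions(sub)
        fits_by_subject[sid] = fits
        age = float(sub["age_years"].iloc[0])
        sset = psy.sensitivity_set(fits, subject_id=sid, age_years=age)
        indices_by_subject[sid] = psy.integration_indices(sset)
        sens_rows.append(
            {
                "subject_id": sid,
                "age_years": age,
                "s_D": sset.s_D,
                "s_M": sset.s_M,
                "s_DM": sset.s_DM,
                "s_DconflictM": sset.s_DconflictM,
                "index1": indices_by_subject[sid].index1,
                "index2": indices_by_subject[sid].index2,
            }
        )
    sens_table = pd.DataFrame(sens_rows)

    included, exclusion_log = psy.apply_exclusions(
        fits_by_subject, indices_by_subject, rules
    )
    inc = sens_table[sens_table["subject_id"].isin(included)].reset_index(drop=True)

    sens_sets = [
        psy.SensitivitySet(
            s_D=r.s_D, s_M=r.s_M, s_DM=r.s_DM, s_DconflictM=r.s_DconflictM,
            subject_id=r.subject_id, age_years=r.age_years,
        )
        for r in inc.itertuples(index=False)
    ]
    bin_tests = psy.group_criteria_tests(sens_sets)

    summary: dict[str, Any] = {
        "n_subjects": int(sens_table.shape[0]),
        "n_included": len(included),
        "n_excluded": int(sens_table.shape[0]) - len(included),
    }
    if len(inc) >= 10 and np.ptp(inc["age_years"].to_numpy()) >= 3.0:
        for name in ("index1", "index2"):
            curve = psy.fit_developmental_curve(
                inc["age_years"].to_numpy(), inc[name].to_numpy()
            )
            summary[f"developmental_fit_{name}"] = {
                "model_form": curve.model_form,
                "params": curve.params,
                "aic_per_model": curve.aic_per_model,
                "zero_crossing_age": curve.zero_crossing_age,
                "half_rise_age": curve.half_rise_age,
            }

    report = RunReport(config={}, summary=summary)
    report.tables["sensitivities"] = sens_table
    report.tables["included_sensitivities"] = inc
    report.tables["exclusion_log"] = exclusion_log
    report.tables["bin_tests"] = bin_tests
    return report


def run_behavioral_pipeline(config: dict[str, Any], out_dir: str | Path | None = None) -> RunReport:
    """Simulate (or load) a behavioral cohort and run the full analysis."""
    cfg = _validate_config(config, section="behavioral")
    design = SessionDesign()
    if "trials_tsv" in cfg:
        from .observer_models import read_trials

        trials = read_trials(cfg["trials_tsv"])
    else:
        spec = CohortSpec(**cfg.get("cohort", {}))
        trials = simulate_cohort(spec, design)
    report = behavioral_summary(trials, calibration=design.calibration)
    report.config = dict(config)
    report.tables["trials_head"] = trials.head(100)
    if out_dir is not None:
        report.write(out_dir)
        write_trials(trials, Path(out_dir) / "trials.tsv")
    return report


_FMRI_DEFAULTS = {
    "n_voxels": 300,
    "n_select": 120,
    "noise_sd": 25.0,
    "channel_gain": 1.0,
    "fused_gain": 1.5,
}


def run_fmri_pipeline(config: dict[str, Any], out_dir: str | Path | None = None) -> RunReport:
    """Generate per-subject scan sessions, decode, and compare age groups.

    Subjects below the cohort switch age get ``fused_gain = 0`` encodings;
    subjects above get the configured positive gain.  Group difference of
    each decoding index is tested with an independent-samples t test.
    """
    cfg = _validate_config(config, section="fmri")
    cohort = CohortSpec(**cfg.get("cohort", {}))
    p = {**_FMRI_DEFAULTS, **cfg.get("fmri", {})}
    scan = ScanDesign()

    rows = []
    for sub in cohort.subjects().itertuples(index=False):
        model = EncodingModel.random(
            n_voxels=int(p["n_voxels"]),
            seed=sub.seed,
            fused_gain=sub.fused_gain * p["fused_gain"],
            noise_sd=p["noise_sd"],
            channel_gain_d=p["channel_gain"],
            channel_gain_m=p["channel_gain"],
        )
        dataset = generate_experiment(model, scan, seed=sub.seed + 1)
        tmap = mvpa.compute_tmap(dataset)
        voxels = mvpa.select_voxels(tmap, n=int(p["n_select"]))
        patterns = mvpa.extract_block_patterns(dataset, voxel_indices=voxels)
        results = mvpa.decode_all_conditions(patterns)
        i1, i2 = mvpa.decoding_integration_indices(results)
        row = {
            "subject_id": sub.subject_id,
            "age_years": sub.age_years,
            "group": "older" if sub.age_years >= cohort.switch_age else "younger",
            "index1": i1,
            "index2": i2,
        }
        for cond, res in results.items():
            row[f"acc_{cond}"] = res.accuracy
            row[f"dprime_{cond}"] = res.dprime
        rows.append(row)
    table = pd.DataFrame(rows)

    summary: dict[str, Any] = {"n_subjects": len(table)}
    young = table[table["group"] == "younger"]
    old = table[table["group"] == "older"]
    if len(young) >= 2 and len(old) >= 2:
        for name in ("index1", "index2"):
            t, pval = stats.ttest_ind(old[name], young[name])
            summary[f"group_test_{name}"] = {
                "t": float(t),
                "p": float(pval),
                "mean_older": float(old[name].mean()),
                "mean_younger": float(young[name].mean()),
            }
    report = RunReport(config=dict(config), summary=summary)
    report.tables["decoding"] = table
    if out_dir is not None:
        report.write(out_dir)
    return report


_KNOWN_KEYS = {
    "behavioral": {"cohort", "trials_tsv"},
    "fmri": {"cohort", "fmri"},
}
_COHORT_KEYS = {f.name for f in dataclasses.fields(CohortSpec)}
_FMRI_KEYS = set(_FMRI_DEFAULTS)


def _validate_config(config: dict[str, Any], section: str) -> dict[str, Any]:
    if not isinstance(config, dict):
        raise ConfigError("config must be a mapping")
    unknown = set(config) - _KNOWN_KEYS[section]
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    cohort = config.get("cohort", {})
    bad = set(cohort) - _COHORT_KEYS
    if bad:
        raise ConfigError(f"unknown cohort keys: {sorted(bad)}")
    fm = config.get("fmri", {})
    bad = set(fm) - _FMRI_KEYS
    if bad:
        raise ConfigError(f"unknown fmri keys: {sorted(bad)}")
    return config


def load_config(path: str | Path) -> dict[str, Any]:
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError("config file must contain a mapping")
    return cfg
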