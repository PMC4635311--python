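"""Generative ideal-observer models for two-cue (disparity + motion) depth discrimination.

Stimuli live in a two-dimensional depth space whose axes are disparity-defined
and motion-defined depth, both expressed in normalized depth units (positive =
behind the surround).  Two readout mechanisms are modeled:

``fusion``
    Reliability-weighted averaging of the two cues into a single fused depth
    estimate with lower variance.  The fused estimate is compromised when the
    cues disagree (conflict averages toward zero) and when one cue is flat
    (the flat cue dilutes the informative one).

``independence``
    Optimal linear readout over separate per-cue channels.  Discriminability
    equals the quadratic (Pythagorean) sum of per-channel discriminabilities
    and is blind to the relative sign of the cues.

Both mechanisms admit closed-form psychometric sensitivities
(:func:`analytic_sensitivity`) that serve as oracles for the Monte-Carlo
simulator (:func:`simulate_session`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Condition",
    "CONDITIONS",
    "Mechanism",
    "DepthStimulus",
    "CueCalibration",
    "ObserverParams",
    "SessionDesign",
    "TRIAL_COLUMNS",
    "make_stimulus_pair",
    "decision_variable",
    "simulate_session",
    "analytic_sensitivity",
    "write_trials",
    "read_trials",
]


class Condition(str, Enum):
    """Cue configuration of a trial.

    D: disparity defines depth, motion flat.  M: motion defines depth,
    disparity flat.  DM: both cues consistent.  D_CONFLICT_M: cues in
    extreme conflict (opposite depth signs).
    """

    D = "D"
    M = "M"
    DM = "DM"
    D_CONFLICT_M = "DconflictM"


CONDITIONS: tuple[Condition, ...] = (
    Condition.D,
    Condition.M,
    Condition.DM,
    Condition.D_CONFLICT_M,
)


class Mechanism(str, Enum):
    FUSION = "fusion"
    INDEPENDENCE = "independence"


@dataclass(frozen=True)
class DepthStimulus:
    """A point in the disparity-motion depth space (normalized units)."""

    disparity_depth: float
    motion_depth: float
    condition: Condition

    def __post_init__(self) -> None:
        c = self.condition
        d, m = self.disparity_depth, self.motion_depth
        if c is Condition.D and m != 0.0:
            raise ValueError("condition D requires a flat motion cue (motion_depth = 0)")
        if c is Condition.M and d != 0.0:
            raise ValueError("condition M requires a flat disparity cue (disparity_depth = 0)")
        if c is Condition.DM and d * m < 0.0:
            raise ValueError("condition DM requires consistent cue signs")
        if c is Condition.D_CONFLICT_M and d * m > 0.0:
            raise ValueError("condition DconflictM requires opposite cue signs")

    @property
    def coords(self) -> np.ndarray:
        return np.array([self.disparity_depth, self.motion_depth])


@dataclass(frozen=True)
class CueCalibration:
    """Maps physical cue magnitudes onto the common normalized depth axis.

    The default sets the consistent-cue standards (8 arcmin of disparity,
    0.25 deg of surround-relative motion) both to 1.0 normalized unit; the
    perceptual exchange rate between arcmin and degrees is not otherwise
    constrained, so the relative geometry of the design is preserved without
    asserting an equivalence.
    """

    arcmin_per_unit: float = 8.0
    deg_per_unit: float = 0.25
    reference_amplitude: float = 0.25

    def __post_init__(self) -> None:
        if self.arcmin_per_unit <= 0 or self.deg_per_unit <= 0:
            raise ValueError("calibration scale factors must be strictly positive")

    def disparity_to_units(self, arcmin: float | np.ndarray) -> np.ndarray:
        return np.asarray(arcmin, dtype=float) / self.arcmin_per_unit

    def motion_to_units(self, deg: float | np.ndarray) -> np.ndarray:
        return np.asarray(deg, dtype=float) / self.deg_per_unit

    def units_to_arcmin(self, units: float | np.ndarray) -> np.ndarray:
        return np.asarray(units, dtype=float) * self.arcmin_per_unit


@dataclass(frozen=True)
class ObserverParams:
    """Internal-noise and readout parameters of a simulated observer.

    sigma_d, sigma_m
        SD of the Gaussian estimation noise of the disparity and motion
        channels, in normalized depth units, per interval.
    mechanism
        ``fusion`` or ``independence`` readout.
    lapse_rate
        Probability of a uniform random response, in [0, 0.1].
    """

    sigma_d: float
    sigma_m: float
    mechanism: Mechanism = Mechanism.FUSION
    lapse_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_d <= 0 or self.sigma_m <= 0:
            raise ValueError("channel noise SDs must be strictly positive")
        if not 0.0 <= self.lapse_rate <= 0.1:
            raise ValueError("lapse_rate must lie in [0, 0.1]")
        object.__setattr__(self, "mechanism", Mechanism(self.mechanism))

    @property
    def fusion_weights(self) -> np.ndarray:
        """Reliability weights (w_d, w_m); sum to 1."""
        vd, vm = self.sigma_d**2, self.sigma_m**2
        return np.array([vm, vd]) / (vd + vm)

    @property
    def sigma_fused(self) -> float:
        """SD of the fused estimate: 1/sigma_f^2 = 1/sigma_d^2 + 1/sigma_m^2."""
        return math.sqrt(
            (self.sigma_d**2 * self.sigma_m**2) / (self.sigma_d**2 + self.sigma_m**2)
        )


def _default_levels(calibration: CueCalibration) -> dict[Condition, np.ndarray]:
    disp = calibration.disparity_to_units(np.linspace(3.0, 13.0, 6))
    mot = calibration.motion_to_units(np.linspace(0.1, 0.4, 6))
    conflict = calibration.motion_to_units(np.linspace(0.6, 0.9, 6))
    return {
        Condition.D: disp,
        Condition.M: mot,
        Condition.DM: disp,
        Condition.D_CONFLICT_M: conflict,
    }


def _default_standards(calibration: CueCalibration) -> dict[Condition, float]:
    one_disp = float(calibration.disparity_to_units(8.0))
    one_mot = float(calibration.motion_to_units(0.25))
    conflict = float(calibration.motion_to_units(0.75))
    return {
        Condition.D: one_disp,
        Condition.M: one_mot,
        Condition.DM: one_disp,
        Condition.D_CONFLICT_M: conflict,
    }


@dataclass(frozen=True)
class SessionDesign:
    """Method-of-constant-stimuli session: 6 comparison levels x 15 trials
    per condition (90 trials/condition by default).

    Physical defaults mirror the behavioral task: disparity 3-13 arcmin
    (standard 8), motion 0.1-0.4 deg (standard 0.25), conflict condition
    standard 0.75 deg with 0.6-0.9 deg comparisons, all mapped through
    ``calibration`` onto the normalized depth axis.

    ``conflict_negates`` names the cue carrying the negated (in-front) depth
    in the conflict condition; the default follows the task description in
    which relative movement depicted the target in front of the plane.
    """

    calibration: CueCalibration = field(default_factory=CueCalibration)
    trials_per_level: int = 15
    levels: dict[Condition, np.ndarray] | None = None
    standards: dict[Condition, float] | None = None
    conflict_negates: str = "motion"

    def __post_init__(self) -> None:
        if self.conflict_negates not in ("motion", "disparity"):
            raise ValueError("conflict_negates must be 'motion' or 'disparity'")
        if self.trials_per_level < 1:
            raise ValueError("trials_per_level must be >= 1")
        if self.levels is None:
            object.__setattr__(self, "levels", _default_levels(self.calibration))
        if self.standards is None:
            object.__setattr__(self, "standards", _default_standards(self.calibration))

    def condition_levels(self, condition: Condition) -> np.ndarray:
        return np.asarray(self.levels[Condition(condition)], dtype=float)

    def standard(self, condition: Condition) -> float:
        return float(self.standards[Condition(condition)])

    def cue_direction(self, condition: Condition) -> np.ndarray:
        """Unit step in (disparity, motion) coordinates per unit of the
        condition's depth-magnitude axis."""
        condition = Condition(condition)
        if condition is Condition.D:
            return np.array([1.0, 0.0])
        if condition is Condition.M:
            return np.array([0.0, 1.0])
        if condition is Condition.DM:
            return np.array([1.0, 1.0])
        if self.conflict_negates == "motion":
            return np.array([1.0, -1.0])
        return np.array([-1.0, 1.0])


def make_stimulus_pair(
    condition: Condition,
    standard: float,
    comparison: float,
    design: SessionDesign,
) -> tuple[DepthStimulus, DepthStimulus]:
    """Build the two-interval stimulus pair for one trial.

    ``standard`` and ``comparison`` are positive depth magnitudes along the
    condition's axis; cue coordinates are set per condition (flat cue = 0 in
    D and M, negated cue per the design's conflict convention in DconflictM).
    """
    condition = Condition(condition)
    if standard <= 0 or comparison <= 0:
        raise ValueError("standard and comparison magnitudes must be positive")
    u = design.cue_direction(condition)
    s1 = u * standard
    s2 = u * comparison
    return (
        DepthStimulus(s1[0], s1[1], condition),
        DepthStimulus(s2[0], s2[1], condition),
    )


def _noisy_measurements(
    pair: tuple[DepthStimulus, DepthStimulus],
    observer: ObserverParams,
    noise_draws: np.ndarray,
) -> np.ndarray:
    """(2, 2) array of noisy channel measurements: rows = intervals,
    cols = (disparity, motion)."""
    draws = np.asarray(noise_draws, dtype=float).reshape(2, 2)
    sigmas = np.array([observer.sigma_d, observer.sigma_m])
    means = np.stack([pair[0].coords, pair[1].coords])
    return means + draws * sigmas


def decision_variable(
    observer: ObserverParams,
    pair: tuple[DepthStimulus, DepthStimulus],
    noise_draws: np.ndarray,
) -> float:
    """Signed decision variable for one two-interval trial.

    ``noise_draws`` is a (2, 2) array of standard-normal samples (interval x
    channel).  Positive values favor interval 2 as "further behind".

    Fusion: each interval's noisy (x_d, x_m) is projected onto the fixed
    reliability-weighted averaging direction (w_d, w_m); the decision variable
    is the interval difference of the fused estimates.

    Independence: each channel's interval difference is weighted by its true
    separation over its noise variance (the optimal per-channel linear
    readout, which realizes the quadratic-sum combination and ignores the
    relative depth sign of the cues).
    """
    x = _noisy_measurements(pair, observer, noise_draws)
    if observer.mechanism is Mechanism.FUSION:
        w = observer.fusion_weights
        return float(w @ (x[1] - x[0]))
    delta = pair[1].coords - pair[0].coords
    weights = delta / np.array([observer.sigma_d**2, observer.sigma_m**2])
    return float(weights @ (x[1] - x[0]))


TRIAL_COLUMNS = [
    "subject_id",
    "age_years",
    "condition",
    "standard_level",
    "comparison_level",
    "chose_comparison",
    "trial_index",
]


def simulate_session(
    observer: ObserverParams,
    design: SessionDesign,
    seed: int,
    subject_id: str = "sim",
    age_years: float = float("nan"),
    conditions: Sequence[Condition] = CONDITIONS,
    trials_per_level: int | None = None,
) -> pd.DataFrame:
    """Simulate a full constant-stimuli session; one row per 2AFC trial.

    For each condition, each of the 6 comparison levels is shown
    ``trials_per_level`` times against the condition standard.  On each trial
    the observer computes its decision variable from fresh Gaussian channel
    noise and chooses the interval judged further behind; ``lapse_rate``
    trials are answered uniformly at random instead.  Reproducible under a
    fixed seed.
    """
    rng = np.random.default_rng(seed)
    n_rep = design.trials_per_level if trials_per_level is None else trials_per_level
    sigmas = np.array([observer.sigma_d, observer.sigma_m])
    frames: list[pd.DataFrame] = []
    trial_index = 0
    for condition in conditions:
        condition = Condition(condition)
        standard = design.standard(condition)
        for level in design.condition_levels(condition):
            pair = make_stimulus_pair(condition, standard, float(level), design)
            sign = math.copysign(1.0, level - standard) if level != standard else 0.0
            # vectorized decision_variable over n_rep independent trials
            draws = rng.standard_normal((n_rep, 2, 2))
            x = np.stack([pair[0].coords, pair[1].coords]) + draws * sigmas
            diff = x[:, 1, :] - x[:, 0, :]
            if observer.mechanism is Mechanism.FUSION:
                dv = diff @ observer.fusion_weights
                chose = dv > 0.0
            else:
                delta = pair[1].coords - pair[0].coords
                dv = diff @ (delta / sigmas**2)
                if sign == 0.0:
                    chose = rng.random(n_rep) < 0.5
                else:
                    # the readout reports the signed judgment: dv > 0 means
                    # "comparison differs in its true direction"
                    chose = (dv > 0.0) if sign > 0 else (dv < 0.0)
            if observer.lapse_rate > 0.0:
                lapsed = rng.random(n_rep) < observer.lapse_rate
                chose = np.where(lapsed, rng.random(n_rep) < 0.5, chose)
            frames.append(
                pd.DataFrame(
                    {
                        "subject_id": subject_id,
                        "age_years": age_years,
                        "condition": condition.value,
                        "standard_level": standard,
                        "comparison_level": float(level),
                        "chose_comparison": np.asarray(chose, dtype=bool),
                        "trial_index": np.arange(trial_index, trial_index + n_rep),
                    }
                )
            )
            trial_index += n_rep
    return pd.concat(frames, ignore_index=True).loc[:, TRIAL_COLUMNS]


def analytic_sensitivity(
    observer: ObserverParams,
    condition: Condition,
    design: SessionDesign,
) -> float:
    """Closed-form psychometric sensitivity 1/sigma per normalized depth unit.

    Fusion: 1/sigma = |w . u_c| / (sigma_f * sqrt(2)), with u_c the
    condition's cue direction; the sqrt(2) reflects independent noise in the
    two intervals.  Independence: the quadratic sum of per-channel
    sensitivities, sqrt(sum_c u_c^2 / sigma_c^2) / sqrt(2), blind to cue sign.
    """
    condition = Condition(condition)
    u = design.cue_direction(condition)
    if observer.mechanism is Mechanism.FUSION:
        w = observer.fusion_weights
        return abs(float(w @ u)) / (observer.sigma_fused * math.sqrt(2.0))
    per_channel = u / np.array([observer.sigma_d, observer.sigma_m])
    return float(np.linalg.norm(per_channel)) / math.sqrt(2.0)


def write_trials(trials: pd.DataFrame, path) -> None:
    """Serialize a trial table to tab-separated text with the canonical header."""
    trials.loc[:, TRIAL_COLUMNS].to_csv(path, sep="\t", index=False)


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    df["chose_comparison"] = df["chose_comparison"].astype(bool)
    return df
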