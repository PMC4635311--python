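"""Synthetic block-design BOLD time series with known depth-encoding ground truth.

Each voxel responds through three latent channels — disparity depth, motion
depth, and a fused-depth channel — via per-voxel weight vectors.  With
``fused_gain = 0`` the voxel patterns carry only independent single-cue
signals, so downstream decoding obeys the quadratic-sum identity
(d'_DM = sqrt(d'_D^2 + d'_M^2) = d'_DconflictM in expectation); with
``fused_gain > 0`` an extra signal present only when the cues agree breaks
both identities in the fusion direction.  This gives the pattern-analysis
stage input with a switchable, known mechanism.

Hemodynamics are modeled as a pure two-volume (4 s) onset delay of the
block boxcar — the same shift the analysis applies — rather than a
convolution kernel.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .observer_models import CONDITIONS, Condition

__all__ = [
    "EncodingModel",
    "ScanDesign",
    "FmriDataset",
    "channel_signal",
    "generate_run",
    "generate_experiment",
    "HEMODYNAMIC_SHIFT",
]

HEMODYNAMIC_SHIFT = 2  # volumes (2 TRs = 4 s)

NEAR, FAR = -1, +1  # near = disparity in front of the surround


@dataclass(frozen=True)
class EncodingModel:
    """Per-voxel linear encoding of the three depth channels.

    ``fused_gain`` scales the fused channel: 0 reproduces the
    "younger-child" regime (no fusion signal), positive values the
    "older-child" regime.  Weights are in arbitrary BOLD-like response units
    per unit depth sign; ``noise_sd`` is i.i.d. Gaussian per voxel per
    volume.
    """

    w_disparity: np.ndarray
    w_motion: np.ndarray
    w_fused: np.ndarray
    fused_gain: float = 0.0
    noise_sd: float = 1.0
    baseline: np.ndarray | float = 100.0
    w_stimulus: np.ndarray | None = None

    def __post_init__(self) -> None:
        wd = np.asarray(self.w_disparity, dtype=float)
        wm = np.asarray(self.w_motion, dtype=float)
        wf = np.asarray(self.w_fused, dtype=float)
        if not (wd.shape == wm.shape == wf.shape) or wd.ndim != 1:
            raise ValueError("channel weight vectors must be 1-D and equal length")
        if self.fused_gain < 0:
            raise ValueError("fused_gain must be >= 0")
        object.__setattr__(self, "w_disparity", wd)
        object.__setattr__(self, "w_motion", wm)
        object.__setattr__(self, "w_fused", wf)
        ws = self.w_stimulus
        ws = np.zeros_like(wd) if ws is None else np.asarray(ws, dtype=float)
        if ws.shape != wd.shape:
            raise ValueError("w_stimulus must match the channel weight length")
        object.__setattr__(self, "w_stimulus", ws)

    @property
    def n_voxels(self) -> int:
        return self.w_disparity.shape[0]

    @property
    def weight_matrix(self) -> np.ndarray:
        """(n_voxels, 3) weights for (disparity, motion, fused)."""
        return np.column_stack([self.w_disparity, self.w_motion, self.w_fused])

    @classmethod
    def random(
        cls,
        n_voxels: int,
        seed: int,
        fused_gain: float = 0.0,
        noise_sd: float = 1.0,
        channel_gain_d: float = 1.0,
        channel_gain_m: float = 1.0,
        pure_fraction: float = 0.0,
        baseline: float = 100.0,
    ) -> "EncodingModel":
        """Draw zero-mean Gaussian channel weights (mixed selectivity).

        ``pure_fraction`` of voxels are made channel-pure: half keep only
        their disparity weight, half only their motion weight.  Each voxel
        also gets a nonnegative overall stimulus-response weight, larger for
        selective voxels, so that selection by the t contrast against
        baseline enriches informative voxels as it does for responsive
        gray matter.
        """
        rng = np.random.default_rng(seed)
        wd = rng.standard_normal(n_voxels) * channel_gain_d
        wm = rng.standard_normal(n_voxels) * channel_gain_m
        wf = rng.standard_normal(n_voxels)
        n_pure = int(round(pure_fraction * n_voxels))
        if n_pure:
            pure = rng.choice(n_voxels, size=n_pure, replace=False)
            half = n_pure // 2
            wm[pure[:half]] = 0.0
            wd[pure[half:]] = 0.0
        ws = 0.5 * (np.abs(wd) + np.abs(wm)) + np.abs(rng.normal(0.0, 0.5, n_voxels))
        return cls(
            w_disparity=wd,
            w_motion=wm,
            w_fused=wf,
            fused_gain=fused_gain,
            noise_sd=noise_sd,
            baseline=baseline,
            w_stimulus=ws,
        )


@dataclass(frozen=True)
class ScanDesign:
    """Block-design scan parameters.

    Defaults mirror the scan protocol: TR 2 s, 8-volume (16 s) blocks of
    eight 1 s stimulus + 1 s fixation presentations, 3 blocks per
    condition x depth sign per run, 6 runs, 16 s fixation baseline at the
    start and end of each run.  Run length follows from the block
    arithmetic: blocks_per_run * 8 + 16 volumes.
    """

    tr_seconds: float = 2.0
    volumes_per_block: int = 8
    blocks_per_condition_per_run: int = 3  # per depth sign
    n_runs: int = 6
    baseline_volumes: int = 8  # at start and at end
    conditions: tuple[Condition, ...] = CONDITIONS

    @property
    def n_configurations(self) -> int:
        return 2 * len(self.conditions)  # condition x depth sign

    @property
    def blocks_per_run(self) -> int:
        return self.n_configurations * self.blocks_per_condition_per_run

    @property
    def volumes_per_run(self) -> int:
        return self.blocks_per_run * self.volumes_per_block + 2 * self.baseline_volumes


@dataclass
class FmriDataset:
    """Labeled multi-run voxel time series.

    ``runs``: list of (n_voxels, n_volumes) arrays.  ``block_table``: one
    row per block with run, onset_volume (block onset before the
    hemodynamic shift), condition, depth (near|far).  ``voxel_grid``:
    (n_voxels, 3) integer coordinates for searchlight neighborhoods.
    """

    runs: list[np.ndarray]
    block_table: pd.DataFrame
    voxel_grid: np.ndarray
    design: ScanDesign

    @property
    def n_voxels(self) -> int:
        return self.runs[0].shape[0]

    def validate(self) -> None:
        for r, run in enumerate(self.runs):
            tab = self.block_table[self.block_table["run"] == r]
            last = tab["onset_volume"].max() + self.design.volumes_per_block
            if last > run.shape[1]:
                raise ValueError(f"run {r}: block window exceeds run length")

    def write(self, directory: str | Path, prefix: str = "run") -> None:
        """Write one 4-D NIfTI per run plus a TSV block-table sidecar."""
        import nibabel as nib

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        shape = tuple(self.voxel_grid.max(axis=0) + 1)
        for r, run in enumerate(self.runs):
            vol = np.zeros(shape + (run.shape[1],), dtype=np.float32)
            ix, iy, iz = self.voxel_grid.T
            vol[ix, iy, iz, :] = run
            img = nib.Nifti1Image(vol, affine=np.eye(4))
            img.header["pixdim"][4] = self.design.tr_seconds
            nib.save(img, directory / f"{prefix}_{r:02d}.nii")
        self.block_table.to_csv(directory / f"{prefix}_blocks.tsv", sep="\t", index=False)


def channel_signal(condition: Condition, depth_sign: int, fused_gain: float) -> np.ndarray:
    """Latent (disparity, motion, fused) channel activations for one block.

    The informative cue carries ``depth_sign`` (+1 far, -1 near), a flat cue
    carries 0, and the conflict condition negates the motion channel.  The
    fused channel responds to the mean of the two cue activations scaled by
    ``fused_gain`` — full strength for consistent cues, half for single
    cues, zero under conflict.
    """
    condition = Condition(condition)
    if depth_sign not in (NEAR, FAR):
        raise ValueError("depth_sign must be +1 (far) or -1 (near)")
    if condition is Condition.D:
        c_d, c_m = depth_sign, 0
    elif condition is Condition.M:
        c_d, c_m = 0, depth_sign
    elif condition is Condition.DM:
        c_d, c_m = depth_sign, depth_sign
    else:  # conflict: disparity carries the depth sign, motion the opposite
        c_d, c_m = depth_sign, -depth_sign
    return np.array([c_d, c_m, fused_gain * (c_d + c_m) / 2.0])


def _run_block_order(design: ScanDesign, rng: np.random.Generator) -> list[tuple[Condition, int]]:
    configs = [
        (cond, sign)
        for cond in design.conditions
        for sign in (NEAR, FAR)
        for _ in range(design.blocks_per_condition_per_run)
    ]
    order = rng.permutation(len(configs))
    return [configs[i] for i in order]


def generate_run(
    model: EncodingModel,
    design: ScanDesign,
    run_index: int,
    seed: int,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Simulate one run: (n_voxels, volumes_per_run) signal + block labels.

    Signal per volume = baseline + W @ channel_signal during the block's
    volumes (shifted forward by the 2-volume hemodynamic delay) + Gaussian
    noise.  The returned onsets are pre-shift block onsets, as an acquisition
    log would record them.
    """
    rng = np.random.default_rng(seed)
    order = _run_block_order(design, rng)
    n_vol = design.volumes_per_run
    signal = np.zeros((model.n_voxels, n_vol))
    signal += np.reshape(np.asarray(model.baseline, dtype=float), (-1, 1))

    records = []
    W = model.weight_matrix
    for b, (cond, sign) in enumerate(order):
        onset = design.baseline_volumes + b * design.volumes_per_block
        ch = channel_signal(cond, sign, model.fused_gain)
        start = onset + HEMODYNAMIC_SHIFT
        stop = min(start + design.volumes_per_block, n_vol)
        signal[:, start:stop] += (W @ ch + model.w_stimulus)[:, None]
        records.append(
            {
                "run": run_index,
                "block": b,
                "onset_volume": onset,
                "condition": Condition(cond).value,
                "depth": "far" if sign == FAR else "near",
            }
        )
    if model.noise_sd > 0:
        signal += rng.normal(0.0, model.noise_sd, size=signal.shape)
    return signal, pd.DataFrame(records)


def _compact_grid(n_voxels: int) -> np.ndarray:
    """Fill a near-cubic 3-D lattice with n_voxels points."""
    side = int(np.ceil(n_voxels ** (1.0 / 3.0)))
    coords = np.array(
        [(x, y, z) for x in range(side) for y in range(side) for z in range(side)][:n_voxels],
        dtype=int,
    )
    return coords


def generate_experiment(
    model: EncodingModel,
    design: ScanDesign,
    seed: int,
) -> FmriDataset:
    """Simulate a full session: ``design.n_runs`` runs with independently
    permuted block orders, a complete block table, and a compact 3-D voxel
    lattice for searchlight analysis."""
    root = np.random.default_rng(seed)
    run_seeds = root.integers(0, 2**31 - 1, size=design.n_runs)
    runs, tables = [], []
    for r in range(design.n_runs):
        sig, tab = generate_run(model, design, r, int(run_seeds[r]))
        runs.append(sig)
        tables.append(tab)
    dataset = FmriDataset(
        runs=runs,
        block_table=pd.concat(tables, ignore_index=True),
        voxel_grid=_compact_grid(model.n_voxels),
        design=design,
    )
    dataset.validate()
    return dataset
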