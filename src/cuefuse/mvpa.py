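"""Multivoxel pattern analysis: near/far depth decoding per cue condition.

The pipeline mirrors a standard block-design decoding analysis: select the
most stimulus-responsive voxels by a t contrast against the fixation
baseline, z-score each voxel's time course within run, shift block windows
by two TRs (4 s) for the hemodynamic delay, average the eight volumes of
each block into one pattern, mean-center each pattern across voxels, then
classify near vs far with a linear support vector machine (C = 1) under
leave-one-run-out cross-validation (15 + 15 training patterns, 3 + 3 test
patterns per fold with the default six-run design).  Accuracies convert to
d' via d' = 2 * erfinv(2 * accuracy - 1); chance and significance come from
a label-shuffling permutation null.  Fusion is diagnosed at the decoding
level with the same two criteria as in behavior:

    index1 = d'_DM - d'_DconflictM
    index2 = d'_DM - sqrt(d'_D^2 + d'_M^2)

A volumetric searchlight repeats the whole per-condition decoding in a
spherical neighborhood around every voxel, mapping both indices.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import erfinv
from sklearn.svm import SVC

from .observer_models import CONDITIONS, Condition
from .synthetic_fmri import HEMODYNAMIC_SHIFT, FmriDataset

__all__ = [
    "BlockPatterns",
    "DecodingResult",
    "PermutationNull",
    "SearchlightMap",
    "compute_tmap",
    "select_voxels",
    "preprocess_run",
    "extract_block_patterns",
    "decode_condition",
    "accuracy_to_dprime",
    "permutation_null",
    "decoding_integration_indices",
    "searchlight_map",
    "mm_to_voxel_radius",
]


@dataclass
class BlockPatterns:
    """One activation pattern per block.

    ``X``: (n_blocks, n_voxels) z-unit, mean-centered patterns;
    ``meta``: per-block run / block / condition / depth labels, row-aligned
    with ``X``.
    """

    X: np.ndarray
    meta: pd.DataFrame

    def for_condition(self, condition: Condition) -> "BlockPatterns":
        mask = (self.meta["condition"] == Condition(condition).value).to_numpy()
        return BlockPatterns(self.X[mask], self.meta[mask].reset_index(drop=True))

    def select(self, voxel_indices: np.ndarray) -> "BlockPatterns":
        return BlockPatterns(self.X[:, voxel_indices], self.meta)


@dataclass(frozen=True)
class DecodingResult:
    condition: str
    accuracy: float
    dprime: float
    fold_accuracies: tuple[float, ...]
    n_train: int
    n_test: int


@dataclass(frozen=True)
class PermutationNull:
    n_permutations: int
    null_accuracies: np.ndarray
    upper_bound_97_5: float


@dataclass(frozen=True)
class SearchlightMap:
    index1: np.ndarray  # per-voxel, NaN outside mask
    index2: np.ndarray
    dprimes: dict[str, np.ndarray]
    radius_voxels: float
    mask: np.ndarray  # boolean, per voxel


def _shifted_window(onset: int, volumes_per_block: int) -> slice:
    start = onset + HEMODYNAMIC_SHIFT
    return slice(start, start + volumes_per_block)


def compute_tmap(dataset: FmriDataset) -> np.ndarray:
    """Per-voxel two-sample t: all (shifted) block volumes vs baseline volumes.

    Volumes covered by no shifted block window count as baseline; both
    groups pool across runs.  Zero-variance voxels get t = 0 with a warning.
    """
    design = dataset.design
    stim_chunks, base_chunks = [], []
    for r, run in enumerate(dataset.runs):
        in_block = np.zeros(run.shape[1], dtype=bool)
        tab = dataset.block_table[dataset.block_table["run"] == r]
        for onset in tab["onset_volume"]:
            win = _shifted_window(int(onset), design.volumes_per_block)
            in_block[win] = True
        stim_chunks.append(run[:, in_block])
        base_chunks.append(run[:, ~in_block])
    stim = np.concatenate(stim_chunks, axis=1)
    base = np.concatenate(base_chunks, axis=1)

    n1, n2 = stim.shape[1], base.shape[1]
    m1, m2 = stim.mean(axis=1), base.mean(axis=1)
    v1, v2 = stim.var(axis=1, ddof=1), base.var(axis=1, ddof=1)
    pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    denom = np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    t = np.zeros(dataset.n_voxels)
    ok = denom > 0
    if not ok.all():
        warnings.warn(f"{int((~ok).sum())} zero-variance voxels; t set to 0", stacklevel=2)
    t[ok] = (m1 - m2)[ok] / denom[ok]
    return t


def select_voxels(tmap: np.ndarray, n: int = 400) -> np.ndarray:
    """Indices of the ``n`` largest t values (the most stimulus-responsive
    voxels); ties broken by ascending voxel index."""
    if n < 1:
        raise ValueError("n must be >= 1")
    tmap = np.asarray(tmap)
    if n >= tmap.shape[0]:
        if n > tmap.shape[0]:
            warnings.warn(
                f"requested {n} voxels but only {tmap.shape[0]} exist; returning all",
                stacklevel=2,
            )
        return np.arange(tmap.shape[0])
    order = np.argsort(-tmap, kind="stable")
    return np.sort(order[:n])


def preprocess_run(run: np.ndarray) -> np.ndarray:
    """Z-score each voxel's time course within the run.

    Zero-SD voxels become all zeros (flagged with a warning).
    """
    run = np.asarray(run, dtype=float)
    if run.shape[1] < 3:
        raise ValueError("run must have >= 3 volumes")
    mean = run.mean(axis=1, keepdims=True)
    sd = run.std(axis=1, ddof=0, keepdims=True)
    flat = sd[:, 0] == 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} constant voxels zeroed in z-scoring", stacklevel=2)
    sd[flat] = 1.0
    z = (run - mean) / sd
    z[flat] = 0.0
    return z


def extract_block_patterns(
    dataset: FmriDataset,
    voxel_indices: np.ndarray | None = None,
) -> BlockPatterns:
    """Z-score runs, average each block's 8 shifted volumes, mean-center.

    One pattern per block: the mean of its ``volumes_per_block`` volumes
    read from onset + 2, minus the pattern's mean across voxels.
    """
    design = dataset.design
    zruns = [preprocess_run(run) for run in dataset.runs]
    rows, metas = [], []
    for rec in dataset.block_table.itertuples(index=False):
        z = zruns[rec.run]
        win = _shifted_window(int(rec.onset_volume), design.volumes_per_block)
        if win.stop > z.shape[1]:
            raise ValueError(
                f"block {rec.block} in run {rec.run}: shifted window exceeds run end"
            )
        pattern = z[:, win].mean(axis=1)
        if voxel_indices is not None:
            pattern = pattern[voxel_indices]
        rows.append(pattern - pattern.mean())
        metas.append(
            {"run": rec.run, "block": rec.block, "condition": rec.condition,
             "depth": rec.depth}
        )
    return BlockPatterns(np.vstack(rows), pd.DataFrame(metas))


def accuracy_to_dprime(accuracy: float, clip: float = 1.0 / 72.0) -> float:
    """d' = 2 * erfinv(2 * accuracy - 1), with accuracy clipped to
    [clip, 1 - clip] so the finite-trial ceiling maps to a finite d'.

    The default clip 1/(2*36) corresponds to half a test trial out of the
    36 test patterns of the six-fold design.
    """
    if not 0.0 <= accuracy <= 1.0:
        raise ValueError("accuracy must lie in [0, 1]")
    a = min(max(accuracy, clip), 1.0 - clip)
    return float(2.0 * erfinv(2.0 * a - 1.0))


def _fold_labels(meta: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    y = (meta["depth"] == "far").to_numpy().astype(int)
    runs = meta["run"].to_numpy()
    return y, runs


def decode_condition(
    patterns: BlockPatterns,
    labels: np.ndarray | None = None,
    C: float = 1.0,
) -> DecodingResult:
    """Leave-one-run-out linear-SVM decoding of near vs far for one condition.

    Each of the runs serves once as the test set; with the default design
    that is 15 + 15 training and 3 + 3 test patterns per fold.  ``labels``
    overrides the near/far labels (used by the permutation null).
    """
    y, runs = _fold_labels(patterns.meta)
    if labels is not None:
        y = np.asarray(labels, dtype=int)
    run_ids = np.unique(runs)
    if len(run_ids) < 2:
        raise ValueError("need >= 2 runs for leave-one-run-out cross-validation")
    for r in run_ids:
        counts = np.bincount(y[runs == r], minlength=2)
        if counts[0] != counts[1]:
            raise ValueError(f"run {r}: unbalanced near/far labels {counts.tolist()}")

    fold_acc = []
    n_train = n_test = 0
    for r in run_ids:
        train, test = runs != r, runs == r
        clf = SVC(kernel="linear", C=C)
        clf.fit(patterns.X[train], y[train])
        fold_acc.append(float(clf.score(patterns.X[test], y[test])))
        n_train, n_test = int(train.sum()), int(test.sum())
    accuracy = float(np.mean(fold_acc))
    total_test = n_test * len(run_ids)
    cond = patterns.meta["condition"].iloc[0] if len(patterns.meta) else ""
    return DecodingResult(
        condition=str(cond),
        accuracy=accuracy,
        dprime=accuracy_to_dprime(accuracy, clip=1.0 / (2.0 * total_test)),
        fold_accuracies=tuple(fold_acc),
        n_train=n_train,
        n_test=n_test,
    )


def _shuffle_within_run(y: np.ndarray, runs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = y.copy()
    for r in np.unique(runs):
        idx = np.flatnonzero(runs == r)
        out[idx] = y[idx][rng.permutation(len(idx))]
    return out


def permutation_null(
    patterns: BlockPatterns,
    n_perm: int = 1000,
    seed: int = 0,
    C: float = 1.0,
) -> PermutationNull:
    """Empirical chance distribution: re-decode with near/far labels shuffled
    within run, ``n_perm`` times; the 97.5th percentile is the significance
    bound."""
    y, runs = _fold_labels(patterns.meta)
    rng = np.random.default_rng(seed)
    accs = np.empty(n_perm)
    for i in range(n_perm):
        perm = _shuffle_within_run(y, runs, rng)
        accs[i] = decode_condition(patterns, labels=perm, C=C).accuracy
    return PermutationNull(
        n_permutations=n_perm,
        null_accuracies=accs,
        upper_bound_97_5=float(np.percentile(accs, 97.5)),
    )


def decode_all_conditions(
    patterns: BlockPatterns,
    conditions: tuple[Condition, ...] = CONDITIONS,
    C: float = 1.0,
) -> dict[str, DecodingResult]:
    return {
        Condition(c).value: decode_condition(patterns.for_condition(c), C=C)
        for c in conditions
    }


def decoding_integration_indices(results: dict[str, DecodingResult]) -> tuple[float, float]:
    """Both fusion criteria in d' units from the four condition decodings."""
    missing = {c.value for c in CONDITIONS} - set(results)
    if missing:
        raise ValueError(f"missing decoded conditions: {sorted(missing)}")
    d = {k: v.dprime for k, v in results.items()}
    index1 = d[Condition.DM.value] - d[Condition.D_CONFLICT_M.value]
    index2 = d[Condition.DM.value] - math.hypot(d[Condition.D.value], d[Condition.M.value])
    return index1, index2


def mm_to_voxel_radius(radius_mm: float, voxel_size_mm: float = 2.3) -> int:
    """Convert a searchlight radius in mm to whole voxels (floor, min 1)."""
    return max(1, int(radius_mm / voxel_size_mm))


def searchlight_map(
    dataset: FmriDataset,
    radius_voxels: float = 3.0,
    smooth_fwhm_voxels: float = 0.0,
    C: float = 1.0,
) -> SearchlightMap:
    """Spherical-searchlight map of both decoding integration indices.

    For every voxel, the per-condition near/far decoding runs on the voxels
    within ``radius_voxels`` (Euclidean, on the integer voxel grid); both
    indices are stored at the center voxel.  Neighborhoods with fewer than
    two voxels are masked out.  ``smooth_fwhm_voxels`` > 0 applies Gaussian
    smoothing to the finished maps (NaN-aware), mirroring the 3-mm FWHM map
    smoothing used before group statistics.
    """
    if radius_voxels < 1:
        raise ValueError("radius_voxels must be >= 1")
    grid = dataset.voxel_grid
    patterns = extract_block_patterns(dataset)
    n_vox = grid.shape[0]
    index1 = np.full(n_vox, np.nan)
    index2 = np.full(n_vox, np.nan)
    dprimes = {c.value: np.full(n_vox, np.nan) for c in CONDITIONS}
    mask = np.zeros(n_vox, dtype=bool)

    for v in range(n_vox):
        dist2 = ((grid - grid[v]) ** 2).sum(axis=1)
        neigh = np.flatnonzero(dist2 <= radius_voxels**2)
        if len(neigh) < 2:
            continue
        local = patterns.select(neigh)
        results = decode_all_conditions(local, C=C)
        i1, i2 = decoding_integration_indices(results)
        index1[v], index2[v] = i1, i2
        for k, res in results.items():
            dprimes[k][v] = res.dprime
        mask[v] = True

    if smooth_fwhm_voxels > 0:
        sigma = smooth_fwhm_voxels / (2.0 * math.sqrt(2.0 * math.log(2.0)))
        index1 = _smooth_on_grid(index1, grid, sigma)
        index2 = _smooth_on_grid(index2, grid, sigma)
    return SearchlightMap(
        index1=index1,
        index2=index2,
        dprimes=dprimes,
        radius_voxels=radius_voxels,
        mask=mask,
    )


def _smooth_on_grid(values: np.ndarray, grid: np.ndarray, sigma: float) -> np.ndarray:
    """NaN-aware Gaussian smoothing of per-voxel values on their 3-D lattice."""
    shape = tuple(grid.max(axis=0) + 1)
    vol = np.full(shape, np.nan)
    ix, iy, iz = grid.T
    vol[ix, iy, iz] = values
    ok = ~np.isnan(vol)
    filled = np.where(ok, vol, 0.0)
    num = ndimage.gaussian_filter(filled, sigma)
    den = ndimage.gaussian_filter(ok.astype(float), sigma)
    with np.errstate(invalid="ignore", divide="ignore"):
        sm = num / den
    sm[~ok] = np.nan
    return sm[ix, iy, iz]
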