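"""Voxel-wise discriminative maps from weight ensembles.

The classifier's weight vector assigns one coefficient per masked voxel.
Refitting on the full anchor dataset across repeated CV partitions gives an
ensemble of weight vectors; the per-voxel ratio of their mean to their
standard deviation (the stability ratio) localizes the voxels that drive
the discrimination consistently, and is written back into masked 3-D volume
space for inspection. Sign convention: with labels CN = 0 / AD = 1 and
atrophy coded as lower intensity, voxels whose atrophy predicts AD carry
negative weights; signs are recorded, interpretation is left to the caller.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .linear_model import _validate_labels, _values
from .model_selection import SearchGrid, _rep_seed_sequence, select_and_fit_full

__all__ = [
    "TissueMask",
    "WeightEnsemble",
    "DiscriminativeMap",
    "weight_ensemble",
    "stability_ratio",
    "to_volume",
    "vectorize_volume",
    "masks_disjoint",
]

SENTINEL_CAP = 1e6  # signed cap replacing mean/0 ratios (SD = 0, mean != 0)


@dataclass(frozen=True)
class TissueMask:
    """Boolean voxel mask with its voxel-to-world affine."""

    flags: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        flags = np.asarray(self.flags, dtype=bool)
        if flags.ndim != 3:
            raise ValueError("mask flags must be a 3-D boolean grid")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        object.__setattr__(self, "flags", flags)
        object.__setattr__(self, "affine", affine)

    @property
    def shape(self) -> tuple:
        return self.flags.shape

    @property
    def voxel_count(self) -> int:
        return int(self.flags.sum())

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def scan_indices(self):
        """Masked voxel coordinates in scan order (fastest-varying first axis)."""
        flat = np.flatnonzero(self.flags.ravel(order="F"))
        return np.unravel_index(flat, self.shape, order="F")


def masks_disjoint(masks: Sequence[TissueMask]) -> bool:
    """True iff no voxel belongs to more than one of the given masks."""
    total = np.zeros(masks[0].shape, dtype=int)
    for m in masks:
        if m.shape != masks[0].shape:
            raise ValueError("masks live on different grids")
        total += m.flags.astype(int)
    return bool(np.all(total <= 1))


@dataclass
class WeightEnsemble:
    """Repetitions x p coefficient matrix from full-data refits."""

    coefficients: np.ndarray
    intercepts: np.ndarray
    pairs: tuple
    seed: int

    @property
    def n_repetitions(self) -> int:
        return self.coefficients.shape[0]


@dataclass
class DiscriminativeMap:
    """Per-masked-voxel mean/SD weight stability ratio."""

    ratio: np.ndarray
    n_repetitions: int
    sentinel_mask: np.ndarray
    sentinel_cap: float = SENTINEL_CAP
    mask: Optional[TissueMask] = None
    sign_convention: str = "negative_weights_load_on_class_1_atrophy"


def weight_ensemble(
    X,
    y,
    repetitions: int,
    grid: Optional[SearchGrid] = None,
    seed: int = 0,
    K2: int = 10,
    tol: float = 1e-7,
) -> WeightEnsemble:
    """One full-anchor-data fit per repetition, regularization re-selected
    per repetition's CV partition; rows are coefficients on the original
    feature scale."""
    if grid is None:
        grid = SearchGrid()
    Xv = _values(X)
    y = _validate_labels(y)
    coefs = np.empty((repetitions, Xv.shape[1]))
    intercepts = np.empty(repetitions)
    pairs = []
    for rep in range(repetitions):
        seed_r = int(_rep_seed_sequence(seed, rep).generate_state(1)[0] % (2**31))
        try:
            pair, model = select_and_fit_full(Xv, y, grid, K2=K2, seed=seed_r, tol=tol)
        except Exception as err:
            raise RuntimeError(f"weight-ensemble fit failed at repetition {rep}") from err
        coefs[rep] = model.coefficients
        intercepts[rep] = model.intercept
        pairs.append(pair)
    return WeightEnsemble(coefs, intercepts, tuple(pairs), int(seed))


def stability_ratio(ensemble: WeightEnsemble, mask: Optional[TissueMask] = None) -> DiscriminativeMap:
    """Per-voxel mean weight divided by its SD across repetitions (ddof=1).

    Voxels with SD = 0 and mean = 0 map to ratio 0; SD = 0 with a nonzero
    mean maps to the signed sentinel cap and is flagged. A single-repetition
    ensemble has a degenerate SD everywhere and follows the same rules.
    """
    W = np.asarray(ensemble.coefficients, dtype=float)
    if W.size == 0:
        raise ValueError("empty weight ensemble")
    R = W.shape[0]
    mean = W.mean(axis=0)
    sd = W.std(axis=0, ddof=1) if R >= 2 else np.zeros(W.shape[1])
    ratio = np.zeros_like(mean)
    ok = sd > 0
    ratio[ok] = mean[ok] / sd[ok]
    sentinel = (~ok) & (mean != 0)
    ratio[sentinel] = np.sign(mean[sentinel]) * SENTINEL_CAP
    return DiscriminativeMap(
        ratio=ratio,
        n_repetitions=R,
        sentinel_mask=sentinel,
        mask=mask,
    )


def _map_values(m) -> np.ndarray:
    return m.ratio if isinstance(m, DiscriminativeMap) else np.asarray(m, dtype=float)


def to_volume(dmap, mask: TissueMask) -> np.ndarray:
    """Write masked-voxel values back into a 3-D volume (zeros outside).

    Values fill masked voxels in the fixed scan order (fastest-varying first
    axis), the exact inverse of ``vectorize_volume``.
    """
    values = _map_values(dmap)
    if values.shape[0] != mask.voxel_count:
        raise ValueError(
            f"map length {values.shape[0]} does not match mask voxel_count {mask.voxel_count}"
        )
    vol = np.zeros(mask.shape, dtype=float)
    vol[mask.scan_indices()] = values
    return vol


def vectorize_volume(volume: np.ndarray, mask: TissueMask) -> np.ndarray:
    """Masked voxels of one volume in scan order (inverse of to_volume)."""
    volume = np.asarray(volume)
    if volume.shape != mask.shape:
        raise ValueError("volume shape does not match the mask")
    return volume[mask.scan_indices()]
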