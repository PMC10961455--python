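"""Seed-based connectivity matrices via the multi-seed-region approach.

For every atlas region a small seed patch is placed at its centre of
mass; the seed-patch mean time course is correlated with every in-brain
voxel, the correlation map is thresholded with the Benjamini-Yekutieli
FDR (valid under the strong spatial dependence of voxel maps), and the
mean surviving r per target region becomes one row of an asymmetric
region x region matrix.  Matrices are Fisher z-transformed with negative
correlations zeroed, and averaged across sessions into juvenile (3-5
months) and adult (6-8 months) group matrices.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats as _st

from .io import Volume
from .stats_core import fdr_adjust

__all__ = [
    "ConnectivityMatrix",
    "define_seeds",
    "seed_correlation_map",
    "by_fdr_mask",
    "build_connectivity_matrix",
    "to_fisher_z",
    "average_matrices",
]

#: Fisher z clip bound: atanh of the largest admissible |r|
R_CLIP = 0.999999


@dataclasses.dataclass
class ConnectivityMatrix:
    """Region x region connectivity weights.

    Row = seed region, column = target region (asymmetric at
    construction).  ``kind`` flags r- or z-valued entries; z-valued
    matrices are non-negative.  The diagonal is excluded (stored as 0).
    """

    values: np.ndarray
    region_ids: np.ndarray
    kind: str = "r"  # "r" | "z"
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.region_ids = np.asarray(self.region_ids)
        n = self.region_ids.size
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match region ids")
        if self.kind not in ("r", "z"):
            raise ValueError(f"kind must be 'r' or 'z', got {self.kind!r}")


def define_seeds(atlas: Volume) -> dict[int, np.ndarray]:
    """Seed patch per region: centre-of-mass voxel plus its in-label
    6-neighbours.

    A centroid falling outside its (concave) label is moved to the
    nearest in-label voxel by Euclidean distance, ties broken by lowest
    linear index.  Returns {region_id: (n_voxels, 3) int array}.
    """
    labels = np.asarray(atlas.data)
    seeds: dict[int, np.ndarray] = {}
    for rid in np.unique(labels):
        if rid == 0:
            continue
        coords = np.argwhere(labels == rid)
        if coords.size == 0:
            raise ValueError(f"region {rid} is empty")
        com = coords.mean(axis=0)
        centre = np.floor(com + 0.5).astype(int)
        if labels[tuple(centre)] != rid:
            d2 = ((coords - com) ** 2).sum(axis=1)
            # argmin on stable-sorted coords (raster order) breaks ties by
            # lowest linear index
            centre = coords[int(np.argmin(d2))]
        patch = [centre]
        for axis in range(3):
            for step in (-1, 1):
                nb = centre.copy()
                nb[axis] += step
                if np.all(nb >= 0) and np.all(nb < labels.shape) and labels[tuple(nb)] == rid:
                    patch.append(nb)
        seeds[int(rid)] = np.array(patch)
    return seeds


def _standardize(ts: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-norm rows; zero-variance rows become all-NaN."""
    ts = ts - ts.mean(axis=-1, keepdims=True)
    norm = np.linalg.norm(ts, axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(norm > 0, ts / norm, np.nan)


def seed_correlation_map(
    series: Volume, seed_patch: np.ndarray, brain_mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r (and two-sided p) between the seed-patch mean course and
    every in-mask voxel.

    p comes from t = r sqrt((n-2)/(1-r^2)) with n time points.  Zero
    variance voxels (or seed) yield NaN and are excluded from any
    downstream FDR.  Returns 3-D r and p maps (NaN outside the mask).
    """
    data = np.asarray(series.data, dtype=float)
    if data.ndim != 4 or data.shape[3] < 3:
        raise ValueError("need a 4-D series with >= 3 time points")
    if len(seed_patch) == 0:
        raise ValueError("empty seed patch")
    mask = np.asarray(brain_mask, dtype=bool)
    seed_course = data[tuple(np.asarray(seed_patch).T)].mean(axis=0)
    z_seed = _standardize(seed_course[None, :])[0]
    vox = _standardize(data[mask])
    r = vox @ z_seed
    n = data.shape[3]
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / np.clip(1.0 - r**2, 1e-300, None))
    p = 2.0 * _st.t.sf(np.abs(t), n - 2)
    r_map = np.full(data.shape[:3], np.nan)
    p_map = np.full(data.shape[:3], np.nan)
    r_map[mask] = r
    p_map[mask] = p
    return r_map, p_map


def by_fdr_mask(p_values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Yekutieli step-up rejection mask over finite p-values.

    NaN entries (excluded voxels) are never rejected.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value input")
    finite = np.isfinite(p)
    out = np.zeros(p.shape, dtype=bool)
    if finite.any():
        out[finite] = fdr_adjust(p[finite], method="BY", q=q).rejected
    return out


def build_connectivity_matrix(
    series: Volume,
    atlas: Volume,
    region_table: pd.DataFrame,
    q: float = 0.05,
    brain_mask: np.ndarray | None = None,
    meta: dict | None = None,
) -> ConnectivityMatrix:
    """Asymmetric r-valued region x region matrix.

    Entry (i, j) is the mean r over the voxels of region j that survive
    the BY-FDR mask (at ``q``) of seed i's correlation map; 0 when no
    voxel survives.  The diagonal is excluded.
    """
    labels = np.asarray(atlas.data)
    if brain_mask is None:
        brain_mask = labels > 0
    ids = region_table["region_id"].to_numpy()
    n = ids.size
    seeds = define_seeds(atlas)
    data = np.asarray(series.data, dtype=float)
    n_t = data.shape[3]

    mask = np.asarray(brain_mask, dtype=bool)
    vox = _standardize(data[mask])  # (V, T), NaN rows for flat voxels
    vox_labels = labels[mask]
    seed_courses = np.stack(
        [data[tuple(seeds[int(r)].T)].mean(axis=0) for r in ids]
    )
    z_seeds = _standardize(seed_courses)  # (n, T)
    r_all = vox @ z_seeds.T  # (V, n) correlation of every voxel with every seed
    with np.errstate(invalid="ignore", divide="ignore"):
        t_all = r_all * np.sqrt((n_t - 2) / np.clip(1.0 - r_all**2, 1e-300, None))
    p_all = 2.0 * _st.t.sf(np.abs(t_all), n_t - 2)

    matrix = np.zeros((n, n))
    for i in range(n):
        surviving = by_fdr_mask(p_all[:, i], q=q)
        for j, rid in enumerate(ids):
            if j == i:
                continue
            sel = surviving & (vox_labels == rid)
            if sel.any():
                matrix[i, j] = float(np.nanmean(r_all[sel, i]))
    return ConnectivityMatrix(
        matrix, ids, kind="r",
        meta={"q": q, "n_timepoints": n_t, **(meta or {})},
    )


def to_fisher_z(matrix: ConnectivityMatrix) -> ConnectivityMatrix:
    """Fisher z transform keeping only positive correlations.

    z = atanh(r) for r > 0; entries with r <= 0 become 0.  |r| at 1 is
    clipped to atanh(0.999999) with a warning.
    """
    if matrix.kind != "r":
        raise ValueError("input must be r-valued")
    r = matrix.values.copy()
    if np.any(np.abs(r) >= 1.0):
        import warnings

        warnings.warn("|r| = 1 encountered; clipping to 0.999999 before atanh")
        r = np.clip(r, -R_CLIP, R_CLIP)
    z = np.where(r > 0.0, np.arctanh(np.clip(r, 0.0, R_CLIP)), 0.0)
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(z, matrix.region_ids, kind="z", meta=dict(matrix.meta))


def average_matrices(
    matrices: list[ConnectivityMatrix], group_label: str | None = None
) -> ConnectivityMatrix:
    """Element-wise mean of same-shape matrices (e.g. the session
    averages forming the juvenile and adult group matrices)."""
    if not matrices:
        raise ValueError("nothing to average")
    first = matrices[0]
    for m in matrices[1:]:
        if m.values.shape != first.values.shape or not np.array_equal(
            m.region_ids, first.region_ids
        ):
            raise ValueError("matrices differ in shape or region ordering")
        if m.kind != first.kind:
            raise ValueError("cannot average r- with z-valued matrices")
    mean = np.mean([m.values for m in matrices], axis=0)
    meta = {
        "n_averaged": len(matrices),
        "sessions": sorted({m.meta.get("session") for m in matrices if "session" in m.meta}),
    }
    if group_label:
        meta["group"] = group_label
    return ConnectivityMatrix(mean, first.region_ids, kind=first.kind, meta=meta)
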