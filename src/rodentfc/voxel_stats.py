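"""Voxelwise group inference for MEMRI volumes and atlas-based volumetry.

The MEMRI chain: 7x7x7 median smoothing of each registered T1w volume, a
homoscedastic two-sample t-map (epileptic vs control), threshold-free
cluster enhancement (TFCE) of the t-map, a permutation null (random group
relabelings, 100 by default) whose pooled 99.9th percentile provides the
significance threshold, and a >500-voxel cluster filter.  Region-wise
intensity statistics (unpaired t per region, FDR across regions) and
label-volume tables with group comparisons round out the module.

TFCE integrates cluster extent e(h) and height h over all thresholds:
``TFCE(v) = sum_h e(h, v)^E * h^H * dh`` with the standard defaults
E = 0.5, H = 2 and 26-connectivity; negative statistics are enhanced by
applying the same transform to the negated map and negating the result.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as _st

from .io import Volume
from .stats_core import fdr_adjust

__all__ = [
    "TMap",
    "ClusterTable",
    "median_smooth",
    "voxelwise_t",
    "tfce",
    "permutation_threshold",
    "cluster_filter",
    "region_intensity_stats",
    "region_volumes",
    "compare_volumes",
]

TFCE_E = 0.5
TFCE_H = 2.0
DEFAULT_CONNECTIVITY = 26
DEFAULT_PERCENTILE = 99.9
DEFAULT_MIN_CLUSTER_VOXELS = 500


@dataclasses.dataclass
class TMap:
    values: np.ndarray  # 3-D, zero outside mask
    mask: np.ndarray
    n_a: int
    n_b: int

    @property
    def df(self) -> int:
        return self.n_a + self.n_b - 2


def _structure(connectivity: int) -> np.ndarray:
    if connectivity not in (6, 18, 26):
        raise ValueError("connectivity must be 6, 18 or 26")
    rank = {6: 1, 18: 2, 26: 3}[connectivity]
    return ndimage.generate_binary_structure(3, rank)


def median_smooth(volume: Volume, kernel_edge: int = 7) -> Volume:
    """Median filter with a cubic ``kernel_edge``^3 neighbourhood
    (edge-replicated borders).  Kernel edge must be odd."""
    if kernel_edge < 1 or kernel_edge % 2 == 0:
        raise ValueError("kernel edge must be an odd integer >= 1")
    out = ndimage.median_filter(
        np.asarray(volume.data, dtype=float), size=kernel_edge, mode="nearest"
    )
    return Volume(data=out, spacing=volume.spacing, affine=volume.affine)


def voxelwise_t(
    volumes_a: list[Volume], volumes_b: list[Volume], mask: np.ndarray | None = None
) -> TMap:
    """Pooled-variance two-sample t per in-mask voxel; df = n_a + n_b - 2.

    Voxels with zero pooled variance get t = 0 (flagged by the mask of
    the returned map staying True — they simply carry no evidence).
    """
    if len(volumes_a) < 2 or len(volumes_b) < 2:
        raise ValueError("need at least two volumes per group")
    a = np.stack([np.asarray(v.data, dtype=float) for v in volumes_a])
    b = np.stack([np.asarray(v.data, dtype=float) for v in volumes_b])
    if a.shape[1:] != b.shape[1:]:
        raise ValueError("groups are on different grids")
    if mask is None:
        mask = np.ones(a.shape[1:], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    n_a, n_b = a.shape[0], b.shape[0]
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    sp2 = ((n_a - 1) * va + (n_b - 1) * vb) / (n_a + n_b - 2)
    se = np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
    diff = a.mean(axis=0) - b.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(se > 0, diff / se, 0.0)
    t = np.where(mask, t, 0.0)
    return TMap(values=t, mask=mask, n_a=n_a, n_b=n_b)


def tfce(
    stat_map: np.ndarray,
    e: float = TFCE_E,
    h: float = TFCE_H,
    dh: float | None = None,
    connectivity: int = DEFAULT_CONNECTIVITY,
) -> np.ndarray:
    """Threshold-free cluster enhancement of a 3-D statistic map.

    Thresholds step from ``dh`` to the map maximum in increments of
    ``dh`` (default max|stat|/100); at each threshold every voxel in a
    connected supra-threshold component of size ``c`` accumulates
    ``c**e * h**h_exponent * dh``.  Negative values are enhanced
    symmetrically and returned negative.
    """
    stat_map = np.asarray(stat_map, dtype=float)
    if not np.all(np.isfinite(stat_map)):
        raise ValueError("statistic map contains non-finite values")
    structure = _structure(connectivity)
    vmax = np.abs(stat_map).max()
    if vmax == 0:
        return np.zeros_like(stat_map)
    if dh is None:
        dh = vmax / 100.0
    if dh <= 0:
        raise ValueError("dh must be positive")

    def _enhance(pos: np.ndarray) -> np.ndarray:
        out = np.zeros_like(pos)
        top = pos.max()
        if top <= 0:
            return out
        heights = np.arange(dh, top + 0.5 * dh, dh)
        for height in heights:
            labels, n_lab = ndimage.label(pos >= height, structure=structure)
            if n_lab == 0:
                continue
            sizes = np.bincount(labels.ravel())
            contrib = sizes.astype(float) ** e * height**h * dh
            contrib[0] = 0.0
            out += contrib[labels]
        return out

    return _enhance(np.clip(stat_map, 0, None)) - _enhance(np.clip(-stat_map, 0, None))


def permutation_threshold(
    volumes_a: list[Volume],
    volumes_b: list[Volume],
    mask: np.ndarray | None = None,
    n_perm: int = 100,
    percentile: float = DEFAULT_PERCENTILE,
    seed: int = 0,
    pipeline: str = "tfce",
    median_kernel: int = 1,
    connectivity: int = DEFAULT_CONNECTIVITY,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Permutation-based multiple-comparison correction.

    For each of ``n_perm`` random group relabelings (sampled without
    replacement from the label-permutation space, the observed labeling
    excluded) the statistic map is recomputed through the same pipeline —
    ``"tfce"`` enhances the t-map first, ``"t"`` uses raw t values — and
    all in-mask permutation values are pooled.  The threshold is the
    requested percentile of that pooled null; the significant mask marks
    observed values above it.

    Returns (threshold, significant_mask, observed_map).
    """
    if n_perm < 10:
        raise ValueError("need at least 10 permutations")
    if pipeline not in ("tfce", "t"):
        raise ValueError("pipeline must be 'tfce' or 't'")
    vols = volumes_a + volumes_b
    if median_kernel > 1:
        vols = [median_smooth(v, median_kernel) for v in vols]
    n_a = len(volumes_a)
    n_total = len(vols)
    if mask is None:
        mask = np.ones(vols[0].data.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)

    def stat_map(order: np.ndarray) -> np.ndarray:
        ga = [vols[i] for i in order[:n_a]]
        gb = [vols[i] for i in order[n_a:]]
        tmap = voxelwise_t(ga, gb, mask)
        if pipeline == "tfce":
            return tfce(tmap.values, connectivity=connectivity)
        return tmap.values

    observed = stat_map(np.arange(n_total))
    rng = np.random.default_rng(seed)
    # distinctness is judged on the group assignment, not the ordering
    seen = {tuple(range(n_a))}
    null_values = []
    tries = 0
    while len(seen) - 1 < n_perm:
        perm = rng.permutation(n_total)
        key = tuple(sorted(perm[:n_a]))
        tries += 1
        if key in seen:
            if tries > 50 * n_perm + 1000:
                raise ValueError("too few subjects for the requested distinct permutations")
            continue
        seen.add(key)
        null_values.append(stat_map(perm)[mask])
    pooled = np.concatenate(null_values)
    threshold = float(np.percentile(pooled, percentile))
    significant = (observed > threshold) & mask
    return threshold, significant, observed


@dataclasses.dataclass
class ClusterTable:
    table: pd.DataFrame  # size, centroid_{xyz}, peak_{xyz}, peak_value
    min_voxels: int
    connectivity: int


def cluster_filter(
    mask: np.ndarray,
    min_voxels: int = DEFAULT_MIN_CLUSTER_VOXELS,
    connectivity: int = DEFAULT_CONNECTIVITY,
    value_map: np.ndarray | None = None,
) -> ClusterTable:
    """Connected components of a significance mask, keeping those with
    more than ``min_voxels`` voxels.

    Centroids and peaks are reported as 0-based voxel indices; peaks need
    ``value_map`` (falls back to the centroid voxel otherwise).
    """
    mask = np.asarray(mask, dtype=bool)
    labels, n_lab = ndimage.label(mask, structure=_structure(connectivity))
    rows = []
    for lab in range(1, n_lab + 1):
        sel = labels == lab
        size = int(sel.sum())
        if size <= min_voxels:
            continue
        coords = np.argwhere(sel)
        centroid = coords.mean(axis=0)
        if value_map is not None:
            vals = np.asarray(value_map)[sel]
            peak = coords[int(np.argmax(vals))]
            peak_value = float(vals.max())
        else:
            peak = np.floor(centroid + 0.5).astype(int)
            peak_value = float("nan")
        rows.append(
            dict(
                size=size,
                centroid_x=centroid[0], centroid_y=centroid[1], centroid_z=centroid[2],
                peak_x=int(peak[0]), peak_y=int(peak[1]), peak_z=int(peak[2]),
                peak_value=peak_value,
            )
        )
    cols = ["size", "centroid_x", "centroid_y", "centroid_z",
            "peak_x", "peak_y", "peak_z", "peak_value"]
    table = pd.DataFrame(rows, columns=cols).sort_values("size", ascending=False, ignore_index=True) if rows else pd.DataFrame(columns=cols)
    return ClusterTable(table, min_voxels, connectivity)


# ---------------------------------------------------------------------------
# region-wise statistics and volumetry


def region_intensity_stats(
    volumes_a: list[Volume],
    volumes_b: list[Volume],
    atlas: Volume,
    alpha: float = 0.01,
    fdr_method: str = "BH",
) -> pd.DataFrame:
    """Per-region mean intensities compared by unpaired homoscedastic t,
    FDR-corrected across regions at q = ``alpha``.

    Returns a table with region_id, group means, t, p, q (adjusted p) and
    the significance flag.
    """
    labels = np.asarray(atlas.data)
    ids = [int(r) for r in np.unique(labels) if r != 0]
    masks = {rid: labels == rid for rid in ids}
    for rid, m in masks.items():
        if not m.any():
            raise ValueError(f"region {rid} is empty")

    def region_means(vols: list[Volume]) -> np.ndarray:
        return np.array([[float(np.asarray(v.data)[masks[r]].mean()) for r in ids] for v in vols])

    a = region_means(volumes_a)
    b = region_means(volumes_b)
    n_a, n_b = a.shape[0], b.shape[0]
    sp2 = ((n_a - 1) * a.var(axis=0, ddof=1) + (n_b - 1) * b.var(axis=0, ddof=1)) / (
        n_a + n_b - 2
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (a.mean(axis=0) - b.mean(axis=0)) / np.sqrt(sp2 * (1 / n_a + 1 / n_b))
    t = np.nan_to_num(t)
    p = 2.0 * _st.t.sf(np.abs(t), n_a + n_b - 2)
    fdr = fdr_adjust(p, method=fdr_method, q=alpha)
    return pd.DataFrame(
        {
            "region_id": ids,
            "mean_a": a.mean(axis=0),
            "mean_b": b.mean(axis=0),
            "t": t,
            "p": p,
            "q": fdr.adjusted_p,
            "significant": fdr.rejected,
        }
    ).set_index("region_id", drop=False)


def region_volumes(
    label_volume: Volume, tissue_classes: dict[str, list[int]] | None = None
) -> pd.DataFrame:
    """Per-region voxel counts and volumes (mm^3) from an integer label
    image; optional tissue-class totals appended as extra rows."""
    labels = np.asarray(label_volume.data)
    if not np.issubdtype(labels.dtype, np.integer):
        if not np.all(labels == np.round(labels)):
            raise ValueError("label volume must be integer-coded")
        labels = labels.astype(np.int64)
    voxel_mm3 = float(np.prod(label_volume.spacing))
    ids, counts = np.unique(labels, return_counts=True)
    rows = [
        dict(region_id=int(r), n_voxels=int(c), volume_mm3=float(c) * voxel_mm3)
        for r, c in zip(ids, counts) if r != 0
    ]
    df = pd.DataFrame(rows, columns=["region_id", "n_voxels", "volume_mm3"])
    if tissue_classes:
        lut = df.set_index("region_id")
        extra = []
        for name, members in tissue_classes.items():
            present = [m for m in members if m in lut.index]
            extra.append(
                dict(
                    tissue_class=name,
                    n_voxels=int(lut.loc[present, "n_voxels"].sum()) if present else 0,
                    volume_mm3=float(lut.loc[present, "volume_mm3"].sum()) if present else 0.0,
                )
            )
        df.attrs["tissue_totals"] = pd.DataFrame(extra)
    return df


def compare_volumes(
    tables_a: list[pd.DataFrame], tables_b: list[pd.DataFrame], paired: bool = False
) -> pd.DataFrame:
    """Per-region t-test (unpaired homoscedastic, or paired) on volume
    tables from two groups of subjects, plus a whole-label total row."""
    if not tables_a or not tables_b:
        raise ValueError("empty group")
    if paired and len(tables_a) != len(tables_b):
        raise ValueError("paired comparison needs equal group sizes")
    regions = list(tables_a[0]["region_id"])
    for t in tables_a + tables_b:
        if list(t["region_id"]) != regions:
            raise ValueError("volume tables cover different region sets")

    def stack(tables: list[pd.DataFrame]) -> np.ndarray:
        arr = np.stack([t["volume_mm3"].to_numpy(dtype=float) for t in tables])
        return np.column_stack([arr, arr.sum(axis=1)])  # append whole-label total

    a = stack(tables_a)
    b = stack(tables_b)
    n_a, n_b = a.shape[0], b.shape[0]
    if paired:
        d = a - b
        sd = d.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = np.where(sd > 0, d.mean(axis=0) / (sd / np.sqrt(n_a)), 0.0)
        df_ = n_a - 1
    else:
        sp2 = ((n_a - 1) * a.var(axis=0, ddof=1) + (n_b - 1) * b.var(axis=0, ddof=1)) / (
            n_a + n_b - 2
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            t = np.where(
                sp2 > 0,
                (a.mean(axis=0) - b.mean(axis=0)) / np.sqrt(sp2 * (1 / n_a + 1 / n_b)),
                0.0,
            )
        df_ = n_a + n_b - 2
    p = 2.0 * _st.t.sf(np.abs(t), df_)
    return pd.DataFrame(
        {
            "region_id": regions + ["total"],
            "mean_a_mm3": a.mean(axis=0),
            "mean_b_mm3": b.mean(axis=0),
            "t": t,
            "p": p,
        }
    )
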