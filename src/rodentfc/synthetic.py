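"""Synthetic two-strain cohort generator.

Emulates a longitudinal rodent imaging study: a bilateral cuboid-parcel
atlas phantom (80 or 114 regions), BOLD-like 4-D series whose region
signals are band-limited (0.01-0.08 Hz, inside the resting-state band)
Gaussian processes mixed by the Cholesky factor of a target correlation
matrix with planted community structure, motion-parameter traces with
optional position jumps, manganese-enhanced (MEMRI-like) T1w intensity
volumes with region-wise offsets, and per-subject label volumes with a
planted volumetric group effect.

Everything is fully determined by (config, seed).  The ground-truth
region correlation matrix is returned alongside every simulated series so
recovery can be tested.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as rio
from .io import Volume

__all__ = [
    "CommunitySpec",
    "NoiseSpec",
    "CohortConfig",
    "make_atlas_phantom",
    "build_target_matrix",
    "simulate_bold",
    "simulate_motion",
    "simulate_memri",
    "simulate_cohort",
    "homotopic_pairs",
]


# ---------------------------------------------------------------------------
# atlas phantom


def make_atlas_phantom(
    n_regions: int,
    grid_shape: tuple[int, int, int] = (32, 32, 12),
    spacing: tuple[float, float, float] = (0.5, 0.5, 1.0),
    parcel_edge: int = 3,
) -> tuple[Volume, pd.DataFrame]:
    """Build a bilateral atlas phantom of mirror-symmetric cuboid parcels.

    Regions come in left/right pairs sharing a base name; left regions get
    odd labels (2p-1) and their right mirrors even labels (2p).  Parcels
    are ``parcel_edge``-sided cubes (>= 27 voxels at the default edge 3)
    tiled in the left half of the grid and mirrored about the mid-sagittal
    plane (first axis).  Background is label 0.

    Returns the label :class:`~rodentfc.io.Volume` and the region table
    (region_id, name, hemisphere, functional_group).
    """
    if n_regions % 2:
        raise ValueError("n_regions must be even for bilateral construction")
    if parcel_edge < 3:
        raise ValueError("parcel edge must be >= 3 so every region has >= 27 voxels")
    nx, ny, nz = grid_shape
    half = nx // 2
    slots = [
        (x, y, z)
        for z in range(0, nz - parcel_edge + 1, parcel_edge)
        for y in range(0, ny - parcel_edge + 1, parcel_edge)
        for x in range(0, half - parcel_edge + 1, parcel_edge)
    ]
    n_pairs = n_regions // 2
    if len(slots) < n_pairs:
        raise ValueError(
            f"grid {grid_shape} hosts only {len(slots)} parcel slots per "
            f"hemisphere; {n_pairs} needed"
        )
    labels = np.zeros(grid_shape, dtype=np.int32)
    rows = []
    e = parcel_edge
    for p in range(n_pairs):
        x, y, z = slots[p]
        left_id, right_id = 2 * p + 1, 2 * p + 2
        labels[x : x + e, y : y + e, z : z + e] = left_id
        # mirror about the mid-sagittal plane
        labels[nx - x - e : nx - x, y : y + e, z : z + e] = right_id
        group = rio.FUNCTIONAL_GROUPS[p % len(rio.FUNCTIONAL_GROUPS)]
        base = f"region{p + 1:03d}"
        rows.append((left_id, f"{base}_L", "left", group))
        rows.append((right_id, f"{base}_R", "right", group))
    table = pd.DataFrame(
        rows, columns=["region_id", "name", "hemisphere", "functional_group"]
    ).set_index("region_id", drop=False)
    return Volume(data=labels, spacing=spacing), table


def homotopic_pairs(region_table: pd.DataFrame) -> list[tuple[int, int]]:
    """Left/right region-id pairs sharing a base name (name minus _L/_R)."""
    base = region_table["name"].str.replace(r"_(L|R)$", "", regex=True)
    pairs = []
    for _, grp in region_table.groupby(base, sort=False):
        if len(grp) == 2 and set(grp["hemisphere"]) == {"left", "right"}:
            left = int(grp.loc[grp["hemisphere"] == "left", "region_id"].iloc[0])
            right = int(grp.loc[grp["hemisphere"] == "right", "region_id"].iloc[0])
            pairs.append((left, right))
    return pairs


# ---------------------------------------------------------------------------
# target covariance


@dataclasses.dataclass
class CommunitySpec:
    """Planted community covariance for the region-level latent signals.

    ``blocks`` partitions region ids into communities; correlations are
    ``within_block_r`` inside a block, ``between_block_r`` across blocks,
    and at least ``homotopic_r`` for left/right pairs.  ``strain_effect``
    is an additive correlation increment applied to ``strain_effect_edges``
    for the epileptic group only.
    """

    blocks: list[list[int]]
    within_block_r: float = 0.6
    between_block_r: float = 0.1
    homotopic_r: float = 0.5
    strain_effect: float = 0.0
    strain_effect_edges: list[tuple[int, int]] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 < self.within_block_r < 1.0):
            raise ValueError("within_block_r must lie in (0, 1)")
        if not (0.0 <= self.between_block_r < self.within_block_r):
            raise ValueError("between_block_r must lie in [0, within_block_r)")

    def block_labels(self, region_ids: Sequence[int]) -> np.ndarray:
        lookup = {}
        for b, block in enumerate(self.blocks):
            for rid in block:
                lookup[rid] = b
        return np.array([lookup[r] for r in region_ids])


@dataclasses.dataclass
class NoiseSpec:
    """Observation-noise and signal-band parameters.

    ``band`` (Hz) bounds the shared region signals; the upper limit must
    stay below the Nyquist frequency 1/(2 TR).  ``noise_sd`` scales the
    voxelwise white observation noise relative to the unit-variance region
    signal.  ``drift_amplitude`` adds a per-voxel linear drift.
    """

    noise_sd: float = 1.0
    band: tuple[float, float] = (0.01, 0.08)
    drift_amplitude: float = 0.0
    baseline: float = 100.0  # mean signal level, gives realistic tSNR


def _nearest_psd(mat: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(mat)
    vals = np.clip(vals, 1e-10, None)
    out = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return out


def build_target_matrix(
    spec: CommunitySpec,
    region_table: pd.DataFrame,
    strain: str = "control",
) -> np.ndarray:
    """Target region correlation matrix for one strain.

    Slightly indefinite user specs are projected to the nearest
    positive-semidefinite correlation matrix with a warning.
    """
    ids = region_table["region_id"].to_numpy()
    n = ids.size
    lab = spec.block_labels(ids)
    target = np.where(lab[:, None] == lab[None, :], spec.within_block_r, spec.between_block_r)
    idx = {rid: i for i, rid in enumerate(ids)}
    for left, right in homotopic_pairs(region_table):
        i, j = idx[left], idx[right]
        target[i, j] = target[j, i] = max(target[i, j], spec.homotopic_r)
    if strain == "epileptic" and spec.strain_effect:
        for a, b in spec.strain_effect_edges:
            i, j = idx[a], idx[b]
            target[i, j] = target[j, i] = min(target[i, j] + spec.strain_effect, 0.999)
    np.fill_diagonal(target, 1.0)
    if np.linalg.eigvalsh(target).min() < -1e-8:
        warnings.warn("community spec is indefinite; projecting to nearest PSD matrix")
        target = _nearest_psd(target)
    return target


# ---------------------------------------------------------------------------
# BOLD simulation


def _band_limited_noise(
    n_signals: int, n_volumes: int, band: tuple[float, float], tr: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance Gaussian signals with power confined to ``band`` (Hz)."""
    lo, hi = band
    nyquist = 0.5 / tr
    if hi >= nyquist:
        raise ValueError(f"band upper limit {hi} Hz exceeds Nyquist {nyquist} Hz")
    white = rng.standard_normal((n_signals, n_volumes))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_volumes, d=tr)
    spec[:, (freqs < lo) | (freqs > hi)] = 0.0
    sig = np.fft.irfft(spec, n=n_volumes, axis=1)
    sig -= sig.mean(axis=1, keepdims=True)
    sd = sig.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return sig / sd


def simulate_bold(
    atlas: Volume,
    region_table: pd.DataFrame,
    community_spec: CommunitySpec,
    noise_spec: NoiseSpec,
    n_volumes: int = 900,
    tr: float = 1.0,
    seed: int | np.random.Generator = 0,
    strain: str = "control",
) -> tuple[Volume, np.ndarray]:
    """Simulate a BOLD-like 4-D series on the atlas grid.

    Each voxel's time course is the band-limited latent signal of its
    region (latents drawn with the target covariance via its Cholesky
    factor) plus independent Gaussian observation noise.  Returns the
    series and the ground-truth region correlation matrix.
    """
    if n_volumes < 100:
        raise ValueError("need at least 100 volumes for a meaningful series")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    target = build_target_matrix(community_spec, region_table, strain=strain)
    n = target.shape[0]
    latents = _band_limited_noise(n, n_volumes, noise_spec.band, tr, rng)
    chol = np.linalg.cholesky(target + 1e-9 * np.eye(n))
    mixed = chol @ latents  # (n_regions, n_volumes), unit-variance rows approx.

    labels = atlas.data
    ids = region_table["region_id"].to_numpy()
    data = np.zeros(labels.shape + (n_volumes,), dtype=np.float32)
    for i, rid in enumerate(ids):
        mask = labels == rid
        nvox = int(mask.sum())
        if nvox == 0:
            raise ValueError(f"region {rid} empty in atlas")
        series = (
            noise_spec.baseline
            + mixed[i][None, :]
            + noise_spec.noise_sd * rng.standard_normal((nvox, n_volumes))
        )
        if noise_spec.drift_amplitude:
            ramp = np.linspace(-0.5, 0.5, n_volumes)
            coefs = rng.uniform(-1, 1, size=(nvox, 1))
            series = series + noise_spec.drift_amplitude * coefs * ramp[None, :]
        data[mask] = series.astype(np.float32)
    return Volume(data=data, spacing=atlas.spacing, tr=tr), target


# ---------------------------------------------------------------------------
# motion and MEMRI


def simulate_motion(
    n_volumes: int,
    jump_at: int | None = None,
    jump_mm: float = 0.0,
    seed: int | np.random.Generator = 0,
    jitter_mm: float = 0.01,
    jitter_deg: float = 0.01,
) -> np.ndarray:
    """Motion trace (n_volumes x 6): Gaussian jitter plus an optional step.

    The step of ``jump_mm`` is applied to the first translation axis from
    volume ``jump_at`` onward, emulating a head-position shift.
    """
    if jump_mm < 0 or jitter_mm < 0 or jitter_deg < 0:
        raise ValueError("amplitudes must be non-negative")
    if jump_at is not None and not (0 <= jump_at < n_volumes):
        raise ValueError(f"jump_at {jump_at} outside [0, {n_volumes})")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    trace = np.zeros((n_volumes, 6))
    trace[:, :3] = jitter_mm * rng.standard_normal((n_volumes, 3))
    trace[:, 3:] = jitter_deg * rng.standard_normal((n_volumes, 3))
    if jump_at is not None and jump_mm > 0:
        trace[jump_at:, 0] += jump_mm
    return trace


def simulate_memri(
    atlas: Volume,
    region_offsets: dict[int, float],
    noise_sd: float = 1.0,
    seed: int | np.random.Generator = 0,
    base_intensity: float = 100.0,
) -> Volume:
    """MEMRI-like T1w intensity volume: base + region offset + noise."""
    labels = atlas.data
    present = set(np.unique(labels)) - {0}
    unknown = set(region_offsets) - present
    if unknown:
        raise ValueError(f"offsets for unknown region id(s): {sorted(unknown)}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    vol = np.full(labels.shape, base_intensity, dtype=np.float64)
    for rid, off in region_offsets.items():
        vol[labels == rid] += off
    if noise_sd:
        vol += noise_sd * rng.standard_normal(labels.shape)
    return Volume(data=vol, spacing=atlas.spacing)


def simulate_subject_matrices(
    region_table: pd.DataFrame,
    community_spec: CommunitySpec,
    n_subjects: int = 12,
    subject_sd: float = 0.15,
    effect: float = 0.0,
    effect_edges: Sequence[tuple[int, int]] = (),
    seed: int | np.random.Generator = 0,
):
    """Subject-level Fisher-z connectivity matrices drawn around a group
    ground truth.

    The group matrix is atanh of the community-spec target correlations;
    each subject adds symmetric Gaussian noise of SD ``subject_sd``
    (between-subject variability of session-averaged z estimates) and,
    for a planted group difference, ``effect`` on ``effect_edges``.
    Negative entries are clipped at 0 (z matrices are positive-only).
    Returns a list of :class:`~rodentfc.connectivity.ConnectivityMatrix`.
    """
    from .connectivity import ConnectivityMatrix

    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    target = build_target_matrix(community_spec, region_table)
    base = np.arctanh(np.clip(target, 0.0, 0.99))
    ids = region_table["region_id"].to_numpy()
    idx = {int(r): i for i, r in enumerate(ids)}
    np.fill_diagonal(base, 0.0)
    for a, b in effect_edges:
        base[idx[a], idx[b]] += effect
        base[idx[b], idx[a]] += effect
    n = base.shape[0]
    out = []
    for _ in range(n_subjects):
        noise = rng.standard_normal((n, n)) * subject_sd
        noise = 0.5 * (noise + noise.T)
        vals = np.clip(base + noise, 0.0, None)
        np.fill_diagonal(vals, 0.0)
        out.append(ConnectivityMatrix(vals, ids, kind="z"))
    return out


# ---------------------------------------------------------------------------
# whole-cohort generation


@dataclasses.dataclass
class CohortConfig:
    """Study-design defaults: 12 epileptic + 12 control subjects imaged at
    3-8 months (sessions), 80-region bilateral atlas, TR 1 s, 900-volume
    (15 min) series."""

    n_per_strain: int = 12
    sessions: tuple[int, ...] = (3, 4, 5, 6, 7, 8)
    n_regions: int = 80
    grid_shape: tuple[int, int, int] = (32, 32, 12)
    spacing: tuple[float, float, float] = (0.5, 0.5, 1.0)
    n_volumes: int = 900
    tr: float = 1.0
    community: CommunitySpec | None = None
    noise: NoiseSpec = dataclasses.field(default_factory=NoiseSpec)
    # MEMRI: intensity offsets planted in the epileptic group
    memri_effect_regions: tuple[int, ...] = (1, 2, 3, 4, 9, 10, 11, 12)
    memri_effect: float = 1.5  # in units of memri_noise_sd
    memri_noise_sd: float = 2.0
    # volumetry: parcels dilated by one voxel layer in the epileptic group
    volume_effect_regions: tuple[int, ...] = (5, 6)
    label_jitter_voxels: int = 2  # per-subject boundary voxels toggled per region

    def default_community(self, region_table: pd.DataFrame) -> CommunitySpec:
        """Three planted communities over bilateral pairs, with a focal
        epileptic-strain increment on a 15-edge cortical block (edges among
        regions 1-6)."""
        ids = list(region_table["region_id"])
        pairs = homotopic_pairs(region_table)
        # blocks respect bilateral pairs so homotopic coupling stays
        # within-community
        n_p = len(pairs)
        thirds = [
            [r for pair in chunk for r in pair]
            for chunk in (pairs[: n_p // 3], pairs[n_p // 3 : 2 * n_p // 3], pairs[2 * n_p // 3 :])
        ]
        focal = ids[:6]
        edges = [(a, b) for i, a in enumerate(focal) for b in focal[i + 1 :]]
        return CommunitySpec(
            blocks=thirds,
            within_block_r=0.6,
            between_block_r=0.1,
            homotopic_r=0.5,
            strain_effect=0.2,
            strain_effect_edges=edges,
        )


def _jitter_labels(
    labels: np.ndarray, dilate_ids: Sequence[int], jitter: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-subject label volume: dilate ``dilate_ids`` by one voxel layer
    into background, then toggle a few random boundary voxels per region so
    volumes vary across subjects."""
    from scipy import ndimage

    out = labels.copy()
    for rid in dilate_ids:
        grown = ndimage.binary_dilation(labels == rid)
        out[grown & (out == 0)] = rid
    if jitter:
        for rid in np.unique(labels):
            if rid == 0:
                continue
            region = out == rid
            shell = region & ~ndimage.binary_erosion(region)
            coords = np.argwhere(shell)
            if coords.size == 0:
                continue
            # binomial count so volumes vary across subjects
            n_off = int(rng.binomial(2 * jitter, 0.5))
            take = rng.choice(len(coords), size=min(n_off, len(coords)), replace=False)
            for c in coords[take]:
                out[tuple(c)] = 0
    return out


def simulate_cohort(
    config: CohortConfig, seed: int, out_dir: str | Path
) -> pd.DataFrame:
    """Generate the full on-disk synthetic study and return its manifest.

    Writes the atlas phantom and region table, one BOLD series + motion
    trace per (subject, session), and one MEMRI volume + subject label
    volume per subject (imaged once, at the final session).  The epileptic
    group carries the planted connectivity, intensity and volume effects.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    atlas, table = make_atlas_phantom(config.n_regions, config.grid_shape, config.spacing)
    rio.write_volume(atlas, out / "atlas.nii.gz")
    table.to_csv(out / "regions.tsv", sep="\t", index=False)
    community = config.community or config.default_community(table)

    rows = []
    for strain in rio.STRAINS:
        for s in range(config.n_per_strain):
            subject = f"{strain[:3]}{s + 1:02d}"
            for session in config.sessions:
                bold_path = out / f"bold_{subject}_m{session}.nii.gz"
                motion_path = out / f"motion_{subject}_m{session}.tsv"
                series, _ = simulate_bold(
                    atlas, table, community, config.noise,
                    n_volumes=config.n_volumes, tr=config.tr, seed=rng, strain=strain,
                )
                rio.write_volume(series, bold_path)
                rio.write_motion_tsv(
                    simulate_motion(config.n_volumes, seed=rng), motion_path
                )
                rows.append(
                    dict(subject_id=subject, strain=strain, session=session,
                         bold=bold_path.name, motion=motion_path.name)
                )
            # MEMRI + subject labels at study end
            present = set(int(v) for v in np.unique(atlas.data)) - {0}
            offsets = (
                {int(r): config.memri_effect * config.memri_noise_sd
                 for r in config.memri_effect_regions if int(r) in present}
                if strain == "epileptic" else {}
            )
            memri = simulate_memri(atlas, offsets, config.memri_noise_sd, seed=rng)
            rio.write_volume(memri, out / f"memri_{subject}.nii.gz")
            dilate = config.volume_effect_regions if strain == "epileptic" else ()
            sub_labels = _jitter_labels(
                atlas.data, dilate, config.label_jitter_voxels, rng
            )
            rio.write_volume(
                Volume(data=sub_labels, spacing=config.spacing),
                out / f"labels_{subject}.nii.gz",
            )
    manifest = pd.DataFrame(rows)
    manifest["age_group"] = [rio.age_group_for_session(s) for s in manifest["session"]]
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    return manifest
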