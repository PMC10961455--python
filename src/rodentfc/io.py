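"""Readers and writers for the pipeline's on-disk formats.

Images are NIfTI-1 (via nibabel); tables, motion traces, manifests and
connectivity matrices are TSV so every artifact is diffable and
language-neutral.  Voxel coordinates are 0-based array indices throughout;
world coordinates follow the NIfTI affine.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "Volume",
    "read_volume",
    "write_volume",
    "load_manifest",
    "load_region_table",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_motion_tsv",
    "write_motion_tsv",
]

#: sessions (months of age) pooled into each age group
JUVENILE_SESSIONS = (3, 4, 5)
ADULT_SESSIONS = (6, 7, 8)

STRAINS = ("epileptic", "control")

FUNCTIONAL_GROUPS = (
    "association cortex",
    "sensorimotor cortex",
    "basal ganglia",
    "limbic",
    "sensory input",
    "thalamus",
    "brain stem",
)

HEMISPHERES = ("left", "right", "midline")


@dataclasses.dataclass
class Volume:
    """A 3-D or 4-D image with voxel spacing (mm) and, for 4-D, TR (s)."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    tr: float | None = None
    affine: np.ndarray | None = None

    @property
    def is_series(self) -> bool:
        return self.data.ndim == 4

    @property
    def n_volumes(self) -> int:
        if not self.is_series:
            raise ValueError("not a 4-D series")
        return self.data.shape[3]


def read_volume(path: str | Path) -> Volume:
    """Read a NIfTI-1 volume; spacing from the header zooms, TR from the
    fourth zoom for 4-D series.

    Raises ``FileNotFoundError`` for a missing path and ``ValueError``
    (naming the path) for unreadable payloads or a 4-D file without a
    time-axis zoom.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image: {path}")
    try:
        img = nib.load(path)
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # nibabel raises several classes
        raise ValueError(f"could not read NIfTI file {path}: {exc}") from exc
    if data.ndim not in (3, 4):
        raise ValueError(f"{path}: expected 3-D or 4-D image, got {data.ndim}-D")
    zooms = img.header.get_zooms()
    spacing = tuple(float(z) for z in zooms[:3])
    tr = None
    if data.ndim == 4:
        if len(zooms) < 4 or zooms[3] <= 0:
            raise ValueError(f"{path}: 4-D series without a positive TR in header")
        tr = float(zooms[3])
    return Volume(data=data, spacing=spacing, tr=tr, affine=np.asarray(img.affine))


def write_volume(vol: Volume, path: str | Path) -> Path:
    """Write a :class:`Volume` as NIfTI-1, preserving spacing and TR."""
    path = Path(path)
    affine = vol.affine
    if affine is None:
        affine = np.diag(list(vol.spacing) + [1.0])
    img = nib.Nifti1Image(vol.data, affine)
    zooms = list(vol.spacing)
    if vol.data.ndim == 4:
        if vol.tr is None or vol.tr <= 0:
            raise ValueError("4-D series needs a positive TR to be written")
        zooms.append(vol.tr)
    img.header.set_zooms(zooms)
    if vol.data.ndim == 4:
        img.header.set_xyzt_units("mm", "sec")
    nib.save(img, path)
    return path


# ---------------------------------------------------------------------------
# cohort manifest


def age_group_for_session(session: int) -> str:
    if session in JUVENILE_SESSIONS:
        return "juvenile"
    if session in ADULT_SESSIONS:
        return "adult"
    raise ValueError(
        f"session {session} outside the study design (months {JUVENILE_SESSIONS + ADULT_SESSIONS})"
    )


def load_manifest(path: str | Path) -> pd.DataFrame:
    """Load and validate the cohort manifest TSV.

    Required columns: subject_id, strain, session plus any path columns.
    The age_group column is derived from the session (3-5 months juvenile,
    6-8 months adult) and overrides any stored value.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    required = {"subject_id", "strain", "session"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns: {sorted(missing)}")
    bad = set(df["strain"]) - set(STRAINS)
    if bad:
        raise ValueError(f"unknown strain value(s): {sorted(bad)}")
    dup = df.duplicated(subset=["subject_id", "session"])
    if dup.any():
        pairs = df.loc[dup, ["subject_id", "session"]].to_records(index=False)
        raise ValueError(f"duplicate (subject, session) rows: {list(pairs)[:5]}")
    df["session"] = df["session"].astype(int)
    df["age_group"] = [age_group_for_session(s) for s in df["session"]]
    return df


def load_region_table(path: str | Path) -> pd.DataFrame:
    """Load the atlas region table (region_id, name, hemisphere,
    functional_group), validating enums and uniqueness."""
    df = pd.read_csv(path, sep="\t")
    required = {"region_id", "name", "hemisphere", "functional_group"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"region table missing columns: {sorted(missing)}")
    if df["region_id"].duplicated().any():
        raise ValueError("duplicate region_id in region table")
    if (df["region_id"] <= 0).any():
        raise ValueError("region_id labels must be positive integers")
    bad_h = set(df["hemisphere"]) - set(HEMISPHERES)
    if bad_h:
        raise ValueError(f"unknown hemisphere value(s): {sorted(bad_h)}")
    bad_g = set(df["functional_group"]) - set(FUNCTIONAL_GROUPS)
    if bad_g:
        raise ValueError(f"unknown functional group(s): {sorted(bad_g)}")
    return df.set_index("region_id", drop=False)


# ---------------------------------------------------------------------------
# matrices and motion traces


def write_matrix_tsv(
    matrix: np.ndarray,
    region_ids: np.ndarray,
    path: str | Path,
    metadata: dict | None = None,
) -> Path:
    """Persist a square region x region matrix as TSV with region_id
    header row/column; optional JSON metadata sidecar."""
    path = Path(path)
    df = pd.DataFrame(matrix, index=region_ids, columns=region_ids)
    df.to_csv(path, sep="\t", index_label="region_id", float_format="%.8g")
    if metadata is not None:
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(metadata, indent=1, sort_keys=True)
        )
    return path


def read_matrix_tsv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a matrix TSV; returns (matrix, region_ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = df.index.to_numpy(dtype=int)
    cols = df.columns.to_numpy(dtype=int)
    if not np.array_equal(ids, cols):
        raise ValueError(f"{path}: row and column region ids differ")
    return df.to_numpy(dtype=float), ids


MOTION_COLUMNS = ["trans_x_mm", "trans_y_mm", "trans_z_mm", "rot_x_deg", "rot_y_deg", "rot_z_deg"]


def write_motion_tsv(trace: np.ndarray, path: str | Path) -> Path:
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 2 or trace.shape[1] != 6:
        raise ValueError("motion trace must be (n_volumes, 6)")
    pd.DataFrame(trace, columns=MOTION_COLUMNS).to_csv(path, sep="\t", index=False)
    return Path(path)


def read_motion_tsv(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != MOTION_COLUMNS:
        raise ValueError(f"{path}: expected columns {MOTION_COLUMNS}")
    return df.to_numpy(dtype=float)
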