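"""Readers and writers for OCTA volumes, vessel masks, surface meshes and cohort tables.

Geometric conventions
---------------------
A volume is stored as a 3D array indexed ``voxels[i, j, k]`` with

* axis 0 = x, the fast lateral scan direction,
* axis 1 = y, the slow lateral scan direction,
* axis 2 = z, depth (one en-face plane per ``k``).

Voxel ``(i, j, k)`` is centred at ``((i+0.5)*dx, (j+0.5)*dy, (k+0.5)*dz)`` mm
where ``(dx, dy, dz)`` is the physical spacing derived from the acquisition
extent.  The default geometry is the macular OCTA cube of 3 x 3 x 2 mm sampled
at 245 x 245 x 1024 voxels.

Raw binary dialect
------------------
The vendor's ``.img`` export layout is undocumented, so this package defines
its own raw dialect: unsigned 8-bit, x varying fastest, then y, en-face frames
stacked along z, with a JSON metadata sidecar next to the ``.raw`` file.
Directories of en-face image slices (BMP/PNG/TIFF, lexicographic filename
order = ascending depth) are accepted as the interchange format.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import trimesh

__all__ = [
    "VolumeMeta",
    "OCTAVolume",
    "VesselMask",
    "CohortTable",
    "COHORT_COLUMNS",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_mesh",
    "write_mesh",
    "read_cohort_table",
    "write_cohort_table",
]

_SLICE_EXTENSIONS = {".bmp", ".png", ".tif", ".tiff"}


@dataclass(frozen=True)
class VolumeMeta:
    """Acquisition geometry and metadata of an OCTA cube.

    ``signal_quality`` is the device's 0-10 signal-strength grade; it is
    carried as metadata only and never enforced or recomputed.
    """

    n_fast: int = 245
    n_slow: int = 245
    n_depth: int = 1024
    extent_mm: tuple[float, float, float] = (3.0, 3.0, 2.0)
    signal_quality: int | None = None
    eye: str = "unknown"

    def __post_init__(self) -> None:
        for n, name in ((self.n_fast, "n_fast"), (self.n_slow, "n_slow"), (self.n_depth, "n_depth")):
            if int(n) < 2:
                raise ValueError(f"{name} must be >= 2, got {n}")
        if len(self.extent_mm) != 3 or any(e <= 0 for e in self.extent_mm):
            raise ValueError(f"extent_mm must be 3 positive lengths, got {self.extent_mm!r}")
        if self.eye not in ("OD", "OS", "unknown"):
            raise ValueError(f"eye must be 'OD', 'OS' or 'unknown', got {self.eye!r}")
        object.__setattr__(self, "extent_mm", tuple(float(e) for e in self.extent_mm))

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.n_fast, self.n_slow, self.n_depth)

    @property
    def spacing_mm(self) -> tuple[float, float, float]:
        """(dx, dy, dz) voxel pitch in mm; extent / voxel count per axis."""
        return (
            self.extent_mm[0] / self.n_fast,
            self.extent_mm[1] / self.n_slow,
            self.extent_mm[2] / self.n_depth,
        )

    @property
    def n_voxels(self) -> int:
        return self.n_fast * self.n_slow * self.n_depth

    def to_dict(self) -> dict:
        return {
            "n_fast": self.n_fast,
            "n_slow": self.n_slow,
            "n_depth": self.n_depth,
            "extent_mm": list(self.extent_mm),
            "signal_quality": self.signal_quality,
            "eye": self.eye,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VolumeMeta":
        known = {f.name for f in dataclasses.fields(cls)}
        kwargs = {k: v for k, v in d.items() if k in known}
        if "extent_mm" in kwargs:
            kwargs["extent_mm"] = tuple(kwargs["extent_mm"])
        return cls(**kwargs)


@dataclass
class OCTAVolume:
    """A 3D OCTA flow volume: scalar voxel grid plus acquisition metadata.

    Voxels are unsigned 8-bit on ingest and real-valued after filtering.
    """

    voxels: np.ndarray
    meta: VolumeMeta

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.shape != self.meta.shape:
            raise ValueError(
                f"voxel grid shape {self.voxels.shape} does not match meta shape {self.meta.shape}"
            )
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("volume intensities must be finite")


@dataclass
class VesselMask:
    """Binary segmentation aligned voxel-for-voxel to an :class:`OCTAVolume`."""

    voxels: np.ndarray
    meta: VolumeMeta

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.dtype != bool:
            raise ValueError(f"mask voxels must be boolean, got dtype {self.voxels.dtype}")
        if self.voxels.shape != self.meta.shape:
            raise ValueError(
                f"mask shape {self.voxels.shape} does not match meta shape {self.meta.shape}"
            )

    @property
    def n_vessel_voxels(self) -> int:
        return int(self.voxels.sum())


COHORT_COLUMNS = [
    "subject_id",
    "eye",
    "sex",
    "age",
    "se",
    "al",
    "va",
    "surface_mm2",
    "surface_corrected_mm2",
]

_NUMERIC_COHORT_COLUMNS = ["age", "se", "al", "va", "surface_mm2", "surface_corrected_mm2"]


@dataclass
class CohortTable:
    """Per-eye records of a normative cohort.

    One row per (subject, eye): laterality, sex, age (years), spherical
    equivalent SE (dioptres), axial length AL (mm), decimal visual acuity VA,
    and the measured vessel surface area in mm^2 (raw and, optionally,
    magnification-corrected).  Missing covariates are NaN / empty cells; the
    pair (subject_id, eye) is unique.
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.df.copy()
        missing = [c for c in COHORT_COLUMNS if c not in df.columns]
        for c in missing:
            df[c] = np.nan
        df = df[COHORT_COLUMNS].reset_index(drop=True)
        df["subject_id"] = df["subject_id"].astype(str)
        df["eye"] = df["eye"].astype(str).str.strip().str.upper()
        bad_eye = ~df["eye"].isin(["OD", "OS"])
        if bad_eye.any():
            raise ValueError(f"eye must be OD or OS; bad rows: {list(df.index[bad_eye])}")
        sex = df["sex"].astype(str).str.strip().str.lower()
        sex = sex.map(lambda v: {"m": "male", "f": "female", "nan": np.nan, "": np.nan, "none": np.nan}.get(v, v))
        bad_sex = sex.notna() & ~sex.isin(["male", "female"])
        if bad_sex.any():
            raise ValueError(f"sex must be male or female; bad rows: {list(df.index[bad_sex])}")
        df["sex"] = sex
        for c in _NUMERIC_COHORT_COLUMNS:
            try:
                df[c] = pd.to_numeric(df[c])
            except (ValueError, TypeError) as exc:
                bad = pd.to_numeric(df[c], errors="coerce").isna() & df[c].notna()
                raise ValueError(
                    f"non-numeric values in column {c!r} at rows {list(df.index[bad])}"
                ) from exc
        dup = df.duplicated(subset=["subject_id", "eye"], keep=False)
        if dup.any():
            offenders = df.loc[dup, ["subject_id", "eye"]].drop_duplicates().values.tolist()
            raise ValueError(f"duplicate (subject_id, eye) pairs: {offenders}")
        if (df["al"].dropna() <= 0).any():
            raise ValueError("axial length must be positive where present")
        if (df["surface_mm2"].dropna() <= 0).any():
            raise ValueError("surface_mm2 must be positive where present")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def eye_subset(self, eye: str) -> "CohortTable":
        return CohortTable(self.df[self.df["eye"] == eye.upper()])


# ---------------------------------------------------------------------------
# volumes


def _sidecar_path(raw_path: Path) -> Path:
    return raw_path.with_suffix(".json")


def write_volume(volume: OCTAVolume, path: str | Path) -> None:
    """Write a volume in the package raw dialect: ``<name>.raw`` + JSON sidecar."""
    path = Path(path)
    vox = volume.voxels
    if vox.dtype != np.uint8:
        if vox.min() < 0 or vox.max() > 255:
            raise ValueError("only ingest-range [0, 255] volumes can be written as raw uint8")
        vox = np.rint(vox).astype(np.uint8)
    # x fastest, then y, frames along z -> C-order on the (z, y, x) view
    vox.transpose(2, 1, 0).tofile(path)
    _sidecar_path(path).write_text(json.dumps(volume.meta.to_dict(), indent=1))


def _read_raw(path: Path, meta: VolumeMeta) -> np.ndarray:
    expected = meta.n_voxels
    actual = path.stat().st_size
    if actual != expected:
        raise ValueError(
            f"raw volume size mismatch for {path}: expected {expected} bytes "
            f"({meta.n_fast}x{meta.n_slow}x{meta.n_depth} uint8), found {actual}"
        )
    flat = np.fromfile(path, dtype=np.uint8)
    return flat.reshape(meta.n_depth, meta.n_slow, meta.n_fast).transpose(2, 1, 0)


def _read_slice_stack(path: Path, meta: VolumeMeta) -> np.ndarray:
    files = sorted(p for p in path.iterdir() if p.suffix.lower() in _SLICE_EXTENSIONS)
    if not files:
        raise ValueError(f"no BMP/PNG/TIFF slices found in {path}")
    if len(files) != meta.n_depth:
        raise ValueError(f"expected {meta.n_depth} slices in {path}, found {len(files)}")
    vox = np.empty(meta.shape, dtype=np.uint8)
    for k, f in enumerate(files):
        try:
            img = iio.imread(f)
        except Exception as exc:  # noqa: BLE001 - re-raise with slice index
            raise IOError(f"unreadable slice {k} ({f.name}): {exc}") from exc
        if img.ndim == 3:  # grayscale stored as RGB
            img = img[..., 0]
        if img.shape != (meta.n_slow, meta.n_fast):
            raise ValueError(
                f"slice {k} ({f.name}) has shape {img.shape}, expected "
                f"({meta.n_slow}, {meta.n_fast})"
            )
        vox[:, :, k] = img.T
    return vox


def read_volume(path: str | Path, meta: VolumeMeta | None = None) -> OCTAVolume:
    """Read an OCTA volume from a raw file or a directory of en-face slices.

    For raw files the JSON sidecar supplies the geometry unless ``meta`` is
    given explicitly.  Slices in a directory are ordered lexicographically,
    shallowest depth first, each stored as (y, x) image rows.
    """
    path = Path(path)
    if path.is_dir():
        if meta is None:
            sidecar = path / "meta.json"
            if not sidecar.exists():
                raise ValueError(f"slice-stack directory {path} needs a meta.json or explicit meta")
            meta = VolumeMeta.from_dict(json.loads(sidecar.read_text()))
        vox = _read_slice_stack(path, meta)
    else:
        if meta is None:
            sidecar = _sidecar_path(path)
            if not sidecar.exists():
                raise ValueError(f"raw volume {path} has no sidecar {sidecar.name} and no explicit meta")
            meta = VolumeMeta.from_dict(json.loads(sidecar.read_text()))
        vox = _read_raw(path, meta)
    return OCTAVolume(vox, meta)


def write_slice_stack(volume: OCTAVolume, directory: str | Path, ext: str = ".png") -> None:
    """Write a volume as one en-face image per depth plane plus meta.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    vox = volume.voxels
    if vox.dtype != np.uint8:
        vox = np.rint(np.clip(vox, 0, 255)).astype(np.uint8)
    width = len(str(volume.meta.n_depth - 1))
    for k in range(volume.meta.n_depth):
        iio.imwrite(directory / f"slice_{k:0{width}d}{ext}", vox[:, :, k].T)
    (directory / "meta.json").write_text(json.dumps(volume.meta.to_dict(), indent=1))


# ---------------------------------------------------------------------------
# masks


def write_mask(mask: VesselMask, path: str | Path) -> None:
    """Write a vessel mask as a multi-page TIFF, one 0/255 page per depth slice."""
    pages = (mask.voxels.transpose(2, 1, 0).astype(np.uint8)) * 255
    tifffile.imwrite(str(path), pages, metadata={"meta": json.dumps(mask.meta.to_dict())})


def read_mask(path: str | Path, meta: VolumeMeta | None = None) -> VesselMask:
    with tifffile.TiffFile(str(path)) as tif:
        pages = tif.asarray()
        if meta is None:
            stored = None
            md = tif.shaped_metadata or tif.imagej_metadata
            if md:
                md0 = md[0] if isinstance(md, (list, tuple)) else md
                stored = md0.get("meta")
            if stored is None:
                raise ValueError(f"mask TIFF {path} carries no metadata; pass meta explicitly")
            meta = VolumeMeta.from_dict(json.loads(stored))
    if pages.ndim == 2:
        pages = pages[None]
    return VesselMask((pages > 0).transpose(2, 1, 0), meta)


# ---------------------------------------------------------------------------
# meshes


def write_mesh(
    vertices: np.ndarray,
    faces: np.ndarray,
    path: str | Path,
    format: str | None = None,
) -> None:
    """Write a triangle mesh (mm coordinates) as binary STL or PLY.

    The format is taken from the file suffix unless given explicitly.
    """
    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces)
    if len(faces) < 1:
        raise ValueError("mesh must have at least one triangle")
    if not np.all(np.isfinite(vertices)):
        raise ValueError("mesh vertex coordinates must be finite")
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in ("stl", "ply"):
        raise ValueError(f"unsupported mesh format {fmt!r}; use STL or PLY")
    mesh = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    mesh.export(str(path), file_type=fmt)


def read_mesh(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    mesh = trimesh.load_mesh(str(path), process=False)
    return np.asarray(mesh.vertices, dtype=float), np.asarray(mesh.faces, dtype=np.int64)


# ---------------------------------------------------------------------------
# cohort tables


def read_cohort_table(path: str | Path) -> CohortTable:
    """Read a per-eye cohort CSV (UTF-8, '.' decimal, blank cells = missing)."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = [c for c in COHORT_COLUMNS[:8] if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV {path} is missing required columns: {missing}")
    return CohortTable(df)


def write_cohort_table(table: CohortTable, path: str | Path) -> None:
    table.df.to_csv(path, index=False, float_format="%.10g")
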