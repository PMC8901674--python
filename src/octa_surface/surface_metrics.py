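"""Total vessel surface area in physical units, with ocular-magnification correction.

Two estimators are provided.  The default triangulates the 0.5-isosurface of
the binary mask with marching cubes at the mask's physical voxel spacing and
sums triangle areas; the mask is zero-padded first so vasculature touching
the crop boundary is capped rather than left open.  The second estimator
counts exposed voxel faces (6-neighbourhood) and sums their physical areas —
exact integer-weighted arithmetic that serves as an independent check.  On
smooth digitised solids the face count over-estimates area (staircase
effect), so mesh/faces ratios sit below 1.

Ocular magnification: the device converts scan angle to mm assuming a
reference axial length.  Following Littmann's telecentric method with
Bennett's simplification, the true lateral scale of an eye of axial length
AL differs by k = (AL - 1.82) / (AL_ref - 1.82); the correction rescales
lateral (x, y) mesh coordinates by k and recomputes the area.  A "planar"
mode multiplying the area by k^2 (the 2D en-face convention) is provided for
comparison, since it is unsettled whether planar formulas carry over to
surfaces embedded in 3D.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

logger = logging.getLogger(__name__)

from .volume_io import VesselMask

__all__ = [
    "SurfaceResult",
    "MagnificationParams",
    "surface_area_mesh",
    "surface_area_voxel_faces",
    "bennett_scale",
    "apply_magnification_correction",
    "mask_to_mesh",
    "mesh_area",
]


@dataclass
class SurfaceResult:
    """Total vessel surface area in mm^2, raw and optionally magnification-corrected."""

    area_mm2: float
    method: str  # "mesh" | "voxel_faces"
    n_triangles: int = 0
    corrected_area_mm2: float | None = None
    correction_factor_k: float | None = None

    def __post_init__(self) -> None:
        if self.area_mm2 < 0:
            raise ValueError("surface area cannot be negative")
        if (self.corrected_area_mm2 is None) != (self.correction_factor_k is None):
            raise ValueError("corrected area and k must be set together")
        if self.correction_factor_k is not None and self.correction_factor_k <= 0:
            raise ValueError("correction factor k must be positive")

    def to_dict(self) -> dict:
        return {
            "area_mm2": self.area_mm2,
            "method": self.method,
            "n_triangles": self.n_triangles,
            "corrected_area_mm2": self.corrected_area_mm2,
            "correction_factor_k": self.correction_factor_k,
        }


@dataclass(frozen=True)
class MagnificationParams:
    """Axial length of the measured eye and the scale convention of the device.

    ``al_ref_mm`` is the axial length the device assumes when converting scan
    angle to lateral mm (24.46 mm, a common emmetropic assumption, by
    default).  ``bennett_constant`` (mm^-1) and ``bennett_offset`` (mm) are
    the constants of Bennett's reduced-eye formula q = 0.01306 (AL - 1.82)
    relating axial length to retinal mm per degree.
    """

    al_mm: float
    al_ref_mm: float = 24.46
    bennett_constant: float = 0.01306
    bennett_offset: float = 1.82

    def __post_init__(self) -> None:
        if self.al_mm <= self.bennett_offset:
            raise ValueError(
                f"axial length {self.al_mm} mm must exceed the Bennett offset "
                f"{self.bennett_offset} mm"
            )
        if self.al_ref_mm <= self.bennett_offset:
            raise ValueError("reference axial length must exceed the Bennett offset")


def mask_to_mesh(
    mask: VesselMask, smooth_sigma_mm: float | str | None = "auto"
) -> tuple[np.ndarray, np.ndarray]:
    """Marching-cubes triangulation of the mask's 0.5-isosurface, in mm.

    The binary field is first anti-aliased with a Gaussian of physical width
    ``smooth_sigma_mm`` (default "auto" = the coarsest voxel pitch) before
    the isosurface is extracted: on a raw 0/1 field the staircase facets of
    the digitisation inflate the area of smooth solids by ~20% (worse on
    anisotropic grids), while the 0.5-level set of the smoothed field tracks
    the true boundary to sub-voxel accuracy.  If smoothing would erase a
    structure thinner than the smoothing width (no voxel stays above 0.5),
    the raw binary field is used instead.  Pass ``smooth_sigma_mm=None`` or
    ``0`` to force binary extraction.

    The field is padded by background on all sides so boundary-touching
    vessels produce closed (capped) surfaces; vertex coordinates follow the
    voxel-centre convention (voxel (i,j,k) at ((i+0.5)dx, (j+0.5)dy,
    (k+0.5)dz)).
    """
    if mask.n_vessel_voxels == 0:
        raise ValueError("no vessel voxels: cannot extract a surface from an empty mask")
    spacing = np.asarray(mask.meta.spacing_mm)
    sigma_mm = float(spacing.max()) if smooth_sigma_mm == "auto" else float(smooth_sigma_mm or 0.0)
    pad = 1 if sigma_mm == 0 else 1 + int(np.ceil(3 * sigma_mm / spacing.min()))
    field = np.pad(mask.voxels, pad).astype(np.float32)
    if sigma_mm > 0:
        smoothed = ndimage.gaussian_filter(field, sigma=sigma_mm / spacing, mode="constant")
        if smoothed.max() > 0.5:
            field = smoothed
        else:
            logger.info(
                "mask_to_mesh: structure thinner than smoothing width %.4g mm; "
                "falling back to binary isosurface",
                sigma_mm,
            )
    verts, faces, _, _ = measure.marching_cubes(field, level=0.5, spacing=tuple(spacing))
    verts = verts - (pad - 0.5) * spacing  # undo padding shift, apply centre offset
    return verts, faces


def mesh_area(vertices: np.ndarray, faces: np.ndarray) -> float:
    """Sum of triangle areas of a mesh in mm coordinates."""
    return float(measure.mesh_surface_area(np.asarray(vertices, float), np.asarray(faces)))


def surface_area_mesh(
    mask: VesselMask, smooth_sigma_mm: float | str | None = "auto"
) -> tuple[SurfaceResult, tuple[np.ndarray, np.ndarray]]:
    """Total vessel surface area from the marching-cubes isosurface.

    ``smooth_sigma_mm`` is forwarded to :func:`mask_to_mesh` (anti-aliased
    extraction by default; pass ``None`` for the raw binary isosurface,
    which is preferable for deliberately blocky solids).  Returns the result
    together with the (vertices, faces) mesh so callers can export it or
    apply magnification correction.
    """
    verts, faces = mask_to_mesh(mask, smooth_sigma_mm=smooth_sigma_mm)
    return (
        SurfaceResult(area_mm2=mesh_area(verts, faces), method="mesh", n_triangles=len(faces)),
        (verts, faces),
    )


def surface_area_voxel_faces(mask: VesselMask) -> SurfaceResult:
    """Exact total area of exposed voxel faces (6-neighbourhood).

    A face is exposed when the neighbour across it is background or outside
    the volume.  Face areas are dy*dz, dx*dz and dx*dy for faces normal to
    x, y and z.
    """
    dx, dy, dz = mask.meta.spacing_mm
    m = np.pad(mask.voxels, 1)
    face_areas = (dy * dz, dx * dz, dx * dy)
    total = 0.0
    for axis, fa in enumerate(face_areas):
        shifted_fwd = np.roll(m, -1, axis=axis)
        shifted_back = np.roll(m, 1, axis=axis)
        exposed = int(np.sum(m & ~shifted_fwd)) + int(np.sum(m & ~shifted_back))
        total += exposed * fa
    return SurfaceResult(area_mm2=total, method="voxel_faces")


def bennett_scale(params: MagnificationParams) -> float:
    """Lateral magnification factor k = (AL - 1.82) / (AL_ref - 1.82).

    k is the factor by which the true lateral extent of the scanned region
    exceeds the nominal extent assumed by the device; k = 1 at the reference
    axial length, k > 1 for longer (myopic) eyes.
    """
    return (params.al_mm - params.bennett_offset) / (params.al_ref_mm - params.bennett_offset)


def apply_magnification_correction(
    result: SurfaceResult,
    mesh: tuple[np.ndarray, np.ndarray] | None,
    params: MagnificationParams,
    mode: str = "mesh",
) -> SurfaceResult:
    """Rescale the measurement to the eye's true lateral scale.

    ``mode="mesh"`` multiplies lateral (x, y) vertex coordinates by k, leaves
    depth unchanged, and recomputes the triangle areas — correct for a
    surface embedded in 3D, where purely axial facets scale by k, not k^2.
    ``mode="planar"`` applies the 2D en-face convention area * k^2.
    """
    k = bennett_scale(params)
    if mode == "planar":
        corrected = result.area_mm2 * k * k
    elif mode == "mesh":
        if mesh is None:
            raise ValueError(
                "mesh-mode correction needs the triangulated surface; run surface_area_mesh first"
            )
        verts, faces = mesh
        scaled = np.asarray(verts, float).copy()
        scaled[:, 0] *= k
        scaled[:, 1] *= k
        corrected = mesh_area(scaled, faces)
    else:
        raise ValueError(f"mode must be 'mesh' or 'planar', got {mode!r}")
    return SurfaceResult(
        area_mm2=result.area_mm2,
        method=result.method,
        n_triangles=result.n_triangles,
        corrected_area_mm2=corrected,
        correction_factor_k=k,
    )
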