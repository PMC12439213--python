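"""Geometric agreement metrics between binary structure masks.

Five metrics are computed for a (test, reference) pair on a shared grid:

* DSC — Dice similarity coefficient, ``2|A∩B| / (|A| + |B|)`` by voxel count.
* HD — Hausdorff distance: the symmetric maximum of nearest-surface
  distances, with surfaces extracted by face-connected binary erosion and
  distances from an anisotropic Euclidean distance transform (mm).
* MSD — mean surface distance: the average of the two directed mean
  nearest-surface distances (the "average symmetric surface distance").
* VD — signed volume difference, test minus reference, in cc, plus the
  relative form in % of the reference volume.
* CMD — Euclidean distance between the occupancy centroids in physical
  coordinates (mm).

Distances are measured between surface-voxel centers; there is no
sub-voxel surface model.  For spinal cords, :func:`apply_caudal_cutoff`
harmonizes the caudal (inferior) extent of all masks in a comparison
before the surface metrics are taken, so equal longitudinal extents are
compared (z increases cranially).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import EmptyMaskError, GridMismatchError
from .io import ImageGrid, StructureMask

__all__ = [
    "GeometryReport",
    "SurfaceSet",
    "surface_voxels",
    "directed_surface_distances",
    "dice",
    "hausdorff",
    "mean_surface_distance",
    "volume_cc",
    "volume_difference",
    "centre_of_mass_difference",
    "apply_caudal_cutoff",
    "evaluate_pair",
]

# face-connected (6-neighbourhood) structuring element
_STRUCT6 = ndimage.generate_binary_structure(3, 1)


@dataclass(frozen=True)
class GeometryReport:
    """The five per-pair agreement metrics; NaN marks a missing value."""

    msd_mm: float
    dsc: float
    hd_mm: float
    vd_cc: float
    vd_rel_pct: float
    cmd_mm: float

    def as_dict(self) -> dict[str, float]:
        return {
            "msd_mm": self.msd_mm,
            "dsc": self.dsc,
            "hd_mm": self.hd_mm,
            "vd_cc": self.vd_cc,
            "vd_rel_pct": self.vd_rel_pct,
            "cmd_mm": self.cmd_mm,
        }


@dataclass
class SurfaceSet:
    """Boolean surface occupancy of a structure plus its parent grid."""

    voxels: np.ndarray
    grid: ImageGrid

    @property
    def indices(self) -> np.ndarray:
        """(n, 3) integer voxel indices of the surface."""
        return np.argwhere(self.voxels)


def _check_same_grid(a: StructureMask, b: StructureMask) -> None:
    if not a.grid.compatible(b.grid):
        raise GridMismatchError(
            f"masks {a.structure_name!r} and {b.structure_name!r} are on different grids"
        )


def _require_nonempty(mask: StructureMask) -> None:
    if mask.is_empty:
        raise EmptyMaskError(f"empty structure {mask.structure_name!r}")


def _surface_array(voxels: np.ndarray) -> np.ndarray:
    # outside-volume counts as unset, so border voxels are surface
    eroded = ndimage.binary_erosion(voxels, structure=_STRUCT6, border_value=0)
    return voxels & ~eroded


def surface_voxels(mask: StructureMask) -> SurfaceSet:
    """Voxels set in the mask but not in its face-connected erosion.

    A single isolated voxel (and any one-voxel-thick sheet) is entirely
    surface, since the erosion removes it.
    """
    _require_nonempty(mask)
    return SurfaceSet(_surface_array(mask.voxels), mask.grid)


def _directed_distances(from_surf: np.ndarray, to_surf: np.ndarray, spacing) -> np.ndarray:
    # EDT of the complement of `to`: distance from every voxel to the
    # nearest `to` surface voxel, with per-axis sampling = spacing (mm)
    dt = ndimage.distance_transform_edt(~to_surf, sampling=spacing)
    return dt[from_surf]


def directed_surface_distances(
    from_surface: SurfaceSet, to_surface: SurfaceSet, spacing=None
) -> np.ndarray:
    """For each voxel of ``from_surface``, distance (mm) to the nearest
    voxel of ``to_surface``, anisotropic spacing applied."""
    if not from_surface.grid.compatible(to_surface.grid):
        raise GridMismatchError("surfaces are on different grids")
    if spacing is None:
        spacing = from_surface.grid.spacing
    return _directed_distances(from_surface.voxels, to_surface.voxels, spacing)


def _cropped_pair(a: StructureMask, b: StructureMask):
    """Crop both occupancy arrays to the union bounding box plus one voxel.

    The pad preserves erosion border behaviour except where the original
    array border was already the limit, so surface extraction and surface
    distances are identical to the full-grid computation.
    """
    union = a.voxels | b.voxels
    sl = []
    for ax in range(3):
        proj = np.any(union, axis=tuple(i for i in range(3) if i != ax))
        nz = np.flatnonzero(proj)
        sl.append(slice(max(int(nz[0]) - 1, 0), min(int(nz[-1]) + 2, union.shape[ax])))
    sl = tuple(sl)
    return a.voxels[sl], b.voxels[sl]


def _surface_distance_sets(a: StructureMask, b: StructureMask):
    _check_same_grid(a, b)
    _require_nonempty(a)
    _require_nonempty(b)
    va, vb = _cropped_pair(a, b)
    sa, sb = _surface_array(va), _surface_array(vb)
    spacing = a.grid.spacing
    return (
        _directed_distances(sa, sb, spacing),
        _directed_distances(sb, sa, spacing),
    )


def dice(a: StructureMask, b: StructureMask) -> float:
    """Dice similarity coefficient by voxel counting; undefined if both empty."""
    _check_same_grid(a, b)
    na = int(a.voxels.sum())
    nb = int(b.voxels.sum())
    if na + nb == 0:
        raise EmptyMaskError("undefined DSC: both masks are empty")
    inter = int((a.voxels & b.voxels).sum())
    return 2.0 * inter / (na + nb)


def hausdorff(a: StructureMask, b: StructureMask) -> float:
    """Symmetric maximum nearest-surface distance in mm."""
    d_ab, d_ba = _surface_distance_sets(a, b)
    return float(max(d_ab.max(), d_ba.max()))


def mean_surface_distance(a: StructureMask, b: StructureMask) -> float:
    """Average of the two directed mean nearest-surface distances, mm."""
    d_ab, d_ba = _surface_distance_sets(a, b)
    return float((d_ab.mean() + d_ba.mean()) / 2.0)


def volume_cc(mask: StructureMask) -> float:
    """Occupied volume in cc: set-voxel count times voxel volume."""
    return float(mask.voxels.sum()) * mask.grid.voxel_volume_cc


def volume_difference(test: StructureMask, ref: StructureMask) -> tuple[float, float]:
    """Signed (test − reference) volume difference: absolute cc and % of reference.

    The relative form is NaN when the reference is empty; the absolute form
    is always returned.
    """
    _check_same_grid(test, ref)
    v_test = volume_cc(test)
    v_ref = volume_cc(ref)
    vd_cc = v_test - v_ref
    vd_rel = 100.0 * vd_cc / v_ref if v_ref > 0 else float("nan")
    return vd_cc, vd_rel


def centre_of_mass_difference(a: StructureMask, b: StructureMask) -> float:
    """Distance in mm between the occupancy centroids in physical coordinates."""
    _check_same_grid(a, b)
    _require_nonempty(a)
    _require_nonempty(b)
    spacing = np.asarray(a.grid.spacing)
    com_a = np.asarray(ndimage.center_of_mass(a.voxels)) * spacing
    com_b = np.asarray(ndimage.center_of_mass(b.voxels)) * spacing
    return float(np.linalg.norm(com_a - com_b))


def apply_caudal_cutoff(masks: list[StructureMask]) -> list[StructureMask]:
    """Truncate all masks at the most cranial of their caudal (lowest-z) ends.

    With z increasing cranially, the cut slice z* is the maximum over masks
    of each mask's lowest occupied slice index; all voxels below z* are
    cleared, voxels at and above z* are untouched.  Idempotent.
    """
    if len(masks) < 2:
        raise ValueError("caudal cut-off needs at least two masks")
    for m in masks:
        _require_nonempty(m)
        if not m.grid.compatible(masks[0].grid):
            raise GridMismatchError("caudal cut-off requires a shared grid")
    lowest = [int(np.nonzero(m.voxels.any(axis=(0, 1)))[0][0]) for m in masks]
    z_star = max(lowest)
    out = []
    for m in masks:
        vox = m.voxels.copy()
        vox[:, :, :z_star] = False
        out.append(StructureMask(m.grid, vox, m.structure_name))
    return out


def evaluate_pair(test: StructureMask, ref: StructureMask) -> GeometryReport:
    """All five metrics for one (test, reference) pair.

    Degraded inputs do not raise: if either mask is empty the surface and
    centroid metrics are NaN, DSC is 0 when exactly one is empty (NaN when
    both are), and the absolute volume difference is always computed.
    Spinal-cord pairs should be passed through :func:`apply_caudal_cutoff`
    first; the pipeline enforces this by structure name.
    """
    _check_same_grid(test, ref)
    nan = float("nan")
    voxel_cc = test.grid.voxel_volume_cc
    if test.is_empty and ref.is_empty:
        return GeometryReport(nan, nan, nan, 0.0, nan, nan)
    if test.is_empty or ref.is_empty:
        vd_cc, vd_rel = volume_difference(test, ref)
        return GeometryReport(nan, dice(test, ref), nan, vd_cc, vd_rel, nan)
    # all metrics from one union-bbox crop; distances and counts are
    # identical to the full-grid computation
    va, vb = _cropped_pair(test, ref)
    spacing = np.asarray(test.grid.spacing)
    na, nb = int(va.sum()), int(vb.sum())
    inter = int((va & vb).sum())
    sa, sb = _surface_array(va), _surface_array(vb)
    d_ab = _directed_distances(sa, sb, spacing)
    d_ba = _directed_distances(sb, sa, spacing)
    com_a = np.asarray(ndimage.center_of_mass(va)) * spacing
    com_b = np.asarray(ndimage.center_of_mass(vb)) * spacing
    vd_cc = (na - nb) * voxel_cc
    return GeometryReport(
        msd_mm=float((d_ab.mean() + d_ba.mean()) / 2.0),
        dsc=2.0 * inter / (na + nb),
        hd_mm=float(max(d_ab.max(), d_ba.max())),
        vd_cc=vd_cc,
        vd_rel_pct=100.0 * vd_cc / (nb * voxel_cc),
        cmd_mm=float(np.linalg.norm(com_a - com_b)),
    )
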