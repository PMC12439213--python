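"""Reading and writing external representations of contour studies.

Coordinate convention, used everywhere in the package: voxel index
``(i, j, k)`` maps to patient coordinates ``origin + index * spacing`` in
millimetres, where the axes are (x, y, z) and z increases cranially
(toward the head).  The z convention matters for the spinal-cord caudal
cut-off applied by :mod:`contourqa.geometry`.

Supported formats
-----------------
* Planar contours: a small JSON dialect,
  ``{"structure": str, "slices": [{"z": mm, "polygons": [[[x, y], ...], ...]}]}``.
* Volumetric masks and dose grids: NIfTI (``.nii`` / ``.nii.gz``) via
  nibabel, with spacing taken from the header zooms and origin from the
  affine translation.  (NRRD is not supported in this build.)
* DVH summaries: a minimal plain-text block dialect standing in for a TPS
  export (the real export layout is vendor-specific); blocks are separated
  by blank lines, each starting ``Structure: <name>`` followed by
  ``Min/Max/Mean/Median Dose [Gy]: <value>`` lines.
* Contouring times: CSV with columns ``patient_id,group,minutes``.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

from .errors import ParseError

__all__ = [
    "ImageGrid",
    "ContourSet",
    "StructureMask",
    "DVHSummary",
    "TimingRecord",
    "TIMED_GROUPS",
    "read_contour_json",
    "write_contour_json",
    "rasterize",
    "read_mask_volume",
    "write_mask_volume",
    "read_dvh_export",
    "write_dvh_export",
    "read_timing_csv",
    "write_timing_csv",
    "round_half_minute",
]

TIMED_GROUPS = ("manual", "adjusted", "processing")


@dataclass(frozen=True)
class ImageGrid:
    """A regular 3D voxel lattice in patient coordinates (mm)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if len(self.shape) != 3 or any(n < 1 for n in self.shape):
            raise ValueError(f"grid shape must be three integers >= 1, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"grid spacing must be three positive reals, got {self.spacing}")

    @property
    def voxel_volume_cc(self) -> float:
        """Volume of one voxel in cubic centimetres."""
        sx, sy, sz = self.spacing
        return sx * sy * sz / 1000.0

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical coordinates (mm) of voxel centers along one axis."""
        return self.origin[axis] + np.arange(self.shape[axis]) * self.spacing[axis]

    def compatible(self, other: "ImageGrid", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and all(abs(a - b) <= tol for a, b in zip(self.spacing, other.spacing))
            and all(abs(a - b) <= tol for a, b in zip(self.origin, other.origin))
        )

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff


@dataclass
class ContourSet:
    """Planar polygons of one structure, grouped per axial slice.

    ``slices`` is a list of ``(z_mm, polygons)`` with strictly increasing z;
    each polygon is an ``(n, 2)`` array of (x, y) vertices in mm, n >= 3.
    """

    structure_name: str
    slices: list[tuple[float, list[np.ndarray]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        zs = [z for z, _ in self.slices]
        if any(b <= a for a, b in zip(zs, zs[1:])):
            raise ValueError("slice z values must be strictly increasing")
        for z, polys in self.slices:
            for poly in polys:
                if np.asarray(poly).shape[0] < 3:
                    raise ValueError(f"polygon with < 3 vertices on slice z={z}")


@dataclass
class StructureMask:
    """Binary occupancy of one structure on an :class:`ImageGrid`."""

    grid: ImageGrid
    voxels: np.ndarray
    structure_name: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.shape != self.grid.shape:
            raise ValueError(
                f"occupancy shape {self.voxels.shape} != grid shape {self.grid.shape}"
            )

    @property
    def is_empty(self) -> bool:
        return not self.voxels.any()

    def copy(self) -> "StructureMask":
        return StructureMask(self.grid, self.voxels.copy(), self.structure_name)


@dataclass(frozen=True)
class DVHSummary:
    """Dose summary of one structure: Dmin/Dmax/Dmean/Dmedian in Gy."""

    structure_name: str
    d_min: float
    d_max: float
    d_mean: float
    d_median: float

    def __post_init__(self) -> None:
        tol = 1e-9
        if not (
            self.d_min <= self.d_median + tol
            and self.d_median <= self.d_max + tol
            and self.d_min <= self.d_mean + tol
            and self.d_mean <= self.d_max + tol
        ):
            raise ValueError(
                f"inconsistent dose summary for {self.structure_name!r}: "
                f"min={self.d_min}, median={self.d_median}, mean={self.d_mean}, max={self.d_max}"
            )

    def value(self, metric: str) -> float:
        return {"d_min": self.d_min, "d_max": self.d_max,
                "d_mean": self.d_mean, "d_median": self.d_median}[metric]


@dataclass(frozen=True)
class TimingRecord:
    """Minutes spent on one patient's structure set, at half-minute resolution."""

    patient_id: str
    group: str
    minutes: float

    def __post_init__(self) -> None:
        if self.group not in TIMED_GROUPS:
            raise ValueError(f"unknown timing group {self.group!r}; expected one of {TIMED_GROUPS}")
        if self.minutes < 0:
            raise ValueError(f"negative minutes: {self.minutes}")
        if abs(self.minutes * 2 - round(self.minutes * 2)) > 1e-9:
            raise ValueError(f"minutes must be at half-minute resolution, got {self.minutes}")


def round_half_minute(minutes: float) -> float:
    """Round to the nearest half minute; exact ties round up (17.25 -> 17.5)."""
    return math.floor(minutes * 2.0 + 0.5) / 2.0


# ---------------------------------------------------------------------------
# contour JSON


def read_contour_json(path: str | Path) -> ContourSet:
    """Read the contour JSON dialect; slices are returned sorted by z."""
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: malformed JSON: {exc}") from exc
    if not isinstance(payload, dict) or "structure" not in payload or "slices" not in payload:
        raise ParseError(f"{path}: expected object with 'structure' and 'slices' keys")
    slices: list[tuple[float, list[np.ndarray]]] = []
    for entry in payload["slices"]:
        try:
            z = float(entry["z"])
        except (KeyError, TypeError, ValueError) as exc:
            raise ParseError(f"{path}: slice with missing or non-numeric z: {entry!r}") from exc
        polys = []
        for poly in entry.get("polygons", []):
            try:
                arr = np.asarray(poly, dtype=float)
            except (TypeError, ValueError) as exc:
                raise ParseError(f"{path}: slice z={z}: non-numeric coordinate") from exc
            if arr.ndim != 2 or arr.shape[1] != 2 or not np.all(np.isfinite(arr)):
                raise ParseError(f"{path}: slice z={z}: non-numeric or malformed polygon")
            if arr.shape[0] < 3:
                raise ParseError(f"{path}: slice z={z}: polygon with {arr.shape[0]} < 3 vertices")
            polys.append(arr)
        slices.append((z, polys))
    slices.sort(key=lambda item: item[0])
    try:
        return ContourSet(str(payload["structure"]), slices)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_contour_json(contours: ContourSet, path: str | Path) -> None:
    payload = {
        "structure": contours.structure_name,
        "slices": [
            {"z": z, "polygons": [np.asarray(p, dtype=float).tolist() for p in polys]}
            for z, polys in contours.slices
        ],
    }
    Path(path).write_text(json.dumps(payload, sort_keys=True))


# ---------------------------------------------------------------------------
# rasterization

_EDGE_EPS = 1e-9


def _points_in_polygon(xs: np.ndarray, ys: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Even-odd inclusion of points in one polygon; on-edge counts as inside.

    ``xs``/``ys`` are flat coordinate arrays of equal length.  Crossing
    number with the half-open edge rule [y1 <= y < y2), plus an explicit
    on-segment test so points exactly on the boundary are inside.
    """
    x1, y1 = poly[:, 0], poly[:, 1]
    x2, y2 = np.roll(x1, -1), np.roll(y1, -1)
    inside = np.zeros(xs.shape, dtype=bool)
    on_edge = np.zeros(xs.shape, dtype=bool)
    for ex1, ey1, ex2, ey2 in zip(x1, y1, x2, y2):
        crosses = (ey1 <= ys) != (ey2 <= ys)
        if np.any(crosses):
            x_int = ex1 + (ys[crosses] - ey1) * (ex2 - ex1) / (ey2 - ey1)
            hit = np.zeros(xs.shape, dtype=bool)
            hit[crosses] = xs[crosses] < x_int
            inside ^= hit
        # on-segment: zero cross product and inside the segment's bbox
        cross = (ex2 - ex1) * (ys - ey1) - (ey2 - ey1) * (xs - ex1)
        scale = max(abs(ex2 - ex1), abs(ey2 - ey1), 1.0)
        bbox = (
            (xs >= min(ex1, ex2) - _EDGE_EPS)
            & (xs <= max(ex1, ex2) + _EDGE_EPS)
            & (ys >= min(ey1, ey2) - _EDGE_EPS)
            & (ys <= max(ey1, ey2) + _EDGE_EPS)
        )
        on_edge |= bbox & (np.abs(cross) <= _EDGE_EPS * scale)
    return inside | on_edge


def rasterize(contours: ContourSet, grid: ImageGrid) -> StructureMask:
    """Convert planar contours to a binary volumetric mask.

    A voxel is set iff its center lies inside an odd number of the slice's
    polygons (even-odd rule; centers exactly on an edge count as inside),
    so a polygon drawn inside another cuts a hole.  Every contour z must lie
    within half a slice spacing of a grid slice.
    """
    nx, ny, nz = grid.shape
    sx, sy, sz = grid.spacing
    ox, oy, oz = grid.origin
    voxels = np.zeros(grid.shape, dtype=bool)
    for z, polys in contours.slices:
        k = int(round((z - oz) / sz))
        if k < 0 or k >= nz or abs(z - (oz + k * sz)) > sz / 2 + 1e-9:
            raise ParseError(
                f"contour slice z={z} mm is farther than {sz / 2} mm from every grid slice"
            )
        parity = np.zeros((nx, ny), dtype=bool)
        for poly in polys:
            lo = poly.min(axis=0) - _EDGE_EPS
            hi = poly.max(axis=0) + _EDGE_EPS
            i0 = max(0, math.ceil((lo[0] - ox) / sx))
            i1 = min(nx - 1, math.floor((hi[0] - ox) / sx))
            j0 = max(0, math.ceil((lo[1] - oy) / sy))
            j1 = min(ny - 1, math.floor((hi[1] - oy) / sy))
            if i1 < i0 or j1 < j0:
                continue
            ii, jj = np.meshgrid(
                np.arange(i0, i1 + 1), np.arange(j0, j1 + 1), indexing="ij"
            )
            xs = ox + ii.ravel() * sx
            ys = oy + jj.ravel() * sy
            hit = _points_in_polygon(xs, ys, poly).reshape(ii.shape)
            parity[i0 : i1 + 1, j0 : j1 + 1] ^= hit
        voxels[:, :, k] |= parity
    return StructureMask(grid, voxels, contours.structure_name)


# ---------------------------------------------------------------------------
# volumetric masks (NIfTI)


def read_mask_volume(path: str | Path) -> StructureMask:
    """Read a NIfTI volume as a binary mask; non-zero voxels are set."""
    path = Path(path)
    img = nib.load(str(path))
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    if len(zooms) < 3 or any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise ParseError(f"{path}: missing or invalid voxel spacing in header (zooms={zooms})")
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        data = np.squeeze(data)
        if data.ndim != 3:
            raise ParseError(f"{path}: expected a 3D volume, got shape {data.shape}")
    origin = tuple(float(v) for v in np.asarray(img.affine)[:3, 3])
    grid = ImageGrid(data.shape, zooms, origin)
    name = path.name.removesuffix(".gz").removesuffix(".nii")
    return StructureMask(grid, data != 0, name)


def write_mask_volume(mask: StructureMask, path: str | Path) -> None:
    """Write a mask as uint8 NIfTI with a diagonal affine (spacing + origin).

    Note: NIfTI stores zooms as float32, so spacings should be float32-
    representable for exact round-trips.
    """
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), affine=mask.grid.affine())
    img.header.set_zooms(mask.grid.spacing)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# DVH text export

_DVH_FIELDS = {
    "Min Dose [Gy]": "d_min",
    "Max Dose [Gy]": "d_max",
    "Mean Dose [Gy]": "d_mean",
    "Median Dose [Gy]": "d_median",
}


def read_dvh_export(path: str | Path) -> list[DVHSummary]:
    """Parse the plain-text DVH block dialect into per-structure summaries."""
    path = Path(path)
    blocks = [b for b in path.read_text().split("\n\n") if b.strip()]
    summaries = []
    for block in blocks:
        lines = [ln.strip() for ln in block.splitlines() if ln.strip()]
        if not lines[0].startswith("Structure:"):
            raise ParseError(f"{path}: block does not start with 'Structure:': {lines[0]!r}")
        name = lines[0].split(":", 1)[1].strip()
        values: dict[str, float] = {}
        for line in lines[1:]:
            key, _, raw = line.partition(":")
            key = key.strip()
            if key in _DVH_FIELDS:
                try:
                    values[_DVH_FIELDS[key]] = float(raw)
                except ValueError as exc:
                    raise ParseError(f"{path}: structure {name!r}: bad dose value {raw!r}") from exc
        missing = set(_DVH_FIELDS.values()) - set(values)
        if missing:
            raise ParseError(
                f"{path}: structure {name!r} missing dose lines: {sorted(missing)}"
            )
        summaries.append(DVHSummary(name, **values))
    return summaries


def write_dvh_export(summaries: Sequence[DVHSummary], path: str | Path) -> None:
    blocks = []
    for s in summaries:
        blocks.append(
            "\n".join(
                [
                    f"Structure: {s.structure_name}",
                    f"Min Dose [Gy]: {s.d_min:.6g}",
                    f"Max Dose [Gy]: {s.d_max:.6g}",
                    f"Mean Dose [Gy]: {s.d_mean:.6g}",
                    f"Median Dose [Gy]: {s.d_median:.6g}",
                ]
            )
        )
    Path(path).write_text("\n\n".join(blocks) + "\n")


# ---------------------------------------------------------------------------
# timing CSV


def read_timing_csv(path: str | Path) -> list[TimingRecord]:
    """Read timing records; minutes are rounded to the nearest half minute."""
    path = Path(path)
    records = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"patient_id", "group", "minutes"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ParseError(f"{path}: expected CSV header patient_id,group,minutes")
        for row in reader:
            try:
                minutes = float(row["minutes"])
            except ValueError as exc:
                raise ParseError(f"{path}: non-numeric minutes {row['minutes']!r}") from exc
            if minutes < 0:
                raise ParseError(f"{path}: negative minutes for patient {row['patient_id']!r}")
            group = row["group"].strip()
            if group not in TIMED_GROUPS:
                raise ParseError(
                    f"{path}: unknown group {group!r} (timed groups are {TIMED_GROUPS}; "
                    "AI processing time belongs to group 'processing')"
                )
            records.append(TimingRecord(row["patient_id"], group, round_half_minute(minutes)))
    return records


def write_timing_csv(records: Sequence[TimingRecord], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id", "group", "minutes"])
        for r in records:
            writer.writerow([r.patient_id, r.group, f"{r.minutes:g}"])
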