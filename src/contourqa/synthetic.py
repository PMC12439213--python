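"""Synthetic multi-observer contouring study generator.

Because no clinical cohort ships with the package, every pipeline stage is
exercised on a digital phantom: ~12 head-and-neck organ-at-risk analogues
built from parametric shapes (ellipsoids, z-aligned elliptic cylinders for
the spinal cord and brainstem, a half-torus mandible), contoured by three
groups of simulated observers:

* ``manual`` — high observer noise (default boundary SD 2.0 mm), no bias;
* ``adjusted`` — AI contours after clinician correction: low residual
  noise (0.8 mm) but retaining the AI's slight systematic expansion
  (+0.5 mm), mirroring the observation that AI-enlarged diameters largely
  survive correction;
* ``ai_only`` — the raw AI output: lowest noise (0.6 mm), +0.5 mm margin,
  one deterministic "observer".

Observer noise is modelled on the signed distance field of the ground
truth: a white-noise field smoothed with a ~6 mm Gaussian is scaled to the
target boundary SD, added together with the systematic margin, and the
result re-thresholded at zero.  This yields spatially correlated boundary
errors rather than voxel salt-and-pepper.  Tubular organs additionally get
integer caudal-extent jitter.  Contouring times are log-normal (median 55
min manual, 17 min adjusted, 10 min AI processing — right-skewed like
observed ranges 17–151 / 7–42 / 7–21 min).

Everything is deterministic given the seeds; per-mask RNG streams are
derived from (seed, observer, patient, organ) so any single mask can be
regenerated in isolation.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .dose import DoseGrid
from .errors import ContourQAError
from .io import (
    ImageGrid,
    StructureMask,
    TimingRecord,
    read_mask_volume,
    read_timing_csv,
    round_half_minute,
    write_mask_volume,
    write_timing_csv,
)

__all__ = [
    "Ellipsoid",
    "ZCylinder",
    "HalfTorus",
    "PhantomSpec",
    "ObserverModel",
    "TimingModel",
    "SyntheticStudy",
    "default_phantom",
    "default_observer_models",
    "make_phantom",
    "perturb_mask",
    "make_dose",
    "make_timing",
    "make_cohort",
    "load_study",
]

GROUPS = ("manual", "adjusted", "ai_only")


def _rng(seed: int, *keys) -> np.random.Generator:
    """Deterministic child generator from an integer seed plus string keys."""
    entropy = [int(seed) & 0x7FFFFFFF] + [zlib.crc32(str(k).encode()) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))


# ---------------------------------------------------------------------------
# parametric shapes (implicit solids, coordinates in mm)


@dataclass(frozen=True)
class Ellipsoid:
    center: tuple[float, float, float]
    radii: tuple[float, float, float]

    def contains(self, x, y, z):
        cx, cy, cz = self.center
        rx, ry, rz = self.radii
        return ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2 <= 1.0

    def bounds(self):
        c = np.asarray(self.center)
        r = np.asarray(self.radii)
        return c - r, c + r

    def translated(self, offset):
        return replace(self, center=tuple(np.asarray(self.center) + offset))


@dataclass(frozen=True)
class ZCylinder:
    """Elliptic cylinder along z, for spinal-cord / brainstem analogues.

    The z interval is half-open ([z0, z1)) so a span landing exactly on
    slice positions covers span/spacing slices, not one extra.
    """

    center_xy: tuple[float, float]
    radii_xy: tuple[float, float]
    z_range: tuple[float, float]

    def contains(self, x, y, z):
        cx, cy = self.center_xy
        rx, ry = self.radii_xy
        z0, z1 = self.z_range
        return (((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 <= 1.0) & (z >= z0) & (z < z1)

    def bounds(self):
        cx, cy = self.center_xy
        rx, ry = self.radii_xy
        z0, z1 = self.z_range
        return np.array([cx - rx, cy - ry, z0]), np.array([cx + rx, cy + ry, z1])

    def translated(self, offset):
        dx, dy, dz = offset
        return replace(
            self,
            center_xy=(self.center_xy[0] + dx, self.center_xy[1] + dy),
            z_range=(self.z_range[0] + dz, self.z_range[1] + dz),
        )


@dataclass(frozen=True)
class HalfTorus:
    """Anterior half of a torus in the axial plane — a mandible analogue."""

    center: tuple[float, float, float]
    major_radius: float
    tube_radius: float

    def contains(self, x, y, z):
        cx, cy, cz = self.center
        ring = np.sqrt((x - cx) ** 2 + (y - cy) ** 2) - self.major_radius
        return (ring**2 + (z - cz) ** 2 <= self.tube_radius**2) & (y <= cy)

    def bounds(self):
        cx, cy, cz = self.center
        reach = self.major_radius + self.tube_radius
        return (
            np.array([cx - reach, cy - reach, cz - self.tube_radius]),
            np.array([cx + reach, cy, cz + self.tube_radius]),
        )

    def translated(self, offset):
        return replace(self, center=tuple(np.asarray(self.center) + offset))


# ---------------------------------------------------------------------------
# phantom specification


@dataclass(frozen=True)
class PhantomSpec:
    """Grid plus named organ shapes; organs must fit with a 2-voxel margin."""

    grid: ImageGrid = ImageGrid((96, 96, 64), (2.0, 2.0, 2.0))
    organs: Mapping[str, object] = field(default_factory=dict)
    tubular: tuple[str, ...] = ("spinal_cord",)


def default_phantom() -> PhantomSpec:
    """Twelve OAR analogues on a 96x96x64 grid at 2 mm isotropic spacing.

    Positions are schematic head-and-neck anatomy in a 192x192x128 mm
    volume: the cord runs the z extent posteriorly, the brainstem sits
    above it, the mandible arcs anteriorly, paired parotids/cochleas flank.
    """
    organs = {
        "brainstem": ZCylinder((96.0, 120.0), (8.0, 7.0), (88.0, 114.0)),
        "cochlea_l": Ellipsoid((55.0, 115.0, 100.0), (4.0, 4.0, 4.0)),
        "cochlea_r": Ellipsoid((137.0, 115.0, 100.0), (4.0, 4.0, 4.0)),
        "larynx": Ellipsoid((96.0, 85.0, 35.0), (15.0, 14.0, 16.0)),
        "mandible": HalfTorus((96.0, 70.0, 42.0), 35.0, 6.0),
        "oral_cavity": Ellipsoid((96.0, 60.0, 70.0), (20.0, 18.0, 14.0)),
        "parotid_l": Ellipsoid((44.0, 95.0, 62.0), (12.0, 16.0, 20.0)),
        "parotid_r": Ellipsoid((148.0, 95.0, 62.0), (12.0, 16.0, 20.0)),
        "pcm": ZCylinder((96.0, 105.0), (13.0, 5.0), (30.0, 80.0)),
        "spinal_cord": ZCylinder((96.0, 130.0), (5.0, 5.0), (10.0, 86.0)),
        "submandibular_r": Ellipsoid((125.0, 70.0, 45.0), (9.0, 8.0, 11.0)),
        "thyroid": Ellipsoid((96.0, 95.0, 20.0), (14.0, 10.0, 9.0)),
    }
    return PhantomSpec(organs=organs)


def _organ_crop(grid: ImageGrid, shape_obj, pad_vox: int = 1):
    """Index slices covering the shape's bounds plus padding, or None if the
    organ would not fit with a 2-voxel margin."""
    lo_mm, hi_mm = shape_obj.bounds()
    origin = np.asarray(grid.origin)
    spacing = np.asarray(grid.spacing)
    lo = np.floor((np.asarray(lo_mm) - origin) / spacing).astype(int)
    hi = np.ceil((np.asarray(hi_mm) - origin) / spacing).astype(int)
    if np.any(lo < 2) or np.any(hi > np.asarray(grid.shape) - 3):
        return None
    lo = np.maximum(lo - pad_vox, 0)
    hi = np.minimum(hi + pad_vox + 1, grid.shape)
    return tuple(slice(int(l), int(h)) for l, h in zip(lo, hi))


def _rasterize_shape(grid: ImageGrid, shape_obj, name: str) -> StructureMask:
    sl = _organ_crop(grid, shape_obj)
    if sl is None:
        raise ContourQAError(f"organ {name!r} does not fit in the grid with a 2-voxel margin")
    coords = [grid.axis_coords(axis)[sl[axis]] for axis in range(3)]
    X, Y, Z = np.meshgrid(*coords, indexing="ij", sparse=True)
    voxels = np.zeros(grid.shape, dtype=bool)
    voxels[sl] = shape_obj.contains(X, Y, Z)
    return StructureMask(grid, voxels, name)


def make_phantom(spec: PhantomSpec) -> dict[str, StructureMask]:
    """Rasterize each organ's implicit equation at voxel centers (no RNG)."""
    return {name: _rasterize_shape(spec.grid, shp, name) for name, shp in spec.organs.items()}


# ---------------------------------------------------------------------------
# observer model


@dataclass(frozen=True)
class ObserverModel:
    """Boundary-noise model for one contouring arm."""

    group: str
    radial_sd_mm: float
    systematic_margin_mm: float = 0.0
    caudal_jitter_slices: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.radial_sd_mm < 0 or self.caudal_jitter_slices < 0:
            raise ValueError("radial SD and caudal jitter must be non-negative")


def default_observer_models(
    n_manual: int = 5, n_adjusted: int = 3, seed: int = 0
) -> dict[str, list[ObserverModel]]:
    """Default arms: noisy manual observers, corrected-AI, and one raw AI."""
    return {
        "manual": [
            ObserverModel("manual", radial_sd_mm=2.0, caudal_jitter_slices=2, seed=seed)
            for _ in range(n_manual)
        ],
        "adjusted": [
            ObserverModel(
                "adjusted", radial_sd_mm=0.8, systematic_margin_mm=0.5,
                caudal_jitter_slices=1, seed=seed,
            )
            for _ in range(n_adjusted)
        ],
        "ai_only": [
            ObserverModel(
                "ai_only", radial_sd_mm=0.6, systematic_margin_mm=0.5,
                caudal_jitter_slices=1, seed=seed,
            )
        ],
    }


_NOISE_SMOOTH_MM = 6.0  # Gaussian sigma of the boundary-noise field


def _signed_distance(voxels: np.ndarray, spacing) -> np.ndarray:
    """Signed distance in mm to the structure boundary, negative inside.

    The two EDTs measure distances between voxel *centers*; the boundary
    lies between opposite-phase voxels, so each side is offset toward it.
    A quarter-voxel offset is used as the even-handed compromise between
    the face-neighbor gap (half a voxel) and the larger diagonal gaps:
    empirically it keeps both margin-dilation and margin-erosion volumes
    within ~10% of their analytic values on coarse grids, where a full
    half-voxel offset over-includes diagonal neighbors.
    """
    half = 0.25 * float(np.mean(spacing))
    d_out = ndimage.distance_transform_edt(~voxels, sampling=spacing)
    d_in = ndimage.distance_transform_edt(voxels, sampling=spacing)
    return np.where(voxels, -(d_in - half), d_out - half)


def _perturb_crop(
    sdf: np.ndarray,
    spacing,
    model: ObserverModel,
    rng: np.random.Generator,
) -> np.ndarray:
    """Threshold the SDF after adding smooth noise and the systematic margin."""
    threshold = model.systematic_margin_mm
    # one retry at halved noise before giving up on an emptied mask
    for sd in (model.radial_sd_mm, model.radial_sd_mm / 2.0):
        if sd == 0:
            noise = 0.0
        else:
            white = rng.standard_normal(sdf.shape)
            smooth = ndimage.gaussian_filter(white, sigma=[_NOISE_SMOOTH_MM / s for s in spacing])
            smooth_sd = smooth.std()
            noise = smooth * (sd / smooth_sd) if smooth_sd > 0 else 0.0
        out = sdf <= threshold + noise
        if out.any():
            return out
    raise ContourQAError("perturbation emptied the mask even at halved noise")


def _apply_caudal_jitter(voxels: np.ndarray, shift: int) -> None:
    """Shift the caudal (lowest-z) end by ``shift`` slices, in place.

    Positive shift retracts the caudal end; negative extends it by
    replicating the lowest occupied slice downward.
    """
    occupied = np.nonzero(voxels.any(axis=(0, 1)))[0]
    if occupied.size == 0 or shift == 0:
        return
    k0 = int(occupied[0])
    if shift > 0:
        voxels[:, :, k0 : min(k0 + shift, voxels.shape[2])] = False
    else:
        template = voxels[:, :, k0]
        for k in range(max(0, k0 + shift), k0):
            voxels[:, :, k] = template


def perturb_mask(
    gt: StructureMask,
    model: ObserverModel,
    observer_id: str,
    patient_id: str,
    is_tubular: bool = False,
    _sdf_crop=None,
) -> StructureMask:
    """Simulate one observer's contour of a ground-truth structure.

    Reproducible: the RNG stream is derived from (model.seed, observer_id,
    patient_id, structure name).  With zero noise and zero margin the
    output equals the input.  ``_sdf_crop`` lets a cohort generator reuse
    the ground truth's signed distance field across observers.
    """
    if gt.is_empty:
        raise ContourQAError(f"cannot perturb empty structure {gt.structure_name!r}")
    rng = _rng(model.seed, observer_id, patient_id, gt.structure_name)
    spacing = gt.grid.spacing
    if _sdf_crop is None:
        _sdf_crop = _sdf_for_mask(gt, model)
    sdf, sl = _sdf_crop
    voxels = np.zeros(gt.grid.shape, dtype=bool)
    voxels[sl] = _perturb_crop(sdf, spacing, model, rng)
    if is_tubular and model.caudal_jitter_slices > 0:
        shift = int(rng.integers(-model.caudal_jitter_slices, model.caudal_jitter_slices + 1))
        _apply_caudal_jitter(voxels, shift)
        if not voxels.any():
            raise ContourQAError("caudal jitter emptied the mask")
    return StructureMask(gt.grid, voxels, gt.structure_name)


def _noise_reach_mm(model: ObserverModel) -> float:
    return 3.0 * model.radial_sd_mm + abs(model.systematic_margin_mm) + 2.0 * _NOISE_SMOOTH_MM


def _sdf_for_mask(gt: StructureMask, model: ObserverModel, reach_mm: float | None = None):
    """Signed distance field on a crop generous enough for the noise model."""
    margin_mm = _noise_reach_mm(model) if reach_mm is None else reach_mm
    pad = np.ceil(margin_mm / np.asarray(gt.grid.spacing)).astype(int) + 1
    idx = np.argwhere(gt.voxels)
    lo = np.maximum(idx.min(axis=0) - pad, 0)
    hi = np.minimum(idx.max(axis=0) + pad + 1, gt.grid.shape)
    sl = tuple(slice(int(l), int(h)) for l, h in zip(lo, hi))
    return _signed_distance(gt.voxels[sl], gt.grid.spacing), sl


# ---------------------------------------------------------------------------
# dose field


def make_dose(
    grid: ImageGrid,
    target_center_mm: Sequence[float],
    prescription_gy: float = 68.0,
    falloff_mm: float = 30.0,
) -> DoseGrid:
    """Gaussian dose falloff around a target center (deterministic).

    dose(v) = prescription * exp(-d(v, center)^2 / (2 * falloff^2)); the
    default prescription emulates 2 Gy x 34 fractions.
    """
    if falloff_mm <= 0:
        raise ValueError("falloff must be positive")
    coords = [grid.axis_coords(axis) for axis in range(3)]
    X, Y, Z = np.meshgrid(*coords, indexing="ij", sparse=True)
    cx, cy, cz = target_center_mm
    d2 = (X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2
    return DoseGrid(grid, prescription_gy * np.exp(-d2 / (2.0 * falloff_mm**2)))


# ---------------------------------------------------------------------------
# timing


@dataclass(frozen=True)
class TimingModel:
    """Log-normal per-patient contouring times (medians in minutes)."""

    manual_median_min: float = 55.0
    manual_dispersion: float = 0.40
    adjusted_median_min: float = 17.0
    adjusted_dispersion: float = 0.33
    processing_median_min: float = 10.0
    processing_dispersion: float = 0.20
    seed: int = 0

    def params(self, group: str) -> tuple[float, float]:
        return {
            "manual": (self.manual_median_min, self.manual_dispersion),
            "adjusted": (self.adjusted_median_min, self.adjusted_dispersion),
            "processing": (self.processing_median_min, self.processing_dispersion),
        }[group]


def make_timing(
    model: TimingModel, n_patients: int, patient_ids: Sequence[str] | None = None
) -> list[TimingRecord]:
    """One manual, adjusted and processing record per patient, half-minute
    rounded; a zero dispersion reproduces the group median exactly."""
    if n_patients < 1:
        raise ValueError("need at least one patient")
    if patient_ids is None:
        patient_ids = [f"P{i + 1:02d}" for i in range(n_patients)]
    records = []
    for pid in patient_ids:
        for group in ("manual", "adjusted", "processing"):
            median, sigma = model.params(group)
            rng = _rng(model.seed, "timing", group, pid)
            minutes = median * float(np.exp(sigma * rng.standard_normal()))
            records.append(TimingRecord(pid, group, round_half_minute(minutes)))
    return records


# ---------------------------------------------------------------------------
# full cohort


@dataclass
class SyntheticStudy:
    """In-memory synthetic study: ground truth, observer masks, dose, timing."""

    grid: ImageGrid
    organs: list[str]
    tubular: tuple[str, ...]
    patients: list[str]
    observers: dict[str, list[str]]  # group -> observer ids
    gt: dict[str, dict[str, StructureMask]]  # patient -> organ -> mask
    masks: dict[tuple[str, str, str], dict[str, StructureMask]]  # (patient, group, obs)
    dose: dict[str, DoseGrid]
    timing: list[TimingRecord]
    manifest: dict

    def write(self, out_dir: str | Path) -> Path:
        """Write the study directory in the package's external formats."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for pid, organs in self.gt.items():
            d = out / "masks" / pid / "gt"
            d.mkdir(parents=True, exist_ok=True)
            for organ, mask in organs.items():
                write_mask_volume(mask, d / f"{organ}.nii")
        for (pid, group, obs), organs in self.masks.items():
            d = out / "masks" / pid / f"{group}__{obs}"
            d.mkdir(parents=True, exist_ok=True)
            for organ, mask in organs.items():
                write_mask_volume(mask, d / f"{organ}.nii")
        if self.dose:
            import nibabel as nib

            (out / "dose").mkdir(exist_ok=True)
            for pid, dg in self.dose.items():
                nib.save(
                    nib.Nifti1Image(dg.dose.astype(np.float32), affine=dg.grid.affine()),
                    str(out / "dose" / f"{pid}.nii"),
                )
        if self.timing:
            write_timing_csv(self.timing, out / "timing.csv")
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=1, sort_keys=True))
        return out


def make_cohort(
    phantom: PhantomSpec | None = None,
    observers: Mapping[str, list[ObserverModel]] | None = None,
    timing: TimingModel | None = None,
    n_patients: int = 10,
    seed: int = 0,
    out_dir: str | Path | None = None,
    omit: Sequence[tuple[str, str, str, str]] = (),
    with_dose: bool = True,
    anatomy_jitter_mm: float = 1.5,
) -> SyntheticStudy:
    """Generate a complete synthetic study, optionally written to disk.

    Patients share the phantom's organ repertoire but differ by small
    random translations of each organ (``anatomy_jitter_mm`` SD per axis).
    ``omit`` lists (patient, group, observer, organ) contours to skip —
    the bookkeeping "exceptions".  Fully reproducible from ``seed``.
    """
    if phantom is None:
        phantom = default_phantom()
    if observers is None:
        observers = default_observer_models(seed=seed)
    if timing is None:
        timing = TimingModel(seed=seed)
    if any(len(models) < 1 for models in observers.values()):
        raise ValueError("every group needs at least one observer")
    omit_set = {tuple(entry) for entry in omit}
    patient_ids = [f"P{i + 1:02d}" for i in range(n_patients)]
    observer_ids = {
        group: [f"{group}{i + 1:02d}" for i in range(len(models))]
        for group, models in observers.items()
    }

    gt: dict[str, dict[str, StructureMask]] = {}
    masks: dict[tuple[str, str, str], dict[str, StructureMask]] = {}
    dose: dict[str, DoseGrid] = {}
    for pid in patient_ids:
        jitter_rng = _rng(seed, "anatomy", pid)
        organs = {}
        for name, shp in phantom.organs.items():
            # clipped at 2 SD so organs keep their grid margin
            offset = np.clip(
                jitter_rng.normal(0.0, anatomy_jitter_mm, size=3),
                -2.0 * anatomy_jitter_mm,
                2.0 * anatomy_jitter_mm,
            )
            organs[name] = _rasterize_shape(phantom.grid, shp.translated(offset), name)
        gt[pid] = organs
        if with_dose:
            # target sits between larynx and cord so serial organs see high dose
            center = np.asarray(phantom.grid.origin) + np.asarray(phantom.grid.shape) * np.asarray(
                phantom.grid.spacing
            ) * np.array([0.5, 0.55, 0.4])
            dose[pid] = make_dose(phantom.grid, center)
        # one SDF per organ, on a crop wide enough for the noisiest model
        reach = max(_noise_reach_mm(m) for models in observers.values() for m in models)
        sdf_cache = {name: _sdf_for_mask(gt_mask, None, reach) for name, gt_mask in organs.items()}
        for group, models in observers.items():
            for obs_id, model in zip(observer_ids[group], models):
                model = replace(model, seed=model.seed if model.seed else seed)
                organ_masks = {}
                for name, gt_mask in organs.items():
                    if (pid, group, obs_id, name) in omit_set:
                        continue
                    organ_masks[name] = perturb_mask(
                        gt_mask,
                        model,
                        obs_id,
                        pid,
                        is_tubular=name in phantom.tubular,
                        _sdf_crop=sdf_cache[name],
                    )
                masks[(pid, group, obs_id)] = organ_masks

    timing_records = make_timing(timing, n_patients, patient_ids)
    manifest = {
        "organs": sorted(phantom.organs),
        "tubular": list(phantom.tubular),
        "patients": patient_ids,
        "observers": observer_ids,
        "omitted": sorted(list(entry) for entry in omit_set),
        "seed": seed,
        "grid": {
            "shape": list(phantom.grid.shape),
            "spacing": list(phantom.grid.spacing),
            "origin": list(phantom.grid.origin),
        },
        "with_dose": with_dose,
    }
    study = SyntheticStudy(
        grid=phantom.grid,
        organs=sorted(phantom.organs),
        tubular=tuple(phantom.tubular),
        patients=patient_ids,
        observers=observer_ids,
        gt=gt,
        masks=masks,
        dose=dose,
        timing=timing_records,
        manifest=manifest,
    )
    if out_dir is not None:
        study.write(out_dir)
    return study


def load_study(study_dir: str | Path) -> SyntheticStudy:
    """Read a study directory written by :meth:`SyntheticStudy.write`."""
    import nibabel as nib

    root = Path(study_dir)
    manifest = json.loads((root / "manifest.json").read_text())
    grid = ImageGrid(
        tuple(manifest["grid"]["shape"]),
        tuple(manifest["grid"]["spacing"]),
        tuple(manifest["grid"]["origin"]),
    )
    gt: dict[str, dict[str, StructureMask]] = {}
    masks: dict[tuple[str, str, str], dict[str, StructureMask]] = {}
    for pid in manifest["patients"]:
        pdir = root / "masks" / pid
        gt[pid] = {
            p.name.removesuffix(".nii"): read_mask_volume(p)
            for p in sorted((pdir / "gt").glob("*.nii"))
        }
        for obs_dir in sorted(pdir.iterdir()):
            if obs_dir.name == "gt" or not obs_dir.is_dir():
                continue
            group, _, obs = obs_dir.name.partition("__")
            masks[(pid, group, obs)] = {
                p.name.removesuffix(".nii"): read_mask_volume(p)
                for p in sorted(obs_dir.glob("*.nii"))
            }
    dose: dict[str, DoseGrid] = {}
    dose_dir = root / "dose"
    if dose_dir.is_dir():
        for p in sorted(dose_dir.glob("*.nii")):
            img = nib.load(str(p))
            dose[p.name.removesuffix(".nii")] = DoseGrid(
                ImageGrid(
                    img.shape[:3],
                    tuple(float(z) for z in img.header.get_zooms()[:3]),
                    tuple(float(v) for v in np.asarray(img.affine)[:3, 3]),
                ),
                np.asanyarray(img.dataobj).astype(float),
            )
    timing = read_timing_csv(root / "timing.csv") if (root / "timing.csv").exists() else []
    return SyntheticStudy(
        grid=grid,
        organs=manifest["organs"],
        tubular=tuple(manifest["tubular"]),
        patients=manifest["patients"],
        observers=manifest["observers"],
        gt=gt,
        masks=masks,
        dose=dose,
        timing=timing,
        manifest=manifest,
    )
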