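"""Per-structure dose summaries and group-vs-reference dose differences.

Dose metrics follow head-and-neck clinical goals: serial organs
(brainstem, spinal cord) and the mandible are judged by maximum dose,
parallel organs (parotids, larynx, oral cavity, pharynx constrictors,
submandibular and thyroid glands, cochleas) by mean dose.  Dmax is the
absolute single-voxel maximum inside the structure — on a 0.25 cm dose
grid one voxel represents 0.0156 cc.  Dose and mask must share a grid;
no resampling is performed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .errors import EmptyMaskError, GridMismatchError, PolicyError
from .io import DVHSummary, ImageGrid, StructureMask

__all__ = [
    "DoseGrid",
    "DoseDifferenceRecord",
    "DEFAULT_METRIC_POLICY",
    "dvh_from_dose",
    "dose_difference",
    "organ_metric_policy",
]


@dataclass
class DoseGrid:
    """A 3D dose distribution in Gy on an :class:`ImageGrid`."""

    grid: ImageGrid
    dose: np.ndarray

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=float)
        if self.dose.shape != self.grid.shape:
            raise ValueError(f"dose shape {self.dose.shape} != grid shape {self.grid.shape}")
        if np.any(self.dose < 0):
            raise ValueError("dose values must be non-negative")


@dataclass(frozen=True)
class DoseDifferenceRecord:
    """Signed dose-metric difference (group minus reference) for one contour."""

    patient_id: str
    structure_name: str
    group: str
    metric: str  # "d_mean" or "d_max"
    delta_gy: float


def dvh_from_dose(dose: DoseGrid, mask: StructureMask) -> DVHSummary:
    """Dmin/Dmax/Dmean/Dmedian in Gy over the mask's voxels.

    Dmax is the absolute single-voxel maximum; the median of an even voxel
    count is the mean of the two central values (numpy convention).
    """
    if not dose.grid.compatible(mask.grid):
        raise GridMismatchError(
            f"dose grid and mask {mask.structure_name!r} are on different grids"
        )
    if mask.is_empty:
        raise EmptyMaskError(f"empty structure {mask.structure_name!r}")
    values = dose.dose[mask.voxels]
    return DVHSummary(
        structure_name=mask.structure_name,
        d_min=float(values.min()),
        d_max=float(values.max()),
        d_mean=float(values.mean()),
        d_median=float(np.median(values)),
    )


def dose_difference(test: DVHSummary, ref: DVHSummary, metric: str) -> float:
    """Signed test − reference for one metric; structure names must match."""
    if test.structure_name != ref.structure_name:
        raise ValueError(
            f"structure mismatch: {test.structure_name!r} vs {ref.structure_name!r}"
        )
    return test.value(metric) - ref.value(metric)


# canonical structure name -> clinical goal metric
DEFAULT_METRIC_POLICY: dict[str, str] = {
    "brainstem": "d_max",
    "spinal_cord": "d_max",
    "mandible": "d_max",
    "parotid": "d_mean",
    "larynx": "d_mean",
    "oral_cavity": "d_mean",
    "pharynx_constrictor": "d_mean",
    "submandibular": "d_mean",
    "thyroid": "d_mean",
    "cochlea": "d_mean",
}

_ALIASES = {
    "sc": "spinal_cord",
    "spinalcord": "spinal_cord",
    "cord": "spinal_cord",
    "pcm": "pharynx_constrictor",
    "pharynxconst": "pharynx_constrictor",
    "oralcavity": "oral_cavity",
    "cavity_oral": "oral_cavity",
    "glnd_submand": "submandibular",
    "glnd_thyroid": "thyroid",
}

_LATERALITY = {"l", "r", "left", "right"}


def _canonical(name: str) -> str:
    tokens = [t for t in re.split(r"[^a-z0-9]+", name.lower()) if t]
    tokens = [t for t in tokens if t not in _LATERALITY]
    key = "_".join(tokens)
    key = _ALIASES.get(key, key)
    return _ALIASES.get(key.replace("_", ""), key)


def organ_metric_policy(structure_name: str, policy: Mapping[str, str] | None = None) -> str:
    """Clinical dose metric ("d_max" or "d_mean") for a structure name.

    Laterality suffixes and common aliases are normalized, so "Parotid_L"
    and "parotid_r" both resolve to the parotid entry.  Entries in
    ``policy`` (keyed by canonical name) override the defaults.
    """
    key = _canonical(structure_name)
    table = dict(DEFAULT_METRIC_POLICY)
    if policy:
        table.update({_canonical(k): v for k, v in policy.items()})
    if key not in table:
        raise PolicyError(f"no dose-metric policy for structure {structure_name!r}")
    return table[key]
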