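"""End-to-end study evaluation: ingest, spinal-cord harmonization, geometry,
dose, aggregation and report serialization.

:func:`run_study` takes a study (a directory written by
:mod:`contourqa.synthetic`, or an in-memory :class:`SyntheticStudy`) and
produces a :class:`RunReport` with

* ``records`` — one tidy row per (patient, OAR, group, observer) with the
  five geometric metrics and the clinical dose-metric delta;
* ``summaries`` — per (metric, OAR, group) percentile summaries;
* ``headline`` — mean observer SDs per metric and group with percent
  reductions relative to the manual arm, median contouring times and time
  saved with/without AI processing, and contour bookkeeping;
* ``exceptions`` — machine-readable reasons for every skipped or degraded
  record.

Tubular organs (default: the spinal cord) are caudally harmonized per
patient across ground truth and all observer masks before the geometric
metrics; dose metrics use the uncut masks, as a planning system would.
Geometry-excluded organs (default: the cochleas, whose extreme relative
size discrepancies distort the geometric tables) are kept in the dose and
time analyses.  Every headline percentage is recomputed from the emitted
summaries as an internal consistency check.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import stats as cstats
from .dose import dvh_from_dose, organ_metric_policy
from .errors import ContourQAError, PolicyError
from .geometry import apply_caudal_cutoff, evaluate_pair
from .synthetic import SyntheticStudy, load_study

__all__ = ["RunConfig", "RunReport", "run_study", "report", "GEOMETRY_METRICS"]

logger = logging.getLogger("contourqa.pipeline")

GEOMETRY_METRICS = ("msd_mm", "dsc", "hd_mm", "vd_cc", "vd_rel_pct", "cmd_mm")
# metrics whose inter-observer SD forms the headline variability numbers
VARIABILITY_METRICS = ("msd_mm", "dsc", "hd_mm", "vd_cc", "cmd_mm")

RECORD_COLUMNS = [
    "patient_id",
    "oar",
    "group",
    "observer",
    *GEOMETRY_METRICS,
    "dose_metric",
    "dose_delta_gy",
]


@dataclass(frozen=True)
class RunConfig:
    """Knobs of one evaluation run; defaults mirror the standard analysis."""

    geometry_excluded: tuple[str, ...] = ("cochlea_l", "cochlea_r")
    tubular: tuple[str, ...] | None = None  # None -> take from study manifest
    processing_time_min: float = 10.0  # fallback if no 'processing' records
    metric_policy: Mapping[str, str] | None = None
    reference_group: str = "manual"
    out_dir: str | Path | None = None


@dataclass
class RunReport:
    records: pd.DataFrame
    summaries: pd.DataFrame
    headline: dict
    exceptions: list[dict] = field(default_factory=list)


def _geometry_rows(study: SyntheticStudy, config: RunConfig, exceptions: list[dict]):
    tubular = set(study.tubular if config.tubular is None else config.tubular)
    rows = []
    for pid in study.patients:
        gt_organs = study.gt.get(pid, {})
        obs_keys = [key for key in study.masks if key[0] == pid]
        for organ in study.organs:
            gt_mask = gt_organs.get(organ)
            if gt_mask is None or gt_mask.is_empty:
                exceptions.append(
                    {"patient_id": pid, "oar": organ, "reason": "missing_ground_truth"}
                )
                continue
            # caudal harmonization across GT and every observer's mask
            if organ in tubular:
                members = [(None, gt_mask)]
                for key in obs_keys:
                    m = study.masks[key].get(organ)
                    if m is not None and not m.is_empty:
                        members.append((key, m))
                if len(members) >= 2:
                    cut = apply_caudal_cutoff([m for _, m in members])
                    harmonized = {key: mask for (key, _), mask in zip(members, cut)}
                    gt_eval = harmonized[None]
                else:
                    harmonized, gt_eval = {}, gt_mask
            else:
                harmonized, gt_eval = None, gt_mask
            for key in obs_keys:
                _, group, obs = key
                mask = study.masks[key].get(organ)
                if mask is None:
                    exceptions.append(
                        {
                            "patient_id": pid,
                            "oar": organ,
                            "group": group,
                            "observer": obs,
                            "reason": "missing_contour",
                        }
                    )
                    continue
                if mask.is_empty:
                    exceptions.append(
                        {
                            "patient_id": pid,
                            "oar": organ,
                            "group": group,
                            "observer": obs,
                            "reason": "empty_contour",
                        }
                    )
                test_eval = mask
                if harmonized is not None:
                    test_eval = harmonized.get(key, mask)
                geo = evaluate_pair(test_eval, gt_eval)
                rows.append(
                    {
                        "patient_id": pid,
                        "oar": organ,
                        "group": group,
                        "observer": obs,
                        **geo.as_dict(),
                        "_mask": mask,
                        "_gt": gt_mask,
                    }
                )
    return rows


def _add_dose_deltas(rows, study: SyntheticStudy, config: RunConfig, exceptions: list[dict]):
    gt_dvh_cache: dict[tuple[str, str], object] = {}
    for row in rows:
        pid, organ = row["patient_id"], row["oar"]
        dose = study.dose.get(pid)
        row["dose_metric"] = None
        row["dose_delta_gy"] = float("nan")
        if dose is None:
            continue
        try:
            metric = organ_metric_policy(organ, config.metric_policy)
        except PolicyError:
            exceptions.append({"patient_id": pid, "oar": organ, "reason": "no_dose_policy"})
            continue
        key = (pid, organ)
        if key not in gt_dvh_cache:
            gt_dvh_cache[key] = dvh_from_dose(dose, row["_gt"])
        mask = row["_mask"]
        if mask.is_empty:
            continue
        test_dvh = dvh_from_dose(dose, mask)
        row["dose_metric"] = metric
        row["dose_delta_gy"] = test_dvh.value(metric) - gt_dvh_cache[key].value(metric)


def _summaries_frame(records: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    out = []
    geo = records[~records["oar"].isin(config.geometry_excluded)]
    for metric in GEOMETRY_METRICS:
        for (oar, group), cell in geo.groupby(["oar", "group"], sort=True):
            values = cell[metric].dropna()
            if values.empty:
                continue
            gs = cstats.group_summary(values)
            out.append({"metric": metric, "oar": oar, "group": group, **gs.__dict__})
    dose_rows = records.dropna(subset=["dose_delta_gy"])
    for (oar, group, metric), cell in dose_rows.groupby(
        ["oar", "group", "dose_metric"], sort=True
    ):
        gs = cstats.group_summary(cell["dose_delta_gy"])
        out.append(
            {"metric": f"delta_{metric}_gy", "oar": oar, "group": group, **gs.__dict__}
        )
    return pd.DataFrame(out)


def _variability_headline(records: pd.DataFrame, config: RunConfig) -> dict:
    geo = records[~records["oar"].isin(config.geometry_excluded)]
    oars = sorted(geo["oar"].unique())
    groups = sorted(geo["group"].unique())
    result: dict[str, dict] = {}
    for metric in VARIABILITY_METRICS:
        per_group = {}
        for group in groups:
            sds = [cstats.observer_variability(geo, oar, group, metric) for oar in oars]
            try:
                per_group[group] = cstats.mean_variability(sds)
            except ValueError:
                per_group[group] = float("nan")
        entry: dict = {"mean_sd": per_group}
        ref = per_group.get(config.reference_group)
        if ref and not math.isnan(ref):
            entry["pct_change_vs_manual"] = {
                g: cstats.percent_change(ref, v)
                for g, v in per_group.items()
                if g != config.reference_group and not math.isnan(v)
            }
            entry["pct_change_vs_manual_exact"] = {
                g: cstats.percent_change_exact(ref, v)
                for g, v in per_group.items()
                if g != config.reference_group and not math.isnan(v)
            }
        result[metric] = entry
    return result


def _timing_headline(study: SyntheticStudy, config: RunConfig) -> dict | None:
    manual = [r for r in study.timing if r.group == "manual"]
    adjusted = [r for r in study.timing if r.group == "adjusted"]
    if not manual or not adjusted:
        return None
    processing = [r.minutes for r in study.timing if r.group == "processing"]
    processing_min = float(np.median(processing)) if processing else config.processing_time_min
    ts = cstats.time_saving(manual, adjusted, processing_min)
    return {
        "processing_median_min": processing_min,
        "quartile_separation": cstats.quartile_separation(manual, adjusted),
        **ts.__dict__,
    }


def _bookkeeping(study: SyntheticStudy, exceptions: list[dict]) -> dict:
    n_oars = len(study.organs)
    n_patients = len(study.patients)
    counts = {}
    for group, obs_ids in study.observers.items():
        planned = n_patients * n_oars * len(obs_ids)
        missing = sum(
            1
            for e in exceptions
            if e.get("group") == group and e["reason"] == "missing_contour"
        )
        counts[group] = {
            "planned": planned,
            "exceptions": missing,
            "contours": cstats.contour_count(n_patients, n_oars, len(obs_ids), missing),
        }
    return counts


def _verify_headline(headline: dict, summaries: pd.DataFrame, config: RunConfig) -> None:
    """Recompute headline percentages from emitted numbers; raise on drift."""
    var = headline.get("variability", {})
    for metric, entry in var.items():
        ref = entry["mean_sd"].get(config.reference_group)
        for group, pct in entry.get("pct_change_vs_manual", {}).items():
            recomputed = cstats.percent_change(ref, entry["mean_sd"][group])
            if recomputed != pct:
                raise AssertionError(
                    f"headline inconsistency for {metric}/{group}: {pct} != {recomputed}"
                )
    timing = headline.get("timing")
    if timing:
        expect = -cstats.percent_change(
            timing["median_manual_min"], timing["median_adjusted_min"]
        )
        if expect != timing["pct_saved"]:
            raise AssertionError("headline timing percentage inconsistent")


def run_study(study: SyntheticStudy | str | Path, config: RunConfig | None = None) -> RunReport:
    """Run the full analysis on a study directory or in-memory study."""
    if config is None:
        config = RunConfig()
    if not isinstance(study, SyntheticStudy):
        study = load_study(study)
    exceptions: list[dict] = []
    rows = _geometry_rows(study, config, exceptions)
    _add_dose_deltas(rows, study, config, exceptions)
    for row in rows:
        row.pop("_mask", None)
        row.pop("_gt", None)
    records = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    summaries = _summaries_frame(records, config)
    headline = {
        "variability": _variability_headline(records, config),
        "timing": _timing_headline(study, config),
        "contours": _bookkeeping(study, exceptions),
        "n_exceptions": len(exceptions),
    }
    _verify_headline(headline, summaries, config)
    for e in exceptions:
        logger.warning("exception: %s", e)
    report_obj = RunReport(records, summaries, headline, exceptions)
    if config.out_dir is not None:
        _write_outputs(report_obj, Path(config.out_dir))
    return report_obj


def _write_outputs(report_obj: RunReport, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    report_obj.records.to_csv(out / "records.csv", index=False)
    report_obj.summaries.to_csv(out / "summaries.csv", index=False)
    (out / "headline.json").write_text(json.dumps(report_obj.headline, indent=1, sort_keys=True))
    (out / "exceptions.json").write_text(json.dumps(report_obj.exceptions, indent=1))


def report(records_csv: str | Path, config: RunConfig | None = None) -> pd.DataFrame:
    """Re-render the summary tables from a prior run's record-level CSV."""
    if config is None:
        config = RunConfig()
    records = pd.read_csv(records_csv)
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise ContourQAError(f"records CSV is missing columns: {missing}")
    return _summaries_frame(records, config)
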