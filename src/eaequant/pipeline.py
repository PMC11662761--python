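"""End-to-end study orchestration: gait, histology, qPCR and clinical runs.

Each ``run_*`` function consumes a :class:`StudyConfig` (usually loaded from
YAML), composes the analysis modules over all inputs, applies the study's
inclusion rules (gait is only analysed on days the animal scored at or below
the inclusion maximum, 2.5 by default), and writes tidy long-format CSV
tables plus a structured run log in which every exclusion or per-item error
carries a machine-readable reason code.  Routine downstream statistics
(repeated-measures ANOVA and the like) are deliberately left to external
tools; the tables are shaped for them.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from . import histology, kinematics, pose_io, qpcr, stats

__all__ = [
    "StudyConfig",
    "RunLog",
    "load_config",
    "read_clinical_scores",
    "run_gait_study",
    "run_histology",
    "run_qpcr",
    "run_clinical",
]

log = logging.getLogger("eaequant")

EXIT_CLEAN, EXIT_FATAL, EXIT_PARTIAL = 0, 1, 2


@dataclass
class StudyConfig:
    """Paths, thresholds and inclusion rules for one study run."""

    # gait
    gait_recordings: list = field(default_factory=list)  # {animal_id, group, dpi, pose_csv}
    calibration_yaml: str | None = None
    image_height_px: float = 600.0
    baseline_dpi: int = -2
    gait_max_score: float = 2.5
    likelihood_min: float = pose_io.LIKELIHOOD_MIN_DEFAULT
    phase_params: kinematics.PhaseParams = field(default_factory=kinematics.PhaseParams)
    n_phase: int = kinematics.N_PHASE_DEFAULT
    # clinical
    clinical_csv: str | None = None
    cumulative_window: tuple = (16, 44)
    control_group: str = "vehicle"
    treated_group: str = "treated"
    # histology
    eyfp_images: list = field(default_factory=list)  # {name, intensity, wm, gm, healthy}
    eyfp_factor: float = histology.EYFP_FACTOR_DEFAULT
    nr_images: list = field(default_factory=list)  # {name, rgb, wm}
    nr_red_blue_min: float = histology.NR_RED_BLUE_MIN_DEFAULT
    axon_fields: list = field(default_factory=list)  # {name, axon, myelin, pixel_size_um}
    g_cutoff: float = histology.G_CUTOFF_DEFAULT
    min_axon_area_px: int = histology.MIN_AXON_AREA_PX_DEFAULT
    # qPCR
    cq_csv: str | None = None
    qpcr_targets: list = field(default_factory=list)
    qpcr_references: list = field(default_factory=list)
    qpcr_tissue: str = "tissue"  # tissue | culture, picks the geNorm threshold
    seed: int = 0


class RunLog:
    """Append-only structured run log; one JSON object per event."""

    def __init__(self) -> None:
        self.events: list[dict] = []

    def add(self, code: str, **detail) -> None:
        self.events.append({"code": code, **detail})
        log.warning("%s %s", code, detail)

    def write(self, path: Path) -> None:
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            for ev in self.events:
                fh.write(json.dumps(ev, default=str) + "\n")

    @property
    def has_errors(self) -> bool:
        return any(ev["code"].startswith("error") for ev in self.events)


def load_config(path) -> StudyConfig:
    """Load a study YAML into a :class:`StudyConfig`."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    pp = doc.pop("phase_params", None)
    cfg = StudyConfig(**doc)
    if pp:
        cfg.phase_params = kinematics.PhaseParams(**pp)
    if isinstance(cfg.cumulative_window, list):
        cfg.cumulative_window = tuple(cfg.cumulative_window)
    return cfg


def read_clinical_scores(path) -> list[stats.ClinicalTrajectory]:
    """Read a long-format scores CSV (animal_id, group, dpi, score)."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    out = []
    for (aid, group), sub in df.groupby(["animal_id", "group"], sort=True):
        out.append(
            stats.ClinicalTrajectory(
                animal_id=str(aid),
                group=str(group),
                scores={int(r.dpi): float(r.score) for r in sub.itertuples()},
            )
        )
    return out


def _score_lookup(trajectories) -> dict:
    return {
        (t.animal_id, dpi): s for t in trajectories for dpi, s in t.scores.items()
    }


def run_gait_study(config: StudyConfig, out_dir) -> tuple[pd.DataFrame, RunLog]:
    """Per animal x timepoint gait metrics with the clinical-score filter.

    Recordings on days the animal scored above ``gait_max_score`` are
    excluded (the animal cannot walk reliably); otherwise the pose track is
    calibrated, joint angles computed, phases detected, the representative
    cycle built, and average angles plus RMS vs the animal's baseline cycle
    emitted.  Animals without a baseline recording keep their average-angle
    rows but RMS is marked unavailable.  Also writes exploratory per-day
    group contrasts (one-tailed Mann-Whitney on each metric).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    runlog = RunLog()
    if not config.gait_recordings:
        raise ValueError("no gait recordings configured")
    if config.calibration_yaml is None:
        raise ValueError("calibration_yaml is required for a gait run")
    cal = pose_io.read_calibration_yaml(config.calibration_yaml)
    scores = (
        _score_lookup(read_clinical_scores(config.clinical_csv))
        if config.clinical_csv
        else {}
    )

    cycles: dict[tuple[str, int], kinematics.RepresentativeCycle] = {}
    meta: dict[tuple[str, int], dict] = {}
    for rec in config.gait_recordings:
        aid, group, dpi = rec["animal_id"], rec["group"], int(rec["dpi"])
        key = (aid, dpi)
        score = scores.get(key)
        if dpi != config.baseline_dpi and score is not None and score > config.gait_max_score:
            runlog.add(
                "excluded_gait_score", animal_id=aid, dpi=dpi,
                score=score, reason=f"score>{config.gait_max_score}",
            )
            continue
        try:
            track = pose_io.read_pose_track(rec["pose_csv"])
            ctrack = pose_io.calibrate_track(
                track, cal, config.likelihood_min, config.image_height_px
            )
            angles = kinematics.joint_angle_series(ctrack)
            seg = kinematics.detect_phases(ctrack, config.phase_params)
            if seg.n_cycles == 0:
                runlog.add("error_gait_no_cycles", animal_id=aid, dpi=dpi)
                continue
            cycles[key] = kinematics.representative_cycle(angles, seg, config.n_phase)
            meta[key] = {"group": group, "score": score, "n_cycles": seg.n_cycles}
        except (ValueError, OSError) as exc:
            runlog.add("error_gait_recording", animal_id=aid, dpi=dpi, detail=str(exc))

    rows = []
    for (aid, dpi), cyc in sorted(cycles.items()):
        base = cycles.get((aid, config.baseline_dpi))
        if base is None and dpi != config.baseline_dpi:
            runlog.add("warning_no_baseline", animal_id=aid, dpi=dpi)
        m = kinematics.gait_metrics(cyc, base if dpi != config.baseline_dpi else None)
        rows.append(
            {
                "animal_id": aid,
                "group": meta[(aid, dpi)]["group"],
                "dpi": dpi,
                "clinical_score": meta[(aid, dpi)]["score"],
                "n_cycles": m.n_cycles,
                "avg_hip_deg": m.avg_hip_deg,
                "avg_knee_deg": m.avg_knee_deg,
                "avg_ankle_deg": m.avg_ankle_deg,
                "knee_rms_deg": m.knee_rms_deg,
                "ankle_rms_deg": m.ankle_rms_deg,
            }
        )
    table = pd.DataFrame(rows).sort_values(["animal_id", "dpi"]).reset_index(drop=True)
    table.to_csv(out_dir / "gait_metrics.csv", index=False)

    # exploratory per-day group contrasts
    contrasts = []
    if not table.empty:
        for dpi, sub in table.groupby("dpi"):
            for metric in ("avg_knee_deg", "avg_ankle_deg", "knee_rms_deg", "ankle_rms_deg"):
                a = sub.loc[sub.group == config.treated_group, metric].dropna()
                b = sub.loc[sub.group == config.control_group, metric].dropna()
                if len(a) and len(b):
                    alt = "a_greater" if metric.startswith("avg") else "a_less"
                    res = stats.mann_whitney_u_one_tailed(a, b, alt)
                    contrasts.append(
                        {
                            "dpi": dpi, "metric": metric, "U": res.U,
                            "p_one_tailed": res.p_one_tailed,
                            "alternative": res.alternative, "method": res.method,
                            "note": "exploratory",
                        }
                    )
    pd.DataFrame(contrasts).to_csv(out_dir / "gait_group_contrasts.csv", index=False)
    runlog.write(out_dir / "run_log.jsonl")
    return table, runlog


def _load_mask(path) -> np.ndarray:
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr


def _load_intensity(path) -> np.ndarray:
    path = str(path)
    if path.endswith((".tif", ".tiff")):
        return tifffile.imread(path).astype(float)
    return iio.imread(path).astype(float)


def run_histology(config: StudyConfig, out_dir) -> tuple[dict, RunLog]:
    """Compose the histology quantifications over all configured images.

    The eYFP standardized ratio is computed once over the run's whole image
    batch, then applied per image.  A missing or unreadable file is logged
    per item and the run continues (callers should report a partial exit).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    runlog = RunLog()
    results: dict[str, pd.DataFrame] = {}

    images = []
    for spec_ in config.eyfp_images:
        try:
            images.append(
                histology.ImageWithMasks(
                    intensity=_load_intensity(spec_["intensity"]),
                    wm_mask=_load_mask(spec_["wm"]) > 0,
                    gm_mask=_load_mask(spec_["gm"]) > 0,
                    healthy_wm_mask=_load_mask(spec_["healthy"]) > 0,
                    name=spec_.get("name", str(spec_["intensity"])),
                )
            )
        except (OSError, KeyError, ValueError) as exc:
            runlog.add("error_eyfp_image", name=spec_.get("name"), detail=str(exc))
    if images:
        ratio = histology.eyfp_standardized_ratio(images)
        rows = []
        for img in images:
            r = histology.eyfp_percent_transection(img, ratio, config.eyfp_factor)
            rows.append(
                {
                    "image": r.name, "gm_mean": r.gm_mean, "threshold": r.threshold,
                    "standardized_ratio": r.standardized_ratio, "factor": r.factor,
                    "percent_transection": r.percent_transection,
                }
            )
        results["eyfp"] = pd.DataFrame(rows)
        results["eyfp"].to_csv(out_dir / "eyfp_transection.csv", index=False)

    rows = []
    for spec_ in config.nr_images:
        try:
            pct = histology.nr_percent_wm_loss(
                iio.imread(spec_["rgb"]),
                _load_mask(spec_["wm"]) > 0,
                config.nr_red_blue_min,
            )
            rows.append({"image": spec_.get("name", str(spec_["rgb"])), "percent_wm_loss": pct})
        except (OSError, KeyError, ValueError) as exc:
            runlog.add("error_nr_image", name=spec_.get("name"), detail=str(exc))
    if rows:
        results["nr"] = pd.DataFrame(rows)
        results["nr"].to_csv(out_dir / "nr_wm_loss.csv", index=False)

    axon_rows, summary_rows = [], []
    for spec_ in config.axon_fields:
        try:
            axon = _load_mask(spec_["axon"])
            myelin = _load_mask(spec_["myelin"])
            px = float(spec_["pixel_size_um"])
            records = histology.gratio_records(
                axon, myelin, px, config.min_axon_area_px, config.g_cutoff
            )
            area = axon.shape[0] * axon.shape[1] * px**2
            summ = histology.remyelination_summary(records, area, config.g_cutoff)
            name = spec_.get("name", str(spec_["axon"]))
            for rec in records:
                axon_rows.append({"field": name, **rec.__dict__})
            summary_rows.append(
                {
                    "field": name, "n_axons": summ.n_axons,
                    "n_myelinated": summ.n_myelinated,
                    "n_remyelinating": summ.n_remyelinating,
                    "density_remyelinating_per_um2": summ.density_remyelinating,
                    "percent_remyelinating": summ.percent_remyelinating,
                    "percent_of_myelinated": summ.percent_of_myelinated,
                }
            )
        except (OSError, KeyError, ValueError) as exc:
            runlog.add("error_axon_field", name=spec_.get("name"), detail=str(exc))
    if axon_rows:
        results["axons"] = pd.DataFrame(axon_rows)
        results["axons"].to_csv(out_dir / "axon_records.csv", index=False)
    if summary_rows:
        results["remyelination"] = pd.DataFrame(summary_rows)
        results["remyelination"].to_csv(out_dir / "remyelination_summary.csv", index=False)

    runlog.write(out_dir / "run_log.jsonl")
    return results, runlog


def run_qpcr(config: StudyConfig, out_dir) -> tuple[dict, RunLog]:
    """Triplicate collapse, geNorm reference check, and ddCq fold changes."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    runlog = RunLog()
    if config.cq_csv is None:
        raise ValueError("cq_csv is required for a qPCR run")
    table = qpcr.read_cq_table(config.cq_csv)
    collapsed = qpcr.collapse_triplicates(table)
    threshold = (
        qpcr.GENORM_THRESHOLD_CULTURE
        if config.qpcr_tissue == "culture"
        else qpcr.GENORM_THRESHOLD_TISSUE
    )
    genorm = qpcr.genorm_m(collapsed, config.qpcr_references, threshold=threshold)
    failing = genorm.failing_genes()
    if failing:
        runlog.add(
            "warning_genorm_unstable", genes=failing, threshold=threshold,
            detail=f"geNorm M at or above {threshold} ({config.qpcr_tissue})",
        )
    ddcq = qpcr.relative_expression_ddcq(
        collapsed, config.qpcr_targets, config.qpcr_references, config.control_group
    )
    collapsed.to_csv(out_dir / "cq_collapsed.csv", index=False)
    genorm.m_values.rename_axis("gene").reset_index().to_csv(
        out_dir / "genorm_m.csv", index=False
    )
    ddcq.per_sample.to_csv(out_dir / "ddcq_per_sample.csv", index=False)
    ddcq.group_summary.to_csv(out_dir / "ddcq_group_summary.csv", index=False)
    runlog.write(out_dir / "run_log.jsonl")
    return {"collapsed": collapsed, "genorm": genorm, "ddcq": ddcq}, runlog


def run_clinical(config: StudyConfig, out_dir) -> tuple[pd.DataFrame, RunLog]:
    """Cumulative clinical scores and the primary two-group rank test.

    Sums each animal's daily scores over the configured window (DPI 16-44
    inclusive by default) and compares treated vs control with the exact
    one-tailed Mann-Whitney U test (alternative: treated cumulative scores
    lower).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    runlog = RunLog()
    if config.clinical_csv is None:
        raise ValueError("clinical_csv is required for a clinical run")
    trajectories = read_clinical_scores(config.clinical_csv)
    lo, hi = config.cumulative_window
    rows = []
    for t in trajectories:
        try:
            cum = stats.cumulative_clinical_score(t, lo, hi)
        except ValueError as exc:
            runlog.add("error_clinical_missing_days", animal_id=t.animal_id, detail=str(exc))
            continue
        rows.append({"animal_id": t.animal_id, "group": t.group, "cumulative_score": cum})
    table = pd.DataFrame(rows)
    table.to_csv(out_dir / "cumulative_scores.csv", index=False)

    a = table.loc[table.group == config.treated_group, "cumulative_score"]
    b = table.loc[table.group == config.control_group, "cumulative_score"]
    if len(a) and len(b):
        res = stats.mann_whitney_u_one_tailed(a, b, "a_less")
        report = {
            "U": res.U, "p_one_tailed": res.p_one_tailed,
            "alternative": res.alternative, "method": res.method,
            "n_treated": res.n, "n_control": res.m,
            "window": f"{lo}-{hi}",
        }
        with open(out_dir / "clinical_test.json", "w") as fh:
            json.dump(report, fh, indent=2)
    runlog.write(out_dir / "run_log.jsonl")
    return table, runlog
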