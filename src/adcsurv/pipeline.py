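"""End-to-end orchestration: simulate -> adc -> features -> rsd -> survival.

Each stage reads the previous stage's files from the run directory and
writes its own, so a run can resume from any completed stage. A manifest
(JSON) records the configuration, seeds, package version and per-output
SHA-256 checksums; reruns with the same configuration are bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .adc import load_dwi_pair, preprocess_pair, save_adc_map, load_adc_map
from .features import HistogramConfig, metrics_table, metrics_long, METRIC_NAMES
from .longitudinal import series_from_tables, rsd_table, slopes_table
from .survival import AnalysisConfig, run_endpoint_analysis, km_frame, plot_km, \
    ENDPOINTS
from .synthetic import CohortConfig, generate_cohort, write_cohort

logger = logging.getLogger(__name__)

STAGES = ("simulate", "adc", "features", "rsd", "survival")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and subject."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    out_dir: Path
    stages: tuple = STAGES
    cohort: CohortConfig | None = None         # required for the simulate stage
    data_dir: Path | None = None               # input dir when not simulating
    histogram: HistogramConfig = field(default_factory=HistogramConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    erode_iterations: int = 3
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        self.out_dir = Path(self.out_dir)
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def validate_inputs(subjects_csv: str | Path, survival_csv: str | Path) -> dict:
    """Validate cohort input tables against the inclusion rules.

    Flags (without aborting): subjects with fewer than 3 timepoints
    (excluded — a slope needs three visits), non-increasing visit days,
    PFS > OS, and missing covariates.

    Returns a report dict with keys ``excluded_insufficient_timepoints``,
    ``non_increasing_days``, ``invalid_survival``, ``missing_covariates``
    and ``included`` (the subject ids passing all checks).
    """
    try:
        subjects = pd.read_csv(subjects_csv)
    except Exception as exc:
        raise ValueError(f"unparseable subjects file {subjects_csv}: {exc}") from exc
    try:
        survival = pd.read_csv(survival_csv)
    except Exception as exc:
        raise ValueError(f"unparseable survival file {survival_csv}: {exc}") from exc
    for df, path, required in (
            (subjects, subjects_csv, {"subject_id", "timepoint", "day"}),
            (survival, survival_csv,
             {"subject_id", "pfs_days", "pfs_event", "os_days", "os_event"})):
        missing = required - set(df.columns)
        if missing:
            raise ValueError(
                f"unparseable file {path}: missing columns {sorted(missing)}")

    report = {
        "excluded_insufficient_timepoints": [],
        "non_increasing_days": [],
        "invalid_survival": [],
        "missing_covariates": [],
        "included": [],
    }
    surv = survival.set_index(survival["subject_id"].astype(str))
    for sid, grp in subjects.groupby(subjects["subject_id"].astype(str)):
        ok = True
        if len(grp) < 3:
            report["excluded_insufficient_timepoints"].append(sid)
            ok = False
        days = grp.sort_values("timepoint")["day"].to_numpy(dtype=float)
        if np.any(np.diff(days) <= 0):
            report["non_increasing_days"].append(sid)
            ok = False
        if sid not in surv.index:
            report["invalid_survival"].append(sid)
            ok = False
        else:
            rec = surv.loc[sid]
            if float(rec["pfs_days"]) > float(rec["os_days"]):
                report["invalid_survival"].append(sid)
                ok = False
            if "mgmt" in surv.columns and pd.isna(rec["mgmt"]):
                report["missing_covariates"].append(sid)  # flagged, not excluded
        if ok:
            report["included"].append(sid)
    return report


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order; return the run manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stages": list(config.stages),
        "histogram_config": config.histogram.to_dict(),
        "analysis_config": dataclasses.asdict(config.analysis),
        "erode_iterations": config.erode_iterations,
        "checksums": {},
    }

    data_dir = Path(config.data_dir) if config.data_dir else out / "raw"

    if "simulate" in config.stages:
        if config.cohort is None:
            raise StageError("simulate stage requires a cohort configuration")
        logger.info("stage simulate: %d subjects", config.cohort.n_subjects)
        subjects, truth = generate_cohort(config.cohort, config.histogram)
        write_cohort(subjects, truth, data_dir, b_value=config.cohort.b_value)
        manifest["cohort_config"] = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config.cohort).items()
            if not isinstance(v, (dict,))
        }

    subjects_csv = data_dir / "subjects.csv"
    survival_csv = data_dir / "survival.csv"
    if not subjects_csv.exists():
        raise StageError(f"missing subjects index {subjects_csv}")
    validation = validate_inputs(subjects_csv, survival_csv)
    manifest["validation"] = validation
    included = set(validation["included"])

    maps_dir = out / "adc"
    if "adc" in config.stages:
        maps_dir.mkdir(exist_ok=True)
        index = pd.read_csv(subjects_csv)
        for _, row in index.iterrows():
            sid = str(row["subject_id"])
            if sid not in included:
                continue
            tp = int(row["timepoint"])
            try:
                pair = load_dwi_pair(data_dir / row["b0_path"],
                                     data_dir / row["b1000_path"],
                                     b=float(row.get("b_value", 1000.0)))
                adc_map = preprocess_pair(pair,
                                          erode_iterations=config.erode_iterations)
            except Exception as exc:
                raise StageError(
                    f"stage adc failed for subject {sid} timepoint {tp}: {exc}"
                ) from exc
            save_adc_map(adc_map, maps_dir / f"{sid}_tp{tp:02d}_adc.nii.gz")

    metrics_csv = out / "metrics.csv"
    if "features" in config.stages:
        index = pd.read_csv(subjects_csv)
        entries = []
        for _, row in index.iterrows():
            sid = str(row["subject_id"])
            if sid not in included:
                continue
            tp = int(row["timepoint"])
            path = maps_dir / f"{sid}_tp{tp:02d}_adc.nii.gz"
            if not path.exists():
                raise StageError(
                    f"stage features: missing ADC map for subject {sid} "
                    f"timepoint {tp} ({path})")
            entries.append((sid, tp, float(row["day"]), load_adc_map(path)))
        table = metrics_table(entries, config.histogram)
        table.to_csv(metrics_csv, index=False)
        metrics_long(table).to_csv(out / "metrics_long.csv", index=False)
        (out / "metrics_config.json").write_text(
            json.dumps(config.histogram.to_dict(), indent=2))

    rsd_csv = out / "rsd.csv"
    if "rsd" in config.stages:
        metrics_df = pd.read_csv(metrics_csv)
        survival_df = pd.read_csv(survival_csv)
        cohort = series_from_tables(metrics_df, survival_df)
        rsd_df = rsd_table(cohort)
        rsd_df.to_csv(rsd_csv, index=False)
        slopes_table(cohort).to_csv(out / "slopes.csv", index=False)

    if "survival" in config.stages:
        rsd_df = pd.read_csv(rsd_csv)
        for endpoint in ENDPOINTS:
            report = run_endpoint_analysis(rsd_df, endpoint, config.analysis)
            edir = out / endpoint.lower()
            edir.mkdir(exist_ok=True)
            report.table().to_csv(edir / "table1.csv")
            if report.fg is not None:
                (edir / "fg.json").write_text(
                    json.dumps(report.fg.as_dict(), indent=2))
                report.fg.partial_corr_frame().to_csv(edir / "partial_corr.csv")
            else:
                (edir / "fg.json").write_text(
                    json.dumps({"degenerate": True}, indent=2))
            (edir / "alasso.json").write_text(
                json.dumps(report.alasso.as_dict(), indent=2))
            (edir / "screened.json").write_text(json.dumps({
                "screened": list(report.screened),
                "excluded": report.excluded,
            }, indent=2))
            for name, curve in report.km.items():
                km_frame(curve).to_csv(edir / f"km_{name}.csv", index=False)
                ax = plot_km(curve, title=f"{endpoint} by {name}")
                ax.figure.savefig(edir / f"km_{name}.png", dpi=120)
                import matplotlib.pyplot as plt
                plt.close(ax.figure)

    # checksum text outputs (plots and volumes carry format metadata that
    # is not byte-stable across library versions)
    for path in sorted(out.rglob("*.csv")) + sorted(out.rglob("*.json")):
        if path.name == "manifest.json":
            continue
        manifest["checksums"][str(path.relative_to(out))] = _sha256(path)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
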