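"""Cohort readers/writers and result serialization.

On-disk cohort layout: one CSV per subject (T rows x N ROI columns,
header roi_01..roi_NN) plus ``phenotype.csv`` with columns subject_id,
site, dx (ASD|control).  Subjects with a missing/empty diagnosis are
excluded on read with a logged count, mirroring how unlabeled
individuals are removed from multi-site repositories before analysis.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .types import ROITimeSeries
from .synthetic import SyntheticCohort

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1"


def roi_names(n: int) -> list:
    return [f"roi_{i + 1:02d}" for i in range(n)]


def write_cohort(cohort, out_dir) -> Path:
    """Write per-subject time-series CSVs plus the phenotype table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    subjects = cohort.subjects if isinstance(cohort, SyntheticCohort) else cohort
    rows = []
    for s in subjects:
        df = pd.DataFrame(s.data, columns=roi_names(s.n_rois))
        df.to_csv(out / f"{s.subject_id}.csv", index=False)
        rows.append({"subject_id": s.subject_id, "site": s.site_id, "dx": s.label})
    pd.DataFrame(rows).to_csv(out / "phenotype.csv", index=False)
    (out / "manifest.json").write_text(
        json.dumps({"schema_version": SCHEMA_VERSION, "n_subjects": len(rows)}, indent=2)
    )
    return out


def read_cohort(in_dir) -> list:
    """Read a cohort directory back into ROITimeSeries objects.

    Raises on missing time-series files, ragged/non-numeric data and
    duplicate subject ids; excludes (and counts) subjects without a
    diagnosis label.
    """
    root = Path(in_dir)
    pheno_path = root / "phenotype.csv"
    if not pheno_path.exists():
        raise FileNotFoundError(f"phenotype CSV not found: {pheno_path}")
    pheno = pd.read_csv(pheno_path, dtype=str)
    required = {"subject_id", "site", "dx"}
    if not required <= set(pheno.columns):
        raise ValueError(f"phenotype CSV must have columns {sorted(required)}")
    if pheno["subject_id"].duplicated().any():
        dups = pheno.loc[pheno["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject id(s) in phenotype: {dups}")

    subjects = []
    excluded = 0
    for _, row in pheno.iterrows():
        sid = row["subject_id"]
        dx = row["dx"]
        if pd.isna(dx) or str(dx).strip() == "":
            excluded += 1
            continue
        if dx not in ("ASD", "control"):
            raise ValueError(f"subject {sid}: unknown diagnosis {dx!r}")
        ts_path = root / f"{sid}.csv"
        if not ts_path.exists():
            raise FileNotFoundError(f"missing time-series file for subject {sid}: {ts_path}")
        try:
            df = pd.read_csv(ts_path)
            data = df.to_numpy(dtype=float)
        except (ValueError, pd.errors.ParserError) as exc:
            raise ValueError(f"subject {sid}: unreadable time series ({ts_path}): {exc}") from exc
        subjects.append(
            ROITimeSeries(subject_id=sid, site_id=row["site"], label=dx, data=data)
        )
    if excluded:
        logger.info("excluded %d subject(s) without a diagnosis label", excluded)
    n_rois = {s.n_rois for s in subjects}
    if len(n_rois) > 1:
        raise ValueError(f"inconsistent ROI counts across cohort: {sorted(n_rois)}")
    return subjects


def write_connectivity(cm, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(cm.values, columns=roi_names(cm.n_rois))
    path = out / f"{cm.subject_id}_{cm.kind}.csv"
    df.to_csv(path, index=False)
    return path


def write_embedding_csv(subject_id: str, Z: np.ndarray, path) -> None:
    n, d = Z.shape
    df = pd.DataFrame(Z, columns=[f"dim_{k}" for k in range(d)])
    df.insert(0, "node", roi_names(n))
    df.to_csv(path, index=False)


def write_cv_result(result, out_path) -> None:
    """Per-fold CSV mirroring the site/#subjects/#ASD/accuracy/F-score layout."""
    rows = []
    for f in result.folds:
        rows.append(
            {
                "fold": f.fold_id,
                "n_subjects": f.n_subjects,
                "n_ASD": f.n_positive,
                "accuracy": f.metrics.accuracy,
                "fscore": f.metrics.fscore,
                "precision": f.metrics.precision,
                "recall": f.metrics.recall,
            }
        )
    rows.append(
        {
            "fold": "Mean",
            "n_subjects": sum(f.n_subjects for f in result.folds),
            "n_ASD": sum(f.n_positive for f in result.folds),
            "accuracy": result.mean_metrics.accuracy,
            "fscore": result.mean_metrics.fscore,
            "precision": result.mean_metrics.precision,
            "recall": result.mean_metrics.recall,
        }
    )
    out_path = Path(out_path)
    pd.DataFrame(rows).to_csv(out_path.with_suffix(".csv"), index=False)
    summary = {
        "schema_version": SCHEMA_VERSION,
        "scheme": result.scheme,
        "mean_accuracy": result.mean_metrics.accuracy,
        "mean_fscore": result.mean_metrics.fscore,
        "folds": [
            {
                "fold": f.fold_id,
                "n_subjects": f.n_subjects,
                "n_ASD": f.n_positive,
                "TP": f.counts.TP,
                "FP": f.counts.FP,
                "FN": f.counts.FN,
                "TN": f.counts.TN,
                "accuracy": f.metrics.accuracy,
                "fscore": f.metrics.fscore,
            }
            for f in result.folds
        ],
    }
    out_path.with_suffix(".json").write_text(json.dumps(summary, indent=2))
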