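"""Plain-text interchange: cohorts, matrices, selections and reports.

Everything is headered TSV/CSV so runs are auditable with standard tools.
Floating-point values are written with 17 significant digits, which makes
write → read round-trips exact for doubles.

A cohort on disk is a directory with

* ``manifest.csv`` — one row per subject: subject_id, site_id, label, path
  (time-series file, relative to the manifest);
* one time-series TSV per subject (T rows × N columns, ROI-name header);

which is exactly what the synthetic generator writes and every subcommand
reads back.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .features import SelectionResult
from .types import ConnectivityMatrix, Layer, RoiTimeSeries, edge_index_pairs

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.17g"

__all__ = [
    "roi_names",
    "write_cohort",
    "read_cohort",
    "write_matrix",
    "read_matrix",
    "write_selection",
    "read_selection",
]


def roi_names(n_rois: int, names: list[str] | None = None) -> list[str]:
    """ROI column labels; defaults to ROI0001..ROInnnn."""
    if names is not None:
        if len(names) != n_rois:
            raise ValueError("ROI name list length does not match n_rois")
        return list(names)
    return [f"ROI{k + 1:04d}" for k in range(n_rois)]


def write_cohort(
    cohort: list[RoiTimeSeries], outdir: str | Path, names: list[str] | None = None
) -> Path:
    """Write per-subject TSVs, a phenotype CSV and the manifest; returns the manifest path."""
    outdir = Path(outdir)
    ts_dir = outdir / "timeseries"
    ts_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for ts in cohort:
        rel = Path("timeseries") / f"{ts.subject_id}.tsv"
        frame = pd.DataFrame(ts.data, columns=roi_names(ts.n_rois, names))
        frame.to_csv(outdir / rel, sep="\t", index=False, float_format=FLOAT_FMT)
        rows.append(
            {
                "subject_id": ts.subject_id,
                "site_id": ts.site_id,
                "label": ts.label,
                "path": rel.as_posix(),
            }
        )
    manifest = pd.DataFrame(rows)
    manifest[["subject_id", "site_id", "label"]].to_csv(
        outdir / "phenotype.csv", index=False
    )
    manifest_path = outdir / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    return manifest_path


def read_cohort(
    manifest_path: str | Path, *, return_rejected: bool = False
):
    """Load and screen a cohort from its manifest.

    Structural problems (missing files, duplicate subject ids, unknown
    labels) raise with the offenders listed.  Per-subject data problems —
    zero-variance ROI columns, fewer than 3 timepoints or ROIs, a ROI count
    different from the cohort's — cause that subject to be *rejected* with a
    named reason (logged), mirroring the screening step that drops subjects
    whose extracted time series are degenerate.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    manifest = pd.read_csv(manifest_path)
    required = {"subject_id", "site_id", "label", "path"}
    if not required.issubset(manifest.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    dupes = manifest["subject_id"][manifest["subject_id"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"duplicate subject ids in manifest: {dupes}")
    bad_labels = manifest.loc[
        ~manifest["label"].isin(["patient", "control"]), "subject_id"
    ].tolist()
    if bad_labels:
        raise ValueError(
            f"labels must be 'patient' or 'control'; offending subjects: {bad_labels}"
        )
    missing = [
        str(manifest_path.parent / p)
        for p in manifest["path"]
        if not (manifest_path.parent / p).exists()
    ]
    if missing:
        raise FileNotFoundError(f"time-series files missing: {missing}")

    cohort: list[RoiTimeSeries] = []
    rejected: dict[str, str] = {}
    n_rois_expected: int | None = None
    for row in manifest.itertuples(index=False):
        data = pd.read_csv(manifest_path.parent / row.path, sep="\t", float_precision="round_trip").to_numpy(float)
        if data.ndim != 2 or data.shape[0] < 3 or data.shape[1] < 3:
            rejected[row.subject_id] = f"wrong dimensions {data.shape}"
            continue
        if n_rois_expected is None:
            n_rois_expected = data.shape[1]
        elif data.shape[1] != n_rois_expected:
            rejected[row.subject_id] = (
                f"ROI count {data.shape[1]} differs from cohort's {n_rois_expected}"
            )
            continue
        dead = np.flatnonzero(np.ptp(data, axis=0) == 0.0)
        if dead.size:
            rejected[row.subject_id] = f"zero-variance ROI at column(s) {dead.tolist()}"
            continue
        cohort.append(RoiTimeSeries(row.subject_id, row.site_id, row.label, data))
    for sid, reason in rejected.items():
        logger.warning("rejected subject %s: %s", sid, reason)
    if return_rejected:
        return cohort, rejected
    return cohort


def write_matrix(
    m: ConnectivityMatrix, path: str | Path, names: list[str] | None = None
) -> None:
    """Connectivity matrix as an N×N TSV with ROI names as header and index."""
    labels = roi_names(m.n_rois, names)
    pd.DataFrame(m.values, index=labels, columns=labels).to_csv(
        path, sep="\t", float_format=FLOAT_FMT, index_label="roi"
    )


def read_matrix(path: str | Path, subject_id: str, layer: Layer) -> ConnectivityMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return ConnectivityMatrix(subject_id, layer, frame.to_numpy(float))


def write_selection(
    sel: SelectionResult, n_rois: int, path: str | Path, names: list[str] | None = None
) -> None:
    """Per-edge selection table: edge index, ROI pair, p-value, selected flag."""
    labels = roi_names(n_rois, names)
    pairs = edge_index_pairs(n_rois)
    chosen = set(sel.selected)
    pd.DataFrame(
        {
            "edge": np.arange(len(pairs)),
            "roi_i": [labels[i] for i, _ in pairs],
            "roi_j": [labels[j] for _, j in pairs],
            "p_value": sel.p_values,
            "selected": [int(e in chosen) for e in range(len(pairs))],
            "threshold": sel.threshold,
            "layer": sel.layer,
            "fold_id": sel.fold_id,
        }
    ).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_selection(path: str | Path) -> SelectionResult:
    frame = pd.read_csv(path, keep_default_na=False, float_precision="round_trip")
    return SelectionResult(
        layer=frame["layer"].iloc[0],
        p_values=frame["p_value"].to_numpy(float),
        selected=frame.loc[frame["selected"] == 1, "edge"].tolist(),
        threshold=float(frame["threshold"].iloc[0]),
        fold_id=str(frame["fold_id"].iloc[0]),
    )
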