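"""Readers and writers for study data and results.

The interchange format is CSV: one row per (patient, session, acquisition,
ROI, voxel, b-value[, direction]) observation with a ``signal`` column —
the shape of a deposited per-voxel signal-versus-b-value table. Per-direction
rows, when present, are averaged into one signal per b-value on read.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model import BValueScheme
from .synthetic import StudyDataset

__all__ = ["read_study", "write_results", "VALID_ROI_LABELS"]

VALID_ROI_LABELS = ("tumour", "normal", "fitregion")

_KEY_COLS = ["patient", "session", "acquisition", "roi", "voxel_id", "b_value"]
_REQUIRED = _KEY_COLS + ["signal"]


def read_study(path: str | Path) -> StudyDataset:
    """Read a study from a CSV file or a fixture directory.

    A directory must contain ``study.csv`` and may contain ``scheme.csv``
    (b_value, n_directions), ``truth.csv`` and ``truth_by_acquisition.csv``
    sidecars. ``patient_id`` is accepted as an alias for the ``patient``
    column. Validation failures (missing columns, duplicate keys, negative
    signals, unknown ROI labels, inconsistent per-voxel b-value sets) raise
    ``ValueError`` naming the offending rows.
    """
    path = Path(path)
    truth = truth_by_acq = None
    scheme = None
    if path.is_dir():
        study_path = path / "study.csv"
        if not study_path.exists():
            raise FileNotFoundError(f"no study.csv in {path}")
        if (path / "scheme.csv").exists():
            sc = pd.read_csv(path / "scheme.csv")
            scheme = BValueScheme(sc["b_value"].to_numpy(), sc["n_directions"].to_numpy())
        if (path / "truth.csv").exists():
            truth = pd.read_csv(path / "truth.csv", float_precision="round_trip")
        if (path / "truth_by_acquisition.csv").exists():
            truth_by_acq = pd.read_csv(path / "truth_by_acquisition.csv", float_precision="round_trip")
    else:
        study_path = path
    data = pd.read_csv(study_path, float_precision="round_trip")
    if "patient_id" in data.columns and "patient" not in data.columns:
        data = data.rename(columns={"patient_id": "patient"})

    missing = set(_REQUIRED) - set(data.columns)
    if missing:
        raise ValueError(f"{study_path}: missing required columns {sorted(missing)}")

    bad_roi = ~data["roi"].isin(VALID_ROI_LABELS)
    if bad_roi.any():
        rows = (data.index[bad_roi] + 2).tolist()[:10]  # +2: header + 1-based
        raise ValueError(
            f"{study_path}: unknown ROI labels {sorted(data.loc[bad_roi, 'roi'].unique())} "
            f"at file lines {rows}"
        )
    neg = data["signal"] < 0
    if neg.any():
        rows = (data.index[neg] + 2).tolist()[:10]
        raise ValueError(f"{study_path}: negative signals at file lines {rows}")

    key_cols = _KEY_COLS + (["direction"] if "direction" in data.columns else [])
    dup = data.duplicated(subset=key_cols, keep=False)
    if dup.any():
        rows = (data.index[dup] + 2).tolist()[:10]
        raise ValueError(f"{study_path}: duplicate {tuple(key_cols)} keys at file lines {rows}")

    if "direction" in data.columns:
        data = (
            data.groupby(_KEY_COLS, as_index=False, sort=False)["signal"].mean()
        )

    # per-voxel b-value sets must all match
    nb_per_voxel = data.groupby(["patient", "session", "acquisition", "roi", "voxel_id"])[
        "b_value"
    ].nunique()
    if nb_per_voxel.nunique() != 1:
        raise ValueError(f"{study_path}: voxels have inconsistent b-value sets")

    b_sorted = np.sort(data["b_value"].unique())
    if scheme is None:
        scheme = BValueScheme(b_sorted, np.ones(b_sorted.size, dtype=int))
    elif not np.array_equal(np.sort(scheme.b_values), b_sorted):
        raise ValueError(f"{study_path}: data b-values do not match scheme.csv")

    data = data.sort_values(
        ["patient", "session", "acquisition", "roi", "voxel_id", "b_value"]
    ).reset_index(drop=True)
    return StudyDataset(data=data, scheme=scheme, truth=truth, truth_by_acquisition=truth_by_acq)


def write_results(fits: pd.DataFrame, report, outdir: str | Path,
                  manifest: dict | None = None) -> list[Path]:
    """Write per-voxel fits, ROI summaries and the evaluation tables.

    Emits ``fits.csv``, one CSV per report table, ``report.json`` (the same
    tables as records, plus dropped-patient counts) and optionally
    ``manifest.json``. Row order is deterministic (sorted by keys).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    fits_path = outdir / "fits.csv"
    fits.sort_values(
        [c for c in ("algorithm", "patient", "session", "acquisition", "roi", "voxel_id")
         if c in fits.columns]
    ).to_csv(fits_path, index=False)
    written.append(fits_path)

    summary: dict = {"dropped": report.dropped}
    for name, table in report.tables().items():
        p = outdir / f"{name}.csv"
        table.to_csv(p, index=False)
        written.append(p)
        summary[name] = json.loads(table.to_json(orient="records"))
    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(summary, indent=2))
    written.append(report_path)

    if manifest is not None:
        mpath = outdir / "manifest.json"
        mpath.write_text(json.dumps(manifest, indent=2, default=str))
        written.append(mpath)
    return written
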