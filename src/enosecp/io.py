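"""Readers and writers for the pipeline's CSV artifacts.

Fixed CSV dialect: comma separator, '.' decimal, UTF-8, mandatory header
row.  Floats are written with 17 significant digits so numeric payloads
round-trip losslessly.  Malformed inputs raise :class:`ParseError` carrying the file and,
where known, the 1-based line and the column involved.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .conformal import ConformalPrediction
from .features import FeatureMatrix
from .simulate import SensorRecord

__all__ = [
    "ParseError",
    "write_feature_matrix",
    "read_feature_matrix",
    "write_dataset",
    "read_dataset",
    "write_cp_report",
    "read_cp_report",
    "write_benchmark_report",
    "load_yaml",
    "dump_yaml",
]


class ParseError(ValueError):
    """A malformed input file; names the file and, if known, line/column."""

    def __init__(self, message: str, file=None, line=None, column=None):
        self.file = str(file) if file is not None else None
        self.line = line
        self.column = column
        loc = []
        if self.file:
            loc.append(f"file {self.file}")
        if line is not None:
            loc.append(f"line {line}")
        if column is not None:
            loc.append(f"column {column}")
        suffix = f" ({', '.join(loc)})" if loc else ""
        super().__init__(message + suffix)


def _read_csv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError("file not found", file=path)
    try:
        return pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise ParseError(f"malformed CSV: {exc}", file=path) from exc


def _numeric_column(df: pd.DataFrame, col: str, path) -> np.ndarray:
    # to_numeric only to locate bad cells; the actual conversion goes through
    # numpy's parser, which is correctly rounded (to_numeric's fast path isn't)
    bad = pd.to_numeric(df[col], errors="coerce").isna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(
            f"non-numeric cell {df[col].iloc[row]!r}",
            file=path,
            line=row + 2,  # header is line 1
            column=col,
        )
    return df[col].to_numpy(dtype=float)


def _labels_from_strings(raw: pd.Series) -> np.ndarray:
    try:
        return raw.astype(int).to_numpy()
    except ValueError:
        return raw.to_numpy()


# ---------------------------------------------------------------- features

def write_feature_matrix(fm: FeatureMatrix, path) -> None:
    df = pd.DataFrame(fm.values, columns=fm.feature_names)
    df["label"] = fm.labels
    df.to_csv(path, index=False, float_format="%.17g")


def read_feature_matrix(path) -> FeatureMatrix:
    df = _read_csv(path)
    if "label" not in df.columns:
        raise ParseError("missing 'label' column", file=path)
    names = [c for c in df.columns if c != "label"]
    values = np.column_stack(
        [_numeric_column(df, c, path) for c in names]
    ) if names else np.empty((len(df), 0))
    labels = _labels_from_strings(df["label"])
    return FeatureMatrix(values, names, labels)


# ---------------------------------------------------------------- datasets

def write_dataset(records: Sequence[SensorRecord], out_dir) -> Path:
    """One CSV per record (time_s, sensor_01, ...) plus manifest.csv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for i, rec in enumerate(records):
        fname = f"sample_{i:04d}.csv"
        cols = {"time_s": rec.times}
        for s in range(rec.n_sensors):
            cols[f"sensor_{s + 1:02d}"] = rec.values[s]
        pd.DataFrame(cols).to_csv(out_dir / fname, index=False, float_format="%.17g")
        manifest.append(
            {
                "sample_id": i,
                "file": fname,
                "label": rec.label,
                "injection_index": rec.injection_index,
                "sampling_rate": rec.sampling_rate,
            }
        )
    pd.DataFrame(manifest).to_csv(out_dir / "manifest.csv", index=False, float_format="%.17g")
    return out_dir


def read_dataset(in_dir) -> list[SensorRecord]:
    """Inverse of :func:`write_dataset`; errors name the offending file."""
    in_dir = Path(in_dir)
    manifest_path = in_dir / "manifest.csv"
    df = _read_csv(manifest_path)
    for col in ("file", "label", "injection_index", "sampling_rate"):
        if col not in df.columns:
            raise ParseError(f"manifest missing column {col!r}", file=manifest_path)
    records = []
    for _, row in df.iterrows():
        fpath = in_dir / row["file"]
        if not fpath.exists():
            raise ParseError("manifest references missing sample file", file=fpath)
        sample = _read_csv(fpath)
        sensor_cols = [c for c in sample.columns if c.startswith("sensor_")]
        if not sensor_cols:
            raise ParseError("no sensor_* columns", file=fpath)
        values = np.vstack(
            [_numeric_column(sample, c, fpath) for c in sensor_cols]
        )
        records.append(
            SensorRecord(
                values=values,
                sampling_rate=float(row["sampling_rate"]),
                injection_index=int(row["injection_index"]),
                label=int(row["label"]),
            )
        )
    return records


# ---------------------------------------------------------------- reports

def write_cp_report(
    predictions: Sequence[ConformalPrediction],
    true_labels,
    path,
    include_p_values: bool = False,
) -> pd.DataFrame:
    """Per-sample CP report: index, truth, forced label, confidence, credibility."""
    rows = []
    for i, (pred, truth) in enumerate(zip(predictions, np.asarray(true_labels).tolist())):
        row = {
            "sample_index": i,
            "true_label": truth,
            "forced_prediction": pred.forced_label,
            "confidence": pred.confidence,
            "credibility": pred.credibility,
        }
        if include_p_values:
            for lab, pv in sorted(pred.p_values.items()):
                row[f"p_{lab}"] = pv
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False, float_format="%.17g")
    return df


def read_cp_report(path) -> pd.DataFrame:
    df = _read_csv(path)
    required = {"sample_index", "true_label", "forced_prediction", "confidence", "credibility"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"CP report missing columns {sorted(missing)}", file=path)
    out = pd.DataFrame(
        {
            "sample_index": _numeric_column(df, "sample_index", path).astype(int),
            "true_label": _labels_from_strings(df["true_label"]),
            "forced_prediction": _labels_from_strings(df["forced_prediction"]),
            "confidence": _numeric_column(df, "confidence", path),
            "credibility": _numeric_column(df, "credibility", path),
        }
    )
    return out


def write_benchmark_report(report, path) -> None:
    report.table.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------- config

def load_yaml(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ParseError("file not found", file=path)
    with open(path, "r", encoding="utf-8") as fh:
        try:
            data = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ParseError(f"malformed YAML: {exc}", file=path) from exc
    if not isinstance(data, dict):
        raise ParseError("top-level YAML value must be a mapping", file=path)
    return data


def dump_yaml(data: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
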