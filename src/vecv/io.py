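"""Reading paired validation data and writing measure reports.

Numeric parsing is locale-independent (dot decimal separator) regardless
of environment; percent-scaled measures are serialized on the printed
scale (95.79, not 0.9579).
"""

from __future__ import annotations

import csv
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import InputError
from .metrics import REPORT_FIELDS, MeasureReport, PairedData

__all__ = ["read_paired_csv", "write_report", "read_report", "sniff_delimiter"]


def sniff_delimiter(path) -> str:
    """Guess the field delimiter of a delimited text file (comma/tab/semicolon)."""
    sample = Path(path).read_text(encoding="utf-8")[:4096]
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
    except csv.Error:
        return ","


def read_paired_csv(
    path,
    observed_col: str = "observed",
    predicted_col: str = "predicted",
    delimiter: str | None = None,
) -> PairedData:
    """Load a two-column delimited file into PairedData.

    The header row must name the observed and predicted columns (defaults
    "observed"/"predicted").  Rows with missing or non-numeric entries are
    rejected with an error naming the offending row — validation pairs must
    be complete.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    delim = delimiter if delimiter is not None else sniff_delimiter(path)
    try:
        df = pd.read_csv(path, sep=delim)
    except pd.errors.EmptyDataError:
        raise InputError(f"empty file: {path}") from None
    for col in (observed_col, predicted_col):
        if col not in df.columns:
            raise InputError(
                f"column {col!r} not found in {path.name}; have {list(df.columns)}"
            )
    sub = df[[observed_col, predicted_col]].apply(pd.to_numeric, errors="coerce")
    bad = sub.isna().any(axis=1)
    if bad.any():
        # +2: header line plus 1-based numbering
        rows = (np.flatnonzero(bad.to_numpy()) + 2)[:5].tolist()
        raise InputError(f"missing or non-numeric value(s) at file row(s) {rows} of {path.name}")
    if len(sub) == 0:
        raise InputError(f"no data rows in {path}")
    return PairedData(sub[observed_col].to_numpy(float), sub[predicted_col].to_numpy(float))


def write_report(report: MeasureReport, path, fmt: str = "json") -> None:
    """Serialize a MeasureReport to JSON or one-row CSV (fixed column order).

    Undefined measures become explicit nulls (empty CSV cells) and their
    reasons are kept: in JSON under "undefined", in CSV as *_reason columns.
    """
    path = Path(path)
    if fmt == "json":
        path.write_text(report.to_json(indent=2) + "\n")
    elif fmt == "csv":
        row = report.to_dict()
        fields = list(REPORT_FIELDS) + [f"{k}_reason" for k in sorted(report.undefined)]
        for k, reason in report.undefined.items():
            row[f"{k}_reason"] = reason
        with path.open("w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=fields)
            writer.writeheader()
            writer.writerow({k: ("" if row.get(k) is None else row.get(k)) for k in fields})
    else:
        raise InputError(f"unknown report format {fmt!r}; use 'json' or 'csv'")


def read_report(path, fmt: str | None = None) -> dict:
    """Read back a serialized report as a plain dict (None for undefined entries)."""
    path = Path(path)
    if fmt is None:
        fmt = "json" if path.suffix == ".json" else "csv"
    if fmt == "json":
        data = json.loads(path.read_text())
        return {k: data.get(k) for k in REPORT_FIELDS}
    df = pd.read_csv(path)
    out = {}
    for k in REPORT_FIELDS:
        v = df[k].iloc[0] if k in df.columns else float("nan")
        out[k] = None if (isinstance(v, float) and math.isnan(v)) else float(v)
    return out
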