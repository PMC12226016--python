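"""Tabular I/O for signal records and study tables.

The signal interchange schema is one row per sample point with columns
condition_label, batch_id, ti_ms (empty for single-echo series), te_ms,
magnitude, sigma; CSV and a JSON mirror with identical field names are
supported.  Round trips preserve values to full double precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError
from .signals import SignalRecord

__all__ = ["write_signals", "read_signals", "signals_to_frame",
           "frame_to_signals"]

SIGNAL_COLUMNS = ["condition_label", "batch_id", "ti_ms", "te_ms",
                  "magnitude", "sigma"]


def signals_to_frame(records: list[SignalRecord]) -> pd.DataFrame:
    frames = []
    for rec in records:
        n = rec.te_ms.size
        frames.append(pd.DataFrame({
            "condition_label": [rec.condition_label] * n,
            "batch_id": [rec.batch_id] * n,
            "ti_ms": rec.ti_ms if rec.ti_ms is not None
            else [np.nan] * n,
            "te_ms": rec.te_ms,
            "magnitude": rec.magnitude,
            "sigma": [rec.sigma] * n,
        }))
    return pd.concat(frames, ignore_index=True)


def frame_to_signals(df: pd.DataFrame) -> list[SignalRecord]:
    missing = [c for c in SIGNAL_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"missing columns {missing}")
    for col in ("ti_ms", "te_ms", "magnitude", "sigma"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() if col == "ti_ms" \
            else coerced.isna()
        if bad.any():
            # +2: 1-based counting plus the header line
            raise ParseError(f"non-numeric value in column {col}",
                             line=int(bad.idxmax()) + 2)
        df = df.assign(**{col: coerced})
    records = []
    for (cond, batch), grp in df.groupby(["condition_label", "batch_id"],
                                         sort=False):
        has_ti = grp["ti_ms"].notna().any()
        if has_ti and grp["ti_ms"].isna().any():
            raise ParseError(
                f"mixed ti_ms presence for {cond}/{batch}",
                line=int(grp["ti_ms"].isna().idxmax()) + 2)
        records.append(SignalRecord(
            condition_label=str(cond), batch_id=str(batch),
            te_ms=grp["te_ms"].to_numpy(float),
            magnitude=grp["magnitude"].to_numpy(float),
            ti_ms=grp["ti_ms"].to_numpy(float) if has_ti else None,
            sigma=float(grp["sigma"].iloc[0])))
    return records


def write_signals(records: list[SignalRecord], path: str | Path) -> None:
    """Write records as CSV (.csv) or JSON (.json), by extension."""
    path = Path(path)
    df = signals_to_frame(records)
    if path.suffix.lower() == ".json":
        payload = df.where(pd.notna(df), None).to_dict(orient="records")
        path.write_text(json.dumps(payload, indent=1) + "\n")
    else:
        df.to_csv(path, index=False, float_format="%.17g")


def read_signals(path: str | Path) -> list[SignalRecord]:
    path = Path(path)
    if path.suffix.lower() == ".json":
        try:
            payload = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ParseError(str(exc), line=exc.lineno) from exc
        df = pd.DataFrame(payload)
    else:
        try:
            df = pd.read_csv(path, float_precision="round_trip")
        except pd.errors.ParserError as exc:
            raise ParseError(str(exc)) from exc
    return frame_to_signals(df)
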