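"""Reading and writing trial tables.

The canonical trial table is comma-delimited text with a header and the
columns ``participant, session, adapter_soa_s, phase, trial, test_soa_s,
response``.  SOAs are in seconds (negative: auditory lead); ``response``
is ``A``, ``S`` or ``V``.  Files written in milliseconds can be imported
with ``units="ms"``; a seconds-file whose SOA magnitudes exceed 5 is
rejected with a hint that the values look like milliseconds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import COLUMNS, PHASES, Dataset
from .psychometrics import RESPONSES

__all__ = ["read_trials", "write_trials"]


def _report_bad_rows(df: pd.DataFrame, mask, what: str, allowed) -> None:
    if mask.any():
        # +2: one for the header line, one for 1-based numbering
        lines = (df.index[mask] + 2).tolist()[:10]
        values = sorted(map(str, df.loc[mask, what.split()[0]].unique()))[:10]
        raise ValueError(
            f"invalid {what} value(s) {values} at line(s) {lines}; "
            f"expected one of {list(allowed)}"
        )


def read_trials(path, units: str = "s") -> Dataset:
    """Read and validate a trial table; malformed rows are reported by line."""
    if units not in ("s", "ms"):
        raise ValueError("units must be 's' or 'ms'")
    df = pd.read_csv(path, dtype={"participant": str, "phase": str,
                                  "response": str})
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")
    _report_bad_rows(df, ~df["response"].isin(RESPONSES), "response", RESPONSES)
    _report_bad_rows(df, ~df["phase"].isin(PHASES), "phase", PHASES)
    for col in ("adapter_soa_s", "test_soa_s"):
        values = pd.to_numeric(df[col], errors="coerce")
        _report_bad_rows(df, values.isna() & df[col].notna(), col, ["numeric"])
        df[col] = values
    if units == "ms":
        df["adapter_soa_s"] = df["adapter_soa_s"] / 1000.0
        df["test_soa_s"] = df["test_soa_s"] / 1000.0
    elif not df.empty and (np.abs(df[["adapter_soa_s", "test_soa_s"]]).to_numpy()
                           > 5.0).any():
        raise ValueError(
            "SOA magnitudes exceed 5 s; the file appears to be in "
            "milliseconds — re-read with units='ms'"
        )
    return Dataset(df)


def write_trials(dataset: Dataset, path) -> None:
    """Write a trial table (seconds, comma-delimited, lossless round trip)."""
    dataset.frame.to_csv(path, index=False, columns=COLUMNS)
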