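"""Trial-level container for ternary TOJ experiments.

A :class:`Dataset` wraps a pandas DataFrame with one row per TOJ trial
and the columns

    participant, session, adapter_soa_s, phase, trial, test_soa_s, response

where ``phase`` is ``pre`` or ``post``, ``response`` is one of ``A``
(auditory first), ``S`` (simultaneous) or ``V`` (visual first), and SOAs
are in seconds with the sign convention negative = auditory lead.  All
sessions must share the same test-SOA grid.  Likelihood code consumes the
per-cell response counts, which are sufficient statistics for every model
in the package.
"""

from __future__ import annotations

import hashlib

import numpy as np
import pandas as pd

from .psychometrics import RESPONSES

__all__ = ["Dataset", "COLUMNS"]

COLUMNS = ["participant", "session", "adapter_soa_s", "phase", "trial",
           "test_soa_s", "response"]

PHASES = ("pre", "post")


class Dataset:
    """Validated trial-level ternary TOJ data across sessions and phases."""

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        if validate:
            missing = [c for c in COLUMNS if c not in df.columns]
            if missing:
                raise ValueError(f"missing required columns: {missing}")
            bad = ~df["response"].isin(RESPONSES)
            if bad.any():
                raise ValueError(
                    f"invalid response codes {sorted(df.loc[bad, 'response'].unique())}; "
                    f"expected one of {RESPONSES}"
                )
            bad = ~df["phase"].isin(PHASES)
            if bad.any():
                raise ValueError(
                    f"invalid phase values {sorted(df.loc[bad, 'phase'].unique())}; "
                    f"expected one of {PHASES}"
                )
            grids = df.groupby("session")["test_soa_s"].unique().map(
                lambda g: tuple(sorted(g)))
            if len(set(grids)) > 1:
                raise ValueError("sessions do not share the same test-SOA grid")
        self._df = df.reset_index(drop=True)

    # ------------------------------------------------------------------
    @property
    def frame(self) -> pd.DataFrame:
        return self._df

    @property
    def n_trials(self) -> int:
        return len(self._df)

    @property
    def sessions(self) -> np.ndarray:
        return np.sort(self._df["session"].unique())

    @property
    def test_soas(self) -> np.ndarray:
        return np.sort(self._df["test_soa_s"].unique())

    def adapter_soa(self, session) -> float:
        values = self._df.loc[self._df["session"] == session, "adapter_soa_s"].unique()
        if len(values) != 1:
            raise ValueError(f"session {session} has {len(values)} adapter SOAs")
        return float(values[0])

    @property
    def adapter_soas(self) -> np.ndarray:
        return np.array([self.adapter_soa(j) for j in self.sessions])

    def session(self, session) -> "Dataset":
        sub = self._df[self._df["session"] == session]
        if sub.empty:
            raise ValueError(f"no trials for session {session}")
        return Dataset(sub, validate=False)

    def phase(self, phase: str) -> "Dataset":
        if phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}")
        return Dataset(self._df[self._df["phase"] == phase], validate=False)

    # ------------------------------------------------------------------
    def counts(self, phase: str) -> np.ndarray:
        """Response counts per (session, test SOA) cell for one phase.

        Returns an integer array of shape ``(J, S, 3)`` in the canonical
        (A, S, V) response order, sessions and SOAs sorted ascending.
        """
        if phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}")
        sessions = self.sessions
        soas = self.test_soas
        out = np.zeros((len(sessions), len(soas), 3), dtype=int)
        sub = self._df[self._df["phase"] == phase]
        j_idx = np.searchsorted(sessions, sub["session"].to_numpy())
        s_idx = np.searchsorted(soas, sub["test_soa_s"].to_numpy())
        r_idx = np.searchsorted(np.asarray(RESPONSES), sub["response"].to_numpy())
        np.add.at(out, (j_idx, s_idx, r_idx), 1)
        return out

    def fingerprint(self) -> str:
        """Stable digest of the per-cell counts, for comparing fits."""
        h = hashlib.sha1()
        for phase in PHASES:
            h.update(np.ascontiguousarray(self.counts(phase)).tobytes())
        h.update(np.ascontiguousarray(self.test_soas).tobytes())
        h.update(np.ascontiguousarray(self.adapter_soas).tobytes())
        return h.hexdigest()

    def __repr__(self) -> str:
        return (f"Dataset({self.n_trials} trials, {len(self.sessions)} sessions, "
                f"{len(self.test_soas)} test SOAs)")
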