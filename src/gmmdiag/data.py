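"""Long-format longitudinal data container.

A dataset is a collection of (subject, time, response) records in long
format, as produced e.g. by biennial panel surveys.  Panels may be
unbalanced: subjects can miss occasions.  Internally subjects are grouped
by their observed time pattern so the likelihood can batch subjects that
share a marginal covariance matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class _Pattern:
    """Subjects sharing one observed time vector."""

    times: np.ndarray        # (T,)
    responses: np.ndarray    # (n_subjects, T)
    subject_ids: list        # length n_subjects


class LongitudinalDataset:
    """Unbalanced subject x time x response records.

    Parameters
    ----------
    subject_id : array-like
        Opaque subject labels; one entry per record.
    time : array-like of float
        Time of measurement (e.g. occasion index 0..3, or age - 6 in
        years). Must be finite.
    response : array-like of float
        Continuous response (e.g. PIAT reading-recognition score / 10).
        Must be finite.
    """

    def __init__(self, subject_id, time, response):
        sid = np.asarray(subject_id)
        t = np.asarray(time, dtype=float)
        y = np.asarray(response, dtype=float)
        if not (len(sid) == len(t) == len(y)):
            raise ValueError("subject_id, time and response must have equal length")
        if len(sid) == 0:
            raise ValueError("dataset is empty")
        if not np.all(np.isfinite(t)):
            raise ValueError("non-finite time values")
        if not np.all(np.isfinite(y)):
            raise ValueError("non-finite response values")
        self._df = pd.DataFrame({"id": sid, "time": t, "y": y})
        # stable subject order: first appearance
        self._subjects = list(dict.fromkeys(sid.tolist()))
        self._patterns = self._build_patterns()

    def _build_patterns(self) -> list[_Pattern]:
        groups: dict[tuple, list] = {}
        by_subj = {s: g for s, g in self._df.groupby("id", sort=False)}
        for s in self._subjects:
            g = by_subj[s].sort_values("time", kind="stable")
            key = tuple(g["time"].to_numpy())
            groups.setdefault(key, []).append((s, g["y"].to_numpy()))
        pats = []
        for key, members in groups.items():
            times = np.asarray(key, dtype=float)
            resp = np.vstack([y for _, y in members])
            ids = [s for s, _ in members]
            pats.append(_Pattern(times=times, responses=resp, subject_ids=ids))
        return pats

    # ------------------------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self._subjects)

    @property
    def n_records(self) -> int:
        return len(self._df)

    @property
    def subjects(self) -> list:
        return list(self._subjects)

    @property
    def patterns(self) -> list[_Pattern]:
        """Groups of subjects sharing an observed time vector."""
        return self._patterns

    @property
    def subject_order(self) -> list:
        """Subject ids in the order rows of per-subject matrices refer to.

        Pattern-major: all subjects of pattern 0 first, then pattern 1, ...
        """
        out = []
        for p in self._patterns:
            out.extend(p.subject_ids)
        return out

    def to_frame(self) -> pd.DataFrame:
        return self._df.copy()

    def to_csv(self, path) -> None:
        self._df.to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, id_col="id", time_col="time",
                       y_col="y") -> "LongitudinalDataset":
        missing = [c for c in (id_col, time_col, y_col) if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        return cls(df[id_col], df[time_col], df[y_col])

    def subject_records(self, subject) -> tuple[np.ndarray, np.ndarray]:
        g = self._df[self._df["id"] == subject].sort_values("time", kind="stable")
        if len(g) == 0:
            raise KeyError(f"unknown subject {subject!r}")
        return g["time"].to_numpy(), g["y"].to_numpy()

    def mean_records_per_subject(self) -> float:
        return self.n_records / self.n_subjects

    def __repr__(self) -> str:  # pragma: no cover
        return (f"LongitudinalDataset(n_subjects={self.n_subjects}, "
                f"n_records={self.n_records}, "
                f"patterns={len(self._patterns)})")


def read_long_csv(path, id_col="id", time_col="time", y_col="y") -> LongitudinalDataset:
    """Read a long-format CSV with columns id,time,y (header required).

    Raises a ``ValueError`` naming the offending row for blank or
    non-numeric cells.
    """
    df = pd.read_csv(path)
    missing = [c for c in (id_col, time_col, y_col) if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if len(df) == 0:
        raise ValueError(f"{path}: no data rows")
    for col in (time_col, y_col):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.nonzero(~np.isfinite(vals.to_numpy()))[0]
        if bad.size:
            # +2: 1-based and header line
            raise ValueError(
                f"{path}: non-numeric or blank {col!r} at row {bad[0] + 2}")
        df[col] = vals
    return LongitudinalDataset.from_dataframe(df, id_col, time_col, y_col)
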