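"""Longitudinal data model, table I/O and interval pairing.

The canonical input is a *long-format* follow-up table: one row per
observation interval with columns ``ID, IndicatorDeath, Age, AgeNext,
<covariate...>``.  Covariates are measured at ``Age``; ``AgeNext`` is the age
of the next observation of the same subject (the two must chain exactly), or
the age at death/censoring on a subject's final row.

:func:`prepare_data` turns validated records into the two per-interval paired
datasets the estimators consume: one resampled onto a fixed grid by linear
interpolation (discrete-time model) and one at the native, possibly irregular
observation times (continuous-time model).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FormatError, ParseError, ValidationError

__all__ = [
    "LongitudinalRecords",
    "PairedObservations",
    "load_long_table",
    "write_long_table",
    "prepare_data",
]

_CANON = ["id", "event", "t1", "t2"]
_TABLE_HEADER = ["ID", "IndicatorDeath", "Age", "AgeNext"]
_CHAIN_TOL = 1e-6


@dataclass
class LongitudinalRecords:
    """Validated long-format follow-up records.

    ``frame`` has columns ``id, event, t1, t2`` plus one column per covariate
    (values measured at ``t1``; NaN marks a missing measurement).  Rows are
    sorted by ``(id, t1)``; within a subject consecutive rows chain
    (``t2 == next t1``) and ``event == 1`` may occur only on the last row.
    """

    frame: pd.DataFrame
    covariate_names: list

    def __post_init__(self):
        self.covariate_names = list(self.covariate_names)
        cols = _CANON + self.covariate_names
        missing = [c for c in cols if c not in self.frame.columns]
        if missing:
            raise FormatError(f"missing required columns: {missing}")
        df = self.frame.loc[:, cols].copy()
        for c in cols[1:]:
            df[c] = df[c].astype(float)
        df["event"] = df["event"].fillna(0.0).astype(int)
        df = df.sort_values(["id", "t1"], kind="mergesort").reset_index(drop=True)
        if len(df):
            if not set(np.unique(df["event"])) <= {0, 1}:
                raise ValidationError("event indicator must be 0 or 1")
            bad = df["t2"] <= df["t1"]
            if bad.any():
                raise ValidationError(
                    f"t2 <= t1 on {int(bad.sum())} row(s), first at index "
                    f"{int(np.flatnonzero(bad)[0])}"
                )
            ids = df["id"].to_numpy()
            t1 = df["t1"].to_numpy()
            t2 = df["t2"].to_numpy()
            ev = df["event"].to_numpy()
            same = ids[1:] == ids[:-1]
            dup = same & (t1[1:] == t1[:-1])
            if dup.any():
                i = int(np.flatnonzero(dup)[0]) + 1
                raise ValidationError(
                    f"duplicate observation for subject {ids[i]!r} at age {t1[i]}"
                )
            broken = same & (np.abs(t2[:-1] - t1[1:]) > _CHAIN_TOL)
            if broken.any():
                i = int(np.flatnonzero(broken)[0])
                raise ValidationError(
                    f"subject {ids[i]!r}: AgeNext does not coincide with the "
                    "next row's Age"
                )
            early = same & (ev[:-1] == 1)
            if early.any():
                i = int(np.flatnonzero(early)[0])
                raise ValidationError(
                    f"subject {ids[i]!r}: event=1 before the final record"
                )
        self.frame = df

    # -- convenience ------------------------------------------------------

    @property
    def k(self) -> int:
        return len(self.covariate_names)

    @property
    def n_subjects(self) -> int:
        return self.frame["id"].nunique()

    @property
    def n_events(self) -> int:
        return int(self.frame["event"].sum())

    def __len__(self) -> int:
        return len(self.frame)

    def covariates(self) -> np.ndarray:
        """(n_rows, k) matrix of covariate values measured at ``t1``."""
        return self.frame[self.covariate_names].to_numpy(dtype=float)

    def equals(self, other: "LongitudinalRecords", rtol: float = 1e-12) -> bool:
        if self.covariate_names != other.covariate_names:
            return False
        if len(self) != len(other):
            return False
        a, b = self.frame, other.frame
        if list(a["id"].astype(str)) != list(b["id"].astype(str)):
            return False
        if not (a["event"].to_numpy() == b["event"].to_numpy()).all():
            return False
        fa = a[["t1", "t2"] + self.covariate_names].to_numpy(float)
        fb = b[["t1", "t2"] + self.covariate_names].to_numpy(float)
        return bool(np.allclose(fa, fb, rtol=rtol, atol=0.0, equal_nan=True))


@dataclass
class PairedObservations:
    """Per-interval rows consumed by the estimators.

    ``frame`` columns: ``id, case, t1, t2, <cov>..., <cov>.next...``.  ``y2``
    columns are NaN on terminal rows (no measurement at death/censoring).
    """

    frame: pd.DataFrame
    covariate_names: list

    def __post_init__(self):
        self.covariate_names = list(self.covariate_names)
        cols = ["id", "case", "t1", "t2"] + self.covariate_names + self.next_names
        missing = [c for c in cols if c not in self.frame.columns]
        if missing:
            raise FormatError(f"missing required columns: {missing}")
        df = self.frame.loc[:, cols].reset_index(drop=True)
        if len(df) and (df["t2"].to_numpy() <= df["t1"].to_numpy()).any():
            raise ValidationError("paired rows must have t2 > t1")
        self.frame = df

    @property
    def next_names(self) -> list:
        return [f"{c}.next" for c in self.covariate_names]

    @property
    def k(self) -> int:
        return len(self.covariate_names)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def y1(self) -> np.ndarray:
        return self.frame[self.covariate_names].to_numpy(dtype=float)

    @property
    def y2(self) -> np.ndarray:
        return self.frame[self.next_names].to_numpy(dtype=float)

    @property
    def case(self) -> np.ndarray:
        return self.frame["case"].to_numpy(dtype=int)

    @property
    def t1(self) -> np.ndarray:
        return self.frame["t1"].to_numpy(dtype=float)

    @property
    def t2(self) -> np.ndarray:
        return self.frame["t2"].to_numpy(dtype=float)

    def interval_lengths(self) -> np.ndarray:
        return self.t2 - self.t1

    def is_fixed_interval(self, interval: float | None = None, tol: float = 1e-9) -> bool:
        dt = self.interval_lengths()
        if not len(dt):
            return True
        ref = float(interval) if interval is not None else float(np.median(dt))
        return bool(np.max(np.abs(dt - ref)) <= tol)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PairedObservations":
        df = pd.read_csv(path)
        need = ["id", "case", "t1", "t2"]
        if [c.lower() for c in df.columns[:4].tolist()] != need:
            raise FormatError(f"paired table must start with columns {need}")
        df.columns = need + df.columns[4:].tolist()
        covs = [c for c in df.columns[4:] if not c.endswith(".next")]
        return cls(frame=df, covariate_names=covs)


# ---------------------------------------------------------------------------
# long-table I/O


def load_long_table(path_or_stream, covariate_names=None) -> LongitudinalRecords:
    """Read a long-format follow-up table (CSV, or sas7bdat by extension).

    The first four columns are positional — subject id, death indicator,
    interval start age, interval end age — regardless of their header names;
    every remaining column is a covariate unless ``covariate_names`` selects
    a subset by name.  Rows with ``t2 <= t1`` are dropped with a warning.
    """
    if isinstance(path_or_stream, str) and path_or_stream.endswith(".sas7bdat"):
        df = pd.read_sas(path_or_stream)
    else:
        df = pd.read_csv(path_or_stream, na_values=["NA"], skipinitialspace=True)
    if df.shape[1] < 4:
        raise FormatError(
            "expected at least 4 columns (id, death indicator, age, next age); "
            f"got {df.shape[1]}"
        )
    header = df.columns.tolist()
    if covariate_names is not None:
        covariate_names = list(covariate_names)
        missing = [c for c in covariate_names if c not in header[4:]]
        if missing:
            raise FormatError(f"covariate column(s) not found: {missing}")
    else:
        covariate_names = header[4:]
    out = pd.DataFrame({"id": df.iloc[:, 0]})
    for name, col in zip(_CANON[1:], [1, 2, 3]):
        raw = df.iloc[:, col]
        num = pd.to_numeric(raw, errors="coerce")
        bad = num.isna() & raw.notna()
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"non-numeric value {raw.iloc[i]!r} in column "
                f"{header[col]!r} at row {i}"
            )
        out[name] = num
    for c in covariate_names:
        num = pd.to_numeric(df[c], errors="coerce")
        bad = num.isna() & df[c].notna()
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(f"non-numeric value {df[c].iloc[i]!r} in column {c!r} at row {i}")
        out[c] = num
    if len(out):
        drop = ~(out["t2"] > out["t1"])
        if drop.any():
            warnings.warn(
                f"dropped {int(drop.sum())} row(s) violating t2 > t1",
                stacklevel=2,
            )
            out = out[~drop]
    return LongitudinalRecords(frame=out, covariate_names=covariate_names)


def write_long_table(records: LongitudinalRecords, path) -> None:
    """Write records as CSV in the canonical column order, loss-free."""
    df = records.frame.copy()
    df.columns = _TABLE_HEADER + records.covariate_names
    df.to_csv(path, index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# preparation


def _impute_interior(times: np.ndarray, vals: np.ndarray) -> np.ndarray:
    """Fill interior NaNs of one covariate by linear interpolation in time.

    Leading/trailing gaps are left missing — values are never extrapolated.
    """
    out = vals.copy()
    obs = np.isfinite(vals)
    if obs.sum() < 2:
        return out
    first, last = np.flatnonzero(obs)[[0, -1]]
    interior = ~obs
    interior[:first] = False
    interior[last:] = False
    if interior.any():
        out[interior] = np.interp(times[interior], times[obs], vals[obs])
    return out


def _interp_with_nan(grid, times, vals):
    """np.interp that returns NaN outside the observed support."""
    obs = np.isfinite(vals)
    out = np.full(grid.shape, np.nan)
    if not obs.any():
        return out
    lo, hi = times[obs][0], times[obs][-1]
    inside = (grid >= lo - 1e-9) & (grid <= hi + 1e-9)
    out[inside] = np.interp(grid[inside], times[obs], vals[obs])
    return out


def prepare_data(records: LongitudinalRecords, interval: float = 1.0,
                 impute: bool = True):
    """Build the fixed-interval and arbitrary-interval paired datasets.

    Returns ``(fixed, arbitrary)``.  The arbitrary dataset pairs consecutive
    same-subject observations at their native times; the fixed dataset
    resamples each subject's trajectory onto the grid ``t0, t0+interval, ...``
    anchored at the subject's own first observation age, interpolating
    covariates linearly and never extrapolating beyond the last observation.
    With ``impute`` set, interior missing covariate values are filled by
    within-subject linear interpolation before pairing.  Terminal event
    intervals carry ``case = 1`` and have no ``y2``.
    """
    interval = float(interval)
    if interval <= 0:
        raise ValueError(f"interval must be > 0, got {interval}")
    names = records.covariate_names
    k = records.k
    # per-subject chunks: (ids, case, t1, t2, y1 (n,k), y2 (n,k))
    fixed_chunks, arb_chunks = [], []
    n_dropped_subjects = 0
    all_ids = records.frame["id"].to_numpy()
    all_t1 = records.frame["t1"].to_numpy(float)
    all_t2 = records.frame["t2"].to_numpy(float)
    all_ev = records.frame["event"].to_numpy(int)
    all_Y = records.frame[names].to_numpy(float) if k else np.empty((len(all_t1), 0))
    starts = np.concatenate([[0], np.flatnonzero(all_ids[1:] != all_ids[:-1]) + 1,
                             [len(all_ids)]]) if len(all_ids) else np.array([0, 0])
    for si in range(len(starts) - 1):
        lo, hi = int(starts[si]), int(starts[si + 1])
        if lo == hi:
            continue
        sid = all_ids[lo]
        times = all_t1[lo:hi]
        t2s = all_t2[lo:hi]
        events = all_ev[lo:hi]
        Y = all_Y[lo:hi]
        if not np.isfinite(Y).any():
            n_dropped_subjects += 1
            continue
        if impute and k:
            Y = np.column_stack([
                _impute_interior(times, Y[:, j]) for j in range(k)
            ])
        tau = t2s[-1]
        ev_last = int(events[-1])
        n = len(times)
        # arbitrary-interval rows at native times (y2 = next row's value)
        y2 = np.vstack([Y[1:], np.full((1, k), np.nan)])
        ok = np.isfinite(Y).all(axis=1)
        arb_chunks.append((np.repeat(sid, ok.sum()), events[ok], times[ok],
                           t2s[ok], Y[ok], y2[ok]))
        # fixed-interval rows on the subject-anchored grid
        m = int(np.floor((times[-1] - times[0]) / interval + 1e-9))
        grid = times[0] + interval * np.arange(m + 1)
        Yg = np.column_stack([
            _interp_with_nan(grid, times, Y[:, j]) for j in range(k)
        ]) if k else np.empty((m + 1, 0))
        okg = np.isfinite(Yg).all(axis=1)
        keep = okg[:-1] & okg[1:]
        fixed_chunks.append((np.repeat(sid, keep.sum()), np.zeros(keep.sum(), int),
                             grid[:-1][keep], grid[1:][keep], Yg[:-1][keep],
                             Yg[1:][keep]))
        if okg[-1] and (ev_last == 1 or tau >= grid[-1] + interval - 1e-9):
            fixed_chunks.append((np.repeat(sid, 1), np.array([ev_last]),
                                 grid[-1:], grid[-1:] + interval,
                                 Yg[-1:], np.full((1, k), np.nan)))
    if n_dropped_subjects and n_dropped_subjects == records.n_subjects:
        warnings.warn("all covariates missing for all subjects; outputs are empty",
                      stacklevel=2)

    def _build(chunks):
        cols = ["id", "case", "t1", "t2"] + names + [f"{c}.next" for c in names]
        if not chunks:
            df = pd.DataFrame({c: pd.Series(dtype=float) for c in cols})
            return PairedObservations(frame=df, covariate_names=names)
        df = pd.DataFrame({
            "id": np.concatenate([c[0] for c in chunks]),
            "case": np.concatenate([c[1] for c in chunks]).astype(int),
            "t1": np.concatenate([c[2] for c in chunks]),
            "t2": np.concatenate([c[3] for c in chunks]),
        })
        y1 = np.concatenate([c[4] for c in chunks], axis=0)
        y2 = np.concatenate([c[5] for c in chunks], axis=0)
        for j, c in enumerate(names):
            df[c] = y1[:, j]
        for j, c in enumerate(names):
            df[f"{c}.next"] = y2[:, j]
        return PairedObservations(frame=df, covariate_names=names)

    return _build(fixed_chunks), _build(arb_chunks)
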