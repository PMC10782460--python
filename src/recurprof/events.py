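"""Counting-process event histories on a discrete daily calendar grid.

The data model is a long-format table of half-open intervals ``(start, stop]``
per subject.  A subject is at risk on every integer day ``d`` with
``start < d <= stop`` for some recorded interval; covariates are
left-continuous step functions, constant within an interval.  An event
(``event == 1``) is counted at the ``stop`` day of its interval, so at most
one event can occur per subject-day.  Subjects are clustered in facilities
(dialysis units, hospitals, ...), and the facility label is constant within
subject.

:class:`RiskIndex` is the compiled form every estimator consumes: the sorted
grid of unique event days, per-interval activity ranges on that grid, and the
per-facility event counts.  It is built once by a sweep over interval
endpoints; records are never split per event.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("subject_id", "facility_id", "start", "stop", "event")


class TableError(ValueError):
    """Raised when an event-history table violates a structural invariant."""


@dataclass(frozen=True)
class EventHistoryTable:
    """A validated long-format clustered recurrent-event table.

    Attributes
    ----------
    data:
        Frame with columns ``subject_id, facility_id, start, stop, event``
        plus one column per covariate, sorted by subject then interval start.
    covariates:
        Names of the covariate columns, in model order.
    """

    data: pd.DataFrame
    covariates: tuple[str, ...]

    @property
    def n_subjects(self) -> int:
        return self.data["subject_id"].nunique()

    @property
    def n_facilities(self) -> int:
        return self.data["facility_id"].nunique()

    @property
    def n_events(self) -> int:
        return int(self.data["event"].sum())

    def write_csv(self, path: str | Path) -> None:
        """Write the table in the canonical CSV dialect."""
        cols = list(REQUIRED_COLUMNS) + list(self.covariates)
        self.data.loc[:, cols].to_csv(path, index=False)


def read_table(path: str | Path, covariates: list[str] | None = None) -> EventHistoryTable:
    """Read and validate a table from the canonical CSV dialect.

    The header must start with ``subject_id,facility_id,start,stop,event``;
    every remaining column is treated as a covariate unless ``covariates``
    restricts the set.  Missing covariate values are an error (no imputation).
    """
    df = pd.read_csv(path)
    return validate_table(df, covariates=covariates)


def validate_table(
    data: pd.DataFrame, covariates: list[str] | None = None
) -> EventHistoryTable:
    """Check all structural invariants and return a canonicalised table.

    Raises
    ------
    TableError
        Naming the offending subject for: overlapping intervals, more than
        one event on a subject-day, a facility change within a subject,
        ``start >= stop``, a non-0/1 event code, or missing covariates.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in data.columns]
    if missing:
        raise TableError(f"missing required columns: {missing}")
    if covariates is None:
        covariates = [c for c in data.columns if c not in REQUIRED_COLUMNS]
    else:
        absent = [c for c in covariates if c not in data.columns]
        if absent:
            raise TableError(f"covariate columns not in table: {absent}")
    if len(data) == 0:
        raise TableError("empty table")

    df = data.copy()
    for col in ("start", "stop"):
        vals = df[col].to_numpy()
        if not np.all(np.isfinite(vals)) or not np.allclose(vals, np.round(vals)):
            raise TableError(f"column {col!r} must be integer days")
        df[col] = np.asarray(np.round(vals), dtype=np.int64)

    ev = df["event"].to_numpy()
    if not np.isin(ev, (0, 1)).all():
        bad = df.loc[~np.isin(ev, (0, 1)), "subject_id"].iloc[0]
        raise TableError(
            f"subject {bad!r}: event must be 0/1 (at most one event per subject-day)"
        )
    df["event"] = ev.astype(np.int64)

    for c in covariates:
        col = pd.to_numeric(df[c], errors="coerce")
        if col.isna().any():
            bad = df.loc[col.isna(), "subject_id"].iloc[0]
            raise TableError(f"subject {bad!r}: missing covariate {c!r}")
        df[c] = col.astype(np.float64)

    bad = df["start"] >= df["stop"]
    if bad.any():
        sid = df.loc[bad, "subject_id"].iloc[0]
        raise TableError(f"subject {sid!r}: interval with start >= stop")

    df = df.sort_values(["subject_id", "start"], kind="mergesort").reset_index(drop=True)

    nfac = df.groupby("subject_id", sort=False)["facility_id"].nunique()
    if (nfac > 1).any():
        sid = nfac.index[nfac > 1][0]
        raise TableError(f"subject {sid!r}: facility changes within subject")

    # overlap: within a subject (sorted by start) each interval must end
    # before the next one opens; equal stops would also collide on event days
    sid_arr = df["subject_id"].to_numpy()
    same = sid_arr[1:] == sid_arr[:-1]
    overlap = same & (df["stop"].to_numpy()[:-1] > df["start"].to_numpy()[1:])
    if overlap.any():
        sid = sid_arr[:-1][overlap][0]
        raise TableError(f"subject {sid!r}: overlapping intervals")

    return EventHistoryTable(data=df, covariates=tuple(covariates))


@dataclass
class RiskIndex:
    """Risk-set index over the unique event days of a validated table.

    All identifiers are coded as dense integers; ``facility_ids`` and
    ``subject_ids`` map codes back to the original labels.  Interval ``r`` is
    active at event-day slot ``m`` iff ``row_lo[r] <= m < row_hi[r]``.
    """

    event_times: np.ndarray       # (M,) sorted unique event days
    facility_ids: np.ndarray      # (F,) original labels, sorted
    subject_ids: np.ndarray       # (n,) original labels, sorted
    subject_facility: np.ndarray  # (n,) facility code per subject
    covariate_names: tuple[str, ...]

    row_subject: np.ndarray       # (R,)
    row_facility: np.ndarray      # (R,)
    row_lo: np.ndarray            # (R,) first active event-day slot
    row_hi: np.ndarray            # (R,) one past last active slot
    Z: np.ndarray                 # (R, p) covariates on the interval

    event_row: np.ndarray         # (K,) interval index of each event
    event_m: np.ndarray           # (K,) event-day slot of each event
    event_pair: np.ndarray        # (K,) index into the (facility, day) pairs
    dN_total: np.ndarray          # (M,) events per day, all facilities

    pair_fac: np.ndarray          # (P,) facility code per event pair
    pair_m: np.ndarray            # (P,) day slot per event pair
    pair_dN: np.ndarray           # (P,) events in that facility on that day
    pair_Zsum: np.ndarray         # (P, p) sum of event covariates in the pair
    fac_observed: np.ndarray      # (F,) O_j

    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def n_days(self) -> int:
        return len(self.event_times)

    @property
    def n_facilities(self) -> int:
        return len(self.facility_ids)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_covariates(self) -> int:
        return self.Z.shape[1]

    def subject_observed(self) -> np.ndarray:
        """O_ij: observed event count per subject."""
        return np.bincount(
            self.row_subject[self.event_row], minlength=self.n_subjects
        ).astype(np.float64)


def build_risk_index(table: EventHistoryTable) -> RiskIndex:
    """Compile a validated table into a :class:`RiskIndex`.

    Raises
    ------
    TableError
        If the table holds no events (no baseline is then estimable).
    """
    df = table.data
    if int(df["event"].sum()) == 0:
        raise TableError("table has no events; baseline rate is not estimable")

    fac_codes, fac_ids = pd.factorize(df["facility_id"], sort=True)
    subj_codes, subj_ids = pd.factorize(df["subject_id"], sort=True)
    start = df["start"].to_numpy()
    stop = df["stop"].to_numpy()
    is_event = df["event"].to_numpy() == 1

    event_times = np.unique(stop[is_event])
    row_lo = np.searchsorted(event_times, start, side="right")
    row_hi = np.searchsorted(event_times, stop, side="right")

    event_row = np.flatnonzero(is_event)
    event_m = np.searchsorted(event_times, stop[event_row])
    ev_fac = fac_codes[event_row]

    subject_facility = np.zeros(len(subj_ids), dtype=np.int64)
    subject_facility[subj_codes] = fac_codes

    Z = (
        df[list(table.covariates)].to_numpy(dtype=np.float64)
        if table.covariates
        else np.empty((len(df), 0))
    )

    # group events into unique (facility, day) pairs, sorted by facility then day
    order = np.lexsort((event_m, ev_fac))
    key = ev_fac[order] * (len(event_times) + 1) + event_m[order]
    uniq, first, inv, counts = np.unique(
        key, return_index=True, return_inverse=True, return_counts=True
    )
    pair_fac = ev_fac[order][first]
    pair_m = event_m[order][first]
    pair_dN = counts.astype(np.float64)
    p = Z.shape[1]
    pair_Zsum = np.zeros((len(uniq), p))
    np.add.at(pair_Zsum, inv, Z[event_row][order])
    event_pair = np.empty(len(event_row), dtype=np.int64)
    event_pair[order] = inv

    dN_total = np.bincount(event_m, minlength=len(event_times)).astype(np.float64)
    fac_observed = np.bincount(ev_fac, minlength=len(fac_ids)).astype(np.float64)

    return RiskIndex(
        event_times=event_times,
        facility_ids=np.asarray(fac_ids),
        subject_ids=np.asarray(subj_ids),
        subject_facility=subject_facility,
        covariate_names=table.covariates,
        row_subject=subj_codes.astype(np.int64),
        row_facility=fac_codes.astype(np.int64),
        row_lo=row_lo.astype(np.int64),
        row_hi=row_hi.astype(np.int64),
        Z=Z,
        event_row=event_row.astype(np.int64),
        event_m=event_m.astype(np.int64),
        event_pair=event_pair,
        dN_total=dN_total,
        pair_fac=pair_fac.astype(np.int64),
        pair_m=pair_m.astype(np.int64),
        pair_dN=pair_dN,
        pair_Zsum=pair_Zsum,
        fac_observed=fac_observed,
    )
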