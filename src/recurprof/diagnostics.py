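"""Model diagnostics and time-varying covariate construction.

Three tools: Schoenfeld-type residuals for tied daily data (to inspect the
proportional-rates assumption over calendar time), observed-vs-expected
event series in calendar bins (weekly by default), and a builder for the
staged infection-history covariate used to let an epidemic's effect on the
event rate vary with time since diagnosis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels
from .estimation import FittedModel
from .events import RiskIndex

STAGES = ("no-COVID", "COVID1", "COVID2", "post-COVID", "late-COVID")


@dataclass
class ResidualSeries:
    """Per-bin per-covariate Schoenfeld residuals s_k.

    With bins partitioning the study window and the fit's own weighting for
    the at-risk averages, the residuals sum (approximately) to the score at
    beta-hat, i.e. to ~0 componentwise.
    """

    bin_edges: np.ndarray      # (K+1,) day edges; bin k is (edge_k, edge_{k+1}]
    residuals: np.ndarray      # (K, p)
    n_events: np.ndarray       # (K,)
    empty_bin: np.ndarray      # (K,) flag: no event day fell in the bin

    def to_frame(self, names: tuple[str, ...]) -> pd.DataFrame:
        df = pd.DataFrame(self.residuals, columns=list(names))
        df.insert(0, "bin_start", self.bin_edges[:-1])
        df.insert(1, "bin_end", self.bin_edges[1:])
        df["n_events"] = self.n_events
        df["empty_bin"] = self.empty_bin
        return df


def schoenfeld_residuals(
    index: RiskIndex,
    beta: np.ndarray,
    alpha: np.ndarray | None = None,
    bins: np.ndarray | None = None,
    weighted: bool = True,
) -> ResidualSeries:
    """Schoenfeld residuals for tied daily data.

    For each event day: the covariate sum of patients with events minus the
    number of events times the at-risk covariate average; residuals are
    accumulated over day bins.  With ``weighted`` (default) the average uses
    the fitted weights exp(Z'beta + alpha); the unweighted variant is the
    plain at-risk mean.
    """
    beta = np.asarray(beta, dtype=np.float64)
    if weighted:
        w = np.exp(_kernels.linear_predictor(index, beta))
        if alpha is not None:
            w = w * np.exp(np.asarray(alpha, dtype=np.float64))[index.row_facility]
    else:
        w = np.ones(len(index.row_lo))
    S0, S1 = _kernels.pooled_moments(index, w)
    zbar = S1 / S0[:, None]

    p = index.n_covariates
    ev_Zsum = np.zeros((index.n_days, p))
    np.add.at(ev_Zsum, index.event_m, index.Z[index.event_row])
    per_day = ev_Zsum - index.dN_total[:, None] * zbar

    if bins is None:
        bins = np.array([0, int(index.event_times.max())])
    bins = np.asarray(bins)
    K = len(bins) - 1
    which = np.searchsorted(bins, index.event_times, side="left") - 1
    which = np.clip(which, 0, K - 1)
    residuals = np.zeros((K, p))
    n_events = np.zeros(K)
    np.add.at(residuals, which, per_day)
    np.add.at(n_events, which, index.dN_total)
    return ResidualSeries(
        bin_edges=bins,
        residuals=residuals,
        n_events=n_events,
        empty_bin=n_events == 0,
    )


def oe_series(
    fitted: FittedModel,
    bin_days: int = 7,
    facilities: np.ndarray | list | None = None,
) -> pd.DataFrame:
    """Observed and expected events per calendar bin (weekly by default).

    E in a bin sums Y_i exp(Z'beta + alpha_j) dmu0 over the bin's event
    days, restricted to the given facilities (all by default).  Two
    residual standardisations are emitted: ``(O-E)/E`` and the
    Poisson-scaled ``(O-E)/sqrt(E)``.
    """
    index = fitted.index
    beta = fitted.covariate_effects.beta
    alpha = fitted.facility_effects.alpha
    w = np.exp(_kernels.linear_predictor(index, beta) + alpha[index.row_facility])
    if facilities is not None:
        codes = np.searchsorted(index.facility_ids, np.asarray(facilities))
        keep_fac = np.zeros(index.n_facilities, dtype=bool)
        keep_fac[codes] = True
        w = np.where(keep_fac[index.row_facility], w, 0.0)
        ev_keep = keep_fac[index.row_facility[index.event_row]]
    else:
        ev_keep = np.ones(len(index.event_row), dtype=bool)

    S0_sel, _ = _kernels.pooled_moments(index, w)
    E_day = S0_sel * fitted.baseline.increments
    O_day = np.bincount(
        index.event_m[ev_keep], minlength=index.n_days
    ).astype(np.float64)

    which = (index.event_times - 1) // bin_days
    n_bins = int(which.max()) + 1
    O = np.bincount(which, weights=O_day, minlength=n_bins)
    E = np.bincount(which, weights=E_day, minlength=n_bins)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(E > 0, (O - E) / E, np.nan)
        std = np.where(E > 0, (O - E) / np.sqrt(E), np.nan)
    return pd.DataFrame(
        {
            "bin": np.arange(n_bins),
            "day_start": np.arange(n_bins) * bin_days + 1,
            "day_end": (np.arange(n_bins) + 1) * bin_days,
            "observed": O,
            "expected": E,
            "oe_ratio_residual": ratio,
            "oe_std_residual": std,
        }
    )


def profiling_filter(
    observed: np.ndarray,
    expected: np.ndarray,
    e_min: float = 5.0,
    e_max: float = 800.0,
) -> np.ndarray:
    """Mask of facilities to keep in profiling report outputs.

    Funnel-plot and histogram summaries exclude facilities whose expected
    count is extreme (E < e_min: too noisy; E > e_max: off the plot scale)
    or that observed no events at all.
    """
    observed = np.asarray(observed, dtype=np.float64)
    expected = np.asarray(expected, dtype=np.float64)
    return (observed > 0) & (expected >= e_min) & (expected <= e_max)


@dataclass
class StageTimeline:
    """Ordered infection-stage intervals (days inclusive) for one patient."""

    intervals: list[tuple[int, int, str]]  # (first_day, last_day, stage)

    def stage_on(self, day: int) -> str | None:
        for a, b, s in self.intervals:
            if a <= day <= b:
                return s
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.intervals, columns=["start", "stop", "stage"])


def covid_stages(
    diagnosis_days: list[int],
    covid_hosp_days: list[int],
    followup: tuple[int, int],
    covid1_days: int = 10,
    clear_gap_days: int = 21,
) -> StageTimeline:
    """Build the staged infection-history timeline for one patient.

    The patient starts in ``no-COVID``.  The first diagnosis (or
    COVID-coded hospitalisation) day d1 opens the COVID state: ``COVID1``
    covers the first 10 days [d1, d1+9], ``COVID2`` the remainder.  The
    COVID state ends once 21 consecutive days pass with no further
    diagnosis: each diagnosis at day d inside the state pushes its end to
    d + 20, and ``post-COVID`` starts the following day.  A COVID-coded
    hospitalisation while post-COVID switches the patient to the absorbing
    ``late-COVID`` state.  Days outside follow-up are ignored with a
    warning.  Stages partition the follow-up window and only move forward.
    """
    f0, f1 = followup
    if f0 > f1:
        raise ValueError("empty follow-up window")

    def _clean(days: list[int], label: str) -> list[int]:
        kept = sorted({int(d) for d in days if f0 <= d <= f1})
        dropped = [d for d in days if not f0 <= d <= f1]
        if dropped:
            warnings.warn(f"{label} days outside follow-up ignored: {dropped}")
        return kept

    diag = _clean(diagnosis_days, "diagnosis")
    hosp = _clean(covid_hosp_days, "COVID hospitalisation")
    marks = sorted({(d, d in hosp) for d in set(diag) | set(hosp)})
    if not marks:
        return StageTimeline([(f0, f1, "no-COVID")])

    d1 = marks[0][0]
    covid_end = d1 + clear_gap_days - 1
    late_start: int | None = None
    for d, is_hosp in marks[1:]:
        if d <= covid_end:
            covid_end = max(covid_end, d + clear_gap_days - 1)
        elif is_hosp:
            late_start = d
            break
        # a bare diagnosis after the COVID state has closed does not reopen it

    intervals: list[tuple[int, int, str]] = []
    if d1 > f0:
        intervals.append((f0, d1 - 1, "no-COVID"))
    c1_end = min(d1 + covid1_days - 1, covid_end, f1)
    intervals.append((d1, c1_end, "COVID1"))
    if covid_end > c1_end and d1 + covid1_days <= f1:
        intervals.append((d1 + covid1_days, min(covid_end, f1), "COVID2"))
    post_start = covid_end + 1
    if post_start <= f1:
        post_end = f1 if late_start is None else late_start - 1
        if post_end >= post_start:
            intervals.append((post_start, min(post_end, f1), "post-COVID"))
        if late_start is not None and late_start <= f1:
            intervals.append((late_start, f1, "late-COVID"))
    return StageTimeline(intervals)
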