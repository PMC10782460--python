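"""Fitting the proportional-rates model with high-dimensional facility effects.

The marginal rate of recurrent events for subject i in facility j is

    E{dN_i(t) | Y_i(t), Z_i(t)} = Y_i(t) exp{alpha_j + Z_i(t)' beta} dmu0(t),

with a non-parametric baseline rate dmu0 on the calendar-day grid.  Fitting
is decoupled: beta is estimated once from the facility-stratified Breslow
partial likelihood (facility effects drop out of the strata), then the
facility effects alpha are obtained by a fixed-point iteration that
alternates a Nelson-Aalen baseline update with the closed-form update
exp(alpha_j) = C * O_j / E_j, where O_j and E_j are the observed and
expected event counts of facility j and C = sum(E)/sum(O) recentres the
effects so that the identifiability constraint sum(O) = sum(E) holds; the
pooled standardised ratio is then exactly 1 and exp(alpha_j) converges to
the standardised event ratio O_j/E_j.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from . import _kernels
from .events import EventHistoryTable, RiskIndex, TableError, build_risk_index

ZERO_EVENT_ALPHA = -10.0  # sentinel effect for facilities with no events


class ConvergenceWarning(UserWarning):
    pass


@dataclass
class CovariateEffects:
    """Estimated covariate effects from the stratified Breslow fit."""

    beta: np.ndarray
    information: np.ndarray
    n_iter: int
    converged: bool
    log_partial_likelihood: float
    covariate_names: tuple[str, ...] = ()


@dataclass
class BaselineRate:
    """Nelson-Aalen baseline increments on the event-day grid (zero elsewhere)."""

    event_times: np.ndarray
    increments: np.ndarray

    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.increments)


@dataclass
class FacilityEffects:
    """Facility effects, observed/expected counts and standardised ratios."""

    facility_ids: np.ndarray
    alpha: np.ndarray
    observed: np.ndarray        # O_j
    expected: np.ndarray        # E_j at the final baseline
    shr: np.ndarray             # O_j / E_j (0 for zero-event facilities)
    zero_event: np.ndarray      # bool mask
    scaling_history: np.ndarray  # C^(s) per iteration
    n_iter: int
    converged: bool


@dataclass
class FittedModel:
    """Covariate effects, baseline and facility effects fitted on one table."""

    index: RiskIndex
    covariate_effects: CovariateEffects
    baseline: BaselineRate
    facility_effects: FacilityEffects
    subject_observed: np.ndarray  # O_ij
    subject_expected: np.ndarray  # E_ij at the final baseline
    settings: dict[str, Any] = field(default_factory=dict)


def stratified_score(
    index: RiskIndex, beta: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Score U(beta) and observed information I(beta) of the stratified
    Breslow partial likelihood.  Strata without events contribute nothing."""
    stats = _kernels.stratum_statistics(index, beta, need_information=True)
    return stats.score, stats.information


def _collinear_columns(info: np.ndarray, names: tuple[str, ...]) -> list[str]:
    vals, vecs = np.linalg.eigh(info)
    null = vecs[:, vals < 1e-10 * max(vals.max(), 1.0)]
    if null.size == 0:
        return []
    loading = np.abs(null).max(axis=1)
    labels = names if names else tuple(f"z{k}" for k in range(len(loading)))
    return [labels[k] for k in np.flatnonzero(loading > 1e-6)]


def fit_beta(
    index: RiskIndex,
    init: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> CovariateEffects:
    """Newton-Raphson with step-halving for the stratified Breslow estimator.

    Convergence is declared when ``max|U(beta)| <= tol``.  A singular
    information matrix raises an error naming the collinear columns; failure
    to converge (e.g. monotone likelihood) is reported through the
    ``converged`` flag and a :class:`ConvergenceWarning`, never silently.
    """
    p = index.n_covariates
    if p < 1:
        raise ValueError("fit_beta requires at least one covariate")
    beta = np.zeros(p) if init is None else np.asarray(init, dtype=np.float64).copy()
    stats = _kernels.stratum_statistics(index, beta)
    n_iter = 0
    converged = bool(np.max(np.abs(stats.score)) <= tol)
    while not converged and n_iter < max_iter:
        n_iter += 1
        try:
            step = np.linalg.solve(stats.information, stats.score)
        except np.linalg.LinAlgError:
            cols = _collinear_columns(stats.information, index.covariate_names)
            raise np.linalg.LinAlgError(
                f"singular information matrix; collinear columns: {cols}"
            ) from None
        # step-halving: do not accept a real decrease of the log partial
        # likelihood (tolerance scaled to its float resolution)
        ll_floor = stats.log_partial_likelihood - 1e-9 * (
            abs(stats.log_partial_likelihood) + 1.0
        )
        for _ in range(25):
            cand = _kernels.stratum_statistics(index, beta + step)
            if cand.log_partial_likelihood >= ll_floor:
                break
            step = step / 2.0
        beta = beta + step
        stats = cand
        converged = bool(np.max(np.abs(stats.score)) <= tol)
    if not converged:
        warnings.warn(
            f"fit_beta did not converge in {max_iter} iterations "
            f"(max |score| = {np.max(np.abs(stats.score)):.3g})",
            ConvergenceWarning,
        )
    return CovariateEffects(
        beta=beta,
        information=stats.information,
        n_iter=n_iter,
        converged=converged,
        log_partial_likelihood=stats.log_partial_likelihood,
        covariate_names=index.covariate_names,
    )


def nelson_aalen_baseline(
    index: RiskIndex,
    beta: np.ndarray,
    alpha: np.ndarray,
    s0_grid: np.ndarray | None = None,
) -> BaselineRate:
    """dmu0(t_m) = dN.(t_m) / S^(0)(t_m) with facility effects in S^(0)."""
    alpha = np.asarray(alpha, dtype=np.float64)
    if len(alpha) != index.n_facilities:
        raise ValueError("alpha must have one entry per facility")
    if s0_grid is None:
        s0_grid = _kernels.stratum_s0_grid(index, beta)
    S0 = np.exp(alpha) @ s0_grid
    if np.any(S0 <= 0):
        raise TableError("empty risk set on an event day")
    return BaselineRate(event_times=index.event_times, increments=index.dN_total / S0)


def expected_events(
    index: RiskIndex, baseline: BaselineRate, beta: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Expected counts under the national norm (no facility effect).

    Returns ``(E_j, E_ij, O_j, O_ij)`` where
    ``E_ij = sum_m Y_i(t_m) exp(Z_i(t_m)' beta) dmu0(t_m)``.
    """
    w = np.exp(_kernels.linear_predictor(index, np.asarray(beta, dtype=np.float64)))
    row_E = w * _kernels.range_sums(index, baseline.increments)
    E_ij = np.bincount(index.row_subject, weights=row_E, minlength=index.n_subjects)
    E_j = np.bincount(index.row_facility, weights=row_E, minlength=index.n_facilities)
    O_ij = index.subject_observed()
    return E_j, E_ij, index.fac_observed.copy(), O_ij


def fixed_point_alpha(
    index: RiskIndex,
    beta: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 2000,
) -> FacilityEffects:
    """Constrained fixed-point iteration for the facility effects.

    Starting from alpha = 0, each sweep recomputes the baseline at the
    current alpha, the expected counts E_j^(s), the recentring factor
    C^(s) = sum(E^(s))/sum(O), and updates
    alpha_j^(s+1) = log(C^(s) O_j / E_j^(s)).  Iteration stops when
    ``max_j |alpha_j^(s+1) - alpha_j^(s)| <= tol`` over facilities with
    events; zero-event facilities are pinned at the sentinel effect -10
    (their subjects still contribute to the risk sets and to E_j).
    """
    F = index.n_facilities
    O_j = index.fac_observed
    zero = O_j == 0
    alpha = np.zeros(F)
    alpha[zero] = ZERO_EVENT_ALPHA
    s0_grid = _kernels.stratum_s0_grid(index, beta)
    w = np.exp(_kernels.linear_predictor(index, np.asarray(beta, dtype=np.float64)))
    O_total = O_j.sum()

    history: list[float] = []
    converged = False
    n_iter = 0
    E_j = np.zeros(F)
    while n_iter < max_iter:
        n_iter += 1
        S0 = np.exp(alpha) @ s0_grid
        dmu = index.dN_total / S0
        row_E = w * _kernels.range_sums(index, dmu)
        E_j = np.bincount(index.row_facility, weights=row_E, minlength=F)
        bad = (E_j <= 0) & ~zero
        if bad.any():
            fid = index.facility_ids[np.flatnonzero(bad)[0]]
            raise TableError(
                f"facility {fid!r} has events but zero expected count "
                "(no at-risk overlap with event days)"
            )
        C = E_j.sum() / O_total
        history.append(C)
        new = alpha.copy()
        new[~zero] = np.log(C * O_j[~zero] / E_j[~zero])
        delta = np.max(np.abs(new[~zero] - alpha[~zero])) if (~zero).any() else 0.0
        alpha = new
        if delta <= tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"fixed_point_alpha did not converge in {max_iter} iterations",
            ConvergenceWarning,
        )

    shr = np.zeros(F)
    shr[~zero] = O_j[~zero] / E_j[~zero]
    return FacilityEffects(
        facility_ids=index.facility_ids,
        alpha=alpha,
        observed=O_j.copy(),
        expected=E_j,
        shr=shr,
        zero_event=zero,
        scaling_history=np.asarray(history),
        n_iter=n_iter,
        converged=converged,
    )


def fit_model(
    table: EventHistoryTable | RiskIndex,
    beta_init: np.ndarray | None = None,
    beta_tol: float = 1e-8,
    beta_max_iter: int = 50,
    alpha_tol: float = 1e-6,
    alpha_max_iter: int = 2000,
) -> FittedModel:
    """Full two-part fit: stratified beta, then constrained facility effects.

    beta is estimated once, before the alpha loop, and is not re-estimated
    inside the fixed-point iteration.
    """
    index = table if isinstance(table, RiskIndex) else build_risk_index(table)
    cov = fit_beta(index, init=beta_init, tol=beta_tol, max_iter=beta_max_iter)
    fac = fixed_point_alpha(index, cov.beta, tol=alpha_tol, max_iter=alpha_max_iter)
    baseline = nelson_aalen_baseline(index, cov.beta, fac.alpha)
    E_j, E_ij, _, O_ij = expected_events(index, baseline, cov.beta)
    # refresh expected counts at the final baseline (C has converged to 1)
    fac.expected = E_j
    fac.shr = np.where(fac.zero_event, 0.0, np.divide(
        fac.observed, E_j, out=np.zeros_like(E_j), where=E_j > 0))
    return FittedModel(
        index=index,
        covariate_effects=cov,
        baseline=baseline,
        facility_effects=fac,
        subject_observed=O_ij,
        subject_expected=E_ij,
        settings={
            "beta_tol": beta_tol,
            "beta_max_iter": beta_max_iter,
            "alpha_tol": alpha_tol,
            "alpha_max_iter": alpha_max_iter,
        },
    )
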