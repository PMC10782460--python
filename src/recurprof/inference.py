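"""Naive and robust (sandwich) variance estimation and Wald intervals.

The information-based ("naive") covariance of beta-hat assumes a complete
intensity model; under the marginal rate model, within-subject dependence
of recurrent events makes it anti-conservative, and the sandwich estimator

    V = I(beta)^{-1} [ sum_i U_i U_i' ] I(beta)^{-1}

with per-subject score contributions U_i is the robust alternative.  For
the facility effects, the naive standard error of alpha_j is 1/sqrt(O_j)
(its information equals the observed count), and the robust version is the
facility-level sandwich V_j built from per-subject observed and expected
counts.  Variability of beta-hat and of the baseline is ignored in the
alpha standard errors: with many facilities both are estimated from the
whole population and their noise is negligible next to a single facility's.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from . import _kernels
from .estimation import CovariateEffects, FittedModel
from .events import RiskIndex


@dataclass
class VarianceReport:
    """Covariances and standard errors for one fitted model."""

    beta_naive_cov: np.ndarray
    beta_sandwich_cov: np.ndarray
    alpha_naive_se: np.ndarray      # 1/sqrt(O_j); NaN where O_j = 0
    alpha_sandwich_se: np.ndarray   # sqrt(V_j);   NaN where O_j = 0
    alpha_se_undefined: np.ndarray  # bool mask (zero-event facilities)
    ci_level: float = 0.95

    @property
    def beta_naive_se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.beta_naive_cov))

    @property
    def beta_sandwich_se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.beta_sandwich_cov))


def subject_scores(index: RiskIndex, fit: CovariateEffects) -> np.ndarray:
    """Per-subject contributions U_i to the stratified score at beta-hat.

    U_i = sum_m {Z_i(t_m) - Zbar_j(t_m)} {dN_i(t_m) - dN_j(t_m) w_i(t_m)/S0_j(t_m)}
    over the days the subject is at risk, with j the subject's facility.
    """
    beta = fit.beta
    p = index.n_covariates
    F, M = index.n_facilities, index.n_days
    stats = _kernels.stratum_statistics(index, beta, need_information=False)

    # per-facility day series dN_j/S0_j and dN_j Zbar_j/S0_j, prefix-summed
    a0 = np.zeros((F, M))
    a1 = np.zeros((F, M, p))
    r = index.pair_dN / stats.pair_S0
    a0[index.pair_fac, index.pair_m] = r
    a1[index.pair_fac, index.pair_m] = r[:, None] * stats.pair_Zbar
    c0 = np.concatenate([np.zeros((F, 1)), np.cumsum(a0, axis=1)], axis=1)
    c1 = np.concatenate([np.zeros((F, 1, p)), np.cumsum(a1, axis=1)], axis=1)

    w = np.exp(_kernels.linear_predictor(index, beta))
    fac = index.row_facility
    s0 = c0[fac, index.row_hi] - c0[fac, index.row_lo]
    s1 = c1[fac, index.row_hi] - c1[fac, index.row_lo]
    row_term = -w[:, None] * (index.Z * s0[:, None] - s1)

    U = np.zeros((index.n_subjects, p))
    np.add.at(U, index.row_subject, row_term)
    ev_term = index.Z[index.event_row] - stats.pair_Zbar[index.event_pair]
    np.add.at(U, index.row_subject[index.event_row], ev_term)
    return U


def sandwich_beta(index: RiskIndex, fit: CovariateEffects) -> np.ndarray:
    """Robust covariance I^{-1} (sum_i U_i U_i') I^{-1} of beta-hat."""
    U = subject_scores(index, fit)
    try:
        Iinv = np.linalg.inv(fit.information)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError("singular information matrix") from None
    meat = U.T @ U
    return Iinv @ meat @ Iinv


def alpha_ses(
    O_ij: np.ndarray,
    E_ij: np.ndarray,
    subject_facility: np.ndarray,
    O_j: np.ndarray,
    E_j: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Naive and sandwich standard errors of the facility effects.

    naive_j = 1/sqrt(O_j);  sandwich_j = sqrt(V_j) with
    V_j = sum_{i in j} (O_ij - E_ij O_j/E_j)^2 / O_j^2.
    Both are NaN for zero-event facilities (the effect is a sentinel there).
    """
    O_j = np.asarray(O_j, dtype=np.float64)
    zero = O_j == 0
    with np.errstate(divide="ignore"):
        naive = np.where(zero, np.nan, 1.0 / np.sqrt(np.where(zero, 1.0, O_j)))
    ratio = np.divide(O_j, E_j, out=np.zeros_like(O_j), where=E_j > 0)
    resid = O_ij - E_ij * ratio[subject_facility]
    V = np.bincount(subject_facility, weights=resid**2, minlength=len(O_j))
    V = np.divide(V, O_j**2, out=np.full_like(V, np.nan), where=~zero)
    return naive, np.sqrt(V)


def wald_ci(
    estimate: float | np.ndarray, se: float | np.ndarray, level: float = 0.95
) -> tuple[np.ndarray, np.ndarray]:
    """estimate +/- z_{(1+level)/2} * se; se = 0 gives a degenerate interval."""
    if not 0.0 < level < 1.0:
        raise ValueError("confidence level must be in (0, 1)")
    se = np.asarray(se, dtype=np.float64)
    if np.any(se < 0):
        raise ValueError("standard errors must be non-negative")
    z = sps.norm.ppf(0.5 * (1.0 + level))
    estimate = np.asarray(estimate, dtype=np.float64)
    return estimate - z * se, estimate + z * se


def alpha_difference_se(
    se: np.ndarray, j: int, ref: int = 0, combine: bool = True
) -> float:
    """Standard error for the re-referenced effect alpha_j - alpha_ref.

    With ``combine`` (default) the two facilities are treated as
    independent, se = sqrt(se_j^2 + se_ref^2); otherwise the reference is
    treated as fixed and se_j alone is returned.
    """
    if combine:
        return float(np.sqrt(se[j] ** 2 + se[ref] ** 2))
    return float(se[j])


def variance_report(fitted: FittedModel, ci_level: float = 0.95) -> VarianceReport:
    """Assemble all naive and robust variances for a fitted model."""
    if not 0.0 < ci_level < 1.0:
        raise ValueError("confidence level must be in (0, 1)")
    fit = fitted.covariate_effects
    naive_cov = np.linalg.inv(fit.information)
    robust_cov = sandwich_beta(fitted.index, fit)
    naive_a, robust_a = alpha_ses(
        fitted.subject_observed,
        fitted.subject_expected,
        fitted.index.subject_facility,
        fitted.facility_effects.observed,
        fitted.facility_effects.expected,
    )
    return VarianceReport(
        beta_naive_cov=naive_cov,
        beta_sandwich_cov=robust_cov,
        alpha_naive_se=naive_a,
        alpha_sandwich_se=robust_a,
        alpha_se_undefined=fitted.facility_effects.zero_event.copy(),
        ci_level=ci_level,
    )
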