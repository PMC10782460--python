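"""Indirect and direct standardisation of facility event counts.

Indirect standardisation compares a facility's observed events O_j with the
expected count E_j its own patients would have under the national norm:
SHR_j = O_j/E_j.  Direct standardisation applies the facility's rate to the
whole population: SHR*_j = E(j)*/sum_k O_k, with E(j)* the population
expected count if everyone were treated at facility j.  Under the fitting
constraint sum(O) = sum(E) the two coincide facility by facility, so the
reported ratios carry both interpretations; this module computes both sides
independently and reports the (numerical) gap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels
from .estimation import BaselineRate, FittedModel
from .events import RiskIndex


@dataclass
class StandardisedMeasures:
    """Per-facility indirect and direct standardised ratios."""

    facility_ids: np.ndarray
    shr_indirect: np.ndarray            # O_j / E_j
    shr_direct: np.ndarray              # E(j)* / sum_k O_k
    whole_population_expected: np.ndarray  # E(j)*
    zero_event: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "facility_id": self.facility_ids,
                "shr_indirect": self.shr_indirect,
                "shr_direct": self.shr_direct,
                "whole_population_expected": self.whole_population_expected,
                "equivalence_gap": self.shr_indirect - self.shr_direct,
                "zero_event": self.zero_event,
            }
        )


def direct_expected(
    index: RiskIndex, baseline: BaselineRate, beta: np.ndarray, alpha_j: float
) -> float:
    """E(j)*: expected events in the whole population at facility j's rate,
    sum_i sum_m Y_i(t_m) dmu0(t_m) exp{Z_i(t_m)' beta + alpha_j}."""
    w = np.exp(_kernels.linear_predictor(index, np.asarray(beta, dtype=np.float64)))
    total = float(w @ _kernels.range_sums(index, baseline.increments))
    return float(np.exp(alpha_j)) * total


def standardise(fitted: FittedModel) -> StandardisedMeasures:
    """Both standardised measures for every facility of a converged fit.

    Zero-event facilities report an indirect SHR of 0 and are flagged; their
    direct measure uses the sentinel effect and is essentially 0 as well.
    """
    fac = fitted.facility_effects
    O_total = fac.observed.sum()
    estar = np.array(
        [
            direct_expected(fitted.index, fitted.baseline, fitted.covariate_effects.beta, a)
            for a in fac.alpha
        ]
    )
    return StandardisedMeasures(
        facility_ids=fac.facility_ids,
        shr_indirect=fac.shr.copy(),
        shr_direct=estar / O_total,
        whole_population_expected=estar,
        zero_event=fac.zero_event.copy(),
    )


def recentre_alpha(
    alpha: np.ndarray,
    method: str = "sum_oe",
    sizes: np.ndarray | None = None,
    zero_event: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Shift facility effects to an alternative reporting constraint.

    Estimation always uses the sum(O) = sum(E) constraint (the only one under
    which indirect and direct standardisation agree); this helper re-centres
    the *reported* effects only.  Returns ``(alpha - shift, shift)``; the
    baseline would be multiplied by exp(shift) to leave all rates and SHRs
    unchanged.

    Methods: ``"sum_oe"`` (no shift), ``"size_weighted"``
    (sum_j n_j alpha_j = 0), ``"median"`` (median alpha = 0).  Zero-event
    sentinel facilities are excluded from the shift computation.
    """
    alpha = np.asarray(alpha, dtype=np.float64)
    keep = np.ones(len(alpha), dtype=bool) if zero_event is None else ~zero_event
    if method == "sum_oe":
        shift = 0.0
    elif method == "size_weighted":
        if sizes is None:
            raise ValueError("size_weighted recentring needs facility sizes")
        sizes = np.asarray(sizes, dtype=np.float64)
        shift = float((sizes[keep] * alpha[keep]).sum() / sizes[keep].sum())
    elif method == "median":
        shift = float(np.median(alpha[keep]))
    else:
        raise ValueError(f"unknown recentring method {method!r}")
    out = alpha.copy()
    out[keep] = alpha[keep] - shift
    return out, shift
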