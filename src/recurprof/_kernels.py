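"""Shared prefix-sum kernels over the risk-set index.

Every stratum statistic S_j^(r)(t_m) = sum over at-risk intervals in
facility j of w * Z^{(x)r} is a sum of interval contributions over a
contiguous range of event-day slots.  Instead of rebuilding risk sets per
day, each interval deposits +c at its first active slot and -c one past its
last active slot (a sparse scatter built once), and a cumulative sum along
the day axis yields S at every (facility, day) cell.  Facilities are
processed in chunks to bound the dense (chunk, M+1, width) workspace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .events import RiskIndex

_CHUNK_CELL_CAP = 16_000_000  # floats in one (chunk, M+1, width) workspace


def _facility_chunks(index: RiskIndex, width: int):
    """Cached list of (fac_lo, fac_hi, scatter_csr, row_selector)."""
    M1 = index.n_days + 1
    chunk_f = max(1, int(_CHUNK_CELL_CAP // (M1 * max(width, 1))))
    key = ("chunks", chunk_f)
    if key in index._cache:
        return index._cache[key]
    chunks = []
    F = index.n_facilities
    order = np.argsort(index.row_facility, kind="stable")
    fac_sorted = index.row_facility[order]
    for lo in range(0, F, chunk_f):
        hi = min(lo + chunk_f, F)
        a, b = np.searchsorted(fac_sorted, [lo, hi])
        rows = order[a:b]
        nfac = hi - lo
        local = (index.row_facility[rows] - lo) * M1
        cols = np.arange(len(rows))
        mat = sparse.coo_matrix(
            (
                np.concatenate([np.ones(len(rows)), -np.ones(len(rows))]),
                (
                    np.concatenate([local + index.row_lo[rows], local + index.row_hi[rows]]),
                    np.concatenate([cols, cols]),
                ),
            ),
            shape=(nfac * M1, len(rows)),
        ).tocsr()
        chunks.append((lo, hi, mat, rows))
    index._cache[key] = chunks
    return chunks


def _features(index: RiskIndex, order: int) -> np.ndarray:
    """Per-interval feature rows [1, Z, vec(Z Z^T)] up to the given order."""
    key = ("features", order)
    if key in index._cache:
        return index._cache[key]
    p = index.n_covariates
    R = len(index.row_lo)
    parts = [np.ones((R, 1))]
    if order >= 1:
        parts.append(index.Z)
    if order >= 2:
        parts.append(np.einsum("ra,rb->rab", index.Z, index.Z).reshape(R, p * p))
    feat = np.concatenate(parts, axis=1)
    index._cache[key] = feat
    return feat


@dataclass
class StratumStatistics:
    """Stratified Breslow statistics at a fixed coefficient vector."""

    beta: np.ndarray
    score: np.ndarray            # U(beta), (p,)
    information: np.ndarray | None  # I(beta), (p, p)
    log_partial_likelihood: float
    pair_S0: np.ndarray          # S^(0)_j(t_m) at each event pair
    pair_Zbar: np.ndarray        # Zbar_j(t_m) at each event pair


def linear_predictor(index: RiskIndex, beta: np.ndarray) -> np.ndarray:
    eta = index.Z @ beta if index.n_covariates else np.zeros(len(index.row_lo))
    return np.clip(eta, -500.0, 500.0)


def stratum_statistics(
    index: RiskIndex, beta: np.ndarray, need_information: bool = True
) -> StratumStatistics:
    """Score, observed information and log partial likelihood of the
    facility-stratified Breslow model, plus S0/Zbar at every event pair."""
    beta = np.asarray(beta, dtype=np.float64)
    if not np.all(np.isfinite(beta)):
        raise ValueError("beta contains non-finite entries")
    p = index.n_covariates
    M1 = index.n_days + 1
    w = np.exp(linear_predictor(index, beta))
    order = 2 if need_information else 1
    feat = _features(index, order)
    width = feat.shape[1]

    U = index.pair_Zsum.sum(axis=0)  # sum of event-day covariates
    info = np.zeros((p, p)) if need_information else None
    ll = float((index.Z[index.event_row] @ beta).sum()) if p else 0.0
    P = len(index.pair_fac)
    pair_S0 = np.empty(P)
    pair_Zbar = np.empty((P, p))

    for lo, hi, mat, rows in _facility_chunks(index, width):
        sel = (index.pair_fac >= lo) & (index.pair_fac < hi)
        if not sel.any():
            continue
        C = feat[rows] * w[rows, None]
        S = (mat @ C).reshape(hi - lo, M1, width)
        np.cumsum(S, axis=1, out=S)
        Sp = S[index.pair_fac[sel] - lo, index.pair_m[sel]]
        S0 = Sp[:, 0]
        Zbar = Sp[:, 1 : 1 + p] / S0[:, None]
        dn = index.pair_dN[sel]
        pair_S0[sel] = S0
        pair_Zbar[sel] = Zbar
        U = U - dn @ Zbar
        ll -= float(dn @ np.log(S0))
        if need_information:
            S2 = Sp[:, 1 + p :].reshape(-1, p, p)
            info += np.einsum("k,kab->ab", dn / S0, S2)
            info -= np.einsum("k,ka,kb->ab", dn, Zbar, Zbar)

    return StratumStatistics(
        beta=beta,
        score=U,
        information=info,
        log_partial_likelihood=ll,
        pair_S0=pair_S0,
        pair_Zbar=pair_Zbar,
    )


def stratum_s0_grid(index: RiskIndex, beta: np.ndarray) -> np.ndarray:
    """S^(0)_j(t_m) without facility effects, as a dense (F, M) grid."""
    M1 = index.n_days + 1
    w = np.exp(linear_predictor(index, np.asarray(beta, dtype=np.float64)))
    out = np.empty((index.n_facilities, index.n_days))
    for lo, hi, mat, rows in _facility_chunks(index, 1):
        S = (mat @ w[rows, None]).reshape(hi - lo, M1)
        np.cumsum(S, axis=1, out=S)
        out[lo:hi] = S[:, : index.n_days]
    return out


def range_sums(index: RiskIndex, values_by_day: np.ndarray) -> np.ndarray:
    """Per-interval sum of a day-indexed series over the active slot range."""
    prefix = np.concatenate([[0.0], np.cumsum(values_by_day)])
    return prefix[index.row_hi] - prefix[index.row_lo]


def pooled_moments(
    index: RiskIndex, weights: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Unstratified S^(0)(t_m) and S^(1)(t_m) for given interval weights."""
    M1 = index.n_days + 1
    p = index.n_covariates
    diff = np.zeros((M1, 1 + p))
    C = np.concatenate([weights[:, None], index.Z * weights[:, None]], axis=1)
    np.add.at(diff, index.row_lo, C)
    np.add.at(diff, index.row_hi, -C)
    S = np.cumsum(diff[: index.n_days], axis=0)
    return S[:, 0], S[:, 1:]
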