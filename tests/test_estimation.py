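"""Estimator correctness against independent oracles and exact identities."""

import subprocess
import sys
import warnings

import numpy as np
import pandas as pd
import pytest

import recurprof as rp
from recurprof import _kernels
from recurprof.estimation import ConvergenceWarning

from conftest import make_table, random_table


def symmetric_stratum():
    # two subjects (Z = 1, Z = 0) both at risk days 1-2; events on day 1
    # (Z = 0) and day 2 (Z = 1): perfectly balanced, so beta-hat = 0
    return make_table(
        [
            (1, "a", 0, 1, 1, 0.0),
            (1, "a", 1, 2, 0, 0.0),
            (2, "a", 0, 2, 1, 1.0),
        ]
    )


def breslow_loglik_bruteforce(table, beta):
    """Stratified Breslow log partial likelihood by explicit summation."""
    df = table.data
    znames = list(table.covariates)
    ll = 0.0
    for fac, sub in df.groupby("facility_id"):
        ev = sub[sub["event"] == 1]
        for day in np.sort(ev["stop"].unique()):
            events = ev[ev["stop"] == day]
            at_risk = sub[(sub["start"] < day) & (day <= sub["stop"])]
            s0 = np.exp(at_risk[znames].to_numpy() @ beta).sum()
            ll += float((events[znames].to_numpy() @ beta).sum())
            ll -= len(events) * np.log(s0)
    return ll


class TestScore:
    def test_balanced_stratum_scores_zero(self):
        idx = rp.build_risk_index(symmetric_stratum())
        U, info = rp.stratified_score(idx, np.zeros(1))
        assert U == pytest.approx([0.0], abs=1e-12)
        assert info[0, 0] == pytest.approx(0.5)

    def test_constant_covariate_stratum_contributes_nothing(self):
        # all subjects share Z, so Zbar = Z at every event day
        t = make_table(
            [(i, "a", 0, 10, 1, 0.7) for i in range(4)]
            + [(i, "b", 0, 10, 1, float(i)) for i in range(4, 8)]
        )
        idx = rp.build_risk_index(t)
        t_b = make_table([(i, "b", 0, 10, 1, float(i)) for i in range(4, 8)])
        idx_b = rp.build_risk_index(t_b)
        for beta in ([0.0], [0.3], [-1.1]):
            U_all, _ = rp.stratified_score(idx, np.array(beta))
            U_b, _ = rp.stratified_score(idx_b, np.array(beta))
            assert U_all == pytest.approx(U_b, abs=1e-10)

    @pytest.mark.parametrize("seed", range(3))
    def test_score_matches_finite_difference_of_loglik(self, seed):
        """U(beta) equals centred finite differences of the explicitly
        summed Breslow log partial likelihood, at random beta points."""
        t = random_table(seed, n_fac=2, n_subj=20, p=2)
        idx = rp.build_risk_index(t)
        rng = np.random.default_rng(seed + 100)
        h = 1e-5
        for _ in range(5):
            beta = rng.normal(0, 0.5, 2)
            U, _ = rp.stratified_score(idx, beta)
            for k in range(2):
                e = np.zeros(2)
                e[k] = h
                fd = (
                    breslow_loglik_bruteforce(t, beta + e)
                    - breslow_loglik_bruteforce(t, beta - e)
                ) / (2 * h)
                assert U[k] == pytest.approx(fd, rel=1e-6, abs=1e-6)

    def test_nonfinite_beta_rejected(self):
        idx = rp.build_risk_index(symmetric_stratum())
        with pytest.raises(ValueError, match="non-finite"):
            rp.stratified_score(idx, np.array([np.nan]))


class TestFitBeta:
    def test_balanced_stratum_estimate_is_zero(self):
        fit = rp.fit_beta(rp.build_risk_index(symmetric_stratum()))
        assert fit.converged
        assert fit.beta == pytest.approx([0.0], abs=1e-12)

    def test_matches_grid_refinement_maximiser(self):
        """1-d problem: Newton solution agrees with nested grid search on
        the brute-force log partial likelihood to 1e-4."""
        t = random_table(9, n_fac=2, n_subj=25, p=1)
        idx = rp.build_risk_index(t)
        fit = rp.fit_beta(idx)
        lo, hi = -3.0, 3.0
        for _ in range(6):
            grid = np.linspace(lo, hi, 41)
            vals = [breslow_loglik_bruteforce(t, np.array([b])) for b in grid]
            k = int(np.argmax(vals))
            lo, hi = grid[max(k - 1, 0)], grid[min(k + 1, 40)]
        assert fit.beta[0] == pytest.approx((lo + hi) / 2, abs=1e-4)

    def test_collinear_columns_named(self):
        t = random_table(4, p=1)
        df = t.data.copy()
        df["z_dup"] = 2.0 * df["z1"]
        idx = rp.build_risk_index(rp.validate_table(df))
        with pytest.raises(np.linalg.LinAlgError, match="z"):
            rp.fit_beta(idx)

    def test_monotone_likelihood_flagged_not_silent(self):
        # the covariate perfectly orders events: partial likelihood is
        # maximised at beta -> infinity
        t = make_table(
            [
                (1, "a", 0, 1, 1, 1.0),
                (2, "a", 0, 2, 1, 0.0),
                (3, "a", 0, 3, 1, 0.0),
            ]
        )
        idx = rp.build_risk_index(t)
        with pytest.warns(ConvergenceWarning):
            fit = rp.fit_beta(idx, max_iter=10)
        assert not fit.converged

    def test_agrees_with_r_survival_coxph(self, tmp_path):
        """Independent oracle: R survival::coxph on the same start-stop
        data, Breslow ties, stratified by facility."""
        t = random_table(21, n_fac=3, n_subj=40, tau=80, p=2, rate=0.04)
        csv = tmp_path / "d.csv"
        t.write_csv(csv)
        script = f"""
        d <- read.csv("{csv}")
        suppressMessages(library(survival))
        f <- coxph(Surv(start, stop, event) ~ z1 + z2 + strata(facility_id),
                   data = d, ties = "breslow", control = coxph.control(eps = 1e-12))
        cat(sprintf("%.10f %.10f", coef(f)[1], coef(f)[2]))
        """
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        r_beta = np.array([float(x) for x in out.stdout.split()])
        fit = rp.fit_beta(rp.build_risk_index(t))
        assert fit.beta == pytest.approx(r_beta, abs=1e-5)


class TestBaseline:
    def test_occurrence_over_exposure(self):
        # 10 subjects at risk on day 4, one event, no covariates / effects
        rows = [(i, "a", 0, 10, 0) for i in range(9)] + [(9, "a", 0, 4, 1), (9, "a", 4, 10, 0)]
        t = rp.validate_table(
            pd.DataFrame(rows, columns=["subject_id", "facility_id", "start", "stop", "event"])
        )
        idx = rp.build_risk_index(t)
        base = rp.nelson_aalen_baseline(idx, np.zeros(0), np.zeros(1))
        assert base.increments == pytest.approx([0.1])

    def test_alpha_shift_rescales_increments(self, small_sim):
        """Adding log 2 to every facility effect halves every increment
        (the identifiability non-uniqueness)."""
        _, _, fitted = small_sim
        idx = fitted.index
        beta = fitted.covariate_effects.beta
        alpha = fitted.facility_effects.alpha
        b1 = rp.nelson_aalen_baseline(idx, beta, alpha)
        b2 = rp.nelson_aalen_baseline(idx, beta, alpha + np.log(2.0))
        assert b2.increments == pytest.approx(b1.increments / 2.0, rel=1e-12)

    @pytest.mark.parametrize("seed", [2, 8])
    def test_increments_match_naive_scan(self, seed):
        t = random_table(seed, p=1)
        idx = rp.build_risk_index(t)
        rng = np.random.default_rng(seed)
        beta = rng.normal(0, 0.3, 1)
        alpha = rng.normal(0, 0.3, idx.n_facilities)
        base = rp.nelson_aalen_baseline(idx, beta, alpha)
        df = t.data
        fcode = pd.factorize(df["facility_id"], sort=True)[0]
        for m, day in enumerate(idx.event_times):
            at = (df["start"].to_numpy() < day) & (day <= df["stop"].to_numpy())
            s0 = np.sum(np.exp(df["z1"].to_numpy()[at] * beta[0] + alpha[fcode[at]]))
            dn = ((df["stop"].to_numpy() == day) & (df["event"].to_numpy() == 1)).sum()
            assert base.increments[m] == pytest.approx(dn / s0, rel=1e-10)


class TestExpectedEvents:
    def test_sum_order_independence(self, small_sim):
        """Facility-major totals equal an independent subject-major loop."""
        _, _, fitted = small_sim
        idx = fitted.index
        beta = fitted.covariate_effects.beta
        E_j, E_ij, O_j, O_ij = rp.expected_events(idx, fitted.baseline, beta)
        # subject-major re-summation from raw interval ranges
        expect = np.zeros(idx.n_subjects)
        for r in range(len(idx.row_lo)):
            inc = fitted.baseline.increments[idx.row_lo[r] : idx.row_hi[r]].sum()
            expect[idx.row_subject[r]] += inc * np.exp(idx.Z[r] @ beta)
        assert E_ij == pytest.approx(expect, rel=1e-10)
        assert E_j.sum() == pytest.approx(expect.sum(), rel=1e-12)
        assert O_j.sum() == O_ij.sum()

    def test_never_at_risk_facility_has_zero_expected(self):
        t = make_table(
            [
                (1, "a", 0, 5, 1, 0.0),
                (1, "a", 5, 9, 0, 0.0),
                (2, "b", 20, 30, 0, 1.0),  # facility b: at risk after all events
            ]
        )
        idx = rp.build_risk_index(t)
        base = rp.nelson_aalen_baseline(idx, np.zeros(1), np.zeros(2))
        E_j, *_ = rp.expected_events(idx, base, np.zeros(1))
        assert E_j[1] == 0.0


class TestFixedPointAlpha:
    def test_single_facility_converges_immediately(self):
        t = random_table(12, n_fac=1, n_subj=15)
        idx = rp.build_risk_index(t)
        fit = rp.fit_beta(idx)
        fac = rp.fixed_point_alpha(idx, fit.beta)
        assert fac.converged
        assert fac.alpha == pytest.approx([0.0], abs=1e-12)
        assert fac.shr == pytest.approx([1.0], rel=1e-10)
        assert fac.scaling_history[0] == pytest.approx(1.0)

    def test_identical_facilities_all_neutral(self):
        # same patients replicated across 4 facilities: symmetry forces
        # alpha = 0 and SHR = 1 everywhere
        rows = []
        for j in range(4):
            for i in range(6):
                sid = j * 10 + i
                rows.append((sid, j, 0, 5 + i, 1, 0.1 * i))
                rows.append((sid, j, 5 + i, 20, 0, 0.1 * i))
        t = make_table(rows)
        idx = rp.build_risk_index(t)
        fit = rp.fit_beta(idx)
        fac = rp.fixed_point_alpha(idx, fit.beta)
        assert fac.alpha == pytest.approx(np.zeros(4), abs=1e-7)
        assert fac.shr == pytest.approx(np.ones(4), abs=1e-7)

    def test_matches_joint_indicator_partial_likelihood(self):
        """Oracle: appending facility indicators to the covariates and
        maximising one unstratified partial likelihood by direct Newton
        gives the same facility contrasts (to 2e-3) as the fixed-point
        algorithm run at the same covariate coefficients."""
        t = random_table(33, n_fac=5, n_subj=120, tau=90, p=2, rate=0.03)
        idx = rp.build_risk_index(t)

        df = t.data.copy()
        fcode = pd.factorize(df["facility_id"], sort=True)[0]
        F = fcode.max() + 1
        for j in range(1, F):
            df[f"fac{j}"] = (fcode == j).astype(float)
        df["facility_id"] = 0  # single stratum: baseline absorbs dmu0
        joint = rp.fit_beta(rp.build_risk_index(rp.validate_table(df)), max_iter=80)
        assert joint.converged
        # both routes optimise the same profile likelihood in the facility
        # contrasts once they share beta
        fac = rp.fixed_point_alpha(idx, joint.beta[:2])
        ref = fac.alpha - fac.alpha[0]
        assert ref[1:] == pytest.approx(joint.beta[2:], abs=2e-3)
        assert ref[1:] == pytest.approx(joint.beta[2:], abs=1e-6)

    def test_zero_event_facility_gets_sentinel(self):
        t = make_table(
            [
                (1, "a", 0, 5, 1, 0.0),
                (1, "a", 5, 9, 0, 0.0),
                (2, "b", 0, 9, 0, 1.0),
            ]
        )
        idx = rp.build_risk_index(t)
        fac = rp.fixed_point_alpha(idx, np.zeros(1))
        assert fac.converged
        assert fac.zero_event[1]
        assert fac.alpha[1] == -10.0
        assert fac.shr[1] == 0.0


class TestFitModel:
    def test_constraint_and_shr_identity(self, small_sim):
        _, _, fitted = small_sim
        fac = fitted.facility_effects
        assert fac.converged
        assert fac.expected.sum() == pytest.approx(fac.observed.sum(), rel=1e-6)
        assert fac.scaling_history[-1] == pytest.approx(1.0, abs=1e-6)
        live = ~fac.zero_event
        assert np.exp(fac.alpha[live]) == pytest.approx(fac.shr[live], rel=1e-5)

    def test_profile_loglik_nondecreasing_over_iterations(self):
        """The alpha log likelihood (fixed beta, recentred baseline) never
        decreases across fixed-point sweeps."""
        t = random_table(17, n_fac=4, n_subj=60, rate=0.08)
        idx = rp.build_risk_index(t)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            fit = rp.fit_beta(idx)
        s0_grid = _kernels.stratum_s0_grid(idx, fit.beta)
        w = np.exp(_kernels.linear_predictor(idx, fit.beta))
        O_j = idx.fac_observed
        alpha = np.zeros(idx.n_facilities)
        alpha[O_j == 0] = -10.0

        def loglik(alpha):
            # Poisson-form log likelihood in alpha with the baseline
            # profiled at the current alpha
            S0 = np.exp(alpha) @ s0_grid
            dmu = idx.dN_total / S0
            row_E = w * _kernels.range_sums(idx, dmu)
            E_j = np.bincount(idx.row_facility, weights=row_E, minlength=len(O_j))
            ll = float((O_j * alpha).sum() - (np.exp(alpha) * E_j).sum())
            ll += float(idx.dN_total @ np.log(dmu))
            return ll

        lls = [loglik(alpha)]
        live = O_j > 0
        for _ in range(8):
            S0 = np.exp(alpha) @ s0_grid
            dmu = idx.dN_total / S0
            row_E = w * _kernels.range_sums(idx, dmu)
            E_j = np.bincount(idx.row_facility, weights=row_E, minlength=len(O_j))
            C = E_j.sum() / O_j.sum()
            alpha = np.where(live, np.log(C * np.maximum(O_j, 1) / E_j), alpha)
            lls.append(loglik(alpha))
        assert np.all(np.diff(lls) >= -1e-9)

    def test_rescaling_invariance_of_shr(self, small_sim):
        """Shifting alpha by c and scaling the baseline by e^c leaves every
        E_j (hence every SHR) unchanged."""
        _, _, fitted = small_sim
        idx = fitted.index
        beta = fitted.covariate_effects.beta
        alpha = fitted.facility_effects.alpha
        c = 0.37
        b1 = rp.nelson_aalen_baseline(idx, beta, alpha)
        b2 = rp.nelson_aalen_baseline(idx, beta, alpha + c)
        E1, *_ = rp.expected_events(idx, b1, beta)
        b2_scaled = rp.BaselineRate(b2.event_times, b2.increments * np.exp(c))
        E2, *_ = rp.expected_events(idx, b2_scaled, beta)
        assert E2 == pytest.approx(E1, rel=1e-12)
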