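"""Univariable MR estimators: closed-form oracles, invariances, calibration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from micromr.gwas_io import harmonize, select_instruments
from micromr.simulate import UnivariableSimSpec, simulate_univariable
from micromr.univariable import (
    InsufficientInstrumentsError,
    ScreenConfig,
    bh_fdr,
    cochran_q,
    ivw,
    leave_one_out,
    mr_egger,
    run_univariable_screen,
    steiger_test,
    wald_ratio,
)

from conftest import make_instruments


class TestWaldRatio:
    def test_arithmetic(self):
        est = wald_ratio(0.5, 0.02, 0.1, 0.05)
        assert est.theta_hat == pytest.approx(0.2)
        assert est.se == pytest.approx(0.1)
        assert est.or_point == pytest.approx(np.exp(0.2))

    def test_zero_outcome_effect(self):
        assert wald_ratio(0.5, 0.02, 0.0, 0.05).theta_hat == 0.0

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(0.0, 0.02, 0.1, 0.05)

    def test_delta_se_matches_monte_carlo(self, rng):
        # strong instrument: first-order delta SE ~ SD of the simulated ratio
        bx, sx, by, sy = 0.5, 0.01, 0.1, 0.05
        draws = rng.normal(by, sy, 100_000) / rng.normal(bx, sx, 100_000)
        assert wald_ratio(bx, sx, by, sy).se == pytest.approx(draws.std(), rel=0.05)


class TestIVW:
    def test_single_instrument_equals_wald(self):
        hs = make_instruments([0.4], 0.02, [0.12], 0.05)
        est = ivw(hs)
        ref = wald_ratio(0.4, 0.02, 0.12, 0.05)
        assert est.theta_hat == ref.theta_hat
        assert est.se == ref.se

    def test_two_instruments_precision_weighted_mean(self):
        # fixed effects IVW == precision-weighted mean of Wald ratios with
        # weights beta_x^2/se_y^2
        bx, by, sy = [0.4, 0.2], [0.08, 0.06], [0.05, 0.03]
        hs = make_instruments(bx, 0.02, by, sy)
        ratios = np.array(by) / np.array(bx)
        w = np.array(bx) ** 2 / np.array(sy) ** 2
        expected = float(np.sum(w * ratios) / np.sum(w))
        assert ivw(hs, "fixed").theta_hat == pytest.approx(expected)

    def test_mre_se_never_below_fe(self, rng):
        for _ in range(20):
            j = rng.integers(2, 30)
            hs = make_instruments(
                rng.normal(0.3, 0.1, j), 0.02, rng.normal(0.05, 0.05, j),
                rng.uniform(0.01, 0.1, j),
            )
            assert ivw(hs, "multiplicative_random").se >= ivw(hs, "fixed").se - 1e-15

    def test_allele_recode_invariance(self, rng):
        j = 10
        bx = rng.normal(0.3, 0.1, j)
        by = rng.normal(0.06, 0.02, j)
        hs1 = make_instruments(bx, 0.02, by, 0.05)
        signs = rng.choice([-1, 1], j)
        hs2 = make_instruments(bx * signs, 0.02, by * signs, 0.05)
        assert ivw(hs1).theta_hat == pytest.approx(ivw(hs2).theta_hat)
        assert ivw(hs1).se == pytest.approx(ivw(hs2).se)

    def test_empty_set_rejected(self):
        with pytest.raises(InsufficientInstrumentsError):
            ivw(make_instruments([], 0.02, [], 0.05))

    def test_parameter_recovery_and_coverage(self):
        # theta = 0.2, J = 50, no pleiotropy: near-unbiased with ~95% CI coverage
        hits, biases = 0, []
        n_seeds = 100
        for seed in range(n_seeds):
            exp, out, _, _ = simulate_univariable(UnivariableSimSpec(seed=seed))
            hs = harmonize(select_instruments(exp, 1e-5), out)
            est = ivw(hs)
            biases.append(est.theta_hat - 0.2)
            hits += est.ci_low <= 0.2 <= est.ci_high
        assert abs(np.mean(biases)) < 0.02
        assert 0.88 <= hits / n_seeds <= 0.99


class TestEgger:
    def test_collinear_design_rejected(self):
        hs = make_instruments([0.3, 0.3, 0.3], 0.02, [0.1, 0.2, 0.15], 0.05)
        with pytest.raises(np.linalg.LinAlgError):
            mr_egger(hs)

    def test_too_few_instruments_rejected(self):
        with pytest.raises(InsufficientInstrumentsError):
            mr_egger(make_instruments([0.3, 0.4], 0.02, [0.1, 0.1], 0.05))

    def test_allele_recode_invariance(self, rng):
        j = 12
        bx = rng.normal(0.3, 0.1, j)
        by = 0.2 * bx + rng.normal(0, 0.02, j)
        hs1 = make_instruments(bx, 0.02, by, 0.05)
        signs = rng.choice([-1, 1], j)
        hs2 = make_instruments(bx * signs, 0.02, by * signs, 0.05)
        e1, e2 = mr_egger(hs1), mr_egger(hs2)
        assert e1.theta_hat == pytest.approx(e2.theta_hat)
        assert e1.intercept == pytest.approx(e2.intercept)

    def test_directional_pleiotropy_detected(self):
        # one-signed direct effects with mean 0.05: intercept test has power
        hits = 0
        n_seeds = 60
        for seed in range(n_seeds):
            exp, out, _, _ = simulate_univariable(
                UnivariableSimSpec(pleiotropy_mode="directional", seed=seed)
            )
            hs = harmonize(select_instruments(exp, 1e-5), out)
            hits += mr_egger(hs).intercept_p < 0.05
        assert hits / n_seeds >= 0.8

    def test_balanced_pleiotropy_calibrated(self):
        hits = 0
        n_seeds = 150
        for seed in range(n_seeds):
            exp, out, _, _ = simulate_univariable(
                UnivariableSimSpec(pleiotropy_mode="balanced", seed=seed)
            )
            hs = harmonize(select_instruments(exp, 1e-5), out)
            hits += mr_egger(hs).intercept_p < 0.05
        assert 0.01 <= hits / n_seeds <= 0.10


class TestCochranQ:
    def test_identical_ratios_give_zero(self):
        bx = np.array([0.2, 0.4, 0.5])
        hs = make_instruments(bx, 0.02, 0.3 * bx, 0.05)
        res = cochran_q(hs, 0.3)
        assert res.q == pytest.approx(0.0, abs=1e-12)
        assert res.df == 2

    def test_null_distribution_matches_chi_square(self, rng):
        # with known theta and pure outcome noise, Q ~ chi2(J)
        j, n_rep = 10, 400
        qs = []
        for _ in range(n_rep):
            bx = rng.normal(0.3, 0.1, j)
            by = 0.2 * bx + rng.normal(0, 0.05, j)
            qs.append(cochran_q(make_instruments(bx, 0.001, by, 0.05), 0.2).q)
        assert stats.kstest(qs, stats.chi2(df=j).cdf).pvalue > 0.01

    def test_planted_outlier_detected(self):
        # one 5-sigma outlier among 20 instruments; condition on it surviving
        # the weak-instrument filter
        rej = tot = 0
        for seed in range(120):
            exp, out, _, truth = simulate_univariable(
                UnivariableSimSpec(
                    n_variants=20, outlier_fraction=1 / 20,
                    palindromic_fraction=0.0, seed=seed,
                )
            )
            hs = harmonize(exp, out)
            if not set(truth["outlier_ids"]) & set(hs.variant_ids):
                continue
            tot += 1
            rej += cochran_q(hs, ivw(hs).theta_hat).q_pvalue < 0.05
        assert rej / tot >= 0.85


class TestBHFDR:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_pvalue_unchanged(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(1e-8, 1.0), min_size=2, max_size=30))
    def test_monotone_and_dominating(self, pvals):
        adj = bh_fdr(pvals)
        assert np.all(adj >= np.asarray(pvals) - 1e-15)
        order = np.argsort(pvals)
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestSteiger:
    def test_symmetric_profiles_give_p_one(self):
        hs = make_instruments([0.3, 0.4], 0.02, [0.3, 0.4], 0.02)
        res = steiger_test(hs, 5000, 5000)
        assert res.pvalue == pytest.approx(1.0)
        assert not res.direction_forward

    def test_swap_flips_direction(self):
        hs = make_instruments([0.3, 0.4, 0.5], 0.02, [0.03, 0.04, 0.05], 0.02)
        fwd = steiger_test(hs, 5000, 5000)
        swapped = make_instruments([0.03, 0.04, 0.05], 0.02, [0.3, 0.4, 0.5], 0.02)
        rev = steiger_test(swapped, 5000, 5000)
        assert fwd.direction_forward and not rev.direction_forward

    def test_forward_direction_recovered_in_simulation(self):
        correct = 0
        n_seeds = 50
        for seed in range(n_seeds):
            exp, out, _, _ = simulate_univariable(UnivariableSimSpec(seed=seed))
            hs = harmonize(select_instruments(exp, 1e-5), out)
            res = steiger_test(hs, 7738, 220_000)
            correct += res.direction_forward and res.pvalue < 0.05
        assert correct / n_seeds >= 0.95


class TestScreen:
    def test_causal_exposure_reaches_fdr_tier(self):
        from micromr.simulate import MultivariableSimSpec, simulate_multivariable

        exposures, outcome, _ = simulate_multivariable(
            MultivariableSimSpec(n_exposures=8, causal_subset={2: 0.3}, seed=4)
        )
        rows = run_univariable_screen(exposures, outcome, ScreenConfig())
        by_id = {r.exposure_id: r for r in rows}
        assert by_id["exposure_2"].tier == "significant_fdr"

    def test_empty_panel(self):
        from micromr.simulate import UnivariableSimSpec, simulate_univariable

        _, outcome, _, _ = simulate_univariable(UnivariableSimSpec(seed=0))
        assert run_univariable_screen([], outcome) == []

    def test_single_instrument_uses_wald(self):
        exp, out, _, _ = simulate_univariable(UnivariableSimSpec(seed=2))
        # keep exactly one instrument above threshold
        strongest = exp.table.sort_values("pval").iloc[[0]]
        single = exp.with_table(strongest)
        rows = run_univariable_screen([single], out)
        assert rows[0].estimate.method == "wald_ratio"
        assert rows[0].estimate.n_snps == 1

    def test_failures_recorded_not_raised(self):
        exp, out, _, _ = simulate_univariable(UnivariableSimSpec(seed=2))
        weak = exp.with_table(exp.table.assign(beta=0.0001))
        rows = run_univariable_screen([weak], out)
        assert rows[0].estimate is None
        assert "InsufficientInstruments" in rows[0].error


def test_leave_one_out_rows_match_instrument_count():
    exp, out, _, _ = simulate_univariable(UnivariableSimSpec(seed=3))
    hs = harmonize(select_instruments(exp, 1e-5), out)
    loo = leave_one_out(hs)
    assert len(loo) == len(hs)
    assert loo["theta_hat"].std() < 0.05  # no single instrument dominates
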