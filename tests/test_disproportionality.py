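"""The four signal statistics, threshold logic, and published-row inversion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, special, stats

from faerspv import (ContingencyTable, MgpsPrior, SignalThresholds, bcpnn_ic,
                     ebgm, evaluate_signal, fit_mgps, invert_published_stats,
                     prr_chi2, ror)
from faerspv.disproportionality import (chi2_statistic, mgps_marginal_loglik,
                                        posterior_mixture)

Z = 1.959963984540054

cells = st.integers(min_value=0, max_value=2000)
tables = st.tuples(cells, cells, cells, cells).filter(
    lambda t: t[0] + t[1] > 0 and t[2] + t[3] > 0 and t[0] + t[2] > 0 and t[1] + t[3] > 0)


class TestRor:
    def test_balanced_table_is_null(self):
        r = ror(ContingencyTable(10, 10, 10, 10))
        assert r.point == pytest.approx(1.0)
        assert np.log(r.low) == pytest.approx(-np.log(r.high))

    def test_direct_formula_example(self):
        r = ror(ContingencyTable(5, 45, 95, 9855))
        assert r.point == pytest.approx(5 * 9855 / (45 * 95), abs=1e-10)
        assert r.point == pytest.approx(11.5263, abs=1e-4)
        se = np.sqrt(1 / 5 + 1 / 45 + 1 / 95 + 1 / 9855)
        assert r.low == pytest.approx(r.point * np.exp(-Z * se), rel=1e-12)
        assert r.high == pytest.approx(r.point * np.exp(Z * se), rel=1e-12)

    def test_zero_cell_correction(self):
        r = ror(ContingencyTable(3, 0, 50, 1000))
        assert r.corrected and np.isfinite(r.point) and r.low < r.point < r.high

    @given(tables)
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_transpose_invariance(self, t):
        a, b, c, d = (x + 1 for x in t)  # strictly positive cells
        assert ror(ContingencyTable(a, b, c, d)).point == pytest.approx(
            ror(ContingencyTable(a, c, b, d)).point, rel=1e-12)


class TestPrrChi2:
    def test_independence_table(self):
        # a/E = 1 exactly: [10, 90; 100, 900]
        p = prr_chi2(ContingencyTable(10, 90, 100, 900), yates=False)
        assert p.point == pytest.approx(1.0)
        assert p.chi2 == pytest.approx(0.0, abs=1e-12)

    def test_direct_formula_example(self):
        p = prr_chi2(ContingencyTable(5, 45, 95, 9855), yates=False)
        assert p.point == pytest.approx((5 / 50) / (95 / 9950), abs=1e-10)
        assert p.point == pytest.approx(10.4737, abs=1e-4)
        # textbook shortcut formula for the 2x2 chi-squared
        a, b, c, d = 5.0, 45.0, 95.0, 9855.0
        N = a + b + c + d
        shortcut = N * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert p.chi2 == pytest.approx(shortcut, rel=1e-12)

    def test_yates_shrinks_chi2(self):
        ct = ContingencyTable(5, 45, 95, 9855)
        assert prr_chi2(ct, yates=True).chi2 < prr_chi2(ct, yates=False).chi2

    def test_zero_c_corrected(self):
        p = prr_chi2(ContingencyTable(3, 40, 0, 1000))
        assert p.corrected and np.isfinite(p.point)

    @given(tables)
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_ci_brackets_point(self, t):
        a, b, c, d = (x + 1 for x in t)
        p = prr_chi2(ContingencyTable(a, b, c, d))
        r = ror(ContingencyTable(a, b, c, d))
        assert p.low <= p.point <= p.high
        assert r.low <= r.point <= r.high
        assert p.chi2 >= 0


class TestMonotonicity:
    def test_all_statistics_increase_with_a(self):
        """Moving a pair from (b, c) into a with margins n1, n2 fixed raises
        every disproportionality measure."""
        prior = MgpsPrior(Q=0.3, alpha1=0.5, beta1=0.3, alpha2=2.0, beta2=2.0)
        lo = ContingencyTable(10, 90, 190, 9710)
        hi = ContingencyTable(20, 80, 180, 9720)   # same n1=100, n2=200
        assert ror(hi).point > ror(lo).point
        assert prr_chi2(hi).point > prr_chi2(lo).point
        assert bcpnn_ic(hi).ic > bcpnn_ic(lo).ic
        assert ebgm(hi.a, hi.expected, prior=prior).ebgm > \
            ebgm(lo.a, lo.expected, prior=prior).ebgm


class TestBcpnn:
    def test_independence_limit(self):
        ic = bcpnn_ic(ContingencyTable(1000, 9000, 99000, 891000))
        assert abs(ic.ic) < 0.01
        assert ic.ic025 < ic.ic

    def test_asymptotic_log2_oe(self):
        # the IC shrinks log2(O/E) by about log2(E/(E+1)); with a large
        # expected count the two agree closely
        ct = ContingencyTable(415, 2585, 269_585, 7_830_000)
        assert ct.expected > 90
        expected = np.log2(ct.a / ct.expected)
        assert bcpnn_ic(ct).ic == pytest.approx(expected, abs=0.02)

    def test_noren_variant(self):
        ct = ContingencyTable(40, 60, 400, 99_500)
        ic = bcpnn_ic(ct, variant="noren")
        assert ic.ic == pytest.approx(np.log2((40 + 0.5) / (ct.expected + 0.5)))
        assert ic.ic025 == pytest.approx(ic.ic - 3.3 * 40.5 ** -0.5 - 2 * 40.5 ** -1.5)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            bcpnn_ic(ContingencyTable(1, 1, 1, 1), variant="mcmc")


class TestMgps:
    def test_null_data_prior_concentrates_near_one(self):
        rng = np.random.default_rng(12)
        E = rng.uniform(1, 30, 2000)
        a = rng.poisson(E)   # all true lambda = 1
        prior = fit_mgps(a, E)
        mean = prior.Q * prior.alpha1 / prior.beta1 \
            + (1 - prior.Q) * prior.alpha2 / prior.beta2
        assert 0.8 <= mean <= 1.25

    def test_optimum_beats_starting_point(self):
        rng = np.random.default_rng(3)
        E = rng.uniform(0.5, 20, 500)
        a = rng.poisson(1.5 * E)
        from faerspv.disproportionality import DUMOUCHEL_START
        prior = fit_mgps(a, E)
        assert prior.loglik >= mgps_marginal_loglik(a, E, DUMOUCHEL_START)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            fit_mgps(np.array([1.0, 2.0]), np.array([1.0, 0.0]))


class TestEbgm:
    prior = MgpsPrior(Q=0.3, alpha1=0.7, beta1=0.4, alpha2=3.0, beta2=2.5)

    def test_single_component_closed_form_vs_quadrature(self):
        # Q ~ 1: posterior is a single gamma; EBGM = exp(psi(a1+a) - ln(b1+E))
        prior = MgpsPrior(Q=1 - 1e-12, alpha1=2.0, beta1=1.5, alpha2=1.0, beta2=1.0)
        a, E = 7, 3.2
        r = ebgm(a, E, prior=prior)
        closed = np.exp(special.digamma(2.0 + a) - np.log(1.5 + E))
        assert r.ebgm == pytest.approx(closed, abs=1e-9)
        val, _ = integrate.quad(
            lambda lam: np.log(lam) * stats.gamma.pdf(lam, 2.0 + a, scale=1 / (1.5 + E)),
            0, np.inf)
        assert r.ebgm == pytest.approx(np.exp(val), abs=1e-6)

    def test_limiting_behaviour(self):
        diffuse = MgpsPrior(Q=0.5, alpha1=0.01, beta1=0.01, alpha2=0.02, beta2=0.02)
        r = ebgm(500, 10.0, prior=diffuse)
        assert r.ebgm == pytest.approx(50.0, rel=0.02)  # shrinkage vanishes
        null_centered = MgpsPrior(Q=0.5, alpha1=2.0, beta1=2.0, alpha2=5.0, beta2=5.0)
        assert ebgm(0, 5.0, prior=null_centered).ebgm < 1.0

    def test_eb05_below_ebgm(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a, E = int(rng.integers(0, 100)), float(rng.uniform(0.1, 50))
            r = ebgm(a, E, prior=self.prior)
            assert r.eb05 < r.ebgm

    def test_shrinkage_decreases_with_count(self):
        # along constant a/E = 3, |ln EBGM - ln(a/E)| shrinks as a grows
        gaps = [abs(np.log(ebgm(a, a / 3, prior=self.prior).ebgm) - np.log(3))
                for a in (3, 9, 30, 90, 300)]
        assert all(x > y for x, y in zip(gaps, gaps[1:]))


class TestSignalEvaluation:
    def test_null_table_unflagged(self):
        ct = ContingencyTable(10, 90, 100, 900)
        flags = evaluate_signal(ct.a, ror(ct), prr_chi2(ct), bcpnn_ic(ct),
                                ebgm(ct.a, ct.expected, prior=TestEbgm.prior))
        assert not any(flags.values())

    def test_min_n_edge(self):
        # overwhelming association but only 2 reports: ROR/PRR rules fail on n
        ct = ContingencyTable(2, 1, 1, 10_000)
        flags = evaluate_signal(ct.a, ror(ct), prr_chi2(ct), bcpnn_ic(ct),
                                ebgm(ct.a, ct.expected, prior=TestEbgm.prior))
        assert not flags["flag_ror"] and not flags["flag_prr"]

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            SignalThresholds(min_n=0)


class TestInversion:
    def test_roundtrip_recovery(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            a = int(rng.integers(3, 500))
            b = int(rng.integers(a, 5000))
            c = int(rng.integers(b + 1, 200_000))
            d = int(rng.integers(c * 10, 20_000_000))
            ct = ContingencyTable(a, b, c, d)
            r, p = ror(ct), prr_chi2(ct)
            inv = invert_published_stats(a, r.point, (r.low, r.high), p.chi2)
            for got, want in [(inv.b, b), (inv.c, c), (inv.d, d)]:
                assert abs(got - want) / want < 1e-3

    def test_degenerate_ci_rejected(self):
        with pytest.raises(ValueError):
            invert_published_stats(10, 2.0, (3.0, 2.5), 50.0)
        with pytest.raises(ValueError):
            invert_published_stats(10, 2.0, (1.9, 1.91), 50.0)  # CI too narrow

    def test_chi2_conventions_both_tried(self):
        ct = ContingencyTable(50, 2000, 90_000, 8_000_000)
        r = ror(ct)
        plain = prr_chi2(ct, yates=False).chi2
        inv = invert_published_stats(50, r.point, (r.low, r.high), plain)
        assert not inv.yates
        assert abs(inv.b - 2000) / 2000 < 1e-3
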