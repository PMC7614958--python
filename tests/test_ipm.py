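"""The owls integrated population model: rates, likelihoods, simulator, chain."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom, multinomial, poisson

from chainmeld.errors import ChainValidationError, LayoutError
from chainmeld.ipm import (
    CountData,
    CRData,
    FecundityData,
    IPMState,
    build_ipm_chain,
    count_loglik,
    cr_loglik,
    fecundity_loglik,
    link_rates,
    log_prior_initial_pop,
    log_prior_rho,
    log_priors,
    recapture_cell_probs,
    simulate_ipm,
    trunc_normal_logpdf,
)
from chainmeld.model_spec import validate_chain


def _state(T=5, **kw):
    defaults = dict(
        alpha0=0.0, alpha1=0.0, alpha2=0.0, alpha4=0.0, alpha6=0.0,
        alpha5=np.zeros(T - 1), rho=1.0,
    )
    defaults.update(kw)
    return IPMState(**defaults)


def expit(x):
    return 1.0 / (1.0 + np.exp(-x))


class TestLinkRates:
    def test_zero_coefficients_give_half_survival(self):
        delta, pi, eta = link_rates(_state())
        assert np.allclose(delta, 0.5)
        assert np.allclose(pi[:, 1:], 0.5)
        assert np.allclose(eta, 1.0)

    def test_indicator_structure(self):
        st_ = _state(alpha0=-1.0, alpha1=0.3, alpha2=1.2, alpha4=-0.5, alpha5=np.full(4, 0.7))
        delta, pi, eta = link_rates(st_)
        # ages: 0=J, 1=A; sexes: 0=M, 1=F
        assert delta[1, 1, 0] == pytest.approx(expit(-1.0 + 1.2))   # adult female
        assert delta[0, 0, 0] == pytest.approx(expit(-1.0 + 0.3))   # juvenile male
        assert delta[0, 1, 0] == pytest.approx(expit(-1.0))         # juvenile female
        assert pi[0, 1] == pytest.approx(expit(-0.5 + 0.7))         # male
        assert pi[1, 1] == pytest.approx(expit(0.7))                # female

    def test_immigration_rate_constant(self):
        _, _, eta = link_rates(_state(alpha6=-1.6))
        assert np.allclose(eta, np.exp(-1.6))


class TestRecaptureCellProbs:
    def test_half_rates_hand_product(self):
        """T = 3, delta = pi = 0.5: released year 1 gives 0.25 then 0.0625."""
        T = 3
        Q = recapture_cell_probs(np.full(T, 0.5), np.full(T, 0.5), T)
        assert Q[0, 1] == pytest.approx(0.25)
        assert Q[0, 2] == pytest.approx(0.0625)
        assert Q[0, 0] == 0.0

    @settings(max_examples=30, deadline=None)
    @given(
        d=st.floats(0.01, 0.99),
        p=st.floats(0.01, 0.99),
        T=st.integers(2, 12),
    )
    def test_rows_sum_to_one(self, d, p, T):
        Q = recapture_cell_probs(np.full(T, d), np.full(T, p), T)
        np.testing.assert_allclose(Q.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(Q >= 0)
        for t in range(T):
            assert np.all(Q[t, : t + 1] == 0.0)

    def test_vanishing_survival_sends_mass_to_never_column(self):
        T = 4
        Q = recapture_cell_probs(np.full(T, 1e-12), np.full(T, 0.5), T)
        np.testing.assert_allclose(Q[:, T], 1.0, atol=1e-11)


class TestCRLoglik:
    def _small(self):
        T = 3
        m = np.zeros((2, 2, T, T + 1), dtype=int)
        m[0, 0, 0] = [0, 3, 1, 6]
        m[1, 1, 1] = [0, 0, 4, 8]
        return CRData(m), T

    def test_matches_scipy_multinomial(self):
        data, T = self._small()
        st_ = _state(T=T, alpha0=0.2, alpha2=-0.4, alpha4=0.1, alpha5=np.full(T - 1, 0.5))
        delta, pi, _ = link_rates(st_)
        from chainmeld.ipm import _all_cell_probs

        Q = _all_cell_probs(delta, pi, T)
        expect = 0.0
        for ia in range(2):
            for isx in range(2):
                for t in range(T):
                    row = data.m[ia, isx, t]
                    if row.sum() > 0:
                        expect += multinomial.logpmf(row, row.sum(), Q[ia, isx, t])
        assert cr_loglik(data, Q) == pytest.approx(expect, abs=1e-12)

    def test_no_releases_gives_zero(self):
        T = 3
        data = CRData(np.zeros((2, 2, T, T + 1), dtype=int))
        Q = np.tile(recapture_cell_probs(np.full(T, 0.5), np.full(T, 0.5), T), (2, 2, 1, 1))
        assert cr_loglik(data, Q) == 0.0

    def test_single_release_recaptured_next_year(self):
        T = 3
        m = np.zeros((2, 2, T, T + 1), dtype=int)
        m[0, 1, 0, 1] = 1
        Q = np.tile(recapture_cell_probs(np.full(T, 0.5), np.full(T, 0.5), T), (2, 2, 1, 1))
        assert cr_loglik(CRData(m), Q) == pytest.approx(np.log(Q[0, 1, 0, 1]), abs=1e-12)

    def test_positive_count_in_zero_cell_is_minus_inf(self):
        T = 3
        m = np.zeros((2, 2, T, T + 1), dtype=int)
        m[0, 0, 0, 1] = 2
        Q = np.zeros((2, 2, T, T + 1))
        Q[..., T] = 1.0
        assert cr_loglik(CRData(m), Q) == -np.inf


class TestCountLoglik:
    def _inputs(self, T=4):
        st_ = _state(T=T, alpha0=-0.5, alpha2=1.0, alpha6=-1.0, rho=2.0)
        delta, _, eta = link_rates(st_)
        return st_, delta, eta

    def test_matches_scipy_pmfs(self):
        T = 4
        st_, delta, eta = self._inputs(T)
        y = np.array([10, 12, 9, 11])
        xJ = np.array([5, 6, 4, 5])
        xA1, sur = 6, np.array([5, 6, 4])
        imm = np.array([2, 1, 2])
        got = count_loglik(CountData(y), xJ, xA1, sur, imm, st_.rho, delta, eta)
        xA = np.array([xA1, sur[0] + imm[0], sur[1] + imm[1], sur[2] + imm[2]])
        x = xJ + xA
        dJF, dAF = delta[0, 1, 0], delta[1, 1, 0]
        expect = poisson.logpmf(y, x).sum()
        expect += poisson.logpmf(xJ[1:], x[:-1] * st_.rho / 2 * dJF).sum()
        expect += binom.logpmf(sur, x[:-1], dAF).sum()
        expect += poisson.logpmf(imm, x[:-1] * eta[1:]).sum()
        assert got == pytest.approx(expect, abs=1e-12)

    def test_zero_population_point_masses(self):
        T = 3
        st_, delta, eta = self._inputs(T)
        y = np.zeros(T, dtype=int)
        ok = count_loglik(CountData(y), np.zeros(T), 0, np.zeros(2), np.zeros(2),
                          st_.rho, delta, eta)
        assert ok == 0.0  # all point masses at zero, Poisson(0|0) observation
        bad = count_loglik(CountData(y), np.zeros(T), 0, np.zeros(2),
                           np.array([1, 0]), st_.rho, delta, eta)
        assert bad == -np.inf

    def test_more_survivors_than_population_impossible(self):
        T = 3
        st_, delta, eta = self._inputs(T)
        y = np.array([3, 3, 3])
        val = count_loglik(CountData(y), np.array([2, 1, 1]), 1,
                           np.array([10, 1]), np.array([0, 0]), st_.rho, delta, eta)
        assert val == -np.inf


class TestFecundityLoglik:
    def test_all_zero_years_contribute_nothing(self):
        data = FecundityData(np.zeros(3, dtype=int), np.zeros(3, dtype=int))
        assert fecundity_loglik(data, 0.5) == 0.0

    def test_single_year_matches_poisson_pmf(self):
        data = FecundityData(np.array([10]), np.array([5]))
        assert fecundity_loglik(data, 0.5) == pytest.approx(poisson.logpmf(5, 5.0), abs=1e-12)

    def test_zero_females_with_fledglings_impossible(self):
        data = FecundityData(np.array([0]), np.array([2]))
        assert fecundity_loglik(data, 1.0) == -np.inf

    def test_maximised_near_ratio_estimate(self):
        rng = np.random.default_rng(4)
        N = rng.integers(10, 40, size=12)
        n = rng.poisson(N * 1.7)
        data = FecundityData(N, n)
        grid = np.linspace(0.05, 9.95, 991)
        vals = [fecundity_loglik(data, r) for r in grid]
        assert grid[np.argmax(vals)] == pytest.approx(n.sum() / N.sum(), abs=0.02)

    def test_rho_outside_prior_support(self):
        data = FecundityData(np.array([10]), np.array([5]))
        assert fecundity_loglik(data, 12.0) == -np.inf


class TestPriors:
    def test_alpha_outside_truncation(self):
        assert trunc_normal_logpdf(np.array([11.0])) == -np.inf
        st_ = _state(alpha0=11.0, xJ=np.zeros(5), xA1=0, sur=np.zeros(4), imm=np.zeros(4))
        assert log_priors(st_) == -np.inf

    def test_uniform_and_discrete_contributions(self):
        assert log_prior_rho(5.0) == pytest.approx(np.log(0.1))
        assert log_prior_rho(-1.0) == -np.inf
        assert log_prior_initial_pop(25) == pytest.approx(np.log(1 / 51))
        assert log_prior_initial_pop(51) == -np.inf
        assert log_prior_initial_pop(3.5) == -np.inf

    def test_truncated_normal_normalises(self):
        from scipy.integrate import quad

        val, _ = quad(lambda x: np.exp(trunc_normal_logpdf(np.array([x]))), -10, 10)
        assert val == pytest.approx(1.0, abs=1e-10)


class TestSimulator:
    def test_reproducible_given_seed(self):
        a = simulate_ipm(T=6, releases_per_stratum=20, seed=9)
        b = simulate_ipm(T=6, releases_per_stratum=20, seed=9)
        np.testing.assert_array_equal(a[0].m, b[0].m)
        np.testing.assert_array_equal(a[1].y, b[1].y)
        np.testing.assert_array_equal(a[2].fledglings, b[2].fledglings)

    def test_vanishing_survival_never_recaptured(self):
        cr, *_ = simulate_ipm(truth={"alpha0": -25.0, "alpha2": 0.0}, T=5,
                              releases_per_stratum=50, seed=1)
        recaptured = cr.m[:, :, :, :5].sum()
        # adults keep alpha2 = 0 so survival ~ 0 everywhere
        assert recaptured == 0

    def test_large_immigration_grows_population(self):
        _, counts, _, _ = simulate_ipm(truth={"alpha6": 1.0}, T=10, seed=3)
        assert counts.y[-3:].mean() > 3 * counts.y[:3].mean()

    def test_recapture_frequencies_match_cell_probs(self):
        """Empirical recapture frequencies at 1e5 releases match Q."""
        T = 5
        cr, *_ , truth = simulate_ipm(T=T, releases_per_stratum=100_000, seed=17)
        delta, pi, _ = link_rates(truth, T)
        Q = recapture_cell_probs(delta[0, 1], pi[1], T)
        freq = cr.m[0, 1, 0] / cr.m[0, 1, 0].sum()
        se = np.sqrt(Q[0] * (1 - Q[0]) / 100_000)
        assert np.all(np.abs(freq - Q[0]) < 4 * se + 1e-9)


class TestDataContainers:
    def test_cr_invariants(self):
        T = 3
        m = np.zeros((2, 2, T, T + 1), dtype=int)
        m[0, 0, 1, 1] = 2  # recapture at/before release year
        with pytest.raises(ValueError, match="release year"):
            CRData(m)
        with pytest.raises(ValueError, match="negative"):
            CRData(np.full((2, 2, T, T + 1), -1))

    def test_cr_frame_roundtrip(self, owl_data):
        cr = owl_data[0]
        again = CRData.from_frame(cr.to_frame())
        np.testing.assert_array_equal(cr.m, again.m)

    def test_count_and_fecundity_frames(self, owl_data):
        _, counts, fec, _ = owl_data
        np.testing.assert_array_equal(CountData.from_frame(counts.to_frame()).y, counts.y)
        ff = FecundityData.from_frame(fec.to_frame())
        np.testing.assert_array_equal(ff.fledglings, fec.fledglings)

    def test_release_totals_are_row_sums(self, owl_data):
        cr = owl_data[0]
        np.testing.assert_array_equal(cr.releases, cr.m.sum(axis=3))


class TestChainAssembly:
    def test_chain_validates(self, owl_data):
        cr, counts, fec, _ = owl_data
        chain, pooled = build_ipm_chain(cr, counts, fec, "log")
        assert validate_chain(chain.submodels) == []
        assert pooled.layout.names == ("alpha02", "rho")

    def test_half_weight_log_pooling_reproduces_shared_priors(self, owl_data):
        """All submodels share the same priors, so the pooled prior equals
        the original independent priors and the middle factor is flat."""
        cr, counts, fec, _ = owl_data
        _, pooled = build_ipm_chain(cr, counts, fec, "log")
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.normal(scale=2, size=2)
            r = rng.uniform(0.1, 9.9)
            phi = np.concatenate([a, [r]])
            expect = trunc_normal_logpdf(a) + log_prior_rho(r)
            assert pooled(phi) == pytest.approx(expect, abs=1e-12)
            assert pooled.middle(a, np.array([r])) == pytest.approx(0.0, abs=1e-12)

    def test_poe_pooling_concentrates_shared_prior(self, owl_data):
        """PoE squares the truncated-normal prior: twice the log-density
        drop away from zero compared with half-weight pooling."""
        cr, counts, fec, _ = owl_data
        _, log_pool = build_ipm_chain(cr, counts, fec, "log")
        _, poe_pool = build_ipm_chain(cr, counts, fec, "poe")
        at0 = np.array([0.0, 0.0, 5.0])
        at1 = np.array([2.0, 2.0, 5.0])
        drop_log = log_pool(at0) - log_pool(at1)
        drop_poe = poe_pool(at0) - poe_pool(at1)
        assert drop_poe == pytest.approx(2 * drop_log, abs=1e-12)

    def test_linear_pooling_of_identical_priors_is_identity(self, owl_data):
        cr, counts, fec, _ = owl_data
        _, lin = build_ipm_chain(cr, counts, fec, "linear")
        phi = np.array([0.7, -1.1, 3.3])
        expect = trunc_normal_logpdf(phi[:2]) + log_prior_rho(phi[2])
        assert lin(phi) == pytest.approx(expect, abs=1e-12)

    def test_unknown_pooling_rejected(self, owl_data):
        cr, counts, fec, _ = owl_data
        with pytest.raises(LayoutError):
            build_ipm_chain(cr, counts, fec, "median")

    def test_inconsistent_years_rejected(self, owl_data):
        cr, counts, fec, _ = owl_data
        short = CountData(counts.y[:-1])
        with pytest.raises(LayoutError):
            build_ipm_chain(cr, short, fec, "log")

    def test_submodel_joints_finite_at_reasonable_state(self, owl_data):
        from chainmeld.ipm_fit import initial_psi2

        cr, counts, fec, _ = owl_data
        chain, _ = build_ipm_chain(cr, counts, fec, "log")
        phi = np.array([-1.0, 1.3, 2.6])
        assert np.isfinite(chain.submodels[0].log_joint(phi[:2], np.zeros(chain.submodels[0].psi_dim)))
        assert np.isfinite(chain.submodels[1].log_joint(phi, initial_psi2(counts)))
        assert np.isfinite(chain.submodels[2].log_joint(phi[2:], np.empty(0)))

    def test_fecundity_direct_sampler_matches_truncated_gamma(self, owl_data):
        """The conjugate sampler's draws match the analytic subposterior."""
        from scipy.stats import gamma

        cr, counts, fec, _ = owl_data
        chain, _ = build_ipm_chain(cr, counts, fec, "log")
        rho, _ = chain.submodels[2].sampler(np.random.default_rng(0), 50_000)
        shape = 1 + fec.fledglings.sum()
        rate = fec.breeding_females.sum()
        expect_mean = gamma.mean(shape, scale=1 / rate)
        assert rho.mean() == pytest.approx(expect_mean, rel=0.01)
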