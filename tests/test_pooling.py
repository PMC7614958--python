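"""Pooling operators against closed-form and quadrature oracles.

The recurring example pools p1 = N(-2.5, 1) over phi12, a bivariate
p2 = N(0, [[1, .8], [.8, 1]]) over (phi12, phi23), and p3 = N(2.5, 1)
over phi23.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chainmeld.errors import (
    DegeneratePoolingError,
    ImproperPooledPriorError,
    InvalidWeightsError,
    LayoutError,
    SupportMismatchError,
)
from chainmeld.phi import PhiLayout
from chainmeld.pooling import (
    DensityComponent,
    SubmodelPrior,
    WeightVector,
    decompose_pooled,
    gaussian_component,
    gaussian_pool_closed_form,
    grid_moments_2d,
    grid_table,
    marginal_via_quadrature,
    normalise_on_grid,
    pool_dictatorial_complete,
    pool_dictatorial_partial,
    pool_linear,
    pool_log,
)

RHO = 0.8
COV2 = np.array([[1.0, RHO], [RHO, 1.0]])


@pytest.fixture(scope="module")
def comps(layout2):
    p1 = gaussian_component(-2.5, 1.0, ("phi12",))
    p2 = gaussian_component(np.zeros(2), COV2, ("phi12", "phi23"))
    p3 = gaussian_component(2.5, 1.0, ("phi23",))
    return p1, p2, p3


@pytest.fixture(scope="module")
def gauss_triplet():
    return [
        (np.array([-2.5]), np.eye(1), ("phi12",)),
        (np.zeros(2), COV2, ("phi12", "phi23")),
        (np.array([2.5]), np.eye(1), ("phi23",)),
    ]


def _subpriors(layout2):
    """SubmodelPrior objects for the three-Gaussian example."""
    p1 = gaussian_component(-2.5, 1.0, ("phi12",))
    p2j = gaussian_component(np.zeros(2), COV2, ("phi12", "phi23"))
    p3 = gaussian_component(2.5, 1.0, ("phi23",))
    p2m12 = gaussian_component(0.0, 1.0, ("phi12",))
    p2m23 = gaussian_component(0.0, 1.0, ("phi23",))
    return [
        SubmodelPrior(1, p1, {"phi12": p1}),
        SubmodelPrior(2, p2j, {"phi12": p2m12, "phi23": p2m23}),
        SubmodelPrior(3, p3, {"phi23": p3}),
    ]


# ---------------------------------------------------------------------------
# weights


class TestWeights:
    def test_negative_weight_rejected(self):
        with pytest.raises(InvalidWeightsError):
            WeightVector(np.array([1.0, -0.1, 1.0]))

    def test_all_zero_rejected(self):
        with pytest.raises(DegeneratePoolingError):
            WeightVector(np.zeros(3))

    def test_linear_pair_summing_to_zero_rejected(self):
        with pytest.raises(DegeneratePoolingError):
            WeightVector(np.array([[0.0, 0.0], [0.5, 0.5]]), mode="linear")

    def test_sum_constraint_warns_not_raises(self, comps, layout2):
        with pytest.warns(UserWarning, match="improper"):
            pool_log(list(comps), np.array([0.2, 0.2, 0.2]), layout2)


# ---------------------------------------------------------------------------
# logarithmic pooling


class TestLogPooling:
    @pytest.mark.parametrize("lam", [(1.0, 1.0, 1.0), (0.5, 0.5, 0.5)])
    def test_matches_gaussian_precision_addition(self, comps, gauss_triplet, layout2, lam):
        """Grid-normalised pooled density equals the closed-form Gaussian."""
        pooled = pool_log(list(comps), np.array(lam), layout2, check_sum_constraint=False)
        g = gaussian_pool_closed_form(gauss_triplet, np.array(lam), layout2)
        sd = np.sqrt(np.diag(g.cov))
        ranges = [(g.mean[i] - 8 * sd[i], g.mean[i] + 8 * sd[i]) for i in range(2)]
        log_k, axes, vals = normalise_on_grid(pooled.log_density, ranges, 201)
        exact = np.array([[g.logpdf(np.array([x, y])) for y in axes[1]] for x in axes[0]])
        assert np.abs(vals - log_k - exact).max() < 1e-6

    def test_poe_correlation_from_precision_addition(self, gauss_triplet, layout2):
        """PoE pooled correlation equals the precision-addition value."""
        g = gaussian_pool_closed_form(gauss_triplet, np.ones(3), layout2)
        # independent oracle: add Sigma2^{-1} to the identity contributions
        prec = np.linalg.inv(COV2) + np.eye(2)
        cov = np.linalg.inv(prec)
        expect = cov[0, 1] / np.sqrt(cov[0, 0] * cov[1, 1])
        got = g.cov[0, 1] / np.sqrt(g.cov[0, 0] * g.cov[1, 1])
        assert got == pytest.approx(expect, abs=1e-12)
        # cross-check against 2-D grid integration
        pooled = pool_log(
            [gaussian_component(m, c, b) for m, c, b in gauss_triplet],
            np.ones(3), layout2, check_sum_constraint=False,
        )
        mom = grid_moments_2d(pooled.log_density, [(-8, 8), (-8, 8)], 201)
        assert mom["corr"] == pytest.approx(expect, abs=1e-6)

    def test_single_weight_on_side_is_flat_in_other_overlap(self, comps, layout2):
        """lambda = (1, 0, 0) leaves the pooled density constant in phi23."""
        pooled = pool_log(list(comps), np.array([1.0, 0.0, 0.0]), layout2)
        p1 = comps[0]
        for x in (-3.0, 0.0, 2.0):
            vals = [pooled(np.array([x, y])) for y in (-5.0, 0.0, 5.0)]
            assert np.ptp(vals) < 1e-12
            assert vals[0] == pytest.approx(p1(np.array([x])), abs=1e-12)

    def test_middle_dictator_retains_correlation(self, comps, layout2):
        """lambda = (0, 1, 0) keeps the middle prior's rho = 0.8."""
        pooled = pool_log(list(comps), np.array([0.0, 1.0, 0.0]), layout2)
        mom = grid_moments_2d(pooled.log_density, [(-8, 8), (-8, 8)], 201)
        assert mom["corr"] == pytest.approx(RHO, abs=1e-6)

    def test_all_weights_one_is_product_of_marginals(self, comps, layout2, rng):
        pooled = pool_log(list(comps), np.ones(3), layout2, check_sum_constraint=False)
        pts = rng.normal(size=(200, 2), scale=2.0)
        diffs = [
            pooled(p) - sum(c(layout2.extract(p, c.blocks)) for c in comps) for p in pts
        ]
        assert np.ptp(diffs) < 1e-12


# ---------------------------------------------------------------------------
# linear pooling


class TestLinearPooling:
    @pytest.fixture
    def pairs(self):
        p1 = gaussian_component(-2.5, 1.0, ("phi12",))
        p2a = gaussian_component(0.0, 1.0, ("phi12",))
        p2b = gaussian_component(0.0, 1.0, ("phi23",))
        p3 = gaussian_component(2.5, 1.0, ("phi23",))
        return [(p1, p2a), (p2b, p3)]

    def test_degenerate_weight_pair_rejected(self, pairs, layout2):
        with pytest.raises(DegeneratePoolingError):
            pool_linear(pairs, np.array([[0.0, 0.0], [1.0, 0.0]]), layout2)

    def test_unit_weight_recovers_first_marginal(self, pairs, layout2):
        pooled = pool_linear(pairs, np.array([[1.0, 0.0], [1.0, 0.0]]), layout2)
        p1, p2b = pairs[0][0], pairs[1][0]
        for x, y in [(-2.0, 1.0), (0.5, -0.5), (3.0, 0.0)]:
            expect = p1(np.array([x])) + p2b(np.array([y]))
            assert pooled(np.array([x, y])) == pytest.approx(expect, abs=1e-12)

    def test_density_matches_direct_mixture_product(self, pairs, layout2):
        """Pointwise re-evaluation of the mixture product as an oracle."""
        w = np.array([[0.3, 0.7], [0.6, 0.4]])
        pooled = pool_linear(pairs, w, layout2)
        for x, y in [(-1.0, 0.5), (2.0, 2.0), (0.0, -3.0)]:
            m1 = w[0, 0] * np.exp(pairs[0][0](np.array([x]))) + w[0, 1] * np.exp(
                pairs[0][1](np.array([x]))
            )
            m2 = w[1, 0] * np.exp(pairs[1][0](np.array([y]))) + w[1, 1] * np.exp(
                pairs[1][1](np.array([y]))
            )
            assert pooled(np.array([x, y])) == pytest.approx(np.log(m1 * m2), abs=1e-12)

    def test_overlap_components_uncorrelated(self, pairs, layout2, rng):
        """Equal-weight linear pooling yields independent overlap components."""
        pooled = pool_linear(pairs, np.full((2, 2), 0.5), layout2)
        draws = pooled.sample(rng, 100_000)
        assert abs(np.corrcoef(draws.T)[0, 1]) < 0.02


# ---------------------------------------------------------------------------
# dictatorial pooling


class TestDictatorialPooling:
    def test_partial_middle_authority_is_p2_exactly(self, layout2):
        sps = _subpriors(layout2)
        pooled = pool_dictatorial_partial(sps, 2, layout2)
        for pt in [np.array([0.3, -0.7]), np.array([-2.0, 1.5])]:
            assert pooled(pt) == pytest.approx(sps[1].joint(pt), abs=1e-12)

    def test_partial_authority_out_of_range(self, layout2):
        with pytest.raises(LayoutError):
            pool_dictatorial_partial(_subpriors(layout2), 4, layout2)

    def test_partial_result_normalises_to_one(self, layout2):
        """The middle-authoritative pooled prior is a proper bivariate normal."""
        pooled = pool_dictatorial_partial(_subpriors(layout2), 2, layout2)
        log_k, _, _ = normalise_on_grid(pooled.log_density, [(-8, 8), (-8, 8)], 201)
        assert log_k == pytest.approx(0.0, abs=1e-8)

    def test_complete_merge_rule_recovers_joint(self, layout2):
        """Both overlaps assigned to the middle submodel reproduce its joint."""
        sps = _subpriors(layout2)
        pooled = pool_dictatorial_complete(sps, [2, 2], layout2)
        for pt in [np.array([0.0, 0.0]), np.array([1.2, -0.4])]:
            assert pooled(pt) == pytest.approx(sps[1].joint(pt), abs=1e-12)

    def test_complete_outer_selection_is_independent_product(self, layout2):
        sps = _subpriors(layout2)
        pooled = pool_dictatorial_complete(sps, [1, 3], layout2)
        for pt in [np.array([-2.0, 2.0]), np.array([0.5, 0.5])]:
            expect = sps[0].marginals["phi12"](pt[:1]) + sps[2].marginals["phi23"](pt[1:])
            assert pooled(pt) == pytest.approx(expect, abs=1e-12)
        mom = grid_moments_2d(pooled.log_density, [(-9, 9), (-9, 9)], 201)
        assert abs(mom["corr"]) < 1e-8

    def test_complete_invalid_selection(self, layout2):
        with pytest.raises(LayoutError):
            pool_dictatorial_complete(_subpriors(layout2), [3, 3], layout2)

    def test_complete_five_chain_worked_example(self):
        """M=5, selections (1, 3, 3, 5): p1(phi12) p3(phi23, phi34) p5(phi45)."""
        layout = PhiLayout(("v1", "v2", "v3", "v4"), (1, 1, 1, 1))
        rng = np.random.default_rng(5)
        means = rng.normal(size=5)
        j3 = gaussian_component(means[2] + np.zeros(2), np.array([[1.0, 0.5], [0.5, 1.0]]), ("v2", "v3"))
        sps = [
            SubmodelPrior(1, gaussian_component(means[0], 1.0, ("v1",)),
                          {"v1": gaussian_component(means[0], 1.0, ("v1",))}),
            SubmodelPrior(2, gaussian_component(means[1] + np.zeros(2), np.eye(2), ("v1", "v2")),
                          {"v1": gaussian_component(means[1], 1.0, ("v1",)),
                           "v2": gaussian_component(means[1], 1.0, ("v2",))}),
            SubmodelPrior(3, j3,
                          {"v2": gaussian_component(means[2], 1.0, ("v2",)),
                           "v3": gaussian_component(means[2], 1.0, ("v3",))}),
            SubmodelPrior(4, gaussian_component(means[3] + np.zeros(2), np.eye(2), ("v3", "v4")),
                          {"v3": gaussian_component(means[3], 1.0, ("v3",)),
                           "v4": gaussian_component(means[3], 1.0, ("v4",))}),
            SubmodelPrior(5, gaussian_component(means[4], 1.0, ("v4",)),
                          {"v4": gaussian_component(means[4], 1.0, ("v4",))}),
        ]
        pooled = pool_dictatorial_complete(sps, [1, 3, 3, 5], layout)
        for pt in rng.normal(size=(20, 4)):
            expect = (
                sps[0].marginals["v1"](pt[:1])
                + j3(pt[1:3])
                + sps[4].marginals["v4"](pt[3:])
            )
            assert pooled(pt) == pytest.approx(expect, abs=1e-12)


# ---------------------------------------------------------------------------
# decomposition


class TestDecomposition:
    def test_flat_sides_middle_carries_everything(self, comps, layout2):
        pooled = pool_log(list(comps), np.ones(3), layout2, check_sum_constraint=False)
        dec = decompose_pooled(pooled, "flat-sides")
        pt = np.array([0.4, -1.1])
        assert dec.left(pt[:1]) == 0.0 and dec.right(pt[1:]) == 0.0
        assert dec.middle(pt[:1], pt[1:]) == pytest.approx(dec(pt), abs=1e-12)
        assert set(dec.improper_factors) == {"left", "right"}

    @pytest.mark.parametrize("mode", ["flat-sides", "subprior-sides"])
    def test_recombination_identity(self, comps, layout2, rng, mode):
        """left + middle + right reproduces the joint at 1000 random points."""
        pooled = pool_log(list(comps), np.ones(3), layout2, check_sum_constraint=False)
        sides = (comps[0], comps[2]) if mode == "subprior-sides" else None
        dec = decompose_pooled(pooled, mode, sides)
        pts = rng.normal(size=(1000, 2), scale=3.0)
        for pt in pts:
            assert dec.decomposition_log_density(pt) == pytest.approx(dec(pt), abs=1e-12)

    def test_side_prior_zero_raises(self, comps, layout2):
        bounded = DensityComponent(
            lambda x: 0.0, ("phi12",), support=((-1.0, 1.0),)
        )
        pooled = pool_log(list(comps), np.ones(3), layout2, check_sum_constraint=False)
        dec = decompose_pooled(pooled, "subprior-sides", (bounded, comps[2]))
        with pytest.raises(SupportMismatchError):
            dec.middle(np.array([5.0]), np.array([0.0]))

    @settings(max_examples=25, deadline=None)
    @given(
        lam=st.tuples(*[st.floats(0.1, 2.0) for _ in range(3)]),
        x=st.floats(-4, 4),
        y=st.floats(-4, 4),
    )
    def test_recombination_property_any_weights(self, lam, x, y):
        layout = PhiLayout(("phi12", "phi23"), (1, 1))
        p1 = gaussian_component(-2.5, 1.0, ("phi12",))
        p2 = gaussian_component(np.zeros(2), COV2, ("phi12", "phi23"))
        p3 = gaussian_component(2.5, 1.0, ("phi23",))
        pooled = pool_log([p1, p2, p3], np.array(lam), layout, check_sum_constraint=False)
        dec = decompose_pooled(pooled, "subprior-sides", (p1, p3))
        pt = np.array([x, y])
        assert dec.decomposition_log_density(pt) == pytest.approx(dec(pt), abs=1e-12)


# ---------------------------------------------------------------------------
# Gaussian closed form & diagnostics


class TestGaussianClosedForm:
    def test_zero_middle_weight_gives_independence(self, gauss_triplet, layout2):
        g = gaussian_pool_closed_form(gauss_triplet, np.array([1.0, 0.0, 1.0]), layout2)
        assert g.cov[0, 1] == pytest.approx(0.0, abs=1e-14)

    def test_half_weights_match_grid_moments(self, comps, gauss_triplet, layout2):
        lam = np.full(3, 0.5)
        g = gaussian_pool_closed_form(gauss_triplet, lam, layout2)
        pooled = pool_log(list(comps), lam, layout2, check_sum_constraint=False)
        mom = grid_moments_2d(pooled.log_density, [(-10, 10), (-10, 10)], 201)
        np.testing.assert_allclose(mom["mean"], g.mean, atol=1e-6)
        np.testing.assert_allclose(mom["cov"], g.cov, atol=1e-6)

    def test_correlation_nondecreasing_in_middle_weight(self, gauss_triplet, layout2):
        cors = []
        for lam2 in np.linspace(0.01, 3.0, 25):
            g = gaussian_pool_closed_form(gauss_triplet, np.array([0.5, lam2, 0.5]), layout2)
            cors.append(abs(g.cov[0, 1] / np.sqrt(g.cov[0, 0] * g.cov[1, 1])))
        assert np.all(np.diff(cors) >= -1e-12)

    def test_rank_deficient_pooling_rejected(self, layout2):
        only_left = [(np.array([0.0]), np.eye(1), ("phi12",))]
        with pytest.raises(ImproperPooledPriorError):
            gaussian_pool_closed_form(only_left, np.array([1.0]), layout2)

    def test_grid_table_shape(self, comps, layout2):
        pooled = pool_log(list(comps), np.ones(3), layout2, check_sum_constraint=False)
        tab = grid_table(pooled.log_density, [(-4, 4), (-4, 4)], n=21)
        assert list(tab.columns) == ["x1", "x2", "log_density"]
        assert len(tab) == 21 * 21
        assert np.isfinite(tab["log_density"]).all()


class TestQuadratureMarginal:
    def test_bivariate_normal_marginalises_to_univariate(self):
        joint = gaussian_component(np.zeros(2), COV2, ("phi12", "phi23"))
        marg = marginal_via_quadrature(joint, "phi23", (-10.0, 10.0), keep_first=False)
        ref = gaussian_component(0.0, 1.0, ("phi23",))
        for x in (-1.5, 0.0, 2.0):
            assert marg(np.array([x])) == pytest.approx(ref(np.array([x])), abs=1e-8)
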