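"""Reference chains whose melded posteriors are exactly computable.

Two fully specified three-submodel chains used to validate the pooling
operators and the two-stage sampler against independent oracles:

:class:`GaussianChainDemo`
    A conjugate chain of Gaussian submodels.  Every factor of the melded
    model is quadratic in the joint parameter vector, so the melded
    posterior is Gaussian with precision and shift obtained by direct
    bookkeeping -- an analytic benchmark for sampler moments.

:class:`DiscreteChainDemo`
    Every variable lives in {0, 1, 2}.  The melded posterior (243 joint
    states) is enumerable, and the three stage-two block kernels can be
    written down as transition matrices, allowing exact detailed-balance
    and stationarity checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .gaussian_meld import GaussianSummary
from .model_spec import ChainModel, SubmodelSpec
from .phi import PhiLayout
from .pooling import (
    DensityComponent,
    PooledPrior,
    decompose_pooled,
    gaussian_component,
    pool_log,
)
from .samplers import StageOneDraws, accept_prob_psi2, accept_prob_side1, accept_prob_side3

__all__ = ["GaussianChainDemo", "DiscreteChainDemo", "UniformDiscreteKernel"]

_LOG2PI = np.log(2.0 * np.pi)


def _norm_logpdf_sum(y: np.ndarray, mean: float, sd: float) -> float:
    r = (y - mean) / sd
    return float(-0.5 * np.sum(r * r) - y.size * (np.log(sd) + 0.5 * _LOG2PI))


def _std_norm_logpdf(x: float) -> float:
    return -0.5 * (x * x + _LOG2PI)


class GaussianChainDemo:
    """Conjugate Gaussian three-chain with an analytic melded posterior.

    Structure (all scalars, standard-normal priors on every parameter):

    - submodel 1: ``Y1_j ~ N(phi12 + psi1, sd^2)``
    - submodel 2: ``Y2_j ~ N(phi12 + phi23 + psi2, sd^2)``
    - submodel 3: ``Y3_j ~ N(phi23 + psi3, sd^2)``

    Adjacent submodels place the same N(0,1) prior on their shared
    quantity, so with logarithmic pooling at weights (1/2, 1/2, 1/2) the
    pooled prior equals the common prior and the melded model is the
    natural joint model.  The joint parameter order used throughout is
    ``(phi12, phi23, psi1, psi2, psi3)``.
    """

    PARAM_ORDER = ("phi12", "phi23", "psi1", "psi2", "psi3")

    def __init__(
        self,
        n_obs: tuple[int, int, int] = (5, 5, 5),
        truth: dict | None = None,
        obs_sd: float = 1.0,
        lam: tuple[float, float, float] = (0.5, 0.5, 0.5),
        data_seed: int = 20240901,
    ):
        self.truth = truth or {"phi12": 0.8, "phi23": -0.5, "psi1": 0.3, "psi2": -0.2, "psi3": 0.6}
        self.obs_sd = float(obs_sd)
        self.lam = tuple(float(x) for x in lam)
        rng = np.random.default_rng(data_seed)
        t = self.truth
        self.y1 = t["phi12"] + t["psi1"] + obs_sd * rng.standard_normal(n_obs[0])
        self.y2 = t["phi12"] + t["phi23"] + t["psi2"] + obs_sd * rng.standard_normal(n_obs[1])
        self.y3 = t["phi23"] + t["psi3"] + obs_sd * rng.standard_normal(n_obs[2])
        self.layout = PhiLayout(names=("phi12", "phi23"), dims=(1, 1))
        self._build_chain()

    # -- chain ------------------------------------------------------------

    def _build_chain(self) -> None:
        sd = self.obs_sd
        y1, y2, y3 = self.y1, self.y2, self.y3

        def log_joint_1(phi: np.ndarray, psi: np.ndarray) -> float:
            return (
                _std_norm_logpdf(phi[0])
                + _std_norm_logpdf(psi[0])
                + _norm_logpdf_sum(y1, phi[0] + psi[0], sd)
            )

        def log_joint_2(phi: np.ndarray, psi: np.ndarray) -> float:
            return (
                _std_norm_logpdf(phi[0])
                + _std_norm_logpdf(phi[1])
                + _std_norm_logpdf(psi[0])
                + _norm_logpdf_sum(y2, phi[0] + phi[1] + psi[0], sd)
            )

        def log_joint_3(phi: np.ndarray, psi: np.ndarray) -> float:
            return (
                _std_norm_logpdf(phi[0])
                + _std_norm_logpdf(psi[0])
                + _norm_logpdf_sum(y3, phi[0] + psi[0], sd)
            )

        def marg_1(phi: np.ndarray) -> float:
            return _std_norm_logpdf(phi[0])

        def marg_2(phi: np.ndarray) -> float:
            return _std_norm_logpdf(phi[0]) + _std_norm_logpdf(phi[1])

        self.sub1 = SubmodelSpec(1, log_joint_1, marg_1, ("phi12",), (1,), psi_dim=1)
        self.sub2 = SubmodelSpec(2, log_joint_2, marg_2, ("phi12", "phi23"), (1, 1), psi_dim=1)
        self.sub3 = SubmodelSpec(3, log_joint_3, marg_1, ("phi23",), (1,), psi_dim=1)
        self.chain = ChainModel([self.sub1, self.sub2, self.sub3])

    def pooled_prior(self, decomposition: str = "subprior-sides") -> PooledPrior:
        comps = [
            gaussian_component(0.0, 1.0, ("phi12",)),
            gaussian_component(np.zeros(2), np.eye(2), ("phi12", "phi23")),
            gaussian_component(0.0, 1.0, ("phi23",)),
        ]
        pooled = pool_log(comps, np.asarray(self.lam), self.layout, check_sum_constraint=False)
        if decomposition == "subprior-sides":
            side1 = DensityComponent(lambda x: _std_norm_logpdf(x[0]), ("phi12",))
            side3 = DensityComponent(lambda x: _std_norm_logpdf(x[0]), ("phi23",))
            return decompose_pooled(pooled, "subprior-sides", (side1, side3))
        return decompose_pooled(pooled, "flat-sides")

    # -- oracles ----------------------------------------------------------

    def exact_melded_posterior(self) -> GaussianSummary:
        """Melded posterior over (phi12, phi23, psi1, psi2, psi3).

        The melded log density is ``log p_pool(phi) + sum_m [log lik_m +
        log prior(psi_m)]`` (the submodel phi-priors cancel against their
        marginals), a quadratic form assembled here term by term.
        """
        lam1, lam2, lam3 = self.lam
        P = np.zeros((5, 5))
        b = np.zeros(5)
        # pooled prior: N(0,1)^(lam_m sums) per shared block
        P[0, 0] += lam1 + lam2
        P[1, 1] += lam2 + lam3
        # psi priors
        for i in (2, 3, 4):
            P[i, i] += 1.0
        # likelihood design rows
        prec = 1.0 / self.obs_sd**2
        for y, rows in ((self.y1, (0, 2)), (self.y2, (0, 1, 3)), (self.y3, (1, 4))):
            a = np.zeros(5)
            a[list(rows)] = 1.0
            P += y.size * prec * np.outer(a, a)
            b += prec * y.sum() * a
        cov = np.linalg.inv(P)
        return GaussianSummary(cov @ b, 0.5 * (cov + cov.T), "melded")

    def fit_two_stage(
        self,
        seed: int = 0,
        n_stage_one: int = 5000,
        sweeps: int = 5000,
        chains: int = 4,
        stage_one_iterations: Optional[int] = None,
    ):
        """Run the full two-stage sampler on this chain.

        Stage one samples both side subposteriors by adaptive random-walk
        Metropolis (subprior-sides decomposition, so these are the
        ordinary subposteriors), retaining ``n_stage_one`` draws per side;
        stage two recycles them.  Returns
        :class:`~chainmeld.samplers.MeldedPosteriorDraws`.
        """
        from .samplers import MHConfig, StageTwoConfig, run_stage_two, sample_stage_one

        pooled = self.pooled_prior("subprior-sides")
        root = np.random.default_rng(seed)
        r1, r3, r2 = root.spawn(3)
        iters = stage_one_iterations or (2 * n_stage_one)
        cfg = MHConfig(iterations=iters + n_stage_one, warmup=iters, thin=1, init_scale=0.5)
        phi1, psi1, info1 = sample_stage_one(self.sub1, pooled.left, cfg, r1, x0=np.zeros(2))
        phi3, psi3, info3 = sample_stage_one(self.sub3, pooled.right, cfg, r3, x0=np.zeros(2))
        stage_one = StageOneDraws(
            phi1=phi1, psi1=psi1, phi3=phi3, psi3=psi3,
            provenance={"side1": info1, "side3": info3, "seed": seed},
        )
        s2cfg = StageTwoConfig(sweeps=sweeps, chains=chains)
        return run_stage_two(
            stage_one, self.sub2, pooled, s2cfg, psi2_init=np.zeros(1), rng=r2
        )

    def exact_side_subposterior(self, side: int) -> GaussianSummary:
        """Subposterior of an outer submodel over (phi_side, psi_side)."""
        y = self.y1 if side == 1 else self.y3
        prec = 1.0 / self.obs_sd**2
        a = np.ones(2)
        P = np.eye(2) + y.size * prec * np.outer(a, a)
        b = prec * y.sum() * a
        cov = np.linalg.inv(P)
        return GaussianSummary(cov @ b, 0.5 * (cov + cov.T), f"side{side}")


class UniformDiscreteKernel:
    """Independence proposal uniform over a finite value set (symmetric)."""

    def __init__(self, values: tuple[int, ...] = (0, 1, 2)):
        self.values = np.asarray(values, dtype=float)
        self.accepted = 0
        self.proposed = 0
        self.adapting = False

    def step(self, rng, psi2, log_post, lp_cur=None):
        lp = log_post(psi2) if lp_cur is None else lp_cur
        prop = np.array([self.values[rng.integers(self.values.size)]])
        lp_prop = log_post(prop)
        self.proposed += 1
        if np.log(rng.random()) < lp_prop - lp:
            self.accepted += 1
            return prop, lp_prop
        return psi2.copy(), lp


class DiscreteChainDemo:
    """Fully discrete three-chain with enumerable melded posterior.

    All five variables take values in {0, 1, 2}.  Submodel joints (data
    baked in) and prior phi-marginals are fixed positive probability
    tables drawn once from a seeded generator.  Pooling is
    product-of-experts over the three marginals, decomposed with
    subprior sides, so the stage-one targets are the (normalised)
    submodel joints themselves.
    """

    K = 3

    def __init__(self, table_seed: int = 7):
        rng = np.random.default_rng(table_seed)
        K = self.K

        def table(*shape):
            t = rng.gamma(2.0, size=shape) + 0.05
            return t / t.sum()

        self.t1 = table(K, K)       # p_1(phi12, psi1, Y1)
        self.t2 = table(K, K, K)    # p_2(phi12, phi23, psi2, Y2)
        self.t3 = table(K, K)       # p_3(phi23, psi3, Y3)
        self.m1 = table(K)          # p_1(phi12)
        self.m2 = table(K, K)       # p_2(phi12, phi23)
        self.m3 = table(K)          # p_3(phi23)
        self.layout = PhiLayout(names=("phi12", "phi23"), dims=(1, 1))
        self._build()

    def _build(self) -> None:
        logt1, logt2, logt3 = np.log(self.t1), np.log(self.t2), np.log(self.t3)
        logm1, logm2, logm3 = np.log(self.m1), np.log(self.m2), np.log(self.m3)

        # direct stage-one samplers: iid draws from the exact side targets
        p1_joint = self.t1 / self.t1.sum()
        p3_joint = self.t3 / self.t3.sum()

        def sampler_factory(pmf):
            flat = pmf.ravel()
            K = self.K

            def sampler(rng, n):
                idx = rng.choice(flat.size, size=n, p=flat)
                return (idx // K).astype(float)[:, None], (idx % K).astype(float)[:, None]

            return sampler

        self.sub1 = SubmodelSpec(
            1,
            lambda phi, psi: float(logt1[int(phi[0]), int(psi[0])]),
            lambda phi: float(logm1[int(phi[0])]),
            ("phi12",),
            (1,),
            psi_dim=1,
            sampler=sampler_factory(p1_joint),
        )
        self.sub2 = SubmodelSpec(
            2,
            lambda phi, psi: float(logt2[int(phi[0]), int(phi[1]), int(psi[0])]),
            lambda phi: float(logm2[int(phi[0]), int(phi[1])]),
            ("phi12", "phi23"),
            (1, 1),
            psi_dim=1,
        )
        self.sub3 = SubmodelSpec(
            3,
            lambda phi, psi: float(logt3[int(phi[0]), int(psi[0])]),
            lambda phi: float(logm3[int(phi[0])]),
            ("phi23",),
            (1,),
            psi_dim=1,
            sampler=sampler_factory(p3_joint),
        )
        self.chain = ChainModel([self.sub1, self.sub2, self.sub3])

        def joint_pool(phi):
            i, j = int(phi[0]), int(phi[1])
            return float(logm1[i] + logm2[i, j] + logm3[j])

        base = PooledPrior(layout=self.layout, log_density=joint_pool)
        left = DensityComponent(lambda a: float(logm1[int(a[0])]), ("phi12",))
        right = DensityComponent(lambda b: float(logm3[int(b[0])]), ("phi23",))
        self.pooled = decompose_pooled(base, "subprior-sides", (left, right))

    # -- enumeration oracles ----------------------------------------------

    def melded_joint_pmf(self) -> np.ndarray:
        """Exact melded posterior over (phi12, phi23, psi1, psi2, psi3)."""
        K = self.K
        p = np.zeros((K, K, K, K, K))
        for i in range(K):
            for j in range(K):
                pool = self.m1[i] * self.m2[i, j] * self.m3[j]
                for a in range(K):
                    for k in range(K):
                        for c in range(K):
                            p[i, j, a, k, c] = (
                                pool
                                * self.t1[i, a] / self.m1[i]
                                * self.t2[i, j, k] / self.m2[i, j]
                                * self.t3[j, c] / self.m3[j]
                            )
        return p / p.sum()

    def melded_marginal_pmf(self) -> np.ndarray:
        """Exact melded posterior over the stage-two state (phi12, phi23, psi2)."""
        return self.melded_joint_pmf().sum(axis=(2, 4))

    def side_marginal(self, side: int) -> np.ndarray:
        """Exact stage-one target marginal over the side's shared quantity."""
        t = self.t1 if side == 1 else self.t3
        m = t.sum(axis=1)
        return m / m.sum()

    # -- exact block kernels ----------------------------------------------

    def block_kernels(self) -> dict[str, np.ndarray]:
        """The three stage-two block kernels as 27x27 transition matrices.

        States enumerate (phi12, phi23, psi2) in C order.  Side proposals
        use the exact stage-one marginals (the infinite-pool limit of
        recycling); the psi2 proposal is uniform over {0, 1, 2}.
        """
        K = self.K
        q1 = self.side_marginal(1)
        q3 = self.side_marginal(3)
        n_states = K**3

        def sid(i, j, k):
            return (i * K + j) * K + k

        kernels = {}
        for name in ("side1", "side3", "psi2"):
            Kmat = np.zeros((n_states, n_states))
            for i in range(K):
                for j in range(K):
                    for k in range(K):
                        s = sid(i, j, k)
                        if name == "side1":
                            for ip in range(K):
                                a = accept_prob_side1(
                                    np.array([float(ip)]), np.array([float(i)]),
                                    self.sub2, self.pooled.middle,
                                    np.array([float(j)]), np.array([float(k)]),
                                )
                                Kmat[s, sid(ip, j, k)] += q1[ip] * a
                                Kmat[s, s] += q1[ip] * (1 - a)
                        elif name == "side3":
                            for jp in range(K):
                                a = accept_prob_side3(
                                    np.array([float(jp)]), np.array([float(j)]),
                                    self.sub2, self.pooled.middle,
                                    np.array([float(i)]), np.array([float(k)]),
                                )
                                Kmat[s, sid(i, jp, k)] += q3[jp] * a
                                Kmat[s, s] += q3[jp] * (1 - a)
                        else:
                            for kp in range(K):
                                a = accept_prob_psi2(
                                    np.array([float(kp)]), np.array([float(k)]),
                                    self.sub2,
                                    np.array([float(i)]), np.array([float(j)]),
                                )
                                Kmat[s, sid(i, j, kp)] += a / K
                                Kmat[s, s] += (1 - a) / K
            kernels[name] = Kmat
        return kernels

    def stage_one_pool(self, rng: np.random.Generator, n1: int, n3: int) -> StageOneDraws:
        """IID stage-one pools drawn from the exact side targets."""
        phi1, psi1 = self.sub1.sampler(rng, n1)
        phi3, psi3 = self.sub3.sampler(rng, n3)
        return StageOneDraws(
            phi1=phi1, psi1=psi1, phi3=phi3, psi3=psi3,
            provenance={"sampler": "exact-iid", "N1": n1, "N3": n3},
        )
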