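"""Posterior estimation for the owls integrated population model.

Provides the end-to-end two-stage melding fit (stage one: capture-recapture
subposterior by adaptive random-walk Metropolis and fecundity subposterior
by direct conjugate sampling; stage two: Metropolis-within-Gibbs with
recycled draws and a structured psi_2 kernel), a count-submodel-only
posterior for information comparisons, and a single-block MCMC fit of the
monolithic joint model used as a benchmark: with logarithmic pooling at
weights (1/2, 1/2, 1/2) the melded posterior and the joint posterior are
the same distribution, so the two fits should agree within Monte-Carlo
error.

The latent population states (juvenile counts, survivors, immigrants,
initial populations) are updated by single-site discrete random-walk
proposals (+-1, +-2); they are never marginalised out.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .ipm import (
    CountData,
    CRData,
    FecundityData,
    build_ipm_chain,
    psi2_layout,
)
from .samplers import (
    GaussianRWKernel,
    MHConfig,
    StageOneDraws,
    StageTwoConfig,
    MeldedPosteriorDraws,
    run_stage_two,
    sample_stage_one,
)

__all__ = [
    "IPMPsi2Kernel",
    "initial_psi2",
    "fit_ipm_two_stage",
    "count_only_posterior",
    "fit_ipm_joint",
    "extract_ipm_params",
]


class IPMPsi2Kernel:
    """Structured psi_2 update for the count submodel.

    One step updates alpha6 by an adaptive Gaussian random walk, then each
    latent site (juvenile counts, initial adult population, survivors,
    immigrants) by a symmetric integer random walk with steps in
    {-2, -1, +1, +2}.  Scale adaptation runs only while ``adapting``.
    """

    STEPS = np.array([-2.0, -1.0, 1.0, 2.0])

    def __init__(self, T: int, alpha6_scale: float = 0.2, update_alpha6: bool = True):
        self.T = T
        self.layout = psi2_layout(T)
        self.dim = 3 * T
        self.log_scale = np.log(alpha6_scale)
        self.update_alpha6 = update_alpha6
        self.adapting = True
        self._step_count = 0
        self.accepted = 0
        self.proposed = 0
        self._site_idx = np.arange(1, 3 * T)  # everything but alpha6

    def step(self, rng, psi2, log_post, lp_cur=None):
        x = psi2.copy()
        lp = log_post(x) if lp_cur is None else lp_cur
        self._step_count += 1

        if self.update_alpha6:
            # alpha6: Gaussian random walk
            prop = x.copy()
            prop[0] += np.exp(self.log_scale) * rng.standard_normal()
            lp_prop = log_post(prop)
            accept = np.log(rng.random()) < lp_prop - lp
            if accept:
                x, lp = prop, lp_prop
                self.accepted += 1
            self.proposed += 1
            if self.adapting:
                self.log_scale += ((1.0 if accept else 0.0) - 0.44) / self._step_count**0.6

        # latent sites: symmetric integer moves
        n_sites = self._site_idx.size
        steps = self.STEPS[rng.integers(4, size=n_sites)]
        logu = np.log(rng.random(n_sites))
        for k, i in enumerate(self._site_idx):
            newv = x[i] + steps[k]
            if newv < 0:
                self.proposed += 1
                continue
            old = x[i]
            x[i] = newv
            lp_prop = log_post(x)
            if logu[k] < lp_prop - lp:
                lp = lp_prop
                self.accepted += 1
            else:
                x[i] = old
            self.proposed += 1
        return x, lp


def initial_psi2(counts: CountData) -> np.ndarray:
    """A finite-density starting point for psi_2 derived from the counts.

    Splits each observed count evenly between juveniles and adults and
    attributes adults half to survival (capped by the previous total) and
    half to immigration.  Initial populations are clipped to the prior
    support {0..50}; alpha6 starts at -1 (immigration rate ~ 0.37).
    """
    T = counts.T
    y = np.maximum(counts.y, 1)
    layout = psi2_layout(T)
    psi = np.zeros(3 * T)
    psi[layout["alpha6"]] = -1.0
    xJ = np.maximum(y // 2, 0)
    xA = np.maximum(y - xJ, 0)
    xJ[0] = min(xJ[0], 50)
    xA1 = min(xA[0], 50)
    sur = np.zeros(T - 1)
    imm = np.zeros(T - 1)
    xprev = xJ[0] + xA1
    for t in range(1, T):
        sur[t - 1] = min(xprev, xA[t] // 2)
        imm[t - 1] = max(xA[t] - sur[t - 1], 0)
        xprev = xJ[t] + sur[t - 1] + imm[t - 1]
    psi[layout["xJ"]] = xJ
    psi[layout["xA1"]] = xA1
    psi[layout["sur"]] = sur
    psi[layout["imm"]] = imm
    return psi


@dataclass
class IPMFitResult:
    """Melded-posterior draws plus the chain objects that produced them."""

    draws: MeldedPosteriorDraws
    stage_one: StageOneDraws
    pooling: str
    params: dict = field(default_factory=dict)


def fit_ipm_two_stage(
    cr: CRData,
    counts: CountData,
    fec: FecundityData,
    pooling: str = "log",
    seed: int = 0,
    stage_one_config: Optional[MHConfig] = None,
    stage_two_config: Optional[StageTwoConfig] = None,
) -> IPMFitResult:
    """Fit the owls model by two-stage chained melding.

    Stage one: the capture-recapture subposterior over (alpha0, alpha2,
    alpha1, alpha4, alpha5_2..T) by adaptive random-walk Metropolis, and
    the fecundity subposterior over rho by direct truncated-Gamma
    sampling.  Stage two: Metropolis-within-Gibbs with recycled draws and
    the structured :class:`IPMPsi2Kernel`.
    """
    T = cr.T
    chain, pooled = build_ipm_chain(cr, counts, fec, pooling)
    s1cfg = stage_one_config or MHConfig(iterations=16_000, warmup=6_000, thin=2, init_scale=0.1)
    s2cfg = stage_two_config or StageTwoConfig(sweeps=4_000, chains=2)
    root = np.random.default_rng(seed)
    r1, r3, r2 = root.spawn(3)

    n1 = (s1cfg.iterations - s1cfg.resolved_warmup()) // s1cfg.thin
    phi1, psi1, info1 = sample_stage_one(
        chain.submodels[0], pooled.left, s1cfg, r1, x0=np.zeros(2 + chain.submodels[0].psi_dim)
    )
    phi3, psi3, info3 = sample_stage_one(
        chain.submodels[2], pooled.right, s1cfg, r3, n_direct=n1
    )
    stage_one = StageOneDraws(
        phi1=phi1, psi1=psi1, phi3=phi3, psi3=psi3,
        provenance={"side1": info1, "side3": info3, "seed": seed},
    )
    draws = run_stage_two(
        stage_one,
        chain.submodels[1],
        pooled,
        s2cfg,
        psi2_init=initial_psi2(counts),
        psi2_kernel_factory=lambda: IPMPsi2Kernel(T),
        rng=r2,
    )
    return IPMFitResult(
        draws=draws, stage_one=stage_one, pooling=pooling, params=extract_ipm_params(draws)
    )


def extract_ipm_params(draws: MeldedPosteriorDraws) -> dict[str, np.ndarray]:
    """Named (chains, kept) arrays for the shared quantities."""
    return {
        "alpha0": draws.phi12[:, :, 0],
        "alpha2": draws.phi12[:, :, 1],
        "rho": draws.phi23[:, :, 0],
    }


# ---------------------------------------------------------------------------
# count-submodel-only posterior


def count_only_posterior(
    cr: CRData,
    counts: CountData,
    fec: FecundityData,
    sweeps: int = 6000,
    chains: int = 2,
    warmup_frac: float = 0.25,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Posterior of (alpha0, alpha2, rho) under the count submodel alone.

    Only the count data enter the likelihood (the capture-recapture and
    fecundity datasets are used solely to size the model), so the shared
    quantities are weakly identified and remain close to their priors --
    the comparison target for how much melding sharpens them.
    """
    chain, _ = build_ipm_chain(cr, counts, fec, "log")
    sub2 = chain.submodels[1]
    T = counts.T
    warmup = int(round(warmup_frac * sweeps))
    kept = sweeps - warmup
    rngs = np.random.default_rng(seed).spawn(chains)
    out = {k: np.empty((chains, kept)) for k in ("alpha0", "alpha2", "rho")}

    for c, rng in enumerate(rngs):
        phi = np.array([0.0, 0.0, 2.0])  # (alpha0, alpha2, rho)
        psi = initial_psi2(counts)
        phi_kernel = GaussianRWKernel(3, scale=0.3)
        psi_kernel = IPMPsi2Kernel(T)
        lp = sub2.log_joint(phi, psi)
        if lp == -np.inf:
            raise RuntimeError("count-only sampler failed to initialise")
        for t in range(sweeps):
            if t == warmup:
                phi_kernel.adapting = False
                psi_kernel.adapting = False
            phi, lp = phi_kernel.step(rng, phi, lambda p: sub2.log_joint(p, psi), lp)
            psi, lp = psi_kernel.step(rng, psi, lambda p: sub2.log_joint(phi, p), lp)
            if t >= warmup:
                k = t - warmup
                out["alpha0"][c, k] = phi[0]
                out["alpha2"][c, k] = phi[1]
                out["rho"][c, k] = phi[2]
    return out


# ---------------------------------------------------------------------------
# monolithic joint IPM (benchmark)


def fit_ipm_joint(
    cr: CRData,
    counts: CountData,
    fec: FecundityData,
    sweeps: int = 10_000,
    chains: int = 2,
    warmup_frac: float = 0.3,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Direct MCMC on the monolithic joint model (all three likelihoods).

    The joint model places single shared priors on (alpha0, alpha2) and
    rho and multiplies all three likelihoods -- the model the chained
    melded posterior with logarithmic pooling at weights (1/2, 1/2, 1/2)
    reproduces.  Continuous parameters are updated componentwise with
    adaptive scales; latent states by the same integer random walk as the
    melded fit.  Returns (chains, kept) arrays for the shared quantities.
    """
    chain, _ = build_ipm_chain(cr, counts, fec, "log")
    sub1, sub2, sub3 = chain.submodels
    T = counts.T
    d_cont = 2 + sub1.psi_dim + 2  # (alpha0, alpha2), psi1, alpha6, rho
    # continuous vector: [alpha0, alpha2, alpha1, alpha4, alpha5..., alpha6, rho]
    i_alpha6 = 2 + sub1.psi_dim
    i_rho = i_alpha6 + 1

    p2l = psi2_layout(T)

    def log_post_cont(theta: np.ndarray, lat: np.ndarray) -> float:
        phi1 = theta[:2]
        psi1 = theta[2:i_alpha6]
        phi2 = np.array([theta[0], theta[1], theta[i_rho]])
        psi2 = lat.copy()
        psi2[p2l["alpha6"]] = theta[i_alpha6]
        l1 = sub1.log_joint(phi1, psi1)
        if l1 == -np.inf:
            return -np.inf
        l2 = sub2.log_joint(phi2, psi2)
        if l2 == -np.inf:
            return -np.inf
        l3 = sub3.log_joint(np.array([theta[i_rho]]), np.empty(0))
        # shared priors appear in every submodel joint; subtract the
        # duplicates so each is counted once (Markov combination)
        dup = sub1.log_phi_marginal(phi1) + sub3.log_phi_marginal(np.array([theta[i_rho]]))
        return l1 + l2 + l3 - dup

    warmup = int(round(warmup_frac * sweeps))
    kept = sweeps - warmup
    rngs = np.random.default_rng(seed).spawn(chains)
    out = {k: np.empty((chains, kept)) for k in ("alpha0", "alpha2", "rho")}

    for c, rng in enumerate(rngs):
        theta = np.zeros(d_cont)
        theta[i_rho] = 2.0
        lat = initial_psi2(counts)  # alpha6 slot ignored in log_post_cont
        cont_kernel = GaussianRWKernel(d_cont, scale=0.15)
        lat_kernel = IPMPsi2Kernel(T, update_alpha6=False)
        lp = log_post_cont(theta, lat)
        if lp == -np.inf:
            raise RuntimeError("joint sampler failed to initialise")
        for t in range(sweeps):
            if t == warmup:
                cont_kernel.adapting = False
                lat_kernel.adapting = False
            theta, lp = cont_kernel.step(rng, theta, lambda th: log_post_cont(th, lat), lp)

            # latent block: only the count submodel depends on it
            phi2 = np.array([theta[0], theta[1], theta[i_rho]])
            lat[p2l["alpha6"]] = theta[i_alpha6]

            def lat_post(ps):
                return sub2.log_joint(phi2, ps)

            lp2 = lat_post(lat)
            lat, _ = lat_kernel.step(rng, lat, lat_post, lp2)
            lat[p2l["alpha6"]] = theta[i_alpha6]
            lp = log_post_cont(theta, lat)
            if t >= warmup:
                k = t - warmup
                out["alpha0"][c, k] = theta[0]
                out["alpha2"][c, k] = theta[1]
                out["rho"][c, k] = theta[i_rho]
    return out
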