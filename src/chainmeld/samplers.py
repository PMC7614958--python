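"""Two-stage parallel MCMC for the chained melded posterior (M = 3).

Stage one samples, independently and in parallel, the prior-adjusted
subposteriors of the two outer submodels:

    p_meld,1(phi_{1∩2}, psi_1 | Y_1) ∝ p_pool,1(phi_{1∩2}) p_1(phi_{1∩2}, psi_1, Y_1) / p_1(phi_{1∩2})
    p_meld,3(phi_{2∩3}, psi_3 | Y_3) ∝ p_pool,3(phi_{2∩3}) p_3(phi_{2∩3}, psi_3, Y_3) / p_3(phi_{2∩3})

With the subprior-sides decomposition these are the ordinary subposteriors
and any existing implementation can produce the draws.

Stage two runs a Metropolis-within-Gibbs sweep over three blocks:
(phi_{1∩2}, psi_1) proposed by recycling a uniformly drawn stage-one row,
(phi_{2∩3}, psi_3) likewise, and psi_2 by a generic proposal kernel.  The
acceptance ratios involve only the middle submodel and the middle pooled
factor, so the expensive outer submodels are never re-evaluated.  Accepted
row indices are stored so psi_1 and psi_3 are reattached verbatim from the
stage-one arrays.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

logger = logging.getLogger(__name__)

from .errors import InitialisationError, InvalidStateError, ProposalSupportError
from .model_spec import SubmodelSpec
from .pooling import PooledPrior

__all__ = [
    "MHConfig",
    "adaptive_rwmh",
    "StageOneDraws",
    "stage_one_log_target",
    "sample_stage_one",
    "accept_prob_side1",
    "accept_prob_side3",
    "accept_prob_psi2",
    "GaussianRWKernel",
    "StageTwoConfig",
    "StageTwoState",
    "MeldedPosteriorDraws",
    "run_stage_two",
]


# ---------------------------------------------------------------------------
# generic adaptive random-walk Metropolis


@dataclass
class MHConfig:
    """Settings for the adaptive random-walk Metropolis sampler.

    ``iterations`` counts total sweeps; the first ``warmup`` are discarded
    (and are the only ones during which the proposal adapts), and the rest
    are thinned by ``thin``.
    """

    iterations: int = 10_000
    warmup: Optional[int] = None  # default: iterations // 2
    thin: int = 1
    init_scale: float = 0.5
    target_accept: float = 0.234
    adapt_cov: bool = True

    def resolved_warmup(self) -> int:
        return self.iterations // 2 if self.warmup is None else self.warmup


def adaptive_rwmh(
    log_target: Callable[[np.ndarray], float],
    x0: np.ndarray,
    config: MHConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float]:
    """Adaptive multivariate random-walk Metropolis.

    The global step size follows a Robbins–Monro recursion toward
    ``target_accept`` and the proposal covariance tracks the running
    empirical covariance of the chain (both frozen after warmup, so the
    retained draws come from a fixed Markov kernel).  Returns
    ``(draws, acceptance_rate)`` with draws of shape ``(n_kept, d)``.
    """
    x = np.atleast_1d(np.asarray(x0, dtype=float)).copy()
    d = x.size
    lp = log_target(x)
    if not np.isfinite(lp):
        raise InitialisationError(f"log target not finite at initial point {x0}")

    warmup = config.resolved_warmup()
    n_kept = (config.iterations - warmup) // config.thin
    draws = np.empty((n_kept, d))
    log_scale = np.log(config.init_scale)
    mean = x.copy()
    cov = np.eye(d)
    chol = np.linalg.cholesky(cov)
    accepts = 0
    kept = 0
    adapt_start = max(50, 5 * d)

    for it in range(config.iterations):
        z = rng.standard_normal(d)
        prop = x + np.exp(log_scale) * (chol @ z)
        lp_prop = log_target(prop)
        accept = np.log(rng.random()) < lp_prop - lp
        if accept:
            x, lp = prop, lp_prop
            accepts += 1
        if it < warmup:
            # Robbins-Monro on the log step size
            rate = 1.0 if accept else 0.0
            log_scale += (rate - config.target_accept) / (1.0 + it) ** 0.6
            if config.adapt_cov:
                # running moments for the Haario-style covariance proposal
                w = 1.0 / (it + 2.0)
                delta = x - mean
                mean = mean + w * delta
                cov = (1.0 - w) * (cov + w * np.outer(delta, delta))
                if it >= adapt_start and (it + 1) % 25 == 0:
                    try:
                        chol = np.linalg.cholesky(cov + 1e-10 * np.eye(d))
                    except np.linalg.LinAlgError:
                        pass
        else:
            if (it - warmup) % config.thin == 0 and kept < n_kept:
                draws[kept] = x
                kept += 1
    return draws[:kept], accepts / config.iterations


# ---------------------------------------------------------------------------
# stage one


@dataclass
class StageOneDraws:
    """Recycled subposterior draws for the two outer submodels.

    Side 1 rows pair ``phi_{1∩2}`` with ``psi_1``; side 3 rows pair
    ``phi_{2∩3}`` with ``psi_3``.  Provenance records how each side was
    produced (sampler, iterations, warmup, thinning, acceptance rate).
    """

    phi1: np.ndarray
    psi1: np.ndarray
    phi3: np.ndarray
    psi3: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.phi1 = np.atleast_2d(np.asarray(self.phi1, dtype=float))
        self.phi3 = np.atleast_2d(np.asarray(self.phi3, dtype=float))
        self.psi1 = self._psi(self.psi1, self.phi1.shape[0])
        self.psi3 = self._psi(self.psi3, self.phi3.shape[0])
        for name in ("phi1", "psi1", "phi3", "psi3"):
            arr = getattr(self, name)
            if arr.shape[0] < 1:
                raise ValueError(f"stage-one side {name} has no rows")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite entries in stage-one array {name}")
        if self.psi1.shape[0] != self.phi1.shape[0]:
            raise ValueError("side-1 phi/psi row counts differ")
        if self.psi3.shape[0] != self.phi3.shape[0]:
            raise ValueError("side-3 phi/psi row counts differ")

    @staticmethod
    def _psi(arr, n_rows) -> np.ndarray:
        arr = np.asarray(arr, dtype=float)
        if arr.size == 0:
            return np.empty((n_rows, 0))
        return np.atleast_2d(arr) if arr.ndim > 1 else arr.reshape(n_rows, -1)

    @property
    def N1(self) -> int:
        return self.phi1.shape[0]

    @property
    def N3(self) -> int:
        return self.phi3.shape[0]


def stage_one_log_target(
    sub: SubmodelSpec, pooled_side: Callable[[np.ndarray], float]
) -> Callable[[np.ndarray], float]:
    """Log target over the concatenated ``(phi_side, psi_side)`` vector."""
    d_phi = sub.phi_dim

    def log_target(x: np.ndarray) -> float:
        phi = x[:d_phi]
        psi = x[d_phi:]
        lmarg = sub.log_phi_marginal(phi)
        if lmarg == -np.inf:
            return -np.inf
        lpool = pooled_side(phi)
        if lpool == -np.inf:
            return -np.inf
        return lpool + sub.log_joint(phi, psi) - lmarg

    return log_target


def sample_stage_one(
    sub: SubmodelSpec,
    pooled_side: Callable[[np.ndarray], float],
    config: MHConfig,
    rng: np.random.Generator,
    x0: Optional[np.ndarray] = None,
    n_direct: Optional[int] = None,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Draws from one stage-one side target.

    Uses the submodel's direct subposterior sampler when available (valid
    under the subprior-sides decomposition, where the side target *is* the
    subposterior); otherwise adaptive random-walk Metropolis on
    :func:`stage_one_log_target`.  Returns ``(phi draws, psi draws, info)``.
    """
    if sub.sampler is not None:
        n = n_direct if n_direct is not None else (
            (config.iterations - config.resolved_warmup()) // config.thin
        )
        phi, psi = sub.sampler(rng, n)
        phi = np.atleast_2d(np.asarray(phi, dtype=float))
        if phi.shape[0] != n:
            phi = phi.reshape(n, -1)
        psi = np.asarray(psi, dtype=float).reshape(n, -1)
        return phi, psi, {"sampler": "direct", "n": n}
    if x0 is None:
        x0 = np.zeros(sub.phi_dim + sub.psi_dim)
    target = stage_one_log_target(sub, pooled_side)
    draws, acc = adaptive_rwmh(target, x0, config, rng)
    info = {
        "sampler": "adaptive-rwmh",
        "iterations": config.iterations,
        "warmup": config.resolved_warmup(),
        "thin": config.thin,
        "acceptance_rate": acc,
    }
    return draws[:, : sub.phi_dim], draws[:, sub.phi_dim :], info


# ---------------------------------------------------------------------------
# stage-two acceptance probabilities


def _middle_terms(
    middle: SubmodelSpec,
    pool_middle: Callable[[np.ndarray, np.ndarray], float],
    phi12: np.ndarray,
    phi23: np.ndarray,
    psi2: np.ndarray,
) -> float:
    phi_m = np.concatenate([np.atleast_1d(phi12), np.atleast_1d(phi23)])
    lpool = pool_middle(np.atleast_1d(phi12), np.atleast_1d(phi23))
    if lpool == -np.inf:
        return -np.inf
    lj = middle.log_joint(phi_m, np.atleast_1d(np.asarray(psi2, dtype=float)))
    if lj == -np.inf:
        return -np.inf
    return lpool + lj - middle.log_phi_marginal(phi_m)


def accept_prob_side1(
    phi12_prop: np.ndarray,
    phi12_cur: np.ndarray,
    middle: SubmodelSpec,
    pool_middle: Callable[[np.ndarray, np.ndarray], float],
    phi23: np.ndarray,
    psi2: np.ndarray,
) -> float:
    """Acceptance probability for the recycled side-1 proposal.

    The proposal is a uniformly drawn stage-one side-1 row, so the
    stage-one factors cancel and the ratio contains only middle-submodel
    and middle-pooled-factor terms; it does not depend on psi_1 or psi_3.
    """
    cur = _middle_terms(middle, pool_middle, phi12_cur, phi23, psi2)
    if cur == -np.inf:
        raise InvalidStateError("current state has zero middle-submodel density")
    prop = _middle_terms(middle, pool_middle, phi12_prop, phi23, psi2)
    return float(min(1.0, np.exp(prop - cur)))


def accept_prob_side3(
    phi23_prop: np.ndarray,
    phi23_cur: np.ndarray,
    middle: SubmodelSpec,
    pool_middle: Callable[[np.ndarray, np.ndarray], float],
    phi12: np.ndarray,
    psi2: np.ndarray,
) -> float:
    """Mirror of :func:`accept_prob_side1` with ``phi_{1∩2}`` held fixed."""
    cur = _middle_terms(middle, pool_middle, phi12, phi23_cur, psi2)
    if cur == -np.inf:
        raise InvalidStateError("current state has zero middle-submodel density")
    prop = _middle_terms(middle, pool_middle, phi12, phi23_prop, psi2)
    return float(min(1.0, np.exp(prop - cur)))


def accept_prob_psi2(
    psi2_prop: np.ndarray,
    psi2_cur: np.ndarray,
    middle: SubmodelSpec,
    phi12: np.ndarray,
    phi23: np.ndarray,
    log_q: Optional[Callable[[np.ndarray, np.ndarray], float]] = None,
) -> float:
    """Acceptance probability for the generic psi_2 proposal.

    ``log_q(to, frm)`` is the proposal log-density; ``None`` means the
    proposal is symmetric and the correction cancels.
    """
    phi_m = np.concatenate([np.atleast_1d(phi12), np.atleast_1d(phi23)])
    cur = middle.log_joint(phi_m, np.atleast_1d(np.asarray(psi2_cur, dtype=float)))
    if cur == -np.inf:
        raise InvalidStateError("current psi2 state has zero middle-submodel density")
    prop = middle.log_joint(phi_m, np.atleast_1d(np.asarray(psi2_prop, dtype=float)))
    log_r = prop - cur
    if log_q is not None:
        back = log_q(np.asarray(psi2_cur, float), np.asarray(psi2_prop, float))
        fwd = log_q(np.asarray(psi2_prop, float), np.asarray(psi2_cur, float))
        if back == -np.inf:
            raise ProposalSupportError("proposal density is zero at the current point")
        log_r += back - fwd
    return float(min(1.0, np.exp(log_r)))


# ---------------------------------------------------------------------------
# psi2 kernels


class GaussianRWKernel:
    """Componentwise Gaussian random walk for psi_2.

    Per-component scales adapt toward ``target_accept`` only while
    ``adapting`` is true (stage two's warmup phase) and are frozen
    afterwards, preserving the correct stationary distribution.
    """

    def __init__(self, dim: int, scale: float = 0.5, target_accept: float = 0.44):
        self.dim = dim
        self.log_scales = np.full(dim, np.log(scale))
        self.target_accept = target_accept
        self.adapting = True
        self._step_count = 0
        self.accepted = 0
        self.proposed = 0

    def step(
        self,
        rng: np.random.Generator,
        psi2: np.ndarray,
        log_post: Callable[[np.ndarray], float],
        lp_cur: Optional[float] = None,
    ) -> tuple[np.ndarray, float]:
        x = psi2.copy()
        lp = log_post(x) if lp_cur is None else lp_cur
        self._step_count += 1
        scales = np.exp(self.log_scales)
        for i in range(self.dim):
            prop = x.copy()
            prop[i] += scales[i] * rng.standard_normal()
            lp_prop = log_post(prop)
            accept = np.log(rng.random()) < lp_prop - lp
            if accept:
                x, lp = prop, lp_prop
                self.accepted += 1
            self.proposed += 1
            if self.adapting:
                rate = 1.0 if accept else 0.0
                self.log_scales[i] += (rate - self.target_accept) / self._step_count**0.6
        return x, lp


# ---------------------------------------------------------------------------
# stage two


@dataclass
class StageTwoConfig:
    """Settings for the stage-two Metropolis-within-Gibbs sampler."""

    sweeps: int = 5000
    chains: int = 4
    warmup_frac: float = 0.1
    seed: Optional[int] = None
    block_order: tuple[str, ...] = ("side1", "side3", "psi2")
    random_scan: bool = False
    mixing_window: int = 1000

    def warmup(self) -> int:
        return int(round(self.warmup_frac * self.sweeps))


@dataclass
class StageTwoState:
    """Current state of one stage-two chain, with cached middle factors."""

    n1: int
    n3: int
    psi2: np.ndarray
    log_pool_middle: float
    log_joint2: float
    log_marg2: float


@dataclass
class MeldedPosteriorDraws:
    """Joint melded-posterior draws with the stage-one index trace.

    Arrays have shape ``(chains, kept, dim)`` (indices: ``(chains, kept)``).
    Every row's side pairs exist verbatim in the stage-one arrays at the
    stored indices.
    """

    phi12: np.ndarray
    phi23: np.ndarray
    psi1: np.ndarray
    psi2: np.ndarray
    psi3: np.ndarray
    idx1: np.ndarray
    idx3: np.ndarray
    acceptance: dict = field(default_factory=dict)
    stage_one: Optional[StageOneDraws] = None

    @property
    def n_chains(self) -> int:
        return self.phi12.shape[0]

    @property
    def n_kept(self) -> int:
        return self.phi12.shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """Draws of one quantity pooled across chains, shape (chains*kept, d)."""
        arr = getattr(self, name)
        return arr.reshape(-1, arr.shape[-1]) if arr.ndim == 3 else arr.reshape(-1)


def run_stage_two(
    stage_one: StageOneDraws,
    middle: SubmodelSpec,
    pooled: PooledPrior,
    config: StageTwoConfig,
    psi2_init: np.ndarray,
    psi2_kernel_factory: Optional[Callable[[], object]] = None,
    rng: Optional[np.random.Generator] = None,
) -> MeldedPosteriorDraws:
    """Stage-two Metropolis-within-Gibbs targeting the melded posterior.

    One sweep updates, in ``config.block_order`` (default side1, side3,
    psi2): the side-1 pair by a recycled stage-one row, the side-3 pair
    likewise, and psi_2 by the supplied kernel (default componentwise
    Gaussian random walk, adapting only during warmup).  The middle pooled
    factor and middle submodel are the only densities evaluated.
    """
    if pooled.middle is None:
        raise InvalidStateError("pooled prior has no decomposition; call decompose_pooled")
    if rng is None:
        if config.seed is None:
            raise InvalidStateError("either an rng or a config seed is required")
        rng = np.random.default_rng(config.seed)
    chain_rngs = rng.spawn(config.chains)

    N1, N3 = stage_one.N1, stage_one.N3
    if N1 == 1 or N3 == 1:
        warnings.warn("a stage-one side has a single row; that block is degenerate", stacklevel=2)
    warmup = config.warmup()
    kept = config.sweeps - warmup
    psi2_dim = int(np.atleast_1d(psi2_init).size)

    out = MeldedPosteriorDraws(
        phi12=np.empty((config.chains, kept, stage_one.phi1.shape[1])),
        phi23=np.empty((config.chains, kept, stage_one.phi3.shape[1])),
        psi1=np.empty((config.chains, kept, stage_one.psi1.shape[1])),
        psi2=np.empty((config.chains, kept, psi2_dim)),
        psi3=np.empty((config.chains, kept, stage_one.psi3.shape[1])),
        idx1=np.empty((config.chains, kept), dtype=np.int64),
        idx3=np.empty((config.chains, kept), dtype=np.int64),
        stage_one=stage_one,
    )
    acc = {"side1": 0, "side3": 0, "psi2_kernels": []}
    pool_middle = pooled.middle
    log_joint = middle.log_joint
    log_marg = middle.log_phi_marginal

    for c, crng in enumerate(chain_rngs):
        kernel = (psi2_kernel_factory or (lambda: GaussianRWKernel(psi2_dim)))()
        # initialise at a finite-density point; retry over random stage-one rows
        psi2 = np.atleast_1d(np.asarray(psi2_init, dtype=float)).copy()
        state = None
        for _ in range(100):
            n1 = int(crng.integers(N1))
            n3 = int(crng.integers(N3))
            phi12, phi23 = stage_one.phi1[n1], stage_one.phi3[n3]
            phi_m = np.concatenate([phi12, phi23])
            lp_pool = pool_middle(phi12, phi23)
            lj = log_joint(phi_m, psi2)
            if np.isfinite(lp_pool) and np.isfinite(lj):
                state = StageTwoState(n1, n3, psi2, lp_pool, lj, log_marg(phi_m))
                break
        if state is None:
            raise InitialisationError(
                "could not find a finite-density initial state in 100 attempts"
            )

        # pre-drawn randomness for the index blocks
        prop1 = crng.integers(N1, size=config.sweeps)
        prop3 = crng.integers(N3, size=config.sweeps)
        logu1 = np.log(crng.random(config.sweeps))
        logu3 = np.log(crng.random(config.sweeps))
        since_accept = {"side1": 0, "side3": 0}
        warned = set()
        block_acc = {"side1": 0, "side3": 0}

        for t in range(config.sweeps):
            if t > 0 and t % 1000 == 0 and logger.isEnabledFor(logging.INFO):
                for blk, n_acc in block_acc.items():
                    logger.info(
                        "chain=%d sweep=%d block=%s accept_rate=%.3f", c, t, blk, n_acc / t
                    )
                if getattr(kernel, "proposed", 0):
                    logger.info(
                        "chain=%d sweep=%d block=psi2 accept_rate=%.3f",
                        c, t, kernel.accepted / kernel.proposed,
                    )
            if t == warmup and hasattr(kernel, "adapting"):
                kernel.adapting = False
            order = config.block_order
            if config.random_scan:
                order = tuple(crng.permutation(list(config.block_order)))
            for block in order:
                if block == "side1":
                    j = int(prop1[t])
                    phi12_p = stage_one.phi1[j]
                    phi23 = stage_one.phi3[state.n3]
                    lp_pool_p = pool_middle(phi12_p, phi23)
                    if lp_pool_p > -np.inf:
                        phi_m_p = np.concatenate([phi12_p, phi23])
                        lj_p = log_joint(phi_m_p, state.psi2)
                        lm_p = log_marg(phi_m_p)
                        log_r = (lp_pool_p + lj_p - lm_p) - (
                            state.log_pool_middle + state.log_joint2 - state.log_marg2
                        )
                    else:
                        log_r = -np.inf
                    if logu1[t] < log_r:
                        state.n1 = j
                        state.log_pool_middle = lp_pool_p
                        state.log_joint2 = lj_p
                        state.log_marg2 = lm_p
                        if t >= warmup:
                            acc["side1"] += 1
                        block_acc["side1"] += 1
                        since_accept["side1"] = 0
                    else:
                        since_accept["side1"] += 1
                elif block == "side3":
                    j = int(prop3[t])
                    phi23_p = stage_one.phi3[j]
                    phi12 = stage_one.phi1[state.n1]
                    lp_pool_p = pool_middle(phi12, phi23_p)
                    if lp_pool_p > -np.inf:
                        phi_m_p = np.concatenate([phi12, phi23_p])
                        lj_p = log_joint(phi_m_p, state.psi2)
                        lm_p = log_marg(phi_m_p)
                        log_r = (lp_pool_p + lj_p - lm_p) - (
                            state.log_pool_middle + state.log_joint2 - state.log_marg2
                        )
                    else:
                        log_r = -np.inf
                    if logu3[t] < log_r:
                        state.n3 = j
                        state.log_pool_middle = lp_pool_p
                        state.log_joint2 = lj_p
                        state.log_marg2 = lm_p
                        if t >= warmup:
                            acc["side3"] += 1
                        block_acc["side3"] += 1
                        since_accept["side3"] = 0
                    else:
                        since_accept["side3"] += 1
                else:  # psi2
                    phi_m = np.concatenate(
                        [stage_one.phi1[state.n1], stage_one.phi3[state.n3]]
                    )
                    new_psi2, lp_new = kernel.step(
                        crng, state.psi2, lambda p: log_joint(phi_m, p), state.log_joint2
                    )
                    state.psi2 = new_psi2
                    state.log_joint2 = lp_new
            for name, n_since in since_accept.items():
                if n_since >= config.mixing_window and name not in warned:
                    warnings.warn(
                        f"no accepted {name} proposals in {config.mixing_window} sweeps "
                        f"(chain {c}); the sampler may be mixing poorly",
                        stacklevel=2,
                    )
                    warned.add(name)
            if t >= warmup:
                k = t - warmup
                out.phi12[c, k] = stage_one.phi1[state.n1]
                out.phi23[c, k] = stage_one.phi3[state.n3]
                out.psi1[c, k] = stage_one.psi1[state.n1]
                out.psi2[c, k] = state.psi2
                out.psi3[c, k] = stage_one.psi3[state.n3]
                out.idx1[c, k] = state.n1
                out.idx3[c, k] = state.n3
        acc["psi2_kernels"].append(
            {"accepted": getattr(kernel, "accepted", None), "proposed": getattr(kernel, "proposed", None)}
        )

    denom = config.chains * kept
    out.acceptance = {
        "side1": acc["side1"] / denom,
        "side3": acc["side3"] / denom,
        "psi2": _kernel_rate(acc["psi2_kernels"]),
    }
    return out


def _kernel_rate(kernel_stats: list[dict]) -> Optional[float]:
    tot_a = sum(s["accepted"] for s in kernel_stats if s["accepted"] is not None)
    tot_p = sum(s["proposed"] for s in kernel_stats if s["proposed"] is not None)
    return tot_a / tot_p if tot_p else None
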