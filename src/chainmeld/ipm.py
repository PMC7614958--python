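"""Integrated population model for little owls: the worked chained example.

Three submodels observe the same owl population:

1. **Capture-recapture** (``p_1``): owls of age class ``a`` (J = juvenile,
   A = adult) and sex ``s`` released in year ``t`` are recaptured in year
   ``u > t`` (or never) with multinomial cell probabilities built from the
   annual survival probabilities ``delta_{a,s,t}`` and recapture
   probabilities ``pi_{s,u}``.
2. **Female counts** (``p_2``): observed counts ``y_t`` are Poisson around
   a latent female population ``x_t = x_{J,t} + x_{A,t}`` whose dynamics
   mix local recruitment (Poisson, rate ``x_{t-1} (rho/2) delta_{J,F,t-1}``
   -- half of fledglings are female), adult survival (binomial) and
   immigration (Poisson, rate ``x_{t-1} eta_t``).
3. **Fecundity** (``p_3``): fledgling totals ``n_t`` are Poisson with mean
   ``N_t rho`` given ``N_t`` observed breeding females.

Rates are parameterised by linear predictors

    logit(delta_{a,s,t}) = alpha0 + alpha1 1(s=M) + alpha2 1(a=A)
    log(eta_t)           = alpha6
    logit(pi_{s,u})      = alpha4 1(s=M) + alpha5_u,   u = 2..T

so the quantities shared along the chain are ``phi_{1∩2} = (alpha0,
alpha2)`` (survival intercept and adult effect, present in both the
capture-recapture and count submodels) and ``phi_{2∩3} = rho`` (fecundity,
present in both the count and fecundity submodels).

Priors: every alpha component is Normal(0, 2^2) truncated to [-10, 10];
rho is Uniform(0, 10); the initial populations ``x_{J,1}`` and ``x_{A,1}``
have independent discrete uniform priors on {0, ..., 50}.

Internally all years are 0-based: ``t = 0..T-1``; recapture-year index
``T`` means "never recaptured"; ``pi[s, u]`` is defined for ``u = 1..T-1``
(entry 0 is unused).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln

from .errors import LayoutError
from .model_spec import ChainModel, SubmodelSpec
from .phi import PhiLayout
from .pooling import (
    DensityComponent,
    PooledPrior,
    decompose_pooled,
    pool_linear,
    pool_log,
)

__all__ = [
    "AGES",
    "SEXES",
    "CRData",
    "CountData",
    "FecundityData",
    "IPMState",
    "link_rates",
    "recapture_cell_probs",
    "cr_loglik",
    "count_loglik",
    "fecundity_loglik",
    "log_priors",
    "simulate_ipm",
    "build_ipm_chain",
    "trunc_normal_logpdf",
    "log_prior_rho",
    "log_prior_initial_pop",
]

AGES = ("J", "A")
SEXES = ("M", "F")

ALPHA_SD = 2.0
ALPHA_BOUND = 10.0
RHO_MAX = 10.0
INIT_POP_MAX = 50

_LOG2PI = np.log(2.0 * np.pi)

try:  # compiled hot paths; the pure-numpy equivalents remain the reference
    from numba import njit as _njit
except ImportError:  # pragma: no cover
    def _njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap if not (args and callable(args[0])) else args[0]

# normalising constant of Normal(0, 2^2) truncated to [-10, 10]
from scipy.stats import norm as _norm

_TRUNC_LOG_Z = float(np.log(_norm.cdf(ALPHA_BOUND / ALPHA_SD) - _norm.cdf(-ALPHA_BOUND / ALPHA_SD)))


# ---------------------------------------------------------------------------
# priors


def trunc_normal_logpdf(x) -> float:
    """Log density of Normal(0, 2^2) truncated to [-10, 10], summed over x."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if np.any(np.abs(x) > ALPHA_BOUND):
        return -np.inf
    return float(
        np.sum(-0.5 * (x / ALPHA_SD) ** 2)
        - x.size * (np.log(ALPHA_SD) + 0.5 * _LOG2PI + _TRUNC_LOG_Z)
    )


def log_prior_rho(rho: float) -> float:
    """Uniform(0, 10) prior for fecundity."""
    return -np.log(RHO_MAX) if 0.0 < rho < RHO_MAX else -np.inf


def log_prior_initial_pop(x) -> float:
    """Discrete uniform {0, ..., 50} prior for an initial population size."""
    x = float(x)
    if x < 0 or x > INIT_POP_MAX or x != np.rint(x):
        return -np.inf
    return -np.log(INIT_POP_MAX + 1.0)


# ---------------------------------------------------------------------------
# data containers


@dataclass
class CRData:
    """Capture-recapture release/recapture matrices.

    ``m[a, s]`` is a (T, T+1) integer matrix: row ``t`` counts owls of age
    class ``a`` and sex ``s`` released in year ``t``, by recapture year
    (column ``T`` = never recaptured).  Entries below/on the diagonal of
    the recapture block are zero: recapture precedes release is
    impossible.
    """

    m: np.ndarray  # (2, 2, T, T+1)

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m)
        if self.m.ndim != 4 or self.m.shape[:2] != (2, 2) or self.m.shape[3] != self.m.shape[2] + 1:
            raise LayoutError(f"CR matrix must have shape (2, 2, T, T+1), got {self.m.shape}")
        if np.any(self.m < 0):
            raise ValueError("negative capture-recapture count")
        T = self.T
        for t in range(T):
            if np.any(self.m[:, :, t, : t + 1] != 0):
                raise ValueError(f"nonzero recapture count at or before release year {t}")

    @property
    def T(self) -> int:
        return self.m.shape[2]

    @property
    def releases(self) -> np.ndarray:
        """Release totals R_{a,s,t} (row sums)."""
        return self.m.sum(axis=3)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: age, sex, release_year, recapture_year, count.

        Years are 1-based; recapture_year T+1 encodes 'never recaptured'.
        """
        rows = []
        T = self.T
        for ia, a in enumerate(AGES):
            for isx, s in enumerate(SEXES):
                for t in range(T):
                    for u in range(T + 1):
                        rows.append(
                            (a, s, t + 1, u + 1 if u < T else T + 1, int(self.m[ia, isx, t, u]))
                        )
        return pd.DataFrame(rows, columns=["age", "sex", "release_year", "recapture_year", "count"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CRData":
        T = int(df["release_year"].max())
        m = np.zeros((2, 2, T, T + 1), dtype=np.int64)
        for _, r in df.iterrows():
            ia, isx = AGES.index(r["age"]), SEXES.index(r["sex"])
            u = int(r["recapture_year"]) - 1
            m[ia, isx, int(r["release_year"]) - 1, min(u, T)] = int(r["count"])
        return cls(m)


@dataclass
class CountData:
    """Observed female counts y_t, one per year."""

    y: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.int64)
        if self.y.ndim != 1 or np.any(self.y < 0):
            raise ValueError("counts must be a 1-D nonnegative integer array")

    @property
    def T(self) -> int:
        return self.y.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": np.arange(1, self.T + 1), "count": self.y})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountData":
        return cls(df.sort_values("year")["count"].to_numpy())


@dataclass
class FecundityData:
    """Breeding females N_t and fledged chicks n_t, one pair per year."""

    breeding_females: np.ndarray
    fledglings: np.ndarray

    def __post_init__(self) -> None:
        self.breeding_females = np.asarray(self.breeding_females, dtype=np.int64)
        self.fledglings = np.asarray(self.fledglings, dtype=np.int64)
        if self.breeding_females.shape != self.fledglings.shape:
            raise ValueError("breeding-female and fledgling series differ in length")
        if np.any(self.breeding_females < 0) or np.any(self.fledglings < 0):
            raise ValueError("fecundity data must be nonnegative")

    @property
    def T(self) -> int:
        return self.breeding_females.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": np.arange(1, self.T + 1),
                "breeding_females": self.breeding_females,
                "fledglings": self.fledglings,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FecundityData":
        df = df.sort_values("year")
        return cls(df["breeding_females"].to_numpy(), df["fledglings"].to_numpy())


@dataclass
class IPMState:
    """Full parameter + latent state of the owls model.

    ``alpha5`` has one entry per recapture year ``u = 2..T`` (length
    T - 1); latent series are 0-based with ``xJ[0]`` and ``xA1`` the
    initial populations and ``sur``/``imm`` starting at the transition
    into year 2.
    """

    alpha0: float
    alpha1: float
    alpha2: float
    alpha4: float
    alpha6: float
    alpha5: np.ndarray
    rho: float
    xJ: Optional[np.ndarray] = None
    xA1: Optional[int] = None
    sur: Optional[np.ndarray] = None
    imm: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.alpha5 = np.asarray(self.alpha5, dtype=float)

    @property
    def T(self) -> int:
        return self.alpha5.size + 1

    def xA(self) -> np.ndarray:
        out = np.empty(self.T, dtype=np.int64)
        out[0] = self.xA1
        out[1:] = self.sur + self.imm
        return out

    def x_total(self) -> np.ndarray:
        return np.asarray(self.xJ, dtype=np.int64) + self.xA()


# ---------------------------------------------------------------------------
# rates and likelihoods


def link_rates(state: IPMState, T: Optional[int] = None):
    """Survival, recapture and immigration rates from the linear predictors.

    Returns ``(delta, pi, eta)``: ``delta[a, s, t]`` with shape (2, 2, T)
    (constant over t under this parameterisation, stored per-year to keep
    the multinomial machinery general), ``pi[s, u]`` with shape (2, T)
    defined for ``u = 1..T-1`` (entry 0 unused, set to nan), and
    ``eta[t] = exp(alpha6)``.
    """
    T = state.T if T is None else T
    delta = np.empty((2, 2, T))
    for ia in range(2):  # 0=J, 1=A
        for isx in range(2):  # 0=M, 1=F
            lin = state.alpha0 + state.alpha1 * (isx == 0) + state.alpha2 * (ia == 1)
            delta[ia, isx, :] = expit(lin)
    pi = np.full((2, T), np.nan)
    for isx in range(2):
        pi[isx, 1:] = expit(state.alpha4 * (isx == 0) + state.alpha5)
    eta = np.full(T, np.exp(state.alpha6))
    return delta, pi, eta


def recapture_cell_probs(delta_t: np.ndarray, pi_u: np.ndarray, T: int) -> np.ndarray:
    """Multinomial cell probabilities Q for one (age, sex) stratum.

    ``Q[t, u] = delta_t pi_u prod_{r=t+1}^{u-1} delta_r (1 - pi_r)`` for
    ``u = t+1..T-1``, zero for ``u <= t``, and the last column is the
    complement so every row sums to exactly one.
    """
    delta_t = np.asarray(delta_t, dtype=float)
    pi_safe = np.where(np.isnan(pi_u), 0.0, np.asarray(pi_u, dtype=float))
    c = delta_t * (1.0 - pi_safe)  # survive year r and not be recaptured
    C = np.concatenate([[1.0], np.cumprod(c)])  # C[k] = prod_{r<k} c[r]
    Q = np.zeros((T, T + 1))
    t_idx = np.arange(T)[:, None]
    u_idx = np.arange(T)[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = C[u_idx] / C[t_idx + 1]  # prod_{r=t+1}^{u-1} c[r]
    body = delta_t[:, None] * pi_safe[None, :] * ratio
    mask = u_idx > t_idx
    Q[:, :T][mask] = body[mask]
    Q[:, T] = 1.0 - Q[:, :T].sum(axis=1)
    np.clip(Q[:, T], 0.0, 1.0, out=Q[:, T])
    return Q


@_njit(cache=True)
def _q_all_core(delta: np.ndarray, pi: np.ndarray, T: int) -> np.ndarray:
    Q = np.zeros((2, 2, T, T + 1))
    for ia in range(2):
        for isx in range(2):
            for t in range(T):
                p = delta[ia, isx, t]
                rowsum = 0.0
                for u in range(t + 1, T):
                    q = p * pi[isx, u]
                    Q[ia, isx, t, u] = q
                    rowsum += q
                    p *= delta[ia, isx, u] * (1.0 - pi[isx, u])
                c = 1.0 - rowsum
                Q[ia, isx, t, T] = c if c > 0.0 else 0.0
    return Q


def _all_cell_probs(delta: np.ndarray, pi: np.ndarray, T: int) -> np.ndarray:
    pi_safe = np.where(np.isnan(pi), 0.0, pi)
    return _q_all_core(np.ascontiguousarray(delta), np.ascontiguousarray(pi_safe), T)


def cr_loglik(data: CRData, Q: np.ndarray) -> float:
    """Multinomial log likelihood of the release/recapture matrices.

    A positive count in a zero-probability cell yields ``-inf`` (not an
    exception).  Includes the multinomial coefficients, so values agree
    with direct pmf evaluation.
    """
    m = data.m
    R = data.releases
    with np.errstate(divide="ignore"):
        logQ = np.log(Q)
    bad = (m > 0) & (Q == 0.0)
    if np.any(bad):
        return -np.inf
    term = np.where(m > 0, m * np.where(np.isfinite(logQ), logQ, 0.0), 0.0)
    ll = term.sum() + gammaln(R + 1.0).sum() - gammaln(m + 1.0).sum()
    return float(ll)


def _poisson_logpmf(k: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Elementwise Poisson log-pmf; mu == 0 is a point mass at zero."""
    k = np.asarray(k, dtype=float)
    mu = np.asarray(mu, dtype=float)
    out = np.where(
        mu > 0,
        k * np.log(np.where(mu > 0, mu, 1.0)) - mu - gammaln(k + 1.0),
        np.where(k == 0, 0.0, -np.inf),
    )
    return out


def _binom_logpmf(k: np.ndarray, n: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Elementwise binomial log-pmf; n == 0 is a point mass at zero."""
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    invalid = (k < 0) | (k > n)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (
            gammaln(n + 1.0)
            - gammaln(k + 1.0)
            - gammaln(n - k + 1.0)
            + k * np.log(p)
            + (n - k) * np.log1p(-p)
        )
    out = np.where((k == 0) & ((n == 0) | (p == 0.0)), 0.0, out)
    out = np.where((k == n) & (p == 1.0), 0.0, out)
    return np.where(invalid, -np.inf, out)


@_njit(cache=True)
def _pois_lpmf(k: float, mu: float) -> float:
    if mu > 0.0:
        return k * np.log(mu) - mu - math.lgamma(k + 1.0)
    return 0.0 if k == 0.0 else -np.inf


@_njit(cache=True)
def _count_core(
    y: np.ndarray,
    xJ: np.ndarray,
    xA1: int,
    sur: np.ndarray,
    imm: np.ndarray,
    rho: float,
    dJF: np.ndarray,
    dAF: np.ndarray,
    eta: np.ndarray,
) -> float:
    T = y.shape[0]
    x_prev = float(xJ[0] + xA1)
    ll = _pois_lpmf(float(y[0]), x_prev)
    for t in range(1, T):
        ll += _pois_lpmf(float(xJ[t]), x_prev * 0.5 * rho * dJF[t - 1])
        s = float(sur[t - 1])
        if s > x_prev:
            return -np.inf
        if x_prev > 0.0:
            p = dAF[t - 1]
            ll += (
                math.lgamma(x_prev + 1.0)
                - math.lgamma(s + 1.0)
                - math.lgamma(x_prev - s + 1.0)
                + s * np.log(p)
                + (x_prev - s) * np.log1p(-p)
            )
        elif s != 0.0:
            return -np.inf
        ll += _pois_lpmf(float(imm[t - 1]), x_prev * eta[t - 1])
        x_t = float(xJ[t] + sur[t - 1] + imm[t - 1])
        ll += _pois_lpmf(float(y[t]), x_t)
        if ll == -np.inf:
            return -np.inf
        x_prev = x_t
    return ll


def count_loglik(
    data: CountData,
    xJ: np.ndarray,
    xA1: int,
    sur: np.ndarray,
    imm: np.ndarray,
    rho: float,
    delta: np.ndarray,
    eta: np.ndarray,
) -> float:
    """Log likelihood of the count submodel (observation + latent process).

    Sums Poisson(y_t | x_t) over all years and, for each transition,
    Poisson recruitment of juvenile females at rate
    ``x_{t-1} (rho/2) delta_{J,F,t-1}``, binomial survival
    ``sur_t ~ Binomial(x_{t-1}, delta_{A,F,t-1})`` and Poisson immigration
    at rate ``x_{t-1} eta_t``.  A zero population forces point masses at
    zero; ``sur_t > x_{t-1}`` gives ``-inf``.  Priors are not included.
    """
    T = data.T
    xJ = np.asarray(np.rint(xJ), dtype=np.int64)
    sur = np.asarray(np.rint(sur), dtype=np.int64)
    imm = np.asarray(np.rint(imm), dtype=np.int64)
    xA1 = int(np.rint(xA1))
    if xJ.size != T or sur.size != T - 1 or imm.size != T - 1:
        raise LayoutError("latent series lengths inconsistent with the count series")
    if np.any(xJ < 0) or np.any(sur < 0) or np.any(imm < 0) or xA1 < 0:
        return -np.inf
    return float(
        _count_core(
            data.y,
            xJ,
            xA1,
            sur,
            imm,
            float(rho),
            np.ascontiguousarray(delta[0, 1, :-1]),
            np.ascontiguousarray(delta[1, 1, :-1]),
            np.ascontiguousarray(eta[1:]),
        )
    )


def fecundity_loglik(data: FecundityData, rho: float) -> float:
    """Poisson log likelihood of the fledgling counts given fecundity rho."""
    if not 0.0 < rho < RHO_MAX:
        return -np.inf
    return float(_poisson_logpmf(data.fledglings, data.breeding_females * rho).sum())


def log_priors(state: IPMState) -> float:
    """Joint log prior of all parameters and initial populations.

    Truncated normals for every alpha component, Uniform(0, 10) for rho,
    discrete uniform {0..50} for both initial populations.  Each shared
    parameter is counted once (the monolithic-model convention).
    """
    lp = trunc_normal_logpdf(
        np.concatenate(
            [[state.alpha0, state.alpha1, state.alpha2, state.alpha4, state.alpha6], state.alpha5]
        )
    )
    lp += log_prior_rho(state.rho)
    if state.xJ is not None:
        lp += log_prior_initial_pop(state.xJ[0])
    if state.xA1 is not None:
        lp += log_prior_initial_pop(state.xA1)
    return float(lp)


# ---------------------------------------------------------------------------
# simulator


DEFAULT_TRUTH = dict(
    alpha0=-1.05,  # logit juvenile female survival ~ 0.26
    alpha1=0.2,    # male survival offset
    alpha2=1.3,    # adult effect: adult female survival ~ 0.56
    alpha4=-0.3,   # male recapture offset
    alpha6=-1.6,   # immigration rate ~ 0.20 per resident female
    rho=2.6,       # fledglings per breeding female
)


def simulate_ipm(
    truth: Optional[dict] = None,
    T: int = 15,
    releases_per_stratum: int = 50,
    initial_pops: tuple[int, int] = (20, 20),
    seed: int = 0,
) -> tuple[CRData, CountData, FecundityData, IPMState]:
    """Generate a full synthetic data triple from the exact likelihoods.

    Defaults mirror a small owl monitoring scheme: T years of annual
    surveys, ``releases_per_stratum`` tagged owls per age/sex/year, and
    initial juvenile/adult female populations around 20.  ``alpha5``
    defaults to a constant 0.5 (female recapture probability ~ 0.62).
    Breeding females are the total female population
    (``N_t = x_t``) and fledgling totals are Poisson with mean
    ``N_t rho``.  Returns the data triple and the true state (with the
    realised latent series) for parameter-recovery studies.
    """
    params = dict(DEFAULT_TRUTH)
    if truth:
        params.update(truth)
    alpha5 = params.pop("alpha5", np.full(T - 1, 0.5))
    state = IPMState(alpha5=np.asarray(alpha5, dtype=float), **params)
    if state.T != T:
        raise LayoutError("alpha5 length must be T - 1")
    rng = np.random.default_rng(seed)
    delta, pi, eta = link_rates(state, T)

    # capture-recapture
    Q = _all_cell_probs(delta, pi, T)
    m = np.zeros((2, 2, T, T + 1), dtype=np.int64)
    for ia in range(2):
        for isx in range(2):
            for t in range(T):
                m[ia, isx, t] = rng.multinomial(releases_per_stratum, Q[ia, isx, t])
    cr = CRData(m)

    # latent population and counts
    xJ = np.zeros(T, dtype=np.int64)
    sur = np.zeros(T - 1, dtype=np.int64)
    imm = np.zeros(T - 1, dtype=np.int64)
    xJ[0], xA1 = initial_pops
    xA = np.zeros(T, dtype=np.int64)
    xA[0] = xA1
    for t in range(1, T):
        xprev = xJ[t - 1] + xA[t - 1]
        xJ[t] = rng.poisson(xprev * (state.rho / 2.0) * delta[0, 1, t - 1])
        sur[t - 1] = rng.binomial(xprev, delta[1, 1, t - 1])
        imm[t - 1] = rng.poisson(xprev * eta[t])
        xA[t] = sur[t - 1] + imm[t - 1]
    x = xJ + xA
    counts = CountData(rng.poisson(x))

    # fecundity: breeding females = total females
    fledglings = rng.poisson(x * state.rho)
    fec = FecundityData(x.copy(), fledglings)

    state.xJ, state.xA1, state.sur, state.imm = xJ, int(xA1), sur, imm
    return cr, counts, fec, state


# ---------------------------------------------------------------------------
# chain assembly


PSI1_DIM = lambda T: 2 + (T - 1)  # noqa: E731  (alpha1, alpha4, alpha5_2..T)


def psi2_layout(T: int) -> dict[str, slice]:
    """Packing of the count submodel's idiosyncratic vector psi_2."""
    return {
        "alpha6": slice(0, 1),
        "xJ": slice(1, 1 + T),
        "xA1": slice(1 + T, 2 + T),
        "sur": slice(2 + T, 1 + 2 * T),
        "imm": slice(1 + 2 * T, 3 * T),
    }


def build_ipm_chain(
    cr: CRData,
    counts: CountData,
    fec: FecundityData,
    pooling: str = "log",
) -> tuple[ChainModel, PooledPrior]:
    """Wire the three owl submodels into a chain with a pooled prior.

    Shared slots: ``alpha02 = (alpha0, alpha2)`` between submodels 1 and 2
    and ``rho`` between submodels 2 and 3.  Since all submodels place the
    same independent priors on the shared quantities, logarithmic pooling
    with weights (1/2, 1/2, 1/2) reproduces those priors exactly and the
    melded model coincides with the monolithic IPM; product-of-experts
    pooling squares (and renormalises) the shared priors, concentrating
    them around zero; linear pooling with equal weights mixes identical
    densities and again reproduces the original priors.

    Returns the chain and the pooled prior decomposed with subprior sides,
    so stage one targets the ordinary subposteriors.
    """
    T = cr.T
    if counts.T != T or fec.T != T:
        raise LayoutError("data triple has inconsistent numbers of years")
    layout = PhiLayout(names=("alpha02", "rho"), dims=(2, 1))
    p2l = psi2_layout(T)

    # --- submodel 1: capture-recapture ---------------------------------
    # hot path: multinomial coefficients are data constants, and only the
    # cells with nonzero counts contribute log-probability terms
    _cr_const = float(gammaln(cr.releases + 1.0).sum() - gammaln(cr.m + 1.0).sum())
    _nz = np.where(cr.m > 0)
    _m_nz = cr.m[_nz].astype(float)
    _alpha_norm = -(np.log(ALPHA_SD) + 0.5 * _LOG2PI + _TRUNC_LOG_Z)

    def log_joint_1(phi: np.ndarray, psi: np.ndarray) -> float:
        alpha0, alpha2 = phi
        alpha1, alpha4 = psi[0], psi[1]
        alpha5 = psi[2:]
        av = np.concatenate([[alpha0, alpha2, alpha1, alpha4], alpha5])
        if np.any(np.abs(av) > ALPHA_BOUND):
            return -np.inf
        lp = float(-0.5 * np.sum((av / ALPHA_SD) ** 2)) + av.size * _alpha_norm
        delta = np.empty((2, 2, T))
        for ia in range(2):
            for isx in range(2):
                delta[ia, isx] = expit(alpha0 + alpha1 * (isx == 0) + alpha2 * (ia == 1))
        pi = np.full((2, T), np.nan)
        pi[0, 1:] = expit(alpha4 + alpha5)
        pi[1, 1:] = expit(alpha5)
        Q = _all_cell_probs(delta, pi, T)
        q = Q[_nz]
        if np.any(q <= 0.0):
            return -np.inf
        return lp + _cr_const + float(_m_nz @ np.log(q))

    def marg_1(phi: np.ndarray) -> float:
        return trunc_normal_logpdf(phi)

    sub1 = SubmodelSpec(1, log_joint_1, marg_1, ("alpha02",), (2,), psi_dim=2 + (T - 1))

    # --- submodel 2: counts ---------------------------------------------
    def log_joint_2(phi: np.ndarray, psi: np.ndarray) -> float:
        alpha0, alpha2, rho = phi
        alpha6 = psi[0]
        if not 0.0 < rho < RHO_MAX:
            return -np.inf
        if abs(alpha0) > ALPHA_BOUND or abs(alpha2) > ALPHA_BOUND or abs(alpha6) > ALPHA_BOUND:
            return -np.inf
        lp = (
            -0.5 * (alpha0**2 + alpha2**2 + alpha6**2) / ALPHA_SD**2
            + 3.0 * _alpha_norm
            - np.log(RHO_MAX)
        )
        xJ = psi[p2l["xJ"]]
        xA1 = psi[p2l["xA1"]][0]
        lp += log_prior_initial_pop(xJ[0]) + log_prior_initial_pop(xA1)
        if lp == -np.inf:
            return -np.inf
        delta = np.empty((2, 2, T))
        delta[0, 1] = expit(alpha0)
        delta[1, 1] = expit(alpha0 + alpha2)
        delta[0, 0] = delta[0, 1]
        delta[1, 0] = delta[1, 1]
        eta = np.full(T, np.exp(alpha6))
        return lp + count_loglik(
            counts, xJ, int(xA1), psi[p2l["sur"]], psi[p2l["imm"]], rho, delta, eta
        )

    def marg_2(phi: np.ndarray) -> float:
        return trunc_normal_logpdf(phi[:2]) + log_prior_rho(phi[2])

    sub2 = SubmodelSpec(2, log_joint_2, marg_2, ("alpha02", "rho"), (2, 1), psi_dim=3 * T)

    # --- submodel 3: fecundity ------------------------------------------
    def log_joint_3(phi: np.ndarray, psi: np.ndarray) -> float:
        rho = phi[0]
        lp = log_prior_rho(rho)
        return lp + fecundity_loglik(fec, rho) if lp > -np.inf else -np.inf

    def marg_3(phi: np.ndarray) -> float:
        return log_prior_rho(phi[0])

    # direct subposterior sampler: conjugate truncated Gamma
    from scipy.stats import gamma as _gamma

    shape_post = 1.0 + fec.fledglings.sum()
    rate_post = float(fec.breeding_females.sum())

    def sampler_3(rng: np.random.Generator, n: int):
        lo = _gamma.cdf(0.0, shape_post, scale=1.0 / rate_post)
        hi = _gamma.cdf(RHO_MAX, shape_post, scale=1.0 / rate_post)
        u = lo + (hi - lo) * rng.random(n)
        rho = _gamma.ppf(u, shape_post, scale=1.0 / rate_post)
        return rho[:, None], np.empty((n, 0))

    sub3 = SubmodelSpec(3, log_joint_3, marg_3, ("rho",), (1,), psi_dim=0, sampler=sampler_3)

    chain = ChainModel([sub1, sub2, sub3])

    # --- pooled prior ---------------------------------------------------
    def comp_alpha(x):
        return trunc_normal_logpdf(x)

    def comp_rho(x):
        return log_prior_rho(x[0])

    c1 = DensityComponent(comp_alpha, ("alpha02",), dim=2)
    c2 = DensityComponent(lambda v: comp_alpha(v[:2]) + comp_rho(v[2:]), ("alpha02", "rho"), dim=3)
    c3 = DensityComponent(comp_rho, ("rho",), dim=1)

    if pooling in ("log", "poe"):
        lam = np.full(3, 0.5) if pooling == "log" else np.ones(3)
        pooled = pool_log([c1, c2, c3], lam, layout, check_sum_constraint=False)
    elif pooling == "linear":
        c2_alpha = DensityComponent(comp_alpha, ("alpha02",), dim=2)
        c2_rho = DensityComponent(comp_rho, ("rho",), dim=1)
        pooled = pool_linear(
            [(c1, c2_alpha), (c2_rho, c3)], np.full((2, 2), 0.5), layout
        )
    else:
        raise LayoutError(f"unknown pooling choice {pooling!r}; use 'log', 'poe' or 'linear'")

    pooled = decompose_pooled(pooled, "subprior-sides", (c1, c3))
    return chain, pooled
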