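"""Pooled priors over the shared quantities of a submodel chain.

A chain of ``M`` submodels needs a single joint prior ``p_pool(phi)`` over
the concatenated shared vector ``phi = (phi_{1∩2}, ..., phi_{M-1∩M})``.
Each submodel only specifies a prior marginal for the shared quantities it
actually contains, so the classic opinion-pooling operators have to be
generalised before they apply.  This module implements the four chained
operators:

``pool_log``
    Chained logarithmic pooling: ``p_pool(phi) ∝ prod_m p_m(phi_m)^{lam_m}``.
    With all weights equal to one this is product-of-experts (PoE) pooling.
    Correlation between overlap components inside a single submodel's prior
    is retained.
``pool_linear``
    Chained linear pooling: per overlap, a two-component mixture of the two
    adjacent submodels' marginals; the pooled prior is the product of these
    intermediaries, so distinct overlap components are independent.
``pool_dictatorial_partial``
    One submodel's joint prior is authoritative for its own shared
    quantities; the remaining components are pooled by a standard operator
    on each side.
``pool_dictatorial_complete``
    Every overlap component is assigned to exactly one of its two adjacent
    submodels; consecutive components assigned to the same submodel keep
    that submodel's joint dependence.

All densities are handled in log space and may be unnormalised: the
normalising constants cancel in every Metropolis--Hastings ratio the
samplers form.  Quadrature-based normalisation and moment diagnostics are
available for problems of dimension <= 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import quad, simpson

from .errors import (
    DegeneratePoolingError,
    ImproperPooledPriorError,
    InvalidWeightsError,
    LayoutError,
    SupportMismatchError,
)
from .phi import PhiLayout

__all__ = [
    "DensityComponent",
    "WeightVector",
    "PooledPrior",
    "SubmodelPrior",
    "gaussian_component",
    "marginal_via_quadrature",
    "pool_log",
    "pool_linear",
    "pool_dictatorial_partial",
    "pool_dictatorial_complete",
    "decompose_pooled",
    "gaussian_pool_closed_form",
    "grid_table",
    "normalise_on_grid",
    "grid_moments_2d",
]


# ---------------------------------------------------------------------------
# density components


@dataclass
class DensityComponent:
    """A log-density over a declared subset of the shared vector.

    Parameters
    ----------
    logpdf
        Maps the subvector covering ``blocks`` (1-D ndarray) to a float.
        May be unnormalised.
    blocks
        Names of the overlap blocks this component covers, in layout order.
    support
        Optional per-coordinate ``(lo, hi)`` intervals.  The evaluator
        returns ``-inf`` outside the declared support without calling
        ``logpdf``.
    proper
        Whether the component integrates to one over its support.
    sampler
        Optional ``sampler(rng, n) -> (n, d)`` draws; used to build exact
        samplers for mixture-structured pooled priors.
    """

    logpdf: Callable[[np.ndarray], float]
    blocks: tuple[str, ...]
    support: Optional[tuple[tuple[float, float], ...]] = None
    proper: bool = True
    sampler: Optional[Callable] = None
    dim: Optional[int] = None

    def __call__(self, x: np.ndarray) -> float:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        if self.support is not None:
            for xi, (lo, hi) in zip(x, self.support):
                if xi < lo or xi > hi:
                    return -np.inf
        return float(self.logpdf(x))


def gaussian_component(
    mean,
    cov,
    blocks: tuple[str, ...],
    rng_samplable: bool = True,
) -> DensityComponent:
    """A (multivariate) normal :class:`DensityComponent` with exact sampler."""
    mean = np.atleast_1d(np.asarray(mean, dtype=float))
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    prec = np.linalg.inv(cov)
    _, logdet = np.linalg.slogdet(cov)
    const = -0.5 * (mean.size * np.log(2.0 * np.pi) + logdet)

    def logpdf(x: np.ndarray) -> float:
        d = x - mean
        return const - 0.5 * float(d @ prec @ d)

    sampler = None
    if rng_samplable:
        chol = np.linalg.cholesky(cov)

        def sampler(rng: np.random.Generator, n: int) -> np.ndarray:
            z = rng.standard_normal((n, mean.size))
            return mean + z @ chol.T

    return DensityComponent(logpdf=logpdf, blocks=blocks, sampler=sampler, dim=mean.size)


@dataclass
class SubmodelPrior:
    """A submodel's prior over its shared quantities, joint and marginals.

    ``joint`` covers all of the submodel's overlap blocks; ``marginals``
    holds one single-block component per overlap.  For interior submodels
    whose joint prior does not factorise, the marginalisation
    ``p_m(phi_{m∩m+1}) = ∫ p_m(phi_{m-1∩m}, phi_{m∩m+1}) d phi_{m-1∩m}``
    must be supplied in closed form or obtained by 1-D quadrature
    (:func:`marginal_via_quadrature`); it is never estimated from draws.
    """

    index: int
    joint: DensityComponent
    marginals: dict[str, DensityComponent] = field(default_factory=dict)

    @classmethod
    def from_independent(cls, index: int, marginals: dict[str, DensityComponent]) -> "SubmodelPrior":
        """Build the joint as the product of independent per-block marginals."""
        names = tuple(marginals.keys())
        dims = [1] * len(names)  # refined below if components declare support
        comps = list(marginals.values())

        def logpdf(x: np.ndarray) -> float:
            total, i = 0.0, 0
            for c in comps:
                d = _component_dim(c)
                total += c(x[i : i + d])
                i += d
            return total

        joint = DensityComponent(logpdf=logpdf, blocks=names)
        del dims
        return cls(index=index, joint=joint, marginals=dict(marginals))


def _component_dim(c: DensityComponent) -> int:
    if c.dim is not None:
        return c.dim
    if c.support is not None:
        return len(c.support)
    return 1


def marginal_via_quadrature(
    joint: DensityComponent,
    keep: str,
    integrate_support: tuple[float, float],
    keep_first: Optional[bool] = None,
) -> DensityComponent:
    """Integrate a two-block, 1-D-per-block joint down to one block.

    Performs the marginalisation of an interior submodel's joint prior by
    adaptive 1-D quadrature on the declared support of the integrated-out
    coordinate.  Intended for diagnostics and small examples.
    """
    if len(joint.blocks) != 2:
        raise LayoutError("quadrature marginalisation needs a two-block joint")
    if keep not in joint.blocks:
        raise LayoutError(f"{keep!r} is not a block of {joint.blocks}")
    if keep_first is None:
        keep_first = joint.blocks[0] == keep
    lo, hi = integrate_support

    def logpdf(x: np.ndarray) -> float:
        xk = float(x[0])

        def integrand(y: float) -> float:
            pt = np.array([xk, y]) if keep_first else np.array([y, xk])
            return np.exp(joint(pt))

        val, _ = quad(integrand, lo, hi, limit=200)
        return np.log(val) if val > 0 else -np.inf

    return DensityComponent(logpdf=logpdf, blocks=(keep,), proper=joint.proper)


# ---------------------------------------------------------------------------
# weights


@dataclass
class WeightVector:
    """Nonnegative pooling weights.

    ``mode='log'`` (also dictatorial sides): one weight per submodel.
    ``mode='linear'``: one ``(lam_{m,1}, lam_{m,2})`` pair per overlap.
    """

    values: np.ndarray
    mode: str = "log"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.mode not in ("log", "linear"):
            raise InvalidWeightsError(f"unknown weight mode {self.mode!r}")
        if np.any(self.values < 0):
            raise InvalidWeightsError(f"negative pooling weight in {self.values}")
        if self.mode == "log":
            if self.values.ndim != 1:
                raise InvalidWeightsError("log-mode weights must be a flat vector")
            if np.all(self.values == 0):
                raise DegeneratePoolingError("all logarithmic pooling weights are zero")
        else:
            if self.values.ndim != 2 or self.values.shape[1] != 2:
                raise InvalidWeightsError("linear-mode weights must be (n_overlaps, 2) pairs")
            if np.any(self.values.sum(axis=1) == 0):
                raise DegeneratePoolingError("a linear pooling weight pair sums to zero")

    def validate_sum_constraint(self) -> None:
        """Warn if sum(lam) < 1; propriety of the log-pooled prior may fail."""
        if self.mode == "log" and self.values.sum() < 1.0:
            warnings.warn(
                "logarithmic pooling weights sum to "
                f"{self.values.sum():.3g} < 1; the pooled prior may be improper",
                stacklevel=3,
            )


def _as_weights(weights, mode: str, n: int) -> WeightVector:
    if not isinstance(weights, WeightVector):
        weights = WeightVector(np.asarray(weights, dtype=float), mode=mode)
    if weights.mode != mode:
        raise InvalidWeightsError(f"expected {mode}-mode weights, got {weights.mode}")
    expected = n if mode == "log" else (n, 2)
    if weights.values.shape != ((expected,) if mode == "log" else expected):
        raise InvalidWeightsError(
            f"weights have shape {weights.values.shape}, expected {expected}"
        )
    return weights


# ---------------------------------------------------------------------------
# pooled prior container


@dataclass
class PooledPrior:
    """Joint log-density over the full shared vector plus its decomposition.

    The three-factor decomposition ``p_pool = p_pool,1(phi_{1∩2}) *
    p_pool,2(phi_{1∩2}, phi_{2∩3}) * p_pool,3(phi_{2∩3})`` is what the
    two-stage sampler consumes (only defined for two-overlap chains); the
    joint evaluator equals the sum of the three log-factors at every point.
    """

    layout: PhiLayout
    log_density: Callable[[np.ndarray], float]
    left: Optional[Callable[[np.ndarray], float]] = None
    middle: Optional[Callable[[np.ndarray, np.ndarray], float]] = None
    right: Optional[Callable[[np.ndarray], float]] = None
    normalised: bool = False
    improper_factors: tuple[str, ...] = ()
    sampler: Optional[Callable] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.layout.n_overlaps == 2 and self.middle is None:
            self._attach_flat_decomposition()

    def _attach_flat_decomposition(self) -> None:
        joint, layout = self.log_density, self.layout

        def middle(a: np.ndarray, b: np.ndarray) -> float:
            return joint(np.concatenate([np.atleast_1d(a), np.atleast_1d(b)]))

        self.left = lambda a: 0.0
        self.right = lambda b: 0.0
        self.middle = middle
        self.improper_factors = ("left", "right")
        del layout

    def __call__(self, phi: np.ndarray) -> float:
        return float(self.log_density(np.atleast_1d(np.asarray(phi, dtype=float))))

    def split(self, phi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Split a full phi vector into (first-overlap, last-overlap) parts."""
        if self.layout.n_overlaps != 2:
            raise LayoutError("split is defined for two-overlap chains only")
        phi = np.atleast_1d(np.asarray(phi, dtype=float))
        return (
            phi[self.layout.slice_of(self.layout.names[0])],
            phi[self.layout.slice_of(self.layout.names[1])],
        )

    def decomposition_log_density(self, phi: np.ndarray) -> float:
        """Sum of the three decomposition factors at ``phi``."""
        if self.middle is None:
            raise LayoutError("no decomposition attached")
        a, b = self.split(phi)
        return float(self.left(a) + self.middle(a, b) + self.right(b))

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.sampler is None:
            raise NotImplementedError("this pooled prior has no exact sampler")
        return self.sampler(rng, n)


# ---------------------------------------------------------------------------
# pooling operators


def pool_log(
    marginals: Sequence[DensityComponent],
    weights,
    layout: PhiLayout,
    check_sum_constraint: bool = True,
) -> PooledPrior:
    """Chained logarithmic pooling: ``log p_pool = sum_m lam_m log p_m(phi_m)``.

    ``marginals[m]`` is submodel ``m+1``'s prior over its own shared blocks.
    With all weights 1 this is product-of-experts pooling.  Any correlation
    between overlap components inside an interior submodel's prior carries
    through to the pooled prior.
    """
    w = _as_weights(weights, "log", len(marginals))
    if check_sum_constraint:
        w.validate_sum_constraint()
    lam = w.values
    comps = list(marginals)

    def log_density(phi: np.ndarray) -> float:
        total = 0.0
        for lam_m, comp in zip(lam, comps):
            if lam_m == 0.0:
                continue
            lp = comp(layout.extract(phi, comp.blocks))
            if lp == -np.inf:
                return -np.inf
            total += lam_m * lp
        return total

    return PooledPrior(
        layout=layout,
        log_density=log_density,
        meta={"operator": "log", "weights": lam.copy()},
    )


def pool_linear(
    adjacent_marginals: Sequence[tuple[DensityComponent, DensityComponent]],
    weights,
    layout: PhiLayout,
) -> PooledPrior:
    """Chained linear pooling: per-overlap mixtures, multiplied together.

    ``adjacent_marginals[k]`` holds the two single-block marginals of
    overlap ``k`` (from submodels ``k+1`` and ``k+2``); any required
    marginalisation of an interior joint prior must already have been
    applied.  The result makes all overlap components mutually independent.
    """
    if len(adjacent_marginals) != layout.n_overlaps:
        raise LayoutError(
            f"need one marginal pair per overlap ({layout.n_overlaps}), got {len(adjacent_marginals)}"
        )
    w = _as_weights(weights, "linear", len(adjacent_marginals))
    lam = w.values
    pairs = [tuple(p) for p in adjacent_marginals]
    for k, (a, b) in enumerate(pairs):
        want = (layout.names[k],)
        if a.blocks != want or b.blocks != want:
            raise LayoutError(
                f"overlap {layout.names[k]!r} marginals must cover exactly that block"
            )

    with np.errstate(divide="ignore"):
        log_lam = np.log(lam)

    def log_density(phi: np.ndarray) -> float:
        total = 0.0
        for k, (a, b) in enumerate(pairs):
            x = phi[layout.slice_of(layout.names[k])]
            total += np.logaddexp(log_lam[k, 0] + a(x), log_lam[k, 1] + b(x))
        if np.isnan(total):
            return -np.inf
        return float(total)

    sampler = None
    if all(a.sampler is not None and b.sampler is not None for a, b in pairs):
        probs = lam / lam.sum(axis=1, keepdims=True)

        def sampler(rng: np.random.Generator, n: int) -> np.ndarray:
            out = np.empty((n, layout.total_dim))
            for k, (a, b) in enumerate(pairs):
                sl = layout.slice_of(layout.names[k])
                pick = rng.random(n) < probs[k, 0]
                da = a.sampler(rng, n)
                db = b.sampler(rng, n)
                out[:, sl] = np.where(pick[:, None], da, db)
            return out

    return PooledPrior(
        layout=layout,
        log_density=log_density,
        sampler=sampler,
        meta={"operator": "linear", "weights": lam.copy()},
    )


def pool_dictatorial_partial(
    chain_priors: Sequence[SubmodelPrior],
    authoritative_index: int,
    layout: PhiLayout,
    side_pooling_modes: tuple[str, str] = ("log", "log"),
    side_weights: tuple[Optional[np.ndarray], Optional[np.ndarray]] = (None, None),
) -> PooledPrior:
    """Partial dictatorial pooling: one submodel's joint prior is verbatim.

    The authoritative submodel ``m`` (1-based) supplies
    ``p_m(phi_{m-1∩m}, phi_{m∩m+1})`` exactly; overlaps strictly to its
    left/right are pooled among the remaining submodels' marginals with the
    requested standard operator.  For ``M = 3`` with ``m = 2`` both sides
    are vacuous and the result is ``p_2`` exactly.
    """
    M = len(chain_priors)
    if not (1 <= authoritative_index <= M):
        raise LayoutError(f"authoritative index {authoritative_index} out of range 1..{M}")
    m = authoritative_index
    middle_comp = chain_priors[m - 1].joint
    middle_blocks = middle_comp.blocks

    side_factors: list[PooledPrior] = []
    for side, mode in zip(("left", "right"), side_pooling_modes):
        if side == "left":
            overlap_names = [n for n in layout.names if n not in middle_blocks and layout.index(n) < layout.index(middle_blocks[0])]
            members = chain_priors[: m - 1]
        else:
            overlap_names = [n for n in layout.names if n not in middle_blocks and layout.index(n) > layout.index(middle_blocks[-1])]
            members = chain_priors[m:]
        if not overlap_names:
            side_factors.append(None)
            continue
        sub_layout = PhiLayout(
            names=tuple(overlap_names),
            dims=tuple(layout.dims[layout.index(n)] for n in overlap_names),
        )
        if mode == "log":
            comps = [
                sp.joint if len(sp.joint.blocks) > 1 else sp.joint
                for sp in members
                if all(b in overlap_names for b in sp.joint.blocks)
            ]
            # fall back to marginals of boundary submodels whose joint leaks
            # into the authoritative blocks
            for sp in members:
                if not all(b in overlap_names for b in sp.joint.blocks):
                    for b, comp in sp.marginals.items():
                        if b in overlap_names:
                            comps.append(comp)
            wts = side_weights[0 if side == "left" else 1]
            wts = np.ones(len(comps)) if wts is None else np.asarray(wts, float)
            side_factors.append(pool_log(comps, wts, sub_layout, check_sum_constraint=False))
        elif mode == "linear":
            pairs = []
            for name in overlap_names:
                k = layout.index(name)  # overlap k joins submodels k+1, k+2
                pairs.append(
                    (chain_priors[k].marginals[name], chain_priors[k + 1].marginals[name])
                )
            wts = side_weights[0 if side == "left" else 1]
            wts = np.ones((len(pairs), 2)) if wts is None else np.asarray(wts, float)
            side_factors.append(pool_linear(pairs, wts, sub_layout))
        else:
            raise InvalidWeightsError(f"unknown side pooling mode {mode!r}")

    left_pool, right_pool = side_factors

    def log_density(phi: np.ndarray) -> float:
        total = middle_comp(layout.extract(phi, middle_blocks))
        for pool in (left_pool, right_pool):
            if pool is not None:
                total += pool(layout.extract(phi, pool.layout.names))
        return float(total)

    return PooledPrior(
        layout=layout,
        log_density=log_density,
        meta={"operator": "dictatorial-partial", "authoritative": m},
    )


def pool_dictatorial_complete(
    chain_priors: Sequence[SubmodelPrior],
    selections: Sequence[int],
    layout: PhiLayout,
) -> PooledPrior:
    """Complete dictatorial pooling: one submodel prior per overlap component.

    ``selections[k]`` (1-based submodel index) must be one of the two
    submodels adjacent to overlap ``k``.  When consecutive overlaps are both
    assigned to the submodel containing both, the two single-component
    marginals are merged into that submodel's joint prior, retaining its
    dependence.
    """
    n = layout.n_overlaps
    if len(selections) != n:
        raise LayoutError(f"need one selection per overlap ({n}), got {len(selections)}")
    for k, s in enumerate(selections):
        if s not in (k + 1, k + 2):
            raise LayoutError(
                f"selection for overlap {layout.names[k]!r} must be submodel "
                f"{k + 1} or {k + 2}, got {s}"
            )

    factors: list[tuple[DensityComponent, tuple[str, ...]]] = []
    k = 0
    while k < n:
        s = selections[k]
        # overlaps k and k+1 both assigned to submodel k+2, which contains both
        if k + 1 < n and s == k + 2 and selections[k + 1] == k + 2:
            sp = chain_priors[s - 1]
            factors.append((sp.joint, (layout.names[k], layout.names[k + 1])))
            k += 2
        else:
            sp = chain_priors[s - 1]
            comp = sp.marginals.get(layout.names[k])
            if comp is None:
                raise LayoutError(
                    f"submodel {s} supplies no marginal for {layout.names[k]!r}"
                )
            factors.append((comp, (layout.names[k],)))
            k += 1

    def log_density(phi: np.ndarray) -> float:
        total = 0.0
        for comp, blocks in factors:
            total += comp(layout.extract(phi, blocks))
        return float(total)

    return PooledPrior(
        layout=layout,
        log_density=log_density,
        meta={"operator": "dictatorial-complete", "selections": tuple(selections)},
    )


# ---------------------------------------------------------------------------
# decomposition


def decompose_pooled(
    pooled: PooledPrior,
    mode: str = "flat-sides",
    side_priors: Optional[tuple[DensityComponent, DensityComponent]] = None,
) -> PooledPrior:
    """Attach the three-factor decomposition the two-stage sampler needs.

    ``flat-sides``
        ``p_pool,1`` and ``p_pool,3`` are (improper) flat factors; the
        middle factor carries the whole pooled density.
    ``subprior-sides``
        ``p_pool,1 = p_1(phi_{1∩2})`` and ``p_pool,3 = p_3(phi_{2∩3})``
        (the supplied side priors), so the stage-one targets are the
        ordinary subposteriors; the middle factor is the pooled density
        divided by the two side factors.
    """
    if pooled.layout.n_overlaps != 2:
        raise LayoutError("the three-factor decomposition needs exactly two overlaps")
    joint = pooled.log_density
    layout = pooled.layout
    if mode == "flat-sides":
        out = PooledPrior(
            layout=layout,
            log_density=joint,
            normalised=pooled.normalised,
            sampler=pooled.sampler,
            meta=dict(pooled.meta),
        )
        return out
    if mode != "subprior-sides":
        raise LayoutError(f"unknown decomposition mode {mode!r}")
    if side_priors is None:
        raise LayoutError("subprior-sides decomposition requires the two side priors")
    left_prior, right_prior = side_priors

    def left(a: np.ndarray) -> float:
        return left_prior(a)

    def right(b: np.ndarray) -> float:
        return right_prior(b)

    def middle(a: np.ndarray, b: np.ndarray) -> float:
        phi = np.concatenate([np.atleast_1d(a), np.atleast_1d(b)])
        lj = joint(phi)
        if lj == -np.inf:
            return -np.inf
        la, lb = left_prior(a), right_prior(b)
        if la == -np.inf or lb == -np.inf:
            raise SupportMismatchError(
                "side prior is zero where the pooled prior is positive "
                "(division by zero in the middle factor)"
            )
        return lj - la - lb

    return PooledPrior(
        layout=layout,
        log_density=joint,
        left=left,
        middle=middle,
        right=right,
        normalised=pooled.normalised,
        improper_factors=(),
        sampler=pooled.sampler,
        meta=dict(pooled.meta),
    )


# ---------------------------------------------------------------------------
# Gaussian closed form


def gaussian_pool_closed_form(
    gaussian_components: Sequence[tuple[np.ndarray, np.ndarray, tuple[str, ...]]],
    weights,
    layout: PhiLayout,
):
    """Exact logarithmic pooling of Gaussian prior marginals.

    Each component is ``(mean, cov, blocks)``.  Weighted precisions are
    scattered into the full phi coordinates and added:

    ``P = sum_m lam_m S_m' Sigma_m^{-1} S_m``,
    ``P mu = sum_m lam_m S_m' Sigma_m^{-1} mu_m``,

    where ``S_m`` selects submodel ``m``'s blocks.  Returns a
    :class:`~chainmeld.gaussian_meld.GaussianSummary`; raises
    :class:`ImproperPooledPriorError` when the pooled precision is not
    positive definite (the pooled prior would not be integrable).
    """
    from .gaussian_meld import GaussianSummary

    w = _as_weights(weights, "log", len(gaussian_components))
    lam = w.values
    D = layout.total_dim
    P = np.zeros((D, D))
    h = np.zeros(D)
    for lam_m, (mean, cov, blocks) in zip(lam, gaussian_components):
        if lam_m == 0.0:
            continue
        mean = np.atleast_1d(np.asarray(mean, dtype=float))
        cov = np.atleast_2d(np.asarray(cov, dtype=float))
        idx = np.concatenate(
            [np.arange(layout.slice_of(b).start, layout.slice_of(b).stop) for b in blocks]
        )
        prec = np.linalg.inv(cov)
        P[np.ix_(idx, idx)] += lam_m * prec
        h[idx] += lam_m * prec @ mean
    eigvals = np.linalg.eigvalsh(P)
    if eigvals.min() <= 0:
        raise ImproperPooledPriorError(
            f"pooled precision not positive definite (min eigenvalue {eigvals.min():.3g})"
        )
    cov_pool = np.linalg.inv(P)
    cov_pool = 0.5 * (cov_pool + cov_pool.T)
    return GaussianSummary(mean=cov_pool @ h, cov=cov_pool, label="pooled")


# ---------------------------------------------------------------------------
# grid diagnostics (dimension <= 2)


def _grid_axes(ranges: Sequence[tuple[float, float]], n: int) -> list[np.ndarray]:
    return [np.linspace(lo, hi, n) for lo, hi in ranges]


def _grid_logdensity(log_density, ranges, n):
    axes = _grid_axes(ranges, n)
    if len(axes) == 1:
        vals = np.array([log_density(np.array([x])) for x in axes[0]])
    elif len(axes) == 2:
        vals = np.array(
            [[log_density(np.array([x, y])) for y in axes[1]] for x in axes[0]]
        )
    else:
        raise LayoutError("grid diagnostics support dimension <= 2 only")
    return axes, vals


def grid_table(
    log_density: Callable[[np.ndarray], float],
    ranges: Sequence[tuple[float, float]],
    n: int = 201,
) -> pd.DataFrame:
    """Flat table of log-density values on a regular grid (<= 2-D)."""
    axes, vals = _grid_logdensity(log_density, ranges, n)
    if len(axes) == 1:
        return pd.DataFrame({"x1": axes[0], "log_density": vals})
    xx, yy = np.meshgrid(axes[0], axes[1], indexing="ij")
    return pd.DataFrame(
        {"x1": xx.ravel(), "x2": yy.ravel(), "log_density": vals.ravel()}
    )


def normalise_on_grid(
    log_density: Callable[[np.ndarray], float],
    ranges: Sequence[tuple[float, float]],
    n: int = 201,
) -> tuple[float, list[np.ndarray], np.ndarray]:
    """Log normalising constant by Simpson quadrature on a regular grid.

    Returns ``(log_K, axes, log_values)`` so the normalised log-density on
    the grid is ``log_values - log_K``.
    """
    axes, vals = _grid_logdensity(log_density, ranges, n)
    shift = vals.max()
    dens = np.exp(vals - shift)
    if len(axes) == 1:
        integral = simpson(dens, x=axes[0])
    else:
        integral = simpson(simpson(dens, x=axes[1], axis=1), x=axes[0])
    return float(np.log(integral) + shift), axes, vals


def grid_moments_2d(
    log_density: Callable[[np.ndarray], float],
    ranges: Sequence[tuple[float, float]],
    n: int = 201,
) -> dict:
    """Mean, covariance and correlation of a 2-D density via grid quadrature."""
    log_k, axes, vals = normalise_on_grid(log_density, ranges, n)
    dens = np.exp(vals - log_k)
    x, y = axes
    def integ2(f):
        return simpson(simpson(f, x=y, axis=1), x=x)
    xx, yy = np.meshgrid(x, y, indexing="ij")
    mx = integ2(dens * xx)
    my = integ2(dens * yy)
    vx = integ2(dens * (xx - mx) ** 2)
    vy = integ2(dens * (yy - my) ** 2)
    cxy = integ2(dens * (xx - mx) * (yy - my))
    corr = cxy / np.sqrt(vx * vy)
    return {
        "mean": np.array([mx, my]),
        "cov": np.array([[vx, cxy], [cxy, vy]]),
        "corr": float(corr),
        "log_norm_const": log_k,
    }
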