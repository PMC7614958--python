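"""Chains of Bayesian submodels and the chained melded model.

A submodel ``m`` of a chain contributes a joint density
``p_m(phi_m, psi_m, Y_m)`` over its shared quantities ``phi_m`` and
idiosyncratic parameters ``psi_m`` (the data are baked into the
evaluator), together with its prior marginal ``p_m(phi_m)``.  Adjacent
submodels share one overlap block; non-adjacent submodels share nothing.

Marginal replacement swaps a submodel's prior marginal for the pooled
prior:

    p_repl,m(phi, psi_m, Y_m) = p_pool(phi) p_m(phi_m, psi_m, Y_m) / p_m(phi_m)

which is the KL-closest modification of ``p_m`` whose phi-marginal is the
pooled prior.  The Markov combination of the replaced submodels is the
chained melded model:

    p_meld(phi, psi, Y) = p_pool(phi) prod_m p_m(phi_m, psi_m, Y_m) / p_m(phi_m)

whose posterior the samplers module targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .errors import ChainValidationError, LayoutError, SupportMismatchError
from .phi import PhiLayout
from .pooling import PooledPrior

__all__ = [
    "SubmodelSpec",
    "ChainModel",
    "MeldedModel",
    "marginal_replace",
    "melded_log_density",
    "validate_chain",
]


@dataclass
class SubmodelSpec:
    """One link of the chain.

    Parameters
    ----------
    index
        1-based position in the chain.
    log_joint
        ``log p_m(phi_m, psi_m, Y_m)`` with the data baked in; takes the
        submodel's own shared subvector and its psi vector.  Must not
        depend on any shared component outside ``phi_m``.
    log_phi_marginal
        ``log p_m(phi_m)``: the submodel's prior marginal over its shared
        quantities, in closed (or user-fitted parametric) form.  The
        library never estimates it from draws.
    blocks
        Names of the overlap blocks this submodel touches: one for the two
        chain ends, two (left, right) for interior submodels.
    block_dims
        Dimension of each named block.
    psi_dim
        Dimension of the idiosyncratic parameter vector (0 allowed).
    sampler
        Optional direct subposterior sampler
        ``sampler(rng, n) -> (phi draws (n, d_phi), psi draws (n, psi_dim))``
        used by stage one in place of MCMC when available.
    """

    index: int
    log_joint: Callable[[np.ndarray, np.ndarray], float]
    log_phi_marginal: Callable[[np.ndarray], float]
    blocks: tuple[str, ...]
    block_dims: tuple[int, ...]
    psi_dim: int = 0
    sampler: Optional[Callable] = None

    @property
    def phi_dim(self) -> int:
        return int(sum(self.block_dims))


@dataclass
class ChainModel:
    """An ordered chain of ``M >= 3`` submodels with its phi layout."""

    submodels: Sequence[SubmodelSpec]
    layout: PhiLayout = field(init=False)

    def __post_init__(self) -> None:
        report = validate_chain(self.submodels, raise_on_fatal=True)
        assert not report  # fatal issues raise inside validate_chain
        self.layout = chain_layout(self.submodels)

    @property
    def M(self) -> int:
        return len(self.submodels)

    def phi_m(self, phi: np.ndarray, m: int) -> np.ndarray:
        """Submodel ``m``'s (1-based) shared subvector of the full phi."""
        return self.layout.extract(phi, self.submodels[m - 1].blocks)


def chain_layout(submodels: Sequence[SubmodelSpec]) -> PhiLayout:
    names, dims = [], []
    for m, sub in enumerate(submodels[:-1], start=1):
        right = sub.blocks[-1]
        names.append(right)
        dims.append(sub.block_dims[-1])
        del m
    return PhiLayout(names=tuple(names), dims=tuple(dims))


def validate_chain(
    submodels: Sequence[SubmodelSpec], raise_on_fatal: bool = False
) -> list[str]:
    """Check the adjacency/slot contract; return a list of issues.

    Fatal violations (wrong block counts, non-adjacent sharing, slot
    dimension mismatches, duplicate overlap names) raise
    :class:`ChainValidationError` when ``raise_on_fatal`` is true.
    """
    issues: list[str] = []
    M = len(submodels)
    if M < 3:
        issues.append(f"chain needs at least 3 submodels, got {M}")
    for pos, sub in enumerate(submodels, start=1):
        if sub.index != pos:
            issues.append(f"submodel at position {pos} declares index {sub.index}")
        expected_n = 1 if pos in (1, M) else 2
        if len(sub.blocks) != expected_n:
            issues.append(
                f"submodel {pos} declares {len(sub.blocks)} overlap blocks, expected {expected_n}"
            )
        if len(sub.blocks) != len(sub.block_dims):
            issues.append(f"submodel {pos}: blocks and block_dims lengths differ")
    # adjacency: right block of m must be the left block of m+1, with equal dims
    for pos in range(1, M):
        a, b = submodels[pos - 1], submodels[pos]
        if not a.blocks or not b.blocks:
            continue
        if a.blocks[-1] != b.blocks[0]:
            issues.append(
                f"submodels {pos} and {pos + 1} disagree on their overlap "
                f"({a.blocks[-1]!r} vs {b.blocks[0]!r})"
            )
        elif a.block_dims[-1] != b.block_dims[0]:
            issues.append(
                f"overlap {a.blocks[-1]!r} has dimension {a.block_dims[-1]} in "
                f"submodel {pos} but {b.block_dims[0]} in submodel {pos + 1}"
            )
    # non-adjacent sharing / duplicated overlap names
    overlap_names = [s.blocks[-1] for s in submodels[:-1] if s.blocks]
    if len(set(overlap_names)) != len(overlap_names):
        issues.append(f"duplicated overlap names across the chain: {overlap_names}")
    for pos, sub in enumerate(submodels, start=1):
        allowed = set()
        if pos > 1:
            allowed.add(submodels[pos - 2].blocks[-1])
        if pos < M:
            allowed.add(sub.blocks[-1])
        extra = [b for b in sub.blocks if b not in allowed and b not in overlap_names]
        stray = [
            b
            for b in sub.blocks
            if b in overlap_names and b not in allowed
        ]
        if stray:
            issues.append(
                f"submodel {pos} shares {stray} with a non-adjacent submodel"
            )
        del extra
    if raise_on_fatal and issues:
        raise ChainValidationError("; ".join(issues))
    return issues


def marginal_replace(
    sub: SubmodelSpec, pooled: PooledPrior
) -> Callable[[np.ndarray, np.ndarray], float]:
    """The marginally replaced submodel's log-density over (phi, psi_m).

    ``log p_repl,m = log p_pool(phi) + log p_m(phi_m, psi_m, Y_m) - log p_m(phi_m)``.
    Raises :class:`SupportMismatchError` if the submodel's prior marginal
    vanishes at a point where the pooled prior places mass.
    """
    layout = pooled.layout

    def log_density(phi: np.ndarray, psi_m: np.ndarray) -> float:
        phi = np.atleast_1d(np.asarray(phi, dtype=float))
        lpool = pooled(phi)
        if lpool == -np.inf:
            return -np.inf
        phi_m = layout.extract(phi, sub.blocks)
        lmarg = sub.log_phi_marginal(phi_m)
        if lmarg == -np.inf:
            raise SupportMismatchError(
                f"submodel {sub.index} prior marginal is zero at a point where "
                "the pooled prior is positive"
            )
        return lpool + sub.log_joint(phi_m, np.asarray(psi_m, dtype=float)) - lmarg

    return log_density


@dataclass
class MeldedModel:
    """A chain plus a pooled prior, with the melded log-density evaluator."""

    chain: ChainModel
    pooled: PooledPrior

    def __post_init__(self) -> None:
        if self.pooled.layout.names != self.chain.layout.names:
            raise LayoutError(
                f"pooled prior layout {self.pooled.layout.names} does not match "
                f"chain layout {self.chain.layout.names}"
            )
        if self.pooled.layout.dims != self.chain.layout.dims:
            raise LayoutError("pooled prior and chain disagree on block dimensions")

    def log_density(self, phi: np.ndarray, psis: Sequence[np.ndarray]) -> float:
        return melded_log_density(self, phi, psis)


def melded_log_density(
    model: MeldedModel, phi: np.ndarray, psis: Sequence[np.ndarray]
) -> float:
    """Evaluate ``log p_meld(phi, psi, Y)`` for the chained melded model."""
    chain = model.chain
    if len(psis) != chain.M:
        raise LayoutError(f"need {chain.M} psi vectors, got {len(psis)}")
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    if phi.shape != (chain.layout.total_dim,):
        raise LayoutError(
            f"phi has shape {phi.shape}, layout expects ({chain.layout.total_dim},)"
        )
    total = model.pooled(phi)
    if total == -np.inf:
        return -np.inf
    for sub, psi in zip(chain.submodels, psis):
        psi = np.atleast_1d(np.asarray(psi, dtype=float)) if sub.psi_dim else np.empty(0)
        if psi.shape != (sub.psi_dim,):
            raise LayoutError(
                f"submodel {sub.index} psi has shape {psi.shape}, expected ({sub.psi_dim},)"
            )
        phi_m = chain.phi_m(phi, sub.index)
        lj = sub.log_joint(phi_m, psi)
        if lj == -np.inf:
            return -np.inf
        total += lj - sub.log_phi_marginal(phi_m)
    return float(total)
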