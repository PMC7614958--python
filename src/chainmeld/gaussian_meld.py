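"""Normal-approximation melding.

Instead of recycling stage-one draws, the two outer subposteriors and their
priors can be summarised by Gaussians.  Under complete dictatorial pooling
with the middle submodel authoritative, the melded posterior reduces to

    p_meld(phi_{1∩2}, phi_{2∩3}, psi_2 | Y)
        ∝ [p_1(phi_{1∩2}|Y_1)/p_1(phi_{1∩2})] p_2(phi_{1∩2}, phi_{2∩3}, psi_2 | Y_2)
          [p_3(phi_{2∩3}|Y_3)/p_3(phi_{2∩3})]

and replacing the bracketed ratios by ratios of Gaussian densities yields a
single Gaussian correction factor with

    Sigma = (Sigma_nu^{-1} - Sigma_de^{-1})^{-1}
    mu    = Sigma (Sigma_nu^{-1} mu_nu - Sigma_de^{-1} mu_de)

where the numerator stacks the two subposterior approximations
block-diagonally and the denominator the two prior approximations.  Under
product-of-experts pooling the denominator terms disappear and the
correction is the numerator Gaussian itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Union

import numpy as np
from scipy.linalg import block_diag
from scipy.optimize import minimize

from .errors import ImproperCorrectionError, RankDeficiencyError
from .model_spec import SubmodelSpec

__all__ = [
    "GaussianSummary",
    "fit_gaussian",
    "fit_gaussian_laplace",
    "stack_block_diag",
    "gaussian_correction",
    "approx_melded_log_density",
]

_EIG_FLOOR = 1e-10


@dataclass
class GaussianSummary:
    """A mean vector and SPD covariance tied to a shared-quantity slot."""

    mean: np.ndarray
    cov: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        self.cov = np.atleast_2d(np.asarray(self.cov, dtype=float))
        if self.cov.shape != (self.mean.size, self.mean.size):
            raise ValueError(
                f"covariance shape {self.cov.shape} does not match mean size {self.mean.size}"
            )
        if not np.allclose(self.cov, self.cov.T, atol=1e-12):
            raise ValueError("covariance is not symmetric (tolerance 1e-12)")
        eigvals = np.linalg.eigvalsh(self.cov)
        if eigvals.min() <= 0:
            raise RankDeficiencyError(
                f"covariance not positive definite (min eigenvalue {eigvals.min():.3g})"
            )

    @property
    def dim(self) -> int:
        return self.mean.size

    @property
    def precision(self) -> np.ndarray:
        return np.linalg.inv(self.cov)

    def logpdf(self, x: np.ndarray) -> float:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        d = x - self.mean
        _, logdet = np.linalg.slogdet(self.cov)
        return float(
            -0.5 * (self.dim * np.log(2 * np.pi) + logdet + d @ self.precision @ d)
        )

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        chol = np.linalg.cholesky(self.cov)
        return self.mean + rng.standard_normal((n, self.dim)) @ chol.T

    def to_frame(self):
        """Labelled mean/covariance tables for serialisation."""
        import pandas as pd

        names = [f"{self.label or 'x'}[{i}]" for i in range(self.dim)]
        return (
            pd.DataFrame({"parameter": names, "mean": self.mean}),
            pd.DataFrame(self.cov, index=names, columns=names),
        )


def fit_gaussian(
    draws: Union[np.ndarray, GaussianSummary], label: str = ""
) -> GaussianSummary:
    """Moment-matched Gaussian summary of draws (or identity on a Gaussian).

    Requires at least ``d + 1`` draws for dimension ``d``; a singular
    sample covariance raises :class:`RankDeficiencyError`.
    """
    if isinstance(draws, GaussianSummary):
        return GaussianSummary(draws.mean.copy(), draws.cov.copy(), label or draws.label)
    draws = np.asarray(draws, dtype=float)
    if draws.ndim == 1:
        draws = draws[:, None]
    n, d = draws.shape
    if n < d + 1:
        raise RankDeficiencyError(f"need at least {d + 1} draws for dimension {d}, got {n}")
    mean = draws.mean(axis=0)
    cov = np.atleast_2d(np.cov(draws, rowvar=False, ddof=1))
    if np.linalg.eigvalsh(cov).min() <= _EIG_FLOOR * max(1.0, np.trace(cov)):
        raise RankDeficiencyError("sample covariance of the draws is (numerically) singular")
    return GaussianSummary(mean, cov, label)


def fit_gaussian_laplace(
    log_density: Callable[[np.ndarray], float],
    x0: np.ndarray,
    label: str = "",
) -> GaussianSummary:
    """Laplace approximation: Gaussian at the mode with inverse negative Hessian."""
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    res = minimize(lambda x: -log_density(x), x0, method="BFGS")
    mode = res.x
    d = mode.size
    h = 1e-4 * np.maximum(1.0, np.abs(mode))
    hess = np.empty((d, d))
    for i in range(d):
        for j in range(i, d):
            pp = mode.copy(); pp[i] += h[i]; pp[j] += h[j]
            pm = mode.copy(); pm[i] += h[i]; pm[j] -= h[j]
            mp = mode.copy(); mp[i] -= h[i]; mp[j] += h[j]
            mm = mode.copy(); mm[i] -= h[i]; mm[j] -= h[j]
            hess[i, j] = hess[j, i] = (
                log_density(pp) - log_density(pm) - log_density(mp) + log_density(mm)
            ) / (4 * h[i] * h[j])
    cov = np.linalg.inv(-hess)
    cov = 0.5 * (cov + cov.T)
    return GaussianSummary(mode, cov, label)


def stack_block_diag(a: GaussianSummary, b: GaussianSummary, label: str = "") -> GaussianSummary:
    """Stack two summaries block-diagonally (side 1 above side 3)."""
    return GaussianSummary(
        mean=np.concatenate([a.mean, b.mean]),
        cov=block_diag(a.cov, b.cov),
        label=label or f"{a.label}+{b.label}",
    )


def gaussian_correction(
    numerator: GaussianSummary,
    denominator: Optional[GaussianSummary] = None,
    label: str = "correction",
) -> GaussianSummary:
    """The Gaussian correction factor from a ratio of Gaussian densities.

    ``Sigma = (Sigma_nu^{-1} - Sigma_de^{-1})^{-1}`` and
    ``mu = Sigma (Sigma_nu^{-1} mu_nu - Sigma_de^{-1} mu_de)``.  A missing
    denominator (product-of-experts pooling) returns the numerator
    unchanged.  Block-diagonal inputs give a block-diagonal result.  The
    precision difference must be positive definite; otherwise the density
    ratio is not integrable and :class:`ImproperCorrectionError` reports
    the offending eigenvalue.
    """
    if denominator is None:
        return GaussianSummary(numerator.mean.copy(), numerator.cov.copy(), label)
    if denominator.dim != numerator.dim:
        raise ValueError("numerator and denominator dimensions differ")
    p_nu = numerator.precision
    p_de = denominator.precision
    diff = p_nu - p_de
    eigvals = np.linalg.eigvalsh(diff)
    if eigvals.min() <= _EIG_FLOOR:
        raise ImproperCorrectionError(
            "precision difference is not positive definite "
            f"(min eigenvalue {eigvals.min():.3g}); the subposterior must be "
            "strictly more concentrated than the prior in every direction"
        )
    cov = np.linalg.inv(diff)
    cov = 0.5 * (cov + cov.T)
    mean = cov @ (p_nu @ numerator.mean - p_de @ denominator.mean)
    return GaussianSummary(mean, cov, label)


def approx_melded_log_density(
    correction: GaussianSummary,
    middle: SubmodelSpec,
) -> Callable[[np.ndarray, np.ndarray], float]:
    """Log-density of the approximate melded posterior (up to a constant).

    Returns a callable over ``(phi_m, psi_2)`` where ``phi_m`` concatenates
    ``(phi_{1∩2}, phi_{2∩3})``: the Gaussian correction factor plus the
    middle submodel's log joint.  Samplable with any generic MH kernel.
    """
    if correction.dim != middle.phi_dim:
        raise ValueError(
            f"correction dimension {correction.dim} does not match the middle "
            f"submodel's shared dimension {middle.phi_dim}"
        )

    def log_density(phi_m: np.ndarray, psi2: np.ndarray) -> float:
        phi_m = np.atleast_1d(np.asarray(phi_m, dtype=float))
        lj = middle.log_joint(phi_m, np.atleast_1d(np.asarray(psi2, dtype=float)))
        if lj == -np.inf:
            return -np.inf
        return correction.logpdf(phi_m) + lj

    return log_density
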