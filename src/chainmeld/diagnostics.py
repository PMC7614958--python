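"""Convergence diagnostics and posterior interval summaries.

Split-R̂ and effective sample size are delegated to ArviZ; quantile
intervals use the type-7 (linear interpolation) convention, which is
numpy's default.
"""

from __future__ import annotations

from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

__all__ = ["rhat", "ess", "mcse_mean", "diagnostics_table", "summarise_intervals"]

DEFAULT_LEVELS = (0.5, 0.8, 0.95, 0.99)


def _as_chain_draw(draws: np.ndarray) -> np.ndarray:
    draws = np.asarray(draws, dtype=float)
    if draws.ndim == 1:
        draws = draws[None, :]
    if draws.ndim != 2:
        raise ValueError("expected draws with shape (chains, draws)")
    return draws


def rhat(draws: np.ndarray) -> float:
    """Split-R̂ of one scalar quantity, draws shaped (chains, draws)."""
    import arviz as az

    val = az.rhat(az.convert_to_dataset(_as_chain_draw(draws)[:, :, None]))
    return float(np.asarray(val["x"]).ravel()[0])


def ess(draws: np.ndarray) -> float:
    """Bulk effective sample size of one scalar quantity."""
    import arviz as az

    val = az.ess(az.convert_to_dataset(_as_chain_draw(draws)[:, :, None]))
    return float(np.asarray(val["x"]).ravel()[0])


def mcse_mean(draws: np.ndarray) -> float:
    """Monte-Carlo standard error of the posterior mean (sd / sqrt(ESS))."""
    d = _as_chain_draw(draws)
    return float(d.std(ddof=1) / np.sqrt(max(ess(d), 1.0)))


def diagnostics_table(quantities: Mapping[str, np.ndarray]) -> pd.DataFrame:
    """Per-parameter mean, sd, split-R̂, ESS and MCSE.

    ``quantities`` maps parameter names to (chains, draws) arrays.
    """
    rows = []
    for name, arr in quantities.items():
        d = _as_chain_draw(arr)
        e = ess(d)
        rows.append(
            {
                "parameter": name,
                "mean": d.mean(),
                "sd": d.std(ddof=1),
                "rhat": rhat(d),
                "ess": e,
                "mcse_mean": d.std(ddof=1) / np.sqrt(max(e, 1.0)),
            }
        )
    return pd.DataFrame(rows)


def summarise_intervals(
    draws: Union[pd.DataFrame, Mapping[str, np.ndarray]],
    levels: Sequence[float] = DEFAULT_LEVELS,
) -> pd.DataFrame:
    """Central credible intervals per parameter per level.

    Returns a long table (parameter, level, lower, median, upper).  A
    central ``p`` interval runs from the ``(1-p)/2`` to the ``(1+p)/2``
    quantile, so intervals at increasing levels are nested.
    """
    if isinstance(draws, pd.DataFrame):
        if draws.shape[0] == 0:
            raise ValueError("empty draws")
        items = [(c, draws[c].to_numpy(dtype=float)) for c in draws.columns]
    else:
        items = [(k, np.asarray(v, dtype=float).ravel()) for k, v in draws.items()]
        if any(v.size == 0 for _, v in items) or not items:
            raise ValueError("empty draws")
    for level in levels:
        if not 0.0 < level < 1.0:
            raise ValueError(f"interval level {level} outside (0, 1)")
    rows = []
    for name, values in items:
        med = float(np.quantile(values, 0.5))
        for level in levels:
            lo = float(np.quantile(values, (1 - level) / 2))
            hi = float(np.quantile(values, (1 + level) / 2))
            rows.append(
                {"parameter": name, "level": level, "lower": lo, "median": med, "upper": hi}
            )
    return pd.DataFrame(rows)
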