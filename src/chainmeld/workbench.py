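"""Experiment glue: configuration, runnable experiments, draw tables.

A :class:`RunConfig` (plain YAML / dict) fully determines an experiment:
every emitted artefact is a deterministic function of (config, seed).  Two
experiment kinds are built in:

``gaussian-demo``
    The conjugate Gaussian three-chain of
    :class:`~chainmeld.validation.GaussianChainDemo`, fitted with the
    two-stage sampler.
``ipm``
    Simulate an owls dataset and fit it by two-stage chained melding.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .diagnostics import diagnostics_table, summarise_intervals
from .errors import ConfigError

__all__ = ["RunConfig", "run_experiment", "draw_table", "summarise_intervals"]


@dataclass
class RunConfig:
    """Declarative description of one experiment run.

    ``seed`` is mandatory: it is the single root of all randomness.
    ``sampler`` holds stage-one/stage-two settings; ``simulate`` the
    synthetic-data settings for the ipm kind.
    """

    name: str
    kind: str
    seed: int
    pooling: str = "log"
    sampler: dict = field(default_factory=dict)
    simulate: dict = field(default_factory=dict)
    outdir: Optional[str] = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("a seed is mandatory in every run configuration")
        if self.kind not in ("gaussian-demo", "ipm"):
            raise ConfigError(f"unknown experiment kind {self.kind!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {"name", "kind", "seed", "pooling", "sampler", "simulate", "outdir"}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unresolvable config keys: {sorted(unknown)}")
        if "seed" not in d:
            raise ConfigError("a seed is mandatory in every run configuration")
        for key in ("name", "kind"):
            if key not in d:
                raise ConfigError(f"config key {key!r} is required")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def draw_table(named_draws: dict, idx1=None, idx3=None) -> pd.DataFrame:
    """Flatten (chains, kept[, dim]) arrays into one labelled draw table.

    One row per retained sweep per chain; columns are the parameter names
    plus ``chain``, ``sweep`` and, where supplied, the stage-one index
    traces.
    """
    cols = {}
    shape = None
    for name, arr in named_draws.items():
        arr = np.asarray(arr)
        if arr.ndim == 3:
            for j in range(arr.shape[2]):
                key = name if arr.shape[2] == 1 else f"{name}[{j}]"
                cols[key] = arr[:, :, j]
        else:
            cols[name] = arr
        shape = arr.shape[:2]
    if len({c.shape for c in cols.values()}) != 1:
        raise ConfigError("draw arrays have inconsistent shapes")
    chains, kept = shape
    out = {k: v.ravel() for k, v in cols.items()}
    out["chain"] = np.repeat(np.arange(chains), kept)
    out["sweep"] = np.tile(np.arange(kept), chains)
    if idx1 is not None:
        out["idx1"] = np.asarray(idx1).ravel()
    if idx3 is not None:
        out["idx3"] = np.asarray(idx3).ravel()
    df = pd.DataFrame(out)
    if df.columns.duplicated().any():
        raise ConfigError("duplicate column labels in draw table")
    bad = df.drop(columns=["chain", "sweep"]).apply(lambda c: ~np.isfinite(c)).to_numpy().any()
    if bad:
        raise ConfigError("non-finite values in retained draws")
    return df


def run_experiment(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run one configured experiment; return (draw table, diagnostics).

    Deterministic given the config (same config + seed gives identical
    tables).  When ``config.outdir`` is set, writes ``draws.csv``,
    ``diagnostics.csv``, ``intervals.csv`` and an acceptance-rate log.
    """
    s = config.sampler
    if config.kind == "gaussian-demo":
        from .validation import GaussianChainDemo

        demo = GaussianChainDemo()
        draws = demo.fit_two_stage(
            seed=config.seed,
            n_stage_one=int(s.get("n_stage_one", 2000)),
            sweeps=int(s.get("sweeps", 2000)),
            chains=int(s.get("chains", 4)),
        )
        named = {
            "phi12": draws.phi12,
            "phi23": draws.phi23,
            "psi1": draws.psi1,
            "psi2": draws.psi2,
            "psi3": draws.psi3,
        }
        table = draw_table(named, draws.idx1, draws.idx3)
        scalar = {k: v[:, :, 0] for k, v in named.items()}
        acceptance = draws.acceptance
    else:  # ipm
        from .ipm import simulate_ipm
        from .ipm_fit import fit_ipm_two_stage
        from .samplers import MHConfig, StageTwoConfig

        sim = dict(config.simulate)
        cr, counts, fec, _truth = simulate_ipm(
            truth=sim.get("truth"),
            T=int(sim.get("T", 15)),
            releases_per_stratum=int(sim.get("releases_per_stratum", 50)),
            initial_pops=tuple(sim.get("initial_pops", (20, 20))),
            seed=int(sim.get("seed", config.seed)),
        )
        s1 = MHConfig(
            iterations=int(s.get("stage_one_iterations", 16_000)),
            warmup=int(s.get("stage_one_warmup", 6_000)),
            thin=int(s.get("stage_one_thin", 2)),
            init_scale=0.1,
        )
        s2 = StageTwoConfig(
            sweeps=int(s.get("sweeps", 4000)), chains=int(s.get("chains", 2))
        )
        fit = fit_ipm_two_stage(
            cr, counts, fec, pooling=config.pooling, seed=config.seed,
            stage_one_config=s1, stage_two_config=s2,
        )
        scalar = fit.params
        table = draw_table(
            {k: v for k, v in fit.params.items()}, fit.draws.idx1, fit.draws.idx3
        )
        acceptance = fit.draws.acceptance

    diag = diagnostics_table(scalar)
    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "draws.csv", index=False)
        diag.to_csv(out / "diagnostics.csv", index=False)
        params = table.drop(columns=[c for c in ("chain", "sweep", "idx1", "idx3") if c in table])
        summarise_intervals(params).to_csv(out / "intervals.csv", index=False)
        with open(out / "run.json", "w") as fh:
            json.dump(
                {"name": config.name, "kind": config.kind, "seed": config.seed,
                 "acceptance": acceptance},
                fh, indent=2,
            )
    return table, diag
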