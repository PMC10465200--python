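"""Ensemble protocols: temperature sweeps, influence transitions, profiles.

Each protocol generates networks across a range of generation temperatures,
runs a measurement per network, and returns a tidy :class:`pandas.DataFrame`
(one row per network) carrying the generating seed and realized incoherence
``F`` so that every row is individually reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dynamics import (
    KuramotoConfig,
    kuramoto_run,
    lowest_level_nodes,
    majority_vote_run,
    spin_state,
    voter_run,
)
from .generator import GeneratorConfig, generate_network
from .graph_core import out_component_sizes
from .spectral import spectral_summary
from .trophic import incoherence

logger = logging.getLogger(__name__)

__all__ = [
    "SweepSpec",
    "default_temperatures",
    "influence_sweep",
    "structure_sweep",
    "out_component_profile",
    "aggregate_by_temperature",
]


def default_temperatures(low: float = 1e-1, high: float = 1e2, n: int = 10) -> tuple:
    """Log-spaced generation temperatures (dynamics sweeps span 1e-1..1e2,
    structure sweeps 1e-2..1e2)."""
    return tuple(np.logspace(np.log10(low), np.log10(high), n))


@dataclass(frozen=True)
class SweepSpec:
    """Protocol description shared by the sweep drivers.

    Defaults are desk-scale (N = 100, 10 networks per temperature); pass the
    larger values explicitly to reproduce ensemble figures at full size.
    """

    temperatures: tuple = field(default_factory=default_temperatures)
    networks_per_temperature: int = 10
    n_nodes: int = 100
    mean_degree: float = 5.0
    n_basal: int = 0
    dynamics: str = "majority"
    fraction: float = 0.2
    n_steps: int = 1000
    t_end: float = 20.0
    coupling_multiplier: float = 20.0
    epsilon: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        temps = tuple(float(t) for t in self.temperatures)
        if any(t <= 0 for t in temps) or list(temps) != sorted(temps):
            raise ValueError("temperatures must be positive and sorted")
        object.__setattr__(self, "temperatures", temps)
        if self.dynamics not in ("majority", "voter", "kuramoto"):
            raise ValueError("dynamics must be majority, voter or kuramoto")


def _run_seed(spec: SweepSpec, t_index: int, rep: int) -> int:
    # deterministic per-cell seed, independent of iteration order, < 2**31
    ss = np.random.SeedSequence(entropy=spec.seed, spawn_key=(t_index, rep))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def _generate(spec: SweepSpec, t_gen: float, seed: int):
    cfg = GeneratorConfig(
        n_nodes=spec.n_nodes,
        mean_degree=spec.mean_degree,
        t_gen=t_gen,
        n_basal=spec.n_basal,
        seed=seed,
    )
    return generate_network(cfg)


def influence_sweep(spec: SweepSpec) -> pd.DataFrame:
    """Perturb the lowest-level fraction of nodes and record the outcome.

    Outcome is the post-run mean spin (majority, voter) or the mean node
    frequency (Kuramoto, with coupling ``coupling_multiplier * mean_degree``
    and natural frequencies -1 on the perturbed set, +1 elsewhere).
    Generation failures at extreme parameters are logged and skipped.
    """
    rows = []
    for ti, t_gen in enumerate(spec.temperatures):
        for rep in range(spec.networks_per_temperature):
            seed = _run_seed(spec, ti, rep)
            try:
                net, levels = _generate(spec, t_gen, seed)
            except ValueError as err:
                logger.warning("generation failed at T=%g seed=%d: %s", t_gen, seed, err)
                continue
            f = incoherence(net, levels).F
            low = lowest_level_nodes(levels, spec.fraction)
            row = {"temperature": t_gen, "seed": seed, "F": f, "fraction": spec.fraction}
            if spec.dynamics == "kuramoto":
                omegas = np.ones(net.n_nodes)
                omegas[low] = -1.0
                cfg = KuramotoConfig(
                    coupling=spec.coupling_multiplier * spec.mean_degree,
                    omegas=omegas,
                    t_end=spec.t_end,
                )
                res = kuramoto_run(net, cfg)
                row.update(
                    outcome=res.mean_state,
                    order_parameter=res.order_parameter,
                    frequency_std=res.frequency_std,
                )
            else:
                s0 = spin_state(net.n_nodes, low)
                if spec.dynamics == "majority":
                    res = majority_vote_run(net, s0, spec.n_steps)
                else:
                    res = voter_run(net, s0, spec.n_steps, seed=seed + 1)
                row.update(outcome=res.mean_state)
            rows.append(row)
    return pd.DataFrame(rows)


def structure_sweep(spec: SweepSpec, pseudospectrum: bool = True) -> pd.DataFrame:
    """Spectral metrics (IPR, entropy, LR overlap, pseudospectral radius) per
    generated network across the temperature range."""
    rows = []
    for ti, t_gen in enumerate(spec.temperatures):
        for rep in range(spec.networks_per_temperature):
            seed = _run_seed(spec, ti, rep)
            try:
                net, levels = _generate(spec, t_gen, seed)
            except ValueError as err:
                logger.warning("generation failed at T=%g seed=%d: %s", t_gen, seed, err)
                continue
            f = incoherence(net, levels).F
            if pseudospectrum:
                summ = spectral_summary(net, epsilon=spec.epsilon)
                rows.append(
                    {
                        "temperature": t_gen,
                        "seed": seed,
                        "F": f,
                        "mean_ipr": summ.mean_ipr,
                        "mean_entropy": summ.mean_entropy,
                        "lr_overlap": summ.lr_overlap,
                        "pseudospectral_radius_scaled": summ.pseudospectral_radius_scaled,
                    }
                )
            else:
                from .spectral import mean_entropy, mean_ipr, principal_lr_overlap

                rows.append(
                    {
                        "temperature": t_gen,
                        "seed": seed,
                        "F": f,
                        "mean_ipr": mean_ipr(net),
                        "mean_entropy": mean_entropy(net),
                        "lr_overlap": principal_lr_overlap(net),
                    }
                )
    return pd.DataFrame(rows)


def out_component_profile(
    t_gens=(0.02, 1.0, 100.0),
    n_nodes: int = 1000,
    mean_degree: float = 10.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-node out-component size against trophic level rescaled by its
    maximum, for one network per temperature regime."""
    rows = []
    for ti, t_gen in enumerate(t_gens):
        run_seed = _run_seed(
            SweepSpec(temperatures=tuple(sorted(t_gens)), seed=seed), ti, 0
        )
        cfg = GeneratorConfig(
            n_nodes=n_nodes, mean_degree=mean_degree, t_gen=t_gen, seed=run_seed
        )
        net, levels = generate_network(cfg)
        f = incoherence(net, levels).F
        sizes = out_component_sizes(net)
        hmax = levels.h.max()
        rescaled = levels.h / hmax if hmax > 0 else np.zeros_like(levels.h)
        for node in range(n_nodes):
            rows.append(
                {
                    "t_gen": t_gen,
                    "seed": run_seed,
                    "F": f,
                    "node": node,
                    "level_rescaled": rescaled[node],
                    "out_component_size": int(sizes[node]),
                }
            )
    return pd.DataFrame(rows)


def aggregate_by_temperature(df: pd.DataFrame, value: str = "outcome") -> pd.DataFrame:
    """Mean, standard deviation and count of ``value`` per temperature."""
    g = df.groupby("temperature")[value]
    out = g.agg(["mean", "std", "count"]).reset_index()
    return out
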