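"""Per-cell reference implementation of the serial-dilution model.

Keeps one record per cell so that virion placement collisions, segregation
and the transfer bottleneck are simulated exactly (the bottleneck samples
cells without replacement rather than thinning class counts binomially).
Semantics otherwise match :func:`ppsim.simulate.run_simulation`; the class
aggregation used there is validated against this oracle on small populations.
Intended for testing only — the guard refuses founder populations above 10^4.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import (
    GenerationRecord,
    PopulationState,
    SimConfig,
    Trajectory,
    make_record,
)

logger = logging.getLogger(__name__)

AGENT_N0_MAX = 10_000


@dataclass
class AgentPopulation:
    """Per-cell state: parallel arrays of wild-type / mutant copy counts."""

    a: np.ndarray
    b: np.ndarray
    pending_virions: int = 0
    generation: int = 0
    cycle: int = 0
    extinct: bool = False

    @property
    def n_cells(self) -> int:
        return int(self.a.size)

    def as_state(self) -> PopulationState:
        """Aggregate to class counts so records are built by the same code."""
        classes: dict[tuple[int, int], int] = {}
        if self.a.size:
            pairs, counts = np.unique(
                np.stack([self.a, self.b], axis=1), axis=0, return_counts=True
            )
            classes = {(int(x), int(y)): int(c) for (x, y), c in zip(pairs, counts)}
        return PopulationState(
            classes=classes,
            pending_virions=self.pending_virions,
            generation=self.generation,
            cycle=self.cycle,
            extinct=self.extinct,
        )


def _init_agents(config: SimConfig) -> AgentPopulation:
    if config.initial_classes is not None:
        a_list, b_list = [], []
        for key, count in config.initial_classes.items():
            ai, bi = (int(x) for x in key)
            a_list.extend([ai] * int(count))
            b_list.extend([bi] * int(count))
        return AgentPopulation(np.array(a_list, dtype=np.int64), np.array(b_list, dtype=np.int64))
    a = np.full(config.n0, config.initial_wt_copies, dtype=np.int64)
    b = np.zeros(config.n0, dtype=np.int64)
    return AgentPopulation(a, b)


def _seed_mutation(pop: AgentPopulation, rng: np.random.Generator) -> None:
    total_wt = int(pop.a.sum())
    if total_wt == 0:
        logger.warning("seed_mutation: no wild-type copies in population; skipping")
        return
    weights = pop.a / total_wt
    i = rng.choice(pop.n_cells, p=weights)
    pop.a[i] -= 1
    pop.b[i] += 1


def _reinfect(pop: AgentPopulation, config: SimConfig, rng: np.random.Generator) -> None:
    v = pop.pending_virions
    pop.pending_virions = 0
    n = pop.n_cells
    if v == 0 or n == 0:
        return
    hits = np.bincount(rng.integers(0, n, size=v), minlength=n)
    if config.copy_cap is not None:
        hits = np.minimum(hits, np.maximum(config.copy_cap - (pop.a + pop.b), 0))
    pop.b += hits


def _divide(pop: AgentPopulation, config: SimConfig, rng: np.random.Generator) -> int:
    n_draw = pop.a + pop.b
    pool_wt = 2 * pop.a
    pool_mut = 2 * pop.b
    if config.mu > 0.0:
        e = rng.binomial(pop.a, config.mu)
        pool_wt = pool_wt - e
        pool_mut = pool_mut + e
    a1 = rng.hypergeometric(pool_wt, pool_mut, n_draw)
    d1a, d1b = a1, n_draw - a1
    d2a, d2b = pool_wt - a1, pool_mut - (n_draw - a1)
    a_new = np.concatenate([d1a, d2a])
    b_new = np.concatenate([d1b, d2b])
    n_lysed = 0
    if config.enable_lysis:
        alive = a_new > 0
        n_lysed = int((~alive).sum())
        a_new, b_new = a_new[alive], b_new[alive]
        if n_lysed > 0:
            if config.reinfection_draw == "poisson":
                pop.pending_virions += int(rng.poisson(config.r * n_lysed))
            else:
                pop.pending_virions += int(round(config.r * n_lysed))
    pop.a, pop.b = a_new, b_new
    pop.generation += 1
    if pop.n_cells == 0:
        pop.extinct = True
    return n_lysed


def _bottleneck(pop: AgentPopulation, config: SimConfig, rng: np.random.Generator) -> None:
    n = pop.n_cells
    size = n // config.d
    if rng.random() < (n % config.d) / config.d:  # stochastic rounding keeps E[size]=n/d
        size += 1
    if size > 0:
        keep = rng.choice(n, size=size, replace=False)
        pop.a, pop.b = pop.a[keep], pop.b[keep]
    else:
        pop.a = pop.a[:0]
        pop.b = pop.b[:0]
        pop.extinct = True
    pop.pending_virions = int(rng.binomial(pop.pending_virions, 1.0 / config.d))
    pop.cycle += 1


def run_agent_simulation(config: SimConfig, rng: np.random.Generator | None = None) -> Trajectory:
    """Cell-by-cell simulation with the same schedule as the aggregated model.

    Raises
    ------
    ValueError
        If ``n0`` exceeds 10^4 — use :func:`ppsim.simulate.run_simulation`
        for production-size populations.
    """
    n_founders = (
        sum(config.initial_classes.values())
        if config.initial_classes is not None
        else config.n0
    )
    if n_founders > AGENT_N0_MAX:
        raise ValueError(
            f"agent oracle refuses n0={n_founders} > {AGENT_N0_MAX}; "
            "use ppsim.simulate.run_simulation for large populations"
        )
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    pop = _init_agents(config)
    traj = Trajectory(config=config, records=[make_record(pop.as_state(), config, 0, 0)])
    if config.seed_generation == 0:
        _seed_mutation(pop, rng)
    g = config.gens_per_cycle
    for t in range(1, config.total_generations + 1):
        if pop.extinct:
            break
        _reinfect(pop, config, rng)
        n_lysed = _divide(pop, config, rng)
        traj.records.append(make_record(pop.as_state(), config, n_lysed, (t - 1) % g + 1))
        if config.seed_generation == t:
            _seed_mutation(pop, rng)
        if t % g == 0 and t < config.total_generations:
            _bottleneck(pop, config, rng)
    return traj


def compare_trajectories(
    ens_a: list[Trajectory], ens_b: list[Trajectory], z_flag: float = 4.0
) -> pd.DataFrame:
    """Per-generation comparison of two trajectory ensembles.

    For each generation and each of ``mutant_allele_freq``, ``n_cells`` and
    ``mean_copy_number``, reports the difference of ensemble means, its
    standard error, and the z-score; rows with ``|z| > z_flag`` are flagged.
    Ensembles of unequal horizon are aligned on the shortest with a warning.
    """
    if not ens_a or not ens_b:
        raise ValueError("both ensembles must be non-empty")
    len_a = min(len(t) for t in ens_a)
    len_b = min(len(t) for t in ens_b)
    horizon = min(len_a, len_b)
    if len_a != len_b:
        logger.warning("ensemble horizons differ (%d vs %d); aligning on %d", len_a, len_b, horizon)

    metrics = {
        "mutant_allele_freq": lambda t: t.mutant_allele_freq[:horizon],
        "n_cells": lambda t: t.n_cells[:horizon].astype(float),
        "mean_copy_number": lambda t: t.mean_copy_number[:horizon],
    }
    rows = []
    for name, get in metrics.items():
        mat_a = np.stack([get(t) for t in ens_a])
        mat_b = np.stack([get(t) for t in ens_b])
        mean_a, mean_b = mat_a.mean(axis=0), mat_b.mean(axis=0)
        se = np.sqrt(
            mat_a.var(axis=0, ddof=1) / mat_a.shape[0]
            + mat_b.var(axis=0, ddof=1) / mat_b.shape[0]
        )
        diff = mean_a - mean_b
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(se > 0, diff / se, np.where(diff == 0, 0.0, np.inf))
        for gen in range(horizon):
            rows.append(
                {
                    "generation": gen,
                    "metric": name,
                    "mean_a": mean_a[gen],
                    "mean_b": mean_b[gen],
                    "diff": diff[gen],
                    "se": se[gen],
                    "z": z[gen],
                    "flag": bool(abs(z[gen]) > z_flag),
                }
            )
    return pd.DataFrame(rows)
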