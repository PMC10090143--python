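"""Trajectory summaries and simulation-based recovery of the re-infection
efficiency R.

The summaries mirror the two headline features of the system's dynamics:
the mutant allele rises by roughly half the population within one dilution
cycle of first detection, and then saturates below fixation.  The inference
stage recovers R from cycle-end sequencing trajectories by grid search:
for each candidate R an ensemble of simulations is run and the mean squared
error between observed and simulated ensemble-mean allele frequencies at the
observed generations is minimised.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import SimConfig, Trajectory, run_simulation


@dataclass(frozen=True)
class ObservedTrajectory:
    """Cycle-end sequencing measurements of a mutant allele's spread.

    Each timepoint is ``(generation, depth, mutant_reads)``: at a given
    generation the locus was sequenced to ``depth`` reads of which
    ``mutant_reads`` support the mutant allele.
    """

    generations: np.ndarray
    depth: np.ndarray
    mutant_reads: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.generations, dtype=int)
        d = np.asarray(self.depth, dtype=int)
        m = np.asarray(self.mutant_reads, dtype=int)
        if not (g.shape == d.shape == m.shape) or g.ndim != 1:
            raise ValueError("generations, depth, mutant_reads must be 1-D and equal length")
        if np.any(np.diff(g) <= 0):
            raise ValueError("generations must be strictly increasing")
        if np.any(d < 1):
            raise ValueError("depth must be >= 1 at every timepoint")
        if np.any(m < 0) or np.any(m > d):
            raise ValueError("mutant_reads must satisfy 0 <= mutant_reads <= depth")
        object.__setattr__(self, "generations", g)
        object.__setattr__(self, "depth", d)
        object.__setattr__(self, "mutant_reads", m)

    @property
    def freq(self) -> np.ndarray:
        """Observed mutant allele frequency (mutant_reads / depth)."""
        return self.mutant_reads / self.depth

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "generation": self.generations,
                "depth": self.depth,
                "mutant_reads": self.mutant_reads,
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ObservedTrajectory":
        required = {"generation", "depth", "mutant_reads"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"observed trajectory table missing columns: {sorted(missing)}")
        return cls(
            df["generation"].to_numpy(),
            df["depth"].to_numpy(),
            df["mutant_reads"].to_numpy(),
        )


def saturation_frequency(traj: Trajectory, window: int | None = None) -> float:
    """Mean mutant allele frequency over the final ``window`` generations.

    The default window is one dilution cycle, so for a run that has reached
    its plateau this is the saturation frequency of the mutant genotype.
    """
    if window is None:
        window = traj.config.gens_per_cycle
    if window < 1:
        raise ValueError("window must be >= 1")
    if len(traj) < window:
        raise ValueError(f"trajectory has {len(traj)} records, shorter than window {window}")
    return float(traj.mutant_allele_freq[-window:].mean())


def rise_within_cycle(
    traj: Trajectory,
    detection_threshold: float = 0.05,
    cycle_len: int | None = None,
    cadence: int | str = 1,
) -> float:
    """Frequency one dilution cycle after the mutant first becomes detectable.

    Finds the first generation at which the mutant allele frequency reaches
    ``detection_threshold`` (default 5%, a typical variant-calling floor) and
    returns the frequency exactly ``cycle_len`` generations later.

    ``cadence`` controls where detection can happen: 1 checks every recorded
    generation; ``"cycle_end"`` restricts detection to end-of-cycle
    timepoints, emulating a study design that sequences the population only
    at each transfer.  An integer stride restricts detection to multiples of
    that stride.
    """
    if cycle_len is None:
        cycle_len = traj.config.gens_per_cycle
    freq = traj.mutant_allele_freq
    gens = traj.generations
    if cadence == "cycle_end":
        stride = traj.config.gens_per_cycle
    else:
        stride = int(cadence)
        if stride < 1:
            raise ValueError("cadence must be 'cycle_end' or a positive integer")
    detectable = freq >= detection_threshold
    if stride > 1:
        detectable &= (gens > 0) & (gens % stride == 0)
    above = np.nonzero(detectable)[0]
    if above.size == 0:
        raise ValueError(
            f"mutant allele frequency never reached detection threshold {detection_threshold}"
        )
    t0 = int(above[0])
    t1 = t0 + cycle_len
    if t1 >= len(freq):
        raise ValueError(
            f"trajectory ends at generation {len(freq) - 1}, before {t1} "
            f"(detection at {t0} + cycle of {cycle_len})"
        )
    return float(freq[t1])


def time_to_first_lysis(traj: Trajectory) -> int | None:
    """First generation with at least one lysed cell, or None if none ever."""
    lysed = np.nonzero(traj.n_lysed > 0)[0]
    if lysed.size == 0:
        return None
    return int(traj.generations[lysed[0]])


@dataclass
class RFitResult:
    """Grid-search fit of the re-infection efficiency R.

    ``loss[i]`` is the (alignment-minimised) mean squared error of candidate
    ``grid[i]``; ``best_r`` is the argmin.  ``offsets`` records the seeding
    alignment (in generations) chosen for each candidate.
    """

    grid: list[float]
    loss: list[float]
    best_r: float
    replicates_per_candidate: int
    rng_seed: int
    offsets: list[int] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(vars(self), indent=2) + "\n")

    def loss_table(self) -> pd.DataFrame:
        return pd.DataFrame({"r": self.grid, "loss": self.loss, "offset": self.offsets})


def ensemble_mean_freq(
    config: SimConfig, replicates: int, base_seed: int, tag: int = 0
) -> np.ndarray:
    """Per-generation ensemble-mean mutant allele frequency.

    Replicate k runs with an independent stream derived from
    ``(base_seed, tag, k)``.  Trajectories truncated by extinction are padded
    with zero frequency (an extinct culture carries no mutant copies).
    """
    horizon = config.total_generations + 1
    acc = np.zeros(horizon)
    for k in range(replicates):
        rng = np.random.default_rng([base_seed % (2**31), tag, k])
        traj = run_simulation(config, rng=rng)
        f = traj.mutant_allele_freq
        acc[: len(f)] += f
    return acc / replicates


def fit_reinfection_efficiency(
    obs: ObservedTrajectory,
    template: SimConfig,
    grid: list[float],
    replicates: int = 10,
    rng_seed: int = 0,
    align_window: int | None = None,
) -> RFitResult:
    """Recover R by grid search against simulated ensemble-mean trajectories.

    For each candidate R, ``replicates`` simulations are run from ``template``
    (with the mutation seeded at generation 0) and the ensemble-mean mutant
    allele frequency is compared with the observed frequencies
    ``mutant_reads / depth`` at the observed generations, by mean squared
    error.  Because the timing of the spontaneous mutation in data is unknown,
    the simulated curve may be shifted later by up to ``align_window``
    generations (default: one dilution cycle); the best-aligned MSE is the
    candidate's loss, so mutation-timing lag is not penalised.
    """
    if not grid:
        raise ValueError("candidate grid must be non-empty")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if align_window is None:
        align_window = template.gens_per_cycle
    align_window = max(1, int(align_window))

    max_gen = int(obs.generations.max())
    if max_gen > template.total_generations:
        raise ValueError(
            f"observed generations extend to {max_gen}, beyond the template "
            f"horizon of {template.total_generations} generations"
        )

    obs_freq = obs.freq
    losses: list[float] = []
    offsets: list[int] = []
    for i, r in enumerate(grid):
        config = template.with_(r=float(r), seed_generation=0)
        mean_freq = ensemble_mean_freq(config, replicates, rng_seed, tag=i)
        best = (np.inf, 0)
        for s in range(align_window):
            shifted_idx = obs.generations - s
            pred = np.where(shifted_idx >= 0, mean_freq[np.maximum(shifted_idx, 0)], 0.0)
            mse = float(np.mean((obs_freq - pred) ** 2))
            if mse < best[0]:
                best = (mse, s)
        losses.append(best[0])
        offsets.append(best[1])

    best_i = int(np.argmin(losses))
    return RFitResult(
        grid=[float(r) for r in grid],
        loss=losses,
        best_r=float(grid[best_i]),
        replicates_per_candidate=replicates,
        rng_seed=rng_seed,
        offsets=offsets,
    )
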