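"""Synthetic sequencing experiments and packaged scenario configurations.

The measurement process emulated here is population sequencing at the end of
each dilution cycle: the mutant allele frequency of the simulated culture is
observed through binomially distributed read counts at a finite depth.  No
read-level artifacts (mapping bias, indel-calling error) are modelled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .observables import ObservedTrajectory
from .simulate import SimConfig, Trajectory


@dataclass(frozen=True)
class Scenario:
    """A named, ready-to-run simulation configuration.

    ``sweep`` optionally maps a config field to a list of values, for
    scenarios that are parameter sweeps rather than single runs.
    """

    name: str
    config: SimConfig
    description: str
    sweep: dict[str, list] | None = None

    def expand(self) -> list[SimConfig]:
        """Materialise the sweep (or the single config) as a config list."""
        if not self.sweep:
            return [self.config]
        (fld, values), = self.sweep.items()
        return [self.config.with_(**{fld: v}) for v in values]


def sequencing_noise(
    traj: Trajectory,
    depth: int = 100,
    cadence: int | str = "cycle_end",
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> ObservedTrajectory:
    """Sample an observed trajectory from a simulated one.

    At each sampled generation t, ``mutant_reads ~ Binomial(depth, freq(t))``.
    ``cadence`` is either ``"cycle_end"`` (sample at the end of every dilution
    cycle, the study's measurement schedule) or an integer stride in
    generations.
    """
    if depth < 1:
        raise ValueError("sequencing depth must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    gens = traj.generations
    freq = traj.mutant_allele_freq
    if cadence == "cycle_end":
        g = traj.config.gens_per_cycle
        mask = (gens > 0) & (gens % g == 0)
    else:
        stride = int(cadence)
        if stride < 1:
            raise ValueError("cadence must be 'cycle_end' or a positive integer")
        mask = (gens > 0) & (gens % stride == 0)
    sampled_gens = gens[mask]
    sampled_freq = freq[mask]
    reads = rng.binomial(depth, sampled_freq)
    return ObservedTrajectory(
        generations=sampled_gens,
        depth=np.full(sampled_gens.shape, depth, dtype=int),
        mutant_reads=reads,
    )


def builtin_scenarios() -> list[Scenario]:
    """The shipped scenario registry.

    ``baseline`` carries the study-condition parameters: one million founder
    cells each with a single wild-type plasmid copy, six doublings per cycle,
    dilution factor 64, re-infection efficiency R=5, and one loss-of-function
    mutation seeded at generation 0.
    """
    baseline = SimConfig(
        n0=1_000_000,
        gens_per_cycle=6,
        n_cycles=12,
        d=64,
        r=5.0,
        initial_wt_copies=1,
        seed_generation=0,
    )
    return [
        Scenario(
            "baseline",
            baseline,
            "Study conditions: N0=1e6, 6 generations/cycle, d=64, R=5, one "
            "mutant plasmid copy seeded at generation 0; 12 cycles reach the "
            "saturation plateau.",
        ),
        Scenario(
            "high_copy",
            baseline.with_(
                initial_wt_copies=3, seed_generation=None, mu=1e-6, n_cycles=10
            ),
            "Elevated repressor dosage: founders carry 3 wild-type copies and "
            "mutations arise recurrently (mu=1e-6 per copy per replication, an "
            "illustrative rate); extra copies delay the first induction.",
        ),
        Scenario(
            "r_sweep",
            baseline,
            "Baseline swept over re-infection efficiency R; the saturation "
            "frequency increases with R.",
            sweep={"r": [1.0, 2.0, 5.0, 8.0]},
        ),
        Scenario(
            "no_reinfection",
            baseline.with_(r=0.0, n_cycles=3),
            "R=0 control: the seeded mutant lyses without producing successful "
            "re-infections, so the allele is purged immediately.",
        ),
        Scenario(
            "small_oracle",
            baseline.with_(n0=1000, n_cycles=4),
            "Small population (N0=1000, 4 cycles) for validating the "
            "class-aggregated simulator against the per-cell agent oracle.",
        ),
    ]


def get_scenario(name: str) -> Scenario:
    for s in builtin_scenarios():
        if s.name == name:
            return s
    names = ", ".join(s.name for s in builtin_scenarios())
    raise KeyError(f"unknown scenario {name!r}; available: {names}")
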