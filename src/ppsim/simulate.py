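"""Serial-dilution eco-evolutionary simulator for a phage-plasmid.

The model is Wright-Fisher-like with a dynamic population size.  Each dilution
cycle starts from roughly ``N0`` cells which double for ``gens_per_cycle``
generations (``N_t = N0 * 2**t``) and are then bottlenecked by a dilution
factor ``d``.  Every cell carries ``a`` wild-type and ``b`` mutant copies of a
phage-plasmid; at division the copies duplicate and segregate randomly
(see :mod:`ppsim.kernel`).  Daughters left with zero wild-type copies lose
repression of the lytic genes and lyse; each lysed cell seeds on average ``R``
successful re-infections, each adding one mutant copy to a random live cell in
the next generation.  The interplay of lysis, re-infection and segregational
drift lets the mutant allele spread rapidly yet saturate below fixation.

The population is aggregated by genotype class ``(a, b)`` so cost scales with
the number of distinct classes, not with cell count.  A brute-force per-cell
implementation with identical semantics lives in :mod:`ppsim.agent` and is
used to validate the aggregation on small populations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Iterator

import numpy as np
import pandas as pd
from scipy.stats import binom as binom_dist
from scipy.stats import poisson as poisson_dist

from .kernel import segregation_pmf

logger = logging.getLogger(__name__)

# Above this population size virion placement switches from exact
# balls-in-bins to the per-class Poisson-occupancy draw (see apply_reinfection).
EXACT_PLACEMENT_MAX = 150_000

_CONFIG_FIELDS = (
    "n0",
    "gens_per_cycle",
    "n_cycles",
    "d",
    "r",
    "initial_wt_copies",
    "seed_generation",
    "mu",
    "copy_cap",
    "reinfection_draw",
    "rng_seed",
    "enable_lysis",
    "initial_classes",
)


@dataclass(frozen=True)
class SimConfig:
    """All parameters of one simulation run.

    Parameters
    ----------
    n0 : int
        Cells at the start of each dilution cycle (default one million).
    gens_per_cycle : int
        Doublings per dilution cycle (default 6).
    n_cycles : int
        Number of serial-dilution cycles to simulate.
    d : int
        Dilution factor: a fraction 1/d of cells is carried over at transfer.
        In the standard regime ``d == 2**gens_per_cycle`` so the population
        returns to ``n0`` when nothing lyses; other combinations run but are
        flagged in the log.
    r : float
        Re-infection efficiency: mean number of released virions that
        successfully infect a live cell, per cell lysed (epidemiological
        R0 analogue; the best-fitting value for the study system is 5).
    initial_wt_copies : int
        Wild-type plasmid copies per founder cell.
    seed_generation : int or None
        Generation at which a single plasmid copy, chosen uniformly among all
        wild-type copies in the population, is switched to the mutant allele.
        ``None`` disables seeding (use ``mu`` for recurrent mutation instead).
    mu : float
        Per-copy, per-replication loss-of-function mutation probability
        applied to each newly synthesised wild-type copy at duplication.
    copy_cap : int or None
        Optional ceiling on plasmid copies per cell; infections of cells at
        the cap are dropped.  Default: unbounded.
    reinfection_draw : {"poisson", "fixed"}
        Whether the number of successful re-infections produced by L lysed
        cells is drawn as Poisson(R*L) or set deterministically to round(R*L).
    rng_seed : int
        Seed for the run's random generator; runs are bit-reproducible.
    enable_lysis : bool
        Test hook: when False, cells with zero wild-type copies survive and
        no virions are produced, reducing the model to pure segregational
        drift (useful for martingale checks).
    initial_classes : dict or None
        Advanced override of the founder population, mapping ``(a, b)`` to a
        cell count.  When given, ``n0``/``initial_wt_copies`` only label the
        config; the state starts from exactly these classes.
    """

    n0: int = 1_000_000
    gens_per_cycle: int = 6
    n_cycles: int = 12
    d: int = 64
    r: float = 5.0
    initial_wt_copies: int = 1
    seed_generation: int | None = 0
    mu: float = 0.0
    copy_cap: int | None = None
    reinfection_draw: str = "poisson"
    rng_seed: int = 0
    enable_lysis: bool = True
    initial_classes: dict | None = None

    def __post_init__(self) -> None:
        if self.n0 <= 0:
            raise ValueError("n0 must be a positive integer")
        if self.gens_per_cycle < 1 or self.n_cycles < 1:
            raise ValueError("gens_per_cycle and n_cycles must be >= 1")
        if self.d < 1:
            raise ValueError("dilution factor d must be >= 1")
        if self.r < 0:
            raise ValueError("re-infection efficiency r must be >= 0")
        if self.initial_wt_copies < 1:
            raise ValueError("initial_wt_copies must be >= 1")
        if self.seed_generation is not None and self.seed_generation < 0:
            raise ValueError("seed_generation must be >= 0 or None")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("mu must lie in [0, 1]")
        if self.copy_cap is not None and self.copy_cap < 1:
            raise ValueError("copy_cap must be >= 1 or None")
        if self.reinfection_draw not in ("poisson", "fixed"):
            raise ValueError("reinfection_draw must be 'poisson' or 'fixed'")
        if self.d != 2 ** self.gens_per_cycle:
            logger.warning(
                "d=%d != 2**gens_per_cycle=%d: population will not return to "
                "n0 after dilution even without lysis",
                self.d,
                2 ** self.gens_per_cycle,
            )

    @property
    def total_generations(self) -> int:
        return self.n_cycles * self.gens_per_cycle

    def with_(self, **kwargs) -> "SimConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass
class PopulationState:
    """Mutable simulation state: genotype-class counts plus free virions."""

    classes: dict[tuple[int, int], int]
    pending_virions: int = 0
    generation: int = 0
    cycle: int = 0
    extinct: bool = False

    @property
    def n_cells(self) -> int:
        return sum(self.classes.values())

    def total_copies(self) -> tuple[int, int]:
        """(wild-type copies, mutant copies) summed over the population."""
        wt = sum(a * k for (a, _), k in self.classes.items())
        mut = sum(b * k for (_, b), k in self.classes.items())
        return wt, mut


@dataclass(frozen=True)
class GenerationRecord:
    """Observables of one generation, mirroring the axes of the study's
    trajectory plots (allele frequency vs generation, OD600 proxy)."""

    generation: int
    cycle: int
    n_cells: int
    n_lysed: int
    pending_virions: int
    mutant_allele_freq: float
    heterozygote_fraction: float
    mean_copy_number: float
    od_proxy: float
    mutant_cell_fraction: float


@dataclass
class Trajectory:
    """Ordered per-generation records of one simulation run."""

    config: SimConfig
    records: list[GenerationRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[GenerationRecord]:
        return iter(self.records)

    @property
    def generations(self) -> np.ndarray:
        return np.array([r.generation for r in self.records])

    @property
    def mutant_allele_freq(self) -> np.ndarray:
        return np.array([r.mutant_allele_freq for r in self.records])

    @property
    def n_lysed(self) -> np.ndarray:
        return np.array([r.n_lysed for r in self.records])

    @property
    def mean_copy_number(self) -> np.ndarray:
        return np.array([r.mean_copy_number for r in self.records])

    @property
    def n_cells(self) -> np.ndarray:
        return np.array([r.n_cells for r in self.records])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records])


def init_population(config: SimConfig) -> PopulationState:
    """Founder population: ``n0`` cells each carrying ``initial_wt_copies``
    wild-type plasmid copies (or the explicit ``initial_classes`` override)."""
    if config.initial_classes is not None:
        classes = {}
        for key, count in config.initial_classes.items():
            a, b = (int(x) for x in key)
            if a < 0 or b < 0 or a + b < 1 or count < 0:
                raise ValueError(f"invalid initial class {key}: {count}")
            if count > 0:
                classes[(a, b)] = int(count)
        if not classes:
            raise ValueError("initial_classes must contain at least one cell")
    else:
        classes = {(config.initial_wt_copies, 0): config.n0}
    return PopulationState(classes=classes)


def seed_mutation(state: PopulationState, rng: np.random.Generator) -> PopulationState:
    """Convert one plasmid copy, uniform over all wild-type copies, to mutant.

    One cell moves from class ``(a, b)`` to ``(a-1, b+1)`` with probability
    proportional to ``a * count``.  If the population carries no wild-type
    copies this is a warned no-op.
    """
    items = [(cls, k) for cls, k in state.classes.items() if cls[0] > 0 and k > 0]
    if not items:
        logger.warning("seed_mutation: no wild-type copies in population; skipping")
        return state
    weights = np.array([a * k for (a, _), k in items], dtype=float)
    idx = rng.choice(len(items), p=weights / weights.sum())
    (a, b), _ = items[idx]
    state.classes[(a, b)] -= 1
    if state.classes[(a, b)] == 0:
        del state.classes[(a, b)]
    state.classes[(a - 1, b + 1)] = state.classes.get((a - 1, b + 1), 0) + 1
    return state


def _add(classes: dict, key: tuple[int, int], count: int) -> None:
    if count:
        classes[key] = classes.get(key, 0) + int(count)


@lru_cache(maxsize=None)
def _mutation_pmf(a: int, mu: float) -> np.ndarray:
    """Binomial(a, mu) pmf over mutated new copies per cell, normalised."""
    pe = binom_dist.pmf(np.arange(a + 1), a, mu)
    pe = np.clip(pe, 0.0, None)
    pe = pe / pe.sum()
    pe.setflags(write=False)
    return pe


def _capped_gain(a: int, b: int, j: int, cap: int | None) -> int:
    """Mutant copies actually gained when j infections hit an (a, b) cell."""
    if cap is None:
        return j
    return max(0, min(j, cap - (a + b)))


def apply_reinfection(
    state: PopulationState, config: SimConfig, rng: np.random.Generator
) -> PopulationState:
    """Distribute pending virions uniformly at random over live cells.

    Each successful infection adds one mutant plasmid copy to its target;
    multiple hits on one cell accumulate (up to ``copy_cap`` if set).  Virions
    with no live cells to infect are discarded.

    For small populations the placement is an exact balls-in-bins draw.  For
    large populations each class draws its cells' hit-count multiplicities
    from the Poisson occupancy law with rate ``v / N``; together with the
    Poisson draw of the virion count this equals the exact uniform placement
    in distribution (Poisson thinning) at a cost independent of N.
    """
    v = state.pending_virions
    state.pending_virions = 0
    n_total = state.n_cells
    if v == 0 or n_total == 0:
        return state

    items = list(state.classes.items())
    counts = np.array([k for _, k in items], dtype=float)

    if n_total <= EXACT_PLACEMENT_MAX:
        per_class = rng.multinomial(v, counts / counts.sum())
        for ((a, b), k), vc in zip(items, per_class):
            if vc == 0:
                continue
            if k == 1:
                gain = _capped_gain(a, b, int(vc), config.copy_cap)
                if gain:
                    _add(state.classes, (a, b), -1)
                    if state.classes[(a, b)] == 0:
                        del state.classes[(a, b)]
                    _add(state.classes, (a, b + gain), 1)
                continue
            hits_per_cell = np.bincount(rng.integers(0, k, size=int(vc)))
            hit = hits_per_cell[hits_per_cell > 0]
            multiplicity = np.bincount(hit)  # multiplicity[j] cells got j hits
            _move_infected(state.classes, (a, b), multiplicity, config.copy_cap)
    else:
        lam = v / n_total
        j_max = max(4, int(math.ceil(lam + 10.0 * math.sqrt(lam) + 10.0)))
        pvec = poisson_dist.pmf(np.arange(j_max + 1), lam)
        pvec[-1] = max(0.0, 1.0 - pvec[:-1].sum())
        pvec = pvec / pvec.sum()
        for (a, b), k in items:
            occupancy = rng.multinomial(k, pvec)
            _move_infected(state.classes, (a, b), occupancy, config.copy_cap, from_j=1)
    return state


def _move_infected(
    classes: dict,
    cls: tuple[int, int],
    multiplicity: np.ndarray,
    cap: int | None,
    from_j: int = 1,
) -> None:
    """Move cells of class ``cls`` that received j >= from_j infections."""
    a, b = cls
    for j in range(from_j, len(multiplicity)):
        m = int(multiplicity[j])
        if m == 0:
            continue
        gain = _capped_gain(a, b, j, cap)
        if gain == 0:
            continue
        _add(classes, (a, b), -m)
        _add(classes, (a, b + gain), m)
    if classes.get((a, b)) == 0:
        del classes[(a, b)]


def divide_and_segregate(
    state: PopulationState, config: SimConfig, rng: np.random.Generator
) -> int:
    """One synchronous generation: duplicate, (optionally) mutate, segregate,
    lyse wild-type-free daughters and produce virions.

    Returns the number of cells lysed this generation.  Division is aggregated
    per genotype class with a multinomial draw over the class's exact offspring
    distribution; per-replication mutation (rate ``mu`` per newly synthesised
    wild-type copy) peels affected cells out of the bulk and divides them
    individually.
    """
    new: dict[tuple[int, int], int] = {}
    for (a, b), k in state.classes.items():
        n = a + b
        k_bulk = k
        # Mutation strikes newly replicated wild-type copies: each of a cell's
        # a new copies mutates independently, so the number of cells with e
        # mutated new copies is Multinomial(k, Binomial(a, mu)).
        if config.mu > 0.0 and a > 0 and k > 0:
            per_cell = _mutation_pmf(a, config.mu)
            counts_e = rng.multinomial(k, per_cell)
            k_bulk = int(counts_e[0])
            for e in range(1, a + 1):
                c = int(counts_e[e])
                if c == 0:
                    continue
                pool_wt, pool_mut = 2 * a - e, 2 * b + e
                a1s = rng.hypergeometric(pool_wt, pool_mut, n, size=c)
                for a1, cnt in zip(*np.unique(a1s, return_counts=True)):
                    a1 = int(a1)
                    _add(new, (a1, n - a1), int(cnt))
                    _add(new, (pool_wt - a1, pool_mut - (n - a1)), int(cnt))
        if k_bulk == 0:
            continue
        if b == 0:
            _add(new, (a, 0), 2 * k_bulk)
        elif a == 0:
            _add(new, (0, b), 2 * k_bulk)
        else:
            values, probs = segregation_pmf(a, b)
            counts = rng.multinomial(k_bulk, probs)
            for a1, c in zip(values, counts):
                if c == 0:
                    continue
                a1 = int(a1)
                _add(new, (a1, n - a1), c)
                _add(new, (2 * a - a1, 2 * b - (n - a1)), c)

    n_lysed = 0
    if config.enable_lysis:
        doomed = [cls for cls in new if cls[0] == 0]
        for cls in doomed:
            n_lysed += new.pop(cls)
        if n_lysed > 0:
            if config.reinfection_draw == "poisson":
                burst = int(rng.poisson(config.r * n_lysed))
            else:
                burst = int(round(config.r * n_lysed))
            state.pending_virions += burst

    state.classes = new
    state.generation += 1
    if not new:
        state.extinct = True
    return n_lysed


def apply_bottleneck(
    state: PopulationState, config: SimConfig, rng: np.random.Generator
) -> PopulationState:
    """Dilute the culture: thin every class count binomially with p = 1/d.

    Free virions transfer with the supernatant and are thinned identically.
    Binomial thinning is the aggregated stand-in for sampling cells without
    replacement; at the model's census sizes the two are indistinguishable
    (the per-cell oracle implements the exact version).
    """
    p = 1.0 / config.d
    survivors: dict[tuple[int, int], int] = {}
    for cls, k in state.classes.items():
        kept = int(rng.binomial(k, p))
        if kept:
            survivors[cls] = kept
    state.classes = survivors
    state.pending_virions = int(rng.binomial(state.pending_virions, p))
    state.cycle += 1
    if not survivors:
        state.extinct = True
    return state


def make_record(
    state: PopulationState, config: SimConfig, n_lysed: int, gen_in_cycle: int
) -> GenerationRecord:
    n_cells = state.n_cells
    wt, mut = state.total_copies()
    total = wt + mut
    het = sum(k for (a, b), k in state.classes.items() if a >= 1 and b >= 1)
    carriers = sum(k for (_, b), k in state.classes.items() if b >= 1)
    return GenerationRecord(
        generation=state.generation,
        cycle=state.cycle,
        n_cells=n_cells,
        n_lysed=n_lysed,
        pending_virions=state.pending_virions,
        mutant_allele_freq=(mut / total) if total else 0.0,
        heterozygote_fraction=(het / n_cells) if n_cells else 0.0,
        mean_copy_number=(total / n_cells) if n_cells else 0.0,
        od_proxy=n_cells / (config.n0 * 2 ** gen_in_cycle),
        mutant_cell_fraction=(carriers / n_cells) if n_cells else 0.0,
    )


def run_simulation(config: SimConfig, rng: np.random.Generator | None = None) -> Trajectory:
    """Run the full serial-dilution model and record every generation.

    Event order within generation t: virions pending from generation t-1
    infect first, then all cells divide and segregate, lysis removes
    wild-type-free daughters and produces the next round of virions.  The
    cycle-end record is taken before the bottleneck, matching a measurement
    of the culture at the end of each dilution cycle.  Fully reproducible
    from ``config.rng_seed``.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    state = init_population(config)
    traj = Trajectory(config=config, records=[make_record(state, config, 0, 0)])
    if config.seed_generation == 0:
        seed_mutation(state, rng)
    g = config.gens_per_cycle
    for t in range(1, config.total_generations + 1):
        if state.extinct:
            break
        apply_reinfection(state, config, rng)
        n_lysed = divide_and_segregate(state, config, rng)
        gen_in_cycle = (t - 1) % g + 1
        traj.records.append(make_record(state, config, n_lysed, gen_in_cycle))
        if config.seed_generation == t:
            seed_mutation(state, rng)
        if t % g == 0 and t < config.total_generations:
            apply_bottleneck(state, config, rng)
    return traj
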