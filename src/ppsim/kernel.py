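"""Exact combinatorics of plasmid duplication and random segregation.

A host cell carries ``a`` wild-type and ``b`` mutant copies of a multicopy
phage-plasmid.  At division every copy is first duplicated, producing a pool
of ``2a`` wild-type and ``2b`` mutant copies, which is then partitioned
uniformly at random into two daughter cells of ``a + b`` copies each (copy
number per cell is conserved).  The number ``a1`` of wild-type copies
inherited by the first daughter therefore follows a hypergeometric law::

    P(a1) = C(2a, a1) * C(2b, a+b-a1) / C(2a+2b, a+b)

with support ``max(0, a-b) <= a1 <= min(2a, a+b)``.  The second daughter
receives the complement ``(2a - a1, 2b - (a+b-a1))``.

This kernel is what drives segregational drift: a heterozygous cell can
produce a daughter carrying only mutant copies (``a1 = 2a`` so the second
daughter has no wild-type), which in the full model loses repression of the
lytic genes and is killed.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.stats import hypergeom


@dataclass(frozen=True, order=True)
class GenotypeClass:
    """A host-cell genotype: copy counts of wild-type and mutant plasmid.

    Parameters
    ----------
    a : int
        Number of wild-type (lysogenic, repressor-intact) plasmid copies.
    b : int
        Number of mutant (constitutively lytic) plasmid copies.

    A cell always carries at least one plasmid copy in this model; plasmid-free
    segregants are not part of the dynamics.
    """

    a: int
    b: int

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0:
            raise ValueError(f"copy counts must be non-negative, got ({self.a}, {self.b})")
        if self.a + self.b < 1:
            raise ValueError("a cell must carry at least one plasmid copy")

    @property
    def copy_number(self) -> int:
        return self.a + self.b

    @property
    def is_heterozygous(self) -> bool:
        return self.a >= 1 and self.b >= 1


@dataclass(frozen=True)
class OffspringDistribution:
    """Full distribution over ordered daughter pairs for one parent genotype.

    ``outcomes`` lists ``(daughter1, daughter2, probability)`` for every value
    of ``a1`` in the hypergeometric support; probabilities sum to one and every
    outcome conserves the duplicated copy pool (``2a`` wild-type, ``2b``
    mutant) across the two daughters.
    """

    parent: GenotypeClass
    outcomes: tuple[tuple[GenotypeClass, GenotypeClass, float], ...]


@lru_cache(maxsize=None)
def segregation_pmf(a: int, b: int) -> tuple[np.ndarray, np.ndarray]:
    """Support and probabilities of ``a1``, the first daughter's wild-type count.

    Returns read-only arrays ``(values, probs)``; cached because the simulator
    evaluates the same genotype classes every generation.  Probabilities are
    computed in log space (via :func:`scipy.stats.hypergeom.pmf`) so large copy
    numbers do not overflow, and normalised to sum to exactly 1.0 in floating
    point so they can be fed to multinomial samplers.
    """
    if a < 0 or b < 0 or a + b < 1:
        raise ValueError(f"invalid genotype ({a}, {b})")
    n = a + b
    lo = max(0, a - b)
    hi = min(2 * a, n)
    values = np.arange(lo, hi + 1)
    if len(values) == 1:
        probs = np.ones(1)
    else:
        probs = hypergeom.pmf(values, 2 * a + 2 * b, 2 * a, n)
        probs = np.clip(probs, 0.0, None)
        probs = probs / probs.sum()
    values.setflags(write=False)
    probs.setflags(write=False)
    return values, probs


def daughter_distribution(parent: GenotypeClass) -> OffspringDistribution:
    """Exact offspring distribution of one cell division.

    Homozygous parents short-circuit to a single certain outcome: with only
    one allele present the daughters are copies of the parent.
    """
    a, b, n = parent.a, parent.b, parent.copy_number
    if a == 0 or b == 0:
        return OffspringDistribution(parent, ((parent, parent, 1.0),))
    values, probs = segregation_pmf(a, b)
    outcomes = []
    for a1, p in zip(values, probs):
        a1 = int(a1)
        d1 = GenotypeClass(a1, n - a1)
        d2 = GenotypeClass(2 * a - a1, 2 * b - (n - a1))
        outcomes.append((d1, d2, float(p)))
    return OffspringDistribution(parent, tuple(outcomes))


def prob_homozygous_mutant_daughter(parent: GenotypeClass) -> float:
    """Probability that a division yields >=1 daughter free of wild-type copies.

    Such a daughter carries only constitutively lytic plasmid and lyses.  The
    two events (first daughter has ``a1 = 0``; second daughter has ``a1 = 2a``)
    are disjoint for a >= 1, so the probability is the sum of the two extreme
    pmf terms.  It is zero exactly when ``0 < b < a`` (a daughter needs ``a+b``
    mutant copies but only ``2b < a+b`` exist in the pool), and one for a
    parent that has no wild-type copies at all.
    """
    a, b = parent.a, parent.b
    if a == 0:
        return 1.0
    if b < a:  # includes b == 0
        return 0.0
    values, probs = segregation_pmf(a, b)
    p = 0.0
    if values[0] == 0:
        p += float(probs[0])
    if values[-1] == 2 * a:
        p += float(probs[-1])
    return min(p, 1.0)


def prob_homozygous_wildtype_daughter(parent: GenotypeClass) -> float:
    """Probability that a division yields >=1 daughter free of mutant copies.

    Symmetric counterpart of :func:`prob_homozygous_mutant_daughter`; this is
    the segregational route by which a heterozygous mother produces cured,
    purely lysogenic offspring.
    """
    return prob_homozygous_mutant_daughter(GenotypeClass(parent.b, parent.a))


def sample_division(
    parent: GenotypeClass, rng: np.random.Generator
) -> tuple[GenotypeClass, GenotypeClass]:
    """Draw one daughter pair from the exact segregation kernel."""
    a, b, n = parent.a, parent.b, parent.copy_number
    if a == 0 or b == 0:
        return parent, parent
    a1 = int(rng.hypergeometric(2 * a, 2 * b, n))
    d1 = GenotypeClass(a1, n - a1)
    d2 = GenotypeClass(2 * a - a1, 2 * b - (n - a1))
    return d1, d2
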