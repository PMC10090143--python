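import numpy as np
import pytest

from ppsim.simulate import GenerationRecord, SimConfig, Trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_trajectory(freqs, config=None, n_lysed=None, gens_per_cycle=6):
    """Build a Trajectory with given per-generation allele frequencies."""
    if config is None:
        config = SimConfig(n0=1000, gens_per_cycle=gens_per_cycle, n_cycles=max(1, (len(freqs) - 1) // gens_per_cycle))
    if n_lysed is None:
        n_lysed = [0] * len(freqs)
    records = [
        GenerationRecord(
            generation=t,
            cycle=t // gens_per_cycle,
            n_cells=1000,
            n_lysed=n_lysed[t],
            pending_virions=0,
            mutant_allele_freq=float(f),
            heterozygote_fraction=0.0,
            mean_copy_number=1.0,
            od_proxy=1.0,
            mutant_cell_fraction=float(f),
        )
        for t, f in enumerate(freqs)
    ]
    return Trajectory(config=config, records=records)
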