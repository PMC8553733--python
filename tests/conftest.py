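import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from microhap.simulate import (SimulationConfig, simulate_coverage,
                               simulate_frequencies, simulate_genotypes)

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Three regions x two populations, eight loci: enough structure for
    every downstream stage, cheap enough to simulate per session."""
    return SimulationConfig(
        n_regions=3, populations_per_region=(2, 2, 2), n_loci=8,
        alleles_per_locus=(3, 6), region_drift=(0.02, 0.1, 0.2),
        population_drift=0.02, effective_size=200, sample_sizes=25, seed=11)


@pytest.fixture(scope="session")
def small_world(small_config):
    freqs = simulate_frequencies(small_config)
    genotypes = simulate_genotypes(freqs, small_config.sample_sizes, seed=12)
    coverage, truth = simulate_coverage(genotypes, seed=13)
    return {"config": small_config, "freqs": freqs, "genotypes": genotypes,
            "coverage": coverage, "truth": truth}


def make_coverage(total_reads, fracs=None, amplicon=None, n_loci=10):
    """Coverage table builder for QC tests: uniform amplicons unless given."""
    n = len(total_reads)
    fracs = fracs if fracs is not None else [0.95] * n
    rows = []
    for i in range(n):
        if amplicon is not None:
            per_locus = list(amplicon[i])
        else:
            per_locus = [total_reads[i] // n_loci] * n_loci
        rows.append([f"S{i:02d}", total_reads[i], fracs[i], *per_locus])
    loci = [f"L{k:02d}" for k in range(len(rows[0]) - 3)]
    return pd.DataFrame(rows, columns=["sample_id", "total_reads",
                                       "frac_bases_100x", *loci])
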