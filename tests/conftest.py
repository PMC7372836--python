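import numpy as np
import pandas as pd
import pytest

from stemethyl import io as mio
from stemethyl.synthetic import SyntheticConfig, generate_genome


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(seed=11, genome_length=80_000, n_chromosomes=2,
                           n_genes=8, n_tes=6, lambda_length=10_000)


@pytest.fixture(scope="session")
def small_genome(small_config):
    return generate_genome(small_config)


@pytest.fixture(scope="session")
def small_contexts(small_genome):
    return mio.classify_contexts(small_genome.sequences)


def random_calls(rng: np.random.Generator, n: int, chrom: str = "chr1",
                 length: int = 100_000) -> pd.DataFrame:
    """A random but valid call table (contexts not reference-consistent)."""
    pos = np.sort(rng.choice(length, size=n, replace=False))
    total = rng.poisson(30, size=n) + 1
    mc = rng.binomial(total, rng.beta(0.5, 0.5, size=n))
    return pd.DataFrame({
        "chrom": chrom,
        "pos": pos,
        "strand": rng.choice(["+", "-"], size=n),
        "context": rng.choice(["CG", "CHG", "CHH"], size=n),
        "mc_count": mc,
        "total_count": total,
    })
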