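import numpy as np
import pytest

from atacrna import motif as mo
from atacrna import synthetic as syn


@pytest.fixture(scope="session")
def uniform_bg() -> mo.MarkovBackground:
    return mo.MarkovBackground(0, np.array([0.25, 0.25, 0.25, 0.25]))


@pytest.fixture(scope="session")
def small_dataset() -> syn.SyntheticDataset:
    """A small but fully structured synthetic dataset (with genome)."""
    cfg = syn.SyntheticConfig.small(
        n_genes=12, n_chroms=4, n_peaks=60, chrom_length=500_000,
        fragments_per_sample=60_000, seed=5)
    return syn.generate_dataset(cfg, include_genome=True)


def random_sequences(rng: np.random.Generator, n: int, length: int):
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    return [bases[rng.integers(0, 4, size=length)].tobytes().decode("ascii")
            for _ in range(n)]
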