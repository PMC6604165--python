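import numpy as np
import pandas as pd
import pytest

from nuclize.intervals import NucleosomeMap
from nuclize.simulate import SimConfig, simulate_tables


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def tiled_map():
    """50 nucleosomes of 147 bp tiled every 200 bp on chr1."""
    starts = 100 + 200 * np.arange(50)
    return NucleosomeMap.from_intervals(
        pd.DataFrame(
            {
                "chrom": ["chr1"] * 50,
                "start": starts,
                "end": starts + 147,
                "dyad": starts + 73,
            }
        )
    )


@pytest.fixture(scope="session")
def tiny_sim():
    """Small full simulation shared by slower integration tests."""
    cfg = SimConfig(
        seed=7, chrom_length_bp=50_000, n_marked_random=20, n_artifacts=6,
        n_genes=6,
    )
    return simulate_tables(cfg)


def brute_force_assign(frags: pd.DataFrame, nucmap: NucleosomeMap) -> np.ndarray:
    """Exhaustive per-fragment scan over all nucleosomes (oracle)."""
    out = np.full(len(frags), -1, dtype=np.int64)
    nuc = list(nucmap)
    for i, row in enumerate(frags.itertuples(index=False)):
        mid = row.midpoint
        for n in nuc:
            if n.chrom == row.chrom and n.start <= mid < n.end:
                out[i] = n.id
                break
    return out
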