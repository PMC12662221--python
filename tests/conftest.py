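import numpy as np
import pytest

from tecomp.intervals import GenomicInterval, RegionSet
from tecomp.simulate import (
    default_cluster_spec,
    simulate_cluster_expression,
    simulate_regulome_dataset,
)


def random_region_set(rng: np.random.Generator, n: int, named: bool = True) -> RegionSet:
    """Random non-degenerate intervals on a few chromosomes (may overlap)."""
    chroms = rng.choice(["chr1", "chr2", "chr3"], size=n)
    starts = rng.integers(0, 5_000, size=n)
    lengths = rng.integers(1, 400, size=n)
    ivs = [
        GenomicInterval(
            str(c), int(s), int(s + l), name=f"iv{i:04d}" if named else None
        )
        for i, (c, s, l) in enumerate(zip(chroms, starts, lengths))
    ]
    return RegionSet(ivs)


@pytest.fixture(scope="session")
def regulome_sim():
    """Default synthetic regulome experiment, shared across tests."""
    return simulate_regulome_dataset(seed=1)


@pytest.fixture(scope="session")
def zero_noise_sim():
    return simulate_regulome_dataset(noise_sd=0.0, dose_ratio=1.0, seed=11)


@pytest.fixture(scope="session")
def cluster_sim():
    clusters_ref, clusters_query, match = default_cluster_spec()
    sim = simulate_cluster_expression(
        clusters_ref, clusters_query, separation=10.0, match=match, seed=1
    )
    return sim, match
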