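import logging

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from cernaforge.annotation import GeneModel
from cernaforge.pipeline import bundle_from_dataset
from cernaforge.synthetic_data import SimConfig, generate_dataset

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")

logging.getLogger("cernaforge").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_dataset():
    """One default-condition simulated dataset (seed 1), shared read-only."""
    return generate_dataset(SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_bundle(default_dataset):
    return bundle_from_dataset(default_dataset)


@pytest.fixture()
def toy_genes():
    """Two protein-coding genes on chr1 (g1: 3 exons, g2: 2 exons) and one on chr2."""
    g1 = GeneModel("g1", "chr1", "+", 100, 1000,
                   exons=[(100, 300), (500, 700), (900, 1000)])
    g2 = GeneModel("g2", "chr1", "+", 2000, 2600, exons=[(2000, 2200), (2400, 2600)])
    g3 = GeneModel("g3", "chr2", "-", 50, 500, exons=[(50, 200), (300, 500)])
    return [g1, g2, g3]


def make_junction(chrom, start, end, strand=".", name="j", reads=None, callers=None):
    from cernaforge.annotation import CircJunction

    reads = reads if reads is not None else {"Day4": 3.0}
    return CircJunction(chrom=chrom, start=start, end=end, strand=strand, name=name,
                        junction_reads=pd.Series(reads, dtype=float),
                        callers=set(callers or {"A"}))
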