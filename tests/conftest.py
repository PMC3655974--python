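import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import candidate_interactome as ci

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def toy_snps():
    """12 SNPs on two chromosomes with assorted p-values."""
    return [
        ci.SnpRecord("rs1", "1", 5_000, 0.20),
        ci.SnpRecord("rs2", "1", 12_000, 0.01),
        ci.SnpRecord("rs3", "1", 18_000, 0.04),
        ci.SnpRecord("rs4", "1", 40_000, 0.30),
        ci.SnpRecord("rs5", "1", 40_001, 0.002),
        ci.SnpRecord("rs6", "1", 90_000, 0.60),
        ci.SnpRecord("rs7", "1", 120_000, 0.03),
        ci.SnpRecord("rs8", "2", 8_000, 0.90),
        ci.SnpRecord("rs9", "2", 15_000, 0.049),
        ci.SnpRecord("rs10", "2", 15_500, 0.05),
        ci.SnpRecord("rs11", "2", 700_000, 0.001),
        ci.SnpRecord("rs12", "2", 2_000_000, 0.02),
    ]


@pytest.fixture
def toy_genes():
    return [
        ci.GeneRecord("GA", "1", 10_000, 20_000),
        ci.GeneRecord("GB", "1", 60_000, 80_000),
        ci.GeneRecord("GC", "1", 110_000, 130_000),
        ci.GeneRecord("GD", "2", 10_000, 16_000),
        ci.GeneRecord("GE", "2", 1_990_000, 2_010_000),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
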