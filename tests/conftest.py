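import numpy as np
import pandas as pd
import pytest

from prsdiff.config import SimulationConfig
from prsdiff.simulate import simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """One modest synthetic cohort shared across read-only tests."""
    cfg = SimulationConfig(seed=11, n_target=300, n_blocks=4, snps_per_block=25)
    return cfg, simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2357)


def qc_ready(cohort):
    """Variant table with per-variant stats plus string-chrom sumstats."""
    from prsdiff.qc import variant_stats

    stats = variant_stats(cohort["genotypes"], cohort["variants"])
    stats["chrom"] = stats["chrom"].astype(str)
    ss = cohort["sumstats"].copy()
    ss["chrom"] = ss["chrom"].astype(str)
    return stats, ss


@pytest.fixture(scope="session")
def small_qc(small_cohort):
    _, cohort = small_cohort
    return qc_ready(cohort)
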