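import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from popstrat.panels import GenotypePanel
from popstrat.simdata import SimConfig, simulate_dataset

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_panel(genotypes, pop="POP", chrom=None, pos=None, snp_ids=None, alleles=None):
    """GenotypePanel from a raw matrix with auto-generated labels."""
    g = np.asarray(genotypes, dtype=np.int8)
    n, m = g.shape
    return GenotypePanel(
        population_id=pop,
        animal_ids=[f"a{i}" for i in range(n)],
        snp_ids=snp_ids or [f"s{j}" for j in range(m)],
        chrom=chrom if chrom is not None else np.full(m, "1"),
        pos_bp=pos if pos is not None else (np.arange(m) + 1) * 10_000,
        genotypes=g,
        alleles=alleles,
    )


@pytest.fixture(scope="session")
def small_dataset():
    """One modest two-population dataset shared by read-only tests."""
    cfg = SimConfig(n_animals=150, n_snp=600, n_chrom=2, seed=11)
    return simulate_dataset(cfg)
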