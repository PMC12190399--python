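import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from phasekin import synthetic  # noqa: E402


@pytest.fixture(scope="session")
def small_genome():
    """A compact deterministic genome: 20 genes, 1 chromosome, mtDNA."""
    cfg = synthetic.SimConfig(n_genes=20, chrom_lengths=(60_000,), seed=42)
    return synthetic.make_genome(cfg)


@pytest.fixture(scope="session")
def small_rates(small_genome):
    return synthetic.truth_rates(small_genome)


@pytest.fixture(scope="session")
def small_timecourse(small_genome, small_rates):
    cfg = small_genome.config
    return synthetic.simulate_timecourse(small_rates, cfg.timepoints)


@pytest.fixture(scope="session")
def trna_genome():
    """Genome with tRNA genes carrying TFIIIB/TFIIIC/intron subregions."""
    cfg = synthetic.SimConfig(
        n_genes=60, n_trna=30, chrom_lengths=(170_000,),
        motif="CG", mean_site_interval=16, seed=7,
    )
    return synthetic.make_genome(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
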