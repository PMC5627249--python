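import numpy as np
import pytest

from grabld import BlockLD, SimConfig, run_theory_experiment
from grabld.simulate import write_cohort_fixture


@pytest.fixture(scope="session")
def theory_scaled():
    """Shared LD-correction theory run at reduced problem size.

    Block-LD region of 90 SNPs, 2,000 target individuals, external study of
    30,000, 500 replicates at each genetic-variance set-point — small enough
    to run in under a minute, large enough that Monte-Carlo error, not bias,
    dominates the covariance comparison.
    """
    config = SimConfig(
        m_snps=90,
        n_target=2000,
        n_external=30000,
        pool_haplotypes=20000,
        h2_grid=(0.1, 0.3, 0.5),
        n_reps=500,
        ld_model=BlockLD(),
        seed=11,
    )
    return run_theory_experiment(config)


@pytest.fixture(scope="session")
def cohort_fixture(tmp_path_factory):
    """Small simulated cohort written as PLINK + TSV files."""
    outdir = tmp_path_factory.mktemp("cohort")
    config = SimConfig(
        m_snps=60, n_target=120, n_external=5000, pool_haplotypes=2000, seed=5
    )
    paths, arrays = write_cohort_fixture(outdir, config)
    return paths, arrays


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
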