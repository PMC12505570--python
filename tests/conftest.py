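import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from subgenome_scan import SimParams, simulate

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cohort():
    """Small two-sub-genome cohort shared by read-only tests."""
    params = SimParams(seed=11, n_chrom_pairs=1, chrom_length=300_000,
                       pop_sizes=(8, 8), n_genes_per_chrom=6,
                       n_outlier_windows=1, outlier_window_size=50_000)
    return simulate(params)


@pytest.fixture(scope="session")
def cohort_files(cohort, tmp_path_factory):
    from subgenome_scan import write_cohort
    outdir = tmp_path_factory.mktemp("cohort")
    return write_cohort(cohort, str(outdir))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
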