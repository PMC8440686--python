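import logging

import pytest

from varprio import SimSpec, load_run_config, reanalyse_cohort, simulate_cohort

logging.getLogger("varprio").setLevel(logging.ERROR)

#: fixed seed of the end-to-end study cohort
STUDY_SEED = 97


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A 60-family fixture cohort: cheap, but still large enough that one
    family's homozygous causative allele (2 of 120 index alleles) stays under
    the 2% internal-frequency ceiling."""
    out = tmp_path_factory.mktemp("small-cohort")
    return simulate_cohort(SimSpec(seed=42, n_families=60, n_background_sites=500), out)


@pytest.fixture(scope="session")
def small_run(small_cohort):
    config = load_run_config(small_cohort.config_path)
    return config, reanalyse_cohort(config)


@pytest.fixture(scope="session")
def study_cohort(tmp_path_factory):
    """The 200-family synthetic study cohort used for end-to-end acceptance."""
    out = tmp_path_factory.mktemp("study-cohort")
    return simulate_cohort(SimSpec(seed=STUDY_SEED), out)


@pytest.fixture(scope="session")
def study_run(study_cohort):
    config = load_run_config(study_cohort.config_path)
    return config, reanalyse_cohort(config)
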