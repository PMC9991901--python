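import pytest

from proteorelapse.synthio import SynthConfig, generate_cohort

# A small but complete cohort: every biotype present, enough pairs for the
# paired statistics, fast enough to regenerate freely.
SMALL_COHORT = dict(
    n_pairs_adult=8,
    n_pairs_pediatric=6,
    n_controls=3,
    n_protein_coding=10,
    n_pseudogene=4,
    n_lincrna=2,
    n_antisense=2,
    n_proteins=400,
)


@pytest.fixture(scope="session")
def small_config():
    return SynthConfig(seed=11, **SMALL_COHORT)


@pytest.fixture(scope="session")
def cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory, small_config):
    out = tmp_path_factory.mktemp("cohort")
    generate_cohort(small_config, out)
    return out
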