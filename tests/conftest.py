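import numpy as np
import pytest

from gw2drug.synthetic_data import (
    GeneratorConfig,
    generate_bundle,
    paper_drug_fixture,
    table1_fixture,
    table1_gene_flags,
)

#: small, fast bundle used across pipeline-level tests
SMALL_CONFIG = GeneratorConfig(
    n_snps=30,
    fraction_significant=0.5,
    n_genes=12,
    mean_block_size=3.0,
    n_neighbor_genes=4,
    n_hit_drugs=6,
    n_drugs_in_trial=2,
    seed=11,
)


@pytest.fixture(scope="session")
def small_bundle():
    return generate_bundle(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_bundle_dir(small_bundle, tmp_path_factory):
    d = tmp_path_factory.mktemp("bundle")
    small_bundle.write(d)
    return d


@pytest.fixture(scope="session")
def table1():
    return table1_fixture()


@pytest.fixture(scope="session")
def table1_scores_input():
    return table1_gene_flags()


@pytest.fixture(scope="session")
def drug_fixture():
    return paper_drug_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)
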