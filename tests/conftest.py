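import numpy as np
import pytest

from scnanosim.counts import write_count_matrix
from scnanosim.fixtures import (
    make_synthetic_paf,
    make_toy_matrix,
    make_toy_reference,
    write_toy_reference,
)
from scnanosim.templates import load_transcriptome


@pytest.fixture(scope="session")
def toy_reference():
    return make_toy_reference(n_genes=5, isoforms_per_gene=2, seed=11)


@pytest.fixture(scope="session")
def toy_reference_paths(toy_reference, tmp_path_factory):
    return write_toy_reference(toy_reference, tmp_path_factory.mktemp("ref"))


@pytest.fixture(scope="session")
def toy_index(toy_reference_paths):
    return load_transcriptome(
        toy_reference_paths["transcripts"],
        toy_reference_paths["gtf"],
        toy_reference_paths["genome"],
    )


@pytest.fixture(scope="session")
def toy_matrix(toy_reference):
    return make_toy_matrix(
        list(toy_reference.gene_to_transcripts), n_cells=8, mean=1.5, seed=5
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
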