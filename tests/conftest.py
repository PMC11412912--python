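import numpy as np
import pytest

from synprot.synthetic_data import (
    SimulationDesign,
    make_gene_model,
    simulate_experiment,
)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def gene22():
    """22-exon gene with a full-length isoform and a truncation isoform
    starting at exon 17 (an alternative-transcription-start short form)."""
    return make_gene_model(
        n_exons=22, exon_len_range=(20, 60), seed=3,
        start_exons=["17"], gene_id="G",
    )


@pytest.fixture
def small_experiment():
    design = SimulationDesign(
        group_labels=["a"] * 3 + ["b"] * 3,
        n_proteins=8, n_peptides_per_protein=(3, 6),
        noise_cv=0.1, seed=7,
    )
    table, truth = simulate_experiment(design)
    return design, table, truth
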