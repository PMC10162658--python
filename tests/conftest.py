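import numpy as np
import pytest

from capsmhc.encoding import AlleleTable, load_substitution_matrix
from capsmhc.model import CapsNetMHC, records_to_Xy
from capsmhc.records import BindingRecord
from capsmhc.simulate import allele_table_entries, generate_alleles, generate_dataset


@pytest.fixture(scope="session")
def blosum62():
    return load_substitution_matrix("blosum62")


@pytest.fixture(scope="session")
def motif_models():
    return generate_alleles(2, seed=7, noise_sd=0.1)


@pytest.fixture(scope="session")
def allele_table(motif_models):
    return AlleleTable(allele_table_entries(motif_models))


@pytest.fixture(scope="session")
def small_dataset(motif_models):
    return generate_dataset(
        motif_models, n_per_allele=100, binder_fraction=0.4, noise_sd=0.1, seed=7
    )


@pytest.fixture(scope="session")
def small_labelled(small_dataset):
    """(records-with-binary-labels, pairs, targets, labels) for the small set."""
    pairs, y, labels = records_to_Xy(small_dataset.records)
    binary = [
        BindingRecord(r.peptide, r.allele, "binary", float(l))
        for r, l in zip(small_dataset.records, labels)
    ]
    return binary, pairs, y, labels


@pytest.fixture(scope="session")
def trained_small_model(allele_table, small_labelled):
    """A quickly trained capsule model on the small synthetic set."""
    binary, pairs, y, labels = small_labelled
    est = CapsNetMHC(
        allele_table=allele_table, loss="bce", epochs=25, lr=2e-3, random_state=0
    )
    est.fit(pairs, labels.astype(float))
    return est
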