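import numpy as np
import pytest

from qmerloc import (FixtureConfig, generate_annotations, generate_sequences,
                     select_gene_transcripts)

# The worked 3-mer example sequence used throughout the mismatch tests.
EXAMPLE_SEQ = "AGCUAGUA"

# Printed per-cell-line localization labels (1 cytoplasmic, 0 nuclear) for
# three genes observed in 13 of 14 cell lines; the dict omits the line with
# no CN-RCI value.
SWITCHING_EXAMPLES = {
    "ENSG00000264207": {
        "A549": 1, "GM12878": 0, "HeLa.S3": 0, "HepG2": 1, "HT1080": 1,
        "HUVEC": 1, "IMR.90": 0, "K562": 0, "MCF.7": 1, "NCI.H460": 0,
        "SK.MEL.5": 0, "SK.N.DZ": 1, "SK.N.SH": 1,
    },
    "ENSG00000248049": {
        "A549": 1, "GM12878": 1, "HeLa.S3": 0, "HepG2": 0, "HT1080": 1,
        "HUVEC": 0, "K562": 0, "MCF.7": 0, "NCI.H460": 1, "NHEK": 1,
        "SK.MEL.5": 0, "SK.N.DZ": 1, "SK.N.SH": 0,
    },
    "ENSG00000117242": {
        "A549": 0, "GM12878": 1, "HeLa.S3": 0, "HepG2": 1, "HT1080": 0,
        "HUVEC": 1, "IMR.90": 1, "K562": 1, "MCF.7": 0, "NCI.H460": 1,
        "NHEK": 0, "SK.N.DZ": 0, "SK.N.SH": 1,
    },
}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240614)


@pytest.fixture(scope="session")
def small_fixture_genes():
    """120 synthetic genes with the default planted-motif signal."""
    config = FixtureConfig(n_genes=120, seed=11)
    records, _ = generate_sequences(config)
    return select_gene_transcripts(records, generate_annotations(config))


def random_rna(rng, length):
    return "".join(np.array(list("ACGU"))[rng.integers(0, 4, size=length)])
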