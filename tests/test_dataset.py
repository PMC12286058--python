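"""Dataset construction: FASTA/RCI parsing, filtering, labels, splits."""

import numpy as np
import pytest

from qmerloc import (FixtureConfig, LocalizationAnnotation, SequenceRecord,
                     featurize, generate_annotations, generate_sequences,
                     grouped_split, label_by_threshold, read_fasta,
                     read_rci_table, select_gene_transcripts, to_fasta)

from conftest import random_rna


def _ann(gene, line="K562", rci=1.0):
    return LocalizationAnnotation(gene_id=gene, cell_line=line, cn_rci=rci)


def test_read_fasta_gencode_dialect(tmp_path):
    path = tmp_path / "t.fa"
    path.write_text(
        ">ENST0000000001.1|ENSG0000000009.2|x|y\nACGTACGT\n"
        ">ENST0000000002.7|ENSG0000000010.1|\nacgtacgt\n")
    records = read_fasta(path)
    assert len(records) == 2
    assert records[0].transcript_id == "ENST0000000001"
    assert records[0].gene_id == "ENSG0000000009"
    assert records[0].sequence == "ACGUACGU"  # canonicalized DNA -> RNA
    assert records[1].sequence == "ACGUACGU"


def test_read_fasta_plain_dialect(tmp_path):
    path = tmp_path / "t.fa"
    path.write_text(">TX1.3 gene=G9.1 extra\nACGU\n")
    (rec,) = read_fasta(path)
    assert (rec.transcript_id, rec.gene_id) == ("TX1", "G9")


def test_read_fasta_skips_bad_header_errors_when_empty(tmp_path):
    path = tmp_path / "t.fa"
    path.write_text(">no_gene_info_here\nACGU\n")
    with pytest.raises(ValueError):
        read_fasta(path)
    path.write_text("")
    with pytest.raises(ValueError):
        read_fasta(path)


def test_read_rci_table_drop_rules(tmp_path):
    path = tmp_path / "rci.tsv"
    path.write_text(
        "gene_id\tcell_line\tcn_rci\tbiotype\n"
        "ENSG01\tK562\t1.3\tnc\n"
        "ENSG01\tK562\t\tnc\n"          # NaN CN-RCI dropped
        "ENSG02\tK562\t0.5\tcoding\n")   # coding biotype dropped
    anns = read_rci_table(path)
    assert len(anns) == 1
    assert anns[0].gene_id == "ENSG01" and anns[0].cn_rci == 1.3


def test_read_rci_table_missing_columns(tmp_path):
    path = tmp_path / "rci.tsv"
    path.write_text("gene_id\tsomething\n" "G1\t2\n")
    with pytest.raises(ValueError, match="cell_line"):
        read_rci_table(path)


def test_select_longest_transcript_and_bounds(rng):
    genes = [
        SequenceRecord("G1", "T1a", random_rna(rng, 300)),
        SequenceRecord("G1", "T1b", random_rna(rng, 900)),
        SequenceRecord("G2", "T2", random_rna(rng, 199)),   # too short
        SequenceRecord("G3", "T3", random_rna(rng, 200)),   # boundary kept
        SequenceRecord("G4", "T4", random_rna(rng, 5001)),  # too long
        SequenceRecord("G5", "T5", random_rna(rng, 400)),   # unannotated
    ]
    anns = [_ann(g) for g in ("G1", "G2", "G3", "G4")]
    selected = select_gene_transcripts(genes, anns)
    by_gene = {g.gene_id: g for g in selected}
    assert set(by_gene) == {"G1", "G3"}
    assert by_gene["G1"].transcript.transcript_id == "T1b"


def test_select_tie_breaks_lexicographically(rng):
    seq = random_rna(rng, 250)
    records = [SequenceRecord("G1", "T1b", seq),
               SequenceRecord("G1", "T1a", seq)]
    (gene,) = select_gene_transcripts(records, [_ann("G1")])
    assert gene.transcript.transcript_id == "T1a"


@pytest.mark.parametrize("rci, label", [
    (0.0, 1),   # the boundary belongs to the cytoplasmic class
    (-1.2, 0),
    (2.8, 1),
])
def test_label_by_threshold(rci, label):
    assert label_by_threshold(rci) == label


def test_label_by_threshold_rejects_nonfinite():
    with pytest.raises(ValueError):
        label_by_threshold(float("nan"))


def test_grouped_split_ratio_determinism_no_leakage(small_fixture_genes):
    train, test = grouped_split(small_fixture_genes, 0.2, seed=7)
    assert len(test) == round(0.2 * len(small_fixture_genes))
    train2, test2 = grouped_split(small_fixture_genes, 0.2, seed=7)
    assert [g.gene_id for g in train] == [g.gene_id for g in train2]
    assert not ({g.gene_id for g in train} & {g.gene_id for g in test})


def test_grouped_split_requires_five_genes(small_fixture_genes):
    with pytest.raises(ValueError):
        grouped_split(small_fixture_genes[:4])


def test_featurize_shapes_and_monotonicity(small_fixture_genes):
    genes = small_fixture_genes[:10]
    fm0 = featurize(genes, "CL1", 3, 0, normalize=False)
    fm1 = featurize(genes, "CL1", 3, 1, normalize=False)
    assert fm0.X.shape == (10, 64)
    assert (fm1.X >= fm0.X).all()
    assert set(np.unique(fm0.y)) <= {0, 1}
    assert fm0.gene_ids == sorted(fm0.gene_ids)


def test_featurize_excludes_unlabeled_gene(small_fixture_genes):
    genes = list(small_fixture_genes[:6])
    clone = genes[0]
    # remove CL1 from one gene: it must vanish from the CL1 matrix
    genes[0] = type(clone)(gene_id=clone.gene_id, transcript=clone.transcript,
                           labels={k: v for k, v in clone.labels.items()
                                   if k != "CL1"},
                           cn_rci={k: v for k, v in clone.cn_rci.items()
                                   if k != "CL1"})
    fm = featurize(genes, "CL1", 3, 0)
    assert clone.gene_id not in fm.gene_ids
    assert len(fm.gene_ids) == 5


def test_featurize_errors_on_unknown_cell_line(small_fixture_genes):
    with pytest.raises(ValueError):
        featurize(small_fixture_genes, "NOPE", 3, 0)


def test_roundtrip_fixture_through_files(tmp_path):
    """Generated FASTA + RCI table parse back into the same dataset."""
    config = FixtureConfig(n_genes=20, seed=2)
    records, _ = generate_sequences(config)
    (tmp_path / "genes.fa").write_text(to_fasta(records))
    from qmerloc import generate_rci_table
    generate_rci_table(config).to_csv(tmp_path / "rci.tsv", sep="\t",
                                      index=False)
    parsed = read_fasta(tmp_path / "genes.fa")
    assert [r.sequence for r in parsed] == [r.sequence for r in records]
    anns = read_rci_table(tmp_path / "rci.tsv")
    genes = select_gene_transcripts(parsed, anns)
    assert len(genes) == 20
    direct = select_gene_transcripts(records, generate_annotations(config))
    assert [g.gene_id for g in genes] == [g.gene_id for g in direct]
    assert all(a.labels == b.labels for a, b in zip(genes, direct))
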