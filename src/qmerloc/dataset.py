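"""Dataset construction: FASTA + CN-RCI tables -> labeled feature matrices.

Follows the lncATLAS/GENCODE construction: join transcripts to per-gene,
per-cell-line CN-RCI values (log2 cytoplasmic/nuclear concentration
ratio), keep genes whose longest transcript is 200-5000 nt, label a gene
cytoplasmic (1) when CN-RCI >= threshold (default 0, no middle
exclusion) and nuclear (0) otherwise, and split train/test at the gene
level so no gene leaks across partitions.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

from .mismatch import (SequenceRecord, canonicalize_sequence,
                       mismatch_profile, normalize_profile)

logger = logging.getLogger(__name__)

_VERSION_RE = re.compile(r"\.\d+$")


def _strip_version(accession: str) -> str:
    return _VERSION_RE.sub("", accession)


@dataclass(frozen=True)
class LocalizationAnnotation:
    """One (gene, cell line, CN-RCI) observation from an annotation table."""

    gene_id: str
    cell_line: str
    cn_rci: float
    biotype: str = "nc"

    def __post_init__(self):
        if not self.cell_line:
            raise ValueError("cell_line must be non-empty")
        if not math.isfinite(self.cn_rci):
            raise ValueError(f"CN-RCI must be finite, got {self.cn_rci}")


@dataclass
class LabeledGene:
    """A gene with its chosen (longest) transcript and per-cell-line labels."""

    gene_id: str
    transcript: SequenceRecord
    labels: dict[str, int]
    cn_rci: dict[str, float] = field(default_factory=dict)


@dataclass
class FeatureMatrix:
    """Row-per-gene profile matrix with binary labels for one cell line."""

    gene_ids: list[str]
    X: np.ndarray
    y: np.ndarray
    q: int
    k: int
    normalized: bool
    cell_line: str
    threshold: float = 0.0

    def __post_init__(self):
        if not (len(self.gene_ids) == self.X.shape[0] == self.y.shape[0]):
            raise ValueError("gene_ids, X and y must be congruent")


def _parse_header(description: str) -> tuple[str, str] | None:
    """Extract (transcript_id, gene_id) from a FASTA header.

    Accepts the GENCODE pipe-delimited dialect
    ``ENST...|ENSG...|...`` and a plain ``transcript_id gene=gene_id``
    dialect.  Version suffixes are stripped for joining.
    """
    token = description.split()[0]
    if "|" in token:
        parts = token.split("|")
        if len(parts) >= 2 and parts[0] and parts[1]:
            return _strip_version(parts[0]), _strip_version(parts[1])
        return None
    m = re.search(r"gene=(\S+)", description)
    if m:
        return _strip_version(token), _strip_version(m.group(1))
    return None


def read_fasta(path) -> list[SequenceRecord]:
    """Read transcripts from FASTA; skip entries with unparseable headers."""
    records = []
    for entry in SeqIO.parse(str(path), "fasta"):
        parsed = _parse_header(entry.description)
        if parsed is None:
            logger.warning("skipping FASTA entry with unparseable header: %s",
                           entry.description)
            continue
        transcript_id, gene_id = parsed
        records.append(SequenceRecord(
            gene_id=gene_id,
            transcript_id=transcript_id,
            sequence=canonicalize_sequence(str(entry.seq)),
        ))
    if not records:
        raise ValueError(f"no usable FASTA records in {path}")
    return records


_COLUMN_ALIASES = {
    "gene_id": {"gene_id", "gene", "geneid", "ensembl_id", "ensembl_gene_id"},
    "cell_line": {"cell_line", "cellline", "data_source"},
    "cn_rci": {"cn_rci", "cnrci", "rci", "value"},
    "biotype": {"biotype", "coding_type"},
}

_NONCODING = {"nc", "noncoding", "non-coding", "non_coding", "lncrna", "lincrna"}


def _resolve_columns(columns) -> dict[str, str]:
    normalized = {re.sub(r"[\s.-]+", "_", c.strip().lower()): c for c in columns}
    resolved = {}
    for canonical, aliases in _COLUMN_ALIASES.items():
        for norm, original in normalized.items():
            if norm in aliases:
                resolved[canonical] = original
                break
    return resolved


def read_rci_table(path) -> list[LocalizationAnnotation]:
    """Read a delimited CN-RCI annotation table.

    Rows with missing CN-RCI are dropped; when a biotype column exists,
    only non-coding rows are kept.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    cols = _resolve_columns(df.columns)
    missing = [c for c in ("gene_id", "cell_line", "cn_rci") if c not in cols]
    if missing:
        raise ValueError(f"annotation table missing required columns: {missing}")
    df = df.dropna(subset=[cols["cn_rci"]])
    if "biotype" in cols:
        biotype = df[cols["biotype"]].astype(str).str.strip().str.lower()
        df = df[biotype.isin(_NONCODING)]
    out = []
    for row in df.itertuples(index=False):
        r = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        out.append(LocalizationAnnotation(
            gene_id=_strip_version(str(r[cols["gene_id"]]).strip()),
            cell_line=str(r[cols["cell_line"]]).strip(),
            cn_rci=float(r[cols["cn_rci"]]),
            biotype=str(r[cols["biotype"]]).strip() if "biotype" in cols else "nc",
        ))
    return out


def label_by_threshold(cn_rci: float, threshold: float = 0.0) -> int:
    """1 (cytoplasmic) iff CN-RCI >= threshold, else 0 (nuclear)."""
    if not math.isfinite(cn_rci):
        raise ValueError(f"CN-RCI must be finite, got {cn_rci}")
    return 1 if cn_rci >= threshold else 0


def select_gene_transcripts(records: list[SequenceRecord],
                            annotations: list[LocalizationAnnotation],
                            min_len: int = 200, max_len: int = 5000,
                            threshold: float = 0.0) -> list[LabeledGene]:
    """Keep, per annotated gene, the longest transcript with length in bounds.

    Bounds are inclusive (an lncRNA is >= 200 nt by definition, so 200
    is admissible).  Length ties break to the lexicographically smallest
    transcript_id for determinism.  Genes with no annotation, or whose
    transcripts all fall outside the bounds, are dropped.
    """
    by_gene: dict[str, dict[str, float]] = {}
    for a in annotations:
        by_gene.setdefault(a.gene_id, {})[a.cell_line] = a.cn_rci

    candidates: dict[str, SequenceRecord] = {}
    for rec in records:
        if rec.gene_id not in by_gene:
            continue
        if not (min_len <= len(rec) <= max_len):
            continue
        best = candidates.get(rec.gene_id)
        if (best is None or len(rec) > len(best)
                or (len(rec) == len(best) and rec.transcript_id < best.transcript_id)):
            candidates[rec.gene_id] = rec

    genes = []
    for gene_id in sorted(candidates):
        rci = by_gene[gene_id]
        genes.append(LabeledGene(
            gene_id=gene_id,
            transcript=candidates[gene_id],
            labels={cl: label_by_threshold(v, threshold) for cl, v in rci.items()},
            cn_rci=dict(rci),
        ))
    if not genes:
        raise ValueError("no genes survive the join and length filters")
    return genes


def grouped_split(genes: list[LabeledGene], test_fraction: float = 0.2,
                  seed: int = 0) -> tuple[list[LabeledGene], list[LabeledGene]]:
    """Gene-level train/test partition (default 4:1); no gene on both sides."""
    if len(genes) < 5:
        raise ValueError(f"need at least 5 genes to split, got {len(genes)}")
    ordered = sorted(genes, key=lambda g: g.gene_id)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ordered))
    n_test = int(round(test_fraction * len(ordered)))
    test_idx = set(perm[:n_test].tolist())
    train = [g for i, g in enumerate(ordered) if i not in test_idx]
    test = [g for i, g in enumerate(ordered) if i in test_idx]
    return train, test


def featurize(genes: list[LabeledGene], cell_line: str, q: int, k: int,
              normalize: bool = True, threshold: float = 0.0) -> FeatureMatrix:
    """Build the (q, k)-mismatch feature matrix for genes labeled in a cell line.

    Rows are sorted by gene_id; genes without a CN-RCI in ``cell_line``
    are excluded.
    """
    labeled = sorted((g for g in genes if cell_line in g.labels),
                     key=lambda g: g.gene_id)
    if not labeled:
        raise ValueError(f"no genes labeled in cell line {cell_line!r}")
    rows, y, ids = [], [], []
    for g in labeled:
        profile = mismatch_profile(g.transcript, q, k)
        if normalize:
            profile = normalize_profile(profile)
        rows.append(profile.values)
        if g.cn_rci:
            y.append(label_by_threshold(g.cn_rci[cell_line], threshold))
        else:
            y.append(g.labels[cell_line])
        ids.append(g.gene_id)
    return FeatureMatrix(gene_ids=ids, X=np.vstack(rows),
                         y=np.array(y, dtype=np.int64),
                         q=q, k=k, normalized=normalize,
                         cell_line=cell_line, threshold=threshold)
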