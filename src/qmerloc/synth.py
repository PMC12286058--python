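"""Synthetic fixtures: random RNA with planted motifs + CN-RCI tables.

The sequence generator emits uniform-random RNA backbones and plants
class-discriminative q-length motifs into each sequence according to
its class, optionally corrupting each planted copy with point
substitutions.  Corrupted planting is what makes the central premise of
the mismatch profile testable synthetically: exact q-mer counts spread
over the corrupted variants while a (q, k>=1) profile re-concentrates
them onto the canonical motif.

The annotation generator emits a matching lncATLAS-style CN-RCI table:
each gene gets a base effect whose sign follows its class, plus
per-cell-line Gaussian noise; a controllable fraction of genes are
planted as *switching* genes whose CN-RCI sign alternates across cell
lines so their cytoplasmic/nuclear counts stay within one of each
other.

Class and switching assignments are deterministic functions of the gene
index, so the two generators agree without sharing random state: gene i
has class i % 2, and the last ``round(switching_fraction * n)`` genes
are the switching ones.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import LocalizationAnnotation
from .mismatch import ALPHABET, SequenceRecord

DEFAULT_MOTIFS = {
    1: ("GCGUAC", "AUCGCA", "CGUUGG"),  # cytoplasmic class
    0: ("UACGUA", "GGAUCC", "CAACGU"),  # nuclear class
}

DEFAULT_CELL_LINES = ("CL1", "CL2", "CL3", "CL4", "CL5", "CL6")


@dataclass(frozen=True)
class FixtureConfig:
    """Study conditions for the synthetic fixtures.

    Defaults give a clearly separable two-class problem: 400 genes,
    200-500 nt (inside the 200-5000 nt lncRNA window, short enough that
    planted 6-mers stand out against the background), eight exact motif
    copies per sequence (roughly one recognition element per 50 nt, the
    density of a strongly repeated protein-binding element), a +/-2
    log2-unit localization effect with 0.5 sd per-cell-line noise, and
    no switching genes.
    """

    n_genes: int = 400
    length_range: tuple[int, int] = (200, 500)
    motifs: dict[int, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_MOTIFS))
    motif_rate: float = 1.0
    copies: int = 8
    corruption_subs: int = 0
    cell_lines: tuple[str, ...] = DEFAULT_CELL_LINES
    effect_size: float = 2.0
    noise_sd: float = 0.5
    switching_fraction: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.length_range
        if not (200 <= lo <= hi <= 5000):
            raise ValueError("length_range must lie within [200, 5000]")
        if not 0.0 <= self.motif_rate <= 1.0:
            raise ValueError("motif_rate must be in [0, 1]")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be in [0, 1]")
        if not 0.0 <= self.switching_fraction <= 1.0:
            raise ValueError("switching_fraction must be in [0, 1]")
        for motif_list in self.motifs.values():
            for m in motif_list:
                if len(m) > lo:
                    raise ValueError(
                        f"motif {m!r} longer than minimum length {lo}")

    def gene_id(self, i: int) -> str:
        return f"SYNTG{i:06d}"

    def gene_class(self, i: int) -> int:
        return i % 2

    def is_switching(self, i: int) -> bool:
        n_switch = int(round(self.switching_fraction * self.n_genes))
        return i >= self.n_genes - n_switch


def generate_sequences(config: FixtureConfig
                       ) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Random backbones with class motifs planted at ``motif_rate``.

    Returns the transcript records and a truth table (gene_id, class,
    switching flag, planted motif count and positions).
    """
    rng = np.random.default_rng([config.seed, 0])
    lo, hi = config.length_range
    alphabet = np.array(list(ALPHABET))
    records, truth = [], []
    for i in range(config.n_genes):
        cls = config.gene_class(i)
        length = int(rng.integers(lo, hi + 1))
        seq = rng.integers(0, 4, size=length)
        positions: list[int] = []
        motif_list = config.motifs.get(cls, ())
        if motif_list and rng.random() < config.motif_rate:
            for _ in range(config.copies):
                motif = motif_list[rng.integers(0, len(motif_list))]
                codes = np.array([ALPHABET.index(c) for c in motif])
                if config.corruption_subs:
                    pos = rng.choice(len(codes),
                                     size=min(config.corruption_subs,
                                              len(codes)),
                                     replace=False)
                    for p in pos:
                        codes[p] = (codes[p] + rng.integers(1, 4)) % 4
                start = int(rng.integers(0, length - len(codes) + 1))
                seq[start:start + len(codes)] = codes
                positions.append(start)
        gene_id = config.gene_id(i)
        records.append(SequenceRecord(
            gene_id=gene_id, transcript_id=gene_id + "T1",
            sequence="".join(alphabet[seq])))
        truth.append({"gene_id": gene_id, "cls": cls,
                      "switching": config.is_switching(i),
                      "n_motifs": len(positions),
                      "positions": ";".join(map(str, positions))})
    return records, pd.DataFrame(truth)


def generate_rci_table(config: FixtureConfig) -> pd.DataFrame:
    """lncATLAS-style long table: gene_id, cell_line, cn_rci, gene_name, biotype."""
    rng = np.random.default_rng([config.seed, 1])
    lines = list(config.cell_lines)
    rows = []
    for i in range(config.n_genes):
        cls = config.gene_class(i)
        base = config.effect_size if cls == 1 else -config.effect_size
        for j, line in enumerate(lines):
            if config.is_switching(i):
                # alternate compartments across lines -> |C - N| <= 1
                mu = config.effect_size if j % 2 == 0 else -config.effect_size
            else:
                mu = base
            rows.append({"gene_id": config.gene_id(i), "cell_line": line,
                         "cn_rci": mu + rng.normal(0.0, config.noise_sd),
                         "gene_name": f"SYN-{i}", "biotype": "nc"})
    df = pd.DataFrame(rows)
    if config.missing_rate > 0:
        keep = rng.random(len(df)) >= config.missing_rate
        # never orphan a gene entirely
        first_of_gene = ~df["gene_id"].duplicated()
        df = df[keep | first_of_gene].reset_index(drop=True)
    return df


def generate_annotations(config: FixtureConfig) -> list[LocalizationAnnotation]:
    """The CN-RCI table as LocalizationAnnotation objects."""
    df = generate_rci_table(config)
    return [LocalizationAnnotation(gene_id=r.gene_id, cell_line=r.cell_line,
                                   cn_rci=float(r.cn_rci), biotype=r.biotype)
            for r in df.itertuples(index=False)]


def to_fasta(records: list[SequenceRecord], width: int = 60) -> str:
    """GENCODE-dialect FASTA text (transcript|gene pipe headers)."""
    buf = io.StringIO()
    for rec in records:
        buf.write(f">{rec.transcript_id}|{rec.gene_id}|\n")
        for start in range(0, len(rec.sequence), width):
            buf.write(rec.sequence[start:start + width] + "\n")
    return buf.getvalue()
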