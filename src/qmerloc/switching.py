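"""Switching-gene census: lncRNAs whose compartment flips across cell lines.

For each gene, its CN-RCI value in each cell line is thresholded into a
binary label (1 cytoplasmic, 0 nuclear).  C counts the cell lines where
the gene is cytoplasmic and N where it is nuclear; a *switching*
(shuttling) gene is one observed in both compartments in at least two
cell lines each with near-balanced counts:

    C > 1  and  N > 1  and  |C - N| <= 1.

The H1.hESC cell line, an outlier with low CN-RCI correlation to the
other lines, is excluded by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .dataset import LocalizationAnnotation, label_by_threshold

DEFAULT_EXCLUDE = ("H1.hESC",)


@dataclass
class SwitchingRow:
    gene_id: str
    labels: dict[str, int]

    @property
    def c(self) -> int:
        """Number of cell lines where the gene is cytoplasmic."""
        return sum(v == 1 for v in self.labels.values())

    @property
    def n(self) -> int:
        """Number of cell lines where the gene is nuclear."""
        return sum(v == 0 for v in self.labels.values())

    @property
    def cell_count(self) -> int:
        return len(self.labels)

    @property
    def diff(self) -> int:
        return self.c - self.n

    @property
    def is_switching(self) -> bool:
        return self.c > 1 and self.n > 1 and abs(self.diff) <= 1


def localization_table(annotations: list[LocalizationAnnotation],
                       threshold: float = 0.0,
                       exclude: tuple[str, ...] = DEFAULT_EXCLUDE
                       ) -> list[SwitchingRow]:
    """One row per gene with its per-cell-line binary labels and C/N counts."""
    excluded = set(exclude)
    labels: dict[str, dict[str, int]] = {}
    lines = set()
    for a in annotations:
        if a.cell_line in excluded:
            continue
        lines.add(a.cell_line)
        labels.setdefault(a.gene_id, {})[a.cell_line] = label_by_threshold(
            a.cn_rci, threshold)
    if len(lines) < 2:
        raise ValueError(
            "need annotations spanning at least 2 cell lines after exclusion")
    return [SwitchingRow(gene_id=g, labels=labels[g]) for g in sorted(labels)]


def identify_switching(rows: list[SwitchingRow]) -> list[str]:
    """Gene IDs meeting the switching criterion, sorted."""
    return sorted(r.gene_id for r in rows if r.is_switching)


def switching_frame(rows: list[SwitchingRow]) -> pd.DataFrame:
    """Census table: per-line labels plus Cell Count / N / C / C-N columns."""
    lines = sorted({cl for r in rows for cl in r.labels})
    data = []
    for r in rows:
        record = {"gene_id": r.gene_id}
        record.update({cl: r.labels.get(cl, pd.NA) for cl in lines})
        record.update({"Cell Count": r.cell_count, "Nuclear (N)": r.n,
                       "Cyto (C)": r.c, "C-N": r.diff,
                       "switching": r.is_switching})
        data.append(record)
    return pd.DataFrame(data)
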