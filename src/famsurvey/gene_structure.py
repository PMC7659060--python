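"""Stage 4 — exon/intron/UTR summaries and per-group structure statistics."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from famsurvey.io_formats import GeneModel, ValidationError, log


@dataclass
class StructureSummary:
    """Exon/intron/UTR layout of one gene's representative transcript."""

    gene_id: str
    exon_count: int
    intron_count: int
    has_utr5: bool
    has_utr3: bool
    intron_lengths: list[int]

    def __post_init__(self) -> None:
        if self.intron_count != self.exon_count - 1:
            raise ValidationError(
                f"{self.gene_id}: intron count {self.intron_count} != "
                f"exon count {self.exon_count} - 1"
            )
        if any(length <= 0 for length in self.intron_lengths):
            raise ValidationError(f"{self.gene_id}: non-positive intron length")


def summarize_structure(
    gene_models: Sequence[GeneModel],
) -> list[StructureSummary]:
    """Introns are the gaps between consecutive exons (transcription order
    does not change counts or lengths, so genomic order is used)."""
    summaries = []
    for gm in gene_models:
        for (s1, e1), (s2, e2) in zip(gm.exons, gm.exons[1:]):
            if s2 <= e1:
                raise ValidationError(f"{gm.gene_id}: overlapping exons")
        introns = [s2 - e1 - 1 for (s1, e1), (s2, e2) in zip(gm.exons, gm.exons[1:])]
        if any(i <= 0 for i in introns):
            raise ValidationError(f"{gm.gene_id}: adjacent exons with no intron gap")
        summaries.append(
            StructureSummary(
                gene_id=gm.gene_id,
                exon_count=len(gm.exons),
                intron_count=len(gm.exons) - 1,
                has_utr5=bool(gm.utr5),
                has_utr3=bool(gm.utr3),
                intron_lengths=introns,
            )
        )
    return summaries


def group_structure_stats(
    summaries: Iterable[StructureSummary],
    clade_assignment: dict[str, str],
) -> pd.DataFrame:
    """Per-group member count, single/multi-intron fractions and mean exon
    count.  Groups with no summarized member are omitted with a warning."""
    by_group: dict[str, list[StructureSummary]] = {}
    for summary in summaries:
        if summary.gene_id not in clade_assignment:
            raise ValidationError(
                f"{summary.gene_id}: no group assignment"
            )
        by_group.setdefault(clade_assignment[summary.gene_id], []).append(summary)

    for group in sorted(set(clade_assignment.values()) - set(by_group)):
        log("structure", f"group {group!r} has no summarized genes; omitted")

    rows = []
    for group in sorted(by_group):
        members = by_group[group]
        n = len(members)
        rows.append(
            {
                "group": group,
                "n_genes": n,
                "fraction_zero_intron": sum(
                    1 for m in members if m.intron_count == 0
                ) / n,
                "fraction_one_intron": sum(
                    1 for m in members if m.intron_count == 1
                ) / n,
                "fraction_multi_intron": sum(
                    1 for m in members if m.intron_count >= 2
                ) / n,
                "mean_exon_count": sum(m.exon_count for m in members) / n,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["group", "n_genes", "fraction_zero_intron",
                 "fraction_one_intron", "fraction_multi_intron",
                 "mean_exon_count"],
    )


def structure_table(summaries: Iterable[StructureSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": s.gene_id,
                "exon_count": s.exon_count,
                "intron_count": s.intron_count,
                "has_utr5": s.has_utr5,
                "has_utr3": s.has_utr3,
                "intron_lengths": ",".join(str(l) for l in s.intron_lengths),
            }
            for s in summaries
        ],
        columns=["gene_id", "exon_count", "intron_count", "has_utr5",
                 "has_utr3", "intron_lengths"],
    )
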