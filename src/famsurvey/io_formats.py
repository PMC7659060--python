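"""Readers/writers for the external formats the survey touches.

All genomic coordinates are GFF3-style 1-based inclusive throughout the
package; a 1 bp feature has start == end.  FASTA parsing is delegated to
Biopython and GFF3 parsing to gffutils; this module adds the validation the
pipeline's contracts require (duplicate ids, CDS-within-exon checks,
representative-isoform selection) and the flat TSV tables the stages
exchange.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO

Interval = tuple[int, int]

#: Closed vocabulary of conserved-domain names the census understands.
#: inhibitor_I29 is the auto-inhibitory prodomain, peptidase_C1 the papain
#: catalytic domain, GRAN the C-terminal granulin domain; the propeptide_C1 +
#: cathepsin-B pair is the alternative architecture seen in a minority of
#: family members.
DOMAIN_NAMES = frozenset(
    {
        "inhibitor_I29",
        "peptidase_C1",
        "GRAN",
        "propeptide_C1",
        "peptidase_C1A_cathepsinB",
    }
)


class ParseError(ValueError):
    """Malformed external input (carries file/line context in the message)."""


class ValidationError(ValueError):
    """Structurally parseable input that violates a pipeline invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


def _check_intervals(name: str, ivs: Sequence[Interval], gene_id: str) -> None:
    for s, e in ivs:
        if s < 1 or e < s:
            raise ValidationError(
                f"gene {gene_id}: bad {name} interval ({s}, {e})"
            )
    for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
        if s2 <= e1:
            raise ValidationError(
                f"gene {gene_id}: {name} intervals unsorted or overlapping"
            )


@dataclass
class GeneModel:
    """A gene's representative transcript structure on its chromosome.

    ``exons``/``cds``/``utr5``/``utr3`` are ordered lists of 1-based
    inclusive (start, end) intervals in ascending genomic coordinate,
    regardless of strand.
    """

    gene_id: str
    chromosome: str
    strand: str
    span: Interval
    exons: list[Interval]
    cds: list[Interval] = field(default_factory=list)
    utr5: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        _check_intervals("exon", self.exons, self.gene_id)
        _check_intervals("cds", self.cds, self.gene_id)
        if self.exons:
            lo = min(s for s, _ in self.exons)
            hi = max(e for _, e in self.exons)
            if self.span[0] > lo or self.span[1] < hi:
                raise ValidationError(
                    f"gene {self.gene_id}: span {self.span} does not cover exons"
                )
        for cs, ce in self.cds:
            if not any(es <= cs and ce <= ee for es, ee in self.exons):
                raise ValidationError(
                    f"gene {self.gene_id}: CDS ({cs}, {ce}) not contained in any exon"
                )

    @property
    def n_exons(self) -> int:
        return len(self.exons)


@dataclass(frozen=True)
class DomainHit:
    """One conserved-domain match on a protein (1-based residue coords)."""

    protein_id: str
    domain: str
    start: int
    end: int
    reference_length: int

    def __post_init__(self) -> None:
        if self.domain not in DOMAIN_NAMES:
            raise ValidationError(f"unknown domain name {self.domain!r}")
        if not (1 <= self.start <= self.end):
            raise ValidationError(
                f"{self.protein_id}: bad domain coordinates {self.start}..{self.end}"
            )
        if self.reference_length < 1:
            raise ValidationError(
                f"{self.protein_id}: reference_length must be positive"
            )

    @property
    def coverage(self) -> float:
        """Fraction of the full-length domain model this hit spans."""
        return (self.end - self.start + 1) / self.reference_length


@dataclass
class RunConfig:
    """Tunable knobs of the pipeline, mirrored by CLI flags.

    ``clock_rate`` is the synonymous substitution rate λ in
    substitutions/synonymous site/year; divergence dating uses
    T = Ks / (2λ) × 1e-6 Mya.
    """

    clock_rate: float = 6.1e-9
    tandem_max_intervening: int = 1
    collinearity_window: int = 25
    collinearity_min_anchors: int = 18
    bootstrap_replicates: int = 100
    random_seed: int = 0
    fold_change_threshold: float = 2.0
    expression_high_quantile: float = 0.75
    truncation_coverage_min: float = 0.6
    wgd_ks_min: float = 0.06
    wgd_ks_max: float = 0.45
    pair_ks_reduction: str = "min"  # or "mean"

    def __post_init__(self) -> None:
        if self.clock_rate <= 0:
            raise ValidationError("clock_rate must be positive")
        for name in ("collinearity_window", "collinearity_min_anchors",
                     "bootstrap_replicates"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be a positive integer")
        if self.tandem_max_intervening < 0:
            raise ValidationError("tandem_max_intervening must be >= 0")
        if not 0 < self.expression_high_quantile < 1:
            raise ValidationError("expression_high_quantile must be in (0, 1)")
        if self.pair_ks_reduction not in ("min", "mean"):
            raise ValidationError("pair_ks_reduction must be 'min' or 'mean'")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Read a ``key = value`` config file; unknown keys are rejected."""
        known = {f.name: f.type for f in fields(cls)}
        kwargs: dict[str, object] = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ParseError(f"{path}:{lineno}: expected 'key = value'")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in known:
                raise ParseError(f"{path}:{lineno}: unknown config key {key!r}")
            default = getattr(cls(), key)
            if isinstance(default, bool):
                kwargs[key] = value.lower() in ("1", "true", "yes")
            elif isinstance(default, int):
                kwargs[key] = int(value)
            elif isinstance(default, float):
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)  # type: ignore[arg-type]

    def to_file(self, path: str | Path) -> None:
        lines = [f"{f.name} = {getattr(self, f.name)}" for f in fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")

    def with_overrides(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)


@dataclass
class TreeNode:
    """Minimal rooted tree node used by the phylogeny stage.

    Leaves carry ``label``; internal nodes may carry a bootstrap ``support``
    (written as the internal node label in Newick).  ``length`` is the branch
    length to the parent (None at the root).
    """

    label: str | None = None
    length: float | None = None
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for child in self.children:
            out.extend(child.leaves())
        return out

    def leaf_labels(self) -> list[str]:
        return [leaf.label or "" for leaf in self.leaves()]

    def walk(self) -> Iterable["TreeNode"]:
        yield self
        for child in self.children:
            yield from child.walk()


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ordered (id, upper-cased sequence) pairs.

    Duplicate record ids, empty sequences and data before the first header
    are rejected with the offending line number in the message.
    """
    path = Path(path)
    header_lines: dict[int, int] = {}  # record index -> line number
    index = -1
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                index += 1
                header_lines[index] = lineno
                if len(line) == 1:
                    raise ParseError(f"{path}:{lineno}: empty FASTA header")
            elif index < 0:
                raise ParseError(
                    f"{path}:{lineno}: sequence data before first header"
                )
    if index < 0:
        raise ParseError(f"{path}: no FASTA records found")

    records: list[tuple[str, str]] = []
    seen: dict[str, int] = {}
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        seq = str(rec.seq).upper()
        if not seq:
            raise ParseError(
                f"{path}:{header_lines[i]}: record {rec.id!r} has an empty sequence"
            )
        if rec.id in seen:
            raise ParseError(
                f"{path}:{header_lines[i]}: duplicate record id {rec.id!r} "
                f"(first seen at line {seen[rec.id]})"
            )
        seen[rec.id] = header_lines[i]
        records.append((rec.id, seq))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path,
                width: int = 60) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_UTR5_TYPES = {"five_prime_UTR", "five_prime_utr", "5'UTR"}
_UTR3_TYPES = {"three_prime_UTR", "three_prime_utr", "3'UTR"}


def _spliced_length(intervals: Sequence[Interval]) -> int:
    return sum(e - s + 1 for s, e in intervals)


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3, one :class:`GeneModel` per gene.

    The longest mRNA (by spliced exon length, ties broken by transcript id)
    is taken as the representative isoform.  Coordinates are kept 1-based
    inclusive exactly as in the file.
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    for ftype in ("CDS", "exon"):
        for feat in db.features_of_type(ftype):
            if "Parent" not in feat.attributes:
                raise ValidationError(
                    f"{path}: {ftype} feature at {feat.seqid}:{feat.start} "
                    "has no Parent attribute"
                )

    models: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        if not mrnas:
            continue
        by_length = []
        for mrna in mrnas:
            exons = sorted(
                (f.start, f.end) for f in db.children(mrna, featuretype="exon")
            )
            by_length.append((_spliced_length(exons), mrna, exons))
        by_length.sort(key=lambda item: (-item[0], item[1].id))
        _, rep, exons = by_length[0]
        cds = sorted((f.start, f.end) for f in db.children(rep, featuretype="CDS"))
        utr5 = sorted(
            (f.start, f.end)
            for t in _UTR5_TYPES
            for f in db.children(rep, featuretype=t)
        )
        utr3 = sorted(
            (f.start, f.end)
            for t in _UTR3_TYPES
            for f in db.children(rep, featuretype=t)
        )
        models.append(
            GeneModel(
                gene_id=gene.id,
                chromosome=gene.seqid,
                strand=gene.strand,
                span=(gene.start, gene.end),
                exons=exons,
                cds=cds,
                utr5=utr5,
                utr3=utr3,
            )
        )
    return models


def write_gff3(models: Iterable[GeneModel], path: str | Path | None = None) -> str:
    """Serialize gene models to GFF3 (one mRNA per gene)."""
    lines = ["##gff-version 3"]
    for gm in models:
        gid, mid = gm.gene_id, f"{gm.gene_id}.t1"
        base = f"{gm.chromosome}\tfamsurvey\t"
        tail = f"\t.\t{gm.strand}\t."
        lines.append(
            f"{base}gene\t{gm.span[0]}\t{gm.span[1]}{tail}\tID={gid}"
        )
        lines.append(
            f"{base}mRNA\t{gm.span[0]}\t{gm.span[1]}{tail}\tID={mid};Parent={gid}"
        )
        for ftype, ivs in (
            ("exon", gm.exons),
            ("CDS", gm.cds),
            ("five_prime_UTR", gm.utr5),
            ("three_prime_UTR", gm.utr3),
        ):
            for s, e in ivs:
                lines.append(f"{base}{ftype}\t{s}\t{e}{tail}\tParent={mid}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------


def _newick_node(node: TreeNode) -> str:
    if node.is_leaf:
        if not node.label:
            raise ValidationError("unlabeled leaf in tree")
        text = node.label
    else:
        inner = ",".join(_newick_node(c) for c in node.children)
        sup = "" if node.support is None else f"{node.support:g}"
        text = f"({inner}){sup}"
    if node.length is not None:
        if node.length < 0:
            raise ValidationError(
                f"negative branch length {node.length} at {node.label or 'internal node'}"
            )
        text += f":{node.length:g}"
    return text


def write_newick(tree: TreeNode) -> str:
    """Serialize a tree to Newick, bootstrap supports as internal labels."""
    return _newick_node(tree) + ";"


def read_newick(text: str) -> TreeNode:
    """Parse Newick (via dendropy) back into a :class:`TreeNode` tree."""
    import dendropy

    dtree = dendropy.Tree.get(data=text, schema="newick",
                              suppress_internal_node_taxa=True)

    def convert(dnode) -> TreeNode:
        node = TreeNode(
            label=dnode.taxon.label if dnode.taxon is not None else None,
            length=dnode.edge.length,
        )
        if dnode.label is not None and not dnode.is_leaf():
            try:
                node.support = float(dnode.label)
            except ValueError:
                node.label = dnode.label
        node.children = [convert(c) for c in dnode.child_nodes()]
        return node

    return convert(dtree.seed_node)


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

SEGMENT_PAIR_COLUMNS = [
    "pair", "gene_a", "gene_b", "Ka", "Ks", "Ka/Ks", "time_mya",
]


def write_segment_pair_table(pairs, path: str | Path | None = None) -> str:
    """Write the divergence table for duplicated segment pairs.

    One row per member gene pair: pair number, the two gene ids (emitted
    verbatim as supplied), Ka, Ks, ω = Ka/Ks (2 decimals) and estimated time
    in Mya (2 decimals).  Ka and ω cells are left blank when Ka is
    unavailable.
    """
    rows = []
    for pair in pairs:
        for gene_a, gene_b in pair.member_pairs:
            ka = "" if pair.Ka is None else f"{pair.Ka:.4f}"
            omega = "" if pair.omega is None else f"{pair.omega:.2f}"
            rows.append(
                {
                    "pair": pair.pair_id,
                    "gene_a": gene_a,
                    "gene_b": gene_b,
                    "Ka": ka,
                    "Ks": f"{pair.Ks:.4f}",
                    "Ka/Ks": omega,
                    "time_mya": f"{pair.time_mya:.2f}",
                }
            )
    df = pd.DataFrame(rows, columns=SEGMENT_PAIR_COLUMNS)
    text = df.to_csv(sep="\t", index=False)
    if path is not None:
        Path(path).write_text(text)
    return text


def read_domain_hits(path: str | Path) -> list[DomainHit]:
    """Read a domain-annotation TSV (protein_id, domain, start, end,
    reference_length), emulating a parsed CD-search result table."""
    df = pd.read_csv(path, sep="\t")
    required = {"protein_id", "domain", "start", "end", "reference_length"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return [
        DomainHit(
            protein_id=str(row.protein_id),
            domain=str(row.domain),
            start=int(row.start),
            end=int(row.end),
            reference_length=int(row.reference_length),
        )
        for row in df.itertuples()
    ]


def write_domain_hits(hits: Iterable[DomainHit], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "protein_id": h.protein_id,
                "domain": h.domain,
                "start": h.start,
                "end": h.end,
                "reference_length": h.reference_length,
            }
            for h in hits
        ],
        columns=["protein_id", "domain", "start", "end", "reference_length"],
    ).to_csv(path, sep="\t", index=False)


def log(stage: str, message: str) -> None:
    """Stage-tagged progress line on standard error."""
    print(f"[{stage}] {message}", file=sys.stderr)
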