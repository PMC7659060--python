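"""Synthetic genome with a known duplication history and expression dynamics.

The generator emulates the history the survey is built to recover: a set of
unrelated ancestral coding genes, tandem expansion of a few loci into
arrays, then a whole-genome duplication (WGD) copying every proto-chromosome
— so tandem arrays appear on *both* derived chromosomes, the configuration
that makes real segment pairs look complex.  Each duplicate pair accumulates
synonymous changes with a controlled expectation (one single-nucleotide
change per mutated codon, synonymous and nonsynonymous codons disjoint
between the two copies, so pathway counting downstream is exact) and
nonsynonymous changes at a lower configurable rate.  A chosen fraction of
family genes is pseudogenized by one of the census's two trigger paths:
truncation below 150 codons, or an in-frame internal deletion removing a
large part of the catalytic peptidase_C1 domain.

Because tandem expansion predates the WGD, adjacent array copies are *more*
diverged than WGD partners; min-Ks matching therefore pairs every gene with
its true WGD partner, and gene order is emitted in duplication-block order
so collinearity holds by construction (a shuffle switch breaks it for
negative controls).

``simulate_expression`` layers a five-timepoint nodule time course on top:
class-defining mean profiles with ≥2-fold moves, Ct values generated as
baseline − log_E(relative quantity) plus Gaussian noise, three replicates
per sample, two designed stable reference genes and two unstable ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from famsurvey.duplication import (
    CODON_TO_AA,
    NUCLEOTIDES,
    STOP_CODONS,
    ng86_kaks,
)
from famsurvey.expression import ExpressionMatrix, PATTERN_CLASSES, QpcrTable
from famsurvey.io_formats import (
    DomainHit,
    GeneModel,
    ValidationError,
    write_domain_hits,
    write_fasta,
    write_gff3,
)

SENSE_CODONS = sorted(CODON_TO_AA)

NODULE_TIMEPOINTS = ("12dN", "30dN", "42dN", "64dN", "84dN")
SYMBIOSIS_TISSUES = (
    "Nodules", "RootHairs", "Roots", "NodulesSym", "RootsSym",
)

#: Class-defining mean fold-change profiles over the five nodule timepoints
#: (relative to the first).  Moves that define a class are ≥3-fold so the
#: classifier's 2-fold threshold keeps a noise margin.
CLASS_PROFILES: dict[str, tuple[float, ...]] = {
    "senescence_up": (1.0, 3.0, 9.0, 27.0, 81.0),
    "development_down": (1.0, 0.33, 0.11, 0.037, 0.025),
    "mid_peak": (1.0, 3.0, 9.0, 3.0, 1.0),
    "down_then_up": (1.0, 0.25, 0.25, 1.5, 9.0),
    "up_then_down": (1.0, 3.0, 9.0, 27.0, 3.0),
    "bimodal": (1.0, 10.0, 1.0, 1.0, 16.0),
    "flat": (1.0, 1.0, 1.0, 1.0, 1.0),
}

REFERENCE_GENES = ("REF_ELF1B", "REF_QACT")
UNSTABLE_REFERENCES = ("REF_G6PD", "REF_UBIQ")


@dataclass
class SimConfig:
    """Study conditions of the synthetic genome.

    ``wgd_target_ks`` is the expected synonymous divergence of WGD pairs
    (the recent-WGD cohort of the survey sits near 0.1–0.34);
    ``tandem_adjacent_ks`` the expected divergence between adjacent tandem
    copies, deliberately above the WGD window because the arrays predate the
    WGD.  ``ka_ks_ratio`` sets the nonsynonymous rate as a fraction of the
    synonymous one (purifying selection).
    """

    n_ancestral_genes: int = 20
    wgd_target_ks: float = 0.2
    ka_ks_ratio: float = 0.2
    tandem_cluster_sizes: tuple[int, ...] = (3, 2)
    tandem_adjacent_ks: float = 0.3
    pseudogene_fraction: float = 0.1
    codon_length: int = 300
    n_chromosomes: int = 4
    intergenic_spacer: int = 2000
    n_background_between: int = 3
    expression_classes: dict[str, str] | None = None
    qpcr_noise_sd: float = 0.2
    efficiency: float = 2.0
    seed: int = 0
    shuffle_gene_order: bool = False

    def __post_init__(self) -> None:
        if self.wgd_target_ks < 0 or self.tandem_adjacent_ks < 0:
            raise ValidationError("target Ks values must be non-negative")
        if not 0 <= self.pseudogene_fraction < 1:
            raise ValidationError("pseudogene_fraction must be in [0, 1)")
        if not 1 < self.efficiency <= 2:
            raise ValidationError("efficiency must be in (1, 2]")
        if self.n_chromosomes < 2 or self.n_chromosomes % 2:
            raise ValidationError("n_chromosomes must be even and ≥ 2")
        if self.codon_length < 60:
            raise ValidationError("codon_length must be ≥ 60")
        if any(size < 2 for size in self.tandem_cluster_sizes):
            raise ValidationError("tandem cluster sizes must be ≥ 2")
        if self.n_ancestral_genes < 1:
            raise ValidationError("need at least one ancestral gene")


@dataclass(frozen=True)
class DuplicatePair:
    gene_a: str
    gene_b: str
    true_ks: float
    origin: str  # "WGD" | "tandem"


@dataclass
class GroundTruth:
    """True events of the synthetic genome, the recovery oracle."""

    duplicate_pairs: list[DuplicatePair] = field(default_factory=list)
    pseudogenes: dict[str, str] = field(default_factory=dict)  # id -> reason
    group_assignment: dict[str, str] = field(default_factory=dict)
    expression_class: dict[str, str] = field(default_factory=dict)
    rns_genes: set[str] = field(default_factory=set)
    reference_genes: tuple[str, ...] = REFERENCE_GENES
    unstable_references: tuple[str, ...] = UNSTABLE_REFERENCES

    def wgd_pairs(self, exclude_pseudogenes: bool = True) -> list[DuplicatePair]:
        pairs = [p for p in self.duplicate_pairs if p.origin == "WGD"]
        if exclude_pseudogenes:
            pairs = [
                p for p in pairs
                if p.gene_a not in self.pseudogenes
                and p.gene_b not in self.pseudogenes
            ]
        return pairs


@dataclass
class SimBundle:
    """Everything one simulation emits, plus its ground truth."""

    config: SimConfig
    cds: list[tuple[str, str]]  # family genes only
    proteins: list[tuple[str, str]]
    gene_models: list[GeneModel]  # family + background genes
    domain_hits: list[DomainHit]
    paralog_pairs: list[tuple[str, str]]  # WGD paralogy incl. background
    ground_truth: GroundTruth
    family_ids: list[str] = field(default_factory=list)

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_fasta(self.cds, directory / "cds.fasta")
        write_fasta(self.proteins, directory / "proteins.fasta")
        write_gff3(self.gene_models, directory / "genome.gff3")
        write_domain_hits(self.domain_hits, directory / "domain_hits.tsv")
        pd.DataFrame(self.paralog_pairs, columns=["gene_a", "gene_b"]).to_csv(
            directory / "paralogy.tsv", sep="\t", index=False
        )
        gt = self.ground_truth
        pd.DataFrame(
            [
                {"gene_a": p.gene_a, "gene_b": p.gene_b,
                 "true_ks": f"{p.true_ks:.6f}", "origin": p.origin}
                for p in gt.duplicate_pairs
            ]
        ).to_csv(directory / "truth_pairs.tsv", sep="\t", index=False)
        pd.DataFrame(
            sorted(gt.pseudogenes.items()), columns=["gene_id", "reason"]
        ).to_csv(directory / "truth_pseudogenes.tsv", sep="\t", index=False)
        pd.DataFrame(
            sorted(gt.group_assignment.items()), columns=["gene_id", "group"]
        ).to_csv(directory / "truth_groups.tsv", sep="\t", index=False)
        pd.DataFrame(
            sorted(gt.expression_class.items()), columns=["gene_id", "class"]
        ).to_csv(directory / "truth_expression_class.tsv", sep="\t", index=False)
        manifest = pd.DataFrame(
            [
                {"file": "cds.fasta", "records": len(self.cds)},
                {"file": "proteins.fasta", "records": len(self.proteins)},
                {"file": "genome.gff3", "records": len(self.gene_models)},
                {"file": "domain_hits.tsv", "records": len(self.domain_hits)},
                {"file": "paralogy.tsv", "records": len(self.paralog_pairs)},
                {"file": "truth_pairs.tsv",
                 "records": len(gt.duplicate_pairs)},
            ]
        )
        manifest.to_csv(directory / "manifest.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# sequence evolution helpers
# ---------------------------------------------------------------------------


def _neighbors(codon: str) -> tuple[list[str], list[str]]:
    """Single-nucleotide non-stop neighbors, split (synonymous, nonsynonymous)."""
    syn, nonsyn = [], []
    aa = CODON_TO_AA[codon]
    for pos in range(3):
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            mutant = codon[:pos] + nt + codon[pos + 1 :]
            if mutant in STOP_CODONS:
                continue
            (syn if CODON_TO_AA[mutant] == aa else nonsyn).append(mutant)
    return syn, nonsyn


_NEIGHBOR_CACHE = {codon: _neighbors(codon) for codon in SENSE_CODONS}


def _syn_site_count(codon: str) -> float:
    syn = 0.0
    aa = CODON_TO_AA[codon]
    for pos in range(3):
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            mutant = codon[:pos] + nt + codon[pos + 1 :]
            if mutant not in STOP_CODONS and CODON_TO_AA[mutant] == aa:
                syn += 1.0 / 3.0
    return syn


def _p_from_ks(ks: float) -> float:
    """Invert the Jukes–Cantor correction: expected proportion of differing
    sites for a target divergence."""
    return 0.75 * (1.0 - math.exp(-4.0 * ks / 3.0))


def _diverge_pair(
    codons: list[str], ks_target: float, ka_target: float, rng
) -> tuple[list[str], list[str]]:
    """Produce two descendant copies with expected pairwise Ks/Ka targets.

    Each codon hosts at most one change across both copies and the changed
    codon sets of the two copies are disjoint, so downstream difference
    counting is exact (no multi-hit codons within a pair).
    """
    p_syn = _p_from_ks(ks_target)
    p_nonsyn = _p_from_ks(ka_target)
    copy_a = list(codons)
    copy_b = list(codons)
    for i, codon in enumerate(codons):
        syn_nb, nonsyn_nb = _NEIGHBOR_CACHE[codon]
        a = p_syn * _syn_site_count(codon) if syn_nb else 0.0
        b = p_nonsyn * (3.0 - _syn_site_count(codon)) if nonsyn_nb else 0.0
        if a + b > 1.0:
            raise ValidationError(
                "divergence targets too large for one-change-per-codon evolution"
            )
        u = rng.random()
        if u < a:
            mutant = syn_nb[rng.integers(len(syn_nb))]
        elif u < a + b:
            mutant = nonsyn_nb[rng.integers(len(nonsyn_nb))]
        else:
            continue
        if rng.random() < 0.5:
            copy_a[i] = mutant
        else:
            copy_b[i] = mutant
    return copy_a, copy_b


def _diverge_one(codons: list[str], ks_target: float, ka_target: float,
                 rng) -> list[str]:
    """One descendant copy accumulating all changes itself."""
    derived, unchanged = _diverge_pair(codons, ks_target, ka_target, rng)
    # merge: _diverge_pair splits changes over two copies; collapse onto one
    return [
        d if d != orig else u
        for d, u, orig in zip(derived, unchanged, codons)
    ]


def _random_orf(n_codons: int, rng) -> list[str]:
    codons = ["ATG"]
    choices = rng.integers(0, len(SENSE_CODONS), size=n_codons - 1)
    codons.extend(SENSE_CODONS[c] for c in choices)
    return codons


def translate(codons: list[str]) -> str:
    return "".join(CODON_TO_AA[c] for c in codons)


# ---------------------------------------------------------------------------
# genome assembly
# ---------------------------------------------------------------------------


@dataclass
class _Locus:
    """One ancestral locus: a single gene or a pre-WGD tandem array."""

    ancestor_index: int
    codon_lists: list[list[str]]  # 1 entry per tandem copy
    adjacent_true_ks: list[float]  # between consecutive copies


def _domain_plan(
    n_codons: int, architecture: str
) -> list[tuple[str, int, int, int]]:
    """(domain, start, end, reference_length) for an intact protein."""
    c1_start = int(0.4 * n_codons)
    c1_end = int(0.95 * n_codons)
    if architecture == "I29+C1+GRAN":
        c1_end = int(0.8 * n_codons)
        gran = ("GRAN", int(0.85 * n_codons), n_codons - 2,
                n_codons - 2 - int(0.85 * n_codons) + 1)
        return [
            ("inhibitor_I29", 20, int(n_codons / 3), int(n_codons / 3) - 19),
            ("peptidase_C1", c1_start, c1_end, c1_end - c1_start + 1),
            gran,
        ]
    if architecture == "proC1+cathepsinB":
        return [
            ("propeptide_C1", 20, int(n_codons / 3), int(n_codons / 3) - 19),
            ("peptidase_C1A_cathepsinB", c1_start, c1_end,
             c1_end - c1_start + 1),
        ]
    return [
        ("inhibitor_I29", 20, int(n_codons / 3), int(n_codons / 3) - 19),
        ("peptidase_C1", c1_start, c1_end, c1_end - c1_start + 1),
    ]


def _ancestor_architecture(index: int) -> str:
    if index % 7 == 3:
        return "I29+C1+GRAN"
    if index % 11 == 5:
        return "proC1+cathepsinB"
    return "I29+C1"


def simulate_family(config: SimConfig) -> SimBundle:
    """Generate the synthetic genome bundle (see module docstring).

    Raises an error when a requested tandem array does not fit on its
    proto-chromosome.  Deterministic under a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n_proto = config.n_chromosomes // 2
    capacity = math.ceil(config.n_ancestral_genes / n_proto)
    for size in config.tandem_cluster_sizes:
        if size > capacity:
            raise ValidationError(
                f"tandem cluster of {size} exceeds chromosome capacity {capacity}"
            )
    if len(config.tandem_cluster_sizes) > config.n_ancestral_genes:
        raise ValidationError("more tandem clusters than ancestral genes")

    # ancestral genes and tandem expansion (pre-WGD)
    ancestors = [_random_orf(config.codon_length, rng)
                 for _ in range(config.n_ancestral_genes)]
    array_at = {}
    n_arrays = len(config.tandem_cluster_sizes)
    for k, size in enumerate(config.tandem_cluster_sizes):
        idx = (k + 1) * config.n_ancestral_genes // (n_arrays + 1)
        while idx in array_at:
            idx += 1
        array_at[idx % config.n_ancestral_genes] = size

    ka_tandem = config.tandem_adjacent_ks * config.ka_ks_ratio
    loci: list[_Locus] = []
    for i, ancestor in enumerate(ancestors):
        copies = [ancestor]
        adj_ks: list[float] = []
        for _ in range(array_at.get(i, 1) - 1):
            nxt = _diverge_one(copies[-1], config.tandem_adjacent_ks,
                               ka_tandem, rng)
            adj_ks.append(ng86_kaks("".join(copies[-1]), "".join(nxt)).Ks)
            copies.append(nxt)
        loci.append(_Locus(i, copies, adj_ks))

    # WGD: each proto-chromosome is copied; every copy diverges
    chunks = np.array_split(np.arange(len(loci)), n_proto)
    truth = GroundTruth()
    ka_wgd = config.wgd_target_ks * config.ka_ks_ratio

    family_seqs: dict[str, list[str]] = {}
    chrom_layout: dict[str, list[str]] = {}  # chromosome -> gene ids in order
    paralog_pairs: list[tuple[str, str]] = []
    architectures: dict[str, str] = {}
    tandem_members: set[str] = set()

    for proto_idx, chunk in enumerate(chunks):
        chrom_a = f"Chr{2 * proto_idx + 1:02d}"
        chrom_b = f"Chr{2 * proto_idx + 2:02d}"
        order_a: list[str] = []
        order_b: list[str] = []
        for locus_pos, locus_idx in enumerate(chunk):
            locus = loci[locus_idx]
            ids_a, ids_b = [], []
            # background spacer genes separate loci (never array members);
            # the WGD copied them too, so they anchor collinearity
            if locus_pos > 0:
                for j in range(config.n_background_between):
                    bg_a = f"BG{chrom_a[-2:]}G{locus_pos:03d}_{j}"
                    bg_b = f"BG{chrom_b[-2:]}G{locus_pos:03d}_{j}"
                    order_a.append(bg_a)
                    order_b.append(bg_b)
                    paralog_pairs.append((bg_a, bg_b))
            for copy_idx, codons in enumerate(locus.codon_lists):
                gid_a = f"FAM{chrom_a[-2:]}G{locus_pos:03d}{copy_idx}"
                gid_b = f"FAM{chrom_b[-2:]}G{locus_pos:03d}{copy_idx}"
                copy_a, copy_b = _diverge_pair(
                    codons, config.wgd_target_ks, ka_wgd, rng
                )
                family_seqs[gid_a] = copy_a
                family_seqs[gid_b] = copy_b
                arch = _ancestor_architecture(locus.ancestor_index)
                architectures[gid_a] = architectures[gid_b] = arch
                truth.duplicate_pairs.append(
                    DuplicatePair(
                        gid_a, gid_b,
                        ng86_kaks("".join(copy_a), "".join(copy_b)).Ks,
                        "WGD",
                    )
                )
                group = f"G{locus.ancestor_index:03d}"
                truth.group_assignment[gid_a] = group
                truth.group_assignment[gid_b] = group
                ids_a.append(gid_a)
                ids_b.append(gid_b)
            if len(ids_a) > 1:
                tandem_members.update(ids_a)
                tandem_members.update(ids_b)
                for (ga1, ga2), (gb1, gb2), ks in zip(
                    zip(ids_a, ids_a[1:]), zip(ids_b, ids_b[1:]),
                    locus.adjacent_true_ks,
                ):
                    truth.duplicate_pairs.append(
                        DuplicatePair(ga1, ga2, ks, "tandem")
                    )
                    truth.duplicate_pairs.append(
                        DuplicatePair(gb1, gb2, ks, "tandem")
                    )
            order_a.extend(ids_a)
            order_b.extend(ids_b)
        chrom_layout[chrom_a] = order_a
        chrom_layout[chrom_b] = order_b
        for ga, gb in zip(order_a, order_b):
            paralog_pairs.append((ga, gb))

    # pseudogenization: alternate the two trigger paths
    family_ids_all = sorted(family_seqs)
    n_pseudo = round(config.pseudogene_fraction * len(family_ids_all))
    eligible = [g for g in family_ids_all if g not in tandem_members]
    if n_pseudo > len(eligible):
        n_pseudo = len(eligible)
    pseudo_ids = [
        str(g) for g in rng.choice(np.array(eligible), size=n_pseudo,
                                   replace=False)
    ] if n_pseudo else []
    for k, gid in enumerate(sorted(pseudo_ids)):
        codons = family_seqs[gid]
        if k % 2 == 0:
            family_seqs[gid] = codons[:120]  # truncation below 150 codons
            truth.pseudogenes[gid] = "truncation"
        else:
            # in-frame deletion of 45% of the catalytic domain
            plan = _domain_plan(len(codons), architectures[gid])
            c1 = next(p for p in plan
                      if p[0] in ("peptidase_C1", "peptidase_C1A_cathepsinB"))
            _, start, end, ref_len = c1
            cut = int(0.45 * ref_len)
            family_seqs[gid] = codons[: start - 1] + codons[start - 1 + cut :]
            truth.pseudogenes[gid] = "domain_deletion"

    # domain hits reflect what remains of each protein
    domain_hits: list[DomainHit] = []
    for gid in family_ids_all:
        length = len(family_seqs[gid])
        reason = truth.pseudogenes.get(gid)
        plan = _domain_plan(
            config.codon_length if reason != "truncation" else config.codon_length,
            architectures[gid],
        )
        for domain, start, end, ref_len in plan:
            if reason == "truncation":
                end = min(end, length)
                if start > length or end - start + 1 < 10:
                    continue  # domain lost entirely
            elif reason == "domain_deletion" and domain in (
                "peptidase_C1", "peptidase_C1A_cathepsinB"
            ):
                cut = int(0.45 * ref_len)
                end = end - cut
            elif reason == "domain_deletion" and start > end - 1:
                continue
            if reason == "domain_deletion" and domain == "GRAN":
                # GRAN sits C-terminal of the deletion; shift left
                cut = int(0.45 * next(
                    p[3] for p in plan if p[0] == "peptidase_C1"
                ))
                start, end = start - cut, end - cut
            end = min(end, length)
            if start > end:
                continue
            domain_hits.append(
                DomainHit(gid, domain, start, end, ref_len)
            )

    # optional negative control: destroy collinearity (paralogy is already
    # fixed, so permuting gene order breaks anchor chains)
    if config.shuffle_gene_order:
        for chrom in sorted(chrom_layout):
            rng.shuffle(chrom_layout[chrom])

    # coordinate layout
    gene_models: list[GeneModel] = []
    cds_records: list[tuple[str, str]] = []
    protein_records: list[tuple[str, str]] = []
    for chrom in sorted(chrom_layout):
        cursor = 1 + config.intergenic_spacer
        for gid in chrom_layout[chrom]:
            if gid.startswith("BG"):
                model, cursor = _lay_out_gene(
                    gid, chrom, "+", _random_orf(100, rng), 1,
                    cursor, config.intergenic_spacer,
                )
                gene_models.append(model)
                continue
            n_exons = int(rng.integers(1, 5))
            strand = "+" if rng.random() < 0.5 else "-"
            model, cursor = _lay_out_gene(
                gid, chrom, strand, family_seqs[gid], n_exons,
                cursor, config.intergenic_spacer,
            )
            gene_models.append(model)
            cds_records.append((gid, "".join(family_seqs[gid])))
            protein_records.append((gid, translate(family_seqs[gid])))

    # temporal expression classes for census members, cycling the class list
    members = [g for g in family_ids_all if g not in truth.pseudogenes]
    if config.expression_classes is not None:
        truth.expression_class = dict(config.expression_classes)
    else:
        for i, gid in enumerate(members):
            truth.expression_class[gid] = PATTERN_CLASSES[
                i % len(PATTERN_CLASSES)
            ]

    return SimBundle(
        config=config,
        cds=cds_records,
        proteins=protein_records,
        gene_models=gene_models,
        domain_hits=domain_hits,
        paralog_pairs=paralog_pairs,
        ground_truth=truth,
        family_ids=family_ids_all,
    )


def _lay_out_gene(
    gene_id: str,
    chrom: str,
    strand: str,
    codons: list[str],
    n_exons: int,
    cursor: int,
    spacer: int,
    utr5_len: int = 60,
    utr3_len: int = 40,
    intron_len: int = 150,
) -> tuple[GeneModel, int]:
    """Place one gene at ``cursor``; returns the model and the next cursor."""
    cds_len = 3 * len(codons)
    n_exons = max(1, min(n_exons, max(1, cds_len // 30)))
    chunk = cds_len // n_exons
    chunk -= chunk % 3
    sizes = [chunk] * (n_exons - 1) + [cds_len - chunk * (n_exons - 1)]

    left_utr = utr5_len if strand == "+" else utr3_len
    right_utr = utr3_len if strand == "+" else utr5_len

    start = cursor
    exons: list[tuple[int, int]] = []
    cds: list[tuple[int, int]] = []
    at = start
    for i, size in enumerate(sizes):
        exon_start = at
        if i == 0:
            at += left_utr
        cds_start = at
        at += size
        cds.append((cds_start, at - 1))
        if i == n_exons - 1:
            at += right_utr
        exons.append((exon_start, at - 1))
        if i < n_exons - 1:
            at += intron_len
    end = at - 1
    left_iv = [(start, start + left_utr - 1)]
    right_iv = [(end - right_utr + 1, end)]
    utr5 = left_iv if strand == "+" else right_iv
    utr3 = right_iv if strand == "+" else left_iv
    model = GeneModel(
        gene_id=gene_id,
        chromosome=chrom,
        strand=strand,
        span=(start, end),
        exons=exons,
        cds=cds,
        utr5=utr5,
        utr3=utr3,
    )
    return model, end + 1 + spacer


# ---------------------------------------------------------------------------
# expression simulation
# ---------------------------------------------------------------------------


def simulate_expression(
    ground_truth: GroundTruth,
    timepoints: tuple[str, ...] = NODULE_TIMEPOINTS,
    config: SimConfig | None = None,
) -> tuple[ExpressionMatrix, QpcrTable]:
    """Expression matrix and qPCR Ct table consistent with the truth classes.

    The matrix emulates the tissue screen: per-sample abundances with a
    designed set of genes highly expressed in both symbiosis-related tissues
    and nodule stages (recorded in ``ground_truth.rns_genes``), plus decoys
    high in only one tissue class.  The qPCR table carries the nodule time
    course: replicate Ct values from the class mean profiles with Gaussian
    noise, plus two stable and two unstable reference-gene candidates.
    """
    config = config or SimConfig()
    if len(timepoints) < 3:
        raise ValidationError("need at least 3 timepoints")
    rng = np.random.default_rng(config.seed + 1)
    genes = sorted(ground_truth.expression_class)
    if not genes:
        raise ValidationError("ground truth carries no expression classes")
    for gid, cls in ground_truth.expression_class.items():
        if cls not in CLASS_PROFILES:
            raise ValidationError(f"{gid}: unknown class label {cls!r}")

    # ---- tissue matrix with a deterministic high/low split --------------
    n = len(genes)
    samples = list(SYMBIOSIS_TISSUES) + list(timepoints)
    # the number of high genes per column is chosen so the per-sample
    # 0.75-quantile falls between the low and high clusters
    n_high = n - int(math.floor(0.75 * (n - 1))) - 1
    n_high = min(max(n_high, 2), n)
    n_decoy = min(max(1, n_high // 4), n - n_high)
    n_rns = max(1, n_high - n_decoy)
    picked = [str(g) for g in rng.choice(np.array(genes),
                                         size=n_rns + 2 * n_decoy,
                                         replace=False)]
    rns = sorted(picked[:n_rns])
    sym_only = sorted(picked[n_rns : n_rns + n_decoy])
    nod_only = sorted(picked[n_rns + n_decoy :])
    ground_truth.rns_genes = set(rns)

    values = pd.DataFrame(
        rng.uniform(1.0, 10.0, size=(n, len(samples))),
        index=genes, columns=samples,
    )
    for col in SYMBIOSIS_TISSUES:
        values.loc[rns + sym_only, col] = rng.uniform(
            500.0, 1500.0, size=len(rns) + len(sym_only)
        )
    for col in timepoints:
        values.loc[rns + nod_only, col] = rng.uniform(
            500.0, 1500.0, size=len(rns) + len(nod_only)
        )
    sample_class = {s: "symbiosis_tissue" for s in SYMBIOSIS_TISSUES}
    sample_class.update({t: "nodule_stage" for t in timepoints})
    matrix = ExpressionMatrix(values=values, sample_class=sample_class)

    # ---- qPCR time course ----------------------------------------------
    profiles: dict[str, np.ndarray] = {}
    base5 = np.linspace(0, 1, len(NODULE_TIMEPOINTS))
    grid = np.linspace(0, 1, len(timepoints))
    for gid in genes:
        prof = np.array(CLASS_PROFILES[ground_truth.expression_class[gid]])
        profiles[gid] = np.interp(grid, base5, prof)
    for ref in ground_truth.reference_genes:
        profiles[ref] = np.ones(len(timepoints))
    for ref in ground_truth.unstable_references:
        profiles[ref] = 2.0 ** rng.uniform(-3.0, 3.0, size=len(timepoints))

    rows = []
    log_e = math.log(config.efficiency)
    for gid in list(genes) + list(ground_truth.reference_genes) + list(
        ground_truth.unstable_references
    ):
        base_ct = rng.uniform(20.0, 28.0)
        for t, sample in enumerate(timepoints):
            mean_ct = base_ct - math.log(profiles[gid][t]) / log_e
            for rep in range(1, 4):
                noise = rng.normal(0.0, config.qpcr_noise_sd) \
                    if config.qpcr_noise_sd > 0 else 0.0
                rows.append(
                    {
                        "gene_id": gid,
                        "sample_id": sample,
                        "replicate": rep,
                        "ct": mean_ct + noise,
                        "efficiency": config.efficiency,
                    }
                )
    qpcr = QpcrTable(pd.DataFrame(rows))
    return matrix, qpcr
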