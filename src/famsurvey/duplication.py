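"""Stage 2 — duplication analysis.

Tandem-cluster detection from chromosome gene order, Nei–Gojobori (1986)
Ka/Ks estimation with equal-weight mutational-pathway averaging and
Jukes–Cantor correction, molecular-clock dating of duplications
(T = Ks / 2λ), selection classification from ω = Ka/Ks, and
whole-genome-duplication segment-pair identification validated by two
criteria: co-clustering in the family phylogeny and collinearity of the
flanking gene order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations
from typing import Callable, Iterable, Mapping, Sequence

from Bio.Data.CodonTable import unambiguous_dna_by_id

from famsurvey.io_formats import GeneModel, RunConfig, TreeNode, ValidationError

_TABLE = unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_TABLE.stop_codons)
CODON_TO_AA = dict(_TABLE.forward_table)
NUCLEOTIDES = "ACGT"


class KaKsError(ValueError):
    """Ka/Ks estimation cannot proceed on these inputs."""


class SaturationError(KaKsError):
    """pS or pN ≥ 3/4: the Jukes–Cantor correction is undefined."""


# ---------------------------------------------------------------------------
# NG86 Ka/Ks
# ---------------------------------------------------------------------------


@dataclass
class KaKsResult:
    """Site counts, difference counts and corrected rates for one pair.

    S/N are synonymous/nonsynonymous site counts (S + N = 3 × codons),
    Sd/Nd the pathway-averaged difference counts, pS/pN the raw proportions
    and Ka/Ks the Jukes–Cantor-corrected rates.  ``omega`` is None when
    Ks = 0.
    """

    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    Ks: float
    Ka: float

    @property
    def omega(self) -> float | None:
        if self.Ks == 0:
            return None
        return self.Ka / self.Ks


@lru_cache(maxsize=None)
def _codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one sense codon.

    At each position, each of the 3 possible point mutations contributes
    1/3 site; a mutation preserving the amino acid is synonymous, any other
    (including to a stop codon) is nonsynonymous.
    """
    aa = CODON_TO_AA[codon]
    syn = 0.0
    for pos in range(3):
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            mutant = codon[:pos] + nt + codon[pos + 1 :]
            if mutant not in STOP_CODONS and CODON_TO_AA[mutant] == aa:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def _codon_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) differences for a codon pair.

    All orderings of the observed nucleotide changes are enumerated;
    pathways passing through a stop codon are excluded.  In the (rare) case
    where every pathway is blocked, all pathways are used.
    """
    positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not positions:
        return 0.0, 0.0

    def walk(order: tuple[int, ...]) -> tuple[float, float] | None:
        syn = nonsyn = 0.0
        current = codon_a
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                return None
            if CODON_TO_AA[current] == CODON_TO_AA[nxt]:
                syn += 1
            else:
                nonsyn += 1
            current = nxt
        return syn, nonsyn

    results = [walk(order) for order in permutations(positions)]
    valid = [r for r in results if r is not None]
    if not valid:  # every ordering crosses a stop; fall back to all orderings
        valid = [
            _walk_through_stops(codon_a, codon_b, order)
            for order in permutations(positions)
        ]
    syn = sum(r[0] for r in valid) / len(valid)
    nonsyn = sum(r[1] for r in valid) / len(valid)
    return syn, nonsyn


def _walk_through_stops(codon_a: str, codon_b: str,
                        order: tuple[int, ...]) -> tuple[float, float]:
    syn = nonsyn = 0.0
    current = codon_a
    for pos in order:
        nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
        aa_from = CODON_TO_AA.get(current, "*")
        aa_to = CODON_TO_AA.get(nxt, "*")
        if aa_from == aa_to:
            syn += 1
        else:
            nonsyn += 1
        current = nxt
    return syn, nonsyn


def _split_codons(cds: str, which: str) -> list[str]:
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise KaKsError(f"sequence {which}: length {len(cds)} not divisible by 3")
    if "-" in cds:
        raise KaKsError(f"sequence {which}: gaps are not allowed")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    for i, codon in enumerate(codons):
        if codon in STOP_CODONS:
            raise KaKsError(f"sequence {which}: internal stop codon at codon {i + 1}")
        if codon not in CODON_TO_AA:
            raise KaKsError(f"sequence {which}: invalid codon {codon!r} at codon {i + 1}")
    return codons


def jukes_cantor(p: float) -> float:
    """Jukes–Cantor multiple-hit correction K = −3/4 ln(1 − 4p/3)."""
    if p >= 0.75:
        raise SaturationError(
            f"proportion of differences {p:.4f} ≥ 0.75; correction undefined"
        )
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def ng86_counts(cds_a: str, cds_b: str) -> tuple[float, float, float, float]:
    """Raw NG86 counts (S, N, Sd, Nd) for two aligned in-frame CDS.

    Site counts are averaged over the two sequences; multi-hit codons are
    averaged over all minimal mutational pathways with equal weight,
    excluding pathways through stop codons.
    """
    codons_a = _split_codons(cds_a, "a")
    codons_b = _split_codons(cds_b, "b")
    if len(codons_a) != len(codons_b):
        raise KaKsError(
            f"sequences differ in length ({len(cds_a)} vs {len(cds_b)} nt)"
        )
    S = N = Sd = Nd = 0.0
    for ca, cb in zip(codons_a, codons_b):
        sa, na = _codon_sites(ca)
        sb, nb = _codon_sites(cb)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        ds, dn = _codon_differences(ca, cb)
        Sd += ds
        Nd += dn
    return S, N, Sd, Nd


def ng86_kaks(cds_a: str, cds_b: str) -> KaKsResult:
    """Nei–Gojobori (1986) Ka/Ks for two aligned in-frame CDS.

    Counts come from :func:`ng86_counts`; pS = Sd/S and pN = Nd/N are
    Jukes–Cantor corrected into Ks and Ka (an error when either proportion
    reaches saturation at 3/4).  Symmetric in its arguments.
    """
    S, N, Sd, Nd = ng86_counts(cds_a, cds_b)
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    return KaKsResult(
        S=S, N=N, Sd=Sd, Nd=Nd, pS=pS, pN=pN,
        Ks=jukes_cantor(pS), Ka=jukes_cantor(pN),
    )


# ---------------------------------------------------------------------------
# dating and selection
# ---------------------------------------------------------------------------


def divergence_time(ks: float, clock_rate: float = 6.1e-9) -> float:
    """Divergence time T = Ks / (2λ) × 1e−6 Mya, reported to 2 decimals.

    ``clock_rate`` λ is the synonymous substitution rate per site per year.
    """
    if ks < 0:
        raise ValidationError(f"Ks must be non-negative, got {ks}")
    if clock_rate <= 0:
        raise ValidationError("clock_rate must be positive")
    return round(ks / (2.0 * clock_rate) * 1e-6, 2)


def selection_class(omega: float) -> str:
    """Classify selection from ω = Ka/Ks: <1 purifying, >1 directional."""
    if omega < 0:
        raise ValidationError("omega must be non-negative")
    if omega < 1.0:
        return "purifying"
    if omega > 1.0:
        return "directional"
    return "neutral"


# ---------------------------------------------------------------------------
# tandem clusters
# ---------------------------------------------------------------------------


@dataclass
class TandemCluster:
    """A run of ≥2 family genes on one chromosome separated by at most a
    configured number of intervening non-family genes."""

    chromosome: str
    members: list[str]
    span: tuple[int, int]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValidationError("tandem cluster needs ≥2 members")


def _chromosome_orders(
    gene_models: Sequence[GeneModel],
) -> dict[str, list[GeneModel]]:
    by_chrom: dict[str, list[GeneModel]] = {}
    for gm in gene_models:
        by_chrom.setdefault(gm.chromosome, []).append(gm)
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda g: (g.span[0], g.span[1], g.gene_id))
    return by_chrom


def find_tandem_clusters(
    gene_models: Sequence[GeneModel],
    family_ids: Iterable[str],
    tandem_max_intervening: int = 1,
) -> list[TandemCluster]:
    """Maximal runs of family genes in chromosome order.

    Two consecutive family genes belong to the same run when at most
    ``tandem_max_intervening`` non-family genes sit between them; runs of
    length ≥2 are reported as disjoint clusters.
    """
    family = set(family_ids)
    known = {gm.gene_id for gm in gene_models}
    missing = family - known
    if missing:
        raise ValidationError(
            f"family ids absent from gene models: {sorted(missing)[:5]}"
        )
    clusters: list[TandemCluster] = []
    for chrom, genes in sorted(_chromosome_orders(gene_models).items()):
        run: list[GeneModel] = []
        gap = 0
        for gm in genes:
            if gm.gene_id in family:
                if run and gap > tandem_max_intervening:
                    if len(run) >= 2:
                        clusters.append(_make_cluster(chrom, run))
                    run = []
                run.append(gm)
                gap = 0
            elif run:
                gap += 1
        if len(run) >= 2:
            clusters.append(_make_cluster(chrom, run))
    return clusters


def _make_cluster(chrom: str, run: list[GeneModel]) -> TandemCluster:
    return TandemCluster(
        chromosome=chrom,
        members=[g.gene_id for g in run],
        span=(min(g.span[0] for g in run), max(g.span[1] for g in run)),
    )


# ---------------------------------------------------------------------------
# collinearity
# ---------------------------------------------------------------------------


def _longest_chain(anchors: list[tuple[int, int]]) -> int:
    """Longest chain strictly increasing in both coordinates (O(n²) DP)."""
    if not anchors:
        return 0
    anchors = sorted(anchors)
    best = [1] * len(anchors)
    for i, (ai, bi) in enumerate(anchors):
        for j in range(i):
            aj, bj = anchors[j]
            if aj < ai and bj < bi:
                best[i] = max(best[i], best[j] + 1)
    return max(best)


def collinearity_support(
    segment_a: Sequence[str],
    segment_b: Sequence[str],
    homolog_pairs: Iterable[tuple[str, str]],
    focal_pair: tuple[str, str],
    window: int = 25,
) -> int:
    """Anchor count of the best collinear chain around a focal gene pair.

    ``segment_a``/``segment_b`` are ordered gene-id lists (chromosome order);
    ``homolog_pairs`` relates genes across the two segments.  Anchors are
    restricted to ±``window`` genes around the focal pair on both segments,
    and the better of segment_b's forward and reversed orientation is taken,
    so an inverted segment scores the same as a direct copy.
    """
    pos_a = {g: i for i, g in enumerate(segment_a)}
    pos_b = {g: i for i, g in enumerate(segment_b)}
    pairs = [
        (a, b) for a, b in homolog_pairs if a in pos_a and b in pos_b
    ] + [
        (b, a) for a, b in homolog_pairs if b in pos_a and a in pos_b
    ]
    fa, fb = focal_pair
    if (fa, fb) not in pairs and (fb, fa) in pairs:
        fa, fb = fb, fa
    if (fa, fb) not in pairs:
        raise ValidationError(f"focal pair {focal_pair} not in homolog_pairs")

    ca, cb = pos_a[fa], pos_b[fb]
    windowed = [
        (pos_a[a], pos_b[b])
        for a, b in pairs
        if abs(pos_a[a] - ca) <= window and abs(pos_b[b] - cb) <= window
    ]
    forward = _longest_chain(windowed)
    reverse = _longest_chain([(pa, -pb) for pa, pb in windowed])
    return max(forward, reverse)


# ---------------------------------------------------------------------------
# segment pairs
# ---------------------------------------------------------------------------


@dataclass
class SegmentPair:
    """Two chromosomal runs of family genes descended from one WGD block."""

    pair_id: int
    segment_a: tuple[str, list[str]]  # (chromosome, ordered family gene ids)
    segment_b: tuple[str, list[str]]
    member_pairs: list[tuple[str, str]]
    Ks: float
    Ka: float | None
    time_mya: float
    phylo_grouped: bool = False
    collinear_anchors: int = 0
    validated: bool = False

    def __post_init__(self) -> None:
        if self.time_mya < 0:
            raise ValidationError("time_mya must be non-negative")
        if self.validated != (
            self.phylo_grouped and self.collinear_anchors > 0
        ) and self.validated:
            raise ValidationError("validated pair lacks supporting criteria")

    @property
    def omega(self) -> float | None:
        if self.Ka is None or self.Ks == 0:
            return None
        return self.Ka / self.Ks


def _smallest_clade_leafset(tree: TreeNode, label_a: str,
                            label_b: str) -> set[str]:
    """Smallest leaf set containing both labels over all edges of the
    (unrooted) tree — each edge offers its two sides, so a cherry sitting at
    the root trifurcation is still recognized as a 2-leaf clade."""
    all_leaves = set(tree.leaf_labels())
    if label_a not in all_leaves or label_b not in all_leaves:
        raise ValidationError(f"{label_a} and/or {label_b} not in tree")
    best = all_leaves
    for node in tree.walk():
        if node is tree:
            continue
        side = set(node.leaf_labels())
        for candidate in (side, all_leaves - side):
            if label_a in candidate and label_b in candidate \
                    and len(candidate) < len(best):
                best = candidate
    return best


def _lookup(table, a: str, b: str):
    if callable(table):
        return table(a, b)
    return table.get((a, b), table.get((b, a)))


def identify_segment_pairs(
    gene_models: Sequence[GeneModel],
    family_ids: Iterable[str],
    ks_lookup: Mapping[tuple[str, str], float] | Callable[[str, str], float | None],
    tree: TreeNode | None,
    config: RunConfig | None = None,
    homolog_pairs: Iterable[tuple[str, str]] | None = None,
    ka_lookup=None,
) -> list[SegmentPair]:
    """Identify WGD-derived duplicated segment pairs.

    The three-step candidate procedure: (1) per-gene-pair Ks from
    ``ks_lookup``; (2) family genes are placed in chromosome order and
    cross-chromosome gene pairs whose Ks falls in the configured WGD window
    are matched one-to-one by ascending Ks; (3) matched pairs on the same
    chromosome pair are chained into candidate segments when consecutive
    members sit within the collinearity window on both chromosomes.

    Each candidate is then scored by two validation criteria:
    ``phylo_grouped`` — for every member pair, the smallest clade of the
    supplied tree containing both genes stays within the two segments — and
    ``collinear_anchors`` ≥ the configured minimum, computed on the full
    chromosome gene order using family membership plus any supplied paralogy
    as anchors.  A pair is ``validated`` only when both criteria hold.

    The representative Ks is the minimum (or mean, per config) over member
    pairs; Ka is taken from ``ka_lookup`` for the representative member pair
    when available, and the divergence time is Ks/(2λ) × 1e−6 Mya.
    """
    config = config or RunConfig()
    family = [str(f) for f in family_ids]
    if not family:
        raise ValidationError("empty family")
    family_set = set(family)
    by_chrom = _chromosome_orders(gene_models)
    chrom_of = {gm.gene_id: gm.chromosome for gm in gene_models}
    chrom_order = {
        chrom: [g.gene_id for g in genes] for chrom, genes in by_chrom.items()
    }
    fam_pos = {}
    for chrom, order in chrom_order.items():
        fam_genes = [g for g in order if g in family_set]
        for i, g in enumerate(fam_genes):
            fam_pos[g] = i
    missing = family_set - set(chrom_of)
    if missing:
        raise ValidationError(
            f"family ids absent from gene models: {sorted(missing)[:5]}"
        )

    # step 2: cross-chromosome candidates in the WGD Ks window,
    # matched one-to-one by ascending Ks
    candidates = []
    for i, a in enumerate(family):
        for b in family[i + 1 :]:
            if chrom_of[a] == chrom_of[b]:
                continue
            ks = _lookup(ks_lookup, a, b)
            if ks is None:
                continue
            if config.wgd_ks_min <= ks <= config.wgd_ks_max:
                a_, b_ = sorted((a, b), key=lambda g: chrom_of[g])
                candidates.append((ks, a_, b_))
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    matched: list[tuple[float, str, str]] = []
    used: set[str] = set()
    for ks, a, b in candidates:
        if a in used or b in used:
            continue
        matched.append((ks, a, b))
        used.update((a, b))

    # step 3: chain matched pairs into segments per chromosome pair
    groups: dict[tuple[str, str], list[tuple[float, str, str]]] = {}
    for ks, a, b in matched:
        groups.setdefault((chrom_of[a], chrom_of[b]), []).append((ks, a, b))

    raw_segments: list[list[tuple[float, str, str]]] = []
    pos_in_chrom = {
        g: i for order in chrom_order.values() for i, g in enumerate(order)
    }
    for key in sorted(groups):
        members = sorted(groups[key], key=lambda m: pos_in_chrom[m[1]])
        current = [members[0]]
        for prev, nxt in zip(members, members[1:]):
            gap_a = abs(pos_in_chrom[nxt[1]] - pos_in_chrom[prev[1]])
            gap_b = abs(pos_in_chrom[nxt[2]] - pos_in_chrom[prev[2]])
            if gap_a <= config.collinearity_window and gap_b <= config.collinearity_window:
                current.append(nxt)
            else:
                raw_segments.append(current)
                current = [nxt]
        raw_segments.append(current)

    anchors = list(homolog_pairs) if homolog_pairs is not None else []
    pairs: list[SegmentPair] = []
    for pair_id, seg in enumerate(raw_segments, start=1):
        member_pairs = [(a, b) for _, a, b in seg]
        ks_values = [ks for ks, _, _ in seg]
        if config.pair_ks_reduction == "min":
            rep_idx = min(range(len(seg)), key=lambda i: ks_values[i])
        else:
            rep_idx = 0
        rep_ks = (
            min(ks_values)
            if config.pair_ks_reduction == "min"
            else sum(ks_values) / len(ks_values)
        )
        rep_pair = member_pairs[rep_idx]
        ka = _lookup(ka_lookup, *rep_pair) if ka_lookup is not None else None
        chrom_a, chrom_b = chrom_of[rep_pair[0]], chrom_of[rep_pair[1]]
        seg_a_genes = sorted((a for _, a, _ in seg), key=pos_in_chrom.get)
        seg_b_genes = sorted((b for _, _, b in seg), key=pos_in_chrom.get)

        phylo_ok = False
        if tree is not None:
            allowed = set(seg_a_genes) | set(seg_b_genes)
            phylo_ok = all(
                _smallest_clade_leafset(tree, a, b) <= allowed
                for a, b in member_pairs
            )

        chain_anchors = anchors + member_pairs
        support = collinearity_support(
            chrom_order[chrom_a],
            chrom_order[chrom_b],
            chain_anchors,
            focal_pair=rep_pair,
            window=config.collinearity_window,
        )
        validated = phylo_ok and support >= config.collinearity_min_anchors
        pairs.append(
            SegmentPair(
                pair_id=pair_id,
                segment_a=(chrom_a, seg_a_genes),
                segment_b=(chrom_b, seg_b_genes),
                member_pairs=member_pairs,
                Ks=rep_ks,
                Ka=ka,
                time_mya=divergence_time(rep_ks, config.clock_rate),
                phylo_grouped=phylo_ok,
                collinear_anchors=support,
                validated=validated,
            )
        )
    return pairs
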