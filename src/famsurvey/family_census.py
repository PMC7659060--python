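"""Stage 1 — family census: member/pseudogene calls and protein properties.

A candidate locus is called a pseudogene when any of the survey's three
criteria fire: the peptide is shorter than 150 residues, it lacks a papain
(peptidase_C1-type) catalytic domain entirely, or its best catalytic-domain
hit covers too small a fraction of the full-length domain model (a large
internal deletion).  Everything else is a family member, annotated with its
domain architecture.

Molecular weight uses average isotopic residue masses; the isoelectric point
solves net charge = 0 with the Bjellqvist pKa set (the ExPASy ProtParam
convention) by bisection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio.Data.IUPACData import protein_weights

from famsurvey.io_formats import DomainHit, ValidationError

#: Mass of one water molecule (average isotopic), Da.
WATER_MW = 18.01524

#: Average residue masses: free amino-acid mass minus one water.
RESIDUE_MW = {aa: mw - 18.0153 for aa, mw in protein_weights.items()
              if aa in "ACDEFGHIKLMNPQRSTVWY"}

#: Bjellqvist pKa values as used by ExPASy ProtParam.
PKA_POSITIVE = {"Nterm": 7.5, "K": 10.0, "R": 12.0, "H": 5.98}
PKA_NEGATIVE = {"Cterm": 3.55, "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}

#: Residue-count threshold below which a locus is a putative pseudogene.
MIN_MEMBER_LENGTH = 150

#: Domains accepted as the catalytic papain-type protease domain.
CATALYTIC_DOMAINS = frozenset({"peptidase_C1", "peptidase_C1A_cathepsinB"})


@dataclass(frozen=True)
class ProteinRecord:
    """A protein with its computed physicochemical properties."""

    protein_id: str
    sequence: str
    molecular_weight: float
    isoelectric_point: float

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class CensusCall:
    """Census verdict for one candidate locus."""

    protein_id: str
    status: str  # "member" | "pseudogene"
    reasons: set[str] = field(default_factory=set)
    architecture: str = "other"

    def __post_init__(self) -> None:
        if self.status not in ("member", "pseudogene"):
            raise ValidationError(f"bad status {self.status!r}")
        if (self.status == "pseudogene") != bool(self.reasons):
            raise ValidationError(
                f"{self.protein_id}: pseudogene status and reasons inconsistent"
            )


def _validate_sequence(sequence: str) -> None:
    if not sequence:
        raise ValidationError("empty protein sequence")
    for i, aa in enumerate(sequence):
        if aa not in RESIDUE_MW:
            raise ValidationError(
                f"unknown residue {aa!r} at position {i + 1}"
            )


def molecular_weight(sequence: str) -> float:
    """Average-isotopic molecular weight in Da.

    Sum of residue masses plus one water for the free termini.
    """
    _validate_sequence(sequence)
    return sum(RESIDUE_MW[aa] for aa in sequence) + WATER_MW


def net_charge(sequence: str, ph: float) -> float:
    """Net protein charge at a given pH (Henderson–Hasselbalch sums).

    Positive groups (N-terminus, K, R, H) contribute 1/(1+10^(pH−pKa));
    negative groups (C-terminus, D, E, C, Y) contribute −1/(1+10^(pKa−pH)).
    Monotone decreasing in pH, so the isoelectric point is a unique root.
    """
    charge = 1.0 / (1.0 + 10 ** (ph - PKA_POSITIVE["Nterm"]))
    charge -= 1.0 / (1.0 + 10 ** (PKA_NEGATIVE["Cterm"] - ph))
    for aa in sequence:
        if aa in PKA_POSITIVE:
            charge += 1.0 / (1.0 + 10 ** (ph - PKA_POSITIVE[aa]))
        elif aa in PKA_NEGATIVE:
            charge -= 1.0 / (1.0 + 10 ** (PKA_NEGATIVE[aa] - ph))
    return charge


def isoelectric_point(sequence: str, tolerance: float = 1e-3) -> float:
    """pH at which the net charge crosses zero, by bisection on [0, 14]."""
    _validate_sequence(sequence)
    lo, hi = 0.0, 14.0
    if net_charge(sequence, lo) < 0:
        return lo
    if net_charge(sequence, hi) > 0:
        return hi
    while hi - lo > tolerance:
        mid = (lo + hi) / 2.0
        if net_charge(sequence, mid) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def build_protein_records(
    proteins: Iterable[tuple[str, str]]
) -> list[ProteinRecord]:
    """Attach MW and pI to raw (id, sequence) pairs."""
    return [
        ProteinRecord(
            protein_id=pid,
            sequence=seq,
            molecular_weight=molecular_weight(seq),
            isoelectric_point=isoelectric_point(seq),
        )
        for pid, seq in proteins
    ]


def _architecture(domains: set[str]) -> str:
    if {"inhibitor_I29", "peptidase_C1"} <= domains:
        if "GRAN" in domains:
            return "I29+C1+GRAN"
        return "I29+C1"
    if {"propeptide_C1", "peptidase_C1A_cathepsinB"} <= domains:
        return "proC1+cathepsinB"
    return "other"


def call_census(
    proteins: Sequence[tuple[str, str]],
    domain_hits: Iterable[DomainHit],
    truncation_coverage_min: float = 0.6,
) -> list[CensusCall]:
    """Partition candidate loci into family members and pseudogenes.

    Parameters
    ----------
    proteins : ordered (protein_id, sequence) pairs, the candidate set.
    domain_hits : conserved-domain matches for those proteins; a hit whose
        protein is absent from ``proteins`` is an error.
    truncation_coverage_min : minimum fraction of the full-length catalytic
        domain a hit must cover; below it the locus carries a large internal
        deletion and is called a pseudogene.

    Every input protein receives exactly one call.
    """
    lengths = {pid: len(seq) for pid, seq in proteins}
    hits_by_protein: dict[str, list[DomainHit]] = {pid: [] for pid in lengths}
    for hit in domain_hits:
        if hit.protein_id not in lengths:
            raise ValidationError(
                f"domain hit for unknown protein {hit.protein_id!r}"
            )
        if hit.end > lengths[hit.protein_id]:
            raise ValidationError(
                f"{hit.protein_id}: domain hit end {hit.end} beyond protein "
                f"length {lengths[hit.protein_id]}"
            )
        hits_by_protein[hit.protein_id].append(hit)

    calls: list[CensusCall] = []
    for pid, _ in proteins:
        hits = hits_by_protein[pid]
        catalytic = [h for h in hits if h.domain in CATALYTIC_DOMAINS]
        reasons: set[str] = set()
        if lengths[pid] < MIN_MEMBER_LENGTH:
            reasons.add("length_lt_150")
        if not catalytic:
            reasons.add("missing_peptidase_C1")
        else:
            best = max(catalytic, key=lambda h: h.coverage)
            if best.coverage < truncation_coverage_min:
                reasons.add("truncated_peptidase_C1")
        domains = {h.domain for h in hits}
        calls.append(
            CensusCall(
                protein_id=pid,
                status="pseudogene" if reasons else "member",
                reasons=reasons,
                architecture=_architecture(domains),
            )
        )
    return calls


def census_table(calls: Iterable[CensusCall],
                 records: Iterable[ProteinRecord]):
    """Census calls + protein properties as a tidy DataFrame."""
    import pandas as pd

    props = {r.protein_id: r for r in records}
    rows = []
    for call in calls:
        rec = props.get(call.protein_id)
        rows.append(
            {
                "protein_id": call.protein_id,
                "status": call.status,
                "reasons": ",".join(sorted(call.reasons)),
                "architecture": call.architecture,
                "length": rec.length if rec else None,
                "molecular_weight": None if rec is None
                else round(rec.molecular_weight, 2),
                "isoelectric_point": None if rec is None
                else round(rec.isoelectric_point, 2),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["protein_id", "status", "reasons", "architecture",
                 "length", "molecular_weight", "isoelectric_point"],
    )
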