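"""Annotation auditing: claimed vs. sequence-derived family labels.

Public-database AOX/PTOX records go wrong in recurring ways: PTOX proteins
deposited as "alternative oxidase", records labeled only by the
``immutans`` synonym, entries called simply "AOX" with no member, and
entirely unannotated sequences.  The audit normalizes each record's
claimed label, recomputes the family from fingerprint evidence, attaches
the gene-structure verdict when a gene model is available, and bins every
record into one category of that typology.  Fingerprint evidence outranks
structure evidence; when the two disagree the record is surfaced as
``conflicting_evidence``, never silently resolved.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .fingerprints import (
    DEFAULT_WEAK_BUDGET,
    FamilyClassification,
    Motif,
    classify_sequence,
    default_motifs,
)
from .genestructure import StructureVerdict, structure_verdict
from .seqio import GeneModel, SequenceRecord

CATEGORIES = (
    "concordant",
    "PTOX_as_AOX",
    "AOX_as_PTOX",
    "synonym_only",
    "vague_AOX",
    "unannotated",
    "conflicting_evidence",
)

_PTOX_KEYWORDS = (
    "plastoquinol terminal oxidase",
    "plastid terminal oxidase",
    "immutans",
    "ptox",
)
_AOX_KEYWORDS = ("alternative oxidase", "ubiquinol oxidase")
_AOX_SHORT_RE = re.compile(r"\baox")
_MEMBER_RES = (
    re.compile(r"\baox[\s_-]?([0-9][a-z]?)\b"),
    re.compile(r"(?:alternative|ubiquinol)\s+oxidase\s*([0-9][a-z]?)\b"),
)
_VALID_MEMBER_RE = re.compile(r"^[12][a-z]?$")


@dataclass(frozen=True)
class Claim:
    """A normalized claimed annotation.

    ``family`` is AOX, PTOX, or ``None`` (unannotated); ``member`` is the
    captured member suffix (e.g. ``1a``) if any; ``synonym`` is set when
    the claim relied on the immutans synonym.
    """

    family: str | None
    member: str | None
    synonym: bool
    text: str

    @property
    def member_valid(self) -> bool:
        """True when the member suffix names a real subfamily member."""
        return self.member is not None and bool(_VALID_MEMBER_RE.match(self.member))


def normalize_claim(description: str) -> Claim:
    """Map a free-text description to a normalized family claim.

    Matching is case-insensitive keyword search; PTOX keywords (including
    the immutans synonym) take precedence over the more promiscuous AOX
    keywords.  Text with no recognized keyword is unannotated.
    """
    text = description or ""
    lower = text.lower()
    for kw in _PTOX_KEYWORDS:
        if kw in lower:
            return Claim(family="PTOX", member=None,
                         synonym=(kw == "immutans"), text=text)
    is_aox = any(kw in lower for kw in _AOX_KEYWORDS) or _AOX_SHORT_RE.search(lower)
    if is_aox:
        member = None
        for pattern in _MEMBER_RES:
            match = pattern.search(lower)
            if match and match.group(1):
                member = match.group(1)
                break
        return Claim(family="AOX", member=member, synonym=False, text=text)
    return Claim(family=None, member=None, synonym=False, text=text)


@dataclass(frozen=True)
class AnnotationAudit:
    """Claimed vs. computed label for one sequence, with its category."""

    sequence_id: str
    claimed: Claim
    computed: str
    structure: StructureVerdict | None
    subfamily: str | None
    category: str


def categorize(
    claim: Claim,
    computed: str,
    structure: StructureVerdict | None = None,
) -> str:
    """The audit category — a pure function of (claim, computed, structure).

    Structure evidence can only demote a record to ``conflicting_evidence``
    (canonical count for the *other* family); it never overrides the
    fingerprint call.
    """
    structure_family = None
    if structure is not None:
        structure_family = {
            "canonical_AOX": "AOX", "canonical_PTOX": "PTOX",
        }.get(structure.verdict)
    if (structure_family is not None and computed in ("AOX", "PTOX")
            and structure_family != computed):
        return "conflicting_evidence"
    if claim.family is None:
        return "unannotated"
    if computed not in ("AOX", "PTOX"):
        # a claim that the sequence evidence can neither confirm nor refute
        return "conflicting_evidence"
    if claim.family == "AOX" and computed == "PTOX":
        return "PTOX_as_AOX"
    if claim.family == "PTOX" and computed == "AOX":
        return "AOX_as_PTOX"
    if claim.synonym:
        return "synonym_only"
    if claim.family == "AOX" and not claim.member_valid:
        return "vague_AOX"
    return "concordant"


def audit(
    records: Sequence[SequenceRecord],
    claims: Mapping[str, str] | None = None,
    aox_motifs: Sequence[Motif] | None = None,
    ptox_motifs: Sequence[Motif] | None = None,
    models: Mapping[str, GeneModel] | None = None,
    max_weak_mismatches: int = DEFAULT_WEAK_BUDGET,
) -> tuple[list[AnnotationAudit], dict[str, int]]:
    """Audit protein records against their claimed annotations.

    Claims come from the ``claims`` table (sequence_id -> claimed text)
    when given, else from each record's description line.  ``models`` maps
    sequence ids to gene models for the optional structure check.  Returns
    the per-record audits (input order) and category counts summing to the
    number of records.
    """
    if aox_motifs is None or ptox_motifs is None:
        defaults = default_motifs()
        aox_motifs = defaults["AOX"] if aox_motifs is None else aox_motifs
        ptox_motifs = defaults["PTOX"] if ptox_motifs is None else ptox_motifs
    if claims is not None:
        known = {r.id for r in records}
        unknown = sorted(set(claims) - known)
        if unknown:
            raise ValueError(
                f"audit: claims table references unknown sequence ids: {unknown}"
            )
    audits: list[AnnotationAudit] = []
    counts = {cat: 0 for cat in CATEGORIES}
    for record in records:
        ungapped = record.ungapped() if "-" in record.residues else record
        classification = classify_sequence(
            ungapped, aox_motifs, ptox_motifs, max_weak_mismatches
        )
        text = (claims.get(record.id, record.description)
                if claims is not None else record.description)
        claim = normalize_claim(text)
        verdict = None
        if models is not None and record.id in models:
            verdict = structure_verdict(models[record.id])
        category = categorize(claim, classification.label, verdict)
        counts[category] += 1
        audits.append(
            AnnotationAudit(
                sequence_id=record.id,
                claimed=claim,
                computed=classification.label,
                structure=verdict,
                subfamily=None,
                category=category,
            )
        )
    return audits, counts


def audits_to_frame(audits: Sequence[AnnotationAudit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sequence_id": [a.sequence_id for a in audits],
            "claimed_text": [a.claimed.text for a in audits],
            "claimed_family": [a.claimed.family or "none" for a in audits],
            "claimed_member": [a.claimed.member or "" for a in audits],
            "computed": [a.computed for a in audits],
            "structure": [a.structure.verdict if a.structure else "" for a in audits],
            "category": [a.category for a in audits],
        }
    )


def write_audit_tsv(audits: Sequence[AnnotationAudit], path: str | Path) -> None:
    audits_to_frame(audits).to_csv(path, sep="\t", index=False)


def format_summary(counts: Mapping[str, int]) -> str:
    """Human-readable summary block of the category counts."""
    total = sum(counts.values())
    flagged = total - counts.get("concordant", 0)
    lines = [f"audited sequences: {total}"]
    for cat in CATEGORIES:
        lines.append(f"  {cat:<21} {counts.get(cat, 0)}")
    lines.append(f"records needing attention: {flagged}")
    return "\n".join(lines)
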