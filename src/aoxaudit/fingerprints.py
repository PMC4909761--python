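"""Diagnostic amino-acid fingerprints for AOX vs. PTOX discrimination.

Plant alternative oxidase (AOX, mitochondrial) and plastid terminal oxidase
(PTOX) are the two membrane-bound members of the di-iron carboxylate
superfamily and are routinely confused in database annotations.  Each
subfamily carries short, diagnostic signature motifs: ``ERMHLVT`` and
``YLEEEA`` for AOX, ``(F)GWWRR`` and ``HHLL(I)ME`` for PTOX.  A
parenthesized letter marks a weakly conserved position: any residue is
accepted there, but a non-preferred residue consumes the motif's
weak-mismatch budget.

This module parses and scans such motifs, classifies sequences by
fingerprint evidence, computes alignment-column profiles (residue
frequencies plus information content, the textual equivalent of a sequence
logo), and searches grouped alignments for new discriminative windows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .seqio import GAP, PROTEIN_RESIDUES, SequenceRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
MAX_IC_BITS = math.log2(20)

#: Published subfamily signatures, in motif notation.
AOX_FINGERPRINTS: tuple[str, ...] = ("ERMHLVT", "YLEEEA")
PTOX_FINGERPRINTS: tuple[str, ...] = ("(F)GWWRR", "HHLL(I)ME")

#: Default per-motif budget of weak positions allowed to miss their
#: preferred residue.
DEFAULT_WEAK_BUDGET = 1


@dataclass(frozen=True)
class MotifPosition:
    residue: str
    weak: bool


@dataclass(frozen=True)
class Motif:
    """An ordered amino-acid signature; positions are strict or weak."""

    name: str
    positions: tuple[MotifPosition, ...]

    def __post_init__(self) -> None:
        if len(self.positions) < 2:
            raise ValueError(f"motif {self.name!r}: length must be >= 2")
        for p in self.positions:
            if p.residue not in AMINO_ACIDS:
                raise ValueError(
                    f"motif {self.name!r}: invalid residue {p.residue!r}"
                )

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def n_weak(self) -> int:
        return sum(p.weak for p in self.positions)

    @property
    def notation(self) -> str:
        return "".join(
            f"({p.residue})" if p.weak else p.residue for p in self.positions
        )


@dataclass(frozen=True)
class MotifHit:
    motif_name: str
    sequence_id: str
    start: int
    end: int
    weak_mismatches: int


@dataclass(frozen=True)
class FamilyClassification:
    """Family call for one sequence from fingerprint evidence.

    ``scores`` counts, per family, the distinct fingerprints with at least
    one hit.  The label is AOX or PTOX for a strict majority, ``ambiguous``
    on a nonzero tie, ``unclassified`` when nothing hits.
    """

    sequence_id: str
    label: str
    evidence: tuple[MotifHit, ...]
    scores: Mapping[str, int]


@dataclass(frozen=True)
class ProfileColumn:
    """One alignment column: residue frequencies and information content."""

    frequencies: Mapping[str, float]
    ic_bits: float
    n: int


@dataclass(frozen=True)
class FingerprintCandidate:
    """A candidate discriminative window over a grouped alignment.

    ``consensus_a``/``consensus_b`` are motif-notation strings (one position
    per window column; weakly conserved positions parenthesized).
    """

    start: int
    end: int
    consensus_a: str
    consensus_b: str
    score: float


def parse_motif(notation: str, name: str | None = None) -> Motif:
    """Parse motif notation such as ``"(F)GWWRR"`` into a :class:`Motif`.

    Bare letters are strict positions; a single parenthesized letter is a
    weak position.  Multi-letter groups and unbalanced parentheses are
    errors.
    """
    positions: list[MotifPosition] = []
    i = 0
    while i < len(notation):
        ch = notation[i]
        if ch == "(":
            close = notation.find(")", i + 1)
            if close == -1:
                raise ValueError(f"motif {notation!r}: unbalanced parenthesis")
            group = notation[i + 1:close]
            if len(group) != 1:
                raise ValueError(
                    f"motif {notation!r}: parenthesized group {group!r} must be "
                    "a single letter"
                )
            positions.append(MotifPosition(group.upper(), weak=True))
            i = close + 1
        elif ch == ")":
            raise ValueError(f"motif {notation!r}: unbalanced parenthesis")
        else:
            positions.append(MotifPosition(ch.upper(), weak=False))
            i += 1
    return Motif(name=name or notation, positions=tuple(positions))


def default_motifs() -> dict[str, list[Motif]]:
    """The four published AOX/PTOX fingerprints, keyed by family."""
    return {
        "AOX": [parse_motif(n) for n in AOX_FINGERPRINTS],
        "PTOX": [parse_motif(n) for n in PTOX_FINGERPRINTS],
    }


def load_motif_config(path: str | Path) -> dict[str, list[Motif]]:
    """Read a plain-text motif config: ``family<TAB>notation`` per line.

    Blank lines and ``#`` comments are skipped.
    """
    motifs: dict[str, list[Motif]] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(
                f"{path}:{lineno}: expected 'family<TAB>notation', got {raw!r}"
            )
        family, notation = parts[0].strip(), parts[1].strip()
        motifs.setdefault(family, []).append(parse_motif(notation))
    return motifs


def scan_motif(
    motif: Motif,
    record: SequenceRecord,
    max_weak_mismatches: int = DEFAULT_WEAK_BUDGET,
) -> list[MotifHit]:
    """All offsets where the motif matches the protein sequence.

    Strict positions must match exactly; weak positions always match but a
    non-preferred residue counts against ``max_weak_mismatches``.
    Overlapping hits are all reported, sorted by start.  A motif longer than
    the sequence yields an empty result.
    """
    if record.alphabet != "protein":
        raise ValueError(
            f"scan_motif: record {record.id!r} is not a protein sequence"
        )
    record.require_ungapped("scan_motif")
    seq = record.residues
    m = len(motif)
    hits: list[MotifHit] = []
    for start in range(len(seq) - m + 1):
        weak_miss = 0
        ok = True
        for j, p in enumerate(motif.positions):
            ch = seq[start + j]
            if ch == p.residue:
                continue
            if p.weak:
                weak_miss += 1
                if weak_miss > max_weak_mismatches:
                    ok = False
                    break
            else:
                ok = False
                break
        if ok:
            hits.append(
                MotifHit(
                    motif_name=motif.name,
                    sequence_id=record.id,
                    start=start,
                    end=start + m,
                    weak_mismatches=weak_miss,
                )
            )
    return hits


def classify_sequence(
    record: SequenceRecord,
    aox_motifs: Sequence[Motif],
    ptox_motifs: Sequence[Motif],
    max_weak_mismatches: int = DEFAULT_WEAK_BUDGET,
) -> FamilyClassification:
    """Label a protein sequence AOX/PTOX/ambiguous/unclassified.

    The per-family score is the number of *distinct* fingerprints with at
    least one hit; ties are reported as ambiguous, never resolved silently.
    """
    if not aox_motifs and not ptox_motifs:
        raise ValueError("classify_sequence: no motifs supplied for either family")
    evidence: list[MotifHit] = []
    scores = {"AOX": 0, "PTOX": 0}
    for family, motifs in (("AOX", aox_motifs), ("PTOX", ptox_motifs)):
        for motif in motifs:
            hits = scan_motif(motif, record, max_weak_mismatches)
            if hits:
                scores[family] += 1
                evidence.extend(hits)
    if scores["AOX"] > scores["PTOX"]:
        label = "AOX"
    elif scores["PTOX"] > scores["AOX"]:
        label = "PTOX"
    elif scores["AOX"] > 0:
        label = "ambiguous"
    else:
        label = "unclassified"
    return FamilyClassification(
        sequence_id=record.id,
        label=label,
        evidence=tuple(evidence),
        scores=scores,
    )


def build_profile(records: Sequence[SequenceRecord]) -> list[ProfileColumn]:
    """Per-column residue frequencies and information content of an alignment.

    Frequencies are over the 20 standard amino acids; gaps and ``X`` are
    excluded from column counts.  ``ic_bits = log2(20) - H`` where ``H`` is
    the Shannon entropy of the column distribution in bits (no small-sample
    correction).  All-gap columns get ``n = 0`` and ``ic_bits = 0``.
    """
    if not records:
        raise ValueError("build_profile: no records")
    length = len(records[0].residues)
    for r in records:
        if r.alphabet != "protein":
            raise ValueError(f"build_profile: record {r.id!r} is not protein")
        if len(r.residues) != length:
            raise ValueError(
                f"build_profile: record {r.id!r} has length {len(r.residues)}, "
                f"expected {length}"
            )
    columns: list[ProfileColumn] = []
    for c in range(length):
        counts: dict[str, int] = {}
        for r in records:
            ch = r.residues[c]
            if ch in (GAP, "X"):
                continue
            counts[ch] = counts.get(ch, 0) + 1
        n = sum(counts.values())
        if n == 0:
            columns.append(ProfileColumn(frequencies={}, ic_bits=0.0, n=0))
            continue
        freqs = {aa: cnt / n for aa, cnt in sorted(counts.items())}
        probs = np.array(list(freqs.values()))
        entropy = float(-(probs * np.log2(probs)).sum())
        ic = max(0.0, MAX_IC_BITS - entropy)
        columns.append(ProfileColumn(frequencies=freqs, ic_bits=ic, n=n))
    return columns


def _column_discrimination(col_a: ProfileColumn, col_b: ProfileColumn) -> float:
    """(IC_A + IC_B) scaled by one minus the frequency-distribution overlap."""
    if col_a.n == 0 or col_b.n == 0:
        return 0.0
    residues = set(col_a.frequencies) | set(col_b.frequencies)
    overlap = sum(
        min(col_a.frequencies.get(r, 0.0), col_b.frequencies.get(r, 0.0))
        for r in residues
    )
    return (col_a.ic_bits + col_b.ic_bits) * (1.0 - overlap)


def _consensus(columns: Sequence[ProfileColumn], weak_threshold: float) -> str:
    out = []
    for col in columns:
        if col.n == 0:
            out.append("-")
            continue
        # modal residue; alphabetical tie-break
        modal = max(sorted(col.frequencies), key=lambda r: col.frequencies[r])
        if col.frequencies[modal] < weak_threshold:
            out.append(f"({modal})")
        else:
            out.append(modal)
    return "".join(out)


def discover_fingerprints(
    group_a: Sequence[SequenceRecord],
    group_b: Sequence[SequenceRecord],
    min_len: int = 5,
    max_len: int = 9,
    top_k: int = 2,
    weak_threshold: float = 0.9,
) -> list[FingerprintCandidate]:
    """Search two grouped alignments for discriminative windows.

    Per column ``c`` the discrimination score is
    ``d(c) = (IC_A(c) + IC_B(c)) * (1 - sum_r min(freq_A(r), freq_B(r)))``;
    a window scores the mean of ``d`` over its columns.  The ``top_k``
    non-overlapping windows are selected greedily by score, ties broken by
    smaller start column, then by longer window.  Consensus strings are the
    per-group modal residues, parenthesized (weak) when the modal frequency
    falls below ``weak_threshold``.
    """
    if min_len < 2:
        raise ValueError("discover_fingerprints: min_len must be >= 2")
    if max_len < min_len:
        raise ValueError("discover_fingerprints: max_len must be >= min_len")
    prof_a = build_profile(group_a)
    prof_b = build_profile(group_b)
    if len(prof_a) != len(prof_b):
        raise ValueError(
            "discover_fingerprints: groups are aligned to different column "
            f"spaces ({len(prof_a)} vs {len(prof_b)} columns)"
        )
    ncol = len(prof_a)
    d = np.array([_column_discrimination(a, b) for a, b in zip(prof_a, prof_b)])
    windows: list[tuple[float, int, int]] = []  # (score, start, end)
    for wlen in range(min_len, min(max_len, ncol) + 1):
        for start in range(ncol - wlen + 1):
            windows.append((float(d[start:start + wlen].mean()), start, start + wlen))
    windows.sort(key=lambda w: (-w[0], w[1], -(w[2] - w[1])))
    chosen: list[tuple[float, int, int]] = []
    for score, start, end in windows:
        if len(chosen) == top_k:
            break
        if any(start < e and s < end for _, s, e in chosen):
            continue
        chosen.append((score, start, end))
    return [
        FingerprintCandidate(
            start=start,
            end=end,
            consensus_a=_consensus(prof_a[start:end], weak_threshold),
            consensus_b=_consensus(prof_b[start:end], weak_threshold),
            score=score,
        )
        for score, start, end in chosen
    ]
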