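"""In-silico PCR with degenerate (IUPAC) primers.

Virtual amplification mimics the classic wet-lab screen for AOX coding
sequences with "universal" primers: both primer sites are located on the
template, every forward/reverse site pair within the product-size cap
yields an amplicon (primers included in the product), and a strict length
filter keeps only products at the canonical size — 444 bp with zero
tolerance by default, i.e. no insertions or deletions relative to the
canonical amplicon.

The published universal primer pair (P1/P2) is cited to the primary
literature and not distributed here; primer sequences are supplied by the
user through a TSV config, and the synthetic fixture generator emits its
own primer pairs for testing.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .seqio import SequenceRecord, revcomp

#: Expansion of each IUPAC nucleotide code into the concrete bases it matches.
IUPAC_EXPANSION: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

#: Canonical AOX amplicon length between the universal primers.
CANONICAL_AMPLICON_BP = 444

#: Minimum length enforced for primers read from a config file.
MIN_PRIMER_LENGTH = 10


@dataclass(frozen=True)
class Primer:
    """A PCR primer, written 5'->3'; ``role`` is ``forward`` or ``reverse``."""

    name: str
    sequence: str
    role: str

    def __post_init__(self) -> None:
        if self.role not in ("forward", "reverse"):
            raise ValueError(f"primer {self.name!r}: invalid role {self.role!r}")
        for pos, ch in enumerate(self.sequence):
            if ch not in IUPAC_EXPANSION:
                raise ValueError(
                    f"primer {self.name!r}: invalid IUPAC code {ch!r} at "
                    f"position {pos}"
                )


@dataclass(frozen=True)
class PrimerSite:
    """One primer annealing site on the + strand, 0-based half-open."""

    start: int
    end: int
    mismatches: int


@dataclass(frozen=True)
class Amplicon:
    """A virtual PCR product on the + strand of a template."""

    template_id: str
    start: int
    end: int
    fwd_site: PrimerSite
    rev_site: PrimerSite

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("amplicon must have positive length")
        if not (self.start <= self.fwd_site.start
                and self.fwd_site.end <= self.rev_site.start
                and self.rev_site.end <= self.end):
            raise ValueError("primer sites must lie ordered within the amplicon")

    @property
    def length(self) -> int:
        return self.end - self.start


def iupac_match(pattern_char: str, text_char: str) -> bool:
    """True iff the template base falls within the primer code's expansion.

    An ambiguous template base matches only if its entire expansion is
    covered by the pattern code (``N`` in the pattern matches everything).
    """
    try:
        pattern_set = IUPAC_EXPANSION[pattern_char]
    except KeyError:
        raise ValueError(f"invalid IUPAC code {pattern_char!r} in pattern") from None
    try:
        text_set = IUPAC_EXPANSION[text_char]
    except KeyError:
        raise ValueError(f"invalid IUPAC code {text_char!r} in text") from None
    return text_set <= pattern_set


def find_primer_sites(
    primer: Primer,
    template: SequenceRecord,
    max_mismatches: int = 0,
) -> list[PrimerSite]:
    """All annealing sites of a primer on the + strand of a template.

    Forward primers are searched as written; reverse primers are searched as
    their reverse complement (their binding site on the + strand).  A site
    is reported where at most ``max_mismatches`` positions fail
    :func:`iupac_match`.
    """
    if template.alphabet != "nucleotide":
        raise ValueError(
            f"find_primer_sites: template {template.id!r} is not nucleotide"
        )
    template.require_ungapped("find_primer_sites")
    pattern = primer.sequence if primer.role == "forward" else revcomp(primer.sequence)
    seq = template.residues
    m = len(pattern)
    sites: list[PrimerSite] = []
    for start in range(len(seq) - m + 1):
        mismatches = 0
        for j in range(m):
            if not iupac_match(pattern[j], seq[start + j]):
                mismatches += 1
                if mismatches > max_mismatches:
                    break
        else:
            sites.append(PrimerSite(start=start, end=start + m, mismatches=mismatches))
    return sites


def amplify(
    template: SequenceRecord,
    fwd: Primer,
    rev: Primer,
    max_mismatches: int = 0,
    max_product: int = 5000,
) -> list[Amplicon]:
    """Enumerate all virtual PCR products of a primer pair on a template.

    Every (forward site, downstream reverse site) pair whose product length
    does not exceed ``max_product`` yields one amplicon spanning from the
    start of the forward site to the end of the reverse site — both primer
    annealing sites are part of the product, the standard PCR convention.
    Templates are treated as linear; only the + strand is scanned, reverse
    primers having been pre-reverse-complemented.
    """
    if fwd.role != "forward":
        raise ValueError(f"amplify: primer {fwd.name!r} is not a forward primer")
    if rev.role != "reverse":
        raise ValueError(f"amplify: primer {rev.name!r} is not a reverse primer")
    fwd_sites = find_primer_sites(fwd, template, max_mismatches)
    rev_sites = find_primer_sites(rev, template, max_mismatches)
    products: list[Amplicon] = []
    for fs in fwd_sites:
        for rs in rev_sites:
            if rs.start < fs.end:
                continue
            if rs.end - fs.start > max_product:
                continue
            products.append(
                Amplicon(
                    template_id=template.id,
                    start=fs.start,
                    end=rs.end,
                    fwd_site=fs,
                    rev_site=rs,
                )
            )
    return products


def amplicon_filter(
    amplicons: Sequence[Amplicon],
    expected_length: int = CANONICAL_AMPLICON_BP,
    tolerance: int = 0,
) -> list[Amplicon]:
    """Keep amplicons within ``tolerance`` of the expected length.

    The defaults (444 bp, tolerance 0) implement the no-indel screen: only
    products at exactly the canonical length pass.
    """
    if expected_length <= 0:
        raise ValueError("amplicon_filter: expected_length must be positive")
    if tolerance < 0:
        raise ValueError("amplicon_filter: tolerance must be >= 0")
    return [a for a in amplicons if abs(a.length - expected_length) <= tolerance]


def extract_product(template: SequenceRecord, amplicon: Amplicon) -> SequenceRecord:
    """The product sequence of an amplicon as a new record."""
    if template.id != amplicon.template_id:
        raise ValueError(
            f"extract_product: amplicon is on {amplicon.template_id!r}, "
            f"not {template.id!r}"
        )
    return SequenceRecord(
        id=f"{template.id}|{amplicon.start}-{amplicon.end}",
        residues=template.residues[amplicon.start:amplicon.end],
        alphabet="nucleotide",
        description=f"amplicon {amplicon.length} bp",
    )


def write_bed(amplicons: Sequence[Amplicon], path: str | Path) -> None:
    """Write amplicons as BED (0-based half-open) intervals."""
    lines = [
        "\t".join([a.template_id, str(a.start), str(a.end),
                   f"amplicon_{a.length}bp"])
        for a in amplicons
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def load_primer_config(path: str | Path) -> list[Primer]:
    """Read a primer TSV (columns: name, role, sequence).

    Config primers must be at least 10 nt long; shorter entries are
    rejected as implausible.
    """
    primers: list[Primer] = []
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        required = {"name", "role", "sequence"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(
                f"{path}: primer config must have columns {sorted(required)}"
            )
        for row in reader:
            seq = row["sequence"].strip().upper()
            if len(seq) < MIN_PRIMER_LENGTH:
                raise ValueError(
                    f"{path}: primer {row['name']!r} is shorter than "
                    f"{MIN_PRIMER_LENGTH} nt"
                )
            primers.append(
                Primer(name=row["name"].strip(), sequence=seq,
                       role=row["role"].strip())
            )
    return primers


def write_primer_config(primers: Sequence[Primer], path: str | Path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t")
        writer.writerow(["name", "role", "sequence"])
        for p in primers:
            writer.writerow([p.name, p.role, p.sequence])
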