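"""Seeded synthetic AOX/PTOX fixtures.

Every stage of the tool chain is exercised on generated data: protein sets
carrying the published subfamily fingerprints, nucleotide gene fixtures
with canonical exon/intron layouts and primer sites spaced for the
canonical amplicon, fragment sets, and misannotation scenarios with known
ground truth.  Backgrounds are i.i.d. draws from uniform residue
frequencies followed by per-family consensus mutation — the simplest model
that exercises every classifier code path; compositional realism is a
non-goal.  All generators are bit-reproducible for a fixed seed, and
rejection sampling guarantees that no fixture carries a cross-family
fingerprint by chance.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .fingerprints import AMINO_ACIDS, Motif, default_motifs, scan_motif
from .insilico_pcr import CANONICAL_AMPLICON_BP, Primer
from .seqio import GeneModel, SequenceRecord, revcomp

NUCLEOTIDES = "ACGT"

_FAMILY_CODE = {"AOX": 1, "PTOX": 2}

#: Alignment offsets at which family fingerprints are embedded.
_MOTIF_SITES = (60, 200)
#: Residues sampled for the weakly conserved fingerprint positions.
_WEAK_FIRST = "FLM"   # leading position of the (F)GWWRR signature
_WEAK_FIFTH = "ILV"   # the (I) of HHLL(I)ME

_PRIMER_LENGTH = 20
_CDS_LENGTH = 900
_FWD_OFFSET = 100  # forward-site start within the spliced CDS

_MAX_ATTEMPTS = 500


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic fixture set."""

    family: str
    n: int
    seed: int
    protein_length: int = 330
    mutation_rate: float = 0.1
    plant_fingerprints: bool = True
    amplicon_spacing: int = CANONICAL_AMPLICON_BP
    exon_layout: str = "canonical"

    def __post_init__(self) -> None:
        if self.family not in _FAMILY_CODE:
            raise ValueError(f"unknown family {self.family!r}")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not (0.0 <= self.mutation_rate < 1.0):
            raise ValueError("mutation_rate must be in [0, 1)")
        if self.protein_length < 240:
            raise ValueError("protein_length must be >= 240 to hold the fingerprints")
        if self.exon_layout not in ("canonical", "atypical"):
            raise ValueError(f"unknown exon_layout {self.exon_layout!r}")
        if not (2 * _PRIMER_LENGTH + 10 <= self.amplicon_spacing
                <= _CDS_LENGTH - _FWD_OFFSET - 50):
            raise ValueError(
                f"amplicon_spacing {self.amplicon_spacing} out of range for the "
                f"{_CDS_LENGTH} nt fixture CDS"
            )


@dataclass(frozen=True)
class GeneFixtureSet:
    """Genomic templates, their gene models, and the set's primer pair."""

    records: tuple[SequenceRecord, ...]
    models: tuple[GeneModel, ...]
    fwd_primer: Primer
    rev_primer: Primer


def _rng(spec_seed: int, family: str, stream: int) -> np.random.Generator:
    return np.random.default_rng([spec_seed, _FAMILY_CODE[family], stream])


def _plant_fingerprints(seq: list[str], family: str,
                        rng: np.random.Generator) -> None:
    """Overwrite the fingerprint sites in-place; mutations never touch them."""
    if family == "AOX":
        motifs = ("ERMHLVT", "YLEEEA")
    else:
        motifs = (
            rng.choice(list(_WEAK_FIRST)) + "GWWRR",
            "HHLL" + rng.choice(list(_WEAK_FIFTH)) + "ME",
        )
    for site, motif in zip(_MOTIF_SITES, motifs):
        seq[site:site + len(motif)] = list(motif)


def _mutate(consensus: np.ndarray, rate: float,
            rng: np.random.Generator) -> np.ndarray:
    seq = consensus.copy()
    mask = rng.random(seq.size) < rate
    # substitute to a uniformly chosen *different* residue
    seq[mask] = (seq[mask] + rng.integers(1, 20, mask.sum())) % 20
    return seq


def _hits_any(record: SequenceRecord, motifs: Sequence[Motif]) -> bool:
    return any(scan_motif(m, record) for m in motifs)


def make_protein_set(spec: FixtureSpec) -> list[SequenceRecord]:
    """Generate ``spec.n`` family-background protein sequences.

    All sequences share a random family consensus and the same length, so a
    set (or the union of an AOX and a PTOX set) is a gap-free alignment.
    With ``plant_fingerprints`` the family's two signatures are embedded at
    fixed alignment offsets; rejection sampling discards any draw that by
    chance carries a cross-family signature (or, with
    ``plant_fingerprints=False``, any signature at all).
    """
    rng = _rng(spec.seed, spec.family, 101)
    consensus = rng.integers(0, 20, spec.protein_length)
    motifs = default_motifs()
    own = motifs[spec.family]
    cross = motifs["PTOX" if spec.family == "AOX" else "AOX"]
    forbidden = cross if spec.plant_fingerprints else motifs["AOX"] + motifs["PTOX"]
    records: list[SequenceRecord] = []
    for i in range(spec.n):
        for _ in range(_MAX_ATTEMPTS):
            seq = _mutate(consensus, spec.mutation_rate, rng)
            chars = [AMINO_ACIDS[k] for k in seq]
            if spec.plant_fingerprints:
                _plant_fingerprints(chars, spec.family, rng)
            record = SequenceRecord(
                id=f"{spec.family}{i:03d}",
                residues="".join(chars),
                alphabet="protein",
                description=f"synthetic {spec.family} fixture",
                aligned=True,
            )
            if _hits_any(record, forbidden):
                continue
            if spec.plant_fingerprints and not all(
                scan_motif(m, record) for m in own
            ):
                continue
            records.append(record)
            break
        else:
            raise RuntimeError(
                f"make_protein_set: rejection sampling failed for {spec.family} "
                f"sequence {i} after {_MAX_ATTEMPTS} attempts"
            )
    return records


def make_fragment_set(
    spec: FixtureSpec,
    references: Sequence[SequenceRecord],
    fragment_length: int = CANONICAL_AMPLICON_BP // 3,
) -> list[SequenceRecord]:
    """Amplicon-equivalent fragments cut from full-length fixtures.

    Each fragment keeps the full alignment column space (flanks gapped out),
    so it aligns against full-length references; its ungapped length is
    ``fragment_length`` (default 148 residues, the 444 nt amplicon in amino
    acids).
    """
    if fragment_length >= spec.protein_length:
        raise ValueError("fragment_length must be shorter than the protein")
    rng = _rng(spec.seed, spec.family, 303)
    start_max = spec.protein_length - fragment_length
    fragments: list[SequenceRecord] = []
    for record in references:
        start = int(rng.integers(0, start_max + 1))
        residues = (
            "-" * start
            + record.residues[start:start + fragment_length]
            + "-" * (spec.protein_length - start - fragment_length)
        )
        fragments.append(
            SequenceRecord(
                id=f"frag-{record.id}",
                residues=residues,
                alphabet="protein",
                description=f"fragment of {record.id}",
                aligned=True,
            )
        )
    return fragments


def _random_nt(rng: np.random.Generator, length: int) -> str:
    return "".join(NUCLEOTIDES[k] for k in rng.integers(0, 4, length))


def _exon_count(spec: FixtureSpec, rng: np.random.Generator) -> int:
    canonical = 4 if spec.family == "AOX" else 9
    if spec.exon_layout == "canonical":
        return canonical
    choices = [canonical - 1, canonical + 1]
    return int(rng.choice(choices))


def make_gene_set(spec: FixtureSpec) -> GeneFixtureSet:
    """Generate nucleotide gene fixtures with primer sites and exon layouts.

    Canonical AOX genes get 4 exons / 3 introns, canonical PTOX genes 9
    exons / 8 introns; both carry primer annealing sites spaced so the
    product on the *spliced* sequence is exactly ``spec.amplicon_spacing``
    (444 bp by default).  Atypical layouts perturb the exon count by one
    and plant a 3 nt insertion or deletion between the primer sites, so the
    no-indel amplicon filter drops them.  The set's primer pair is a
    generated, template-unique 20-mer pair.
    """
    rng = _rng(spec.seed, spec.family, 202)
    fwd_seq = _random_nt(rng, _PRIMER_LENGTH)
    rev_binding = _random_nt(rng, _PRIMER_LENGTH)
    fwd = Primer(name="synP1", sequence=fwd_seq, role="forward")
    rev = Primer(name="synP2", sequence=revcomp(rev_binding), role="reverse")

    records: list[SequenceRecord] = []
    models: list[GeneModel] = []
    for i in range(spec.n):
        for _ in range(_MAX_ATTEMPTS):
            cds = list(_random_nt(rng, _CDS_LENGTH))
            cds[_FWD_OFFSET:_FWD_OFFSET + _PRIMER_LENGTH] = list(fwd_seq)
            rev_start = _FWD_OFFSET + spec.amplicon_spacing - _PRIMER_LENGTH
            cds[rev_start:rev_start + _PRIMER_LENGTH] = list(rev_binding)
            if spec.exon_layout == "atypical":
                # 3 nt indel strictly between the primer sites
                pos = int(rng.integers(_FWD_OFFSET + _PRIMER_LENGTH + 5,
                                       rev_start - 8))
                if rng.random() < 0.5:
                    del cds[pos:pos + 3]
                else:
                    cds[pos:pos] = list(_random_nt(rng, 3))
            cds_str = "".join(cds)
            if cds_str.count(fwd_seq) != 1 or cds_str.count(rev_binding) != 1:
                continue
            n_exons = _exon_count(spec, rng)
            cuts = sorted(
                int(c) for c in rng.choice(
                    np.arange(30, len(cds_str) - 30), size=n_exons - 1,
                    replace=False,
                )
            )
            bounds = [0, *cuts, len(cds_str)]
            exon_seqs = [cds_str[a:b] for a, b in zip(bounds, bounds[1:])]
            introns = [_random_nt(rng, int(rng.integers(60, 121)))
                       for _ in range(n_exons - 1)]
            if any(fwd_seq in intron or rev_binding in intron
                   for intron in introns):
                continue
            genomic_parts: list[str] = []
            exons: list[tuple[int, int]] = []
            cursor = 0
            for j, exon_seq in enumerate(exon_seqs):
                exons.append((cursor, cursor + len(exon_seq)))
                genomic_parts.append(exon_seq)
                cursor += len(exon_seq)
                if j < len(introns):
                    genomic_parts.append(introns[j])
                    cursor += len(introns[j])
            genomic = "".join(genomic_parts)
            if genomic.count(fwd_seq) != 1 or genomic.count(rev_binding) != 1:
                continue
            template_id = f"{spec.family}g{i:03d}"
            records.append(
                SequenceRecord(
                    id=template_id,
                    residues=genomic,
                    alphabet="nucleotide",
                    description=f"synthetic {spec.family} gene fixture "
                                f"({spec.exon_layout})",
                )
            )
            models.append(
                GeneModel(gene_id=f"{template_id}-g1", template_id=template_id,
                          strand="+", exons=tuple(exons))
            )
            break
        else:
            raise RuntimeError(
                f"make_gene_set: could not build gene {i} for {spec.family} "
                f"after {_MAX_ATTEMPTS} attempts"
            )
    return GeneFixtureSet(
        records=tuple(records), models=tuple(models),
        fwd_primer=fwd, rev_primer=rev,
    )


def make_discovery_groups(
    seed: int,
    n_per_group: int = 20,
    n_columns: int = 60,
    window_start: int = 25,
    motif_a: str = "ERMHLVT",
    motif_b: str = "AAAAAAA",
    mutation_rate: float = 0.05,
    weak_column: bool = False,
) -> tuple[list[SequenceRecord], list[SequenceRecord], tuple[int, int]]:
    """Two aligned groups differing only in a planted discriminative window.

    Both groups derive from one shared consensus mutated at
    ``mutation_rate``; inside the window group A is fixed to ``motif_a``
    and group B to ``motif_b``.  With ``weak_column`` the window's first
    column of group A is only 80% conserved, which the consensus emitter
    must report as a weak (parenthesized) position.  Returns the groups
    and the planted window as a half-open column interval.
    """
    if len(motif_a) != len(motif_b):
        raise ValueError("planted motifs must have equal length")
    window = (window_start, window_start + len(motif_a))
    if window[1] > n_columns:
        raise ValueError("planted window does not fit the alignment")
    rng = np.random.default_rng([seed, 404])
    consensus = rng.integers(0, 20, n_columns)

    def build(group_label: str, motif: str) -> list[SequenceRecord]:
        out = []
        for i in range(n_per_group):
            seq = _mutate(consensus, mutation_rate, rng)
            chars = [AMINO_ACIDS[k] for k in seq]
            chars[window[0]:window[1]] = list(motif)
            if group_label == "A" and weak_column and i % 5 == 4:
                # every fifth sequence breaks the first window column: 80/20
                alt = "W" if motif[0] != "W" else "Y"
                chars[window[0]] = alt
            out.append(
                SequenceRecord(
                    id=f"grp{group_label}{i:03d}", residues="".join(chars),
                    alphabet="protein", aligned=True,
                )
            )
        return out

    return build("A", motif_a), build("B", motif_b), window


#: Misannotation typology planted by :func:`make_misannotation_scenario`:
#: (true family, candidate claimed descriptions, expected audit category).
SCENARIO_CATEGORIES: tuple[tuple[str, tuple[str, ...], str], ...] = (
    ("PTOX", ("alternative oxidase",
              "alternative oxidase, partial",
              "putative alternative oxidase"), "PTOX_as_AOX"),
    ("PTOX", ("immutans",
              "protein IMMUTANS, chloroplastic"), "synonym_only"),
    ("AOX", ("AOX", "AOX protein"), "vague_AOX"),
    ("AOX", ("hypothetical protein",
             "unknown protein", ""), "unannotated"),
)


def make_misannotation_scenario(
    seed: int, n: int,
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """A mixed protein set with claimed labels covering the error typology.

    Cycles through four planted categories — a PTOX deposited as
    "alternative oxidase", a PTOX labeled only by the immutans synonym, an
    AOX labeled vaguely as "AOX" with no member, and an unannotated entry —
    so ``n = 4`` yields one record per category.  Returns the records (the
    claimed text in their descriptions) and a ground-truth table with
    columns ``sequence_id``, ``true_family``, ``claimed_text``,
    ``category``.
    """
    if n < 4:
        raise ValueError("make_misannotation_scenario: n must be >= 4")
    rng = np.random.default_rng([seed, 505])
    n_by_family = {"AOX": 0, "PTOX": 0}
    plan = []
    for i in range(n):
        family, texts, category = SCENARIO_CATEGORIES[i % len(SCENARIO_CATEGORIES)]
        plan.append((family, texts[int(rng.integers(0, len(texts)))], category))
        n_by_family[family] += 1
    pools = {
        fam: iter(make_protein_set(FixtureSpec(family=fam, n=count, seed=seed)))
        for fam, count in n_by_family.items() if count
    }
    records: list[SequenceRecord] = []
    rows = []
    for i, (family, text, category) in enumerate(plan):
        base = next(pools[family])
        rec = SequenceRecord(
            id=f"q{i:03d}", residues=base.residues, alphabet="protein",
            description=text, aligned=False,
        )
        records.append(rec)
        rows.append({"sequence_id": rec.id, "true_family": family,
                     "claimed_text": text, "category": category})
    return records, pd.DataFrame(rows)
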