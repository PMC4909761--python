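"""Sequence and gene-model I/O primitives.

FASTA and GFF3 are the exchange formats; internally every coordinate is
0-based, half-open.  GFF3 uses 1-based inclusive coordinates and the
conversion happens exactly once, at the I/O boundary.

Gap characters (``-``) are legal only in records flagged as aligned;
operations that need unaligned input reject gapped records explicitly
rather than silently stripping gaps.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

PROTEIN_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")
#: IUPAC DNA codes (no U; RNA input is out of scope).
NUCLEOTIDE_RESIDUES = frozenset("ACGTRYSWKMBDHVN")
GAP = "-"

_ALPHABETS = {"protein": PROTEIN_RESIDUES, "nucleotide": NUCLEOTIDE_RESIDUES}

FASTA_WRAP = 60


@dataclass(frozen=True)
class SequenceRecord:
    """One identified protein or nucleotide sequence.

    Parameters
    ----------
    id
        Unique identifier within a dataset; non-empty.
    residues
        Uppercase residue string, length >= 1.
    alphabet
        ``"protein"`` or ``"nucleotide"``.
    description
        Free text after the identifier on the FASTA header; may carry a
        claimed annotation.
    aligned
        When true, ``-`` gap characters are permitted in ``residues``.
    """

    id: str
    residues: str
    alphabet: str
    description: str = ""
    aligned: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if self.alphabet not in _ALPHABETS:
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        if len(self.residues) == 0:
            raise ValueError(f"record {self.id!r}: empty sequence")
        allowed = _ALPHABETS[self.alphabet]
        if self.aligned:
            allowed = allowed | {GAP}
        for pos, ch in enumerate(self.residues):
            if ch not in allowed:
                raise ValueError(
                    f"record {self.id!r}: residue {ch!r} at position {pos} "
                    f"is not a valid {self.alphabet} character"
                )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def ungapped_length(self) -> int:
        return len(self.residues) - self.residues.count(GAP)

    def ungapped(self) -> "SequenceRecord":
        """Copy of this record with gaps removed and ``aligned`` cleared."""
        return SequenceRecord(
            id=self.id,
            residues=self.residues.replace(GAP, ""),
            alphabet=self.alphabet,
            description=self.description,
            aligned=False,
        )

    def require_ungapped(self, operation: str) -> None:
        if GAP in self.residues:
            raise ValueError(
                f"{operation}: record {self.id!r} contains gap characters; "
                "supply an unaligned sequence"
            )


@dataclass(frozen=True)
class GeneModel:
    """Exon intervals of one gene on a template sequence.

    ``exons`` are 0-based half-open intervals, sorted ascending and
    non-overlapping; the intron count is exon count - 1.
    """

    gene_id: str
    template_id: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: invalid strand {self.strand!r}")
        if len(self.exons) == 0:
            raise ValueError(f"gene {self.gene_id!r}: no exons")
        object.__setattr__(self, "exons", tuple((int(s), int(e)) for s, e in self.exons))
        prev_end = None
        for start, end in self.exons:
            if end <= start or start < 0:
                raise ValueError(
                    f"gene {self.gene_id!r}: invalid exon interval [{start}, {end})"
                )
            if prev_end is not None and start < prev_end:
                raise ValueError(
                    f"gene {self.gene_id!r}: exons overlap or are unsorted at [{start}, {end})"
                )
            prev_end = end

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def intron_count(self) -> int:
        return len(self.exons) - 1

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


def read_fasta(path: str | os.PathLike, alphabet: str) -> list[SequenceRecord]:
    """Read a multi-FASTA file into :class:`SequenceRecord` objects.

    Residues are uppercased (soft-masking is not interpreted); records
    containing ``-`` are flagged ``aligned``.  Duplicate identifiers and
    residues outside the alphabet raise ``ValueError``.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for bio in SeqIO.parse(str(path), "fasta"):
        if bio.id in seen:
            raise ValueError(f"duplicate sequence id {bio.id!r} in {path}")
        seen.add(bio.id)
        residues = str(bio.seq).upper()
        desc = bio.description
        if desc.startswith(bio.id):
            desc = desc[len(bio.id):].strip()
        records.append(
            SequenceRecord(
                id=bio.id,
                residues=residues,
                alphabet=alphabet,
                description=desc,
                aligned=GAP in residues,
            )
        )
    return records


def write_fasta(records: Sequence[SequenceRecord], path: str | os.PathLike) -> None:
    """Write records as FASTA, 60-column wrapped; round-trips losslessly."""
    if not records:
        raise ValueError("write_fasta: no records to write")
    bio_records = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(bio_records, str(path), "fasta")


def read_gff(path: str | os.PathLike) -> list[GeneModel]:
    """Parse gene/exon features from a GFF3 file into :class:`GeneModel` s.

    GFF3 1-based inclusive coordinates become 0-based half-open; exons are
    sorted ascending per gene.  An exon whose Parent does not resolve to a
    gene in the file is an error, as are overlapping exons within a gene.
    """
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    gene_ids = {g.id for g in db.features_of_type("gene")}
    exons_by_gene: dict[str, list[tuple[int, int]]] = {g: [] for g in gene_ids}
    gene_meta: dict[str, tuple[str, str]] = {
        g.id: (g.seqid, g.strand) for g in db.features_of_type("gene")
    }
    for exon in db.features_of_type("exon"):
        parents = exon.attributes.get("Parent", [])
        resolved = [p for p in parents if p in gene_ids]
        if not resolved:
            raise ValueError(
                f"exon at {exon.seqid}:{exon.start}-{exon.end} has no parent gene "
                f"(Parent={parents!r})"
            )
        for parent in resolved:
            # GFF3 is 1-based inclusive -> 0-based half-open
            exons_by_gene[parent].append((exon.start - 1, exon.end))
    models = []
    for gene_id in sorted(gene_ids):
        seqid, strand = gene_meta[gene_id]
        exons = sorted(exons_by_gene[gene_id])
        if not exons:
            raise ValueError(f"gene {gene_id!r} has no exon features")
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValueError(
                    f"gene {gene_id!r}: overlapping exons [{s1},{e1}) and [{s2},{e2})"
                )
        models.append(GeneModel(gene_id=gene_id, template_id=seqid, strand=strand,
                                exons=tuple(exons)))
    return models


def write_gff(models: Sequence[GeneModel], path: str | os.PathLike,
              source: str = "aoxaudit") -> None:
    """Write gene models as GFF3 gene + exon features (1-based inclusive)."""
    if not models:
        raise ValueError("write_gff: no gene models to write")
    lines = ["##gff-version 3"]
    for m in models:
        start, end = m.span
        lines.append(
            "\t".join([m.template_id, source, "gene", str(start + 1), str(end),
                       ".", m.strand, ".", f"ID={m.gene_id}"])
        )
        for i, (es, ee) in enumerate(m.exons, start=1):
            lines.append(
                "\t".join([m.template_id, source, "exon", str(es + 1), str(ee),
                           ".", m.strand, ".",
                           f"ID={m.gene_id}.exon{i};Parent={m.gene_id}"])
            )
    Path(path).write_text("\n".join(lines) + "\n")


_COMPLEMENT_OK = NUCLEOTIDE_RESIDUES


def revcomp(seq: str) -> str:
    """Reverse-complement with IUPAC-aware complementation (R<->Y, K<->M, ...).

    An involution: ``revcomp(revcomp(x)) == x``.  Raises ``ValueError`` with
    the offending position on non-IUPAC input.
    """
    upper = seq.upper()
    for pos, ch in enumerate(upper):
        if ch not in _COMPLEMENT_OK:
            raise ValueError(
                f"revcomp: invalid nucleotide {ch!r} at position {pos}"
            )
    return str(Seq(upper).reverse_complement())


def splice(template: SequenceRecord, model: GeneModel) -> SequenceRecord:
    """Concatenate a gene model's exons from its template (the mature CDS).

    Minus-strand models are reverse-complemented after concatenation.
    """
    if template.alphabet != "nucleotide":
        raise ValueError("splice: template must be a nucleotide record")
    template.require_ungapped("splice")
    if model.template_id != template.id:
        raise ValueError(
            f"splice: model {model.gene_id!r} is on template "
            f"{model.template_id!r}, not {template.id!r}"
        )
    if model.span[1] > len(template.residues):
        raise ValueError(
            f"splice: gene {model.gene_id!r} extends past the end of {template.id!r}"
        )
    spliced = "".join(template.residues[s:e] for s, e in model.exons)
    if model.strand == "-":
        spliced = revcomp(spliced)
    return SequenceRecord(
        id=model.gene_id, residues=spliced, alphabet="nucleotide",
        description=f"spliced from {template.id}",
    )
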