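"""Exon/intron structure checks for AOX vs. PTOX affiliation.

In plants the typical AOX gene has 4 exons interrupted by 3 introns while
PTOX is structured in 9 exons and 8 introns, so the exon count alone is
corroborating evidence for family affiliation.  Intron gain and loss is
known in some AOX members, so any other count maps to ``atypical`` rather
than to a family call: the verdict is advisory and never overrides
fingerprint evidence.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .seqio import GeneModel

CANONICAL_AOX_EXONS = 4
CANONICAL_PTOX_EXONS = 9


@dataclass(frozen=True)
class StructureVerdict:
    gene_id: str
    exon_count: int
    intron_count: int
    verdict: str  # canonical_AOX | canonical_PTOX | atypical


def structure_verdict(model: GeneModel) -> StructureVerdict:
    """Classify a gene model by exon count.

    4 exons -> ``canonical_AOX``; 9 exons -> ``canonical_PTOX``; anything
    else -> ``atypical``.  The verdict depends only on the exon count, not
    on exon coordinates or sizes.
    """
    n_exons = model.exon_count
    if n_exons == CANONICAL_AOX_EXONS:
        verdict = "canonical_AOX"
    elif n_exons == CANONICAL_PTOX_EXONS:
        verdict = "canonical_PTOX"
    else:
        verdict = "atypical"
    return StructureVerdict(
        gene_id=model.gene_id,
        exon_count=n_exons,
        intron_count=model.intron_count,
        verdict=verdict,
    )


def write_verdicts(verdicts: Sequence[StructureVerdict], path: str | Path) -> None:
    """Write structure verdicts as TSV."""
    lines = ["gene_id\texon_count\tintron_count\tverdict"]
    lines += [
        f"{v.gene_id}\t{v.exon_count}\t{v.intron_count}\t{v.verdict}"
        for v in verdicts
    ]
    Path(path).write_text("\n".join(lines) + "\n")
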