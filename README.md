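# aoxaudit

Signature-based discrimination of plant **AOX** (alternative oxidase,
mitochondrial) from **PTOX** (plastid/plastoquinol terminal oxidase) and
auditing of claimed database annotations.

AOX and PTOX are the two membrane-bound quinol oxidases of the di-iron
carboxylate superfamily. They are close enough in sequence that
homology-based annotation pipelines routinely confuse them: PTOX proteins
get deposited as "alternative oxidase", records are labeled only by the
*immutans* synonym, or called simply "AOX" with no subfamily member, and
such errors propagate into new genome annotations. `aoxaudit` is for
molecular plant researchers and curators who need to confirm that a
sequence really is an AOX (or a PTOX), and at what resolution the data
supports a finer call.

## What it computes

* **Fingerprint classification.** Each family carries short diagnostic
  amino-acid signatures: `ERMHLVT` and `YLEEEA` for AOX, `(F)GWWRR` and
  `HHLL(I)ME` for PTOX, where a parenthesized letter is a weakly conserved
  position (any residue matches, but a non-preferred residue consumes the
  motif's weak-mismatch budget, 1 by default). A sequence is labeled by
  the family with more distinct fingerprint hits; ties are `ambiguous`,
  no hits `unclassified`.
* **Fingerprint discovery.** Given two grouped alignments, every column
  `c` gets a discrimination score
  `d(c) = (IC_A(c) + IC_B(c)) · (1 − Σ_r min(f_A(r), f_B(r)))`,
  where `IC = log2(20) − H` is the information content (bits) of the
  column's residue distribution — the quantity a sequence logo draws.
  The top non-overlapping windows by mean `d` are reported with
  per-group consensus motifs.
* **In-silico PCR.** Degenerate (IUPAC) primer sites are located on the
  template, every forward/reverse site pair yields a virtual product
  (primers included), and the no-indel filter keeps only products at the
  canonical **444 bp** length (tolerance 0 by default).
* **Gene structure.** Plant AOX genes typically have 4 exons / 3 introns
  and PTOX 9 exons / 8 introns; exon counts parsed from GFF3 give an
  advisory `canonical_AOX` / `canonical_PTOX` / `atypical` verdict that
  never overrides fingerprint evidence.
* **Neighbor joining.** Saitou–Nei NJ implemented from scratch on
  uncorrected p-distances (pairwise gap deletion), with deterministic
  tie-breaking, Newick output, and an unrooted-monophyly test
  (`is_separated`) for clade checks. Subfamily assignment calls the
  nearest reference, under a **fragment guard**: queries no longer than
  148 residues (the 444 nt amplicon in amino acids) can only receive
  subfamily-level labels (AOX1/AOX2), never member-level ones (AOX1a, …).
* **Annotation audit.** Claimed labels (FASTA descriptions or a TSV) are
  normalized and compared with the computed family; every record lands in
  one category: `concordant`, `PTOX_as_AOX`, `AOX_as_PTOX`,
  `synonym_only`, `vague_AOX`, `unannotated`, or `conflicting_evidence`.

A seeded generator (`aoxaudit.synthetic`) produces AOX/PTOX-like protein
sets, gene fixtures with canonical exon layouts and primer sites, amplicon
fragments, and misannotation scenarios with known ground truth, so the
whole pipeline is testable without any downloads.

## Worked example

Simulate a small misannotation scenario and audit it:

```sh
$ aoxaudit simulate --kind scenario --n 8 --seed 1 --out fixtures
$ aoxaudit audit fixtures/scenario.fasta --out audit.tsv
audited sequences: 8
  concordant            0
  PTOX_as_AOX           2
  AOX_as_PTOX           0
  synonym_only          2
  vague_AOX             2
  unannotated           2
records needing attention: 8
```

The scenario planted two PTOX sequences deposited as "alternative
oxidase" (recovered as `PTOX_as_AOX`), two labeled only by the immutans
synonym, two vague "AOX" claims, and two unannotated records — the audit
recovers every planted category from sequence evidence alone.

Run the canonical amplicon screen on simulated AOX genes:

```sh
$ aoxaudit simulate --kind genes --family AOX --n 3 --seed 1 --out fixtures
$ aoxaudit pcr fixtures/aox_spliced.fasta --primers fixtures/primers.tsv \
    --out-bed amplicons.bed
3 amplicons passed the 444±0 bp filter
$ cat amplicons.bed
AOXg000-g1	100	544	amplicon_444bp
AOXg001-g1	100	544	amplicon_444bp
AOXg002-g1	100	544	amplicon_444bp
```

Each spliced coding sequence yields exactly one product of 444 bp —
an amplicon of any other length would indicate an insertion or deletion
and be rejected by the filter.

The published universal primer pair is not redistributed here; supply your
own primer TSV (`name  role  sequence`), or use the generated fixture
primers as above.

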