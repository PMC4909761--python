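# Methods

## Problem setting

Alternative oxidase (AOX) and plastid terminal oxidase (PTOX) are the
membrane-bound members of the di-iron carboxylate protein superfamily.
AOX sits in the inner mitochondrial membrane and oxidizes ubiquinol; PTOX
is stromal and oxidizes plastoquinol. In higher plants AOX is a small
multigene family organized into two subfamilies, AOX1 and AOX2, with
members such as AOX1a–AOX1d. Because the two families are homologous and
database annotation is largely homology-driven, PTOX records are
regularly deposited under AOX names and vice versa. This package encodes
a set of sequence-level criteria that resolve the family (and sometimes
the subfamily) unambiguously, and an audit that compares those criteria
against what a record claims to be.

## Fingerprint model

A fingerprint is a short ordered amino-acid motif in which each position
is either *strict* (the residue must match exactly) or *weak*
(parenthesized in the notation; any residue matches, but a non-preferred
residue draws on a per-motif weak-mismatch budget, default 1). The
shipped defaults are `ERMHLVT` and `YLEEEA` for AOX and `(F)GWWRR` and
`HHLL(I)ME` for PTOX. The notation source never defines the parenthesis
formally; reading it as "weakly conserved, substitutable" is this
package's decision, consistent with the partial conservation a logo shows
at those positions, and the budget is configurable per scan.

Classification counts, per family, the number of *distinct* fingerprints
with at least one hit. The label goes to the strict majority; equal
nonzero scores are reported `ambiguous` and zero scores `unclassified` —
the tool's job is flagging, not guessing, so ties are never silently
resolved.

## Profiles and fingerprint discovery

Alignment columns are summarized by residue frequencies over the 20
standard amino acids (gaps and `X` excluded from the counts) and by
information content `IC = log2(20) − H` in bits, with no small-sample
correction — the plain logo convention. All-gap columns carry `n = 0`
and `IC = 0`.

Discovery scores each column of two group alignments (same column space
required) by

    d(c) = (IC_A(c) + IC_B(c)) · (1 − Σ_r min(f_A(r), f_B(r)))

so a column is valuable when it is conserved *within* each group and the
two groups' residue distributions barely overlap. A candidate window's
score is the mean of `d` over its columns; the top `k` non-overlapping
windows are chosen greedily, ties broken by smaller start column and then
by longer window. Group consensus strings report the modal residue per
column, parenthesized as weak when the modal frequency is below 0.9
(configurable). Mean scoring deliberately favors compact windows; when a
planted window is perfectly conserved, all of its sub-windows tie with it
exactly, so recovery checks in the test suite fix the window length
(`min_len == max_len`), i.e. they test coordinate recovery at known motif
width. Searching a length range remains the right mode for exploratory
use, where the trailing tie-break keeps results deterministic.

## In-silico PCR

Primer sites are found by sliding-window comparison under IUPAC
semantics: a template base matches a primer code when its expansion is a
subset of the code's expansion (so `N` in a primer matches anything, and
an ambiguous template base must be fully covered). Forward primers are
scanned as written and reverse primers as their reverse complement, on
the + strand only; templates are linear. Every forward/reverse site pair
with the reverse site fully downstream and product length at most
`max_product` (default 5000) yields one amplicon spanning from the start
of the forward site to the end of the reverse site — the product
*includes* both primer sites, the standard PCR-product convention; under
that convention the canonical screen length of 444 bp is met exactly by
the fixture geometry. The default filter keeps only products of exactly
444 bp (tolerance 0): any insertion or deletion between the primers
disqualifies a product. The classic universal AOX primer pair is cited
to primary literature and not redistributed; primers arrive via a TSV
config (entries must be ≥ 10 nt), and the fixture generator emits
template-unique 20-mers.

## Gene structure

Plant AOX genes typically carry 4 exons and 3 introns, PTOX 9 exons and 8
introns. The structure verdict is a pure function of the exon count: 4 →
`canonical_AOX`, 9 → `canonical_PTOX`, anything else `atypical`. Known
AOX variants with 3 or 5 exons (intron loss/gain) therefore land in
`atypical` deliberately — structure is corroborating evidence only and
never produces a family call on its own. In the audit, a structure
verdict that names the *other* family than the fingerprints is surfaced
as `conflicting_evidence` rather than resolved.

## Distances, neighbor joining, clades

The distance model is the uncorrected p-distance with pairwise gap
deletion (proportion of differing residues over columns where neither
sequence is gapped); a Poisson-corrected variant (`−ln(1 − p)`) is
available as an option. Neighbor joining is the Saitou–Nei algorithm:
at each step join the pair minimizing
`Q(i,j) = (n−2)·d(i,j) − Σ_k d(i,k) − Σ_k d(j,k)`, with branch lengths by
the standard formulas and the new node's distances by the reduction
formula. Numerical details that matter:

* `Q` is evaluated on the upper triangle in row-major order, so
  `argmin`'s first-occurrence rule implements a lexicographic tie-break
  exactly (and avoids the one-ulp asymmetry that evaluating `Q[i,j]` and
  `Q[j,i]` separately can produce);
* negative branch lengths are clamped to zero with a warning;
* two taxa give a single edge of length `d` (serialized as two
  half-edges), three taxa the closed-form star.

Newick serialization orders children by their smallest contained leaf
label and prints branch lengths at fixed 6-decimal precision, so the same
tree always serializes byte-identically; labels with Newick-special
characters are quoted. Monophyly (`is_separated`) holds when some
internal edge's bipartition equals the group or its complement.

Subfamily assignment calls the nearest reference by p-distance and
reports the margin to the second-best subfamily. Two guards apply: a
query equidistant from two subfamilies is `unresolved`, and a *fragment*
(ungapped length ≤ 148 residues, one third of the 444 nt amplicon;
444 nt for nucleotide data) is truncated to a subfamily-level label
regardless of the nearest member — the conserved fragment discriminates
AOX1 from AOX2 but carries no member-level signal, so member names from
fragment homology would be over-annotation.

## Synthetic fixtures

The generator emulates the curated datasets the classifiers assume, not
real plant proteomes. Defaults: protein length 330 (a typical plant AOX
precursor scale), per-site substitution rate 0.1 away from a random
family consensus, fingerprints embedded at fixed alignment offsets (60
and 200) with the two weak positions drawn from small residue sets
({F,L,M} and {I,L,V}), gene fixtures built from a 900 nt coding sequence
with the forward primer site at offset 100 and the reverse site placed
for an exact 444 bp product, introns of 60–120 nt, and atypical layouts
that perturb the exon count by one and plant a 3 nt indel between the
primer sites. Backgrounds are i.i.d. uniform over residues; rejection
sampling discards any draw that happens to contain a cross-family
fingerprint (or any fingerprint, for motif-free sets), which is what
makes the specificity tests exact rather than probabilistic. Scenario
generation cycles through the four planted error types (PTOX claimed as
AOX, immutans-only labels, vague "AOX", unannotated) with known ground
truth.

What passing on these fixtures does *not* show: tolerance to alignment
error, to real amino-acid composition, to fingerprint degeneracy in
distant taxa (the signatures are validated for plants only; non-plant
input is outside the validated scope), or robustness of NJ clade
separation at divergences far above the fixture default. The acceptance
checks are desk-scale analogues of database-wide results, which depend on
database snapshots and are out of scope here.

## Problem sizes

The shipped test suite runs on deliberately small instances chosen to
keep the whole suite fast while still exercising every code path: 100
AOX + 100 PTOX proteins across 20 seeds for specificity, 50 random
additive trees of 4–12 leaves for NJ recovery, 20-seed discovery and
fragment-guard sweeps, and 1000-instance brute-force equivalence checks
for the two scanners. The acceptance script screens 6 canonical AOX gene
fixtures per run.

## Known limitations

* No graphical logo rendering, HMM/PSSM search, thermodynamic PCR
  modeling, multiple sequence alignment, or Bayesian phylogenetics;
  aligned input is required where an alignment is assumed.
* Nucleotide records are never auto-translated; auditing takes protein
  sequences (silent frame errors are worse than an explicit step).
* `X` residues match nothing in motif scans and are excluded from
  profiles; heavily masked sequences will under-classify.
* The structure verdict ignores exon sizes, although coding-exon size
  conservation is known in AOX, because no robust rule is available.
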