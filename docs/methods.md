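# Methods

This note records the scientific model implemented by `annobench`, the
choices made where the design was genuinely open, and what the synthetic
benchmark does and does not establish about real data.

## Read simulation

Reads are fixed-length windows slid over a genome with stride `step`
(1-based provenance recorded per read). A linear genome of length `G`
yields exactly `⌊(G−L)/step⌋+1` reads of length `L`; circular genomes use
every `step`-th start once, wrapping across the origin. Reads are taken
from the forward strand only: translated search is strand-agnostic, so
simulating reverse-complement reads would change no downstream quantity
while complicating provenance.

Each read's origin is classified from a per-position category mask:
*KO gene* / *non-KO gene* / *intergenic*, with *multi* for reads spanning
categories. A position covered by at least one KO gene counts as KO-gene
territory even when a non-KO gene overlaps it — KO evidence dominates —
and strand is ignored. Overlap fractions always sum to 1 per read.

Sequencing error is substitution-only (no indels), drawn independently per
position from a position-dependent rate profile; the profile can be
uniformly magnified to a target aggregate rate (refusing to push any
position past probability 1). Replacement bases follow an optional 4×4
row-stochastic substitution matrix, else are uniform over the three
alternatives. Defaults of interest are the aggregate rates 0.15%, 1.5% and
3%, spanning typical Illumina error levels. Error injection is deterministic
given (reads, profile, seed).

## Annotation protocols and weighting

Alignments come in as 12-column tabular (blastx `outfmt 6` dialect) rows.
Hits with E ≥ 1 are dropped (strict `<`); remaining hits are sorted by
E ascending, bitscore descending, then subject id. **Ties are defined by
equality of the E-value text as printed by the aligner**, not by float
equality: aligners print coarse precision and a float round-trip would
split printed ties. Top-N truncation extends through ties with the N-th
hit, so equally scoring alignments are treated jointly.

The four protocols (*top gene*, *top KO*, *top 20 genes*, *top 20 KOs*) are
described in the README. Weights over the considered alignments derive
from the chance-match probability `P_i = 1 − exp(−E_i)`. Two readings of
"weighted by P-value" are defensible, and both are implemented:

* `complement` (default): `w_i ∝ 1 − P_i = exp(−E_i)` — better hits weigh
  more. This avoids the pathological case where a perfect hit (`P ≈ 0`)
  receives zero weight.
* `literal`: `w_i ∝ P_i`, with a uniform fallback when all `P_i = 0`.

The choice of functional form has little practical effect for the E-value
ranges that matter (all considered `exp(−E) ≈ 1`, weights near-uniform);
neither form is asserted to be "the" historical one. A hit to a gene with
several KOs splits its weight equally among them, preserving unit sums.
`no_result` (considered hits carry no KO) is distinguished from `no_hit`
(no alignment at all) so recall accounting can separate the two causes.

## Database exclusion

Exclusion filters the alignment table, never recomputes it: removing all
hits whose subject belongs to the focal strain/species/genus is equivalent
to replacing those database sequences by non-matching sequences of equal
length, which preserves database-size-based statistics (E-values) exactly.
The distance mode removes subjects whose genome sits at precomputed
distance strictly below a cutoff (cutoff 0 removes nothing); it is exact in
the same sense only while the database size assumption holds, so consumers
of distance-filtered tables at large cutoffs must know their E-values
reflect the original database.

## Evaluation

Classification is per considered alignment: gene correctness means the
subject *is* a gene the read overlaps; KO correctness means the subject's
KO set intersects the source gene's. Weights aggregate into seven labels
(correct/incorrect gene × correct/incorrect/no KO, plus
`no_result`/`no_hit`); for annotated reads label weights sum to 1.

The headline metrics are operationalized as weighted counts with reads as
the unit:

* `recall_ko` — correct-KO weight summed over KO-gene-origin reads, divided
  by the **count** of such reads. Unannotated reads count in the
  denominator: a read that produced no alignment is still a missed KO read.
* `precision_ko` — correct-KO weight divided by all KO-assigned weight over
  every evaluated read; an empty denominator is reported as NaN.
  Unannotated reads therefore reduce recall but never precision.
* `recall_gene` — analogous with gene correctness, over gene-origin reads.

Multi-category reads are excluded by default (their correct annotation is
ill-defined). The `coverage_weighted` policy instead evaluates them as a
mixture: each alignment's weight is split by the read's category coverage,
the gene-covered share judged against the overlapped genes and the
remainder counted as incorrect-by-construction; such reads enter recall
denominators at their KO-gene coverage fraction. A companion table groups
partially overlapping reads by overlap bases and reports mean
correct / incorrect / no-result probabilities (rows sum to 1).

## Profiles, copy numbers, distances

Per-KO counts are the summed fractional weights. Length normalization
divides each contribution by the **aligned** gene's length (simulating
ignorance of the true source gene; multi-hit reads contribute
weight-averaged reciprocal lengths in a single linear pass), or
alternatively by the KO's mean member-gene length. Copy number is the
normalized count divided by the mean normalized count over a configurable
panel of single-copy marker KOs; absent markers contribute zero to that
mean, and an all-zero marker panel is an error. The real 15-marker
ribosomal panel is database-specific, so markers are always an explicit
argument and synthetic fixtures declare their own.

Profile comparisons use the Jensen-Shannon distance: vectors are
zero-filled over the KO/pathway union, normalized to sum 1, and compared
with the base-2 `√JSD` (0·log 0 ≡ 0), a metric bounded by [0, 1]. Pathway
abundances add each KO's abundance to every pathway it belongs to and
normalize per sample. Enrichment of poorly recalled KOs uses the one-sided
hypergeometric upper tail with Benjamini–Hochberg correction (FDR was
specified only as "0.05 FDR"; BH is the standard choice). Per-KO recall
CIs across datasets use the normal approximation (±1.96 SE, clipped to
[0, 1]). Protocol comparison runs paired Wilcoxon signed-rank tests per
pathway against a reference protocol, restricted to pathways with nonzero
paired differences in at least `min_samples` (default 10) samples, again
BH-corrected.

## Synthetic communities and the oracle aligner

The generator arranges genomes on a strains-within-species-within-genera
grid. Genes occupy fixed slots; the slot-`s` genes across one genus form a
homolog family sharing one KO (when the slot is KO-annotated). Marker
slots reuse one global KO id across all genomes and are single-copy
everywhere. Sequence content is random nucleotide filler — homology lives
entirely in the oracle's declared hit structure, which keeps every
downstream number exactly derivable and the tests fast; nothing depends on
sequence similarity.

The oracle emits, for each gene-origin read: a self hit at `self_evalue`;
hits to every same-family homolog at the E-value of the taxonomic
relationship (same-genome paralog < sibling strain < sibling species, i.e.
nested E-values); optionally a cross-genus "remote" hit to the same slot in
another genus — a *different* KO, so genus-level exclusion leaves only
wrong annotations; and, with probability `decoy_rate`, a random unrelated
hit in a high-E decoy band. Intergenic reads receive only decoys. With
probability `corruption_rate` a read fails to map entirely: its self *and*
family hits are dropped. This read-level interpretation of mappability
failure is deliberate — dropping only the self hit would let same-KO
homologs rescue the read, making measured recall insensitive to the
corruption rate and biasing copy-number recovery upward for duplicated
KOs; with read-level failure, top-gene recall equals `1 − corruption_rate`
in expectation and copy numbers stay unbiased. Multi-category reads
receive no family hits by default (keeping copy-number fixtures exact); an
opt-in flag gives them their dominant gene's hits for overlap-mappability
studies.

Two hand-worked fixtures anchor the arithmetic: a three-read case whose
precision/recall are computed by hand (top gene: precision 1/2, recall 1;
top KO: precision 1/3), and an equal-length community where a duplicated
KO's copy number is exactly 2 because window counts `(l − L + 1)` and equal
gene lengths cancel.

## What the benchmark does and does not show

Passing tests establish that the pipeline's bookkeeping — weighting,
classification, metric accounting, normalization, exclusion — is exactly
correct under a declared homology structure, and that stochastic inputs
(error rates, corruption rates, copy numbers) are recovered within
binomial sampling error. They do **not** establish anything about real
aligner behavior: E-value distributions, low-complexity artifacts,
alignment-length effects and genuine sequence divergence are outside the
oracle's model, and conclusions about a real database require real
alignment tables, which the package consumes in the same formats.

## Problem sizes and numerical notes

The bundled analyses use communities of 8 genomes (~10 genes × ~300 bp
each, ~30k step-1 reads of 101 bp) — large enough for binomial bounds at
the 2-SE level while keeping any run to seconds. Error-injection
calibration uses ~10⁶ bases. Exact assertions (fixtures, perfect-oracle
limit, metric identities) are made to machine precision; stochastic
assertions state their 2-SE tolerance explicitly. Degenerate inputs
(all-zero profiles, empty hit lists, absent markers, zero-length genes)
raise typed validation errors rather than propagating NaNs, with the single
documented exception of NaN precision when no KO weight was assigned at
all.
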