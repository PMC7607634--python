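# Methods

## Locus model and alignment

A locus is a set of `ParalogCopy` records (transcript-orientation sequence,
exon/3'-trailer intervals, a 200-kDa-generative flag, a pseudogene flag)
grouped into alleles with a genetic-action label. Sequences are strict
A/C/G/T; ambiguity codes are rejected at load because everything downstream
relies on exact-match semantics. Coordinates are 0-based half-open
throughout.

Copies are aligned with a star-progressive strategy: global
Needleman–Wunsch (Biopython's `PairwiseAligner`, affine gaps; defaults
match 1, mismatch −2, open −4, extend −0.5) of every copy against the first
copy, merged on the shared centre coordinate system ("once a gap, always a
gap"; insertions at the same centre position are left-justified). For the
>90%-identical sequences of a paralog cluster this is equivalent to a full
MSA in practice, is deterministic for fixed inputs and parameters, and the
round trip (ungapping any row) reproduces each input exactly — a tested
invariant. Gap placement in ties follows the pairwise aligner's first
optimal alignment; since no reference alignment of the real locus is
reproduced here, tie-breaking is a free choice and only determinism is
guaranteed.

## Diagnostic sites

A site is either a single variant column (SNP) or a maximal run of
contiguous columns with an identical row-gap pattern (indel; a 6-bp
deletion is one site, not six). States are the literal row slices; copies
with identical states form the site's partition. Given a target partition
(e.g. generative vs non-generative), a site is kept iff its partition
refines the target — the exact condition under which the site assigns every
copy to its target block with zero errors. Two trailer SNPs that jointly
split four copies into three groups are fused into one composite site.

## Read classification and counting

A read pair matches a copy when mate1 occurs verbatim on the sense strand,
the reverse complement of mate2 occurs verbatim downstream (fragment cap 2
kb), and both occurrences are consistent with one fragment; unstranded mode
also tries the swapped orientation. A single substitution anywhere voids
the match. Pairs matching a proper, non-empty subset of copies are
informative.

A pair contributes to a site only when (a) its matched set equals one state
block and (b) the site's full column span lies within the sequenced bases
of a single mate. Condition (b) prevents a subtle bias: a mate covering
only one SNP of the composite trailer site would resolve block {4} but not
{3} or {1,2}, inflating the singleton fraction.

Counts are converted to block fractions with a read-length bias
correction: a mate of length R can cover a span of σ template positions
from R − σ + 1 start offsets, and σ differs between indel haplotypes (a
deletion junction needs σ = 2; the insertion haplotype needs σ = 2 + indel
length). Raw counts therefore over-represent the deletion block by a few
percent at a 6-bp indel; inverse weighting by the offset count removes the
first-order effect. The correction is exact for single-mate coverage and
leaves a second-order residual well below the statistical noise at the
depths used here.

## Ratio deconvolution

With indel blocks {1,4} | {2,3} and trailer blocks {4} | {3} | {1,2}, the
estimator is r₄ = g₄, r₃ = g₃, r₁ = f₁₄ − g₄, r₂ = 1 − r₁ − r₃ − r₄
(closure). The mapping is derived structurally — each indel block must
contain exactly one trailer singleton — so the code works for any copy
labelling with this shape. Negative intermediates, which finite depth can
produce when f₁₄ < g₄, are clipped to 0 and the vector renormalized, with a
flag. Both sites must reach a minimum informative depth (default 50 reads,
giving a binomial SE below 0.07 at the observed fractions). Fractions are
never rounded internally; two-decimal rounding happens only in reports.

The composite-trailer fractions plus the indel fraction determine the four
ratios exactly (three free fractions, three unknowns), so the subtraction
route and the closure route for r₂ coincide identically and cannot check
each other. The reported `consistency_gap` therefore uses extra data: one
trailer SNP is re-counted on its own (accepting reads resolved beyond its
blocks by other sites), giving a second, partially independent measurement
of the singleton fraction; the gap is the absolute difference between the
two implied estimates and decays as 1/√depth. Without the auxiliary count
the gap is 0 by construction.

Replicates are summarized with per-copy mean ± SD and a Tukey HSD
(statsmodels) compact letter display: letters are the maximal cliques of
the not-significantly-different graph, lettered from the largest mean.
With zero residual variance the test is degenerate; following its limit
behaviour, distinct means receive distinct letters and exactly equal means
share one.

## Primer design and in-silico PCR

Binding requires exact full-length identity on either strand; a
mismatch-tolerant mode is deliberately absent from the default path because
the discrimination mechanism — a 3-bp indel under the 3' terminus — is
encoded conservatively by exactness. Products are enumerated exhaustively:
every plus-strand forward site upstream of a minus-strand reverse site
within the size cap. The designer anchors the forward primer's 3' end 1–4
bases past the indel on a target-block representative, requires the primer
to span the indel's left flank, places the reverse primer in the first
downstream run of invariant columns, and accepts a candidate only after
`predict_amplicons` confirms it amplifies all of, and only, the target
block. Melting temperatures use the Wallace rule (2·AT + 4·GC) with bounds
50–65 °C and lengths 18–25 nt — simple, testable criteria chosen because no
thermodynamic specification constrains the design. Genotyping-style size
markers are reported as expected amplicon-length multisets per allele.

## Densitometry, Δ, and the dose model

`complex_ratio` averages replicated 250-kDa/420-kDa intensity ratios; an
all-zero genotype is "not detected". Δ = baseline mean − genotype mean,
clamped to [0, baseline]: the baseline is the assay's ceiling, so a
not-detected genotype realizes the full baseline drop and negative Δ is not
meaningful. Δ is computed from genotype-level means (not per-blot pairing)
because the measurements arrive as genotype summaries. The dose model is
additive with a hard ceiling: potential = n × per-allele Δ, realized =
min(potential, baseline), residual = potential − realized, and
realized + residual = potential holds exactly.

Relative qPCR expression is 2^(Ct_ref − Ct_target); amplification
efficiency is a parameter (default 2.0, the standard assumption, chosen so
simulation round-trips invert exactly). A no-amplification sentinel (NaN
Ct) maps to abundance 0 with a detected=False flag. The mRNA–Δ correlation
is Pearson's r with an ordinary least-squares line over genotype-level
points (four in the headline analysis); at n = 4 the r value is a direction
check, not a precise estimate.

## What the simulators emulate — and what they do not

Read simulation reproduces the aspects that matter to an exact-match
counter: multinomial copy sampling, uniform fragment starts, Gaussian
fragment lengths (default 300 ± 50 nt, resampled up to 10× then clamped
into [read length, transcript length]), dUTP-style strandedness (mate1 on
the sense strand), and i.i.d. substitution errors. Indel sequencing
errors, quality scores, PCR duplicates, intron splicing, and transcriptome
background are not modelled — the exact-match rule discards any mismatching
read, so the substitution rate alone controls informative-read yield, and a
passing test here says nothing about alignment-stage artefacts in real
libraries. Densitometry noise is truncated-Gaussian (intensity ratios
cannot be negative); qPCR noise is Gaussian on the Ct scale, the standard
instrument error model. Sequencing depth is a free parameter (the real
study's informative-read depths are not published); the package default of
20,000 pairs per replicate puts per-copy sampling error near 0.01, and the
test suite uses 5,000–20,000 pairs to keep runs fast while leaving
statistical headroom.

The bundled locus fixture is synthetic: it reproduces the published
polymorphism structure (copy counts per allele, the generative/pseudogene
flags, the 6-bp and 3-bp indels, the trailer SNPs, allele-private SNPs) on
a random 1,100-nt backbone, not the real sequences — positions of the
planted variants are structural stand-ins. Real sequences drop in through
`load_catalog` with the same metadata schema. One bookkeeping note: the
cluster counts eleven gene copies when the pseudogene is excluded; the
fixture carries all twelve members across six alleles.

## Known limitations

- Exact-match classification discards ~1 − (1 − e)^(2·101) of pairs at
  substitution rate e; it does not rescue or model ambiguity.
- The star alignment assumes high similarity; divergent inputs would need a
  real progressive/iterative MSA.
- Δ values measured on different blot series are assumed to share an
  intensity scale; the correlation inherits that assumption.
- The compact letter display is the clique-cover convention; other CLD
  algorithms can letter borderline patterns differently.
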