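# Methods

This note documents the models, the synthetic-data generator, the
numerical choices and the known limitations of `svasm`, in the spirit of a
statistical-software methods appendix.

## Coordinate and representation conventions

All internal coordinates are 0-based half-open on the reference forward
strand. Minus-strand MAF query coordinates are converted to forward-strand
coordinates at parse time; the strand survives as a flag and the gapped
rows are stored exactly as aligned (reference-oriented). VCF output is
dialect 4.2, 1-based, bi-allelic only, and always writes full allele
sequences — never symbolic ALTs — because nucleotide resolution is the
point of assembly-based calling. Indels carry a left anchor base; at a
chromosome start the anchor falls back to the right. Every call set is
left-normalized: shared allele suffixes/prefixes are trimmed (extending
left through the reference when an allele would empty), which yields the
unique leftmost representation. Complex replacement alleles are first
passed through align-gap-excise realignment to strip matching flank
sequence before trimming. Normalization is idempotent and verified against
an exhaustive shift-enumeration oracle in the tests.

## Alignment kernels

Global and local affine-gap alignment use Biopython's `PairwiseAligner`
(match +1, mismatch −2, gap open −4, gap extend −1 by default; a gap of
length L costs open + (L−1)·extend). These defaults are a conventional
scheme chosen once; all downstream rules operate on identity/ratio
thresholds, not raw scores. Two similarity summaries drive the
characterization rules:

* **identity** — matches divided by all alignment columns, gap columns
  included;
* **aligned ratio** — aligned query bases divided by query length.

When the DP size (query × target) exceeds 2×10⁷ cells, similarity
screening switches to edlib's bit-parallel semi-global alignment: identity
is derived from the edit distance of the best target infix and the whole
query is aligned by construction. This is a screening approximation — for
a query half-contained in the target it reports depressed identity rather
than a clipped high-identity hit — and both routes reach the same
accept/reject decisions at the 0.95 thresholds used throughout.

The align-gap-excise realignment implements the split-maximization core of
the AGE family: H[i,j] (best global score of the prefixes) and B[i,j]
(suffixes) are computed with a row-vectorized three-state DP, and the
split maximizing prefix + suffix score is recovered from H plus a suffix
maximum of B in O(nm). Opening a horizontal gap from a cell whose best
path ends in a horizontal gap is dominated by extending whenever
gap open ≤ gap extend, which the `Scoring` type enforces; this makes the
in-row scan exact. Ties resolve leftmost (smallest left breakpoints, then
smallest right breakpoints); when the optimal excision is empty the
breakpoints are reported at the window ends. The five-matrix formulation
of the original AGE method (which also handles inversions inside the
window) is intentionally not reproduced; block-level strand flips are
handled upstream by the discovery layer.

## Discovery

Within a block, mismatch columns are SNPs and gap runs are anchored
indels; columns containing N are not called (assembly gaps are not
variants). Between adjacent blocks of one scaffold (sorted 5'→3' on the
scaffold), the gap pattern decides the category: query-only gap →
insertion, reference-only gap → deletion, both → simultaneous gap (split
into block substitution or length-asymmetric replacement by interior
lengths), interior strand flip flanked by collinear same-strand blocks →
inversion, chromosome change → inter-chromosomal breakpoint, non-collinear
order → intra-chromosomal breakpoint, anything else → no solution.
Numerical guards: adjacent blocks overlapping on the query by up to 20 bp
(split aligners duplicate repeat edges) are trimmed before gap
arithmetic, larger overlaps become no-solution; gaps above 50 kb become
no-solution (the size spectrum the pipeline targets runs 1 bp–50 kb).
Translocation and no-solution records carry a junction position but no
allele sequences, so they are reported alongside the call set rather than
merged into the VCF.

Merging across individuals collapses records with identical normalized
(chrom, pos, ref, alt) — exact-breakpoint semantics — and counts carriers;
records seen in ≥ 2 individuals are flagged double-hit and serve as the
default positive training set for recalibration. Unaligned scaffold spans
≥ 100 bp are emitted as clipped (partially aligned scaffold) or nomadic
(fully unaligned scaffold) segments; uncovered reference intervals are
inter-/intra-scaffold gaps depending on whether the flanking coverage
comes from one scaffold.

## Genotyping

The three-state mixture is fitted by EM on all non-missing intensity
pairs, to a log-likelihood change below 10⁻⁶ or 200 iterations. The
"linear constraints" are implemented as (i) a per-coordinate box
|μ<sub>j</sub> − m·μ<sub>j,expected</sub>| ≤ 0.3 and (ii) strict ordering
of the centers along the A-intensity axis, both enforced by projection
after each M-step (clip to the box, then separate adjacent violators by
10⁻⁴). Covariances are diagonal by default for robustness at small N,
with a variance floor of 10⁻⁴; a state that loses all responsibility mass
keeps its current parameters and a warning is raised. The constraint bias
used for selecting m is the L1 distance of the fitted centers from the
scaled expected centers; with trios available, the per-m bias and
Mendelian error rate are each ranked across the five fits and the smallest
rank-sum wins, ties resolving toward m = 1. Equal posteriors break to the
earlier state in RR < RA < AA. Note that with a "neither allele" read
fraction of ~5 % the true intensity centers sit ~0.93 of the ideal ones,
so m = 0.9 is the correct selection on such data — the scaling grid exists
precisely to absorb this kind of systematic shrinkage.

## Recalibration

Each class mixture selects its cluster count (1–8) by BIC with a fixed
random state. The printed log-odds score is undefined for raw mixture
densities above 1, so the implementation feeds it the prior-weighted
two-class-normalized probability P_pos = p01·L_pos/(p01·L_pos + p02·L_neg)
and P_neg = 1 − P_pos, computed on the log scale and clamped to
[10⁻¹⁰, 1 − 10⁻¹⁰]; the score is then a base-10 logit, monotone in the
Bayes factor. Since the AUC itself is threshold-free, the PASS threshold
is the ROC cutoff maximizing Youden's J = TPR − FPR (ties take the highest
threshold), which operationalizes "keep most positives while minimizing
negatives". Cross-validation is stratified k-fold with seeded shuffling,
refitting both mixtures and the threshold inside each fold. The
inbreeding filter uses strict inequalities at the printed −0.4/0.7 bounds
and skips monomorphic loci, where F is undefined.

Feature operationalizations (the TSV input path accepts any subset
directly): gap ratio = N-base fraction of the scaffold within ±500 bp;
misalignment probability = 10^(−MQ/10) of the carrying alignment; local
identity and alignment score from the enclosing block; scaffold position
normalized to [0,1]; read-level depths and proper/improper ratios from a
read summary.

## Ancestral state and mechanism

The per-outgroup rule table: both alleles above 0.95/0.95 in every
outgroup → Common; longer allele passing and shorter failing in some
outgroup → Deletion; the reverse → Insertion; both directions present
across outgroups → Conflict; something alignable (≥ 0.5/0.5) but no
decision → NA; nothing alignable anywhere → NONE. Reading
"longer-allele-ancestral" as a deletion event (and symmetrically) is the
evolutionary logic that also drives type rectification: a discovered
insertion whose longer allele is ancestral was a deletion from the
ancestral sequence. Aligned ratio is measured on the allele (query) side.
The four-primate outgroup set used for human data is a documented preset;
any FASTA set works and nothing is downloaded.

Mechanism precedence is CCC → TEI → VNTR → NAHR → NHR, first match wins:
CCC is the most specific (exact equality with the same-length 3'
sequence), repeat-library evidence (local hit with identity ≥ 0.80
covering ≥ 0.80 of the variant) outranks flank homology, NAHR requires
reciprocal flank identity > 0.85 over 200 bp windows with an alignment
span of at least 50 bp, and NHR requires a junction microhomology of
≥ 2 bp (and less than the variant length). Variants under 50 bp are
UNSURE; variants matching no rule are NA. Note that a VNTR contraction
removing at most half of an array is genuinely ambiguous with CCC (the
removed units exactly equal the sequence that follows), and the precedence
order calls it CCC — this is an inherent property of the rule set, not an
implementation artifact.

## Novel sequence

"Not well aligned to the reference" uses the same inclusive 0.95/0.95
identity/aligned-ratio pair that defines similarity to other genomes, so a
single threshold pair governs both directions. The > 100 bp length
threshold applies to the novel interior (the inserted allele without its
anchor). Nomadic candidates need corroboration from at least one other
genome; with none supplied, everything is discarded with a
machine-readable reason. Closest-relative linking ignores local hits
covering under half the novel sequence (short spurious hits are trivially
high-identity) and reports no link below 0.5 identity.

## The synthetic-data generator

The generator emulates a ten-trio population study (30 individuals) on a
2 × 1 Mb reference at GC 0.41, with planted repeat structure per
chromosome: 20 Alu-like 300 bp and 2 LINE-like 6 kb consensus copies at
3 % divergence, 15 tandem arrays (3–11 bp units × 20–60), 12 tandem
duplications and 6 homologous 200 bp pairs. It plants ≈ 950 variants:
400 SNPs, 250 small indels (1–10 bp), 60 TEI events (consensus-copy
deletions/insertions, echoing the 300 bp and 6 kb size peaks of
transposition), 40 VNTR unit-count changes, 40 CCC copies, 12 NAHR spacer
deletions between homologous pairs, 60 NHR indels with 2–8 bp junction
microhomology, 20 inversions and 80 replacements, spaced ≥ 600 bp apart.
Construction details chosen so the planted truth is recoverable and
unambiguous: VNTR contractions remove more than half the array and
expansions at least double it (otherwise the CCC exact-copy test fires
first, legitimately); NHR deletions are placed where the reference
naturally provides the microhomology; replacement payloads differ from the
reference at both boundaries so planted coordinates are already canonical.
Truth records are canonicalized with the same left-alignment routine the
pipeline uses — representation only; breakpoint recovery from the
alignments is still the thing under test.

Genotypes are Mendelian by construction: parental haplotypes are Bernoulli
draws at an allele frequency ~ Uniform(0.1, 0.9) per event, children
inherit one haplotype from each parent, and each individual's *assembly*
is haplotype 1 (so a heterozygote's variant is visible to discovery only
half the time, as with real haploid-consensus assemblies). An event
carried by nobody's first haplotype is forced onto one parent to keep
every planted record discoverable. Alignments are emitted error-free:
SNPs and sub-50 bp indels as in-block columns, larger events as
between-block gap/strand structure. Read intensities are Poisson depth
(default 30×) with binomial allele sampling, 2 % cross-allele mismapping
and a 5 % neither-allele fraction. Recalibration features come from
well-separated multivariate normals per class. Outgroup windows carry the
designated ancestral allele (deletions: alt ancestral with probability
0.28; insertions: 0.09 — matching observed rectification rates) plus
background divergence on a primate-like ladder (1.3/1.7/1.8/6.4 %), so the
most diverged outgroup typically fails the 0.95 bar, as real macaque-grade
outgroups do.

What passing tests on this generator do **not** show: robustness to
assembler misjoins and consensus errors, aligner-specific block artifacts
beyond small edge overlaps, read-level sequencing error, reference bias in
read realignment, or mechanism signatures blurred by repeat-internal
variation. The generator is deliberately error-free in the places where a
production run depends on an external aligner's behaviour.

## Problem sizes and determinism

The test suite and the acceptance script regenerate all data at run time
from seeds; integer RNG streams make outputs identical across platforms.
Sizes used: full study ≈ 950 variants × 30 individuals for discovery
(≈ 10 s); 500 individuals for EM parameter recovery; 1,800
individual-locus calls for depth-30 concordance; 100 loci × 10 trios for
error-free Mendelian checks; 50 constructed fixtures per mechanism and
ancestral class; 800 feature vectors for recalibration; 1,000 HWE loci for
the inbreeding calibration; 80 events for end-to-end ancestral accuracy.
The acceptance script completes in about one minute on one CPU.

## Known limitations

* Bi-allelic loci only; multi-allelic sites are emitted as separate
  records and genotyped against a single alternative.
* The genotyper's box/ordering constraints are a reconstruction of the
  published method's unspecified linear constraints; they are documented
  as such and not asserted to be the original.
* Translocation and no-solution calls are breakpoint reports, not
  sequence-resolved VCF records.
* The AGE-style realignment handles excision only (no within-window
  inversion handling).
* Semi-global screening of very large targets approximates aligned ratio
  as 1; identity carries the decision there.
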