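# svasm

Discovery, genotyping, quality recalibration and biological
characterization of structural variants (SVs) from population-scale
*de novo* assembly-versus-reference alignments.

Re-sequencing pipelines recover SNPs and small indels well but are biased
against complex structural variation and novel sequence. When whole-genome
*de novo* assemblies are available instead, every variant — from a SNP to a
multi-kilobase insertion — is encoded at nucleotide resolution in the
assembly-versus-reference alignment. `svasm` is a toolkit for people
working with such cohorts: it walks each assembled scaffold 5'→3' over its
alignment blocks, categorizes everything it sees (SNP, deletion, insertion,
inversion, block substitution, length-asymmetric replacement,
translocation breakpoints, unaligned "clipped"/"nomadic" sequence,
uncovered reference gaps), normalizes and merges the calls into one
population VCF, genotypes them from read support, recalibrates their
quality, and annotates ancestral state, formation mechanism and novel
sequence.

## The models at the core

**Genotyping.** Per variant and individual *i*, the observation is
d<sub>i</sub> = (R intensity, A intensity): the fractions of reads uniquely
supporting the reference and alternative allele after realigning reads
against both allele sequences. Across a population these cluster into
three genotype states j ∈ {RR, RA, AA}, modelled as a constrained Gaussian
mixture:

    P(G_ij | d_i) = w_j N(d_i | μ_j, Σ_j) / Σ_k w_k N(d_i | μ_k, Σ_k)

fitted by EM with w initialized at (1/3, 1/3, 1/3) and centers at
m·{(1, 0.001), (0.5, 0.5), (0.001, 1)} for a scaling factor m scanned over
{0.8, 0.9, 1.0, 1.1, 1.2} (five training rounds). The M-step projects
centers back into a box around the scaled expected centers and enforces
μ<sub>RR,A</sub> < μ<sub>RA,A</sub> < μ<sub>AA,A</sub>; the best m
minimizes the rank-sum of the constraint bias and the trio Mendelian error
rate. Calls are posterior argmax with GQ = −10·log10(1 − p), capped at 99.

**Recalibration.** Two Gaussian mixtures (1–8 clusters, chosen by BIC) are
trained over up to nine technical features (assembly gap ratio, alt/neither
read depths, misalignment probability, alignment score, local identity,
scaffold position, proper/improper read ratios) on positive (e.g.
double-hit) and negative training variants, combined with known/novel
priors (0.6/0.4 vs 0.4/0.6), and scored as

    Score(x) = −lg(1 − P_pos(x)) + lg(1 − P_neg(x))

with the PASS threshold at the ROC point maximizing TPR − FPR. Loci with
excess hetero-/homozygosity among unrelated individuals are filtered on
the inbreeding coefficient F = 1 − N_het/(2pqN), removing F < −0.4 or
F > 0.7.

**Characterization.** Each allele (±500 bp flanks) is compared against
outgroup genomes by local alignment; an allele is ancestral-grade when both
identity and aligned ratio exceed 0.95. Longer-allele-ancestral variants
are Deletion events, shorter-allele-ancestral ones Insertion events (with
Common/NA/NONE/Conflict for the remaining configurations), and
insertion/deletion labels are rectified to match. Formation mechanisms are
tested in the order CCC → TEI → VNTR → NAHR → NHR (variant equal to its 3'
neighbour sequence; mobile-element library hit; tandem-repeat library hit;
breakpoint flank identity > 0.85; junction microhomology ≥ 2 bp); variants
under 50 bp are UNSURE. Inserted alleles > 100 bp absent from the
reference (identity/aligned ratio below 0.95/0.95) are novel sequence, as
are nomadic scaffolds corroborated by other genomes.

## Worked example

A synthetic study with known ground truth exercises the whole pipeline —
no downloads needed:

```bash
svasm simulate --seed 5 --out-dir demo --chrom-length 120000 --trios 2
# 181 planted variants in demo
svasm detect --maf demo/father0.maf --reference demo/reference.fa \
      --scaffolds demo/father0.fa --sample father0 --out-vcf demo/father0.vcf
# 90 variants, 5 unaligned segments
svasm genotype --vcf demo/truth.vcf --intensities demo/intensities.tsv \
      --ped demo/pedigree.ped --out demo/genotyped.vcf
# scaling factor m=0.9
svasm report --vcf demo/truth.vcf --out demo/report.tsv
```

The report tabulates the call set per type:

```
      Number  Length  Min_length  Max_length  Individual_number_mean  ...
DEL       83   38039           1        6000               57.333333
INS       13    6915         280         954                8.333333
REPL       1     119         119         119                0.333333
SNP       84      84           1           1               58.500000
```

`simulate` plants 181 variants into a 2×120 kb reference for two trios;
`detect` recovers the 90 that sit on father0's assembled haplotype (one of
the two haplotypes is assembled, so roughly half the carried heterozygous
variants are visible); `genotype` picks the intensity scaling factor
m = 0.9, reflecting that ~5 % of simulated reads support neither allele
and shrink both intensities below their ideal centers. Every library
function is also importable directly (`svasm.discovery`,
`svasm.genotyper`, …); the CLI is a thin layer over them.

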