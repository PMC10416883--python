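# Methods

## The marker scan

Given a cohort of diploid genotype calls over S sites and a partition of
samples into a target breed T and a pooled comparison panel O (all other
breeds), a (site, allele) pair is reported as a breed-specific marker when

1. among the |T| target samples, `non-carriers + missing ≤ r`, where a
   sample *carries* an allele iff its call is non-missing and contains the
   allele at least once, and
2. no sample in O carries the allele.

The relaxation budget r (default 1) deliberately pools non-carriers and
missing calls: its purpose is to tolerate one deviating animal per breed —
whether the deviation is biological (an animal clustering with a sibling
breed) or technical (a dropped call) is indistinguishable at n = 4–5.
Setting r = 0 gives the strict scan. Monotonicity holds by construction:
the marker set at r is a subset of the set at r + 1.

Two readings of "breed-private" are provided. **Allele mode** (default)
treats the allele as private regardless of zygosity; this is the standard
private-allele notion and the stricter absence condition. **Genotype mode**
requires all target samples (minus the budget) to share one unordered
genotype that no comparison sample has; records then carry the shared
genotype. The REF allele is eligible to be private by default (privateness
is symmetric in allele identity); `allow_ref_allele=False` restricts
reporting to ALT alleles.

Missing comparison-panel calls do **not** disqualify a site under the
default `permissive` policy: with hundreds of panel animals, treating every
missing call as potential carriage would annihilate the candidate set. The
`strict` policy (any missing panel call disqualifies the site) is retained
for sensitivity analysis. Output is strictly sorted by
(chrom, pos, allele_index) and invariant to sample order.

`brute_force_scan` re-implements the same contract as plain Python triple
loops with no shared counting code; it serves as the independent oracle in
the tests (200 randomized cohorts, both modes, r ∈ {0, 1, 2}) and as the
adjudicator of "complete truth" on simulated data (below).

## Structure

The dosage matrix counts the first ALT allele per call; multi-allelic sites
are excluded from dosage-based analyses by default (they remain first-class
in the scan). Site frequency p comes from observed calls only; missing
cells are mean-imputed to 2p before PCA, which keeps the sample covariance
PSD and the result deterministic. Each retained column is standardized to
(d − 2p)/√(2p(1−p)) — the variance-standardized relationship-matrix
convention — and the covariance ZZᵀ/m is eigendecomposed (via SVD). Scores
are projections onto the top-k principal axes; eigen-signs are fixed by
making the largest-magnitude loading positive so runs are reproducible.
Monomorphic sites are excluded; a MAF ≥ 0.05 filter is the default for
PCA/MDS and is an explicit flag, not a claim about any upstream tool's
settings.

IBS distance is 1 − mean per-site allele-sharing fraction
(1 − |dᵢ − dⱼ|/2), pairwise-complete over missingness; a pair with no
shared observed site is an error. Classical MDS double-centres the squared
distances, takes the top-k eigenpairs and scales by √λ; negative
eigenvalues (non-Euclidean input) are truncated to zero with a warning.
The test suite cross-checks the embedding against an independent principal
coordinates implementation (scikit-bio's `pcoa`).

## LD decay

r² is the squared Pearson correlation of genotype dosages over
pairwise-complete samples — the genotypic, phase-free definition, matching
unphased diploid data. Pairs need ≥ 3 complete entries and both vectors
non-constant; otherwise r² is undefined, skipped and tallied. Defaults:
window 100,000 bp (0.1 Mb), bin width 1,000 bp (chosen to give 100 curve
points; binning conventions of external LD tools vary and none is claimed
here), within-breed MAF ≥ 0.05 (avoids degenerate correlations at n = 4–5).
Bins are half-open [lo, hi); a pair at exactly the window limit falls in
the final bin so counts are bit-reproducible. Breed ranking uses the
trapezoidal area under the curve over bins defined in *every* compared
curve, most extensive LD first.

## Annotation and enrichment

Gene models are read from GFF3 (gffutils, in-memory) into per-chromosome
interval trees over gene, exon and CDS features; intervals are 0-based
half-open internally and queries convert from 1-based positions at the
boundary. Classification precedence is CDS > non-coding exon > intron >
upstream/downstream > intergenic; upstream/downstream are strand-aware
within a 5,000 bp flank (a common effect-predictor default, exposed as a
flag). The nearest gene is chosen by minimal edge distance with ties broken
by smaller start then lexicographic id, so annotation is deterministic for
overlapping models. Only region-level classes are assigned — codon-level
effect prediction would require the genome sequence and adds no surface the
downstream analysis (genic/intergenic split + gene lists) uses.

Enrichment is the upper-tail hypergeometric test
P(X ≥ k | N, K, n) per pathway on a user-supplied pathway→gene table,
with query genes outside the universe dropped (logged) and BH adjustment
across tested pathways. The default universe is the gene set of the
supplied GFF3.

## Phenotypes

Schaeffer's formula W = l·g²/300 takes body length and heart girth in
inches and returns pounds; conversion to kilograms uses the international
pound (0.45359237 kg). Breed comparisons use a two-tailed t-test; Welch's
unequal-variance form is the default because at n = 4–5 with visibly
different spreads the pooled test is anticonservative, and Student's pooled
variant is a flag. Two zero-variance groups with equal means give p = 1 by
convention. Superscript letters: two breeds share a letter iff their
pairwise p ≥ α (default 0.05). No multiple-testing correction is applied
across conformation parameters by default, mirroring per-parameter
reporting practice; a BH option exists in the enrichment module if needed.

## The simulator

The generator emulates the statistical shape the other modules assume — a
handful of small target breeds (4–5 animals), larger comparison panels,
breed-level drift, missing calls and planted private alleles — not any
particular real dataset. Drift is Balding–Nichols: ancestral frequency p
per site (Beta(1,1) by default, or fixed), breed frequency ~
Beta(p(1−F)/F, (1−p)(1−F)/F) at differentiation F, genotypes
Binomial(2, p_breed). Planted sites overwrite the background: the private
ALT allele goes hom to all target samples except the configured dropout
count, and to nobody else. Missingness is i.i.d. per cell but never erodes
a planted site's target carriers, so the planted truth table stays exact.
All randomness flows from one mandatory integer seed; identical configs
give byte-identical VCF output.

Drift also creates *coincidental* private alleles; rather than letting
these make precision tests flaky, truth is oracle-adjudicated: the
brute-force scan defines the complete positive set, of which the planted
table is a guaranteed subset.

Linked cohorts draw each breed's haplotypes as mosaics of **two** ancestral
haplotypes per block: along a block, a haplotype keeps its ancestral
assignment between adjacent sites with probability (1−c)^distance (c =
per-bp recombination), so c = 0 gives r² = 1 exactly for every defined
within-block pair (with two ancestral haplotypes, every polymorphic site's
dosage is an affine function of the shared assignment count) and c = 1
gives free recombination. Two ancestral haplotypes is the minimal choice
that makes the zero-recombination limit exact; it also caps within-breed
haplotype diversity, which is the intended regime (small drifted breeds).

What the simulator does **not** model: coalescent genealogies and
recombination maps, selection, block-wise (non-i.i.d.) missingness,
genotyping error, and multi-allelic private markers (planting uses the
first ALT). Passing tests therefore demonstrate algorithmic correctness on
cohorts with the assumed structure, not robustness to every artefact of
real resequencing data.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale, chosen so the whole
suite completes in well under a minute of compute per module: oracle
equivalence on 200 randomized cohorts of 200 sites × 18 samples; planted
recovery on a 600-site, 48-sample cohort with 50 markers per target breed;
structure recovery at 2,000 sites × 20 samples; LD fixtures of 120–150
sites. Tolerances: exact equality for integer counts and sorted record
lists; 1e−8 for eigen-identities (trace preservation, score orthogonality,
MDS distance recovery); 1e−9 for t-test closed forms; 1e−12 for
hypergeometric arithmetic. The permutation-null LD check uses a standard
error of the null r̄ with the number of *sites* (not pairs) as the
effective sample size, since pairs sharing a site are dependent.

## Known limitations

- The scan's absence condition is exact, not statistical: no p-value
  accompanies a marker, and a single genotyping error in the comparison
  panel suppresses a true marker (the relaxation budget applies to the
  target side only).
- Dosage-based modules use only the first ALT allele; cohorts dominated by
  multi-allelic sites lose most loci to the biallelic filter.
- Streaming VCF reader: no tabix/index support, so region queries scan the
  file; fine at desk scale, slow for whole-genome files.
- IBS and LD computations are O(n²) in samples and sites respectively
  within the window; they target cohorts of tens-to-hundreds of samples.
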