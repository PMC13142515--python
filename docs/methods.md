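# Methods

This note documents the models implemented in `pleiomap`, the choices made
where the design was genuinely open, what the synthetic-cohort generator does
and does not emulate, and the numerical conventions used throughout. It states
no empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Conventions

Coordinates are 1-based inclusive. Variant identifiers are underscore
delimited `chr_pos_ref_alt` (e.g. `19_44908684_T_C`). Genome-wide
significance defaults to p ≤ 1 × 10⁻⁸; credible-set lead p-value thresholds
are 1 × 10⁻⁵ for GWAS-class and 1 × 10⁻³ for molQTL-class sets, with
per-study overrides (e.g. 1.7 × 10⁻¹¹ for a proteomics biobank). All
randomness flows from one root seed through named child streams (one per
operation), so stages are individually reproducible and adding draws to one
stage never perturbs another.

## Synthetic cohort generator

The generator emulates the statistical structure a post-GWAS pipeline
consumes, not genomes themselves:

- **LD-blocked genome.** Per block, signed AR(1)-style LD
  r_ij = s_i s_j ρ^|i−j| (default ρ = 0.92), positive semi-definite by
  construction; draws failing a PSD check (tolerance −1e−8 on the smallest
  eigenvalue) are projected to the nearest correlation matrix or re-drawn
  with bounded retries. MAFs are Beta(0.6, 1.2)/2 on (0.002, 0.5] — a free
  parameter documented, not calibrated, since no quantitative MAF spectrum is
  specified for the cohorts this stands in for.
- **Summary statistics.** Marginal z-scores follow the standard RSS model
  z ~ N(R z_causal, R) per block, via a Cholesky factor with 1e−8 diagonal
  jitter. This makes PICS and CLPP behave realistically without
  individual-level genotype simulation.
- **Effect–frequency coupling.** Planted effects follow
  |β| = β₀ · [2f(1−f)]^(−α) with α = 0.5 and β₀ = 0.045. α = 0.5 makes
  detection power approximately MAF-independent while reproducing the inverse
  relationship between MAF and |β| among detected signals; β₀ puts planted
  non-centralities at z ≈ 5.7–20 over the simulated sample-size range
  (n ∈ 10^4.2–10^5.3), so detection is high but not certain.
- **Planted pleiotropy.** A pleiotropy plan assigns each causal gene a set of
  diseases (default sizes cycling 1–8 over a 21-disease, 7-therapeutic-area
  pool); all of a gene's diseases share one causal variant near its TSS, so
  variant- and gene-level pleiotropy are planted jointly. Effect signs are
  concordant per gene up to a 10% discordance rate.
- **molQTL credible sets.** For a configurable fraction (default 0.8) of
  causal genes, a molecular-QTL credible set shares the planted causal
  variant as its highest-PIP member (lead PIP uniform on 0.55–0.9, the rest
  spread over r² ≥ 0.5 proxies, truncated at cumulative PIP ≥ 0.95), so
  planted pairs colocalise by construction (CLPP ≥ 0.25 · 0.25).
- **Annotations.** Consequence categories are drawn with a per-MAF-bin
  protein-altering-variant (PAV) rate decreasing in MAF; pathogenicity scores
  are Beta(6,2) for PAVs and Beta(1.2,8) otherwise; per-population allele
  frequencies jitter the simulated MAF.
- **Clinical pipeline.** Approval is Bernoulli with
  logit P = base + b₁·support + b₂·log(uD+1) + b₃·log(uD+1)², where uD is
  the target's unique-disease count; non-approved records receive their
  maximum phase from sequential Bernoulli transitions (Phase I→II 0.835,
  II→III 0.46 — chosen to match the marginal phase distribution of a large
  curated clinical corpus of 37,377 target–indication pairs). Approval is
  drawn marginally over all records rather than conditionally on reaching
  Phase III: with a single binary covariate the marginal logistic odds ratio
  then equals exp(b₁) exactly, which is what the enrichment stage estimates
  and what the recovery tests check. The default bonus is b₁ = log 3.6.
  In the integrated cohort, a supported record's indication is one of its
  target's planted diseases and an unsupported record's indication lies
  outside that set, so support is recoverable from the evidence tables alone.

What the generator does **not** emulate: individual-level genotypes,
recombination maps, multi-ancestry LD admixture, genetic correlation between
diseases, winner's-curse effect-size inflation, and realistic ontology depth
(the synthetic disease ontology is two levels: disease → therapeutic area).
Tests passing on this cohort therefore demonstrate correctness of the
*methods* under a known generative model, not performance claims about real
GWAS corpora.

## Harmonisation

- **Major-ancestry MAF.** Single population → that population; uneven mixture
  → largest proportion; exact tie → NFE preferred, else the first population
  listed. MAF = min(EAF, 1 − EAF); missing frequencies mark the annotation
  failed and exclude the variant downstream.
- **Rescaling.** |Z| = √(χ²₁ quantile at 1 − p);
  SE = 1/√(2nf(1−f)·K(1−K)) for binary traits, 1/√(2nf(1−f)) for
  quantitative; β̂_resc = SE·Z signed by the study or fine-mapping. P-values
  below the double-precision floor must enter as log₁₀(p); inversion uses the
  log-space normal quantile (`ndtri_exp`), never producing infinities.
- **Power.** NCP = maxBeta²·maxEffN·2·maxMAF(1−maxMAF)/11; the divisor 11 is
  implemented exactly as printed in the source formula even though the
  accompanying prose ("an order of magnitude") suggests 10 — the difference
  is a constant factor on the NCP and does not change any qualitative
  behaviour. Effective sample size, unspecified in the source, is the
  standard GWAS convention 4/(1/cases + 1/controls) for binary designs and n
  for quantitative ones. Power is floored at 10⁻⁸ (the central case equals
  the tail threshold).
- **Qualification.** Disease studies: binary, n > 1000 (strict), in-study
  prevalence n_cases/n > 0.1% (no external population prevalence source is
  assumed). Measurement studies: quantitative, excluding protein and
  microbiome measurements. Credible sets: minor allele count 2·n·MAF ≥ 20
  and |β̂_resc| < 3 (strict); rare leads (MAF < 1%) additionally need a
  significant molQTL colocalisation, a PAV in the set, or replication.
  Qualification is monotone: adding evidence never un-qualifies a set.
- **Replication.** A GWAS credible set replicates when its (lead variant,
  trait) pair recurs in a different cohort/biobank, publication or ancestry
  group; a molQTL set when its (lead variant, gene) pair recurs at least
  twice anywhere.
- **Therapeutic areas.** Ancestor traversal over child→parent ontology edges
  collects reachable TA roots; 'measurement' is dropped; a configurable
  priority table (oncology first; a documented default ordering of 23 areas
  ships with the package) breaks multi-root ties; no reachable root →
  'other'.

## Locus definition and PICS

Three clumping strategies: greedy ±500 kb distance windows; greedy LD
absorption at r² ≥ 0.5 (r² is the square of signed r; assignment is greedy
by significance, not transitive closure); and the three-step locus breaker
(distance clumping; clustering of p < 1e−5 variants within 250 kb gaps,
keeping clusters containing a genome-wide significant variant; splitting
clusters over 1.5 Mb into ±750 kb sub-loci around the distance-clump leads,
so every output locus spans ≤ 1.5 Mb). "Most significant" ties break by
larger |β̂|, then lexicographic variant id, for determinism.

PICS assigns proxy causal probabilities from the lead's S = −log₁₀ p:
μ = r²·S, σ = √(1 − r^k)·√S/2 with k = 6.4 (configurable), relative
probability 2·(1 − Φ((S − μ)/σ)). A literal normal *density* at S would
degenerate at r² = 1 (σ = 0 gives the lead infinite weight); the upper-tail
form is the cited method's published behaviour, is continuous with value 1 at
r² = 1, and yields the expected 0.5/0.5 split for a perfect proxy.
Probabilities are renormalised over the r² ≥ 0.5 proxy set (not the full
locus) by default; both the exponent and the normalisation set are
configuration knobs pinned by a dual-implementation oracle test.

## Colocalisation

CLPP is the exact shared-variant sum of PIP products; it is symmetric and
invariant to member reordering. The five-hypothesis posterior uses Wakefield
approximate Bayes factors per variant (prior effect s.d. 0.15 for
quantitative, 0.2 for binary traits) combined by single-causal-variant
configuration enumeration in log space with priors p1 = p2 = 1e−4,
p12 = 1e−5 — the method's canonical defaults, configurable. H4 is computed
from summary statistics (not upstream fine-mapping Bayes factors). Regions
with fewer than two variants are unassessable and excluded. Direction calls
first harmonise alleles (flip β on swapped effect/other alleles;
strand-ambiguous A/T and C/G pairs at MAF > 0.4 are unusable), then take the
sign of the PIP-weighted shared evidence; any unusable sign makes the call
'unknown'.

## Locus-to-gene model

The exact production feature list is not public; the implemented roster is a
documented interpretation, config-driven and pinned by tests: 12 individual
features (sentinel/PIP-weighted-mean distance to TSS and to the gene
footprint, with distance score 1 − min(d, 500 kb)/500 kb; maximum CLPP and
maximum H4 against eQTL/pQTL/sQTL sets of the gene; PIP-weighted mean and
maximum variant pathogenicity), their 12 neighbourhood counterparts
(individual ÷ per-credible-set maximum, 0 when the maximum is 0), and four
context features (gene counts — deliberately unscaled — fine-mapping-method
confidence tier, nearest-protein-coding indicator). Candidate genes lie
within ±500 kb of the credible-set region; missing evidence encodes as 0.

Training positives are credible-set × gene rows matching a deduplicated
gold-standard (gene, trait) pair; negatives are the other protein-coding
genes on the same credible set. The 80/20 split groups credible sets through
shared positive genes (union–find) so no positive gene spans partitions. The
classifier is a gradient-boosted tree ensemble (xgboost) with an optional
small cross-validated grid over depth/learning-rate/trees selected by
average precision; a fixed seed makes scores reproducible. Selection takes
every gene scoring ≥ 0.5 per credible set, falling back to the top gene if
it scores ≥ 0.1.

## Pleiotropy

Clustering seeds on the unassigned credible set with the smallest lead p
(ties: larger |β̂_resc|, then cs_id) and alternates two expansions to a full
fixed point: pull in all significantly colocalised sets, then all sets
sharing any lead variant in the cluster. The fixed point (rather than
expanding around the seed only) makes the result a partition equal to
connected components of the union relation, which the oracle tests exploit.
vPS = unique diseases in the cluster (union over all leads); gPS = unique
diseases over a gene's prioritised variants; directionality concordance is
the largest same-sign fraction (1 for a single association).

Tissue specificity follows the standard expression-atlas rubric: ≥4-fold
above every other tissue → 1 (boundary inclusive); 2–5 tissues each ≥4-fold
above all others → 0.75; ≥4-fold above the mean of the others → 0.5; else
−1; binary = score > 0.75; undetected genes are excluded.

Count models are negative-binomial GLMs (log link) with maximum-likelihood
dispersion and a Poisson fallback when the dispersion estimate diverges —
appropriate for small synthetic cohorts where overdispersion may be weak.
Covariates are min–max scaled to [0, 1]; constant covariates are dropped
with a warning. Accuracy is the Pearson R² between predicted and observed
counts; a covariate's contribution is R²(full) − R²(without it). Gene-set
enrichment regresses membership on log₂(gPS) per set with Wald tests and
Benjamini–Hochberg correction across sets; empty or degenerate sets are
skipped with a logged reason.

## Clinical translation

Evidence propagates **down** the disease ontology only: evidence on the
indication or any descendant counts as support; ancestors do not (except
exact match). This captures indirect associations without over-propagating
broad terms; the direction is configurable. Oncology indications are removed
before modelling. Fisher enrichment reports the sample OR = ad/bc and
RS = row-wise approval ratio with log-scale normal confidence intervals;
when a cell is zero the exact Fisher p is still reported and the OR falls
back to the conditional maximum-likelihood estimate (0/∞ limits apply),
avoiding ad-hoc 0.5 corrections in headline numbers. A multinomial-resampling
percentile bootstrap of the OR is available as a cross-check. Stratified
comparisons fit approval ~ flagA + flagB and t-test the coefficient
difference, BH-corrected across requested pairs. The non-linear pleiotropy
analysis compares baseline/linear/quadratic nested logistic models in
log(count+1) by likelihood-ratio tests, with 200-resample percentile
bootstrap bands over a 50-point grid and a LOWESS curve (span 0.6, fixed).
Phase-transition probabilities P(II|I), P(III|II), P(approval|III) are
reported per pleiotropy group (1 / 2–5 / ≥6 therapeutic areas) with
closed-form Wilson 95% intervals and BH-corrected pairwise two-proportion
tests; empty groups are omitted. The strict-support flag is PAV support
combined with genetic support in 2–5 therapeutic areas.

## Problem sizes and degenerate inputs

The default demo configuration uses 8 LD blocks × 60 variants, 24 genes, 42
disease + 8 measurement studies and 10,000 clinical records — sizes chosen so
the full pipeline and its Monte-Carlo validations run in seconds on one CPU
while every stage still has non-trivial structure (replicated studies,
multi-gene loci, background molQTLs). Degenerate inputs are handled
explicitly: empty genome-wide-significant sets yield empty loci (not errors);
single-variant colocalisation regions are unassessable; empty strata and
empty gene-set overlaps fail or skip with messages naming the offender; and
PIP, probability and span invariants are validated at construction.

## Known limitations

- PICS is single-causal-variant by design; no conditional or multi-signal
  fine-mapping is attempted.
- The colocalisation posterior enumerates single-causal configurations only.
- gPS inherits the upper-bound character of disease counting: it conflates
  vertical and horizontal pleiotropy and is inflated by correlated diseases;
  the synthetic cohort does not model that correlation, so the pipeline's
  recovery results bound method error, not epidemiological bias.
- The L2G feature roster approximates an unpublished production list; scores
  are comparable within this package only.
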