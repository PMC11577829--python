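# Methods note

Model, assumptions, generator design and numerical choices behind
`locus2gene`. Thresholds quoted here are the package defaults
(`locus2gene.pipeline.PipelineConfig`); all are parameters.

## 1. Statistical model

### Locus definition and candidate genes

Variants pass QC with MAF ≥ 1e-4 and p ∈ (0, 1]; the extended HLA region
(chr6:25–34 Mb) is excluded because its LD structure breaks the locus model.
Loci are built from variants with p < 1e-6 by merging overlapping ±250 kb
windows; the lead variant is the minimum-p member (ties broken by smaller SE,
then variant id, so results are order-independent). Candidate genes are those
whose footprint lies within 250 kb (inclusive) of any member variant; the
nearest gene is the one with the smallest lead-to-footprint distance
(lexicographic tie-break).

### Variant annotation

A variant is **coding** if its consequence is missense or its impact is HIGH;
it is **pathogenic** if impact is HIGH, or it is coding and carries any of
the pathogenicity / destabilization / conservation flags. **Associated
variants** of a locus are members with p < 1e-6 *and* p ≤ p_lead·10⁵
(inclusive); the lead always qualifies, so lead evidence implies associated
evidence. ABC enhancer-gene intervals are 0-based half-open (BED); a variant
at 1-based position *x* overlaps intervals containing *x*−1. **ABCmax** at a
variant is the candidate gene with the highest ABC score among overlapping
intervals (score ties flag all tied genes); **any-link** is any overlap.

### Mendelian randomization

Two-sample MR with molecular traits as exposures. Instruments: molQTL
variants with p < 1e-4 and MAF ≥ 1%, greedily clumped (smallest p first,
removing variants with r² > 0.01 within 10 Mb; p-ties break by variant id).
Harmonization re-expresses the outcome effect for the exposure's effect
allele (sign flip + frequency complement when alleles are swapped);
palindromic variants (A/T, C/G) are kept only when both frequencies fall on
the same side of 0.5 and outside [0.42, 0.58]. One instrument → Wald ratio
β_out/β_exp with first-order delta SE = se_out/|β_exp| (exposure-side
uncertainty ignored — standard, anti-conservative for weak instruments; the
p < 1e-4 gate keeps instruments strong). Two or more → fixed-effect IVW,
equal to the zero-intercept WLS slope with weights 1/se_out². Multiple
testing: Benjamini–Hochberg across all gene × dataset tests per GWAS,
significance at q < 0.05.

### Colocalization

Per-variant Wakefield log approximate Bayes factors,
log ABF = ½(log(1−r) + r·z²) with r = W/(V+W), prior effect SD √W = 0.15 for
quantitative and 0.20 for binary (log-odds) traits. Hypothesis weights use
per-variant priors p1 = p2 = 1e-4 (single-trait causal) and p12 = 1e-5
(shared causal). Assumptions inherited from the ABF framework: at most one
causal variant per trait in the region, and both datasets measured on the
same variants in comparable populations. Colocalization is run gene × dataset
only where MR passed FDR, over variants shared within ±250 kb of the lead.
Evidence counts datasets with PP(H4) strictly > 0.8.

### Rank table

Tier criteria, top-down (any satisfied criterion sets at least its tier; a
gene's tier is the maximum):

| tier | criteria |
| --- | --- |
| Very high | lead pathogenic; coloc in > 2 datasets + ABCmax at lead |
| High | lead coding; associated pathogenic; coloc > 2 + ABCmax at associated; coloc ≥ 1 + ABCmax at lead |
| Moderate | coloc ≥ 1; MR pQTL q < 0.05; ABCmax at lead; associated coding |
| Weak | nearest gene; ABCmax at associated; ABC any-link at lead |
| Very weak | MR eQTL q < 0.05; ABC any-link at associated |

Per locus: if the nearest gene is in the top-tier set it alone is
prioritized; otherwise all top-tier genes are. If nothing fires, the nearest
gene is the fallback so the output stays total.

### Translation

Gold-standard benchmarking restricts to genome-wide significant loci
(p < 5e-8) and, per indication, to loci containing a gold-standard gene;
Fisher exact (two-sided) with precision/recall/F1 per selector. Three
contingency cubes (disease × gene × dataset; GWAS × gene × category;
category × gene × dataset) are tested focal-cell-vs-margins: a = focal sum,
b = row − a, c = column − a, d = remainder, BH across tested pairs. Disease
ontology is a single-rooted is-a DAG; IC(t) = −log(cumulative usage of t's
descendants / total); similarity = mean of max-IC-scaled Resnik and Lin,
standardized per row so each disease's best match scores 1; target-indication
pairs link at standardized similarity ≥ 0.7 (cancer indications excluded),
keeping the supporting GWAS with the smallest lead p. Clinical-phase risk
ratios use the per-pair maximum phase: RR = P(phase ≥ X | supported) /
P(phase ≥ X | unsupported). MoA directionality: a low-frequency (MAF < 5%,
strict) lead coding variant is treated as disruptive, so a risk-increasing
minor allele predicts activation as beneficial; the MR consensus rule
requires q < 0.05, PP(H4) > 0.8 and the same effect sign in strictly more
than 75% of qualifying datasets (negative = more expression, less risk →
activation). Predictions are compared with actual drug mechanisms
(antagonist/inhibitor/degrader vs agonist/activator; other keywords
excluded) for drugs at phase ≥ 2.

## 2. Synthetic-data generators

### Haplotypes and LD

Within a block of size *B*, haplotype alleles follow a two-state Markov
chain: the first variant is Bernoulli(f); each subsequent allele copies its
predecessor with probability ρ, else is redrawn Bernoulli(f). Blocks are
independent. This yields *exactly* corr(Xᵢ, Xⱼ) = ρ^|i−j| within a block for
binary alleles — a deliberate deviation from the more common
Gaussian-threshold construction, whose post-dichotomization correlation only
approximates the target and would have made the LD panel disagree with the
realized genotype correlation that clumping and colocalization see.
Limitation: per-block allele frequency is shared, and long-range LD,
recombination hotspots and population structure are absent.

### Association statistics

Quantitative traits: y = Σ g·β + N(0,1); per-variant OLS slope/SE/t-test.
Binary traits: liability score passed through a logistic link whose intercept
is solved (Brent) to hit the target case fraction; per-variant logistic
*score* test with one-step effect estimate U/V and SE 1/√V. The score test
is exact under the null (type-I error verified at 0.05 ± 0.02) and its
one-step beta is consistent near the null; it slightly attenuates large
effects relative to full MLE — acceptable because planted effects are read
out through ratios and significance, not absolute calibration of large
betas. Monomorphic variants get an SE = ∞ sentinel and are dropped by the
ingestion QC.

### Evidence planting

`simulate_study` plants per-locus evidence plans: consequence rows, ABC
intervals (top-scoring gene plus a low-score decoy) and gene models. Three
design points matter:

* Gene models place the *second* listed gene (a decoy) nearest to the lead
  by default, so causal-gene recovery cannot ride on proximity.
* Lead-variant evidence is planted at the **realized** lead (argmin p), not
  the true causal variant: a strong LD proxy can out-score the causal
  variant by sampling noise, and "the lead variant is pathogenic" is a
  statement about the realized lead.
* Associated-variant evidence is planted on a variant that actually
  satisfies the eligibility rule in the realized data. This is a physical
  constraint: under AR(1) LD the exponent gap between the lead and its best
  proxy grows with lead strength (≈ (1−ρ²)·exponent), so the 5-order
  magnitude window closes for very strong leads — scenarios that plant
  associated evidence must use moderate effect sizes (the shipped scenarios
  use β = 0.35 at ρ = 0.95).

### Drug / ontology tables

The toy ontology is a balanced is-a tree plus one cross edge (a genuine DAG)
with diseases mapped to leaves. Drugs draw a target and indication uniformly;
genetically supported pairs advance past phase 1 at `advance_rr` times the
base rate with shared conditional rates thereafter, so the cumulative risk
ratio is constant by construction. MoA keywords are drawn concordant with a
planted direction map at a configurable rate.

## 3. Numerical choices

* **Colocalization in log space.** Raw ABFs overflow doubles once |z| ≳ 38;
  all hypothesis weights are accumulated with log-sum-exp. The H3 term is
  the *exact* off-diagonal m×m grid (diagonal set to −∞) rather than the
  common subtraction identity L1·L2 − L4, which loses all precision when the
  shared-variant term dominates; the grid is O(m²) but loci are ≤ a few
  hundred variants. With one shared variant H3 is an empty sum and PP(H3) is
  exactly 0.
* **BH FDR** delegates to `statsmodels.stats.multitest` and is
  order-preserving with the input; validated against the sort-based step-up
  definition.
* **Fisher exact** delegates to `scipy.stats.fisher_exact`; the reported
  odds ratio is the sample cross-product ratio with a Haldane–Anscombe 0.5
  correction applied only when a zero cell occurs, and a zero margin returns
  (NaN, p = 1) rather than raising.
* **Determinism.** Every generator takes an integer seed; study-level
  generation derives child seeds from one root `numpy` Generator, so any
  scenario is bit-reproducible from a single seed.

## 4. Open design decisions

* The multi-dataset colocalization criterion reads "more than 2 datasets"
  literally (n_coloc > 2, i.e. ≥ 3); `coloc_multi` is a parameter for sites
  that prefer ≥ 2.
* MR uses only Wald/IVW; pleiotropy-robust estimators (Egger, weighted
  median) are out of scope because the generator plants no pleiotropy.
  The FDR gate before colocalization mirrors common practice but means
  coloc-only evidence (without MR significance) is never observed.
* The Wald SE ignores exposure-side uncertainty (first-order delta method);
  with the p < 1e-4 instrument gate the relative bias is < 5% in the
  shipped scenarios.
* Associated-variant eligibility uses the inclusive boundary
  p ≤ p_lead·10⁵; the alternative strict reading changes only exact-boundary
  fixtures.
* Gene-locus distance is measured to the gene footprint (0 inside the
  gene), not the TSS; TSS-based distance would change nearest-gene calls for
  long genes.
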