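# Methods

`vmrgem` implements an integrated analysis of how genotype (G), prenatal
environment (E), their additive combination (G+E) and their interaction
(G×E) explain inter-individual variation in neonatal DNA methylation at
variably methylated regions (VMRs). This note describes the statistical
model, the conventions the implementation pins down, the synthetic-data
generator that stands in for access-restricted cohort data, and the known
limitations of both.

## VMR detection

Per-CpG variability is the unscaled median absolute deviation of the beta
values, `MAD = median(|x_i − median(x)|)`, with missing values excluded and
no consistency constant — it is a raw variability score, not a robust SD
estimate. Candidate CpGs are those whose MAD *strictly* exceeds the
empirical 90th percentile computed with the type-7 (linear-interpolation)
quantile convention, the default in R. The strictness and the convention
matter: on a panel of 428,619 distinct scores, strict type-7 selection keeps
exactly 42,862 CpGs, which is the pinned behaviour in the acceptance suite
and pins down both conventions simultaneously.

Candidates are sorted by (chromosome, position) and chained into regions
while consecutive candidates are at most 1 kb apart (boundary inclusive);
chains with fewer than two probes are discarded. "Contiguous" is interpreted
over candidate CpGs only — intervening non-candidate array probes do not
break a chain. The alternative reading (any intervening probe breaks the
chain) is available via `cluster_vmrs(..., break_on_noncandidate=True)`.
Each region is represented downstream by its tagCpG, the member with the
largest MAD (ties broken toward the smaller position), and we record the
Pearson correlation between the tag and the per-sample mean beta over all
members as a coherence diagnostic.

## The four-family competition

For each tagCpG the four linear models are fitted on beta values over the
cis window (same chromosome, ±1 Mb around the tag, boundary inclusive;
optionally restricted to SNPs pre-flagged as functional by a sequence-based
regulatory predictor):

    E    : beta ~ covariates + environment              (one fit per E)
    G    : beta ~ covariates + SNP                      (one fit per cis SNP)
    G+E  : beta ~ covariates + SNP + E                  (one fit per pair)
    G×E  : beta ~ covariates + SNP + E + SNP×E          (one fit per pair)

Covariates are always the child's sex, gestational age, the estimated cell
proportions and the leading ancestry components (default 2, configurable
2–5). The seven cell proportions sum to one, so the design includes only six
of them — the seventh acts as the reference cell type; including all seven
with an intercept would be rank-deficient. Genotypes are coded 0/1/2 minor-
allele counts, with the minor allele recomputed from the loaded cohort
rather than trusted from VCF REF/ALT. Continuous environments enter as
provided; binary ones as 0/1.

AIC is the `lm`-style Gaussian form: `lnL = −n/2·(ln 2π + ln(RSS/n) + 1)`
and `AIC = 2k − 2·lnL` with `k` = number of coefficients + 1 for the error
variance. Within each family the fit with minimal AIC is the family best;
the across-family winner has minimal AIC overall, with exact ties broken
toward the simpler family (E < G < G+E < G×E), then lexicographically by SNP
and environment id. A `select_by="p"` option picks within-family bests by
smallest raw p-value instead. Each family's coefficient of interest — the E
slope, the SNP slope (also in G+E, where it is the adjusted quantity), or
the interaction term — carries a two-sided t-test p-value, Bonferroni-
adjusted by the number of candidates actually fitted in that family, and
winners' adjusted p-values are then Benjamini–Hochberg corrected across
tagCpGs. Tags with no cis SNP are flagged and excluded from winner
statistics. Rows with missing values are dropped per fit; SNPs monomorphic
in the analysis subsample are skipped as candidates.

### What the competition can and cannot calibrate to

Under the global null with one candidate SNP and one environment, the G×E
family wins when its AIC beats *all three* other families. The familiar
shorthand `P(χ²₂ > 4) ≈ 13.5%` describes only the pairwise G-vs-G×E
comparison; the four-way winner must also beat E (another χ²₂-type margin)
and G+E (a χ²₁-type margin), which brings the null G×E win rate down to
roughly 6–8%, and correspondingly caps the win rate of a planted pure-G
effect near 76–79% (the G model must survive spurious AIC improvements from
the env and interaction terms). The calibration tests measure and report
these rates; the asymptotic four-way winner distribution under the null is
approximately (E, G, G+E, G×E) ≈ (0.46, 0.46, 0.02, 0.06). The winner's-
curse behaviour — the null G×E win rate grows with the number of candidate
(SNP, environment) pairs — is checked at 1/5/25 candidates.

## Genotype QC and linkage disequilibrium

QC removes SNPs with call rate < 98%, minor-allele frequency < 1%, or an
exact-test Hardy–Weinberg p ≤ 1e-6 (all thresholds are parameters; real
cohorts differ). HWE uses the exact conditional enumeration of heterozygote
counts given allele counts, computed stably through a log-space recurrence —
the exact test, not the chi-square approximation, because exactness matters
at low genotype counts.

LD r² is the squared Pearson correlation of dosage vectors on pairwise-
complete samples; it is symmetric and invariant to 0↔2 allele flips.
Pruning is the greedy sliding-window variant: within each window of 50
consecutive surviving SNPs the later member of any pair with r² > 0.2 is
removed, the window advances by 5, and passes repeat to a fixed point so the
post-condition (no surviving within-window pair above the threshold) holds
exhaustively — the named parameters, not a bit-exact clone of any particular
tool. LD proxies of an index SNP are all same-chromosome SNPs within 1 Mb at
r² ≥ 0.8, always including the index SNP itself.

## Enrichment

All enrichment tests are two-sided Fisher exact tests on 2×2 tables using
the probability-mass rule (sum of hypergeometric probabilities no larger
than the observed table's), reported at a nominal 0.05 level without
cross-test correction (a BH option exists). The sample odds ratio
(a·d)/(b·c) is primary, +∞ when the denominator is empty with a non-empty
numerator; the conditional-MLE odds ratio is reported alongside. A zero
margin yields p = 1 and no direction.

CpG-island context is assigned from an island interval track: Island inside
an interval, Shore within 2 kb of the nearest island edge, Shelf within
4 kb, OpenSea beyond (boundaries inclusive; N = lower-coordinate side).
Intervals arrive as BED (0-based half-open) and are converted to the
package's 1-based inclusive convention on read. Winner-family enrichment
compares each family's tagCpGs against tags won by the other families; SNP-
set enrichment uses explicit backgrounds (e.g. non-functional SNPs). GWAS
enrichment expands each SNP set with its LD proxies, scores a member as a
hit when it or any proxy position-matches a GWAS variant with p below the
nominal threshold (matching by chromosome and position only), and excludes
members with neither proxies nor a position match from both margins.

## Replication meta-analysis

Matched tagCpG–SNP–environment combinations from a discovery and a
replication cohort are pooled with the DerSimonian–Laird random-effects
estimator: fixed weights `w = 1/se²`, `Q = Σw(β−β_fixed)²`,
`τ² = max(0, (Q−(k−1))/(Σw−Σw²/Σw))`, random weights `w* = 1/(se²+τ²)`, and
a two-sided normal p for the pooled estimate. τ² is truncated at zero, so
pooling reduces to the fixed-effect estimate whenever Q ≤ k−1. A combination
*replicates* when the effect has the same direction in both cohorts, the
meta-analysis p is smaller than the discovery-cohort p, and the BH-adjusted
meta-analysis p (across all combinations entering the meta-analysis — the
FDR universe is a parameter) is below 0.05. The coefficient meta-analysed is
the family's coefficient of interest (interaction term for G×E, SNP slope
for G+E). Cross-cohort consistency restricts to tags with a winner in every
cohort and reports the modal winner and agreement level per tag, with modal
ties broken toward the simpler family and flagged.

## The synthetic-data generator

Real cohorts of this kind are access-restricted, so the generator emulates
the processed inputs directly; its defaults define the conditions every
calibration in the test suite runs under.

* **Genotypes** are drawn in LD blocks (default 10 SNPs): each block has an
  anchor haplotype pair drawn per sample from Hardy–Weinberg at a block MAF
  (uniform on 0.05–0.5), and each SNP copies the anchor alleles with a 2%
  per-allele mutation rate — preserving HWE per SNP while inducing
  within-block genotype r² around 0.8. About 30% of SNPs carry a functional
  flag with a plausible e-value.
* **Methylation**: background CpGs sit at a per-CpG mean (uniform 0.15–0.85)
  with 0.01 SD idiosyncratic noise. Planted VMR members share a per-region
  latent factor (SD 0.05) with member loadings uniform on 0.7–1.3 plus 0.02
  SD member noise, giving them MADs an order of magnitude above background
  (reliably in the top decile) and within-region correlations around 0.85.
  Every CpG receives small centred covariate effects (sex, gestational age,
  cell proportions, ancestry) so that covariate adjustment is non-trivial.
* **Environments**: ten exposures in three categories
  (stress/glucocorticoid, general maternal, metabolic), mixing standardised
  Gaussian continuous variables and binary variables at perinatal-cohort
  prevalences (0.04–0.45), with mild within-category correlation (latent
  factor, ρ = 0.2).
* **Covariates**: sex ~ Bernoulli(0.5), gestational age ~ N(39.5, 1.5²)
  weeks, seven cell proportions from a granulocyte-dominated Dirichlet
  (summing to one exactly), Gaussian ancestry components.
* **Effects** are planted per `EffectSpec` as mean-centred additive terms on
  the beta scale (the models are fitted on beta values, so planted
  coefficients are the estimands exactly). Default planted effect sizes
  (β_g = 0.04 per allele, β_gxe = 0.05, member noise 0.03) are chosen for
  test power, not taken from any empirical effect-size distribution — none
  is available. Betas are clipped to [0.01, 0.99]; the clipped fraction is
  recorded and stays well below 1% at defaults.

Reproducibility: one seed drives independent per-matrix substreams
(genotypes, covariates, environments, methylation, annotation), so identical
spec + seed reproduces every matrix exactly and growing the CpG panel does
not perturb the genotypes.

What the generator does **not** emulate: probe-type bias and detection
p-values, batch effects, bimodal genome-wide beta distributions, population
stratification beyond Gaussian components, realistic LD decay with distance,
or correlated missingness. Passing calibrations therefore demonstrate that
the machinery is correct and well-calibrated under the stated statistical
model, not that effect estimates on real arrays would be unbiased under
array artefacts.

## Problem sizes and numerical choices

Calibration suites use cohorts of 100–500 samples, 3–5,000 CpGs and 1–50
SNPs with 100–2,000 Monte-Carlo seeds per scenario, sized to give binomial
standard errors comfortably inside the asserted bands. Rank deficiency is
detected through pivoted QR with an eps-scaled tolerance and reported with
the offending column's name; perfect fits (RSS numerically zero) raise
rather than return −∞ AIC. Exact AIC ties break toward the simpler family;
candidate enumeration order does not affect verdicts. Degenerate binary
environment draws (all one level at small n) are nudged to two levels to
keep the table valid; samples missing any variable of a given fit are
dropped from that fit only.
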