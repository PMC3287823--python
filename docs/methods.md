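# Methods

## The problem and the approach

Single rare variants (MAF ≲ 0.05, often ≪ 0.01) cannot be tested for
case/control association one at a time: carrier counts are tiny and the
usual contingency-table or regression machinery is invalid or powerless.
Collapsing methods aggregate rare variants over a functional unit (a gene,
a window) into one analyzable predictor. The approach implemented here has
two distinguishing features: variants are combined **only when they show a
joint effect on the phenotype** (selection by an L1-penalized model, not
unconditional pooling), and variants that do not sit in a gene — or sit in
genes too small for within-gene collapsing to help — are grouped **by
chromosomal position** so nothing is discarded.

## Pipeline stages and their parameters

### QC (`raremark.preprocess`)

* `maf_max = 0.05`: variants with MAF *strictly above* 0.05 are excluded
  (a variant at exactly 0.05 is retained — thresholds are read as strict
  inequalities throughout).
* `hwe_alpha = 1e-4`: variants with an exact Hardy-Weinberg p *strictly
  below* 1e-4 are excluded. The test is the exact conditional test
  (conditioning on the subject total and minor-allele count, the p-value
  sums the probabilities of all heterozygote counts no more probable than
  the observed one). An exact test is used because rare variants put most
  genotype classes at single-digit expected counts, where the chi-square
  approximation fails. It is computed on the pooled sample: genotypes are
  fixed across phenotype replicates, so QC is replicate-independent.
  Whether HWE should instead be assessed within population strata is a
  defensible alternative; pooled is the documented choice here.
* Missing genotypes are excluded from MAF/HWE denominators but treated as
  non-carriers when coding dummies (a conservative choice that can only
  dilute a signal); variants with > 5% missingness are flagged in the log.

### Grouping (`raremark.grouping`)

* `min_gene_size = 5`: a gene needs at least 5 surviving variants to form
  its own group. Below that, within-gene collapsing cannot raise the
  aggregate carrier frequency enough to matter.
* `bin_size = 20`: leftover variants (small genes + intergenic), sorted by
  position within a chromosome, are chunked into bins of 20 variants; a
  trailing bin smaller than half of `bin_size` is merged into its left
  neighbor. Bins are sized by variant count rather than base pairs so every
  group offers the selection stage a comparable number of candidates
  regardless of local variant density. Both knobs are exposed in the
  config; no principled universal value exists, only the trade-off between
  group resolution and aggregate carrier frequency.

### Marker construction (`raremark.markers`, solver in `raremark.lasso`)

Carrier (dominant) coding is forced by the construct being modeled —
presence or absence of a rare allele; genotype dosage would treat the
near-nonexistent rare homozygotes as twice the evidence.

Per group the solver maximizes `ℓ(β) − λ‖β_D‖₁` over a path of 100
log-spaced penalties from `λ_max` (the largest absolute dummy score at the
covariates-only fit — the smallest penalty at which the penalized block is
entirely zero) down to `0.001·λ_max`. The intercept and the covariates
(population one-hot with the largest group as reference, age, sex,
smoking) are never penalized. Numerical choices:

* Proximal Newton with cyclic coordinate descent on the weighted
  least-squares surrogate, warm starts along the path, and an active-set
  inner loop.
* Internally the covariate block is centered and scaled (the optimum is
  invariant to affine maps of an unpenalized block; conditioning improves
  by orders of magnitude with an unscaled age column). Dummies are *not*
  standardized: they are already comparable 0/1 variables and raw weights
  read as per-carrier log-odds contributions.
* Every path point is certified against the exact-problem KKT conditions
  at tolerance 1e-6 on the mean-gradient (per-observation) scale; a point
  failing certification is flagged, never silently accepted.
* Quasi-separation at small penalties is handled by capping |coefficient|
  at 30 (log-odds far beyond any biological plausibility) with a warning.
* AIC = 2k − 2ℓ selects the path point, with k counting all nonzero
  coefficients including the unpenalized ones (a constant offset that
  cannot change the argmin, counted for reproducibility); exact ties go to
  the larger penalty, i.e. the sparser model.

A group's marker is the fitted combination v_j = Σ β̂_k d_jk over the
selected dummies, kept only if nonzero in ≥ `prevalence_min = 0.05` of
subjects. `value_mode="union"` substitutes the 0/1 union of selected
carriers — useful to check robustness of downstream trees to the weighting,
since "a linear combination of selected dummies" admits either reading.

### Tree ensemble (`raremark.trees`)

One CART tree per phenotype replicate (Gini impurity), excluding the
replicate used for construction — reusing it would let the markers grade
their own homework. Growth gates mirror rpart's defaults: a node needs 20
subjects to split, leaves keep ≥ 7, depth ≤ 30, and a split must improve
population-weighted Gini by ≥ `complexity_penalty = 0.01` times the root
impurity. The gate is applied at growth time (pre-pruning) rather than by
cost-complexity post-pruning: simpler, deterministic, and it makes the
per-split improvement invariant checkable structurally; it can retain a
split that post-pruning would remove when a strong subtree hangs below a
marginal one. Fitting is delegated to scikit-learn's
`DecisionTreeClassifier`; ties between equal-gain splits are resolved by
its seeded internal ordering, so trees are reproducible given inputs and
seed (the package pins per-replicate seeds derived from one stage seed).

Two usage-counting conventions coexist because "how often a marker is
used" is ambiguous when a tree can split on the same (continuous-valued)
marker at several thresholds: `counts` tallies a marker once per tree
(default, and what significance consumes); `split_counts` tallies every
split. S is always the raw total number of splits, covariate splits
included; covariate splits are never attributed to markers. In the
many-marker regime the conventions nearly coincide (repeat use within one
tree is rare); with few markers they diverge, and the distinct convention
is the conservative one.

### Significance (`raremark.significance`)

Under the null (phenotype ⊥ markers | covariates) and exchangeable
markers, each of M markers is equally likely at any split, so a marker's
count across S splits is modeled Bin(S, 1/M), treating split choices as
independent. With Bonferroni level α/M the critical count is the smallest
integer q with CDF(q) ≥ 1 − α/M; a count **meeting or exceeding** q is
significant. The quantile convention is load-bearing: the stricter
"smallest k with upper tail ≤ α/M" rule sits one unit higher at
representative sizes (S ≈ 2263, M = 493: 14 vs 15). When S = 0 the
threshold is floored at one occurrence so an empty ensemble flags nothing.

Caveats, verified empirically in the test suite:

* The equal-selection null is exactly right only for markers with
  identical value distributions. Realized composite markers differ in
  prevalence and in how many distinct values they take, which makes some
  systematically more attractive to trees; per-marker counts are then
  over-dispersed relative to Bin(S, 1/M). Bonferroni slack absorbs much of
  this — family-wise error on heterogeneous null markers measures ≈ 0.05
  at the scales tested — but the null is known-fragile, which is why the
  permutation route exists.
* The permutation test (`permutation_null`) shuffles affection status
  (preserving case/control totals exactly), refits the tree per
  permutation, and uses the max-per-marker split count as the
  FWER-controlling reference. On a single tree this is weak: a binary
  marker can be used at most about once per tree, and at small n noise
  splits clear the complexity gate often enough to drown modest signals.
  It becomes informative for strong, multi-split (continuous) markers or
  larger cohorts.

### Orchestration (`raremark.pipeline`, `raremark.cli`)

One global seed fans out to stage seeds via `numpy.random.SeedSequence`,
so any stage can be rerun in isolation bit-identically; the effective
config is written alongside the artifacts and reproduces the run. The
construction replicate defaults to the first.

## The synthetic-data generator (`raremark.simulate`)

Defaults mirror the scale of the motivating cohort: 697 unrelated
subjects in 17 population groups, 24,487 variants, 200 phenotype
replicates, and a MAF spectrum drawn from four strata (< 0.001,
0.001–0.01, 0.01–0.05, > 0.05) with weights 0.385/0.355/0.132/0.128 — the
cumulative fractions 38.5% < 0.001, 74.0% < 0.01, 87.2% < 0.05. MAFs are
log-uniform within a stratum; genotypes are Binomial(2, MAF); genes are
contiguous positional blocks (about 20% of variants relabeled intergenic
to exercise positional grouping); phenotype replicates are iid Bernoulli
draws on fixed genotypes from a logistic model

    logit P(case) = β₀ + a_pop + β_age(age − 50) + β_sex·sex + β_smk·smk
                    + Σ_g β_g · carrier_g

with defaults β₀ = −1.2, β_age = 0.02 per year, β_sex = β_smk = 0.4, and
per-population intercepts drawn N(0, 0.3) — values chosen once to give a
case fraction near 30% and covariate effects of realistic magnitude. The
liability scale is logistic deliberately, matching the selection stage.
`causal_maf_range` lets a causal gene's variants be re-drawn in a chosen
MAF band so the aggregate carrier prevalence is controlled.

What the generator does **not** emulate: linkage disequilibrium (variants
are independent), realistic population-specific allele-frequency
divergence (populations shift baseline risk only), gene-length
distributions, genotyping error, and relatedness. Consequently, passing
tests demonstrate the machinery's statistical behavior under its own
assumptions — calibration of the exact tests, FWER control on exchangeable
nulls, recovery of planted carrier-mediated effects — not performance on
LD-structured real genomes, where grouping by position interacts with
correlation among variants in unmodeled ways.

`simulate_null_markers` draws iid composite-marker-shaped columns (a few
Bernoulli carrier dummies with random weights) for null calibration
studies where the number of markers must be fixed and exchangeability
exact by construction — per-group selection on a null cohort would give a
random M and non-exchangeable markers.

## Problem sizes used in the bundled checks

The calibration and recovery studies run at reduced scale chosen for
desk-scale reproducibility: family-wise error uses 200 Monte-Carlo runs of
400 subjects × 50 markers × 50 replicates; parameter recovery uses 50
cohorts of 600 subjects × 800 variants (60 genes) × 50 replicates with one
causal gene at 1.0 log-odds per carrier. Oracle equivalences (exact HWE
enumeration, exhaustive binomial CDF, exhaustive Gini search) run at the
sizes where exhaustive computation is feasible.

## Degenerate inputs and edge rules

* All-missing variant → error naming the variant (MAF undefined).
* Monomorphic variant → MAF 0, HWE p = 1 (kept; its dummy is constant and
  unselectable).
* Group whose dummies are all constant → skipped with a log entry.
* Phenotype replicate without both classes → rejected at load; the
  generator redraws such columns.
* Empty post-QC variant set → warning, empty downstream artifacts.
* Marker-set files are versioned; an unknown version is a hard error.

## Known limitations

* AIC on the LASSO path uses the nonzero-coefficient count as k, the
  common pragmatic choice; it is not an unbiased degrees-of-freedom
  estimate for logistic models.
* The pre-pruning gate only approximates rpart's cost-complexity pruning.
* The binomial null's independence-across-splits assumption ignores both
  within-tree exclusivity and across-tree dependence from fixed marker
  values (see the over-dispersion caveat above).
* Positional bins by variant count can straddle recombination structure;
  a base-pair-window mode would be a natural extension.
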