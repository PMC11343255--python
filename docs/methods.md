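# Methods

`phenomix` implements a person-centered decomposition of phenotypic
heterogeneity: a mixed-data-type finite mixture model over questionnaire-style
phenotype features, diagnostics for choosing the number of latent classes,
category-level "affinity" profiles of the classes, cross-cohort replication
with a permutation test, and class-stratified genetic analyses (rare-variant
burden, odds ratios, developmental-expression enrichment, polygenic-score
contrasts). Because the motivating cohorts sit behind controlled access, the
package ships a first-class synthetic-cohort generator with known ground
truth; every statistical claim made by the test suite is a claim about
behaviour on such generated data.

## The mixture model

Each individual i belongs to one of K latent classes. Conditional on the
class, features are independent with a family per feature type:

* continuous features x ~ N(mu_fk, sigma²_fk),
* binary items x ~ Bernoulli(p_fk),
* categorical items x ~ Multinomial(theta_fk), levels coded 0..L-1.

The class prior depends on covariates c_i = (1, sex_i, age_i) through a
multinomial logit, pi_k(c_i) = softmax_k(beta_k·c_i) with beta_0 = 0 for
identifiability; this is the "1-step with covariates" configuration:
covariates shape class membership but never enter the feature densities. Age
is used in years as-is and sex as 0/1 — the intercept absorbs scale, so
covariate standardization is unnecessary.

Fitting is EM with multi-start. Each chain starts from random soft
assignments (Dirichlet(1,...,1) rows), the least-assumption initialization
given that only "multiple random restarts" is inherent to the procedure. The
E-step works entirely in log space (log-sum-exp), so per-row densities down
to exp(-700) do not underflow. The M-step uses closed-form weighted MLEs for
all feature parameters and a damped Newton solver (analytic gradient and
Hessian, warm-started from the current coefficients, gradient tolerance
1e-8) for the prior coefficients; the warm start is retained whenever the
solver fails to improve it, so the EM objective is non-decreasing by
construction (asserted at 1e-8 everywhere in the tests).

Numerical guards: Gaussian variances are floored at 1e-4 (prevents singular
components on duplicated points), categorical level probabilities receive a
1e-10 pseudo-mass (prevents -inf at predict time on unseen levels),
Bernoulli probabilities are clipped away from {0,1} only inside log terms. A
class whose responsibility mass falls below 1e-6·n aborts the chain
(degenerate-class error); a fit fails only if every chain degenerates.
Defaults: `tol = 1e-6` on the log-likelihood, `max_iter = 500`, `n_init = 20`
at demo scale (the study-scale setting is 200 restarts; 20 is the package's
desk-scale default and is already past the point where the best-of-restarts
likelihood stops improving on the generator cohorts used here).

Assignment is max posterior probability, with exact ties broken toward the
lower class index so prediction is deterministic. Parameter counting for
information criteria: 3(K-1) prior coefficients plus per class 2 per
continuous feature, 1 per binary, L-1 per categorical.

## Choosing K

`enumerate_models` tabulates, per candidate K and repetition: log-likelihood,
AIC = -2LL + 2p, BIC = -2LL + p·ln n, CAIC = BIC + p, SABIC with the
ln((n+2)/24) penalty, optional 3-fold cross-validated held-out log-likelihood
(simple random folds, summed over held-out individuals), relative entropy
1 - Σ(-γ ln γ)/(n ln K), per-class average posterior probability, and the
smallest class size. The likelihood-ratio test between consecutive K is the
plain chi-square on 2·ΔLL with df = Δp, and every output row carries
`lrt_kind = "naive"`: this reference distribution is known to be wrong for
mixture-order testing (the boundary/non-identifiability problem that the
Lo-Mendell-Rubin adjustment addresses). Our null simulations measure the
naive statistic at roughly twice its nominal df, i.e. the test over-rejects
badly, and the package therefore exposes it for descriptive elbow-reading
only. Final choice of K is deliberately a user decision informed by the
table; nothing auto-selects.

## Affinity profiles

After assignment, each feature is tested in each class against the pooled
remaining classes: exact one-sided binomial tails (both directions) for
binary items, with the pooled-other success rate as the null proportion; and
one-sided independent t-tests (pooled variance by default, Welch by flag)
for continuous and categorical items, the latter scored by level index.
Benjamini-Hochberg correction is applied within each (class, direction)
family across features, and "significant" means q < 0.05 throughout. Features
are excluded if (1) never significant in any class/direction, (2) numeric
with |Cohen's d| < 0.2 everywhere, or (3) binary with fold enrichment < 1.5
everywhere. Each (class, category) cell of the affinity matrix is then
(#contributory features enriched - #depleted) / #contributory in the
category — a signed proportion in [-1, 1]; categories with no contributory
feature are NaN.

A note on the binomial construction: treating the pooled-other (or sibling)
rate as a *fixed* null proportion conditions away its sampling noise, which
makes the test mildly anti-conservative when the comparison group is not
much larger than the class (measured ~0.076 at alpha 0.05 with a background
three times the class size). The null-calibration tests therefore use large
backgrounds; on real data a user should read borderline q-values near the
threshold with this in mind.

## Replication

`transfer_model` refits on the discovery cohort restricted to the features
shared with an independent cohort, predicts labels there, and recomputes the
contributory-feature exclusion on the training data only. Similarity between
the two affinity matrices is summarized by a Pearson r per category (across
the K class values) and one overall r on the flattened K×7 matrix — the only
construction that yields a single permutable scalar. Significance comes from
shuffling the test cohort's label vector (class sizes preserved) n_perm
times, recomputing the test affinity with the contributory set frozen, and
reporting p = (1 + #{r_perm >= r_obs}) / (1 + n_perm); zero exceedances at
n_perm = 10,000 are reported as p < 1e-4.

Two deliberate conventions: (a) a permuted affinity matrix with no
significant cell (the typical outcome of a random labeling) has undefined
correlation; its similarity is defined as 0 so the exceedance count is
always over the full n_perm. (b) Because the affinity statistic is
thresholded, it is massively tied at 0 under a global null, and with the
deterministic >= convention the permutation p is valid at every level
(P(p<=a) <= a, verified by simulation) but *sub-uniform* — expect
conservative, not exactly uniform, null p-values. Exact uniformity would
require randomized tie-breaking, which we do not do because the reported p
would no longer be reproducible from the exceedance count.

## Genetics

Variants are consumed pre-annotated. Classification: a variant is LoF_HC if
its consequence is one of {stop_gained, frameshift_variant,
splice_acceptor_variant, splice_donor_variant, start_lost, stop_lost,
transcript_ablation} *and* carries an HC confidence flag; missense_damaging
if in {missense_variant, inframe_deletion, inframe_insertion,
protein_altering_variant} *and* flagged likely_pathogenic; synonymous_variant
maps to synonymous; everything else (including unknown strings, warned once
each) is other.

De novo QC: individuals above mean + 3 SD of total call count (computed once
on the full roster, zero-callers included, not iterated) are dropped;
variants whose identity key — (gene, chrom, pos, ref, alt) when positional
fields exist, else (gene, variant id) — appears in more than one family are
removed from every family; individuals with no surviving calls appear in all
count vectors with explicit zeros. Rare inherited variants are those with
allele frequency < 1%; records with missing frequency are kept and flagged
`rare_by_absence` (absence from the population reference implies rarity),
with the flagged count logged.

Burden tests compare per-individual counts (gene-set-restricted, zeros
included) of each proband class against siblings with a one-sided
(class-exceeds-siblings) t-test, pooled variance by default; fold enrichment
is the ratio of means; BH is applied across classes within each (gene set,
variant class) family. Odds ratios use carrier status, a one-sided Fisher
exact test, and the Haldane-Anscombe +0.5 correction on the odds ratio (not
the p-value) when any cell is zero. Constraint bins: pLI >= 0.995 high,
0.5 <= pLI < 0.995 intermediate. The devDEG scan repeats the burden test for
each (expression trend x cell type) gene set, for every class and for the
pooled probands, with BH per gene set. Mood's median test on the pLI of
impacted genes builds the 2x2 above/at-or-below-grand-median table (ties to
the <= cell) and reports the chi-square statistic with a one-sided Fisher p
in a pre-declared direction. Term enrichment is the upper-tail
hypergeometric against a fixed gene background with FE = (k/n)/(K_t/N) and
BH across terms. Polygenic scores are residualized on (intercept, sex,
ancestry PCs) by least squares over all individuals, centered on the sibling
mean and scaled by the sibling SD (center-only by flag), and compared class
versus siblings two-sided — depletions are as meaningful as enrichments
here — with BH across (class, trait).

## The synthetic generator

`spark_like_spec()` emulates the discovery cohort's structure at desk scale:
four latent classes with mixing proportions matching the reported class
sizes (1976/554/1860/1002 of 5392 ≈ 0.366/0.103/0.345/0.186), covariates
age ~ N(8.56, 3.15) years and 77.4% male, and a default 60-feature schema
mixing milestone-age-like continuous features (months scale, mean 14, SD 5),
binary questionnaire items (base rate 0.45), 0-3 categorical items, and
t-score-like continuous features (mean 55, SD 10). Class effects are
assigned per phenotype category from a fixed 4x7 pattern emulating the
study's class structure — one class below other probands everywhere, one
above everywhere, one elevated on social/behavioural categories without
developmental delay, one combining developmental delay and repetitive
behaviour — and scaled globally by `separation`, expressed in SD units
(logit units for binary, level-tilt units for categorical). Separation 0
makes every class identical, which is how all type-I-error suites are built.
Siblings draw from a reference distribution shifted -1.5 SD on the
questionnaire/milestone subset and are missing all other features, mirroring
the limited sibling battery. Missingness is completely at random only; the
completeness filter (drop features < 90% complete, then incomplete
individuals) is the pipeline's answer to it. Milestone truncation at 0
months exists as an off-by-default misspecification toggle.

The genetic generator plants Poisson counts per (variant type, gene set,
group): defaults approximate the reported cohort magnitudes (~2.71 de novo
calls per proband and 2.47 per sibling before QC; 4.5% zero-callers), with
class-specific de novo LoF elevations in a risk gene set and an inherited
LoF elevation in the developmental-delay-like class. Rates are free
parameters where only cohort means are known. Inherited allele frequencies
are log-uniform on [1e-5, 0.5] so the rarity filter has work to do. PGS
tables are class shift + 0.2·sex + PC effects + unit noise, siblings always
at zero shift.

What the generator does *not* emulate: item-level correlation beyond what
the latent class induces (real questionnaires have residual factor
structure), informative missingness, linkage structure among variants,
realistic gene lengths or per-gene mutability, and ancestry stratification
beyond independent Gaussian PCs. Passing tests therefore demonstrate
correctness of the machinery and recoverability under the model's own
assumptions, not robustness to their violation.

## Problem sizes and determinism

The test suite and acceptance script run at desk scale as the package's own
defaults: recovery cohorts of n = 2000 probands with 60 features, a
replication cohort of n = 861, 20 restarts for headline fits and 3-8 for
scans, 10,000 permutations for the headline replication p and 200 for
calibration sweeps, and 500-1000 replicates for type-I calibrations. All
randomness flows from a single integer seed through stage-derived
substreams; rerunning any pipeline stage with the same config and seed
reproduces numeric outputs byte-for-byte (the manifest records config,
seeds, input checksums and row counts).

## Known limitations

* No missing-data EM: the model requires complete cases, as the pipeline's
  completeness filter produces.
* The naive LRT is descriptive only (see above); no bootstrap LRT.
* Affinity permutation p-values are conservative under weak signal (see
  above).
* The binomial enrichment test conditions on the background rate.
* Covariates enter only the class prior; feature distributions are not
  covariate-adjusted.
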