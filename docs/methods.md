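# Methods

`placnet` implements an analytic framework linking the transplacental
transfer efficiency (TPTE) of PFAS compounds — the mean cord:maternal blood
concentration ratio — to the architecture of placental transcriptional
mediation of two perinatal outcomes, birth weight and gestational age.  The
pipeline runs: exposure preprocessing → negative-binomial differential
expression → transcriptome-wide causal mediation → a parameter-swept signed
co-expression network with consensus hubs → edge-weighted module topology →
TPTE-scaling regressions and the hub-versus-DE mediation comparison.  A
synthetic-data generator with recorded ground truth provides the study
conditions on which every recovery claim is evaluated.

## Exposure preprocessing

Concentrations below the limit of quantification or detection are imputed
at LOQ/2 and LOD/2 respectively, the standard biomonitoring convention.
Exposures enter all models as z-scores of log concentration.  Z-scores use
the sample standard deviation (n−1).  TPTE is the mean fetal/maternal
concentration ratio over samples with both measurements (samples with zero
maternal concentration are excluded with a warning); because cohort-level
TPTE estimates are typically taken from reference studies, the compound
table also accepts user-supplied values, and the generator's design values
are what the scaling regressions use.  Ratios are computed on the raw
concentration scale; a log-scale ratio is the natural alternative and
differs only by Jensen-gap factors at these noise levels.

## Differential expression

A negative-binomial GLM with log link is fitted per feature by iteratively
reweighted least squares, with median-of-ratios size factors as offsets and
the exposure z-score plus fetal sex, gestational-age z-score and estimated
latent factors as covariates.  Dispersions are per-feature method-of-moments
estimates floored at 1e-4 and lightly shrunk (weight 0.2 in log space)
toward a mean–dispersion trend `a0 + a1/mean` for stability at n ≈ 124.
This is intentionally a simple engine — no shrinkage of fold changes, no
outlier replacement — validated by null calibration (Kolmogorov–Smirnov
uniformity of null p-values) and recovery of planted log2 fold changes, and
cross-checked coefficient-by-coefficient against `statsmodels` NB GLM fits.
Features are called significant at Benjamini–Hochberg FDR < 0.10 with
|log2FC| > 1.  Cross-study concordance uses Fisher's exact test on the
2×2 table of concordant features (nominally significant, same direction in
both studies) against the experimental study's hit set, with
Haldane–Anscombe correction for the log odds ratio on zero cells; for
transcript-level tables the unit is collapsed to genes (a gene qualifies if
any isoform does).

## Causal mediation

For each feature, mediator model `m ~ x + C` and outcome model
`y ~ x + m + C` are fitted by OLS, where `m` is the variance-stabilized
count (log2 of median-of-ratios-normalized count + 1 — a documented
stand-in for a full variance-stabilizing transformation), `x` the exposure
z-score and `y` the outcome z-score.  Covariates are fetal sex plus
gestational age for birth weight, fetal sex alone for gestational age, with
the same covariate set in both stages; gestational-age analyses are
restricted to spontaneous-labor births.  Uncertainty is quasi-Bayesian:
coefficients are drawn from their asymptotic normal distributions, each
draw yields ACME = a·b, ADE = c′ and total = ACME + ADE, and point
estimates and 95% percentile intervals come from 1,000 draws by default.
The two-sided ACME p-value is `2·min(Pr(ACME ≤ 0), Pr(ACME ≥ 0))`.  Because
a product of two independent normal draws is negative exactly when the
draws disagree in sign, this probability has the closed form
`2·min(q, 1−q)` with `q = Φ(t_a)Φ(t_b) + (1−Φ(t_a))(1−Φ(t_b))`; the
default evaluates it analytically (the infinite-draw limit, giving full
tail resolution for multiple-testing control), and `p_method="montecarlo"`
restores the empirical draw frequency floored at `1/(n_sims+1)`.  Draws are
assigned in feature-ID order, so results do not depend on row order.
Significance: BH FDR < 0.05 within one compound × source × outcome family
(all tested features) and 95% CI excluding zero; a flag switches to the
nominal-p rule.  Inverse-variance-weighted mean ADEs use the per-feature
ADE draw variances.

## Co-expression networks

Features detected (nonzero) in ≥20% of samples with variance above the 10th
percentile are retained; one latent technical factor (the first principal
component of exposure-residualized expression, which leaves
exposure-associated signal intact) is regressed out before network
construction.  Signed adjacency is `((1+cor)/2)^β`, with β selected as the
first three integers whose connectivity distribution reaches scale-free fit
R² ≥ 0.85 (signed index, 10 log-spaced bins).  Topological overlap converts
shared-neighbour weight into similarity, and modules come from
average-linkage clustering of TOM dissimilarity with a recursive gap-based
tree cut: a node of the dendrogram is split when its merge height exceeds a
static cut placed a deep-split-dependent fraction {2: 0.10, 3: 0.14,
4: 0.25} of the height range below the top merge, or when the relative gap
to its tallest child exceeds {2: 0.50, 3: 0.25, 4: 0.10}; clusters below the
minimum size are left unassigned.  Deeper split levels cut lower and split
on smaller gaps, so their partitions refine shallower ones.  This is a
deliberate simplification of hybrid dynamic tree cutting, tuned to
reproduce the deeper-split → more-modules behaviour; equality with any
reference implementation is a non-goal.  Modules whose sign-aligned
eigengenes correlate above 1 − mergeCutHeight are merged iteratively.  The
eigengene is the unit-norm first principal component of standardized member
expression, sign-aligned so mean member kME ≥ 0; kME is the Pearson
correlation between a feature and an eigengene.  The full parameter sweep
crosses 3 powers × 4 minimum sizes × 3 split depths × 4 merge heights = 144
iterations per expression level (TOM and the dendrogram depend only on the
power and are cached per power); consensus hubs are the union over
module × iteration of the top-10 members by |kME| (ties broken by feature
ID).

## Module topology

Per module and iteration, a graph over member features keeps edges with
signed adjacency ≥ 0.10, carrying the adjacency (centrality weight) and
1/|r| (distance weight; the absolute value guards the rare weak negative
correlations that pass the floor at low powers).  The hub is the member
with maximum eigenvector centrality, computed by power iteration with an
identity shift (plain iteration oscillates on bipartite graphs) on the
largest connected component, ties to the smallest ID.  Adjacency is rebuilt
per outcome on that outcome's sample set (all samples for birth weight,
spontaneous-labor births for gestational age).  Shortest paths from the hub
to each significant mediator assigned to the module use Dijkstra's
algorithm on the distance weights; the peak distance D (and peak |kME|) is
the mode of a Gaussian KDE with Silverman bandwidth on a 512-point grid
spanning [min − 3h, max + 3h], falling back to the median when fewer than
three values exist.  A module × iteration unit contributes to a
compound × source only when at least `min_mediators_per_unit` (default 3)
of that source's mediators are reachable — a one-feature "distribution" has
no mode, and stray false positives would otherwise replicate into every
iteration.  Compartmentalization is |D_fetal − D_maternal| per unit
(requiring both sources present); all statistics aggregate to
compound × source × outcome means ± SE over units.

## TPTE scaling and the hub comparison

Compound-level summaries — the number of unique significant mediators, peak
|kME|, peak distance, compartmentalization, and the maternal–fetal log2FC
correlation — are regressed on TPTE with Pearson correlation (two-sided t,
n−2 df) and OLS slope with a normal-theory 95% CI; R² is reported as
exactly r².  No multiplicity correction is applied across the eight-compound
regressions.  For the architecture summary, network centrality is the
negated peak distance, so a positive slope means mediators move toward the
hub as TPTE rises.  The mediation-strength comparison pools |ACME| over
analyses into three disjoint categories — significant DE features,
consensus-hub mediators, consensus-hub non-mediators, with hub status
taking precedence for overlapping features (configurable) — and compares
them by one-way ANOVA plus Tukey HSD via the studentized-range
distribution, bootstrapped (1,000 draws of 100 per category) with p-values
averaged across draws; a test mode without resampling reproduces a direct
Tukey(-Kramer) HSD exactly.  Degenerate zero-variance groups report p = 1
with a flag.

## Synthetic study conditions

The generator's defaults are the package's study conditions; they were
designed once to make every planted property detectable at cohort scale and
are not per-analysis knobs.

**Exposures.** 124 samples; eight compounds (PFOS, PFDA, PFUnDA, PFNA,
PFHxS, PFOA, PFBA, PFBS) with TPTE 0.40–2.40, decreasing with carbon chain
length.  Maternal log-concentrations are Normal(0, 0.6); fetal equals
log(T) plus a maternal component with weight ρ(T), piecewise linear from
0.85 (T ≤ 1) to 0.05 (T ≥ 2), so maternal and fetal exposures are
correlated for low-transfer compounds and near-independent above T ≈ 2.
Lognormal marginals are an assumption; the real marginals are not public.
The lowest 4% of each measurement series is censored below the LOD and the
next 4% below the LOQ.

**Expression.** 3,000 transcripts (desk scale): one birth-weight-wired
module of 700, one gestational-age-wired module of 500, eight background
modules of ~90, a technical block of 500, and ~1,100 unstructured
transcripts.  The unstructured majority mirrors real transcriptomes and
anchors the median-of-ratios size factors so module-factor swings do not
masquerade as library-size changes.  Transcript log2-means combine a
Uniform(5, 9.5) baseline, a module factor scaled 1.6 with per-feature
loadings (hubs 0.95–0.99, members 0.30–0.85), planted exposure effects, a
fetal-sex term on 5% of features, and — for the technical block — signed
loadings (±0.8–1.8 log2 units) on one latent batch variable, a
subset-confined composition effect that size factors cannot absorb and that
the latent-factor removal is meant to find.  Counts are NB with dispersion
0.15 and size factors log-uniform in [0.7, 1.4].  Transcripts nest in genes
(1–4 isoforms); for 30% of multi-isoform responsive genes a sibling isoform
responds with the opposite sign, so gene-level aggregation cancels the
transcript-level change.

**Mediation structure.** Outcome effects are wired at the module level: the
outcome receives the standardized per-module sum of its planted mediators'
standardized expression (weights 1.9 for birth weight, 3.0 for gestational
age), so a mediator's outcome-side coefficient is proportional to its
module loading.  This concentration of outcome signal in co-expression
modules is what makes transcriptome-wide mediation detectable at n ≈ 124 —
a mediator's marginal association flows through the shared factor — and is
itself the hub-mediation architecture the analysis is designed to detect.
The mediated paths dominate outcome variance at these settings; that is a
deliberate stress-test regime, not a claim about real effect sizes.  Per
compound: fetal birth-weight mediators number round(14 + 20·T) in a loading
stratum 0.46 + 0.19·T; maternal mediators number round(7 + 8·T) in the same
stratum minus 0.21·max(T−1, 0) — the separation opens only once fetal
exposure decouples from maternal, so cross-detected maternal mediators
never sit in a displaced stratum while the exposures are still correlated.
Gestational-age mediators (round(10 + 10·T)) sit in one fixed stratum
(loading 0.82) and respond to both exposure sources with effect
1.9/sqrt(2(1+ρ(T))), which holds the total exposure variance each feature
carries — and hence its co-expression attenuation and hub distance —
constant across compounds; no centrality or compartmentalization trend is
planted for this outcome.  Exposure effects on birth-weight mediators are
0.75 + 0.08·T log2 units per exposure z.  One designated hub per
compound × source × outcome also mediates (effect 0.4), rotating so no hub
accumulates effects from more than two analyses.  Fifteen
differential-expression-only features per compound × source (log2FC 1.5)
are planted in peripheral strata.  Outcomes add direct exposure effects
(−0.08 per z), a fetal-sex term, a gestational-age term in birth weight,
and Gaussian noise (SD 0.5); z-scores map to grams (3050 ± 400) and weeks
(39.0 ± 1.1); 58% of births are spontaneous-labor.

**What the generator does not emulate.** Real isoform quantification
uncertainty, cell-type composition, nonlinear dose–response, missing
exposure patterns (the synthetic cohort is complete-case), confounding of
the mediator–outcome path, and real exposure marginals.  Passing recovery
tests therefore demonstrates that the pipeline detects the stated structure
when present at the planted effect sizes, not that the cohort findings
would replicate.

## Problem sizes used in tests and the acceptance script

Replicate simulations use a scaled-down design with the same structure
(2,000 transcripts: wired modules of 340/260, two background modules of 50,
300 technical, 1,000 unstructured; mediator counts scaled accordingly) and
a 4-point network grid (powers 4–5, split depths 2–3, merge height 0.15) —
one grid point per distinct clustering regime, since peak statistics
averaged over near-identical iterations add no information.  The family
size of ~2,000 features matters for realism: Benjamini–Hochberg thresholds
scale with the family, and an unrealistically small family admits
marginally-associated features of other compounds into a compound's
mediator set, where their short, tightly clustered hub distances can hijack
the kernel-density mode.  Hub recovery is evaluated on the full default
design.  The mediation engine's calibration uses direct linear-Gaussian
simulation at n = 124.

## Numerical choices and edge cases

Ties in hub ranking break lexicographically by feature ID; eigenvector
centrality tolerance 1e-10 with a 10,000-iteration cap; KDE ties resolve to
the smallest grid value; BH treats missing p-values as outside the family;
non-converged NB fits keep estimates but are excluded from the family;
zero-variance mediators are skipped with a warning; empty mediator units
contribute nothing; regression rows with fewer than three compounds or
zero variance are skipped with warnings.  Pipeline TSVs are written at 12
significant digits, and the per-stage manifest (config hash, stage seeds,
output checksums) makes a completed run directory idempotent: re-running is
a no-op and a corrupted output triggers recomputation of just that stage.

## Known limitations

The tree cut and the variance-stabilizing transform are documented
simplifications of their reference counterparts; eight compounds give the
scaling regressions limited power, so single-replicate significance
patterns are noisy (hence the replicate-fraction form of the recovery
claims); the mediation model assumes sequential ignorability and no
exposure–mediator interaction; and the KDE-mode peak statistic is sensitive
to multimodal distance distributions when mediator sets are contaminated —
the minimum-mediators-per-unit rule mitigates but does not eliminate this.
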