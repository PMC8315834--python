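# Methods

This note documents the models and procedures implemented in `phenonet`,
the numerical conventions, the design of the synthetic claims generator,
and the choices made where the design was genuinely open.

## Study timeline and population

The timeline is split at five anchors t₀ < t₁ < t₂ < t₃ < t₄ into a
no-admission window [t₀,t₁), a feature window [t₁,t₂), a target window
[t₂,t₃) and a follow-up window [t₃,t₄); the reference configuration is
6 + 3 + 3 + 6 years (1997–2015).  A patient enters the study population
when they have no stay in the no-admission window and at least one stay in
each of the feature and target windows — selecting people who were
hospitalisation-free for six years and alive through t₂.

A stay that spans a window boundary is attributed to exactly one window by
its **exit date** (the default; claims datasets of this kind are keyed on
exit dates).  Entry-date attribution is available as an option.  Boundary
instants belong to the later window ([t, t') intervals).

Diagnoses are role-suffixed three-character codes: `E66p` primary, `E66s`
secondary.  The package accepts any letter+two-digit code so synthetic
universes need not be valid ICD-10.  The feature matrix X₀ records codes
received during the feature window; the target matrix Y accumulates codes
through the end of the target window (**monotonicity**: once diagnosed,
a condition is treated as present ever after).  X₀'s support is therefore
a per-patient subset of Y's, and every feature trivially "predicts" its
own codes — such trivial associations are flagged and excluded from
ranked interaction reports.

## Higher-order diagnosis features

Candidates are all code sets of size 1..m (m = model order) with
co-occurrence support ≥ support_min = 30.  Sets of size ≥ 2 must also pass
the minIDP filter:

minIDP(S) = min_{d∈S} 10·log₁₀( P̂(d | S∖{d}) / P̂(d) )  db,

with +1/+2 Laplace smoothing in both the conditional and the marginal
estimate.  The exact estimator behind the published measure is not
documented; this reconstruction matches its name and stated purpose
(every member of a feature must be more likely given the rest of the
feature than a priori).  Singletons bypass the filter — their prior ratio
is identically 1 and any positive threshold would delete them all.
Support is anti-monotone over supersets and is used for level-wise lattice
expansion; minIDP is not anti-monotone and is applied only as a final
filter.  The enumerator is bespoke (no suitable itemset-mining library is
a dependency) and is verified against brute-force subset enumeration.

Candidates are ordered by cardinality (desc), minIDP (desc), raw support
(desc) and lexicographic code string (asc — a determinism tie-break added
here).  Features are then **greedily assigned**: walking the ordered set,
a feature is assigned to a patient iff its codes are present and none is
already covered; assigned codes become covered.  Features whose assigned
support falls below support_min are pruned **one at a time** (front of
the order first, because re-assignment of a pruned feature's patients can
re-support later features), and the assignment is repeated until all
supports hold.  Assignment is per-patient independent, so the
implementation re-walks only the patients of the pruned feature.

## Multi-target naive Bayes in decibans

For each target t, patients split into target-positive/negative classes.
The default coefficient is the conditional-probability (weight-of-
evidence) ratio with Bernoulli-style smoothing:

C(f,t) = 10·log₁₀( θ_{1,f} / θ_{0,f} ),  θ_{c,f} = (N_{c,f}+α)/(n_c+2α),

where N_{c,f} counts class-c patients with feature f and n_c the class
size; π(t) = 10·log₁₀(n₁/n₀).  This is the formula the coefficients are
defined by, it matches scikit-learn's `BernoulliNB` smoothing, and it has
the calibration property that C → 0 for independent feature–target pairs.
A `multinomial` variant (occurrence-normalised θ, matching
`MultinomialNB`; Σ_f θ_{c,f} = 1) is available behind a switch for
sensitivity analysis — note that its per-class occurrence normalisation
adds a common occupancy bias to every coefficient of a target, so it does
not share the independence calibration.

Prediction is by the linear score Δ(p,t) = Σ_{f assigned} C(f,t) + π(t),
strictly positive for "present" (an exact tie predicts absent).  Scoring
uses precision, recall and F1 per target with zero-denominator
conventions of 0; a target's support is its true-positive count and the
total F1 is the support-weighted mean.  Cross-validation uses seeded
uniform unstratified folds (k = 5); features are mined, pruned and fitted
on training patients only and assigned to held-out patients for scoring.
Scored targets are fixed before fitting: at least 200 positives in every
fold, top-1000 by total support, ties lexicographic.  Held-out scores are
the headline numbers; training scores are reported alongside.

Hyperparameters: α (log-scaled, default bounds 10⁻³..10) and minIDP_min
(0..5 db) are tuned by grid search or by a Gaussian-process surrogate with
expected improvement; support_min stays fixed.  Grid search is the
reference strategy; the GP route exists for budgets too small for a grid.

## Interaction lift

L(f,t) = C(f,t) − Σ_{g∈G} C^{|g|}(g,t).  G is built by walking the
ordered feature set downward starting just after f, collecting every
feature that fits inside the uncovered remainder of f's code set; the
ordering guarantees disjointness.  Constituent coefficients come from the
model whose order equals the constituent's cardinality, so lift always
contrasts a fit that could use the full combination with fits that could
not.  Singletons have lift 0 by convention and are excluded from
rankings; features whose partition cannot be completed have missing (not
imputed) lift.  Ranked tables filter to non-trivial records with joint
support ≥ 50 patients and C ≥ 8 db, and report the median lift per
feature over its qualifying targets.

## Generalized disease network

Nodes are the features of the all-data model.  Φ(f₁,f₂) = −½·ln(1−ρ²)
with ρ the Pearson correlation of coefficient rows; natural log (only the
relative edge order matters downstream, which is base-invariant); ρ² is
clipped at 1−10⁻¹² and constant rows get ρ = 0.  Weights are discretised
into 30 equal-width integer bins over the off-diagonal range, with exact
zeros staying zero so absent similarity creates no null-model mass.  The
weighted configuration model — the maximum-entropy ensemble fixing node
strengths s_i = Σ_j w_ij — is fitted by trust-region least squares on the
residuals Σ_{j≠i} y_i y_j/(1−y_i y_j) − s_i over y ∈ [0,1)^N to max
|residual| < 10⁻⁶.  The first start is a constant random vector: the
residuals constrain products y_i y_j, not the ordering of equal-strength
nodes, and a symmetric start preserves their symmetry (the two-node
closed form y* = √(w/(1+w)) is a test); restarts use fully random
vectors.  An edge survives iff γ_ij = (y*_i y*_j)^{w_ij} < 0.05
(strict, as an already multiplicity-adjusted filter; no additional FDR
layer).  Louvain modularity (resolution 1, seeded, edge weight Φ) labels
clusters; the giant component is the final network.

## Matched cohort comparison

For an index code, the two clusters with the most index-code features
define two cohorts; a patient joins a cohort through ≥1 assigned
index-code feature of that cluster.  Controls have no index-code
diagnosis (either role) in the feature period.  Patients qualifying for
both clusters are excluded and counted (a config option assigns them to
the cluster with more matching features instead); index-positive patients
outside both clusters are likewise excluded.  The smaller cohort anchors
1:3:10 matching without replacement — exact sex and region, birth year
within ±2 — in seeded random anchor order; anchors with insufficient
pools are excluded and counted.  Comparisons per diagnosis block
(inclusive code ranges over both roles) and sex: prevalence = any block
code in the feature window; incidence = first-ever block code in the
target window; mortality = in-hospital death during follow-up;
hospitalisation days = Σ (exit−entry+1) over feature+target windows.
Effect sizes ES = 10·(log₁₀ n_j − log₁₀ n_i) db on relative frequencies
(missing when a frequency is zero); G-test 2·Σ O·ln(O/E) with χ²(1)
p-values, no continuity correction, stars at p < 10⁻², 10⁻⁴, 10⁻⁶.

## Synthetic claims generator

Given latent assignments, codes are independent Bernoulli draws —
pairwise and higher-order statistics are therefore analytically
controllable.  Components:

* **Phenotypes**: mixing weights; members' core codes elevated in the
  feature window and target codes in the target window.
* **Three-way clusters**: triples drawn from {all-on: m, exactly-one: u
  each, iid q₀}, with u solved from m and q₀ so each pair is *exactly*
  independent while the triple co-occurs above chance.  Pairs of such a
  triple fail the minIDP filter and the triple passes it, so the lift
  decomposition is forced to singletons — the cleanest beyond-pairwise
  test case.
* **Synergies**: the odds of a target code are multiplied by `boost` only
  for carriers of the full feature set (multiplicative odds rather than
  noisy-OR so the planted ground truth is exactly 10·log₁₀(boost) db).
  Even so, the *recovered* lift is attenuated by decomposition leakage:
  each singleton constituent absorbs P(full set | that code)·(boost−1)
  worth of odds, ≈0.4–0.7 db total under the fixture conditions, so a
  boost of 2 (3.01 db) recovers ≈2.3–2.7 db.
* Every patient gets ≥1 feature-window and ≥1 target-window stay, none in
  the no-admission window, so the whole simulated population passes study
  selection.  Stay dates are uniform within windows.  Under the default
  primary policy the first drawn code of a stay is primary and the rest
  secondary; the canned fixtures use the `filler` policy (a Z00 check-up
  code is always primary and all disease codes secondary) so planted
  structure is not fragmented across the p/s role split.  Deaths are
  Bernoulli per patient with per-phenotype rates, emitted as a follow-up
  stay with the death flag.

**Fixture design.**  The two-phenotype fixture (n = 20,000) plants a
metabolic group (weight 0.16; cores E66, E11, E78, I10 at 0.6) and a
musculoskeletal group (weight 0.02; cores E66, M54, M17, M81 at 0.6),
sharing E66.  Two design elements are essential for the network stage and
worth stating plainly.  First, both phenotypes develop shared
high-penetrance sequelae (G47, R07 at 0.95 in the target window, ≈0
elsewhere): these create a strong shared coefficient axis across both
phenotypes' features, without which the backbone separates the two
feature blocks into disconnected components (the configuration-model
filter removes edges explainable by node strengths, and the cross-block
correlation otherwise rides only on the shared index-code association).
Second, forty unstructured background codes pad the universe: with too
few nodes, the block hubs dominate the strength sequence, every y* is
pushed toward 1 and no moderate edge can be significant; padding
re-creates the many-moderate-nodes regime the backbone is designed for.
The 1:8 weight ratio keeps the larger cohort more than three times the
smaller, as 1:3:10 matching requires.  What passing tests on this
generator do **not** show: robustness to coding errors, seasonality,
length-of-stay structure, inter-code correlations beyond the planted
ones, or any transfer to real claims.

## Numerical conventions and edge cases

Smoothing is additive everywhere (α for the classifier, +1/+2 for
minIDP).  Targets with a one-sided class are dropped from fits with a
warning.  Ties: Δ = 0 predicts absent; feature ordering ties break
lexicographically; cluster selection ties break by cluster id.  The WCM
fit raises after five restarts with the best residual in the message.
Degenerate similarity ranges (all off-diagonal entries equal) bin to 1
with a warning.  Zero frequencies make effect sizes missing rather than
infinite; a zero G-test margin is an error.

## Known limitations

Model orders above 4 are permitted but warned against (combinatorial
growth; unexplored).  The minIDP estimator and the greedy assignment are
reconstructions of procedures whose original definitions are not public;
both are pinned by oracle tests here but may differ in detail from other
implementations.  The multinomial coefficient variant is not calibration-
equivalent to the default.  Louvain is seeded but its cluster *labels*
are arbitrary; only partitions are meaningful.  No significance testing
is attached to lifts, and no survival modelling beyond crude in-hospital
mortality fractions.
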