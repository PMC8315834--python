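# phenonet

Data-driven identification of complex disease phenotypes from hospital
claims.  The package is aimed at epidemiologists and biostatisticians who
have stay-level diagnosis records (one primary and any number of secondary
ICD-10 three-character codes per stay) and want to go from raw claims to

1. **higher-order diagnosis features** — sets of co-occurring, role-suffixed
   codes (`E66s` = obesity coded as a secondary diagnosis) mined by frequent
   itemset enumeration with a support floor and a *minimum information
   difference to prior* (minIDP) filter, greedily assigned so that each
   patient's features have disjoint code sets;
2. **a multi-target naive-Bayes model** whose coefficients are weights of
   evidence in decibans,

   C(f,t) = 10·log₁₀[ Pr(X_f=1 | Y_t=1) / Pr(X_f=1 | Y_t=0) ]  db,

   with prior log-odds π(t) and linear decision function
   Δ(p,t) = Σ_{f∈p} C(f,t) + π(t) (target predicted present iff Δ > 0),
   scored by support-weighted F1 under fivefold cross-validation;
3. **interaction lift** — L(f,t) = C(f,t) − Σ_{g∈G} C^{|g|}(g,t), the excess
   evidence of a feature over its lower-order decomposition G (positive =
   synergy, negative = redundancy), with each constituent's coefficient
   taken from the model of its own order;
4. **a generalized disease network** — features as nodes, similarity
   Φ = −½·ln(1−ρ²) from the Pearson correlation of coefficient rows,
   filtered to a maximum-entropy backbone under the weighted configuration
   model (edge kept iff γ_ij = (y*_i·y*_j)^{w_ij} < 0.05) and clustered by
   Louvain modularity; and
5. **matched phenotype cohorts** — the two network clusters richest in an
   index disease (e.g. obesity, E66) define candidate phenotypes whose
   members are matched 1:3:10 to the larger cohort and to non-index
   controls (exact sex and region, birth year within ±2), then compared
   block-wise with effect sizes ES_{i,j} = 10·(log₁₀ n_j − log₁₀ n_i) db
   and likelihood-ratio G-tests.

Real claims datasets of this kind are not redistributable, so the package
ships a seeded synthetic claims generator (`phenonet.simulate`) with
planted latent phenotypes, three-way co-occurrence structure with zero
pairwise excess, and beyond-pairwise target synergies — every stage of the
pipeline is testable end to end without access to protected data.

## Worked example

Two latent obesity phenotypes share the index code E66 but have disjoint
comorbidity cores (metabolic: E11, E78, I10; musculoskeletal: M54, M17,
M81).  The pipeline recovers them as two network clusters and quantifies
the metabolic contrast between the matched cohorts:

```python
from phenonet import simulate as sim
from phenonet.claims import (select_study_population, build_matrices,
                             patient_demographics)
from phenonet.pipeline import fit_order_models
from phenonet.network import (similarity, discretize, fit_wcm, backbone,
                              cluster_and_reduce, index_disease_view)
from phenonet.cohorts import assign_cohorts, match, compare

cfg = sim.two_phenotype_fixture(seed=1)
stays, truth = sim.simulate(cfg)
pop = select_study_population(stays, cfg.periods)
X0, Y = build_matrices(stays, pop, cfg.periods)

fits = fit_order_models(X0, Y, orders=[2])
res = fits[2].results
sim_m = similarity(res)
W = discretize(sim_m)
y = fit_wcm(W, seed=1)
H = cluster_and_reduce(
    backbone(sim_m, W, y, features=list(fits[2].feature_set)), seed=1)
print(index_disease_view(H, "E66"))

asg = assign_cohorts(H, fits[2].X, X0, "E66")
demo = patient_demographics(stays, pop)
ms = match(asg, demo, seed=1)
tab = compare(ms, stays, cfg.periods, [("diabetes", "E10", "E14")], demo)
```

Printed output (seed 1):

```
study population: 20000 patients, 55 role-suffixed codes
final order-2 feature set: 116 features (63 pairs)
backbone giant component: 111 features, 183 edges, 9 clusters

index-disease view for E66:
 cluster_id  n_features  fraction
          2           3       0.5
          5           3       0.5

diabetes prevalence (f): control 13.7%  cohort_1 3.8%  cohort_2 66.8%  ES = +12.5 db***
diabetes prevalence (m): control 14.3%  cohort_1 5.2%  cohort_2 65.8%  ES = +11.0 db***
```

The E66 features split evenly over two clusters — the planted phenotypes.
The metabolic cohort's diabetes-block prevalence exceeds the
musculoskeletal cohort's by 11–12.5 db (a >10-fold frequency ratio,
"strong" on the Jeffreys scale; `***` marks G-test p < 10⁻⁶).  Individual
coefficients read the same way: `C(E11s E66s → I25s) = +5.6 db` means that
carrying the diabetes+obesity pair multiplies the odds of a later
ischaemic-heart-disease code by ≈3.6 (substantial evidence), while the
largest coefficients in any fit are the trivial self-associations
(`C(A73s → A73s) ≈ +40 db`): under monotone accumulation a feature
guarantees its own codes as targets.

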