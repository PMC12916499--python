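# factorverse

**Multiverse arbitration of latent symptom dimensions against cognitive
outcomes.**

Transdiagnostic psychiatry replaces diagnostic categories with latent
symptom dimensions estimated from the covariation of questionnaire items —
for example the Anxious-depression, Compulsivity and Intrusive Thought, and
Social Withdrawal dimensions estimated from a battery of nine clinical
questionnaires (209 ordinal items). But the dimensions one obtains depend on
analytic choices that are rarely defended: how many factors to retain, which
questionnaires to include, and how to rotate the solution. `factorverse`
implements a *cognitive arbitration* procedure for adjudicating among these
choices: it enumerates the full multiverse of candidate dimensions, scores
participants on every candidate in independent datasets, and ranks the
candidates by how strongly they associate with objective cognitive measures
(model-based planning from sequential decision tasks; mean confidence from
metacognition tasks).

## What the package computes

1. **Polychoric correlations.** Ordinal items are modelled as discretised
   bivariate normals; each pairwise correlation is estimated in two steps
   (thresholds from the margins via Φ⁻¹, then ρ by maximum likelihood), with
   eigenvalue-flooring repair to positive semi-definiteness.
2. **Exploratory factor models.** Maximum-likelihood extraction on the
   correlation matrix R, minimising
   F = log|Σ| + tr(RΣ⁻¹) − log|R| − p with Σ = ΛΛ′ + Ψ, followed by
   gradient-projection rotation (oblimin/quartimin or varimax), RMSEA/TLI
   fit indices, Thurstone regression score weights W = R⁻¹ΛΦ, Anderson-Rubin
   scores with exactly identity sample covariance, and a Schmid-Leiman
   hierarchical bifactor solution (general "p" factor plus group factors).
3. **The multiverse.** Three manipulation arms generate candidate
   dimensions from a discovery dataset: factor number (k = 1…10 on the full
   battery → 55 candidates), questionnaire combination (all 511 non-empty
   subsets × k = 1…5 → 7665 candidates), and rotation
   (oblimin / varimax / bifactor at k = 3 → 10 candidates).
4. **Signed effect sizes.** Each candidate is scored in every dataset
   (score = Σ item × weight), regressed on a cognitive outcome controlling
   for age, gender and IQ, and summarised as a signed Cohen's
   f² = (R²_full − R²_reduced)/(1 − R²_full), pooled across datasets by
   sample-size weighting and ranked in the direction of interest.
5. **Supervised comparator.** A cross-validated partial least squares
   regression of the items on the residualised outcome (75/25 split, 10-fold
   CV component selection) provides the fully supervised alternative against
   which the unsupervised winners are benchmarked.

Because the clinical datasets behind this design are restricted-access, the
package ships a first-class synthetic-data module: ordinal responses from a
planted oblique three-factor model over the nine-questionnaire battery,
demographic covariates, and outcomes whose *partial* effect sizes against
the latent factors are planted exactly (signed f² of −0.014 for planning on
the compulsivity factor; +0.038 and −0.030 for confidence on the
compulsivity and anxious-depression factors).

## Worked example

```python
import numpy as np
import factorverse as fv
import factorverse.multiverse as mv

# three synthetic studies of n = 2000; the first is the discovery sample
datasets = fv.make_benchmark(3, 2000, seed=1)
discovery = datasets[0]

# polychoric matrix and the benchmark 3-factor oblimin solution
R = fv.heterogeneous_matrix(discovery.responses)
bench = [c for c in fv.run_factor_number_arm(discovery, 3, R=R) if c.k == 3]

# evaluate the three factors against planning across all datasets
table = fv.evaluate_candidates(bench, datasets, "model_based_planning",
                               "most_negative", conditioning="joint")
print(table.table[["candidate_id", "f2_weighted", "rank"]])
```

Output:

```
          candidate_id  f2_weighted  rank
0  factor_number|k3|f1    -0.016104   1.0
1  factor_number|k3|f2     0.000061   2.0
2  factor_number|k3|f3     0.001397   3.0
```

The first factor of the three-factor solution — the compulsivity-like
dimension, which correlates r = 0.97 with the planted compulsivity factor —
carries a weighted f² of −0.016 against model-based planning, recovering the
planted −0.014 within Monte-Carlo error; the other two factors carry no
planning effect, as planted. Each `examples/` script walks through one
capability in the same style (simulation, polychoric estimation, factor
models, the scaled multiverse, and the PLS comparison) and prints what the
numbers mean.

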