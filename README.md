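# moe-subtyper

Semi-supervised discovery of gray-matter atrophy subtypes in mild cognitive
impairment (MCI), for neuroimaging researchers studying the heterogeneous
prodromal stage of Alzheimer's disease (AD).

MCI sits between normal aging (CN) and AD, and MCI cohorts are not
homogeneous: different patients atrophy in different cortical regions and
progress at different speeds. Because the thickness difference between MCI
and CN is subtle, clustering MCI directly works poorly. This package
implements the alternative strategy of anchoring subtype discovery in the
well-separated AD-vs-CN contrast and then *mapping* MCI subjects onto the
discovered AD subtypes.

## The model

Subjects are represented by mean cortical thickness in the 68 ROIs of the
Desikan–Killiany atlas. After residualizing age, sex, education and
intracranial volume with a GLM fitted **on CN subjects only**
(β estimated from CN, then `residual = thickness − β·[1, age, sex, edu, ICV]`
applied to everyone), a mixture of K linear max-margin experts is trained
jointly with fuzzy C-means (FCM) memberships over the AD cohort:

```
min_{w_k, b_k, m_ik}  Σ_k [ ½‖w_k‖₁
                            + C Σ_i s_i m_ik (1 − y_i (w_kᵀx_i + b_k))²
                            + t Σ_i m_ik² ‖x_i − d_k‖² ]
s.t.  Σ_k m_ik = 1,  m_ik ∈ [0, 1],   d_k = Σ_i m_ik² x_i / Σ_i m_ik²
```

CN subjects (y = −1) are the shared "anchor": they enter every expert's
classification loss with fixed unit weight, while AD subjects (y = +1)
distribute fuzzy membership m_ik across experts; s_i is an AD:CN class
weight ρ. Block coordinate descent alternates exact solutions of the three
subproblems (a sample-weighted lasso per expert, the closed-form FCM
centroid, and a closed-form simplex QP per membership row), so the
objective is monotone non-increasing. Model selection over the (C, t, ρ)
grid uses cross-validated accuracy (Acc), the maximum pairwise inner
product of unit-normalized expert weights (W_r, small = distinct experts)
and the Bezdek partition coefficient (BPC ∈ [1/K, 1], 1 = crisp).

Each fitted expert is a hyperplane separating one AD subgroup from CN.
Experts are named by atrophy severity of their members (MIN / MID / DIF for
K = 3), every MCI subject is assigned to the subtype whose hyperplane is
geometrically closest (`d_k = |w_kᵀx + b_k| / ‖w_k‖₂`, smallest d wins),
and longitudinal visits are screened with a 24-month cut-off (missing M24
recovered from M36 when the subject stayed MCI) to produce per-period
at-risk sets, MCI→AD conversion rates, APOE ε4/ε2 carrier statistics among
converters, and conversion-time subtype attribution.

A seeded synthetic cohort generator plants three anatomically motivated
atrophy patterns (temporal, frontal, posterior-predominant diffuse) with
covariate effects, APOE genotypes, visit missingness and conversion events,
so the whole pipeline is testable end to end without access to restricted
clinical data.

## Worked example

```python
from moe_subtyper import CohortSpec, MOEConfig, run_pipeline

result = run_pipeline(spec=CohortSpec(seed=1),        # 228 CN / 192 AD / 396 MCI
                      config=MOEConfig(seed=1, n_restarts=3), seed=1)
print(result.shares[["subtype", "n", "share_pct"]])
print(result.at_risk)
print(result.metrics)
```

prints (seed 1):

```
subtype   n  share_pct
    MIN 102       25.8
    DIF 173       43.7
    MID 121       30.6
period  n_at_risk  n_convert  n_revert     rate
   m06        373         32         4 0.085791
   m12        334         34         6 0.101796
   m18        292         26         3 0.089041
   m24        261         25         3 0.095785
{'ad_subtype_ari': 1.0, 'mci_assignment_ari': 1.0, 'bpc': 1.0,
 'wr': 0.302, 'final_objective': 85.344}
```

Reading this: 25.8% of the synthetic MCI cohort maps to the
minimal-atrophy subtype; 373 screened MCI subjects are at risk at month 6
and 8.6% of them convert to AD in that period; the fitted experts recover
the planted AD subtypes perfectly (adjusted Rand index 1.0 against the
generator's truth), the min-distance mapping recovers the planted MCI
subtypes (ARI 1.0), and the three expert weight vectors are nearly
orthogonal (W_r = 0.30). `result.apoe_converters` additionally shows ε4
carrier rates of 62–80% among converters versus ~50% in the MCI cohort —
the carrier enrichment the generator plants via an ε4 conversion hazard.

The same pipeline is scriptable from the shell:

```bash
moe-subtyper synth --out cohort/ --seed 1
moe-subtyper harmonize --thickness cohort/thickness_bl.tsv \
    --subjects cohort/subjects.tsv --out residuals.tsv
moe-subtyper fit --residuals residuals.tsv --subjects cohort/subjects.tsv \
    --k 3 --seed 1 --out model.json
moe-subtyper assign --model model.json --residuals residuals.tsv --out assignments.tsv
moe-subtyper screen --visits cohort/visits.tsv --out screened/
moe-subtyper report --assignments assignments.tsv --subjects cohort/subjects.tsv \
    --screened screened/ --out report/
```

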