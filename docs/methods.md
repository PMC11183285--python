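# Methods

## Problem and approach

The package addresses subtype discovery in mild cognitive impairment (MCI)
from Desikan–Killiany cortical thickness (68 ROIs, mm). Direct clustering
of MCI is ill-conditioned because MCI–CN differences are small; instead,
subtypes are discovered where the signal is strong — in the AD-vs-CN
contrast — and MCI subjects are subsequently mapped onto the discovered AD
subtypes through the experts' hyperplanes.

The pipeline has five stages, each a module:

1. `synth_cohort` — seeded generator of ADNI-like cross-sectional and
   longitudinal tables with planted subtypes (study conditions, below);
2. `harmonize` — per-ROI OLS of thickness on age, sex (F = 1), education
   and ICV, fitted on CN rows only, subtracted from every subject;
3. `moe_core` — the semi-supervised mixture of experts (below);
4. `subtype_map` — severity naming, min-distance MCI assignment,
   conversion-time attribution;
5. `longitudinal_screen` / `report_stats` — the 24-month visit screen and
   the summary tables (shares, conversion rates, APOE carriers,
   trajectories, ROI atrophy flags, group comparisons).

## The mixture-of-experts estimator

K linear experts (w_k, b_k) and fuzzy memberships m over the N_AD AD
subjects minimize

    Σ_k [ ½‖w_k‖₁ + C Σ_i s_i m_ik (1 − y_i(w_kᵀx_i + b_k))²
          + t Σ_{i∈AD} m_ik² ‖x_i − d_k‖² ],
    Σ_k m_ik = 1, m_ik ≥ 0,  d_k = Σ m_ik² x_i / Σ m_ik².

Design choices where the formulation left room:

* **CN anchoring.** The membership constraint is only well-defined over AD
  subjects; CN subjects are the fixed negative class of *every* expert with
  unit weight and no membership variables. This realizes the "anchor" role
  of controls and couples the K hyperplanes.
* **Loss.** The squared loss (1 − y f)² is used literally
  (least-squares-SVM style, no truncation). A squared-hinge variant
  max(0, 1 − y f)² is available behind `MOEConfig(squared_hinge=True)`
  (solved by bound-constrained L-BFGS on the split (w⁺, w⁻) problem) but is
  off by default.
* **Intercept.** An unpenalized intercept b_k is fitted; hyperplane
  distances and class imbalance make a through-origin boundary
  unreasonable for thickness residuals. `fit_intercept=False` restores the
  strict no-intercept form.
* **FCM exponent.** α = 2 throughout, so the stated centroid formula is the
  exact minimizer of the distance term and the descent is monotone.
* **Class weight.** ρ (AD:CN, 1–5) multiplies C for AD samples only.

### Exact block updates

Each block attains its conditional optimum, so the objective trace is
non-increasing (asserted on every run of the test suite):

* **Experts.** With y ∈ {−1, +1}, (1 − y f)² = (y − f)², so each expert
  solves a sample-weighted lasso (weights ρ·m_ik for AD, 1 for CN). The
  solver is scikit-learn's `Lasso` with the penalty mapped as
  α = 1/(4·C·Σweights), which makes its objective exactly proportional to
  the expert subproblem; an independent bound-constrained QP oracle checks
  this in the tests.
* **Centroids.** d_k = Σ m² x / Σ m² over AD rows.
* **Memberships.** Each row minimizes Σ_k [CρL_ik m + t D_ik m²] on the
  simplex; the KKT conditions give m_ik = max(0, (λ_i − CρL_ik)/(2tD_ik))
  with λ_i found exactly by a sorted active-set sweep. D_ik is floored at
  1e-12. The tests compare against a brute-force oracle that enumerates
  every active set.

Initialization is plain FCM on the AD rows from seeded random centroids;
the fit runs the best of `n_restarts` (default 5) restarts by final
objective. A "dead" expert (membership mass < 1e-8) is re-seeded at the
worst-fit AD point up to three times before the fit fails. Convergence:
max membership change < 1e-4 (default), max 100 sweeps.

### Model selection

`grid_search_select` evaluates every (C, t) on a powers-of-two grid
(default 2⁻³…2¹⁰) times ρ ∈ {1…5}, recording 10-fold cross-validated
accuracy, W_r and BPC, and selects lexicographically: max Acc, then min
W_r, then max BPC, then smallest C, t, ρ. The full table is always
returned so a user can re-select under another rule. The packaged defaults
C = 8 = 2³ and t = 0.125 = 2⁻³ are the operating point this rule selects
on the default synthetic conditions; on those conditions the selected fits
show W_r ≈ 0.2–0.4 and crisp memberships (BPC near 1, a consequence of the
planted clusters being well separated — real cohorts sit closer to the
fuzzy end).

### Prediction and mapping

A CN/AD label for a new point uses its nearest-centroid expert's decision
sign (ties: 0 → +1, lowest index). MCI subjects carry no memberships and
are assigned by smallest unsigned geometric distance
|w_kᵀx + b_k|/‖w_k‖₂ (a signed mode exists for sensitivity analysis).
AD subjects' own subtype labels come from argmax membership. Experts are
named by ranking the mean ROI residual of their argmax members (least
negative = MIN); naming is invariant to expert permutation.

## Synthetic study conditions

The generator's defaults are the package's study conditions:

* 228 CN, 192 AD, 396 MCI; age ~ N(75, 6.5) clipped to [55, 90], 45%
  female, education ~ N(15.8, 3), ICV ~ N(1.5e6, 1.5e5) mm³.
* Covariate slopes on thickness: −0.008 mm/yr age, +0.02 mm female,
  +0.002 mm/yr education, 0 for ICV (thickness, unlike volume, is weakly
  ICV-dependent; ICV is still residualized downstream). Measurement noise
  0.1 mm per ROI.
* Three planted patterns at 0.4 mm focal deficit, prevalences
  0.26/0.34/0.40, MCI expressing half the AD deficit (`mci_scale` 0.5):
  **MIN** temporal lobe; **MID** frontal cortex, sparing the medial
  temporal lobe; **DIF** diffuse across all 68 ROIs with posterior
  predominance (0.4 mm parieto-occipital/cingulate/insula, 0.15 mm
  elsewhere). These follow the canonical neuropathological AD variants
  (limbic-predominant, hippocampal-sparing, typical/diffuse). The patterns
  are deliberately **not** nested with equal magnitudes: if they were, a
  half-scale MCI subject would lie exactly on the hyperplane of every
  subtype whose region set contains its own and min-distance mapping would
  be information-less. Mean atrophy burden orders MIN < MID < DIF.
* APOE alleles drawn as two independent draws with per-group ε4/ε2
  frequencies (CN 0.14/0.05; MIN 0.27/0.056; MID 0.34/0.034;
  DIF 0.33/0.030); carrier = at least one allele.
* Cognitive scores are linear maps of mean atrophy burden plus noise
  (e.g., MMSE 29.1 − 14.5·burden, clipped to [0, 30]); they exist to
  exercise the trajectory reports, not any estimator.
* Longitudinal schedule: visits bl, m06…m36 with missingness
  0/0.08/0.10/0.12/0.15/0.25; per-period conversion 0.033/0.055/0.060 for
  MIN/MID/DIF with a ×2.5 hazard for ε4 carriers (reproducing the strong
  carrier enrichment among converters seen in amnestic-MCI cohorts);
  reversion 0.01; conversion and reversion are absorbing. A converter's
  atrophy ramps from `mci_scale` by +0.1 per 6-month period toward full
  expression — freshly converted subjects are early AD, which is also what
  makes conversion-time min-distance attribution well-posed (a point deep
  past its own hyperplane can be nearer an oblique neighbor's plane).
* One random stream per concern (demographics, subtypes, APOE, noise,
  visits, scores), spawned from the master seed, so changing one count
  does not perturb unrelated draws.

What the generator does **not** emulate: site/scanner effects, spatially
correlated measurement noise, skewed covariate distributions,
within-subtype severity gradients, ADAS item structure, CSF biomarkers
(fields are absent), and informative (outcome-dependent) missingness.
Passing tests therefore demonstrate correctness of the estimator and
pipeline mechanics under clean planted structure, not expected performance
on clinical data — in particular the near-perfect accuracies and crisp
memberships reflect the planted separation.

## Longitudinal screening

Baseline keeps subjects with an MCI diagnosis and a baseline scan. The
follow-up screen treats M24 as the cut-off: a subject with an M24 scan is
followable at every period; without one, a period is retained only with
that period's scan plus an M36 recovery scan, and screening is
*sequential* — a subject failing retention at one period stays excluded
afterward, which makes at-risk counts monotone non-increasing by
construction. A subject with no M24 scan who remained MCI is kept for the
M24 period only when m06–m18 and m36 were all scanned and the m36 state is
still MCI (`imputed_from_m36`); an AD or CN state at m36 makes the
conversion time indeterminable and excludes the subject. The forward sweep
records the first visit at which AD (conversion) or CN (reversion) is
observed at a scanned visit; events are terminal. Diagnoses recorded at
scan-less visits are ignored for event detection by default
(`require_scan=True`), and such rows are flagged with a warning. Each
subject ends in exactly one terminal category (retained at M24, converter,
reverter, or one-reason exclusion), a conservation property the tests
assert.

## Reporting conventions

Percentages are rounded half-up to one decimal (`report_stats.percent`),
which reproduces standard clinical-table arithmetic (103/396 → 26.0).
Per-ROI atrophy flags use Welch's t-test vs. CN at uncorrected p < 0.05,
with an exact-equality short-circuit for degenerate zero-variance
samples; no multiple-testing correction is applied (a deliberate
limitation, matching common practice for descriptive atrophy maps).
One-way ANOVA compares continuous variables across subtypes, with
Dunnett's test against the first subtype reported only when ANOVA
p < 0.05; carrier proportions use chi-square with degenerate tables
skipped and noted. Trajectory means at each visit use the subjects
retained at that visit (no last-observation-carried-forward).

## Problem sizes and numerical settings

The test suite and the acceptance script run reduced problem sizes chosen
to exercise every code path at full fidelity: optimizer exactness on
random instances up to K = 4 and 30 AD subjects (checked to 1e-6 against
enumeration, typically agreeing to machine precision), monotonicity over
20 seeded 200-subject fits (tol 1e-8), subtype recovery at 150 CN + 150 AD
training subjects with 300 mapped MCI subjects, and the end-to-end study
at the full default cohort (816 subjects). Lasso subproblems run at
tol 1e-12 so that block updates are exact to well below the monotonicity
tolerance. Plotting is intentionally omitted: all artifacts are TSV/JSON
tables, which is what the tests and downstream analyses consume.

## Known limitations

* The squared (untruncated) loss penalizes well-classified outliers; the
  squared-hinge option mitigates this but is not the default form.
* Min-distance mapping degrades when subtype patterns are strongly
  collinear at matched magnitudes (see the generator discussion); W_r is
  the practical diagnostic — selected fits with high W_r should not be
  trusted for MCI mapping.
* With K = 1, W_r is undefined (returned as NaN) and the selection rule
  falls through to BPC.
* The screening rules implement one reading of an ambiguous clinical
  protocol; the scan-pattern predicate is isolated in
  `retained_by_scan_pattern` so alternative readings can be swapped.
* ICV is residualized even though its default generative effect is zero;
  with real data the CN-fitted slope absorbs whatever ICV dependence
  exists.
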