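# Methods

## The model

Healthy ageing is treated as a multidimensional construct with three
components — intrinsic capacity (physiological–metabolic health, geriatric
syndromes, cardiovascular risk factors, physical capacity, cognition,
psychological well-being), the social and political environment (social
welfare, political environment), and the interaction of the older adult with
the environment (community participation, family support) — ten domains in
all. Each domain is operationalized as a list of binary criteria over raw
survey indicators; a respondent is *healthy* in a domain when the domain's
rule is satisfied and receives an intra-domain score

    score = round(10 · criteria met / criteria applicable),

so 10 is the best attainable status. Respondents are then partitioned into a
*healthy ageing* and a *less healthy ageing* group by clustering the
ten-score profiles, and group membership is related to socio-demographic
determinants by expansion-weighted logistic regression.

## Domain rules and instrument cut-offs

Defaults follow the published operationalization for the SABE 2010 Ecuador
survey; every cut-off sits in a `Thresholds` object and can be changed.

| domain | rule (healthy) | criteria |
|---|---|---|
| physiological | every chronic disease absent, or controlled / non-limiting | 9 (one per disease slot) |
| geriatric syndromes | no polypharmacy (≥ 5 meds), no urinary/fecal incontinence, no falls syndrome (≥ 2 falls/yr) | 4 |
| risk factors | BP not above 150/90 (strict >), glucose < 126 mg/dL, BMI < 30, ATP-III lipids normal, alcohol ≤ 1 day/wk, no tobacco, physically active | 7 |
| physical | ≥ 6 of 7 performance items AND no Katz ADL disability | 8 |
| cognitive | no dementia AND modified Mini-Mental ≥ 14 | 2 |
| psychological | no physical/sexual/psychological abuse AND no depression | 4 |
| social welfare | no negligence, no economic violence, Gijón ≤ 9 | 3 |
| political environment | (social security OR pension) AND health access AND institutional support | 3 |
| participation | recreation AND monthly volunteering | 2 |
| support | receives OR provides family support | 1 |

Decisions where the published rules leave gaps:

* **Mini-Mental gap.** Healthy is defined at ≥ 14 and deficit below 13,
  leaving 13 unassigned; the default assigns 13 to *less healthy* so the
  partition is total (`minimental_gap_to_healthy` flips it). Likewise the
  Gijón gap value 10 (good ≤ 9, altered > 10) defaults to *less healthy*.
* **Yesavage direction.** The rule is implemented as printed in the source
  survey analysis — depression when the score is ≤ 4 — although standard GDS
  scoring is the reverse; `yesavage_direction="ge"` selects the
  conventional direction. The generator and all defaults use the printed
  rule, so the two stay consistent.
* **Polypharmacy and falls** are not numerically defined in the source;
  defaults use the standard ≥ 5 concurrent medications and ≥ 2 falls in the
  past year.
* **Institutional support** is read as a conjunct of the political-
  environment rule (configurable), the stricter of the two readings.
* **Missing items** are dropped from the applicable set, never imputed; a
  domain with no applicable criterion is non-evaluable, and a record with
  more than 3 non-evaluable domains is excluded from clustering. For the
  physical domain the 6-of-7 requirement is prorated to
  `ceil(6/7 · applicable items)` when items are missing.
* **Score rounding** is half-up (`floor(x + 0.5)`), keeping the score
  monotone in the criteria and avoiding the bankers'-rounding asymmetry.

The conclusion section of the source analysis speaks of nine domains while
its own table and figure enumerate ten; the implementation follows the
table's ten.

## Two-step clustering

Profiles (the ten scores, treated as continuous) are pre-grouped by
sequential insertion: a record joins the nearest sub-cluster when the
log-likelihood distance increase is at most a threshold, else starts a new
one. Sub-clusters are then merged greedily under

    d(a, b) = ξ(a) + ξ(b) − ξ(a ∪ b),
    ξ(s) = −N_s Σ_k ½ log(σ̂_k² + σ̂_{s,k}²),

with σ̂_k² the overall per-feature variance and σ̂_{s,k}² the within-cluster
(MLE) variance; sufficient statistics (N, Σx, Σx²) make merges O(d). The
distance is symmetric and nonnegative; merge distances need not be
monotone along the agglomeration. Zero-variance features are dropped from
the distance with a warning. Numerical choices:

* **Threshold default**: the 25th percentile of pairwise singleton distances
  on a 200-record subsample (seeded); if pre-clusters exceed the branching
  limit (512) the threshold doubles and the pass restarts.
* **Tie-breaks**: merges and assignment pick the lexicographically lowest
  index pair / lowest cluster id, so results are deterministic given input
  order and seed.
* **Cluster count**: BIC(k) = −2 Σ ξ(cluster) + 2·k·d·log n, minimized over
  1..k_max, or bypassed with `force_k=2` — the published pipeline. Because
  ξ is a classification (hard-assignment) likelihood, the gain from
  splitting grows roughly linearly in n while the penalty grows as log n,
  so the BIC minimum over-segments diffuse data at larger n; automatic
  selection is reliable for well-separated clusters and for unstructured
  data only at modest n. The pipeline therefore forces k = 2.
* **Weights** play no role in fitting (respondents are clustered
  unweighted); expansion weights enter only the reported weighted means and
  frequencies, matching an analysis that clusters respondents and then
  reports population-expanded tables.
* **Labeling**: the cluster with the greater grand mean of domain scores is
  the healthy-ageing group; an exact tie raises an error rather than
  guessing.
* **Domain comparison**: weighted means per cluster and a Welch test on
  effective sample sizes `n_eff = (Σw)²/Σw²`, two-sided, no multiplicity
  adjustment (matching the per-domain reporting style of the source).

## Weighted logistic regression

Both association tables run on one IRLS engine: weighted maximum likelihood,
convergence when the largest score component is below 1e-8 (at most 100
damped Newton steps), and a weights-only sandwich covariance
`H⁻¹ (Σ w_i²(y_i−p_i)² x_i x_iᵀ) H⁻¹` with weights normalized to sum to the
record count — population-scale expansion factors therefore do not deflate
standard errors. This is an approximation to full complex-sample variance:
without the design's strata/PSU identifiers only the weights can be
modelled, so confidence intervals are comparable to, but not identical
with, design-based ones. Consequences and conventions:

* For a single categorical covariate the fitted ORs equal the weighted
  cross-product ORs exactly (saturated-model identity); the weighted 2×2
  cells are attached to each contrast.
* Crude ORs use Woolf CIs on the log scale; a zero cell is an error unless
  the optional 0.5 continuity correction is enabled.
* The multivariate table includes the variables with any bivariately
  significant contrast (p < 0.05 by default), fits them jointly with
  casewise deletion (counts reported), and flags |log OR| > 15 as separated
  / unreliable instead of suppressing it — mirroring how near-empty cells
  produce extremely wide published intervals.
* p-values are two-sided Wald tests on the log-odds scale, unadjusted.
* Reference categories: man, 65–74, urban, primary education, bad health,
  satisfied, not poor, mestizo.

## Synthetic cohort generator

The generator emulates the structure of the SABE 2010 Ecuador survey and is
latent-state-first so that every downstream stage has exact ground truth:

1. Demographics and outcome-perception variables are drawn from declared
   margins. Defaults: the published weighted demographic margins
   renormalized over non-missing (e.g. urban 0.651, women 0.568); perceived
   health, life satisfaction and income poverty from the published weighted
   row totals of the group cross-table.
2. The latent healthy state follows
   `logit P(healthy) = α + Σ log(OR_j)·x_j`, with the published bivariate
   odds ratios as default effects and α calibrated by bisection so the mean
   probability over the drawn covariates equals the target prevalence
   π = 0.5315 (tolerance < 1e-10; realized prevalence then varies only by
   binomial noise). An effect set that cannot reach π raises an error.
3. Per domain, an intended score is drawn as N(μ_state, sd) on the 0–10
   scale and discretized to a met-criteria count; the met criteria are
   chosen uniformly at random and the raw indicators (diagnoses and control
   flags, medication and fall counts, blood pressure, glucose, BMI,
   instrument totals, flags) are then drawn to realize that pattern exactly,
   so the rule engine reproduces the intended scores verbatim. Defaults:
   healthy mean 8.5, gap 3.5, sd 1.5 — a separation consistent with a radar
   profile whose two groups are distinct in every informative domain.
   Domains in the `decoupled` set (default: risk factors) use the midpoint
   mean for both states, reproducing the one domain where the published
   groups do not differ.
4. Weights are unit or lognormal (σ = 0.6) rescaled to the population total
   898,152; missingness is MCAR at configurable per-variable rates
   (defaults: the published missing shares — age 9.53%, education 27.62%,
   ethnicity 4.18%, sex 0.22%).

What the generator does **not** emulate: the real three-stage sampling
design (strata/PSU; weights are marginal only), inter-domain correlation
beyond the single latent factor, informative missingness, and any
measurement error in the instruments. Passing recovery tests therefore show
that the pipeline is correct under these idealized conditions, not that the
published prevalence or multivariate point estimates are reproducible —
those depend on the actual microdata and design variables. Score
discretization also means few-criterion domains realize the nominal
gap/sd only coarsely (the 1-criterion support domain yields 0/10 scores, so
its realized gap exceeds the nominal one); recovery checks use domains with
enough criteria for the nominal parameters to bind.

## Problem sizes used in the checks

Worked-example odds ratios are exact arithmetic on the published weighted
cells. Pipeline recovery runs at the design size n = 1,797; calibration and
margin checks at n = 10,000–50,000; parameter recovery at n = 20,000 with
CI-coverage over 200 replicates of n = 2,000 — sizes at which Monte-Carlo
error is small relative to the tolerances while the whole suite stays
inexpensive.

## Known limitations

* Design-based variance (Taylor linearization over strata/PSU) is out of
  scope; the sandwich CIs approximate it from weights alone.
* The published ethnicity odds ratios are not reproducible from the
  published cross-table cells (the reference coding there cannot be
  recovered); ethnicity is included in pipeline outputs but excluded from
  the worked examples, as are the education rows with zero less-healthy
  cells.
* Automatic k selection is trustworthy only in the regimes described above;
  the supported analysis path forces k = 2.
* The rule engine consumes instrument totals and flags as recorded in the
  survey; it does not re-administer Katz, Mini-Mental, Yesavage or Gijón at
  item level.
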