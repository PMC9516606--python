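# Methods

## Hypergraph model

A cohort is a binary participants × diseases matrix (after resolving
missing flags; see below). Nodes are the catalog's diseases in a fixed,
recorded order — that order indexes every matrix and breaks ranking ties.
A hyperedge is a multimorbidity cluster: by default, every *distinct
complete diagnosis profile* of size ≥ 2 observed in at least one
participant. This profile universe is deliberately narrower than the
closure of all subsets of observed profiles: it keeps the edge count at
the scale of observed phenotypes rather than exploding combinatorially,
and matches how cluster counts are reported for survey cohorts. A
subset-closure universe (`edge_universe="subsets"`) is available for
exploration.

Edge membership counts use **superset semantics**: a participant supports
edge *e* if their diseases include all of *e*, possibly more ("people
with all the diseases in the set"). Exact-profile counting
(`counting="exact"`) is available as a variant.

The overlap weighting coefficient of an edge,

    W_E(e) = #(participants with every disease in e) / min_{d in e} #(participants with d),

lies in (0, 1] and measures nesting: W_E = 1 means the rarest member
disease never occurs outside the cluster. It is undefined (an error) if
any member disease has zero cases — impossible for edges enumerated from
the data, possible for user-supplied sets. Node weights W_N(d) are crude
prevalences (count / n). Using a proportion rather than a raw count is
recorded in output metadata because the dual-level centralities are not
scale-invariant in W_N (node-level centralities are invariant to any
positive rescaling of W_E, and this is property-tested).

Node adjacency: A = Mᵀ·diag(W_E)·M with the diagonal forced to zero (a
node is not adjacent to itself). Dual adjacency:
A* = diag(W_E)·(M·diag(W_N)·Mᵀ − D_E)·diag(W_E), i.e. two clusters are
adjacent in proportion to the summed prevalence of their shared diseases,
scaled by both overlap weights, zero diagonal. The orientation (M rows =
edges, columns = diseases) is what makes both products well-formed.

## Eigenvector centrality

Default: dense symmetric eigendecomposition (`scipy.linalg.eigh`) — the
matrices are at most a few hundred square. The graph is first split into
connected components; the reported vector is the leading eigenvector of
the component attaining the largest eigenvalue, with zeros elsewhere
(this is the well-defined extension to disconnected graphs, and avoids
the mixed-sign vectors a global eigendecomposition can return under
near-ties). The vector is sign-fixed to be non-negative
(Perron–Frobenius guarantees this per component; entries below −1e-8
after the sign fix raise an error), clipped at zero, and scaled to unit
Euclidean norm. A power-iteration implementation (tolerance 1e-12, cap
10,000 iterations) is kept as an independent numerical route and is
cross-checked against the dense route to 1e-8 in tests. An all-zero
adjacency raises a degenerate-graph error rather than returning an
arbitrary vector.

Ranking is descending with competition ranks: ties share the lower rank
number and keep catalog order. Displayed values are rounded to two
decimals; machine-readable outputs keep full precision.

## Study-design stages

* **Obesity** is derived from BMI with an inclusive ≥ 30 kg/m² threshold;
  missing BMI propagates to a missing flag.
* **Missing diagnosis flags** resolve to *absent* by default
  (complete-case style coding); the *present* policy — every missing
  flag recoded positive — is exactly the missing-to-positive sensitivity
  analysis. The default is a documented inference, not a reported fact
  of the design the package emulates.
* **No-disease exclusion** drops participants with zero diseases after
  binarization, preserving order.
* **Periodontitis extent** is the proportion of probed sites with CAL at
  or above 3 mm (inclusive). **Quartiles** are rank-based equal-count
  groups computed on the analysis cohort after exclusions: sort by
  (extent, participant id) — the id is the deterministic tie-break — and
  cut into four contiguous groups whose sizes differ by at most one,
  remainders to the lower quartiles. Quartile 4 is the most severe.
  Equal-count (not fixed-threshold) quartiles are the reading consistent
  with exactly equal matched group sizes.
* **Matching** is exact-cell: stratify by (sex, age cell of width
  caliper + 1 years), take the minimum per-quartile count in each cell,
  and select that many participants per quartile per cell uniformly at
  random under a fixed seed. At caliper 0 the post-match (sex, age)
  composition of the four quartile groups is identical by construction.
  The procedure is deterministic given the seed and idempotent. Exact-cell
  matching was chosen over distance-minimising optimal matching because it
  is simple, reproducible, and equalises the matched marginals exactly;
  nothing in the pipeline depends on which optimal-matching variant a
  given study used.
* **Stratification** restricts to quartiles 1 and 4 and splits by
  ethnicity (white/other), smoking (yes/no) or household income
  dichotomised as quintiles {1,2} = low vs {4,5} = high (middle quintile
  excluded; configurable). Participants with a missing stratification
  value fall outside all levels and are counted in provenance.
* **Sensitivity analyses** rerun the quartile analysis with one survey
  cycle's participants removed, or with missing flags recoded positive.
  Both are no-ops (identical analytical output) on cohorts without the
  targeted cycle or missingness.

Hypergraphs are rebuilt per stratum from that stratum's participants
only, so all weights are stratum-local — the construction under which
per-quartile centralities can differ at all. Strata with fewer than two
represented diseases are skipped with the reason recorded in provenance.

## Synthetic cohort generator

The generator emulates a matched NHANES-style periodontal cohort and is
the package's test bed. Disease flags: each planted cluster *c*
contributes a shared standard-normal factor g_c per participant; disease
*d*'s latent score is Σ_{c∋d} strength_c·g_c plus independent standard
normal noise, and the flag is the score exceeding the quantile matching
the target prevalence (the score's variance is known in closed form, so
marginals are exact in expectation regardless of the planted structure).
Pairwise association within a planted cluster is monotone in the
strength parameter; diseases sharing no cluster are independent.

Defaults are the emulated study's conditions: prevalences from
hypertension 0.639 down to emphysema 0.023; age ~ N(58.16, 13.22²)
truncated at 30 and rounded; 57.7% female; ethnicity white 0.461;
income-quintile distribution (0.157, 0.153, 0.219, 0.208, 0.263 for
quintiles 1–5); smoking 0.474; three survey cycles uniform. Per-field
MCAR missingness defaults mirror the emulated survey's reported rates
(diabetes 3.8%, osteoporosis 35.4% — the question was absent from one
cycle — BMI 1.0%, income 9.6%, ...). CAL extent is
expit(logit(0.20) + 0.6·smoker + 0.4·other-ethnicity +
0.15·(3 − income quintile) + N(0, 1)); the covariate effect sizes are not
reported quantities anywhere and were chosen once for test power (clear
gradients at n ≈ 2,000), not realism. The default planted clusters —
{hypertension, obesity} at strength 1.0, {hypertension, arthritis} at
0.6, {diabetes, hypertension, obesity} at 0.5 — encode the qualitative
structure the analysis should recover: a dominant hypertension–obesity
pair and a hypertension hub.

BMI is generated conditional on the latent obesity flag (≥ 30 when
obese), so deriving obesity from BMI downstream reproduces the flag;
missing BMI is the sole source of missing obesity.

What the generator does **not** emulate: survey design and sampling
weights, within-household correlation, age-dependent prevalence and
missingness (missingness is MCAR by construction), diagnosis timing, and
per-site CAL measurements (extent is generated directly; the per-site
path is exercised through `cal_extent` separately). Passing tests
therefore demonstrate correctness of the algorithms under controlled
conditions, not epidemiological validity on real survey data.

## Numerical choices and problem sizes

Tolerances: adjacency oracle equivalence 1e-12; dense vs power-iteration
centrality 1e-8; unit-norm contract 1e-10. Degenerate inputs: all-zero
adjacency, empty site lists, < 4 participants for quartiles and empty
quartile groups for matching all raise typed errors rather than
returning defaults. Test and acceptance problem sizes — 200 random
cohorts of ≤ 30 participants × ≤ 6 diseases for oracle equivalence, 100
replicates of n = 2,000 × 10 diseases for planted-structure recovery,
n = 10,000 for the matching contract, n = 6,542 for the end-to-end run —
were chosen so the full suite completes in well under a minute while
keeping binomial noise far below the effects being detected.

## Limitations

* Cross-sectional only: no temporal ordering of diagnoses.
* The profile edge universe means a cluster unseen as a complete profile
  contributes no edge even if all its diseases co-occur inside larger
  profiles (superset counting still credits it as support for its
  sub-profiles that were observed).
* Dual-level centralities depend on the W_N scale convention (proportion
  here); comparisons across cohorts of very different size should use
  node-level centralities.
* No inferential statistics are attached to centrality differences
  between strata; the pipeline reports point values, as descriptive
  network analyses of this kind do.
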