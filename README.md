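# hypermorb

Hypergraph multimorbidity clustering for periodontitis cohorts.

People with periodontitis frequently carry several systemic conditions at
once. Classical network analyses of multimorbidity are pairwise: an edge
joins exactly two diseases, so a cluster of three or more conditions is
never represented as the object it is. `hypermorb` implements a
hypergraph alternative for cross-sectional survey cohorts: every distinct
combination of ≥2 diseases observed in at least one participant is a
hyperedge (a *multimorbidity cluster*), and eigenvector centrality on the
weighted hypergraph quantifies how influential each single disease — or
each whole cluster — is to multimorbid presentation. The package is aimed
at epidemiologists analysing NHANES-style tabular cohorts (demographics,
self-reported diagnoses, clinical attachment loss from periodontal
examination) and ships a synthetic-cohort generator with planted
structure so the whole pipeline is testable without any data download.

## The model

Let the binary matrix of participants × diseases define hyperedges from
observed diagnosis profiles. With incidence matrix **M** (edges ×
diseases), the edge weights are the overlap coefficients

W_E(e) = |{participants with all diseases in e}| / min_{d∈e} |{participants with d}|,

and node weights W_N(d) are crude prevalences. The node-level adjacency is

**A** = **M**ᵀ W_E **M** − D_N

(off-diagonal: summed weights of edges containing both diseases; diagonal
zeroed), and the dual (cluster-level) adjacency is

**A\*** = W_E (**M** W_N **M**ᵀ − D_E) W_E.

Eigenvector centrality is the leading eigenvector of **A** (or **A\***),
non-negative by Perron–Frobenius and scaled to unit Euclidean norm.

Around that core the pipeline reproduces a full study design: derivation
of obesity from BMI (≥30 kg/m²), exclusion of participants without any
systemic disease, periodontitis extent as the proportion of sites with
CAL ≥ 3 mm split into four equal-count quartiles, 1:1 age/sex matching
across quartiles, covariate stratification (ethnicity, smoking,
household income) within the extreme quartiles, and two sensitivity
analyses (dropping a survey cycle; recoding missing diagnoses as
positive).

## Worked example

Five participants with diagnosis profiles {H,O}, {H,O}, {H,O,D}, {H},
{D} (H hypertension, O obesity, D diabetes) give two clusters. Running
`python examples/01_toy_hypergraph.py` prints:

```
multimorbidity clusters:
  {hypertension, obesity}: support 3, W_E = 1.0
  {hypertension, obesity, diabetes}: support 1, W_E = 0.5

node adjacency A = M^T W_E M (zero diagonal):
[[0.  1.5 0.5]
 [1.5 0.  0.5]
 [0.5 0.5 0. ]]

leading eigenvalue: 1.7808
  rank 1: hypertension C = 0.6572
  rank 2: obesity C = 0.6572
  rank 3: diabetes C = 0.3690
```

W_E({H,O}) = 3/min(4,3) = 1.0 because everyone with obesity also has
hypertension; the adjacency entry A[H,O] = 1.0 + 0.5 sums both clusters
containing the pair; and the leading eigenvalue solves
λ² − 1.5λ − 0.5 = 0, i.e. λ = (1.5 + √4.25)/2. Hypertension and obesity
tie for most central because they sit in every cluster.

On a full synthetic cohort (`python examples/03_full_pipeline.py`: 6,542
participants generated, no-disease exclusion, quartiles, matching,
analysis) the matched cohort of 4,408 yields 653 unique clusters;
hypertension is the most central disease (C = 0.53), followed by obesity
(0.46) and arthritis (0.43), and {hypertension, obesity} is the
heaviest cluster (W_E = 0.83) — the structure planted by the generator's
defaults.

There is also a thin CLI mirroring the pipeline stages:

```bash
hypermorb generate --out cohort.csv --seed 5 --n 800
hypermorb quartiles --in cohort.csv --out withq.csv
hypermorb match --in cohort.csv --caliper 0 --seed 17 --out matched.csv
hypermorb analyze --in matched.csv --out-dir results/
```

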