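# Methods

## The model in brief

A drug's pharmacology is summarized by its receptor fingerprint: the vector
of adjusted binding affinities across all retained receptors. Two drugs are
considered similar when their fingerprints are highly Pearson-correlated,
which deliberately discounts overall potency (a uniformly more potent drug
has a linearly rescaled fingerprint and correlates perfectly with its
weaker twin — correlation absorbs dosing differences). The taxonomy is the
modularity-maximizing partition of the correlation graph, and its worth is
measured by out-of-sample prediction of clinical effect profiles.

## Ingest

* **Units.** Input Ki is nanomolar (the PDSP convention);
  pKi = 9 − log₁₀(Ki nM). Molar input can be accommodated by rescaling
  before parsing.
* **Aggregation.** Replicate (drug, receptor) measurements are collapsed by
  the median of Ki *before* conversion. Because log₁₀ is monotone, median-
  then-convert and convert-then-median agree; the choice is documented, not
  consequential.
* **Filters and their order.** Receptors with fewer than 5 measured drugs
  are dropped first, then drugs with fewer than 5 remaining receptors, then
  receptor columns whose Ki is identical across their (≥ 2) observed drugs.
  The two count filters are applied once, in that order, by default;
  `iterate_filters=True` repeats them to a fixed point for the (rare) case
  where removing a drug pushes a receptor back below threshold. Both
  thresholds are parameters with default 5.
* **Species matching** is case-insensitive string equality to "human" — a
  deterministic, auditable filter, with no fuzzy matching.

## Adjustment

The floor constant is fixed at 4 (pKi 4 = Ki 100 µM, the weakest binding
worth recording), so adjusted affinity 0 means "no meaningful binding".
Values below the floor are allowed (they go negative) with a warning rather
than clipped, so synthetic data with other ranges pass through unchanged.
Agonists and partial agonists are treated identically: a single binary sign
flip. Graded intrinsic activity is out of scope; the inversion is applied
*before* imputation, so the latent structure the imputation model learns is
the functionally signed one.

## Probabilistic PCA

`fit_ppca` implements the isotropic-noise factor model x = μ + Wz + ε.
With complete data its maximum-likelihood solution is the classical PCA
eigenbasis (verified against an eigendecomposition oracle to < 1e-6
subspace angle). With missing entries the model is fitted by **expectation
conditional maximization**: one E-step computes each row's latent posterior
given its observed coordinates (M = W_oᵀW_o + σ²I; ẑ = M⁻¹W_oᵀ(x_o − μ_o);
Σ_z = σ²M⁻¹), and three conditional M-steps update μ, then W, then σ²
against those expectations, including the posterior covariance between the
missing coordinates and the latents. Each conditional step maximizes the
same expected complete-data objective, so the observed-data log-likelihood
— computed exactly per iteration via the Woodbury identity — is
non-decreasing; the tests assert this at 1e-8.

Numerical choices:

* deterministic initialization from the SVD of the column-mean-imputed
  matrix (a seeded random initialization is available via `init="random"`);
* convergence on relative log-likelihood change < 1e-6, max 1000 iterations;
* σ² is floored at 1e-12 to keep the noiseless limit well-defined;
* component identifiability: directions come from the SVD of W, ordered by
  singular value, each sign-fixed so its largest-magnitude loading is
  positive — without this, run-to-run sign flips would make the
  characterization tables irreproducible.

The imputation rank q defaults to 5: at least the 3 interpreted components
plus slack, comfortably below the number of drugs. Scores are posterior
means in the canonical basis (shrunken projections s/(s² + σ²)·uᵀ(x − μ)).
"Variance explained" is defined on the eigen-spectrum of the *completed*
matrix's sample covariance — the denominator convention is stated because
different choices change the number. Component summaries for clusters use
drug scores; receptor summaries use loading vectors (clusters contain
drugs, so drug-level quantities are the dimensionally consistent ones).

## Clustering

Louvain modularity maximization assumes non-negative weights, so negative
correlations must be mapped by an explicit policy. The default `clip_zero`
(w = max(r, 0)) treats anticorrelation as mere absence of attraction;
`shift_min` and `abs` are available for sensitivity analysis and the chosen
policy is recorded in the partition metadata. Self-correlations are never
edges. Determinism comes from a seeded restart protocol: `n_restarts`
(default 100) node orders derived from one master seed, best modularity
wins, ties broken by the lexicographically smallest canonical assignment
vector. The winning partition then receives a deterministic single-node
local-moving pass (including moves into a fresh singleton) until no move
improves Q: greedy aggregation occasionally locks in a split that one node
move improves, and on exhaustively enumerable graphs (n ≤ 8) this protocol
matches brute-force optimal modularity in ≈ 99/100 random trials, never
worse than 0.02. Cluster ids are relabeled by size, then smallest member.
The modularity reported with a partition is recomputed from the formula
independently of the community-detection code. Resolution is fixed at 1.0
and exposed only for diagnostics.

## Prediction

* **Encoding.** Categorical schemes become one-hot matrices (D = number of
  categories); the completed fingerprint matrix passes through (D =
  number of receptors).
* **Protocol.** For each held-out drug: missing clinical cells are
  PPCA-imputed *within the training fold only*; predictors and targets are
  centered and unit-scaled on training statistics (constant columns pass
  through with zero weight); a multi-target PLS (scikit-learn NIPALS) is
  fitted; the held-out drug's error is the median absolute error over its
  *observed* effects only — imputed values are never used as ground truth.
  The summary is the median of per-drug medians. A poisoning test asserts
  the held-out drug's values cannot influence its own prediction.
* **Components.** n_components defaults to 2 — with 3–7 one-hot predictors
  and ~26 training rows, small counts are the only defensible choice — and
  is capped at the training rank. At full rank PLS predictions coincide
  with ordinary least squares (the test oracle). When NIPALS exhausts the
  target residual on degenerate folds, the fit retries with fewer
  components and, in the limit of no usable predictor variance, predicts
  the training mean.
* **Permutation null.** Each of the n_perm (default 500) replicates
  shuffles the drug-to-predictor alignment within the training data — a
  fresh permutation per fold by default; a single permutation shared across
  folds via `shuffle="per_replicate"` — and recomputes the full LOO
  summary. p = (1 + #{null ≤ observed}) / (1 + n_perm): the add-one rule
  keeps p strictly positive and ties count against the observed statistic.
  Calibration is verified empirically: with targets independent of
  predictors the test rejects at 5% within sampling error over 200
  replicates.

## Synthetic data: what it emulates, and what it does not

The generator plants K cluster centers at the vertices of a regular simplex
embedded in receptor space by a seeded orthonormal map, so "separation" has
exactly one meaning: the pairwise center distance in units of the
within-cluster standard deviation. The shared baseline profile is mid-range
pKi (6.5) with mild per-receptor jitter (sd 0.25); the between-cluster
offsets carry the signal. A strongly heterogeneous shared baseline would
dominate the drug–drug correlations and mask the planted structure, which
would make "separation" meaningless as a control knob. Fingerprints are
center + isotropic Gaussian noise; observed cells are exported as
`records_per_cell` replicate Ki measurements scattered log-normally
(sd 0.1 in log₁₀) around the cell's true Ki, so median aggregation is
exercised on the Ki scale. Agonism flags are planted per (cluster,
receptor) and disjoint across clusters — drug classes partial-agonize
their own receptors, and a receptor flipped in two classes would spuriously
correlate them. Clinical effects are a linear function of cluster
membership (or, optionally, of the adjusted profile) plus Gaussian noise.

The benchmark configuration — 27 drugs × 42 receptors, 4 clusters,
separation 8, noise sd 0.5, 20% MCAR missingness, 16 effects with
between-group sd 1.0 and residual sd 0.5, 3 replicates per cell — mirrors
the scale of published antipsychotic receptor-affinity datasets and is the
workload for the end-to-end recovery checks and the acceptance script.

Limitations of the emulation: missingness is MCAR, whereas real screening
data are missing not-at-random (research interest drives what gets
measured); replicate scatter is i.i.d. log-normal with no study-level
heterogeneity; clinical scores are exactly linear in group membership.
Passing the recovery tests therefore demonstrates the pipeline's
correctness under its stated assumptions, not robustness to informative
missingness or non-linear clinical structure.

## Problem sizes used by the default test run

Simulation-based tests are sized to be decisive yet quick: PPCA oracles at
60×40, Louvain brute-force comparison at n ≤ 8 over 100 graphs, type-I
calibration with 12 drugs × 4 effects × 200 replicates at n_perm = 99, and
one full benchmark run at the reference shape with n_perm = 500. These are
the package's chosen defaults for its own verification; all are
configurable upward.

## Known limitations

* The taxonomy depends on the negative-correlation policy and, weakly, on
  the imputation rank q; both are surfaced as parameters and recorded in
  run manifests rather than hidden.
* Only binary agonism is modeled; graded partial agonism and functional
  assay readouts are out of scope.
* The clinical table is consumed as given; no attempt is made to re-derive
  or re-weight the underlying effect sizes.
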