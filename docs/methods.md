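# Methods

## The staging problem

Three diagnostic groups — CON, MCI, AD — are treated as ordinal stages
0/1/2 of one process. Two cohorts measured on different array platforms are
analyzed jointly. Two signal classes are modeled: per-gene expression
changes with stage, and shifts of the blood cell composition with stage,
summarized at the level of five lineages (HSC, Lymphoid, Myeloid,
Epithelial, Stroma; the first three are hematopoietic).

## Synthetic study generator

The generator exists so that every downstream stage can be validated
against planted ground truth. For gene g and sample j of stage s in cohort
c:

    mu_gj = (B f_j)_g * 2^(d_g * delta * m_g(s)) * a_gc
    x_gj  = mu_gj * exp(eps_gj),    eps_gj ~ N(0, noise_sd^2)

* **Mixture basis B** (genes × cell types): each cell type has a disjoint
  marker signature expressed at `marker_high` (default 400 intensity units)
  in its own type and `marker_low` (5) elsewhere; non-marker genes carry a
  flat log-normal baseline (median 40, log-sd 0.8), so a marker's
  within-sample rank is driven by its own cell type's abundance crossing a
  dense baseline bulk.
* **Compositions f_j**: per-cell-type logits = baseline log proportions
  (whole blood: HSC 0.15, Lymphoid 0.35, Myeloid 0.35, Epithelial 0.08,
  Stroma 0.07, split evenly within lineage) + stage × lineage drift +
  N(0, noise_sd²) jitter, softmax-normalized. Default drifts (logit units
  per stage step): HSC −0.25, Lymphoid −0.20, Myeloid −0.15, Epithelial
  +0.30, Stroma +0.35 — hematopoietic lineages shrink with stage. With
  `noise_sd = 0` compositions are exact deterministic functions of stage,
  which is what the exactness tests rely on.
* **Differential genes**: `n_de_genes` (default 120) non-marker genes get a
  ±`de_effect_size` (default 0.8) log2 shift scaled by an onset profile
  drawn per gene — linear (0,1,2), early (0,2,2) or late (0,0,2) across
  stages. Without the early/late profiles the middle stage would be the
  exact midpoint of the other two on every informative axis and no
  one-vs-rest linear model could isolate it; mixed onsets also match how
  pairwise contrast DEG sets differ in real staging cohorts.
* **Platform factor a_gc**: one log-normal per-gene factor per cohort
  (log-sd `cohort_shift_sd`, default 0.15), mimicking probe-efficiency
  differences between array generations; removable by per-sample
  normalization plus per-cohort standardization.
* **Seeding**: all randomness flows from one integer seed through keyed
  `numpy` SeedSequences — signatures, gene universe, platform factors
  (keyed additionally by a CRC of the cohort id) and noise use separate
  sub-streams, so two cohorts generated with the same noise seed differ
  exactly by their platform factors (a rank-1 matrix in log space), while
  `generate_study` gives each cohort independent noise.
* **Default layout**: two cohorts with group sizes 57/46/58 and 44/34/61
  (CON/MCI/AD), 300 samples total; 2000 genes, 10 cell types (two per
  lineage) with 15-gene signatures. These dimensions keep every simulation
  in the test suite fast while preserving the dense-baseline rank geometry
  the scoring model needs.

What the generator does **not** emulate: probe-level artifacts, quantile
normalization, correlated gene-gene noise, within-lineage composition
differences beyond jitter, and label noise. Passing tests therefore
demonstrate correctness of the algorithms under the stated generative
model, not expected performance on real cohorts — real accuracy will be far
below the clean-simulation ceiling.

## Normalization

Parts-per-million scaling per sample, `x' = x / Σx × 10⁶`; idempotent and
invariant to per-sample global rescaling. Downstream analyses run on
`log2(x' + 1)`; a raw-scale mode is retained. For pooling cohorts in
modeling, each gene is z-scored within each cohort (mean 0, variance 1),
which removes additive platform offsets after the log; differential
expression runs on the un-standardized log scale so effect sizes stay in
log2 units.

## Moderated t

Pooled two-sample variance `s²_g` with `d_g = n₁+n₂−2` degrees of freedom
is shrunk toward a prior: `s̃²_g = (d₀s₀² + d_g s²_g)/(d₀+d_g)`, t-statistic
`Δmean/(s̃_g √(1/n₁+1/n₂))`, p from a t distribution on `d₀+d_g` df. The
prior is fitted by moment matching on `z = log s²_g`: under the scaled
inverse-chi-square model, `Var(z) = ψ'(d_g/2) + ψ'(d₀/2)`, inverted for
`d₀` by Newton iteration on the trigamma, and the mean equation gives
`s₀²`. When `Var(z)` does not exceed the sampling variance the prior df is
infinite (all variances pinned at `s₀²`, normal tails); with fewer than ten
informative genes the fit degrades gracefully to `d₀ = 0`, the ordinary
pooled t. A zero-variance gene with a nonzero mean difference and `d₀ = 0`
reports an infinite t with p = 0.

BH adjustment is the step-up rule `q_(i) = min_{j≥i} m p_(j)/j`, capped at
1. DEG selection defaults to `q ≤ 0.05` with no effect-size floor.

## Cell scoring

Score of a signature in a sample = mean of `(rank − 0.5)/G` over its marker
genes, with ascending average ranks within the sample over all `G` genes.
The score lies in (0,1), equals 0.5 for a signature containing every gene,
and is invariant to any strictly monotone per-sample transform. It is a
deliberate transparent surrogate for enrichment-based deconvolution
(ssGSEA-with-calibration style tools): same monotone-in-abundance contract,
none of the spillover machinery; externally curated signatures can be
supplied as GMT. Exact rank monotonicity holds when marker genes cross only
baseline genes as compositions change; when two cell types' markers occupy
the same expression band and decline at different rates, marker-marker
crossings can locally break it — the default gene universe keeps the
baseline bulk dense enough that the own-fraction effect dominates.

Lineage composition per diagnosis group: mean score over the lineage's cell
types and the group's samples, renormalized across lineages to sum to 1.

## Feature engineering cascade

Ratio features are log-scale: on log2 input the ratio of parents a, b is
the difference `a − b`, stored once per unordered pair under the
lexicographic name `a/b` (the reverse orientation is its negation); a
raw-scale mode uses `log2((a+ε)/(b+ε))`, ε = 1e-8. mRNA ratio candidates
default to the 100 most important genes by a single one-vs-rest linear fit
(all-pairs over thousands of genes would be quadratically many and mostly
noise); all cell-type pairs are used.

Cascade stages, in order, each optional:

1. **SD filter** — absolute threshold, or quantile mode keeping the top
   fraction (default 75%) by SD; ties keep the higher SD, then name order.
   Skipped in the mixed-feature workflow (model 2) because mRNA z-scores,
   ratio differences and [0,1] cell scores live on incomparable scales.
2. **Collinearity filter** — features visited in descending-SD order; keep
   a feature iff its max |Pearson r| against the kept set ≤ 0.9 (keeping
   the higher-variance member preserves information). The survivor-set
   invariant (no pair above the bound) is asserted on every cascade run.
3. **Recursive elimination** — standardize features, fit a linear
   one-vs-rest classifier (L2, deterministic primal solver), importance =
   mean |coefficient| across the three class models, remove
   `max(1, ⌈1% of current⌉)` lowest-importance features per iteration (ties
   by name), down to a floor of max(10, 20% of input); stratified 5-fold CV
   accuracy recorded per iteration. Elimination order defines the ranking;
   the procedure is deterministic given data, labels and seed.
4. **Cumulative-importance cut** — normalize the survivors' importances to
   sum 1 and keep the smallest descending prefix reaching 75% mass.

Stage bookkeeping (counts in/out, thresholds, RFE history) is returned as a
selection report and written as JSON.

## Classification

Four families: linear SVM (one-vs-rest, hinge, L2), AdaBoost over depth-1
stumps (50 rounds), random forest (100 trees), and a feed-forward net with
hidden layers 64/32/16 and a 3-unit softmax head trained with
cross-entropy (adam, learning rate 1e-3, batch 32, 100 epochs) — the net is
scikit-learn's multilayer perceptron with exactly this architecture. All
estimators are seeded; same seed, same predictions.

Evaluation: 3×3 confusion matrix (rows true, columns predicted), accuracy,
per-class recall and per-class one-vs-rest AUC computed from continuous
scores (SVM decision margins; class probabilities otherwise) via the
Mann–Whitney U with ties counted 1/2. "Mean accuracy" is the unweighted
mean of the per-cohort test accuracies. Two protocols are reported
separately because real studies are ambiguous about the carve: (A) train on
a pooled stratified 70% (strata = diagnosis × cohort), test on each
cohort's 30% partition; (B) train on cohort 1, test on cohort 2.

## Homeostasis trends

For every ordered cell pair (A,B) the ratio `log2((score_A+ε)/(score_B+ε))`,
ε = 1e-4 (scores live in [0,1]; the offset prevents blow-ups at near-zero
scores and preserves scale-invariance when scaled along with the scores).
A pair is called "up" iff the CON/MCI/AD group medians are strictly
increasing **and** the trend test rejects at α = 0.05; "down" symmetric.
The test is Jonckheere–Terpstra: statistic = sum of pairwise Mann–Whitney
counts over stage-ordered group pairs; exact permutation null for pooled
n ≤ 12, otherwise a normal approximation with continuity correction.
Because the direction is read from the data, the reported p is the
two-sided ordered-alternative value `min(1, 2·min(p_inc, p_dec))`; a
one-sided p in the data-chosen direction would double the false-call rate
(the null simulation in the test suite verifies ≤7% pooled calls at
α = 0.05). BH q-values are attached across all pairs. Pairs are classed
as hematopoietic/hematopoietic, non-hematopoietic/hematopoietic, etc. from
the lineage map.

## Enrichment statistics

Over-representation p is the upper cumulative hypergeometric
`P(X ≥ x) = 1 − Σ_{i<x} C(k,i)C(r−k,s−i)/C(r,s)` for a query of size s from
a universe of r genes with k annotated to the term; the universe is an
explicit required input (no ontology is bundled), term sets arrive as GMT,
and BH runs across terms. The activation z-score over the overlap of a
regulator's expected directions with observed directions is
`z = (N⁺−N⁻)/√(N⁺+N⁻)`; z > 0 predicts activation, z < 0 inhibition, and
an empty overlap is flagged undefined rather than scored.

## Pipeline and determinism

`run_pipeline` executes either workflow from one flat configuration:
model 1 uses DEG-union mRNA features only; model 2 adds cell scores, both
ratio classes, trend analysis and (when term sets are supplied) enrichment
of the optimal mRNA features. Every stage writes plain-text artifacts
(TSV/CSV/GMT/JSON) that round-trip through the package readers, and a
manifest records the configuration hash and a SHA-256 per artifact; the
manifest hash is reproducible bit-for-bit for a fixed configuration. Each
stage is also runnable standalone from prior artifacts through the CLI.

## Numerical and degenerate-input conventions

* Sample with zero total intensity → error naming the sample.
* Zero-variance features: rejected by the collinearity filter and
  standardization (run the SD filter first); label correlation reports
  r = 0 with a flag instead of NaN.
* Degenerate AUC class (no positives or no negatives) → flagged None.
* Trigamma inversion uses asymptotic branches outside [1e-6, 1e7] and
  Newton iteration inside; prior fit falls back to d₀ = 0 with a warning
  when under ten genes have positive variance.
* All tie-breaks (SD order, importance order, top-k ratios) fall back to
  name order, making every selection permutation-invariant.

## Known limitations

* The rank-based cell score is uncalibrated: comparable across samples for
  one cell type, not across cell types (lineage composition renormalizes
  per group, which is a relative, not absolute, view).
* The simulator's strong-signal defaults make the classification ceiling
  100%; they exercise correctness, not difficulty.
* The moderated-t model assumes equal group variances and no covariates;
  multi-factor designs are out of scope.
* Trend calls assume the three-stage ordering is known and fixed; no
  correction is applied for the pair-level multiplicity beyond the reported
  BH q-values.
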