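# Methods

## Problem and probabilistic model

A protein's candidate annotation over a GO DAG G = (V, E) is a binary
vector x indexed by the terms. The True Path Rule (TPR) restricts valid
annotations to ancestrally closed positive sets: no edge may carry a
positive child under a negative parent. Modelling the DAG as a Bayesian
network, the joint density factorizes into per-term conditionals
p(x_g | x_pa(g)) given by a constrained CPT: when min over parents of x is
1 (vacuously so at roots, where θ_g acts as the root marginal), x_g = 1
with probability θ_g; when any parent is 0, x_g = 0 with probability 1.
Inconsistent labelings therefore carry zero probability and the decoder
never has to repair its output.

A consequence worth keeping in mind when interpreting results: terms lying
below a negative parent contribute log 1 = 0 to the log-density, so the
density objective implicitly favours *small* ancestrally closed sets — with
uninformative probabilities the empty labeling is frequently the global
optimum. This shapes several optimizer choices below.

## Objectives

Three interchangeable objectives are scored over consistent labelings:

* `eq1` — the log-density itself.
* `deltal` — Σ_g log p(x_g|θ_g)/p(x_g|θ*_g): per term, log(θ_g/θ*_g) when
  positive and log((1−θ_g)/(1−θ*_g)) when negative, summed over **all**
  terms unconditionally. The CPT-conditional reading (difference of two
  log-densities, in which terms under a negative parent cancel) is
  available via `delta_l(..., conditional=True)`; the unconditional sum is
  the default because the per-term score description defines the objective
  term by term, independent of parent state. When θ = θ* every consistent
  labeling scores exactly 0, so the objective is flat (and multimodal near
  the null); no mitigation beyond the optimizer's restarts is attempted.
* `logitr` — the log-density of the calibrated vector
  logit θc = logit θ* + α (logit θ − logit θ*). α > 0; default α = 2,
  exposed as a parameter. α = 1 is the identity and θ = θ* is a fixed
  point for every α; the map is strictly increasing in θ.

Probabilities are clipped into [ε, 1−ε] with ε = 1e−6 before any log or
logit, since both transforms are undefined at {0, 1}. Priors default to a
flat 0.5 when none are supplied; otherwise they are estimated as the
fraction of proteins whose up-propagated annotation set contains each term.
Terms missing from an input θ matrix are imputed with their prior — the
neutral choice: a zero contribution in either direction under `deltal` and
a calibration fixed point under `logitr`.

## The search

The optimizer is a discrete differential evolution over consistent
labelings. The element-wise OR and AND of two consistent labelings are
consistent (each edge configuration of the result already existed in an
operand), so the four proposal strategies

    S1  R1 ∨ R2 ∨ e            S3  Ri ∨ R1 ∨ R2 ∨ e
    S2  (R1 ∧ R2) ∨ e          S4  (Ri ∧ R1) ∨ R2 ∨ e

never leave the feasible space. R1, R2 are distinct population members
drawn uniformly without replacement from the population excluding the
target Ri; e is a freshly sampled random ancestral subgraph (a uniform
term plus all its ancestors); the strategy is picked uniformly per
proposal. Acceptance is strictly greedy: the candidate replaces Ri only if
it scores higher, so the best score is non-decreasing and plateaus are not
inflated by drift. The printed form of S4 is ambiguous; standard
AND-before-OR precedence is used, with the alternative grouping
(Ri ∧ (R1 ∨ R2)) ∨ e available via `OptimizerConfig.s4_grouping`.

Population size defaults to 2|V| (with a floor of 4 so donor sampling is
well-defined, and cappable through the config for large vocabularies).
Initialization draws each term independently — with probability θ for
`eq1`, the calibrated θc for `logitr`, and logistic(logit θ − logit θ*)
for `deltal` (the logistic of the per-term score difference between the
two label values, which reduces to θ under flat 0.5 priors) — and
up-propagates the draw to a consistent labeling.

Two structural facts about this move set drive the remaining design:

1. Every candidate contains the non-empty subgraph e, so the empty
   labeling can never be proposed — yet under the CPT density it is often
   the optimum. Each initial population therefore seeds one member with
   the empty labeling (the bottom of the consistent-set lattice): it can
   be kept from initialization, and outcompeted when a better non-empty
   solution exists, but would otherwise be unrepresentable.
2. The element-wise AND of all members (the population meet) is
   non-decreasing: every candidate is a superset of intersections of
   members, so once the meet overshoots the optimum no sequence of moves
   can shrink back to it. The run is effectively decided by its
   initialization. Accordingly `evolve` restarts: when the population best
   fails to improve for `plateau_generations` (default 100) consecutive
   generations, a fresh random population is drawn and the search resumes,
   keeping the best-ever labeling across rounds, until the total budget of
   `max_generations` (default 10,000) is spent or `stale_rounds` (default
   10) consecutive rounds end without improving the best-ever score.

With these defaults, retrieval of the exhaustive optimum on the shipped
fixtures (100 uniform probability vectors, flat priors) is at or near
100/100 for both fixture sizes and all objectives; a single
plateau-terminated round without restarts retrieves only ~30% on the
6-term fixture, almost entirely because of the two facts above.

Determinism: all randomness flows through one `numpy` Generator. The
model-level `fit(seed=...)` derives an independent stream per protein by
SHA-256 hashing of the protein identifier with the run seed (kept below
2³¹), so results are bit-reproducible and invariant to protein order.

## Exhaustive oracle

For |V| ≤ 20 (configurable cap), all ancestrally closed subsets are
enumerated by recursion in topological order, branching on a term only
when all its parents are positive — exact pruning, no 2^|V| filtering. The
argmax uses a lexicographic tie-break on the bit vector for determinism.
This is the ground truth for the simulation study and the upper bound the
evolutionary search can never exceed.

## Evaluation and the maxF baseline

Precision is |pred ∩ truth| / |pred|, recall |pred ∩ truth| / |truth| with
truth up-propagated first; F defaults to the harmonic mean (F1), with a
geometric-mean variant behind a flag. Empty predictions score (0, 0, 0)
and are excluded from per-protein macro averages (which run over proteins
with ≥ 1 prediction); proteins with empty truth are excluded and logged.
Root terms are excluded from metrics by default — predicting a root is
vacuous and would inflate precision — includable via flag. Per-term
metrics pool proteins as instances for every term appearing in truth or
predictions.

The maxF baseline thresholds each term's probability at the cutoff
maximizing that term's training F, searching the midpoints between
consecutive distinct observed values plus the minimum (predict-all);
ties go to the smallest cutoff (maximal recall). Terms without positive
training examples get +∞ (never predicted). Because terms are thresholded
independently, maxF output may violate the TPR; the evaluator flags such
proteins and the CLI's `evaluate --lint` fails on them.

## Synthetic data

`random_dag` grows a connected, single-rooted DAG term by term, each new
term drawing 1..max_parents parents uniformly among earlier terms; a
multi-parent term is guaranteed for n ≥ 4 so diamonds are always present.
The two frozen fixture DAGs (6 and 15 terms, generated once at seed 11 and
stored as literal edge lists) are synthetic stand-ins for small benchmark
topologies; retrieval behaviour at these sizes is robust to the exact
wiring.

`uniform_theta` draws i.i.d. U(0,1) probabilities — the simulation
protocol's condition, deliberately uninformative.

`planted_truth_dataset` emulates the structure of real upstream inputs:
each protein's truth is the up-propagation of 1–3 random leaves; at
noise = 0 probabilities are deterministic (1−ε on true terms, ε
elsewhere); for noise ∈ (0, 0.5) they are Beta draws (concentration 30)
whose means sit at 0.5 ± (0.5 − noise)·0.85^depth — the separation decays
geometrically with term depth, mimicking methods that return confident
probabilities for general terms and attenuated ones for detailed terms.
Priors are estimated from the planted truths. What passing tests on this
generator show is recoverability under its independence assumptions
(per-term conditionally independent noise, depth-stationary decay); real
posteriors have correlated errors across related terms and
protein-specific calibration drift, which the generator does not emulate.

## Problem sizes used in the shipped experiments

The retrieval experiments use 100 probability vectors per condition on the
6- and 15-term fixtures; the optimizer-vs-oracle sweep uses 500 random
DAGs of 4–12 terms; the closure check covers 100,000 proposals; the
planted-truth check uses 100 proteins on a 20-term DAG at zero noise and
30 proteins per noise level on a 12-term DAG for the degradation curve
(with a reduced search budget of 1,000 generations / 3 stale rounds, ample
for these separations). These sizes keep each experiment to a few minutes
on one CPU while leaving the estimates' Monte-Carlo error far below the
effect sizes of interest.

## Known limitations

* The restart mechanism recovers global reachability across rounds, but a
  single round remains meet-monotone; pathological landscapes whose optima
  are only reachable through very lucky initializations would need more
  rounds than the default budget.
* Population size 2|V| makes a full-ontology run (thousands of terms)
  expensive; cap it via `OptimizerConfig.population_size` at some cost in
  move diversity.
* maxF requires labelled training data and is included for comparison
  only; no attempt is made to reconcile its inconsistent outputs.
* The package decodes given probabilities; it does not learn θ from data,
  nor recover conditional from marginal probabilities.
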