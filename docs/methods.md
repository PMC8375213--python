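# Methods

## Label model

Measured potencies are treated as draws from a normal distribution centred
on the (unknown) true potency with standard deviation σ, assumed constant
across the potency range (homoscedastic).  Under that assumption the
probability that a compound with measured pActivity *p* is truly active at
threshold *t* is the normal CDF Φ((p − t)/σ), computed in double precision
via `scipy.special.erf`.  σ = 0 is the degenerate step-function case; ties
at the threshold map to the active class, following the usual
"pActivity ≥ threshold ⇒ active" convention (with σ > 0 the value at the
threshold is 0.5 regardless, so the convention only matters for hard
labels).  Stored labels are never clipped; probabilities enter logs only
inside downstream statistics, which guard their own domains.

One σ applies to the whole dataset.  Replicate-variability audits
(`replicate_sd`) are the intended way to choose it: the sample standard
deviation (n−1 denominator) of repeated measurements per compound–target
pair, grouped intra-assay, cross-assay, or within a readout type, with the
median across groups as a robust summary.  The n−1 convention is the
default because the per-group replicate counts are small and the audit is
an estimate of an underlying measurement sd; a population-denominator flag
is provided for comparison with sources that use n.

Putative inactives — compounds assumed inactive without any measurement —
receive Δy = 0 at every σ.  They are the one place where the label model is
deliberately overconfident: no measurement exists from which to quantify
their uncertainty.

## The probabilistic forest

Each training sample carries a class-probability pair (p_A, p_B) =
(Δy, 1 − Δy) and a propagation probability π ∈ (0, 1] (the probability of
reaching the current node).  Node class probabilities are π-weighted
expectations P̄ = Σ π p / Σ π; impurity is Ḡ = 1 − (P̄_A² + P̄_B²); a split's
cost is the π-mass-weighted mean of the child impurities.  A node splits
only when the best candidate strictly lowers the cost below the node's own
impurity (with a 1e−12 float guard); otherwise it becomes terminal and
stores its P̄ pair.  Terminal and internal nodes both store P̄_A — the
internal value serves as a fallback prediction when propagation pruning
removes every branch.

Binary features route value 0 left and 1 right at a fixed threshold of 0.5.
This is a convention, not a fit: binary fingerprints admit exactly one
nontrivial threshold per feature.  Candidate features per node default to
⌈√n_features⌉, trees are grown on bootstrap resamples, and 100 trees are
the default — conventional random-forest settings, all configurable.
Split ties are broken toward the lowest feature id, with ties detected to a
1e−12 tolerance so that mathematically equal costs computed by different
float paths cannot reorder; this makes fitting bit-reproducible for a fixed
seed and invariant to sample order when bootstrapping is off.

Training assumes exact features, so π ∈ {0, 1} during fitting and every
sample contributes to exactly one node per level.  Feature uncertainty
enters at prediction time as an optional per-feature Gaussian sd: a
sample's mass then splits across both branches by Φ((x − 0.5)/sd), branches
whose mass falls below `keep_proba` (default 0.05) are pruned, and the
surviving leaf masses are renormalised so the output probabilities still
sum to 1 exactly.  If pruning removes everything the heaviest single path
is followed instead, so a prediction always exists.  With no feature
uncertainty the floor is inert and each sample reaches one leaf per tree.

With all labels in {0, 1} the weighted expectations equal class fractions
and the cost equals the classical fraction-weighted Gini, so the soft-label
learner fitted on binary labels and the `fit_hard_rf` baseline produce
identical forests for the same seed.  This degeneracy is asserted
tree-for-tree in the tests, and the hard-label mode is additionally checked
for concordance against scikit-learn's `RandomForestClassifier` (an
independent implementation with its own tie-breaking and bootstrap stream,
hence concordance is checked on predictions, not trees).

The primary forest output is the mean over trees of the per-tree
probability Σ π(leaf)·P̄_A.  The fraction of trees voting for each class
and the across-tree dispersion are exposed alongside it
(`predict_detail`) as certainty readouts.

## Benchmarking statistics

Both forests are scored against the *ideal label*: Δy recomputed on the
test set under the test-time (threshold, σ_test).  The per-sample signed
error margin is y_ideal − p.  Two comparison statistics are derived:

* the margin delta (RF margin − PRF margin, identically p_PRF − p_RF; the
  identity is asserted to 1e−12 wherever records are built);
* the relative score, 100·(|e_worse| − |e_better|)/|e_worse|, using the
  **absolute** error of the worse classifier as the denominator — the only
  reading under which the canonical worked examples (50% for 0.75→0.70 and
  25% for 0.85→0.80 at an ideal of 0.65) come out right.  When both errors
  are zero the score is defined as 0.  The formula depends only on the two
  absolute errors, so classifiers erring on opposite sides of the ideal are
  compared by magnitude alone; which classifier improved is recorded
  separately.

Grid summaries are reported per (σ_train, σ_test, ideal-label bin) cell
with the five default bins 0–0.2, …, 0.8–1.0, half-open except the last.
The better algorithm per cell is the one with the smaller mean absolute
margin; exact equality is reported as "tie".  Distribution comparisons use
a one-sample KS test against a normal with the sample's own mean and sd
(reported, not used to gate anything) followed by Welch's unequal-variance
two-sample t-test; when both collections have zero variance the test is
reported as undefined rather than fabricating a statistic.

## Synthetic data generator

The generator emulates a per-target modelling set: `n_active` = 160
measured actives, 300 measured inactives and 100 putative inactives by
default (active:inactive ratio 0.4, typical of curated per-target
corpora), 64 binary features of which 16 are informative, and experimental
noise σ = 0.3 log units — the middle of the 0.2–0.4 range that replicate
audits of public data typically produce.

Latent potencies are drawn per class on the appropriate side of the
threshold from a two-component mixture: a near-threshold component
(half-normal offsets, scale 0.35 log units, weight 0.2) and a uniform far
component over the rest of the 3–8 potency range.  The near component
exists because the marginal regime — compounds whose ideal labels land in
0.4–0.6 — is precisely where soft and hard labels disagree, and the
generator must be able to populate it on demand (`near_threshold_fraction`
measures how well a spec hits a desired marginal mass).  Observed potency =
latent + N(0, σ_experimental); hard labels computed from the *observed*
value therefore flip near the threshold, which is the label noise the
method is designed to absorb.

Informative bits are Bernoulli with a rate that ramps logistically (width
0.5 log units) from the inactive rate 0.15 to the active rate 0.65 as the
latent potency crosses the threshold; remaining bits are background noise
at rate 0.08.  The ramp rather than a two-level class-conditional rate
makes near-threshold compounds structurally ambiguous as well as
label-ambiguous, which mirrors real congeneric series and is what gives
the probabilistic forest something to be better *at*; in the sharp-ramp
limit the mechanism reduces to class-conditional rates.  Putative inactives
are background-rate rows rejection-sampled against the sphere-exclusion
constraint (Jaccard similarity < 0.4 to every active) with a bounded
attempt budget and an actionable error when the budget is exhausted.

What the generator does **not** emulate: real chemistry (no molecular
graphs or SMILES), assay-specific heteroscedastic noise, censored/operand
values, correlated fingerprint bits, or the true distributional shape of
per-target potencies in public databases.  Tests passing on this generator
therefore demonstrate that the algorithms behave as specified under the
stated noise model — not that the same effect sizes will appear on any
particular real corpus.

## Problem sizes and numerical choices

The test suite and examples use datasets of roughly 500–1000 compounds,
50–100 trees and σ grids over {0, 0.4}; these sizes make every property
deterministic to check in seconds while leaving all mechanisms (bootstrap,
feature subsampling, pruning, binning) fully exercised.  The benchmark
trend check uses five fixed seeds and requires the probabilistic forest to
win the marginal bin in at least four, acknowledging sampling variability
in bins that contain few test compounds.  All randomness flows from
`numpy.random.default_rng` seeded per run; CSV floats are written with six
significant digits so reruns are byte-identical.

## Known limitations

* Binary features only; continuous descriptors would need threshold search
  in the split routine.
* Two classes only; the label model is inherently binary (active vs not).
* Training does not propagate feature uncertainty (π ∈ {0,1} while
  fitting); the prediction-time contract is the documented hook.
* Putative inactives carry zero label uncertainty by construction, which
  can make a forest overconfident on chemistry far from measured space —
  the audit of that effect is the purpose of the sphere-exclusion
  comparison utilities, not something the learner corrects by itself.
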