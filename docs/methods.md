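# Methods

## Screen filtering and orthologue translation

A genetic-interaction screen row carries a gene pair, an interaction score ε
and a p-value. Synthetic-lethal calls use inclusive cutoffs,
ε ≤ −0.08 and p ≤ 0.05 by default; both are parameters of
`filter_negative_interactions`. Inclusivity at the boundary is a
convention choice (screens publish cutoff values, not strictness), made
configurable by passing different cutoffs. Gene identifiers are upper-cased
on construction and unordered pairs stored lexicographically, so duplicate
rows and reversed pairs collapse deterministically with merged provenance.
A p-value outside [0, 1] is a record-level validation error naming the
offending rows. Filtering is monotone: relaxing either cutoff can only add
pairs.

Orthologue translation expands each yeast pair to the full Cartesian
product of its two genes' human orthologue sets — no pruning rule is
imposed on one-to-many orthology. Two combination rules over the five
supported orthology sources are provided: `union` (any single source
suffices; the default) and `min_sources k` (an assignment must be present
in ≥ k sources). Neither is privileged; provenance records the supporting
sources per assignment either way. Self-pairs (both yeast genes mapping to
the same human gene) are discarded; a yeast pair that produces no human
pair is counted in an `untranslatable` tally rather than raising.

## Pair features

Each candidate pair is described by:

* **Dice coefficients** per annotation namespace, 2|A∩B|/(|A|+|B|) over the
  genes' term sets. Two empty sets score 0, not 1: the absence of
  annotation is no evidence of shared function. A gene missing from a
  corpus contributes an empty set.
* **Mean node measures** over the two endpoints on an undirected, unweighted
  interaction network: degree, normalised betweenness centrality, local
  clustering coefficient and closeness centrality (with the
  reachable-fraction scaling on disconnected graphs). The set of measures
  is a package decision recorded in the feature manifest, so any
  experiment's feature table is self-describing. The network itself is
  caller-supplied (any interactome edge list); node measures are computed
  once per graph and cached, since betweenness and closeness are
  whole-graph quantities.
* **Shortest path**: the unweighted geodesic length, with a `connected`
  flag. A disconnected (or absent) pair receives the finite sentinel
  `n_nodes + 1`, which is strictly larger than any realisable geodesic and
  keeps tree models monotone in "farther apart".

A gene absent from the network is treated as an isolated node (all measures
zero, disconnected) and logged, not raised. Features are symmetric in the
pair by construction.

## Classifier

A random forest (default 500 trees, unlimited depth, √p features per split)
consumes the feature vectors. Screens provide only positives, so the
negative class is drawn uniformly at random from non-positive unordered
gene pairs in the universe, default ratio 1:1 — a standard construction for
interaction inference, recorded in the model metadata as an assumption
rather than a fact about biology. The train/test split is stratified, 25%
held out by default; AUC, accuracy and confusion counts are computed only
on the held-out pairs at the recorded decision threshold (default 0.5).
Every stochastic step (negative sampling, splitting, forest construction)
takes an explicit seed and runs single-threaded, which makes the entire
train→predict path bit-reproducible; model metadata retains the manifest,
hyperparameters, seed and class counts needed to retrain identically.
Prediction refuses feature tables whose columns do not match the model's
manifest, naming the offending columns.

## Drug-combination mining

Treatment combinations are MeSH-tagged drug sets from clinical trials or
clinical practice. Two queries run against a predicted SL set:

* **Clinical SL pairs**: unordered drug pairs co-occurring in at least one
  practice combination whose target sets *span* an SL pair — one drug must
  hit one side and the other drug the other side; both drugs hitting the
  same gene does not qualify.
* **Candidate (rearranged) pairs**: one drug from each of two different
  combinations, same indication by default (a cross-indication mode
  exists), that do not already co-occur in *any* existing combination —
  trial or practice, regardless of other regimen members — and whose
  targets span ≥ 1 SL pair. Every member of a multi-drug regimen is an
  eligible donor. Duplicates across combination pairs merge with full
  provenance.

The low-toxicity filter keeps pairs where *both* drugs carry the
`non_cytostatic_low_toxicity` annotation. Toxicity class is an explicit
per-drug input column, never inferred; a missing annotation either raises
(strict, default) or drops the pair with a warning (lenient). All outputs
are canonically ordered, so results are invariant to input row order.

## Median-effect fitting and combination indices

Single-agent viability (fraction of vehicle control; values > 1.05 trigger
a normalisation warning) is converted to fraction affected fa = 1 − v.
Replicates at the same dose are averaged before fitting. The median-effect
model fa/fu = (d/Dm)^m is fit by ordinary least squares on the linearised
form log(fa/fu) = m·log d − m·log Dm, requiring ≥ 3 distinct doses; the
slope is m, Dm = exp(−intercept/m) is the IC50, and the line's Pearson r is
reported as fit quality. fa values of exactly 0 or 1 are clipped into
[ε, 1−ε] with ε = 0.005 (configurable) so the logit is defined; clipping
emits a warning. All-identical fa values are a degenerate-fit error.

The combination index uses the mutually exclusive two-term form
CI = d1/Dx1 + d2/Dx2 with Dx_i = Dm_i·(fa/(1−fa))^(1/m_i); the
non-exclusive third term is deliberately omitted, following the common
two-term convention. CI is symmetric in drug order and strictly decreasing
in fa for m > 0. The synergy call applies an additivity band
|CI − 1| ≤ 0.05 (configurable) before declaring synergy or antagonism, so
fit noise at CI ≈ 1 is not over-interpreted. Fits with m ≤ 0 are rejected
for CI computation.

## Synthetic-data generators

Each generator is a pure function of a `GeneratorConfig`; per-generator
pseudo-random streams are derived from the master seed plus a fixed offset,
so regenerating one input leaves the others untouched, and two runs with
the same config are byte-identical. Planted truth objects are returned
alongside the data, never re-derived from it.

Defaults, and what they emulate:

* **GI screen** — 1,200 interactions over 80 yeast genes, 10% planted SL
  pairs with ε ~ N(−0.30, 0.05²) and p ~ U(0, 0.05); null pairs
  ε ~ N(0, 0.03²), p ~ U(0, 1). The planted mean sits well over two
  standard deviations below the −0.08 cutoff (configs that violate this are
  rejected), so the standard filter recovers essentially the whole planted
  class; the occasional null pair clears both cutoffs, which is why
  precision is high but not exactly 1.
* **Orthology** — 85% of yeast genes covered, 1 + Poisson(0.3) human
  orthologues each, each assignment supported by a random subset of the
  five sources.
* **Annotations and interactome** — 4 namespaces × 50 terms, 4 baseline
  terms per gene, an Erdős–Rényi graph at edge probability 0.03 over 200
  human genes. With probability `dice_signal_strength` (default 0.9) an SL
  pair shares 5 extra terms per namespace and a direct edge. Strength 0
  makes SL and null pairs exchangeable — the null-control corpora.
* **Classifier corpus** — 400 pairs, half planted SL, over the human gene
  universe.
* **Drug universe** — 3 planted clinical practice pairs and 4 planted
  rearrangeable candidate pairs (2 of them low-toxicity) over gene-disjoint
  SL pairs, padded with filler drugs and combinations whose targets avoid
  all SL genes, so the mining output equals the planted truth exactly, by
  construction.
* **Plates** — median-effect truth Dm = 1 and 4 µM, m = 1 and 1.5, a
  two-fold seven-dose ladder centred on each Dm, triplicate wells with
  Gaussian noise σ = 0.02 on viability (plate-reader-scale noise).
  Combination points are constructed on the CI identity at chosen fa
  levels: d_i = c·split_i·Dx_i(fa) gives CI = c exactly, with c = 1 for the
  additive scenario and c < 1 (default 0.5) for the synergistic one.

What the generators do *not* emulate: the empirical score distribution of
real SGA screens, correlated annotation structure (term hierarchies,
namespace redundancy), scale-free interactome topology, polypharmacology
beyond a few targets per drug, and plate artefacts (edge effects, drift).
Passing tests therefore demonstrate that the pipeline's logic recovers
planted structure under controlled conditions, not that the classifier's
absolute performance transfers to real databases.

## Problem sizes and tolerances

Test and acceptance runs use deliberately small instances: screens of
~1,200 rows, graphs of ≤ 200 nodes (≤ 8 for the exhaustive
path-enumeration oracles, whose cost is exponential), 400-pair classifier
corpora, 30-drug universes, 200-replicate noise studies. Noiseless
median-effect recovery is checked to 1e−9 relative error (the
linearisation is exact); CI identities to 1e−6; noisy Dm recovery as a
median within 5% of truth; classifier bounds as AUC > 0.8 (signal) and
mean AUC within 0.5 ± 0.1 over 10 seeds (null).

## Known limitations

* The classifier cannot be compared against any published fitted model —
  its training corpus here is synthetic — so its outputs are demonstrations
  of the pipeline, not biological predictions.
* Union-mode orthology plus full combinatorial expansion deliberately
  over-generates human pairs; `min_sources` trims it, but no attempt is
  made to weight sources by reliability.
* The rearrangement novelty check treats any co-occurrence in any regimen
  as "already combined", which is conservative for regimens where the two
  drugs never act concurrently.
* The two-term CI assumes mutually exclusive drug action; mechanistically
  non-exclusive pairs would need the third term this package omits.
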