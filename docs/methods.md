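# Methods

## Model overview

`seqppi` treats protein–protein interaction (PPI) prediction as binary
classification of protein *pairs* described solely by sequence-derived
composition statistics. The pipeline is: per-protein descriptors →
mean/SD discretization → pair encoding under a nominal attribute schema →
instance refinement → class balancing → bagged decision-tree ensembles →
a combined probabilistic scorer. Each stage is exposed as a library
function and a CLI subcommand; every stage is deterministic given its seed.

The central modeling assumptions are:

* the propensity of two proteins to interact carries a signal in their
  global amino-acid composition (not in positional or structural features —
  alignment, domains and motifs are deliberately out of scope);
* that signal survives coarse discretization of each descriptor into four
  bands around the training mean;
* interaction is symmetric, so a pair attribute built from the same
  descriptor on both proteins must not depend on protein order.

## Descriptors and discretization

The *frequency* set holds 20 values, 100·N_A/N per amino acid, ordered
alphabetically by one-letter code (a fixed order chosen for reproducible
serialization). The *composition* set holds 21 values: for each of seven
physicochemical properties, every residue falls in one of three groups and
the three group percentages are reported. The property partitions ship in
`src/seqppi/data/ctd_groups.yaml` using the standard three-group CTD
divisions (hydrophobicity, normalized van der Waals volume, polarity,
polarizability, charge, secondary structure, solvent accessibility). The
file is user-replaceable; the loader enforces that each property's three
groups partition the 20-letter alphabet exactly.

Discretization fits a mean (`avg`) and a *sample* standard deviation
(`stdv`, n−1 denominator) per descriptor on the training proteins.
Bin rules: A if x < avg−stdv; B if avg−stdv ≤ x ≤ avg; C if
avg < x ≤ avg+stdv; D if x > avg+stdv. Two conventions had to be fixed:

* the boundary x = avg−stdv is not assigned by the strict-inequality
  formulation of the low/moderate bands; it is placed in B (moderate closed
  below), preserving the strict "low" band exactly;
* with stdv = 0 the rules collapse to A below the mean, B at the mean, D
  above; C is unreachable.

The fitted model is frozen: test-time discretization always reuses the
training statistics, a property asserted by the test suite.

## Pair encoding

Six schemas: F (400 = 20×20 ordered frequency combinations), F′ (20
symmetric ones), C (441), C′ (21), F+C (841), F′+C′ (41). Symmetric
attributes (same descriptor on both proteins) are standardized by sorting
the two bin letters (BA→AB, …, DC→CD), so their value domain is the 10
unordered codes and pair order is irrelevant by construction. Asymmetric
attributes (in F, C and their concatenations) are *not* reordered —
standardization applies to symmetric attributes only — so F-schema
instances depend on the input order of the two proteins; users of the
asymmetric schemas should fix a pair orientation convention upstream.
Attribute names follow `X~Y` (descriptor of protein 1 ~ descriptor of
protein 2). The default schema is F′, the smallest adequate representation.

## Instance refinement and balancing

Three filters run before training: (1) records identical under unordered
pair comparison (and equal label) collapse to their first occurrence;
(2) any pair recorded with both labels is removed entirely; (3) proteins
whose full descriptor vector duplicates another protein's are removed
— *all* members of an identical-feature group, not keep-one — together with
every pair referencing them. Self-pairs are legal instances.

Balancing with P positives and N negatives (P ≥ N): positives are shuffled
(seeded) and cut into k = ⌊P/N⌋ blocks of N, each joined with the complete
negative set; a non-zero remainder r = P − kN forms one further dataset of
r positives and r negatives sampled uniformly without replacement (these
negatives necessarily overlap the full sets). Every positive appears in
exactly one dataset. Label shuffling permutes each dataset's existing label
multiset over its instances — preserving class counts exactly — rather than
drawing labels independently.

## Tree learning

The learner is a C4.5-style multiway categorical tree:

* split criterion: gain ratio (information gain / split information), with
  candidates restricted to attributes whose gain is at least the average
  gain of the admissible candidates — the classic guard against
  many-valued attributes with inflated ratios;
* a split is admissible only if at least two branches receive the minimum
  leaf count (default 2) and both gain and split information are positive;
* ties in gain ratio break toward the earliest attribute in schema order,
  making growth fully deterministic;
* one child per domain value; values absent from the local training
  partition become leaves carrying the parent's class distribution, which
  also serves as the prediction-time fallback for locally unseen values;
* optional pessimistic pruning (default on, confidence 0.25) replaces a
  subtree by a leaf when the leaf's upper-confidence error bound does not
  exceed the subtree's plus 0.1, using the standard binomial/normal
  pessimistic-error estimate. Subtree raising is not implemented; with the
  shallow trees these nominal domains produce, replacement-only pruning is
  sufficient in practice.

Bagging draws `n_bags` (default 10) bootstrap resamples of the training
dataset and averages the member trees' leaf probabilities. The combined
model averages the per-dataset bagged probabilities with equal weights —
the simplest rule consistent with a probabilistic ensemble score. The
decision rule rounds the score to two decimals before thresholding, so
exactly 0.50 is attainable and yields "unclassified"; the raw score is also
reported, always on the interaction-score scale (a no-PPI confidence c is
reported as 1 − c).

## Evaluation

Cross-validation is stratified (10 folds by default; the balanced datasets
make stratification nearly neutral, but it stabilizes small-fold variance)
and metrics are pooled over the held-out predictions of all folds rather
than averaged per fold. Reported metrics: per-class precision and recall at
the 0.5 threshold, and one model-level rank-based AUC for the interaction
class (ties count one half); undefined ratios (empty denominators) are
flagged as missing rather than coerced to 0. Feature-set comparisons apply
the two-sided Mann–Whitney U test to each metric's distribution across the
per-dataset reports, using exact enumeration for tie-free groups of at most
8 and the tie-corrected normal approximation otherwise, with significance
reported at 0.05.

## Synthetic data

The generator emulates a desk-scale study: by default 2,000 proteins of
length 100–600 with i.i.d. residues from configurable weights (uniform by
default). Labels come from one of three regimes:

* **planted rule** — interaction is determined by whether the standardized
  code of one symmetric discretized attribute (default N~N, accepting
  {AA, AB, BB}) lies in an accepting set, with independent label flips at
  rate ε ∈ [0, 0.5). Because the rule lives exactly in the tree learner's
  hypothesis space, noise-free recovery should be essentially perfect, and
  the test suite requires the planted attribute to root ≥ 90% of the
  ensemble models with held-out AUC ≥ 0.95;
* **continuous rule** — labels threshold the *raw* summed descriptor value,
  a boundary that cuts through bin interiors, for harder approximate
  recovery;
* **null** — labels independent of all features, the analogue of the
  label-shuffled control; trained models should score at chance
  (AUC ≈ 0.5).

What these simulations do **not** emulate: real interactome topology
(degree distributions, hubs, modules — pairs are sampled independently),
residue autocorrelation along sequences, homology between proteins, or
database biases in positive/negative collection. Passing the synthetic
suite therefore demonstrates correctness of the machinery and
recoverability of composition-level signal, not field performance on
biological corpora.

## Problem sizes and numerical choices

The test suite and the acceptance script run entirely on synthetic data at
these scales, chosen to exercise every code path at full fidelity where the
quantity is exact (schema arithmetic, the 41,975/1,390 balancing layout)
and at one balanced dataset of 2,780 instances for the stochastic
negative-control measurement (ten shuffle seeds, 10-fold CV, 10 bags —
1,000 trees per measurement). Floating-point conventions: entropies in
bits with 0·log 0 = 0; descriptor percentage sums are checked to 1e−6;
gain and split information below 1e−12 are treated as zero; random streams
are numpy `default_rng` with explicitly derived seeds, so every artifact is
reproducible from its manifest.

## Known limitations

* The asymmetric schemas' dependence on input pair order is inherent to
  their definition; only the primed schemas are order-free.
* Pruning implements subtree replacement only (no raising).
* The grouping-table defaults are a standard CTD partition; swapping in a
  different partition changes the composition descriptors and any model
  trained on them.
* The combined model weights all constituent datasets equally regardless of
  the remainder dataset's smaller size.
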