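# Methods

This note records the modelling choices behind the package, the defaults
and their rationale, and what the synthetic benchmark does and does not
demonstrate.

## The embedding

Seven hashed binary fingerprints of 1024 bits each are stacked as channels
of a 7×1024 tensor, in the fixed order: RDKit path, Morgan r=3, atom-pair,
torsion, layered, feature-Morgan r=2, ECFP4 (Morgan r=2).  The three
circular channels are deliberately non-redundant: the plain Morgan channel
uses radius 3 with connectivity invariants, ECFP4 uses radius 2 (diameter
4), and the feature-Morgan channel uses radius 2 with pharmacophoric atom
roles (donor/acceptor/aromatic/polarity), the FCFP construction.  Exact
radii and path bounds are configuration with documented defaults
(`FingerprintConfig`), not claimed reproductions of any external setup; all
fingerprinting is delegated to RDKit's generators, and a test cross-checks
every channel against RDKit's independent legacy entry points.

Bits are remapped 0 → −1.  The map is information-preserving (channel
popcounts are recoverable as Σ(v+1)/2, asserted in tests) and avoids
feeding mostly-zero inputs to the first convolution, which would otherwise
bias its units toward their bias values.  Tensors are a pure function of
the canonical SMILES: two spellings of one molecule embed identically.

## Architecture

The classifier consumes the 7×1024 tensor as a one-dimensional, 7-channel
signal.  Nine depthwise-separable convolution layers (per layer: one s×1
spatial kernel per input channel, then a 1×1 cross-channel kernel with one
bias per output filter) use kernel size s = 13 and the width schedule

    32, 64, 64, 512, 1024, 1024, 512, 64, 16

drawn from the {1024, 512, 256, 128, 64, 32, 16} filter grid: widths expand
as resolution falls, then compress to 16 channels before the head.  The
first five layers downsample by stride 2 (1024 → 32 positions), the flatten
yields 16·32 = 512 features, and a 64/32/32 ReLU perceptron ends in 20
independent sigmoid units (multi-label: row probabilities are not
constrained to sum to 1).  Activations after every conv layer are PReLU
with the slope fixed at α = 0.25 (learnable α is available behind a flag
and is then included in the parameter count).

This configuration has exactly **2,252,959** trainable parameters
(`count_parameters`, asserted against the built network).  The kernel size,
downsampling points and width ordering were fixed together so that the
analytic count lands on that reference value with all widths on the grid
and a unimodal (expand-then-compress) shape; `count_parameters_classical`
gives the cost of full convolutions at the same shapes, and the separable
factorization reduces per-layer weights by a factor approaching
1/s + 1/f (property-tested).

Downsampling uses strided depthwise convolution rather than pooling.  This
keeps every layer of the network either linear or elementwise, which makes
the attribution pass exactly conservative (below); it is also the standard
choice in modern separable-convolution architectures.

## Training

Mean binary cross-entropy over all outputs, Adam (default learning rate
1e−3, batch 32 — midpoints of the usual [1e−5, 1e−1] and [8, 64] search
ranges), early stopping on validation loss with configurable patience, and
best-validation checkpointing.  The sigmoid and the loss gradient are fused
for numerical stability.  Mini-batch order derives from the training seed,
so recorded histories are bitwise reproducible given data, config and
initial weights.  Divergence to a non-finite loss aborts with a
diagnostic.  All tensor math is float64 NumPy; at the desk scales used in
the tests (≲ 5,000 molecules, reduced architecture) training runs in tens
of seconds on one CPU core.

## Curation

* **Thresholds.**  IC50/Ki: < 1 μM active, > 10 μM inactive, the closed
  band [1, 10] μM ambiguous and excluded downstream — forcing weak binders
  into either class is the main mislabeling risk.  Kd: a single cutoff
  (default 7 μM, ≤ is active).  Multiple records for one (target,
  parameter) are combined by geometric mean, the natural average for
  log-distributed potencies; across parameters the precedence is
  IC50 > Ki > Kd.  A target with no record yields *no label*, distinct from
  inactive.
* **Elbow threshold.**  1-D k-means (scikit-learn, 10 restarts under the
  seed) for k = 1..k_max; WCSS is recomputed explicitly from centroids and
  assignments.  The elbow is operationalized as the k maximizing the
  discrete second difference of the WCSS curve.  At k = 2 the reported
  threshold is the midpoint between the two cluster boundary points (max of
  the lower cluster, min of the upper), which tests verify against the
  exhaustive 1-D two-cluster optimum.  All-identical inputs are a
  degenerate-input error (WCSS = 0 at k = 1, no elbow).
* **Property filter.**  Keep conditions: MW > 100, C > 10, N > 2, O > 2,
  ≥ 1 aromatic ring.  These are *retention* criteria for
  screening-relevant molecules; rejected counts are logged per criterion.
* **Dissimilarity selection.**  Max Tanimoto (ECFP4) against all references
  must lie in [lo, hi] (default [0, 0.15]); output deduplicated by
  canonical SMILES.  Two all-zero fingerprints have T = 1 by convention
  (identical, hence never "dissimilar").
* **Splits.**  Stratified 80/10/10 by exact label pattern, inactive count
  = R × (least-abundant active class), sampled and permuted under one seed;
  partitions are disjoint by molecule id.

## Metrics

EF(x%) = TP / (N_active · x/100) with slice size round(n · x/100),
descending stable sort (ties broken by input order).  Reported EFs round to
the nearest integer, matching the convention of published screening tables;
the raw value is always carried alongside.  Note the saturation regime:
when a target's actives P exceed the slice size, EF is bounded by
slice/(P·x/100) no matter how good the ranking — the TP/P pair disambiguates
such cases.  MCC returns 0 on zero margins; its magnitude equals √(χ²/n),
cross-checked against an independent χ² computation.  AUC is the
rank-sum statistic with average ranks for ties (cross-checked against
scikit-learn).  Threshold metrics (accuracy, sensitivity, F1, MCC) use a
fixed 0.5 cutoff; per-target loss is the binary cross-entropy restricted to
that target's output unit.

## Attribution

Relevance is backpropagated with the rescale rule: linear layers
(convolutions, dense, flatten) pass multipliers through their transpose;
elementwise nonlinearities (PReLU, ReLU, sigmoid) multiply by
(f(x) − f(r)) / (x − r) against the reference activation r, falling back to
the derivative when |x − r| < 1e−9.  Because the network contains only
linear and elementwise layers, Σφ = t − t₀ holds to floating-point
precision for every single-reference attribution, and therefore against the
mean output of a reference set after averaging.  The default background is
a seeded random sample (100 by default in the pipeline) of training
inactives — the natural "null molecule" population in a screening context;
the package does not claim any particular reference set matches an external
setup.  Binning averages contiguous 16-bit groups (64 bins per 1024-bit
channel) and conserves totals exactly.  Per-target summaries report both
mean |φ| (used for ranking channels) and signed mean φ; a channel is
flagged non-contributing when every bin-level mean is below a configurable
epsilon (default 1e−6).

## Synthetic data

Actives for target t contain scaffold t — one of twenty fused
heteroaromatic cores (quinoline, quinazoline, indole, purine, …) validated
to be pairwise non-substructures of each other — decorated with 1–3 random
small fragments joined by single bonds; inactives are assemblies of the
fragments alone, and since single-bond attachment cannot create fused ring
systems they provably contain no scaffold.  Annotations are log-normal
IC50s: median 0.05 μM for actives (clipped below 1 μM) and 50 μM for
inactives (clipped above 10 μM), consistent with the curation thresholds; a
label-flip probability adds noise and an ambiguous 1–10 μM band when
enabled.  Generation is deterministic under the seed.

The recovery benchmark runs 2 targets × 200 actives at 1:20 imbalance
(4,400 molecules) through curation → embedding → reduced model (3 separable
layers, widths 8/16/16, strides 4/4/2, one 32-unit hidden layer) → metrics,
and requires per-target AUC ≥ 0.95 and EF@1% ≥ 20 on the test split.  With
20 test actives per target and a 4-molecule 1% slice, EF@1% = 20 demands a
*perfect* top-4 — the stratified split is what makes the bound attainable
at all.  Passing this shows the pipeline can extract a clean substructure
signal end-to-end; it does not show performance on real screens, where
activity is not a single-substructure property, actives are chemically
diverse, and label noise is structured rather than independent.

## Known limitations

* The full 9-layer configuration is expensive to train in pure NumPy; it
  is built and counted in tests, while training exercises reduced
  configurations of the same layer family.
* Bit collisions at 1024 bits are accepted as-is (binary fingerprints, no
  counts).
* No 3D information, tautomer/protomer handling, or learned embeddings;
  salt stripping and charge neutralization are available but off by
  default.
* The attribution's exactness argument covers this package's layer set;
  adding non-elementwise nonlinearities (e.g. max pooling) would break the
  exact conservation property.
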