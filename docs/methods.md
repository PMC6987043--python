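# Methods

## The model

The package classifies molecules as active/inactive from rendered images of
their 3D structure. The premise is that a molecule's shape — conformation,
size, substituent placement — carries activity-relevant information that a
convolutional or dense image model can extract without descriptor
engineering. Each molecule is depicted as a ball-and-stick model and
photographed from a cube of camera angles; the classifier scores every
snapshot, and the **median** of a molecule's per-image probabilities is its
representative score. Median (not mean) aggregation is robust to a minority
of uninformative viewing angles; for even image counts (the 8-image case is
the common one) the median is the mean of the two central values.

## Structure cleaning

Nine cleaning rules combine a protonation treatment with a coordinate
generator. The protonation heuristics are rule-based:

- *neutralize*: anions are protonated and cations deprotonated wherever a
  proton can be added/removed (charge-balancing hydrogens adjusted).
- *dominant* (pH-7 form): carboxylates stay anionic and aliphatic ammonium
  stays cationic; all other charges are neutralized. This is an open
  functional analog of commercial "wash" implementations, not a
  bit-compatible port — outputs carry `analog`/`cleaning_rule` provenance so
  the distinction is never lost.

Coordinates come from (a) a 2D depiction layout with z ≡ 0, (b) ETKDG
distance-geometry embedding refined with MMFF94, or (c) a second,
deliberately independent pathway (random-coordinate DG embedding refined
with UFF) standing in for an external 3D generator. Both 3D pathways are
deterministic under a seed. Explicit hydrogens are added before embedding
and kept for rendering.

## Rendering

Orthographic projection, one directional light plus an ambient term
(0.35), z-buffered spheres and cylinder sticks:

- Rotation grid: per axis the angles are {kθ : kθ < 360°}, i.e.
  ceil(360/θ) values — the rule forced by the published picture counts
  (240° and 300° both give 8 images). Rotations are extrinsic,
  x-then-y-then-z, about the molecule centroid; the convention is covered by
  a rotation-consistency property test.
- Scale: the molecule's bounding sphere (centers + sphere radii) fills
  ZF% of the frame half-width; default ZF = 100.
- Atom spheres: AT% of the element's van der Waals radius (Bondi values);
  default AT = 25, CPK colors. Bond sticks: radius BR mÅ (default 150)
  mapped through the same world-to-pixel scale.
- Bond inference for bondless inputs: bond iff
  MBD < d(i,j) < BT·(r_cov,i + r_cov,j), defaults MBD = 0.4 Å, BT = 1.25.
- Output: 8-bit RGB PNG without alpha, 256 px default, encoder fixed
  (filter none, zlib level 6) so identical inputs give byte-identical
  files. Six named backgrounds: black/white/red/yellow/green/blue.

ZF/AT/BR/MBD/BT defaults are this package's documented choices; the renderer
is a functional analog of Jmol-style depiction, not pixel-compatible with
it.

## Split design

Scores 40–100 are active, 0–39 inactive (the upstream three-class grouping
0 / 1–39 / 40–100 collapses to this binary rule). Molecules are sorted,
shuffled under the seed, and dealt round-robin into N = Rt + Rv + 1 groups;
fold *f* uses group (f mod N) as test and splits the remaining groups
Rt : Rv into training and validation in cyclic order. Folds default to
min(10, N) — ten rotating test groups at 5:5:1 — and which 10 of 11 groups
serve as test sets is this package's rotation convention. Stratification by
class within the shuffle is on by default (safer under ~9:1 imbalance) and
switchable off. Splits are by molecule; the image-folder writer places all
of a molecule's snapshots in that molecule's split, and tests assert zero
molecule-level leakage in every fold.

## Training

Default 30 epochs; per epoch the harness records train loss, validation
loss (two-class cross-entropy) and validation accuracy, and the reporting
model is the epoch with minimum validation loss, earliest on ties. The
backbone is a named-registry entry. The default, `mlp-small`, is a
single-hidden-layer (64-unit) network over 24×24 RGB pixel vectors
standardized on training statistics — sized so a full cross-validation run
takes CPU seconds-to-minutes; a large pretrained convolutional network can
be registered under another name and used by the identical harness.
Solvers: SGD (momentum 0.9), NAG, Adam; default SGD with learning rate
0.01, batch size 16. No augmentation and no loss re-weighting — class
imbalance is handled by stratified splitting. Runs are deterministic under
the seed (seeded init and seeded minibatch order), and the serialized model
artifact reloads with identical predictions.

## Evaluation

Positive prediction at probability ≥ cutoff (boundary inclusive). The
cutoff maximizing balanced accuracy over all midpoints of adjacent distinct
scores is used when a cutoff must be chosen (equivalent to Youden's J;
lowest such cutoff on ties), selected on validation predictions so the test
set never influences it. MCC is computed with the square root over the
denominator product — the standard definition. Metrics with zero
denominators are reported as undefined (`None`), never as 0. ROC AUC is the
Mann–Whitney rank statistic with half-credit for ties and is verified
against a brute-force pairwise oracle. Run comparisons use the two-sided
Mann–Whitney U test (exact for small tie-free samples) with Bonferroni
correction Pc = min(1, m·p), and difference-of-means intervals are Welch
two-sample t intervals. All metrics are reported on the 0–1 scale,
including validation accuracy.

## Synthetic benchmark

The generator emulates the one property the method fundamentally relies on:
a geometric difference between classes that is visible in rendered images
and in descriptors. Actives are carbon chains ~6 atoms longer than
inactives (or rings, in the `ring_vs_chain` variant), with 0.06 Å
coordinate jitter to individualize conformers; scores are 0/100 so the
binarization threshold reproduces the intended labels, and label noise
flips scores at a configurable rate. It does **not** emulate real assay
noise, chemical diversity, activity cliffs, or the ~9:1 class imbalance of
screening libraries — so a passing benchmark shows the pipeline's machinery
(rendering → split → training → aggregation → metrics) is sound and
leak-free, not that any particular real-world accuracy is attainable.

Problem sizes in the tests and the acceptance script (16–24 molecules per
class, 96-px renders, Rt = Rv = 1 with 2 folds, 5 seeds) are the package's
desk-scale defaults, chosen so a full run completes in well under a quarter
hour on one CPU. The permutation control is summarized as the **median**
over seeds: with test sets of a few dozen molecules the per-seed null AUC
has standard deviation ≈ 0.1, so a per-seed band would be dominated by
sampling noise rather than by the property being checked (the same
median-over-seeds summary used for the true-label benchmark).

## Known limitations

- The protonation heuristics cover common charge patterns, not full
  tautomer/protomer enumeration.
- The renderer is not pixel-compatible with Jmol; absolute pixel values are
  implementation-defined (only the contracts — determinism, background,
  geometry/background separation, rotation consistency — are guaranteed).
- The default backbone is deliberately small; results on real libraries
  will depend on registering a stronger backbone.
- Deduplication of input libraries is limited to exact-id uniqueness;
  stereoisomer/salt resolution is out of scope.
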