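# Methods

`subloc3d` classifies the subcellular localization pattern of a tagged
protein from a two-channel 3-D fluorescence image of a single cell
(channel 0: nuclear reference stain, channel 1: tagged protein), and
augments the image evidence with knowledge-graph information derived from
Gene Ontology (GO) annotations.  This note records the model, the
synthetic data it is validated on, the numerical choices, and the designed
experiments, in enough detail to reproduce or modify any of them.

## The classification model

**Dual-branch encoder.** Two residual convolutional stacks process the
cell in parallel: a 3-D stack on the normalized volume and a 2-D stack on
its maximum-intensity z-projection.  Each residual block is
conv(3)–BatchNorm–ReLU–conv(3)–BatchNorm with a 1×1 projection skip
whenever channels or stride change, ReLU after the sum, and a stride-2
downsampling in the first convolution of the block.  Channels double per
block, capped at eight times the base width.  Global average pooling ends
each branch.  The 2-D projection is cheap and high-contrast (puncta and
shells survive a max projection well); the 3-D branch retains depth
structure such as basal adhesions or the z-extent of the nuclear interior.

**Adaptive gated fusion.** With branch features `f3d` and `f2d`, an
elementwise gate `g = sigmoid(W [f3d; f2d])` mixes the branches,
`g ∘ f3d + (1−g) ∘ f2d`, and a fully connected layer produces the fused
image feature (`fused_dim`, 768 in the full-scale configuration, 128 in
the desk-scale default — see *Desk-scale defaults*).

**Heads.** The classifier concatenates the fused feature with the
protein's knowledge feature (after a linear adapter to `knowledge_dim`)
and applies one sigmoid per class — localization is multi-label.  A
separate softmax head predicts the protein identity of the cell over the
N training proteins.

**Inputs.** Volumes are min–max normalized to [0, 1] per channel per cell
before encoding, which removes acquisition scale; the network is exactly
invariant to per-cell intensity rescaling.

## Losses

All logarithms are natural; probabilities are clamped at `eps = 1e-12`
inside logarithms, so every loss is finite on the closed interval [0, 1].
Per-sample losses are averaged over the batch.

**Classification (ASL + confidence weights).** For class j with label
y_j, prediction p_j, margin m and focusing exponent r:

    L_slc = (1/C) Σ_j α_j [ −y_j ln p_j − (1−y_j) (p_j⁻)^r ln(1 − p_j⁻) ],
    p_j⁻ = max(p_j − m, 0)

Defaults r = 4, m = 0.05.  The asymmetric negative term ignores easy
negatives (p ≤ m contributes exactly zero) and down-weights the rest by
(p⁻)^r, so positives and hard negatives dominate the gradient — the
behavior wanted under heavy class imbalance.  α_j is the class confidence
weight: 1.0 / 0.5 / 0.1 for annotation grades 3 / 2 / 1 on positive
classes, and 1 on negative classes.  Grade semantics follow
endogenous-tagging screens: grade 3 is a prominent signal, grade 1 a
subtle and weak one; down-weighting grade-1 positives protects the model
from per-cell label noise, because weak patterns are the ones most often
absent from an individual cell.

**Knowledge embedding.** For a triple (h, r, t) with distance d and n
same-category corrupted tails t′ᵢ:

    L_ke = −ln σ(γ − d(h,r,t)) − (1/n) Σᵢ ln σ(d(h,r,t′ᵢ) − γ)

γ = 6 and n = 8 by default (neither is dictated by the task; both are
config keys).  During joint training the head entity of a protein–GO
triple is the *current cell's* adapted fused feature, so the image
encoder receives gradients that pull cells of a protein toward the
geometry of its GO annotations.  Negative tails are sampled uniformly
with replacement from the true tail's GO category (CC/MF/BP) — corrupting
within category keeps negatives plausible and informative.

**Protein-ID aggregation.** An asymmetric single-label loss (r_id = 4,
m_id = 0.1) on the ID head, active only for cells whose labels intersect
the nine low-variability localization classes (cytoplasm, nucleoplasm,
nucleolus, focal adhesions, cell contact, membrane, ER, vesicles, Golgi);
cells outside contribute zero (masking rather than filtering — identical
in effect, simpler in the loop).  Its purpose is feature cohesion: cells
of one protein should embed near each other even when individual cells
miss some annotated pattern.

**Combination.** `L = 1.0·L_slc + 0.1·L_ke + 0.1·L_id`.  Setting a side
weight to zero removes that pathway *exactly*: with `w_ke = 0` (or
`k_triples = 0`, or no graph) training reproduces the image-only model
bit for bit, which the tests rely on for ablation wiring.

## Knowledge graphs and the four scoring functions

A graph holds (head, relation, tail) triples over tagged proteins and GO
terms (categorized CC/MF/BP, each with an annotation text).  Filtering to
the tagged neighbourhood keeps protein–GO triples whose head is tagged,
and GO–GO triples only when *both* endpoints are related to strictly more
than two tagged proteins via the kept protein–GO triples; the operation
is idempotent.

Scoring functions (lower d = more plausible):

| method  | d(h, r, t)                                  | relation parameters |
|---------|---------------------------------------------|---------------------|
| TransE  | ‖h + r − t‖₂                                | one vector          |
| RotatE  | ‖h ∘ r − t‖₂, complex pairing, |rᵢ| = 1      | phase vector        |
| PairRE  | ‖h̃ ∘ r_H − t̃ ∘ r_T‖₂, L2-normalized entities | paired vectors      |
| ComplEx | −Re⟨h, r, conj(t)⟩ (similarity, negated)    | complex vector      |

RotatE relations are parameterized by phases, so unit modulus holds by
construction.  Entity vectors have even dimension for RotatE/ComplEx
(real/imaginary halves).

**Head inversion and knowledge features.** At prediction time a protein's
knowledge feature is the average over its protein–GO triples of the head
implied by each triple: ĥ = t − r (TransE), t ∘ r⁻¹ (RotatE),
(t̃ ∘ r_T) ⊘ r_H (PairRE).  The PairRE implied head lives in the
normalized entity space and must be scored with normalization disabled
for the head; PairRE relations are initialized near unit magnitude
(1 + 0.1·N(0,1)) so the division is well-conditioned.  ComplEx admits no
exact inversion; its feature pools t ∘ conj(r) as a documented surrogate.
Averaging raw tail embeddings is available as an alternative pooling
mode.  A protein with no triples receives the zero vector plus an
absent flag.  Because the feature needs only the protein's triples, it is
available for proteins never seen in training — this is what makes the
knowledge pathway useful on held-out proteins.  Features are
L2-normalized per protein before the adapter so their scale is comparable
across proteins and scoring methods.

**Text initialization.** GO entity embeddings are initialized from
annotation-text features through a trainable linear adapter and remain
trainable.  The default text encoder is a deterministic character-trigram
hashing embedder (crc32 buckets with a nonlinearly mixed seed, pseudo
random signs, L2 normalization): dependency-free, reproducible, and
sufficient to give distinct GO terms distinct directions.  Any encoder
with the same `dim`/`embed` interface — e.g. a pre-trained biomedical
transformer — can be plugged in.

## Training

Adam (lr 1e-3), batches of 16, shuffled per epoch, with light geometric
augmentation (random y/x flips and y–x transposition).  Per batch, each
cell samples up to `k_triples = 4` of its protein's protein–GO triples
for the embedding loss (plus a few GO–GO triples per step, which train GO
embeddings directly).  When a graph is present, *modality dropout* zeroes
the fused image feature in the classifier input for a random 40% of
training cells; without it the image pathway, which has many more
dimensions, fits the training labels first and the classifier never
learns to read the knowledge input.  Validation macro-MCC is computed
each epoch and the best-epoch weights are restored (checkpoint selection);
training is deterministic given the seed.

The protein head entity in L_ke is the per-batch adapted cell feature by
default (`protein_rep="batch"`), which is what lets the encoder learn
protein knowledge; an exponential-moving-average memory bank of adapted
features (`protein_rep="ema"`) is available as a more stable alternative
in which the embedding loss trains only the KGE parameters.

Knowledge features fed to the classifier during training are recomputed
from the current embeddings each step but do not themselves carry
gradients; the embeddings learn through L_ke (and the encoder through the
adapted-head path), which keeps the feature distribution stable for the
classifier.

## The synthetic screen

The generator emulates the structure of an endogenous-tagging screen at
desk scale; defaults are (z, y, x) = (12, 32, 32), 30 proteins × 20
cells, six geometrically well-separated classes (nucleoplasm, nucleolus,
cytoplasm, membrane, vesicles, ER; nine renderers exist in total).

* **Geometry.** A random ellipsoidal cell body with an inner nuclear
  ellipsoid; channel 0 is the filled nucleus.  Per-class renderers:
  uniform nucleoplasm; 1–3 nucleolar spheres of radius 1–2 voxels in the
  nuclear interior; uniform cytoplasm; a 1-voxel boundary membrane shell;
  6–13 vesicle puncta in the cytoplasm; a perinuclear ER shell; one Golgi
  blob abutting the nucleus; basal focal-adhesion puncta near the cell
  edge; a lateral cell-contact patch on one side.
* **Labels.** Label combinations are sampled and assigned to groups of
  2–4 proteins (a screen has many proteins per localization pattern, so
  a combination observed at test time has training support even under
  protein-level splits); a combination is multi-label with probability
  0.5 (two classes with probability 0.8, else three).  Class frequencies
  are uniform by default; imbalance is a config dial.
* **Mixing weights and grades.** Each (protein, class) draws a mixing
  weight from `weight_range`, default U(0.5, 1), which scales the
  rendered intensity.  Grades follow weight bands: ≥ 0.7 → 3, 0.3–0.7 →
  2, < 0.3 → 1 (mirroring prominent / clearly detectable / subtle and
  weak, without claiming equivalence).  The default range produces
  clearly detectable patterns (grades 2–3); the full-range setting
  U(0.2, 1) used by the robustness experiments also produces grade-1
  (near-invisible) patterns.
* **Weak annotation.** Every cell inherits its protein's full label set;
  with `weak_annotation_rate` w, each labeled pattern is *rendered* in a
  given cell only with probability 1 − w·κ(grade), where the
  grade-conditional multipliers κ (0.25 / 0.8 / 4.0 for grades 3 / 2 / 1,
  rescaled analytically so the marginal rate over cell-label pairs equals
  w under the configured weight distribution) encode the heterogeneity
  semantics of confidence grades: a subtle grade-1 signal is absent from
  most individual cells, a prominent grade-3 signal from few.  A cell may
  show none of its annotated patterns.  The generator records realized
  patterns per cell (`SimTruth`), the clean-truth oracle for robustness
  experiments.
* **Noise.** Additive background 0.02 with Gaussian jitter 0.01, and
  Poisson shot noise at a photon scale of 60 counts per unit intensity.
* **Knowledge graph.** One GO-CC entity per localization class with a
  hand-written, lexically distinct annotation text; `located_in` triples
  mirror the protein labels exactly at corruption 0 (an oracle for
  knowledge-enhancement tests; corruption is a dial); distractor MF/BP
  entities with deterministic pseudo-descriptions and two random triples
  per protein; small `is_a` hierarchies.  Distinct texts matter: with
  near-identical template sentences all text-hash embeddings collapse
  onto one direction and the initialization carries no information.

What the generator does **not** model: optics (PSF, anisotropic z-blur),
cell crowding and segmentation errors, morphology families, cell-cycle
variation, or biologically structured GO graphs.  Passing tests therefore
demonstrate that the architecture, losses and knowledge wiring behave as
designed on geometrically faithful caricatures — not performance on real
microscopy.

## Evaluation

Each class is scored as an independent binary problem: MCC, F1, Jaccard
and average precision (step-interpolated, ties entering together), at a
0.5 threshold for hard calls.  Macro values are unweighted means across
classes; a class whose evaluated set lacks positives *or* lacks negatives
has undefined discrimination (MCC denominator zero) and is excluded from
the macro — with 4–5 held-out proteins such degenerate classes are
common, and counting them as zero would make the macro meaningless.
Degenerate MCC within an evaluable class maps to 0 by convention.
Image-level evaluation averages per-cell probabilities per source image
before thresholding.  The clustering score is the Calinski–Harabasz ratio
[B/(k−1)] / [W/(n−k)], intended for cells of single-location proteins.

Splits are made at the protein level (seeded shuffle, 70/15/15 by
default) so no protein's cells leak across splits; a stratified variant
splits within each label-combination group so every combination with ≥ 3
proteins is represented in train, validation and test — designed
evaluations that must measure specific classes on held-out proteins use
it.  A cell-level mode exists for datasets whose proteins map one-to-one
to classes.

## Desk-scale defaults

The full-scale encoder configuration (six residual blocks, 768-d fusion)
matches 128×128 inputs; the estimator's defaults are desk scale, chosen
once after benchmarking single-CPU training: 3 blocks, base width 4,
fused_dim 128, knowledge_dim 64, entity_dim 32, batch 16 — about 30 s for
a 600-cell, 10-epoch training.  The balanced fused/knowledge widths
matter: with a 768-d fused feature against a 32-d knowledge feature the
classifier's knowledge weights receive a negligible share of the
gradient and the knowledge pathway goes unused.

## Designed experiments

Four experiments (in `subloc3d.experiments`, also run by
`scripts/acceptance.py`) check the method's qualitative claims, each over
five derived seeds.  In paired comparisons both arms see identical batch
shuffling and augmentation (knowledge-path sampling draws from its own
RNG stream), and each arm reports the mean over independent model-init
replicates (two by default, three for the ID-aggregation experiment) —
training-trajectory noise otherwise dominates modest true effects.

1. **Pattern learnability.** Default screen, image-only model, 10 epochs,
   stratified protein-level splits; held-out-protein macro-MCC at the
   cell and source-image level.
2. **Knowledge enhancement.** Four classes with nucleolus *rendered as*
   nucleoplasm, so the pair is visually indistinguishable while their
   GO-CC triples differ; PairRE-enhanced model vs image-only ablation on
   held-out macro-MCC over 10 epochs.  The class draw is weighted toward
   the confusable pair (the manipulated factor should dominate the
   measured macro), stratified splits guarantee both confusable classes
   are evaluated on held-out proteins, and the graph carries clean
   located_in triples only — the experiment isolates whether compartment
   triples disambiguate confusable classes; robustness to distractor
   triples and corruption is exercised separately.
3. **Weak-annotation robustness.** A fixed 36-protein roster over all
   nine classes with severe imbalance (rare classes down to one or two
   proteins) and graded mixing-weight ladders, fixed protein-level
   splits, dropout rate 0.2; ASL + confidence weights vs plain BCE
   (r = 0, m = 0, α ≡ 1) on clean-truth macro-MCC over held-out
   proteins.  The composition is fixed by design: with randomly drawn
   compositions the winner is decided by how hard the draw happens to be
   — the asymmetric confidence-weighted loss earns its keep in the
   sparse, imbalanced, grade-1-laden regime it was built for, while on
   easy balanced draws plain BCE is competitive (down-weighting clean
   positives has a real cost).  Randomness enters through rendering,
   dropout realization and training only.
4. **Protein-ID aggregation.** Measured in the knowledge-enhanced
   configuration the ID loss was designed to support: PairRE joint
   training on heterogeneous cells (dropout 0.3, full weight range);
   mean within-protein cosine similarity of fused features
   (mean-centered — the raw features share a dominant direction that
   saturates cosines) with `w_id = 0.1` vs `w_id = 0`.  The effect is
   real but small (cosine gains of order 0.003), hence three replicates
   per arm.

## Numerical choices and edge cases

* Float64 end to end; convolution via im2col and a single GEMM, with a
  cached sparse scatter matrix for input gradients; BatchNorm as a fused
  custom-gradient op.  All layer gradients are verified against central
  finite differences.
* Distances add 1e-30 under the square root (floor 1e-15, gradient
  bounded); normalization denominators are guarded at 1e-12.
* Softmax subtracts the row maximum; probabilities entering logarithms
  are clamped at 1e-12.
* The z-projection operator is max by default (mean available); resizing
  during cropping interpolates linearly in (y, x) only and never
  resamples z; out-of-bounds crops are zero-padded (border cells exist),
  but a nucleus center outside the volume is an error naming the center.
* Ties in ranking metrics follow scikit-learn's grouped-threshold
  convention; the test suite's brute-force AP oracle evaluates every
  distinct threshold.
* Training determinism: a single `numpy` Generator seeded from the
  estimator's `seed` drives shuffling, augmentation, triple sampling and
  negative sampling; two runs with equal seeds produce identical loss
  curves.

## Known limitations

* The desk-scale network is small; its absolute accuracies say nothing
  about full-scale microscopy performance.
* Joint KGE training changes GO embeddings while the classifier reads
  features derived from them; the classifier tracks the drift because
  features are recomputed every step, but very high `lr` or `w_ke` can
  destabilize this loop.
* The knowledge pathway's benefit depends on annotation quality
  (corruption 0 is an oracle; real GO annotations are noisy) and on
  modality dropout to avoid being ignored.
* PairRE head inversion requires all |r_H| entries well away from zero;
  the near-unit initialization makes this hold in practice, but a
  long-trained model could in principle drive an entry small, which
  raises an error naming the coordinate rather than returning an
  unstable feature.
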