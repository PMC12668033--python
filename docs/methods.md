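# Methods

This note documents the models, parameter choices and numerical decisions
behind `lewyseg`, and what the synthetic study conditions do and do not
establish about real whole-slide data.

## Imaging model and stain separation

Brightfield IHC chromogens absorb light multiplicatively, so a pixel with
stain concentrations `h ∈ ℝ³` transmits `I = I0 · 10^(−W h)` where the
columns of `W` are unit-norm optical-density (OD) vectors of hematoxylin,
alkaline phosphatase (magenta; marks alpha-synuclein) and DAB (brown;
marks microglia). We work in base-10 OD with `I0 = 255` and `eps = 1e−6`
added before the log; OD is clipped at zero so white-point pixels map
exactly to zero.

`fit_stain_basis` solves the sparse NMF

```
min_{W,H≥0} ‖V − WH‖²_F + λ‖H‖₁,   ‖W[:,k]‖₂ = 1
```

by alternating multiplicative updates (the H step uses the standard
L1-regularized rule; the W step renormalizes columns with the scale folded
into H so the product is unchanged). Numerical choices that matter:

* **λ = 0.01.** At the OD magnitudes of these tiles (concentrations of
  order 1) a strong L1 penalty rotates the rarest stain column (DAB is
  typically < 3 % of tissue pixels) tens of degrees off its true
  direction; λ = 0.01 keeps the sparsity prior without that bias.
* **Initialization.** `W` is initialized from seeded k-means centroids of
  the OD *directions* of tissue pixels. Pure-stain pixel clusters place
  the initializer within ~1–2° of the truth; random initialization
  frequently converges to mixtures.
* **Fit domain.** Pixels with OD-vector norm ≤ 0.15 (background,
  luminosity-filter convention) or any channel OD ≥ 1.5 (< ~3 %
  transmission, where intensity noise makes OD numerically unstable) are
  excluded from fitting, and the fit subsample (≤ 5000 px) is balanced
  across the three direction clusters so abundant counterstain cannot
  out-vote a rare stain. Reconstruction error is reported over the same
  stable-OD domain.
* **Termination.** Iteration stops at the first non-improving objective
  (tolerance 1e−6 relative) and the best iterate is returned; past the
  optimum, the unit-norm projection interacting with the L1 term causes a
  slow upward creep.
* The basis is fitted **per tile** by default; a fixed reference basis can
  be supplied instead (`reuse_reference_basis`), and is also the fallback
  when a tile has too little tissue (< 150 tissue pixels).

Column identities are assigned by optimal one-to-one cosine matching
(Hungarian algorithm) against reference blue/magenta/brown OD vectors,
with a warning when the best assignment beats the runner-up by < 0.01
total similarity.

The alkaline row of `H` is normalized by its **99th percentile** (not the
max, to resist single-pixel outliers) and clipped to [0, 1]. The
normalizer is floored at **0.3 concentration units**: on tiles with no
magenta staining the 99th percentile sits at the unmixing cross-talk
level, and dividing by it would amplify noise into a spurious
full-strength "probability". The stain mask is the strict threshold
`S_alkaline = H_alkaline > 0.5`.

## Attention segmentation and CRF

The `AttentionProvider` contract returns a tile score in [0, 1] and a
last-layer multi-head attention tensor. Two backends ship:

* **surrogate** — emulates a trained tile classifier from reference-basis
  stain projections: magenta evidence minus 1.5× the brown projection
  (the trained network's learned ability to ignore microglia), Gaussian
  blur, patch pooling (16-px patches), plus seeded distractor lobes so
  downstream stages cannot assume a clean map. The score is a logistic in
  the mean of the top 0.1 % evidence pixels (midpoint 0.35 OD, scale
  0.06).
* **oracle** — reads the synthetic ground truth (tests only; 8-px
  patches).

`class_attention` averages the class-token row over heads; the vector is
min-max normalized, reshaped to the patch grid, bilinearly resized to the
tile and min-max normalized again (a constant vector maps to all zeros).
`S_attention = P > τ` with τ = 0.1, deliberately inclusive.

The dense CRF is a two-label mean-field model with Potts compatibility and
the common default hyperparameters (appearance weight 10, spatial sd 80,
color sd 13; smoothness weight 3, sd 3; 5 iterations). Implementation
specifics:

* Gaussian message passing uses three-box-filter cascades (cost
  independent of kernel width).
* The appearance kernel quantizes colors into 8 seeded k-means bins and
  exchanges blurred messages between bins weighted by color affinity.
  Messages are **normalized votes** — blurred label mass divided by
  blurred same-color density — so rare colors (thin magenta neurites) are
  not out-voted by sheer background mass while same-color structures
  still reinforce each other over long range, the property the
  attention-plus-CRF design relies on.
* The attention map is a localization heat map, not a calibrated
  probability, so the unary is a logistic in `(P − τ)` (softness 0.05)
  clipped to [0.05, 0.95]; the clip guarantees the pairwise term can
  always override a confident-looking unary. A flag switches the unary to
  the binarized `S_attention` instead.
* `iterations = 0` passes `S_attention` through unchanged.

Components of the refined mask are kept **in full** when they overlap
`S_alkaline` by at least one pixel (a minimum overlap fraction is
configurable, default 0). 8-connectivity everywhere.

## Instance post-processing

Fixed order: label components → remove area < Ts → associate within Td →
remove Feret < TF, with Ts = 100 px², Td = 20 px, TF = 33 px (≈ 15 µm at
0.45 µm/px). Boundary conventions: *strictly below* is removed, so
area = 100 and Feret = 33 are kept; distance exactly Td merges.
Association distance is boundary-to-boundary (minimum over pixel pairs,
computed on boundary pixels with k-d trees and a bounding-box prescreen);
centroid distance would defeat the purpose of consolidating fragments of
one elongated aggregate. Merging is a union-find transitive closure and is
order- and relabeling-independent. The maximum Feret diameter is the
largest pixel-center distance, computed exactly on convex-hull vertices in
integer squared arithmetic (collinear instances fall back to projection
extremes), so it agrees bit-for-bit with the all-pairs definition. Crops
are 256 × 256, centered on the rounded centroid, padded with the white
point beyond the tile border.

## Retrieval and classification

NT-Xent for 2B embeddings with positives (i, i+B), temperature 0.5:
`L = mean_i [−s(i,p(i)) + log Σ_{j≠i} exp s(i,j)]` on L2-normalized
embeddings. The analytic gradient (softmax minus positive indicator,
symmetrized, projected through the normalization) is verified against
finite differences in the tests.

The desk-scale encoder maps each crop to 26 rotation/translation-invariant
morphology descriptors of the magenta evidence (component count and
areas, maximum Feret, moment axes, solidity, centroid spread, radial mass
profile, intensity statistics), standardized with statistics frozen at
training time, followed by a **single linear projection** to 32
dimensions. A randomly initialized ReLU hidden layer at this input width
destroys neighborhood structure that NT-Xent cannot rebuild at desk scale
(top-20 same-family retrieval 0.73 vs 0.80), so the linear map is the
default; a hidden layer and a raw-pixel featurizer remain available.
Augmentations preserve magenta hue identity: flips, random resized crop
(70–100 % area), ±10 brightness, 0.95–1.05 common gain, occasional mild
blur. Optimization is AdamW (lr 2e−4, weight decay 0.05, β = (0.9, 0.95))
with a warmup-cosine schedule. Retrieval defaults to cosine distance
(Euclidean by flag), ties broken by id; near-duplicates are flagged at
pairwise distance < 1e−6 and outlier removal is left to the annotator.

The classifier harness trains backbone+head (head: ReLU → dropout 0.2 →
linear) with AdamW in full-fine-tune or frozen-backbone mode, softmax
cross-entropy (or BCE with a single logit for the binary tile task),
warmup-cosine or step schedule (×0.1 every 10 epochs by default), and
restores the checkpoint with the lowest validation loss. Balanced
accuracy is the mean of per-class recalls ×100; classes absent from the
ground truth are excluded with a warning. Count agreement is the mean of
|detected − manual|/manual over tiles with positive manual counts; tiles
with zero manual count are reported separately as false-positive counts.

## Synthetic study conditions

The generator composes per-stain concentration maps and renders
`I = I0 · 10^(−W_true H) + ε`, ε ~ N(0, 2) intensity levels by default,
sharing no stain-fitting code with the analysis path. Conditions:

* Background: hematoxylin base 0.15 OD plus smooth texture (sd 0.06) and
  nuclei disks; dense chromogen deposits displace 90 % of the
  counterstain beneath them (this also provides the near-pure pixels that
  make the factorization identifiable).
* Aggregate families (magenta, amplitude 0.75–1.05): Lewy bodies
  (disks/ellipses radius 19–26 px), axons (length 90–130 px, width
  2–4 px, nearly straight), dendrites (50–90 px, width 6–9 px tapering),
  undifferentiated neurites (50–75 px, width 3–5 px, wavier), clusters of
  2–4 closely spaced bodies (radius 9–13 px, 3–6 px gaps — associated
  into one instance by Td), and dispersed speckle artifacts (removed by
  the area filter, as intended). Parameter ranges are disjoint enough
  that the six classes are separable by construction, and every
  detectable family clears Ts and TF with margin (a 38-px Lewy body is
  ≈ 17 µm, within the real 8–30 µm range).
* Microglia (brown, amplitude 1.2–2.4 with a dimmer rim at 0.55× core)
  act as distractors; `contamination` bleeds that fraction of the DAB
  concentration into the magenta map, reproducing the channel-bleed
  failure mode of stain-only thresholding.
* `make_threshold_fixture` builds five exact pixel sets with areas
  {50, 99, 100, 500}, Feret diameters {10, 32, 33, 80} and alternating
  15/25-px gaps placed so the area filter removes the 15-px neighbors
  before association; the expected surviving set is derived inside the
  generator by direct application of the filter rules (brute force),
  independent of the instance-processing implementation.

**What passing these conditions shows — and does not.** The synthetic
tiles validate the mathematics and the operating point of every stage:
unmixing identifiability, CRF boundary recovery, filter boundary
conventions, contamination robustness, and the training/retrieval
machinery. They do not emulate tissue folds, scanner artifacts, staining
batch variability, touching aggregates (the pipeline deliberately does not
split closely spaced Lewy bodies), or the visual difficulty of real
morphology classes; performance numbers measured here therefore bound the
pipeline's plumbing, not its accuracy on real slides, which requires
trained backbones and expert labels.

## Problem sizes and determinism

Tests and the acceptance script run on 256-px tiles (1024-px rendering is
supported and used only in smoke examples), 10 + 10 tiles for stain
recovery, 50 tiles for end-to-end detection, 180-crop retrieval sets and
600-crop classification sets — sizes chosen so the whole suite completes
in minutes on one CPU while keeping every statistic stable across seeds.
All randomness flows from explicit integer seeds (generator specs,
SNMF/k-means initialization, training shuffles); reruns with the same
config are bit-identical, which the tests assert.

## Known limitations

* The surrogate attention backend emulates a trained classifier's
  behavior from stain projections; it exists to exercise the surrounding
  mathematics, not to claim classifier-free segmentation. A real ViT
  backend can be plugged in through the provider contract.
* Closely spaced Lewy bodies are intentionally merged (one
  `multiple_lewy_bodies` instance); per-body counts inside clusters are
  not recovered.
* The mean-field CRF approximates the bilateral kernel with 8 color bins;
  on images with rich color gradients finer binning (configurable) may be
  needed.
* Stain vectors are assumed to be three and mutually > 20° apart;
  additional chromogens are out of scope.
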