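# Methods

## The model

`metacvs` recognises a three-criterion surgical milestone (the critical view
of safety, CVS) in short clips of laparoscopic video sampled at 1 fps, and
couples that primary classification task to an auxiliary anatomy-segmentation
task through bi-level meta-optimization.

The network has three parameter groups,
Θ = (Θ^B, Θ^Pri, Θ^Aux):

* **Shared trunk Θ^B.** Two encoders. (i) A divided space-time attention
  transformer over the whole T-frame clip: each block applies temporal
  attention (tokens at the same spatial position across frames), then spatial
  attention (tokens within a frame, with the classification token broadcast
  to every frame and its updates averaged back), then a two-layer GELU MLP —
  each sub-layer pre-normalized with a residual connection.  Its final-layer
  class token summarises the clip.  (ii) A hybrid CNN–transformer encoder
  over the last frame only: a three-stage stride-2 convolutional stem
  (features at 1/2, 1/4, 1/8 resolution kept as skip connections), a
  stride-2 patch embedding to a 1/16-scale token grid, and a small
  transformer unit with a learned auxiliary class token prepended.
* **Classification head Θ^Pri.** The clip-level class token is concatenated
  with the auxiliary class token and mapped by a one-hidden-layer MLP to
  three logits, one per criterion (multi-label, not mutually exclusive).
* **Segmentation decoder Θ^Aux.** The bottleneck token grid is reshaped to a
  feature map and restored to input resolution by four (2× bilinear
  upsample → 3×3 convolution → ReLU) stages, concatenating the
  matching-scale stem feature before each of the first three convolutions,
  with a final 1×1 projection to per-pixel class logits.  The auxiliary
  class token parameter also belongs to this group.

Losses: the primary loss L_Pri is binary cross-entropy on logits averaged
over criteria and batch; the auxiliary loss L_Aux is multi-class focal loss
(γ = 2 by default) averaged over pixels and batch; the joint loss is the
fixed convex combination L_total = 0.9·L_Pri + 0.1·L_Aux.  Mean reductions
keep the loss scale independent of batch composition, which matters because
the mixed-batch proportions vary.

## Bi-level meta-auxiliary training

Supervision is imbalanced: every frame carries the milestone labels, but
only a fraction carries a pixel-wise mask ("dual-labeled").  Each training
step draws a mixed batch of m dual-labeled + n label-only clips and runs:

1. **Inner adaptation** on the m dual clips:
   Θ̃ = Θ − α_l ∇_Θ L_total(Θ), adapting all three groups.
2. **Outer update** on all m + n clips: L_Pri is evaluated at Θ̃ and its
   gradient with respect to Θ steps Θ^B and Θ^Pri (learning rate α_g);
   Θ^Aux keeps its adapted value, so the segmentation branch learns purely
   through the inner loop.

In `first_order` mode (default) the outer gradient is taken at Θ̃ directly —
the standard approximation that drops the inner Hessian term; in
`second_order` mode the step differentiates through the inner update
exactly, which the numpy autodiff engine supports by double backward.  Both
modes are validated against central finite differences of the composed
objective on a tiny double-precision profile, and their difference vanishes
linearly as α_l → 0, which also makes the scheme collapse to plain
single-task gradient descent in that limit.

Two interpretive choices deserve note.  First, the inner adaptation is
defined per *batch*, not per sample: a single Θ̃ is computed from the whole
dual sub-batch and used to evaluate every outer sample — the only reading
that defines adapted parameters for the n mask-free samples without
inventing supervision.  Second, the *base point* of the outer step
(`outer_base`): the update rule reads Θ ← Θ − α_g ∇L_Pri(Θ̃), which leaves
open whether the step applies to the original Θ (the MAML convention,
discarding the inner update of the shared trunk) or to Θ̃ itself (the
shared and primary groups are "updated again" on top of their inner
update).  The package implements both; the default keeps the inner update
(`outer_base="theta_tilde"`), under which the shared trunk retains the
segmentation-shaped component of every inner step — without it the trunk
receives no persistent auxiliary signal at all and, at desk scale, drifts
to appearance shortcuts.  Both readings coincide exactly as α_l → 0.

Because L_Pri consumes the auxiliary class token (a Θ^Aux parameter), plain
joint training updates that token while the meta outer step never does; the
degeneration equivalence between the two trainers therefore holds over the
shared trainable set (Θ^B, Θ^Pri), which `train_joint_baseline`'s
`update_groups` argument exposes.

### Training hyperparameters

| knob | default | why |
| --- | --- | --- |
| m : n | 10 : 6 (batch 16) | the 5:3 proportion at batch 16 that the method's source experiments found best |
| α_l | 0.1 (desk profile) | the inner step must carry the segmentation branch on its own; smaller values starve Θ^Aux, much larger ones make the outer gradient location too noisy |
| α_g | 1e-3 | standard adaptive-moment step for small transformers trained from scratch |
| outer optimizer | plain step by default; adaptive-moment (`adam`) used in the synthetic experiments | the bi-level equations specify plain gradient steps; from-scratch training at desk scale is far more reliable with adaptive moments |
| outer_base | theta_tilde | keep the inner update of every group; see the interpretive note above |
| lr schedule / clipping | cosine decay, global-norm clip 5 in the synthetic experiments (both off by default) | standard stabilisers for noisy small-batch training |
| weight decay | 0 | available (decoupled, outer groups only); not needed once augmentation is on |
| augmentation | off by default; on in the synthetic experiments | random flips/right-angle rotations plus per-clip channel intensity jitter; exact for this generator because the criteria are distance/count predicates (see below) |
| inner_steps | 1 | a single adaptation per batch, as in the training algorithm; more steps are exposed for experimentation |
| checkpoint selection | every `eval_every` steps on the validation split, score = achievement F1 + mean criterion accuracy + mIOU | a pure-F1 selector is degenerate at desk scale (a ~30-clip validation pool holds only a handful of achievement-positive frames), and the selected checkpoint must serve both tasks |
| focal γ | 2.0 | the canonical focal-loss default; γ = 0 recovers cross-entropy (tested) |

## The synthetic generator

The generator emulates the statistical structure the method assumes, at desk
scale: procedures of 1 fps frames; per-frame milestone labels; masks on a
controllable fraction of frames (default 0.2, matching the roughly
one-in-five dual-labeling of the clinical dataset the method targets); and —
crucially — milestone labels that are *functions of the anatomy geometry*,
so segmentation genuinely informs classification.

Scenes contain a large disk (organA), a medium disk (organB, drawn on top
when they overlap) and thin capsule "ducts", on a smooth per-procedure
background texture with per-procedure colour jitter and additive Gaussian
pixel noise (σ = 0.05, clipped to [0, 1]).  The criteria, recomputed from
the rasterized mask of every frame:

* **C1 (separation):** minimum pixel distance organB→organA > 2.1 px.
* **C2 (exposure):** fraction of organB boundary pixels within 2 px of
  organA < 0.40.
* **C3 (counting):** exactly two duct components touch organB (≤ 1.6 px).

Per procedure, geometry is sampled in crisp regimes — well separated /
lightly touching / deeply overlapping for C1–C2, and one or two attached
fixed-size ducts for C3 (a detached duct-like distractor is available
behind `distractor_prob`, off by default) — then drifts rigidly at
0.5 px/frame, with discrete mid-procedure regime events (a duct
attaching/detaching with probability 0.9 per procedure, a separation-regime
switch with probability 0.7).  The crisp regimes keep borderline
quantization flips rare, and the frequent events make the labels vary
*within* procedures — without that variation a model can fit the labels
from the procedure's background-texture fingerprint alone and the auxiliary
premise is never exercised.  Default scale: 50 procedures × 10 frames of
32×32 px (~350 four-frame clips); the shipped end-to-end experiments use
75 procedures × 7 frames (exactly 300 clips, more appearance diversity).

Deriving labels from the emitted mask makes label–mask consistency hold by
construction; an independent brute-force pixel oracle (explicit distance
scans and BFS connected components, no image-processing library) re-derives
the labels in the test suite.

**What the generator does not model** — and hence what passing tests do not
show about real surgical video: photorealistic appearance, instruments,
occlusion, camera motion beyond rigid drift, annotation noise, and
class-imbalanced anatomy ontologies.  The synthetic task verifies the
*mechanism* (that meta-auxiliary coupling transfers segmentation signal into
the classifier under label imbalance), not clinical performance.

## Evaluation

Per-criterion frame accuracy at a 0.5 threshold; precision/recall/F1 of
milestone *achievement*, a frame counting as achieved iff all three criteria
are positive (the clinical definition; an "any" mode exists); per-class
IOU and Dice with pixel counts pooled over the evaluation set (micro),
background excluded from mIOU, classes with empty union excluded.  Dice and
IOU satisfy Dice = 2·IOU/(1 + IOU) per class, which the tests assert.

## Numerical choices

* All computation in float64; the gradient engine's vector-Jacobian products
  are themselves built from differentiable primitives, so second-order
  (gradient-of-gradient) quantities are exact to round-off.
* Softmax and log-softmax use constant max-shifts; binary cross-entropy uses
  the softplus form; the focal modulation adds 1e-12 inside (1 − p_t)^γ to
  keep the γ-power differentiable at p_t = 1.
* Argmax mask prediction breaks exact ties toward the lowest class index
  (background wins exact ties).
* Largest-remainder rounding apportions the 7:1:2 procedure split; ties in
  the remainder resolve in (train, val, test) order.
* Clip assembly skips anchors lacking a full contiguous 1 fps history
  (a repeat-first-frame padding mode exists); a timestamp gap invalidates
  spanning anchors because the encoder models contiguous seconds of motion.
* Weight initialisation: truncated normal (σ = 0.02, clipped at 2σ) for
  embeddings and linear maps, He-scaled truncated normal for convolutions,
  zero biases; every run is reproducible from its seed, and checkpoints
  embed the parameter-partition table.
* Temporal attention is skipped at T = 1 (no temporal axis), making the
  block coincide with joint space-time attention — the property the
  equivalence test uses.

## Problem sizes in the shipped experiments

The gradient oracles run on a 1-layer, 8-dimensional, 2-head profile over
2-frame 16×16 clips with 3 mask classes (~8 k parameters) — small enough
that finite differences are trustworthy in double precision.  The synthetic
end-to-end experiments use a 1-layer, 32-dimensional model over 4-frame
32×32 clips (~75 k parameters) in float32, trained for 3000 bi-level steps
in the recovery run and 350 per arm in the three-seed batch-composition
sweep and meta-vs-joint comparison — sizes chosen so the full suite runs on
a single CPU core in minutes.  At the short per-arm budget the models almost
never predict the three-criterion conjunction, so achievement F1 is
typically 0 there; the sweep's segmentation scores are the informative
signal at that budget.

## Known limitations

* The full-scale profile (12 layers, 768 dimensions, 224 px, patch 16) is
  implemented and shape-tested but not trained here; numpy on a CPU is not
  a vehicle for GPU-scale video-transformer training.
* The first-order outer gradient is an approximation; its error grows with
  α_l (measured ~2×10⁻³ relative at α_l = 0.01 on the tiny profile).
* Masks are single-channel indexed maps; overlapping anatomy classes are out
  of scope.
* From-scratch milestone classification at this data scale is brittle: the
  per-procedure background texture is a procedure fingerprint, and even with
  exact geometric/photometric augmentation and within-procedure label
  events, a ~75 k-parameter encoder trained on ~50 procedures tends to latch
  onto appearance shortcuts.  Held-out segmentation is reliably strong
  (pixel-level supervision admits no shortcut), while held-out per-criterion
  accuracy varies substantially across seeds and dataset realisations.
  An exact colour-threshold segmenter combined with the label predicates
  solves the held-out task almost perfectly, so the ceiling is one of
  learning, not of information; closing that gap at desk scale without
  pretraining is an open problem for this configuration, and the test suite
  reports it honestly rather than relaxing the targets.
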