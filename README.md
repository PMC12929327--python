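# metacvs

Dual-task **meta-auxiliary learning** for surgical-milestone recognition:
a classifier for the three *critical view of safety* (CVS) criteria in
laparoscopic cholecystectomy video, boosted by an auxiliary
anatomy-segmentation task under imbalanced supervision — every frame has
milestone labels, only a fraction has pixel-wise anatomy masks.

The package is for researchers studying multi-task learning on partially
dual-labeled clinical video.  It implements the full mechanism as a tested,
desk-scale library: the divided space-time attention video encoder, the
hybrid CNN–transformer last-frame encoder with a cascaded-upsampling
segmentation decoder, the weighted joint loss, the bi-level meta-auxiliary
optimizer, task metrics, and a synthetic scene generator whose milestone
labels are exact functions of the anatomy geometry — so every claim about
the mechanism can be verified without clinical data or a GPU.  All tensor
computation runs on a small numpy reverse-mode autodiff engine with double
backward, so the exact second-order meta-gradient is available and testable
against finite differences.

## The model

The trainable weights split into three named groups,
Θ = (Θ<sup>B</sup>, Θ<sup>Pri</sup>, Θ<sup>Aux</sup>): a shared trunk (both
encoders), the classification head, and the segmentation decoder (plus the
auxiliary class token).  With y the triple of criterion labels and
I<sub>mask</sub> the anatomy mask, the joint objective is

    L_total = 0.9 · L_Pri(y)  +  0.1 · L_Aux(I_mask)

where L_Pri is multi-label binary cross-entropy on logits and L_Aux is
multi-class focal loss (γ = 2).  Each training step draws m dual-labeled
plus n label-only clips (default 10 : 6 at batch 16) and performs

    inner:  Θ̃ ← Θ − α_l ∇_Θ L_total          (on the m dual clips)
    outer:  Θ ← Θ − α_g ∇_Θ L_Pri(Θ̃)         (on all m + n clips)

with the outer step updating Θ<sup>B</sup>, Θ<sup>Pri</sup> and the
adapted Θ̃<sup>Aux</sup> persisting.  First-order and exact second-order
outer gradients are both implemented; as α_l → 0 the scheme provably (and
by test) collapses to plain single-task gradient descent.

## Worked example

```python
import numpy as np
import metacvs.autodiff as ad
from metacvs import (MetaAuxiliaryModel, MetaConfig, NetConfig, SceneConfig,
                     TOY_ONTOLOGY, generate_dataset, make_clips,
                     split_by_procedure)
from metacvs.dataset_io import filter_by_split

ad.set_default_dtype(np.float32)            # training precision

records = generate_dataset(SceneConfig(seed=11), "toy_data")
assignment = split_by_procedure(records, seed=0)

net = NetConfig(frame_length=4, input_size=32, patch_size=8, embed_dim=32,
                n_layers=1, n_heads=4, mlp_ratio=2.0, stem_channels=(8, 16, 32),
                aux_embed_dim=32, aux_layers=1, aux_heads=4, n_classes=4,
                decoder_channels=24)
clips = make_clips(records, net.frame_length, image_size=net.input_size)
model = MetaAuxiliaryModel(filter_by_split(clips, assignment, "train"),
                           filter_by_split(clips, assignment, "test"),
                           net, TOY_ONTOLOGY)

results = model.fit(MetaConfig(alpha_l=0.1, alpha_g=1e-3, m=10, n=6,
                               optimizer="adam", augment=True,
                               lr_schedule="cosine", clip_norm=5.0,
                               eval_every=200, seed=0),
                    steps=3000)
report = results.evaluate(filter_by_split(clips, assignment, "test"))
print(results.summary(report))
```

This trains the desk-scale profile on 300 synthetic clips (20 %
dual-labeled, 75 procedures) in a few minutes on one CPU core and prints

```
Meta-auxiliary dual-task model
==============================================
method:            meta
frame length T:    4   input: 32px   patch: 8px
embed dim:         32 (1 layers, 4 heads)
parameters:        75639 (shared 38672, primary 2179, aux 34788)
steps trained:     3000
alpha_l / alpha_g: 0.1 / 0.001   m:n = 10:6   mode: first_order
final L_Pri:       0.1340
----------------------------------------------
criterion accuracy: C1 0.600  C2 0.683  C3 0.600
achievement:        P 0.000  R 0.000  F1 0.000
segmentation:       mIOU 0.528  Dice 0.640
```

— per-criterion frame accuracy at threshold 0.5; precision/recall/F1 of
milestone *achievement* (all three criteria positive); and mean
intersection-over-union / Dice over the three anatomy classes, background
excluded.  Segmentation — per-pixel supervised, so immune to appearance
shortcuts — is learned well at this scale; from-scratch milestone
classification on unseen procedures remains modest (and achievement, the
conjunction of all three criteria, is rarely predicted at these accuracy
levels).  `docs/methods.md` discusses why, and what the desk-scale runs do
and do not demonstrate about the method.

## Command line

    metacvs generate --out DATA --seed 7          # synthetic dataset
    metacvs train --data DATA --out RUN           # meta-auxiliary training
    metacvs train --data DATA --out RUN2 --baseline joint
    metacvs evaluate --checkpoint RUN/checkpoint_final.npz \
                     --data DATA --split test --report report.json
    metacvs predict  --checkpoint RUN/checkpoint_final.npz --data DATA --out PRED
    metacvs ablate-mn --data DATA --out ABL --ratios 7:1,5:3,3:5,1:7

Every command takes `--config cfg.yaml` plus `--set dot.path=value`
overrides and writes a frozen resolved config next to its outputs.  Real
datasets use the same layout the generator emits: a CSV manifest
(`procedure_id,timestamp_s,image,mask,c1,c2,c3`), RGB frame images and
indexed-PNG masks.

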