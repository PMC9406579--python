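# rdaunet

Residual-dense-attention (RDA) U-Net for liver and lesion segmentation in
abdominal CT, with a synthetic phantom generator and the four-metric
evaluation protocol — usable end-to-end on one CPU with no external data.

## Who this is for

Researchers and engineers who need a transparent, fully tested reference
implementation of a hybrid attention U-Net for medical image segmentation:
the encoder stages compose **residual blocks** (`H(x) = F(x) + x`) with
**densely connected blocks** (each layer consumes the concatenation of all
predecessors), and the decoder gates every skip connection with **additive
soft attention** (`alpha = sigmoid(psi(relu(W_g g + W_x x)))`, applied
multiplicatively to the skip feature). Binary probability maps come from a
1x1 convolution + sigmoid head at input resolution.

Around the network sit a CT preprocessing chain (Hounsfield windowing to
[0,1], 512 -> 224 resizing, seeded 8:2 splits, DICOM-series -> NIfTI
conversion, contour overlays), a deterministic phantom generator (nested
liver/lesion regions with per-class HU ranges and Gaussian noise), and the
evaluation protocol

    ACC = (TP+TN)/total      DSC = 2TP/(2TP+FP+FN)
    IoU = TP/(TP+FP+FN)      AVGDIST = (GtoS/|G| + StoG/|S|)/2

plus ROC AUC, where G and S are the boundary point sets of ground truth and
prediction. The network runs on a compact numpy autodiff engine
(`rdaunet.nn`) whose gradients are finite-difference checked — there is no
deep-learning framework dependency.

## Worked example

Train the desk-scale demonstration (80 synthetic phantoms at 64x64, 8:2
split, depth-3/base-8 network, 15 epochs, Adam at 1e-3 — a couple of
minutes on one CPU):

```python
from rdaunet.model import run_desk_scale_experiment

results, per_case, aggregate = run_desk_scale_experiment(seed=1, target="liver")
print(results.summary())
print(aggregate)
```

```
RDA U-Net segmentation results
==============================================
target:            liver
architecture:      depth 3, base 8, input 64x64
parameters:        407,012
loss / optimizer:  bce / adam (lr 0.001)
epochs completed:  15
split:             64 train / 16 val (ratio 0.8, seed 1)
...
{'n_cases': 16, 'acc': 0.983, 'dsc': 0.9483, 'iou': 0.907,
 'avgdist': 0.7528, 'auc': 0.9882, ...}
```

Read: on 16 held-out phantoms the liver model reaches mean Dice 0.948 and
IoU 0.907, its predicted boundary sits on average 0.75 px from the true
boundary, and pixel accuracy 0.983 exceeds IoU because accuracy also
credits the large background (the identity `IoU = DSC/(2-DSC)` and the
bound `ACC >= IoU` hold for every case). The same call with
`target="lesion"` trains the lesion model (BCE+Dice objective, since
lesions cover ~1% of pixels).

The same pipeline is scriptable from the shell:

```bash
rda phantom --n 80 --seed 1 --out data/
rda train --manifest data/manifest.json --out run/ --desk-scale
rda evaluate --model run/checkpoint --manifest data/manifest.json --out eval/
rda report --model run/checkpoint --manifest data/manifest.json --out figs/
rda describe                       # per-node shape/parameter manifest (TSV)
```

For fidelity-scale work, `ArchitectureConfig()` (224x224, depth 4, base 16)
and `TrainConfig()` (100 epochs, batch 8, Adam at 1e-6) carry the full
protocol; `SegmentationModel(samples, arch, cfg).fit()` returns a results
object with `summary()`, `predict()`, `evaluate()` and bit-exact
`save()`/`load()` checkpoints.

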