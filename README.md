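# feccnet

Lightweight dual-encoder segmentation of stroke lesions in brain MRI
slices, with a built-in synthetic data generator so the whole pipeline is
testable on a laptop CPU without any external dataset.

Chronic-stroke lesions on T1 MRI are hypo-intense blobs whose sizes span
three orders of magnitude and whose boundaries are rough; plain U-Net-style
encoder–decoders struggle to balance context capture (for tiny lesions)
against boundary recovery (lost in downsampling). This package implements
a compact network that addresses both:

* a **main encoder–decoder**: four levels of paired 3×3 conv + BN + ReLU
  blocks with squeeze-and-excitation channel attention, 2× max pooling down
  and bilinear upsampling back, with skip connections per level;
* **atrous spatial pyramid pooling (ASPP)** at the bottleneck: parallel 3×3
  convolutions at dilation rates {1, 6, 12, 18} fused by a 1×1 convolution,
  enriching multi-scale context at constant parameter cost;
* an **enhanced encoder**: a parallel branch of stacked depthwise-separable
  convolutions over the raw input that feeds boundary-rich shallow features
  into the decoder through secondary skip connections;
* the **hybrid loss** `HL = sqrt(L_BCE² + L_Dice²)`, the L2 combination of
  mean binary cross entropy and soft Dice loss
  `L_Dice = 1 − (2Σyŷ + δ)/(Σy² + Σŷ² + δ)`, built for the extreme
  foreground/background imbalance of lesion masks (δ ∈ [1e−15, 1e−13]).

The calibrated full network has 7,008,469 trainable parameters (7.0 M);
disabling the enhanced encoder gives the lite variant with 3,808,909
(3.8 M). Evaluation reports DSC, mIoU, recall and precision stratified by
ground-truth lesion size: small [1, 100), medium [100, 1000) and large
[1000, ∞) foreground pixels, lesion-free slices excluded.

The whole stack — layers, backprop, Adam — runs on numpy, with every
gradient verified against finite differences in the test suite.

## Worked example

```python
import numpy as np
from feccnet import FECCNetSegmenter, SynthConfig, generate_dataset

cfg = SynthConfig(image_size=64, n_slices=60, stratum_mix=(0.2, 0.3, 0.3, 0.2), seed=0)
records, manifest = generate_dataset(cfg)
X = np.stack([r.image for r in records])
y = np.stack([r.mask for r in records])

model = FECCNetSegmenter(image_size=64, max_epochs=15, random_state=0)
model.fit(X[:48], y[:48])
print(f"trainable parameters: {model.n_parameters_:,}")
print(f"final training loss:  {model.history_['train_loss'][-1]:.3f}")
print(f"held-out mean DSC:    {model.score(X[48:], y[48:]):.3f}")
```

prints

```
trainable parameters: 359,048
final training loss:  0.291
held-out mean DSC:    0.762
```

i.e. a reduced-width model (359 k parameters at 64×64) trained for 15
epochs on 48 synthetic slices already overlaps held-out lesion masks at a
mean Dice of 0.76; the acceptance smoke test trains longer on more slices
and exceeds 0.8. `model.predict(X)` returns {0,1} masks thresholded at
0.5 on the sigmoid output.

The same functionality is available from the shell:

```sh
fecc synth --out data --n-slices 200 --image-size 64 --seed 7
fecc train --data data --out run --epochs 30 --learning-rate 1e-3
fecc noise --checkpoint run/checkpoint --data data --sigma 40
fecc params --variant full        # 7008469 trainable parameters (7.0M)
```

`fecc slice` cuts real NIfTI volume/mask pairs into resized axial slice
PNGs; `fecc predict` writes mask + overlay PNGs for new images.

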