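# caucseg

Lightweight attention U-Net for pixel-wise crop/weed segmentation in mixed
agricultural fields, built to run on modest hardware.

Selective weed control needs a model that labels every pixel of a field image
as one of `{carrot, sugar beet, sunflower, weed, soil} = {0, 1, 2, 3, 4}` while
staying small enough for edge devices.  `caucseg` implements the CAUC
architecture — a Concatenated Attention U-Net with a Convolutional Block
Attention Module — together with everything needed to exercise it offline:

* **Architecture.** A four-level encoder/decoder.  Each level is a *Linear
  Concatenated Block* (LCB): three 3×3 depthwise-separable convolutions (DSC)
  whose outputs are concatenated with their inputs and squeezed by 1×1
  bottlenecks at half the block's filter allocation N ∈ {16, 32, 64, 128}
  (middle layer: one DSC with 256 filters).  Skip connections pass through
  additive *attention gates* (AG); the four decoder outputs are refined by
  *CBAM* (channel-then-spatial attention), upsampled to the input grid and
  fused into a 240-channel stack before the 5-class softmax head.  The whole
  network totals ≈ 0.36 M parameters.
* **Parameter calculus.** Closed-form reduction ratios for the two budget
  mechanisms — per DSC layer, PR₁ = 1/K² + 1/N; per LCB, PR₂ =
  (3 + N/2 + N²/(4(N+Nᵢ)))/(9+N) — with a brute-force counting oracle that
  verifies them against real block instantiations.
* **Data plumbing.** A deterministic synthetic field-image generator
  (soil-dominated scenes, three crop morphologies, scattered weeds, exact
  ground-truth masks), a label codec between the three source annotation
  palettes and the unified one, paired image/mask augmentation, 90:10 hold-out
  splitting, resampling to balanced per-crop counts, and 5-fold CV.
* **Engine.** The network runs on a compact NHWC numpy autodiff core
  (`caucseg.nn`) with Adam, batch normalization, and channel dropout — no
  deep-learning framework required.

## Worked example

```python
import numpy as np
from caucseg import CaucSegmenter, build_cauc, count_parameters, layer_census
from caucseg.complexity import apr1, apr2, model_dsc_filters, pr1
from caucseg.synthetic import SynthConfig, generate_dataset
from caucseg.train import bundle_arrays

model = build_cauc()
print("total parameters:", count_parameters(model))
print("conv layers by kernel size:", dict(sorted(layer_census(model).items())))
print(f"PR1(16) = {pr1(16):.4f}   PR1(256) = {pr1(256):.4f}")
print(f"APR1 over 25 DSC layers = {apr1(model_dsc_filters()):.4f}")
e, d, pooled = apr2()
print(f"APR2: encoder {e:.4f}, decoder {d:.4f}, pooled {pooled:.4f}")

cfg = SynthConfig(image_size=32, seed=5)
bundle = generate_dataset(cfg, {"carrot": 3, "sugar_beet": 3, "sunflower": 2}, seed=5)
images, labels = bundle_arrays(bundle)
est = CaucSegmenter(input_size=32, epochs=60, batch_size=2,
                    learning_rate=0.01, random_state=1)
est.fit(images, labels)
print("training pixel accuracy:", round(est.score(images, labels), 4))
print("soil-majority baseline: ", round(float((labels == 4).mean()), 4))
```

prints

```
total parameters: 363603
conv layers by kernel size: {1: 28, 3: 27, 7: 4}
PR1(16) = 0.1736   PR1(256) = 0.1150
APR1 over 25 DSC layers = 0.1394
APR2: encoder 0.6298, decoder 0.5353, pooled 0.5825
training pixel accuracy: 0.9736
soil-majority baseline:  0.9507
```

Reading the numbers: the assembled model carries 363,603 parameters in
27 three-by-three, 28 one-by-one and 4 seven-by-seven convolution layers.
Depthwise-separable layers cost 11.5–17.4 % of their standard-convolution
equivalents (average ≈ 14 % over the 25 DSC layers), and each LCB with its 1×1
bottlenecks costs ≈ 58 % of the same block without them.  On eight small
synthetic images the network overfits to 97.4 % training pixel accuracy —
clearly above the 95.1 % a soil-only predictor would score on these
soil-dominated scenes, i.e. it genuinely learns the vegetation classes.

`CaucSegmenter` follows the scikit-learn estimator API
(`get_params`/`set_params`/`fit`/`predict`/`predict_proba`/`score`), so it
composes with sklearn model selection.  The same functionality is scriptable:

```bash
cauc synth --out data/raw --counts carrot=60,sugar_beet=1800,sunflower=146 --seed 1
cauc prepare --in data/raw --out data/prepared --seed 1
cauc build --variant V5 --report shapes,params,census
cauc train --data data/prepared/train --out run/model.npz --epochs 50
cauc evaluate --ckpt run/model.npz --data data/prepared/test --report run/report.json
cauc complexity --json run/complexity.json
```

Ablation variants are first-class: `build_variant("V4")` drops the CBAM fusion,
`"V3"` the attention gates, `"V2"` both, and `"V1"` is a plain double-conv
U-Net baseline (≈ 5.5 M parameters, ~15× the full model).

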