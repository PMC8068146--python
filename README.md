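# spinet

Semantic segmentation of farmland vacancies — the bare patches where crops
failed to establish — from low-altitude RGB imagery, with a strip-pooling
encoder–decoder network and an agronomic summary metric, the vacancy ratio.

The package is aimed at researchers in crop phenotyping and precision
agriculture who want a per-field (not per-region) measure of planting gaps.
An image is segmented into background, crop and vacancy; the field is then
scored by

```
VR = V / (C + V)          vacancy ratio (V: vacant area, C: crop area)
error = |VR_f − VR_p| / VR_f    relative error of the predicted ratio
```

The network, SPINet, combines:

- **strip pooling** — 1×W and H×1 average pooling, `y^h_i = (1/W) Σ_j x_ij`,
  whose directional profiles capture long narrow gaps;
- an **SPM** attention gate and an **MPM** (pyramid pooling + SPM) for
  compact gaps, fused in parallel on the encoder output;
- an **IResNet** trunk — a bottleneck ResNet with Start/Middle/End block
  phasing that keeps negative signals on the identity path, group
  normalization throughout, and strip-pooling blocks in the final stage;
- a skip-connected decoder (×4 bilinear, stage-2 skip, three 3×3 convs, ×4
  bilinear) and an auxiliary "loss reuse" head for small-sample training;
- class-weighted cross-entropy (weights 0.8/1/1.2) with Adam at lr 0.01.

Everything runs on a compact NumPy reverse-mode autodiff engine
(`spinet.grad`) — no GPU or deep-learning framework required — and a
procedural scene generator provides paired imagery and ground truth so the
whole pipeline is testable without field data.

## Worked example

```python
import dataclasses
from spinet import (SceneParams, generate_scene, TrainConfig, toy_model_config,
                    predict_mask, confusion, compute_metrics)
from spinet.training import fit

base = SceneParams.for_size(64, 64)
train = [generate_scene(dataclasses.replace(base, seed=1000 + i)) for i in range(32)]
val = [generate_scene(dataclasses.replace(base, seed=2000 + i)) for i in range(8)]

cfg = TrainConfig(model=toy_model_config(), epochs=25, batch_size=4, seed=0)
result = fit(train, val, cfg)
print(f"val PA={result.epochs[-1].val_pa:.3f}  mIoU={result.epochs[-1].val_miou:.3f}")

img, ref = val[0]
m = compute_metrics(confusion(predict_mask(result.model, img), ref))
print(f"scene VR_f={m.vr_true:.3f}  VR_p={m.vr_pred:.3f}  error={m.vr_error:.3f}")
```

prints (seed 0, ~30 s on one CPU core):

```
val PA=0.974  mIoU=0.898
scene VR_f=0.098  VR_p=0.098  error=0.000
```

i.e. the desk-scale network labels 97% of held-out pixels correctly, and on
the first held-out scene the predicted vacancy ratio matches the true 9.8%
to the printed precision.

The same pipeline is available from the shell:

```
spinet generate --out-dir scenes --count 44 --seed 5
spinet split    --scenes scenes/scenes.json --ratios 8:1:2 --out manifest.json
spinet train    --manifest manifest.json --toy --epochs 25
spinet predict  --checkpoint checkpoints/best.npz --image scenes --out-dir preds
spinet metrics  --pred-dir preds --ref-dir scenes --out-json report.json
```

## Layout

| module | role |
| --- | --- |
| `spinet.imagery` | color-mask codec, tiling, 8:1:2 dataset splits |
| `spinet.synthetic` | scene generator and augmentation operators |
| `spinet.pooling` | strip pooling, SPM, MPM |
| `spinet.backbone` | staged-ResNet trunk with group norm |
| `spinet.model` | encoder–decoder assembly and prediction |
| `spinet.metrics` | weighted loss, confusion-matrix metrics, VR error |
| `spinet.training` | Adam loop, checkpoints, evaluation |
| `spinet.grad` | NumPy reverse-mode autodiff engine |
| `spinet.cli` | `spinet` command-line interface |

See `docs/methods.md` for the model description, design decisions and known
limitations.
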