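# placim

Prenatal prediction and typing of **placental invasion** from T2-weighted
MR-like images.

Placental invasion (placenta accreta spectrum) is graded by how deeply
placental villi penetrate the uterine wall: *accreta* (attachment to the
myometrium), *increta* (invasion into it), *percreta* (penetration through
the serosa). On T2WI the grades show as heterogeneous placental signal,
dark intraplacental bands, myometrial thinning and localized bulges.
`placim` implements a four-class computer-aided typing pipeline for
researchers in medical image analysis:

1. **Phantoms** — clinical cohorts are private, so a seeded generator
   produces abdominal-T2WI-like phantoms (ellipse placenta inside a bright
   myometrium ring) whose invasion grade controls ring erosion, bulges,
   dark bands and signal heterogeneity, with ground-truth masks and labels.
2. **Segmentation** — a U-net (contracting/expansive paths joined by skip
   connections) predicts the placenta mask.
3. **ROI extension** — the mask is extended outward by *d* pixels
   (Euclidean distance transform; default *d* = 40) to capture the
   placenta–myometrium interface.
4. **Radiomic features** — an ordered 100-vector: 18 first-order,
   9 shape, 73 texture features (GLCM 22, GLRLM 16, GLSZM 16, NGTDM 5,
   GLDM 14) over the discretized ROI.
5. **Deep features** — a dynamic-convolution autoencoder ("DDCNN codec").
   Each convolution aggregates N candidate kernels with attention weights
   from a squeeze-and-excitation block,

   w₁ + w₂ + … + w_N = 1,  conv = Σᵢ wᵢ · convᵢ,

   so the effective kernel adapts per input. After unsupervised
   reconstruction training the frozen encoder maps an ROI crop to a
   100-vector.
6. **Fusion classifier** — radiomic ‖ deep (200 dims, z-scored on the
   training split) → MLP with widths 200-100-20-4, ReLU hidden layers and
   softmax output S_i = exp(y_i)/Σⱼ exp(y_j); argmax gives the type.

Evaluation reports the 4×4 confusion matrix, macro one-vs-rest accuracy
(AACC), macro sensitivity (ASEN), macro specificity (ASPE), overall
accuracy (trace/total) and one-vs-rest macro AUC. Everything is NumPy —
no deep-learning framework required — with exact hand-derived gradients
validated against finite differences.

## Worked example

Typing metrics of a published 163-case confusion matrix:

```python
import numpy as np
from placim.metrics import typing_metrics, round3

C = np.array([[62, 0, 1, 0],      # rows: true type, cols: predicted
              [4, 21, 7, 0],      # 0 none, 1 accreta, 2 increta, 3 percreta
              [3, 4, 50, 0],
              [0, 0, 1, 10]])
print({k: round3(v) for k, v in typing_metrics(C).items()})
```

```
{'aacc_macro': 0.939, 'asen': 0.857, 'aspe': 0.954, 'overall_accuracy': 0.877}
```

`overall_accuracy` is trace/total (143/163 = 0.877); `aacc_macro` is the
mean of per-class one-vs-rest accuracies — note the two differ and both
are always reported. ASEN 0.857 means the average per-grade recall;
ASPE 0.954 the average per-grade specificity.

Small end-to-end run from the shell:

```sh
placim generate --n-per-class 3 --size 64 --seed 5 --out phantoms
placim train-seg --manifest phantoms/manifest.csv --epochs 30 --out unet.ckpt
placim features --manifest phantoms/manifest.csv --extend 10 --out rad.csv
placim train-ddcnn --manifest phantoms/manifest.csv --extend 10 --out enc.ckpt
placim deep-features --encoder enc.ckpt --manifest phantoms/manifest.csv --out deep.csv
placim train-clf --radiomic rad.csv --deep deep.csv --labels phantoms/manifest.csv --out clf.ckpt
placim predict --model clf.ckpt --radiomic rad.csv --deep deep.csv --case ph0003
```

The last command prints, e.g.

```
{"case": "ph0003", "probabilities": [0.032737, 0.021675, 0.203698, 0.741891], "predicted_type": 3}
```

i.e. the case is typed percreta with probability ≈ 0.74. `placim run
--config cfg.yaml` executes the whole flow (case-level train/test split,
leakage-guarded) and `placim sweep` repeats the feature + classifier cycle
for several ROI extensions.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's main pipeline from scratch: it generates a seeded
phantom dataset, trains the U-net, extends ROIs, extracts both feature
families, trains the fusion classifier and evaluates the held-out split,
printing the typing metrics and writing the results JSON to `--out`.

## Layout

- `src/placim/phantom.py` — phantom generator
- `src/placim/unet.py`, `src/placim/ddcnn.py`, `src/placim/classifier.py`
  — the learners, on the NumPy layer stack in `src/placim/_nn/`
- `src/placim/roi.py`, `src/placim/radiomics/` — ROI building and the
  100-feature catalog
- `src/placim/metrics.py`, `src/placim/pipeline.py`, `src/placim/cli.py`
  — evaluation, orchestration, command line
- `docs/methods.md` — models, conventions, parameter choices, limitations
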