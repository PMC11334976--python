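# plasmocount

Automated detection, colour classification and counting of plasmonic
nanoparticles (NPs) in darkfield micrographs.

Metal nanoparticles conjugated to antibodies make bright, photostable
labels for membrane proteins: under darkfield (side) illumination each
particle appears as a diffraction-limited coloured spot whose hue is set by
its localized surface plasmon resonance — small Ag-rich alloy particles
scatter blue, intermediate alloys green, large Au particles yellow. Counting
each colour in an image therefore multiplexes protein detection without
fluorophores. `plasmocount` implements the image-analysis half of that
technique for anyone doing single-particle immunolabelling:

1. **Projection** — an RGB z-stack is collapsed by per-pixel, per-channel
   maximum-intensity projection.
2. **Detection** — particles are located as local maxima of the luminance
   after local-median background subtraction and Gaussian smoothing, with
   greedy minimum-separation suppression.
3. **Features** — each detection is summarized by the mean hue, saturation
   and value of the 5×5-pixel region of interest around it (hue averaged
   circularly), z-scored with statistics fitted on the training split.
4. **Classification** — a support-vector machine with RBF kernel
   `K(x, x') = exp(−γ‖x − x'‖²)` (one-vs-one voting), or a Gaussian naive
   Bayes baseline, assigns each particle to a colour class. Models are
   persisted as portable JSON, no pickles.
5. **Quantification** — per-class counts `n_k` are reported with an error
   bar propagated from the validation confusion matrix `c_{i,j}`
   (row-normalized by true-class support):

   `Δn_k = Σ_{i≠k} c_{i,k} n_i + n_k Σ_{j≠k} c_{k,j}`

   i.e. the expected false-positive inflow into class *k* plus the expected
   false-negative outflow from it.

Because classified training data come from single-NP-type **control
samples** (scenes containing one particle class only), the package includes
a synthetic-scene generator that renders darkfield-like z-stacks — Gaussian
PSF spots with class-dependent HSV colour, defocus attenuation, diffuse
membrane clutter, Poisson–Gaussian camera noise — together with exact ground
truth, so the whole pipeline is testable end to end without a microscope.

## Worked example

Train on rendered single-class control scenes with deliberately overlapping
hue clusters (`h_sd = 0.08`), then count a multiplexed scene that truly
contains 120 blue, 40 green and 25 yellow particles:

```python
import pandas as pd
from plasmocount import *

hard = default_colour_model(h_sd=0.08)  # overlapping hue clusters
corpus = pd.concat(
    [control_scene_features(cls, 400, seed, SceneParams(shape=(768, 768)), colours=hard)
     for cls, seed in [("blue", 101), ("green", 102), ("yellow", 103)]],
    ignore_index=True,
)
train, val = split_dataset(corpus, train_fraction=0.7, seed=42)
model = train_classifier(train, kind="svm_rbf")
cm = confusion_matrix(val["label"], model.predict(val), model.class_set)
print(cm.to_dataframe().round(3))

params = SceneParams(shape=(768, 768), counts={"blue": 120, "green": 40, "yellow": 25}, seed=9)
stack, truth = sample_scene(params, hard)
detections, features, labels, report = count_particles(stack, model, cm)
print(f"{len(detections)} particles detected")
for line in report.summary_lines():
    print(line)
```

Output:

```
         blue  green  yellow
blue    0.967  0.033   0.000
green   0.083  0.767   0.150
yellow  0.008  0.075   0.917
185 particles detected
112 ± 8 blue
44 ± 16 green
29 ± 9 yellow
```

The confusion matrix says 23% of true green particles are mislabelled under
this much hue overlap; the propagated error bars widen accordingly, and the
true counts (120/40/25) fall within them. With the default, well-separated
colour model the confusion matrix is the identity and every `Δn_k` is 0.

The same workflow is available from the shell:

```bash
plasmocount simulate --seed 1 --out-dir run/sim
plasmocount train --features labelled.csv --seed 42 --out-dir run/model
plasmocount count --input run/sim/stack.tif --model run/model/model.json --out-dir run/out
```

Each command writes its resolved configuration, a log with seeds and output
checksums, and CSV/JSON artifacts, so a run is reconstructable from its
output directory alone.

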