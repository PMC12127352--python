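# fascal

Training-free layer selection and feature calibration for few-shot plant
disease classification.

Rare crop diseases leave practitioners with a handful of labeled images per
class, so classification must run as an *N-way-K-shot* task: N novel
classes, K labeled support images each, queries assigned to the nearest
class prototype (the mean of the class's support embeddings) in a frozen
backbone's feature space. `fascal` implements two complementary,
training-free ideas for making that pipeline work well, plus everything
needed to evaluate them:

- **Feature Adaptation Score (FAS).** Not every depth of a backbone embeds
  disease images equally well — the penultimate block often beats the last
  one. For layer *l* with features of dimension *n*, class means μᵢ and
  global mean μ, FAS combines the between/within variance ratio with the
  dimension-scaled mean inter-centroid distance:

  σ²_within = (1/M) Σᵢ Σⱼ ‖x_ij − μᵢ‖²,  σ²_between = (1/N) Σᵢ ‖μᵢ − μ‖²,
  D̄ = 2/(N(N−1)) Σ_{i<j} ‖μᵢ − μⱼ‖,

  FAS = σ²_between / σ²_within + D̄ / √n.

  Higher FAS predicts higher few-shot accuracy for that layer's features;
  the best layer is the argmax across the bank.

- **Plant Disease Feature Calibration (PDFC).** A non-parametric correction
  using a large *reference bank* of source-domain feature vectors (e.g.
  embeddings of a curated corpus such as PlantVillage). For each episode
  class, the m reference vectors nearest its support prototype are averaged
  into a centroid; a target point T = (1−λ)·c_a + λ·c_b is placed between
  the prototype's two nearest centroids; the prototype is shifted exactly γ
  feature-space units toward T before classification. γ = 0 reduces exactly
  to the uncalibrated classifier. λ and γ are tuned by exhaustive grid
  search or by Gaussian-process Bayesian optimization with Expected
  Improvement.

The package also provides the episode harness (1000 episodes × 20 runs,
accuracy plus macro precision/recall/F1), an HDF5/TSV feature-bank store, a
pluggable image-folder extractor with a deterministic toy backbone, and a
synthetic generator (Gaussian class clusters, layer-separability series,
source/target covariate-shift pairs) so the entire system runs and is
tested without any dataset download.

## Worked example

```python
from fascal import GaussianClassSpec, make_layer_series, score_layers

bank = make_layer_series(
    GaussianClassSpec(n_classes=10, samples_per_class=50, seed=0),
    separabilities=[0.10, 0.15, 0.25, 0.45, 0.70, 1.00, 0.40],
    dims=[16, 16, 32, 32, 64, 64, 32],
)
report = score_layers(bank)
for c in report.components:
    print(c.layer_id, c.dim, round(c.fas, 4))
print("best layer:", report.best_layer)
```

prints (layer, dimension, FAS):

```
1 16 0.0952
2 16 0.1009
3 32 0.1174
4 32 0.1976
5 64 0.2103
6 64 0.3133
7 32 0.1631
best layer: 6
```

The score rises with the designed class separability of each synthetic
"layer" and peaks at layer 6 — the layer a practitioner should feed to the
few-shot classifier. Calibration on a shifted target
(`examples/03_calibration_under_shift.py`) then prints

```
baseline   : 53.59%
calibrated : 61.71%  (+8.12 points)
```

i.e. shifting each one-shot prototype γ = 0.9 units toward its reference
centroids raises 5-way-1-shot accuracy by ~8 points. The `examples/`
directory has one short script per capability (layer scoring, episode
evaluation, calibration, tuning, image extraction); each prints its numbers
with a note on what they mean.

A CLI mirrors the library for shell use:

```bash
fascal simulate layers --seed 3 --out bank.h5
fascal fas --bank bank.h5 --out report.json
fascal eval --bank bank.h5 --layer 6 --nway 5 --kshot 1 --episodes 1000 \
            --runs 20 --seed 0 --out summary.json
fascal tune --bank target.h5 --layer 0 --ref ref.h5 --method bayes --out tune.json
```

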