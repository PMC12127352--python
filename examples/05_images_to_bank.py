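"""Extract a layer feature bank from an image folder and store it.

Uses the deterministic toy backbone (seeded random projections) on a small
programmatically generated image tree, writes the bank to HDF5, reads it
back, and scores its layers — the same workflow a real backbone adapter
would feed.
"""

import tempfile
from pathlib import Path

import numpy as np
from PIL import Image

from fascal import read_feature_bank, score_layers, write_feature_bank
from fascal.extractor import extract_features, list_image_dataset, toy_backbone

workdir = Path(tempfile.mkdtemp())
rng = np.random.default_rng(0)
for cname in ["healthy", "blight", "rust"]:
    d = workdir / "images" / cname
    d.mkdir(parents=True)
    base = rng.integers(0, 256, (32, 32), dtype=np.uint8)  # class template
    for i in range(4):
        noisy = np.clip(base + rng.integers(-40, 40, base.shape), 0, 255)
        Image.fromarray(noisy.astype(np.uint8)).save(d / f"leaf_{i}.png")

manifest = list_image_dataset(workdir / "images")
backbone = toy_backbone(seed=0, depth=4, dims=[32, 32, 64, 16])
bank = extract_features(backbone, manifest)
write_feature_bank(bank, workdir / "bank.h5")

back = read_feature_bank(workdir / "bank.h5")
print(f"{len(manifest.records)} images, classes {back.class_names}, "
      f"layers {back.layer_ids}")
report = score_layers(back)
for c in report.components:
    print(f"layer {c.layer_id} (dim {c.dim}): FAS {c.fas:.4f}")
print(f"best layer: {report.best_layer}")
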