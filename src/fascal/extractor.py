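"""Bridge from image folders to layer feature banks.

An image dataset is a root directory with one subdirectory per class
containing PNG/JPEG files.  A *backbone handle* maps a batch of images to
one feature matrix per layer; the shipped ``toy_backbone`` is a
deterministic stack of seeded random projections with rectification, so the
whole extraction pipeline is testable without pretrained weights.  An
optional adapter for a real Swin-Transformer V2 backbone is provided for
users with a deep-learning runtime installed; it is never required.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from PIL import Image, UnidentifiedImageError

from .errors import ValidationError
from .feature_store import FeatureSet, LayerFeatureBank

_IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg"}


@dataclass(frozen=True)
class ManifestRecord:
    sample_id: str
    path: Path
    class_name: str
    class_index: int


@dataclass
class ImageManifest:
    """Deterministic listing of an image-folder dataset.

    Class indices are contiguous from 0, assigned by sorted class-name
    order; records are sorted by (class, filename).
    """

    root: Path
    records: list[ManifestRecord]
    class_names: list[str]

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.class_index for r in self.records], dtype=np.int64)


@dataclass
class BackboneHandle:
    """A named feature function over batches of images.

    ``features(batch, layers)`` maps a list of PIL images to a dict
    {layer_id: matrix} with one row per image.
    """

    name: str
    layer_ids: list[int]
    layer_dims: list[int]
    features: Callable[[Sequence[Image.Image], Sequence[int]], dict[int, np.ndarray]]


def list_image_dataset(root: str | Path) -> ImageManifest:
    """Enumerate ``root/<class>/<image>`` deterministically (sorted traversal)."""
    root = Path(root)
    if not root.is_dir():
        raise ValidationError(f"not a directory: {root}")
    class_dirs = sorted(p for p in root.iterdir() if p.is_dir())
    records: list[ManifestRecord] = []
    class_names: list[str] = []
    for cdir in class_dirs:
        files = sorted(
            p for p in cdir.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES
        )
        if not files:
            continue
        class_names.append(cdir.name)
        ci = len(class_names) - 1
        for f in files:
            try:
                with Image.open(f) as im:
                    im.verify()
            except (UnidentifiedImageError, OSError) as e:
                raise ValidationError(f"cannot decode image {f}: {e}") from e
            records.append(
                ManifestRecord(
                    sample_id=f"{cdir.name}/{f.name}",
                    path=f,
                    class_name=cdir.name,
                    class_index=ci,
                )
            )
    if not records:
        raise ValidationError(f"no class subdirectories with images under {root}")
    return ImageManifest(root=root, records=records, class_names=class_names)


def _preprocess(im: Image.Image, side: int) -> np.ndarray:
    """Decode -> resize to side x side -> grayscale -> flat float vector in [0,1]."""
    g = im.convert("L").resize((side, side), Image.BILINEAR)
    return np.asarray(g, dtype=np.float64).ravel() / 255.0


def toy_backbone(
    seed: int = 0,
    depth: int = 7,
    dims: Sequence[int] = (16, 16, 32, 32, 64, 64, 32),
    input_side: int = 32,
) -> BackboneHandle:
    """Deterministic stack of seeded random projections with rectification.

    Layer l (1-based) outputs ``relu(W_l h_{l-1})`` of width ``dims[l-1]``;
    identical images always give identical features.
    """
    dims = list(dims)
    if depth != len(dims):
        raise ValidationError(f"depth {depth} != len(dims) {len(dims)}")
    if any(d < 1 for d in dims):
        raise ValidationError("layer dims must be positive")
    rng = np.random.default_rng(seed)
    in_dim = input_side * input_side
    weights = []
    prev = in_dim
    for d in dims:
        weights.append(rng.standard_normal((prev, d)) / np.sqrt(prev))
        prev = d

    def features(
        batch: Sequence[Image.Image], layers: Sequence[int]
    ) -> dict[int, np.ndarray]:
        wanted = set(layers)
        h = np.stack([_preprocess(im, input_side) for im in batch])
        out: dict[int, np.ndarray] = {}
        for l, w in enumerate(weights, start=1):
            h = np.maximum(h @ w, 0.0)
            if l in wanted:
                out[l] = h.astype(np.float32)
        return out

    return BackboneHandle(
        name=f"toy(seed={seed})",
        layer_ids=list(range(1, depth + 1)),
        layer_dims=dims,
        features=features,
    )


def extract_features(
    bb: BackboneHandle,
    manifest: ImageManifest,
    layers: Sequence[int] | None = None,
    batch_size: int = 32,
) -> LayerFeatureBank:
    """Run the backbone over the manifest and assemble a layer feature bank.

    Row order follows the manifest; batching is invisible in the result.
    """
    layers = list(layers) if layers is not None else list(bb.layer_ids)
    unknown = set(layers) - set(bb.layer_ids)
    if unknown:
        raise ValidationError(f"unknown layer ids {sorted(unknown)}")
    chunks: dict[int, list[np.ndarray]] = {l: [] for l in layers}
    recs = manifest.records
    for start in range(0, len(recs), batch_size):
        batch_recs = recs[start : start + batch_size]
        ims = []
        for r in batch_recs:
            try:
                with Image.open(r.path) as im:
                    ims.append(im.convert("L").copy())
            except (UnidentifiedImageError, OSError) as e:
                raise ValidationError(f"cannot decode image {r.path}: {e}") from e
        out = bb.features(ims, layers)
        for l in layers:
            chunks[l].append(out[l])
    labels = manifest.labels
    bank = LayerFeatureBank(
        layers={
            l: FeatureSet(
                features=np.vstack(chunks[l]),
                labels=labels,
                class_names=manifest.class_names,
                layer_id=l,
            )
            for l in layers
        },
        sample_ids=[r.sample_id for r in recs],
        class_names=manifest.class_names,
    )
    return bank.validate()


def swin_v2_adapter(*args, **kwargs):  # pragma: no cover - needs torch
    """Adapter for a real Swin-Transformer V2 backbone (requires torch).

    Pools each block's token grid by global average to a single vector per
    image.  Raises ImportError with guidance when no deep-learning runtime
    is installed; nothing in the package requires it.
    """
    try:
        import torch  # noqa: F401
        import torchvision  # noqa: F401
    except ImportError as e:
        raise ImportError(
            "swin_v2_adapter requires torch and torchvision; install them to "
            "extract real backbone features (the toy backbone needs neither)"
        ) from e
    raise NotImplementedError(
        "hook the torchvision swin_v2_t feature pyramid here; "
        "kept out of the supported surface"
    )
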