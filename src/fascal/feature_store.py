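"""Labeled feature banks: in-memory model and HDF5 / TSV serialization.

A *feature set* is one layer's embedding matrix with an integer class label
per row.  A *layer feature bank* collects feature sets of the same samples
captured at several depths of one backbone (dimensions may differ per layer).
A *reference bank* is a feature set playing the role of source-domain
features (e.g. embeddings of the PlantVillage training set) used by the
calibration algorithm; its labels are optional diagnostics.

Storage is float32 (typical backbone output precision); all statistics
elsewhere in the package are computed in float64.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

FORMAT_VERSION = "1"


@dataclass
class FeatureSet:
    """One layer's embeddings with per-sample class labels.

    Parameters
    ----------
    features
        Real matrix, rows = samples, columns = embedding dimensions.
    labels
        Integer vector, one label per row, values in ``0..C-1``; every
        class index must occur at least once.
    class_names
        Optional list of the C original class-name strings.
    layer_id
        Integer identifier of the producing layer.
    """

    features: np.ndarray
    labels: np.ndarray
    class_names: list[str] | None = None
    layer_id: int = 0

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features)
        if self.features.ndim == 1:
            self.features = self.features.reshape(-1, 1)
        self.labels = np.asarray(self.labels, dtype=np.int64).ravel()

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def dim(self) -> int:
        return self.features.shape[1]

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    def validate(self) -> "FeatureSet":
        """Check every invariant; raise :class:`ValidationError` naming the rule."""
        if self.features.ndim != 2:
            raise ValidationError(
                f"features must be a 2-D matrix, got ndim={self.features.ndim}"
            )
        if self.features.shape[0] != self.labels.shape[0]:
            raise ValidationError(
                "row count of features must equal length of labels: "
                f"{self.features.shape[0]} != {self.labels.shape[0]}"
            )
        if self.features.shape[0] == 0:
            raise ValidationError("feature set must contain at least one sample")
        if not np.all(np.isfinite(self.features)):
            raise ValidationError("all feature values must be finite")
        if self.labels.min(initial=0) < 0:
            raise ValidationError("labels must be non-negative 0-based class indices")
        c = self.n_classes
        present = np.unique(self.labels)
        if present.size != c:
            missing = sorted(set(range(c)) - set(present.tolist()))
            raise ValidationError(
                f"every class index in 0..{c - 1} must appear at least once; "
                f"missing {missing}"
            )
        if self.class_names is not None and len(self.class_names) != c:
            raise ValidationError(
                f"class_names length {len(self.class_names)} must equal "
                f"number of classes {c}"
            )
        return self

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureSet):
            return NotImplemented
        return (
            self.layer_id == other.layer_id
            and np.array_equal(self.features, other.features)
            and np.array_equal(self.labels, other.labels)
            and (self.class_names or None) == (other.class_names or None)
        )


@dataclass
class LayerFeatureBank:
    """Ordered collection of FeatureSets over the same samples, one per layer."""

    layers: dict[int, FeatureSet]
    sample_ids: list[str]
    class_names: list[str] | None = None
    metadata: dict = field(default_factory=dict)  # not serialized

    def __post_init__(self) -> None:
        # keep layers sorted by layer_id
        self.layers = dict(sorted(self.layers.items()))

    @property
    def layer_ids(self) -> list[int]:
        return list(self.layers)

    @property
    def labels(self) -> np.ndarray:
        return next(iter(self.layers.values())).labels

    def validate(self) -> "LayerFeatureBank":
        if not self.layers:
            raise ValidationError("bank must contain at least one layer")
        ids = self.layer_ids
        if any(b <= a for a, b in zip(ids, ids[1:])):
            raise ValidationError("layer_ids must be strictly increasing")
        ref = None
        for lid, fs in self.layers.items():
            if fs.layer_id != lid:
                raise ValidationError(
                    f"layer key {lid} does not match FeatureSet.layer_id {fs.layer_id}"
                )
            fs.validate()
            if ref is None:
                ref = fs
            else:
                if fs.n_samples != ref.n_samples:
                    raise ValidationError(
                        "every FeatureSet must have identical row count: "
                        f"layer {lid} has {fs.n_samples}, expected {ref.n_samples}"
                    )
                if not np.array_equal(fs.labels, ref.labels):
                    raise ValidationError(
                        f"every FeatureSet must have an identical label vector; "
                        f"layer {lid} differs"
                    )
        if len(self.sample_ids) != ref.n_samples:
            raise ValidationError(
                f"sample_ids length {len(self.sample_ids)} must equal "
                f"sample count {ref.n_samples}"
            )
        return self

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LayerFeatureBank):
            return NotImplemented
        return (
            self.layer_ids == other.layer_ids
            and all(self.layers[i] == other.layers[i] for i in self.layer_ids)
            and self.sample_ids == other.sample_ids
            and (self.class_names or None) == (other.class_names or None)
        )


@dataclass
class ReferenceBank:
    """Source-domain feature vectors used to build calibration centroids.

    Labels are optional and unused by the calibration algorithm itself.
    """

    features: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features)
        if self.features.ndim == 1:
            self.features = self.features.reshape(-1, 1)

    @property
    def n_rows(self) -> int:
        return self.features.shape[0]

    @property
    def dim(self) -> int:
        return self.features.shape[1]

    def validate(self) -> "ReferenceBank":
        if self.features.ndim != 2 or self.features.shape[0] == 0:
            raise ValidationError("reference bank must be a non-empty 2-D matrix")
        if not np.all(np.isfinite(self.features)):
            raise ValidationError("all reference feature values must be finite")
        return self


# ---------------------------------------------------------------------------
# HDF5 serialization
#
# Layout: group /layer_<l> with dataset `features` (float32, M x n); root
# datasets `labels` (int32, M), `sample_ids` (UTF-8, M), `class_names`
# (UTF-8, C); root attribute format_version = "1".
# ---------------------------------------------------------------------------

_STR = h5py.string_dtype(encoding="utf-8")


def write_feature_bank(bank: LayerFeatureBank, path: str | Path) -> None:
    """Write a validated bank to *path* in the canonical HDF5 layout."""
    bank.validate()
    path = Path(path)
    # track_times=False keeps the file byte-stable across rewrites
    with h5py.File(path, "w", track_order=True) as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.create_dataset(
            "labels", data=bank.labels.astype(np.int32), track_times=False
        )
        f.create_dataset(
            "sample_ids",
            data=np.array(bank.sample_ids, dtype=object),
            dtype=_STR,
            track_times=False,
        )
        if bank.class_names is not None:
            f.create_dataset(
                "class_names",
                data=np.array(bank.class_names, dtype=object),
                dtype=_STR,
                track_times=False,
            )
        for lid, fs in bank.layers.items():
            g = f.create_group(f"layer_{lid}")
            g.create_dataset(
                "features", data=fs.features.astype(np.float32), track_times=False
            )


def read_feature_bank(path: str | Path) -> LayerFeatureBank:
    """Read a bank written by :func:`write_feature_bank`; raise on malformed files."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    with h5py.File(path, "r") as f:
        if "labels" not in f:
            raise FormatError("missing required dataset 'labels'")
        labels = np.asarray(f["labels"], dtype=np.int64)
        if "sample_ids" not in f:
            raise FormatError("missing required dataset 'sample_ids'")
        sample_ids = [s.decode() if isinstance(s, bytes) else str(s)
                      for s in f["sample_ids"]]
        class_names = None
        if "class_names" in f:
            class_names = [s.decode() if isinstance(s, bytes) else str(s)
                           for s in f["class_names"]]
        layers: dict[int, FeatureSet] = {}
        for key in f:
            if not key.startswith("layer_"):
                continue
            try:
                lid = int(key.split("_", 1)[1])
            except ValueError as e:
                raise FormatError(f"malformed layer group name {key!r}") from e
            if "features" not in f[key]:
                raise FormatError(f"group '{key}' is missing dataset 'features'")
            feats = np.asarray(f[key]["features"], dtype=np.float32)
            layers[lid] = FeatureSet(
                features=feats, labels=labels,
                class_names=class_names, layer_id=lid,
            )
        if not layers:
            raise FormatError("file contains no 'layer_<l>' groups")
    bank = LayerFeatureBank(layers=layers, sample_ids=sample_ids,
                            class_names=class_names)
    try:
        bank.validate()
    except ValidationError as e:
        raise FormatError(f"file does not satisfy bank invariants: {e}") from e
    return bank


# ---------------------------------------------------------------------------
# TSV dialect (single-layer sets): sample_id \t label \t f1 ... fn
# ---------------------------------------------------------------------------


def write_feature_set_tsv(fs: FeatureSet, path: str | Path,
                          sample_ids: list[str] | None = None) -> None:
    """Write one FeatureSet as tab-separated text (single-layer fallback)."""
    fs.validate()
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(fs.n_samples)]
    cols = {"sample_id": sample_ids, "label": fs.labels}
    feats = fs.features.astype(np.float32)
    for j in range(fs.dim):
        cols[f"f{j + 1}"] = feats[:, j]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_feature_set_tsv(path: str | Path, layer_id: int = 0) -> tuple[FeatureSet, list[str]]:
    """Read the TSV dialect; returns the set and its sample ids."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "label"):
        if col not in df.columns:
            raise FormatError(f"TSV is missing required column '{col}'")
    feat_cols = [c for c in df.columns if c not in ("sample_id", "label")]
    if not feat_cols:
        raise FormatError("TSV contains no feature columns")
    fs = FeatureSet(
        features=df[feat_cols].to_numpy(dtype=np.float32),
        labels=df["label"].to_numpy(dtype=np.int64),
        layer_id=layer_id,
    )
    try:
        fs.validate()
    except ValidationError as e:
        raise FormatError(f"TSV does not satisfy feature-set invariants: {e}") from e
    return fs, df["sample_id"].astype(str).tolist()
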