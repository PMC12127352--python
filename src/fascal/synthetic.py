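"""Synthetic feature-bank generators with known ground truth.

Everything downstream (layer scoring, episode evaluation, calibration,
hyperparameter search) is testable against these generators without any
dataset download:

* Gaussian class clusters — class means placed deterministically on a
  sphere of radius ``between_scale`` along maximally spread (orthonormal)
  directions, isotropic within-class noise of standard deviation
  ``within_scale``;
* an ordered series of "layers" of differing dimension and separability,
  emulating the feature family a deep backbone emits at its successive
  blocks, with the designed separability peak recorded as ground truth;
* a source/target pair with covariate shift — the target shares the source
  class structure but every sample is displaced by one fixed global bias
  vector of known norm, plus optional extra noise.  This is the regime the
  calibration algorithm is designed to correct.

All generators are fully deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ValidationError
from .feature_store import FeatureSet, LayerFeatureBank, ReferenceBank


@dataclass(frozen=True)
class GaussianClassSpec:
    """Isotropic Gaussian class clusters in ``dim`` dimensions."""

    n_classes: int = 10
    samples_per_class: int = 50
    dim: int = 32
    between_scale: float = 0.9
    within_scale: float = 0.3
    seed: int = 0

    def validate(self) -> "GaussianClassSpec":
        if min(self.n_classes, self.samples_per_class, self.dim) < 1:
            raise ValidationError("all counts must be positive")
        if not (np.isfinite(self.between_scale) and self.between_scale >= 0):
            raise ValidationError("between_scale must be finite and >= 0")
        if not (np.isfinite(self.within_scale) and self.within_scale >= 0):
            raise ValidationError("within_scale must be finite and >= 0")
        return self


@dataclass(frozen=True)
class ShiftSpec:
    """Source/target pair: shared class means, global target bias."""

    base: GaussianClassSpec = GaussianClassSpec()
    bank_size_per_class: int = 30
    bias_norm: float = 0.9
    extra_noise: float = 0.0
    seed: int = 0

    def validate(self) -> "ShiftSpec":
        self.base.validate()
        if self.bank_size_per_class < 1:
            raise ValidationError("bank_size_per_class must be >= 1")
        if not (np.isfinite(self.bias_norm) and self.bias_norm >= 0):
            raise ValidationError("bias_norm must be finite and >= 0")
        if not (np.isfinite(self.extra_noise) and self.extra_noise >= 0):
            raise ValidationError("extra_noise must be finite and >= 0")
        return self


@dataclass
class ShiftPair:
    """A generated source/target pair with its ground-truth displacement."""

    reference: ReferenceBank
    target: FeatureSet
    bias: np.ndarray          # the fixed global offset added to every target sample
    class_means: np.ndarray   # source-domain class means (C x dim)


def _class_directions(n_classes: int, dim: int, rng: np.random.Generator) -> np.ndarray:
    """Deterministic maximally spread unit directions.

    The first min(n_classes, dim) directions form a seeded random orthonormal
    basis (QR of a Gaussian matrix); any surplus classes get normalized
    Gaussian draws.
    """
    k = min(n_classes, dim)
    g = rng.standard_normal((dim, k))
    q, r = np.linalg.qr(g)
    q = q * np.sign(np.diag(r))  # fix QR sign ambiguity for determinism
    dirs = q.T[:k]
    if n_classes > k:
        extra = rng.standard_normal((n_classes - k, dim))
        extra /= np.linalg.norm(extra, axis=1, keepdims=True)
        dirs = np.vstack([dirs, extra])
    return dirs


def class_mean_matrix(spec: GaussianClassSpec) -> np.ndarray:
    """The exact class means the generator uses (ground truth)."""
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 0xC1A55)))
    return spec.between_scale * _class_directions(spec.n_classes, spec.dim, rng)


def make_gaussian_classes(spec: GaussianClassSpec, layer_id: int = 0) -> FeatureSet:
    """Sample a labeled feature set from the spec's Gaussian clusters."""
    spec.validate()
    means = class_mean_matrix(spec)
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 0x5A3B1E)))
    m = spec.n_classes * spec.samples_per_class
    labels = np.repeat(np.arange(spec.n_classes), spec.samples_per_class)
    x = means[labels] + spec.within_scale * rng.standard_normal((m, spec.dim))
    return FeatureSet(
        features=x.astype(np.float32), labels=labels, layer_id=layer_id
    ).validate()


def make_layer_series(
    base: GaussianClassSpec,
    separabilities: list[float],
    dims: list[int],
) -> LayerFeatureBank:
    """Bank of layers sharing one label vector, with layer k drawn at
    between-scale ``base.between_scale * separabilities[k]`` and dimension
    ``dims[k]``.  Layer ids are 1-based.  The designed argmax of
    separability is recorded in ``metadata["designed_best_layer"]``."""
    base.validate()
    if len(separabilities) != len(dims):
        raise ValidationError("separabilities and dims must have equal length")
    if not separabilities:
        raise ValidationError("layer series must be non-empty")
    layers: dict[int, FeatureSet] = {}
    for k, (sep, dim) in enumerate(zip(separabilities, dims)):
        lid = k + 1
        spec_k = replace(
            base,
            dim=int(dim),
            between_scale=base.between_scale * float(sep),
            seed=base.seed * 1000 + lid,
        )
        layers[lid] = make_gaussian_classes(spec_k, layer_id=lid)
    sample_ids = [f"s{i}" for i in range(base.n_classes * base.samples_per_class)]
    designed = int(np.argmax(separabilities)) + 1  # ties -> earliest, like argmax
    bank = LayerFeatureBank(
        layers=layers,
        sample_ids=sample_ids,
        metadata={"designed_best_layer": designed},
    )
    return bank.validate()


def make_shift_pair(spec: ShiftSpec) -> ShiftPair:
    """Reference bank from the base Gaussians plus a target set displaced by
    one fixed global bias vector of norm ``bias_norm`` (plus
    ``extra_noise``-scale isotropic noise)."""
    spec.validate()
    base = spec.base
    means = class_mean_matrix(base)
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 0x5317F7)))

    # source-domain reference bank
    bank_labels = np.repeat(np.arange(base.n_classes), spec.bank_size_per_class)
    bank_x = means[bank_labels] + base.within_scale * rng.standard_normal(
        (bank_labels.size, base.dim)
    )
    ref = ReferenceBank(
        features=bank_x.astype(np.float32), labels=bank_labels
    ).validate()

    # fixed global bias of exactly the requested norm
    if spec.bias_norm > 0:
        b = rng.standard_normal(base.dim)
        b *= spec.bias_norm / np.linalg.norm(b)
    else:
        b = np.zeros(base.dim)

    tgt_labels = np.repeat(np.arange(base.n_classes), base.samples_per_class)
    noise = base.within_scale * rng.standard_normal((tgt_labels.size, base.dim))
    if spec.extra_noise > 0:
        noise = noise + spec.extra_noise * rng.standard_normal(noise.shape)
    tgt_x = means[tgt_labels] + b + noise
    target = FeatureSet(
        features=tgt_x.astype(np.float32), labels=tgt_labels
    ).validate()
    return ShiftPair(reference=ref, target=target, bias=b, class_means=means)
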