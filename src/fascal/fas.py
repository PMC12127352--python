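"""Feature Adaptation Score: layer-wise feature-quality scoring.

For each backbone layer l, three statistics are computed from the labeled
embeddings:

* within-class variance  sigma^2_within  = (1/M) sum_i sum_j ||x_ij - mu_i||^2
* between-class variance sigma^2_between = (1/N) sum_i ||mu_i - mu||^2
* mean between-class distance Dbar = 2/(N(N-1)) sum_{i<j} ||mu_i - mu_j||
  (unsquared Euclidean distance between class means)

and combined into

    FAS_l = sigma^2_between / sigma^2_within  +  Dbar / sqrt(n)

where n is the feature dimension of layer l, so that layers of differing
width are compared on one scale.  Higher FAS predicts better few-shot
nearest-prototype accuracy for that layer's features; the best layer is the
argmax (ties broken toward the deeper layer).

Class sizes may be unequal: the formulas use per-class and total sample
counts, which reduce to the balanced N*K form when all classes have K
samples.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .feature_store import FeatureSet, LayerFeatureBank

#: floor on sigma^2_within to avoid division by zero on collapsed features
EPS_WITHIN = 1e-12


@dataclass(frozen=True)
class ClassMeans:
    """Per-class mean feature vectors and the global mean.

    ``global_mean`` is the mean over all samples, i.e. the sample-count-
    weighted average of the class means.
    """

    means: np.ndarray       # C x n, row i = mean of class-i rows
    global_mean: np.ndarray  # n
    counts: np.ndarray      # C, samples per class


@dataclass(frozen=True)
class FASComponents:
    """The three FAS statistics, the dimension, and their combination."""

    layer_id: int
    within_var: float
    between_var: float
    mean_between_dist: float
    dim: int
    fas: float

    def to_dict(self) -> dict:
        return {
            "layer_id": self.layer_id,
            "within_var": self.within_var,
            "between_var": self.between_var,
            "mean_between_dist": self.mean_between_dist,
            "dim": self.dim,
            "fas": self.fas,
        }


@dataclass(frozen=True)
class FASReport:
    """Per-layer FAS components, ordered by layer_id, plus the selected layer."""

    components: list[FASComponents]
    best_layer: int


def class_means(fs: FeatureSet) -> ClassMeans:
    """Arithmetic mean per class and the global mean over all samples."""
    fs.validate()
    x = fs.features.astype(np.float64)
    labels = fs.labels
    c = fs.n_classes
    counts = np.bincount(labels, minlength=c).astype(np.int64)
    if np.any(counts == 0):
        raise ValidationError("every class must be non-empty")
    sums = np.zeros((c, x.shape[1]))
    np.add.at(sums, labels, x)
    means = sums / counts[:, None]
    return ClassMeans(means=means, global_mean=x.mean(axis=0), counts=counts)


def within_class_variance(fs: FeatureSet, cm: ClassMeans) -> float:
    """Mean squared distance of each sample from its class mean."""
    x = fs.features.astype(np.float64)
    diffs = x - cm.means[fs.labels]
    return float(np.einsum("ij,ij->", diffs, diffs) / x.shape[0])


def between_class_variance(cm: ClassMeans) -> float:
    """Mean squared distance of each class mean from the global mean."""
    n_classes = cm.means.shape[0]
    if n_classes < 2:
        raise ValidationError("between-class variance requires at least 2 classes")
    diffs = cm.means - cm.global_mean
    return float(np.einsum("ij,ij->", diffs, diffs) / n_classes)


def mean_between_class_distance(cm: ClassMeans, squared: bool = False) -> float:
    """Average pairwise Euclidean distance between class means.

    ``squared=True`` averages squared distances instead (alternate reading
    of the between-class distance; off by default).
    """
    n_classes = cm.means.shape[0]
    if n_classes < 2:
        raise ValidationError("mean between-class distance requires at least 2 classes")
    from scipy.spatial.distance import pdist

    d = pdist(cm.means, metric="sqeuclidean" if squared else "euclidean")
    return float(d.mean())


def fas_score(
    fs: FeatureSet,
    *,
    scale_by: str = "dim",
    dbar_squared: bool = False,
) -> FASComponents:
    """Compute all FAS components for one layer's feature set.

    Parameters
    ----------
    scale_by
        ``"dim"`` (default) scales Dbar by the square root of the feature
        dimension; ``"count"`` uses the sample count instead.
    dbar_squared
        Average squared rather than plain pairwise distances between class
        means.
    """
    if scale_by not in ("dim", "count"):
        raise ValidationError(f"scale_by must be 'dim' or 'count', got {scale_by!r}")
    cm = class_means(fs)
    if cm.means.shape[0] < 2:
        raise ValidationError("FAS requires at least 2 classes")
    within = within_class_variance(fs, cm)
    between = between_class_variance(cm)
    dbar = mean_between_class_distance(cm, squared=dbar_squared)
    if within < EPS_WITHIN:
        warnings.warn(
            f"within-class variance {within:.3g} below floor {EPS_WITHIN:.0e}; "
            "features are (nearly) collapsed onto class means",
            stacklevel=2,
        )
    n = fs.dim if scale_by == "dim" else fs.n_samples
    fas = between / max(within, EPS_WITHIN) + dbar / math.sqrt(n)
    return FASComponents(
        layer_id=fs.layer_id,
        within_var=within,
        between_var=between,
        mean_between_dist=dbar,
        dim=fs.dim,
        fas=fas,
    )


def score_layers(
    bank: LayerFeatureBank,
    *,
    scale_by: str = "dim",
    dbar_squared: bool = False,
) -> FASReport:
    """Score every layer of a bank and select the best one."""
    bank.validate()
    components = []
    for lid, fs in bank.layers.items():
        try:
            components.append(
                fas_score(fs, scale_by=scale_by, dbar_squared=dbar_squared)
            )
        except ValidationError as e:
            raise ValidationError(f"layer {lid}: {e}") from e
    report = FASReport(components=components, best_layer=0)
    return FASReport(components=components, best_layer=select_best_layer(report))


def select_best_layer(report: FASReport) -> int:
    """Layer id attaining the maximal FAS; ties go to the larger layer id.

    The deeper layer wins a tie, reflecting the usual preference for later
    (more abstract) features when the score cannot distinguish them.
    """
    if not report.components:
        raise ValidationError("report must contain at least one layer")
    best = report.components[0]
    for comp in report.components[1:]:
        if comp.fas >= best.fas:  # >= : later (larger layer_id) wins ties
            best = comp
    return best.layer_id
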