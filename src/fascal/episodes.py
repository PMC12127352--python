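"""N-way-K-shot episode sampling, nearest-prototype classification, and the
multi-run evaluation protocol.

An *episode* is one few-shot task: N classes drawn uniformly without
replacement from the feature set, K labeled support samples and q query
samples per class (disjoint, drawn without replacement), class indices
remapped to 0..N-1.  Each class prototype is the mean of its support
embeddings; a query is assigned to the class of its nearest prototype.

The evaluation protocol samples ``episodes_per_run`` episodes per run for
``runs`` independent runs (mirroring the convention of averaging 20 runs of
1000 sampled tasks each), reporting mean/std accuracy over all episodes and
macro precision/recall/F1 pooled over all queries.

RNG contract: a single integer seed; run r uses the independent substream
``numpy.random.SeedSequence((seed, r))``, so runs are reproducible
individually and jointly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.metrics import precision_recall_fscore_support

from .errors import ValidationError
from .feature_store import FeatureSet


@dataclass(frozen=True)
class EpisodeSpec:
    """Shape of one N-way-K-shot task."""

    n_way: int = 5
    k_shot: int = 1
    q_per_class: int = 15
    metric: str = "euclidean"  # or "cosine"

    def validate(self) -> "EpisodeSpec":
        if self.n_way < 1 or self.k_shot < 1 or self.q_per_class < 1:
            raise ValidationError("n_way, k_shot and q_per_class must be positive")
        if self.metric not in ("euclidean", "cosine"):
            raise ValidationError(f"unknown metric {self.metric!r}")
        return self


@dataclass
class Episode:
    """One sampled task with class indices remapped to 0..N-1."""

    support_features: np.ndarray  # (N*K) x n
    support_labels: np.ndarray    # 0..N-1
    query_features: np.ndarray    # (N*q) x n
    query_labels: np.ndarray      # 0..N-1
    class_map: np.ndarray         # episode index -> original class id

    @property
    def n_way(self) -> int:
        return len(self.class_map)


@dataclass(frozen=True)
class PrototypeSet:
    """Per-class support means, row k = prototype of episode class k."""

    prototypes: np.ndarray  # N x n


@dataclass
class EvaluationSummary:
    """Aggregate of an episode-protocol evaluation."""

    mean_accuracy: float
    std_accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    episodes_per_run: int
    runs: int
    spec: EpisodeSpec
    calibration: object | None = None
    episode_accuracies: np.ndarray | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "mean_accuracy": self.mean_accuracy,
            "std_accuracy": self.std_accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "episodes_per_run": self.episodes_per_run,
            "runs": self.runs,
            "n_way": self.spec.n_way,
            "k_shot": self.spec.k_shot,
            "q_per_class": self.spec.q_per_class,
            "metric": self.spec.metric,
        }


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------


def _class_indices(fs: FeatureSet) -> list[np.ndarray]:
    return [np.flatnonzero(fs.labels == c) for c in range(fs.n_classes)]


def sample_episode(
    fs: FeatureSet,
    spec: EpisodeSpec,
    rng: np.random.Generator,
    _class_idx: list[np.ndarray] | None = None,
) -> Episode:
    """Draw one episode: N classes uniformly without replacement, then K+q
    samples per class without replacement (support first, then queries).
    Deterministic under a fixed generator state."""
    spec.validate()
    n, k, q = spec.n_way, spec.k_shot, spec.q_per_class
    idx = _class_idx if _class_idx is not None else _class_indices(fs)
    if fs.n_classes < n:
        raise ValidationError(
            f"need at least {n} classes, feature set has {fs.n_classes}"
        )
    deficient = [c for c, ix in enumerate(idx) if ix.size < k + q]
    if deficient:
        raise ValidationError(
            f"classes {deficient} have fewer than K+q={k + q} samples"
        )
    chosen = rng.choice(fs.n_classes, size=n, replace=False)
    sup_rows, qry_rows = [], []
    for c in chosen:
        picked = rng.choice(idx[c], size=k + q, replace=False)
        sup_rows.append(picked[:k])
        qry_rows.append(picked[k:])
    sup = np.concatenate(sup_rows)
    qry = np.concatenate(qry_rows)
    x = fs.features
    return Episode(
        support_features=np.asarray(x[sup], dtype=np.float64),
        support_labels=np.repeat(np.arange(n), k),
        query_features=np.asarray(x[qry], dtype=np.float64),
        query_labels=np.repeat(np.arange(n), q),
        class_map=np.asarray(chosen),
    )


# ---------------------------------------------------------------------------
# distances and classification
# ---------------------------------------------------------------------------


def euclidean_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Plain L2 distance between two vectors."""
    a, b = np.asarray(a, dtype=np.float64), np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValidationError(f"dimension mismatch: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a - b))


def cosine_distance(a: np.ndarray, b: np.ndarray) -> float:
    """1 minus the cosine similarity; in [0, 2] for nonzero vectors."""
    a, b = np.asarray(a, dtype=np.float64), np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValidationError(f"dimension mismatch: {a.shape} vs {b.shape}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValidationError("cosine distance is undefined for zero vectors")
    return float(1.0 - np.dot(a, b) / (na * nb))


def compute_prototypes(ep: Episode) -> PrototypeSet:
    """Per-class support means (with K=1 the support rows themselves)."""
    n = ep.n_way
    protos = np.empty((n, ep.support_features.shape[1]))
    for c in range(n):
        protos[c] = ep.support_features[ep.support_labels == c].mean(axis=0)
    return PrototypeSet(prototypes=protos)


def classify_queries(
    protos: PrototypeSet | np.ndarray,
    queries: np.ndarray,
    metric: str = "euclidean",
) -> np.ndarray:
    """Assign each query to its nearest prototype.

    Ties are broken by the smallest class index (argmin convention).
    """
    p = protos.prototypes if isinstance(protos, PrototypeSet) else np.asarray(protos)
    queries = np.asarray(queries, dtype=np.float64)
    if queries.shape[1] != p.shape[1]:
        raise ValidationError(
            f"query dimension {queries.shape[1]} != prototype dimension {p.shape[1]}"
        )
    d = cdist(queries, p, metric=metric)
    return np.argmin(d, axis=1)  # np.argmin returns the first (lowest) index on ties


def episode_accuracy(pred: np.ndarray, truth: np.ndarray) -> float:
    """Fraction of exact label matches."""
    pred, truth = np.asarray(pred), np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValidationError("pred and truth must have equal length")
    return float(np.mean(pred == truth))


def macro_metrics(
    pred: np.ndarray, truth: np.ndarray, n_classes: int
) -> tuple[float, float, float]:
    """Macro-averaged precision, recall and F1.

    Per-class values with a zero denominator (class never predicted, or
    absent from the truth) contribute 0, with a warning.
    """
    pred, truth = np.asarray(pred), np.asarray(truth)
    if pred.min(initial=0) < 0 or pred.max(initial=0) >= n_classes:
        raise ValidationError("predicted label out of range")
    if truth.min(initial=0) < 0 or truth.max(initial=0) >= n_classes:
        raise ValidationError("true label out of range")
    if len(set(range(n_classes)) - set(np.unique(pred))) > 0:
        warnings.warn(
            "some classes never predicted; their precision counts as 0",
            stacklevel=2,
        )
    p, r, f1, _ = precision_recall_fscore_support(
        truth, pred, labels=np.arange(n_classes), average="macro", zero_division=0
    )
    return float(p), float(r), float(f1)


# ---------------------------------------------------------------------------
# protocol engine
# ---------------------------------------------------------------------------

Calibrator = Callable[[Episode, np.ndarray], np.ndarray]
"""Maps (episode, raw prototypes) -> calibrated prototypes of the same shape."""


def run_evaluation(
    fs: FeatureSet,
    spec: EpisodeSpec,
    episodes_per_run: int = 1000,
    runs: int = 20,
    calibrator: Optional[Calibrator] = None,
    seed: int = 0,
    keep_episode_accuracies: bool = False,
) -> EvaluationSummary:
    """Run the full episode protocol and aggregate the results.

    Each run r draws ``episodes_per_run`` episodes from the substream
    ``SeedSequence((seed, r))``.  The optional *calibrator* transforms each
    episode's support prototypes before classification.  Accuracy statistics
    are over episodes; macro precision/recall/F1 pool all query predictions.
    """
    fs.validate()
    spec.validate()
    class_idx = _class_indices(fs)
    accs = np.empty(runs * episodes_per_run)
    # pooled confusion counts over all queries
    all_pred, all_truth = [], []
    i = 0
    for r in range(runs):
        rng = np.random.default_rng(np.random.SeedSequence((seed, r)))
        for _ in range(episodes_per_run):
            ep = sample_episode(fs, spec, rng, _class_idx=class_idx)
            protos = compute_prototypes(ep).prototypes
            if calibrator is not None:
                protos = calibrator(ep, protos)
            pred = classify_queries(protos, ep.query_features, metric=spec.metric)
            accs[i] = episode_accuracy(pred, ep.query_labels)
            all_pred.append(pred)
            all_truth.append(ep.query_labels)
            i += 1
    pred = np.concatenate(all_pred)
    truth = np.concatenate(all_truth)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mp, mr, mf1 = macro_metrics(pred, truth, spec.n_way)
    return EvaluationSummary(
        mean_accuracy=float(accs.mean()),
        std_accuracy=float(accs.std()),
        macro_precision=mp,
        macro_recall=mr,
        macro_f1=mf1,
        episodes_per_run=episodes_per_run,
        runs=runs,
        spec=spec,
        calibration=getattr(calibrator, "params", None),
        episode_accuracies=accs if keep_episode_accuracies else None,
    )
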