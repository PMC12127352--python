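"""Plant Disease Feature Calibration (PDFC).

A training-free, non-parametric correction for covariate shift between a
target few-shot task and a large source-domain *reference bank* of feature
vectors (e.g. embeddings of the PlantVillage or ImageNet training set).

For each episode class i with support prototype s_i:

1. find the m reference vectors nearest (L2) to s_i and average them into a
   per-class reference centroid c_i;
2. among all N centroids, take the two nearest to s_i, c_a (nearest) and
   c_b (second); pick the point T = (1 - lambda) * c_a + lambda * c_b on the
   line through them;
3. shift s_i exactly gamma feature-space units along the unit vector toward
   T (overshooting past T is allowed; if T coincides with s_i the prototype
   is left in place).

Queries are then classified by L2 argmin over the calibrated prototypes.
For K > 1 the prototype is the support mean, computed before calibration.
With gamma = 0 the whole procedure reduces exactly to the uncalibrated
nearest-prototype classifier.

``neighbor_mode="b"`` selects the alternate neighborhood reading in which,
for class i, the two support prototypes nearest to centroid c_i designate
the centroid pair (c_a, c_b) instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .episodes import Episode, classify_queries, compute_prototypes
from .errors import ValidationError
from .feature_store import ReferenceBank

_DEGENERATE_NORM = 1e-12


@dataclass(frozen=True)
class CalibrationParams:
    """PDFC hyperparameters.

    m      -- number of nearest reference vectors averaged per class centroid
    lam    -- position of the target point T along the segment c_a -> c_b
              (0 = nearest centroid, 1 = second; values outside [0, 1]
              extrapolate along the line)
    gamma  -- shift magnitude in feature-space units
    """

    m: int = 10
    lam: float = 0.0
    gamma: float = 0.0
    neighbor_mode: str = "a"

    def validate(self) -> "CalibrationParams":
        if self.m < 1:
            raise ValidationError("m must be a positive integer")
        if not (np.isfinite(self.lam) and np.isfinite(self.gamma)):
            raise ValidationError("lam and gamma must be finite")
        if self.gamma < 0:
            raise ValidationError("gamma must be non-negative")
        if self.neighbor_mode not in ("a", "b"):
            raise ValidationError("neighbor_mode must be 'a' or 'b'")
        return self


@dataclass
class CentroidBank:
    """Per-episode-class reference centroids and their provenance."""

    centroids: np.ndarray            # N x n, row i = c_i
    neighbor_indices: np.ndarray     # N x m reference-bank row indices


@dataclass
class CalibratedSupport:
    """Calibrated class representatives with per-class (a, b, T) provenance."""

    prototypes: np.ndarray           # N x n
    params: CalibrationParams
    provenance: list[tuple[int, int, np.ndarray]]  # per class: (a, b, T)


def class_reference_centroid(
    ref: ReferenceBank, proto: np.ndarray, m: int
) -> tuple[np.ndarray, np.ndarray]:
    """Mean of the m reference rows nearest to *proto* (L2).

    Ties at the m-th smallest distance are broken by the lower row index.
    Returns (centroid, indices of the m rows used).
    """
    ref.validate()
    proto = np.asarray(proto, dtype=np.float64).ravel()
    if proto.shape[0] != ref.dim:
        raise ValidationError(
            f"prototype dimension {proto.shape[0]} != bank dimension {ref.dim}"
        )
    if m > ref.n_rows:
        raise ValidationError(f"m={m} exceeds reference bank size {ref.n_rows}")
    d = np.linalg.norm(ref.features.astype(np.float64) - proto, axis=1)
    idx = np.argsort(d, kind="stable")[:m]  # stable: lower row index wins ties
    return ref.features[idx].astype(np.float64).mean(axis=0), idx


def build_centroids(
    ref: ReferenceBank, protos: np.ndarray, m: int
) -> CentroidBank:
    """One reference centroid per episode class (rows of *protos*)."""
    protos = np.atleast_2d(np.asarray(protos, dtype=np.float64))
    if protos.shape[1] != ref.dim:
        raise ValidationError(
            f"prototype dimension {protos.shape[1]} != bank dimension {ref.dim}"
        )
    if m > ref.n_rows:
        raise ValidationError(f"m={m} exceeds reference bank size {ref.n_rows}")
    # one distance matrix for all classes; stable sort keeps the
    # lower-row-index tie rule of class_reference_centroid
    d = cdist(protos, ref.features.astype(np.float64))
    idxs = np.argsort(d, axis=1, kind="stable")[:, :m]
    cents = ref.features.astype(np.float64)[idxs].mean(axis=1)
    return CentroidBank(centroids=cents, neighbor_indices=idxs)


def calibration_target(
    proto_i: np.ndarray, cb: CentroidBank, lam: float
) -> tuple[np.ndarray, int, int]:
    """Interpolation point T between the two centroids nearest to *proto_i*.

    T = (1 - lam) * c_a + lam * c_b with c_a the nearest centroid; distance
    ties go to the lower class index.  Returns (T, a, b).
    """
    cents = cb.centroids
    if cents.shape[0] < 2:
        raise ValidationError("calibration target requires at least 2 centroids")
    proto_i = np.asarray(proto_i, dtype=np.float64).ravel()
    d = np.linalg.norm(cents - proto_i, axis=1)
    order = np.argsort(d, kind="stable")
    a, b = int(order[0]), int(order[1])
    t = (1.0 - lam) * cents[a] + lam * cents[b]
    return t, a, b


def shift_prototype(proto_i: np.ndarray, t: np.ndarray, gamma: float) -> np.ndarray:
    """Move *proto_i* exactly gamma units along the unit vector toward T.

    Degenerate case: when T is (numerically) the prototype itself the
    direction is undefined and the prototype is returned unchanged.
    """
    proto_i = np.asarray(proto_i, dtype=np.float64)
    t = np.asarray(t, dtype=np.float64)
    if not (np.all(np.isfinite(proto_i)) and np.all(np.isfinite(t))):
        raise ValidationError("shift inputs must be finite")
    direction = t - proto_i
    norm = np.linalg.norm(direction)
    if norm < _DEGENERATE_NORM or gamma == 0.0:
        return proto_i.copy()
    return proto_i + gamma * direction / norm


def calibrate_episode(
    ep: Episode, ref: ReferenceBank, params: CalibrationParams
) -> CalibratedSupport:
    """Full per-episode calibration chain.

    Support prototypes are the per-class support means (so K > 1 reduces to
    the K = 1 case); each is then shifted via its reference centroids.  The
    calibration does not depend on the queries, so it is computed once per
    episode.
    """
    params.validate()
    protos = compute_prototypes(ep).prototypes
    if protos.shape[1] != ref.dim:
        raise ValidationError(
            f"episode dimension {protos.shape[1]} != bank dimension {ref.dim}"
        )
    cb = build_centroids(ref, protos, params.m)
    n = protos.shape[0]
    calibrated = np.empty_like(protos)
    provenance: list[tuple[int, int, np.ndarray]] = []
    for i in range(n):
        if params.neighbor_mode == "a":
            t, a, b = calibration_target(protos[i], cb, params.lam)
        else:
            # reading (B): the two prototypes nearest centroid c_i designate
            # the centroid pair used for class i
            d = np.linalg.norm(protos - cb.centroids[i], axis=1)
            order = np.argsort(d, kind="stable")
            a, b = int(order[0]), int(order[1])
            t = (1.0 - params.lam) * cb.centroids[a] + params.lam * cb.centroids[b]
        calibrated[i] = shift_prototype(protos[i], t, params.gamma)
        provenance.append((a, b, t))
    return CalibratedSupport(prototypes=calibrated, params=params,
                             provenance=provenance)


def pdfc_classify(
    ep: Episode, ref: ReferenceBank, params: CalibrationParams
) -> np.ndarray:
    """Classify the episode's queries against the calibrated prototypes."""
    cal = calibrate_episode(ep, ref, params)
    return classify_queries(cal.prototypes, ep.query_features, metric="euclidean")


def make_calibrator(ref: ReferenceBank, params: CalibrationParams):
    """Closure suitable for :func:`fascal.episodes.run_evaluation`'s
    ``calibrator`` argument; carries ``params`` for provenance."""
    params.validate()
    ref.validate()

    def calibrator(ep: Episode, protos: np.ndarray) -> np.ndarray:
        # protos are the support means run_evaluation already computed;
        # recomputing them inside calibrate_episode would be redundant
        cb = build_centroids(ref, protos, params.m)
        n = protos.shape[0]
        out = np.empty_like(protos)
        for i in range(n):
            if params.neighbor_mode == "a":
                t, _, _ = calibration_target(protos[i], cb, params.lam)
            else:
                d = np.linalg.norm(protos - cb.centroids[i], axis=1)
                order = np.argsort(d, kind="stable")
                t = ((1.0 - params.lam) * cb.centroids[int(order[0])]
                     + params.lam * cb.centroids[int(order[1])])
            out[i] = shift_prototype(protos[i], t, params.gamma)
        return out

    calibrator.params = params  # type: ignore[attr-defined]
    return calibrator
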