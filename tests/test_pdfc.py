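"""Calibration algorithm: sub-operation oracles, the 1-D hand trace, and
the invariants (identity at gamma=0, exact displacement norm, translation
equivariance, shift recovery)."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from fascal.episodes import (
    Episode,
    EpisodeSpec,
    classify_queries,
    compute_prototypes,
    run_evaluation,
    sample_episode,
)
from fascal.errors import ValidationError
from fascal.feature_store import ReferenceBank
from fascal.pdfc import (
    CalibrationParams,
    CentroidBank,
    build_centroids,
    calibrate_episode,
    calibration_target,
    class_reference_centroid,
    make_calibrator,
    pdfc_classify,
    shift_prototype,
)
from fascal.synthetic import GaussianClassSpec, ShiftSpec, make_shift_pair


@pytest.fixture
def shift_setup():
    pair = make_shift_pair(ShiftSpec(seed=23))
    return pair


def random_episode(pair, seed, spec=EpisodeSpec(n_way=5, k_shot=1, q_per_class=4)):
    return sample_episode(pair.target, spec, np.random.default_rng(seed))


# ------------------------------------------------------- reference centroids


def test_centroid_full_bank_is_bank_mean(reference_1d):
    cent, idx = class_reference_centroid(reference_1d, [123.0], m=3)
    assert cent == pytest.approx(reference_1d.features.mean())
    assert sorted(idx.tolist()) == [0, 1, 2]


def test_centroid_two_nearest(reference_1d):
    # bank {0, 1, 10}, proto 0.4, m=2 -> neighbors {0, 1}, centroid 0.5
    cent, idx = class_reference_centroid(reference_1d, [0.4], m=2)
    assert cent == pytest.approx(0.5)
    assert sorted(idx.tolist()) == [0, 1]


def test_centroid_exact_row(reference_1d):
    cent, idx = class_reference_centroid(reference_1d, [10.0], m=1)
    assert cent == pytest.approx(10.0)
    assert idx.tolist() == [2]


def test_centroid_tie_breaks_to_lower_row():
    ref = ReferenceBank(features=np.array([[1.0], [-1.0], [1.0]]))
    _, idx = class_reference_centroid(ref, [0.0], m=2)
    assert sorted(idx.tolist()) == [0, 1]  # rows 0 and 1 beat the tied row 2


def test_centroid_m_too_large(reference_1d):
    with pytest.raises(ValidationError, match="exceeds"):
        class_reference_centroid(reference_1d, [0.0], m=4)


def test_build_centroids_matches_per_class_loop(shift_setup, rng):
    protos = rng.normal(size=(4, shift_setup.reference.dim))
    cb = build_centroids(shift_setup.reference, protos, m=7)
    for i in range(4):
        cent, idx = class_reference_centroid(shift_setup.reference, protos[i], 7)
        assert np.allclose(cb.centroids[i], cent)
        assert np.array_equal(np.sort(cb.neighbor_indices[i]), np.sort(idx))


def test_identical_prototypes_identical_centroids(shift_setup):
    p = shift_setup.reference.features[0].astype(float)
    cb = build_centroids(shift_setup.reference, np.vstack([p, p]), m=5)
    assert np.allclose(cb.centroids[0], cb.centroids[1])


# ------------------------------------------------------- calibration target


def test_target_endpoints_and_interpolation():
    cb = CentroidBank(centroids=np.array([[0.0], [4.0], [10.0]]),
                      neighbor_indices=np.zeros((3, 1), dtype=int))
    t, a, b = calibration_target([1.0], cb, lam=0.0)
    assert (t, a, b) == (pytest.approx(0.0), 0, 1)
    t, _, _ = calibration_target([1.0], cb, lam=1.0)
    assert t == pytest.approx(4.0)
    t, a, b = calibration_target([1.0], cb, lam=0.5)
    assert (t[0], a, b) == (pytest.approx(2.0), 0, 1)


def test_target_requires_two_centroids():
    cb = CentroidBank(centroids=np.array([[0.0]]),
                      neighbor_indices=np.zeros((1, 1), dtype=int))
    with pytest.raises(ValidationError):
        calibration_target([1.0], cb, lam=0.5)


# ------------------------------------------------------- prototype shift


def test_shift_cases():
    p = np.array([0.0, 0.0])
    assert np.array_equal(shift_prototype(p, [3.0, 4.0], 0.0), p)
    assert np.array_equal(shift_prototype(p, p, 1.0), p)
    moved = shift_prototype(p, [3.0, 4.0], 1.0)
    assert np.allclose(moved, [0.6, 0.8])
    with pytest.raises(ValidationError):
        shift_prototype([np.nan], [0.0], 1.0)


def test_shift_overshoot_allowed():
    moved = shift_prototype([0.0], [1.0], 5.0)
    assert moved[0] == pytest.approx(5.0)  # past T, along the same ray


# ------------------------------------------------------- episode calibration


def hand_trace_episode():
    """N=2, 1-D: support {0, 10}, bank {-1, 1, 9, 11}."""
    return Episode(
        support_features=np.array([[0.0], [10.0]]),
        support_labels=np.array([0, 1]),
        query_features=np.array([[1.0], [9.0]]),
        query_labels=np.array([0, 1]),
        class_map=np.array([0, 1]),
    )


def test_hand_traced_calibration():
    """Full trace of the worked 1-D instance, cross-checked against the
    three sub-operation oracles."""
    ep = hand_trace_episode()
    ref = ReferenceBank(features=np.array([[-1.0], [1.0], [9.0], [11.0]]))
    params = CalibrationParams(m=2, lam=0.0, gamma=0.5)
    cal = calibrate_episode(ep, ref, params)
    # per-class centroids: mean of the 2 nearest bank rows
    cb = build_centroids(ref, np.array([[0.0], [10.0]]), m=2)
    assert np.allclose(cb.centroids, [[0.0], [10.0]])
    # T for class 0 is its own centroid 0 == prototype -> degenerate, no shift
    t0, a0, b0 = calibration_target([0.0], cb, 0.0)
    assert (t0[0], a0, b0) == (0.0, 0, 1)
    assert np.allclose(cal.prototypes, [[0.0], [10.0]])
    # provenance records the (a, b, T) triples of the sub-operations
    assert [pv[:2] for pv in cal.provenance] == [(0, 1), (1, 0)]
    assert np.allclose([pv[2][0] for pv in cal.provenance], [0.0, 10.0])


def test_gamma_zero_identity(shift_setup):
    params = CalibrationParams(m=10, lam=0.3, gamma=0.0)
    for seed in range(5):
        ep = random_episode(shift_setup, seed)
        protos = compute_prototypes(ep).prototypes
        assert np.array_equal(pdfc_classify(ep, shift_setup.reference, params),
                              classify_queries(protos, ep.query_features))
        cal = calibrate_episode(ep, shift_setup.reference, params)
        assert np.array_equal(cal.prototypes, protos)


def test_displacement_norm_is_exactly_gamma(shift_setup):
    gamma = 0.37
    params = CalibrationParams(m=10, lam=0.5, gamma=gamma)
    for seed in range(5):
        ep = random_episode(shift_setup, seed)
        protos = compute_prototypes(ep).prototypes
        cal = calibrate_episode(ep, shift_setup.reference, params)
        norms = np.linalg.norm(cal.prototypes - protos, axis=1)
        assert np.all(
            (np.abs(norms - gamma) < 1e-9) | (norms == 0.0)
        )


def test_translation_equivariance(shift_setup):
    v = np.full(shift_setup.reference.dim, 2.5)
    params = CalibrationParams(m=8, lam=0.4, gamma=0.6)
    ep = random_episode(shift_setup, 3)
    ep_t = Episode(
        support_features=ep.support_features + v,
        support_labels=ep.support_labels,
        query_features=ep.query_features + v,
        query_labels=ep.query_labels,
        class_map=ep.class_map,
    )
    ref_t = ReferenceBank(features=shift_setup.reference.features + v.astype(np.float32))
    cal = calibrate_episode(ep, shift_setup.reference, params)
    cal_t = calibrate_episode(ep_t, ref_t, params)
    assert np.allclose(cal_t.prototypes, cal.prototypes + v, atol=1e-4)
    assert np.array_equal(
        pdfc_classify(ep_t, ref_t, params),
        pdfc_classify(ep, shift_setup.reference, params),
    )


def test_pdfc_classify_matches_bruteforce(shift_setup):
    params = CalibrationParams(m=6, lam=0.2, gamma=0.8)
    for seed in range(5):
        ep = random_episode(shift_setup, seed)
        cal = calibrate_episode(ep, shift_setup.reference, params)
        brute = np.argmin(cdist(ep.query_features, cal.prototypes), axis=1)
        assert np.array_equal(pdfc_classify(ep, shift_setup.reference, params),
                              brute)


def test_k_greater_one_averages_first(shift_setup):
    spec = EpisodeSpec(n_way=4, k_shot=5, q_per_class=2)
    ep = random_episode(shift_setup, 11, spec)
    params = CalibrationParams(m=10, lam=0.0, gamma=0.0)
    cal = calibrate_episode(ep, shift_setup.reference, params)
    assert np.array_equal(cal.prototypes, compute_prototypes(ep).prototypes)


def test_neighbor_mode_b_runs_and_differs_generically(shift_setup):
    ep = random_episode(shift_setup, 2)
    pa = calibrate_episode(ep, shift_setup.reference,
                           CalibrationParams(m=5, lam=0.7, gamma=0.5,
                                             neighbor_mode="a"))
    pb = calibrate_episode(ep, shift_setup.reference,
                           CalibrationParams(m=5, lam=0.7, gamma=0.5,
                                             neighbor_mode="b"))
    assert pa.prototypes.shape == pb.prototypes.shape
    # both displace every prototype by exactly gamma (or not at all)
    for cal in (pa, pb):
        norms = np.linalg.norm(
            cal.prototypes - compute_prototypes(ep).prototypes, axis=1)
        assert np.all((np.abs(norms - 0.5) < 1e-9) | (norms == 0.0))


def test_make_calibrator_agrees_with_calibrate_episode(shift_setup):
    params = CalibrationParams(m=10, lam=0.3, gamma=0.7)
    calib = make_calibrator(shift_setup.reference, params)
    ep = random_episode(shift_setup, 13)
    protos = compute_prototypes(ep).prototypes
    assert np.allclose(calib(ep, protos),
                       calibrate_episode(ep, shift_setup.reference,
                                         params).prototypes)


def test_param_validation():
    with pytest.raises(ValidationError):
        CalibrationParams(m=0).validate()
    with pytest.raises(ValidationError):
        CalibrationParams(gamma=-1.0).validate()
    with pytest.raises(ValidationError):
        CalibrationParams(lam=np.inf).validate()
    with pytest.raises(ValidationError):
        CalibrationParams(neighbor_mode="c").validate()


def test_shift_recovery_beats_baseline():
    """Under covariate shift, calibration with lambda=0 and gamma near the
    bias norm beats the uncalibrated baseline (fixed seeds)."""
    pair = make_shift_pair(ShiftSpec(
        base=GaussianClassSpec(seed=41), bias_norm=3 * 0.3, seed=41))
    spec = EpisodeSpec(n_way=5, k_shot=1, q_per_class=15)
    base = run_evaluation(pair.target, spec, episodes_per_run=200, runs=1,
                          seed=0).mean_accuracy
    gamma = float(np.linalg.norm(pair.bias))  # c = 1
    cal = make_calibrator(pair.reference,
                          CalibrationParams(m=10, lam=0.0, gamma=gamma))
    calibrated = run_evaluation(pair.target, spec, episodes_per_run=200,
                                runs=1, seed=0, calibrator=cal).mean_accuracy
    assert calibrated > base
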