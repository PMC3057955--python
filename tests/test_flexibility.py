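"""Rotamer classification, salt-bridge occupancy, Kabsch/RMSD/RMSF."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermoflex.flexibility import (DihedralTrace, DistanceTrace, classify_rotamer,
                                    classify_rotamers, kabsch_superpose, rmsd_series,
                                    rmsf_per_atom, rotamer_statistics,
                                    salt_bridge_occupancy)


@pytest.mark.parametrize("chi, label", [
    ((300, 180, 300, 180), "mtm180"),  # native, bridge-locked rotamer
    ((60, 180, 180, 180), "ptt180"),
    ((180, 180, 60, 180), "ttp180"),
    ((300, 180, 180, 180), "mtt180"),
    ((119.9, 120.0, 240.0, 239.9), "ptm180"),  # half-open bin boundaries
    ((30, 30, 30, 30), "ppp85"),
    ((250, 250, 250, 250), "mmm-85"),
])
def test_classify_rotamer(chi, label):
    assert classify_rotamer(chi) == label


@settings(deadline=None, max_examples=100, derandomize=True)
@given(st.lists(st.floats(0.0, 359.99), min_size=4, max_size=4),
       st.integers(-3, 3))
def test_classification_invariant_to_full_turns(chi, k):
    shifted = [c + 360.0 * k for c in chi]
    assert classify_rotamer(chi) == classify_rotamer(shifted)


def test_classify_rotamers_vectorized_agrees_with_scalar(rng):
    chi = rng.uniform(0, 360, size=(200, 4))
    vec = classify_rotamers(chi)
    assert list(vec) == [classify_rotamer(row) for row in chi]


def test_rotamer_statistics_single_well():
    chi = np.tile([300.0, 180.0, 300.0, 180.0], (50, 1))
    stats = rotamer_statistics(DihedralTrace(time=np.arange(50.0), chi=chi))
    assert stats.occupancy == {"mtm180": 1.0}
    assert stats.transitions == 0
    assert stats.dwell_lengths == {"mtm180": [50]}


def test_rotamer_statistics_alternating_trace():
    n = 40
    chi = np.tile([300.0, 180.0, 300.0, 180.0], (n, 1))
    chi[1::2] = [60.0, 180.0, 180.0, 180.0]
    stats = rotamer_statistics(DihedralTrace(time=np.arange(float(n)), chi=chi))
    assert stats.transitions == n - 1
    assert stats.occupancy["mtm180"] == pytest.approx(0.5)
    assert sum(sum(v) for v in stats.dwell_lengths.values()) == n


def test_rotamer_statistics_markov_stationary_occupancy():
    """Occupancies on a 3-state Markov chain match its stationary
    distribution (0.7, 0.2, 0.1) within ±0.02 at 1e5 frames."""
    P = np.array([[0.97, 0.02, 0.01],
                  [0.07, 0.92, 0.01],
                  [0.07, 0.02, 0.91]])
    # stationary distribution by eigen-decomposition (independent oracle)
    w, v = np.linalg.eig(P.T)
    pi = np.real(v[:, np.argmax(np.real(w))])
    pi /= pi.sum()
    np.testing.assert_allclose(pi, [0.7, 0.2, 0.1], atol=1e-8)

    wells = np.array([[300.0, 180.0, 300.0, 180.0],
                      [60.0, 180.0, 180.0, 180.0],
                      [180.0, 180.0, 60.0, 180.0]])
    labels = ["mtm180", "ptt180", "ttp180"]
    rng = np.random.default_rng(42)
    n = 100_000
    path = np.empty(n, dtype=int)
    path[0] = 0
    cums = P.cumsum(axis=1)
    u = rng.random(n - 1)
    for i in range(1, n):
        path[i] = np.searchsorted(cums[path[i - 1]], u[i - 1], side="right")
    chi = wells[path] + np.degrees(rng.vonmises(0.0, 100.0, size=(n, 4)))
    stats = rotamer_statistics(DihedralTrace(time=np.arange(float(n)), chi=chi))
    for lab, p in zip(labels, pi):
        assert abs(stats.occupancy.get(lab, 0.0) - p) < 0.02
    assert sum(stats.occupancy.values()) == pytest.approx(1.0, abs=1e-9)


@pytest.mark.parametrize("d, expected", [
    (3.5, 1.0),   # persistent bridge
    (6.0, 0.0),   # broken-bridge signature
])
def test_salt_bridge_occupancy_constant_traces(d, expected):
    trace = DistanceTrace(time=np.arange(100.0), d=np.full(100, d))
    s = salt_bridge_occupancy(trace)
    assert s.occupancy == expected
    assert s.mean_d == pytest.approx(d)


def test_salt_bridge_occupancy_mixed_trace():
    d = np.concatenate([np.full(50, 3.0), np.full(50, 5.0)])
    s = salt_bridge_occupancy(DistanceTrace(time=np.arange(100.0), d=d))
    assert s.occupancy == 0.5
    assert s.max_d == 5.0


def _rotation(angles):
    from scipy.spatial.transform import Rotation
    return Rotation.from_euler("xyz", angles).as_matrix()


def test_kabsch_identity_and_rigid_motion(rng):
    P = rng.normal(size=(12, 3))
    rot, trans, rmsd = kabsch_superpose(P, P)
    assert rmsd == pytest.approx(0.0, abs=1e-12)
    np.testing.assert_allclose(rot, np.eye(3), atol=1e-10)
    Q = P @ _rotation([0.0, 0.0, np.pi / 2]).T + np.array([5.0, -3.0, 2.0])
    assert kabsch_superpose(P, Q)[2] == pytest.approx(0.0, abs=1e-10)


def test_kabsch_rmsd_symmetric_and_prerotation_invariant(rng):
    P = rng.normal(size=(8, 3))
    Q = P + rng.normal(scale=0.3, size=(8, 3))
    r1 = kabsch_superpose(P, Q)[2]
    r2 = kabsch_superpose(Q, P)[2]
    assert r1 == pytest.approx(r2, rel=1e-10)
    U = _rotation([0.4, -0.2, 0.9])
    r3 = kabsch_superpose(P @ U.T, Q @ U.T)[2]
    assert r3 == pytest.approx(r1, rel=1e-9)


def test_kabsch_matches_brute_force_rotation_grid(rng):
    """On 4-atom toys the optimal RMSD matches an exhaustive Euler-angle
    grid search to 1e-3 Å."""
    from scipy.optimize import minimize
    from scipy.spatial.transform import Rotation

    def grid_search_rmsd(P, Q):
        Pc = P - P.mean(axis=0)
        Qc = Q - Q.mean(axis=0)

        def cost(angles):
            Rm = Rotation.from_euler("zyz", angles).as_matrix()
            d = Pc @ Rm.T - Qc
            return float(np.sqrt((d**2).sum() / Pc.shape[0]))

        az = np.linspace(0, 2 * np.pi, 24, endpoint=False)
        tilt = np.linspace(0, np.pi, 13)
        angles = np.array([[a, b, c] for a in az for b in tilt for c in az])
        mats = Rotation.from_euler("zyz", angles).as_matrix()
        resid = np.einsum("nij,aj->nai", mats, Pc) - Qc
        costs = np.sqrt((resid**2).sum(axis=(1, 2)) / Pc.shape[0])
        best0 = angles[int(np.argmin(costs))]
        # polish the best grid point with a derivative-free local search
        res = minimize(cost, best0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
        return float(res.fun)

    for trial in range(3):
        P = rng.normal(size=(4, 3))
        Q = rng.normal(size=(4, 3))
        rmsd = kabsch_superpose(P, Q)[2]
        best = grid_search_rmsd(P, Q)
        assert rmsd <= best + 1e-9  # Kabsch is optimal
        assert best - rmsd < 1e-3


def test_kabsch_rejects_degenerate_input(rng):
    line = np.outer(np.arange(5.0), np.array([1.0, 0.0, 0.0]))
    with pytest.raises(ValueError, match="collinear"):
        kabsch_superpose(line, line)
    with pytest.raises(ValueError, match=">=3 atoms"):
        kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


def test_rmsd_series_static_rigid_and_perturbed(rng):
    P = rng.normal(size=(10, 3))
    static = np.stack([P] * 4)
    series, stable = rmsd_series(static)
    np.testing.assert_allclose(series, 0.0, atol=1e-12)
    assert stable

    moving = np.stack([P @ _rotation([0, 0, 0.1 * i]).T + i for i in range(4)])
    series, stable = rmsd_series(moving)
    np.testing.assert_allclose(series, 0.0, atol=1e-10)

    perturbed = np.stack([P] * 4)
    perturbed[2] = P + rng.normal(scale=2.0, size=P.shape)
    series, stable = rmsd_series(perturbed)
    assert series[2] > 1.5 and not stable
    assert series[[0, 1, 3]] == pytest.approx([0.0, 0.0, 0.0], abs=1e-10)


def test_rmsf_static_and_single_oscillating_atom(rng):
    P = rng.normal(size=(20, 3)) * 10.0
    static = np.stack([P] * 6)
    np.testing.assert_allclose(rmsf_per_atom(static), 0.0, atol=1e-10)

    # one atom oscillating ±a along x in a large, otherwise rigid body:
    # its rmsf → a and the rest → 0 (the mean-structure superposition
    # absorbs a vanishing share of the motion as the body grows)
    a = 0.5
    body = rng.normal(size=(100, 3)) * 10.0
    frames = []
    for i in range(200):
        F = body.copy()
        F[0, 0] += a * (1 if i % 2 == 0 else -1)
        frames.append(F)
    rmsf = rmsf_per_atom(np.stack(frames))
    assert rmsf[0] == pytest.approx(a, rel=0.05)
    assert np.all(rmsf[1:] < 0.05 * a)

    # rigid global rotation → all zero
    rigid = np.stack([P @ _rotation([0, 0.05 * i, 0]).T for i in range(5)])
    np.testing.assert_allclose(rmsf_per_atom(rigid), 0.0, atol=1e-9)
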