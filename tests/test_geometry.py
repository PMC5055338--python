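"""Superposition, RMSD/RMSF and reaction-coordinate selection."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from sarahmd import geometry, synth
from sarahmd.core import ProtomerPair, Trajectory
from conftest import make_structure


def _random_rigid(seed):
    rng = np.random.default_rng(seed)
    R = Rotation.random(random_state=int(seed)).as_matrix()
    t = rng.normal(0, 10, 3)
    return R, t


def _apply(s, R, t):
    return s.with_coords(s.coords @ R.T + t)


def test_self_superposition_is_identity(helix40):
    res = geometry.kabsch_superpose(helix40, helix40)
    assert res.rmsd == pytest.approx(0.0, abs=1e-10)
    assert np.allclose(res.rotation, np.eye(3), atol=1e-8)


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_rigid_motion_invariance_and_proper_rotation(helix40, seed):
    R, t = _random_rigid(seed)
    moved = _apply(helix40, R, t)
    res = geometry.kabsch_superpose(moved, helix40)
    assert res.rmsd <= 1e-8
    assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-8)


def test_rmsd_symmetry(helix40):
    rng = np.random.default_rng(8)
    jittered = helix40.with_coords(
        helix40.coords + rng.normal(0, 0.4, helix40.coords.shape)
    )
    ab = geometry.kabsch_superpose(helix40, jittered).rmsd
    ba = geometry.kabsch_superpose(jittered, helix40).rmsd
    assert ab == pytest.approx(ba, abs=1e-10)


def test_kabsch_matches_rotation_grid_minimum():
    """Independent oracle: exhaustive Euler-angle grid + local refinement
    of the RMSD over rotations, on a 4-point toy set."""
    rng = np.random.default_rng(42)
    ref = rng.normal(0, 2, (4, 3))
    mob = ref + rng.normal(0, 0.3, (4, 3))
    rows_r = [("CA", "C", "ALA", i + 1, "A", ref[i]) for i in range(4)]
    rows_m = [("CA", "C", "ALA", i + 1, "A", mob[i]) for i in range(4)]
    s_ref = make_structure(rows_r)
    s_mob = make_structure(rows_m)
    kab = geometry.kabsch_superpose(s_mob, s_ref).rmsd

    refc = ref - ref.mean(axis=0)
    mobc = mob - mob.mean(axis=0)

    def rmsd_of(angles):
        Rm = Rotation.from_euler("zyx", angles).as_matrix()
        return np.sqrt(np.mean(np.sum((mobc @ Rm.T - refc) ** 2, axis=1)))

    best = None
    grid = np.radians(np.arange(0, 360, 30))
    half = np.radians(np.arange(-90, 91, 30))
    for a in grid:
        for b in half:
            for c in grid:
                v = rmsd_of((a, b, c))
                if best is None or v < best[0]:
                    best = (v, (a, b, c))
    refined = minimize(rmsd_of, best[1], method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14})
    assert kab == pytest.approx(refined.fun, abs=1e-4)
    assert kab <= refined.fun + 1e-10  # analytic optimum is never worse


def test_superposition_requires_three_atoms():
    s = make_structure([("CA", "C", "ALA", 1, "A", (0, 0, 0)),
                        ("CA", "C", "ALA", 2, "A", (3, 0, 0))])
    with pytest.raises(ValueError, match="3"):
        geometry.kabsch_superpose(s, s)


def test_rmsd_series_static_and_rigid(helix40):
    static = Trajectory(helix40, np.repeat(helix40.coords[None], 4, axis=0))
    assert np.allclose(geometry.rmsd_series(static, helix40), 0.0, atol=1e-10)
    frames = []
    for seed in range(3):
        R, t = _random_rigid(seed + 10)
        frames.append(helix40.coords @ R.T + t)
    moved = Trajectory(helix40, np.stack(frames))
    assert np.all(geometry.rmsd_series(moved, helix40) <= 1e-8)


def test_rmsd_series_matches_per_frame_superposition(helix40):
    traj = synth.jitter_trajectory(helix40, 2, sigma=0.5, seed=3)
    series = geometry.rmsd_series(traj, helix40)
    for f in range(2):
        single = geometry.kabsch_superpose(traj.frame(f), helix40).rmsd
        assert series[f] == pytest.approx(single, abs=1e-12)


def test_average_structure_static_and_midpoint(helix40):
    static = Trajectory(helix40, np.repeat(helix40.coords[None], 3, axis=0))
    avg = geometry.average_structure(static)
    assert np.allclose(avg.coords, helix40.coords, atol=1e-10)

    d = np.array([0.3, -0.2, 0.5])
    two = Trajectory(
        helix40, np.stack([helix40.coords - d, helix40.coords + d])
    )
    avg = geometry.average_structure(two, tol=1e-9)
    assert np.allclose(avg.coords, helix40.coords, atol=1e-7)


def test_average_structure_frame_order_invariant(helix40):
    traj = synth.jitter_trajectory(helix40, 12, sigma=0.3, seed=4)
    fwd = geometry.average_structure(traj, tol=1e-8, max_iter=50)
    rng = np.random.default_rng(0)
    perm = rng.permutation(12)
    shuffled = Trajectory(helix40, traj.frames[perm])
    back = geometry.average_structure(shuffled, tol=1e-8, max_iter=50)
    assert np.abs(fwd.coords - back.coords).max() < 1e-5


def test_rmsf_static_zero_and_single_frame_error(helix40):
    static = Trajectory(helix40, np.repeat(helix40.coords[None], 3, axis=0))
    prof = geometry.rmsf(static)
    assert np.allclose(prof.values, 0.0, atol=1e-10)
    single = Trajectory(helix40, helix40.coords[None])
    with pytest.raises(ValueError, match="RMSF undefined"):
        geometry.rmsf(single)


def test_rmsf_two_point_alternation():
    """One Cα alternating ±d/2 about its mean inside a large rigid anchor
    recovers RMSF = d/2 (analytic two-point variance) within 1%."""
    helix = synth.ideal_helix(synth.HelixSpec(n_res=200, chain_id="A"))
    d = 1.0
    idx = helix.atom_index("A", 100, "CA")
    frames = np.repeat(helix.coords[None], 10, axis=0)
    frames[::2, idx, 0] += d / 2
    frames[1::2, idx, 0] -= d / 2
    prof = geometry.rmsf(Trajectory(helix, frames))
    res_idx = [i for i, r in enumerate(prof.residues) if r[1] == 100][0]
    assert prof.values[res_idx] == pytest.approx(d / 2, rel=0.01)


def test_rmsf_isotropic_jitter_recovers_sigma_sqrt3(helix40):
    sigma = 0.3
    traj = synth.jitter_trajectory(helix40, 2000, sigma=sigma, seed=5)
    prof = geometry.rmsf(traj)
    assert prof.values.mean() == pytest.approx(sigma * np.sqrt(3), rel=0.05)


def test_min_avg_ca_pair_matches_brute_force(demo_dimer, pair):
    traj = synth.jitter_trajectory(demo_dimer, 20, sigma=0.3, seed=6)
    got = geometry.min_avg_ca_pair(traj, pair)
    topo = traj.topology
    is_ca = np.array([n == "CA" for n in topo.name])
    best = None
    for i in np.flatnonzero(is_ca & (topo.chain_id == "A")):
        for j in np.flatnonzero(is_ca & (topo.chain_id == "B")):
            avg = np.mean(
                np.linalg.norm(traj.frames[:, i] - traj.frames[:, j], axis=1)
            )
            key = (avg, int(topo.res_seq[i]), int(topo.res_seq[j]))
            if best is None or key < best[0]:
                best = (key, int(topo.res_seq[i]), int(topo.res_seq[j]))
    assert got == (("A", best[1]), ("B", best[2]))


def test_min_avg_ca_pair_minimizes_average_not_single_frame():
    """Hand-built 2x2 case where each frame favors a different pair but
    the average favors a third."""
    rows = [
        ("CA", "C", "ALA", 1, "A", (0.0, 0, 0)),
        ("CA", "C", "ALA", 2, "A", (0.0, 10, 0)),
        ("CA", "C", "ALA", 1, "B", (5.0, 0, 0)),
        ("CA", "C", "ALA", 2, "B", (5.0, 10, 0)),
    ]
    s = make_structure(rows)
    f0 = s.coords.copy()
    f1 = s.coords.copy()
    # frame 0: B1 swings close to A1 (d=1); frame 1: far (d=9)  -> avg 5
    f0[2, 0] = 1.0
    f1[2, 0] = 9.0
    # pair (A2, B2) fixed at 4 in both frames -> avg 4 wins
    f0[3, 0] = 4.0
    f1[3, 0] = 4.0
    traj = Trajectory(s, np.stack([f0, f1]))
    assert geometry.min_avg_ca_pair(traj, ProtomerPair("A", "B")) == (
        ("A", 2), ("B", 2)
    )
    single = Trajectory(s, f0[None])
    assert geometry.min_avg_ca_pair(single, ProtomerPair("A", "B")) == (
        ("A", 1), ("B", 1)
    )


def test_distance_series_values(demo_dimer):
    rows = [
        ("CA", "C", "ALA", 1, "A", (0.0, 0, 0)),
        ("CA", "C", "ALA", 1, "B", (3.0, 4.0, 0)),
    ]
    s = make_structure(rows)
    traj = Trajectory(s, np.repeat(s.coords[None], 3, axis=0))
    d = geometry.distance_series(traj, ("A", 1, "CA"), ("B", 1, "CA"))
    assert np.allclose(d, 5.0)
    coincident = s.with_coords(np.zeros_like(s.coords))
    traj0 = Trajectory(coincident, coincident.coords[None])
    assert geometry.distance_series(traj0, ("A", 1, "CA"), ("B", 1, "CA"))[0] == 0.0
    jit = synth.jitter_trajectory(s, 5, 0.4, seed=2)
    d = geometry.distance_series(jit, ("A", 1, "CA"), ("B", 1, "CA"))
    manual = np.linalg.norm(jit.frames[:, 0] - jit.frames[:, 1], axis=1)
    assert np.allclose(d, manual)
    with pytest.raises(KeyError):
        geometry.distance_series(jit, ("A", 9, "CA"), ("B", 1, "CA"))
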