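"""Synthetic-structure and dynamics generators."""

import numpy as np
import pytest
import scipy.integrate

from sarahmd import contacts, synth
from sarahmd.core import ProtomerPair


def test_helix_geometry():
    spec = synth.HelixSpec(n_res=10, chain_id="A")
    h = synth.ideal_helix(spec)
    ca = np.array(
        [h.coords[h.atom_index("A", i, "CA")] for i in range(1, 11)]
    )
    steps = np.linalg.norm(np.diff(ca, axis=0), axis=1)
    assert np.all(np.abs(steps - 3.8) < 0.1)
    rises = np.diff(ca[:, 2])
    assert np.allclose(rises, 1.5)


def test_helix_pitch_near_two_turns_per_seven_residues():
    h = synth.ideal_helix(synth.HelixSpec(n_res=12, chain_id="A"))
    ca1 = h.coords[h.atom_index("A", 1, "CA")]
    ca8 = h.coords[h.atom_index("A", 8, "CA")]
    az = [np.arctan2(c[1], c[0]) for c in (ca1, ca8)]
    delta = np.degrees(abs(az[1] - az[0]))
    delta = min(delta, 360 - delta)
    assert delta == pytest.approx(20.0, abs=1e-6)  # 700 deg = 2 turns - 20


def test_charged_positions_carry_tip_atoms():
    h = synth.ideal_helix(
        synth.HelixSpec(n_res=8, chain_id="A", residues={5: "LYS"})
    )
    assert h.atom_index("A", 5, "NZ") >= 0
    with pytest.raises(KeyError):
        h.atom_index("A", 4, "NZ")


def test_helix_spec_validation():
    with pytest.raises(ValueError):
        synth.HelixSpec(n_res=3)
    with pytest.raises(ValueError):
        synth.HelixSpec(n_res=5, sequence="AAAA")


def test_dimer_orientation_flips_chain_direction():
    sa = synth.HelixSpec(n_res=8, chain_id="A")
    sb = synth.HelixSpec(n_res=8, chain_id="B")
    anti = synth.two_helix_dimer(sa, sb, 10.0, "antiparallel")
    para = synth.two_helix_dimer(sa, sb, 10.0, "parallel")

    def axis_direction(s, chain):
        z_first = s.coords[s.atom_index(chain, 1, "CA")][2]
        z_last = s.coords[s.atom_index(chain, 8, "CA")][2]
        return np.sign(z_last - z_first)

    assert axis_direction(anti, "A") == -axis_direction(anti, "B")
    assert axis_direction(para, "A") == axis_direction(para, "B")


def test_far_separated_dimer_has_no_contacts(pair):
    far = synth.two_helix_dimer(
        synth.HelixSpec(n_res=8, chain_id="A"),
        synth.HelixSpec(n_res=8, chain_id="B"),
        separation=50.0,
    )
    assert contacts.contact_map(far, pair, 5.5) == set()


def test_demo_dimer_interface_is_engineered(demo_dimer, pair):
    cm = contacts.contact_map(demo_dimer, pair, 5.5)
    charged = {
        (("A", 445, "LYS"), ("B", 320, "GLU")),
        (("A", 452, "ARG"), ("B", 313, "ASP")),
        (("A", 455, "ASP"), ("B", 310, "LYS")),
    }
    assert charged <= cm


def test_telegraph_trajectory_deterministic(demo_dimer):
    _, specs = synth.demo_dimer()
    t1 = synth.telegraph_contact_trajectory(demo_dimer, specs, 50, seed=33)
    t2 = synth.telegraph_contact_trajectory(demo_dimer, specs, 50, seed=33)
    assert np.array_equal(t1.frames, t2.frames)
    t3 = synth.telegraph_contact_trajectory(demo_dimer, specs, 50, seed=34)
    assert not np.array_equal(t1.frames, t3.frames)


def test_telegraph_controls_exact_tip_distance(demo_dimer):
    spec = synth.TelegraphSpec(("A", 445), ("B", 320), p=0.6,
                               bound_distance=3.0, unbound_distance=8.0)
    traj = synth.telegraph_contact_trajectory(demo_dimer, [spec], 200, seed=2)
    nz = demo_dimer.atom_index("A", 445, "NZ")
    oe1 = demo_dimer.atom_index("B", 320, "OE1")
    d = np.linalg.norm(traj.frames[:, nz] - traj.frames[:, oe1], axis=1)
    assert set(np.round(d, 9)) <= {3.0, 8.0}


def test_telegraph_symmetric_rates_balance_dwell_times(demo_dimer):
    spec = synth.TelegraphSpec(("A", 445), ("B", 320), p=0.5,
                               switch_rate=0.4)
    traj = synth.telegraph_contact_trajectory(
        demo_dimer, [spec], 20_000, seed=44, jitter_sigma=0.0
    )
    nz = demo_dimer.atom_index("A", 445, "NZ")
    oe1 = demo_dimer.atom_index("B", 320, "OE1")
    d = np.linalg.norm(traj.frames[:, nz] - traj.frames[:, oe1], axis=1)
    bound = d < 5.0

    def dwells(mask):
        runs, cur = [], 1
        for a, b in zip(mask[:-1], mask[1:]):
            if a == b:
                cur += 1
            else:
                runs.append(cur)
                cur = 1
        return np.array(runs[1:])  # drop the truncated first run

    mean_on = dwells(bound)[::2].mean()
    mean_off = dwells(~bound)[::2].mean()
    assert mean_on == pytest.approx(mean_off, rel=0.15)
    assert mean_on == pytest.approx(1 / 0.2, rel=0.15)  # 1/k_off


def test_unattainable_switching_probability_rejected():
    with pytest.raises(ValueError, match="unattainable"):
        synth.TelegraphSpec(("A", 445), ("B", 320), p=0.9, switch_rate=1.5)
    with pytest.raises(ValueError):
        synth.TelegraphSpec(("A", 445), ("B", 320), p=1.5)
    with pytest.raises(ValueError):
        synth.TelegraphSpec(
            ("A", 445), ("B", 320), p=0.5,
            bound_distance=9.0, unbound_distance=3.0,
        )


def test_jitter_trajectory_properties(helix40):
    static = synth.jitter_trajectory(helix40, 5, sigma=0.0, seed=0)
    assert np.array_equal(
        static.frames, np.repeat(helix40.coords[None], 5, axis=0)
    )
    a = synth.jitter_trajectory(helix40, 5, sigma=0.5, seed=1)
    b = synth.jitter_trajectory(helix40, 5, sigma=0.5, seed=1)
    assert np.array_equal(a.frames, b.frames)
    with pytest.raises(ValueError):
        synth.jitter_trajectory(helix40, 5, sigma=-0.1, seed=1)


def test_langevin_harmonic_boltzmann_variance():
    kT, k = 0.6161, 2.0
    x = synth.langevin_1d(
        synth.PolynomialPotential.harmonic(k), 500_000, dt=0.01, kT=kT,
        seed=11,
    )
    assert x.var() == pytest.approx(kT / k, rel=0.05)


def test_langevin_zero_temperature_stays_at_minimum():
    pot = synth.PolynomialPotential.harmonic(3.0, x0=1.5)
    x = synth.langevin_1d(pot, 2000, dt=0.01, kT=0.0, seed=0, x0=1.5)
    assert np.abs(x - 1.5).max() < 1e-12


def test_langevin_divergence_detected():
    # unstable: dt too large for the stiffness
    pot = synth.PolynomialPotential.harmonic(1e4)
    with pytest.raises(FloatingPointError, match="dt"):
        synth.langevin_1d(pot, 5000, dt=0.01, kT=0.6, seed=1, x0=1.0)


def test_double_well_populations_match_boltzmann_integral():
    """Numerical Boltzmann-integral oracle for a tilted double well."""
    kT = 0.6161
    pot = synth.PolynomialPotential([2 * kT, 0.3, -4 * kT, 0.0, 2 * kT])
    x = synth.langevin_1d(pot, 400_000, dt=0.005, kT=kT, seed=22, x0=-1.0)
    frac_right = float((x > 0).mean())
    grid = np.linspace(-2.5, 2.5, 4001)
    w = np.exp(-(pot(grid) - pot(grid).min()) / kT)
    expected = (
        scipy.integrate.trapezoid(w[grid > 0], grid[grid > 0])
        / scipy.integrate.trapezoid(w, grid)
    )
    assert frac_right == pytest.approx(expected, rel=0.15)
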