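"""Interface contacts, salt bridges, hydrogen bonds and Ile-Leu pairs."""

import numpy as np
import pytest

from sarahmd import contacts, synth
from sarahmd.core import ProtomerPair, Structure, Trajectory, side_chain_mask
from conftest import make_structure


def _cb_pair(distance):
    return make_structure(
        [
            ("CB", "C", "ALA", 1, "A", (0.0, 0, 0)),
            ("CB", "C", "ALA", 1, "B", (distance, 0, 0)),
        ]
    )


@pytest.mark.parametrize(
    "distance,cutoff,expected", [(5.4, 5.5, 1), (5.5, 5.5, 1), (5.6, 5.5, 0)]
)
def test_contact_cutoff_boundary_inclusive(distance, cutoff, expected, pair):
    cm = contacts.contact_map(_cb_pair(distance), pair, cutoff)
    assert len(cm) == expected


def test_contact_map_matches_brute_force_scan(demo_dimer, pair):
    """O(n^2) oracle: scan every side-chain atom pair directly."""
    cutoff = 5.5
    cm = contacts.contact_map(demo_dimer, pair, cutoff)
    sc = side_chain_mask(demo_dimer)
    oracle = set()
    idx_a = np.flatnonzero(sc & (demo_dimer.chain_id == "A"))
    idx_b = np.flatnonzero(sc & (demo_dimer.chain_id == "B"))
    for i in idx_a:
        for j in idx_b:
            if np.linalg.norm(demo_dimer.coords[i] - demo_dimer.coords[j]) <= cutoff:
                oracle.add(
                    (
                        ("A", int(demo_dimer.res_seq[i]), str(demo_dimer.res_name[i])),
                        ("B", int(demo_dimer.res_seq[j]), str(demo_dimer.res_name[j])),
                    )
                )
    assert cm == oracle
    assert len(cm) > 0


def test_contact_monotone_in_cutoff(demo_dimer, pair):
    maps = [contacts.contact_map(demo_dimer, pair, c) for c in (5.0, 5.5, 6.0)]
    assert maps[0] <= maps[1] <= maps[2]


def _salt_fixture():
    """LYS on A and GLU on B, tip atoms placed directly."""
    return make_structure(
        [
            ("NZ", "N", "LYS", 5, "A", (0.0, 0, 0)),
            ("CB", "C", "LYS", 5, "A", (-2.0, 0, 0)),
            ("OE1", "O", "GLU", 9, "B", (3.5, 0, 0)),
            ("OE2", "O", "GLU", 9, "B", (3.5, 1.0, 0)),
        ]
    )


def test_salt_bridge_frame_counting(pair):
    s = _salt_fixture()
    frames = np.repeat(s.coords[None], 4, axis=0)
    far = 9.0
    frames[2, 2, 0] = far  # frame 3 broken (OE1 and OE2 both far)
    frames[2, 3, 0] = far
    traj = Trajectory(s, frames)
    bridges = contacts.salt_bridges(traj, pair, cutoff=4.0, burn_in=0.0)
    assert len(bridges) == 1
    b = bridges[0]
    assert b.residue_a == ("A", 5, "LYS")
    assert b.residue_b == ("B", 9, "GLU")
    assert b.p_formed == 0.75
    assert b.n_formed == 3 and b.n_frames_used == 4


def test_salt_bridge_burn_in_removal(pair):
    s = _salt_fixture()
    frames = np.repeat(s.coords[None], 10, axis=0)
    frames[0, 2:4, 0] = 9.0  # broken only during the burn-in window
    traj = Trajectory(s, frames)
    bridges = contacts.salt_bridges(traj, pair, burn_in=0.10)
    assert bridges[0].n_frames_used == 9
    assert bridges[0].p_formed == 1.0


def test_plain_histidine_is_not_basic(pair):
    rows = [
        ("NE2", "N", "HIS", 1, "A", (0.0, 0, 0)),
        ("OD1", "O", "ASP", 2, "B", (3.0, 0, 0)),
    ]
    s = make_structure(rows)
    traj = Trajectory(s, s.coords[None])
    assert contacts.salt_bridges(traj, pair, burn_in=0.0) == []
    rows[0] = ("NE2", "N", "HSP", 1, "A", (0.0, 0, 0))
    s2 = make_structure(rows)
    traj2 = Trajectory(s2, s2.coords[None])
    assert len(contacts.salt_bridges(traj2, pair, burn_in=0.0)) == 1


def test_no_charged_residues_gives_empty_list(pair):
    s = _cb_pair(3.0)
    traj = Trajectory(s, s.coords[None])
    assert contacts.salt_bridges(traj, pair, burn_in=0.0) == []


def test_salt_bridge_table_highlight_threshold():
    """Formation probabilities {0.05, 0.154} filtered at the 10%
    highlighting threshold leave exactly {0.154} bold."""
    mk = lambda p, n: contacts.ContactTimeSeries(
        ("A", 473, "LYS"), ("B", 366, "GLU"),
        np.arange(n) < int(p * n), n,
    )
    table = contacts.salt_bridge_table([mk(0.05, 1000), mk(0.154, 1000)])
    assert list(table["bold"]) == [False, True]
    assert set(table.loc[table["bold"], "p_formed"]) == {0.154}


def test_telegraph_recovery_within_markov_envelope(demo_dimer, pair):
    p, n = 0.8, 10_000
    spec = synth.TelegraphSpec(("A", 445), ("B", 320), p=p)
    traj = synth.telegraph_contact_trajectory(demo_dimer, [spec], n, seed=80)
    bridges = contacts.salt_bridges(traj, pair, burn_in=0.0)
    est = [b for b in bridges if b.residue_a == ("A", 445, "LYS")][0].p_formed
    # two-state chain with total switching rate s: lag-1 autocorrelation
    # rho = 1 - s inflates the binomial variance by (1+rho)/(1-rho)
    rho = 1 - spec.switch_rate
    n_eff = n * (1 - rho) / (1 + rho)
    assert abs(est - p) < 3 * np.sqrt(p * (1 - p) / n_eff)


def test_p_formed_monotone_in_cutoff(demo_dimer, pair):
    spec = synth.TelegraphSpec(("A", 445), ("B", 320), p=0.5,
                               bound_distance=3.5, unbound_distance=8.0)
    traj = synth.telegraph_contact_trajectory(demo_dimer, [spec], 500, seed=4)
    ps = []
    for cutoff in (3.0, 4.0, 8.5):
        bridges = contacts.salt_bridges(traj, pair, cutoff=cutoff, burn_in=0.0)
        match = [b for b in bridges if b.residue_a == ("A", 445, "LYS")]
        ps.append(match[0].p_formed if match else 0.0)
    assert ps[0] <= ps[1] <= ps[2]
    assert ps[2] == 1.0  # cutoff beyond the unbound distance


# -- hydrogen bonds ---------------------------------------------------------

def _hb_fixture(da=2.9, angle_deg=10.0):
    """Lys NZ donor with an explicit hydrogen, Glu OE1 acceptor on the
    other chain; the hydrogen sits 1.0 Å from NZ, rotated ``angle_deg``
    away from the N->O axis (= the D-H-A deviation from linearity)."""
    h = np.array(
        [np.cos(np.radians(angle_deg)), np.sin(np.radians(angle_deg)), 0.0]
    )
    return make_structure(
        [
            ("NZ", "N", "LYS", 1, "A", (0.0, 0, 0)),
            ("HZ1", "H", "LYS", 1, "A", tuple(h)),
            ("OE1", "O", "GLU", 2, "B", (da, 0, 0)),
        ]
    )


@pytest.mark.parametrize(
    "da,angle,expected",
    [
        (2.9, 10.0, 1),   # inside both cutoffs
        (3.5, 10.0, 0),   # distance fails at the 3.0 Å default
        (2.9, 25.0, 0),   # deviation from linearity fails at 20 deg
    ],
)
def test_hbond_distance_and_angle_criterion(da, angle, expected, pair):
    s = _hb_fixture(da, angle)
    traj = Trajectory(s, s.coords[None])
    records = contacts.hydrogen_bonds(traj, pair, burn_in=0.0)
    assert len(records) == expected
    if expected:
        r = records[0]
        assert r.donor[3] == "NZ" and r.acceptor[3] == "OE1"
        assert r.occupancy == 1.0
        assert r.hydrogen == "HZ1"
        assert not r.heavy_atom_only


def test_hbond_ideal_geometry_reconstruction(pair):
    """Without explicit hydrogens the H is rebuilt along the donor's
    antibonding direction: a backbone-like N bonded to one neighbor
    pointing away from the acceptor donates."""
    s = make_structure(
        [
            ("CB", "C", "SER", 1, "A", (-1.4, 0, 0)),
            ("OG", "O", "SER", 1, "A", (0.0, 0, 0)),
            ("OE1", "O", "GLU", 2, "B", (2.8, 0, 0)),
        ]
    )
    traj = Trajectory(s, s.coords[None])
    records = contacts.hydrogen_bonds(traj, pair, burn_in=0.0)
    assert len(records) == 1
    assert records[0].hydrogen is None  # placeholder, not a real atom


def test_hbond_heavy_atom_fallback_flagged(pair):
    s = make_structure(
        [
            ("NZ", "N", "LYS", 1, "A", (0.0, 0, 0)),
            ("OE1", "O", "GLU", 2, "B", (3.3, 0, 0)),
        ]
    )
    traj = Trajectory(s, s.coords[None])
    assert contacts.hydrogen_bonds(traj, pair, burn_in=0.0) == []
    records = contacts.hydrogen_bonds(
        traj, pair, burn_in=0.0, heavy_atom_only=True
    )
    assert len(records) == 1 and records[0].heavy_atom_only


def test_hbond_occupancy_filter_at_one_percent():
    mk = lambda occ: contacts.HBondRecord(
        donor=("A", 470, "TYR", "OH"),
        acceptor=("B", 462, "GLU", "OE1"),
        occupancy=occ,
        n_frames_used=1000,
        donor_chain="A",
    )
    table = contacts.hbond_table([mk(0.009), mk(0.012)], "A")
    assert list(table["occupancy"]) == [0.012]


def test_hbond_partition_exhaustive_and_disjoint(demo_dimer, pair):
    traj = synth.demo_trajectory(n_frames=150, seed=9)
    records = contacts.hydrogen_bonds(
        traj, pair, burn_in=0.0, heavy_atom_only=True
    )
    assert records, "demo interface should form heavy-atom hydrogen bonds"
    donors_a = [r for r in records if r.donor_chain == "A"]
    donors_b = [r for r in records if r.donor_chain == "B"]
    assert len(donors_a) + len(donors_b) == len(records)
    for r in records:
        assert r.donor[0] != r.acceptor[0]
    table = contacts.hbond_table(records, "A", min_occupancy=0.0)
    assert set(table["section"]) <= {"donor", "acceptor"}


# -- Ile-Leu pairs ----------------------------------------------------------

def test_ile_leu_pair_detection_and_exclusion(pair):
    rows = [
        ("CD1", "C", "ILE", 1, "A", (0.0, 0, 0)),
        ("CD1", "C", "LEU", 2, "B", (5.0, 0, 0)),
    ]
    s = make_structure(rows)
    assert len(contacts.ile_leu_pairs(s, pair)) == 1
    rows[1] = ("CG1", "C", "VAL", 2, "B", (4.0, 0, 0))
    s2 = make_structure(rows)
    assert contacts.ile_leu_pairs(s2, pair) == set()


def test_ile_leu_equals_filtered_contact_map(demo_dimer, pair):
    cm = contacts.contact_map(demo_dimer, pair, 5.5)
    expected = {
        (ra, rb) for ra, rb in cm
        if ra[2] in {"ILE", "LEU"} and rb[2] in {"ILE", "LEU"}
    }
    assert contacts.ile_leu_pairs(demo_dimer, pair, 5.5) == expected
    assert len(expected) == 2  # engineered demo interface


def test_exact_frame_counting_integer_arithmetic(pair):
    s = _salt_fixture()
    n = 7
    frames = np.repeat(s.coords[None], n, axis=0)
    broken = [1, 4]
    for f in broken:
        frames[f, 2:4, 0] = 9.0
    traj = Trajectory(s, frames)
    b = contacts.salt_bridges(traj, pair, burn_in=0.0)[0]
    assert b.n_formed == n - len(broken)
    assert b.p_formed == (n - len(broken)) / n
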