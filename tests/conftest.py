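import numpy as np
import pytest

from sarahmd import synth
from sarahmd.core import Atom, ProtomerPair, Structure


@pytest.fixture(scope="session")
def demo_dimer():
    dimer, specs = synth.demo_dimer()
    return dimer


@pytest.fixture(scope="session")
def pair():
    return ProtomerPair("A", "B")


@pytest.fixture(scope="session")
def demo_traj():
    return synth.demo_trajectory(n_frames=300, seed=7)


@pytest.fixture(scope="session")
def helix40():
    return synth.ideal_helix(synth.HelixSpec(n_res=40, chain_id="A"))


def make_structure(spec_rows, title=""):
    """Build a Structure from (name, element, res_name, res_seq, chain, xyz)
    rows, with optional trailing vdw_radius."""
    atoms = []
    for i, row in enumerate(spec_rows, start=1):
        name, element, res_name, res_seq, chain, xyz = row[:6]
        vdw = row[6] if len(row) > 6 else None
        atoms.append(
            Atom(
                serial=i,
                name=name,
                element=element,
                res_name=res_name,
                res_seq=res_seq,
                chain_id=chain,
                coords=np.asarray(xyz, dtype=float),
                vdw_radius=vdw,
            )
        )
    return Structure(atoms, title=title)
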