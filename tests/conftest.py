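import numpy as np
import pytest

from hingeflow.core import Atom, Box, Frame, Molecule, WATER, WATER_H, WATER_O


def make_water(mol_id, o_pos, h1_dir=(0, 0, 1.0), h2_dir=None, atom_id0=0):
    """Minimal 3-site water with O-H bonds of 0.96 Å."""
    o_pos = np.asarray(o_pos, dtype=float)
    h1 = np.asarray(h1_dir, dtype=float)
    h1 = h1 / np.linalg.norm(h1)
    if h2_dir is None:
        h2 = np.array([h1[1], -h1[0], 0.0])
        if np.linalg.norm(h2) < 1e-8:
            h2 = np.array([1.0, 0.0, 0.0])
        h2 = h2 / np.linalg.norm(h2)
    else:
        h2 = np.asarray(h2_dir, dtype=float)
        h2 = h2 / np.linalg.norm(h2)
    atoms = [
        Atom(atom_id0, "O", WATER_O, o_pos),
        Atom(atom_id0 + 1, "H", WATER_H, o_pos + 0.96 * h1),
        Atom(atom_id0 + 2, "H", WATER_H, o_pos + 0.96 * h2),
    ]
    return Molecule(mol_id, WATER, atoms)


def random_water_frame(rng, n, box_len=15.0, time=0.0):
    """n randomly placed and oriented waters in a cubic periodic box."""
    box = Box(box_len, box_len, box_len)
    mols = []
    for i in range(n):
        o = rng.uniform(0, box_len, 3)
        d1 = rng.normal(size=3)
        d2 = rng.normal(size=3)
        mols.append(make_water(i, o, d1, d2, atom_id0=3 * i))
    return Frame(time, mols, box)


@pytest.fixture(scope="session")
def slab_fixture():
    """One generated biphasic slab with its ground truth (session cached)."""
    from hingeflow.synth import SlabSpec, gen_slab

    return gen_slab(SlabSpec(seed=42))


@pytest.fixture(scope="session")
def slab_assignment(slab_fixture):
    from hingeflow.hbond import detect_hbonds
    from hingeflow.layers import assign_layers

    frame, truth = slab_fixture
    graph = detect_hbonds(frame)
    return frame, truth, graph, assign_layers(frame, graph)
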