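import numpy as np
import pytest

from cdrscore import (ALL, AtomFrame, AtomRecord, BACKBONE_ATOMS,
                      RegionSelection, default_region, make_loop_reference)


def make_frame(spec_rows, coords):
    """Build an AtomFrame from (chain, resnum, resname, atom, element) rows."""
    atoms = tuple(AtomRecord(chain_id=c, residue_number=r, residue_name=rn,
                             atom_name=an, element=el)
                  for c, r, rn, an, el in spec_rows)
    return AtomFrame(atoms, np.asarray(coords, dtype=float))


@pytest.fixture
def loop_reference():
    return make_loop_reference(12, seed=7)


@pytest.fixture
def loop_region():
    return default_region(12)


@pytest.fixture
def tripeptide_backbone():
    """Three residues, backbone-only (12 atoms), on a bent chain."""
    rows, xyz = [], []
    for r in range(1, 4):
        for name, off in (("N", (-0.1, 0.05, 0.0)), ("CA", (0.0, 0.0, 0.0)),
                          ("C", (0.12, 0.06, 0.01)), ("O", (0.14, 0.18, 0.0))):
            rows.append(("A", r, "GLY", name, name[0]))
            xyz.append([0.38 * r + off[0], 0.2 * (r % 2) + off[1], off[2]])
    return make_frame(rows, xyz)


def random_rigid(rng):
    """A random proper rotation matrix and translation vector."""
    from scipy.spatial.transform import Rotation
    return Rotation.random(random_state=rng).as_matrix(), rng.uniform(-2, 2, 3)
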