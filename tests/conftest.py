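import numpy as np
import pytest

import coopnet as cn


@pytest.fixture(scope="session")
def bundle():
    """Mid-size planted fixture shared by read-only tests."""
    return cn.make_interface_fixture(n_nodes=20, n_frames=2000, seed=7)


@pytest.fixture(scope="session")
def learned(bundle):
    """Network learned on the shared fixture (read-only)."""
    return cn.learn_structure(bundle.fingerprints, restarts=15, seed=7)


@pytest.fixture
def copy_pair_data():
    """Two perfectly coupled columns: b copies a, 1000 frames."""
    rng = np.random.default_rng(5)
    a = (rng.random(1000) < 0.5).astype(np.uint8)
    labels = [cn.ContactNodeId.parse("3×50_G.H5.23"),
              cn.ContactNodeId.parse("7×55_G.H5.24")]
    return cn.FingerprintMatrix(node_labels=labels,
                                values=np.column_stack([a, a]))


def make_residue(chain, resid, resname, atoms):
    from coopnet.contacts import Residue
    return Residue(chain, resid, resname,
                   {k: np.asarray(v, dtype=float) for k, v in atoms.items()})


@pytest.fixture
def salt_bridge_pair():
    """Asp carboxylate O 3.5 A from Arg guanidinium N."""
    asp = make_residue("R", 10, "ASP", {
        "CA": (0, 0, 0), "CB": (1.5, 0, 0), "CG": (2.5, 0.8, 0),
        "OD1": (3.5, 0.5, 0), "OD2": (2.4, 2.0, 0),
    })
    arg = make_residue("A", 50, "ARG", {
        "CA": (10, 0, 0), "CZ": (8.0, 0.5, 0),
        "NH1": (7.0, 0.5, 0), "NH2": (8.5, 1.6, 0), "NE": (8.6, -0.7, 0),
    })
    return asp, arg
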