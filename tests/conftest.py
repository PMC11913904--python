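import numpy as np
import pytest

import tunnelstates as ts


@pytest.fixture(scope="session")
def world_spec():
    """A small gated world: 2 channels, 3 hidden states, 2 short runs."""
    return ts.SyntheticWorldSpec(n_frames=400, n_trajectories=2, seed=7)


@pytest.fixture(scope="session")
def protein(world_spec):
    return ts.build_sphere_protein(world_spec)


@pytest.fixture(scope="session")
def tunnel_config():
    return ts.TunnelSearchConfig()


@pytest.fixture(scope="session")
def gated(world_spec):
    return ts.generate_gated_ensemble(world_spec)


@pytest.fixture(scope="session")
def membrane(world_spec):
    return ts.build_membrane_slab(world_spec)


def toy_frame(positions, radii=None, residues=None, names=None,
              elements=None, chain="A", box=None):
    """Hand-built FrameCoordinates for small geometric tests."""
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    return ts.FrameCoordinates(
        positions=positions,
        atom_radius=np.asarray(radii if radii is not None else np.ones(n),
                               dtype=float),
        atom_name=np.asarray(names if names is not None else ["C"] * n),
        residue_number=np.asarray(residues if residues is not None
                                  else np.arange(1, n + 1), dtype=int),
        residue_name=np.asarray(["RES"] * n),
        chain=np.full(n, chain),
        element=np.asarray(elements if elements is not None else ["C"] * n),
        box_lengths=np.asarray(box, dtype=float) if box is not None else None,
    )
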