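import numpy as np
import pytest

from pdzbind.structures import AtomRecord, Trajectory
from pdzbind.synthetic import default_ensemble_config, generate_ensemble


@pytest.fixture(scope="session")
def planted_ensemble():
    """Default planted complex, 400 frames: (config, trajectory, manifest)."""
    cfg = default_ensemble_config(seed=11, n_frames=400)
    traj, manifest = generate_ensemble(cfg)
    return cfg, traj, manifest


def make_chain_traj(n_res=100, chain="A", coords=None, atom_names=("N", "CA", "C")):
    """Simple single-chain trajectory: n_res residues x len(atom_names) atoms."""
    atoms = []
    serial = 1
    rng = np.random.default_rng(7)
    ref = []
    for r in range(1, n_res + 1):
        for j, name in enumerate(atom_names):
            xyz = (3.0 * r + 0.5 * j, float(rng.normal(0, 2)), float(rng.normal(0, 2)))
            atoms.append(AtomRecord(serial, name, name[0], "ALA", r, chain, xyz))
            ref.append(xyz)
            serial += 1
    c = np.array(ref)[None] if coords is None else coords
    return Trajectory(atoms, c)


@pytest.fixture
def chain100():
    return make_chain_traj(100)
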