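import numpy as np
import pytest

from ctfold.structure_io import Conformation


def make_frame(coords, residues=None, elements=None, time=0.0, box=None, names=None):
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if residues is None:
        residues = np.arange(1, n + 1)
    if elements is None:
        elements = np.array(["C"] * n)
    masses = np.where(np.asarray(elements) == "H", 1.008, 12.011)
    return Conformation(
        frame_time=time,
        atom_coords=coords,
        residue_index=np.asarray(residues),
        element=np.asarray(elements),
        atom_mass=masses,
        atom_name=np.asarray(names) if names is not None else None,
        box=box,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
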