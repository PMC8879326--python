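"""Shared fixtures: hand-written SDF text and cached synthetic libraries."""

from __future__ import annotations

import numpy as np
import pytest

from foulqsar.charges import assign_partial_charges
from foulqsar.chem_io import add_hydrogens, from_smiles
from foulqsar.descriptors import featurize
from foulqsar.synthetic import SyntheticConfig, embed_3d, generate_library

ETHANOL_BLOCK = """\
ethanol
     RDKit          3D

  9  8  0  0  0  0  0  0  0  0999 V2000
   -0.9265    0.0389   -0.0062 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.5119   -0.3706    0.1273 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.3032    0.7586    0.1695 O   0  0  0  0  0  0  0  0  0  0  0  0
   -1.0142    1.0351   -0.5072 H   0  0  0  0  0  0  0  0  0  0  0  0
   -1.3515    0.1531    1.0224 H   0  0  0  0  0  0  0  0  0  0  0  0
   -1.5581   -0.6904   -0.5278 H   0  0  0  0  0  0  0  0  0  0  0  0
    0.6446   -0.9004    1.1057 H   0  0  0  0  0  0  0  0  0  0  0  0
    0.7766   -1.0932   -0.6540 H   0  0  0  0  0  0  0  0  0  0  0  0
    1.6140    1.0688   -0.7296 H   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  1  0
  1  4  1  0
  1  5  1  0
  1  6  1  0
  2  7  1  0
  2  8  1  0
  3  9  1  0
M  END
>  <percent_inhibition>
61.0

$$$$
"""


@pytest.fixture
def ethanol_sdf(tmp_path):
    path = tmp_path / "ethanol.sdf"
    path.write_text(ETHANOL_BLOCK)
    return path


def embedded_molecule(smiles: str, mol_id: str = "m", seed: int = 5):
    """SMILES -> explicit-H molecule with 3D coordinates and PEOE charges."""
    mol = embed_3d(add_hydrogens(from_smiles(smiles, mol_id)), seed=seed)
    return assign_partial_charges(mol)


_LIBRARY_CACHE: dict[int, list] = {}
_FEATURE_CACHE: dict[int, tuple] = {}


def planted_library(seed: int, n: int = 200):
    """Cached standard-condition synthetic library (default generator settings)."""
    if seed not in _LIBRARY_CACHE:
        _LIBRARY_CACHE[seed] = generate_library(
            SyntheticConfig(n_molecules=n, seed=seed)
        )
    return _LIBRARY_CACHE[seed]


def planted_features(seed: int, n: int = 200):
    """(DescriptorMatrix, labels) for the cached library at ``seed``."""
    if seed not in _FEATURE_CACHE:
        recs = planted_library(seed, n)
        _FEATURE_CACHE[seed] = (
            featurize(recs),
            [r.activity.activity_class for r in recs],
        )
    return _FEATURE_CACHE[seed]


@pytest.fixture(scope="session")
def small_library():
    """A small embedded+charged library for descriptor-oracle sweeps."""
    cfg = SyntheticConfig(n_molecules=50, heavy_atom_range=(10, 22), seed=17)
    return generate_library(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(123)
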