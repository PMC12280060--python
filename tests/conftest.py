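"""Shared fixtures: toy receptor, surrogate predictors, random toy complexes."""

import numpy as np
import pytest

from pepevo import PredictedComplex, Structure3D, toy_receptor_input
from pepevo.predictor import AA3, ToySurrogate


@pytest.fixture(scope="session")
def receptor():
    return toy_receptor_input()


@pytest.fixture(scope="session")
def design_surrogate():
    return ToySurrogate(motif_seed=11)


@pytest.fixture(scope="session")
def validation_surrogate():
    return ToySurrogate(motif_seed=23, d_far=30.0)


def random_structure(rng, n_residues, chain="A", spread=10.0, center=(0, 0, 0)):
    """Random CA+CB structure for brute-force oracle tests."""
    aas = list(AA3.values())
    chains, resid, resname, atomname, coords = [], [], [], [], []
    for i in range(n_residues):
        base = rng.normal(0.0, spread, 3) + np.asarray(center, dtype=float)
        name = aas[rng.integers(len(aas))]
        for atom in ("CA", "CB"):
            chains.append(chain)
            resid.append(i + 1)
            resname.append(name)
            atomname.append(atom)
            coords.append(base + rng.normal(0.0, 1.0, 3))
    return Structure3D(chains, resid, resname, atomname, np.asarray(coords))


def random_complex(rng, n_rec=8, n_pep=4, separation=5.0, with_pae=False):
    """Random toy complex (<= 50 atoms) with valid plDDT and optional PAE."""
    rec = random_structure(rng, n_rec, chain="A")
    pep = random_structure(rng, n_pep, chain="B", spread=4.0, center=(separation, 0, 0))
    plddt = rng.uniform(40.0, 100.0, n_pep)
    pae = None
    if with_pae:
        n = n_rec + n_pep
        pae = rng.uniform(0.5, 30.0, (n, n))
    return PredictedComplex(rec, pep, plddt, pae=pae)


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
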