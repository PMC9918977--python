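import numpy as np
import pytest
from biotite.structure import AtomArray

from carragel import amide1, synthetic


@pytest.fixture(scope="session")
def native_spectrum():
    return synthetic.make_protein_spectrum("native")


@pytest.fixture(scope="session")
def gel_spectrum():
    return synthetic.make_protein_spectrum("gel")


@pytest.fixture(scope="session")
def native_fit(native_spectrum):
    return amide1.deconvolve(native_spectrum)


@pytest.fixture(scope="session")
def gel_fit(gel_spectrum, native_fit):
    return amide1.gel_refit(gel_spectrum, native_fit)


def make_structure(residues):
    """Build an AtomArray from (chain, res_id, res_name, element, (x, y, z))."""
    arr = AtomArray(len(residues))
    arr.chain_id = np.array([r[0] for r in residues])
    arr.res_id = np.array([r[1] for r in residues])
    arr.res_name = np.array([r[2] for r in residues])
    arr.element = np.array([r[3] for r in residues])
    arr.atom_name = np.array(
        [f"{r[3]}{i}" for i, r in enumerate(residues)]
    )
    arr.coord = np.array([r[4] for r in residues], dtype=float)
    return arr
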