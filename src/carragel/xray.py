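"""Secondary-structure fractions from an atomic structure.

Cross-check utility: infrared-derived fractions can be compared against the
assignment computed from a crystal structure (e.g. GAPDH, PDB entry 1ZNQ).
Uses biotite's P-SEA annotation on the C-alpha trace.
"""

from __future__ import annotations

import numpy as np
from biotite.structure import AtomArray, annotate_sse

from .docking import read_structure

__all__ = ["secondary_structure_fractions", "secondary_structure_from_pdb"]


def secondary_structure_fractions(structure: AtomArray) -> dict[str, float]:
    """Percent of residues annotated beta-strand / alpha-helix / coil."""
    sse = annotate_sse(structure)
    if sse.size == 0:
        raise ValueError("structure has no annotatable amino-acid residues")
    n = sse.size
    return {
        "beta": 100.0 * float(np.count_nonzero(sse == "b")) / n,
        "alpha": 100.0 * float(np.count_nonzero(sse == "a")) / n,
        "coil": 100.0 * float(np.count_nonzero(sse == "c")) / n,
    }


def secondary_structure_from_pdb(path) -> dict[str, float]:
    """Convenience wrapper: annotate a PDB file by path."""
    return secondary_structure_fractions(read_structure(path))
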