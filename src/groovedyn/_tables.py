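"""Element tables: standard atomic weights and Bondi van der Waals radii.

Lookups are keyed by element symbol so they are total over every residue,
including non-standard ones (benzothienylalanine, 5-fluorotryptophan) whose
atoms are ordinary C/N/O/S/F.
"""

from __future__ import annotations

import numpy as np

# Standard atomic weights (u), abridged to elements that occur in proteins,
# common ligands and ions.
ATOMIC_MASS: dict[str, float] = {
    "H": 1.008,
    "D": 2.014,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "NA": 22.990,
    "MG": 24.305,
    "P": 30.974,
    "S": 32.06,
    "CL": 35.45,
    "K": 39.098,
    "CA": 40.078,
    "MN": 54.938,
    "FE": 55.845,
    "CO": 58.933,
    "NI": 58.693,
    "CU": 63.546,
    "ZN": 65.38,
    "SE": 78.971,
    "BR": 79.904,
    "I": 126.904,
}

# Bondi (1964) van der Waals radii in Angstrom, by element.
VDW_RADIUS: dict[str, float] = {
    "H": 1.20,
    "D": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "NA": 2.27,
    "MG": 1.73,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "K": 2.75,
    "CA": 2.31,
    "NI": 1.63,
    "CU": 1.40,
    "ZN": 1.39,
    "SE": 1.90,
    "BR": 1.85,
    "I": 1.98,
}

# Fallback for exotic elements absent from the table.
DEFAULT_VDW_RADIUS = 1.70

# Backbone heavy-atom names (used by selection classes).
BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "OXT"})


class TableError(KeyError):
    """An element could not be resolved in a mass/radius table."""


def element_masses(elements: np.ndarray) -> np.ndarray:
    """Map an array of element symbols to atomic masses (u)."""
    try:
        return np.array([ATOMIC_MASS[e.upper()] for e in elements])
    except KeyError as exc:
        raise TableError(f"no atomic mass for element {exc.args[0]!r}") from None


def element_radii(elements: np.ndarray) -> np.ndarray:
    """Map an array of element symbols to Bondi vdW radii (A)."""
    return np.array(
        [VDW_RADIUS.get(e.upper(), DEFAULT_VDW_RADIUS) for e in elements]
    )
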