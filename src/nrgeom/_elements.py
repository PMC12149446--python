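"""Atomic masses and van der Waals radii used across the package.

Masses are IUPAC 2021 standard atomic weights (Da); vdW radii are the
Bondi set (Å) with the common extension for elements Bondi did not cover.
"""

from __future__ import annotations

ATOMIC_MASS: dict[str, float] = {
    "H": 1.008, "D": 2.014, "C": 12.011, "N": 14.007, "O": 15.999,
    "S": 32.06, "P": 30.974, "SE": 78.971, "F": 18.998, "CL": 35.45,
    "BR": 79.904, "I": 126.904, "ZN": 65.38, "MG": 24.305, "CA": 40.078,
    "FE": 55.845, "MN": 54.938, "NA": 22.990, "K": 39.098, "CU": 63.546,
}

# Bondi (1964) vdW radii; 2.0 Å fallback for anything exotic.
VDW_RADIUS: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "ZN": 1.39, "MG": 1.73, "CA": 2.00, "FE": 2.00, "MN": 2.00,
    "NA": 2.27, "K": 2.75, "CU": 1.40,
}

DEFAULT_MASS = 12.011
DEFAULT_VDW = 2.0


def element_mass(element: str) -> float:
    return ATOMIC_MASS.get(element.upper().strip(), DEFAULT_MASS)


def element_vdw(element: str) -> float:
    return VDW_RADIUS.get(element.upper().strip(), DEFAULT_VDW)
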