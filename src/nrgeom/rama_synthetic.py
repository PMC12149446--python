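"""Synthetic Ramachandran reference densities and contour thresholds.

This is a constructed stand-in for empirically derived backbone-dihedral
reference tables: each residue class (general, glycine, proline,
pre-proline, isoleucine-valine) is modelled as a mixture of wrapped
Gaussian basins placed at the textbook φ/ψ minima (right-handed α,
β/extended, polyproline-II, left-handed α, and the glycine-specific
mirror basins). The *favored* and *allowed* boundaries are the density
contours enclosing 98% and 99.8% of each class's probability mass,
computed numerically on a 1° grid and cached. Absolute boundaries differ
in detail from survey-derived tables, but the classification semantics
(favored ⊃ allowed complement ⊃ outlier at the stated mass levels) are
identical, and the table is its own oracle for tests.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

__all__ = ["RESIDUE_CLASSES", "residue_class", "classify", "class_density"]

RESIDUE_CLASSES = ("general", "glycine", "proline", "pre-proline", "isoleucine-valine")

# (phi_mean, psi_mean, sigma_phi, sigma_psi, weight) per basin
_BASINS: dict[str, list[tuple[float, float, float, float, float]]] = {
    "general": [
        (-63.0, -43.0, 14.0, 14.0, 0.46),   # right-handed alpha
        (-120.0, 130.0, 26.0, 22.0, 0.30),  # beta / extended
        (-65.0, 145.0, 16.0, 16.0, 0.17),   # polyproline II
        (58.0, 42.0, 12.0, 12.0, 0.07),     # left-handed alpha
    ],
    "glycine": [
        (-63.0, -41.0, 16.0, 16.0, 0.28),
        (63.0, 41.0, 16.0, 16.0, 0.28),
        (-85.0, 175.0, 22.0, 26.0, 0.22),
        (85.0, -175.0, 22.0, 26.0, 0.22),
    ],
    "proline": [
        (-63.0, -33.0, 10.0, 15.0, 0.45),   # alpha
        (-63.0, 148.0, 10.0, 15.0, 0.55),   # polyproline II / beta
    ],
    "pre-proline": [
        (-63.0, -40.0, 13.0, 13.0, 0.38),
        (-125.0, 128.0, 22.0, 20.0, 0.37),
        (-65.0, 150.0, 15.0, 15.0, 0.25),
    ],
    "isoleucine-valine": [
        (-63.0, -45.0, 11.0, 12.0, 0.45),
        (-115.0, 125.0, 20.0, 16.0, 0.55),
    ],
}


def _wrap(delta: np.ndarray | float) -> np.ndarray | float:
    """Map an angle difference to (−180, 180]."""
    return -((180.0 - np.asarray(delta)) % 360.0 - 180.0)


def class_density(cls: str, phi, psi):
    """Unnormalized mixture density at (φ, ψ); broadcasts over arrays."""
    if cls not in _BASINS:
        raise KeyError(f"unknown residue class {cls!r}")
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    dens = np.zeros(np.broadcast(phi, psi).shape)
    for mphi, mpsi, sphi, spsi, w in _BASINS[cls]:
        dphi = _wrap(phi - mphi) / sphi
        dpsi = _wrap(psi - mpsi) / spsi
        dens = dens + w / (sphi * spsi) * np.exp(-0.5 * (dphi**2 + dpsi**2))
    return dens


@lru_cache(maxsize=None)
def _thresholds(cls: str) -> tuple[float, float]:
    """Density levels enclosing 98% (favored) and 99.8% (allowed) of the mass."""
    grid = np.arange(-179.5, 180.0, 1.0)
    phi, psi = np.meshgrid(grid, grid, indexing="ij")
    dens = class_density(cls, phi, psi).ravel()
    order = np.argsort(dens)[::-1]
    cum = np.cumsum(dens[order]) / dens.sum()
    favored = dens[order][np.searchsorted(cum, 0.98)]
    allowed = dens[order][np.searchsorted(cum, 0.998)]
    return float(favored), float(allowed)


def residue_class(res_name: str, next_res_name: str | None = None) -> str:
    """Route a residue to its Ramachandran class (pre-proline wins for non-Gly/Pro)."""
    name = res_name.upper()
    if name == "GLY":
        return "glycine"
    if name == "PRO":
        return "proline"
    if next_res_name is not None and next_res_name.upper() == "PRO":
        return "pre-proline"
    if name in ("ILE", "VAL"):
        return "isoleucine-valine"
    return "general"


def classify(cls: str, phi: float, psi: float) -> str:
    """'favored' | 'allowed' | 'outlier' for a (φ, ψ) pair of the given class."""
    if phi is None or psi is None or not (np.isfinite(phi) and np.isfinite(psi)):
        raise ValueError("phi and psi must be defined finite angles")
    favored, allowed = _thresholds(cls)
    d = float(class_density(cls, phi, psi))
    if d >= favored:
        return "favored"
    if d >= allowed:
        return "allowed"
    return "outlier"
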