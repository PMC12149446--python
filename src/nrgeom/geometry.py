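"""Inter-domain architecture descriptors: ε, θ and DH.

A two-domain chain (DNA-binding domain and ligand-binding domain joined
by a flexible hinge) is summarized by three numbers: the distance ε
between the domain centers of mass, the angle θ at the hinge midpoint
(the average of the last DBD Cα and the first LBD Cα), and the signed
torsion DH about the hinge axis defined by those two Cα atoms. Circular
dispersion statistics and a cosine conformational-similarity measure
support cross-structure comparison of the angular descriptors.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._elements import element_mass
from .io import AtomRecord, ChainModel, DomainSpan, select_domain

__all__ = [
    "DomainGeometry",
    "CircularStats",
    "center_of_mass",
    "domain_distance",
    "hinge_com",
    "domain_angle",
    "domain_dihedral",
    "chain_domain_geometry",
    "circular_dispersion",
    "conformational_similarity",
    "homodimer_asymmetry",
]


@dataclass
class DomainGeometry:
    epsilon: float  # Å
    theta: float  # degrees, [0, 180]
    dihedral: float  # degrees, (-180, 180]
    structure_id: str = ""
    chain_id: str = ""


@dataclass
class CircularStats:
    mean_resultant_R: float
    circular_std: float  # radians; inf when R == 0
    n: int


def center_of_mass(atoms: Sequence[AtomRecord], weighting: str = "mass") -> np.ndarray:
    """Mass-weighted mean position; ``weighting='geometric'`` for the centroid."""
    if len(atoms) == 0:
        raise ValueError("empty atom list")
    coords = np.array([a.coords for a in atoms])
    if weighting == "geometric":
        return coords.mean(axis=0)
    masses = np.array([element_mass(a.element) for a in atoms])
    return masses @ coords / masses.sum()


def domain_distance(dbd_com: np.ndarray, lbd_com: np.ndarray) -> float:
    """ε: Euclidean distance between the two domain centers of mass (Å)."""
    a, b = np.asarray(dbd_com, float), np.asarray(lbd_com, float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite center of mass")
    return float(np.linalg.norm(a - b))


def hinge_com(dbd_last_ca: np.ndarray, lbd_first_ca: np.ndarray) -> np.ndarray:
    """Hinge reference point: unweighted midpoint of the two boundary Cα atoms."""
    return (np.asarray(dbd_last_ca, float) + np.asarray(lbd_first_ca, float)) / 2.0


def domain_angle(dbd_com, hinge, lbd_com) -> float:
    """θ: angle in degrees at the hinge vertex between the two COM arms."""
    v1 = np.asarray(dbd_com, float) - np.asarray(hinge, float)
    v2 = np.asarray(lbd_com, float) - np.asarray(hinge, float)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-9 or n2 < 1e-9:
        raise ValueError("zero-length arm: hinge point coincides with a domain COM")
    cosang = np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def domain_dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion of p1-p2-p3-p4 about the p2→p3 axis, IUPAC sign, (−180, 180].

    For the domain descriptor the four points are DBD COM, last DBD Cα,
    first LBD Cα, LBD COM.
    """
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    if np.linalg.norm(b2) < 1e-9:
        raise ValueError("degenerate geometry: zero-length central axis")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise ValueError("degenerate geometry: collinear points")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = n1 @ n2
    y = m1 @ n2
    ang = float(np.degrees(np.arctan2(y, x)))
    if ang <= -180.0:
        ang += 360.0
    return ang


def _boundary_ca(chain: ChainModel, span: DomainSpan, which: str) -> np.ndarray:
    """Cα of the span boundary residue; nearest present in-span residue as fallback."""
    in_span = [r for r in chain.residues if r.auth_seq in span and r.atom("CA") is not None]
    if not in_span:
        raise ValueError(
            f"chain {chain.chain_id}: no Cα in span {span.domain_name} "
            f"{span.start}-{span.end}"
        )
    res = in_span[-1] if which == "last" else in_span[0]
    return res.atom("CA").coords


def chain_domain_geometry(
    chain: ChainModel,
    dbd: DomainSpan,
    lbd: DomainSpan,
    structure_id: str = "",
    com_weighting: str = "mass",
) -> DomainGeometry:
    """(ε, θ, DH) of one chain given its DBD and LBD spans."""
    dbd_atoms = select_domain(chain, dbd, "all")
    lbd_atoms = select_domain(chain, lbd, "all")
    dbd_com = center_of_mass(dbd_atoms, com_weighting)
    lbd_com = center_of_mass(lbd_atoms, com_weighting)
    ca_last = _boundary_ca(chain, dbd, "last")
    ca_first = _boundary_ca(chain, lbd, "first")
    hinge = hinge_com(ca_last, ca_first)
    return DomainGeometry(
        epsilon=domain_distance(dbd_com, lbd_com),
        theta=domain_angle(dbd_com, hinge, lbd_com),
        dihedral=domain_dihedral(dbd_com, ca_last, ca_first, lbd_com),
        structure_id=structure_id,
        chain_id=chain.chain_id,
    )


def circular_dispersion(angles_deg: Sequence[float]) -> CircularStats:
    """Mean resultant length R and circular SD σ = sqrt(−2 ln R) of angles."""
    angles = np.radians(np.asarray(angles_deg, dtype=float))
    if angles.size < 1:
        raise ValueError("need at least one angle")
    z = np.exp(1j * angles).mean()
    R = float(abs(z))
    if R < 1e-12:
        warnings.warn("mean resultant length is 0; circular std is infinite")
        return CircularStats(0.0, math.inf, angles.size)
    R = min(R, 1.0)
    sigma = math.sqrt(max(-2.0 * math.log(R), 0.0))
    return CircularStats(R, sigma, angles.size)


def conformational_similarity(dh_a: float, dh_b: float) -> float:
    """cos(ΔDH): 1 for identical torsions, −1 for opposite ones."""
    if not (math.isfinite(dh_a) and math.isfinite(dh_b)):
        raise ValueError("non-finite dihedral input")
    return float(math.cos(math.radians(dh_a - dh_b)))


def homodimer_asymmetry(
    geometries: Sequence[DomainGeometry],
    predicted_epsilon: float | None = None,
    threshold: float = 5.0,
) -> dict:
    """Pairwise |Δε| over homodimer monomers and the nearest state to a prediction.

    Flags 'asymmetric' when the largest pairwise ε difference exceeds
    ``threshold`` (Å). When ``predicted_epsilon`` is given, reports which
    monomer's ε the prediction is nearest to.
    """
    if len(geometries) < 2:
        raise ValueError("need at least 2 monomers")
    eps = [g.epsilon for g in geometries]
    deltas = [
        abs(eps[i] - eps[j]) for i in range(len(eps)) for j in range(i + 1, len(eps))
    ]
    report = {
        "epsilons": eps,
        "max_delta_epsilon": max(deltas),
        "asymmetric": max(deltas) > threshold,
    }
    if predicted_epsilon is not None:
        idx = int(np.argmin([abs(predicted_epsilon - e) for e in eps]))
        report["nearest_state"] = {
            "chain_id": geometries[idx].chain_id,
            "epsilon": eps[idx],
            "kind": "extended" if eps[idx] == max(eps) else "compact",
        }
    return report
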