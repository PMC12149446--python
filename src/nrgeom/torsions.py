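"""Backbone φ/ψ torsions, Ramachandran classification, and pairwise
experimental-vs-predicted torsional agreement.

φ(i) is the C(i−1)–N(i)–CA(i)–C(i) torsion, ψ(i) the N(i)–CA(i)–C(i)–N(i+1)
torsion; both are undefined at chain termini and across chain breaks
(consecutive CA–CA distance above 4.5 Å). Agreement between two
structures over the same residues is scored per angle with a circular
RMSD and mean absolute error on the wrapped difference, a plain Pearson
correlation of the paired raw angles, and the first-order Wasserstein
distance between the two marginal angle distributions (on the linear
−180…180 scale). Ramachandran tallies use the residue-class contour
tables of :mod:`nrgeom.rama_synthetic`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import pearsonr, wasserstein_distance

from .geometry import domain_dihedral
from .io import ChainModel
from .rama_synthetic import classify, residue_class

__all__ = [
    "TorsionRecord",
    "TorsionComparison",
    "backbone_torsions",
    "ramachandran_classify",
    "ramachandran_tally",
    "torsion_comparison",
    "wasserstein_1d",
    "wrapped_difference",
]

CHAIN_BREAK_CA_CA = 4.5  # Å


@dataclass
class TorsionRecord:
    auth_seq: int
    res_name: str
    phi: float | None
    psi: float | None
    residue_class: str


@dataclass
class TorsionComparison:
    rmsd_phi: float
    rmsd_psi: float
    mae_phi: float
    mae_psi: float
    wasserstein_phi: float
    wasserstein_psi: float
    pearson_phi: float
    pearson_psi: float
    n_paired: int
    rama_a: dict = field(default_factory=dict)  # tallies of the first structure
    rama_b: dict = field(default_factory=dict)  # tallies of the second structure


def wrapped_difference(a, b):
    """Circular difference a−b mapped to (−180, 180]; antisymmetric."""
    d = (np.asarray(a, float) - np.asarray(b, float) + 180.0) % 360.0 - 180.0
    return np.where(d == -180.0, 180.0, d)


def backbone_torsions(chain: ChainModel) -> list[TorsionRecord]:
    """Per-residue φ/ψ with termini and chain breaks left undefined."""
    residues = [r for r in chain.residues if r.backbone_complete]
    if len(residues) < 2:
        raise ValueError(f"chain {chain.chain_id}: fewer than 2 backbone-complete residues")

    def connected(i: int) -> bool:
        """Residues i and i+1 form a continuous chain segment."""
        a = residues[i].atom("CA").coords
        b = residues[i + 1].atom("CA").coords
        return bool(np.linalg.norm(a - b) <= CHAIN_BREAK_CA_CA)

    records: list[TorsionRecord] = []
    any_defined = False
    for i, res in enumerate(residues):
        phi = psi = None
        if i > 0 and connected(i - 1):
            prev = residues[i - 1]
            phi = domain_dihedral(
                prev.atom("C").coords, res.atom("N").coords,
                res.atom("CA").coords, res.atom("C").coords,
            )
        if i < len(residues) - 1 and connected(i):
            nxt = residues[i + 1]
            psi = domain_dihedral(
                res.atom("N").coords, res.atom("CA").coords,
                res.atom("C").coords, nxt.atom("N").coords,
            )
        next_name = residues[i + 1].res_name if i < len(residues) - 1 else None
        records.append(
            TorsionRecord(
                auth_seq=res.auth_seq,
                res_name=res.res_name,
                phi=phi,
                psi=psi,
                residue_class=residue_class(res.res_name, next_name),
            )
        )
        any_defined = any_defined or phi is not None or psi is not None
    if not any_defined:
        raise ValueError(f"chain {chain.chain_id}: no computable torsion angles")
    return records


def ramachandran_classify(record: TorsionRecord) -> str:
    """'favored' | 'allowed' | 'outlier' for one residue's (φ, ψ)."""
    if record.phi is None or record.psi is None:
        raise ValueError(f"residue {record.auth_seq}: phi/psi undefined")
    return classify(record.residue_class, record.phi, record.psi)


def ramachandran_tally(records: list[TorsionRecord]) -> dict:
    """Favored/allowed percentages and outlier count over classifiable residues."""
    classifiable = [r for r in records if r.phi is not None and r.psi is not None]
    if not classifiable:
        raise ValueError("no residues with both phi and psi defined")
    counts = {"favored": 0, "allowed": 0, "outlier": 0}
    for rec in classifiable:
        counts[ramachandran_classify(rec)] += 1
    n = len(classifiable)
    return {
        "n_classifiable": n,
        "favored_pct": 100.0 * counts["favored"] / n,
        "allowed_pct": 100.0 * (counts["favored"] + counts["allowed"]) / n,
        "outlier_count": counts["outlier"],
    }


def wasserstein_1d(sample_a, sample_b) -> float:
    """First-order Wasserstein distance between two angle samples (degrees)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    return float(wasserstein_distance(a, b))


def torsion_comparison(
    exp_records: list[TorsionRecord],
    pred_records: list[TorsionRecord],
    numbering_offset: int = 0,
    min_pairs: int = 10,
) -> TorsionComparison:
    """Four-metric torsional agreement between paired structures.

    Residues are paired by number after adding ``numbering_offset`` to the
    experimental numbering; only residues with both angles defined in both
    structures enter the paired metrics.
    """
    pred_by_seq = {r.auth_seq: r for r in pred_records}
    pairs: list[tuple[TorsionRecord, TorsionRecord]] = []
    for rec in exp_records:
        other = pred_by_seq.get(rec.auth_seq + numbering_offset)
        if other is None:
            continue
        if None in (rec.phi, rec.psi, other.phi, other.psi):
            continue
        pairs.append((rec, other))
    if len(pairs) < min_pairs:
        raise ValueError(f"only {len(pairs)} torsion pairs; need ≥ {min_pairs}")

    exp_phi = np.array([p[0].phi for p in pairs])
    exp_psi = np.array([p[0].psi for p in pairs])
    pred_phi = np.array([p[1].phi for p in pairs])
    pred_psi = np.array([p[1].psi for p in pairs])

    dphi = wrapped_difference(exp_phi, pred_phi)
    dpsi = wrapped_difference(exp_psi, pred_psi)
    return TorsionComparison(
        rmsd_phi=float(np.sqrt(np.mean(dphi**2))),
        rmsd_psi=float(np.sqrt(np.mean(dpsi**2))),
        mae_phi=float(np.mean(np.abs(dphi))),
        mae_psi=float(np.mean(np.abs(dpsi))),
        wasserstein_phi=wasserstein_1d(exp_phi, pred_phi),
        wasserstein_psi=wasserstein_1d(exp_psi, pred_psi),
        pearson_phi=float(pearsonr(exp_phi, pred_phi)[0]),
        pearson_psi=float(pearsonr(exp_psi, pred_psi)[0]),
        n_paired=len(pairs),
        rama_a=ramachandran_tally(exp_records),
        rama_b=ramachandran_tally(pred_records),
    )
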