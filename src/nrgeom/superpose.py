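"""Rigid-body superposition and the three-level RMSD comparison.

The Kabsch (SVD) least-squares fit is the workhorse; ``refined_superpose``
adds iterative outlier rejection (pairs beyond a distance cutoff are
dropped and the fit repeated) to emulate refinement cycles of
structure-alignment tools. ``rmsd_triple`` runs the fit independently on
all-atom, backbone, and CA selections of a domain, the standard
resolution hierarchy for comparing an experimental structure with its
predicted counterpart.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import BACKBONE_ATOMS, ChainModel, DomainSpan

__all__ = [
    "SuperpositionResult",
    "RMSDTriple",
    "kabsch_superpose",
    "refined_superpose",
    "rmsd_triple",
    "hierarchy_check",
]


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # 3x3, det = +1
    translation: np.ndarray  # applied after rotation
    rmsd: float
    n_pairs: int
    cycles_run: int = 1

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class RMSDTriple:
    all_atom: float
    backbone: float
    c_alpha: float
    domain_name: str = ""
    structure_pair: tuple[str, str] = ("", "")


def _check_coords(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mobile = np.asarray(mobile, dtype=float).reshape(-1, 3)
    target = np.asarray(target, dtype=float).reshape(-1, 3)
    if mobile.shape != target.shape:
        raise ValueError(f"coordinate count mismatch: {len(mobile)} vs {len(target)}")
    if len(mobile) < 3:
        raise ValueError(f"need at least 3 atom pairs, got {len(mobile)}")
    return mobile, target


def kabsch_superpose(mobile: np.ndarray, target: np.ndarray) -> SuperpositionResult:
    """Optimal rigid transform of ``mobile`` onto ``target`` (Kabsch, SVD).

    Returns the proper rotation (det = +1, reflections corrected) and the
    RMSD of the superposed pairs.
    """
    mobile, target = _check_coords(mobile, target)
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    H = (mobile - mc).T @ (target - tc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = tc - R @ mc
    moved = mobile @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1))))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, n_pairs=len(mobile))


def refined_superpose(
    mobile: np.ndarray,
    target: np.ndarray,
    max_cycles: int = 5,
    reject_cutoff: float = 2.0,
) -> SuperpositionResult:
    """Kabsch fit with iterative rejection of far-apart atom pairs.

    After each fit, pairs with post-fit distance above ``reject_cutoff``
    (Å) are removed and the fit repeated, until convergence (no pair
    removed) or ``max_cycles`` extra cycles. ``max_cycles=0`` is a plain
    Kabsch fit.
    """
    mobile, target = _check_coords(mobile, target)
    keep = np.ones(len(mobile), dtype=bool)
    result = kabsch_superpose(mobile, target)
    cycles = 1
    for _ in range(max_cycles):
        moved = result.transform(mobile[keep])
        dist = np.linalg.norm(moved - target[keep], axis=1)
        bad = dist > reject_cutoff
        if not bad.any():
            break
        new_keep = keep.copy()
        new_keep[np.where(keep)[0][bad]] = False
        if new_keep.sum() < 3:
            raise ValueError(
                f"over-trimmed: {new_keep.sum()} pairs remain below cutoff {reject_cutoff} Å"
            )
        keep = new_keep
        result = kabsch_superpose(mobile[keep], target[keep])
        cycles += 1
    return SuperpositionResult(
        rotation=result.rotation,
        translation=result.translation,
        rmsd=result.rmsd,
        n_pairs=int(keep.sum()),
        cycles_run=cycles,
    )


def _paired_coords(
    mobile_chain: ChainModel,
    target_chain: ChainModel,
    span: DomainSpan,
    atom_mode: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Pair atoms by author residue number and atom name within the span.

    Only atoms present in both chains are paired (missing-density atoms
    are skipped); sequences are assumed identical so no alignment is run.
    """
    mob, tar = [], []
    target_res = {r.auth_seq: r for r in target_chain.residues}
    for res in mobile_chain.residues:
        if res.auth_seq not in span or res.auth_seq not in target_res:
            continue
        other = target_res[res.auth_seq]
        if atom_mode in ("backbone", "ca") and not (
            res.backbone_complete and other.backbone_complete
        ):
            continue
        if atom_mode == "ca":
            names = ["CA"]
        elif atom_mode == "backbone":
            names = list(BACKBONE_ATOMS)
        else:
            names = [a.name for a in res.atoms]
        for name in names:
            a, b = res.atom(name), other.atom(name)
            if a is not None and b is not None:
                mob.append(a.coords)
                tar.append(b.coords)
    if len(mob) < 3:
        raise ValueError(
            f"fewer than 3 common atoms in span {span.domain_name} "
            f"{span.start}-{span.end} (mode={atom_mode})"
        )
    return np.array(mob), np.array(tar)


def refined_superpose_chains(
    mobile_chain: ChainModel,
    target_chain: ChainModel,
    span: DomainSpan,
    atom_mode: str = "all",
    max_cycles: int = 5,
    reject_cutoff: float = 2.0,
) -> SuperpositionResult:
    """Residue-correspondence pairing within a span, then refined fit."""
    mob, tar = _paired_coords(mobile_chain, target_chain, span, atom_mode)
    return refined_superpose(mob, tar, max_cycles=max_cycles, reject_cutoff=reject_cutoff)


def rmsd_triple(
    exp_chain: ChainModel,
    pred_chain: ChainModel,
    span: DomainSpan,
    max_cycles: int = 5,
    reject_cutoff: float = 2.0,
    structure_pair: tuple[str, str] = ("", ""),
) -> RMSDTriple:
    """All-atom / backbone / CA RMSDs of one domain, each fitted independently."""
    values = {}
    for mode in ("all", "backbone", "ca"):
        res = refined_superpose_chains(
            pred_chain, exp_chain, span, atom_mode=mode,
            max_cycles=max_cycles, reject_cutoff=reject_cutoff,
        )
        values[mode] = res.rmsd
    return RMSDTriple(
        all_atom=values["all"],
        backbone=values["backbone"],
        c_alpha=values["ca"],
        domain_name=span.domain_name,
        structure_pair=structure_pair,
    )


def hierarchy_check(triple: RMSDTriple) -> bool:
    """True iff the triple obeys the strict hierarchy all-atom > backbone > CA."""
    return triple.all_atom > triple.backbone > triple.c_alpha
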