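"""Secondary-structure assignment and helix/sheet/loop composition.

Assignment follows the hydrogen-bond logic of the Kabsch–Sander (DSSP)
method reduced to three states: an electrostatic N-H···O=C energy below
−0.5 kcal/mol defines a hydrogen bond; two consecutive i→i+4 turns make
an α-helix (H); isolated and laddered bridges make strand (S); everything
else is loop (L). 3-10 and π helices are not distinguished and count as
loop, keeping the coarse H/S/L split used for composition percentages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ChainModel, DomainSpan

__all__ = ["SSEComposition", "assign_sse", "sse_composition", "sse_pearson"]

HBOND_ENERGY_CUTOFF = -0.5  # kcal/mol
_Q1Q2_F = 0.084 * 332.0  # Kabsch–Sander electrostatic constant
_MIN_RESIDUES = 5


@dataclass
class SSEComposition:
    helix_pct: float
    sheet_pct: float
    loop_pct: float
    domain_name: str = ""
    structure_id: str = ""


def _backbone_frames(chain: ChainModel):
    """Positions of N, CA, C, O and a placed amide H per residue (or None)."""
    frames = []
    prev = None
    for res in chain.residues:
        if not res.backbone_complete:
            frames.append(None)
            prev = None
            continue
        n = res.atom("N").coords
        ca = res.atom("CA").coords
        c = res.atom("C").coords
        o = res.atom("O").coords
        h = None
        if prev is not None and res.res_name != "PRO":
            c_prev, o_prev = prev
            d = c_prev - o_prev
            norm = np.linalg.norm(d)
            if norm > 1e-9:
                h = n + d / norm  # 1.0 Å N-H along the previous C=O direction
        frames.append({"N": n, "CA": ca, "C": c, "O": o, "H": h})
        prev = (c, o)
    return frames


def _hbond_energy(acceptor, donor) -> float:
    """Kabsch–Sander energy of CO(acceptor) ··· HN(donor), kcal/mol."""
    if donor is None or acceptor is None or donor["H"] is None:
        return 0.0
    c, o = acceptor["C"], acceptor["O"]
    n, h = donor["N"], donor["H"]
    r_on = np.linalg.norm(o - n)
    r_ch = np.linalg.norm(c - h)
    r_oh = np.linalg.norm(o - h)
    r_cn = np.linalg.norm(c - n)
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:  # clashing placement: no bond
        return 0.0
    return _Q1Q2_F * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)


def assign_sse(chain: ChainModel) -> list[str]:
    """Per-residue H/S/L labels for a chain (one label per residue)."""
    n_complete = sum(1 for r in chain.residues if r.backbone_complete)
    if n_complete < _MIN_RESIDUES:
        raise ValueError(
            f"chain {chain.chain_id}: only {n_complete} backbone-complete residues "
            f"(need ≥ {_MIN_RESIDUES})"
        )
    frames = _backbone_frames(chain)
    n = len(frames)

    def hbond(i: int, j: int) -> bool:
        """True iff CO of residue i accepts the N-H of residue j."""
        if not (0 <= i < n and 0 <= j < n) or abs(i - j) < 2:
            return False
        return _hbond_energy(frames[i], frames[j]) < HBOND_ENERGY_CUTOFF

    labels = ["L"] * n

    # strand: Kabsch–Sander parallel / antiparallel bridge patterns
    for i in range(n):
        for j in range(i + 3, n):
            para = (hbond(i - 1, j) and hbond(j, i + 1)) or (
                hbond(j - 1, i) and hbond(i, j + 1)
            )
            anti = (hbond(i, j) and hbond(j, i)) or (
                hbond(i - 1, j + 1) and hbond(j - 1, i + 1)
            )
            if para or anti:
                labels[i] = "S"
                labels[j] = "S"

    # α-helix: two consecutive 4-turns mark residues i+1..i+4 (precedence over S)
    turn4 = [hbond(i, i + 4) for i in range(n)]
    for i in range(1, n - 4):
        if turn4[i - 1] and turn4[i]:
            for k in range(i + 1, i + 5):
                labels[k] = "H"
            labels[i] = "H"  # the turn start participates in the helix body
    return labels


def sse_composition(
    labels: list[str],
    chain: ChainModel,
    span: DomainSpan,
    structure_id: str = "",
) -> SSEComposition:
    """H/S/L percentages over the residues of ``span``; sums to 100."""
    selected = [
        lab for lab, res in zip(labels, chain.residues) if res.auth_seq in span
    ]
    if not selected:
        raise ValueError(f"span {span.domain_name} {span.start}-{span.end}: no residues")
    total = len(selected)
    h = 100.0 * selected.count("H") / total
    s = 100.0 * selected.count("S") / total
    return SSEComposition(
        helix_pct=h,
        sheet_pct=s,
        loop_pct=100.0 - h - s,
        domain_name=span.domain_name,
        structure_id=structure_id,
    )


def sse_pearson(h_values, l_values) -> float:
    """Pearson correlation between helix and loop content percentages."""
    h = np.asarray(h_values, dtype=float)
    l = np.asarray(l_values, dtype=float)
    if h.shape != l.shape or h.size < 3:
        raise ValueError("need equal-length vectors of at least 3 values")
    if np.std(h) == 0 or np.std(l) == 0:
        raise ValueError("Pearson correlation undefined for zero-variance input")
    return float(np.corrcoef(h, l)[0, 1])
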