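"""Per-residue validation-track comparison (RSCC vs pLDDT vs B-factor).

Experimental real-space correlation coefficients, crystallographic
B-factors and the prediction-confidence pLDDT (already scaled to [0,1])
are aligned on a common residue numbering (the predicted model's
sequence numbering, via constant per-chain offsets) so they can be
correlated and screened for discrepant regions — residues where the
experimental density is well resolved yet the prediction is unconfident,
or vice versa.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import PerResidueTrack

__all__ = [
    "PairedTracks",
    "align_tracks",
    "track_correlation",
    "flag_discrepancies",
]


@dataclass
class PairedTracks:
    residues: list[int]  # common numbering, sorted
    series: dict[str, np.ndarray]  # metric name -> values aligned on residues

    def __post_init__(self) -> None:
        n = len(self.residues)
        for name, vals in self.series.items():
            if len(vals) != n:
                raise ValueError(f"series {name!r} length {len(vals)} != {n} residues")


def align_tracks(
    tracks: Sequence[PerResidueTrack],
    numbering_offsets: Sequence[int] | None = None,
) -> PairedTracks:
    """Intersect tracks on common residue numbers after applying offsets.

    ``numbering_offsets[i]`` is added to every residue key of track *i* to
    bring author numbering onto the common (predicted-model) numbering.
    """
    if len(tracks) < 2:
        raise ValueError("need at least two tracks")
    if numbering_offsets is None:
        numbering_offsets = [0] * len(tracks)
    if len(numbering_offsets) != len(tracks):
        raise ValueError("one offset per track required")
    shifted = [
        {seq + off: val for seq, val in tr.values.items()}
        for tr, off in zip(tracks, numbering_offsets)
    ]
    common = set(shifted[0])
    for s in shifted[1:]:
        common &= set(s)
    if not common:
        raise ValueError("tracks share no residues after offset alignment")
    residues = sorted(common)
    series = {
        tr.metric_name: np.array([s[r] for r in residues])
        for tr, s in zip(tracks, shifted)
    }
    return PairedTracks(residues=residues, series=series)


def track_correlation(paired: PairedTracks, a: str, b: str) -> float:
    """Pearson correlation between two aligned metric series."""
    for name in (a, b):
        if name not in paired.series:
            raise KeyError(f"metric {name!r} not in paired tracks")
    x, y = paired.series[a], paired.series[b]
    if len(x) < 3:
        raise ValueError("need at least 3 common residues")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance series")
    return float(np.corrcoef(x, y)[0, 1])


def flag_discrepancies(
    paired: PairedTracks,
    high_thr: float = 0.9,
    low_thr: float = 0.7,
) -> list[tuple[int, str]]:
    """Residues where RSCC and pLDDT disagree.

    Kind ``A``: well-resolved experimentally (RSCC > high_thr) but low
    prediction confidence (pLDDT < low_thr). Kind ``B``: the reverse. The
    two sets are disjoint whenever high_thr > low_thr.
    """
    for name in ("RSCC", "pLDDT"):
        if name not in paired.series:
            raise KeyError(f"paired tracks lack {name!r}")
    rscc = paired.series["RSCC"]
    plddt = paired.series["pLDDT"]
    flags: list[tuple[int, str]] = []
    for res, r, p in zip(paired.residues, rscc, plddt):
        if r > high_thr and p < low_thr:
            flags.append((res, "A"))
        elif p > high_thr and r < low_thr:
            flags.append((res, "B"))
    return flags
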