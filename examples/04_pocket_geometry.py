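"""Ligand-binding-pocket volumetrics on an analytic spherical cavity.

A closed atom shell encloses a cavity of known volume; the voxelized
rolling-probe construction recovers its solvent-excluded volume and area,
and the shape metrics summarize how sphere-like the pocket is.
"""

import math

from nrgeom import (
    effective_radius,
    make_spherical_cavity,
    pocket_deviation,
    pocket_normalization,
    pocket_volume_area,
    sphericity,
)

model = make_spherical_cavity(5.0)
protein = [a for ch in model.chains for r in ch.residues for a in r.atoms]
ligand = model.hetero_groups[("A", "LIG", 1)]

volume, area = pocket_volume_area(protein, ligand, voxel=0.3)
analytic = 4 / 3 * math.pi * 5.0**3
print(f"pocket volume : {volume:.1f} Å³ (analytic {analytic:.1f})")
print(f"pocket area   : {area:.1f} Å² (analytic {4 * math.pi * 25:.1f})")
print(f"sphericity Ψ  : {sphericity(volume, area):.3f} (1.0 = perfect sphere)")
print(f"effective r   : {effective_radius(volume, area):.2f} Å (3V/A; sphere radius 5)")

# comparing an 'experimental' pocket against a smaller 'predicted' one
pred = make_spherical_cavity(4.6)
pred_atoms = [a for ch in pred.chains for r in ch.residues for a in r.atoms]
v_pred, _ = pocket_volume_area(pred_atoms, pred.hetero_groups[("A", "LIG", 1)], voxel=0.3)
print(f"experimental pocket is {pocket_normalization(volume, v_pred):.1f}% of the predicted one")
print(f"prediction deviates by {pocket_deviation(v_pred, volume):+.1f}% from experiment")
# Values above 100% mean the predicted pocket is too small — the systematic
# under-prediction this comparison is designed to expose.
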