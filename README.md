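# nrgeom

Quantitative comparison of experimentally determined and AI-predicted
multi-domain protein structures, built around the nuclear-receptor (NR)
use case: receptors such as GR, HNF4α, LXRβ, NURR1, PPARγ, RARβ and RXRα
consist of a DNA-binding domain (DBD) and a ligand-binding domain (LBD)
joined by a flexible hinge, and deep-learning structure predictors are
known to reproduce the individual domains far better than their relative
arrangement, the ligand-binding pocket, or functionally important
conformational heterogeneity. `nrgeom` turns that comparison into a
reproducible pipeline for structural biologists and method developers:
every stage is a plain Python function, and a synthetic-structure
generator with exact ground truth makes the whole pipeline testable
without downloading a single file.

## What it computes

For each experimental chain / predicted model pair (with configured
DBD/LBD residue spans):

- **Superposition & RMSD** — Kabsch least-squares fit with iterative
  outlier rejection; RMSD = √(1/N Σᵢ‖xᵢ−yᵢ‖²) computed independently for
  all-atom, backbone (N, Cα, C, O) and Cα-only selections, per domain,
  plus the expected hierarchy check (all-atom > backbone > Cα).
- **Secondary structure** — per-residue H/S/L states from Kabsch–Sander
  backbone hydrogen bonds (E < −0.5 kcal/mol; two consecutive i→i+4 turns
  = helix, bridge ladders = strand), domain-wise percentages, and the
  helix-vs-loop Pearson correlation.
- **Domain architecture** — ε = ‖COM(DBD) − COM(LBD)‖; θ = angle at the
  hinge point (midpoint of the last DBD Cα and first LBD Cα); DH = signed
  torsion COM(DBD)–Cα(L)–Cα(F)–COM(LBD); circular dispersion
  σ_θ = √(−2 ln R̄) and the conformational similarity cos(ΔDH); a
  homodimer-asymmetry report (compact vs extended monomers).
- **Pocket geometry** — solvent-excluded volume and area of the
  ligand-binding pocket from a voxelized rolling-probe (1.4 Å)
  construction seeded at the ligand; sphericity Ψ = π^⅓(6V)^⅔/A and
  effective radius r_eff = 3V/A; normalization of experimental pockets
  against the predicted one and percentage deviations.
- **Validation tracks** — per-residue RSCC (from wwPDB-style validation
  XML), crystallographic B-factors and pLDDT/100 aligned on common
  numbering; correlations and flags for residues where experiment and
  prediction disagree.
- **Backbone torsions** — φ/ψ with chain-break handling, circular RMSD /
  MAE on wrapped differences, 1-D Wasserstein distances, per-residue
  Pearson correlations, and Ramachandran favored/allowed/outlier tallies
  at the 98% / 99.8% contour levels.
- **Statistics layer** — CV = σ/μ·100, Cohen's d, paired t-tests,
  Bonferroni, Kruskal–Wallis, one-way ANOVA + Tukey HSD, OLS regression,
  and average-linkage hierarchical clustering of (r_eff, Ψ).

## Worked example

```python
from nrgeom import (ToySpec, make_two_domain_toy, chain_domain_geometry,
                    perturb_structure)

spec = ToySpec(target_epsilon=45.0, target_theta=110.0, target_dihedral=-75.0)
model, dbd, lbd = make_two_domain_toy(spec)          # exact ground truth
g = chain_domain_geometry(model.chains[0], dbd, lbd)
print(f"{g.epsilon:.3f} {g.theta:.3f} {g.dihedral:.3f}")
# 45.000 110.000 -75.000

noisy = perturb_structure(model.chains[0], sd=0.2, seed=1)
g = chain_domain_geometry(noisy, dbd, lbd)
print(f"{g.epsilon:.3f}")
# 45.002
```

The three printed numbers are the inter-domain distance (Å), hinge angle
(°) and hinge torsion (°) measured from the generated structure — equal
to the prescription because the generator solves the placement exactly —
and the distance re-measured after 0.2 Å Gaussian noise, showing the
descriptor's robustness to coordinate error.

Run the narrative scripts under `examples/` (one per capability), or the
whole pipeline from a shell:

```sh
nrgeom fixtures --out demo --seed 3     # synthetic structures + config
nrgeom run --config demo/config.yaml    # writes rmsd/sse/geometry/pockets/
                                        # tracks/torsions/summary CSVs
```

With real inputs, point the YAML config at PDB/mmCIF files, AlphaFold
models, wwPDB validation reports, chain IDs and domain spans; the same
seven CSV tables are produced.

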