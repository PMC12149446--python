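# Methods

This note documents the models and procedures implemented in `nrgeom`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical choices that affect results.

## Superposition and the RMSD hierarchy

Structure pairs are superposed by the Kabsch algorithm (SVD of the
cross-covariance of centered coordinates, with the determinant correction
that forbids reflections). `refined_superpose` then iteratively removes
atom pairs whose post-fit distance exceeds a cutoff (default 2.0 Å) and
re-fits, up to 5 extra cycles or convergence, and errors out if fewer
than three pairs survive. This emulates the refinement cycles of
sequence-independent structural aligners; because the compared chains
here are the same protein, residues are paired directly by author
number within the configured span rather than by dynamic-programming
alignment, and atoms missing from either structure (unresolved density)
are simply skipped. Absolute RMSDs can therefore differ slightly from
aligner-based values, mainly through the rejection convention.

`rmsd_triple` fits the all-atom, backbone (N, Cα, C, O) and Cα-only
selections independently; `hierarchy_check` tests the strict ordering
all-atom > backbone > Cα, strict because the analysis treats ties and
inversions alike as exceptions worth flagging.

## Secondary structure

Assignment is a three-state reduction of the Kabsch–Sander method. The
amide hydrogen is placed 1.0 Å from N along the previous residue's C→O
direction (prolines and chain starts donate no bond), and the
electrostatic energy E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)
kcal/mol below −0.5 defines a hydrogen bond. Two consecutive i→i+4 turns
mark an α-helix; parallel/antiparallel bridge patterns mark strand, with
isolated bridges counted as strand; 3₁₀ and π helices are deliberately
*not* collapsed into H and fall into loop, matching a coarse H/S/L split.
This reproduces viewer-style assignments to within a few percent of
composition, which is the scale of the differences the comparison is
meant to resolve; the residual assignment differences are a known source
of small composition shifts.

## Domain-architecture descriptors

- ε: Euclidean distance between the domain centers of mass. COMs are
  atomic-mass weighted over all non-hydrogen atoms of the configured
  span (a geometric-centroid option exists; the choice shifts ε by
  fractions of an Å and is logged in the run manifest).
- θ: angle at the hinge reference point, defined as the unweighted
  midpoint of the last DBD Cα and the first LBD Cα. The midpoint rule
  standardizes the hinge across structures with unresolved hinge
  residues; if a boundary residue is missing, the nearest present
  residue inside the span is used.
- DH: signed torsion of COM(DBD)–Cα(last,DBD)–Cα(first,LBD)–COM(LBD)
  about the Cα–Cα axis, IUPAC sign convention (clockwise positive
  looking from the second to the third point), range (−180°, 180°].

All three are rigid-motion invariant (tested to 1e-9); mirroring negates
DH and preserves ε and θ. Angular spread uses circular statistics:
R̄ = |mean unit vector|, σ_θ = √(−2 ln R̄), with σ_θ reported as infinite
when R̄ = 0. Quartiles/IQR use linear interpolation (Type 7). The
homodimer-asymmetry threshold (|Δε| > 5 Å) is a configuration default,
not a derived constant.

## Pocket volumetrics

The ligand-binding pocket is measured with a voxelized rolling-probe
construction that replaces external cavity programs:

1. Grid the ligand's bounding box padded by the lining cutoff (default
   5 Å) at voxel h (default 0.4 Å; analytic validation uses 0.3/0.15 Å).
2. A voxel center is *probe-admissible* if it lies at least r_vdW + r_p
   from every atom center (Bondi radii; probe r_p = 1.4 Å).
3. Flood-fill admissible voxels from the ligand position; the connected
   component(s) reached are the pocket's probe space. Reaching the grid
   boundary means the pocket leaks into bulk solvent; a warning is
   issued and no capping is attempted (open pockets are method-sensitive
   and flagged as such).
4. The pocket is the probe-swept envelope of that component: volume by
   voxel counting, area by marching cubes on the signed distance field.

The discrete distance transform measures distances to voxel *centers*,
which biases the envelope outward by a fraction of a voxel. Each
admissible center is therefore credited with its exact analytic
clearance min_i(|x−c_i| − r_i − r_p), a radius around it guaranteed
admissible, and that clearance is subtracted from the transform — an
O(h²) residual instead of O(h). On analytic fixtures (isolated atom =
its vdW sphere; enclosed spherical cavities of radius 3–5 Å) volumes and
areas land within a few percent of closed forms and change by <2% under
voxel halving from 0.3 Å.

Sphericity Ψ = π^⅓(6V)^⅔/A and effective radius r_eff = 3V/A follow
directly; Ψ ≤ 1 with equality only for spheres (isoperimetric
inequality), asserted with a small voxelization tolerance. Because the
cavity construction differs from external-program pipelines, absolute
pocket volumes are comparable *within* this package but not directly
against volumes from other cavity software; normalized percentages are
the robust quantity.

## Validation tracks

pLDDT is read from the B-factor slot of predicted models and scaled by
1/100 once (values already ≤ 1 are rejected to prevent double scaling);
RSCC comes from wwPDB-style validation XML and residues without density
statistics are omitted, never zero-filled. Tracks align on the predicted
model's numbering via constant per-chain offsets from the configuration —
the sequences are identical, so no alignment is performed. Discrepancy
flags use two thresholds (defaults 0.9 / 0.7): kind A is RSCC > 0.9 with
pLDDT < 0.7 (experiment resolves what the predictor distrusts), kind B
the reverse. B-factors are exported raw, with min-max rescaling left to
downstream plotting.

## Torsions and Ramachandran classification

φ(i) = C(i−1)–N(i)–Cα(i)–C(i), ψ(i) = N(i)–Cα(i)–C(i)–N(i+1); both are
undefined at termini and across chain breaks (consecutive Cα–Cα distance
above 4.5 Å). Pairwise agreement uses the wrapped difference
Δ = ((a−b+180) mod 360) − 180: circular RMSD and MAE on Δ, plain Pearson
on the paired raw angles (a circular-correlation variant was considered;
plain Pearson is used because φ/ψ populations rarely straddle the wrap
for these proteins, and the per-residue pairing is the informative
reading), and the first-order Wasserstein distance between the marginal
angle samples on the linear scale — a deliberate, documented
simplification that slightly inflates distances for wrap-adjacent ψ
populations.

Ramachandran classes (general, glycine, proline, pre-proline,
isoleucine-valine; pre-proline applies to non-Gly/Pro residues preceding
proline) are scored against the constructed reference densities in
`rama_synthetic.py`: mixtures of wrapped Gaussian basins at the textbook
φ/ψ minima, with favored/allowed boundaries at the contour levels
enclosing 98% and 99.8% of each class's probability mass. This is a
synthetic stand-in for survey-derived tables: boundary *placement*
differs in detail from empirical tables, so absolute favored percentages
for real structures are approximate, while the three-way classification
semantics, the class routing, and all internal comparisons are exact and
self-consistent.

## Statistics

CV uses the sample SD (n−1). Cohen's d = |μ₁−μ₂|/√((σ₁²+σ₂²)/2) operates
on summary statistics so it can be evaluated directly on printed tables.
Kruskal–Wallis uses midranks with tie correction (identical pooled data
short-circuit to H = 0, p = 1). Tukey HSD comes from statsmodels;
hierarchical clustering is average-linkage on z-scored (r_eff, Ψ) pairs
— linkage and standardization are package choices where only the metric
(Euclidean) was fixed a priori. Bonferroni is min(1, p·m).

## Synthetic-data generator

The generator provides exact ground truth, not biological realism:

- **Ideal chains** are poly-alanine with Engh–Huber-style bond geometry
  built by natural-extension frame placement; backbone torsions are
  exact by construction (the inverse computation recovers them to
  1e-13). No side chains beyond Cβ, no packing, no energetics.
- **Two-domain toys** place two 30-residue helices so that (ε, θ, DH)
  hit prescribed targets exactly: a vectorized canonical-frame scan
  seeds a least-squares solve for the hinge-frame parameters (gap, two
  arm angles), accepted only below 1e-9 residual; geometrically
  impossible prescriptions (e.g. acute hinge angles with distant COMs,
  given the ~22 Å COM lever arms of 30-residue domains) raise an error
  naming the infeasibility.
- **Antiparallel sheets** apply the two-fold rotation about the
  inter-strand axis with a 5.4 Å separation and a small registration
  shift, chosen once so the cross-strand hydrogen-bond ladder satisfies
  the Kabsch–Sander criterion.
- **Spherical cavities** place shell atoms on a Fibonacci lattice at
  radius R + r_vdW (spheres internally tangent to the target cavity);
  shell density is checked against probe leakage and the construction
  refuses to build cavities the probe cannot enter.
- **Perturbations** add i.i.d. Gaussian noise per coordinate; expected
  unfitted RMSD is σ√3.
- **Correlated tracks** draw bivariate normals at the target
  correlation, mapped affinely into [0, 1].

Passing tests on these fixtures demonstrates correctness of the
*measurement* machinery — superposition, H-bond detection, volumetrics,
descriptors, statistics — under known truth. It does not certify
behavior on features the generator omits: side-chain packing, missing
residues and alternate conformations beyond the implemented policies,
irregular pocket topologies, or real validation-report quirks.

## Problem sizes and defaults

Default analyses run at desk scale: 30-residue toy domains, ~400-atom
cavity shells, 0.3/0.15 Å validation voxels, 1000-replicate null
simulations — sizes chosen so the full suite and the acceptance script
complete in seconds while keeping sampling error well inside the
asserted tolerances. All generator and pipeline randomness is
seed-controlled; identical configurations reproduce byte-identical CSVs.

## Known limitations

- Pocket volumes are internally consistent but not calibrated against
  external cavity programs; open pockets depend on the padding box.
- Ramachandran boundaries are constructed, not survey-derived; absolute
  favored/outlier rates on real structures will differ by a few percent
  from validation-server values.
- Secondary-structure reduction ignores 3₁₀/π helices by design.
- Residue pairing assumes identical sequences between the compared
  structures (true for prediction-vs-experiment comparisons of the same
  protein); no support for homologs.
- NMR ensembles: first model only. No network access in library code; a
  configuration simply points at files already on disk.
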