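"""Synthetic structures, cavities and tracks with known ground truth.

Every pipeline stage is testable without downloading real structures:
ideal helices and strand pairs with exact internal (φ, ψ, ω) geometry
(built by sequential natural-extension frame construction from standard
bond lengths and angles), two-domain toys placed so the inter-domain
descriptors (ε, θ, DH) equal prescribed targets, closed atom shells
enclosing spherical cavities of known volume, Gaussian coordinate
perturbations of known magnitude, and paired per-residue confidence
tracks of known correlation. All randomness is seed-controlled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .geometry import center_of_mass, domain_dihedral
from .io import (
    AtomRecord,
    ChainModel,
    DomainSpan,
    PerResidueTrack,
    ResidueRecord,
    StructureModel,
    select_domain,
)

__all__ = [
    "ToySpec",
    "place_atom",
    "make_ideal_helix",
    "make_antiparallel_sheet",
    "make_two_domain_toy",
    "perturb_structure",
    "make_spherical_cavity",
    "make_correlated_tracks",
]

# standard backbone geometry (Engh–Huber-style values), Å and degrees
B_N_CA, B_CA_C, B_C_N, B_C_O, B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.521
A_N_CA_C, A_CA_C_N, A_C_N_CA, A_CA_C_O, A_N_CA_CB = 111.2, 116.2, 121.7, 120.8, 110.4
T_C_N_CA_CB = 122.6  # proper L-amino-acid branch torsion C-N-CA-CB
OMEGA_TRANS = 180.0


@dataclass(frozen=True)
class ToySpec:
    """Prescription for a two-domain toy structure."""

    n_residues: int = 30
    target_epsilon: float = 50.0  # Å
    target_theta: float = 120.0  # degrees, (0, 180)
    target_dihedral: float = -90.0  # degrees, (-180, 180]
    perturbation_sd: float = 0.0  # Å per coordinate
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 5:
            raise ValueError("need at least 5 residues per domain")
        if not 0.0 < self.target_theta < 180.0:
            raise ValueError(f"theta {self.target_theta} outside (0, 180)")
        if not -180.0 < self.target_dihedral <= 180.0:
            raise ValueError(f"dihedral {self.target_dihedral} outside (-180, 180]")
        if self.target_epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.perturbation_sd < 0:
            raise ValueError("perturbation sd must be non-negative")


def place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Position d with |d−c| = bond, ∠(b,c,d) = angle, torsion(a,b,c,d) = torsion.

    Natural-extension reference frame construction; angles in degrees,
    torsion in the IUPAC sign convention.
    """
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    theta, tau = math.radians(angle), math.radians(torsion)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-math.cos(theta), math.sin(theta) * math.cos(tau), -math.sin(theta) * math.sin(tau)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _build_backbone(n: int, phi: float, psi: float) -> list[dict[str, np.ndarray]]:
    """Backbone (N, CA, C, O, CB) coordinates of an n-residue homopolymer."""
    res: list[dict[str, np.ndarray]] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([B_N_CA, 0.0, 0.0])
    ang = math.radians(A_N_CA_C)
    c0 = ca0 + B_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    res.append({"N": n0, "CA": ca0, "C": c0})
    for _ in range(1, n):
        prev = res[-1]
        n_i = place_atom(prev["N"], prev["CA"], prev["C"], B_C_N, A_CA_C_N, psi)
        ca_i = place_atom(prev["CA"], prev["C"], n_i, B_N_CA, A_C_N_CA, OMEGA_TRANS)
        c_i = place_atom(prev["C"], n_i, ca_i, B_CA_C, A_N_CA_C, phi)
        res.append({"N": n_i, "CA": ca_i, "C": c_i})
    for i, r in enumerate(res):
        # carbonyl O anti to the next amide N: torsion N-CA-C-O = psi + 180
        r["O"] = place_atom(r["N"], r["CA"], r["C"], B_C_O, A_CA_C_O, psi + 180.0)
        r["CB"] = place_atom(r["C"], r["N"], r["CA"], B_CA_CB, A_N_CA_CB, T_C_N_CA_CB)
    return res


def _chain_from_backbone(
    frames: list[dict[str, np.ndarray]],
    chain_id: str = "A",
    start_seq: int = 1,
    res_name: str = "ALA",
    b_value: float = 0.0,
    source_kind: str = "experimental",
) -> ChainModel:
    elements = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}
    residues = [
        ResidueRecord(
            auth_seq=start_seq + i,
            res_name=res_name,
            atoms=[
                AtomRecord(name=k, element=elements[k], coords=v.copy(), b_value=b_value)
                for k, v in frame.items()
            ],
        )
        for i, frame in enumerate(frames)
    ]
    return ChainModel(chain_id, residues, source_kind=source_kind)


def make_ideal_helix(
    n: int,
    phi: float = -57.0,
    psi: float = -47.0,
    chain_id: str = "A",
    start_seq: int = 1,
    b_value: float = 0.0,
    source_kind: str = "experimental",
) -> ChainModel:
    """Poly-alanine chain with exact (φ, ψ, ω = 180°) internal geometry.

    The defaults give a canonical α-helix; other (φ, ψ) values build
    extended or polyproline-like conformations with the same machinery.
    """
    if n < 5:
        raise ValueError(f"need n ≥ 5 residues, got {n}")
    frames = _build_backbone(n, phi, psi)
    return _chain_from_backbone(
        frames, chain_id=chain_id, start_seq=start_seq, b_value=b_value,
        source_kind=source_kind,
    )


def make_antiparallel_sheet(
    n_per_strand: int = 8,
    chain_id: str = "A",
    start_seq: int = 1,
) -> ChainModel:
    """Two-stranded idealized antiparallel β-sheet in one chain.

    Strand geometry uses the canonical antiparallel (φ, ψ) = (−139°, 135°);
    the partner strand is the first strand rotated 180° about the strand
    axis and offset so the cross-strand N-H···O=C ladder satisfies the
    Kabsch–Sander hydrogen-bond criterion. The strands are separated in
    sequence by a numbering gap (no connecting residues), so the pair
    registers as two chain segments.
    """
    if n_per_strand < 4:
        raise ValueError("need at least 4 residues per strand")
    frames = _build_backbone(n_per_strand, -139.0, 135.0)
    ca_first, ca_last = frames[0]["CA"], frames[-1]["CA"]
    axis = ca_last - ca_first
    axis = axis / np.linalg.norm(axis)
    centroid = np.mean([f["CA"] for f in frames], axis=0)
    # sheet frame: strand axis, inter-strand direction, sheet normal
    perp = np.array([0.0, 0.0, 1.0])
    perp = perp - (perp @ axis) * axis
    perp = perp / np.linalg.norm(perp)
    normal = np.cross(axis, perp)

    # antiparallel dyad: 180° rotation about the inter-strand direction,
    # then a 5.4 Å strand separation with a small registration shift —
    # geometry chosen so the cross-strand N-H···O=C ladder closes
    K = np.array(
        [[0, -perp[2], perp[1]], [perp[2], 0, -perp[0]], [-perp[1], perp[0], 0]]
    )
    R = np.eye(3) + 2.0 * (K @ K)  # Rodrigues half-turn
    offset = 5.4 * perp + 0.5 * axis - 0.5 * normal
    partner = [
        {k: (R @ (v - centroid)) + centroid + offset for k, v in f.items()}
        for f in frames
    ]
    all_frames = frames + partner
    chain = _chain_from_backbone(all_frames, chain_id=chain_id, start_seq=start_seq)
    # renumber the partner strand after a sequence gap
    gap = 10
    for i, res in enumerate(chain.residues[n_per_strand:]):
        res.auth_seq = start_seq + n_per_strand + gap + i
    return ChainModel(chain_id, chain.residues, source_kind=chain.source_kind)


def _rotation_between(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Proper rotation mapping unit vector u onto unit vector v."""
    c = float(u @ v)
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        # pick any perpendicular axis for the half-turn
        perp = np.array([1.0, 0.0, 0.0])
        if abs(u[0]) > 0.9:
            perp = np.array([0.0, 1.0, 0.0])
        axis = np.cross(u, perp)
        axis /= np.linalg.norm(axis)
        K = np.array(
            [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
        )
        return np.eye(3) + 2.0 * (K @ K)
    axis = np.cross(u, v)
    s = np.linalg.norm(axis)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + K + K @ K * ((1 - c) / (s * s))


def _toy_seed(
    d1: float, arm: float, eps_t: float, theta_t: float, dh_t: float
) -> np.ndarray:
    """Coarse grid seed for the hinge-frame placement solve.

    Works in a canonical frame (hinge axis on x, hinge midpoint at the
    origin) where the four descriptor points have closed forms, scanning
    (gap, α, β) vectorized and returning the best triple.
    """
    dh = math.radians(dh_t)
    gaps = np.arange(2.0, 120.0, 1.5)
    als = np.radians(np.arange(2.0, 179.0, 1.5))
    bes = np.radians(np.arange(2.0, 179.0, 1.5))
    g = gaps[:, None, None]
    al = als[None, :, None]
    be = bes[None, None, :]
    Dx, Dy = -g / 2 + d1 * np.cos(al), d1 * np.sin(al) + 0.0 * be
    cx = g / 2 - arm * np.cos(be)
    cy = arm * np.sin(be) * math.cos(dh)
    cz = arm * np.sin(be) * math.sin(dh)
    Dn = np.sqrt(Dx**2 + Dy**2)
    cn = np.sqrt(cx**2 + cy**2 + cz**2)
    ct = np.clip((Dx * cx + Dy * cy) / (Dn * cn), -1.0, 1.0)
    theta = np.degrees(np.arccos(ct))
    eps = np.sqrt((cx - Dx) ** 2 + (cy - Dy) ** 2 + cz**2)
    err = np.abs(theta - theta_t) + np.abs(eps - eps_t)
    i, j, k = np.unravel_index(np.argmin(err), err.shape)
    return np.array([gaps[i], math.degrees(als[j]), math.degrees(bes[k])])


def make_two_domain_toy(
    spec: ToySpec,
) -> tuple[StructureModel, DomainSpan, DomainSpan]:
    """Two helical domains placed so (ε, θ, DH) equal the spec targets.

    The first ("DBD") helix is built in place; the second ("LBD") helix is
    rigidly positioned by solving for the hinge-frame angles that put its
    center of mass at distance ε from the first domain's, at hinge angle θ
    and hinge torsion DH. The placement is exact to solver tolerance
    (residuals < 1e-9) before any perturbation is applied.
    """
    n = spec.n_residues
    dbd = make_ideal_helix(n, chain_id="A", start_seq=1)
    lbd_local = make_ideal_helix(n, chain_id="A", start_seq=n + 11)
    dbd_span = DomainSpan("DBD", 1, n)
    lbd_span = DomainSpan("LBD", n + 11, n + 10 + n)

    D = center_of_mass(select_domain(dbd, dbd_span, "all"))
    aL = dbd.residues[-1].atom("CA").coords
    cL_local = center_of_mass(select_domain(lbd_local, lbd_span, "all"))
    aF_local = lbd_local.residues[0].atom("CA").coords
    arm = float(np.linalg.norm(cL_local - aF_local))  # |LBD COM − first Cα|
    d1 = float(np.linalg.norm(D - aL))

    def points(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        gap, alpha, beta = x
        q = place_atom(D + np.array([0.0, 0.0, 5.0]), D, aL, gap, alpha, 0.0)
        c = place_atom(D, aL, q, arm, beta, spec.target_dihedral)
        return q, c

    def residuals(x: np.ndarray) -> np.ndarray:
        q, c = points(x)
        mid = (aL + q) / 2.0
        v1, v2 = D - mid, c - mid
        theta = math.degrees(
            math.acos(
                np.clip(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)), -1, 1)
            )
        )
        eps = float(np.linalg.norm(c - D))
        return np.array([theta - spec.target_theta, eps - spec.target_epsilon])

    x0 = _toy_seed(d1, arm, spec.target_epsilon, spec.target_theta, spec.target_dihedral)
    sol = least_squares(
        residuals, x0=x0,
        bounds=([2.0, 1.0, 1.0], [400.0, 179.0, 179.0]),
        xtol=1e-15, ftol=1e-15, gtol=1e-15,
    )
    if np.max(np.abs(sol.fun)) > 1e-9:
        raise ValueError(
            f"infeasible targets (ε={spec.target_epsilon}, θ={spec.target_theta}, "
            f"DH={spec.target_dihedral}) for domains of {n} residues "
            f"(lever arms {d1:.1f} / {arm:.1f} Å)"
        )
    q, c = points(sol.x)

    u = (cL_local - aF_local) / arm
    v = (c - q) / float(np.linalg.norm(c - q))
    R = _rotation_between(u, v)
    lbd_residues = []
    for res in lbd_local.residues:
        atoms = [
            AtomRecord(
                name=a.name, element=a.element,
                coords=R @ (a.coords - aF_local) + q,
                b_value=a.b_value, occupancy=a.occupancy,
            )
            for a in res.atoms
        ]
        lbd_residues.append(ResidueRecord(res.auth_seq, res.res_name, atoms))

    chain = ChainModel("A", dbd.residues + lbd_residues)
    if spec.perturbation_sd > 0:
        chain = perturb_structure(chain, spec.perturbation_sd, spec.seed)
    model = StructureModel("toy", [chain])
    return model, dbd_span, lbd_span


def perturb_structure(chain: ChainModel, sd: float, seed: int) -> ChainModel:
    """Add i.i.d. Gaussian displacement (sd per coordinate, Å) to every atom."""
    if sd < 0:
        raise ValueError("sd must be non-negative")
    rng = np.random.default_rng(seed)
    residues = []
    for res in chain.residues:
        atoms = [
            AtomRecord(
                name=a.name, element=a.element,
                coords=a.coords + rng.normal(0.0, sd, size=3) if sd > 0 else a.coords.copy(),
                b_value=a.b_value, occupancy=a.occupancy, altloc=a.altloc,
            )
            for a in res.atoms
        ]
        residues.append(ResidueRecord(res.auth_seq, res.res_name, atoms, icode=res.icode))
    return ChainModel(chain.chain_id, residues, source_kind=chain.source_kind)


def make_spherical_cavity(
    radius: float,
    shell_atom_count: int | None = None,
    probe: float = 1.4,
    element: str = "C",
    vdw_radius: float = 1.7,
) -> StructureModel:
    """Closed shell of atoms enclosing an empty spherical cavity.

    Atom centers sit on a sphere of radius ``radius + vdw_radius`` (their
    van der Waals spheres are internally tangent to the cavity sphere), on
    a deterministic Fibonacci lattice dense enough that the probe cannot
    escape between neighbors. A central pseudo-ligand atom is stored as
    hetero group ``("A", "LIG", 1)`` to seed pocket detection. The
    enclosed probe-accessible cavity has analytic volume 4/3·π·radius³.
    """
    if radius <= probe:
        raise ValueError(f"radius {radius} ≤ probe {probe}: probe cannot enter the cavity")
    shell_r = radius + vdw_radius
    if shell_atom_count is None:
        shell_atom_count = int(math.ceil(4.0 * math.pi * shell_r**2 / 1.5))
    # Fibonacci sphere lattice
    k = np.arange(shell_atom_count)
    golden = math.pi * (3.0 - math.sqrt(5.0))
    z = 1.0 - 2.0 * (k + 0.5) / shell_atom_count
    r_xy = np.sqrt(1.0 - z**2)
    theta = golden * k
    pts = shell_r * np.stack([r_xy * np.cos(theta), r_xy * np.sin(theta), z], axis=1)

    # leak check: max gap on the shell sphere must keep the probe out
    m = 4096
    km = np.arange(m)
    zm = 1.0 - 2.0 * (km + 0.5) / m
    rm = np.sqrt(1.0 - zm**2)
    tm = golden * km + 0.7  # offset so probes don't coincide with atoms
    test = shell_r * np.stack([rm * np.cos(tm), rm * np.sin(tm), zm], axis=1)
    from scipy.spatial import cKDTree

    gaps = cKDTree(pts).query(test)[0]
    if gaps.max() >= vdw_radius + probe:
        raise ValueError(
            f"{shell_atom_count} shell atoms leave gaps of {gaps.max():.2f} Å: "
            "the probe can leak out of the cavity"
        )

    # pseudo-residues (GLY/CA) so the shell round-trips through PDB as polymer
    residues = [
        ResidueRecord(
            auth_seq=i + 1,
            res_name="GLY",
            atoms=[AtomRecord(name="CA", element=element, coords=p)],
        )
        for i, p in enumerate(pts)
    ]
    chain = ChainModel("A", residues)
    seed_atom = AtomRecord(name="C1", element=element, coords=np.zeros(3))
    return StructureModel("cavity", [chain], {("A", "LIG", 1): [seed_atom]})


def make_correlated_tracks(
    n: int, target_r: float, seed: int
) -> tuple[PerResidueTrack, PerResidueTrack]:
    """Paired per-residue tracks with population correlation ``target_r``.

    Bivariate normal draws mapped affinely into [0,1] (center 0.5, scale
    0.12, clipped) keyed by residues 1..n. Pearson correlation is affine
    invariant, so the sample correlation estimates ``target_r``.
    """
    if not -1.0 <= target_r <= 1.0:
        raise ValueError("target correlation outside [-1, 1]")
    rng = np.random.default_rng(seed)
    z1 = rng.standard_normal(n)
    z2 = target_r * z1 + math.sqrt(max(0.0, 1.0 - target_r**2)) * rng.standard_normal(n)
    a = np.clip(0.5 + 0.12 * z1, 0.0, 1.0)
    b = np.clip(0.5 + 0.12 * z2, 0.0, 1.0)
    keys = range(1, n + 1)
    return (
        PerResidueTrack("RSCC", dict(zip(keys, a))),
        PerResidueTrack("pLDDT", dict(zip(keys, b))),
    )
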