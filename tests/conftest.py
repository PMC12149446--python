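import numpy as np
import pytest

from nrgeom.synthetic import ToySpec, make_ideal_helix, make_spherical_cavity, make_two_domain_toy


@pytest.fixture(scope="session")
def helix20():
    return make_ideal_helix(20)


@pytest.fixture(scope="session")
def toy_default():
    """Unperturbed two-domain toy with (ε, θ, DH) = (50, 120, −90)."""
    return make_two_domain_toy(
        ToySpec(target_epsilon=50.0, target_theta=120.0, target_dihedral=-90.0)
    )


@pytest.fixture(scope="session")
def cavity5():
    return make_spherical_cavity(5.0)


def structure_atoms(model):
    return [a for ch in model.chains for r in ch.residues for a in r.atoms]


def horn_rmsd(mobile: np.ndarray, target: np.ndarray) -> float:
    """Quaternion (Horn) closed-form optimal-superposition RMSD.

    Independent oracle for the SVD-based Kabsch fit: the optimal rotation
    corresponds to the largest eigenvalue λ of the 4×4 key matrix, and
    rmsd² = (Σ|p|² + Σ|q|² − 2λ)/n on centered coordinates.
    """
    p = mobile - mobile.mean(axis=0)
    q = target - target.mean(axis=0)
    s = p.T @ q
    sxx, sxy, sxz = s[0]
    syx, syy, syz = s[1]
    szx, szy, szz = s[2]
    n4 = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam = np.linalg.eigvalsh(n4)[-1]
    msd = (np.sum(p**2) + np.sum(q**2) - 2.0 * lam) / len(p)
    return float(np.sqrt(max(msd, 0.0)))
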