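"""Self-contained demo/fixture set: synthetic structure pairs on disk.

Writes a small directory that exercises every pipeline stage without any
real data: a two-domain toy as the "experimental" structure, a perturbed
copy with pLDDT-like B-values as the "predicted" model, a matching
synthetic validation report with per-residue RSCC, spherical-cavity
shells for the pocket stage, and a ready-to-run YAML config.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .io import AtomRecord, StructureModel, write_pdb
from .synthetic import ToySpec, make_spherical_cavity, make_two_domain_toy, perturb_structure

__all__ = ["write_demo_set"]


def _write_validation_xml(path: Path, chain_id: str, rscc: dict[int, float]) -> None:
    lines = ['<?xml version="1.0" encoding="UTF-8"?>', "<wwPDB_validation>", "<Entry>"]
    for seq in sorted(rscc):
        lines.append(
            f'<ModelledSubgroup chain="{chain_id}" resnum="{seq}" '
            f'resname="ALA" rscc="{rscc[seq]:.3f}"/>'
        )
    lines += ["</Entry>", "</wwPDB_validation>"]
    path.write_text("\n".join(lines) + "\n")


def write_demo_set(out_dir: str | Path, seed: int = 0) -> Path:
    """Write the synthetic demo set; returns the config YAML path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    spec = ToySpec(
        target_epsilon=45.0, target_theta=110.0, target_dihedral=-75.0, seed=seed
    )
    exp_model, dbd, lbd = make_two_domain_toy(spec)
    exp_chain = exp_model.chains[0]
    for res in exp_chain.residues:  # crystallographic-looking B-factors
        b = float(np.clip(rng.normal(35.0, 10.0), 5.0, 95.0))
        for a in res.atoms:
            a.b_value = b
    write_pdb(exp_model, out / "toy_experimental.pdb")

    pred_chain = perturb_structure(exp_chain, sd=0.3, seed=seed + 1)
    pred_chain.source_kind = "predicted"
    for res in pred_chain.residues:  # pLDDT-like confidence in the B slot
        b = float(np.clip(rng.normal(88.0, 6.0), 40.0, 100.0))
        for a in res.atoms:
            a.b_value = b
    write_pdb(StructureModel("toy_pred", [pred_chain]), out / "toy_predicted.pdb")

    rscc = {
        r.auth_seq: float(np.clip(rng.normal(0.92, 0.05), -0.2, 1.0))
        for r in exp_chain.residues
    }
    _write_validation_xml(out / "toy_validation.xml", exp_chain.chain_id, rscc)

    cavity_exp = make_spherical_cavity(5.0)
    write_pdb(cavity_exp, out / "cavity_experimental.pdb")
    cavity_pred = make_spherical_cavity(4.6)
    cavity_pred.identifier = "cavity_pred"
    write_pdb(cavity_pred, out / "cavity_predicted.pdb")

    config = {
        "output_dir": str(out / "results"),
        "options": {"voxel": 0.4},
        "units": [
            {
                "name": "TOY_A",
                "experimental_file": "toy_experimental.pdb",
                "experimental_chain": "A",
                "predicted_file": "toy_predicted.pdb",
                "predicted_chain": "A",
                "dbd_span": [dbd.start, dbd.end],
                "lbd_span": [lbd.start, lbd.end],
                "validation_report": "toy_validation.xml",
                "stages": ["rmsd", "sse", "geometry", "tracks", "torsions"],
            },
            {
                "name": "CAVITY",
                "experimental_file": "cavity_experimental.pdb",
                "experimental_chain": "A",
                "predicted_file": "cavity_predicted.pdb",
                "predicted_chain": "A",
                "ligand": {"chain": "A", "res_name": "LIG", "auth_seq": 1},
                "stages": ["pockets"],
            },
        ],
    }
    cfg_path = out / "config.yaml"
    cfg_path.write_text(yaml.safe_dump(config, sort_keys=False))
    return cfg_path
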