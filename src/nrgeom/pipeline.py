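"""Pipeline orchestration: run every comparison stage over a configured
set of experimental/predicted structure pairs and emit report tables.

The configuration (YAML or dict) lists comparison units — an experimental
file+chain, its predicted counterpart, the DBD/LBD residue spans, and
optionally a bound ligand, a validation report with per-residue RSCC, and
a numbering offset. ``run_pipeline`` executes the requested stages in
order (rmsd, sse, geometry, pockets, tracks, torsions), writes one CSV
per stage plus a cross-unit summary and a JSON run manifest echoing every
parameter, and keeps partial outputs when a unit fails a stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import pandas as pd
import yaml

from . import __version__
from .geometry import chain_domain_geometry
from .io import (
    DomainSpan,
    load_bfactor_track,
    load_plddt_track,
    read_structure,
    read_validation_rscc,
)
from .pocket import (
    PocketNotFoundError,
    merged_ligand_reference,
    pocket_deviation,
    pocket_metrics,
    pocket_normalization,
    pocket_volume_area,
)
from .sse import assign_sse, sse_composition
from .stats import StatsSummary, summarize
from .superpose import hierarchy_check, rmsd_triple
from .torsions import backbone_torsions, torsion_comparison
from .tracks import align_tracks, flag_discrepancies, track_correlation

ALL_STAGES = ("rmsd", "sse", "geometry", "pockets", "tracks", "torsions")

DEFAULT_OPTIONS = {
    "alpha": 0.05,
    "probe": 1.4,
    "voxel": 0.4,
    "cutoff": 5.0,
    "reject_cutoff": 2.0,
    "max_cycles": 5,
    "high_thr": 0.9,
    "low_thr": 0.7,
    "asymmetry_threshold": 5.0,
}


@dataclass
class ComparisonUnit:
    name: str
    experimental_file: str
    experimental_chain: str
    predicted_file: str
    predicted_chain: str
    dbd_span: tuple[int, int] | None = None
    lbd_span: tuple[int, int] | None = None
    numbering_offset: int = 0
    ligand: dict | None = None  # {chain, res_name, auth_seq}
    validation_report: str | None = None
    stages: list[str] | None = None  # None = all

    def spans(self) -> dict[str, DomainSpan]:
        out = {}
        if self.dbd_span:
            out["DBD"] = DomainSpan("DBD", *self.dbd_span)
        if self.lbd_span:
            out["LBD"] = DomainSpan("LBD", *self.lbd_span)
        return out


@dataclass
class RunConfig:
    units: list[ComparisonUnit]
    output_dir: str = "nrgeom_out"
    options: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        merged = dict(DEFAULT_OPTIONS)
        merged.update(self.options)
        self.options = merged

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw, base_dir=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict, base_dir: Path | None = None) -> "RunConfig":
        units = []
        for u in raw.get("units", []):
            u = dict(u)
            if base_dir is not None:
                for key in ("experimental_file", "predicted_file", "validation_report"):
                    if u.get(key):
                        p = Path(u[key])
                        u[key] = str(p if p.is_absolute() else base_dir / p)
            for key in ("dbd_span", "lbd_span"):
                if u.get(key) is not None:
                    u[key] = tuple(int(v) for v in u[key])
            units.append(ComparisonUnit(**u))
        return cls(
            units=units,
            output_dir=raw.get("output_dir", "nrgeom_out"),
            options=raw.get("options", {}),
        )


def validate_config(config: RunConfig) -> list[str]:
    """Return a list of problems; empty means the config is runnable."""
    problems: list[str] = []
    if not config.units:
        problems.append("config: no comparison units")
    names = [u.name for u in config.units]
    if len(names) != len(set(names)):
        problems.append("config: duplicate unit names")
    for key in ("probe", "voxel", "cutoff", "reject_cutoff"):
        if config.options.get(key, 1) <= 0:
            problems.append(f"options.{key}: must be positive")
    if config.options["high_thr"] <= config.options["low_thr"]:
        problems.append("options: high_thr must exceed low_thr")
    for u in config.units:
        for key in ("experimental_file", "predicted_file"):
            path = getattr(u, key)
            if not Path(path).exists():
                problems.append(f"{u.name}.{key}: missing file {path}")
        if u.validation_report and not Path(u.validation_report).exists():
            problems.append(f"{u.name}.validation_report: missing file {u.validation_report}")
        for key in ("dbd_span", "lbd_span"):
            span = getattr(u, key)
            if span is not None and span[0] > span[1]:
                problems.append(f"{u.name}.{key}: start {span[0]} > end {span[1]}")
        if u.dbd_span and u.lbd_span:
            lo = max(u.dbd_span[0], u.lbd_span[0])
            hi = min(u.dbd_span[1], u.lbd_span[1])
            if lo <= hi:
                problems.append(f"{u.name}: DBD and LBD spans overlap ({lo}-{hi})")
        if u.stages:
            unknown = set(u.stages) - set(ALL_STAGES)
            if unknown:
                problems.append(f"{u.name}.stages: unknown {sorted(unknown)}")
    return problems


def _unit_models(unit: ComparisonUnit):
    exp = read_structure(unit.experimental_file, source_kind="experimental")
    pred = read_structure(unit.predicted_file, source_kind="predicted")
    return exp.chain(unit.experimental_chain), pred.chain(unit.predicted_chain), exp, pred


def _ligand_atoms(model, ligand: dict):
    key = (ligand["chain"], ligand["res_name"], int(ligand["auth_seq"]))
    if key not in model.hetero_groups:
        raise KeyError(f"ligand {key} not found in {model.identifier}")
    return model.hetero_groups[key]


def run_pipeline(
    config: RunConfig,
    stages: Sequence[str] = ALL_STAGES,
    out_dir: str | Path | None = None,
) -> dict:
    """Execute the selected stages for every unit; write CSVs and a manifest.

    Returns a report dict with per-stage DataFrames and an ``errors`` list;
    partial outputs are retained when a unit fails a stage.
    """
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))

    out = Path(out_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    opt = config.options
    rows: dict[str, list[dict]] = {s: [] for s in ALL_STAGES}
    errors: list[dict] = []

    for unit in config.units:
        unit_stages = [s for s in stages if unit.stages is None or s in unit.stages]
        if not unit_stages:
            continue
        try:
            exp_chain, pred_chain, exp_model, pred_model = _unit_models(unit)
        except Exception as exc:  # unreadable unit: report and move on
            errors.append({"unit": unit.name, "stage": "load", "error": str(exc)})
            continue
        spans = unit.spans()

        for stage in unit_stages:
            try:
                if stage == "rmsd":
                    for dom, span in spans.items():
                        triple = rmsd_triple(
                            exp_chain, pred_chain, span,
                            max_cycles=opt["max_cycles"],
                            reject_cutoff=opt["reject_cutoff"],
                            structure_pair=(unit.name, pred_model.identifier),
                        )
                        rows["rmsd"].append(
                            {
                                "unit": unit.name, "domain": dom,
                                "all_atom": triple.all_atom,
                                "backbone": triple.backbone,
                                "c_alpha": triple.c_alpha,
                                "hierarchy_ok": hierarchy_check(triple),
                            }
                        )
                elif stage == "sse":
                    for kind, chain in (("experimental", exp_chain), ("predicted", pred_chain)):
                        labels = assign_sse(chain)
                        for dom, span in spans.items():
                            span_use = span
                            if kind == "predicted" and unit.numbering_offset:
                                span_use = DomainSpan(
                                    dom,
                                    span.start + unit.numbering_offset,
                                    span.end + unit.numbering_offset,
                                )
                            comp = sse_composition(labels, chain, span_use, unit.name)
                            rows["sse"].append(
                                {
                                    "unit": unit.name, "source": kind, "domain": dom,
                                    "helix_pct": comp.helix_pct,
                                    "sheet_pct": comp.sheet_pct,
                                    "loop_pct": comp.loop_pct,
                                }
                            )
                elif stage == "geometry":
                    if "DBD" not in spans or "LBD" not in spans:
                        raise ValueError("geometry stage needs both DBD and LBD spans")
                    for kind, chain in (("experimental", exp_chain), ("predicted", pred_chain)):
                        dbd, lbd = spans["DBD"], spans["LBD"]
                        if kind == "predicted" and unit.numbering_offset:
                            off = unit.numbering_offset
                            dbd = DomainSpan("DBD", dbd.start + off, dbd.end + off)
                            lbd = DomainSpan("LBD", lbd.start + off, lbd.end + off)
                        geo = chain_domain_geometry(chain, dbd, lbd, unit.name)
                        rows["geometry"].append(
                            {
                                "unit": unit.name, "source": kind,
                                "epsilon": geo.epsilon, "theta": geo.theta,
                                "dihedral": geo.dihedral,
                            }
                        )
                elif stage == "pockets":
                    if unit.ligand is None:
                        raise ValueError("pockets stage needs a ligand entry")
                    lig = _ligand_atoms(exp_model, unit.ligand)
                    exp_atoms = [
                        a for ch in exp_model.chains for r in ch.residues for a in r.atoms
                    ]
                    v_e, a_e = pocket_volume_area(
                        exp_atoms, lig, cutoff=opt["cutoff"],
                        probe=opt["probe"], voxel=opt["voxel"],
                    )
                    me = pocket_metrics(v_e, a_e, unit.name, "experimental")
                    row = {
                        "unit": unit.name,
                        "exp_volume": me.volume, "exp_area": me.area,
                        "exp_sphericity": me.sphericity,
                        "exp_effective_radius": me.effective_radius,
                    }
                    if "LBD" in spans:
                        # carry the ligand into the predicted frame via LBD fit
                        pred_lig = merged_ligand_reference(
                            pred_chain, [exp_chain], [lig], spans["LBD"]
                        )
                    else:
                        pred_lig = lig  # structures share one frame
                    pred_atoms = [
                        a for ch in pred_model.chains for r in ch.residues for a in r.atoms
                    ]
                    v_p, a_p = pocket_volume_area(
                        pred_atoms, pred_lig, cutoff=opt["cutoff"],
                        probe=opt["probe"], voxel=opt["voxel"],
                    )
                    mp = pocket_metrics(v_p, a_p, unit.name, "predicted")
                    row.update(
                        {
                            "pred_volume": mp.volume, "pred_area": mp.area,
                            "pred_sphericity": mp.sphericity,
                            "pred_effective_radius": mp.effective_radius,
                            "pct_of_predicted": pocket_normalization(v_e, v_p),
                            "volume_deviation_pct": pocket_deviation(v_p, v_e),
                        }
                    )
                    rows["pockets"].append(row)
                elif stage == "tracks":
                    if unit.validation_report is None:
                        raise ValueError("tracks stage needs a validation_report")
                    rscc = read_validation_rscc(
                        unit.validation_report, unit.experimental_chain
                    )
                    plddt = load_plddt_track(pred_model, unit.predicted_chain)
                    bfac = load_bfactor_track(exp_model, unit.experimental_chain)
                    paired = align_tracks(
                        [rscc, plddt, bfac],
                        [unit.numbering_offset, 0, unit.numbering_offset],
                    )
                    r_rp = track_correlation(paired, "RSCC", "pLDDT")
                    r_bp = track_correlation(paired, "b_factor", "pLDDT")
                    flags = flag_discrepancies(
                        paired, opt["high_thr"], opt["low_thr"]
                    )
                    for res, vals in zip(
                        paired.residues,
                        zip(*(paired.series[m] for m in paired.series)),
                    ):
                        rows["tracks"].append(
                            {
                                "unit": unit.name, "residue": res,
                                **dict(zip(paired.series, vals)),
                                "flag": next((k for r, k in flags if r == res), ""),
                                "r_rscc_plddt": r_rp, "r_bfactor_plddt": r_bp,
                            }
                        )
                elif stage == "torsions":
                    exp_tors = backbone_torsions(exp_chain)
                    pred_tors = backbone_torsions(pred_chain)
                    comp = torsion_comparison(
                        exp_tors, pred_tors, numbering_offset=unit.numbering_offset
                    )
                    rows["torsions"].append(
                        {
                            "unit": unit.name,
                            "rmsd_phi": comp.rmsd_phi, "rmsd_psi": comp.rmsd_psi,
                            "mae_phi": comp.mae_phi, "mae_psi": comp.mae_psi,
                            "wasserstein_phi": comp.wasserstein_phi,
                            "wasserstein_psi": comp.wasserstein_psi,
                            "pearson_phi": comp.pearson_phi,
                            "pearson_psi": comp.pearson_psi,
                            "n_paired": comp.n_paired,
                            "exp_favored_pct": comp.rama_a["favored_pct"],
                            "exp_outliers": comp.rama_a["outlier_count"],
                            "pred_favored_pct": comp.rama_b["favored_pct"],
                            "pred_outliers": comp.rama_b["outlier_count"],
                        }
                    )
            except Exception as exc:
                errors.append({"unit": unit.name, "stage": stage, "error": str(exc)})

    report: dict[str, Any] = {"errors": errors, "tables": {}}
    for stage in stages:
        if rows[stage]:
            df = pd.DataFrame(rows[stage])
            df.to_csv(out / f"{stage}.csv", index=False)
            report["tables"][stage] = df

    summary_rows = _summaries(report["tables"])
    if summary_rows:
        df = pd.DataFrame(summary_rows)
        df.to_csv(out / "summary.csv", index=False)
        report["tables"]["summary"] = df

    manifest = {
        "package_version": __version__,
        "stages": list(stages),
        "options": opt,
        "units": [u.name for u in config.units],
        "errors": errors,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    report["output_dir"] = str(out)
    return report


def _summaries(tables: dict[str, pd.DataFrame]) -> list[dict]:
    """Cross-unit means/SD/CV of the headline quantities per stage."""
    out: list[dict] = []

    def add(stage: str, quantity: str, values) -> None:
        values = [v for v in values if pd.notna(v)]
        if len(values) < 2:
            return
        try:
            s = summarize(values)
            cv = s.cv
        except ValueError:  # zero mean: CV undefined, keep the rest
            import numpy as np

            arr = np.asarray(values, dtype=float)
            q1, q3 = (float(q) for q in np.percentile(arr, [25, 75]))
            s = StatsSummary(
                mean=float(arr.mean()), sd=float(arr.std(ddof=1)), cv=float("nan"),
                n=arr.size, q1=q1, q3=q3, iqr=q3 - q1,
            )
            cv = None
        out.append(
            {
                "stage": stage, "quantity": quantity, "n": s.n,
                "mean": s.mean, "sd": s.sd, "cv_pct": cv,
                "q1": s.q1, "q3": s.q3, "iqr": s.iqr,
            }
        )

    if "rmsd" in tables:
        df = tables["rmsd"]
        for dom in df["domain"].unique():
            sub = df[df["domain"] == dom]
            for col in ("all_atom", "backbone", "c_alpha"):
                add("rmsd", f"{dom}_{col}", sub[col])
    if "geometry" in tables:
        df = tables["geometry"]
        for col in ("epsilon", "theta", "dihedral"):
            add("geometry", col, df[col])
    if "pockets" in tables:
        df = tables["pockets"]
        for col in ("exp_volume", "exp_sphericity", "exp_effective_radius"):
            if col in df:
                add("pockets", col, df[col])
    if "torsions" in tables:
        df = tables["torsions"]
        for col in ("pearson_phi", "pearson_psi", "wasserstein_phi", "wasserstein_psi"):
            add("torsions", col, df[col])
    if "sse" in tables:
        df = tables["sse"]
        for dom in df["domain"].unique():
            sub = df[df["domain"] == dom]
            for col in ("helix_pct", "sheet_pct", "loop_pct"):
                add("sse", f"{dom}_{col}", sub[col])
    return out
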