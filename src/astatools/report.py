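"""Pipeline orchestration and machine-readable reporting.

A run configuration (TOML file or plain dict) names the stages to execute;
stages run in dependency order (contacts -> conservation -> superposition/
clash -> SAXS) and each writes its numbers into a single JSON-serializable
report, together with provenance (input hashes, package version, the
verbatim config). Identical config + inputs produce byte-identical JSON.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from pathlib import Path
from typing import Any

from . import __version__, conservation, geometry, sasa, saxs, tables
from .structure import SelectionExpr, read_pdb


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _hash_file(path: str) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        return path_or_dict
    with open(path_or_dict, "rb") as fh:
        return tomllib.load(fh)


def _stage_contacts(cfg: dict) -> dict:
    ensemble = read_pdb(cfg["pdb"])
    from .structure import assign_radii_ensemble
    ensemble = assign_radii_ensemble(ensemble)
    if not cfg.get("include_hydrogens", False):
        from .structure import StructureEnsemble
        ensemble = StructureEnsemble([m.heavy_atoms() for m in ensemble])
    table = sasa.ensemble_contacts(
        ensemble, SelectionExpr.parse(cfg["ligand"]),
        cutoff=cfg.get("cutoff", tables.CONTACT_CUTOFF),
        probe=cfg.get("probe", tables.PROBE_RADIUS),
        n_points=cfg.get("points", tables.N_SPHERE_POINTS),
        model=cfg.get("model"))
    return {
        "cutoff": table.cutoff,
        "ensemble_size": table.ensemble_size,
        "contact_residues": table.contact_residue_numbers,
        "records": [
            {"chain": r.residue_key[0], "residue": r.residue_key[1],
             "name": r.residue_key[3],
             "delta_sasa_mean": round(r.delta_sasa_aggregate, 6),
             "is_contact": r.is_contact}
            for r in table.records],
    }


def _stage_conserve(cfg: dict, contact_positions: list[int] | None) -> dict:
    msa_g = conservation.read_msa(cfg["msa_group"], cfg.get("format", "fasta"),
                                  label="group",
                                  reference=cfg.get("reference"),
                                  ref_start=cfg.get("ref_start", 1))
    msa_f = conservation.read_msa(cfg["msa_family"],
                                  cfg.get("format", "fasta"), label="family",
                                  reference=cfg.get("family_reference"),
                                  ref_start=cfg.get("family_ref_start",
                                                    cfg.get("ref_start", 1)))
    positions = cfg.get("positions") or contact_positions
    if not positions:
        raise ValueError("no positions given and no contacts stage ran")
    result = conservation.classify_positions(
        list(positions), msa_g, msa_f,
        threshold=cfg.get("threshold", 0.8))
    return {
        "threshold": cfg.get("threshold", 0.8),
        "positions": [
            {"position": p.position, "score_group": round(p.score_group, 6),
             "score_family": round(p.score_family, 6),
             "category": p.category, "consensus_group": p.consensus_group,
             "consensus_family": p.consensus_family}
            for p in result],
    }


def _stage_superpose(cfg: dict) -> dict:
    ref = read_pdb(cfg["reference"])[0]
    mobile = read_pdb(cfg["mobile"])[0]
    anchors = {name: (tuple(v[0]), tuple(v[1]))
               for name, v in cfg["anchors"].items()}
    result = geometry.motif_superpose(ref, mobile, anchors,
                                      atom_name=cfg.get("atoms", "CA"))
    out = {"anchor_rmsd": round(result.anchor_rmsd, 6),
           "shared_ca_rmsd": (round(result.shared_ca_rmsd, 6)
                              if result.shared_ca_rmsd is not None else None),
           "n_shared_ca": result.n_shared_ca,
           "n_anchor_atoms": result.superposition.n_atoms_used}
    if cfg.get("write_transformed"):
        from .structure import write_pdb
        with open(cfg["write_transformed"], "w") as fh:
            write_pdb(result.transformed, fh)
        out["transformed_pdb"] = cfg["write_transformed"]
    return out


def _stage_clash(cfg: dict) -> dict:
    from .structure import assign_radii, split_complex
    model = read_pdb(cfg["pdb"])[0]
    protein, ligand = split_complex(model, SelectionExpr.parse(cfg["ligand"]))
    protein = assign_radii(protein.heavy_atoms())
    ligand = assign_radii(ligand.heavy_atoms())
    tol = cfg.get("tolerance", tables.CLASH_TOLERANCE)
    clashes = geometry.detect_clashes(protein, ligand, tol)
    return {
        "tolerance": tol,
        "note": "only the given rotamer coordinates are evaluated",
        "clashes": [
            {"residue": c.atom_a.residue_number,
             "residue_name": c.atom_a.residue_name,
             "atom": c.atom_a.name, "ligand_atom": c.atom_b.name,
             "distance": round(c.distance, 4),
             "overlap": round(c.overlap, 4)}
            for c in clashes],
    }


def _stage_saxs(cfg: dict) -> dict:
    curve = saxs.read_dat(cfg["data"], unit=cfg["unit"])
    guinier = saxs.guinier_fit(curve, srg_max=cfg.get("srg_max", 1.3),
                               s_min=cfg.get("s_min"))
    porod = saxs.porod_volume(curve, guinier)
    saxs.mw_estimates(porod, guinier, curve)
    out = {
        "unit": cfg["unit"],
        "rg_nm": round(guinier.rg, 4),
        "rg_err_nm": round(guinier.rg_err, 4),
        "i0": guinier.i0,
        "srg_limits": [round(v, 4) for v in guinier.srg_limits],
        "guinier_points": guinier.n_points,
        "porod_volume_nm3": round(porod.porod_volume, 4),
        "porod_plateau_ok": porod.plateau_ok,
        "mw_porod_kda": round(porod.mw_porod, 4),
        "vc_nm2": round(porod.vc, 4),
        "mw_vc_kda": round(porod.mw_vc, 4),
    }
    if cfg.get("model"):
        model = read_pdb(cfg["model"])[0].heavy_atoms()
        theory = saxs.debye_intensity(model, curve.in_nm().s, unit="nm^-1")
        fit = saxs.chi2_fit(theory, curve,
                            fit_offset=cfg.get("fit_offset", True))
        out["model_fit"] = {"chi2": round(fit.chi2, 4),
                            "scale": fit.scale, "offset": fit.offset}
    return out


_STAGES = ("contacts", "conserve", "superpose", "clash", "saxs")


def run_pipeline(config) -> dict[str, Any]:
    """Execute the configured stages and return the report dict."""
    cfg = load_config(config)
    report: dict[str, Any] = {
        "version": __version__,
        "config": cfg,
        "inputs": {},
    }
    for stage_cfg in cfg.values():
        if isinstance(stage_cfg, dict):
            for key in ("pdb", "data", "reference", "mobile", "msa_group",
                        "msa_family", "model"):
                path = stage_cfg.get(key)
                if isinstance(path, str) and Path(path).is_file():
                    report["inputs"][path] = _hash_file(path)
    contact_positions: list[int] | None = None
    for stage in _STAGES:
        if stage not in cfg:
            continue
        try:
            if stage == "contacts":
                result = _stage_contacts(cfg[stage])
                contact_positions = result["contact_residues"]
            elif stage == "conserve":
                result = _stage_conserve(cfg[stage], contact_positions)
            elif stage == "superpose":
                result = _stage_superpose(cfg[stage])
            elif stage == "clash":
                result = _stage_clash(cfg[stage])
            else:
                result = _stage_saxs(cfg[stage])
        except Exception as exc:  # noqa: BLE001 - re-raised with stage name
            raise StageError(stage, exc) from exc
        report[stage] = result
    return report


def report_json(report: dict) -> str:
    return json.dumps(report, indent=2, sort_keys=True, default=str)
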