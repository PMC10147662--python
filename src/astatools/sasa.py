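"""Solvent-accessible surface area (Shrake-Rupley) and ligand-contact
calling by SASA change.

The SASA of an atom is estimated by placing a deterministic Fibonacci
spiral lattice of test points on the sphere of radius ``r_vdw + probe``
around it and counting the points not occluded by any neighbouring atom's
probe-expanded sphere:

    area_i = (accessible points / n_points) * 4 * pi * (r_i + probe)**2

A residue is called a ligand contact when its mean SASA change on adding
the ligand as a pure occluder (dSASA) meets the cutoff (default 10 Å²,
inclusive). The point set contains no randomness, so results are exactly
reproducible and checkable against a brute-force point test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from . import tables
from .structure import (ResidueKey, SelectionExpr, StructureEnsemble,
                        StructureModel, split_complex)


def sphere_points(n: int) -> np.ndarray:
    """Deterministic Fibonacci-spiral lattice of ``n`` unit vectors."""
    if n < 10:
        raise ValueError("n_points must be >= 10")
    k = np.arange(n, dtype=float)
    # golden-angle longitude, uniform-area latitude
    phi = k * (np.pi * (3.0 - np.sqrt(5.0)))
    z = 1.0 - (2.0 * k + 1.0) / n
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack((rho * np.cos(phi), rho * np.sin(phi), z))


@dataclass
class SASAResult:
    probe_radius: float
    n_sphere_points: int
    per_atom_area: np.ndarray  # Å², aligned with the input model's atoms
    residue_keys: list[ResidueKey]
    per_residue_area: dict[ResidueKey, float]

    @property
    def total_area(self) -> float:
        return float(self.per_atom_area.sum())


def _accessible_fractions(coords: np.ndarray, radii: np.ndarray,
                          probe: float, n_points: int,
                          occ_coords: np.ndarray | None = None,
                          occ_radii: np.ndarray | None = None) -> np.ndarray:
    """Fraction of lattice points accessible for each atom in ``coords``.

    ``occ_coords``/``occ_radii`` add occluders that do not themselves
    receive area (the ligand in a dSASA computation).
    """
    unit = sphere_points(n_points)
    n = len(coords)
    if occ_coords is not None and len(occ_coords):
        all_coords = np.vstack([coords, occ_coords])
        all_radii = np.concatenate([radii, occ_radii])
    else:
        all_coords = coords
        all_radii = radii
    expanded = all_radii + probe
    tree = cKDTree(all_coords)
    r_max = expanded.max() if len(expanded) else 0.0
    frac = np.empty(n)
    for i in range(n):
        ri = radii[i] + probe
        # any occluding sphere centre lies within ri + r_other of atom i
        neigh = tree.query_ball_point(coords[i], ri + r_max)
        neigh = [j for j in neigh
                 if j != i and
                 np.linalg.norm(all_coords[j] - coords[i]) < ri + expanded[j]]
        if not neigh:
            frac[i] = 1.0
            continue
        pts = coords[i] + ri * unit
        occluded = np.zeros(n_points, dtype=bool)
        for j in neigh:
            d2 = np.sum((pts - all_coords[j]) ** 2, axis=1)
            occluded |= d2 < expanded[j] ** 2
            if occluded.all():
                break
        frac[i] = 1.0 - occluded.mean()
    return frac


def shrake_rupley(model: StructureModel,
                  probe: float = tables.PROBE_RADIUS,
                  n_points: int = tables.N_SPHERE_POINTS,
                  occluders: StructureModel | None = None) -> SASAResult:
    """Per-atom and per-residue SASA of ``model`` (radii must be assigned).

    ``occluders`` atoms shadow the surface but contribute no area of their
    own.
    """
    if n_points < 10:
        raise ValueError("n_points must be >= 10")
    coords = model.coords
    radii = model.radii
    occ_c = occluders.coords if occluders is not None else None
    occ_r = occluders.radii if occluders is not None else None
    frac = _accessible_fractions(coords, radii, probe, n_points, occ_c, occ_r)
    per_atom = frac * 4.0 * np.pi * (radii + probe) ** 2
    per_res: dict[ResidueKey, float] = {}
    for a, area in zip(model, per_atom):
        per_res[a.residue_key] = per_res.get(a.residue_key, 0.0) + float(area)
    return SASAResult(probe, n_points, per_atom, list(per_res), per_res)


def delta_sasa(complex_model: StructureModel,
               ligand: SelectionExpr,
               probe: float = tables.PROBE_RADIUS,
               n_points: int = tables.N_SPHERE_POINTS) -> dict[ResidueKey, float]:
    """Per-residue SASA loss of the protein upon adding the ligand as an
    occluder; values are clamped at 0 (the ligand can only bury area)."""
    protein, lig = split_complex(complex_model, ligand)
    alone = shrake_rupley(protein, probe, n_points)
    bound = shrake_rupley(protein, probe, n_points, occluders=lig)
    return {key: max(0.0, alone.per_residue_area[key]
                     - bound.per_residue_area[key])
            for key in alone.residue_keys}


@dataclass
class ContactRecord:
    residue_key: ResidueKey
    delta_sasa_per_model: list[float]
    delta_sasa_aggregate: float  # mean over models, Å²
    is_contact: bool


@dataclass
class ContactTable:
    records: list[ContactRecord]
    cutoff: float
    ensemble_size: int

    @property
    def contacts(self) -> list[ContactRecord]:
        return [r for r in self.records if r.is_contact]

    @property
    def contact_residue_numbers(self) -> list[int]:
        return sorted(r.residue_key[1] for r in self.contacts)

    def to_frame(self):
        import pandas as pd
        rows = []
        for r in self.records:
            chain, num, icode, name = r.residue_key
            row = {"chain": chain, "residue_number": num,
                   "insertion_code": icode, "residue_name": name,
                   "delta_sasa_mean": r.delta_sasa_aggregate,
                   "is_contact": r.is_contact}
            for i, v in enumerate(r.delta_sasa_per_model, start=1):
                row[f"model_{i}"] = v
            rows.append(row)
        return pd.DataFrame(rows)


def ensemble_contacts(ensemble: StructureEnsemble,
                      ligand: SelectionExpr,
                      cutoff: float = tables.CONTACT_CUTOFF,
                      probe: float = tables.PROBE_RADIUS,
                      n_points: int = tables.N_SPHERE_POINTS,
                      model: int | None = None) -> ContactTable:
    """dSASA contact calls aggregated over an ensemble.

    The aggregate is the arithmetic mean of per-model dSASA; a residue is a
    contact when the mean meets ``cutoff`` (inclusive). ``model`` restricts
    the computation to a single model (by position, 0-based) for
    sensitivity checks.
    """
    if not ensemble.shared_topology:
        raise ValueError("ensemble models differ in topology")
    models = ensemble.models if model is None else [ensemble.models[model]]
    per_model = [delta_sasa(m, ligand, probe, n_points) for m in models]
    keys = list(per_model[0])
    records = []
    for key in keys:
        values = [dm[key] for dm in per_model]
        mean = float(np.mean(values))
        records.append(ContactRecord(key, values, mean, mean >= cutoff))
    return ContactTable(records, cutoff, len(models))
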