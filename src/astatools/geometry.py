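"""Rigid-body superposition (Kabsch), motif-anchored alignment, NMR
ensemble RMSD statistics, and van der Waals clash detection.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import cKDTree

from . import tables
from .structure import Atom, StructureEnsemble, StructureModel

BACKBONE_ATOMS = ("N", "CA", "C")


@dataclass
class Superposition:
    rotation: np.ndarray  # 3x3, det +1
    translation: np.ndarray  # 3-vector, Å
    rmsd: float  # Å, over the fitted atoms
    n_atoms_used: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    def apply_model(self, model: StructureModel) -> StructureModel:
        moved = self.apply(model.coords)
        atoms = [replace(a, position=moved[i]) for i, a in enumerate(model)]
        return StructureModel(model.model_id, atoms)


def kabsch(coords_a: np.ndarray, coords_b: np.ndarray,
           weights: np.ndarray | None = None) -> Superposition:
    """Least-squares rotation+translation mapping ``coords_b`` onto
    ``coords_a`` (reflections are excluded by forcing det=+1).

    Degenerate point sets (rank < 2 after centering, e.g. collinear) raise.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate sets must both be N x 3")
    n = len(a)
    if n < 3:
        raise ValueError("need at least 3 atom pairs")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    w = w / w.sum()
    ca = (w[:, None] * a).sum(axis=0)
    cb = (w[:, None] * b).sum(axis=0)
    a0, b0 = a - ca, b - cb
    h = (w[:, None] * b0).T @ a0
    u, s, vt = np.linalg.svd(h)
    if np.linalg.matrix_rank(np.diag(s), tol=1e-10 * max(s[0], 1.0)) < 2:
        raise ValueError("degenerate (collinear or coincident) point set")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    t = ca - rot @ cb
    moved = b @ rot.T + t
    rmsd = float(np.sqrt((w * np.sum((moved - a) ** 2, axis=1)).sum()))
    return Superposition(rot, t, rmsd, n)


def rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Plain (unfitted) root-mean-square deviation."""
    a, b = np.asarray(coords_a), np.asarray(coords_b)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


# --- motif-anchored superposition ----------------------------------------

MotifAnchors = dict[str, tuple[tuple[int, int], tuple[int, int]]]
"""motif name -> (residue range in A, residue range in B), inclusive and of
equal length per motif."""


def _anchor_atoms(model: StructureModel, lo: int, hi: int,
                  atom_name: str) -> list[Atom]:
    found = {a.residue_number: a for a in model
             if a.name == atom_name and lo <= a.residue_number <= hi
             and not a.is_hetero}
    missing = [n for n in range(lo, hi + 1) if n not in found]
    if missing:
        raise KeyError(f"anchor residues without {atom_name} atom: {missing}")
    return [found[n] for n in range(lo, hi + 1)]


@dataclass
class MotifSuperposition:
    superposition: Superposition
    transformed: StructureModel  # whole structure B in A's frame
    anchor_rmsd: float
    shared_ca_rmsd: float | None  # over residues numbered alike in A and B
    n_shared_ca: int


def motif_superpose(struct_a: StructureModel, struct_b: StructureModel,
                    anchors: MotifAnchors,
                    atom_name: str = "CA") -> MotifSuperposition:
    """Superpose B onto A fitting only the anchor-motif atoms.

    The fit uses the paired residue ranges of each motif; the whole of B is
    then transformed and the RMSD is reported both on the anchors and on
    all residues that carry the same residue number in both structures.
    """
    atoms_a: list[Atom] = []
    atoms_b: list[Atom] = []
    for motif, (ra, rb) in anchors.items():
        if (ra[1] - ra[0]) != (rb[1] - rb[0]):
            raise ValueError(f"motif {motif!r}: ranges differ in length")
        atoms_a.extend(_anchor_atoms(struct_a, *ra, atom_name))
        atoms_b.extend(_anchor_atoms(struct_b, *rb, atom_name))
    sup = kabsch(np.vstack([a.position for a in atoms_a]),
                 np.vstack([a.position for a in atoms_b]))
    moved = sup.apply_model(struct_b)
    ca_a = {a.residue_number: a.position for a in struct_a
            if a.name == atom_name and not a.is_hetero}
    ca_b = {a.residue_number: a.position for a in moved
            if a.name == atom_name and not a.is_hetero}
    shared = sorted(set(ca_a) & set(ca_b))
    shared_rmsd = None
    if shared:
        shared_rmsd = rmsd(np.vstack([ca_a[n] for n in shared]),
                           np.vstack([ca_b[n] for n in shared]))
    return MotifSuperposition(sup, moved, sup.rmsd, shared_rmsd, len(shared))


# --- ensemble statistics --------------------------------------------------

def _atom_matrix(model: StructureModel, residue_numbers: set[int] | None,
                 atom_names: tuple[str, ...] | None) -> np.ndarray:
    rows = [a.position for a in model
            if not a.is_hetero
            and (residue_numbers is None or a.residue_number in residue_numbers)
            and (atom_names is None or a.name in atom_names)]
    if not rows:
        raise ValueError("atom selection is empty")
    return np.vstack(rows)


@dataclass
class EnsembleRMSD:
    per_model: list[float]
    mean: float
    sd: float


def ensemble_rmsd(ensemble: StructureEnsemble,
                  residue_range: tuple[int, int] | None = None,
                  atom_set: str = "backbone",
                  max_iter: int = 20, tol: float = 1e-6) -> EnsembleRMSD:
    """Mean ± SD of per-model RMSD to the iteratively refined mean
    structure.

    Each model is superposed (Kabsch) onto the current mean coordinate set,
    the mean is recomputed, and the cycle repeats to convergence — the
    usual NMR-ensemble precision statistic. ``atom_set`` is ``"backbone"``
    (N, CA, C) or ``"heavy"`` (all non-hydrogen atoms).
    """
    if len(ensemble) < 2:
        raise ValueError("need at least 2 models")
    res = (set(range(residue_range[0], residue_range[1] + 1))
           if residue_range else None)
    if atom_set == "backbone":
        names: tuple[str, ...] | None = BACKBONE_ATOMS
        mats = [_atom_matrix(m, res, names) for m in ensemble]
    elif atom_set == "heavy":
        mats = [_atom_matrix(m.heavy_atoms(), res, None) for m in ensemble]
    else:
        raise ValueError("atom_set must be 'backbone' or 'heavy'")
    shapes = {m.shape for m in mats}
    if len(shapes) > 1:
        raise ValueError("models differ in selected atom counts")
    mean = mats[0].copy()
    for _ in range(max_iter):
        fitted = [kabsch(mean, m).apply(m) for m in mats]
        new_mean = np.mean(fitted, axis=0)
        shift = float(np.abs(new_mean - mean).max())
        mean = new_mean
        mats = fitted
        if shift < tol:
            break
    per_model = [rmsd(mean, m) for m in mats]
    return EnsembleRMSD(per_model, float(np.mean(per_model)),
                        float(np.std(per_model, ddof=1)))


def radius_of_gyration(model: StructureModel,
                       weights: str = "uniform") -> float:
    """Coordinate radius of gyration, Å. ``weights``: ``"uniform"`` or
    ``"electron"`` (atomic-number weighting)."""
    coords = model.coords
    if weights == "electron":
        w = np.array([tables.ELECTRON_COUNTS.get(a.element.upper(), 6)
                      for a in model], dtype=float)
    else:
        w = np.ones(len(coords))
    w = w / w.sum()
    center = (w[:, None] * coords).sum(axis=0)
    return float(np.sqrt((w * np.sum((coords - center) ** 2, axis=1)).sum()))


# --- clash detection ------------------------------------------------------

@dataclass
class ClashRecord:
    atom_a: Atom  # protein side
    atom_b: Atom  # ligand side
    distance: float  # Å
    overlap: float  # Å, r_a + r_b - distance


def detect_clashes(protein: StructureModel, ligand: StructureModel,
                   tolerance: float = tables.CLASH_TOLERANCE) -> list[ClashRecord]:
    """Cross-set vdW overlaps exceeding ``tolerance``, largest first.

    Only the coordinates given are evaluated; no rotamer sampling.
    """
    pc, lc = protein.coords, ligand.coords
    pr, lr = protein.radii, ligand.radii
    if not len(pc) or not len(lc):
        return []
    cutoff = float(pr.max() + lr.max() - tolerance)
    pairs = cKDTree(pc).query_ball_tree(cKDTree(lc), cutoff)
    records = []
    for i, js in enumerate(pairs):
        for j in js:
            d = float(np.linalg.norm(pc[i] - lc[j]))
            overlap = float(pr[i] + lr[j] - d)
            if overlap > tolerance:
                records.append(ClashRecord(protein.atoms[i], ligand.atoms[j],
                                           d, overlap))
    records.sort(key=lambda r: -r.overlap)
    return records
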