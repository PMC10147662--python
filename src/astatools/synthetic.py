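"""Ground-truth synthetic fixtures.

Three generators, each a pure function of its spec and seed:

* a "tunnel" pseudo-protein wrapping a rod ligand, with a known set of
  planted contact residues (rings of Cα-like spheres enclosing the rod) and
  an optional open-jaw variant produced by a known hinge rotation;
* a pair of grouped alignments (small ortholog group vs. large superfamily)
  with planted per-column conservation categories realized by round-robin
  assignment, so classification outcomes are exact by construction;
* noisy scattering curves from analytic bodies (sphere, Gaussian globule)
  or from atomic models via the Debye sum.

These emulate the geometry and group structure of the real study inputs,
not their chemistry: pseudo-residues are single carbon-radius spheres and
alignments are synthetic columns, which is exactly what makes the planted
ground truth recoverable and checkable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import saxs as saxs_mod
from .conservation import GroupedMSA
from .structure import (Atom, SelectionExpr, StructureEnsemble,
                        StructureModel, assign_radii)

LIGAND_RESNAME = "LIG"
LIGAND_SELECTION = SelectionExpr(residue_names=frozenset({LIGAND_RESNAME}))

#: Coordinate jitter applied across ensemble models, Å. Small enough not to
#: flip planted contacts at the shipped geometry.
ENSEMBLE_JITTER = 0.3


# --- tunnel complex -------------------------------------------------------

@dataclass(frozen=True)
class TunnelComplexSpec:
    n_residues: int = 30
    n_rings: int = 4
    ring_size: int = 3
    ring_radius: float = 4.0  # Å, tunnel radius around the rod
    ring_spacing: float = 4.0  # Å along the rod axis
    rod_atoms: int = 8
    rod_spacing: float = 1.4  # Å between rod pseudo-atoms
    jaw_angle_deg: float = 0.0  # hinge rotation applied to the jaw rings
    n_models: int = 1
    seed: int = 0

    @property
    def n_tunnel(self) -> int:
        return self.n_rings * self.ring_size


def _rotation_x(angle_deg: float) -> np.ndarray:
    a = np.radians(angle_deg)
    return np.array([[1, 0, 0],
                     [0, np.cos(a), -np.sin(a)],
                     [0, np.sin(a), np.cos(a)]])


def make_tunnel_complex(spec: TunnelComplexSpec
                        ) -> tuple[StructureEnsemble, list[int]]:
    """Build the rod-in-tunnel complex and return (ensemble, contacts).

    Tunnel residues (numbers 1..n_tunnel) are single carbon-radius spheres
    arranged in rings that enclose the rod within occlusion distance; the
    remaining residues sit on a distant shell where the rod cannot shadow
    them, so the planted contact list is exact by construction. The rod is
    one hetero-residue of ``rod_atoms`` collinear pseudo-atoms.
    """
    n_tunnel = spec.n_tunnel
    if spec.n_residues < n_tunnel + 1:
        raise ValueError("n_residues must exceed the tunnel residue count")
    rod_len = (spec.rod_atoms - 1) * spec.rod_spacing
    tunnel_len = (spec.n_rings - 1) * spec.ring_spacing
    if rod_len > tunnel_len + 2 * spec.ring_spacing:
        raise ValueError("rod longer than tunnel capacity")
    rng = np.random.default_rng(spec.seed)

    protein_xyz: list[np.ndarray] = []
    # rings centred on the rod axis (z), centred at origin
    z0 = -tunnel_len / 2.0
    for ring in range(spec.n_rings):
        z = z0 + ring * spec.ring_spacing
        for k in range(spec.ring_size):
            # stagger alternate rings for tighter enclosure
            phi = 2 * np.pi * (k + 0.5 * (ring % 2)) / spec.ring_size
            protein_xyz.append(np.array([spec.ring_radius * np.cos(phi),
                                         spec.ring_radius * np.sin(phi), z]))
    # distant residues: arc on a shell 25 Å off-axis, far beyond occlusion
    n_far = spec.n_residues - n_tunnel
    for k in range(n_far):
        theta = np.pi * (k + 0.5) / n_far
        protein_xyz.append(np.array([25.0 + 5.0 * np.cos(theta),
                                     5.0 * np.sin(theta),
                                     8.0 * np.sin(3 * theta)]))
    rod_xyz = [np.array([0.0, 0.0, -rod_len / 2.0 + m * spec.rod_spacing])
               for m in range(spec.rod_atoms)]

    if spec.jaw_angle_deg:
        # the "jaw": upper half of every ring (y > 0) hinges about the x
        # axis at the tunnel mouth
        rot = _rotation_x(spec.jaw_angle_deg)
        pivot = np.array([0.0, spec.ring_radius, z0])
        for idx in range(n_tunnel):
            if protein_xyz[idx][1] > 0.1:
                protein_xyz[idx] = rot @ (protein_xyz[idx] - pivot) + pivot

    models = []
    for mi in range(spec.n_models):
        jitter = (rng.normal(0.0, ENSEMBLE_JITTER,
                             (len(protein_xyz) + len(rod_xyz), 3))
                  if spec.n_models > 1 else
                  np.zeros((len(protein_xyz) + len(rod_xyz), 3)))
        atoms = []
        for i, pos in enumerate(protein_xyz):
            atoms.append(Atom(serial=i + 1, name="CA", element="C",
                              residue_name="ALA", chain_id="A",
                              residue_number=i + 1, insertion_code="",
                              position=pos + jitter[i]))
        for m, pos in enumerate(rod_xyz):
            atoms.append(Atom(serial=len(protein_xyz) + m + 1,
                              name=f"C{m + 1}", element="C",
                              residue_name=LIGAND_RESNAME, chain_id="B",
                              residue_number=1, insertion_code="",
                              position=pos + jitter[len(protein_xyz) + m],
                              is_hetero=True))
        models.append(assign_radii(StructureModel(mi + 1, atoms)))
    contacts = list(range(1, n_tunnel + 1))
    return StructureEnsemble(models), contacts


# --- grouped MSAs ---------------------------------------------------------

@dataclass(frozen=True)
class PlantedMSASpec:
    n_group: int = 10
    n_family: int = 150
    categories: tuple[str, ...] = ("both_conserved",) * 5
    seed: int = 0


# residues drawn from five distinct similarity classes; round-robin over
# them caps any class frequency at ~1/5, far below the 0.8 threshold
_VARIABLE_POOL = "LKDSF"
_CONSERVED_RESIDUE = {"both_conserved": "W", "group_specific": "Q",
                      "fas1_only": "E", "variable_in_both": None}


def _column(category: str, n: int, conserved_here: bool,
            rng: np.random.Generator) -> list[str]:
    if conserved_here:
        return [_CONSERVED_RESIDUE[category]] * n
    col = [_VARIABLE_POOL[k % len(_VARIABLE_POOL)] for k in range(n)]
    rng.shuffle(col)
    return col


def make_grouped_msas(spec: PlantedMSASpec
                      ) -> tuple[GroupedMSA, GroupedMSA, dict[int, str]]:
    """Two alignments with planted per-column categories.

    Returns (ortholog group MSA, family MSA, truth) where ``truth`` maps
    reference position (1-based) to planted category. Columns are realized
    by round-robin assignment over five dissimilar residue classes, so a
    "variable" column's best class frequency is ~0.2 — a margin >= 0.2
    below the default 0.8 conservation threshold at any group size >= 5.
    """
    for name, n in (("n_group", spec.n_group), ("n_family", spec.n_family)):
        if n < 5:
            raise ValueError(f"{name} must be >= 5 to realize the planted "
                             "margins")
    bad = [c for c in spec.categories if c not in _CONSERVED_RESIDUE]
    if bad:
        raise ValueError(f"unknown categories {bad}")
    rng = np.random.default_rng(spec.seed)
    cols_g, cols_f = [], []
    truth: dict[int, str] = {}
    for pos, cat in enumerate(spec.categories, start=1):
        truth[pos] = cat
        cons_g = cat in ("both_conserved", "group_specific")
        cons_f = cat in ("both_conserved", "fas1_only")
        cols_g.append(_column(cat, spec.n_group, cons_g, rng))
        cols_f.append(_column(cat, spec.n_family, cons_f, rng))

    def _assemble(cols: list[list[str]], n: int, label: str) -> GroupedMSA:
        seqs = {f"{label}{i:03d}": "".join(col[i] for col in cols)
                for i in range(n)}
        return GroupedMSA(label, seqs, reference=f"{label}000", ref_start=1)

    return (_assemble(cols_g, spec.n_group, "grp"),
            _assemble(cols_f, spec.n_family, "fam"), truth)


# --- scattering curves ----------------------------------------------------

@dataclass(frozen=True)
class CurveSpec:
    body: str = "sphere"  # sphere | gaussian | model
    radius: float = 2.58  # nm (sphere)
    rg: float = 2.0  # nm (gaussian)
    model: object = None  # StructureModel when body == "model"
    s_min: float = 0.05  # nm^-1
    s_max: float = 5.0  # nm^-1
    n_points: int = 400
    i0: float = 1.0
    noise_fraction: float = 0.01  # sigma as a fraction of I(s)
    noise_floor: float = 0.0  # additive sigma floor
    seed: int = 0


def make_curve(spec: CurveSpec
               ) -> tuple[saxs_mod.SAXSCurve, saxs_mod.SAXSCurve]:
    """(noisy, noiseless) scattering curves for a known body.

    sigma(s) = noise_fraction·I(s) + noise_floor is both the generating and
    the stored uncertainty.
    """
    s = np.linspace(spec.s_min, spec.s_max, spec.n_points)
    if spec.body == "sphere":
        if spec.radius <= 0:
            raise ValueError("sphere radius must be positive")
        i = saxs_mod.sphere_form_factor(s, spec.radius, spec.i0)
    elif spec.body == "gaussian":
        if spec.rg <= 0:
            raise ValueError("Rg must be positive")
        i = spec.i0 * np.exp(-(s * spec.rg) ** 2 / 3.0)
    elif spec.body == "model":
        if spec.model is None:
            raise ValueError("body='model' requires a model")
        curve = saxs_mod.debye_intensity(spec.model, s, unit="nm^-1")
        i = curve.intensity * spec.i0 / curve.intensity[0]
    else:
        raise ValueError(f"unknown body {spec.body!r}")
    sigma = spec.noise_fraction * np.abs(i) + spec.noise_floor
    clean = saxs_mod.SAXSCurve(s, i, None, "nm^-1")
    if np.all(sigma == 0):
        return saxs_mod.SAXSCurve(s, i.copy(), None, "nm^-1"), clean
    rng = np.random.default_rng(spec.seed)
    noisy = i + rng.normal(0.0, 1.0, len(s)) * sigma
    return saxs_mod.SAXSCurve(s, noisy, sigma, "nm^-1"), clean
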