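"""Multi-model protein-ligand structures.

A :class:`StructureEnsemble` holds one or more :class:`StructureModel`
objects (e.g. the members of an NMR ensemble), each a flat, ordered list of
:class:`Atom` records. Parsing of PDB-format text is delegated to gemmi;
alternate locations are resolved to the highest-occupancy conformer (ties
broken by file order) and elements missing from the input are inferred from
atom names. Coordinates are Å; residue numbers are author numbers taken
as-is from the file.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Iterator

import gemmi
import numpy as np


class PDBParseError(ValueError):
    """Raised for malformed fixed-width coordinate records."""


class EmptyStructureError(ValueError):
    """Raised when a source contains no atoms."""


# Residue key: (chain_id, residue_number, insertion_code, residue_name)
ResidueKey = tuple[str, int, str, str]


@dataclass(frozen=True)
class Atom:
    serial: int
    name: str
    element: str
    residue_name: str
    chain_id: str
    residue_number: int
    insertion_code: str
    position: np.ndarray  # shape (3,), Å
    occupancy: float = 1.0
    is_hetero: bool = False
    vdw_radius: float | None = None  # Å, assigned via assign_radii

    @property
    def residue_key(self) -> ResidueKey:
        return (self.chain_id, self.residue_number, self.insertion_code,
                self.residue_name)

    @property
    def identifier(self) -> tuple:
        """Topology identity: everything except coordinates/occupancy."""
        return (self.chain_id, self.residue_number, self.insertion_code,
                self.residue_name, self.name)


@dataclass
class StructureModel:
    model_id: int
    atoms: list[Atom]

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self) -> Iterator[Atom]:
        return iter(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """N×3 coordinate array (Å), in atom order."""
        if not self.atoms:
            return np.empty((0, 3))
        return np.vstack([a.position for a in self.atoms])

    @property
    def radii(self) -> np.ndarray:
        r = [a.vdw_radius for a in self.atoms]
        if any(x is None for x in r):
            missing = [a.name for a in self.atoms if a.vdw_radius is None]
            raise ValueError(
                f"{len(missing)} atoms lack vdW radii (e.g. {missing[:5]}); "
                "call assign_radii first")
        return np.asarray(r, dtype=float)

    def identifiers(self) -> list[tuple]:
        return [a.identifier for a in self.atoms]

    def residue_keys(self) -> list[ResidueKey]:
        """Unique residue keys in order of first appearance."""
        seen: dict[ResidueKey, None] = {}
        for a in self.atoms:
            seen.setdefault(a.residue_key, None)
        return list(seen)

    def select(self, expr: "SelectionExpr") -> "StructureModel":
        return StructureModel(self.model_id,
                              [a for a in self.atoms if expr.matches(a)])

    def heavy_atoms(self) -> "StructureModel":
        return self.select(SelectionExpr(exclude_elements=frozenset({"H", "D"})))


@dataclass
class StructureEnsemble:
    models: list[StructureModel]

    def __len__(self) -> int:
        return len(self.models)

    def __iter__(self) -> Iterator[StructureModel]:
        return iter(self.models)

    def __getitem__(self, i: int) -> StructureModel:
        return self.models[i]

    @property
    def shared_topology(self) -> bool:
        if not self.models:
            return True
        first = self.models[0].identifiers()
        return all(m.identifiers() == first for m in self.models[1:])


def _parse_ranges(text: str) -> tuple[tuple[int, int], ...]:
    out = []
    for part in text.split(","):
        part = part.strip()
        if "-" in part[1:]:  # split on the separator, allowing negatives
            i = part.index("-", 1)
            out.append((int(part[:i]), int(part[i + 1:])))
        else:
            out.append((int(part), int(part)))
    return tuple(out)


@dataclass(frozen=True)
class SelectionExpr:
    """Atom selection by chain, residue number/name, hetero flag, element.

    ``None`` means "no constraint". String form (CLI):
    ``"resname:AXT;chain:A;resnum:40-203,210;hetero:true;not-element:H"``.
    """

    chains: frozenset[str] | None = None
    residue_ranges: tuple[tuple[int, int], ...] | None = None
    residue_names: frozenset[str] | None = None
    hetero: bool | None = None
    elements: frozenset[str] | None = None
    exclude_elements: frozenset[str] | None = None

    @classmethod
    def parse(cls, text: str) -> "SelectionExpr":
        kwargs: dict = {}
        for clause in text.split(";"):
            clause = clause.strip()
            if not clause:
                continue
            key, _, value = clause.partition(":")
            key = key.strip().lower()
            value = value.strip()
            if key == "chain":
                kwargs["chains"] = frozenset(v.strip() for v in value.split(","))
            elif key == "resnum":
                kwargs["residue_ranges"] = _parse_ranges(value)
            elif key == "resname":
                kwargs["residue_names"] = frozenset(
                    v.strip().upper() for v in value.split(","))
            elif key == "hetero":
                kwargs["hetero"] = value.lower() in ("true", "1", "yes")
            elif key == "element":
                kwargs["elements"] = frozenset(
                    v.strip().upper() for v in value.split(","))
            elif key in ("not-element", "exclude-element"):
                kwargs["exclude_elements"] = frozenset(
                    v.strip().upper() for v in value.split(","))
            else:
                raise ValueError(f"unknown selection clause {key!r}")
        return cls(**kwargs)

    def matches(self, atom: Atom) -> bool:
        if self.chains is not None and atom.chain_id not in self.chains:
            return False
        if self.residue_ranges is not None and not any(
                lo <= atom.residue_number <= hi
                for lo, hi in self.residue_ranges):
            return False
        if (self.residue_names is not None
                and atom.residue_name.upper() not in self.residue_names):
            return False
        if self.hetero is not None and atom.is_hetero != self.hetero:
            return False
        el = atom.element.upper()
        if self.elements is not None and el not in self.elements:
            return False
        if self.exclude_elements is not None and el in self.exclude_elements:
            return False
        return True


_NAME_ELEMENT_2 = {"CL", "BR", "FE", "ZN", "MG", "MN", "NA", "SE", "CA", "NI",
                   "CU", "CO"}


def _infer_element(name: str, is_hetero: bool) -> str:
    """Atom-name heuristic used when columns 77-78 are blank."""
    stripped = name.strip()
    if not stripped:
        return ""
    # Standard PDB: a two-character element is left-justified in cols 13-14.
    lead = name[:2].strip().upper() if len(name) >= 2 else stripped.upper()
    if is_hetero and lead in _NAME_ELEMENT_2:
        return lead.capitalize() if len(lead) == 1 else lead[0] + lead[1].lower()
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    return ""


def _validate_fixed_width(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line[:6] in ("ATOM  ", "HETATM"):
            if len(line) < 54:
                raise PDBParseError(
                    f"line {lineno}: coordinate record shorter than 54 "
                    "columns")
            try:
                float(line[30:38]); float(line[38:46]); float(line[46:54])
            except ValueError as exc:
                raise PDBParseError(
                    f"line {lineno}: unparsable coordinate field") from exc


def _resolve_altlocs(atoms: list[tuple[str, Atom]]) -> list[Atom]:
    """Keep the highest-occupancy altloc per atom identity; ties keep the
    first listed."""
    best: dict[tuple, int] = {}
    for i, (_altloc, atom) in enumerate(atoms):
        key = atom.identifier
        if key not in best:
            best[key] = i
        elif atom.occupancy > atoms[best[key]][1].occupancy:
            best[key] = i
    keep = sorted(best.values())
    return [atoms[i][1] for i in keep]


def read_pdb(source) -> StructureEnsemble:
    """Read PDB-format text (file path, stream, or string) into an ensemble.

    MODEL/ENDMDL blocks become separate models; a file without MODEL records
    yields a single model. Elements are taken from columns 77-78 when
    present, otherwise inferred from the atom name. Alternate locations are
    resolved to the highest-occupancy conformer.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        s = str(source)
        if "\n" in s or s.lstrip()[:6] in ("ATOM  ", "HETATM", "MODEL ",
                                           "REMARK", "HEADER"):
            text = s
        else:
            with open(s) as fh:
                text = fh.read()
    _validate_fixed_width(text)
    st = gemmi.read_pdb_string(text)
    st.setup_entities()
    models: list[StructureModel] = []
    for mi, gm in enumerate(st):
        raw: list[tuple[str, Atom]] = []
        for chain in gm:
            for res in chain:
                het = res.het_flag == "H"
                for at in res:
                    el = "H" if at.element.is_hydrogen else \
                        at.element.name.upper()
                    if at.element.name in ("X", "") :
                        el = _infer_element(at.name, het)
                    raw.append((at.altloc or "", Atom(
                        serial=at.serial,
                        name=at.name,
                        element=el,
                        residue_name=res.name,
                        chain_id=chain.name,
                        residue_number=res.seqid.num,
                        insertion_code=(res.seqid.icode or "").strip(),
                        position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        occupancy=at.occ,
                        is_hetero=het,
                    )))
        try:
            model_id = int(gm.num)
        except (AttributeError, ValueError, TypeError):
            model_id = mi + 1
        models.append(StructureModel(model_id, _resolve_altlocs(raw)))
    models = [m for m in models if m.atoms]
    if not models:
        raise EmptyStructureError("no atoms found in source")
    return StructureEnsemble(models)


def write_pdb(obj: StructureEnsemble | StructureModel, stream=None) -> str:
    """Serialize to PDB-format text (coordinates to 3 decimals)."""
    if isinstance(obj, StructureModel):
        ens = StructureEnsemble([obj])
    else:
        ens = obj
    out = io.StringIO()
    multi = len(ens) > 1
    for model in ens:
        if multi:
            out.write(f"MODEL     {model.model_id:4d}\n")
        for i, a in enumerate(model, start=1):
            record = "HETATM" if a.is_hetero else "ATOM  "
            name = a.name
            if len(name) < 4 and len(a.element) < 2:
                name = " " + name
            x, y, z = a.position
            out.write(
                f"{record}{i:5d} {name:<4s}{'':1s}{a.residue_name:>3s} "
                f"{a.chain_id:1s}{a.residue_number:4d}{a.insertion_code or '':1s}"
                f"   {x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}"
                f"          {a.element:>2s}\n")
        if multi:
            out.write("ENDMDL\n")
    out.write("END\n")
    text = out.getvalue()
    if stream is not None:
        stream.write(text)
    return text


def split_complex(model: StructureModel,
                  ligand: SelectionExpr) -> tuple[StructureModel, StructureModel]:
    """Partition a model into (protein, ligand) by a ligand selection.

    The union of the two outputs equals the input and order is preserved.
    """
    lig_atoms = [a for a in model if ligand.matches(a)]
    if not lig_atoms:
        raise ValueError("ligand selection matches no atoms")
    lig_set = {id(a) for a in lig_atoms}
    prot_atoms = [a for a in model if id(a) not in lig_set]
    if not prot_atoms:
        raise ValueError("ligand selection matches the entire model")
    return (StructureModel(model.model_id, prot_atoms),
            StructureModel(model.model_id, lig_atoms))


def assign_radii(model: StructureModel,
                 radii_table: dict[str, float] | None = None,
                 default: float | None = None) -> StructureModel:
    """Return a copy of ``model`` with vdW radii assigned per element.

    Unknown elements raise (listing the offending atoms) unless ``default``
    is given; radii are never silently substituted.
    """
    from . import tables
    table = {k.upper(): v for k, v in
             (radii_table or tables.VDW_RADII).items()}
    new_atoms: list[Atom] = []
    unknown: list[str] = []
    for a in model:
        r = table.get(a.element.upper(), default)
        if r is None:
            unknown.append(f"{a.name}/{a.element}")
            continue
        new_atoms.append(replace(a, vdw_radius=r))
    if unknown:
        raise ValueError(
            f"no vdW radius for {len(unknown)} atoms and no default given: "
            f"{unknown[:10]}")
    return StructureModel(model.model_id, new_atoms)


def assign_radii_ensemble(ensemble: StructureEnsemble,
                          radii_table: dict[str, float] | None = None,
                          default: float | None = None) -> StructureEnsemble:
    return StructureEnsemble(
        [assign_radii(m, radii_table, default) for m in ensemble])
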