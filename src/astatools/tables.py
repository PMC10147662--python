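"""Reference tables: van der Waals radii, electron counts, amino-acid
similarity classes, and AstaPo1-specific constants.

All radii are in Å. The radii set is an explicit Bondi-style table; an
element missing from the table raises unless a default is supplied by the
caller — radii are never silently substituted.
"""

from __future__ import annotations

# Bondi (1964) vdW radii with common extensions, Å.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "D": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "NA": 2.27,
    "MG": 1.73,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "K": 2.75,
    "CA": 2.31,
    "MN": 2.05,
    "FE": 2.04,
    "CO": 2.00,
    "NI": 1.63,
    "CU": 1.40,
    "ZN": 1.39,
    "SE": 1.90,
    "BR": 1.85,
    "I": 1.98,
}

#: Atomic numbers used as point-scatterer form factors (electron counts).
ELECTRON_COUNTS: dict[str, int] = {
    "H": 1,
    "D": 1,
    "C": 6,
    "N": 7,
    "O": 8,
    "F": 9,
    "NA": 11,
    "MG": 12,
    "P": 15,
    "S": 16,
    "CL": 17,
    "K": 19,
    "CA": 20,
    "MN": 25,
    "FE": 26,
    "ZN": 30,
    "SE": 34,
    "BR": 35,
    "I": 53,
}

#: Physicochemical similarity classes for conservation scoring. Residues in
#: the same class count as "similar"; residues absent from every class are
#: singletons. The {N,Q} class covers amide interchangeability (Gln/Asn).
SIMILARITY_GROUPS: tuple[frozenset[str], ...] = (
    frozenset("ILVM"),
    frozenset("FWY"),
    frozenset("KR"),
    frozenset("DE"),
    frozenset("ST"),
    frozenset("NQ"),
    frozenset("AG"),
)

#: Default solvent probe radius, Å (water).
PROBE_RADIUS = 1.4

#: Default number of test points per atom for the surface-area lattice.
N_SPHERE_POINTS = 960

#: Ligand-contact cutoff on the mean SASA change, Å² (inclusive).
CONTACT_CUTOFF = 10.0

#: Default steric-clash tolerance, Å (allowed vdW interpenetration).
CLASH_TOLERANCE = 0.4

# --- AstaPo1 construct and anchor conventions (author numbering) ----------

#: The mature AstaPo1 chain used experimentally: residues 21-223 of the
#: preprotein, preceded by the four artificial residues G17-P18-H19-M20
#: left after affinity-tag removal.
ASTAPO1_MATURE_RANGE = (21, 223)
ASTAPO1_N_EXTENSION = "GPHM"  # occupies positions 17-20

#: FAS1 domain boundaries of AstaPo1 (author numbering).
ASTAPO1_FAS1_DOMAIN = (41, 190)

#: Default motif anchor ranges (H1/H2 motifs and the YH dyad) for
#: superposing FAS1 homologs onto AstaPo1. The motifs are defined
#: graphically in the source structure; these ranges are editable
#: approximations covering the tunnel-lining stretches of each motif.
ASTAPO1_MOTIF_ANCHORS: dict[str, tuple[int, int]] = {
    "H1": (63, 77),
    "YH": (117, 118),
    "H2": (165, 179),
}


def construct_length(
    mature_range: tuple[int, int] = ASTAPO1_MATURE_RANGE,
    n_extension: str = ASTAPO1_N_EXTENSION,
) -> int:
    """Number of residues in an expression construct: an inclusive mature
    residue range plus an artificial N-terminal extension."""
    lo, hi = mature_range
    if hi < lo:
        raise ValueError(f"invalid residue range {mature_range}")
    return (hi - lo + 1) + len(n_extension)
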