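"""MSA handling, pairwise identity, per-column conservation, and the
two-group classification of ligand-contact positions.

Conservation is scored per column as the largest fraction of non-gap
sequences that fall in one residue class, where a class is either a single
residue type or one of the physicochemical similarity groups in
:data:`astatools.tables.SIMILARITY_GROUPS`. This frequency/similarity score
deliberately replaces phylogeny-aware conservation grading: the downstream
logic only needs conserved/variable calls per group.

Contact positions are then classified against two alignments — the ortholog
group with the ligand-binding function and the broad domain superfamily —
into four cells: conserved in both, variable in both, conserved only in the
ortholog group (the neofunctionalization signature), or conserved only
family-wide.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass

from Bio import AlignIO

from . import tables

Categories = ("both_conserved", "variable_in_both", "group_specific",
              "fas1_only")


@dataclass
class GroupedMSA:
    label: str
    sequences: dict[str, str]  # id -> aligned sequence, gap '-'
    reference: str
    ref_start: int = 1  # author number of the first reference residue

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError("aligned sequences differ in length")
        if self.reference not in self.sequences:
            raise KeyError(f"reference {self.reference!r} not in alignment")

    @property
    def width(self) -> int:
        return len(next(iter(self.sequences.values())))

    @property
    def column_map(self) -> dict[int, int]:
        """Reference residue number -> 1-based alignment column."""
        out: dict[int, int] = {}
        num = self.ref_start
        for col, ch in enumerate(self.sequences[self.reference], start=1):
            if ch != "-":
                out[num] = col
                num += 1
        return out

    def column(self, col: int) -> list[str]:
        """Residues (including gaps) of 1-based column ``col``."""
        if not 1 <= col <= self.width:
            raise IndexError(f"column {col} outside alignment width "
                             f"{self.width}")
        return [s[col - 1] for s in self.sequences.values()]


def read_msa(source, fmt: str = "fasta", label: str = "",
             reference: str | None = None, ref_start: int = 1) -> GroupedMSA:
    """Read an aligned FASTA or Clustal file/stream into a GroupedMSA.

    Sequences are upper-cased and '.' gaps normalized to '-'. The reference
    defaults to the first sequence.
    """
    if hasattr(source, "read"):
        handle = source
    elif "\n" in str(source):
        handle = io.StringIO(str(source))
    else:
        handle = open(source)
    try:
        aln = AlignIO.read(handle, fmt)
        records = [(rec.id, str(rec.seq)) for rec in aln]
    except ValueError:
        if fmt != "fasta":
            raise
        # re-read record-wise so the offending sequence can be named
        handle.seek(0)
        from Bio import SeqIO
        records = [(rec.id, str(rec.seq))
                   for rec in SeqIO.parse(handle, "fasta")]
    if len(records) < 2:
        raise ValueError("alignment must contain at least 2 sequences")
    seqs: dict[str, str] = {}
    for rid, seq in records:
        seqs[rid] = seq.upper().replace(".", "-")
    width = len(next(iter(seqs.values())))
    ragged = [i for i, s in seqs.items() if len(s) != width]
    if ragged:
        raise ValueError(f"ragged alignment; offending ids: {ragged}")
    return GroupedMSA(label or fmt, seqs, reference or next(iter(seqs)),
                      ref_start)


def pairwise_identity(msa: GroupedMSA, id_a: str, id_b: str) -> float:
    """Percent identity over columns where neither sequence is gapped."""
    try:
        a, b = msa.sequences[id_a], msa.sequences[id_b]
    except KeyError as exc:
        raise KeyError(f"unknown sequence id {exc}") from exc
    pairs = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
    if not pairs:
        return 0.0
    same = sum(1 for x, y in pairs if x == y)
    return 100.0 * same / len(pairs)


def _classes_for(residue: str,
                 groups: tuple[frozenset[str], ...]) -> list[frozenset[str]]:
    hits = [g for g in groups if residue in g]
    return hits if hits else [frozenset({residue})]


def column_conservation(
        msa: GroupedMSA, col: int,
        similarity_groups: tuple[frozenset[str], ...] = tables.SIMILARITY_GROUPS,
) -> tuple[float, str]:
    """Conservation score in [0, 1] and consensus residue for a column.

    Score = max over residue classes (single residues and similarity
    groups) of the fraction of non-gap sequences in that class; gaps are
    excluded from the denominator. An all-gap column scores 0.
    """
    residues = [r for r in msa.column(col) if r != "-"]
    if not residues:
        return 0.0, "-"
    counts = Counter(residues)
    consensus = max(sorted(counts), key=counts.get)
    best = counts[consensus] / len(residues)
    for group in similarity_groups:
        in_group = sum(n for r, n in counts.items() if r in group)
        best = max(best, in_group / len(residues))
    return best, consensus


@dataclass
class PositionClassification:
    position: int  # reference (author) residue number
    score_group: float  # ortholog-group conservation
    score_family: float  # superfamily-wide conservation
    category: str  # one of Categories
    consensus_group: str
    consensus_family: str


def classify_positions(
        positions: list[int],
        msa_group: GroupedMSA,
        msa_family: GroupedMSA,
        threshold: float = 0.8,
        similarity_groups: tuple[frozenset[str], ...] = tables.SIMILARITY_GROUPS,
) -> list[PositionClassification]:
    """Two-group conservation classification of contact positions.

    A position is conserved in a group when its column score meets
    ``threshold``. Cells: conserved in both -> ``both_conserved``; below in
    both -> ``variable_in_both``; conserved only in the ortholog group ->
    ``group_specific``; conserved only family-wide -> ``fas1_only``.
    """
    cmap_g = msa_group.column_map
    cmap_f = msa_family.column_map
    missing = [p for p in positions if p not in cmap_g or p not in cmap_f]
    if missing:
        raise KeyError(f"positions not mappable through both alignments: "
                       f"{missing}")
    out = []
    for pos in positions:
        sg, cg = column_conservation(msa_group, cmap_g[pos], similarity_groups)
        sf, cf = column_conservation(msa_family, cmap_f[pos], similarity_groups)
        if sg >= threshold and sf >= threshold:
            cat = "both_conserved"
        elif sg >= threshold:
            cat = "group_specific"
        elif sf >= threshold:
            cat = "fas1_only"
        else:
            cat = "variable_in_both"
        out.append(PositionClassification(pos, sg, sf, cat, cg, cf))
    return out
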