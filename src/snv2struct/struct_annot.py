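"""Structural context of a mapped residue.

For the residue a variant maps to, this module reports whether it contacts
protein, nucleic acid, ligand or metal entities (heavy-atom distance
criterion), whether it is in a disulphide bond (CYS SG-SG <= 2.5 A), whether
a local table lists it as catalytic, and how conserved its alignment column
is.  Context is aggregated over *all* qualifying structures, not just the
top hit: an interaction seen only in a homologous structure is still an
interaction, and restricting to a single representative structure would
discard it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from typing import Iterable, Sequence

import gemmi
from Bio.Align import substitution_matrices

from .config import Config
from .struct_map import AuthorResId, StructureHit, UNOBSERVED, map_residue, seqres_to_author

logger = logging.getLogger(__name__)

#: monoatomic ion residue names treated as metals
METALS = frozenset(
    {"LI", "NA", "K", "MG", "CA", "MN", "FE", "CO", "NI", "CU", "ZN", "MO", "W", "CD", "HG"}
)

STANDARD_AA = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)
NUCLEIC_RESIDUES = frozenset({"DA", "DC", "DG", "DT", "A", "C", "G", "U"})
WATER_RESIDUES = frozenset({"HOH", "WAT"})

CLASS_PROTEIN = "protein"
CLASS_NUCLEIC = "nucleic"
CLASS_LIGAND = "ligand"
CLASS_METAL = "metal"
CLASS_WATER = "water"

POLYMER_KINDS = ("polymer", "het")


def classify_entity(residue_name: str, chain_polymer_kind: str) -> str:
    """Classify a residue into protein/nucleic/ligand/metal/water.

    Classification is a pure function of the residue name and whether its
    chain is a polymer.  Metals are recognized by the monoatomic-ion naming
    convention (residue name == element symbol).
    """
    name = residue_name.upper().strip()
    if name in WATER_RESIDUES:
        return CLASS_WATER
    if chain_polymer_kind == "polymer":
        if name in STANDARD_AA:
            return CLASS_PROTEIN
        if name in NUCLEIC_RESIDUES:
            return CLASS_NUCLEIC
    if name in METALS:
        return CLASS_METAL
    return CLASS_LIGAND


@dataclass(frozen=True)
class ContactPartner:
    chain_id: str
    author_resid: AuthorResId
    residue_name: str
    entity_class: str
    distance: float


@dataclass
class ResidueContext:
    """Aggregated structural context of one mapped residue."""

    contacts_protein: bool = False
    contacts_nucleic: bool = False
    contacts_ligand: bool = False
    contacts_metal: bool = False
    disulphide_partner: AuthorResId | None = None
    is_catalytic: bool = False
    conservation: float | None = None
    #: per contact-class list of "PDBID_CHAIN" structure tags that contributed
    supporting_structures: dict[str, list[str]] = dc_field(default_factory=dict)

    def merge_flags(self, flags: set[str], tag: str) -> None:
        for cls in sorted(flags):
            attr = f"contacts_{cls}"
            setattr(self, attr, True)
            self.supporting_structures.setdefault(cls, [])
            if tag not in self.supporting_structures[cls]:
                self.supporting_structures[cls].append(tag)


def _reskey(res: gemmi.Residue) -> tuple[int, str]:
    return res.seqid.num, res.seqid.icode.strip()


def polymer_residue_indices(chain: gemmi.Chain) -> dict[tuple[int, str], int]:
    """1-based polymer order index per author residue id of the chain."""
    polymer = chain.get_polymer()
    return {_reskey(res): i for i, res in enumerate(polymer, start=1)}


def find_residue(
    model: gemmi.Model, chain_id: str, author_resid: AuthorResId
) -> gemmi.Residue | None:
    for chain in model:
        if chain.name != chain_id:
            continue
        for res in chain:
            if res.seqid.num == author_resid.num and res.seqid.icode.strip() == author_resid.icode:
                return res
    return None


def contacts(
    structure: gemmi.Structure,
    chain_id: str,
    author_resid: AuthorResId,
    cutoff: float = 4.0,
    protein_min_separation: int = 5,
) -> tuple[set[str], list[ContactPartner]]:
    """Contact classes of one residue by heavy-atom distance.

    A class flag is set iff any heavy atom of the residue lies within
    ``cutoff`` of a heavy atom of an entity of that class.  The residue
    itself is excluded; protein partners must sit on a different chain or at
    least ``protein_min_separation`` residues away along the same chain
    (tertiary contacts count, backbone neighbours do not).  Water never sets
    a flag.  A residue without coordinates has no contacts by definition.
    """
    model = structure[0]
    target = find_residue(model, chain_id, author_resid)
    if target is None:
        return set(), []
    target_atoms = [a for a in target if not a.is_hydrogen()]
    if not target_atoms:
        return set(), []

    chain_indices = {chain.name: polymer_residue_indices(chain) for chain in model}
    target_index = chain_indices.get(chain_id, {}).get(_reskey(target))

    ns = gemmi.NeighborSearch(model, structure.cell, max(5.0, cutoff + 1.0)).populate()
    flags: set[str] = set()
    partners: dict[tuple[str, tuple[int, str]], ContactPartner] = {}
    # pad the search radius: the cutoff itself is inclusive (dist <= cutoff
    # is checked exactly below), and the spatial index must not clip the
    # boundary case
    search_radius = cutoff + 0.01
    for atom in target_atoms:
        for mark in ns.find_atoms(atom.pos, "\0", radius=search_radius):
            cra = mark.to_cra(model)
            other = cra.residue
            if other is None or cra.atom.is_hydrogen():
                continue
            if cra.chain.name == chain_id and _reskey(other) == _reskey(target):
                continue
            dist = atom.pos.dist(cra.atom.pos)
            if dist > cutoff:
                continue
            other_index = chain_indices.get(cra.chain.name, {}).get(_reskey(other))
            in_polymer = other_index is not None
            cls = classify_entity(other.name, "polymer" if in_polymer else "het")
            if cls == CLASS_WATER:
                continue
            if cls == CLASS_PROTEIN:
                if (
                    cra.chain.name == chain_id
                    and target_index is not None
                    and other_index is not None
                    and abs(other_index - target_index) < protein_min_separation
                ):
                    continue
            flags.add(cls)
            key = (cra.chain.name, _reskey(other))
            prev = partners.get(key)
            if prev is None or dist < prev.distance:
                partners[key] = ContactPartner(
                    chain_id=cra.chain.name,
                    author_resid=AuthorResId(other.seqid.num, other.seqid.icode.strip()),
                    residue_name=other.name,
                    entity_class=cls,
                    distance=dist,
                )
    ordered = sorted(
        partners.values(), key=lambda p: (p.chain_id, p.author_resid.num, p.author_resid.icode)
    )
    return flags, ordered


def disulphides(
    structure: gemmi.Structure, cutoff: float = 2.5
) -> list[tuple[tuple[str, AuthorResId], tuple[str, AuthorResId]]]:
    """All unordered CYS-CYS pairs with SG-SG distance <= ``cutoff``."""
    model = structure[0]
    sg_atoms: list[tuple[str, AuthorResId, gemmi.Atom]] = []
    for chain in model:
        for res in chain:
            if res.name != "CYS":
                continue
            for atom in res:
                if atom.name == "SG":
                    sg_atoms.append(
                        (chain.name, AuthorResId(res.seqid.num, res.seqid.icode.strip()), atom)
                    )
    pairs = []
    for i in range(len(sg_atoms)):
        for j in range(i + 1, len(sg_atoms)):
            ci, ri, ai = sg_atoms[i]
            cj, rj, aj = sg_atoms[j]
            if (ci, ri) == (cj, rj):
                continue
            if ai.pos.dist(aj.pos) <= cutoff:
                pairs.append(((ci, ri), (cj, rj)))
    return pairs


def disulphide_partner_of(
    structure: gemmi.Structure, chain_id: str, author_resid: AuthorResId, cutoff: float = 2.5
) -> AuthorResId | None:
    for (c1, r1), (c2, r2) in disulphides(structure, cutoff):
        if (c1, r1) == (chain_id, author_resid):
            return r2
        if (c2, r2) == (chain_id, author_resid):
            return r1
    return None


# ---------------------------------------------------------------------------
# local annotation tables


def load_position_table(path: str) -> dict[tuple[str, int], str]:
    """Load a TSV of (isoform_id, aa_pos[, label]) rows.

    Returns {(isoform_id, aa_pos): label} with label "" for 2-column rows.
    """
    table: dict[tuple[str, int], str] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                continue
            try:
                pos = int(fields[1])
            except ValueError:
                continue  # header
            table[(fields[0], pos)] = fields[2] if len(fields) > 2 else ""
    return table


def catalytic_flag(
    table: dict[tuple[str, int], str], isoform_id: str, aa_pos: int
) -> bool:
    """Exact membership test against a local catalytic-residue table."""
    return (isoform_id, aa_pos) in table


# ---------------------------------------------------------------------------
# conservation


_CONS_MATRIX = None


def _blosum_bounds():
    global _CONS_MATRIX
    if _CONS_MATRIX is None:
        m = substitution_matrices.load("BLOSUM62")
        letters = [c for c in m.alphabet if c not in "BZX*"]
        vals = [m[a, b] for a in letters for b in letters]
        _CONS_MATRIX = (m, min(vals), max(vals))
    return _CONS_MATRIX


GAP_CHARS = frozenset("-.")


def scorecons(msa: Sequence[str], column_index: int) -> float | None:
    """Column conservation as a normalized sum-of-pairs score in [0, 1].

    The mean over all residue pairs (i < j) in the column of a BLOSUM62
    similarity rescaled to [0, 1] by s'(a,b) = (s(a,b) - min) / (max - min),
    where min/max run over the 20x20 standard-residue block.  Gap characters
    are excluded from pairing; a column with fewer than two residues has no
    defined conservation and yields ``None`` (absence, not zero).
    """
    if len(msa) < 2:
        raise ValueError("scorecons needs at least two aligned sequences")
    lengths = {len(row) for row in msa}
    if len(lengths) != 1:
        raise ValueError("alignment rows differ in length")
    if not 0 <= column_index < lengths.pop():
        raise IndexError(f"column {column_index} out of range")
    matrix, smin, smax = _blosum_bounds()
    column = [row[column_index].upper() for row in msa]
    residues = [c for c in column if c not in GAP_CHARS]
    if len(residues) < 2:
        return None
    total = 0.0
    npairs = 0
    for i in range(len(residues)):
        for j in range(i + 1, len(residues)):
            try:
                s = matrix[residues[i], residues[j]]
            except (KeyError, IndexError):
                s = smin
            total += (s - smin) / (smax - smin)
            npairs += 1
    return total / npairs


def load_msa(path: str) -> dict[str, str]:
    """Aligned FASTA -> {id: row}; all rows must have equal length."""
    from Bio import SeqIO

    rows = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}
    if rows and len({len(r) for r in rows.values()}) != 1:
        raise ValueError("MSA rows differ in length")
    return rows


def msa_column_for_position(row: str, aa_pos: int) -> int | None:
    """0-based MSA column holding the ``aa_pos``-th (1-based) residue of ``row``."""
    count = 0
    for col, ch in enumerate(row):
        if ch not in GAP_CHARS:
            count += 1
            if count == aa_pos:
                return col
    return None


def conservation_for_position(msa: dict[str, str], row_id: str, aa_pos: int) -> float | None:
    """Conservation of the column holding ``row_id``'s ``aa_pos``-th residue."""
    row = msa.get(row_id)
    if row is None:
        return None
    col = msa_column_for_position(row, aa_pos)
    if col is None:
        return None
    return scorecons(list(msa.values()), col)


# ---------------------------------------------------------------------------
# aggregation over structures


def residue_context(
    hits: Iterable[StructureHit],
    aa_pos: int,
    config: Config | None = None,
    isoform_id: str | None = None,
    catalytic_table: dict[tuple[str, int], str] | None = None,
    msa: dict[str, str] | None = None,
) -> ResidueContext:
    """Aggregate contact/disulphide context over all qualifying hits.

    Adding one more homologous structure can only add flags, never remove
    them; each flag records which structures support it.
    """
    cfg = config or Config()
    ctx = ResidueContext()
    for hit in hits:
        seq_index = map_residue(hit.alignment, aa_pos)
        if seq_index is None:
            continue
        author = seqres_to_author(hit.chain, seq_index)
        if author == UNOBSERVED or hit.chain.structure is None:
            continue
        tag = f"{hit.pdb_id}_{hit.chain_id}"
        flags, _ = contacts(
            hit.chain.structure,
            hit.chain_id,
            author,
            cutoff=cfg.contact_cutoff,
            protein_min_separation=cfg.protein_min_separation,
        )
        ctx.merge_flags(flags, tag)
        if ctx.disulphide_partner is None:
            partner = disulphide_partner_of(
                hit.chain.structure, hit.chain_id, author, cfg.disulphide_cutoff
            )
            if partner is not None:
                ctx.disulphide_partner = partner
                ctx.supporting_structures.setdefault("disulphide", []).append(tag)
    if isoform_id is not None and catalytic_table is not None:
        ctx.is_catalytic = catalytic_flag(catalytic_table, isoform_id, aa_pos)
    if isoform_id is not None and msa is not None:
        ctx.conservation = conservation_for_position(msa, isoform_id, aa_pos)
    return ctx
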