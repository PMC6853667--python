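"""Sequence-to-structure residue mapping.

The canonical isoform sequence is aligned against every structure chain
sequence with exact Smith-Waterman local alignment under an affine gap model
(a gap of length k costs ``gap_open + k * gap_extend``).  Hits are ranked by
an E-value surrogate

    E = K * m * n * exp(-lambda * score)        (K = 0.1, lambda = 0.27)

whose role is purely ordinal — "closest structure" means lowest E — with
ties broken by resolution (lower is better) then by PDB id + chain.  The
best alignment then carries a residue position from isoform numbering to
the structure's *author* residue numbering (the depositors' numbers, often
offset and sometimes carrying insertion codes), which is what a "position"
in a structure file means.

Chain sequences come from SEQRES records when present (the declared polymer
sequence, including residues without observed coordinates), else from
observed ATOM residues.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
from Bio.Align import substitution_matrices

from .config import Config

logger = logging.getLogger(__name__)

EVALUE_K = 0.1
EVALUE_LAMBDA = 0.27

#: marker for a SEQRES residue with no observed coordinates
UNOBSERVED = "unobserved"


# ---------------------------------------------------------------------------
# alignment


@dataclass(frozen=True)
class AlignmentResult:
    """A scored local alignment with an explicit position mapping.

    ``aligned_pairs`` lists (query_pos, target_pos), both 1-based, for
    match/mismatch columns only — gap columns map nothing.  Pairs are
    strictly increasing in both coordinates.
    """

    query_id: str
    target_id: str
    score: float
    aligned_pairs: tuple[tuple[int, int], ...]
    matches: int
    query_length: int
    target_length: int

    @property
    def identity_fraction(self) -> float:
        return self.matches / len(self.aligned_pairs) if self.aligned_pairs else 0.0

    @property
    def query_coverage(self) -> float:
        return len(self.aligned_pairs) / self.query_length if self.query_length else 0.0

    @property
    def evalue_surrogate(self) -> float:
        return EVALUE_K * self.query_length * self.target_length * math.exp(
            -EVALUE_LAMBDA * self.score
        )

    def map_query_position(self, query_pos: int) -> int | None:
        """Target sequence index aligned with ``query_pos``; None in gaps."""
        for q, t in self.aligned_pairs:
            if q == query_pos:
                return t
        return None

    def map_target_position(self, target_pos: int) -> int | None:
        for q, t in self.aligned_pairs:
            if t == target_pos:
                return q
        return None


def load_matrix(name: str):
    return substitution_matrices.load(name)


def align_local(
    query: str,
    target: str,
    matrix=None,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    query_id: str = "query",
    target_id: str = "target",
) -> AlignmentResult:
    """Optimal Smith-Waterman local alignment with affine gaps.

    Exact dynamic programming, no heuristics: at the scale of one isoform
    against a structure chain exactness is affordable, and the score is
    verifiable against any independent affine-gap DP.  Ties are broken
    deterministically (diagonal over target-gap over query-gap; lowest end
    coordinates first).
    """
    if not query or not target:
        raise ValueError("align_local requires two non-empty sequences")
    if matrix is None:
        matrix = load_matrix("BLOSUM62")
    n, m = len(query), len(target)
    gap_first = gap_open + gap_extend  # cost of the first base of a gap
    NEG = float("-inf")

    def sub(a: str, b: str) -> float:
        try:
            return matrix[a, b]
        except (KeyError, IndexError):
            return -1.0  # letter outside the matrix alphabet

    # H: best score ending at (i, j) with an aligned column; E: gap in query
    # (target consumed); F: gap in target (query consumed).
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best, best_ij = 0.0, (0, 0)
    for i in range(1, n + 1):
        qi = query[i - 1]
        Hi, Hi1, Ei, Fi, Fi1 = H[i], H[i - 1], E[i], F[i], F[i - 1]
        for j in range(1, m + 1):
            e = max(Hi[j - 1] - gap_first, Ei[j - 1] - gap_extend)
            f = max(Hi1[j] - gap_first, Fi1[j] - gap_extend)
            Ei[j], Fi[j] = e, f
            h = max(0.0, Hi1[j - 1] + sub(qi, target[j - 1]), e, f)
            Hi[j] = h
            if h > best:
                best, best_ij = h, (i, j)

    pairs: list[tuple[int, int]] = []
    matches = 0
    if best > 0:
        i, j = best_ij
        state = "H"
        while i > 0 and j > 0:
            if state == "H":
                h = H[i][j]
                if h == 0:
                    break
                s = sub(query[i - 1], target[j - 1])
                if h == H[i - 1][j - 1] + s:
                    pairs.append((i, j))
                    if query[i - 1] == target[j - 1]:
                        matches += 1
                    i, j = i - 1, j - 1
                elif h == E[i][j]:
                    state = "E"
                else:
                    state = "F"
            elif state == "E":
                if E[i][j] == H[i][j - 1] - gap_first:
                    state = "H"
                j -= 1
            else:
                if F[i][j] == H[i - 1][j] - gap_first:
                    state = "H"
                i -= 1
        pairs.reverse()
    return AlignmentResult(
        query_id=query_id,
        target_id=target_id,
        score=best,
        aligned_pairs=tuple(pairs),
        matches=matches,
        query_length=n,
        target_length=m,
    )


def map_residue(aln: AlignmentResult, query_pos: int) -> int | None:
    """Target sequence index for ``query_pos``; absent in gap columns."""
    if query_pos < 1:
        raise ValueError(f"query_pos must be >= 1: {query_pos}")
    return aln.map_query_position(query_pos)


# ---------------------------------------------------------------------------
# structure chains


@dataclass(frozen=True, order=True)
class AuthorResId:
    """Author residue number plus optional insertion code (e.g. 52A)."""

    num: int
    icode: str = ""

    def __str__(self) -> str:
        return f"{self.num}{self.icode}"

    @classmethod
    def parse(cls, text: str) -> "AuthorResId":
        text = text.strip()
        if text and text[-1].isalpha():
            return cls(int(text[:-1]), text[-1])
        return cls(int(text))


@dataclass
class StructureChain:
    """One polymer peptide chain of a structure file.

    ``sequence`` is the SEQRES-derived one-letter sequence when SEQRES is
    present, else the observed-residue sequence; ``author_ids`` maps the
    1-based sequence index of each *observed* residue to its author id —
    SEQRES residues without coordinates still occupy sequence indices but
    have no author id.
    """

    pdb_id: str
    chain_id: str
    sequence: str
    residue_names: tuple[str, ...]
    author_ids: dict[int, AuthorResId]
    resolution: float | None
    sequence_source: str  # "seqres" | "atom"
    structure: gemmi.Structure | None = field(default=None, repr=False, compare=False)

    def __len__(self) -> int:
        return len(self.sequence)


def _one_letter(resname: str) -> str:
    info = gemmi.find_tabulated_residue(resname)
    if info is None:
        return "X"
    code = info.one_letter_code.upper()
    return code if code.isalpha() else "X"


def load_structure(path: str | Path) -> gemmi.Structure:
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    st.assign_label_seq_id()
    return st


def chains_from_structure(st: gemmi.Structure, pdb_id: str | None = None) -> list[StructureChain]:
    """Extract every peptide polymer chain of the first model."""
    if pdb_id is None:
        pdb_id = (st.name.strip() or "XXXX").upper()
    resolution = st.resolution if st.resolution and st.resolution > 0 else None
    chains: list[StructureChain] = []
    model = st[0]
    for chain in model:
        polymer = chain.get_polymer()
        if len(polymer) == 0:
            continue
        ptype = polymer.check_polymer_type()
        if ptype not in (gemmi.PolymerType.PeptideL, gemmi.PolymerType.PeptideD):
            continue
        entity = st.get_entity_of(polymer)
        full_seq = list(entity.full_sequence) if entity is not None else []
        if full_seq:
            names = tuple(gemmi.Entity.first_mon(m) for m in full_seq)
            source = "seqres"
        else:
            names = tuple(res.name for res in polymer)
            source = "atom"
            logger.info(
                "%s chain %s has no SEQRES; sequence taken from observed residues",
                pdb_id,
                chain.name,
            )
        author_ids: dict[int, AuthorResId] = {}
        for idx, res in enumerate(polymer, start=1):
            seq_index = res.label_seq if res.label_seq is not None else idx
            icode = res.seqid.icode.strip()
            author_ids[seq_index] = AuthorResId(res.seqid.num, icode)
        chains.append(
            StructureChain(
                pdb_id=pdb_id,
                chain_id=chain.name,
                sequence="".join(_one_letter(n) for n in names),
                residue_names=names,
                author_ids=author_ids,
                resolution=resolution,
                sequence_source=source,
                structure=st,
            )
        )
    return chains


def load_structure_dir(directory: str | Path) -> list[StructureChain]:
    """Load every ``*.pdb`` / ``*.ent`` file in a directory."""
    directory = Path(directory)
    chains: list[StructureChain] = []
    for path in sorted(directory.iterdir()):
        if path.suffix.lower() not in (".pdb", ".ent"):
            continue
        st = load_structure(path)
        pdb_id = (st.name.strip() or path.stem).upper()
        chains.extend(chains_from_structure(st, pdb_id=pdb_id))
    return chains


def seqres_to_author(chain: StructureChain, seq_index: int) -> AuthorResId | str:
    """Author residue id of the ``seq_index``-th polymer residue.

    Residues declared in SEQRES but missing coordinates still occupy
    sequence indices; they map to the :data:`UNOBSERVED` marker.
    """
    if seq_index < 1 or seq_index > len(chain.sequence):
        raise IndexError(
            f"sequence index {seq_index} outside 1..{len(chain.sequence)} "
            f"for {chain.pdb_id} chain {chain.chain_id}"
        )
    return chain.author_ids.get(seq_index, UNOBSERVED)


# ---------------------------------------------------------------------------
# search and ranking


@dataclass(frozen=True)
class StructureHit:
    """One chain that passed the search floors, with its alignment."""

    pdb_id: str
    chain_id: str
    alignment: AlignmentResult
    resolution: float | None
    chain: StructureChain

    @property
    def target_id(self) -> str:
        return f"{self.pdb_id}_{self.chain_id}"


def search_structures(
    query_sequence: str,
    chains: list[StructureChain],
    config: Config | None = None,
    query_id: str = "query",
) -> list[StructureHit]:
    """Align the query against every chain and rank the qualifying hits.

    Ranking: E-value surrogate ascending, ties by resolution ascending
    (unknown resolution last), then PDB id + chain lexicographic — a total
    order, so input permutation never changes the output.  Chains below the
    identity or query-coverage floors are dropped.
    """
    cfg = config or Config()
    matrix = load_matrix(cfg.matrix)
    hits: list[StructureHit] = []
    for chain in chains:
        aln = align_local(
            query_sequence,
            chain.sequence,
            matrix=matrix,
            gap_open=cfg.gap_open,
            gap_extend=cfg.gap_extend,
            query_id=query_id,
            target_id=f"{chain.pdb_id}_{chain.chain_id}",
        )
        if not aln.aligned_pairs:
            continue
        if aln.identity_fraction < cfg.min_identity or aln.query_coverage < cfg.min_coverage:
            logger.debug(
                "dropping %s_%s: identity %.2f coverage %.2f below floors",
                chain.pdb_id,
                chain.chain_id,
                aln.identity_fraction,
                aln.query_coverage,
            )
            continue
        hits.append(
            StructureHit(
                pdb_id=chain.pdb_id,
                chain_id=chain.chain_id,
                alignment=aln,
                resolution=chain.resolution,
                chain=chain,
            )
        )
    hits.sort(
        key=lambda h: (
            h.alignment.evalue_surrogate,
            h.resolution if h.resolution is not None else float("inf"),
            h.pdb_id + h.chain_id,
        )
    )
    return hits


def map_hit_position(hit: StructureHit, aa_pos: int) -> tuple[AuthorResId | str | None, str | None]:
    """Map an isoform residue position through a hit's alignment.

    Returns (author residue id or UNOBSERVED or None, residue name or None);
    both None when the position falls in a gap or outside the alignment.
    """
    seq_index = map_residue(hit.alignment, aa_pos)
    if seq_index is None:
        return None, None
    return seqres_to_author(hit.chain, seq_index), hit.chain.residue_names[seq_index - 1]
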