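"""Protein isoform registry: loading, transcript pairing and validation.

Alternative splicing means one gene yields several transcripts, each
translating to a (possibly) different protein isoform with its own residue
numbering.  One isoform per gene may be flagged canonical — the reference
sequence against which residue numbering is conventionally reported.  This
module pairs transcripts to isoforms by *exact* translated-sequence
identity: a near-match silently renumbers residues, which is precisely the
failure mode this kind of mapping tool exists to prevent, so near-matches
are reported as ``none`` (with the edit distance logged) rather than
accepted.

FASTA header dialect: ``>ISO_ID GN=<gene_id> [CANON=1] ...``.  The
"select" transcript (the designated representative transcript of a gene,
whose translation may legitimately differ from the canonical isoform) is
marked in the GTF by a ``tag "select"`` attribute.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

from Bio import SeqIO

from .consequence import translate
from .gene_models import TranscriptModel, spliced_cds_sequence

logger = logging.getLogger(__name__)

VALID_AA = frozenset("ACDEFGHIKLMNPQRSTVWYX")

MATCH_EXACT = "exact"
MATCH_NONE = "none"

VALID_OK = "ok"
VALID_MISMATCH = "mismatch"
VALID_OUT_OF_RANGE = "out_of_range"


@dataclass(frozen=True)
class ProteinIsoform:
    isoform_id: str
    gene_id: str
    sequence: str
    is_canonical: bool = False
    source_tag: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"isoform {self.isoform_id}: empty sequence")
        bad = set(self.sequence) - VALID_AA
        if bad:
            raise ValueError(f"isoform {self.isoform_id}: invalid residues {sorted(bad)}")


@dataclass(frozen=True)
class PairingResult:
    transcript_id: str
    isoform_id: str | None
    match_kind: str


class IsoformLoadError(ValueError):
    pass


def load_isoforms(path: str) -> list[ProteinIsoform]:
    """Load isoforms from FASTA; enforce at most one canonical per gene."""
    isoforms: list[ProteinIsoform] = []
    canonical_seen: dict[str, str] = {}
    for record in SeqIO.parse(path, "fasta"):
        tokens = record.description.split()
        gene_id = "?"
        canonical = False
        for tok in tokens[1:]:
            if tok.startswith("GN="):
                gene_id = tok[3:]
            elif tok == "CANON=1":
                canonical = True
        if canonical:
            if gene_id in canonical_seen:
                raise IsoformLoadError(
                    f"gene {gene_id}: two canonical isoforms "
                    f"({canonical_seen[gene_id]} and {record.id})"
                )
            canonical_seen[gene_id] = record.id
        isoforms.append(
            ProteinIsoform(
                isoform_id=record.id,
                gene_id=gene_id,
                sequence=str(record.seq).upper(),
                is_canonical=canonical,
                source_tag=record.description,
            )
        )
    return isoforms


def canonical_for_gene(isoforms: Iterable[ProteinIsoform], gene_id: str) -> ProteinIsoform | None:
    for iso in isoforms:
        if iso.gene_id == gene_id and iso.is_canonical:
            return iso
    return None


def _edit_distance(a: str, b: str) -> int:
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def pair_transcripts(
    transcripts: Iterable[TranscriptModel],
    genome: Mapping[str, str],
    isoforms: Iterable[ProteinIsoform],
) -> list[PairingResult]:
    """Pair each coding transcript to isoforms by exact translation match.

    Two transcripts may pair to the same isoform; a transcript pairing
    several identical isoforms yields one result per equal isoform.
    """
    isoforms = list(isoforms)
    results: list[PairingResult] = []
    for tm in transcripts:
        if not tm.is_coding:
            results.append(PairingResult(tm.transcript_id, None, MATCH_NONE))
            continue
        protein = translate(spliced_cds_sequence(tm, genome))
        matched = [iso for iso in isoforms if iso.sequence == protein]
        if matched:
            for iso in matched:
                results.append(PairingResult(tm.transcript_id, iso.isoform_id, MATCH_EXACT))
        else:
            same_gene = [iso for iso in isoforms if iso.gene_id == tm.gene_id]
            if same_gene:
                nearest = min(same_gene, key=lambda iso: _edit_distance(protein, iso.sequence))
                logger.info(
                    "transcript %s matches no isoform exactly; nearest is %s "
                    "(edit distance %d)",
                    tm.transcript_id,
                    nearest.isoform_id,
                    _edit_distance(protein, nearest.sequence),
                )
            results.append(PairingResult(tm.transcript_id, None, MATCH_NONE))
    return results


def validate_position(iso: ProteinIsoform, aa_pos: int, expected_aa: str) -> str:
    """Check that the residue at ``aa_pos`` (1-based) is ``expected_aa``.

    This is the guard against silently renumbered isoforms: the amino acid
    the transcript mapping predicts must be the amino acid actually present
    in the isoform sequence at that position.
    """
    if aa_pos < 1:
        raise ValueError(f"aa_pos must be >= 1: {aa_pos}")
    if aa_pos > len(iso.sequence):
        return VALID_OUT_OF_RANGE
    return VALID_OK if iso.sequence[aa_pos - 1] == expected_aa else VALID_MISMATCH


def select_concordance(select_translation: str, canonical: ProteinIsoform) -> bool:
    """True iff the select transcript's translation equals the canonical sequence."""
    return select_translation == canonical.sequence
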