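"""Coding consequence calling for SNVs, per transcript.

The consequence of a substitution is called locally: the affected codon is
located through the spliced CDS coordinate, the alternate base substituted
(complemented on minus-strand transcripts, since the CDS is read off the
reverse strand), and the single codon retranslated.  The vocabulary is the
small closed set of SNV coding classes::

    synonymous missense stop_gained stop_lost start_lost
    intronic non_coding_exonic upstream_downstream non_coding_or_malformed

Splice-region classes are deliberately not called; an intronic variant is
"intronic" regardless of distance to the junction.  Protein changes are also
reported in HGVS p. notation with 3-letter residue codes ("Ter" for stops).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

from Bio.Data import CodonTable, IUPACData

from .gene_models import TranscriptModel, cds_to_protein, genomic_to_cds, spliced_cds_sequence
from .variant_io import GenomicVariant

logger = logging.getLogger(__name__)

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_FORWARD = dict(_TABLE.forward_table)
_STOPS = frozenset(_TABLE.stop_codons)
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

AA_1TO3 = {**IUPACData.protein_letters_1to3, "*": "Ter", "X": "Xaa"}

SYNONYMOUS = "synonymous"
MISSENSE = "missense"
STOP_GAINED = "stop_gained"
STOP_LOST = "stop_lost"
START_LOST = "start_lost"
INTRONIC = "intronic"
NON_CODING_EXONIC = "non_coding_exonic"
UPSTREAM_DOWNSTREAM = "upstream_downstream"
NON_CODING_OR_MALFORMED = "non_coding_or_malformed"

CODING_CLASSES = frozenset({SYNONYMOUS, MISSENSE, STOP_GAINED, STOP_LOST, START_LOST})


class TranslationError(ValueError):
    pass


def translate(cds: str) -> str:
    """Translate a CDS with the standard genetic code.

    The trailing stop codon is removed; an internal stop is retained as
    ``*`` (premature stops are information, not errors).  A codon containing
    a non-ACGT character raises :class:`TranslationError` naming the codon.
    """
    if len(cds) % 3 != 0:
        raise TranslationError(f"CDS length {len(cds)} is not a multiple of 3")
    aas: list[str] = []
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3].upper()
        if codon in _STOPS:
            aas.append("*")
        elif codon in _FORWARD:
            aas.append(_FORWARD[codon])
        else:
            raise TranslationError(f"untranslatable codon {codon!r} at CDS position {i + 1}")
    if aas and aas[-1] == "*":
        aas.pop()
    return "".join(aas)


@dataclass(frozen=True)
class ConsequenceRecord:
    """The coding consequence of one SNV on one transcript."""

    transcript_id: str
    consequence: str
    cds_pos: int | None = None
    aa_pos: int | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None
    ref_codon: str | None = None
    alt_codon: str | None = None

    @property
    def is_coding(self) -> bool:
        return self.consequence in CODING_CLASSES


def hgvs_p(rec: ConsequenceRecord) -> str:
    """HGVS protein-level description, e.g. ``p.Gly4Ala``.

    Synonymous changes are written ``p.(=)``; stop codons use ``Ter``.
    """
    if rec.aa_pos is None or rec.ref_aa is None or rec.alt_aa is None:
        raise ValueError(f"record for {rec.transcript_id} lacks protein-change fields")
    if rec.consequence == SYNONYMOUS:
        return "p.(=)"
    return f"p.{AA_1TO3[rec.ref_aa]}{rec.aa_pos}{AA_1TO3[rec.alt_aa]}"


def _codon_at(cds_seq: str, aa_pos: int) -> str:
    return cds_seq[(aa_pos - 1) * 3 : aa_pos * 3]


def call_consequence(
    tm: TranscriptModel, genome: Mapping[str, str], v: GenomicVariant
) -> ConsequenceRecord:
    """Call the consequence of ``v`` on one transcript.

    Non-coding outcomes are values, not errors: a position outside the CDS
    is classified by where it falls (exonic, intronic, or outside the
    transcript span), mirroring how an unmappable position still gets
    transcript-level information.
    """
    if not tm.is_coding:
        return ConsequenceRecord(tm.transcript_id, NON_CODING_OR_MALFORMED)
    coord = genomic_to_cds(tm, v.pos)
    if coord is None:
        if tm.contains_exonic(v.pos):
            return ConsequenceRecord(tm.transcript_id, NON_CODING_EXONIC)
        lo, hi = tm.span
        if lo <= v.pos <= hi:
            return ConsequenceRecord(tm.transcript_id, INTRONIC)
        return ConsequenceRecord(tm.transcript_id, UPSTREAM_DOWNSTREAM)

    cds_seq = spliced_cds_sequence(tm, genome)
    aa_pos, offset = cds_to_protein(coord.cds_pos)
    ref_codon = _codon_at(cds_seq, aa_pos)
    # On minus-strand transcripts the CDS reads the reverse strand, so the
    # substituted base is the complement of the genomic alt allele.
    alt_base = v.alt if tm.strand == "+" else _COMP[v.alt]
    alt_codon = ref_codon[:offset] + alt_base + ref_codon[offset + 1 :]

    ref_aa = "*" if ref_codon in _STOPS else _FORWARD[ref_codon]
    alt_aa = "*" if alt_codon in _STOPS else _FORWARD[alt_codon]

    if alt_codon in _STOPS and ref_codon not in _STOPS:
        consequence = STOP_GAINED
    elif ref_codon in _STOPS and alt_codon not in _STOPS:
        consequence = STOP_LOST
    elif aa_pos == 1 and ref_codon == "ATG" and alt_aa != "M":
        consequence = START_LOST
    elif ref_aa == alt_aa:
        consequence = SYNONYMOUS
    else:
        consequence = MISSENSE
    if aa_pos == 1 and ref_codon != "ATG":
        logger.info("transcript %s: non-ATG start codon %s", tm.transcript_id, ref_codon)

    return ConsequenceRecord(
        transcript_id=tm.transcript_id,
        consequence=consequence,
        cds_pos=coord.cds_pos,
        aa_pos=aa_pos,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
    )
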