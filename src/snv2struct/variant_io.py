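"""Variant input parsing and reference-allele validation.

The input is a tab-separated table of single-nucleotide variants, one per
line::

    chrom <TAB> pos [<TAB> identifier] <TAB> ref <TAB> alt

The identifier column is optional (4- or 5-field lines are accepted) and is
preserved verbatim into the output so that input and output lines can be
cross-referenced directly.  Coordinates are 1-based and fully closed (VCF
convention).  Only SNVs are accepted: a line whose ref or alt allele is not a
single A/C/G/T base is rejected, never silently dropped or fatal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import IO, Iterable, Mapping

from Bio import SeqIO

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")

#: reference-allele check statuses
REF_OK = "ok"
REF_MISMATCH = "mismatch"
REF_CHROM_MISSING = "chrom_missing"
REF_OUT_OF_RANGE = "out_of_range"


@dataclass(frozen=True)
class GenomicVariant:
    """One input SNV.

    ``chrom`` is stored exactly as given; matching against other resources
    strips an optional ``chr`` prefix on both sides.  ``pos`` is 1-based.
    ``user_id`` is an opaque string that round-trips unchanged to the output.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    user_id: str | None = None
    line_no: int = 0

    def __post_init__(self) -> None:
        if self.ref not in VALID_BASES or self.alt not in VALID_BASES:
            raise ValueError(f"alleles must be single A/C/G/T bases: {self.ref}/{self.alt}")
        if self.ref == self.alt:
            raise ValueError("ref equals alt")
        if self.pos < 1:
            raise ValueError(f"position must be positive: {self.pos}")


@dataclass(frozen=True)
class Rejection:
    """A malformed input line, kept with its line number and reason."""

    line_no: int
    line: str
    reason: str


def normalize_chrom(name: str) -> str:
    """Strip an optional ``chr`` prefix so mixed conventions still match."""
    lowered = name.lower()
    if lowered.startswith("chr"):
        return name[3:]
    return name


def _looks_like_header(fields: list[str]) -> bool:
    if len(fields) < 2:
        return False
    try:
        int(fields[1])
    except ValueError:
        return True
    return False


def parse_variant_table(
    stream: IO[str] | Iterable[str],
) -> tuple[list[GenomicVariant], list[Rejection]]:
    """Parse a tab-separated variant table.

    Every well-formed line yields one :class:`GenomicVariant`; malformed
    lines are collected as :class:`Rejection` records with the line number
    and a reason, never aborting the parse.  Lines beginning ``#`` are
    comments; a leading header line (non-numeric second column) is skipped
    with a logged notice.  Input order is preserved in both lists.
    """
    variants: list[GenomicVariant] = []
    rejections: list[Rejection] = []
    seen_data_line = False
    for line_no, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip():
            continue
        if line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if not seen_data_line and _looks_like_header(fields):
            logger.info("line %d looks like a header, skipping: %r", line_no, line)
            seen_data_line = True
            continue
        seen_data_line = True
        if len(fields) == 4:
            chrom, pos_s, ref, alt = fields
            user_id = None
        elif len(fields) == 5:
            chrom, pos_s, user_id, ref, alt = fields
        else:
            rejections.append(Rejection(line_no, line, f"expected 4 or 5 fields, got {len(fields)}"))
            continue
        try:
            pos = int(pos_s)
        except ValueError:
            rejections.append(Rejection(line_no, line, f"position is not an integer: {pos_s!r}"))
            continue
        if pos < 1:
            rejections.append(Rejection(line_no, line, f"position must be positive: {pos}"))
            continue
        ref = ref.strip().upper()
        alt = alt.strip().upper()
        if len(ref) != 1 or len(alt) != 1:
            rejections.append(Rejection(line_no, line, "not an SNV"))
            continue
        if ref not in VALID_BASES or alt not in VALID_BASES:
            rejections.append(Rejection(line_no, line, f"invalid allele {ref}/{alt}"))
            continue
        if ref == alt:
            rejections.append(Rejection(line_no, line, "ref equals alt"))
            continue
        variants.append(
            GenomicVariant(chrom=chrom, pos=pos, ref=ref, alt=alt, user_id=user_id, line_no=line_no)
        )
    return variants, rejections


def serialize_variant(v: GenomicVariant) -> str:
    """Inverse of :func:`parse_variant_table` for accepted lines."""
    if v.user_id is None:
        return f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}"
    return f"{v.chrom}\t{v.pos}\t{v.user_id}\t{v.ref}\t{v.alt}"


def load_genome_fasta(path: str) -> dict[str, str]:
    """Load a genome FASTA into a chromosome -> uppercase-sequence map.

    Keys are normalized with :func:`normalize_chrom`.
    """
    genome: dict[str, str] = {}
    for record in SeqIO.parse(path, "fasta"):
        genome[normalize_chrom(record.id)] = str(record.seq).upper()
    return genome


def check_reference_allele(v: GenomicVariant, genome: Mapping[str, str]) -> str:
    """Check one variant's ref allele against the supplied genome.

    A mismatch typically signals a wrong-assembly input.  Returns one of
    ``ok``, ``mismatch``, ``chrom_missing`` or ``out_of_range``.
    """
    seq = genome.get(normalize_chrom(v.chrom))
    if seq is None:
        return REF_CHROM_MISSING
    if v.pos > len(seq):
        return REF_OUT_OF_RANGE
    return REF_OK if seq[v.pos - 1] == v.ref else REF_MISMATCH


def check_reference_alleles(
    variants: Iterable[GenomicVariant], genome: Mapping[str, str]
) -> list[str]:
    """Per-variant reference check; mismatches never halt other variants."""
    return [check_reference_allele(v, genome) for v in variants]
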