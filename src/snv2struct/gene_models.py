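"""Splice-aware gene models and exact coordinate arithmetic.

A :class:`TranscriptModel` holds the ordered exon and CDS intervals of one
transcript.  All genomic intervals are 1-based, fully closed (GTF
convention).  "Transcript order" means ascending genomic coordinate on the
plus strand and descending on the minus strand; the spliced CDS position
(``cds_pos``) counts coding bases in transcript order starting at 1 at the
translation start, so ``cds_pos`` is what a codon/protein position is
computed from:

    aa_pos = ceil(cds_pos / 3),   codon_offset = (cds_pos - 1) mod 3

GTF files that follow the Ensembl convention of excluding the stop codon
from CDS features are normalized on load: adjacent ``stop_codon`` features
are absorbed so the stored CDS always includes the stop codon and the
multiple-of-3 invariant is uniform.  CDS phase (column 8) is recomputed from
interval arithmetic, never trusted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import gffutils

from .variant_io import normalize_chrom

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CdsCoordinate:
    """1-based offset into the spliced CDS of one transcript."""

    transcript_id: str
    cds_pos: int


@dataclass
class TranscriptModel:
    """Strand-aware exon/CDS interval structure for one transcript."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)
    biotype: str = "protein_coding"
    tags: frozenset[str] = frozenset()
    malformed_reason: str | None = None

    @property
    def is_coding(self) -> bool:
        return bool(self.cds) and self.malformed_reason is None

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    @property
    def span(self) -> tuple[int, int]:
        """Genomic extent covered by the transcript's exons."""
        return self.exons[0][0], self.exons[-1][1]

    def cds_in_transcript_order(self) -> list[tuple[int, int]]:
        if self.strand == "+":
            return list(self.cds)
        return list(reversed(self.cds))

    def contains_exonic(self, gpos: int) -> bool:
        return any(s <= gpos <= e for s, e in self.exons)

    def validate(self) -> None:
        """Check interval invariants; sets ``malformed_reason`` on failure."""
        for intervals, kind in ((self.exons, "exon"), (self.cds, "CDS")):
            for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
                if s2 <= e1:
                    self.malformed_reason = f"overlapping or unsorted {kind} intervals"
                    return
        for c in self.cds:
            if not any(s <= c[0] and c[1] <= e for s, e in self.exons):
                self.malformed_reason = f"CDS interval {c} outside any exon"
                return
        if self.cds and self.cds_length % 3 != 0:
            self.malformed_reason = f"CDS length {self.cds_length} not a multiple of 3"


def _merge_adjacent(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def parse_gtf(path_or_text: str, from_string: bool = False) -> list[TranscriptModel]:
    """Parse GTF into transcript models, one per ``transcript_id``.

    ``exon``, ``CDS`` and ``stop_codon`` features are read; stop codons are
    absorbed into the CDS.  Transcripts violating an invariant (CDS outside
    exons, CDS length not a multiple of 3) are flagged via
    ``malformed_reason`` rather than dropped, so the pipeline can still emit
    a row for them.
    """
    if from_string and not path_or_text.strip():
        return []
    db = gffutils.create_db(
        path_or_text,
        dbfn=":memory:",
        from_string=from_string,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    models: dict[str, TranscriptModel] = {}

    def get_model(feat) -> TranscriptModel:
        tid = feat.attributes["transcript_id"][0]
        if tid not in models:
            gid = feat.attributes.get("gene_id", ["?"])[0]
            biotype = feat.attributes.get(
                "transcript_biotype", feat.attributes.get("gene_biotype", ["protein_coding"])
            )[0]
            tags = frozenset(feat.attributes.get("tag", []))
            models[tid] = TranscriptModel(
                transcript_id=tid,
                gene_id=gid,
                chrom=normalize_chrom(feat.seqid),
                strand=feat.strand,
                biotype=biotype,
                tags=tags,
            )
        else:
            tags = feat.attributes.get("tag", [])
            if tags:
                models[tid].tags = models[tid].tags | frozenset(tags)
        return models[tid]

    stop_codons: dict[str, list[tuple[int, int]]] = {}
    for feat in db.all_features():
        ftype = feat.featuretype.lower()
        if ftype not in ("exon", "cds", "stop_codon", "transcript"):
            continue
        tm = get_model(feat)
        iv = (feat.start, feat.end)
        if ftype == "exon":
            tm.exons.append(iv)
        elif ftype == "cds":
            tm.cds.append(iv)
        elif ftype == "stop_codon":
            stop_codons.setdefault(tm.transcript_id, []).append(iv)

    out: list[TranscriptModel] = []
    for tid in sorted(models):
        tm = models[tid]
        tm.exons = _merge_adjacent(tm.exons)
        tm.cds = _merge_adjacent(tm.cds + stop_codons.get(tid, []))
        tm.validate()
        if tm.malformed_reason:
            logger.warning("transcript %s flagged: %s", tid, tm.malformed_reason)
        out.append(tm)
    return out


def genomic_to_cds(tm: TranscriptModel, gpos: int) -> CdsCoordinate | None:
    """Map a genomic position into the spliced CDS; ``None`` if non-coding.

    Absence is a value, not an error: intronic/UTR/intergenic positions
    simply have no CDS coordinate on this transcript.
    """
    offset = 0
    for s, e in tm.cds_in_transcript_order():
        if s <= gpos <= e:
            within = (gpos - s) if tm.strand == "+" else (e - gpos)
            return CdsCoordinate(tm.transcript_id, offset + within + 1)
        offset += e - s + 1
    return None


def cds_to_genomic(tm: TranscriptModel, cpos: int) -> int:
    """Exact inverse of :func:`genomic_to_cds` on its domain."""
    if cpos < 1 or cpos > tm.cds_length:
        raise ValueError(f"cds position {cpos} outside 1..{tm.cds_length}")
    offset = cpos - 1
    for s, e in tm.cds_in_transcript_order():
        n = e - s + 1
        if offset < n:
            return s + offset if tm.strand == "+" else e - offset
        offset -= n
    raise AssertionError("unreachable")


def cds_to_protein(cpos: int) -> tuple[int, int]:
    """CDS position -> (1-based residue index, codon offset in {0,1,2})."""
    if cpos < 1:
        raise ValueError(f"cds position must be >= 1: {cpos}")
    return (cpos + 2) // 3, (cpos - 1) % 3


def spliced_cds_sequence(tm: TranscriptModel, genome: Mapping[str, str]) -> str:
    """Concatenated CDS sequence in transcript order (revcomp on minus)."""
    chrom = normalize_chrom(tm.chrom)
    if chrom not in genome:
        raise ValueError(f"chromosome {tm.chrom} absent from genome")
    seq = genome[chrom]
    parts: list[str] = []
    for s, e in sorted(tm.cds):
        if e > len(seq):
            raise ValueError(
                f"transcript {tm.transcript_id}: CDS interval ({s},{e}) beyond "
                f"chromosome end {len(seq)}"
            )
        parts.append(seq[s - 1 : e])
    forward = "".join(parts)
    return forward if tm.strand == "+" else reverse_complement(forward)
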