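"""End-to-end annotation: variants -> transcripts -> isoforms -> structure.

For each input variant the pipeline emits exactly one output row per
overlapping transcript (the transcript-isoform pairs are *all* annotated,
not just the reference one — a variant may only be interpretable on a
non-canonical isoform), plus a ``no_transcript`` row when nothing overlaps.
A failure at any stage degrades that variant's rows (a status column is
set, downstream blocks stay empty) and never affects other variants.

The output is a rectangular tab-separated table with a fixed, documented
column order; empty fields are written ``-``; the user-supplied identifier
is echoed verbatim so input and output lines can be cross-referenced.  The
same module reads the format back (``read_tsv`` is the inverse of
``write_tsv``), which is what makes the file greppable/sortable downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable

from .config import Config
from .consequence import ConsequenceRecord, call_consequence, hgvs_p, translate
from .gene_models import TranscriptModel, parse_gtf, spliced_cds_sequence
from .isoform_registry import (
    MATCH_EXACT,
    ProteinIsoform,
    VALID_OK,
    load_isoforms,
    pair_transcripts,
    select_concordance,
    validate_position,
)
from .struct_annot import load_msa, load_position_table, residue_context
from .struct_map import StructureChain, StructureHit, load_structure_dir, map_hit_position, search_structures
from .variant_io import (
    GenomicVariant,
    REF_OK,
    check_reference_allele,
    load_genome_fasta,
    normalize_chrom,
    parse_variant_table,
)

logger = logging.getLogger(__name__)

MISSING = "-"

#: fixed output column order (passthrough columns are appended verbatim)
CORE_COLUMNS = [
    "chrom", "pos", "user_id", "ref", "alt", "ref_check",
    "gene_id", "transcript_id", "biotype", "consequence",
    "cds_pos", "aa_pos", "ref_codon", "alt_codon", "ref_aa", "alt_aa", "hgvs_p",
    "isoform_id", "canonical", "validation", "select_vs_canonical",
    "pdb_id", "chain", "author_resid", "residue_name", "resolution",
    "identity", "coverage",
    "contact_protein", "contact_nucleic", "contact_ligand", "contact_metal",
    "disulphide_partner", "catalytic", "conservation", "disease",
]

AnnotationRow = dict  # column name -> string value; MISSING for empty


@dataclass
class AnnotationTable:
    columns: list[str]
    rows: list[AnnotationRow]


@dataclass
class Resources:
    """All loaded reference data the pipeline runs against."""

    genome: dict[str, str]
    transcripts: list[TranscriptModel]
    isoforms: list[ProteinIsoform]
    chains: list[StructureChain] = field(default_factory=list)
    msa: dict[str, str] | None = None
    catalytic: dict[tuple[str, int], str] | None = None
    disease: dict[tuple[str, int], str] | None = None
    passthrough_columns: list[str] = field(default_factory=list)
    passthrough: dict[tuple[str, int], list[str]] = field(default_factory=dict)

    @classmethod
    def load(
        cls,
        genome: str | Path,
        gtf: str | Path,
        isoforms: str | Path,
        structures: str | Path | None = None,
        msa: str | Path | None = None,
        catalytic: str | Path | None = None,
        disease: str | Path | None = None,
        passthrough: str | Path | None = None,
    ) -> "Resources":
        """Load and validate every resource; fails before any annotation."""
        for label, p in (("genome", genome), ("gtf", gtf), ("isoforms", isoforms)):
            if not Path(p).exists():
                raise FileNotFoundError(f"{label} file not found: {p}")
        res = cls(
            genome=load_genome_fasta(str(genome)),
            transcripts=parse_gtf(str(gtf)),
            isoforms=load_isoforms(str(isoforms)),
        )
        if structures is not None:
            res.chains = load_structure_dir(structures)
        if msa is not None:
            res.msa = load_msa(str(msa))
        if catalytic is not None:
            res.catalytic = load_position_table(str(catalytic))
        if disease is not None:
            res.disease = load_position_table(str(disease))
        if passthrough is not None:
            res.passthrough_columns, res.passthrough = _load_passthrough(str(passthrough))
        return res


def _load_passthrough(path: str) -> tuple[list[str], dict[tuple[str, int], list[str]]]:
    """TSV keyed by (chrom, pos); header row names the extra columns."""
    columns: list[str] = []
    table: dict[tuple[str, int], list[str]] = {}
    with open(path) as fh:
        for i, raw in enumerate(fh):
            fields = raw.rstrip("\n").split("\t")
            if i == 0:
                columns = fields[2:]
                continue
            if len(fields) < 2 or not fields[0].strip():
                continue
            table[(normalize_chrom(fields[0]), int(fields[1]))] = fields[2:]
    return columns, table


def _fmt(value, fmt: str | None = None) -> str:
    if value is None:
        return MISSING
    if fmt:
        return fmt % value
    return str(value)


def _empty_row(columns: list[str]) -> AnnotationRow:
    return {c: MISSING for c in columns}


def annotate(
    variants: Iterable[GenomicVariant],
    resources: Resources,
    config: Config | None = None,
) -> AnnotationTable:
    """Annotate every variant against every overlapping transcript.

    Stage order per variant: reference-allele check, per-transcript
    consequence, isoform pairing and position validation, then — on the
    canonical-isoform row only — structure search, residue mapping and
    structural context.  Rows are ordered by input line, then transcript id.
    """
    cfg = config or Config()
    columns = CORE_COLUMNS + list(resources.passthrough_columns)

    # --- gene-level precomputation (variant-independent)
    translations: dict[str, str] = {}
    for tm in resources.transcripts:
        if tm.is_coding:
            try:
                translations[tm.transcript_id] = translate(spliced_cds_sequence(tm, resources.genome))
            except ValueError as exc:
                logger.warning("cannot translate %s: %s", tm.transcript_id, exc)

    pairings: dict[str, list[str]] = {}
    for pr in pair_transcripts(resources.transcripts, resources.genome, resources.isoforms):
        if pr.match_kind == MATCH_EXACT and pr.isoform_id is not None:
            pairings.setdefault(pr.transcript_id, []).append(pr.isoform_id)
    iso_by_id = {iso.isoform_id: iso for iso in resources.isoforms}
    canonical_by_gene: dict[str, ProteinIsoform] = {
        iso.gene_id: iso for iso in resources.isoforms if iso.is_canonical
    }

    concordance_by_gene: dict[str, str] = {}
    hits_by_gene: dict[str, list[StructureHit]] = {}
    genes = sorted({tm.gene_id for tm in resources.transcripts})
    for gene in genes:
        canonical = canonical_by_gene.get(gene)
        select_tx = [
            tm for tm in resources.transcripts if tm.gene_id == gene and "select" in tm.tags
        ]
        if canonical is None or not select_tx or select_tx[0].transcript_id not in translations:
            concordance_by_gene[gene] = "unknown"
        else:
            same = select_concordance(translations[select_tx[0].transcript_id], canonical)
            concordance_by_gene[gene] = "identical" if same else "different"
        if canonical is not None and resources.chains:
            hits_by_gene[gene] = search_structures(
                canonical.sequence, resources.chains, cfg, query_id=canonical.isoform_id
            )

    by_chrom: dict[str, list[TranscriptModel]] = {}
    for tm in resources.transcripts:
        by_chrom.setdefault(normalize_chrom(tm.chrom), []).append(tm)

    rows: list[AnnotationRow] = []
    for v in sorted(variants, key=lambda v: v.line_no):
        base = _empty_row(columns)
        base.update(
            chrom=v.chrom,
            pos=str(v.pos),
            user_id=v.user_id if v.user_id is not None else MISSING,
            ref=v.ref,
            alt=v.alt,
        )
        for col, val in zip(resources.passthrough_columns,
                            resources.passthrough.get((normalize_chrom(v.chrom), v.pos), [])):
            base[col] = val if val != "" else MISSING
        status = check_reference_allele(v, resources.genome)
        base["ref_check"] = status

        overlapping = sorted(
            (
                tm
                for tm in by_chrom.get(normalize_chrom(v.chrom), [])
                if tm.span[0] - cfg.transcript_flank <= v.pos <= tm.span[1] + cfg.transcript_flank
            ),
            key=lambda tm: tm.transcript_id,
        )
        if not overlapping:
            row = dict(base)
            row["consequence"] = "no_transcript"
            rows.append(row)
            continue
        for tm in overlapping:
            row = dict(base)
            row["gene_id"] = tm.gene_id
            row["transcript_id"] = tm.transcript_id
            row["biotype"] = tm.biotype
            row["select_vs_canonical"] = concordance_by_gene.get(tm.gene_id, "unknown")
            if status != REF_OK:
                row["validation"] = f"ref_{status}"
                rows.append(row)
                continue
            try:
                rec = call_consequence(tm, resources.genome, v)
            except ValueError as exc:
                logger.warning("consequence failed for %s/%s: %s", v.pos, tm.transcript_id, exc)
                row["consequence"] = "error"
                rows.append(row)
                continue
            _fill_consequence(row, rec)
            matched = sorted(pairings.get(tm.transcript_id, []))
            canonical = canonical_by_gene.get(tm.gene_id)
            is_canonical_row = canonical is not None and canonical.isoform_id in matched
            if matched:
                row["isoform_id"] = ",".join(matched)
                row["canonical"] = "yes" if is_canonical_row else "no"
            validation = MISSING
            if matched and rec.aa_pos is not None and rec.ref_aa is not None:
                validation = validate_position(iso_by_id[matched[0]], rec.aa_pos, rec.ref_aa)
                row["validation"] = validation
                for iso_id in matched:
                    label = (resources.disease or {}).get((iso_id, rec.aa_pos))
                    if label is not None:
                        row["disease"] = label or "yes"
                        break
            if is_canonical_row and rec.aa_pos is not None and validation == VALID_OK:
                _fill_structure(row, hits_by_gene.get(tm.gene_id, []), rec, canonical, resources, cfg)
            rows.append(row)
    return AnnotationTable(columns=columns, rows=rows)


def _fill_consequence(row: AnnotationRow, rec: ConsequenceRecord) -> None:
    row["consequence"] = rec.consequence
    row["cds_pos"] = _fmt(rec.cds_pos)
    row["aa_pos"] = _fmt(rec.aa_pos)
    row["ref_codon"] = _fmt(rec.ref_codon)
    row["alt_codon"] = _fmt(rec.alt_codon)
    row["ref_aa"] = _fmt(rec.ref_aa)
    row["alt_aa"] = _fmt(rec.alt_aa)
    if rec.is_coding:
        row["hgvs_p"] = hgvs_p(rec)


def _fill_structure(
    row: AnnotationRow,
    hits: list[StructureHit],
    rec: ConsequenceRecord,
    canonical: ProteinIsoform,
    resources: Resources,
    cfg: Config,
) -> None:
    aa_pos = rec.aa_pos
    assert aa_pos is not None
    ctx = residue_context(
        hits,
        aa_pos,
        cfg,
        isoform_id=canonical.isoform_id,
        catalytic_table=resources.catalytic,
        msa=resources.msa,
    )
    if resources.catalytic is not None:
        row["catalytic"] = "yes" if ctx.is_catalytic else "no"
    if ctx.conservation is not None:
        row["conservation"] = _fmt(ctx.conservation, "%.4f")
    if not hits:
        return
    top = hits[0]
    author, resname = map_hit_position(top, aa_pos)
    row["pdb_id"] = top.pdb_id
    row["chain"] = top.chain_id
    row["author_resid"] = _fmt(author)
    row["residue_name"] = _fmt(resname)
    row["resolution"] = _fmt(top.resolution, "%.2f")
    row["identity"] = _fmt(top.alignment.identity_fraction, "%.3f")
    row["coverage"] = _fmt(top.alignment.query_coverage, "%.3f")
    row["contact_protein"] = "yes" if ctx.contacts_protein else "no"
    row["contact_nucleic"] = "yes" if ctx.contacts_nucleic else "no"
    row["contact_ligand"] = "yes" if ctx.contacts_ligand else "no"
    row["contact_metal"] = "yes" if ctx.contacts_metal else "no"
    row["disulphide_partner"] = _fmt(ctx.disulphide_partner)


# ---------------------------------------------------------------------------
# TSV I/O


def write_tsv(table: AnnotationTable, stream: IO[str]) -> None:
    """Write the rectangular output; inverse of :func:`read_tsv`."""
    stream.write("\t".join(table.columns) + "\n")
    for row in table.rows:
        stream.write("\t".join(row.get(c, MISSING) for c in table.columns) + "\n")


def read_tsv(stream: IO[str]) -> AnnotationTable:
    """Parse a file produced by :func:`write_tsv`."""
    header = stream.readline().rstrip("\n")
    if not header:
        return AnnotationTable(columns=[], rows=[])
    columns = header.split("\t")
    rows: list[AnnotationRow] = []
    for line_no, raw in enumerate(stream, start=2):
        line = raw.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) != len(columns):
            raise ValueError(
                f"line {line_no}: expected {len(columns)} columns, got {len(fields)}"
            )
        rows.append(dict(zip(columns, fields)))
    return AnnotationTable(columns=columns, rows=rows)


def run(
    variants_path: str | Path,
    resources: Resources,
    out_path: str | Path,
    config: Config | None = None,
) -> tuple[AnnotationTable, list]:
    """Parse variants, annotate, and write the TSV; returns (table, rejections)."""
    with open(variants_path) as fh:
        variants, rejections = parse_variant_table(fh)
    for rej in rejections:
        logger.warning("rejected input line %d (%s): %s", rej.line_no, rej.reason, rej.line)
    table = annotate(variants, resources, config)
    with open(out_path, "w") as out:
        write_tsv(table, out)
    logger.info(
        "annotated %d variants -> %d rows (%d input lines rejected)",
        len(variants),
        len(table.rows),
        len(rejections),
    )
    return table, rejections
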