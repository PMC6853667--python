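"""Deterministic synthetic fixtures: locus, isoforms, structures, tables.

The generator builds the classic alternative-splicing scenario end to end,
with every ground-truth expectation recorded in a manifest *by
construction* (never by running the pipeline):

* one gene on "chromosome 12" with four coding exons and three transcripts:
  transcript TR1 uses all exons and is tagged the select transcript, TR2
  lacks exon 3, TR3 lacks exon 2 and translates to the canonical isoform;
* one missense SNV inside exon 3 at genomic position 123456 (DNA change
  G/C) — it therefore maps to protein positions on TR1 and TR3 but not TR2;
* three protein isoforms (exact translations), ISO3 flagged canonical;
* three structures: an exact-match chain for ISO3 with offset author
  numbering, one insertion code and one unobserved terminal residue; a
  ~70%-identity homolog; and a decoy below the search floors.  Placed
  entities exercise every contact class (ZN, ligand, DNA chain, a peptide
  chain), a true disulphide at 2.05 A and a negative CYS pair at 4.0 A.

Topology is hard-coded — it is the thing under test — while sequence
content is seeded-random with the functionally important codons forced.
Exon coding lengths are multiples of 3 so no codon spans a junction and
removing an exon can never introduce a frameshift or premature stop.
Regeneration with the same seed is byte-identical.  ``strand="-"``
reflects every genomic coordinate (g -> L+1-g) and reverse-complements the
chromosome, which flips all coordinate arithmetic while leaving every
protein-level expectation unchanged.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

from .config import Config
from .consequence import AA_1TO3, translate
from .gene_models import reverse_complement
from .struct_map import align_local, load_matrix

GENE_ID = "GENE1"
CHROM = "12"
VARIANT_POS_PLUS = 123456
VARIANT_ID = "var1"

#: codons per coding exon (all multiples of 3 nt)
EXON_CODONS = (10, 12, 15, 13)
UTR5_LEN = 6
UTR3_LEN = 6
INTRON_LENS = (30, 40, 35)
FLANK = 10

#: which exons each transcript uses (1-based exon numbers)
TRANSCRIPT_EXONS = {"TR1": (1, 2, 3, 4), "TR2": (1, 2, 4), "TR3": (1, 3, 4)}
SELECT_TRANSCRIPT = "TR1"
CANONICAL_ISOFORM = "ISO3"
TRANSCRIPT_ISOFORM = {"TR1": "ISO1", "TR2": "ISO2", "TR3": "ISO3"}

#: engineered residue positions, numbered on the canonical isoform (ISO3)
POS_CYS_BOND = (4, 31)  # SG-SG at 2.05 A -> disulphide
POS_CYS_FAR = (8, 34)  # SG-SG at 4.0 A -> not a disulphide
POS_CLEAN = 6  # nearest foreign atom at cutoff + 0.5 A -> no flags
POS_DNA = 12
POS_VARIANT = 16  # GGA codon; middle base G>C -> Gly>Ala
POS_LIGAND = 20
POS_PROTEIN = 24
POS_METAL = 28  # forced His; ZN at 2.1 A from NE2

#: variant codon: exon 3, 6th codon, middle base
VARIANT_EXON = 3
VARIANT_CODON_IN_EXON = 6
VARIANT_CODON_OFFSET = 1

_STOPS = ("TAA", "TAG", "TGA")
_BASES = "ACGT"
#: random codon pool: non-stop, non-cysteine (cysteines are engineered only,
#: so disulphide and metal-proximity expectations hold by construction)
_CODON_POOL = tuple(
    sorted(
        a + b + c
        for a in _BASES
        for b in _BASES
        for c in _BASES
        if a + b + c not in _STOPS + ("TGT", "TGC")
    )
)

_AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: homolog (2BBB) mutated positions — disjoint from engineered positions,
#: 11 of 37 residues -> about 70% identity
HOMOLOG_MUTATED = (2, 3, 5, 9, 13, 18, 22, 26, 30, 33, 36)

#: MSA homolog rows: mutated positions per row (variant column untouched)
MSA_MUTATIONS = {"HOM1": (3, 7, 21), "HOM2": (5, 11, 30), "HOM3": (9, 26, 33)}


@dataclass
class FixtureBundle:
    """Paths of a generated fixture set plus its ground-truth manifest."""

    root: Path
    genome: Path
    gtf: Path
    isoforms: Path
    variants: Path
    structures: list[Path] = field(default_factory=list)
    msa: Path | None = None
    catalytic: Path | None = None
    disease: Path | None = None
    passthrough: Path | None = None
    manifest: dict = field(default_factory=dict)

    @property
    def structure_dir(self) -> Path:
        return self.structures[0].parent if self.structures else self.root / "structures"

    def write_manifest(self) -> Path:
        path = self.root / "manifest.json"
        path.write_text(json.dumps(self.manifest, indent=2, sort_keys=True) + "\n")
        return path


# ---------------------------------------------------------------------------
# sequence design


def _dissimilar(aa: str, shift: int = 7) -> str:
    """Deterministic residue substitution, never identity and never CYS."""
    idx = _AA20.index(aa)
    out = _AA20[(idx + shift) % 20]
    while out == aa or out == "C":
        idx += 1
        out = _AA20[(idx + shift) % 20]
    return out


@dataclass
class LocusDesign:
    """Seeded sequence content on the fixed exon topology."""

    exon_codons: list[list[str]]  # per exon, list of codon strings
    isoform_seqs: dict[str, str]  # translations, stop removed
    variant_ref: str  # genomic plus-strand ref base
    variant_alt: str

    def transcript_cds(self, tid: str) -> str:
        return "".join(
            "".join(self.exon_codons[e - 1]) for e in TRANSCRIPT_EXONS[tid]
        )


def _design_locus(rng: random.Random) -> LocusDesign:
    exon_codons: list[list[str]] = []
    for n in EXON_CODONS:
        exon_codons.append([rng.choice(_CODON_POOL) for _ in range(n)])
    # forced codons (exon index, codon index both 1-based)
    exon_codons[0][0] = "ATG"  # start
    exon_codons[3][-1] = "TAA"  # stop
    exon_codons[2][VARIANT_CODON_IN_EXON - 1] = "GGA"  # variant codon, Gly
    # canonical-isoform positions: exon1 codon k -> k; exon3 codon k -> 10+k;
    # exon4 codon k -> 25+k
    exon_codons[0][POS_CYS_BOND[0] - 1] = "TGT"
    exon_codons[0][POS_CYS_FAR[0] - 1] = "TGT"
    exon_codons[3][POS_METAL - 26] = "CAC"  # His
    exon_codons[3][POS_CYS_BOND[1] - 26] = "TGT"
    exon_codons[3][POS_CYS_FAR[1] - 26] = "TGT"

    iso_seqs = {}
    for tid, iso in TRANSCRIPT_ISOFORM.items():
        cds = "".join("".join(exon_codons[e - 1]) for e in TRANSCRIPT_EXONS[tid])
        iso_seqs[iso] = translate(cds)
    return LocusDesign(
        exon_codons=exon_codons,
        isoform_seqs=iso_seqs,
        variant_ref="G",
        variant_alt="C",
    )


# ---------------------------------------------------------------------------
# genomic layout (plus strand; minus strand is an exact reflection)


@dataclass(frozen=True)
class PlusLayout:
    chrom_length: int
    exons: tuple[tuple[int, int], ...]  # incl. UTRs on exons 1 and 4
    cds: tuple[tuple[int, int], ...]  # incl. stop codon
    variant_pos: int


def _plus_layout() -> PlusLayout:
    cds_lens = [n * 3 for n in EXON_CODONS]
    # anchor: exon 3 starts so that its (VARIANT_CODON_IN_EXON, offset) base
    # lands on VARIANT_POS_PLUS
    within = (VARIANT_CODON_IN_EXON - 1) * 3 + VARIANT_CODON_OFFSET  # 0-based
    e3_start = VARIANT_POS_PLUS - within
    e2_end = e3_start - INTRON_LENS[1] - 1
    e2_start = e2_end - cds_lens[1] + 1
    e1_cds_end = e2_start - INTRON_LENS[0] - 1
    e1_cds_start = e1_cds_end - cds_lens[0] + 1
    e1_start = e1_cds_start - UTR5_LEN
    e3_end = e3_start + cds_lens[2] - 1
    e4_start = e3_end + INTRON_LENS[2] + 1
    e4_cds_end = e4_start + cds_lens[3] - 1
    e4_end = e4_cds_end + UTR3_LEN
    exons = ((e1_start, e1_cds_end), (e2_start, e2_end), (e3_start, e3_end), (e4_start, e4_end))
    cds = ((e1_cds_start, e1_cds_end), (e2_start, e2_end), (e3_start, e3_end),
           (e4_start, e4_cds_end))
    return PlusLayout(
        chrom_length=e4_end + FLANK,
        exons=exons,
        cds=cds,
        variant_pos=VARIANT_POS_PLUS,
    )


def _reflect_interval(iv: tuple[int, int], length: int) -> tuple[int, int]:
    s, e = iv
    return length + 1 - e, length + 1 - s


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


# ---------------------------------------------------------------------------
# file writers


def _write_fasta(path: Path, records: list[tuple[str, str]], width: int = 60) -> None:
    with open(path, "w") as fh:
        for header, seq in records:
            fh.write(f">{header}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _gtf_attrs(gene: str, transcript: str | None = None, tags: tuple[str, ...] = ()) -> str:
    parts = [f'gene_id "{gene}";']
    if transcript:
        parts.append(f'transcript_id "{transcript}";')
        parts.append('transcript_biotype "protein_coding";')
    for t in tags:
        parts.append(f'tag "{t}";')
    return " ".join(parts)


def _write_gtf(
    path: Path,
    strand: str,
    exons_by_tx: dict[str, list[tuple[int, int]]],
    cds_by_tx: dict[str, list[tuple[int, int]]],
    stop_by_tx: dict[str, tuple[int, int]],
) -> None:
    lines = []

    def feat(ftype: str, iv: tuple[int, int], attrs: str, frame: str = ".") -> str:
        return f"{CHROM}\tfixture\t{ftype}\t{iv[0]}\t{iv[1]}\t.\t{strand}\t{frame}\t{attrs}"

    gene_lo = min(iv[0] for ivs in exons_by_tx.values() for iv in ivs)
    gene_hi = max(iv[1] for ivs in exons_by_tx.values() for iv in ivs)
    lines.append(feat("gene", (gene_lo, gene_hi), _gtf_attrs(GENE_ID)))
    for tid in sorted(exons_by_tx):
        tags = ("select",) if tid == SELECT_TRANSCRIPT else ()
        exons = sorted(exons_by_tx[tid])
        span = (exons[0][0], exons[-1][1])
        lines.append(feat("transcript", span, _gtf_attrs(GENE_ID, tid, tags)))
        for iv in exons:
            lines.append(feat("exon", iv, _gtf_attrs(GENE_ID, tid)))
        for iv in sorted(cds_by_tx[tid]):
            lines.append(feat("CDS", iv, _gtf_attrs(GENE_ID, tid), frame="0"))
        lines.append(feat("stop_codon", stop_by_tx[tid], _gtf_attrs(GENE_ID, tid), frame="0"))
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# locus generation


def make_alt_splicing_locus(out_dir: str | Path, seed: int = 0, strand: str = "+") -> FixtureBundle:
    """Generate genome, GTF, isoform FASTA and variant table.

    The manifest records, by construction: the expected consequence on every
    transcript, protein positions and HGVS strings, isoform pairing, the
    select-vs-canonical verdict, and the variant's genomic identity.
    """
    if strand not in "+-":
        raise ValueError("strand must be '+' or '-'")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = random.Random(seed)
    design = _design_locus(rng)
    layout = _plus_layout()
    L = layout.chrom_length

    genome_rng = random.Random(seed + 1)
    seq = genome_rng.choices(_BASES, k=L)
    # overwrite coding intervals with designed codons
    for (s, e), codons in zip(layout.cds, design.exon_codons):
        block = "".join(codons)
        # exon 4's CDS interval excludes the UTR but includes the stop codon
        seq[s - 1 : s - 1 + len(block)] = list(block)
    plus_genome = "".join(seq)
    assert plus_genome[VARIANT_POS_PLUS - 1] == design.variant_ref

    exons_by_tx = {
        tid: [layout.exons[e - 1] for e in exon_ids]
        for tid, exon_ids in TRANSCRIPT_EXONS.items()
    }
    cds_by_tx = {}
    stop_by_tx = {}
    for tid, exon_ids in TRANSCRIPT_EXONS.items():
        cds = [layout.cds[e - 1] for e in exon_ids]
        last = cds[-1]
        stop = (last[1] - 2, last[1])
        cds[-1] = (last[0], last[1] - 3)  # GTF convention: CDS excludes stop
        cds_by_tx[tid] = cds
        stop_by_tx[tid] = stop

    if strand == "+":
        genome = plus_genome
        variant_pos = layout.variant_pos
        ref, alt = design.variant_ref, design.variant_alt
    else:
        genome = reverse_complement(plus_genome)
        variant_pos = L + 1 - layout.variant_pos
        ref, alt = _COMP[design.variant_ref], _COMP[design.variant_alt]
        exons_by_tx = {
            tid: sorted(_reflect_interval(iv, L) for iv in ivs)
            for tid, ivs in exons_by_tx.items()
        }
        cds_by_tx = {
            tid: sorted(_reflect_interval(iv, L) for iv in ivs)
            for tid, ivs in cds_by_tx.items()
        }
        stop_by_tx = {tid: _reflect_interval(iv, L) for tid, iv in stop_by_tx.items()}

    genome_path = out / "genome.fa"
    _write_fasta(genome_path, [(CHROM, genome)])
    gtf_path = out / "gene_models.gtf"
    _write_gtf(gtf_path, strand, exons_by_tx, cds_by_tx, stop_by_tx)

    iso_records = []
    for iso in sorted(design.isoform_seqs):
        canon = " CANON=1" if iso == CANONICAL_ISOFORM else ""
        iso_records.append((f"{iso} GN={GENE_ID}{canon}", design.isoform_seqs[iso]))
    iso_path = out / "isoforms.fa"
    _write_fasta(iso_path, iso_records)

    var_path = out / "variants.tsv"
    var_path.write_text(f"{CHROM}\t{variant_pos}\t{VARIANT_ID}\t{ref}\t{alt}\n")

    # --- manifest: expectations derived from the construction itself
    iso3 = design.isoform_seqs[CANONICAL_ISOFORM]
    var_ref_aa = "G"  # GGA
    var_alt_aa = "A"  # GCA
    codons_before = {  # codons preceding exon 3 in each exon-3-bearing transcript
        "TR1": EXON_CODONS[0] + EXON_CODONS[1],
        "TR3": EXON_CODONS[0],
    }
    tx_expect = {}
    for tid in TRANSCRIPT_EXONS:
        iso = TRANSCRIPT_ISOFORM[tid]
        if tid in codons_before:
            aa_pos = codons_before[tid] + VARIANT_CODON_IN_EXON
            cds_pos = (aa_pos - 1) * 3 + 1 + VARIANT_CODON_OFFSET
            tx_expect[tid] = {
                "consequence": "missense",
                "aa_pos": aa_pos,
                "cds_pos": cds_pos,
                "ref_aa": var_ref_aa,
                "alt_aa": var_alt_aa,
                "ref_codon": "GGA",
                "alt_codon": "GCA",
                "hgvs_p": f"p.{AA_1TO3[var_ref_aa]}{aa_pos}{AA_1TO3[var_alt_aa]}",
                "isoform": iso,
                "canonical": iso == CANONICAL_ISOFORM,
            }
        else:
            tx_expect[tid] = {
                "consequence": "intronic",
                "isoform": iso,
                "canonical": iso == CANONICAL_ISOFORM,
            }

    manifest = {
        "seed": seed,
        "strand": strand,
        "chrom": CHROM,
        "variant": {"pos": variant_pos, "id": VARIANT_ID, "ref": ref, "alt": alt},
        "transcripts": tx_expect,
        "select_transcript": SELECT_TRANSCRIPT,
        "canonical_isoform": CANONICAL_ISOFORM,
        "select_vs_canonical": "different",  # ISO1 != ISO3 by exon topology
        "isoform_lengths": {k: len(v) for k, v in design.isoform_seqs.items()},
        "canonical_sequence": iso3,
        "variant_aa_pos_canonical": POS_VARIANT,
    }
    return FixtureBundle(
        root=out,
        genome=genome_path,
        gtf=gtf_path,
        isoforms=iso_path,
        variants=var_path,
        manifest=manifest,
    )


# ---------------------------------------------------------------------------
# structures


def _author_id(i: int) -> tuple[int, str]:
    """Deliberately offset author numbering with one insertion code.

    Residue 1 is author 30; residue 24 is 52A (insertion); unique overall.
    """
    if i <= 23:
        return 29 + i, ""
    if i == 24:
        return 52, "A"
    return 28 + i, ""


def _atom_line(
    serial: int,
    name: str,
    resname: str,
    chain: str,
    resnum: int,
    icode: str,
    xyz: tuple[float, float, float],
    element: str,
    hetatm: bool = False,
) -> str:
    record = "HETATM" if hetatm else "ATOM  "
    name_field = f"{name:<4s}" if len(element) == 2 else f" {name:<3s}"
    x, y, z = xyz
    return (
        f"{record}{serial:5d} {name_field} {resname:>3s} {chain}{resnum:4d}"
        f"{icode or ' '}   {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{20.0:6.2f}"
        f"          {element:>2s}"
    )


def _seqres_lines(chain: str, resnames: list[str]) -> list[str]:
    lines = []
    for i in range(0, len(resnames), 13):
        chunk = resnames[i : i + 13]
        ser = i // 13 + 1
        lines.append(f"SEQRES {ser:3d} {chain} {len(resnames):4d}  " + " ".join(chunk))
    return lines


def _aa3(seq: str) -> list[str]:
    return [AA_1TO3[c].upper() for c in seq]


class _PdbWriter:
    def __init__(self, pdb_id: str, resolution: float):
        self.lines = [
            f"HEADER    SYNTHETIC PROTEIN                       01-JAN-20   {pdb_id}",
            f"REMARK   2 RESOLUTION.    {resolution:4.2f} ANGSTROMS.",
        ]
        self.serial = 0

    def seqres(self, chain: str, resnames: list[str]) -> None:
        self.lines.extend(_seqres_lines(chain, resnames))

    def atom(self, name, resname, chain, resnum, icode, xyz, element, hetatm=False) -> None:
        self.serial += 1
        self.lines.append(
            _atom_line(self.serial, name, resname, chain, resnum, icode, xyz, element, hetatm)
        )

    def ter(self) -> None:
        self.lines.append("TER")

    def write(self, path: Path) -> None:
        path.write_text("\n".join(self.lines + ["END"]) + "\n")


def _backbone(w: _PdbWriter, resname: str, chain: str, num: int, icode: str, i: int,
              sg_xyz: tuple[float, float, float] | None = None) -> None:
    """Toy residue geometry: CA on the x axis at 6 A spacing."""
    x = 6.0 * i
    w.atom("N", resname, chain, num, icode, (x - 1.2, 0.8, 0.0), "N")
    w.atom("CA", resname, chain, num, icode, (x, 0.0, 0.0), "C")
    w.atom("C", resname, chain, num, icode, (x + 1.2, 0.8, 0.0), "C")
    w.atom("O", resname, chain, num, icode, (x + 1.4, 1.9, 0.0), "O")
    if resname != "GLY":
        w.atom("CB", resname, chain, num, icode, (x, -1.5, 0.0), "C")
    if resname == "CYS":
        w.atom("SG", resname, chain, num, icode, sg_xyz or (x, -3.0, 0.0), "S")
    if resname == "HIS":
        w.atom("NE2", resname, chain, num, icode, (x, -3.5, 0.0), "N")


def _homolog_sequence(iso3: str) -> str:
    seq = list(iso3)
    for pos in HOMOLOG_MUTATED:
        seq[pos - 1] = _dissimilar(seq[pos - 1])
    return "".join(seq)


def _decoy_sequence(iso3: str, seed: int, config: Config) -> str:
    """Random 30-mer constrained (by redraw) to fail the search floors."""
    matrix = load_matrix(config.matrix)
    pool = [a for a in _AA20 if a != "C"]
    for attempt in range(100):
        rng = random.Random(f"{seed}-decoy-{attempt}")
        cand = "".join(rng.choice(pool) for _ in range(30))
        aln = align_local(iso3, cand, matrix=matrix,
                          gap_open=config.gap_open, gap_extend=config.gap_extend)
        if (
            not aln.aligned_pairs
            or aln.identity_fraction < config.min_identity
            or aln.query_coverage < config.min_coverage
        ):
            return cand
    raise RuntimeError("could not construct a below-floor decoy sequence")


def make_structure_set(out_dir: str | Path, seed: int = 0) -> tuple[list[Path], dict]:
    """Write the three structure files; return paths and expectations.

    Engineered coordinates (all distances by construction):

    * 1AAA chain A — exact ISO3 match, author numbering from 30 with
      insertion code 52A, last residue unobserved; ZN at 2.1 A from the
      His NE2 (metal); acetate O at 3.0 A (ligand); DNA C1' at 3.5 A
      (nucleic); peptide chain CA at 3.2 A (protein); a second ZN at 4.5 A
      from the clean residue (no flag); SG-SG pairs at 2.05 and 4.0 A;
      a water at 2.8 A from the variant residue (never a flag).
    * 2BBB chain A — ~70% identity homolog, author 1..37, ZN at 2.2 A from
      the residue matching the canonical variant position.
    * 3CCC chain A — decoy failing the identity/coverage floors.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = _design_locus(random.Random(seed))
    iso3 = design.isoform_seqs[CANONICAL_ISOFORM]
    n = len(iso3)
    cfg = Config()

    # --- 1AAA: exact match
    w = _PdbWriter("1AAA", 1.50)
    names = _aa3(iso3)
    w.seqres("A", names)
    w.seqres("B", ["DA", "DT", "DA"])
    w.seqres("C", ["GLY", "GLY", "GLY"])
    sg_overrides = {
        POS_CYS_BOND[0]: (300.0, 50.0, 0.0),
        POS_CYS_BOND[1]: (302.05, 50.0, 0.0),
        POS_CYS_FAR[0]: (400.0, 50.0, 0.0),
        POS_CYS_FAR[1]: (404.0, 50.0, 0.0),
    }
    for i in range(1, n):  # residue n stays unobserved (SEQRES only)
        num, icode = _author_id(i)
        _backbone(w, names[i - 1], "A", num, icode, i, sg_xyz=sg_overrides.get(i))
    w.ter()
    # DNA chain B near POS_DNA's CA (x = 6*POS_DNA)
    xd = 6.0 * POS_DNA
    w.atom("P", "DA", "B", 1, "", (xd, 0.0, 6.5), "P")
    w.atom("C1'", "DA", "B", 1, "", (xd, 0.0, 3.5), "C")
    w.atom("N1", "DA", "B", 1, "", (xd + 1.0, 0.0, 3.5), "N")
    w.atom("P", "DT", "B", 2, "", (600.0, 0.0, 0.0), "P")
    w.atom("C1'", "DT", "B", 2, "", (601.0, 1.0, 0.0), "C")
    w.atom("P", "DA", "B", 3, "", (606.0, 0.0, 0.0), "P")
    w.atom("C1'", "DA", "B", 3, "", (607.0, 1.0, 0.0), "C")
    w.ter()
    # peptide chain C: first GLY CA at 3.2 A from POS_PROTEIN's CA
    xp = 6.0 * POS_PROTEIN
    w.atom("N", "GLY", "C", 1, "", (xp - 1.0, 1.0, 3.2), "N")
    w.atom("CA", "GLY", "C", 1, "", (xp, 0.0, 3.2), "C")
    w.atom("C", "GLY", "C", 1, "", (xp + 1.2, 0.8, 3.2), "C")
    w.atom("O", "GLY", "C", 1, "", (xp + 1.4, 1.9, 3.2), "O")
    for k, xbase in ((2, 500.0), (3, 506.0)):
        w.atom("N", "GLY", "C", k, "", (xbase - 1.2, 0.8, 0.0), "N")
        w.atom("CA", "GLY", "C", k, "", (xbase, 0.0, 0.0), "C")
        w.atom("C", "GLY", "C", k, "", (xbase + 1.2, 0.8, 0.0), "C")
        w.atom("O", "GLY", "C", k, "", (xbase + 1.4, 1.9, 0.0), "O")
    w.ter()
    # hetero entities
    w.atom("ZN", "ZN", "A", 201, "", (6.0 * POS_METAL, -3.5, 2.1), "ZN", hetatm=True)
    w.atom("ZN", "ZN", "A", 202, "", (6.0 * POS_CLEAN, 0.0, -4.5), "ZN", hetatm=True)
    xl = 6.0 * POS_LIGAND
    w.atom("C", "ACT", "A", 210, "", (xl, 0.0, 5.5), "C", hetatm=True)
    w.atom("O", "ACT", "A", 210, "", (xl, 0.0, 3.0), "O", hetatm=True)
    w.atom("OXT", "ACT", "A", 210, "", (xl + 1.0, 0.0, 5.5), "O", hetatm=True)
    w.atom("O", "HOH", "A", 301, "", (6.0 * POS_VARIANT, 0.0, 2.8), "O", hetatm=True)
    path_exact = out / "1aaa.pdb"
    w.write(path_exact)

    # --- 2BBB: homolog
    hom = _homolog_sequence(iso3)
    w2 = _PdbWriter("2BBB", 2.30)
    names2 = _aa3(hom)
    w2.seqres("A", names2)
    for i in range(1, n + 1):
        _backbone(w2, names2[i - 1], "A", i, "", i)
    w2.ter()
    w2.atom("ZN", "ZN", "A", 301, "", (6.0 * POS_VARIANT, 0.0, 2.2), "ZN", hetatm=True)
    path_hom = out / "2bbb.pdb"
    w2.write(path_hom)

    # --- 3CCC: decoy
    decoy = _decoy_sequence(iso3, seed, cfg)
    w3 = _PdbWriter("3CCC", 2.00)
    names3 = _aa3(decoy)
    w3.seqres("A", names3)
    for i in range(1, len(decoy) + 1):
        _backbone(w3, names3[i - 1], "A", i, "", i)
    w3.ter()
    path_decoy = out / "3ccc.pdb"
    w3.write(path_decoy)

    def author_str(i: int) -> str:
        num, icode = _author_id(i)
        return f"{num}{icode}"

    expectations = {
        "ranked_chains": ["1AAA_A", "2BBB_A"],
        "excluded_chains": ["3CCC_A"],
        "top_hit": {
            "pdb_id": "1AAA",
            "chain_id": "A",
            "resolution": 1.50,
            "identity_fraction": 1.0,
            "author_resid_of_variant": author_str(POS_VARIANT),
            "residue_name_of_variant": AA_1TO3[iso3[POS_VARIANT - 1]].upper(),
        },
        "unobserved_seq_index": n,
        "insertion_code_seq_index": 24,
        "insertion_code_author": "52A",
        "first_author_number": 30,
        "disulphides_1AAA": sorted(
            [sorted([author_str(POS_CYS_BOND[0]), author_str(POS_CYS_BOND[1])])]
        ),
        "not_disulphide_1AAA": sorted([author_str(POS_CYS_FAR[0]), author_str(POS_CYS_FAR[1])]),
        "contexts_1AAA": {
            str(POS_METAL): ["metal"],
            str(POS_DNA): ["nucleic"],
            str(POS_LIGAND): ["ligand"],
            str(POS_PROTEIN): ["protein"],
            str(POS_CLEAN): [],
            str(POS_VARIANT): [],
        },
        "variant_context_aggregated": {
            "contacts_metal": True,
            "supporting": {"metal": ["2BBB_A"]},
        },
        "homolog_identity_count": n - len(HOMOLOG_MUTATED),
        "homolog_length": n,
    }
    return [path_exact, path_hom, path_decoy], expectations


# ---------------------------------------------------------------------------
# annotation tables + MSA


def _make_msa(iso3: str) -> list[tuple[str, str]]:
    rows = [(CANONICAL_ISOFORM, iso3)]
    for rid in sorted(MSA_MUTATIONS):
        seq = list(iso3)
        for pos in MSA_MUTATIONS[rid]:
            seq[pos - 1] = _dissimilar(seq[pos - 1], shift=5)
        if rid == "HOM3":
            seq[-1] = "-"  # one gap column, never the variant column
        rows.append((rid, "".join(seq)))
    return rows


def make_fixture_bundle(out_dir: str | Path, seed: int = 0, strand: str = "+") -> FixtureBundle:
    """Generate the complete fixture set and write ``manifest.json``."""
    bundle = make_alt_splicing_locus(out_dir, seed=seed, strand=strand)
    struct_dir = bundle.root / "structures"
    paths, struct_expect = make_structure_set(struct_dir, seed=seed)
    bundle.structures = paths
    bundle.manifest["structure"] = struct_expect

    iso3 = bundle.manifest["canonical_sequence"]
    msa_rows = _make_msa(iso3)
    bundle.msa = bundle.root / "msa.fa"
    _write_fasta(bundle.msa, msa_rows)
    variant_col = "".join(row[POS_VARIANT - 1] for _, row in msa_rows)
    bundle.manifest["msa"] = {
        "rows": len(msa_rows),
        "variant_column_residues": variant_col,
        "catalytic_column_residues": "".join(row[POS_METAL - 1] for _, row in msa_rows),
    }

    bundle.catalytic = bundle.root / "catalytic.tsv"
    bundle.catalytic.write_text(f"{CANONICAL_ISOFORM}\t{POS_METAL}\n")
    bundle.disease = bundle.root / "disease.tsv"
    bundle.disease.write_text(f"{CANONICAL_ISOFORM}\t{POS_VARIANT}\tToyDisease\n")
    bundle.passthrough = bundle.root / "passthrough.tsv"
    vp = bundle.manifest["variant"]["pos"]
    bundle.passthrough.write_text(f"chrom\tpos\tCADD\n{CHROM}\t{vp}\t24.7\n")
    bundle.manifest["tables"] = {
        "catalytic": {"isoform": CANONICAL_ISOFORM, "aa_pos": POS_METAL},
        "disease": {"isoform": CANONICAL_ISOFORM, "aa_pos": POS_VARIANT, "label": "ToyDisease"},
        "passthrough_columns": ["CADD"],
        "passthrough_value": "24.7",
    }
    bundle.write_manifest()
    return bundle
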