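# snv2struct

Map genomic single-nucleotide variants (SNVs) through splice-aware gene
models to per-transcript protein positions, validate them against canonical
isoform sequences, carry them onto 3D-structure residue numbering by
pairwise alignment, and annotate each mapped residue's structural context —
contacts, disulphides, catalytic sites, conservation — in one tab-separated
output table.

## Why

A variant's structural context (is it buried near a metal site? in a
disulphide? at a DNA interface?) is often what separates a plausibly
pathogenic change from a benign one. But getting from `chr12:123456 G>C` to
"residue 45 of chain A in structure 1AAA" is genuinely error-prone:

* **Alternative splicing.** One coding region yields several transcripts;
  each translates to a different isoform with its own residue numbering. A
  variant may sit in an exon that one transcript splices out entirely.
* **Reference disagreement.** The gene's designated *select* transcript and
  the protein database's *canonical* isoform are independently chosen and
  frequently encode different sequences — so the "same" residue carries
  different numbers in the two coordinate systems.
* **Author numbering.** Structure depositors number residues as they
  please: offsets, gaps, insertion codes (52A), residues declared in SEQRES
  but never observed.

Silently crossing any of these seams mis-numbers every downstream residue.
`snv2struct` makes each hop explicit and checkable: exact interval
arithmetic for genome↔CDS↔protein, *exact-match* transcript→isoform
pairing, per-position validation against the isoform sequence, and
alignment-based sequence→structure mapping with the author numbering
preserved. It is a library first (for pipelines and notebooks), with a thin
CLI for shell use. All inputs are local files — genome FASTA, GTF gene
models, isoform FASTA, PDB-format structures, optional TSV annotation
tables — no remote services.

## The method

For a variant (chrom, pos, ref, alt) and transcript *T* with ordered coding
intervals, the spliced CDS coordinate *c* counts coding bases in transcript
order (reverse-complemented on the − strand); then

```
aa_pos = ⌈c / 3⌉,    codon offset = (c − 1) mod 3
```

The affected codon is re-translated after substituting the (strand-aware)
alternate base, giving the consequence class (synonymous / missense /
stop-gained / stop-lost / start-lost, or intronic / UTR / flanking) and an
HGVS p. description. Transcripts pair to isoforms only by exact translated
identity; the amino acid the mapping predicts at `aa_pos` is verified
against the isoform sequence itself.

The canonical isoform is searched against every structure chain sequence
(SEQRES when present) with exact Smith–Waterman local alignment (BLOSUM62,
affine gaps: a gap of length *k* costs 11 + *k*). Hits below identity 0.3
or query coverage 0.5 are dropped; the rest rank by the E-value surrogate
`E = K·m·n·exp(−λ·score)` (K = 0.1, λ = 0.27; ordinal use only), ties broken
by resolution. The best alignment carries `aa_pos` to a SEQRES index and on
to the author residue id. Context is then computed over **all** qualifying
structures, not just the top hit: heavy-atom contacts within 4.0 Å classed
as protein / nucleic / ligand / metal, disulphides as CYS SG–SG ≤ 2.5 Å,
catalytic flags from a local table, and column conservation as a
BLOSUM62-normalised sum-of-pairs score in [0, 1].

## Worked example

The package ships a deterministic generator for a complete synthetic data
set: one gene with four exons and three transcripts (TR2 lacks exon 3; TR1
is the select transcript; TR3 translates to the canonical isoform ISO3), a
missense SNV inside exon 3, and three structures (exact match, ~70%
homolog, below-floor decoy).

```bash
snv2struct make-fixtures --out fx --seed 1
snv2struct annotate --variants fx/variants.tsv --genome fx/genome.fa \
    --gtf fx/gene_models.gtf --isoforms fx/isoforms.fa \
    --structures fx/structures --msa fx/msa.fa --catalytic fx/catalytic.tsv \
    -o out.tsv --summary
```

or in Python, `python examples/06_full_pipeline.py`, which prints:

```
user_id  transcript_id  consequence  hgvs_p      isoform_id  canonical  validation  pdb_id  author_resid  contact_metal  conservation  disease
var1     TR1            missense     p.Gly28Ala  ISO1        no         ok          -       -             -              -             -
var1     TR2            intronic     -           ISO2        no         -           -       -             -              -             -
var1     TR3            missense     p.Gly16Ala  ISO3        yes        ok          1AAA    45            yes            0.6667        ToyDisease
```

Reading the three rows: the same genomic change `12:123456 G>C` is
p.Gly28Ala on the select transcript but p.Gly16Ala on the canonical isoform
(different numbering, same codon change), and has no protein position on
TR2 because its exon was spliced out. Only the canonical row maps to
structure: residue 16 of ISO3 is *author* residue 45 of chain A in the
exact-match structure, and the aggregated context reports a metal contact —
contributed by the homologous structure, which a single-structure lookup
would have missed. The `examples/` directory walks each stage separately.

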