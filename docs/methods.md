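# Methods

This note documents the models, parameter choices and numerical conventions
behind `snv2struct`, and what the synthetic test data does and does not
demonstrate about real inputs.

## Coordinate model

All genomic coordinates are 1-based, fully closed (the VCF/GTF convention).
A transcript is an ordered set of non-overlapping exon intervals plus CDS
intervals contained in exon space; "transcript order" is ascending genomic
position on the + strand and descending on −. The spliced CDS position of a
genomic base is its 1-based rank among coding bases in transcript order;
`aa_pos = ⌈c/3⌉` and the codon offset `(c−1) mod 3` follow by arithmetic.
`genomic_to_cds` and `cds_to_genomic` are exact inverses on the CDS, and the
test suite checks this exhaustively over every CDS base of the fixtures on
both strands rather than by spot checks.

GTF is the only gene-model dialect read. Files following the Ensembl
convention of excluding the stop codon from CDS features are normalised on
load by absorbing adjacent `stop_codon` features, so the stored CDS always
includes the stop and "CDS length divisible by 3" is a uniform invariant.
The phase column is recomputed from interval arithmetic, never trusted.
Transcripts that violate an invariant (CDS outside exons, length ≢ 0 mod 3)
are flagged `non_coding_or_malformed` and still produce output rows rather
than being dropped: an unmappable variant should degrade visibly, not
vanish.

## Consequence calling

Only SNVs are modelled. The consequence is computed codon-locally —
substitute the (strand-complemented, if −) alternate base at the codon
offset and re-translate that codon — which for an SNV is provably
equivalent to re-translating the whole CDS; the suite verifies the
equivalence against a full-retranslation oracle over every coding position
× every alternate base. Classification order: gained stop, lost stop, lost
start (literal ATG only; non-ATG starts are treated as ordinary codons with
a logged notice), synonymous, missense. The vocabulary is deliberately the
small closed SNV set; splice-region classes are not called because any
donor/acceptor window would be an invented parameter — an intronic variant
is `intronic` regardless of distance to the junction. The standard genetic
code only; selenocysteine and readthrough are out of scope.

## Isoform pairing and validation

Transcript→isoform pairing is exact string equality of the translated CDS
with the isoform sequence. Near-matches are reported as unpaired (the
nearest same-gene isoform and its edit distance are logged) because an
almost-identical isoform is precisely the case that silently shifts residue
numbering. At most one isoform per gene may carry the canonical flag
(`CANON=1` in the FASTA header; the select transcript is `tag "select"` in
the GTF — local conventions standing in for database-side designations).
When multiple identical isoforms match, all pairings are reported. The
predicted reference amino acid at `aa_pos` is checked against the isoform
sequence (`ok` / `mismatch` / `out_of_range`); the structure stage only
runs on validated canonical positions.

## Sequence→structure mapping

Chain sequences come from SEQRES when present, else from observed residues
(decision logged per chain). Alignment is exact Smith–Waterman with affine
gaps; a gap of length *k* costs `gap_open + k·gap_extend` (defaults
BLOSUM62, 11, 1 — the NCBI convention, so scores are directly comparable
with other exact affine-gap engines, which is how the tests verify them).
A heuristic search engine would add nothing at single-protein scale and
would be harder to verify. Traceback tie-breaks prefer the aligned column,
then a target gap, then a query gap, making the reported `aligned_pairs`
deterministic; the score is tie-free regardless.

Ranking uses the surrogate `E = K·m·n·exp(−λ·score)` with fixed K = 0.1,
λ = 0.27. These are nominal Gumbel parameters for BLOSUM62-scored local
alignment; since E is strictly decreasing in score for fixed sequence
lengths, only the *ordering* is meaningful and no database calibration is
attempted. Floors: identity ≥ 0.3 over aligned columns and query coverage
≥ 0.5; ties broken by resolution (unknown last), then chain id, making the
ranking a total order — permutation invariance is tested. Residue mapping
returns the SEQRES index aligned with the query position (absent in gap
columns), then the author residue id; SEQRES residues without coordinates
map to an explicit `unobserved` marker rather than a number.

## Structural context

Contacts use a heavy-atom distance criterion, cutoff 4.0 Å (inclusive),
the conventional non-bonded contact threshold. Entity classes are a pure
function of residue name and chain polymer type: standard amino acids on a
polymer chain → protein; DA/DC/DG/DT/A/C/G/U on a polymer chain → nucleic;
HOH/WAT → water (never a contact); monoatomic ions named by their element
(LI, NA, K, MG, CA, MN, FE, CO, NI, CU, ZN, MO, W, CD, HG) → metal;
everything else → ligand. Protein partners must lie on a different chain or
≥ 5 residues away along the same chain — this subsumes the two backbone
neighbours and excludes trivial short-range contacts while keeping tertiary
ones. The implementation uses a spatial neighbour index (with the search
radius padded so the inclusive boundary is kept exactly); tests compare it
against a brute-force all-pairs scan on every fixture structure.
Coordinates are taken from the asymmetric unit as deposited; biological
assemblies are not generated.

Disulphides are CYS SG–SG pairs ≤ 2.5 Å, reported once per unordered pair.
Catalytic and disease annotations are exact lookups in local TSV tables
keyed by (isoform id, residue position).

Context is aggregated over *all* chains passing the search floors, not the
top hit only: a flag is set if any qualifying structure supports it, each
flag recording its supporting structures. Aggregation is monotone — adding
a structure can add flags, never remove them.

## Conservation

Column conservation is a normalised sum-of-pairs score: the mean over all
residue pairs (i < j) in the column of `(s(a,b) − min) / (max − min)` with
BLOSUM62 entries and min/max taken over the 20×20 standard-residue block
(−4 and 11). Gaps are excluded from pairing; a column with fewer than two
residues has no defined score (absent, not zero). The score is bounded in
[0, 1] and reaches 1 only for columns of tryptophan (the matrix's maximal
self-pair) — it is a comparative signal, not an absolute probability.
Several published variants of column scoring exist; this normalised
sum-of-pairs form was chosen for being parameter-free given the matrix and
directly testable. Building the alignment itself is out of scope: the MSA
is supplied by the user (aligned FASTA), and the variant's column is
located by the canonical sequence's ungapped index in its own row.

## Pipeline and output

Per variant: reference-allele check (a mismatch against the supplied genome
signals a wrong-assembly input and degrades that variant's rows without
halting others) → per-transcript consequence → isoform pairing and
validation → structure search, residue mapping and context on the
validated canonical row → optional pass-through columns keyed by (chrom,
pos). Transcripts within 5 kb of the position are reported (flanking
variants as `upstream_downstream`); a variant touching nothing yields one
`no_transcript` row. Output is a rectangular TSV with a fixed, documented
column order, `-` for empty fields, the input identifier echoed verbatim,
and one row per (variant, transcript) pair, ordered by input line then
transcript id; `read_tsv` is the exact inverse of `write_tsv`, and repeated
runs are byte-identical.

## The synthetic data set

The generator emulates the canonical alternative-splicing pitfall with
hard-coded topology and seeded-random sequence content. Design choices:

* Four coding exons of 10/12/15/13 codons (multiples of 3, so no codon
  spans a junction and removing an exon cannot frameshift), 6 nt UTRs,
  introns of 30–40 nt, placed so the variant falls at position 123456 of a
  "chromosome 12" (~124 kb of random sequence, generated at run time).
* Random codons are drawn from the 59 non-stop, non-cysteine codons;
  start/stop, the variant codon (GGA, middle base G→C ⇒ Gly→Ala), one
  histidine and four cysteines are forced, so every engineered geometric
  expectation (disulphide at 2.05 Å, negative pair at 4.0 Å, ZN at 2.1 Å
  from the His NE2, a clean residue whose nearest foreign atom sits at
  cutoff + 0.5 Å) holds for every seed.
* The exact-match structure numbers its residues from 30 with one
  insertion code (52A) and one unobserved terminal residue; the homolog
  mutates 11 of 37 fixed positions (~70% identity) and carries the metal
  contact at the variant position; the decoy is redrawn (deterministic
  counter-seed) until it fails the search floors, so its exclusion is a
  construction guarantee rather than a statistical hope.
* The minus-strand variant of the data set is an exact coordinate
  reflection plus reverse-complement, which flips every piece of interval
  arithmetic while preserving all protein-level expectations.

What passing on this data shows: the coordinate arithmetic, consequence
logic, pairing/validation rules, alignment, ranking, residue mapping and
contact geometry are exact on inputs whose ground truth is known by
construction, across both strands. What it does not show: robustness to
real-world annotation mess (trans-splicing, non-ATG starts, selenoproteins,
frame-disrupting annotation errors), realistic protein geometry (fixture
side chains are schematic), assembly-level contacts, or the behaviour of
the E-value surrogate on genuinely borderline homologs. Problem sizes
(a 37-residue canonical isoform, ~1100 exhaustive consequence cases, 200
random alignment pairs, 1000 conservation columns) were chosen so the whole
suite verifies every exhaustive claim in seconds.

## Known limitations

Indels/MNVs, VCF input, liftover, splice-region classes, mmCIF structures,
biological assemblies, solvent accessibility and MSA construction are out
of scope. The consequence set and contact chemistry are intentionally
minimal; anything requiring a remote database (allele frequencies,
predictor scores, curated disease records) enters only as user-supplied
local tables passed through to output columns.
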