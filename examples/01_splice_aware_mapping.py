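"""Map a genomic position through three alternatively spliced transcripts.

Builds the synthetic locus (one gene, four exons, three transcripts) and
shows why the same genomic base has a different CDS/protein coordinate on
each transcript — and no coordinate at all on the transcript whose splicing
removed the exon.
"""

import tempfile
from pathlib import Path

from snv2struct.fixtures import make_alt_splicing_locus
from snv2struct.gene_models import cds_to_protein, genomic_to_cds, parse_gtf
from snv2struct.variant_io import parse_variant_table

with tempfile.TemporaryDirectory() as td:
    bundle = make_alt_splicing_locus(Path(td) / "locus", seed=1)
    models = parse_gtf(str(bundle.gtf))
    with open(bundle.variants) as fh:
        (variant,), _ = parse_variant_table(fh)

    print(f"variant: chr{variant.chrom}:{variant.pos} {variant.ref}>{variant.alt}\n")
    for tm in models:
        coord = genomic_to_cds(tm, variant.pos)
        if coord is None:
            print(f"  {tm.transcript_id}: no CDS position (exon spliced out)")
        else:
            aa_pos, offset = cds_to_protein(coord.cds_pos)
            print(
                f"  {tm.transcript_id}: CDS position {coord.cds_pos} "
                f"-> residue {aa_pos} (codon base {offset + 1})"
            )

# The same genomic base is residue 28 on the full-length transcript but
# residue 16 on the canonical-producing transcript, because the latter
# splices out an upstream exon; the transcript lacking exon 3 has no
# protein position at all.  Picking the wrong transcript silently
# renumbers every downstream residue.
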