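"""Run the complete pipeline: variant table in, annotated TSV out.

Equivalent to the CLI:
    snv2struct annotate --variants ... --genome ... --gtf ... --isoforms ...
                        --structures ... --msa ... --catalytic ... -o out.tsv
"""

import tempfile
from pathlib import Path

from snv2struct.fixtures import make_fixture_bundle
from snv2struct.pipeline import Resources, run

with tempfile.TemporaryDirectory() as td:
    bundle = make_fixture_bundle(Path(td) / "fx", seed=1)
    resources = Resources.load(
        genome=bundle.genome, gtf=bundle.gtf, isoforms=bundle.isoforms,
        structures=bundle.structure_dir, msa=bundle.msa,
        catalytic=bundle.catalytic, disease=bundle.disease,
        passthrough=bundle.passthrough,
    )
    out = Path(td) / "annotated.tsv"
    table, rejections = run(bundle.variants, resources, out)

    print(f"{len(table.rows)} rows, {len(rejections)} rejected input lines\n")
    show = ["user_id", "transcript_id", "consequence", "hgvs_p", "isoform_id",
            "canonical", "validation", "pdb_id", "author_resid", "contact_metal",
            "conservation", "disease"]
    print("\t".join(show))
    for row in table.rows:
        print("\t".join(row[c] for c in show))

# One output row per (variant, transcript) pair, the input identifier
# echoed on each.  Only the canonical-isoform row carries the structure
# block: PDB id, author residue number, contact flags, conservation and
# the local disease annotation.  The other rows still carry their
# transcript-level consequences.
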