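"""Annotate the structural context of mapped residues.

Contacts (protein/nucleic/ligand/metal by heavy-atom distance), disulphide
bonds (SG-SG <= 2.5 A), catalytic-site membership from a local table, and
column conservation from a user-supplied alignment.  Context is aggregated
over all qualifying structures, so an interaction visible only in a
homologous structure is still reported.
"""

import tempfile
from pathlib import Path

from snv2struct.fixtures import make_fixture_bundle
from snv2struct.isoform_registry import load_isoforms
from snv2struct.struct_annot import (
    disulphides,
    load_msa,
    load_position_table,
    residue_context,
)
from snv2struct.struct_map import load_structure, load_structure_dir, search_structures

with tempfile.TemporaryDirectory() as td:
    bundle = make_fixture_bundle(Path(td) / "fx", seed=1)
    canonical = next(i for i in load_isoforms(str(bundle.isoforms)) if i.is_canonical)
    chains = load_structure_dir(bundle.structure_dir)
    hits = search_structures(canonical.sequence, chains)
    msa = load_msa(str(bundle.msa))
    catalytic = load_position_table(str(bundle.catalytic))

    print("disulphides in the exact-match structure:")
    for (c1, r1), (c2, r2) in disulphides(load_structure(bundle.structures[0])):
        print(f"  chain {c1} {r1} <-> chain {c2} {r2}")

    print("\nper-residue context (aggregated over all ranked structures):")
    for aa_pos in sorted({int(k) for k in bundle.manifest["structure"]["contexts_1AAA"]}):
        ctx = residue_context(hits, aa_pos, isoform_id=canonical.isoform_id,
                              catalytic_table=catalytic, msa=msa)
        flags = [c for c in ("protein", "nucleic", "ligand", "metal")
                 if getattr(ctx, f"contacts_{c}")]
        cons = f"{ctx.conservation:.2f}" if ctx.conservation is not None else "-"
        print(f"  residue {aa_pos:>2}: contacts={flags or '-'} "
              f"catalytic={ctx.is_catalytic} conservation={cons} "
              f"support={ctx.supporting_structures or '-'}")

# Residue 28 touches a zinc and is listed catalytic; residues 12/20/24
# contact DNA, a ligand and another protein chain; residue 16 (the variant
# position) has a metal contact contributed only by the homologous
# structure 2BBB — single-structure annotation would have missed it.
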