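"""Run configuration: alignment, search-floor and contact parameters.

Config files are flat ``key = value`` text with dotted keys, e.g.::

    alignment.gap_open = 11
    search.min_identity = 0.3
    contacts.cutoff_A = 4.0
"""

from __future__ import annotations

from dataclasses import dataclass, replace


@dataclass(frozen=True)
class Config:
    #: substitution matrix name (anything Bio.Align.substitution_matrices ships)
    matrix: str = "BLOSUM62"
    #: affine gap model: a gap of length k costs gap_open + k * gap_extend
    gap_open: float = 11.0
    gap_extend: float = 1.0
    #: structure-search floors over aligned columns / query length
    min_identity: float = 0.3
    min_coverage: float = 0.5
    #: heavy-atom contact cutoff in Angstrom
    contact_cutoff: float = 4.0
    #: SG-SG distance ceiling for a disulphide bond, Angstrom
    disulphide_cutoff: float = 2.5
    #: minimum in-chain residue separation for a protein-protein contact
    protein_min_separation: int = 5
    #: how far up/downstream of a transcript span a variant is still reported
    transcript_flank: int = 5000


_KEYMAP = {
    "alignment.matrix": ("matrix", str),
    "alignment.gap_open": ("gap_open", float),
    "alignment.gap_extend": ("gap_extend", float),
    "search.min_identity": ("min_identity", float),
    "search.min_coverage": ("min_coverage", float),
    "contacts.cutoff_A": ("contact_cutoff", float),
    "contacts.disulphide_A": ("disulphide_cutoff", float),
    "contacts.protein_min_separation": ("protein_min_separation", int),
    "pipeline.transcript_flank": ("transcript_flank", int),
}


def load_config(path: str, base: Config | None = None) -> Config:
    cfg = base or Config()
    updates = {}
    with open(path) as fh:
        for line_no, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"config line {line_no}: expected 'key = value', got {line!r}")
            key, _, value = line.partition("=")
            key = key.strip()
            if key not in _KEYMAP:
                raise ValueError(f"config line {line_no}: unknown key {key!r}")
            field, cast = _KEYMAP[key]
            updates[field] = cast(value.strip())
    return replace(cfg, **updates)
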