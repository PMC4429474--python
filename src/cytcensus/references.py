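"""Loaders for the packaged reference fixtures.

All packaged reference sequences are *synthetic stand-ins*, generated once
from a fixed seed and frozen as FASTA text: decoy exemplar backbones
(RecJ-like with 3 chance CxxCH motifs, thioredoxin-like with 1 motif plus
an N-terminal TMH), known-cytochrome exemplars, and CCM family seeds.
They carry no real database sequences; users with real reference sets
(e.g. actual RecJ exonucleases or the CcmB/C/E/F/H seeds of their choice)
supply their own FASTA files through the same call signatures.
"""

from __future__ import annotations

import re
from importlib import resources

from cytcensus.ccm import CCM_FAMILIES, CcmQuerySet
from cytcensus.proteome_io import ProteomeSet, read_fasta

_FAMILY_RE = re.compile(r"family=(\S+)")


def _data_path(name: str):
    return resources.files("cytcensus").joinpath("data", name)


def _family_of(rec) -> str | None:
    m = _FAMILY_RE.search(rec.description)
    return m.group(1) if m else None


def load_decoy_references(path=None) -> tuple[ProteomeSet, dict[str, str]]:
    """Decoy exemplars and a protein_id -> decoy_family mapping.

    The family is read from a ``family=<name>`` token in each FASTA header
    description; records without one fall into the ``other`` family.
    """
    ps = read_fasta(path if path is not None else _data_path("synthetic_decoy_refs.fasta"))
    families = {r.protein_id: (_family_of(r) or "other") for r in ps}
    return ps, families


def load_decoy_backbones(path=None) -> dict[str, "ProteinRecord"]:
    """One exemplar backbone per decoy family (first record wins)."""
    ps, families = load_decoy_references(path)
    out = {}
    for rec in ps:
        out.setdefault(families[rec.protein_id], rec)
    return out


def load_cytc_references(path=None) -> ProteomeSet:
    """Known-cytochrome exemplars used to rescue mono/diheme candidates."""
    return read_fasta(path if path is not None else _data_path("synthetic_cytc_refs.fasta"))


def load_ccm_queries(path=None) -> CcmQuerySet:
    """CCM system-I seed set (families B, C, E, F, H)."""
    ps = read_fasta(path if path is not None else _data_path("synthetic_ccm_seeds.fasta"))
    families: dict[str, list] = {f: [] for f in CCM_FAMILIES}
    for rec in ps:
        fam = _family_of(rec)
        if fam not in CCM_FAMILIES:
            raise ValueError(
                f"ccm seed {rec.protein_id!r} lacks a valid family=<B|C|E|F|H> tag")
        families[fam].append(rec)
    return CcmQuerySet(families=families, provenance=str(path or "packaged synthetic seeds"))
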