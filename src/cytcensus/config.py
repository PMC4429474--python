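"""Pipeline configuration.

Every threshold the underlying survey method leaves unstated is surfaced here
as an explicit, tunable default, and the census report echoes the full
configuration so results always carry their provenance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml


@dataclass
class CensusConfig:
    """All tunable thresholds of the census pipeline.

    Attributes
    ----------
    n_terminal_window:
        A TMH counts as "N-terminal" if it starts within this many residues
        of the N-terminus (residues, default 40).
    c_terminal_window:
        A TMH counts as a C-terminal membrane anchor if it ends within this
        many residues of the C-terminus (default 30).
    tmh_window:
        Sliding-window width for Kyte-Doolittle hydropathy (odd, default 19).
    tmh_threshold:
        Windowed mean hydropathy above which a position is helix-like
        (default 1.6).
    tmh_min_run:
        Minimum consecutive helix-like positions reported as a TMH
        (default 16).
    decoy_min_score:
        Local-alignment score to a decoy exemplar at or above which a motif
        hit is rejected as a known false-positive family (default 100).
    cytc_min_score:
        Score to a known cytochrome c reference that rescues a mono/diheme
        candidate (default 60).
    conservation_min:
        Minimum fraction of similarity homologs in which the CxxCH motif is
        conserved for a monoheme candidate to be accepted (default 0.5).
    min_score / min_identity / min_coverage:
        All-vs-all edge thresholds for mutual-similarity clustering
        (default raw score 50, 25% identity, alignment covering 50% of the
        shorter sequence).  Raw local scores carry no length correction, so
        the coverage term is what keeps short chance alignments between
        unrelated ~300-residue proteins out of the similarity graph.
    mask_low_complexity:
        Mask low-complexity segments (SEG-like entropy filter) before
        similarity screens (default true), so hydrophobic membrane anchors
        and signal h-regions do not generate spurious edges.
    ccm_min_score:
        Score to a CCM family seed at or above which a protein counts as a
        maturation-gene homolog (default 60).
    ccm_rounds:
        Iterated-search rounds for low-similarity CCM homologs (default 3).
    ccm_positive_min_families:
        Distinct CCM families required to call a species ccm-positive
        (default 3); if ``ccm_count_copies`` is true, total gene copies are
        counted instead of distinct families.
    accept_conf / flag_conf:
        Structure-evidence confidence (percent) for cluster-level acceptance
        (default 96) and for intermediate-quality flagging (default 90).
    """

    # topology
    n_terminal_window: int = 40
    c_terminal_window: int = 30
    tmh_window: int = 19
    tmh_threshold: float = 1.6
    tmh_min_run: int = 16
    tmh_merge_gap: int = 3
    sec_max_cleavage: int = 35
    tat_max_rr: int = 35
    # classification
    decoy_min_score: float = 100.0
    cytc_min_score: float = 60.0
    conservation_min: float = 0.5
    # similarity / clustering
    matrix: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    min_score: float = 50.0
    min_identity: float = 25.0
    min_coverage: float = 0.5
    mask_low_complexity: bool = True
    # motif grammar variants
    enable_cxxck: bool = False
    spacing_min: int = 2
    spacing_max: int = 2
    # ccm census
    ccm_min_score: float = 60.0
    ccm_rounds: int = 3
    ccm_positive_min_families: int = 3
    ccm_count_copies: bool = False
    # structure adjudication
    accept_conf: float = 96.0
    flag_conf: float = 90.0

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "CensusConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(d) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "CensusConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)
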