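"""Heme c attachment motif scanning.

The canonical attachment site is CxxCH: two cysteines forming thioether
bonds to the heme, with the histidine as proximal iron ligand.  The default
grammar is the strict CxxCH search; a CxxCK variant (seen in some nitrite
reductases) and altered cysteine spacing Cx(n)CH are available as opt-in
variants so census statistics stay comparable to the strict search unless
explicitly widened.

All matches are reported, including overlapping ones; coordinates are
1-based inclusive, the field convention for motif positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

# Ambiguity codes never satisfy the anchored C/H/K positions; wildcard
# positions accept any residue (ambiguity codes included).
_AMBIGUOUS = frozenset("BZXUO")


@dataclass(frozen=True)
class MotifPattern:
    """One anchored pattern: C, (spacing) wildcards, C, terminal H or K."""

    pattern_id: str
    spacing_min: int = 2
    spacing_max: int = 2
    terminal: str = "H"

    def __post_init__(self):
        if self.terminal not in ("H", "K"):
            raise ValueError("terminal residue must be H or K")
        if not (1 <= self.spacing_min <= self.spacing_max <= 15):
            raise ValueError("wildcard span bounds must satisfy 1 <= min <= max <= 15")


@dataclass(frozen=True)
class MotifGrammar:
    """The configurable pattern set driving a census scan.

    The default grammar is the single strict pattern CxxCH.
    """

    patterns: tuple[MotifPattern, ...] = (MotifPattern("CxxCH"),)

    @classmethod
    def default(cls) -> "MotifGrammar":
        return cls()

    @classmethod
    def build(cls, enable_cxxck: bool = False, spacing_min: int = 2,
              spacing_max: int = 2) -> "MotifGrammar":
        """Assemble a grammar from config flags.

        The strict CxxCH pattern is always present; variants only ever add
        patterns, so enabling them never removes a default-grammar hit.
        """
        pats = [MotifPattern("CxxCH")]
        if (spacing_min, spacing_max) != (2, 2):
            pats.append(MotifPattern(
                f"Cx({spacing_min}-{spacing_max})CH",
                spacing_min=spacing_min, spacing_max=spacing_max))
        if enable_cxxck:
            pats.append(MotifPattern("CxxCK", terminal="K"))
        return cls(patterns=tuple(pats))


@dataclass(frozen=True)
class MotifHit:
    """A matched heme attachment site; start/end are 1-based inclusive."""

    protein_id: str
    start: int
    end: int
    matched: str
    pattern_id: str


def _matches_at(seq: str, i: int, spacing: int, terminal: str) -> bool:
    # i is a 0-based start; pattern length = spacing + 3
    end = i + spacing + 3
    if end > len(seq):
        return False
    return (seq[i] == "C" and seq[i + spacing + 1] == "C"
            and seq[end - 1] == terminal)


def scan_protein(seq: str, grammar: MotifGrammar | None = None,
                 protein_id: str = "") -> list[MotifHit]:
    """Return every motif occurrence in ``seq``, overlapping hits included.

    Hits are sorted by start position (then pattern order).  An empty
    sequence yields an empty list.
    """
    if grammar is None:
        grammar = MotifGrammar.default()
    hits: list[MotifHit] = []
    for pat in grammar.patterns:
        for spacing in range(pat.spacing_min, pat.spacing_max + 1):
            plen = spacing + 3
            for i in range(len(seq) - plen + 1):
                if _matches_at(seq, i, spacing, pat.terminal):
                    hits.append(MotifHit(
                        protein_id=protein_id,
                        start=i + 1,
                        end=i + plen,
                        matched=seq[i:i + plen],
                        pattern_id=pat.pattern_id,
                    ))
    hits.sort(key=lambda h: (h.start, h.end, h.pattern_id))
    return hits


def count_motifs(rec_or_seq, grammar: MotifGrammar | None = None) -> int:
    """Number of motif occurrences in a record or raw sequence.

    This count is the per-protein heme number used throughout the census
    (an "octaheme" protein carries 8 CxxCH matches).
    """
    seq = getattr(rec_or_seq, "sequence", rec_or_seq)
    return len(scan_protein(seq, grammar))


def motif_histogram(ps, grammar: MotifGrammar | None = None) -> dict[int, int]:
    """Motif-count frequency spectrum over a proteome.

    Maps motif count -> number of proteins, including an explicit zero bin
    (absent only for an empty proteome).  Order-independent by construction.
    """
    hist: dict[int, int] = {}
    for rec in ps:
        n = count_motifs(rec, grammar)
        hist[n] = hist.get(n, 0) + 1
    return dict(sorted(hist.items()))


def write_hit_table(hits: list[MotifHit], path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tstart\tend\tmatched\tpattern_id\n")
        for h in hits:
            fh.write(f"{h.protein_id}\t{h.start}\t{h.end}\t{h.matched}\t{h.pattern_id}\n")
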