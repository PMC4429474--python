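"""N-terminal export topology: TMH, Sec and twin-arginine (TAT) signals.

Mono- and diheme cytochrome c candidates are only credible if the protein
is exported (or membrane anchored), so each protein is annotated with
transmembrane-helix spans, a Sec-type signal peptide, and a TAT signal.

Two evidence routes exist:

* built-in heuristics — deliberately simple, deterministic, and fully
  specified (Kyte-Doolittle windows for TMHs; the classical n/h/c-region
  plus von Heijne -3,-1 rule for Sec; the S/T-R-R-x-F-L-K core for TAT);
* adapters for external predictor output (TMHMM short format, SOSUI batch
  tables, SignalP <=4 and TatP summaries), which override the heuristics
  for any protein they cover.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from cytcensus.config import CensusConfig

# Kyte & Doolittle hydropathy; ambiguity codes score 0.
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

_SMALL_RESIDUES = frozenset("AGSCT")  # allowed at the -3 and -1 cleavage positions


@dataclass
class TopologyAnnotation:
    """Per-protein topology evidence used by the classification rules."""

    protein_id: str
    tmh_spans: list[tuple[int, int]] = field(default_factory=list)  # 1-based
    has_n_terminal_tmh: bool = False
    has_c_terminal_tmh: bool = False
    sec_signal: int | None = None   # cleavage position (1-based, last signal residue)
    tat_signal: int | None = None   # position of the first R of the RR pair
    source: str = "heuristic"

    @property
    def has_export_evidence(self) -> bool:
        """N-terminal TMH and/or predicted Sec/TAT signal."""
        return self.has_n_terminal_tmh or self.sec_signal is not None \
            or self.tat_signal is not None


def hydropathy_profile(seq: str, window: int = 19) -> list[float]:
    """Mean Kyte-Doolittle hydropathy over a centred sliding window.

    Positions without a full window are omitted, so the profile has
    ``len(seq) - window + 1`` values (empty if the sequence is shorter
    than the window).
    """
    if window < 5 or window % 2 == 0:
        raise ValueError("window must be odd and >= 5")
    n = len(seq)
    if n < window:
        return []
    scores = [KYTE_DOOLITTLE.get(c, 0.0) for c in seq]
    out = []
    s = sum(scores[:window])
    out.append(s / window)
    for i in range(window, n):
        s += scores[i] - scores[i - window]
        out.append(s / window)
    return out


def predict_tmh(seq: str, config: CensusConfig | None = None) -> list[tuple[int, int]]:
    """Transmembrane-helix spans from windowed hydropathy.

    Maximal runs of at least ``tmh_min_run`` consecutive positions whose
    windowed hydropathy exceeds ``tmh_threshold`` are reported (1-based,
    inclusive); runs separated by fewer than ``tmh_merge_gap`` positions
    are merged first.
    """
    cfg = config or CensusConfig()
    prof = hydropathy_profile(seq, cfg.tmh_window)
    if not prof:
        return []
    half = cfg.tmh_window // 2
    # position i of profile corresponds to residue i + half (0-based centre)
    above = [i for i, v in enumerate(prof) if v > cfg.tmh_threshold]
    if not above:
        return []
    # group into runs, merging gaps < tmh_merge_gap
    runs: list[list[int]] = [[above[0], above[0]]]
    for i in above[1:]:
        if i - runs[-1][1] < cfg.tmh_merge_gap:
            runs[-1][1] = i
        else:
            runs.append([i, i])
    spans = []
    for a, b in runs:
        if b - a + 1 >= cfg.tmh_min_run:
            spans.append((a + half + 1, b + half + 1))  # centre residues, 1-based
    return spans


def predict_sec_signal(seq: str, config: CensusConfig | None = None) -> int | None:
    """Sec/GSP signal peptide by the classical tripartite architecture.

    Within the first ``sec_max_cleavage`` residues (default 35) the signal
    needs (a) a charged n-region: at least one K/R in the first 6 residues,
    (b) a hydrophobic h-region: a stretch of >= 8 residues with mean
    Kyte-Doolittle score > 1.5, and (c) a c-region cleavage site after the
    h-region with small residues (A/G/S/C/T) at the -3 and -1 positions
    (von Heijne rule).  Returns the smallest qualifying cleavage position
    (the 1-based index of the last signal residue), or None.
    """
    cfg = config or CensusConfig()
    limit = min(len(seq), cfg.sec_max_cleavage)
    # (a) n-region charge
    if not any(c in "KR" for c in seq[:6]):
        return None
    scores = [KYTE_DOOLITTLE.get(c, 0.0) for c in seq[:limit]]
    # (b) find h-regions: every >= 8-residue window with mean KD > 1.5
    h_end = None  # earliest end (exclusive, 0-based) of a qualifying stretch
    for start in range(0, limit - 8 + 1):
        for end in range(start + 8, limit + 1):
            mean = sum(scores[start:end]) / (end - start)
            if mean > 1.5:
                if h_end is None or end < h_end:
                    h_end = end
                break  # longer stretches from this start cannot end earlier
    if h_end is None:
        return None
    # (c) smallest cleavage position p (1-based) after the h-region with
    # small residues at p-3 and p-1
    for p in range(h_end + 1, limit + 1):
        if p - 3 >= 1 and seq[p - 3 - 1] in _SMALL_RESIDUES \
                and seq[p - 1 - 1] in _SMALL_RESIDUES:
            return p
    return None


def predict_tat_signal(seq: str, config: CensusConfig | None = None) -> int | None:
    """Twin-arginine (TAT) signal: the S/T-R-R-x-F-L-K-type motif.

    Requires an RR pair starting at position <= ``tat_max_rr`` (default 35)
    with a preceding S/T/K/R within 2 residues and a following stretch of
    >= 12 residues whose mean hydropathy exceeds 0.5.  Returns the 1-based
    position of the first R, or None.
    """
    cfg = config or CensusConfig()
    limit = min(len(seq), cfg.tat_max_rr)
    for i in range(limit):  # 0-based position of first R
        if seq[i:i + 2] != "RR":
            continue
        preceding = seq[max(0, i - 2):i]
        if i > 0 and not any(c in "STKR" for c in preceding):
            continue
        rest = seq[i + 2:]
        if len(rest) < 12:
            continue
        window = rest[:12]
        mean = sum(KYTE_DOOLITTLE.get(c, 0.0) for c in window) / 12
        if mean > 0.5:
            return i + 1
    return None


def annotate_protein(rec, config: CensusConfig | None = None) -> TopologyAnnotation:
    """Full heuristic topology annotation of one protein record."""
    cfg = config or CensusConfig()
    seq = getattr(rec, "sequence", rec)
    pid = getattr(rec, "protein_id", "")
    spans = predict_tmh(seq, cfg)
    ann = TopologyAnnotation(
        protein_id=pid,
        tmh_spans=spans,
        has_n_terminal_tmh=any(s <= cfg.n_terminal_window for s, _ in spans),
        has_c_terminal_tmh=any(e >= len(seq) - cfg.c_terminal_window + 1
                               for _, e in spans),
        sec_signal=predict_sec_signal(seq, cfg),
        tat_signal=predict_tat_signal(seq, cfg),
        source="heuristic",
    )
    return ann


def annotate_proteome(ps, config: CensusConfig | None = None,
                      external: dict[str, TopologyAnnotation] | None = None
                      ) -> dict[str, TopologyAnnotation]:
    """Annotate every record; external predictor output overrides heuristics."""
    cfg = config or CensusConfig()
    out = {}
    for rec in ps:
        if external and rec.protein_id in external:
            out[rec.protein_id] = external[rec.protein_id]
        else:
            out[rec.protein_id] = annotate_protein(rec, cfg)
    return out


# ---------------------------------------------------------------------------
# external predictor adapters

class TopologyParseError(ValueError):
    pass


_TMHMM_TOPO = re.compile(r"[io](\d+)-(\d+)")


def _parse_tmhmm(path, cfg, seq_lengths=None) -> list[TopologyAnnotation]:
    """TMHMM short format: one line per protein, key=value columns."""
    anns = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise TopologyParseError(f"{path}:{lineno}: expected >= 6 columns")
            pid = fields[0]
            kv = {}
            for f in fields[1:]:
                if "=" in f:
                    k, _, v = f.partition("=")
                    kv[k] = v
            topo = kv.get("Topology", "")
            spans = [(int(a), int(b)) for a, b in _TMHMM_TOPO.findall(topo)]
            if "PredHel" in kv and len(spans) != int(kv["PredHel"]):
                raise TopologyParseError(
                    f"{path}:{lineno}: PredHel={kv['PredHel']} but "
                    f"{len(spans)} spans in topology string")
            length = int(kv["len"]) if "len" in kv else (
                seq_lengths.get(pid) if seq_lengths else None)
            anns.append(TopologyAnnotation(
                protein_id=pid,
                tmh_spans=spans,
                has_n_terminal_tmh=any(s <= cfg.n_terminal_window for s, _ in spans),
                has_c_terminal_tmh=(
                    any(e >= length - cfg.c_terminal_window + 1 for _, e in spans)
                    if length else False),
                source="tmhmm_file",
            ))
    return anns


def _parse_sosui(path, cfg, seq_lengths=None) -> list[TopologyAnnotation]:
    """SOSUI batch table: protein_id <TAB> n_tmh <TAB> start-end;start-end;..."""
    anns = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise TopologyParseError(f"{path}:{lineno}: expected >= 2 columns")
            pid = parts[0]
            spans = []
            if len(parts) > 2 and parts[2]:
                for chunk in parts[2].split(";"):
                    if not chunk:
                        continue
                    m = re.match(r"(\d+)-(\d+)$", chunk)
                    if not m:
                        raise TopologyParseError(
                            f"{path}:{lineno}: bad span {chunk!r}")
                    spans.append((int(m.group(1)), int(m.group(2))))
            if len(spans) != int(parts[1]):
                raise TopologyParseError(
                    f"{path}:{lineno}: span count mismatch")
            length = seq_lengths.get(pid) if seq_lengths else None
            anns.append(TopologyAnnotation(
                protein_id=pid,
                tmh_spans=spans,
                has_n_terminal_tmh=any(s <= cfg.n_terminal_window for s, _ in spans),
                has_c_terminal_tmh=(
                    any(e >= length - cfg.c_terminal_window + 1 for _, e in spans)
                    if length else False),
                source="sosui_file",
            ))
    return anns


def _parse_signalp(path, cfg, **_) -> list[TopologyAnnotation]:
    """SignalP <= 4 short summary: name ... D-flag Y/N ... cleavage pos.

    Accepts the common dialect ``protein_id <TAB> Y|N <TAB> cleavage_pos``.
    """
    anns = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise TopologyParseError(f"{path}:{lineno}: expected >= 2 columns")
            pid, flag = parts[0], parts[1]
            if flag not in ("Y", "N"):
                raise TopologyParseError(f"{path}:{lineno}: flag must be Y or N")
            cleav = None
            if flag == "Y":
                if len(parts) < 3:
                    raise TopologyParseError(
                        f"{path}:{lineno}: flagged Y but no cleavage position")
                cleav = int(parts[2])
            anns.append(TopologyAnnotation(
                protein_id=pid, sec_signal=cleav, source="signalp_file"))
    return anns


def _parse_tatp(path, cfg, **_) -> list[TopologyAnnotation]:
    """TatP summary dialect: ``protein_id <TAB> Y|N <TAB> rr_position``."""
    anns = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise TopologyParseError(f"{path}:{lineno}: expected >= 2 columns")
            pid, flag = parts[0], parts[1]
            if flag not in ("Y", "N"):
                raise TopologyParseError(f"{path}:{lineno}: flag must be Y or N")
            rr = None
            if flag == "Y":
                if len(parts) < 3:
                    raise TopologyParseError(
                        f"{path}:{lineno}: flagged Y but no RR position")
                rr = int(parts[2])
            anns.append(TopologyAnnotation(
                protein_id=pid, tat_signal=rr, source="tatp_file"))
    return anns


_PARSERS = {
    "tmhmm": _parse_tmhmm,
    "sosui": _parse_sosui,
    "signalp": _parse_signalp,
    "tatp": _parse_tatp,
}


def parse_external_topology(path, format: str,
                            config: CensusConfig | None = None,
                            seq_lengths: dict[str, int] | None = None
                            ) -> list[TopologyAnnotation]:
    """Parse external predictor output into topology annotations.

    ``format`` is one of tmhmm, sosui, signalp, tatp.  Annotations carry a
    source tag and take precedence over heuristic ones for the same protein.
    """
    cfg = config or CensusConfig()
    if format not in _PARSERS:
        raise TopologyParseError(
            f"unknown format {format!r}; expected one of {sorted(_PARSERS)}")
    return _PARSERS[format](path, cfg, seq_lengths=seq_lengths)


def merge_annotations(anns: list[TopologyAnnotation]) -> dict[str, TopologyAnnotation]:
    """Merge per-source annotations for the same protein (union of evidence)."""
    out: dict[str, TopologyAnnotation] = {}
    for a in anns:
        if a.protein_id not in out:
            out[a.protein_id] = TopologyAnnotation(
                protein_id=a.protein_id, tmh_spans=list(a.tmh_spans),
                has_n_terminal_tmh=a.has_n_terminal_tmh,
                has_c_terminal_tmh=a.has_c_terminal_tmh,
                sec_signal=a.sec_signal, tat_signal=a.tat_signal,
                source=a.source)
        else:
            cur = out[a.protein_id]
            cur.tmh_spans.extend(s for s in a.tmh_spans if s not in cur.tmh_spans)
            cur.has_n_terminal_tmh |= a.has_n_terminal_tmh
            cur.has_c_terminal_tmh |= a.has_c_terminal_tmh
            cur.sec_signal = cur.sec_signal if cur.sec_signal is not None else a.sec_signal
            cur.tat_signal = cur.tat_signal if cur.tat_signal is not None else a.tat_signal
            cur.source = f"{cur.source}+{a.source}"
    return out


def write_annotation_table(anns: dict[str, TopologyAnnotation], path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tn_tmh\ttmh_spans\tn_terminal_tmh\tc_terminal_tmh"
                 "\tsec_cleavage\ttat_rr\tsource\n")
        for pid in sorted(anns):
            a = anns[pid]
            spans = ";".join(f"{s}-{e}" for s, e in a.tmh_spans)
            fh.write(f"{pid}\t{len(a.tmh_spans)}\t{spans}\t"
                     f"{int(a.has_n_terminal_tmh)}\t{int(a.has_c_terminal_tmh)}\t"
                     f"{a.sec_signal if a.sec_signal is not None else ''}\t"
                     f"{a.tat_signal if a.tat_signal is not None else ''}\t"
                     f"{a.source}\n")
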