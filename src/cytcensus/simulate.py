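"""Seeded synthetic proteomes with planted cytochromes, decoys and ccm genes.

The generator emulates the composition the census is designed to resolve:
per-species protein sets containing planted mono-/di-/multiheme cytochromes
(with Sec or TAT export signals or N-terminal membrane anchors), RecJ-like
decoys carrying 3 chance CxxCH motifs and no export topology,
thioredoxin-like decoys carrying 1 CxxCH plus an N-terminal TMH, random
background with a controlled motif rate, and planted CCM gene families.
Every record is covered by a ground-truth table, so pipeline recovery can
be asserted exactly.

Planted features are built from the same clause definitions the topology
heuristics test (a constructed Sec signal satisfies the n/h/c-region
clauses by construction), which makes end-to-end recovery exact by design;
the generator verifies each planted feature against the heuristics and
refuses to emit a record whose features would not be detected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from cytcensus.config import CensusConfig
from cytcensus.motif_scan import MotifGrammar, count_motifs, scan_protein
from cytcensus.proteome_io import ProteinRecord, ProteomeSet
from cytcensus.topology import (annotate_protein, predict_sec_signal,
                                predict_tat_signal, predict_tmh)

ALPHABET20 = "ACDEFGHIKLMNPQRSTVWY"
# bodies of planted records avoid C and H so motif counts are exact by
# construction (no chance CxxCH can arise)
BODY_ALPHABET = "ADEFGIKLMNPQRSTVWY"
# ccm gene bodies only need to avoid C (no cysteine -> no motif possible)
NO_C_ALPHABET = "ADEFGHIKLMNPQRSTVWY"
HYDROPHOBIC = "LIVF"

TAXON_ORDERS = ("Desulfurococcales", "Thermoproteales", "Archaeoglobales",
                "Methanosarcinales", "Halobacteriales")


# ---------------------------------------------------------------------------
# sequence constructors


def random_body(rng: np.random.Generator, length: int,
                alphabet: str = BODY_ALPHABET,
                freqs: np.ndarray | None = None) -> list[str]:
    letters = list(alphabet)
    if freqs is None:
        idx = rng.integers(0, len(letters), size=length)
    else:
        freqs = np.asarray(freqs, dtype=float)
        if len(freqs) != len(letters):
            raise ValueError("freqs length must match alphabet")
        if abs(freqs.sum() - 1.0) > 1e-9:
            raise ValueError("residue frequencies must sum to 1")
        idx = rng.choice(len(letters), size=length, p=freqs)
    return [letters[i] for i in idx]


def sec_signal_head(rng: np.random.Generator) -> str:
    """A Sec/GSP signal: charged n-region, >= 8-residue h-region, A-x-A site."""
    n_region = "M" + "".join(rng.choice(list("KR"), size=2))
    h_len = int(rng.integers(9, 13))
    h_region = "".join(rng.choice(list("LIV"), size=h_len))
    c_region = "A" + str(rng.choice(list("QNES"))) + "A"
    return n_region + h_region + c_region


def tat_signal_head(rng: np.random.Generator) -> str:
    """A twin-arginine signal: S-R-R-x-F-L-K core, then a weakly hydrophobic run."""
    core = "MSRRQFLK"
    tail = "".join(rng.choice(list("AL"), size=int(rng.integers(12, 15))))
    return core + tail


def tmh_head(rng: np.random.Generator, core_len: int = 28) -> str:
    """An N-terminal membrane anchor: a long strongly hydrophobic run."""
    core = "".join(rng.choice(list(HYDROPHOBIC), size=core_len))
    return "MK" + core + "KK"


def inject_motif(body: list[str], pos0: int, rng: np.random.Generator) -> None:
    """Write a CxxCH site into ``body`` at 0-based position ``pos0``."""
    if pos0 < 0 or pos0 + 5 > len(body):
        raise ValueError("motif does not fit at requested position")
    w = rng.choice(list(BODY_ALPHABET), size=2)
    body[pos0:pos0 + 5] = ["C", str(w[0]), str(w[1]), "C", "H"]


def choose_motif_positions(rng: np.random.Generator, body_len: int,
                           n_motifs: int, offset: int = 0) -> list[int]:
    """Non-overlapping 0-based motif starts, spaced >= 6 apart."""
    span = 6
    if body_len - offset < n_motifs * span + 5:
        raise ValueError(
            f"body of length {body_len} too short for {n_motifs} motifs")
    # place motifs in n_motifs equal slots, jittered within each slot
    slot = (body_len - offset - 5) // n_motifs
    starts = []
    for k in range(n_motifs):
        lo = offset + k * slot
        hi = offset + (k + 1) * slot - span
        starts.append(int(rng.integers(lo, max(lo + 1, hi))))
    return starts


def mutate(seq: str, rate: float, rng: np.random.Generator,
           protected: set[int] | None = None,
           alphabet: str = BODY_ALPHABET) -> str:
    """Per-site substitution at ``rate``, skipping protected 0-based positions."""
    protected = protected or set()
    out = list(seq)
    draws = rng.random(len(out))
    for i, (c, r) in enumerate(zip(out, draws)):
        if r < rate and i not in protected:
            choices = [a for a in alphabet if a != c]
            out[i] = str(rng.choice(choices))
    return "".join(out)


# ---------------------------------------------------------------------------
# specification and truth


@dataclass
class SyntheticSpec:
    """The stated world a synthetic census is generated from.

    Per-species composition defaults give ~200 proteins over 5 species:
    3 multiheme (3-12 hemes), one diheme each with a Sec signal, an
    N-terminal TMH and a TAT signal, a 4-member monoheme homolog family
    (N-terminal TMH; motif conserved in all members by default), 2
    RecJ-like and 2 thioredoxin-like decoys, and 22 random background
    proteins of mean length 300 with uniform residue frequencies (per-start
    chance CxxCH probability 0.05^2 * 0.05).  Three of the five species get
    a 4-family CCM complement (B, C, E, F), one gets CcmC only, one none.
    """

    n_species: int = 5
    n_multiheme: int = 3
    heme_range: tuple[int, int] = (3, 12)
    n_diheme_sec: int = 1
    n_diheme_tmh: int = 1
    n_diheme_tat: int = 1
    monoheme_family_size: int = 4
    monoheme_conservation: float = 1.0
    n_recj_decoys: int = 2
    n_thioredoxin_decoys: int = 2
    n_background: int = 22
    background_length: int = 300
    background_freqs: tuple[float, ...] | None = None  # over ALPHABET20
    mutation_rate: float = 0.08
    ccm_plan: tuple[tuple[str, ...], ...] | None = None  # families per species
    rng_seed: int = 0

    def __post_init__(self):
        counts = (self.n_species, self.n_multiheme, self.n_diheme_sec,
                  self.n_diheme_tmh, self.n_diheme_tat,
                  self.monoheme_family_size, self.n_recj_decoys,
                  self.n_thioredoxin_decoys, self.n_background)
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if not 0.0 <= self.monoheme_conservation <= 1.0:
            raise ValueError("monoheme_conservation must be in [0, 1]")
        lo, hi = self.heme_range
        if not 3 <= lo <= hi:
            raise ValueError("heme_range must satisfy 3 <= lo <= hi")
        if self.ccm_plan is not None and len(self.ccm_plan) != self.n_species:
            raise ValueError("ccm_plan must have one entry per species")

    def resolved_ccm_plan(self) -> tuple[tuple[str, ...], ...]:
        if self.ccm_plan is not None:
            return self.ccm_plan
        plan = []
        for i in range(self.n_species):
            if i < max(0, self.n_species - 2):
                plan.append(("B", "C", "E", "F"))
            elif i == self.n_species - 2:
                plan.append(("C",))
            else:
                plan.append(())
        return tuple(plan)


@dataclass(frozen=True)
class TruthRow:
    """Ground truth for one generated record."""

    protein_id: str
    species: str
    true_category: str        # multiheme / diheme / monoheme / none
    true_status: str          # predicted / candidate / rejected / none
    n_motifs: int
    motif_starts: tuple[int, ...] = ()   # 1-based
    signal_type: str = "none"            # sec / tat / tmh / none
    decoy_family: str | None = None
    homolog_group: str | None = None
    ccm_family: str | None = None


@dataclass
class TruthTable:
    rows: dict[str, TruthRow] = field(default_factory=dict)

    def add(self, row: TruthRow) -> None:
        if row.protein_id in self.rows:
            raise ValueError(f"duplicate truth row {row.protein_id}")
        self.rows[row.protein_id] = row

    def __len__(self):
        return len(self.rows)

    def __getitem__(self, pid: str) -> TruthRow:
        return self.rows[pid]

    def category_counts(self) -> dict[tuple[str, str], int]:
        """Counts by (true_category, true_status)."""
        out: dict[tuple[str, str], int] = {}
        for r in self.rows.values():
            key = (r.true_category, r.true_status)
            out[key] = out.get(key, 0) + 1
        return out

    def ccm_truth(self) -> dict[str, dict[str, int]]:
        """Per-species planted ccm family copy counts."""
        out: dict[str, dict[str, int]] = {}
        for r in self.rows.values():
            out.setdefault(r.species, {})
            if r.ccm_family:
                out[r.species][r.ccm_family] = \
                    out[r.species].get(r.ccm_family, 0) + 1
        return out

    def expected_ccm_status(self, min_families: int = 3) -> dict[str, str]:
        out = {}
        for sp, fams in self.ccm_truth().items():
            n = sum(1 for v in fams.values() if v >= 1)
            out[sp] = ("ccm_positive" if n >= min_families
                       else "ccm_sparse" if n >= 1 else "ccm_negative")
        return out

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("protein_id\tspecies\ttrue_category\ttrue_status\tn_motifs"
                     "\tmotif_starts\tsignal_type\tdecoy_family\thomolog_group"
                     "\tccm_family\n")
            for pid in sorted(self.rows):
                r = self.rows[pid]
                fh.write("\t".join([
                    r.protein_id, r.species, r.true_category, r.true_status,
                    str(r.n_motifs),
                    ",".join(map(str, r.motif_starts)),
                    r.signal_type, r.decoy_family or "", r.homolog_group or "",
                    r.ccm_family or "",
                ]) + "\n")


# ---------------------------------------------------------------------------
# analytic calibration


def expected_motif_count(length: int, residue_freqs: dict[str, float],
                         grammar: MotifGrammar | None = None) -> float:
    """Expected chance motif hits per protein under an i.i.d. residue model.

    For the default grammar this is ``(L - 4) * f_C^2 * f_H``; variant
    patterns contribute analogously (one term per allowed spacing).
    """
    grammar = grammar or MotifGrammar.default()
    total = 0.0
    f = residue_freqs.get
    for pat in grammar.patterns:
        for spacing in range(pat.spacing_min, pat.spacing_max + 1):
            plen = spacing + 3
            n_starts = max(0, length - plen + 1)
            total += n_starts * f("C", 0.0) ** 2 * f(pat.terminal, 0.0)
    return total


# ---------------------------------------------------------------------------
# generation


class _IdMint:
    def __init__(self):
        self.counter = 0

    def __call__(self, species_idx: int) -> str:
        self.counter += 1
        return f"S{species_idx + 1:02d}_P{self.counter:04d}"


def _head_protected(head_len: int) -> set[int]:
    return set(range(head_len))


def _build_planted(rng, head: str, n_motifs: int, body_len: int):
    """head + body with exactly ``n_motifs`` injected CxxCH sites."""
    body = random_body(rng, body_len)
    starts0 = choose_motif_positions(rng, body_len, n_motifs) if n_motifs else []
    for s in starts0:
        inject_motif(body, s, rng)
    seq = head + "".join(body)
    motif_starts = tuple(len(head) + s + 1 for s in starts0)  # 1-based
    return seq, motif_starts


def _check_detected(seq: str, signal_type: str, cfg: CensusConfig) -> None:
    if signal_type == "sec" and predict_sec_signal(seq, cfg) is None:
        raise AssertionError("planted Sec signal not detected by heuristics")
    if signal_type == "tat" and predict_tat_signal(seq, cfg) is None:
        raise AssertionError("planted TAT signal not detected by heuristics")
    if signal_type == "tmh":
        spans = predict_tmh(seq, cfg)
        if not any(s <= cfg.n_terminal_window for s, _ in spans):
            raise AssertionError("planted N-terminal TMH not detected by heuristics")


def generate_proteome(spec: SyntheticSpec,
                      config: CensusConfig | None = None,
                      decoy_refs=None) -> tuple[ProteomeSet, TruthTable]:
    """Generate a synthetic proteome set and its ground-truth table.

    ``decoy_refs`` may override the packaged decoy exemplar backbones
    (a mapping family -> ProteinRecord); by default the packaged synthetic
    RecJ-like and thioredoxin-like exemplars are used, so pipeline decoy
    screening recognises the planted decoys by similarity.
    """
    from cytcensus.references import load_decoy_backbones

    cfg = config or CensusConfig()
    rng = np.random.default_rng(spec.rng_seed)
    mint = _IdMint()
    if decoy_refs is None:
        decoy_refs = load_decoy_backbones()

    records: list[ProteinRecord] = []
    truth = TruthTable()

    def add(pid, species, taxon, seq, desc, row_kwargs):
        records.append(ProteinRecord(
            protein_id=pid, species=species, taxon_order=taxon,
            description=desc, sequence=seq))
        truth.add(TruthRow(protein_id=pid, species=species, **row_kwargs))

    ccm_plan = spec.resolved_ccm_plan()
    from cytcensus.references import load_ccm_queries
    ccm_seeds = load_ccm_queries().families if any(ccm_plan) else {}

    for si in range(spec.n_species):
        species = f"Synthetic_species_{si + 1:02d}"
        taxon = TAXON_ORDERS[si % len(TAXON_ORDERS)]

        # multiheme cytochromes: motif count alone is decisive
        for _ in range(spec.n_multiheme):
            n_hemes = int(rng.integers(spec.heme_range[0], spec.heme_range[1] + 1))
            body_len = max(250, n_hemes * 25 + 100)
            seq, starts = _build_planted(rng, "M", n_hemes, body_len)
            add(mint(si), species, taxon, seq, "synthetic multiheme cytochrome c",
                dict(true_category="multiheme", true_status="predicted",
                     n_motifs=n_hemes, motif_starts=starts))

        # diheme with Sec signal / N-terminal TMH / TAT signal
        for kind, n in (("sec", spec.n_diheme_sec), ("tmh", spec.n_diheme_tmh),
                        ("tat", spec.n_diheme_tat)):
            for _ in range(n):
                head = {"sec": sec_signal_head, "tat": tat_signal_head,
                        "tmh": tmh_head}[kind](rng)
                seq, starts = _build_planted(rng, head, 2, 200)
                _check_detected(seq, kind, cfg)
                add(mint(si), species, taxon, seq,
                    f"synthetic diheme cytochrome c ({kind})",
                    dict(true_category="diheme", true_status="predicted",
                         n_motifs=2, motif_starts=starts, signal_type=kind))

        # monoheme homolog family: common ancestor with N-terminal anchor,
        # motif conserved in a controlled fraction of the members
        if spec.monoheme_family_size:
            k = spec.monoheme_family_size
            head = tmh_head(rng)
            ancestor, starts = _build_planted(rng, head, 1, 180)
            motif0 = starts[0] - 1
            protected = _head_protected(len(head)) | set(range(motif0, motif0 + 5))
            n_with_motif = int(round(spec.monoheme_conservation * k))
            group = f"fam_{species}"
            for m in range(k):
                seq = mutate(ancestor, spec.mutation_rate, rng, protected)
                if m < n_with_motif:
                    _check_detected(seq, "tmh", cfg)
                    add(mint(si), species, taxon, seq,
                        "synthetic monoheme cytochrome c (homolog family)",
                        dict(true_category="monoheme", true_status="candidate",
                             n_motifs=1, motif_starts=starts, signal_type="tmh",
                             homolog_group=group))
                else:
                    # same fold, motif lost: first motif cysteine replaced
                    lost = list(seq)
                    lost[motif0] = "Y"
                    lost[motif0 + 4] = "Q"
                    add(mint(si), species, taxon, "".join(lost),
                        "synthetic homolog without motif",
                        dict(true_category="none", true_status="none",
                             n_motifs=0, signal_type="tmh",
                             homolog_group=group))

        # decoys: mutated copies of the packaged exemplar backbones
        for fam, n in (("RecJ", spec.n_recj_decoys),
                       ("thioredoxin", spec.n_thioredoxin_decoys)):
            backbone = decoy_refs[fam]
            hits = scan_protein(backbone.sequence)
            protected = set()
            for h in hits:
                protected |= set(range(h.start - 1, h.end))
            if fam == "thioredoxin":
                protected |= _head_protected(32)  # keep the anchor intact
            expected_n = len(hits)
            category = "multiheme" if expected_n >= 3 else "monoheme"
            for _ in range(n):
                seq = mutate(backbone.sequence, spec.mutation_rate, rng, protected)
                if count_motifs(seq) != expected_n:
                    raise AssertionError("decoy mutation altered motif count")
                add(mint(si), species, taxon, seq, f"synthetic {fam}-like decoy",
                    dict(true_category=category, true_status="rejected",
                         n_motifs=expected_n,
                         signal_type="tmh" if fam == "thioredoxin" else "none",
                         decoy_family=fam))

        # planted ccm genes (mutated copies of the family seeds)
        for fam in ccm_plan[si]:
            seed = ccm_seeds[fam][0]
            seq = mutate(seed.sequence, spec.mutation_rate, rng,
                         alphabet=NO_C_ALPHABET)
            add(mint(si), species, taxon, seq, f"synthetic Ccm{fam} homolog",
                dict(true_category="none", true_status="none", n_motifs=0,
                     ccm_family=fam))

        # random background with a controlled chance-motif rate
        for _ in range(spec.n_background):
            freqs = (np.asarray(spec.background_freqs)
                     if spec.background_freqs is not None else None)
            body = random_body(rng, spec.background_length,
                               alphabet=ALPHABET20, freqs=freqs)
            seq = "".join(body)
            add(mint(si), species, taxon, seq, "synthetic background protein",
                dict(true_category="none", true_status="none",
                     n_motifs=count_motifs(seq)))

    return ProteomeSet(records=records, provenance=[f"synthetic(seed={spec.rng_seed})"]), truth
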