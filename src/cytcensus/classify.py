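"""Per-protein cytochrome c calls from motif, topology, similarity and
structure evidence.

The decision rules, applied strictly in order:

1. a strong hit to a known false-positive family (RecJ exonucleases,
   thioredoxins/protein disulfide isomerases, polymerase subunits,
   molybdopterin biosynthesis proteins, endonucleases, Zn-binding domains,
   iron-sulfur proteins) rejects the protein whatever its motif count;
2. >= 3 motifs -> predicted multiheme cytochrome (no topology required:
   multiheme motif counts are specific enough on their own);
3. exactly 2 motifs -> predicted diheme if the protein has export topology
   (N-terminal TMH, Sec or TAT signal) or similarity to a known cytochrome;
4. exactly 1 motif -> monoheme *candidate* only with export topology AND
   corroboration (similarity to a known cytochrome, or motif conservation in
   at least half of its homologs); candidates await cluster-level structure
   adjudication;
5. no motif -> not a cytochrome.

Cluster-level adjudication then promotes or rejects whole clusters on
structure-prediction evidence (>= 96% confidence with a cytochrome template
accepts; 90-96% accepts with an "intermediate" flag; a confident
non-cytochrome template rejects).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from cytcensus.config import CensusConfig
from cytcensus.topology import TopologyAnnotation

DECOY_FAMILIES = (
    "RecJ", "thioredoxin", "polymerase_subunit", "molybdopterin",
    "endonuclease", "zinc_domain", "iron_sulfur", "other",
)

CATEGORIES = ("multiheme", "diheme", "monoheme", "none")
STATUSES = ("predicted", "candidate", "rejected")


@dataclass(frozen=True)
class EvidenceBundle:
    """Everything known about one protein when the rules are applied."""

    protein_id: str
    n_motifs: int
    topology: TopologyAnnotation | None = None
    best_cytc_hit: tuple[str, float] | None = None        # (ref_id, score)
    best_decoy_hit: tuple[str, float] | None = None       # (decoy_family, score)
    homolog_motif_conservation: float | None = None       # fraction in [0, 1]
    structure_evidence: tuple[float, str] | None = None   # (confidence_pct, template_class)

    def __post_init__(self):
        if self.n_motifs < 0:
            raise ValueError("n_motifs must be >= 0")
        if self.best_decoy_hit is not None:
            fam = self.best_decoy_hit[0]
            if fam not in DECOY_FAMILIES:
                raise ValueError(f"unknown decoy family {fam!r}")
        if self.homolog_motif_conservation is not None:
            if not 0.0 <= self.homolog_motif_conservation <= 1.0:
                raise ValueError("conservation fraction must be in [0, 1]")
        if self.structure_evidence is not None:
            conf, cls = self.structure_evidence
            if not 0.0 <= conf <= 100.0 or cls not in ("cytc", "non_cytc"):
                raise ValueError("bad structure evidence")

    @property
    def has_export_evidence(self) -> bool:
        return self.topology is not None and self.topology.has_export_evidence


@dataclass(frozen=True)
class CytcCall:
    """The classification outcome for one protein, with its audit trail."""

    protein_id: str
    category: str
    status: str
    evidence: EvidenceBundle
    rejection_reason: str | None = None
    flags: tuple[str, ...] = ()

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"bad category {self.category!r}")
        if self.category != "none" and self.status not in STATUSES:
            raise ValueError(f"bad status {self.status!r}")
        n = self.evidence.n_motifs
        if self.status != "rejected":
            if self.category == "multiheme" and n < 3:
                raise ValueError("multiheme requires n_motifs >= 3")
            if self.category == "diheme" and n != 2:
                raise ValueError("diheme requires n_motifs == 2")
            if self.category == "monoheme" and n != 1:
                raise ValueError("monoheme requires n_motifs == 1")
        if self.status == "rejected" and not self.rejection_reason:
            raise ValueError("rejected calls need a rejection_reason")

    @property
    def is_cytochrome(self) -> bool:
        return self.status in ("predicted", "candidate") and self.category != "none"


def _category_for(n: int) -> str:
    if n >= 3:
        return "multiheme"
    return {2: "diheme", 1: "monoheme", 0: "none"}[n]


def classify_protein(ev: EvidenceBundle, config: CensusConfig | None = None) -> CytcCall:
    """Apply the ordered decision rules (1)-(5) to one evidence bundle."""
    cfg = config or CensusConfig()
    n = ev.n_motifs

    # (1) known false-positive families win over everything else
    if ev.best_decoy_hit is not None and ev.best_decoy_hit[1] >= cfg.decoy_min_score:
        return CytcCall(ev.protein_id, _category_for(n), "rejected", ev,
                        rejection_reason=f"false_positive:{ev.best_decoy_hit[0]}")

    cytc_hit = (ev.best_cytc_hit is not None
                and ev.best_cytc_hit[1] >= cfg.cytc_min_score)

    # (2) multiheme: motif count alone suffices
    if n >= 3:
        return CytcCall(ev.protein_id, "multiheme", "predicted", ev)

    # (3) diheme: topology or cytochrome similarity
    if n == 2:
        if ev.has_export_evidence or cytc_hit:
            return CytcCall(ev.protein_id, "diheme", "predicted", ev)
        return CytcCall(ev.protein_id, "none", "none", ev)

    # (4) monoheme: topology AND corroboration -> candidate
    if n == 1:
        conserved = (ev.homolog_motif_conservation is not None
                     and ev.homolog_motif_conservation >= cfg.conservation_min)
        if ev.has_export_evidence and (cytc_hit or conserved):
            return CytcCall(ev.protein_id, "monoheme", "candidate", ev)
        return CytcCall(ev.protein_id, "none", "none", ev)

    # (5) no motif
    return CytcCall(ev.protein_id, "none", "none", ev)


def adjudicate_cluster(calls, cluster, structure=None,
                       config: CensusConfig | None = None) -> list[CytcCall]:
    """Cluster-level structure-evidence adjudication.

    ``structure`` is an optional ``(confidence_pct, template_class)`` pair
    for the whole cluster.  A confident cytochrome template promotes every
    candidate member to predicted (flagged ``intermediate`` in the 90-96%
    band); a confident non-cytochrome template rejects every member.
    Absent evidence leaves the calls unchanged.  Decoy rejections (rule 1)
    are never overridden.
    """
    cfg = config or CensusConfig()
    members = set(cluster.member_ids)
    for c in calls:
        if c.protein_id not in members:
            raise ValueError(
                f"call for {c.protein_id} does not belong to cluster {cluster.cluster_id}")
    if structure is None:
        return list(calls)
    conf, template_class = structure
    out = []
    for c in calls:
        if c.status == "rejected":
            out.append(c)
        elif template_class == "cytc" and conf >= cfg.accept_conf:
            if c.status == "candidate":
                c = replace(c, status="predicted")
            out.append(c)
        elif template_class == "cytc" and cfg.flag_conf <= conf < cfg.accept_conf:
            if c.status == "candidate":
                c = replace(c, status="predicted",
                            flags=tuple(c.flags) + ("intermediate",))
            out.append(c)
        elif template_class == "non_cytc" and conf >= cfg.accept_conf:
            out.append(replace(c, status="rejected",
                               rejection_reason="structure_non_cytc"))
        else:
            out.append(c)
    return out


def write_call_table(calls, path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tcategory\tstatus\trejection_reason\tn_motifs"
                 "\texport_evidence\tcytc_hit\tdecoy_hit\tconservation\tflags\n")
        for c in sorted(calls, key=lambda c: c.protein_id):
            ev = c.evidence
            fh.write("\t".join([
                c.protein_id, c.category, c.status, c.rejection_reason or "",
                str(ev.n_motifs), str(int(ev.has_export_evidence)),
                f"{ev.best_cytc_hit[1]:g}" if ev.best_cytc_hit else "",
                f"{ev.best_decoy_hit[0]}:{ev.best_decoy_hit[1]:g}" if ev.best_decoy_hit else "",
                f"{ev.homolog_motif_conservation:.2f}"
                if ev.homolog_motif_conservation is not None else "",
                ";".join(c.flags),
            ]) + "\n")
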