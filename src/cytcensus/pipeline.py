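"""Census orchestration: scan -> topology -> classify -> cluster -> ccm -> report.

``run_census`` executes the whole survey over a proteome set in a fixed
stage order, persisting intermediate tables when an output directory is
given, and returns a :class:`CensusReport` whose summary mirrors the
classical census-statistics table: per-category candidate / topology /
predicted / false-positive counts, cluster count, per-species distribution
split by maturation-gene status, and the motif-count histogram.  Every
threshold used is echoed into the report so results carry their provenance.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from cytcensus import references
from cytcensus.ccm import CcmProfile, ccm_status, iterative_search, write_ccm_table
from cytcensus.classify import (CytcCall, EvidenceBundle, adjudicate_cluster,
                                classify_protein, write_call_table)
from cytcensus.config import CensusConfig
from cytcensus.motif_scan import (MotifGrammar, motif_histogram, scan_protein,
                                  write_hit_table)
from cytcensus.proteome_io import ProteomeSet, deduplicate_records, write_dedup_report
from cytcensus.similarity import (AlignParams, align_pair, all_vs_all,
                                  build_clusters, write_cluster_table,
                                  write_edge_table)
from cytcensus.topology import annotate_protein, write_annotation_table

logger = logging.getLogger("cytcensus")

CATEGORY_ORDER = ("multiheme", "diheme", "monoheme")


@dataclass
class CategoryStats:
    """Census statistics for one heme-count category."""

    n_candidates: int = 0        # proteins in the motif-count band
    n_with_topology: int = 0     # same, with N-term TMH and/or signal
    n_accepted: int = 0          # predicted (or monoheme candidates)
    n_rejected_decoy: int = 0    # rejected as known false-positive families
    n_rejected_structure: int = 0
    n_not_accepted: int = 0      # fell through the rules to 'none'
    n_species: int = 0           # species with accepted proteins


@dataclass
class CensusReport:
    """The full outcome of one census run."""

    n_proteins: int
    n_species: int
    n_proteins_with_motif: int
    n_motif_hits_total: int
    n_duplicated_records: int
    n_unique_among_duplicates: int
    category_stats: dict[str, CategoryStats]
    n_predicted_total: int
    n_clusters: int
    histogram: dict[int, int]
    species_table: pd.DataFrame
    config: dict
    calls: list[CytcCall] = field(repr=False, default_factory=list)
    clusters: list = field(repr=False, default_factory=list)
    ccm_profiles: list[CcmProfile] = field(repr=False, default_factory=list)
    stage_log: list[str] = field(default_factory=list)

    def accepted_calls(self) -> list[CytcCall]:
        return [c for c in self.calls if c.is_cytochrome]

    def summary_dict(self) -> dict:
        d = {
            "n_proteins": self.n_proteins,
            "n_species": self.n_species,
            "n_proteins_with_motif": self.n_proteins_with_motif,
            "n_motif_hits_total": self.n_motif_hits_total,
            "n_duplicated_records": self.n_duplicated_records,
            "n_unique_among_duplicates": self.n_unique_among_duplicates,
            "n_predicted_total": self.n_predicted_total,
            "n_clusters": self.n_clusters,
            "histogram": {str(k): v for k, v in self.histogram.items()},
            "config": self.config,
        }
        for cat in CATEGORY_ORDER:
            s = self.category_stats[cat]
            d[cat] = {
                "candidates": s.n_candidates,
                "with_topology": s.n_with_topology,
                "accepted": s.n_accepted,
                "rejected_decoy": s.n_rejected_decoy,
                "rejected_structure": s.n_rejected_structure,
                "not_accepted": s.n_not_accepted,
                "species": s.n_species,
            }
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _category_band(n: int) -> str | None:
    if n >= 3:
        return "multiheme"
    if n == 2:
        return "diheme"
    if n == 1:
        return "monoheme"
    return None


def run_census(ps: ProteomeSet, config: CensusConfig | None = None,
               outdir=None,
               decoy_refs=None, cytc_refs=None, ccm_queries=None,
               structure_evidence: dict[int, tuple[float, str]] | None = None,
               topology_annotations=None,
               motif_counts: dict[str, int] | None = None) -> CensusReport:
    """Run the full cytochrome c census over a proteome set.

    Parameters
    ----------
    ps:
        Input proteome set (deduplicated internally).
    config:
        Thresholds; defaults are the package defaults, echoed into the report.
    outdir:
        If given, every intermediate table is persisted there as TSV/JSON.
    decoy_refs / cytc_refs / ccm_queries:
        Reference sets; packaged synthetic exemplars by default.
    structure_evidence:
        Optional cluster-level evidence ``{cluster_id: (confidence_pct,
        "cytc"|"non_cytc")}`` applied after clustering.
    topology_annotations / motif_counts:
        Optional precomputed intermediates (e.g. parsed external predictor
        files); stages that received their result are skipped.
    """
    cfg = config or CensusConfig()
    grammar = MotifGrammar.build(cfg.enable_cxxck, cfg.spacing_min, cfg.spacing_max)
    params = AlignParams.from_config(cfg)
    out = Path(outdir) if outdir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    def stage(msg):
        logger.info(msg)
        log.append(msg)

    # ---- stage 1: deduplication ------------------------------------------
    deduped, dup_report = deduplicate_records(ps)
    n_dup_records = sum(len(v) for v in dup_report.values())
    stage(f"dedup: {len(ps)} records -> {len(deduped)} "
          f"({n_dup_records} in {len(dup_report)} duplicate groups)")
    if out:
        write_dedup_report(dup_report, out / "dedup_report.tsv")

    # ---- stage 2: motif scan ---------------------------------------------
    all_hits = []
    counts: dict[str, int] = {}
    if motif_counts is None:
        for rec in deduped:
            hits = scan_protein(rec.sequence, grammar, protein_id=rec.protein_id)
            counts[rec.protein_id] = len(hits)
            all_hits.extend(hits)
    else:
        counts = dict(motif_counts)
        missing = [r.protein_id for r in deduped if r.protein_id not in counts]
        if missing:
            raise ValueError(f"motif_counts missing records, e.g. {missing[:3]}")
    motif_positive = [r for r in deduped if counts[r.protein_id] >= 1]
    histogram = {}
    for rec in deduped:
        histogram[counts[rec.protein_id]] = histogram.get(counts[rec.protein_id], 0) + 1
    histogram = dict(sorted(histogram.items()))
    stage(f"motif scan: {len(motif_positive)} proteins with >= 1 motif "
          f"({sum(counts.values())} total hits)")
    if out and all_hits:
        write_hit_table(all_hits, out / "motif_hits.tsv")

    # ---- stage 3: topology (heuristics, unless precomputed/external) -----
    if topology_annotations is None:
        topo = {r.protein_id: annotate_protein(r, cfg) for r in motif_positive}
    else:
        topo = dict(topology_annotations)
        for r in motif_positive:
            if r.protein_id not in topo:
                topo[r.protein_id] = annotate_protein(r, cfg)
    stage(f"topology: {sum(1 for r in motif_positive if topo[r.protein_id].has_export_evidence)}"
          f"/{len(motif_positive)} motif-positive proteins with export evidence")
    if out:
        write_annotation_table(topo, out / "topology.tsv")

    # ---- stage 4: decoy / reference / conservation evidence --------------
    if decoy_refs is None:
        decoy_ps, decoy_families = references.load_decoy_references()
    else:
        decoy_ps, decoy_families = decoy_refs
    cytc_ps = cytc_refs if cytc_refs is not None else references.load_cytc_references()

    best_decoy: dict[str, tuple[str, float]] = {}
    for rec in motif_positive:
        best = None
        for ref in decoy_ps:
            score, _, _ = align_pair(ref.sequence, rec.sequence, params)
            if best is None or score > best[1]:
                best = (decoy_families[ref.protein_id], score)
        if best and best[1] > 0:
            best_decoy[rec.protein_id] = best

    low_band = [r for r in motif_positive if counts[r.protein_id] in (1, 2)]
    best_cytc: dict[str, tuple[str, float]] = {}
    for rec in low_band:
        best = None
        for ref in cytc_ps:
            score, _, _ = align_pair(ref.sequence, rec.sequence, params)
            if best is None or score > best[1]:
                best = (ref.protein_id, score)
        if best and best[1] > 0:
            best_cytc[rec.protein_id] = best

    # homolog motif conservation for monoheme corroboration: similarity
    # neighbours anywhere in the deduplicated proteome
    conservation: dict[str, float] = {}
    mono_band = [r for r in motif_positive if counts[r.protein_id] == 1]
    for rec in mono_band:
        neighbours = []
        for other in deduped:
            if other.protein_id == rec.protein_id:
                continue
            score, ident, aln_len = align_pair(rec.sequence, other.sequence, params)
            min_len = min(len(rec.sequence), len(other.sequence))
            if score >= params.min_score and ident >= params.min_identity \
                    and aln_len >= params.min_coverage * min_len:
                neighbours.append(other.protein_id)
        if neighbours:
            conserved = sum(1 for pid in neighbours if counts[pid] >= 1)
            conservation[rec.protein_id] = conserved / len(neighbours)
    stage(f"evidence: {len(best_decoy)} decoy hits, {len(best_cytc)} reference hits, "
          f"{len(conservation)} conservation fractions")

    # ---- stage 5: per-protein classification -----------------------------
    calls: list[CytcCall] = []
    for rec in motif_positive:
        ev = EvidenceBundle(
            protein_id=rec.protein_id,
            n_motifs=counts[rec.protein_id],
            topology=topo[rec.protein_id],
            best_cytc_hit=best_cytc.get(rec.protein_id),
            best_decoy_hit=best_decoy.get(rec.protein_id),
            homolog_motif_conservation=conservation.get(rec.protein_id),
        )
        calls.append(classify_protein(ev, cfg))
    stage(f"classify: {sum(1 for c in calls if c.is_cytochrome)} accepted, "
          f"{sum(1 for c in calls if c.status == 'rejected')} rejected")

    # ---- stage 6: clustering of the accepted set --------------------------
    accepted_ids = [c.protein_id for c in calls if c.is_cytochrome]
    accepted_set = deduped.subset(accepted_ids)
    edges = all_vs_all(accepted_set, params) if len(accepted_set) >= 2 else []
    clusters = build_clusters(edges, accepted_set) if accepted_ids else []
    stage(f"cluster: {len(accepted_ids)} proteins in {len(clusters)} clusters")
    if out:
        write_edge_table(edges, out / "similarity_edges.tsv")
        write_cluster_table(clusters, out / "clusters.tsv")

    # ---- stage 7: cluster-level structure adjudication --------------------
    if structure_evidence:
        by_id = {c.protein_id: c for c in calls}
        for cl in clusters:
            ev = structure_evidence.get(cl.cluster_id)
            if ev is None:
                continue
            member_calls = [by_id[pid] for pid in cl.member_ids if pid in by_id]
            for updated in adjudicate_cluster(member_calls, cl, ev, cfg):
                by_id[updated.protein_id] = updated
        calls = [by_id[c.protein_id] for c in calls]
        stage("structure adjudication applied to "
              f"{len(structure_evidence)} clusters")
    if out:
        write_call_table(calls, out / "calls.tsv")

    # ---- stage 8: ccm census ---------------------------------------------
    queries = ccm_queries if ccm_queries is not None else references.load_ccm_queries()
    ccm_hits = iterative_search(queries, deduped, rounds=cfg.ccm_rounds,
                                min_score=cfg.ccm_min_score)
    profiles = ccm_status(deduped, ccm_hits, cfg)
    stage(f"ccm: {len(ccm_hits)} maturation-gene homologs; "
          f"{sum(1 for p in profiles if p.status == 'ccm_positive')} ccm-positive species")
    if out:
        write_ccm_table(profiles, out / "ccm_profiles.tsv")

    # ---- stage 9: report assembly ----------------------------------------
    by_id_call = {c.protein_id: c for c in calls}
    stats = {cat: CategoryStats() for cat in CATEGORY_ORDER}
    species_accepted: dict[str, set[str]] = {cat: set() for cat in CATEGORY_ORDER}
    for rec in motif_positive:
        band = _category_band(counts[rec.protein_id])
        s = stats[band]
        s.n_candidates += 1
        if topo[rec.protein_id].has_export_evidence:
            s.n_with_topology += 1
        call = by_id_call[rec.protein_id]
        if call.is_cytochrome:
            s.n_accepted += 1
            species_accepted[band].add(rec.species)
        elif call.status == "rejected":
            if call.rejection_reason.startswith("false_positive"):
                s.n_rejected_decoy += 1
            else:
                s.n_rejected_structure += 1
        else:
            s.n_not_accepted += 1
    for cat in CATEGORY_ORDER:
        stats[cat].n_species = len(species_accepted[cat])
    n_predicted_total = sum(stats[c].n_accepted for c in CATEGORY_ORDER)

    prof_by_species = {p.species: p for p in profiles}
    rows = []
    for species in deduped.species:
        p = prof_by_species[species]
        accepted = [by_id_call[r.protein_id] for r in deduped
                    if r.species == species and r.protein_id in by_id_call
                    and by_id_call[r.protein_id].is_cytochrome]
        rows.append({
            "species": species,
            "n_mcc": sum(1 for c in accepted if c.category == "multiheme"),
            "n_mono_di": sum(1 for c in accepted if c.category in ("diheme", "monoheme")),
            **{f"ccm{f}": p.family_counts[f] for f in "BCEFH"},
            "ccm_status": p.status,
        })
    species_table = pd.DataFrame(rows)

    report = CensusReport(
        n_proteins=len(deduped),
        n_species=len(deduped.species),
        n_proteins_with_motif=len(motif_positive),
        n_motif_hits_total=sum(counts.values()),
        n_duplicated_records=n_dup_records,
        n_unique_among_duplicates=len(dup_report),
        category_stats=stats,
        n_predicted_total=n_predicted_total,
        n_clusters=len(clusters),
        histogram=histogram,
        species_table=species_table,
        config=cfg.to_dict(),
        calls=calls,
        clusters=clusters,
        ccm_profiles=profiles,
        stage_log=log,
    )
    if out:
        report.to_json(out / "census_report.json")
        species_table.to_csv(out / "species_table.tsv", sep="\t", index=False)
    return report


def per_species_matrix(report: CensusReport) -> pd.DataFrame:
    """Per-species distribution table, partitioned by maturation status.

    One row per species with predicted multiheme count, combined mono/diheme
    count and the CcmB..CcmH homolog counts; the ``block`` column splits
    species with a significant (>= 3 families) CCM complement ("A") from
    those without ("B"), mirroring the census figure layout.
    """
    df = report.species_table.copy()
    df["block"] = ["A" if s == "ccm_positive" else "B" for s in df["ccm_status"]]
    return df.sort_values(["block", "species"]).reset_index(drop=True)
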