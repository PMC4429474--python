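"""Cytochrome c maturation (CCM, system I) gene census.

Detects CcmB/C/E/F/H homologs per species by similarity search with seed
sequences, iterated so that hits recruit further low-similarity homologs
(similarities between unrelated archaea are often low, so a single round
with the original seeds misses transitive homologs).  Each species is then
assigned a maturation status: ``ccm_positive`` with >= 3 of the 5 families
present, ``ccm_sparse`` with 1-2, ``ccm_negative`` with none.

Maturation systems II-V (ResB, heme lyases, CCB proteins) can be searched
through the same engine by supplying additional query families; the
packaged defaults cover system I only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from cytcensus.config import CensusConfig
from cytcensus.proteome_io import ProteinRecord, ProteomeSet
from cytcensus.similarity import AlignParams, align_pair

CCM_FAMILIES = ("B", "C", "E", "F", "H")


@dataclass
class CcmQuerySet:
    """Seed sequences per maturation-gene family.

    All five system-I families must be present as keys (H may be empty:
    CcmH homologs are genuinely rare in archaea).
    """

    families: dict[str, list[ProteinRecord]]
    provenance: str = ""

    def __post_init__(self):
        missing = [f for f in CCM_FAMILIES if f not in self.families]
        if missing:
            raise ValueError(f"missing CCM families: {missing}")
        for fam, seeds in self.families.items():
            if fam != "H" and not seeds:
                raise ValueError(f"family {fam} has no seeds")
            for s in seeds:
                if not s.sequence:
                    raise ValueError(f"empty seed in family {fam}")


@dataclass(frozen=True)
class CcmHit:
    protein_id: str
    family: str
    score: float
    query_id: str


@dataclass(frozen=True)
class CcmProfile:
    """Per-species maturation-gene complement and status."""

    species: str
    family_counts: dict[str, int]
    status: str

    def __post_init__(self):
        if self.status not in ("ccm_positive", "ccm_sparse", "ccm_negative"):
            raise ValueError(f"bad status {self.status!r}")
        if any(v < 0 for v in self.family_counts.values()):
            raise ValueError("family counts must be >= 0")

    @property
    def n_families_present(self) -> int:
        return sum(1 for v in self.family_counts.values() if v >= 1)


def search_family(family_seeds: dict[str, list[ProteinRecord]],
                  target: ProteomeSet,
                  params: AlignParams | None = None,
                  min_score: float | None = None) -> dict[str, CcmHit]:
    """One similarity-search round of all families against a proteome.

    Every target protein scoring >= ``min_score`` against any seed, with
    the alignment covering ``min_coverage`` of the shorter sequence, is a
    hit; a protein hitting several families is assigned to its best-scoring
    one (ties broken by family letter, then query id).
    Returns protein_id -> best CcmHit.
    """
    cfg = CensusConfig()
    params = params or AlignParams.from_config(cfg)
    threshold = cfg.ccm_min_score if min_score is None else min_score
    hits: dict[str, CcmHit] = {}
    for rec in target:
        best: CcmHit | None = None
        for fam in CCM_FAMILIES:
            for seed in family_seeds.get(fam, []):
                score, _, aln_len = align_pair(seed.sequence, rec.sequence, params)
                min_len = min(len(seed.sequence), len(rec.sequence))
                if score < threshold or aln_len < params.min_coverage * min_len:
                    continue
                cand = CcmHit(rec.protein_id, fam, score, seed.protein_id)
                if best is None or (-cand.score, cand.family, cand.query_id) < \
                        (-best.score, best.family, best.query_id):
                    best = cand
        if best is not None:
            hits[rec.protein_id] = best
    return hits


def iterative_search(queries: CcmQuerySet, target: ProteomeSet,
                     rounds: int = 3,
                     params: AlignParams | None = None,
                     min_score: float | None = None) -> dict[str, CcmHit]:
    """Iterated similarity search: hits recruit further homologs.

    Round 1 uses the original seeds; each later round adds the previous
    round's hit sequences to the query set of their assigned family.  Stops
    early at a fixpoint (no new hits).  The hit set grows monotonically:
    a protein once assigned keeps its original family assignment.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    seeds: dict[str, list[ProteinRecord]] = {
        fam: list(s) for fam, s in queries.families.items()}
    hits = search_family(seeds, target, params, min_score)
    for _ in range(rounds - 1):
        grown = {fam: seeds[fam] + _hits_as_seeds(hits, target)[fam]
                 for fam in CCM_FAMILIES}
        new = search_family(grown, target, params, min_score)
        added = {pid: h for pid, h in new.items() if pid not in hits}
        if not added:
            break
        hits.update(added)
    return hits


def _hits_as_seeds(hits: dict[str, CcmHit], target: ProteomeSet
                   ) -> dict[str, list[ProteinRecord]]:
    by_family: dict[str, list[ProteinRecord]] = {f: [] for f in CCM_FAMILIES}
    for pid, h in sorted(hits.items()):
        by_family[h.family].append(target.get(pid))
    return by_family


def ccm_status(ps: ProteomeSet, hits: dict[str, CcmHit],
               config: CensusConfig | None = None) -> list[CcmProfile]:
    """Per-species family counts and maturation status.

    A species is ``ccm_positive`` with >= ``ccm_positive_min_families``
    distinct families detected (or gene copies, if ``ccm_count_copies``),
    ``ccm_sparse`` with some but fewer, ``ccm_negative`` with none.
    """
    cfg = config or CensusConfig()
    for pid in hits:
        if pid not in ps:
            raise ValueError(f"hit references protein {pid!r} absent from proteome")
    profiles = []
    for species in ps.species:
        counts = {f: 0 for f in CCM_FAMILIES}
        for pid in ps.species_index[species]:
            if pid in hits:
                counts[hits[pid].family] += 1
        if cfg.ccm_count_copies:
            n = sum(counts.values())
        else:
            n = sum(1 for v in counts.values() if v >= 1)
        if n >= cfg.ccm_positive_min_families:
            status = "ccm_positive"
        elif n >= 1:
            status = "ccm_sparse"
        else:
            status = "ccm_negative"
        profiles.append(CcmProfile(species, counts, status))
    return profiles


def write_ccm_table(profiles: list[CcmProfile], path) -> None:
    with open(path, "w") as fh:
        fh.write("species\t" + "\t".join(f"ccm{f}" for f in CCM_FAMILIES)
                 + "\tstatus\n")
        for p in sorted(profiles, key=lambda p: p.species):
            fh.write(p.species + "\t"
                     + "\t".join(str(p.family_counts[f]) for f in CCM_FAMILIES)
                     + f"\t{p.status}\n")
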