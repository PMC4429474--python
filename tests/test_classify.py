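"""The ordered cytochrome c decision rules and cluster-level adjudication."""

import itertools

import pytest

from cytcensus.classify import (CytcCall, EvidenceBundle, adjudicate_cluster,
                                classify_protein)
from cytcensus.config import CensusConfig
from cytcensus.similarity import ClusterAssignment
from cytcensus.topology import TopologyAnnotation

CFG = CensusConfig()


def _topo(pid="p", tmh=False, sec=False, tat=False):
    return TopologyAnnotation(
        protein_id=pid,
        tmh_spans=[(5, 25)] if tmh else [],
        has_n_terminal_tmh=tmh,
        sec_signal=20 if sec else None,
        tat_signal=3 if tat else None,
    )


def _ev(n, tmh=False, sec=False, tat=False, cytc=None, decoy=None,
        conservation=None):
    return EvidenceBundle(
        protein_id="p", n_motifs=n,
        topology=_topo(tmh=tmh, sec=sec, tat=tat),
        best_cytc_hit=("ref", cytc) if cytc is not None else None,
        best_decoy_hit=decoy,
        homolog_motif_conservation=conservation,
    )


class TestClassifyExamples:
    def test_recj_decoy_rejected_despite_three_motifs(self):
        call = classify_protein(_ev(3, decoy=("RecJ", 300.0)), CFG)
        assert call.status == "rejected"
        assert call.rejection_reason == "false_positive:RecJ"

    def test_multiheme_without_topology_predicted(self):
        call = classify_protein(_ev(5), CFG)
        assert (call.category, call.status) == ("multiheme", "predicted")

    def test_diheme_with_sec_signal_predicted(self):
        call = classify_protein(_ev(2, sec=True), CFG)
        assert (call.category, call.status) == ("diheme", "predicted")

    def test_thioredoxin_decoy_with_tmh_rejected(self):
        call = classify_protein(_ev(1, tmh=True, decoy=("thioredoxin", 200.0)), CFG)
        assert call.status == "rejected"
        assert call.rejection_reason == "false_positive:thioredoxin"

    def test_no_motif_is_none(self):
        call = classify_protein(_ev(0), CFG)
        assert call.category == "none"

    def test_monoheme_needs_topology_and_corroboration(self):
        assert classify_protein(_ev(1, tmh=True, conservation=0.8), CFG).status == "candidate"
        assert classify_protein(_ev(1, conservation=0.8), CFG).category == "none"
        assert classify_protein(_ev(1, tmh=True), CFG).category == "none"
        assert classify_protein(_ev(1, tmh=True, cytc=100.0), CFG).status == "candidate"

    def test_weak_decoy_hit_does_not_reject(self):
        call = classify_protein(_ev(3, decoy=("RecJ", CFG.decoy_min_score - 1)), CFG)
        assert call.status == "predicted"


def rule_oracle(ev, cfg):
    """Literal re-statement of rules (1)-(5), kept independent of the code."""
    n = ev.n_motifs
    topo = ev.topology is not None and (
        ev.topology.has_n_terminal_tmh or ev.topology.sec_signal is not None
        or ev.topology.tat_signal is not None)
    cytc = ev.best_cytc_hit is not None and ev.best_cytc_hit[1] >= cfg.cytc_min_score
    cons = (ev.homolog_motif_conservation is not None
            and ev.homolog_motif_conservation >= cfg.conservation_min)
    if ev.best_decoy_hit is not None and ev.best_decoy_hit[1] >= cfg.decoy_min_score:
        return "rejected"
    if n >= 3:
        return ("multiheme", "predicted")
    if n == 2:
        return ("diheme", "predicted") if (topo or cytc) else ("none", "none")
    if n == 1:
        return ("monoheme", "candidate") if (topo and (cytc or cons)) else ("none", "none")
    return ("none", "none")


class TestDecisionTableCompleteness:
    def test_exhaustive_grid_matches_rule_oracle(self):
        """Every boolean evidence combination x motif count maps per the rules."""
        grid = itertools.product(
            (0, 1, 2, 3, 8),                      # n_motifs
            (False, True),                        # N-terminal TMH
            (False, True),                        # Sec signal
            (False, True),                        # TAT signal
            (None, CFG.cytc_min_score - 1, CFG.cytc_min_score),
            (None, ("RecJ", CFG.decoy_min_score - 1), ("RecJ", CFG.decoy_min_score)),
            (None, 0.4, 0.5, 1.0),                # conservation fraction
        )
        for n, tmh, sec, tat, cytc, decoy, cons in grid:
            ev = _ev(n, tmh=tmh, sec=sec, tat=tat, cytc=cytc, decoy=decoy,
                     conservation=cons)
            call = classify_protein(ev, CFG)
            expected = rule_oracle(ev, CFG)
            if expected == "rejected":
                assert call.status == "rejected", ev
            else:
                assert (call.category, call.status) == expected, ev

    def test_monotonicity_decoy_and_cytc_hits(self):
        for n in (1, 2, 3):
            base = classify_protein(_ev(n, tmh=True, conservation=1.0), CFG)
            with_decoy = classify_protein(
                _ev(n, tmh=True, conservation=1.0, decoy=("RecJ", 500.0)), CFG)
            assert base.status != "rejected" and with_decoy.status == "rejected"
        # adding a cytc hit can only move none -> candidate/predicted
        none_call = classify_protein(_ev(2), CFG)
        with_hit = classify_protein(_ev(2, cytc=200.0), CFG)
        assert none_call.category == "none" and with_hit.status == "predicted"


class TestCallValidation:
    def test_category_motif_consistency_enforced(self):
        with pytest.raises(ValueError):
            CytcCall("p", "multiheme", "predicted", _ev(2))
        with pytest.raises(ValueError):
            CytcCall("p", "diheme", "predicted", _ev(1))

    def test_rejection_requires_reason(self):
        with pytest.raises(ValueError):
            CytcCall("p", "multiheme", "rejected", _ev(3))

    def test_bad_decoy_family_rejected(self):
        with pytest.raises(ValueError):
            _ev(1, decoy=("not_a_family", 300.0))


def _cluster(ids):
    return ClusterAssignment(cluster_id=1, member_ids=tuple(ids),
                             representative_id=ids[0])


def _candidate(pid):
    ev = EvidenceBundle(protein_id=pid, n_motifs=1, topology=_topo(pid, tmh=True),
                        homolog_motif_conservation=1.0)
    return classify_protein(ev, CFG)


class TestAdjudicateCluster:
    def test_confident_cytc_template_promotes(self):
        calls = [_candidate("a"), _candidate("b")]
        out = adjudicate_cluster(calls, _cluster(["a", "b"]), (98.0, "cytc"), CFG)
        assert all(c.status == "predicted" for c in out)
        assert all("intermediate" not in c.flags for c in out)

    def test_intermediate_band_promotes_with_flag(self):
        out = adjudicate_cluster([_candidate("a")], _cluster(["a"]),
                                 (90.0, "cytc"), CFG)
        assert out[0].status == "predicted" and "intermediate" in out[0].flags

    def test_confident_non_cytc_rejects_all(self):
        out = adjudicate_cluster([_candidate("a")], _cluster(["a"]),
                                 (99.0, "non_cytc"), CFG)
        assert out[0].status == "rejected"
        assert out[0].rejection_reason == "structure_non_cytc"

    def test_absent_evidence_unchanged(self):
        calls = [_candidate("a")]
        assert adjudicate_cluster(calls, _cluster(["a"]), None, CFG) == calls

    def test_low_confidence_non_cytc_unchanged(self):
        out = adjudicate_cluster([_candidate("a")], _cluster(["a"]),
                                 (80.0, "non_cytc"), CFG)
        assert out[0].status == "candidate"

    def test_decoy_rejection_never_overridden(self):
        ev = EvidenceBundle(protein_id="a", n_motifs=1,
                            topology=_topo("a", tmh=True),
                            best_decoy_hit=("thioredoxin", 300.0))
        rejected = classify_protein(ev, CFG)
        out = adjudicate_cluster([rejected], _cluster(["a"]), (99.0, "cytc"), CFG)
        assert out[0].status == "rejected"

    def test_membership_mismatch_error(self):
        with pytest.raises(ValueError):
            adjudicate_cluster([_candidate("zzz")], _cluster(["a"]),
                               (99.0, "cytc"), CFG)
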