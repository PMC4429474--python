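"""Hydropathy profiles, TMH/Sec/TAT heuristics and external-format adapters."""

import numpy as np
import pytest

from cytcensus.config import CensusConfig
from cytcensus.simulate import sec_signal_head, tat_signal_head, tmh_head
from cytcensus.topology import (KYTE_DOOLITTLE, TopologyAnnotation,
                                TopologyParseError, annotate_protein,
                                hydropathy_profile, merge_annotations,
                                parse_external_topology, predict_sec_signal,
                                predict_tat_signal, predict_tmh)

CFG = CensusConfig()


class TestHydropathy:
    def test_poly_ile_single_window(self):
        assert hydropathy_profile("I" * 19, window=19) == [pytest.approx(4.5)]

    def test_poly_arg_single_window(self):
        assert hydropathy_profile("R" * 19, window=19) == [pytest.approx(-4.5)]

    def test_matches_direct_summation(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWYX"), size=21))
        prof = hydropathy_profile(seq, window=7)
        expected = [np.mean([KYTE_DOOLITTLE.get(c, 0.0) for c in seq[i:i + 7]])
                    for i in range(len(seq) - 6)]
        assert prof == pytest.approx(expected)

    def test_short_sequence_empty_profile(self):
        assert hydropathy_profile("MKT", window=19) == []

    def test_window_validation(self):
        with pytest.raises(ValueError):
            hydropathy_profile("A" * 30, window=8)


class TestPredictTmh:
    def test_hydrophobic_core_detected(self):
        seq = "KK" + "L" * 25 + "KK" + "G" * 40
        spans = predict_tmh(seq)
        assert len(spans) == 1
        s, e = spans[0]
        # span (window centres) lies within the poly-L core region
        assert 3 <= s <= 12 and 18 <= e <= 27

    def test_all_glycine_no_span(self):
        assert predict_tmh("G" * 60) == []

    def test_two_separated_runs_two_spans(self):
        seq = "KK" + "L" * 30 + "DDRRKKDDRRKKDDRRKKDD" + "L" * 30 + "KK"
        assert len(predict_tmh(seq)) == 2

    def test_brute_force_run_detection(self):
        cfg = CensusConfig()
        rng = np.random.default_rng(11)
        for _ in range(40):
            seq = "".join(rng.choice(list("LIVFAGSTKRDE"), size=120,
                                     p=[.2, .15, .15, .1, .1, .05, .05, .05, .05, .05, .025, .025]))
            prof = hydropathy_profile(seq, cfg.tmh_window)
            half = cfg.tmh_window // 2
            # oracle: literal run/merge/min-length re-implementation
            flags = [v > cfg.tmh_threshold for v in prof]
            runs, cur = [], None
            for i, f in enumerate(flags):
                if f:
                    if cur and i - cur[1] < cfg.tmh_merge_gap:
                        cur[1] = i
                    else:
                        if cur:
                            runs.append(cur)
                        cur = [i, i]
            if cur:
                runs.append(cur)
            expected = [(a + half + 1, b + half + 1) for a, b in runs
                        if b - a + 1 >= cfg.tmh_min_run]
            assert predict_tmh(seq, cfg) == expected


class TestPredictSec:
    def test_constructed_signal(self):
        seq = "MKK" + "L" * 10 + "AQA" + "DDEEGNQSTDDEEGNQST"
        # cleavage at the first qualifying position after the h-region:
        # small residues at p-3 and p-1 means p is right after the AQA box
        assert predict_sec_signal(seq) == 17

    def test_acidic_mature_like_start_no_signal(self):
        assert predict_sec_signal("MDDDE" + "GNQST" * 8) is None

    def test_no_basic_n_region_no_signal(self):
        seq = "MAA" + "L" * 10 + "AQA" + "DDEEGNQST"
        assert predict_sec_signal(seq) is None

    def test_clause_oracle_on_random_sequences(self):
        """Predictions equal a literal clause-by-clause re-implementation."""
        cfg = CensusConfig()

        def oracle(seq):
            limit = min(len(seq), cfg.sec_max_cleavage)
            if not any(c in "KR" for c in seq[:6]):
                return None
            kd = [KYTE_DOOLITTLE.get(c, 0.0) for c in seq[:limit]]
            h_end = None
            for a in range(limit):
                for b in range(a + 8, limit + 1):
                    if sum(kd[a:b]) / (b - a) > 1.5:
                        h_end = b if h_end is None else min(h_end, b)
                        break
            if h_end is None:
                return None
            for p in range(h_end + 1, limit + 1):
                if p - 3 >= 1 and seq[p - 4] in "AGSCT" and seq[p - 2] in "AGSCT":
                    return p
            return None

        rng = np.random.default_rng(5)
        hydro_biased = list("LIVFAKRGST")
        for _ in range(150):
            seq = "".join(rng.choice(hydro_biased, size=50))
            assert predict_sec_signal(seq, cfg) == oracle(seq), seq


class TestPredictTat:
    def test_canonical_core(self):
        seq = "MSRRQFLK" + "A" * 14 + "DDEEGNQST"
        assert predict_tat_signal(seq) == 3

    def test_rr_to_rk_no_signal(self):
        seq = "MSRKQFLK" + "A" * 14 + "DDEEGNQST"
        assert predict_tat_signal(seq) is None

    def test_rr_outside_window_no_signal(self):
        seq = "M" + "G" * 58 + "SRRQFLK" + "A" * 14
        assert predict_tat_signal(seq) is None


class TestAnnotate:
    def test_n_terminal_flag_consistency(self):
        rng = np.random.default_rng(9)
        cfg = CensusConfig()
        for _ in range(30):
            head_pad = "".join(rng.choice(list("GSTDE"), size=int(rng.integers(0, 60))))
            seq = head_pad + "L" * 26 + "".join(rng.choice(list("GSTDE"), size=40))
            ann = annotate_protein(seq, cfg)
            assert ann.has_n_terminal_tmh == any(
                s <= cfg.n_terminal_window for s, _ in ann.tmh_spans)

    def test_determinism(self):
        seq = "MKK" + "L" * 12 + "ASA" + "GNQSTDE" * 10
        a1, a2 = annotate_protein(seq), annotate_protein(seq)
        assert (a1.tmh_spans, a1.sec_signal, a1.tat_signal) == \
               (a2.tmh_spans, a2.sec_signal, a2.tat_signal)

    def test_heuristics_recover_planted_constructors(self):
        """Wiring check: generator constructors satisfy the detector clauses."""
        rng = np.random.default_rng(2)
        body = "GNQSTDE" * 30
        for _ in range(10):
            assert predict_sec_signal(sec_signal_head(rng) + body) is not None
            assert predict_tat_signal(tat_signal_head(rng) + body) is not None
            spans = predict_tmh(tmh_head(rng) + body)
            assert any(s <= CFG.n_terminal_window for s, _ in spans)


class TestExternalAdapters:
    def test_tmhmm_short_format(self, tmp_path):
        p = tmp_path / "tmhmm.txt"
        p.write_text("prot1\tlen=120\tExpAA=44\tFirst60=22\tPredHel=2\t"
                     "Topology=i10-32o80-102i\n")
        anns = parse_external_topology(p, "tmhmm")
        assert anns[0].tmh_spans == [(10, 32), (80, 102)]
        assert anns[0].has_n_terminal_tmh and anns[0].source == "tmhmm_file"
        assert anns[0].has_c_terminal_tmh  # 102 within 30 of len 120

    def test_tmhmm_predhel_mismatch(self, tmp_path):
        p = tmp_path / "tmhmm.txt"
        p.write_text("prot1\tlen=120\tPredHel=3\tTopology=i10-32o\n")
        with pytest.raises(TopologyParseError, match="1"):
            parse_external_topology(p, "tmhmm")

    def test_signalp_summary(self, tmp_path):
        p = tmp_path / "sp.txt"
        p.write_text("prot1\tY\t24\nprot2\tN\n")
        anns = parse_external_topology(p, "signalp")
        assert anns[0].sec_signal == 24 and anns[1].sec_signal is None

    def test_tatp_summary(self, tmp_path):
        p = tmp_path / "tatp.txt"
        p.write_text("prot1\tY\t7\n")
        assert parse_external_topology(p, "tatp")[0].tat_signal == 7

    def test_sosui_table(self, tmp_path):
        p = tmp_path / "sosui.txt"
        p.write_text("prot1\t2\t5-27;60-82\n")
        assert parse_external_topology(p, "sosui")[0].tmh_spans == [(5, 27), (60, 82)]

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.txt"
        p.write_text("")
        assert parse_external_topology(p, "tmhmm") == []

    def test_unknown_format(self, tmp_path):
        p = tmp_path / "x.txt"
        p.write_text("")
        with pytest.raises(TopologyParseError, match="unknown format"):
            parse_external_topology(p, "octopus")

    def test_merge_unions_evidence(self):
        a = TopologyAnnotation("p", tmh_spans=[(5, 27)], has_n_terminal_tmh=True,
                               source="tmhmm_file")
        b = TopologyAnnotation("p", sec_signal=22, source="signalp_file")
        merged = merge_annotations([a, b])["p"]
        assert merged.has_n_terminal_tmh and merged.sec_signal == 22
        assert merged.source == "tmhmm_file+signalp_file"
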