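#!/usr/bin/env python
"""Annotate motif-positive proteins with export topology evidence.

Runs the built-in heuristics (Kyte-Doolittle TMH windows, tripartite Sec
signal, twin-arginine TAT motif) over every protein carrying at least one
CxxCH motif and writes the annotation table under results/topology/.
Mono- and diheme candidacy hinges on this evidence.
"""

from pathlib import Path

from cytcensus import count_motifs, read_fasta
from cytcensus.topology import annotate_protein, write_annotation_table

IN = Path("results/synthetic")
OUT = Path("results/topology")
OUT.mkdir(parents=True, exist_ok=True)

ps = read_fasta(IN / "proteomes.fasta", species_table=IN / "species.tsv")
positive = [r for r in ps if count_motifs(r) >= 1]
anns = {r.protein_id: annotate_protein(r) for r in positive}
write_annotation_table(anns, OUT / "topology.tsv")

n_tmh = sum(a.has_n_terminal_tmh for a in anns.values())
n_sec = sum(a.sec_signal is not None for a in anns.values())
n_tat = sum(a.tat_signal is not None for a in anns.values())
n_any = sum(a.has_export_evidence for a in anns.values())
print(f"{len(positive)} motif-positive proteins annotated")
print(f"N-terminal TMH: {n_tmh}; Sec signal: {n_sec}; TAT signal: {n_tat}; "
      f"any export evidence: {n_any}")
print(f"annotation table written to {OUT}/topology.tsv")
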