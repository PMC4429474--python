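# Methods

`cytcensus` re-implements, as a desk-scale reproducible pipeline, the
comparative-genomics procedure used to take a census of c-type cytochromes
(Cytc) and their maturation genes across archaeal proteomes. This note
records the models and heuristics, the parameters that matter, the design
choices made where the procedure was genuinely open, and what the synthetic
benchmark does and does not establish.

## The census procedure

A c-type cytochrome binds heme covalently through two cysteines of a
CxxCH sequence motif, whose histidine is the proximal iron ligand. The
census exploits this: motif occurrence plus export topology plus sequence
similarity is enough to enumerate candidate cytochromes from sequence
alone, without structures or HMM libraries.

Stages, in fixed order:

1. **Deduplication.** Byte-identical sequences within the same species are
   collapsed (lexicographically smallest id survives). Cross-species
   identical sequences are kept: they are biological signal, not database
   redundancy.
2. **Motif scan.** Every occurrence of the grammar's patterns is reported,
   overlapping hits included, with 1-based inclusive coordinates. The
   default grammar is strictly CxxCH; CxxCK and altered cysteine spacing
   Cx(n)CH are opt-in variants so default statistics stay comparable to
   the strict search. The motif count *is* the heme count ("octaheme" = 8
   matches). Ambiguity codes (X, B, Z, U, O) never satisfy the anchored
   C/H/K positions but are accepted at wildcard positions.
3. **Topology.** Each motif-positive protein is annotated with
   transmembrane helix (TMH) spans, a Sec-type signal peptide and a
   twin-arginine (TAT) signal, either by the built-in heuristics or from
   parsed external-predictor files (TMHMM short format, SOSUI batch,
   SignalP ≤4, TatP), which override the heuristics per protein.
4. **Evidence screens.** Local-alignment screens against a decoy reference
   set (false-positive families: RecJ exonucleases, thioredoxins, ...), a
   known-cytochrome reference set, and the proteome itself (to measure the
   fraction of a protein's homologs that retain the motif).
5. **Classification.** Ordered decision rules; first match wins:
   1. strong decoy similarity → rejected, whatever the motif count;
   2. ≥ 3 motifs → predicted multiheme (no topology required — at three
      or more motifs the pattern itself is specific enough);
   3. 2 motifs → predicted diheme if export evidence (N-terminal TMH, Sec
      or TAT signal) *or* similarity to a known cytochrome;
   4. 1 motif → monoheme *candidate* if export evidence *and*
      corroboration (reference similarity, or motif conserved in ≥ 50% of
      homologs);
   5. 0 motifs → none.
6. **Clustering.** Accepted proteins are clustered by mutual similarity:
   connected components (single linkage) of the thresholded all-vs-all
   similarity graph.
7. **Structure adjudication (optional).** Cluster-level fold-recognition
   evidence, supplied as a table, promotes candidate clusters (≥ 96%
   confidence with a cytochrome template; 90–96% promotes with an
   "intermediate" flag) or rejects them (confident non-cytochrome
   template). A decoy rejection is never overridden.
8. **CCM census.** CcmB/C/E/F/H homologs are detected per species by
   iterated seed search (hits recruit further low-similarity homologs;
   capped rounds). A species with ≥ 3 of the 5 families is `ccm_positive`,
   1–2 `ccm_sparse`, 0 `ccm_negative`.

## Topology heuristics

External predictor servers cannot be bundled, so the built-in stand-ins are
deliberately simple, deterministic and fully specified:

* **Hydropathy / TMH.** Kyte–Doolittle scores averaged over a centred
  sliding window (default 19, odd); maximal runs of ≥ 16 consecutive
  window centres above 1.6, with runs separated by < 3 positions merged,
  are TMH spans. Span coordinates are window centres, so a span slightly
  undershoots the physical helix ends. "N-terminal" means the span starts
  within the first 40 residues (the window the survey method never
  defines); a C-terminal anchor ends within the last 30.
* **Sec signal.** The classical tripartite architecture within the first
  35 residues: ≥ 1 K/R in the first 6 residues (n-region); a stretch of
  ≥ 8 residues with mean hydropathy > 1.5 (h-region); and the first
  position p after the h-region with small residues (A/G/S/C/T) at p−3 and
  p−1 (von Heijne's −3,−1 rule). The heuristic is organism-agnostic.
* **TAT signal.** An RR pair starting at position ≤ 35, preceded by
  S/T/K/R within 2 residues, followed by a ≥ 12-residue stretch of mean
  hydropathy > 0.5 (the S/T-R-R-x-F-L-K consensus, loosened to its
  functional core).

These heuristics trade recall/precision on real proteomes for exact
testability; with real predictor output available, the adapters preserve
fidelity and take precedence.

## Similarity model

Optimal local (Smith–Waterman) alignment under BLOSUM62 with BLAST-style
affine gaps (a gap of length k costs 11 + k), computed with Biopython's
`PairwiseAligner`. Identity is matches over alignment columns, gaps
included. No E-values are computed — the original search never reported
Karlin–Altschul parameters — so two guards replace length-corrected
statistics:

* **Coverage.** Edges and homolog hits additionally require the alignment
  to span ≥ 50% of the shorter sequence. A raw score threshold of 50–60
  alone is reachable by chance between unrelated ~300-residue proteins
  (measured chance rate ~1–5% per pair), which at census scale would let
  the iterated CCM search drift and melt the similarity graph into one
  component; short chance alignments (20–40 columns) fail the coverage
  term while genuine homologs align near full length.
* **Low-complexity masking.** Before pipeline similarity screens,
  segments whose length-12 window Shannon entropy falls below 2.2 bits are
  masked to X (a SEG-like filter). Hydrophobic membrane anchors and signal
  h-regions otherwise align with each other at scores above threshold —
  shared hydrophobicity is not homology. Masking is a parameter
  (`mask_low_complexity`), on in the pipeline, off in the bare
  `align_pair` API so the aligner remains a faithful textbook
  Smith–Waterman.

Default thresholds (raw score 50 and identity 25% for clustering edges,
60 for CCM and reference hits, 100 for decoy rejection) are explicit
configuration, echoed into every report, because the original study states
none. Even with the guards, borderline chance edges (score 50–53, identity
25–27%, coverage just above half) occasionally merge unrelated clusters —
in the default synthetic world, 2 such edges turn 35 planted groups into 32
clusters. This is a property of raw-score thresholds, reported as such.

## The synthetic world

The generator plants, per species (defaults; 5 species, 193 proteins,
seed-deterministic): 3 multiheme proteins (3–12 motifs), one diheme each
with a Sec signal, an N-terminal TMH and a TAT signal, a 4-member monoheme
homolog family mutated at 8% per site from a common ancestor (motif and
anchor positions protected; motif retained in a controllable fraction of
members, default all), 2 RecJ-like decoys (exactly 3 motifs, no export
topology), 2 thioredoxin-like decoys (1 motif plus an N-terminal TMH), and
22 background proteins (length 300, uniform residue frequencies, so the
chance motif rate per start is 0.05² × 0.05). Three species carry a
B/C/E/F ccm complement, one only CcmC, one none — spanning the
positive/sparse/negative partition.

Planted bodies exclude C and H outside injected motifs, so planted motif
counts are exact; decoys are mutated copies of the packaged exemplar
backbones, so decoy screening recognises them by construction. Signals and
anchors are built from the same clause definitions the heuristics test,
and the generator refuses to emit a record whose planted feature the
heuristics would not detect. A green end-to-end test therefore establishes
*wiring correctness* — every stage consumes and produces what the next
expects, with exact planted recovery — not predictive performance on real
archaeal sequences, whose signals, anchors and decoy families are far
messier. All packaged reference FASTA files (decoy backbones, cytochrome
exemplars, CCM seeds) are synthetic stand-ins labelled as such; no real
database sequences ship with the package.

Background calibration: total chance CxxCH count over n background
proteins has expectation n·(L−4)·f_C²·f_H; the suite checks agreement
within 4 standard deviations across seeds.

## Numerical and procedural choices

* Overlapping motif occurrences are all counted; the original motif engine
  reports all occurrences and collapsing is never mentioned. Flagged in
  report metadata.
* Duplicate collapse keeps the lexicographically smallest id;
  deduplication is idempotent.
* Cluster ids are assigned fresh, by descending size then representative
  id (the longest member, ties lexicographic); published historical
  cluster numberings can be related via a user-supplied mapping table.
* "≥ 3 ccm genes" is read as ≥ 3 *distinct families* detected, matching
  the per-family semantics of the original figure; a config switch
  (`ccm_count_copies`) gives the copy-count reading.
* CCM iteration is capped (default 3 rounds) and stops at a fixpoint; a
  protein keeps the family of its first assignment, so hit sets grow
  monotonically.
* "Conserved in a significant percentage of the homologs" is fixed at
  ≥ 50% (`conservation_min`), tunable because the source states no number.
* Degenerate inputs: empty proteome → all-zero report; empty sequence →
  no motif hits; sequences shorter than the hydropathy window → empty
  profile; zero-score local alignments → (0, 0, 0).

## Known limitations

* Heuristic topology predictors are not TMHMM/SignalP; on real sequences
  they will miss non-canonical signals and over-call hydrophobic
  stretches. Use the adapters with real predictor output for real surveys.
* Decoy detection is by similarity to exemplar sequences, not
  conserved-domain search; a decoy family with no packaged/user exemplar
  cannot be rejected.
* Raw-score similarity thresholds without E-values admit borderline
  chance edges (see above); cluster counts are threshold-dependent.
* The census of the original study's full 2014 database snapshot
  (~880k proteins) is out of desk scope; the report schema mirrors its
  statistics table so a user can run a modern dump and compare row for
  row.
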