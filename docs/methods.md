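# Methods

This note records the models, defaults and design choices behind
`ragath`, in the spirit of a package methods appendix. It states no
empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Cleavage engine

The engine (`ragath.cleavage.CleavageEngineParams`) is a deliberately
hard-edged model of a TAM-dependent RNA-guided nuclease:

* **TAM**: 5 nt, default `AGGAG`, immediately 5′ of the target on the
  non-target strand (NTS). Recognition is all-or-nothing: any
  substitution at any of the five positions sets efficiency to 0. This
  encodes the observed complete loss of activity for single TAM
  mutants; the engine does not model partial TAM tolerance.
* **Guide/target**: 20 nt; positions are numbered 1–20 from the
  TAM-proximal edge (TAM positions are −5…−1). Seed region 1–13 is
  intolerant: one mismatch → efficiency 0. Distal mismatches (14–20)
  each multiply efficiency by `distal_mismatch_factor` (default 0.5 —
  a configurable calibration chosen to reproduce a graded distal
  response; no per-position measurements exist to fit it more finely).
* **Cut sites**: drawn i.i.d. per strand.
  Defaults: TS {22: 0.65, 21: 0.20, 23: 0.15}; NTS {16: 0.85,
  15: 0.075, 17: 0.075}. The modes encode the observed cleavage
  geometry (TS 22 with >60% of events, NTS 16 with >80%); the spread
  around each mode is an invented, configurable smoothing. Overhang is
  reported as TS mode − NTS mode with + meaning a 5′ overhang; the
  defaults give +6 at the TAM-distal end.

Fragments of a cleaved linear duplex are reported per strand (top-strand
pieces split at the NTS cut, bottom-strand pieces at the TS cut), so
per-strand fragment lengths always sum to the substrate length.

## Synthetic data

Generators are pure functions of (spec, seed); one `numpy`
`default_rng(seed)` stream per call (PCG64, recorded in run manifests).
Sequencing noise is substitution-only, with a constant high FASTQ
quality: simulated indel truth therefore stays unambiguous, which is
what lets the amplicon tests assert recovery to ±0.005. Real data
differ in ways the generators deliberately omit: quality-dependent
error profiles, sequencing indels, chimeras, strand biases and
assembly artifacts. Passing tests demonstrate algorithmic correctness
against known truth, not robustness to those artifacts.

* **Genomes**: alternating IGR/gene segments tile each contig exactly;
  roles are drawn i.i.d. from `role_mix`, then planted islands
  overwrite a run of defense/other genes and force housekeeping flanks.
  Island truth is enumerated from the realized role string (maximal
  non-housekeeping runs containing ≥ 1 defense gene), so incidental
  islands created by the random mix are also listed. Planted motif
  instances are embedded wholly inside a chosen IGR (the IGR is grown
  to fit if the random draw was too short). Defense/housekeeping
  proteins are sampled column-wise from profile DBs when provided,
  making role annotation a genuine recovery problem.
* **TAM library**: each molecule carries a uniform random 7-mer; a
  molecule cleaves iff its 5 TAM-proximal bases equal the consensus
  (2 free positions → 16 of 4⁷ sequences for a matched target).
  Cleaved molecules emit adapter-prefixed reads containing 12 nt of
  backbone anchor, the 7-mer, and target sequence up to the NTS cut.
  `n_reads` optionally resamples cleaved molecules with replacement,
  modelling PCR amplification before sequencing; `depth` always means
  library molecules.
* **Run-off reads** are exact strand prefixes ending at the drawn cut;
  **small-RNA reads** come in a deterministic tiling mode or a
  uniform-start random mode; **amplicon reads** plant exactly
  `round(rate × depth)` single indels (1–10 nt, uniform in the window).

## Discovery side

* **Role significance.** Profiles are position-frequency matrices
  scored by the best ungapped full-overlap log-odds placement.
  E-value-like significance is the right-tail probability of a Gumbel
  distribution fitted to best-over-DB scores of 1000 random background
  sequences per query-length bin (bin width 50 aa) — the standard EVD
  approach; raw empirical tails cannot resolve the 10⁻⁴/10⁻⁵ operating
  points. Thresholds: defense 10⁻⁴, housekeeping 10⁻², cluster-graph
  edges 10⁻⁵. Defense wins when a protein passes both databases
  (its threshold is stricter).
* **Islands** are maximal runs of non-housekeeping genes bounded by
  housekeeping genes, kept when they contain ≥ 1 defense gene. Contig
  edges count as boundaries but flag the island `edge=true`. Strand is
  ignored; no cap is placed on island length or interior `other` genes.
* **IGRs**: gaps between merged gene spans (and contig termini),
  discarded below 15 nt. Genes + IGRs + sub-minimum gaps tile each
  contig exactly once.
* **Motif scanner**: fixed-length ungapped windows (no insert/delete
  states — a stated limitation relative to a full covariance model).
  Match columns are those with gap fraction < 0.5; log-odds use
  pseudocount 0.5 against a uniform background; pairs are kept when
  both partners are match columns and score +1/−1 bits
  (compatible = {AU, UA, CG, GC, GU, UG}). DNA is scanned with T≡U.
  The model consensus and maximum score are computed jointly over each
  disjoint pair so they respect the structure. Hits are resolved
  greedily by descending score, ties to the leftmost start. Thresholds
  are empirical (1−FPR) quantiles of i.i.d. uniform background windows
  (default FPR 10⁻³ per window).
* **Clustering**: greedy step thresholds identity ≥ 0.3 and coverage
  ≥ 0.6 (coverage denominator = shorter sequence; local
  Smith–Waterman, BLOSUM62, gap open −11/extend −1). Cluster profiles
  come from a star alignment anchored on the longest member (Laplace
  pseudocount 1); insertions relative to the anchor are dropped —
  deterministic and adequate at family-level divergence. Graph weights
  are cross-profile scores normalized by each protein's own-cluster
  score, symmetrized by averaging, clipped to [0, 1], with
  sub-significance directions dropped. MCL runs at inflation 2.0,
  pruning 10⁻⁵, tolerance 10⁻⁶, ≤ 100 iterations; missing self-loops
  are set to the maximum incident weight; clusters are the connected
  components of the attractor support (overlaps therefore merge to the
  lowest-indexed cluster).
* **Taxonomy**: protein hits filtered at identity > 0.4 and coverage
  > 0.7; consensus is the most specific of the 7 ranks with > 70%
  agreement (computed on full lineage prefixes so ranks nest);
  adopted only when the nucleotide-level lineage agrees at that rank,
  else undetermined.
* **Representatives**: at most 6 proteins per species per cluster,
  longest first, ties by identifier.

## Characterization side

* **TAM extraction** keeps a read when its 5′ end matches the adapter
  within 1 mismatch and the 12-nt backbone anchor matches at its fixed
  offset within 1 mismatch (the anchor must be unique in the backbone).
  A strict exact-anchor rule would cap recall at 0.999¹² ≈ 0.988 at a
  10⁻³ error rate; one tolerated mismatch restores recall ≥ 0.99 while
  keeping the 7-mer excision purely coordinate-based. Enrichment uses
  cleaved-product frequencies against a uniform background (or an
  input-library FASTQ when supplied); consensus bases are called where
  information content ≥ 1 bit, `N` elsewhere.
* **Cut-site mapping** classifies reads per strand as exact-or-noisy
  reference prefixes (NTS) or reverse-complemented suffixes (TS),
  requiring ungapped identity ≥ 0.9 at the length-implied placement;
  the terminal base marks the cut.
* **reRNA anatomy**: reads are placed exactly or by edlib alignment
  (≤ 10% edits). The transcript is the contiguous region around the
  coverage peak with coverage ≥ 10% of the maximum, then extended
  outward down the monotone nonzero coverage ramp. The refinement
  matters: read-length ramps at transcript edges otherwise clip the
  boundaries by read_length × threshold bases; with it, tiling data
  yield exact boundaries and random-depth data are within 1 nt.
* **Indels**: global affine alignment (match +2, mismatch −3, gap open
  −8, extend −1); reads below 0.8 identity over aligned columns are
  discarded and counted. A read is edited iff a gap column overlaps
  the target window (guide span ± 5 nt in typical use); substitutions
  never count. Heatmaps normalize each single-substitution guide's
  indel fraction by the original guide's fraction (error if the WT
  fraction is 0).
* **Off-target enumeration**: both strands, exact TAM, ≤ 3 guide
  mismatches, no bulges; sorted by mismatch count then coordinate.

## Problem sizes and determinism

The test suite runs planted-recovery experiments at deliberately
compact sizes: 4 families × 6 members for clustering recovery, 3
contigs × 10 genes for the end-to-end discovery run, 10⁴ run-off reads
for the cut-site profile, 4 × 10⁵ library molecules sequenced to 5 × 10³
reads for the TAM logo, 10³ amplicon reads per editing rate. These
sizes make every stochastic assertion comfortably inside its
statistical tolerance while keeping the full suite under a minute of
CPU. Every random draw flows through a seeded `numpy` generator;
rerunning any generator or pipeline stage with the same inputs and seed
reproduces byte-identical outputs.

## Known limitations

* The motif scanner has no insert/delete states and no covariation
  statistics; it is a PWM-with-pairs stand-in for a covariance model.
* The greedy clustering step has no analogue of a k-mer prefilter
  sensitivity parameter; all comparisons are exact DP alignments.
* The engine's hard zero for seed mismatches and TAM mutants is a
  simplification of "loss or significant impairment"; partial
  activities in the seed region are not representable.
* Sanger-style trace files are not parsed; run-off analysis consumes
  reads representing product ends.
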