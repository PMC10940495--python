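# Methods

This note documents the models, conventions and numerical choices behind
`ppredit`, and what the synthetic data do and do not establish.

## PPR-code PWM construction

A PLS protein's base preference at target position *i* is read off its
*i*-th repeat motif from the amino acids at motif position 6 and position 1′
(the first residue of the following motif). The mapping
`(motif class, aa6, aa1′) → (pA, pC, pG, pU)` is supplied as a TSV
configuration table; rows are validated at load time (non-negative, sum
within 0.01 of 1, then renormalised exactly). Conventions:

- **Last motif.** Position 1′ of the final repeat is taken as the protein
  residue immediately following the motif span (the E-domain side), so
  every motif remains scoreable; a motif ending at the protein terminus is
  an error.
- **Missing combinations.** Published weighting tables are sparse. A pair
  absent from the table yields a uniform (0.25, 0.25, 0.25, 0.25) column
  carrying a `fallback` flag rather than an error, so sparse tables still
  produce scannable PWMs; fallback columns are visible in every PWM output.
- **Subclasses.** P2/L2/S2 motifs use their base-class row (P/L/S) when no
  subclass-specific row exists.
- **Shipped table.** The packaged default
  (`data/ppr_code_table_synthetic.tsv`) is a synthetic reconstruction of
  the combination→base preferences reported in the PPR-code literature
  (strong T/N→A, T/D→G, N/D→U, N/N→pyrimidine associations, with L-class
  rows mixed halfway toward uniform to reflect the weaker specificity of L
  motifs). It is configuration, not measurement; substitute a curated table
  for real predictions.

## Genome scanning with exact p-values

Scanning is FIMO-style: DNA alphabet (the PWM's U column matches T),
log-odds scores in bits against a 0-order background, both strands via
reverse-complement scanning, hits ranked by p-value (ties broken by
sequence id, start, then strand) and truncated to the top *k* (default 10).

- **Flooring.** Column probabilities are floored by background mixing,
  p̃(b) = (1−ε)·p(b) + ε·b(b) with ε = 0.01, so zero-probability bases score
  finitely; ε = 0 is allowed only for strictly positive columns.
- **Exact null distribution.** Scores are rounded to a grid (granularity
  10⁻³ bits). Under the independent-positions null, the window score's pmf
  is the positionwise convolution of the per-column pmfs on that integer
  grid; P(score ≥ s) follows by suffix summation. Reported window scores
  are themselves sums of the rounded column scores, so each hit's p-value
  is exact for its reported score (difference from the unrounded score is
  bounded by L·5·10⁻⁴ bits). Tests verify the DP against brute-force
  enumeration over all 4^L windows.
- **Background.** Default is the 0-order composition of the scanned
  sequence itself, estimated from both strands. The two-strand estimate
  makes the background strand-symmetric, which in turn makes scan results
  exactly mirror-invariant under reverse complementation of the input.
  `estimate_background` is also available in plain single-strand form
  (counts plus pseudocount).
- **Ambiguity codes.** N (and all other IUPAC codes) score the column
  minimum — conservative, never inflating a hit.
- **Circularity.** Plastomes are circular; `circular=True` appends the
  first L−1 bases so origin-spanning windows are scored, reporting each
  distinct start once. Default is linear.
- **Report threshold.** p ≤ 10⁻³ before top-k truncation.

## Editing quantification

Editing efficiency is the edited-read fraction over *informative* reads
only: f = T/(C+T) at a plus-strand site, and in genome-forward counts
f = A/(G+A) at a minus-strand site. Reads showing a third base are excluded
from the denominator (the statistic is "edited + unedited") but retained in
the reported total depth, so both denominators are visible downstream.

- Base counting reads SAM/BAM in one sequential pass (no index needed),
  applying base-quality ≥ 20 and mapping-quality ≥ 0 defaults — the
  mapping-quality default deliberately keeps multi-mapping reads, which
  matters for edited sites inside repeated regions (e.g. inverted-repeat
  transcripts). Deletions and reference skips at a site contribute nothing.
- Zero informative depth yields fraction NA, never an exception; depth
  below 20 sets a `low_coverage` flag without discarding the measurement.
- Site discovery is a transparent threshold rule: a reference C (+) or
  G (−) position is called when f ≥ 0.05 with informative depth ≥ 20 in at
  least one library; only C→T / G→A changes are ever considered.
- Sanger quantification applies the same two-base proportion to
  chromatogram peak heights; peak tables arrive as TSV (no .ab1 parsing).
- Coordinates are 0-based half-open internally and in BED; GFF3 and
  human-readable reports are 1-based.

## Differential testing

Per site, the silenced (test) group is compared to controls with Welch's
unequal-variance t-test, one-tailed in the 'less' direction by default
(silencing is expected to reduce editing; an editing *increase* is
detectable by rerunning with 'greater'). Degrees of freedom follow
Welch–Satterthwaite. NA measurements are dropped per site; sites with fewer
than two usable values in either group are flagged untestable and retained.

- **Zero-variance degenerate case.** At saturated sites both sample
  variances can be exactly zero. Convention: p = 0.5 when the means are
  equal, p = 0 when the alternative direction holds strictly, p = 1
  otherwise. This is documented behaviour rather than a crash; the
  implementation is in-package for exactly this reason, with
  `scipy.stats.ttest_ind` serving as the independent oracle in tests
  (agreement to 10⁻¹⁰ away from the degenerate case).
- **Multiplicity.** No adjustment by default (significance is raw
  p < 0.05); Benjamini–Hochberg is available behind `adjust="BH"`.
- A vectorised p-value routine backs the large calibration studies; it is
  tested to match the scalar path to 10⁻¹².

## DYW-domain screen

Canonical DYW domains end in Asp-x-Trp (DYW, with DLW/DNW variants), carry
cytidine-deaminase zinc-site signatures, and require a gating glutamate
that completes the catalytic zinc's coordination through a bound water.
The screen is purely sequence-level:

- terminal triplet: last three residues; D-x-W requires D first and W last.
- zinc signatures: all (overlapping) H-x-E and C-x-x-C starts. These
  patterns are a pragmatic signature for the deaminase zinc site, not a
  structural verification.
- gating residue: the query residue aligned to a configured reference
  column under global Needleman–Wunsch/Gotoh alignment with affine gaps
  (match 2, mismatch −1, gap of length k costs −10 − 0.5k). Traceback ties
  break deterministically diagonal > up > left, so reports are
  reproducible. A gap at the column reports NA. The packaged reference
  domain is a constructed synthetic sequence carrying the hallmarks at
  known coordinates; any reference FASTA plus gating coordinate can be
  substituted.

## Synthetic data

The generator emulates the structure of a chloroplast silencing study:
a 150 kb, 38% GC circular-plastome-like i.i.d. genome; 23 C-to-U sites;
three control and four silenced libraries of 250-nt reads; control editing
~0.85 reduced to ~0.55 under silencing; mean per-site depth 300.

- Between-replicate variation is Beta-distributed about the condition mean
  with concentration 200 (sd ≈ 0.03 at f = 0.5) — a plausible model of
  biological replicate scatter, not a fitted one. Depth is Poisson about
  its mean; edited counts are Binomial in the realized fraction; a uniform
  per-read error channel (rate 0.002) converts bases to a random other
  base.
- Planted motif sites are non-overlapping, on random strands, consensus or
  PWM-sampled. Edit sites keep ≥ read-length separation when the genome
  allows, so emitted reads for one site never cover another and the
  SAM-derived pileup equals the direct pileup exactly.
- Emitted alignments reproduce each site's observed base counts read for
  read (MAPQ 60, base quality 30), making the alignment and pileup input
  routes exactly cross-checkable.
- Everything is a pure function of (config, seed); reruns are
  byte-identical.

What the synthetic data do **not** model: realistic error profiles, indels,
splicing, coverage heterogeneity along transcripts, mapper artefacts, or
correlated biological variation across sites. Passing recovery tests
therefore demonstrates correctness of the computations under the stated
model, not robustness to every property of real libraries.

## Problem sizes

Calibration and recovery studies use sizes chosen to give tight Monte-Carlo
error at interactive runtimes: 50 random PWMs (L ≤ 6) for the exact-p-value
check, 1,000 sites at depth 500 for fraction recovery, 1,000 datasets for
reference agreement, 20,000 simulations for null calibration of the 3-vs-4
design, and 20 + 20 sites at depth 300 for end-to-end detection.

## Known limitations

- The scanner's 0-order background and ungapped PWM model match the
  FIMO-class approach but ignore higher-order composition and structure.
- The editing-fraction estimator is per-site maximum likelihood; no
  shrinkage across sites or libraries.
- The Welch test treats per-library fractions as the unit of analysis
  (as in the emulated design); count-aware models (beta-binomial) are out
  of scope.
- The DYW screen cannot confirm zinc-site geometry; it flags sequence
  hallmarks only.
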