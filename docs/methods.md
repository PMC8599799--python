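# Methods

This note documents the models and numerical choices behind `footprintr`:
what each stage computes, which parameters matter, what the synthetic-data
generator does and does not emulate, and where the design was genuinely
open.

## Coordinates and alphabets

Everything is transcript-space, sense strand, 0-based half-open. Sequences
are stored in the DNA alphabet (U → T on input), so RNA motifs such as
`AAUAAA` and transcriptome FASTA files using T interoperate. Genome-space
peak annotations must be projected to transcript coordinates before they
reach the package; no liftover is provided.

## Reactivity model

RT stops are counted at the position one nucleotide 5′ of a read's first
aligned base (the adduct sits one nucleotide 3′ of the polymerase stop);
reads starting at position 0 are dropped. With treatment stops `T_i`,
control stops `B_i`, control base density `D_i`, and the library-size
factor `f = total_mapped(treatment) / total_mapped(control)`, the raw
enrichment score is

```
s_i = max(0, T_i − α·f·B_i) / max(f·D_i, ε)
```

- `α = 0.25` — background subtraction weight. The score must not reward
  positions that stop reverse transcription regardless of probe; α < 1
  avoids over-subtracting noisy control counts.
- `ε = 1` (scaled-count units) — density floor preventing division blow-ups
  at uncovered positions.
- Coverage filters `T_min = t_min = 0` by default: nothing is filtered.
  These exist because real pipelines usually filter low-coverage positions;
  the defaults deliberately disable that final filtering step, and the
  thresholds are config-exposed.
- Library-size scaling uses whole-library totals, not per-transcript
  totals; this is the simplest choice that keeps the score invariant under
  a common rescaling of both libraries.
- Negative raw scores are floored at 0 before normalization: reactivity is
  non-negative by definition.

Normalization divides each transcript's raw scores by the mean of the
non-null positive scores between the 90th and 99th percentiles (a
winsorised mean: robust to the extreme tail, insensitive to the zero-heavy
bulk) and clamps to [0, 1]. All-zero or all-null transcripts pass through
unchanged. The percentile bounds are parameters; the external pipelines
this emulates do not publish their exact internals, so the scheme here is a
documented decision, not a ground truth, and tests pin it against an
independent sort-based oracle.

The VTD track is the in-cell profile minus the in-vitro profile,
null-propagating. Negative VTD at a position means less reactive in cells —
the signature of protein protection. Hexamer summaries average VTD over all
fully-non-null occurrences of each 6-mer (mean of per-occurrence means);
metaprofiles average profiles over anchor-aligned windows with per-offset
counts, truncating at transcript ends.

## Site construction and windows

Positive sites are exact motif occurrences with ≥ 1 base inside an
occupancy peak; every occurrence in a peak counts (no per-peak cap — the
deterministic choice), peaks without the motif are dropped and counted, and
duplicate (transcript, start) pairs arising from overlapping peaks are
collapsed. Negative candidates are occurrences whose full motif span
(plus an optional buffer, default 0) is disjoint from every peak of that
RBP — the stricter disjointness on the negative side buys label purity.
Negatives are sampled without replacement, seeded, to match the positive
count.

Feature windows cover the motif plus `k` flanking nucleotides per side:
15 features per reagent for 5-mer RBP motifs (k = 5) and 46 for the AAUAAA
signal (k = 20). A window is discarded — and logged — if it leaves the
transcript or contains any null score; in the combined design a site must
survive in **every** reagent so rows align across reagents.

The RBP-selection conveniences mirror common practice: a motif filter
requiring ≥ 3 A/G residues (the accessibility probe only reads purines, so
purine-poor motifs carry little signal in that channel; applied to the
motif string) and an expression filter keeping transcripts at ≥ 5 RPKM
(inclusive).

## Classifier harness

- Half-split: stratified at 50/50 (plain random splitting can produce
  single-class halves on small site sets), seeded, disjoint, exhaustive.
- Scaling: per-column min–max to [0, 1] learned on the training half only;
  test values are clamped; constant columns map to 0.
- Hyperparameters: exhaustive grid search over C (and γ for the RBF
  kernel), stratified 5-fold CV on the training half, objective = mean
  held-out AUC (accuracy would be blind to score calibration and the
  evaluation surface is ROC anyway). Ties break toward smaller C, then
  smaller γ. The library-default grids span C ∈ 2⁻⁵…2¹⁵, γ ∈ 2⁻¹⁵…2³ in
  ×4 steps; the packaged experiments use a coarser grid
  (C ∈ 2⁻²…2⁸ ×4, γ ∈ 2⁻⁴…2² ×4) — six by four points comfortably bracket
  the optimum on these feature scales at a fraction of the fits.
- SVM: soft-margin SVC (libsvm backend). Decision-function scores are used
  directly; no probability calibration.
- ROC/AUC: Mann–Whitney rank statistic with half credit for ties,
  identical to the trapezoid over the tie-collapsed curve; tests verify
  exact agreement with a brute-force pair count.
- `compare_reagents` runs the whole harness once per feature design
  (flexibility / accessibility / combined) on the same site rows and the
  same split seed, so design AUCs differ only through the features.

## PolyA-site analysis

3′-end read pileups are thresholded at `min_reads = 5` and positions within
`cluster_distance = 10` nt are merged; a cluster reports its modal position
(ties toward 3′ — cleavage is heterogeneous and the 3′-most mode is a
deterministic representative) with the cluster's summed reads. Each called
site is anchored to the closest upstream AAUAAA whose 3′ end lies 10–40 nt
upstream of cleavage — the canonical signal-to-cleavage spacing; sites
without such a signal stay unassigned. Assigned sites are stratified by
read depth: ≥ 75th percentile → high-usage ("active"), ≤ 25th → low-usage,
middle band excluded from training to sharpen labels (with all counts equal
the strata coincide and the active label wins). Classifier positives are
the signals of active sites; negatives are AAUAAA occurrences not assigned
to any called site. Metaprofiles center on the uridine of AAUAAA
(signal start + 2). No internal-priming filter is applied (config hook
only).

## Synthetic data generator

The generator emulates, with known ground truth, the data the pipeline
consumes; its defaults define the reference conditions used by the tests.

- **Transcriptome**: 100 random transcripts of 500–800 nt. Per transcript:
  5 bound + 5 unbound instances of the purine-rich 5-mer `AGGAC` planted in
  non-overlapping 20-nt slots, a start codon at position 20, two AAUAAA
  elements near the 3′ end (cleavage 18 nt downstream of the signal), and
  two decoy AAUAAA occurrences elsewhere. Spontaneous motif occurrences are
  left in place and join the unbound pool via scanning, exactly as on real
  data.
- **Truth profiles**: baseline accessibility/flexibility are moving
  averages (window 5) of uniform noise — local correlation without a
  folding engine. In-vitro truth equals in-cell truth except at protein
  footprints. Each bound RBP site suppresses in-cell reactivity
  multiplicatively by δ = 0.5 over the motif ± 2-nt shoulders, in **one**
  reagent channel per site (chosen 50/50): this is the complementarity
  knob that makes combining reagents genuinely informative rather than
  redundant. Active polyadenylation signals carry the CPSF-footprint
  accessibility signature (first two adenosines exposed ≈ 0.9, UAAA tail
  suppressed ≤ 0.15) at full strength in-cell, a 50% blend of it in both
  conditions (sequence-intrinsic part), and in-cell rigidification of the
  hexamer in the flexibility channel; the in-cell-only part scales with δ
  so a zero-effect generator has identical conditions everywhere.
- **Counts**: negative-binomial via the Gamma–Poisson mixture with
  dispersion φ = 50 (variance = μ + μ²/φ; mild extra-Poisson noise typical
  of deep count data; φ → ∞ recovers Poisson). Coverage λ = 200 per
  position and library; treatment stop mean `D_i·(β₀ + β₁·truth_i·base_i)`
  with β₀ = 0.02, β₁ = 0.2 (modification:background = 10); control mean
  `D_i·β₀`. Base specificity: accessibility probe A/G = 1.0 vs C/U = 0.1;
  flexibility probe A/U = 1.0 vs C/G = 0.6 (mild skew). These rates were
  fixed once so that the generator, scorer and classifier are mutually
  consistent at the reference conditions — enrichment scores correlate
  with the probe-visible truth (truth × base specificity) at Spearman
  ρ ≈ 0.82 (accessibility) and 0.61 (flexibility), the zero-effect
  generator yields chance-level AUC, and the default-effect generator
  yields combined AUC ≈ 0.89 against ≈ 0.7 per single reagent.
- **Peaks**: one per bound site, motif span ± uniform 0–5 nt jitter;
  unbound instances are never covered (slot spacing guarantees it).
- **3′-end reads**: high-usage signals draw NB(80) reads, low-usage NB(20),
  with ends normally scattered (σ = 2 nt) around the true cleavage
  position, plus ~2 stray uniform reads per transcript. Low-usage sites are
  real but weakly used elements, so the called set genuinely contains high
  and low read-depth sites for the quantile stratification; decoys and
  spontaneous AAUAAA occurrences provide unused-signal negatives.
- **Determinism**: every stage draws from its own `SeedSequence` stream
  derived from (seed, stage id), so regeneration is byte-identical and
  stages can be re-run independently.

What the generator does **not** emulate: thermodynamic folding (baselines
are smooth noise, not structure), read-level sequences (counts suffice for
every stage), mappability or transcript-abundance variation (uniform
coverage), alternative-polyadenylation regulation, or peak-calling noise
beyond boundary jitter. Passing tests therefore demonstrate internal
consistency and correct statistical machinery under a realistic noise
model — not performance on real K562-style libraries, where coverage is
uneven and footprints are smaller and rarer.

## Problem sizes used in tests

The test suite runs the full pipeline at the reference conditions
(100 transcripts, ≈ 500 sites per class) for the calibration and
signal-recovery properties (10 seeds each) and the determinism check, and
at 20–30 transcripts for smoke and integration tests; the δ-monotonicity
property uses 30 transcripts × 5 seeds per effect size. These sizes give
stable statistics (AUC spread ≈ 0.01–0.03 across seeds at full size) while
keeping the whole suite fast.

## Known limitations

- The normalization scheme is one reasonable member of a family; absolute
  reactivity values are not comparable across differently normalized
  datasets.
- Single-RBP runs: the CLI processes one motif per invocation; multi-RBP
  catalogs are a thin loop away in Python.
- The negative definition for the PAS classifier (unassigned AAUAAA
  occurrences from the package's own calls) differs from using an external
  annotation of non-PAS signals; with sparse 3′-end coverage some true PAS
  may leak into the negatives.
- Degenerate (IUPAC) motif letters are unsupported; motifs are exact
  strings.
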