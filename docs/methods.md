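# Methods

This note documents the statistical model behind `tilescan`, the choices
made where the procedure was genuinely open, and what the synthetic
benchmarks do and do not establish.

## Data model

A two-color promoter tiling array measures, per 50-mer probe, a
factor-ChIP channel (Cy5) and a non-immune IgG control channel (Cy3),
stored as log2 intensities. Probes tile ~4.85 kb per promoter (3880 bp
upstream, 970 bp downstream of the TSS). All internal coordinates are
0-based half-open; the 1-based inclusive `chrN:start-end` strings of the
packaged target tables are converted by a single inverse pair of
functions. Raw (non-log) input intensities are log2-transformed with a +1
offset at read time so that `M = Cy5 − Cy3` is simultaneously a log ratio
and a channel difference.

## Normalization

* **GC stratification.** Dye bias on these arrays depends on probe GC
  content, so probes are split into `n_gc_groups` equal-count quantile
  bins of GC fraction (default 10; bins under 20 probes merge into their
  lower neighbor). The grouping rule is a design choice — only "groups by
  GC content" is inherited; equal-count bins keep every LOESS fit equally
  supported.
* **Within-array LOESS.** Per bin, the robust LOESS fit of `M` on `A`
  (tricube weights, local-linear, 3 bisquare iterations, span 0.3) is
  subtracted from `M`; `A` is unchanged. The fit is delegated to
  `statsmodels.nonparametric.lowess`; the test suite checks it against an
  independently written brute-force tricube local regression to < 1e-6.
  `loess_delta` (default 0.01 of the A-range per bin) enables the standard
  interpolation shortcut; 0 gives the exact fit. Degree-2 fits are not
  offered: the A-trends this procedure removes are locally near-linear and
  degree 1 is the robust default of the underlying smoother. A bin whose
  `A` values are all identical has no trend; its median `M` is subtracted.
* **A-quantile across arrays.** Each array's sorted `A` vector is replaced
  by the across-array mean of order statistics, mapped back through the
  array's ranks; ties receive the mean of their tied targets; `M` passes
  through. The operation is idempotent (tested exactly). Order of
  operations is fixed: MA → per-array GC-LOESS → across-array A-quantile.

## Smoothing, scoring, region calling

* Each probe's `M` (then `A`) is replaced by the median over all probes of
  the same promoter within ±300 bp of its center (600 bp window, the
  fragment size). Windows never cross promoter boundaries — the array
  tiles disjoint loci, so smoothing across them has no meaning. Probes
  with missing intensities are rejected at load time, so tracks are dense.
* `z = (M_smooth − mean)/sd` uses the array-wide *moment* estimators of
  the smoothed track ("experimental mean and standard deviation"); a
  median/MAD alternative is exposed (`robust_z`) but off by default, since
  the moment version is the literal reading and is stable at array scale
  (~50k probes). Per-promoter moments would rest on ~49
  probes and were rejected. One-sided tails give `p_pos` (factor
  enrichment) and `p_neg` (IgG enrichment); `p_pos + p_neg = 1` exactly.
* Signed regions are maximal runs of ≥ `min_consecutive` (3) grid-adjacent
  probes with tail `p < 10⁻³`. The region p-value is the *minimum* member
  p — the magnitudes in the published tables (down to 1e-57) are only
  reachable as window extrema, not products or means — and `peak_z` is the
  most extreme member z.
* **Replicate consensus** enforces both published clauses: regions are
  re-called on the probe-wise mean of the smoothed replicate tracks
  ("average of the replicates"), and kept only when every replicate
  individually contains a same-sign overlapping region ("in all three
  replicates"). Consensus p-values come from the averaged track.
* **Questionable positives.** A positive region is flagged when a negative
  (IgG-enriched) consensus region of the same promoter lies within
  `adjacency_bp` (default 1000 bp, edge to edge) and has the larger |peak
  z|. The published screen did this manually; automating it requires
  making "adjacent" a number, which is therefore a parameter.
* Final targets: positive, unflagged regions with `p < 10⁻⁷`; a relaxed
  superset at `p < 10⁻⁵`. One promoter may contribute several regions;
  `best_per_promoter` reports the strongest.

## Motif analysis

* Degenerate patterns use IUPAC codes; `N` in a subject never matches.
  Factor defaults: SRY = `WAACAAW` + `WTTGTTW` (the two printed response
  elements, mutual reverse complements), SOX9 = `YTTGWG` + `WAACAAW`.
  Because the SRY pair already covers both orientations, the default scan
  is forward-strand over both patterns; a both-strands switch exists and
  then a palindromic hit identical to its own reverse complement at the
  same offset counts once.
* Motif counting is restricted to the called region interval (the
  published motif counts are paired with binding-site locations, not whole
  promoters); overlapping hits all count.
* Classification partition: questionable (flag precedence) → direct (≥ 1
  hit of any factor pattern) → atypical. Atypical targets are read as
  recruitment through protein–protein association rather than direct DNA
  contact.
* The consensus PFM stacks scan-anchored sites (minus-strand words
  reverse-complemented), replacing de novo discovery, which is out of
  scope. Column information content is `2 + Σ f log2 f` bits; the
  consensus string degenerates a column when the runner-up base reaches
  25% of sites.

## Gene-set analysis

Percent overlap divides the intersection by the *smaller* set — the most
conservative denominator consistent with the published "<10%" claim; the
report returns all raw counts so any other convention can be derived.
Fisher's exact over-representation is the one-sided upper hypergeometric
tail via `scipy.stats.hypergeom`, verified in tests against exhaustive
enumeration over all tables with fixed margins (N ≤ 40, agreement 1e-12).
Benjamini–Hochberg q-values are emitted alongside raw p-values, never
replacing them. Symbol matching is exact after whitespace trimming; no
alias resolution. The gene universe defaults to the full array design
(15,287 promoters) and is overridable.

## Synthetic data generator

The generator emulates the study conditions: 3 replicates on an identical
grid of 50-mer probes every 100 bp (spacing is not documented for the real
array; 100 bp is an assumption recorded in the config), promoter span
(3880, 970), bound-region widths uniform in [400, 600] bp, mean Cy5
enrichment 1.5 log2 units, per-channel Gaussian noise sd 0.4, IgG
artifacts on Cy3, and a centered polynomial GC dye bias (default linear,
0.5 log2 across the GC range) applied to Cy5. Probe GC fractions are
computed from the actual generated sequence under each probe, which is
what couples dye bias to composition. Defaults for the bound fraction
(1.5% of promoters) and IgG-artifact fraction (1.5%) follow the study's
own detected counts (~230 bound and 213 IgG sites of 15,287 promoters);
30% of bound regions carry a planted response element, mirroring the
direct:atypical ratio. Baseline log2 intensity is fixed at 10 — only
differences propagate downstream.

Enrichment uses a fragment-coverage taper: full effect over the bound
region, decaying linearly to zero over one fragment length (500 bp)
outside it, since ~500 bp immunoprecipitated fragments overlapping the
region's edges also hybridize. Sequences are i.i.d. uniform ACGT outside
planted motifs, so background motif hits are expected and quantified
exactly (see below). All randomness flows through one
`numpy.random.Generator`; identical seeds give bitwise-identical outputs.

What the generator does *not* model: carrier-cell chromatin, amplification
bias, probe cross-hybridization, non-Gaussian heavy-tailed noise, and
correlated replicate artifacts. Passing benchmarks therefore demonstrate
the pipeline's statistical behavior under its own assumptions, not
performance on raw NimbleGen data.

## Benchmarks and numerical notes

* **Specificity**: 10 seeded spike-free experiments of 2,000 promoters
  produce a target false-positive rate ≤ 0.1% of promoters at `p < 10⁻⁷`
  (observed: 0 in 20,000).
* **Power**: at study conditions, ≥ 90% of truth regions are recovered
  with median midpoint error ≤ 300 bp (observed ≈ 97%, ≈ 43 bp over 150
  regions, 5 seeds × 2,000 promoters). Problem sizes were chosen to give
  ≥ 100 truth regions while keeping a full run inside a few minutes on one
  CPU.
* **Classification**: planted-motif targets classify direct at ≥ 95%
  (observed 100%). Motif-free targets acquire background hits at the rate
  expected in i.i.d. sequence; the observed atypical count is compared
  with the *exact* no-hit probability computed by a transfer-matrix
  recursion over the last six bases (not the Poisson `exp(-λ)`
  approximation, which ignores overlap clustering), and must fall in the
  binomial 99% band.
* **Known limitation — signal density.** Because the z reference includes
  all probes and the LOESS fit sees enriched probes at high `A`, both the
  effective z and the post-normalization enrichment shrink as the bound
  fraction grows: sensitivity degrades noticeably above ~3–5% bound
  promoters. This is a property of the published procedure (array-wide
  scaling plus intensity-dependent normalization), not of this
  implementation; at the study's ~1.5% density it is negligible.
* Degenerate inputs: zero-sd smoothed tracks and empty gene sets raise
  errors naming the offending object; empty region lists are valid
  outputs. BED scores encode `round(10 · −log10 p)` capped at 1000.
* The published table counts disagree with their own prose (72 printed
  SRY rows vs "71 genes"; 107 printed SOX9 rows vs "109 promoters"). The
  fixtures store the printed rows verbatim, including original symbol
  spellings, and make no attempt to reconcile the counts.
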