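# Methods

This note documents the generative model, the statistics, and the design
choices behind clonepool, in the order the pipeline runs.

## The screen being modeled

Several clonal Cas9 cell lines are each transduced (MOI 0.3, so essentially
one integration per infected cell) with the same genome-scale sgRNA library,
tagged per line with a 6-nt library ID and, per plasmid, a random 20-nt
barcode. After selection the lines are pooled at equal cell numbers with
coverage ≥ 1000 cells per sgRNA, split into a treated arm (escalating doses
of a selective agent on days 0, 1 and 4: 10, 20, 25 ng/ml, max dose 25) and
an untreated arm, and sampled at days 0 (baseline, before any dose), 4, 9
and 14. Samples are named `<arm>_d<day>`; day-0 samples of both arms are
independent sequencing draws from the same pre-dose pool, and each arm's
trajectories are normalized to its own day-0 sample.

## Generative model (`simulate`)

A **lineage** is one (clone, sgRNA, barcode) triple. Seeding draws, per
clone and sgRNA, `coverage` cells that each pick a barcode uniformly from
the entry's pool (a multinomial split, so the per-sgRNA cell total is exactly
the coverage). Per day *d* a lineage *l* of clone *c* carrying gene *g*
evolves as

    cells <- cells * 2^(growth_c + fitness_shift_g + eta_l)

and on each dose-event day (treated arm; doses are applied after that day's
sample is taken, so the baseline is pre-dose):

    cells <- cells * (1 - s_l * (1 - resistance_g) * (dose/max_dose)^kill_exponent)

Expected mode evolves real-valued expectations (the closed-form product);
stochastic mode uses binomial survival and Poisson growth on integer counts.
The dose response is linear in dose/max_dose by default (`kill_exponent`
configurable); no kill-kinetics calibration is attempted — the defaults are
illustrative study conditions, not fits.

**Sub-clonal heterogeneity.** Two per-lineage components are drawn once at
seeding, both scaled by the clone's `sigma_sub` (default 0.1):

- a growth jitter `eta_l ~ Normal(0, sigma_sub)` (doublings/day), shared by
  both arms — it disperses lineage abundances and read counts but cancels
  exactly in treated-vs-untreated fold changes in expected mode;
- a sensitivity jitter giving each lineage its own kill fraction
  `s_l = clip(sensitivity_c + Normal(0, sigma_sub), 0, 1)` — this is what
  makes the within-sgRNA dispersion of barcode fold changes grow with
  `sigma_sub`, the package's operational definition of sub-clonal response
  heterogeneity.

A growth-only jitter cannot produce treated/untreated fold-change dispersion
beyond sampling noise (it divides out), while a sensitivity-only jitter
would leave untreated barcode abundances unrealistically uniform; modeling
both keeps the invariant that a fully rescuing gene (resistance = 1) makes
the treated trajectory identical to the untreated one in expected mode.

**Sequencing** is a multinomial draw of `read_depth` reads over lineages
proportional to cells; each read's ID/sgRNA/BC bases (46 nt) are substituted
independently at `error_rate`. The internal count table applies the same
acceptance rules as the deconvolution module (exact sgRNA, ≤1-mismatch ID,
manifest pair membership), so deconvolving the simulator's own FASTQ — which
contains every read, including ones both sides reject — reproduces the
internal table exactly at any error rate. FASTQ layout: read 1 = sgRNA +
30-nt constant scaffold pad; read 2 = BC + 10-nt constant spacer + ID +
A-pad; 50-nt reads, Phred-33, layout constants written to a YAML sidecar.

**Demo defaults** (`demo_clones`): one sensitive / one resistant clone per
CRISPR system (sensitivities 0.9/0.1 and 0.85/0.15) with mild proliferation
heterogeneity, the resistant clones growing slightly faster (1.0 vs 0.95 and
1.0 vs 0.9 doublings/day) so that sensitive clones deplete monotonically
under treatment, as observed for the clonal lines the screen design
emulates. MOI is recorded but enters only as the single-integration
assumption; multi-infection is not modeled.

**What the generator does not emulate:** PCR amplification bias and template
switching, quality-score structure, passaging bottlenecks, cell-cycle or
density effects, and any coupling between growth rate and treatment
response. Tests passing on these simulations validate the pipeline's
bookkeeping and statistics under a known truth — not the biology of any
particular real dataset.

## Deconvolution (`readproc`)

Fields are cut from fixed offsets (the real screen's primer offsets are
configuration, not constants); base qualities are ignored; reads with N in a
field, too-short reads, and anchor mismatches (if an anchor is configured)
are rejected with per-reason tallies, and accepted + rejected always equals
total. sgRNAs match exactly by default (a ≤1-mismatch mode exists; unique
nearest match required); IDs match within 1 mismatch — the four shipped IDs
(GCCTAA, TGGTCA, CGTGAT, ACATCG) are pairwise ≥4 apart, so single errors
correct unambiguously. Matched (ID, sgRNA) pairs must exist in the manifest.

## Barcode processing (`counts`)

Stage order is fixed: **collapse → min-count → min-barcodes → replicates →
day-14 replicate filter**, with survivor counts recorded per stage.

- *Collapse* (within one sgRNA): build the Hamming-distance-≤1 graph. A
  2-barcode component sums the smaller into the larger (UMI-style directional
  correction); a component of ≥3 keeps only the largest-count barcode *with
  its own counts* and discards the rest; "count" is the total across samples
  and ties break to the lexicographically smaller barcode. Both rules are
  configurable (`keep_larger`, `sum_into_max`).
- *Min-count*: a barcode needs ≥5 reads in **every** sample of the
  configured sample set (default: all samples). Note that when the set
  includes the day-14 samples, the later day-14 replicate filter can no
  longer remove anything (every replicate is a sum of barcodes that each
  have ≥5 reads there); restricting the set (e.g. to baseline) makes the
  day-14 rule active.
- *Min-barcodes*: sgRNAs keep ≥3 barcodes or are dropped.
- *Replicates*: per sgRNA, barcodes are shuffled (seeded) and dealt
  round-robin into 3 groups (sizes differ by ≤1); group sums per sample are
  the built-in replicates, and the barcode→group map is retained.
- *Day-14 filter*: sgRNAs with any replicate <5 reads in a day-14 sample are
  dropped.

## Enrichment (`enrich`)

Median-of-ratios size factors (sgRNAs with any zero excluded from factor
estimation; total-count fallback with a warning when none qualify), then per
sgRNA the mean over replicate pairs of log2((t+1)/(u+1)) and a dense rank
(1 = most enriched). The gene score is robust rank aggregation: with sgRNA
rank quantiles q(1) ≤ … ≤ q(n),

    rho = min_{j<=k} P(Beta(j, n-j+1) <= q(j)),   k = max(1, #{q <= alpha})

with alpha = 0.25 (only guides in the top quarter of the ranking drive the
score, at least one always considered). Significance is a permutation test:
n quantiles are redrawn (without replacement) from the NTC sgRNAs' quantile
pool and rescored; p = (1 + #(null ≤ observed)) / (n_perm + 1). With fewer
than `min_pool` NTCs surviving the filters the pool falls back to all sgRNA
quantiles (logged). An exact mode enumerates all C(pool, n) subsets
(p = max(count, 1)/N) and is guarded against infeasible sizes. FDR is
Benjamini–Hochberg; gene ranks sort by score with ties broken by name, so
rankings are deterministic and independent of the permutation seed. Using
NTCs as the null pool is a choice, not a given: it conditions the null on
the screen's own no-target behaviour. Positive selection (enrichment) is the
tested direction; depletion analysis would need a sign flip and is untested.
The replicate table also exports bit-exactly to MAGeCK v0.5.x count format
(`sgRNA<TAB>gene<TAB>sample.replicate columns`, integer counts) for users
who want the external tool; normalized tables are refused.

## Sub-clonal statistics (`subclonal`)

Barcode log2 fold changes at day 14 use per-sample total-count scaling (not
median-of-ratios: this operates pre-aggregation at barcode level) and keep
only barcodes with ≥5 reads in both samples, which makes pseudocount 0 safe
(configurable). Per-sgRNA dispersion is IQR = Q3 − Q1 with numpy's
linear-interpolation quantile convention ({1,2,3,4} → 1.5); sgRNAs with <2
barcodes are omitted. Clone comparisons use the two-sided Mann–Whitney test:
exact enumeration of all C(n1+n2, n1) relabelings (ties handled by the
0.5-per-tie U statistic) whenever that count is ≤ 2·10^5 — full enumeration
for much larger groups is combinatorially impossible — and the normal
approximation with tie correction otherwise; the location shift is the
Hodges–Lehmann estimate. Pair reproducibility bins reference-detected pairs
by quantiles of log2 day-14 counts into 10 bins (ties at an edge fall to the
lower bin) and reports per-bin detection (≥1 read) in earlier samples.

**Saturation analysis:** sgRNAs with ≥4 barcodes detected (≥1 read) at
baseline are used, on the post-collapse, pre-min-count table. For each
proportion p and iteration, each sgRNA contributes k barcodes sampled
without replacement, k the achievable proportion k/n closest to p (ties
upward, never 0); counts are summed per sgRNA and the gene ranking is re-run
with days 9 and 14 as the two replicates (built-in replicates are not usable
at small proportions). Iteration i uses seed `seed + i`; ranks are averaged
over iterations. Because gene ranks depend only on scores, p = 1 reproduces
the full analysis bit-identically. Filters are not re-applied inside
iterations.

## Problem sizes and numerics

The test suite and the acceptance script run simulations sized to finish in
minutes on one core as a deliberate choice: the FASTQ round-trip uses the
full demo library (4 clones × 500 genes × 4 sgRNAs × 20 BCs at 2·10^6
reads/sample, days 0 and 14), hit recovery uses 500 genes with five spiked
resistance genes on a single sensitive clone at 6·10^6 reads/sample, null
calibration uses repeated 150-gene screens, and the dispersion/saturation
contracts use 125- and 100-gene screens. All randomness flows from explicit
integer seeds through `numpy.random.Generator` (screens split theirs via
`SeedSequence.spawn` per stage/arm/sample), so identical configurations give
byte-identical outputs. Degenerate inputs are errors, not NaNs: empty
samples, zero baselines, all-zero tables, and infeasible barcode spaces all
raise typed exceptions (`ValidationError` / `DataError`, CLI exit codes
2 / 3).

## Known limitations

- The simulator's dose response and jitter magnitudes are stylized; absolute
  values of fold changes or IQRs should not be compared to any real screen.
- The gene test is a self-contained stand-in that mirrors MAGeCK's alpha-RRA
  in spirit, not a reimplementation of its negative-binomial sgRNA model;
  for publication-grade calls export the counts and run MAGeCK.
- Barcode collapsing is within-sgRNA only (as in the screen design);
  cross-sgRNA chimeras (template switching) are neither simulated nor
  corrected.
- Exact small-sample modes (rank-sum, gene-test enumeration) are bounded by
  combinatorial size guards; beyond them only the asymptotic/permutation
  paths are available.
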