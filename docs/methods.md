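# Methods

This note documents the models, conventions and numerical choices behind
`replitime`, and what the synthetic-data generators do and do not emulate.

## Replication timing index

Repli-seq sorts BrdU-pulse-labeled cells into N consecutive S-phase
fractions (here N = 4: S1 earliest … S4 latest) and sequences nascent DNA
from each. After binning (50-kb bins, reads assigned to the bin containing
their midpoint), the per-bin, per-fraction densities D₁…D_N (reads per bp)
are reduced to a single timing value per bin:

    raw_rti = Σₙ n·Dₙ / Σₙ Dₙ        ∈ [1, N]
    rti     = (raw_rti − 1) / (N − 1) ∈ [0, 1]

so 0 means all signal in the earliest fraction and 1 all signal in the
latest. The affine rescaling is the only map consistent with a weighted
fraction-index mean being reported on a 0–1 scale. The index is invariant
to overall scaling of the densities and monotone under moving density mass
to later fractions.

**Undefined bins.** Bins whose total density falls below a floor (default:
the 1st percentile of positive totals) are masked (NaN) — the ratio is
unstable near 0/0 — and masking propagates through averaging, differential
calling and feature classification.

**Normalization.** Before the index is computed, all fraction columns of
all samples in an analysis are quantile-normalized together: every column
is mapped onto the per-rank mean of the column-sorted values, so fractions
and replicates become comparable in distribution while within-column ranks
are preserved. Ties receive the mean of the reference values they span
(the convention of limma's `normalizeQuantiles`). A consequence worth
knowing: with heavily tied columns (e.g. many empty bins) the tie-averaged
output is not the exact reference multiset, so a second application is not
a strict no-op; for tie-free columns quantile normalization is idempotent.

**Smoothing.** Each fraction is LOESS-smoothed per chromosome against bin
midpoint: tricube-weighted local polynomial regression (default degree 1)
over a fixed genomic span (default 300 kb, i.e. ±3 bins), negative fits
clamped to zero, span reduced to the chromosome length where necessary.
The bandwidth is distance-based rather than nearest-neighbor so the
physical smoothing scale is constant across chromosomes. The sub-megabase
default preserves local features (initiation valleys, termination peaks)
while removing counting noise; it is configurable.

## Differential replication timing

Replicate agreement sets the noise scale: σ is the pooled standard
deviation of per-bin RTI differences between biological replicates of the
same cell line (all within-line pairs, variances pooled weighted by bin
count — the root-mean-square of per-pair SDs at equal counts). Group
profiles are means of cell-line mean RTIs (lines weighted equally). A bin
is called *earlier* in group A when rti_A − rti_B < −2σ and *later* when
the difference exceeds +2σ; no multiple-testing correction is applied —
the method is a fixed two-standard-deviation cutoff by construction, and
the null behavior of that cutoff is verified against a Monte-Carlo oracle
in the test suite. "Regions" are 50-kb bins; adjacent same-call bins can
additionally be merged (`merge_regions`) and are reported separately. The
genome-percentage denominator defaults to the analyzed bin total and can
be fixed to an assembly size.

## Local replication features

A 10-bin (500-kb) window slides one bin at a time; each bin takes the
label of the window centred on it (position 5 of 10, configurable), and
bins without a complete window are masked. Precedence and rules:

1. **CTR** — population variance (ddof 0) of the raw RTI values < 0.006.
   Variance is computed on raw values, not window-mean-normalized ones
   (a flag exposes the alternative reading); the threshold sits on the
   raw-RTI scale. CTR pre-empts the extremum tests because a flat window
   trivially contains a numeric minimum.
2. **IZ** — the window minimum lies strictly interior and the profile
   rises by at least ε = 0.02 RTI units on both sides (prominence guard
   against noise flicker; configurable). Window-mean normalization is a
   shape representation only; using the mean-subtracted profile keeps
   calls invariant under adding a constant to all RTI values.
3. **TS** — symmetric rule for the maximum.
4. **TTR** — everything else.

CTR runs are subdivided by flanking timing (500-kb flanks each side,
defined bins only): flanks replicating later than the run ⇒ **ICTR**
(early plateau seeding outward forks); earlier ⇒ **TCTR**; one flank
missing, the other decides; both missing or exact tie ⇒ TCTR if the run
mean RTI > 0.5 else ICTR. The flank comparison statistic (mean RTI) is a
declared convention.

## Cell-cycle expression integration

Differential expression is taken as given (per-phase tables of log2 fold
change and FDR); the flag is |log2FC| > 1 and FDR < 0.05. For the phase
partition the two S gates (early/late S) pool into one "S" slice, giving
five mutually exclusive slices (unique G1/S/G2, shared among 2–3, shared
all). Gene-to-region assignment is any-bp overlap of the gene body with
the 50-kb bin (midpoint/TSS variants are deliberate non-defaults). The
region × phase matrix averages log2FC over the genes of each differential
bin, rows sorted by timing change.

Phase-ratio profiles are log2((FPKM_q + c)/(FPKM_p + c)) for the four
consecutive transitions G1→ES→LS→G2M→G1 with pseudocount c = 1 FPKM
(bounds ratios at low expression); the four ratios of a gene sum to zero
exactly. Ratios are computed per cell line then averaged within subgroup
(computing on subgroup-mean FPKM is the exposed alternative). Genes silent
in every phase of every cell line are dropped and reported. Clustering is
agglomerative with Ward linkage on Euclidean distances of the ratio rows,
cut at k (default 6); rows are pre-sorted by gene id and cluster ids
renumbered in dendrogram-leaf order, making the partition deterministic
and invariant to input row order. The bundled 39-gene replication panel is
a synthetic stand-in list of canonical replication genes; any list can be
supplied.

## Fiber metrics

Lengths convert as px × (142 nm/px) / 1000 × (2 kb/µm); the stretched-
fiber constant 2 kb per micrometre is the standard conversion. Segments
are cleaned before analysis: gaps ≤ 3 px between same-label segments are
bridged (annotation noise), adjacent same-label segments merged.

*Ongoing forks*: a CldU segment adjacent to an IdU segment on one side and
to unlabeled fiber (gap or fiber end) on the other — the fork ran through
both pulses and was still progressing; its speed is CldU length / 30 min.
CldU flanked by IdU on both sides is a merged termination structure and is
excluded. *Origins*: an IdU segment flanked by CldU on both sides is the
signature of two forks diverging from one firing point under IdU-first
labeling; the origin sits at the segment centre, and distances between
neighboring origins on a fiber are pooled. A flag restores the literal
"midpoint between every consecutive boundary pair" reading. Group
summaries report median and IQR with two-sided Mann-Whitney rank-sum
tests.

## Synthetic data

*Repli-seq*: a piecewise landscape (early/late plateaus, initiation
valleys, termination peaks, transition ramps) defines true timing t per
bin; reads spread over fractions by a discretized Gaussian kernel centred
at 1 + 3t (width 0.5 fraction units, mimicking sorting spread), with
Poisson counting noise (200 expected reads per bin) and per-replicate
timing jitter (SD 0.03 RTI units, within the replicate-agreement range
typical of sorted-fraction timing data). The default landscape strings all
five archetypes together with continuous junctions; excursion amplitudes
(0.45) are sized so planted peaks/valleys exceed the CTR variance
threshold by construction (a triangular excursion of amplitude A has
10-bin variance ≈ A²/12). It does not emulate mappability variation,
copy-number differences, GC bias, or S/G1 contamination — recovery tests
therefore demonstrate correctness of the computation, not robustness to
every artifact of real libraries.

*Fibers*: per fiber, origins accumulate log-normal spacings (median per
preset, log-SD 0.15) and fire asynchronously, uniform over the first
20 min of the IdU pulse; two forks per origin run outward at the origin's
log-normal speed (log-SD 0.15), paint IdU until minute 30 and CldU until
minute 60, stop where converging fronts meet, and all boundaries are
quantized to the 142-nm pixel grid. Asynchronous firing is what keeps
neighboring IdU tracks separated: with the preset spacings and speeds,
synchronously fired neighbors would fuse their first-pulse labels and the
origin signature would vanish. Presets: a tumor-like group (spacing median
35 kb, speed median 0.5 kb/min) and a normal-astrocyte-like group (65 kb,
1.0 kb/min). Remaining detection bias from rare track fusion is below
~1–2% on the medians at these presets.

*Expression*: genes get named archetype profiles (multiplicative steps
between consecutive phases) with log-normal noise; genes inside planted
differential-timing bins receive sign-concordant fold changes (earlier →
up, later → down, |log2FC| = 2) with FDRs passing the filter, in all
phases or a random subset (`de_phase_mode`). Ground truth (archetype,
planted effect) is always returned.

All generators are pure functions of (config, seed); seeds are mandatory.

## Problem sizes and defaults

The default landscape is ~370 bins × 2 chromosomes × 2 replicates —
enough for stable end-to-end recovery (Spearman > 0.95 against planted
timing) while keeping any single analysis under a second. Null-calibration
checks use 10,000 bins; fiber benchmarks 1,000 fibers with ~5 origins
each (≈4,000 distances, ≈2,000 ongoing forks), at which scale the
estimated medians sit well inside 5% of the configured values.

## Known limitations

- The 2σ cutoff has no error-rate control across bins; its calibration is
  exact only under approximately Gaussian replicate noise.
- Feature labels near segment junctions are intrinsically ambiguous
  (windows straddle two features); accuracy guarantees hold away from
  junctions.
- The even 10-bin window has no true centre; the position-5 convention
  shifts labels by half a bin relative to a symmetric window.
- Fiber metrics assume complete annotation of label segments; origins
  whose first-pulse tracks fused with a neighbor's are undetectable by any
  boundary-based rule, slightly biasing inter-origin medians upward.
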