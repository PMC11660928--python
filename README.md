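# replitime

Replication-timing analysis for multi-fraction Repli-seq, from binned read
counts to biology: per-bin replication timing indices, differential timing
between cell groups, local replication-feature annotation, integration
with cell-cycle-phase-resolved expression, and fork metrics from DNA fiber
assays. Written for studies that compare replication programs between
tumor and normal cells — e.g. H3 K27-altered diffuse midline glioma lines
against normal astrocytes — but agnostic to the cell types involved.

## The model

Cells are pulse-labeled with BrdU and FACS-sorted into N consecutive
S-phase fractions (S1…S4); nascent DNA from each fraction is sequenced and
counted over 50-kb bins. After quantile normalization across fractions and
replicates and per-chromosome LOESS smoothing, each bin's densities
D₁…D_N collapse to a replication timing index

```
RTI = ( Σₙ n·Dₙ / Σₙ Dₙ  − 1 ) / (N − 1)   ∈ [0, 1]
```

with 0 = earliest and 1 = latest replication. On top of this single
coordinate:

- **Differential timing** — a bin replicates *earlier*/*later* in group A
  than group B when the group-mean RTI difference exceeds twice the
  standard deviation of within-cell-line replicate differences.
- **Replication features** — a 10-bin sliding window labels each bin as
  initiation zone (IZ, local RTI minimum), termination site (TS, local
  maximum), constant-timing region (window variance < 0.006; subdivided
  into early ICTR / late TCTR plateaus by flanking timing) or timing
  transition region (TTR).
- **Cycle-resolved expression** — differential-expression tables per cell
  cycle phase (G1, early S, late S, G2/M) are partitioned by phase
  membership, related to differential-timing regions by genomic overlap,
  and gene panels are clustered on log2 expression ratios between
  consecutive phases (Ward linkage).
- **Fiber metrics** — dual-pulse (IdU→CldU) fiber tracks yield fork speeds
  (CldU length of ongoing forks / 30 min) and inter-origin distances
  (between centres of IdU segments flanked by CldU), at 2 kb/µm and
  142 nm/px.

A seeded synthetic-data module simulates Repli-seq counts over
constructed timing landscapes, dual-labeled fibers with known origin
spacings and fork speeds, and phase-resolved expression with planted
effects — so every stage is testable end to end with no downloads. See
`docs/methods.md` for conventions and assumptions.

## Worked example

Simulate fibers with the tumor-like and normal presets and compare fork
dynamics (`examples/05_fiber_assay.py`):

```bash
$ python examples/05_fiber_assay.py
inter-origin distance (kb):
        DMG: median  35.2  IQR [31.9, 39.5]  n=1971
  astrocyte: median  66.0  IQR [59.6, 73.7]  n=1944
  rank-sum p = 0.00e+00

fork speed (kb/min):
        DMG: median  0.49  IQR [0.44, 0.54]  n=1144
  astrocyte: median  0.99  IQR [0.90, 1.10]  n=1062
  rank-sum p = 0.00e+00
```

The tumor-like preset plants origins a median 35 kb apart moving at
0.5 kb/min; the normal preset 65 kb and 1.0 kb/min. The fiber-metrics
stage recovers both medians from the simulated label geometry alone —
shorter inter-origin distance with slower forks is the classic fiber
signature of replication stress (more origins fire to compensate for slow
forks). The other examples walk the remaining stages:

- `examples/01_rti_from_counts.py` — counts → RTI, rank correlation with
  planted timing (prints Spearman ≈ 0.98).
- `examples/02_differential_timing.py` — two simulated groups, replicate
  sigma, 2σ calls and genome-percentage summary.
- `examples/03_replication_features.py` — feature labels and BED output
  on a noise-free landscape.
- `examples/04_cycle_expression.py` — DE phase partition, timing-vs-
  expression direction, phase-ratio clustering of the bundled 39-gene
  replication panel.

A thin CLI wraps the same library calls
(`replitime rti|diff|features|cycle|fibers|simulate`, see `--help`).

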