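"""Synthetic data generators for every pipeline stage.

Three generators emit inputs with the statistical structure the analysis
assumes, plus the ground truth needed for recovery tests:

* :func:`simulate_repliseq` — a replication-timing landscape (plateaus,
  initiation valleys, termination peaks, transition ramps) is turned into
  per-bin, per-fraction read counts: each bin's reads spread over the four
  S-phase fractions through a discretized Gaussian kernel centred at
  ``1 + 3t`` for true timing ``t``, with Poisson counting noise and
  replicate-level timing jitter.
* :func:`simulate_fibers` — origins are placed along fibers at log-normal
  spacings and fire asynchronously within the first pulse; bidirectional
  forks run at per-origin log-normal speeds, paint 30 min of IdU then
  30 min of CldU, stop where converging forks meet, and the resulting label
  geometry is quantized to pixels.  Asynchronous firing keeps the IdU
  tracks of neighboring origins separated, as in real fibers, so the
  origin signature (CldU-IdU-CldU) stays detectable.
* :func:`simulate_phase_expression` — genes receive cell-cycle archetype
  profiles over (G1, ES, LS, G2M); genes inside planted differential-timing
  regions get sign-concordant fold changes (earlier -> up, later -> down)
  with FDRs that survive the twofold / FDR < 0.05 filter.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fibers import FiberTrack, IDU, CLDU, GAP, PIXEL_SIZE_NM, KB_PER_UM, LABEL_MINUTES
from .grid import BinGrid
from .profiles import FractionProfile

__all__ = [
    "LandscapeSpec",
    "RepliSimConfig",
    "FiberSimConfig",
    "ExprSimConfig",
    "FIBER_PRESETS",
    "default_landscape",
    "timing_track",
    "simulate_repliseq",
    "simulate_fibers",
    "simulate_phase_expression",
]

SEGMENT_KINDS = ("early_plateau", "late_plateau", "iz_valley", "ts_peak", "ttr_ramp")


@dataclass
class LandscapeSpec:
    """Piecewise replication-timing landscape over one or more chromosomes.

    ``segments`` maps each chromosome to an ordered list of
    (kind, length_bins, t_start, t_end) tuples with timings in [0, 1]:
    plateaus hold ``t_start``; ramps run linearly from ``t_start`` to
    ``t_end``; valleys (initiation zones) dip from ``t_start`` down to
    ``t_end`` and back; peaks (termination sites) rise and return.
    """

    segments: dict[str, list[tuple[str, int, float, float]]]
    bin_width: int = 50_000

    def __post_init__(self):
        for chrom, segs in self.segments.items():
            for kind, length, t0, t1 in segs:
                if kind not in SEGMENT_KINDS:
                    raise ValueError(f"unknown segment kind {kind!r}")
                if length < 1:
                    raise ValueError("segment lengths must be >= 1 bin")
                if not (0 <= t0 <= 1 and 0 <= t1 <= 1):
                    raise ValueError("timings must lie in [0, 1]")

    def chrom_sizes(self) -> dict[str, int]:
        return {
            chrom: sum(s[1] for s in segs) * self.bin_width
            for chrom, segs in self.segments.items()
        }


def timing_track(spec: LandscapeSpec) -> tuple[BinGrid, np.ndarray, np.ndarray]:
    """Expand a landscape into (grid, true timing per bin, segment kind per bin)."""
    grid = BinGrid.from_chrom_sizes(spec.chrom_sizes(), spec.bin_width)
    t = np.empty(len(grid))
    kinds = np.empty(len(grid), dtype=object)
    for chrom, segs in spec.segments.items():
        sl = grid.chrom_slice(chrom)
        pos = sl.start
        for kind, length, t0, t1 in segs:
            u = (np.arange(length) + 0.5) / length
            if kind in ("early_plateau", "late_plateau"):
                vals = np.full(length, t0)
            elif kind == "ttr_ramp":
                vals = t0 + (t1 - t0) * u
            else:  # iz_valley / ts_peak: symmetric excursion t0 -> t1 -> t0
                vals = t0 + (t1 - t0) * (1.0 - np.abs(2.0 * u - 1.0))
            t[pos : pos + length] = vals
            kinds[pos : pos + length] = kind
            pos += length
    return grid, t, kinds


def default_landscape(n_blocks: int = 6, bin_width: int = 50_000) -> LandscapeSpec:
    """A two-chromosome landscape cycling through all feature archetypes.

    Each block strings together an early plateau, a transition ramp to a
    late plateau, a termination peak, a ramp back and an initiation valley
    — giving every classifier label a ground-truth run.
    """
    block = [
        ("early_plateau", 12, 0.15, 0.15),
        ("ttr_ramp", 8, 0.15, 0.85),
        ("late_plateau", 12, 0.85, 0.85),
        ("ttr_ramp", 6, 0.85, 0.45),
        ("ts_peak", 9, 0.45, 0.90),
        ("iz_valley", 9, 0.45, 0.05),
        ("ttr_ramp", 6, 0.45, 0.15),
    ]
    per_chrom = n_blocks // 2 + n_blocks % 2
    return LandscapeSpec(
        segments={
            "chr1": block * per_chrom,
            "chr2": block * (n_blocks - per_chrom),
        },
        bin_width=bin_width,
    )


@dataclass
class RepliSimConfig:
    """Configuration of the Repli-seq count simulator.

    ``fraction_kernel_width`` is the Gaussian spread (in fraction-index
    units) of a bin's signal across S1..S4; ``depth`` the expected reads
    per bin; ``replicate_noise_sd`` a per-replicate timing jitter on the
    RTI scale; ``seed`` is mandatory.
    """

    landscape: LandscapeSpec = field(default_factory=default_landscape)
    fraction_kernel_width: float = 0.5
    depth: float = 200.0
    replicate_noise_sd: float = 0.03
    n_replicates: int = 2
    seed: int = 0
    cell_line: str = "sim"
    subgroup: str = "sim"

    def __post_init__(self):
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.replicate_noise_sd < 0:
            raise ValueError("replicate noise must be >= 0")
        if self.seed is None:
            raise ValueError("seed is mandatory")


def _fraction_weights(t: np.ndarray, width: float, n_fractions: int = 4) -> np.ndarray:
    """Discretized Gaussian over fraction indices centred at 1 + (N-1)*t."""
    centers = 1.0 + (n_fractions - 1) * t
    idx = np.arange(1, n_fractions + 1, dtype=float)
    if width <= 0:
        # degenerate kernel: all mass in the nearest fraction
        w = np.zeros((len(t), n_fractions))
        nearest = np.clip(np.round(centers), 1, n_fractions).astype(int) - 1
        w[np.arange(len(t)), nearest] = 1.0
        return w
    z = (idx[None, :] - centers[:, None]) / width
    w = np.exp(-0.5 * z**2)
    return w / w.sum(axis=1, keepdims=True)


def simulate_repliseq(
    config: RepliSimConfig,
) -> tuple[list[FractionProfile], BinGrid, np.ndarray, np.ndarray]:
    """Simulate raw 4-fraction bin counts for each replicate.

    Returns (profiles, grid, true_timing, segment_kinds): one raw
    :class:`FractionProfile` per replicate, plus the per-bin ground-truth
    timing in [0, 1] and the landscape segment kind of every bin.
    """
    rng = np.random.default_rng(config.seed)
    grid, t_true, kinds = timing_track(config.landscape)
    profiles = []
    for r in range(config.n_replicates):
        t_rep = np.clip(
            t_true + rng.normal(0.0, config.replicate_noise_sd, size=len(t_true)), 0.0, 1.0
        )
        w = _fraction_weights(t_rep, config.fraction_kernel_width)
        counts = rng.poisson(config.depth * w).astype(float)
        D = counts / grid.widths[:, None]
        profiles.append(
            FractionProfile(
                grid,
                D,
                cell_line=config.cell_line,
                subgroup=config.subgroup,
                replicate_id=f"rep{r + 1}",
                stage="raw",
            )
        )
    return profiles, grid, t_true, kinds


@dataclass
class FiberSimConfig:
    """Configuration of the DNA-fiber simulator.

    Medians are the targets of the log-normal spacing and speed draws;
    ``sigma_log`` terms set the (log-scale) dispersion.  ``firing_window``
    spreads origin firing uniformly over the first minutes of the IdU pulse
    — asynchronous firing is what keeps neighboring label tracks from
    merging, as in real fibers.
    """

    origin_spacing_median_kb: float = 50.0
    fork_speed_median_kb_min: float = 0.75
    spacing_sigma_log: float = 0.15
    speed_sigma_log: float = 0.15
    n_fibers: int = 1000
    origins_per_fiber: int = 5
    firing_window_min: float = 20.0
    pixel_size_nm: float = PIXEL_SIZE_NM
    label_minutes: float = LABEL_MINUTES
    kb_per_um: float = KB_PER_UM
    seed: int = 0

    def __post_init__(self):
        for name in (
            "origin_spacing_median_kb",
            "fork_speed_median_kb_min",
            "n_fibers",
            "origins_per_fiber",
            "pixel_size_nm",
            "label_minutes",
            "kb_per_um",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.spacing_sigma_log < 0 or self.speed_sigma_log < 0:
            raise ValueError("dispersions must be >= 0")
        if not 0 <= self.firing_window_min < self.label_minutes:
            raise ValueError("firing window must fit inside the first pulse")
        if self.seed is None:
            raise ValueError("seed is mandatory")


FIBER_PRESETS: dict[str, dict] = {
    # printed medians of the glioma (DMG) and normal astrocyte groups
    "DMG": {"origin_spacing_median_kb": 35.0, "fork_speed_median_kb_min": 0.5},
    "astrocyte": {"origin_spacing_median_kb": 65.0, "fork_speed_median_kb_min": 1.0},
}


def fiber_preset(name: str, **overrides) -> FiberSimConfig:
    """Build a :class:`FiberSimConfig` from a named preset."""
    params = dict(FIBER_PRESETS[name])
    params.update(overrides)
    return FiberSimConfig(**params)


def simulate_fibers(config: FiberSimConfig) -> tuple[list[FiberTrack], pd.DataFrame]:
    """Simulate dual-pulse-labeled fibers and their ground truth.

    Per fiber: origin positions accumulate log-normal spacings; each origin
    fires at a uniform time within the firing window and sends two forks
    outward at the origin's log-normal speed.  Forks paint IdU until minute
    30 and CldU until minute 60, stopping where they meet a converging
    neighbor.  Label intervals are quantized to the pixel grid and emitted
    as ordered (label, px) segments with explicit gaps.

    Returns (tracks, truth) where truth holds per-origin position, firing
    time, speed and per-fiber spacings.
    """
    rng = np.random.default_rng(config.seed)
    t_idu = config.label_minutes
    t_end = 2 * config.label_minutes
    kb_per_px = config.pixel_size_nm / 1000.0 * config.kb_per_um
    mu_s = np.log(config.origin_spacing_median_kb)
    mu_v = np.log(config.fork_speed_median_kb_min)

    tracks: list[FiberTrack] = []
    truth_rows = []
    for f in range(config.n_fibers):
        k = config.origins_per_fiber
        spacings = np.exp(rng.normal(mu_s, config.spacing_sigma_log, size=k - 1))
        margin = 2.5 * config.fork_speed_median_kb_min * t_end  # room for edge forks
        x = margin + np.concatenate([[0.0], np.cumsum(spacings)])
        fire = rng.uniform(0.0, config.firing_window_min, size=k)
        speed = np.exp(rng.normal(mu_v, config.speed_sigma_log, size=k))
        fiber_len = x[-1] + margin

        # fork stop positions: converging neighbors meet where fronts cross
        right_stop = np.full(k, np.inf)
        left_stop = np.full(k, -np.inf)
        for i in range(k - 1):
            vi, vj = speed[i], speed[i + 1]
            # front positions freeze before firing; solve meeting of the two fronts
            tc = (x[i + 1] - x[i] + vi * fire[i] + vj * fire[i + 1]) / (vi + vj)
            tc = max(tc, fire[i], fire[i + 1])
            pc = x[i] + vi * (tc - fire[i])
            if tc <= t_end:
                right_stop[i] = pc
                left_stop[i + 1] = pc

        idu_iv, cldu_iv = [], []
        for i in range(k):
            for sign, stop in ((+1, right_stop[i]), (-1, left_stop[i])):
                # extent of the fork at the end of each pulse, clipped at stop
                d_idu = max(0.0, (t_idu - fire[i])) * speed[i]
                d_end = (t_end - fire[i]) * speed[i]
                a, b = x[i], x[i] + sign * d_idu
                c = x[i] + sign * d_end
                if sign > 0:
                    b, c = min(b, stop), min(c, stop)
                    if b > a:
                        idu_iv.append((a, b))
                    if c > b:
                        cldu_iv.append((b, c))
                else:
                    b, c = max(b, stop), max(c, stop)
                    if b < a:
                        idu_iv.append((b, a))
                    if c < b:
                        cldu_iv.append((c, b))

        segs = _paint_segments(idu_iv, cldu_iv, fiber_len, kb_per_px)
        if segs:
            tracks.append(
                FiberTrack(
                    fiber_id=f"fiber{f}",
                    segments=segs,
                    pixel_size_nm=config.pixel_size_nm,
                    label_minutes=config.label_minutes,
                    kb_per_um=config.kb_per_um,
                )
            )
        for i in range(k):
            truth_rows.append(
                {
                    "fiber_id": f"fiber{f}",
                    "origin_kb": x[i],
                    "fire_min": fire[i],
                    "speed_kb_min": speed[i],
                    "spacing_kb": spacings[i - 1] if i > 0 else np.nan,
                }
            )
    return tracks, pd.DataFrame(truth_rows)


def _paint_segments(idu_iv, cldu_iv, fiber_len_kb, kb_per_px):
    """Turn labeled kb intervals into ordered pixel-quantized segments."""
    events = sorted(
        [(a, b, IDU) for a, b in idu_iv] + [(a, b, CLDU) for a, b in cldu_iv]
    )
    segs: list[tuple[str, float]] = []
    cursor_px = 0
    for a, b, lab in events:
        a_px = int(round(a / kb_per_px))
        b_px = int(round(b / kb_per_px))
        a_px = max(a_px, cursor_px)
        if b_px <= a_px:
            continue
        if a_px > cursor_px:
            segs.append((GAP, float(a_px - cursor_px)))
        if segs and segs[-1][0] == lab:
            segs[-1] = (lab, segs[-1][1] + float(b_px - a_px))
        else:
            segs.append((lab, float(b_px - a_px)))
        cursor_px = b_px
    end_px = int(round(fiber_len_kb / kb_per_px))
    if end_px > cursor_px:
        segs.append((GAP, float(end_px - cursor_px)))
    return segs


@dataclass
class ExprSimConfig:
    """Configuration of the phase-resolved expression simulator.

    Archetypes are named phase-profiles (multiplicative steps between
    consecutive phases); ``de_log2fc`` is the planted effect size for genes
    inside differential-timing regions, sign-concordant with the timing
    shift (earlier -> up, later -> down).
    """

    n_genes: int = 200
    base_fpkm: float = 20.0
    archetypes: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: {
            # log2 step G1->ES, ES->LS, LS->G2M plus the G2M->G1 return
            "flat": (0.0, 0.0, 0.0, 0.0),
            "up_ES_LS": (0.0, 2.0, 0.0, -2.0),
            "up_G1_ES": (2.0, 0.0, 0.0, -2.0),
            "up_G2_G1": (0.0, 0.0, -2.0, 2.0),
        }
    )
    noise_sd_log2: float = 0.15
    de_log2fc: float = 2.0
    de_fdr: float = 1e-4
    null_fdr_low: float = 0.2
    de_phase_mode: str = "all"  # "all": DE in every phase; "random": subset
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.seed is None:
            raise ValueError("seed is mandatory")


PHASES = ("G1", "ES", "LS", "G2M")


def simulate_phase_expression(
    config: ExprSimConfig,
    grid: BinGrid | None = None,
    diff_call: np.ndarray | None = None,
    cell_lines: dict[str, str] | None = None,
) -> dict:
    """Simulate phase expression, DE tables and a gene annotation.

    Genes are laid head-to-tail across ``grid`` (one gene per consecutive
    bin, cycling) and assigned archetypes round-robin.  If ``diff_call``
    (per-bin {earlier, later, none, masked} truth or calls) is given, the
    genes inside earlier/later bins receive a planted log2FC of
    +/-``de_log2fc`` (earlier-replicating -> upregulated) in every phase,
    with FDRs below the filter; all remaining genes are null.

    Returns a dict with keys ``expression`` (long gene/cell_line/subgroup/
    phase/fpkm), ``de`` (gene/phase/log2fc/fdr), ``genes`` (BED-like
    annotation) and ``truth`` (gene/archetype/planted_log2fc).
    """
    rng = np.random.default_rng(config.seed)
    if cell_lines is None:
        cell_lines = {"simA1": "groupA", "simA2": "groupA"}
    arch_names = list(config.archetypes)

    genes = []
    if grid is not None:
        for g in range(config.n_genes):
            b = g % len(grid)
            genes.append(
                {
                    "chrom": grid.chroms[b],
                    "start": int(grid.starts[b]) + 1000,
                    "end": int(grid.ends[b]) - 1000,
                    "gene": f"gene{g}",
                    "bin": b,
                }
            )
    else:
        genes = [
            {"chrom": "chr1", "start": 1000 + 5000 * g, "end": 4000 + 5000 * g,
             "gene": f"gene{g}", "bin": -1}
            for g in range(config.n_genes)
        ]
    genes_df = pd.DataFrame(genes)

    expr_rows, de_rows, truth_rows = [], [], []
    for g, rec in enumerate(genes_df.itertuples(index=False)):
        arch = arch_names[g % len(arch_names)]
        steps = config.archetypes[arch]
        log2_levels = np.concatenate([[0.0], np.cumsum(steps[:3])])
        planted = 0.0
        if diff_call is not None and rec.bin >= 0:
            call = diff_call[rec.bin]
            if call == "earlier":
                planted = +config.de_log2fc
            elif call == "later":
                planted = -config.de_log2fc
        for line, subgroup in cell_lines.items():
            noise = rng.normal(0.0, config.noise_sd_log2, size=4)
            fpkm = config.base_fpkm * 2.0 ** (log2_levels + noise)
            for p, phase in enumerate(PHASES):
                expr_rows.append(
                    {
                        "gene": rec.gene,
                        "cell_line": line,
                        "subgroup": subgroup,
                        "phase": phase,
                        "fpkm": float(fpkm[p]),
                    }
                )
        if planted != 0.0 and config.de_phase_mode == "random":
            n_de = int(rng.integers(1, 5))
            de_phases = set(rng.choice(4, size=n_de, replace=False))
        else:
            de_phases = set(range(4))
        for pi, phase in enumerate(PHASES):
            if planted != 0.0 and pi in de_phases:
                log2fc = planted + rng.normal(0.0, 0.1)
                fdr = config.de_fdr * float(rng.uniform(0.1, 1.0))
            else:
                log2fc = rng.normal(0.0, 0.2)
                fdr = float(rng.uniform(config.null_fdr_low, 1.0))
            de_rows.append(
                {"gene": rec.gene, "phase": phase, "log2fc": float(log2fc), "fdr": fdr}
            )
        truth_rows.append({"gene": rec.gene, "archetype": arch, "planted_log2fc": planted})

    return {
        "expression": pd.DataFrame(expr_rows),
        "de": pd.DataFrame(de_rows),
        "genes": genes_df.drop(columns="bin"),
        "truth": pd.DataFrame(truth_rows),
    }
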