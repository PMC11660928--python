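"""Fraction-density profiles and the replication timing index (RTI).

Repli-seq sorts BrdU-labeled S-phase cells into N consecutive fractions
(here four: S1 early ... S4 late), sequences nascent DNA from each, and
counts reads over fixed genomic bins.  After quantile normalization and
LOESS smoothing of the per-fraction densities D_1..D_N, each bin's timing
is summarized as a weighted mean of fraction indices,

    raw_rti = sum_n n * D_n / sum_n D_n          (in [1, N])

rescaled affinely to rti = (raw_rti - 1) / (N - 1) in [0, 1], where 0 is
earliest and 1 is latest replication.  Bins with total density below a
floor are masked (NaN) and stay masked downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .grid import BinGrid

__all__ = [
    "FractionProfile",
    "RTProfile",
    "bin_counts",
    "quantile_normalize",
    "loess_smooth",
    "compute_rti",
    "replicate_mean_rti",
    "group_mean_rti",
]

FRACTIONS = ("S1", "S2", "S3", "S4")


@dataclass
class FractionProfile:
    """Per-bin read densities for N S-phase fractions of one sample.

    ``D`` is an (n_bins, N) array of non-negative densities in reads per bp.
    ``stage`` tracks where the profile sits in the raw -> quantile_normalized
    -> smoothed pipeline.
    """

    grid: BinGrid
    D: np.ndarray
    cell_line: str = "sample"
    subgroup: str = ""
    replicate_id: str = "rep1"
    stage: str = "raw"

    def __post_init__(self):
        D = np.asarray(self.D, dtype=float)
        if D.ndim != 2 or D.shape[0] != len(self.grid):
            raise ValueError(f"D must be (n_bins, N); got {D.shape} for {len(self.grid)} bins")
        if D.shape[1] < 2:
            raise ValueError("at least 2 fractions are required")
        if self.stage in ("raw", "quantile_normalized") and np.any(D < 0):
            raise ValueError("densities must be non-negative")
        self.D = D

    @property
    def n_fractions(self) -> int:
        return self.D.shape[1]

    @property
    def total_density(self) -> np.ndarray:
        return self.D.sum(axis=1)


@dataclass
class RTProfile:
    """Per-bin replication timing index for one sample or group.

    ``rti`` lies in [0, 1] (0 = earliest, 1 = latest); masked bins are NaN.
    ``raw_rti`` is the unrescaled weighted fraction index in [1, N].
    """

    grid: BinGrid
    rti: np.ndarray
    n_fractions: int = 4
    cell_line: str = "sample"
    subgroup: str = ""
    replicate_id: str = ""

    def __post_init__(self):
        rti = np.asarray(self.rti, dtype=float)
        if rti.shape != (len(self.grid),):
            raise ValueError("rti must be one value per bin")
        ok = ~np.isnan(rti)
        if np.any((rti[ok] < -1e-9) | (rti[ok] > 1 + 1e-9)):
            raise ValueError("rti values must lie in [0, 1]")
        self.rti = rti

    @property
    def raw_rti(self) -> np.ndarray:
        return 1.0 + self.rti * (self.n_fractions - 1)

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the bin is masked (undefined)."""
        return np.isnan(self.rti)


def bin_counts(
    intervals,
    grid: BinGrid,
    cell_line: str = "sample",
    subgroup: str = "",
    replicate_id: str = "rep1",
    fraction_col: str = "fraction",
) -> FractionProfile:
    """Count aligned reads into grid bins and convert to densities.

    Parameters
    ----------
    intervals
        DataFrame-like with columns ``chrom``, ``start``, ``end`` and a
        fraction column giving the S-phase fraction (S1..S4 or 1..N) of each
        read.  Each read is assigned to the single bin containing its
        midpoint.
    grid
        Target bin grid.

    Returns
    -------
    FractionProfile at stage ``raw``, each bin holding count / bin_width
    (reads per bp).  Reads on chromosomes absent from the grid are skipped
    with a warning; empty input yields an all-zero profile with a warning.
    """
    import pandas as pd

    df = pd.DataFrame(intervals)
    frac_labels = list(FRACTIONS)
    if len(df) == 0:
        warnings.warn("no reads supplied; returning an all-zero profile")
        D = np.zeros((len(grid), len(frac_labels)))
        return FractionProfile(grid, D, cell_line, subgroup, replicate_id, "raw")

    frac = df[fraction_col]
    if frac.dtype.kind in "iuf":
        frac_idx = frac.astype(int).to_numpy() - 1
        n_frac = max(len(frac_labels), int(frac_idx.max()) + 1)
    else:
        labels = sorted(frac.unique())
        n_frac = max(len(frac_labels), len(labels))
        order = {lab: i for i, lab in enumerate(frac_labels)}
        for lab in labels:
            if lab not in order:
                order[lab] = len(order)
        frac_idx = frac.map(order).to_numpy()

    counts = np.zeros((len(grid), n_frac))
    mid = ((df["start"].to_numpy() + df["end"].to_numpy()) // 2).astype(np.int64)
    chroms = df["chrom"].to_numpy()
    missing = set()
    for chrom in pd.unique(chroms):
        sel = chroms == chrom
        if chrom not in grid._chrom_index:
            missing.add(chrom)
            continue
        sl = grid.chrom_slice(chrom)
        starts = grid.starts[sl]
        ends = grid.ends[sl]
        pos = mid[sel]
        idx = np.searchsorted(starts, pos, side="right") - 1
        inside = (idx >= 0) & (pos < ends[np.clip(idx, 0, len(ends) - 1)])
        np.add.at(counts, (sl.start + idx[inside], frac_idx[sel][inside]), 1.0)
    if missing:
        warnings.warn(f"skipped reads on chromosomes absent from grid: {sorted(missing)}")

    D = counts / grid.widths[:, None]
    return FractionProfile(grid, D, cell_line, subgroup, replicate_id, "raw")


def quantile_normalize(profiles: list[FractionProfile]) -> list[FractionProfile]:
    """Quantile-normalize fraction densities across samples and fractions.

    All fraction columns of all profiles are pooled as columns of one matrix
    and mapped onto a common reference distribution (the per-rank mean of the
    column-sorted values), so that every column shares an identical sorted
    value multiset while within-column ranks are preserved.  Ties are
    resolved by averaging the reference values of the tied ranks.
    """
    if not profiles:
        return []
    grid = profiles[0].grid
    for p in profiles[1:]:
        if not grid.same_grid(p.grid):
            raise ValueError("all profiles must share one grid")
    cols = np.concatenate([p.D for p in profiles], axis=1)
    if cols.shape[1] < 2:
        warnings.warn("single column: quantile normalization is the identity")
        return [replace(p, D=p.D.copy(), stage="quantile_normalized") for p in profiles]

    normed = _quantile_normalize_matrix(cols)
    out, j = [], 0
    for p in profiles:
        k = p.n_fractions
        out.append(replace(p, D=normed[:, j : j + k], stage="quantile_normalized"))
        j += k
    return out


def _quantile_normalize_matrix(X: np.ndarray) -> np.ndarray:
    import pandas as pd

    df = pd.DataFrame(X)
    reference = np.sort(X, axis=0).mean(axis=1)
    ranks = df.rank(method="average").to_numpy()  # 1-based, ties averaged
    # interpolate the reference at (possibly fractional) tied ranks
    out = np.interp(ranks - 1.0, np.arange(X.shape[0]), reference)
    return out


def loess_smooth(
    profile: FractionProfile, span_bp: int = 300_000, degree: int = 1
) -> FractionProfile:
    """LOESS-smooth each fraction column along the genome, per chromosome.

    Local polynomial regression of density against bin midpoint with tricube
    weights over a symmetric window of total width ``span_bp`` centred on
    each bin.  Chromosomes shorter than the span are smoothed with the span
    reduced to the chromosome length.  Negative fitted values are clamped
    to zero.
    """
    if span_bp < 2 * profile.grid.width:
        raise ValueError(f"span_bp must be at least two bin widths ({2 * profile.grid.width})")
    if degree < 0:
        raise ValueError("degree must be >= 0")
    grid = profile.grid
    out = np.empty_like(profile.D)
    for chrom in grid.chromosomes:
        sl = grid.chrom_slice(chrom)
        x = grid.midpoints[sl]
        chrom_len = float(grid.ends[sl][-1] - grid.starts[sl][0])
        span = min(float(span_bp), chrom_len)
        for k in range(profile.n_fractions):
            out[sl, k] = _loess_1d(x, profile.D[sl, k], span, degree)
    np.clip(out, 0.0, None, out=out)
    return replace(profile, D=out, stage="smoothed")


def _loess_1d(x: np.ndarray, y: np.ndarray, span: float, degree: int) -> np.ndarray:
    """Tricube-weighted local polynomial fit evaluated at every x."""
    n = len(x)
    if n <= degree + 1:
        return y.copy()
    h = span / 2.0
    fitted = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        w = (1.0 - np.minimum(d / h, 1.0) ** 3) ** 3
        use = w > 0
        if use.sum() < degree + 1:
            # widen to the nearest degree+1 points
            nearest = np.argsort(d)[: degree + 1]
            use = np.zeros(n, bool)
            use[nearest] = True
            w = np.where(use, 1.0, 0.0)
        xs = x[use] - x[i]
        V = np.vander(xs, degree + 1, increasing=True)
        sw = np.sqrt(w[use])
        beta, *_ = np.linalg.lstsq(V * sw[:, None], y[use] * sw, rcond=None)
        fitted[i] = beta[0]
    return fitted


def compute_rti(profile: FractionProfile, floor: float | None = None) -> RTProfile:
    """Compute the per-bin replication timing index from fraction densities.

    raw_rti = sum_n n*D_n / sum_n D_n, rescaled to [0, 1] via
    (raw - 1)/(N - 1).  Bins whose total density falls below ``floor`` are
    masked; by default the floor is the 1st percentile of the positive total
    densities, which removes near-empty bins where the ratio is unstable.
    """
    D = profile.D
    if np.any(D < 0):
        raise ValueError("densities must be non-negative")
    N = profile.n_fractions
    total = D.sum(axis=1)
    if floor is None:
        positive = total[total > 0]
        floor = float(np.percentile(positive, 1)) if len(positive) else np.inf
    defined = total >= max(floor, np.finfo(float).tiny)
    if not defined.any():
        raise ValueError("no informative bins: all totals below floor")
    weights = np.arange(1, N + 1, dtype=float)
    rti = np.full(len(total), np.nan)
    raw = (D[defined] @ weights) / total[defined]
    rti[defined] = (raw - 1.0) / (N - 1.0)
    return RTProfile(
        profile.grid, rti, N, profile.cell_line, profile.subgroup, profile.replicate_id
    )


def replicate_mean_rti(rt_profiles: list[RTProfile]) -> RTProfile:
    """Average RTI over biological replicates of one cell line.

    A bin is defined in the mean only where every replicate defines it;
    masked bins propagate.
    """
    if not rt_profiles:
        raise ValueError("at least one replicate required")
    grid = rt_profiles[0].grid
    for p in rt_profiles[1:]:
        if not grid.same_grid(p.grid):
            raise ValueError("replicates must share one grid")
    stacked = np.vstack([p.rti for p in rt_profiles])
    mean = stacked.mean(axis=0)  # NaN wherever any replicate is NaN
    first = rt_profiles[0]
    return RTProfile(grid, mean, first.n_fractions, first.cell_line, first.subgroup, "mean")


def group_mean_rti(cell_line_rt: list[RTProfile], subgroup: str = "") -> RTProfile:
    """Average per-cell-line mean RTIs into a group profile (lines weighted equally)."""
    prof = replicate_mean_rti(cell_line_rt)
    prof.cell_line = subgroup or "group"
    prof.subgroup = subgroup
    return prof
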