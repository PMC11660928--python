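"""Differential replication timing between two groups of cell lines.

A bin replicates differentially when the difference of group-mean RTIs
exceeds twice the standard deviation of RTI differences between biological
replicates of the same cell line — the replicate-pair SD is the empirical
noise scale, and the fixed 2-sigma cutoff is the decision rule.  "Earlier"
means group A replicates earlier than group B at that bin (delta = rti_A -
rti_B < -2*sigma); "later" is the mirror image.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .grid import BinGrid
from .profiles import RTProfile

__all__ = [
    "DiffRTResult",
    "DiffSummary",
    "estimate_sigma",
    "call_differential",
    "summarize_differential",
    "feature_breakdown",
    "merge_regions",
]

CALL_EARLIER = "earlier"
CALL_LATER = "later"
CALL_NONE = "none"
CALL_MASKED = "masked"


@dataclass
class DiffRTResult:
    """Per-bin differential-timing calls for one two-group comparison."""

    grid: BinGrid
    delta: np.ndarray  # rti(A) - rti(B); NaN where masked
    sigma: float
    call: np.ndarray  # of {earlier, later, none, masked}
    group_a: str = "A"
    group_b: str = "B"

    @property
    def threshold(self) -> float:
        return 2.0 * self.sigma

    def to_bed(self) -> pd.DataFrame:
        """BED-like frame of the differential bins (chrom, start, end, delta, call)."""
        sel = (self.call == CALL_EARLIER) | (self.call == CALL_LATER)
        return pd.DataFrame(
            {
                "chrom": self.grid.chroms[sel],
                "start": self.grid.starts[sel],
                "end": self.grid.ends[sel],
                "delta": self.delta[sel],
                "call": self.call[sel],
            }
        )


@dataclass
class DiffSummary:
    n_earlier: int
    n_later: int
    pct_genome: float
    sigma: float

    def to_dict(self) -> dict:
        return {
            "n_earlier": self.n_earlier,
            "n_later": self.n_later,
            "pct_genome": self.pct_genome,
            "sigma": self.sigma,
        }


def estimate_sigma(replicate_rt: dict[str, list[RTProfile]]) -> float:
    """Pooled SD of within-cell-line replicate RTI differences.

    For every cell line with >= 2 replicates, each unordered replicate pair
    contributes the per-bin differences rti_i - rti_j over their commonly
    defined bins.  Pair variances are pooled (weighted by bin count) and the
    square root returned, i.e. the root-mean-square of per-pair SDs when bin
    counts are equal.
    """
    ss, n = 0.0, 0
    for line, reps in replicate_rt.items():
        for a, b in combinations(reps, 2):
            if not a.grid.same_grid(b.grid):
                raise ValueError(f"replicates of {line} are on different grids")
            d = a.rti - b.rti
            d = d[~np.isnan(d)]
            if len(d):
                ss += float(np.sum((d - d.mean()) ** 2))
                n += len(d)
    if n == 0:
        raise ValueError(
            "no replicate pair available to estimate sigma; "
            "pass an explicit sigma (CLI: --sigma)"
        )
    return float(np.sqrt(ss / n))


def call_differential(
    rt_a: RTProfile, rt_b: RTProfile, sigma: float, group_a: str = "A", group_b: str = "B"
) -> DiffRTResult:
    """Call per-bin differential timing at the 2-sigma cutoff.

    delta = rti(A) - rti(B).  delta < -2*sigma -> "earlier" (A earlier than
    B), delta > +2*sigma -> "later", otherwise "none"; bins masked in either
    input stay masked.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if not rt_a.grid.same_grid(rt_b.grid):
        raise ValueError("profiles must share one grid")
    delta = rt_a.rti - rt_b.rti
    thr = 2.0 * sigma
    call = np.full(len(delta), CALL_NONE, dtype=object)
    call[np.isnan(delta)] = CALL_MASKED
    with np.errstate(invalid="ignore"):
        call[delta < -thr] = CALL_EARLIER
        call[delta > thr] = CALL_LATER
    return DiffRTResult(rt_a.grid, delta, float(sigma), call, group_a, group_b)


def summarize_differential(
    result: DiffRTResult, genome_size: int | None = None
) -> DiffSummary:
    """Count earlier/later bins and the percentage of genome they cover.

    ``genome_size`` defaults to the grid's analyzed size (sum of bin widths);
    pass a fixed assembly size to use an external denominator.
    """
    n_earlier = int(np.sum(result.call == CALL_EARLIER))
    n_later = int(np.sum(result.call == CALL_LATER))
    denom = genome_size if genome_size is not None else result.grid.genome_size
    sel = (result.call == CALL_EARLIER) | (result.call == CALL_LATER)
    covered = int(result.grid.widths[sel].sum())
    return DiffSummary(n_earlier, n_later, 100.0 * covered / denom, result.sigma)


def feature_breakdown(result: DiffRTResult, features) -> pd.DataFrame:
    """Cross-tabulate differential calls by replication feature.

    Returns one row per feature label with the count of earlier and later
    bins falling in bins of that feature, plus each count as a fraction of
    all earlier (resp. later) calls.  Empty if there are no differential
    bins.
    """
    labels = np.asarray(features.label, dtype=object)
    if len(labels) != len(result.grid):
        raise ValueError("feature track and result must share one grid")
    rows = []
    diff_sel = (result.call == CALL_EARLIER) | (result.call == CALL_LATER)
    if not diff_sel.any():
        return pd.DataFrame(
            columns=["feature", "earlier", "later", "earlier_frac", "later_frac"]
        )
    total_e = int(np.sum(result.call == CALL_EARLIER))
    total_l = int(np.sum(result.call == CALL_LATER))
    for feat in pd.unique(labels[diff_sel]):
        sel = labels == feat
        e = int(np.sum(sel & (result.call == CALL_EARLIER)))
        l = int(np.sum(sel & (result.call == CALL_LATER)))
        rows.append(
            {
                "feature": feat,
                "earlier": e,
                "later": l,
                "earlier_frac": e / total_e if total_e else 0.0,
                "later_frac": l / total_l if total_l else 0.0,
            }
        )
    return pd.DataFrame(rows).sort_values("feature").reset_index(drop=True)


def merge_regions(result: DiffRTResult) -> pd.DataFrame:
    """Merge adjacent same-call differential bins into maximal regions.

    Reported separately from the per-bin counts: the headline region counts
    treat each 50-kb bin as one region.
    """
    bed = result.to_bed()
    if bed.empty:
        return bed.assign(n_bins=pd.Series(dtype=int))
    rows = []
    cur = None
    for rec in bed.itertuples(index=False):
        if (
            cur is not None
            and rec.chrom == cur["chrom"]
            and rec.call == cur["call"]
            and rec.start == cur["end"]
        ):
            cur["end"] = rec.end
            cur["delta_sum"] += rec.delta
            cur["n_bins"] += 1
        else:
            if cur is not None:
                rows.append(cur)
            cur = {
                "chrom": rec.chrom,
                "start": rec.start,
                "end": rec.end,
                "call": rec.call,
                "delta_sum": rec.delta,
                "n_bins": 1,
            }
    rows.append(cur)
    out = pd.DataFrame(rows)
    out["delta"] = out.pop("delta_sum") / out["n_bins"]
    return out[["chrom", "start", "end", "delta", "call", "n_bins"]]
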