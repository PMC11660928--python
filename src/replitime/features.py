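"""Classification of local replication patterns from RTI profiles.

A 10-bin (500-kb) window slides across each chromosome one bin at a time
and the local RTI shape is classified:

* **CTR** — constant timing region: window variance of the raw RTI values
  below a threshold (default 0.006).
* **IZ** — initiation zone: a local RTI minimum strictly interior to the
  window (replication starts here and forks diverge outward).
* **TS** — termination site: a local RTI maximum strictly interior to the
  window (converging forks meet here).
* **TTR** — timing transition region: everything else, typically a monotone
  RTI slope between timing domains.

CTR runs are then subdivided by comparing the run's mean RTI with the mean
RTI of its flanking 500-kb windows: flanks replicating later than the run
mark an early plateau that seeds outward replication (**ICTR**); flanks
replicating earlier mark a late plateau where replication converges
(**TCTR**).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import BinGrid
from .profiles import RTProfile

__all__ = [
    "FeatureTrack",
    "classify_window",
    "classify_genome",
    "subdivide_ctr",
    "classify_features",
]

WINDOW_BINS = 10
VARIANCE_THRESHOLD = 0.006
PROMINENCE = 0.02
FLANK_BP = 500_000

LABEL_CTR = "CTR"
LABEL_IZ = "IZ"
LABEL_TS = "TS"
LABEL_TTR = "TTR"
LABEL_ICTR = "ICTR"
LABEL_TCTR = "TCTR"
LABEL_MASKED = "masked"


@dataclass
class FeatureTrack:
    """Per-bin replication-feature labels on a grid."""

    grid: BinGrid
    label: np.ndarray  # of {IZ, TS, ICTR, TCTR, TTR, CTR, masked}

    def __post_init__(self):
        label = np.asarray(self.label, dtype=object)
        if label.shape != (len(self.grid),):
            raise ValueError("one label per bin required")
        self.label = label

    def to_bed(self) -> pd.DataFrame:
        """One BED record per maximal same-label run (masked runs dropped)."""
        rows = []
        chroms, starts, ends = self.grid.chroms, self.grid.starts, self.grid.ends
        i = 0
        while i < len(self.label):
            j = i
            while (
                j + 1 < len(self.label)
                and self.label[j + 1] == self.label[i]
                and chroms[j + 1] == chroms[i]
            ):
                j += 1
            if self.label[i] != LABEL_MASKED:
                rows.append(
                    {"chrom": chroms[i], "start": starts[i], "end": ends[j], "name": self.label[i]}
                )
            i = j + 1
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def classify_window(
    rti_window: np.ndarray,
    variance_threshold: float = VARIANCE_THRESHOLD,
    prominence: float = PROMINENCE,
) -> str:
    """Classify one complete 10-bin RTI window as CTR, IZ, TS or TTR.

    Precedence: CTR (population variance of the raw values below the
    threshold) pre-empts the extremum tests, because a flat window trivially
    contains a numeric minimum.  IZ/TS require the extremum to sit strictly
    interior to the window and to be prominent — the profile must rise
    (resp. fall) by at least ``prominence`` RTI units on both sides.
    Any masked (NaN) value masks the window.
    """
    w = np.asarray(rti_window, dtype=float)
    if np.any(np.isnan(w)):
        return LABEL_MASKED
    if np.var(w) < variance_threshold:
        return LABEL_CTR
    n = len(w)
    imin = int(np.argmin(w))
    if 0 < imin < n - 1:
        left = w[:imin].max() - w[imin]
        right = w[imin + 1 :].max() - w[imin]
        if left >= prominence and right >= prominence:
            return LABEL_IZ
    imax = int(np.argmax(w))
    if 0 < imax < n - 1:
        left = w[imax] - w[:imax].min()
        right = w[imax] - w[imax + 1 :].min()
        if left >= prominence and right >= prominence:
            return LABEL_TS
    return LABEL_TTR


def classify_genome(
    rt: RTProfile,
    window_bins: int = WINDOW_BINS,
    variance_threshold: float = VARIANCE_THRESHOLD,
    prominence: float = PROMINENCE,
    center_offset: int | None = None,
) -> FeatureTrack:
    """Slide the window across each chromosome and label every bin.

    Each bin takes the label of the window centred on it; with the default
    even window (10 bins) the bin sits at position 5 of the window
    (``center_offset`` 4, 0-based).  Bins without a complete window —
    chromosome edges, and entire chromosomes shorter than the window — are
    masked.
    """
    if center_offset is None:
        center_offset = (window_bins - 1) // 2  # position 5 of 10, 1-based
    grid = rt.grid
    labels = np.full(len(grid), LABEL_MASKED, dtype=object)
    for chrom in grid.chromosomes:
        sl = grid.chrom_slice(chrom)
        vals = rt.rti[sl]
        n = len(vals)
        if n < window_bins:
            continue
        for start in range(0, n - window_bins + 1):
            w = vals[start : start + window_bins]
            labels[sl.start + start + center_offset] = classify_window(
                w, variance_threshold, prominence
            )
    return FeatureTrack(grid, labels)


def subdivide_ctr(
    track: FeatureTrack, rt: RTProfile, flank_bp: int = FLANK_BP
) -> FeatureTrack:
    """Split CTR runs into initiation (ICTR) and termination (TCTR) classes.

    For each maximal run of CTR-labelled bins, the run-mean RTI is compared
    with the mean RTI over the flanking windows (``flank_bp`` on each side,
    restricted to the same chromosome and to defined bins).  Later flanks
    (higher RTI) mean the plateau replicates first and seeds outward forks
    -> ICTR; earlier flanks mean forks converge onto the plateau -> TCTR.
    With one flank missing the other decides; with both missing (or an exact
    tie) the run is TCTR if its mean RTI > 0.5, else ICTR.
    """
    grid = track.grid
    flank_bins = max(1, int(round(flank_bp / grid.width)))
    labels = track.label.copy()
    for chrom in grid.chromosomes:
        sl = grid.chrom_slice(chrom)
        lab = labels[sl]
        vals = rt.rti[sl]
        n = len(lab)
        i = 0
        while i < n:
            if lab[i] != LABEL_CTR:
                i += 1
                continue
            j = i
            while j + 1 < n and lab[j + 1] == LABEL_CTR:
                j += 1
            run_mean = np.nanmean(vals[i : j + 1])
            flank_vals = []
            left = vals[max(0, i - flank_bins) : i]
            right = vals[j + 1 : j + 1 + flank_bins]
            for side in (left, right):
                side = side[~np.isnan(side)]
                if len(side):
                    flank_vals.append(side.mean())
            if flank_vals:
                flank_mean = float(np.mean(flank_vals))
                if flank_mean > run_mean:
                    new = LABEL_ICTR
                elif flank_mean < run_mean:
                    new = LABEL_TCTR
                else:
                    new = LABEL_TCTR if run_mean > 0.5 else LABEL_ICTR
            else:
                new = LABEL_TCTR if run_mean > 0.5 else LABEL_ICTR
            lab[i : j + 1] = new
            i = j + 1
        labels[sl] = lab
    return FeatureTrack(grid, labels)


def classify_features(rt: RTProfile, **kwargs) -> FeatureTrack:
    """Full classification: sliding-window labels plus the CTR subdivision."""
    flank_bp = kwargs.pop("flank_bp", FLANK_BP)
    track = classify_genome(rt, **kwargs)
    return subdivide_ctr(track, rt, flank_bp=flank_bp)
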