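"""Replication-fork metrics from dual-pulse DNA fiber assays.

Cells are pulse-labeled with IdU then CldU (30 min each), DNA fibers are
stretched and imaged, and each fiber is reduced to an ordered run of
labeled segments with pixel lengths.  Physical lengths convert to genomic
distance with the standard stretched-fiber factor of 2 kb per micrometre
(pixel size 142 nm by default, so 1 px = 0.284 kb).

Two read-outs:

* **fork speed** — CldU track length of an *ongoing* fork (an IdU segment
  directly continued by a CldU segment that runs out into unlabeled fiber
  or off the fiber end) divided by the pulse duration, in kb/min;
* **inter-origin distance** — an origin that fired during the first pulse
  leaves an IdU segment flanked by CldU on both sides (two forks diverging
  outward); the origin sits midway between the two IdU/CldU label
  boundaries, and distances between neighboring origins on the same fiber
  are collected.  A flag restores the literal every-boundary-pair reading.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import mannwhitneyu

__all__ = [
    "FiberTrack",
    "FiberStats",
    "track_length_kb",
    "fork_speed",
    "inter_origin_distances",
    "group_stats",
]

PIXEL_SIZE_NM = 142.0
LABEL_MINUTES = 30.0
KB_PER_UM = 2.0

IDU = "IdU"
CLDU = "CldU"
GAP = "gap"


@dataclass
class FiberTrack:
    """One stretched DNA fiber as an ordered run of labeled segments.

    ``segments`` is a list of (label, length_px) with label in
    {"IdU", "CldU", "gap"} and positive pixel lengths, ordered along the
    fiber.  Small gaps (``gap_tolerance_px``) between same-label segments
    are bridged before analysis to absorb annotation noise.
    """

    fiber_id: str
    segments: list[tuple[str, float]]
    pixel_size_nm: float = PIXEL_SIZE_NM
    label_minutes: float = LABEL_MINUTES
    kb_per_um: float = KB_PER_UM
    gap_tolerance_px: float = 3.0

    def __post_init__(self):
        for label, length in self.segments:
            if length <= 0:
                raise ValueError(f"segment lengths must be positive (got {length})")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")

    def px_to_kb(self, length_px: float) -> float:
        return track_length_kb(length_px, self.pixel_size_nm, self.kb_per_um)

    def cleaned(self) -> list[tuple[str, float]]:
        """Segments with tiny internal gaps bridged and same labels merged."""
        segs = [(lab, ln) for lab, ln in self.segments]
        # bridge gaps <= tolerance that sit between two segments of one label
        out: list[tuple[str, float]] = []
        i = 0
        while i < len(segs):
            lab, ln = segs[i]
            if (
                lab == GAP
                and ln <= self.gap_tolerance_px
                and out
                and i + 1 < len(segs)
                and out[-1][0] == segs[i + 1][0]
                and out[-1][0] != GAP
            ):
                out[-1] = (out[-1][0], out[-1][1] + ln + segs[i + 1][1])
                i += 2
                continue
            if out and out[-1][0] == lab:
                out[-1] = (lab, out[-1][1] + ln)
            else:
                out.append((lab, ln))
            i += 1
        return out


@dataclass
class FiberStats:
    """Per-group fork speeds and inter-origin distances with summaries."""

    fork_speeds: dict[str, np.ndarray]
    inter_origin_distances: dict[str, np.ndarray]
    summary: dict = field(default_factory=dict)


def track_length_kb(
    length_px: float, pixel_size_nm: float = PIXEL_SIZE_NM, kb_per_um: float = KB_PER_UM
) -> float:
    """Convert a pixel length to kb: px * nm/px / 1000 -> um, times kb/um."""
    if length_px < 0 or pixel_size_nm <= 0 or kb_per_um <= 0:
        raise ValueError("lengths and conversion factors must be positive")
    return length_px * pixel_size_nm / 1000.0 * kb_per_um


def fork_speed(track: FiberTrack) -> list[float]:
    """Speeds (kb/min) of the ongoing forks on one fiber.

    An ongoing fork is an IdU segment directly adjacent to a CldU segment
    whose far side is unlabeled (gap or fiber end): the fork was already
    running during the first pulse and progressed freely through the
    second.  CldU segments flanked by IdU on both sides (merged converging
    forks) or without an adjacent IdU segment (origins firing after the
    first pulse) contribute nothing.  Speed = CldU length / pulse duration.
    """
    segs = track.cleaned()
    labels = [lab for lab, _ in segs]
    speeds = []
    for i, (lab, ln) in enumerate(segs):
        if lab != CLDU:
            continue
        left = labels[i - 1] if i > 0 else None
        right = labels[i + 1] if i + 1 < len(segs) else None
        outward_right = left == IDU and right in (None, GAP)
        outward_left = right == IDU and left in (None, GAP)
        if outward_right or outward_left:
            speeds.append(track.px_to_kb(ln) / track.label_minutes)
    return speeds


def inter_origin_distances(track: FiberTrack, literal_boundaries: bool = False) -> list[float]:
    """Distances (kb) between neighboring replication origins on one fiber.

    Default rule: an origin is the centre of an IdU segment flanked by CldU
    on both sides — the signature of bidirectional forks that ran IdU-first
    from a single firing point.  ``literal_boundaries`` instead places an
    origin midway between every consecutive pair of label boundaries.
    Fibers with fewer than two origins return an empty list.
    """
    segs = track.cleaned()
    positions = np.concatenate([[0.0], np.cumsum([ln for _, ln in segs])])
    origins_px = []
    if literal_boundaries:
        boundaries = [
            positions[i]
            for i in range(1, len(segs))
            if segs[i - 1][0] != segs[i][0]
        ]
        origins_px = [
            (boundaries[i] + boundaries[i + 1]) / 2.0 for i in range(len(boundaries) - 1)
        ]
    else:
        for i, (lab, _) in enumerate(segs):
            if lab != IDU:
                continue
            left = segs[i - 1][0] if i > 0 else None
            right = segs[i + 1][0] if i + 1 < len(segs) else None
            if left == CLDU and right == CLDU:
                origins_px.append((positions[i] + positions[i + 1]) / 2.0)
    if len(origins_px) < 2:
        return []
    return [track.px_to_kb(b - a) for a, b in zip(origins_px, origins_px[1:])]


def group_stats(values_by_group: dict[str, np.ndarray]) -> dict:
    """Median, IQR and pairwise rank-sum tests for groups of measurements.

    Returns ``{"groups": {name: {n, median, q1, q3}}, "tests": {"A|B":
    p}}``; the two-sided Mann-Whitney rank-sum test compares each pair of
    groups.  Raises on an empty group.
    """
    summary: dict = {"groups": {}, "tests": {}}
    for name, vals in values_by_group.items():
        v = np.asarray(vals, dtype=float)
        if v.size == 0:
            raise ValueError(f"group {name!r} is empty")
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        summary["groups"][name] = {
            "n": int(v.size),
            "median": float(med),
            "q1": float(q1),
            "q3": float(q3),
        }
    names = list(values_by_group)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a = np.asarray(values_by_group[names[i]], dtype=float)
            b = np.asarray(values_by_group[names[j]], dtype=float)
            stat = mannwhitneyu(a, b, alternative="two-sided")
            summary["tests"][f"{names[i]}|{names[j]}"] = float(stat.pvalue)
    return summary
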