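"""Fixed-width genomic bin grids.

A :class:`BinGrid` is the shared coordinate frame for every replication-timing
computation in this package: per-fraction read densities, RTI profiles,
differential-timing calls and feature labels are all vectors indexed by its
bins.  Bins are 0-based, half-open, non-overlapping, sorted by (chromosome,
start) and of constant width except possibly the last bin of each chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_BIN_WIDTH = 50_000


@dataclass(frozen=True)
class BinGrid:
    """Fixed-width bins tiling a set of chromosomes.

    Parameters
    ----------
    chroms, starts, ends
        Parallel arrays describing each bin, sorted by (chromosome, start).
    width
        Nominal bin width in bp (default 50 kb).  The last bin of a
        chromosome may be shorter.
    """

    chroms: np.ndarray
    starts: np.ndarray
    ends: np.ndarray
    width: int = DEFAULT_BIN_WIDTH
    _chrom_index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        chroms = np.asarray(self.chroms, dtype=object)
        starts = np.asarray(self.starts, dtype=np.int64)
        ends = np.asarray(self.ends, dtype=np.int64)
        if not (len(chroms) == len(starts) == len(ends)):
            raise ValueError("chroms, starts, ends must have equal length")
        if np.any(ends <= starts):
            raise ValueError("bins must have positive width")
        object.__setattr__(self, "chroms", chroms)
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "ends", ends)
        # slice per chromosome; bins of one chromosome must be contiguous
        index: dict[str, slice] = {}
        i = 0
        while i < len(chroms):
            j = i
            while j < len(chroms) and chroms[j] == chroms[i]:
                j += 1
            name = chroms[i]
            if name in index:
                raise ValueError(f"bins of chromosome {name} are not contiguous")
            if np.any(np.diff(starts[i:j]) <= 0):
                raise ValueError(f"bins of chromosome {name} are not sorted")
            if np.any(starts[i + 1 : j] < ends[i : j - 1]):
                raise ValueError(f"bins of chromosome {name} overlap")
            index[name] = slice(i, j)
            i = j
        object.__setattr__(self, "_chrom_index", index)

    @classmethod
    def from_chrom_sizes(cls, sizes: dict[str, int], width: int = DEFAULT_BIN_WIDTH) -> "BinGrid":
        """Tile whole chromosomes with ``width``-bp bins (last bin truncated)."""
        chroms, starts, ends = [], [], []
        for name, size in sizes.items():
            edges = np.arange(0, size, width, dtype=np.int64)
            chroms.extend([name] * len(edges))
            starts.extend(edges)
            ends.extend(np.minimum(edges + width, size))
        return cls(np.array(chroms, dtype=object), np.array(starts), np.array(ends), width)

    @property
    def n_bins(self) -> int:
        return len(self.starts)

    def __len__(self) -> int:
        return self.n_bins

    @property
    def chromosomes(self) -> list[str]:
        return list(self._chrom_index)

    @property
    def widths(self) -> np.ndarray:
        return self.ends - self.starts

    @property
    def genome_size(self) -> int:
        """Total bp covered by the analyzed bins (sum of bin widths)."""
        return int(self.widths.sum())

    @property
    def midpoints(self) -> np.ndarray:
        return (self.starts + self.ends) / 2.0

    def chrom_slice(self, chrom: str) -> slice:
        """Index slice of the bins belonging to one chromosome."""
        return self._chrom_index[chrom]

    def bin_of(self, chrom: str, pos: int) -> int | None:
        """Global bin index containing position ``pos`` (or None if outside)."""
        sl = self._chrom_index.get(chrom)
        if sl is None:
            return None
        starts = self.starts[sl]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i < 0 or pos >= self.ends[sl][i]:
            return None
        return sl.start + i

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"chrom": self.chroms, "start": self.starts, "end": self.ends})

    def same_grid(self, other: "BinGrid") -> bool:
        return (
            len(self) == len(other)
            and bool(np.all(self.chroms == other.chroms))
            and bool(np.all(self.starts == other.starts))
            and bool(np.all(self.ends == other.ends))
        )
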