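"""Reading and writing the plain-text genomic formats the pipeline uses.

All coordinates are 0-based half-open (bedGraph/BED convention).  Count
input is either one bedGraph per fraction or a single bin x sample TSV
with a sample sheet (sample, cell_line, subgroup, replicate, fraction).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import BinGrid
from .profiles import FractionProfile, RTProfile

__all__ = [
    "read_bedgraph",
    "write_bedgraph",
    "read_count_matrix",
    "write_profile_tsv",
    "write_rti_bedgraph",
    "read_fiber_tracks",
    "write_fiber_tracks",
    "write_json",
]

BEDGRAPH_COLS = ["chrom", "start", "end", "value"]


def read_bedgraph(path) -> pd.DataFrame:
    """Read a 4-column bedGraph (no header, track lines skipped)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=BEDGRAPH_COLS, dtype={0: str},
    )
    df = df[~df["chrom"].astype(str).str.startswith("track")]
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    df["value"] = df["value"].astype(float)
    return df.reset_index(drop=True)


def write_bedgraph(df: pd.DataFrame, path) -> None:
    df[BEDGRAPH_COLS].to_csv(path, sep="\t", header=False, index=False)


def grid_from_bedgraph(df: pd.DataFrame, width: int | None = None) -> BinGrid:
    """Build a BinGrid from the intervals of a bedGraph frame."""
    if width is None:
        width = int((df["end"] - df["start"]).mode().iloc[0])
    return BinGrid(
        df["chrom"].to_numpy(dtype=object),
        df["start"].to_numpy(),
        df["end"].to_numpy(),
        width,
    )


def read_count_matrix(counts_path, samples_path) -> list[FractionProfile]:
    """Read a bin x sample count TSV plus its sample sheet into raw profiles.

    The count table has columns chrom, start, end then one column per
    sample; the sample sheet maps sample -> (cell_line, subgroup,
    replicate, fraction).  Counts are divided by bin width to densities.
    One profile is returned per (cell_line, replicate), with fraction
    columns ordered S1..S4.
    """
    counts = pd.read_csv(counts_path, sep="\t")
    sheet = pd.read_csv(samples_path, sep="\t")
    grid = BinGrid(
        counts["chrom"].to_numpy(dtype=object),
        counts["start"].to_numpy(np.int64),
        counts["end"].to_numpy(np.int64),
    )
    widths = grid.widths.astype(float)
    profiles = []
    for (line, rep), grp in sheet.groupby(["cell_line", "replicate"]):
        grp = grp.sort_values("fraction")
        D = np.column_stack(
            [counts[s].to_numpy(float) / widths for s in grp["sample"]]
        )
        profiles.append(
            FractionProfile(
                grid, D,
                cell_line=str(line),
                subgroup=str(grp["subgroup"].iloc[0]),
                replicate_id=str(rep),
                stage="raw",
            )
        )
    return profiles


def write_profile_tsv(profile: FractionProfile, path) -> None:
    df = profile.grid.to_frame()
    for k in range(profile.n_fractions):
        df[f"S{k + 1}"] = profile.D[:, k]
    df.to_csv(path, sep="\t", index=False)


def write_rti_bedgraph(rt: RTProfile, path) -> None:
    """RTI per bin as bedGraph; masked bins are omitted."""
    ok = ~np.isnan(rt.rti)
    df = pd.DataFrame(
        {
            "chrom": rt.grid.chroms[ok],
            "start": rt.grid.starts[ok],
            "end": rt.grid.ends[ok],
            "value": rt.rti[ok],
        }
    )
    write_bedgraph(df, path)


def read_fiber_tracks(path, **track_kwargs) -> list:
    """Read a fiber segment TSV (fiber_id, order, label, length_px).

    Metadata may ride in ``# key=value`` header lines (pixel_size_nm,
    label_min, kb_per_um); explicit keyword arguments win.
    """
    from .fibers import FiberTrack

    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            for part in line[1:].strip().split():
                if "=" in part:
                    k, v = part.split("=", 1)
                    meta[k] = float(v)
    kwargs = {}
    if "pixel_size_nm" in meta:
        kwargs["pixel_size_nm"] = meta["pixel_size_nm"]
    if "label_min" in meta:
        kwargs["label_minutes"] = meta["label_min"]
    if "kb_per_um" in meta:
        kwargs["kb_per_um"] = meta["kb_per_um"]
    kwargs.update(track_kwargs)

    df = pd.read_csv(path, sep="\t", comment="#")
    tracks = []
    for fid, grp in df.groupby("fiber_id", sort=False):
        grp = grp.sort_values("order")
        segs = list(zip(grp["label"], grp["length_px"].astype(float)))
        tracks.append(FiberTrack(fiber_id=str(fid), segments=segs, **kwargs))
    return tracks


def write_fiber_tracks(tracks, path) -> None:
    rows = []
    for t in tracks:
        for i, (lab, ln) in enumerate(t.segments):
            rows.append(
                {"fiber_id": t.fiber_id, "order": i, "label": lab, "length_px": ln}
            )
    first = tracks[0]
    with open(path, "w") as fh:
        fh.write(
            f"# pixel_size_nm={first.pixel_size_nm} label_min={first.label_minutes} "
            f"kb_per_um={first.kb_per_um}\n"
        )
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable) + "\n")


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")
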