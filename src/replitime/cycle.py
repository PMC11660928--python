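"""Integration of replication timing with cell-cycle-phase-resolved expression.

Cells sorted into four cell-cycle gates (G1, early S, late S, G2/M) yield a
phase-resolved expression table per cell line and, per contrast, per-phase
differential-expression (DE) tables.  This module

* partitions DE genes by the phases in which they are called (unique G1 /
  S / G2, shared among 2-3 phases, shared by all), pooling the two S gates;
* builds the region x phase matrix of mean log2 fold changes over genes
  overlapping each differentially replicating bin, to relate timing shifts
  to expression shifts;
* computes per-gene log2 expression ratios between consecutive phases
  (G1->ES, ES->LS, LS->G2, G2->G1) and clusters genes on those ratios
  (Ward linkage), the standard view of cell-cycle-regulated transcription.

A gene is flagged DE when |log2FC| > 1 and FDR < 0.05.
"""

from __future__ import annotations

import warnings
from importlib import resources

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage

from .diffrt import CALL_EARLIER, CALL_LATER, DiffRTResult

__all__ = [
    "PHASES",
    "TRANSITIONS",
    "de_flag",
    "phase_partition",
    "rt_expression_matrix",
    "phase_ratio_matrix",
    "cluster_ratio_genes",
    "cluster_phase_profiles",
    "load_dna_replication_genes",
]

PHASES = ("G1", "ES", "LS", "G2M")
TRANSITIONS = (("G1", "ES"), ("ES", "LS"), ("LS", "G2M"), ("G2M", "G1"))
LOG2FC_CUTOFF = 1.0  # > twofold
FDR_CUTOFF = 0.05


def de_flag(de: pd.DataFrame) -> pd.Series:
    """Differential-expression flag: |log2FC| > 1 and FDR < 0.05."""
    return (de["log2fc"].abs() > LOG2FC_CUTOFF) & (de["fdr"] < FDR_CUTOFF)


def phase_partition(de: pd.DataFrame) -> dict[str, int]:
    """Partition DE genes of one contrast by cell-cycle phase membership.

    ``de`` has columns (gene, phase, log2fc, fdr) with phase in
    {G1, ES, LS, G2M}.  ES and LS pool into a single "S" slice.  Every DE
    gene lands in exactly one slice: unique_G1 / unique_S / unique_G2,
    shared_2_3 (DE in two or three of the pooled phases) or shared_all.
    """
    de = de.copy()
    de["flag"] = de_flag(de)
    pooled = {"G1": "G1", "ES": "S", "LS": "S", "G2M": "G2"}
    de["pooled"] = de["phase"].map(pooled)
    counts = {"unique_G1": 0, "unique_S": 0, "unique_G2": 0, "shared_2_3": 0, "shared_all": 0}
    flagged = de[de["flag"]]
    if flagged.empty:
        warnings.warn("no differentially expressed genes: empty partition")
        return counts
    for gene, grp in flagged.groupby("gene"):
        phases = set(grp["pooled"])
        if phases == {"G1", "S", "G2"}:
            counts["shared_all"] += 1
        elif len(phases) == 1:
            counts[f"unique_{phases.pop()}"] += 1
        else:
            counts["shared_2_3"] += 1
    return counts


def partition_percentages(counts: dict[str, int]) -> dict[str, float]:
    total = sum(counts.values())
    if total == 0:
        return {k: 0.0 for k in counts}
    return {k: 100.0 * v / total for k, v in counts.items()}


def _gene_bins(genes: pd.DataFrame, result: DiffRTResult) -> dict[str, list[int]]:
    """Map gene id -> list of grid bin indices its body overlaps (any bp)."""
    grid = result.grid
    out: dict[str, list[int]] = {}
    for rec in genes.itertuples(index=False):
        sl = grid._chrom_index.get(rec.chrom)
        if sl is None:
            continue
        starts = grid.starts[sl]
        ends = grid.ends[sl]
        lo = int(np.searchsorted(ends, rec.start, side="right"))
        hi = int(np.searchsorted(starts, rec.end, side="left"))
        if hi > lo:
            out.setdefault(rec.gene, []).extend(range(sl.start + lo, sl.start + hi))
    return out


def rt_expression_matrix(
    diff: DiffRTResult, de: pd.DataFrame, genes: pd.DataFrame
) -> pd.DataFrame:
    """Region x phase matrix of mean log2FC over genes in each differential bin.

    ``genes`` is a BED-like frame (chrom, start, end, gene); a gene belongs
    to every differential bin its body overlaps by at least one bp.  Rows
    are differential bins containing at least one tested gene; each cell is
    the mean log2FC of those genes in that phase; the bin's delta-RTI
    direction and magnitude ride along for sorting (rows ordered by region
    RTI change, descending).
    """
    if genes.empty:
        raise ValueError("no annotated genes supplied")
    gene2bins = _gene_bins(genes, diff)
    bin2genes: dict[int, set[str]] = {}
    diff_sel = (diff.call == CALL_EARLIER) | (diff.call == CALL_LATER)
    for gene, bins in gene2bins.items():
        for b in bins:
            if diff_sel[b]:
                bin2genes.setdefault(b, set()).add(gene)

    fc = de.pivot_table(index="gene", columns="phase", values="log2fc", aggfunc="mean")
    rows = []
    for b, gset in sorted(bin2genes.items()):
        present = [g for g in gset if g in fc.index]
        if not present:
            continue
        row = {
            "chrom": diff.grid.chroms[b],
            "start": int(diff.grid.starts[b]),
            "end": int(diff.grid.ends[b]),
            "delta": float(diff.delta[b]),
            "call": diff.call[b],
            "n_genes": len(present),
        }
        for phase in PHASES:
            row[phase] = float(fc.loc[present, phase].mean()) if phase in fc else np.nan
        rows.append(row)
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    return out.sort_values("delta", ascending=False).reset_index(drop=True)


def phase_ratio_matrix(
    expr: pd.DataFrame, gene_list: list[str] | None = None, pseudocount: float = 1.0
) -> tuple[pd.DataFrame, list[str]]:
    """Per-gene log2 ratios of expression between consecutive phases.

    ``expr`` is long-form (gene, cell_line, subgroup, phase, fpkm).  For
    each gene, cell line and transition p->q the ratio
    log2((fpkm_q + c)/(fpkm_p + c)) is computed, then averaged over the
    cell lines of a subgroup.  Columns are "subgroup:p->q".  Genes with zero
    expression in every phase of every cell line are dropped; genes from
    ``gene_list`` absent from the table are recorded, not fatal.

    Returns (matrix, dropped_genes).
    """
    df = expr.copy()
    dropped: list[str] = []
    if gene_list is not None:
        present = set(df["gene"])
        dropped.extend(g for g in gene_list if g not in present)
        df = df[df["gene"].isin(gene_list)]

    totals = df.groupby("gene")["fpkm"].sum()
    silent = totals[totals == 0].index.tolist()
    dropped.extend(silent)
    df = df[~df["gene"].isin(silent)]

    wide = df.pivot_table(
        index=["gene", "subgroup", "cell_line"], columns="phase", values="fpkm"
    )
    missing = [p for p in PHASES if p not in wide.columns]
    if missing:
        raise ValueError(f"expression table lacks phases: {missing}")
    cols = {}
    for p, q in TRANSITIONS:
        cols[f"{p}->{q}"] = np.log2((wide[q] + pseudocount) / (wide[p] + pseudocount))
    ratios = pd.DataFrame(cols)
    by_subgroup = ratios.groupby(level=["gene", "subgroup"]).mean()
    mat = by_subgroup.unstack("subgroup")
    mat.columns = [f"{sub}:{trans}" for trans, sub in mat.columns]
    mat = mat.sort_index(axis=1)
    return mat, dropped


def cluster_ratio_genes(ratios: pd.DataFrame, k: int = 6) -> pd.Series:
    """Hierarchically cluster genes on their phase-ratio profiles.

    Agglomerative clustering with Ward linkage on Euclidean distances of
    the log2 ratio rows, cut into ``k`` flat clusters.  Cluster ids are
    renumbered 1..k in dendrogram leaf order so the labelling is stable
    under row permutations.
    """
    if k > len(ratios):
        raise ValueError(f"k={k} exceeds the {len(ratios)} genes available")
    X = ratios.to_numpy(dtype=float)
    order = np.argsort(np.asarray(ratios.index, dtype=object))
    Z = linkage(X[order], method="ward", metric="euclidean")
    flat = fcluster(Z, t=k, criterion="maxclust")
    leaf_order = leaves_list(Z)
    seen: dict[int, int] = {}
    for leaf in leaf_order:
        c = flat[leaf]
        if c not in seen:
            seen[c] = len(seen) + 1
    renamed = np.array([seen[c] for c in flat])
    labels = pd.Series(index=ratios.index[order], data=renamed, name="cluster")
    return labels.loc[ratios.index]


def cluster_phase_profiles(expr: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Mean expression per cluster, phase and subgroup.

    Arithmetic mean of FPKM over the genes of a cluster and the cell lines
    of a subgroup, per phase — the summary profile of when in the cycle a
    cluster's genes are expressed.  Empty clusters are omitted with a
    warning.
    """
    df = expr.merge(labels.rename("cluster"), left_on="gene", right_index=True)
    empty = set(labels.unique()) - set(df["cluster"].unique())
    if empty:
        warnings.warn(f"clusters without expression data omitted: {sorted(empty)}")
    prof = (
        df.groupby(["cluster", "subgroup", "phase"])["fpkm"].mean().unstack("phase")
    )
    return prof[[p for p in PHASES if p in prof.columns]]


def load_dna_replication_genes() -> list[str]:
    """The bundled DNA-replication gene panel (39 genes).

    A synthetic stand-in panel: 39 canonical human DNA-replication genes
    (origin licensing, helicase, polymerases, clamp/clamp-loader, ssDNA
    binding, fork accessories) assembled to play the role of a curated
    replication-pathway list in examples and tests.  Any gene list can be
    passed to :func:`phase_ratio_matrix` instead.
    """
    text = (
        resources.files("replitime.data")
        .joinpath("dna_replication_genes.synthetic.txt")
        .read_text()
    )
    return [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
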