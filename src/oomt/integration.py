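"""Linking methylation and expression per cell.

Gene-body methylation is quantified per (gene, cell) with a minimum-call
threshold; expression-methylation coupling is the per-gene Pearson
correlation between a gene's expression and its own gene-body methylation
across cells; DMRs are intersected with gene bodies; and concordance is
summarised as the cross-gene correlation between expression log2 fold change
and merged methylation difference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .methylome import quantify_regions

__all__ = [
    "CouplingResult",
    "gene_body_methylation",
    "expr_meth_correlation",
    "couple_genes",
    "overlap_dmrs_with_genes",
    "foldchange_vs_methdiff",
    "cpg_vs_noncpg_correlation",
]


@dataclass
class CouplingResult:
    gene: str
    n_cells: int
    pearson_r: float
    p: float
    meth_diff_pp: float = float("nan")   # aged - young, group-merged
    log2_fc: float = float("nan")
    flagged: Optional[str] = None        # "too_few_cells" / "constant"


def gene_body_methylation(
    cells: Mapping[str, pd.DataFrame],
    gene_intervals: pd.DataFrame,
    context: str = "CpG",
    min_calls: int = 5,
) -> pd.DataFrame:
    """Genes x cells percent-methylation matrix over gene bodies.

    Entries backed by fewer than ``min_calls`` calls are NaN (missing, never
    0%).
    """
    cols = {}
    for cell_id, calls in cells.items():
        q = quantify_regions(calls, gene_intervals, context=context, warn_unmatched=False)
        pct = np.where(q["total"].to_numpy() >= min_calls, q["pct"].to_numpy(), np.nan)
        cols[cell_id] = pct
    return pd.DataFrame(cols, index=gene_intervals["name"].to_numpy())


def expr_meth_correlation(
    expr_row: pd.Series,
    meth_row: pd.Series,
    min_cells: int = 10,
    gene: str = "",
) -> CouplingResult:
    """Pearson correlation between one gene's expression and its gene-body
    methylation across cells (pairs with a missing value dropped).

    The p-value is the two-sided t-based test on the co-observed cells; a
    constant vector makes r undefined and the result is flagged, as is a
    pairing with fewer than ``min_cells`` co-observed cells.
    """
    joined = pd.concat([expr_row, meth_row], axis=1, join="inner").dropna()
    n = len(joined)
    if n < min_cells:
        return CouplingResult(gene, n, float("nan"), float("nan"), flagged="too_few_cells")
    x = joined.iloc[:, 0].to_numpy(dtype=float)
    y = joined.iloc[:, 1].to_numpy(dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        return CouplingResult(gene, n, float("nan"), float("nan"), flagged="constant")
    r, p = stats.pearsonr(x, y)
    return CouplingResult(gene, n, float(r), float(p))


def couple_genes(
    log_expr: pd.DataFrame,
    meth: pd.DataFrame,
    groups: Optional[pd.Series] = None,
    merged_meth_diff: Optional[pd.Series] = None,
    log2_fc: Optional[pd.Series] = None,
    min_cells: int = 10,
) -> list[CouplingResult]:
    """Per-gene coupling over the genes shared by both matrices, attaching
    fold changes and merged methylation differences when supplied."""
    results = []
    for gene in meth.index:
        if gene not in log_expr.index:
            continue
        res = expr_meth_correlation(
            log_expr.loc[gene], meth.loc[gene], min_cells=min_cells, gene=gene
        )
        if merged_meth_diff is not None and gene in merged_meth_diff.index:
            res.meth_diff_pp = float(merged_meth_diff.loc[gene])
        if log2_fc is not None and gene in log2_fc.index:
            res.log2_fc = float(log2_fc.loc[gene])
        results.append(res)
    return results


def overlap_dmrs_with_genes(
    dmrs: pd.DataFrame, gene_intervals: pd.DataFrame
) -> pd.DataFrame:
    """All (DMR, gene) pairs whose half-open intervals share >= 1 bp.

    Returns columns (dmr, gene, overlap_bp); ``attrs["n_genes"]`` carries the
    unique overlapped gene count.
    """
    rows = []
    for chrom, d_idx in dmrs.groupby("chrom", sort=False).groups.items():
        g = gene_intervals[gene_intervals["chrom"] == chrom]
        if not len(g):
            continue
        gs = g["start"].to_numpy()
        ge = g["end"].to_numpy()
        gnames = g["name"].to_numpy()
        order = np.argsort(gs, kind="mergesort")
        gs, ge, gnames = gs[order], ge[order], gnames[order]
        for _, dmr in dmrs.loc[d_idx].iterrows():
            hit = (gs < dmr["end"]) & (ge > dmr["start"])
            for s, e, name in zip(gs[hit], ge[hit], gnames[hit]):
                rows.append(
                    (dmr["name"], name, int(min(e, dmr["end"]) - max(s, dmr["start"])))
                )
    out = pd.DataFrame(rows, columns=["dmr", "gene", "overlap_bp"])
    out.attrs["n_genes"] = out["gene"].nunique()
    return out


def foldchange_vs_methdiff(coupling: Sequence[CouplingResult]) -> dict:
    """Cross-gene Pearson correlation between expression log2 fold change and
    merged methylation difference (aged − young).  Needs >= 3 genes with both
    quantities; otherwise skipped (r = NaN)."""
    rows = [
        (c.gene, c.log2_fc, c.meth_diff_pp)
        for c in coupling
        if np.isfinite(c.log2_fc) and np.isfinite(c.meth_diff_pp)
    ]
    table = pd.DataFrame(rows, columns=["gene", "log2_fc", "meth_diff_pp"])
    if len(table) < 3:
        return {"r": float("nan"), "p": float("nan"), "table": table, "skipped": True}
    r, p = stats.pearsonr(table["log2_fc"], table["meth_diff_pp"])
    return {"r": float(r), "p": float(p), "table": table, "skipped": False}


def cpg_vs_noncpg_correlation(
    cells: Mapping[str, pd.DataFrame],
    gene_intervals: pd.DataFrame,
    min_calls: int = 5,
    min_cells: int = 10,
    noncpg_contexts: tuple[str, ...] = ("CHH", "CHG"),
) -> pd.DataFrame:
    """Per-gene Pearson r between per-cell CpG and non-CpG gene-body percent.

    Genes with too few co-observed cells or a constant context are flagged
    (r NaN, ``flag`` column).
    """
    cpg = gene_body_methylation(cells, gene_intervals, context="CpG", min_calls=min_calls)
    names = gene_intervals["name"].to_numpy()
    nc_cols = {}
    for cell_id, calls in cells.items():
        m = np.zeros(len(names))
        t = np.zeros(len(names))
        for ctx in noncpg_contexts:
            q = quantify_regions(calls, gene_intervals, context=ctx, warn_unmatched=False)
            m += q["meth"].to_numpy()
            t += q["total"].to_numpy()
        nc_cols[cell_id] = np.where(t >= max(min_calls, 1), 100.0 * m / np.maximum(t, 1), np.nan)
    nc_pct = pd.DataFrame(nc_cols, index=names)
    rows = []
    for gene in gene_intervals["name"]:
        res = expr_meth_correlation(
            nc_pct.loc[gene], cpg.loc[gene], min_cells=min_cells, gene=gene
        )
        rows.append((gene, res.n_cells, res.pearson_r, res.p, res.flagged))
    return pd.DataFrame(rows, columns=["gene", "n_cells", "r", "p", "flag"])
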