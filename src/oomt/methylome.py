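"""Single-cell methylome handling: coverage-file IO, QC filtering, quantification.

Coordinate conventions (centralised here, used by every module):

* coverage files and ``CpGCallTable`` positions are 1-based inclusive
  (Bismark coverage dialect);
* all genomic intervals (``DomainSet``, BED files) are 0-based half-open;
* a 1-based call at position ``p`` falls in interval ``[start, end)``
  iff ``p - 1`` is in ``[start, end)``, i.e. ``start < p <= end``.

A ``CpGCallTable`` is a :class:`pandas.DataFrame` with columns
``chrom`` (str), ``pos`` (int, 1-based), ``context`` ({"CpG","CHG","CHH"}),
``meth`` (int), ``unmeth`` (int).  A ``DomainSet`` is a DataFrame with columns
``chrom``, ``start``, ``end``, ``class_label``, ``name``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

CONTEXTS = ("CpG", "CHG", "CHH")

CALL_COLUMNS = ["chrom", "pos", "context", "meth", "unmeth"]
DOMAIN_COLUMNS = ["chrom", "start", "end", "class_label", "name"]

#: rounding slack when checking the percent column of a coverage file against
#: its count columns (Bismark prints ~6 decimals; we accept anything within
#: half a percentage point to tolerate hand-rounded fixtures).
PCT_ROUNDING_TOL = 0.5


class CoverageParseError(ValueError):
    """A malformed line in a Bismark-style coverage file."""


class UndefinedValueError(ValueError):
    """Requested quantity is undefined (e.g. methylation level with 0 calls)."""


def pos_to_offset(pos: np.ndarray | int) -> np.ndarray | int:
    """Convert 1-based call positions to 0-based offsets for interval lookup."""
    return np.asarray(pos) - 1 if not np.isscalar(pos) else pos - 1


def empty_call_table() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=str),
            "pos": pd.Series(dtype=np.int64),
            "context": pd.Series(dtype=str),
            "meth": pd.Series(dtype=np.int64),
            "unmeth": pd.Series(dtype=np.int64),
        }
    )


def make_call_table(chrom, pos, meth, unmeth, context="CpG") -> pd.DataFrame:
    """Assemble a CpGCallTable from column arrays (broadcasting scalars)."""
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.asarray(pos, dtype=np.int64),
            "context": context,
            "meth": np.asarray(meth, dtype=np.int64),
            "unmeth": np.asarray(unmeth, dtype=np.int64),
        }
    )
    return df[CALL_COLUMNS]


# ---------------------------------------------------------------------------
# IO: Bismark coverage dialect, BED, samplesheet
# ---------------------------------------------------------------------------

def read_coverage_file(path, context: str = "CpG") -> pd.DataFrame:
    """Read a Bismark-style coverage file into a CpGCallTable.

    Expected format: six tab-separated columns per line —
    ``chrom  start(1-based)  end  pct_methylated  count_methylated
    count_unmethylated``.  The percent column is validated against the counts;
    a discrepancy beyond rounding raises :class:`CoverageParseError` citing
    the offending line number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if context not in CONTEXTS:
        raise ValueError(f"unknown context {context!r}; expected one of {CONTEXTS}")
    chroms, poss, meths, unmeths = [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise CoverageParseError(
                    f"{path}:{lineno}: expected 6 tab-separated fields, got {len(parts)}"
                )
            chrom, start, _end, pct, m, u = parts
            try:
                pos = int(start)
                pct = float(pct)
                m = int(m)
                u = int(u)
            except ValueError as exc:
                raise CoverageParseError(f"{path}:{lineno}: non-numeric field ({exc})") from exc
            total = m + u
            if total < 1 or m < 0 or u < 0:
                raise CoverageParseError(
                    f"{path}:{lineno}: counts must be non-negative with total >= 1"
                )
            expected = 100.0 * m / total
            if abs(pct - expected) > PCT_ROUNDING_TOL:
                raise CoverageParseError(
                    f"{path}:{lineno}: percent column {pct} inconsistent with counts "
                    f"{m}/{total} (= {expected:.4f})"
                )
            chroms.append(chrom)
            poss.append(pos)
            meths.append(m)
            unmeths.append(u)
    if not poss:
        return empty_call_table()
    return make_call_table(chroms, poss, meths, unmeths, context=context)


def write_coverage_file(calls: pd.DataFrame, path, context: Optional[str] = None) -> None:
    """Write a CpGCallTable (optionally one context) in coverage format."""
    df = calls if context is None else calls[calls["context"] == context]
    total = df["meth"].to_numpy() + df["unmeth"].to_numpy()
    pct = np.where(total > 0, 100.0 * df["meth"].to_numpy() / np.maximum(total, 1), 0.0)
    out = pd.DataFrame(
        {
            "chrom": df["chrom"].to_numpy(),
            "start": df["pos"].to_numpy(),
            "end": df["pos"].to_numpy(),
            "pct": np.round(pct, 6),
            "meth": df["meth"].to_numpy(),
            "unmeth": df["unmeth"].to_numpy(),
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path, class_label: Optional[str] = None) -> pd.DataFrame:
    """Read BED3+ intervals into a DomainSet DataFrame.

    Column 4, if present, is the name; column 5 (or ``class_label``) the class.
    """
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            name = parts[3] if len(parts) > 3 else f"region_{i}"
            label = class_label if class_label is not None else (
                parts[4] if len(parts) > 4 else "region"
            )
            rows.append((parts[0], int(parts[1]), int(parts[2]), label, name))
    df = pd.DataFrame(rows, columns=DOMAIN_COLUMNS)
    bad = df["start"] >= df["end"]
    if bad.any():
        raise ValueError(f"{path}: {int(bad.sum())} intervals with start >= end")
    return df


def write_bed(domains: pd.DataFrame, path) -> None:
    domains[["chrom", "start", "end", "name", "class_label"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_samplesheet(path) -> pd.DataFrame:
    """Tab-separated samplesheet: cell_id, path, age_group[, mapping_efficiency]."""
    df = pd.read_csv(path, sep="\t")
    required = {"cell_id", "path", "age_group"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"samplesheet missing columns: {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# Cells and QC
# ---------------------------------------------------------------------------

@dataclass
class CellQC:
    cell_id: str
    n_cpgs: int
    global_cpg_pct: float
    global_noncpg_pct: float = float("nan")
    x_cgi_pct: float = float("nan")
    mapping_efficiency_pct: Optional[float] = None


@dataclass
class CellMethylome:
    """One cell's methylation calls plus QC metadata.

    ``mapping_efficiency_pct`` is upstream alignment metadata (from the
    samplesheet); the remaining QC metrics derive from the calls themselves.
    """

    cell_id: str
    calls: pd.DataFrame
    mapping_efficiency_pct: Optional[float] = None
    qc: Optional[CellQC] = None

    def compute_qc(self, x_cgi: Optional[pd.DataFrame] = None) -> CellQC:
        cpg = self.calls[self.calls["context"] == "CpG"]
        noncpg = self.calls[self.calls["context"] != "CpG"]
        x_pct = float("nan")
        if x_cgi is not None and len(x_cgi):
            q = quantify_regions(cpg, x_cgi, context="CpG", warn_unmatched=False)
            tot = q["total"].sum()
            x_pct = 100.0 * q["meth"].sum() / tot if tot > 0 else float("nan")
        self.qc = CellQC(
            cell_id=self.cell_id,
            n_cpgs=int(len(cpg)),
            global_cpg_pct=global_methylation(cpg, "CpG") if len(cpg) else float("nan"),
            global_noncpg_pct=(
                100.0 * noncpg["meth"].sum() / (noncpg["meth"].sum() + noncpg["unmeth"].sum())
                if len(noncpg)
                else float("nan")
            ),
            x_cgi_pct=x_pct,
            mapping_efficiency_pct=self.mapping_efficiency_pct,
        )
        return self.qc


@dataclass
class QCThresholds:
    """Discard rules for scBS-seq libraries.

    Defaults: mapping efficiency < 10%, fewer than 500,000 CpGs covered, or
    global CpG methylation > 50% discard a library; X-chromosome CpG-island
    methylation >= 10% flags somatic (granulosa) contamination — oocyte
    libraries sit below 10% while contaminating somatic cells exceed 20%,
    so the gap makes 10% a safe cut.
    """

    min_mapping_efficiency: Optional[float] = 10.0
    min_cpgs: Optional[int] = 500_000
    max_global_cpg: Optional[float] = 50.0
    max_x_cgi: Optional[float] = 10.0


@dataclass
class QCResult:
    kept: list
    discarded: list  # list of (CellMethylome, [reason, ...])


def qc_filter(
    cells: Sequence[CellMethylome],
    thresholds: Optional[QCThresholds] = None,
    x_cgi: Optional[pd.DataFrame] = None,
) -> QCResult:
    """Partition cells into kept / discarded, each discard carrying every
    violated rule.

    QC metrics are computed from the calls unless already attached to the
    cell.  The mapping-efficiency rule is applied only when the metadata is
    present; the X-CGI rule requires either precomputed ``x_cgi_pct`` or the
    X-CGI interval set.
    """
    thresholds = thresholds or QCThresholds()
    kept, discarded = [], []
    for cell in cells:
        qc = cell.qc
        if qc is None:
            if thresholds.max_x_cgi is not None and x_cgi is None:
                raise ValueError(
                    "X-CGI contamination check enabled but no X-CGI intervals supplied"
                )
            qc = cell.compute_qc(x_cgi=x_cgi)
        reasons = []
        if (
            thresholds.min_mapping_efficiency is not None
            and qc.mapping_efficiency_pct is not None
            and qc.mapping_efficiency_pct < thresholds.min_mapping_efficiency
        ):
            reasons.append("min_mapping_efficiency")
        if thresholds.min_cpgs is not None and qc.n_cpgs < thresholds.min_cpgs:
            reasons.append("min_cpgs")
        if (
            thresholds.max_global_cpg is not None
            and np.isfinite(qc.global_cpg_pct)
            and qc.global_cpg_pct > thresholds.max_global_cpg
        ):
            reasons.append("max_global_meth")
        if thresholds.max_x_cgi is not None and np.isfinite(qc.x_cgi_pct):
            if qc.x_cgi_pct >= thresholds.max_x_cgi:
                reasons.append("x_cgi_contamination")
        if reasons:
            discarded.append((cell, reasons))
        else:
            kept.append(cell)
    return QCResult(kept=kept, discarded=discarded)


# ---------------------------------------------------------------------------
# Quantification
# ---------------------------------------------------------------------------

def global_methylation(calls: pd.DataFrame, context: str = "CpG") -> float:
    """Percent methylation over all calls in one context (call-weighted).

    Raises :class:`UndefinedValueError` when the context has zero calls — an
    uncovered context is missing, never 0%.
    """
    sub = calls[calls["context"] == context]
    total = int(sub["meth"].sum() + sub["unmeth"].sum())
    if total == 0:
        raise UndefinedValueError(f"no {context} calls: global methylation undefined")
    return 100.0 * float(sub["meth"].sum()) / total


def quantify_regions(
    calls: pd.DataFrame,
    regions: pd.DataFrame,
    context: str = "CpG",
    warn_unmatched: bool = True,
) -> pd.DataFrame:
    """Sum methylation calls over a set of genomic intervals.

    Returns one row per region (same order as ``regions``) with columns
    ``name, class_label, chrom, start, end, meth, total, pct``; regions with
    ``total == 0`` get ``pct = NaN`` (missing, never 0%).
    """
    sub = calls[calls["context"] == context]
    n = len(regions)
    meth_out = np.zeros(n, dtype=np.int64)
    total_out = np.zeros(n, dtype=np.int64)

    call_chroms = set(sub["chrom"].unique())
    region_chroms = set(regions["chrom"].unique())
    if warn_unmatched and len(sub):
        unmatched = sub["chrom"].isin(call_chroms - region_chroms).sum()
        if unmatched:
            warnings.warn(
                f"{unmatched} calls on chromosomes absent from the region set",
                stacklevel=2,
            )

    for chrom, ridx in regions.groupby("chrom", sort=False).groups.items():
        cc = sub[sub["chrom"] == chrom]
        if not len(cc):
            continue
        offs = cc["pos"].to_numpy() - 1  # 0-based offsets
        order = np.argsort(offs, kind="mergesort")
        offs = offs[order]
        m = cc["meth"].to_numpy()[order]
        u = cc["unmeth"].to_numpy()[order]
        cm = np.concatenate([[0], np.cumsum(m)])
        ct = np.concatenate([[0], np.cumsum(m + u)])
        starts = regions.loc[ridx, "start"].to_numpy()
        ends = regions.loc[ridx, "end"].to_numpy()
        lo = np.searchsorted(offs, starts, side="left")
        hi = np.searchsorted(offs, ends, side="left")
        rows = regions.index.get_indexer(ridx)
        meth_out[rows] = cm[hi] - cm[lo]
        total_out[rows] = ct[hi] - ct[lo]

    pct = np.where(total_out > 0, 100.0 * meth_out / np.maximum(total_out, 1), np.nan)
    return pd.DataFrame(
        {
            "name": regions["name"].to_numpy(),
            "class_label": regions["class_label"].to_numpy(),
            "chrom": regions["chrom"].to_numpy(),
            "start": regions["start"].to_numpy(),
            "end": regions["end"].to_numpy(),
            "meth": meth_out,
            "total": total_out,
            "pct": pct,
        }
    )


def region_count_matrices(
    cells: Mapping[str, pd.DataFrame],
    regions: pd.DataFrame,
    context: str = "CpG",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell per-region (meth, total) count matrices (cells x regions).

    The workhorse behind pseudobulking: each cell is quantified once and
    pseudobulk counts become row sums.
    """
    meth_rows, total_rows, ids = [], [], []
    for cell_id, calls in cells.items():
        q = quantify_regions(calls, regions, context=context, warn_unmatched=False)
        meth_rows.append(q["meth"].to_numpy())
        total_rows.append(q["total"].to_numpy())
        ids.append(cell_id)
    names = regions["name"].to_numpy()
    return (
        pd.DataFrame(np.array(meth_rows), index=ids, columns=names),
        pd.DataFrame(np.array(total_rows), index=ids, columns=names),
    )


def merge_cells(cells: Iterable[pd.DataFrame]) -> pd.DataFrame:
    """Merge per-cell call tables into a pseudobulk: counts summed per site."""
    tables = list(cells)
    if not tables:
        raise ValueError("merge_cells requires at least one cell")
    cat = pd.concat(tables, ignore_index=True)
    merged = (
        cat.groupby(["chrom", "pos", "context"], sort=True, as_index=False)[["meth", "unmeth"]]
        .sum()
    )
    return merged[CALL_COLUMNS]


def gdmr_panel(
    groups: Mapping[str, pd.DataFrame],
    gdmrs: pd.DataFrame,
    context: str = "CpG",
) -> pd.DataFrame:
    """Methylation percent per (gDMR, group) from group-merged call tables.

    Entries with zero coverage are NaN (missing); no thresholding applied.
    """
    if not len(gdmrs):
        raise ValueError("empty gDMR interval set")
    cols = {}
    for name, calls in groups.items():
        q = quantify_regions(calls, gdmrs, context=context, warn_unmatched=False)
        cols[name] = q["pct"].to_numpy()
    return pd.DataFrame(cols, index=gdmrs["name"].to_numpy())


def group_compare(values_a, values_b, test: str = "wilcoxon_ranksum"):
    """Two-sided Wilcoxon rank-sum comparison of two groups of values.

    Exact enumeration for combined n <= 20 without ties; normal approximation
    with tie correction otherwise.  All values tied across both groups gives
    p = 1 by convention.
    """
    if test != "wilcoxon_ranksum":
        raise ValueError(f"unsupported test {test!r}")
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return float("nan"), 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
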