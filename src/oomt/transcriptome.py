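"""Single-cell transcriptome analysis of oocyte ageing.

Counts are normalised by median-of-ratios size factors and log2(x+1)
transformed throughout.  Chromatin state (NSN vs SN) is inferred by
hierarchical clustering on a signature of genes overexpressed at least
two-fold in SN oocytes.  Differential mean expression uses a rank-sum test
on normalised counts; differential variability uses a residual-CV²
permutation test (per-group squared coefficient of variation after
regressing log CV² on log mean); both are deliberately transparent
stand-ins for heavier model-based machinery, so the differential gene sets
can also be supplied as input files downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

from .methylome import group_compare

__all__ = [
    "size_factors",
    "normalize",
    "log_normalize",
    "transcript_diversity",
    "classify_chromatin_state",
    "fisher_proportion_test",
    "pca_with_associations",
    "differential_mean_test",
    "differential_variability_test",
    "pairwise_distance_stat",
    "cluster_trajectory_test",
    "young_like_subgroup",
    "cluster_cells",
]


def _check_matrix(matrix: pd.DataFrame) -> None:
    if matrix.index.duplicated().any() or matrix.columns.duplicated().any():
        raise ValueError("duplicate gene or cell ids")
    if (matrix.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")


def size_factors(matrix: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    factor_c = median over genes of count_gc / geometric_mean_g, restricted
    to genes with a nonzero geometric mean (expressed in every cell).  If no
    such gene exists, falls back to total-count scaling with a warning.
    """
    _check_matrix(matrix)
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 cells")
    X = matrix.to_numpy(dtype=float)
    all_pos = (X > 0).all(axis=1)
    if all_pos.any():
        logX = np.log(X[all_pos])
        log_gm = logX.mean(axis=1, keepdims=True)
        factors = np.exp(np.median(logX - log_gm, axis=0))
    else:
        warnings.warn(
            "no gene expressed in all cells; falling back to total-count scaling",
            stacklevel=2,
        )
        totals = X.sum(axis=0)
        if (totals == 0).any():
            raise ValueError("cell with zero total counts")
        factors = totals
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=matrix.columns, name="size_factor")


def normalize(matrix: pd.DataFrame, factors: Optional[pd.Series] = None) -> pd.DataFrame:
    factors = size_factors(matrix) if factors is None else factors
    return matrix / factors


def log_normalize(matrix: pd.DataFrame, factors: Optional[pd.Series] = None) -> pd.DataFrame:
    """log2(normalised count + 1), the transform used throughout."""
    return np.log2(normalize(matrix, factors) + 1.0)


def transcript_diversity(matrix: pd.DataFrame) -> pd.Series:
    """Per-cell transcript diversity: number of genes detected at >= 1 count."""
    return (matrix >= 1).sum(axis=0).rename("n_detected")


def classify_chromatin_state(
    matrix: pd.DataFrame, signature_genes: Sequence[str]
) -> pd.Series:
    """Assign NSN / SN chromatin state from an SN-overexpression signature.

    Ward hierarchical clustering (Euclidean) on z-scored log-normalised
    signature-gene expression, cut at two clusters; the cluster with the
    higher mean signature expression is labelled SN.  Unresolvable signature
    ids are reported via a warning; a degenerate matrix (all cells identical
    on the signature) yields all-NSN with a warning.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 cells")
    present = [g for g in signature_genes if g in matrix.index]
    missing = sorted(set(signature_genes) - set(present))
    if missing:
        warnings.warn(f"{len(missing)} signature genes not in matrix", stacklevel=2)
    if len(present) < 5:
        raise ValueError(f"only {len(present)} signature genes resolvable; need >= 5")
    logn = log_normalize(matrix).loc[present]
    X = logn.to_numpy().T  # cells x genes
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.any():
        warnings.warn("signature expression identical across cells; all NSN", stacklevel=2)
        return pd.Series("NSN", index=matrix.columns, name="chromatin_state")
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    # sort cells so the assignment is invariant to input cell order
    order = np.lexsort(Z.T[::-1])
    link = linkage(Z[order], method="ward")
    cl_sorted = fcluster(link, t=2, criterion="maxclust")
    cl = np.empty(len(order), dtype=int)
    cl[order] = cl_sorted
    mean_sig = logn.mean(axis=0).to_numpy()
    means = {k: mean_sig[cl == k].mean() for k in np.unique(cl)}
    sn_cluster = max(means, key=means.get)
    labels = np.where(cl == sn_cluster, "SN", "NSN")
    return pd.Series(labels, index=matrix.columns, name="chromatin_state")


def fisher_proportion_test(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 table (hypergeometric sum of
    tables at most as probable as the observed one); zero-margin tables
    give p = 1."""
    t = np.asarray(table)
    if t.shape != (2, 2) or (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        raise ValueError("need a non-negative integer 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return 1.0
    return float(stats.fisher_exact(t).pvalue)


def pca_with_associations(
    matrix: pd.DataFrame,
    covariates: pd.DataFrame,
    n_pcs: int = 5,
    n_top_genes: int = 2000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """PCA of the transcriptome plus PC-covariate association p-values.

    Standard PCA on z-scored log-normalised counts of the ``n_top_genes``
    most variable genes; for each of the first ``n_pcs`` components and each
    covariate column, a simple linear regression F-test p-value (categorical
    covariates are factorised).  Constant covariates give NaN with a warning.

    Returns (scores: cells x PCs, pmat: covariates x PCs).
    """
    if matrix.shape[1] < 6:
        raise ValueError("need at least 6 cells")
    logn = log_normalize(matrix)
    var = logn.var(axis=1)
    top = var.sort_values(ascending=False).index[: min(n_top_genes, len(var))]
    # deterministic gene order regardless of input ordering
    top = sorted(top)
    X = logn.loc[top].to_numpy().T
    sd = X.std(axis=0)
    keep = sd > 0
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    n_pcs = min(n_pcs, min(Z.shape) - 1)
    pca = PCA(n_components=n_pcs, svd_solver="full")
    scores = pca.fit_transform(Z)
    # sign convention: largest-magnitude loading positive
    for j in range(n_pcs):
        comp = pca.components_[j]
        if comp[np.argmax(np.abs(comp))] < 0:
            scores[:, j] = -scores[:, j]
    score_df = pd.DataFrame(
        scores, index=matrix.columns, columns=[f"PC{i+1}" for i in range(n_pcs)]
    )
    pmat = {}
    for name in covariates.columns:
        col = covariates[name].reindex(matrix.columns)
        if col.dtype == object or str(col.dtype) == "category" or col.dtype == bool:
            col = pd.Series(pd.factorize(col)[0], index=col.index).astype(float)
        x = col.to_numpy(dtype=float)
        if np.all(x == x[0]):
            warnings.warn(f"covariate {name!r} is constant; p undefined", stacklevel=2)
            pmat[name] = [np.nan] * n_pcs
            continue
        ps = []
        for j in range(n_pcs):
            res = stats.linregress(x, scores[:, j])
            ps.append(res.pvalue)
        pmat[name] = ps
    pmat_df = pd.DataFrame(pmat, index=score_df.columns).T
    return score_df, pmat_df


def differential_mean_test(
    matrix: pd.DataFrame, groups: Mapping[str, str] | pd.Series
) -> pd.DataFrame:
    """Per-gene two-sided rank-sum test on size-factor-normalised counts.

    Returns a DataFrame (gene, log2_fc, p, q) sorted by input gene order;
    all-zero genes are excluded and reported in the ``excluded`` attribute
    (``result.attrs["excluded"]``).  log2 fold change compares normalised
    group means with a pseudocount of 1.
    """
    groups = pd.Series(groups).reindex(matrix.columns)
    labels = groups.dropna().unique()
    if len(labels) != 2:
        raise ValueError("need exactly 2 groups")
    g1, g2 = sorted(labels)  # g2 vs g1; with young/aged, aged vs young
    if list(sorted(labels)) == ["aged", "young"]:
        g1, g2 = "young", "aged"
    a_cells = groups.index[groups == g1]
    b_cells = groups.index[groups == g2]
    if len(a_cells) < 3 or len(b_cells) < 3:
        raise ValueError("need at least 3 cells per group")
    norm = normalize(matrix)
    A = norm[a_cells].to_numpy()
    B = norm[b_cells].to_numpy()
    expressed = (matrix.to_numpy().sum(axis=1)) > 0
    genes = matrix.index.to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stat, p = stats.mannwhitneyu(
            B[expressed], A[expressed], axis=1, alternative="two-sided",
            method="asymptotic",
        )
    # ties everywhere (e.g. a constant gene) give NaN: no evidence, p = 1
    p = np.where(np.isfinite(p), p, 1.0)
    lfc = np.log2(B[expressed].mean(axis=1) + 1.0) - np.log2(A[expressed].mean(axis=1) + 1.0)
    res = pd.DataFrame(
        {
            "gene": genes[expressed],
            "log2_fc": lfc,
            "p": p,
            "q": _bh(p),
        }
    )
    res.attrs["excluded"] = list(genes[~expressed])
    res.attrs["groups"] = (g1, g2)
    return res


def _bh(p: np.ndarray) -> np.ndarray:
    from .dmr_consensus import bh_fdr

    return bh_fdr(p)


def _trigamma(x: np.ndarray) -> np.ndarray:
    """Vectorised trigamma via the ascending recurrence plus the asymptotic
    series (relative error < 1e-8 for x > 0), faster than the generic
    polygamma route for large arrays."""
    x = np.array(x, dtype=float, copy=True)
    res = np.zeros_like(x)
    for _ in range(7):
        small = x < 6.0
        if not small.any():
            break
        xs = x[small]
        res[small] += 1.0 / (xs * xs)
        x[small] = xs + 1.0
    z = 1.0 / x
    z2 = z * z
    res += z * (1.0 + z * (0.5 + z * (1 / 6 - z2 * (1 / 30 - z2 * (1 / 42 - z2 / 30)))))
    return res


def _nb_log_dispersion(X: np.ndarray, n_iter: int = 3):
    """Per-gene NB maximum-likelihood dispersion on a genes x cells matrix.

    The NB2 mean MLE is the sample mean regardless of dispersion, so only
    theta = log(1/alpha) needs optimising; a few Newton steps on theta from
    the method-of-moments start converge for every practical gene.  Returns
    (log_alpha, var_log_alpha) with the variance from the observed
    information at the last Newton step — genes pinned at an alpha bound
    (e.g. underdispersed samples) get variance inf, i.e. zero weight.
    """
    from scipy.special import psi

    n = X.shape[1]
    mu = X.mean(axis=1)
    s2 = X.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha0 = (s2 - mu) / mu**2
    alpha0 = np.clip(np.where(np.isfinite(alpha0), alpha0, 1e-3), 1e-3, 100.0)
    theta = np.log(1.0 / alpha0)  # log r
    lo, hi = -np.log(100.0), -np.log(1e-3)
    mu_col = mu[:, None]
    h = np.full(theta.shape, -np.inf)
    for _ in range(n_iter):
        r1 = np.exp(theta)
        r = r1[:, None]
        xr = X + r
        dldr = (
            psi(xr).sum(axis=1)
            - n * psi(r1)
            + n * (np.log(r1) - np.log(r1 + mu))
            + ((mu_col - X) / (r + mu_col)).sum(axis=1)
        )
        d2ldr2 = (
            _trigamma(xr).sum(axis=1)
            - n * _trigamma(r1)
            + n / r1
            - n / (r1 + mu)
            - ((mu_col - X) / (r + mu_col) ** 2).sum(axis=1)
        )
        g = r1 * dldr                  # d l / d theta
        h = r1**2 * d2ldr2 + g         # d2 l / d theta2
        with np.errstate(divide="ignore", invalid="ignore"):
            step = np.where(h < 0, g / h, -np.sign(g) * 0.5)  # subtract g/h = Newton
        theta = np.clip(theta - np.clip(np.nan_to_num(step), -2.0, 2.0), lo, hi)
    at_bound = (theta <= lo + 1e-9) | (theta >= hi - 1e-9)
    with np.errstate(divide="ignore"):
        var = np.where((h < 0) & ~at_bound, -1.0 / h, np.inf)
    return -theta, var  # log alpha and its variance


def differential_variability_test(
    matrix: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    n_permutations: int = 50,
    seed: int = 0,
    min_cells_expressed: int = 5,
) -> pd.DataFrame:
    """Differential expression variability via an NB-dispersion permutation test.

    For each gene the per-group negative-binomial dispersion is estimated by
    maximum likelihood on size-factor-normalised counts and the statistic is
    the Wald-standardised difference of log dispersions (second group −
    first; aged − young for young/aged labels).  Dispersion is the
    mean-decoupled overdispersion parameter (variance = mu + alpha mu²), so
    no mean-trend correction is needed.  Significance comes from seeded
    group-label permutations with the null pooled across genes (the
    standardised statistic is exchangeable between genes, and pooling gives
    the p-value resolution that BH across thousands of genes requires);
    q-values are BH-adjusted, conventionally thresholded at q < 0.10.
    Genes expressed in fewer than ``min_cells_expressed`` cells per group
    are excluded.

    Returns (gene, statistic, z, p, q) where ``statistic`` is the log
    dispersion difference.
    """
    groups = pd.Series(groups).reindex(matrix.columns)
    labels = sorted(groups.dropna().unique())
    if len(labels) != 2:
        raise ValueError("need exactly 2 groups")
    g1, g2 = labels
    if labels == ["aged", "young"]:
        g1, g2 = "young", "aged"
    gvec = (groups == g2).to_numpy()  # True = second group
    if gvec.sum() < 10 or (~gvec).sum() < 10:
        raise ValueError("need at least 10 cells per group")
    norm = normalize(matrix)
    X = norm.to_numpy(dtype=float)
    detected = (matrix.to_numpy() > 0)
    keep = (detected[:, gvec].sum(axis=1) >= min_cells_expressed) & (
        detected[:, ~gvec].sum(axis=1) >= min_cells_expressed
    )
    Xk = X[keep]
    genes = matrix.index.to_numpy()[keep]
    n_cells = Xk.shape[1]

    rng = np.random.default_rng(seed)

    def z_and_diff(mask):
        la2, v2 = _nb_log_dispersion(Xk[:, mask])
        la1, v1 = _nb_log_dispersion(Xk[:, ~mask])
        diff = la2 - la1
        with np.errstate(divide="ignore", invalid="ignore"):
            z = diff / np.sqrt(v1 + v2)
        return np.where(np.isfinite(z), z, 0.0), diff

    obs_z, obs_diff = z_and_diff(gvec)
    null = np.empty((n_permutations, Xk.shape[0]))
    for i in range(n_permutations):
        null[i], _ = z_and_diff(gvec[rng.permutation(n_cells)])
    pool = np.sort(np.abs(null.ravel()))
    exceed = pool.size - np.searchsorted(pool, np.abs(obs_z), side="left")
    p = (1.0 + exceed) / (pool.size + 1.0)
    res = pd.DataFrame(
        {"gene": genes, "statistic": obs_diff, "z": obs_z, "p": p, "q": _bh(p)}
    )
    res.attrs["groups"] = (g1, g2)
    return res


def pairwise_distance_stat(
    matrix: pd.DataFrame,
    gene_subset: Sequence[str],
    groups: Mapping[str, str] | pd.Series,
) -> dict:
    """Within-group pairwise Euclidean distances on log-normalised expression
    of a gene subset, with a rank-sum comparison of the two distance sets."""
    missing = sorted(set(gene_subset) - set(matrix.index))
    if missing:
        raise ValueError(f"genes not in matrix: {missing[:10]}")
    groups = pd.Series(groups).reindex(matrix.columns)
    labels = sorted(groups.dropna().unique())
    if len(labels) != 2:
        raise ValueError("need exactly 2 groups")
    logn = log_normalize(matrix).loc[list(gene_subset)]
    dists = {}
    for g in labels:
        cells = groups.index[groups == g]
        if len(cells) < 2:
            raise ValueError(f"group {g!r} needs >= 2 cells")
        dists[g] = pdist(logn[cells].to_numpy().T, metric="euclidean")
    if min(len(d) for d in dists.values()) >= 2:
        stat, p = group_compare(dists[labels[0]], dists[labels[1]])
    else:  # a 2-cell group yields a single distance; no comparison possible
        stat, p = float("nan"), float("nan")
    return {"distances": dists, "statistic": stat, "p": p}


def cluster_trajectory_test(
    matrix: pd.DataFrame,
    cluster_ids: Mapping[str, int] | pd.Series,
    maternal_genes: Optional[Sequence[str]] = None,
) -> tuple[pd.DataFrame, float]:
    """Differential expression along an ordered cluster trajectory.

    Per gene: linear regression of log-normalised expression on the cluster
    index (two-sided t-test on the slope), Bonferroni-adjusted.  Enrichment:
    one-sided rank-sum test that maternal-effect genes rank higher (smaller
    p) than the remaining genes; skipped (NaN) when no maternal gene
    resolves.

    Returns (per-gene table with p / p_bonferroni / slope / rank,
    enrichment p).
    """
    cl = pd.Series(cluster_ids).reindex(matrix.columns)
    if cl.isna().any():
        raise ValueError("cluster id missing for some cells")
    x = cl.to_numpy(dtype=float)
    if len(np.unique(x)) < 2:
        raise ValueError("need at least 2 distinct cluster ids")
    logn = log_normalize(matrix).to_numpy()
    n = len(x)
    xc = x - x.mean()
    sxx = (xc**2).sum()
    slope = (logn @ xc) / sxx
    fitted = slope[:, None] * xc[None, :] + logn.mean(axis=1, keepdims=True)
    rss = ((logn - fitted) ** 2).sum(axis=1)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(rss / df / sxx)
        t = slope / se
    p = 2 * stats.t.sf(np.abs(t), df)
    p = np.where(np.isfinite(p), p, 1.0)
    res = pd.DataFrame(
        {
            "gene": matrix.index,
            "slope": slope,
            "p": p,
            "p_bonferroni": np.minimum(p * len(p), 1.0),
        }
    )
    res["rank"] = res["p"].rank(method="average")
    enrich_p = float("nan")
    if maternal_genes is not None:
        mat = res["gene"].isin(set(maternal_genes)).to_numpy()
        if mat.any() and (~mat).any():
            # maternal genes rank higher = smaller p-value ranks
            enrich_p = float(
                stats.mannwhitneyu(
                    res["rank"][mat], res["rank"][~mat], alternative="less"
                ).pvalue
            )
    return res, enrich_p


def cluster_cells(matrix: pd.DataFrame, n_clusters: int = 4, n_pcs: int = 5) -> pd.Series:
    """Hierarchical (Ward) clustering of cells on PC scores — the transparent
    stand-in for embedding-based clustering when no annotation is supplied."""
    logn = log_normalize(matrix)
    var = logn.var(axis=1)
    top = sorted(var.sort_values(ascending=False).index[: min(2000, len(var))])
    X = logn.loc[top].to_numpy().T
    sd = X.std(axis=0)
    Z = (X[:, sd > 0] - X[:, sd > 0].mean(axis=0)) / sd[sd > 0]
    k = min(n_pcs, min(Z.shape) - 1)
    scores = PCA(n_components=k, svd_solver="full").fit_transform(Z)
    link = linkage(scores, method="ward")
    cl = fcluster(link, t=n_clusters, criterion="maxclust")
    return pd.Series(cl, index=matrix.columns, name="cluster_id")


def young_like_subgroup(
    matrix: pd.DataFrame,
    deg_set: Sequence[str],
    annotations: pd.DataFrame,
) -> pd.Series:
    """Flag aged cells whose age-associated-gene expression resembles young.

    Aged cells are Ward-clustered into two groups on log-normalised DEG
    expression; the aged cluster whose centroid is nearer the young-cell
    centroid is flagged young-like.  Returns a boolean Series over all cells
    (False for young).
    """
    degs = [g for g in deg_set if g in matrix.index]
    if not degs:
        raise ValueError("DEG set empty after resolution")
    ann = annotations.set_index("cell_id")["age_group"].reindex(matrix.columns)
    young_cells = ann.index[ann == "young"]
    aged_cells = ann.index[ann == "aged"]
    if len(young_cells) == 0 or len(aged_cells) == 0:
        raise ValueError("both age groups must be present")
    flags = pd.Series(False, index=matrix.columns, name="young_like")
    if len(aged_cells) < 4:
        warnings.warn("fewer than 4 aged cells; young-like detection skipped",
                      stacklevel=2)
        return flags
    logn = log_normalize(matrix).loc[degs]
    A = logn[aged_cells].to_numpy().T
    order = np.lexsort(A.T[::-1])
    link = linkage(A[order], method="ward")
    cl_sorted = fcluster(link, t=2, criterion="maxclust")
    cl = np.empty(len(order), dtype=int)
    cl[order] = cl_sorted
    young_centroid = logn[young_cells].to_numpy().mean(axis=1)
    d = {
        k: np.linalg.norm(A[cl == k].mean(axis=0) - young_centroid)
        for k in np.unique(cl)
    }
    dmin = min(d.values())
    # ties (e.g. aged cells indistinguishable from young) flag every cluster
    yl_clusters = [k for k, v in d.items() if v <= dmin + 1e-9]
    for k in yl_clusters:
        flags.loc[np.asarray(aged_cells)[cl == k]] = True
    return flags
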