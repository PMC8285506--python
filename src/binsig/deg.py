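"""Differential expression, DEG clustering and population-level scoring.

Differential expression follows a per-gene Welch two-sided t-test on
log-scale expression values, restricted to genes expressed by at least a
minimum fraction of cells in *both* groups, with Benjamini-Hochberg FDR
computed over the tested genes only.  A gene is called differential when
FDR <= 0.05 and |log2 fold change| >= 1 (both thresholds inclusive,
configurable), with log2FC taken as the difference of group means on the
log2 scale.

DEG structure across the four tissue x switch-state populations is
summarized by Z-scoring each gene's population means and cutting a
complete-linkage Euclidean dendrogram at k clusters.  Gene-set scores are
sums of Z-scaled expression (a "module score" without background
subtraction), and the double-negative (DN) B-cell score is the difference
of an up-set and a down-set score.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from statsmodels.stats.multitest import multipletests

from .errors import AnalysisError

LOG_LAYERS = {"log2_cpm", "corrected"}


def _expr(adata) -> np.ndarray:
    return np.asarray(adata.X, dtype=float)


def differential_expression(
    adata,
    group_a: np.ndarray | list,
    group_b: np.ndarray | list,
    min_frac: float = 0.10,
    fdr_max: float = 0.05,
    lfc_min: float = 1.0,
) -> pd.DataFrame:
    """Welch t-test DE between two cell groups on log-scale values.

    ``group_a``/``group_b`` are boolean masks or cell-id lists.  Returns a
    per-gene table (tested genes only) with group means, expressing
    fractions, log2FC (= mean_a - mean_b), p, BH-FDR and ``is_deg``.
    """
    if adata.uns.get("layer") not in LOG_LAYERS:
        raise AnalysisError("differential_expression requires log-scale values")

    def mask_of(sel) -> np.ndarray:
        arr = np.asarray(sel)
        if arr.dtype == bool:
            return arr
        return adata.obs_names.isin(arr)

    ma, mb = mask_of(group_a), mask_of(group_b)
    if (ma & mb).any():
        raise AnalysisError("groups overlap")
    if ma.sum() < 2 or mb.sum() < 2:
        raise AnalysisError("each group needs at least 2 cells")

    X = _expr(adata)
    xa, xb = X[ma], X[mb]
    frac_a = (xa > 0).mean(axis=0)
    frac_b = (xb > 0).mean(axis=0)
    tested = (frac_a >= min_frac) & (frac_b >= min_frac)
    if not tested.any():
        raise AnalysisError("no gene passes the expressing-fraction filter")

    a, b = xa[:, tested], xb[:, tested]
    t, p = stats.ttest_ind(a, b, axis=0, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance-in-both genes
    _, fdr, _, _ = multipletests(p, method="fdr_bh")
    mean_a, mean_b = a.mean(axis=0), b.mean(axis=0)
    lfc = mean_a - mean_b

    out = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "frac_a": frac_a[tested],
            "frac_b": frac_b[tested],
            "log2_fold_change": lfc,
            "t_statistic": t,
            "p_value": p,
            "fdr": fdr,
        },
        index=adata.var_names[tested],
    )
    out["is_deg"] = (out["fdr"] <= fdr_max) & (out["log2_fold_change"].abs() >= lfc_min)
    return out


def deg_union(tables: list[pd.DataFrame]) -> list[str]:
    """Union of ``is_deg`` genes across comparisons, sorted and deduplicated."""
    if not tables:
        raise AnalysisError("at least one DEG table required")
    genes: set[str] = set()
    for t in tables:
        genes.update(t.index[t["is_deg"]])
    return sorted(genes)


def population_means(adata, populations: dict[str, np.ndarray]) -> pd.DataFrame:
    """Mean expression per gene within each named cell population."""
    X = _expr(adata)
    cols = {}
    for name, mask in populations.items():
        mask = np.asarray(mask, dtype=bool)
        if mask.sum() == 0:
            raise AnalysisError(f"population {name!r} is empty")
        cols[name] = X[mask].mean(axis=0)
    return pd.DataFrame(cols, index=adata.var_names.copy())


def zscore_rows(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Row-wise Z-score; constant rows become all-zero and are flagged."""
    vals = df.to_numpy(dtype=float)
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, keepdims=True)
    constant = sd.ravel() == 0
    sd[constant[:, None]] = 1.0
    z = (vals - mu) / sd
    z[constant] = 0.0
    return (
        pd.DataFrame(z, index=df.index, columns=df.columns),
        pd.Series(constant, index=df.index, name="constant"),
    )


def cluster_degs(
    adata,
    genes: list[str],
    populations: dict[str, np.ndarray],
    k: int = 6,
) -> dict:
    """Cut a complete-linkage dendrogram of population-mean Z rows at k.

    Returns ``{"clusters": Series gene->1..k, "z": DataFrame,
    "constant": Series, "linkage": ndarray}``.  Cluster indices are
    relabeled deterministically: descending size, ties by the
    lexicographically smallest member gene.
    """
    genes = [g for g in genes if g in adata.var_names]
    if len(genes) == 0:
        raise AnalysisError("no requested gene present in matrix")
    if k > len(genes):
        raise AnalysisError(f"k={k} exceeds number of genes ({len(genes)})")
    means = population_means(adata, populations).loc[genes]
    z, constant = zscore_rows(means)
    if len(genes) == 1:
        labels = np.array([1])
        lk = np.empty((0, 4))
    else:
        lk = linkage(z.to_numpy(), method="complete", metric="euclidean")
        labels = fcluster(lk, t=k, criterion="maxclust")

    # deterministic relabeling: size desc, then smallest member gene
    order = sorted(
        np.unique(labels),
        key=lambda c: (-(labels == c).sum(), min(np.array(genes)[labels == c])),
    )
    remap = {old: new + 1 for new, old in enumerate(order)}
    clusters = pd.Series([remap[c] for c in labels], index=genes, name="cluster")
    return {"clusters": clusters, "z": z, "constant": constant, "linkage": lk}


def top_variant_genes(adata, n_hv: int = 1000) -> list[str]:
    """The n_hv highest-variance genes (across cells)."""
    var = _expr(adata).var(axis=0)
    order = np.argsort(-var, kind="stable")[:n_hv]
    return list(adata.var_names[np.sort(order)])


def population_correlation(
    adatas,
    populations_list,
    n_hv: int = 1000,
) -> pd.DataFrame:
    """Pearson correlation between population mean vectors over high-variant genes.

    ``adatas`` is one or two AnnData objects, ``populations_list`` the
    matching list of ``{name: mask}`` dicts.  With two datasets the
    top-``n_hv`` lists are intersected before computing means; population
    names must be unique across datasets.  Plasma cells are expected to be
    excluded by the caller.
    """
    if not isinstance(adatas, (list, tuple)):
        adatas = [adatas]
        populations_list = [populations_list]
    if len(adatas) not in (1, 2):
        raise AnalysisError("one or two datasets supported")

    gene_sets = [set(top_variant_genes(a, n_hv)) for a in adatas]
    shared = set.intersection(*gene_sets)
    if len(adatas) == 2:
        shared &= set(adatas[0].var_names) & set(adatas[1].var_names)
    genes = sorted(shared)
    if len(genes) < 2:
        raise AnalysisError("fewer than 2 shared high-variant genes")

    mean_cols = {}
    for a, pops in zip(adatas, populations_list):
        m = population_means(a, pops).loc[genes]
        for name in m.columns:
            if name in mean_cols:
                raise AnalysisError(f"duplicate population name {name!r}")
            mean_cols[name] = m[name].to_numpy()
    mat = pd.DataFrame(mean_cols, index=genes)
    return mat.corr(method="pearson")


def geneset_score(
    values: pd.DataFrame, geneset: list[str]
) -> tuple[pd.Series, list[str]]:
    """Z-sum gene-set score over a genes x samples frame.

    Each member gene's expression is Z-scaled across samples; the score of a
    sample is the sum of those Z values.  Returns ``(scores, missing_genes)``.
    """
    members = [g for g in dict.fromkeys(geneset) if g in values.index]
    missing = [g for g in dict.fromkeys(geneset) if g not in values.index]
    if not members:
        raise AnalysisError("no gene of the set is present")
    z, _ = zscore_rows(values.loc[members])
    return z.sum(axis=0), missing


def geneset_score_cells(adata, geneset: list[str]) -> tuple[pd.Series, list[str]]:
    """Per-cell Z-sum score (genes scaled across cells)."""
    df = pd.DataFrame(_expr(adata).T, index=adata.var_names,
                      columns=adata.obs_names)
    return geneset_score(df, geneset)


def dn_score(adata, up_set: list[str], down_set: list[str]) -> pd.Series:
    """Double-negative B-cell score: up-set Z-sum minus down-set Z-sum."""
    up, _ = geneset_score_cells(adata, up_set)
    down, _ = geneset_score_cells(adata, down_set)
    return up - down


def cluster_scores_on_atlas(
    atlas: pd.DataFrame,
    subset_map: pd.Series,
    clusters: pd.Series,
    ortholog_map: pd.DataFrame,
) -> tuple[pd.DataFrame, list[int]]:
    """Per-cluster Z-sum scores across the murine atlas subsets.

    Human cluster genes are translated to mouse genes via the ortholog map
    (human -> mouse direction); per-replicate Z-sum scores are averaged
    within each subset and each cluster row is then Z-scaled across
    subsets.  Returns ``(cluster x subset Z matrix, clusters with zero
    mappable genes)`` — unmappable clusters appear as all-NaN rows rather
    than being silently dropped.
    """
    h2m: dict[str, list[str]] = {}
    for m, h in ortholog_map.itertuples(index=False):
        h2m.setdefault(h, []).append(m)

    subsets = list(dict.fromkeys(subset_map.loc[atlas.columns]))
    rows, empty = {}, []
    for c in sorted(clusters.unique()):
        hgenes = clusters.index[clusters == c]
        mgenes = sorted(
            {m for h in hgenes for m in h2m.get(h, []) if m in atlas.index}
        )
        if not mgenes:
            empty.append(int(c))
            rows[c] = pd.Series(np.nan, index=subsets)
            continue
        rep_scores, _ = geneset_score(atlas, mgenes)  # per replicate column
        subset_mean = rep_scores.groupby(subset_map.loc[rep_scores.index]).mean()
        rows[c] = subset_mean.reindex(subsets)
    mat = pd.DataFrame(rows).T
    mat.index.name = "cluster"
    ok = mat.index.difference(pd.Index(empty))
    if len(ok):
        z, _ = zscore_rows(mat.loc[ok])
        mat.loc[ok] = z
    return mat, empty
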