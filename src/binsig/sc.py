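"""Single-cell expression core: I/O, log2-CPM normalization, cell-level QC,
immunoglobulin isotype assignment and plasma-cell flagging.

Expression data are carried as :class:`anndata.AnnData` with cells as
observations and genes as variables.  The active scale of ``X`` is recorded
in ``adata.uns["layer"]`` (``raw_counts``, ``log2_cpm`` or ``corrected``);
spike-in rows are marked by a boolean ``var["is_spikein"]`` derived from a
reserved gene-id prefix (``ERCC-`` by default).

The QC model is two cell-level filters applied to raw counts:

* gene coverage — a cell must express (count > 0) between ``min_genes`` and
  ``max_genes`` endogenous genes (spike-ins never count);
* B-cell identity — the sum of log2-CPM values over the immunoglobulin
  heavy-chain constant-region genes must reach ``ig_logcpm_min``.

Isotype is the argmax over the constant-region genes of a cell's expression,
with IgM/IgD counting as unswitched and IgG/IgA/IgE as switched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd

from .errors import AnalysisError, ConfigError, FormatError

#: Heavy-chain constant-region genes in default precedence order
#: (ties in isotype assignment resolve to the earliest entry).
IGH_CONSTANT_GENES = [
    "IGHM",
    "IGHD",
    "IGHG3",
    "IGHG1",
    "IGHA1",
    "IGHG2",
    "IGHG4",
    "IGHE",
    "IGHA2",
]

#: Isotypes whose expression leaves a cell "unswitched".
UNSWITCHED_ISOTYPES = {"IGHM", "IGHD"}

SPIKEIN_PREFIX = "ERCC-"


@dataclass
class QCConfig:
    """Cell-level quality-control thresholds.

    ``min_genes``/``max_genes`` bound the number of expressed endogenous
    genes (both bounds passing, i.e. a cell fails only strictly outside
    them); ``ig_logcpm_min`` is the minimum summed log2-CPM over the
    heavy-chain constant genes.
    """

    min_genes: int = 3000
    max_genes: int = 15000
    ig_logcpm_min: float = 5.0
    igh_constant_genes: list[str] = field(
        default_factory=lambda: list(IGH_CONSTANT_GENES)
    )
    spikein_prefix: str = SPIKEIN_PREFIX

    def __post_init__(self) -> None:
        if self.min_genes >= self.max_genes:
            raise ConfigError(
                f"min_genes ({self.min_genes}) must be below "
                f"max_genes ({self.max_genes})"
            )
        if not self.igh_constant_genes:
            raise ConfigError("igh_constant_genes must be non-empty")


def _mark_spikeins(adata: ad.AnnData, prefix: str = SPIKEIN_PREFIX) -> None:
    adata.var["is_spikein"] = adata.var_names.str.startswith(prefix)


def load_matrix(path: str | Path, fmt: str = "tsv") -> ad.AnnData:
    """Load a gene x cell matrix into AnnData (cells as obs).

    ``fmt="tsv"`` expects a dense table with gene ids in the first column
    and one column per cell.  ``fmt="mtx"`` expects a directory holding
    ``matrix.mtx`` (genes x cells), ``genes.tsv`` and ``barcodes.tsv``.
    """
    path = Path(path)
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        genes = df.index.astype(str)
        cells = df.columns.astype(str)
        values = df.to_numpy(dtype=float).T  # cells x genes
    elif fmt == "mtx":
        from scipy.io import mmread

        mat = mmread(path / "matrix.mtx").toarray()
        genes = pd.Index(
            pd.read_csv(path / "genes.tsv", sep="\t", header=None)[0].astype(str)
        )
        cells = pd.Index(
            pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
        )
        if mat.shape != (len(genes), len(cells)):
            raise FormatError(
                f"matrix is {mat.shape} but sidecars list "
                f"{len(genes)} genes and {len(cells)} barcodes"
            )
        values = mat.T.astype(float)
    else:
        raise ConfigError(f"unknown format {fmt!r}; use 'tsv' or 'mtx'")

    if genes.duplicated().any():
        raise FormatError("duplicate gene ids in input")
    if cells.duplicated().any():
        raise FormatError("duplicate cell ids in input")
    if (values < 0).any():
        raise FormatError("raw count matrix contains negative values")

    adata = ad.AnnData(
        X=values,
        obs=pd.DataFrame(index=pd.Index(cells, name="cell_id")),
        var=pd.DataFrame(index=pd.Index(genes, name="gene_id")),
    )
    adata.uns["layer"] = "raw_counts"
    _mark_spikeins(adata)
    return adata


def write_matrix(adata: ad.AnnData, path: str | Path, fmt: str = "tsv") -> None:
    """Write the matrix back out in the same dialects ``load_matrix`` reads."""
    path = Path(path)
    if fmt == "tsv":
        df = pd.DataFrame(
            adata.X.T, index=adata.var_names, columns=adata.obs_names
        )
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t")
    elif fmt == "mtx":
        from scipy.io import mmwrite
        from scipy.sparse import csr_matrix

        path.mkdir(parents=True, exist_ok=True)
        mmwrite(str(path / "matrix.mtx"), csr_matrix(adata.X.T))
        pd.Series(adata.var_names).to_csv(
            path / "genes.tsv", sep="\t", header=False, index=False
        )
        pd.Series(adata.obs_names).to_csv(
            path / "barcodes.tsv", sep="\t", header=False, index=False
        )
    else:
        raise ConfigError(f"unknown format {fmt!r}")


def log2_cpm(adata: ad.AnnData, exclude_spikeins: bool = True) -> ad.AnnData:
    """Return a new AnnData scaled to log2(1 + CPM).

    Library size per cell is the total raw count, excluding spike-in genes
    when ``exclude_spikeins`` is set (spike-in content varies per well and
    should not dilute endogenous CPM).
    """
    if adata.uns.get("layer") != "raw_counts":
        raise AnalysisError("log2_cpm requires the raw_counts layer")
    counts = np.asarray(adata.X, dtype=float)
    if "is_spikein" not in adata.var:
        _mark_spikeins(adata)
    endo = ~adata.var["is_spikein"].to_numpy()
    lib = counts[:, endo].sum(axis=1) if exclude_spikeins else counts.sum(axis=1)
    bad = np.flatnonzero(lib == 0)
    if bad.size:
        names = ", ".join(adata.obs_names[bad])
        raise AnalysisError(f"zero library size for cell(s): {names}")
    out = adata.copy()
    out.X = np.log2(1.0 + 1e6 * counts / lib[:, None])
    out.uns["layer"] = "log2_cpm"
    return out


def qc_filter(
    adata: ad.AnnData, config: QCConfig | None = None
) -> tuple[pd.DataFrame, ad.AnnData]:
    """Apply the cell-level QC filters; returns (annotation, filtered AnnData).

    The annotation frame has one row per input cell with the expressed-gene
    tally, the Ig log2-CPM sum, a ``qc_pass`` flag and a semicolon-joined
    ``fail_reasons`` string (empty when passing).
    """
    if config is None:
        config = QCConfig()
    if adata.n_obs == 0 or adata.n_vars == 0:
        raise AnalysisError("empty expression matrix")
    if adata.uns.get("layer") != "raw_counts":
        raise AnalysisError("qc_filter requires raw counts")

    counts = np.asarray(adata.X, dtype=float)
    if "is_spikein" not in adata.var:
        _mark_spikeins(adata, config.spikein_prefix)
    endo = ~adata.var["is_spikein"].to_numpy()
    n_genes = (counts[:, endo] > 0).sum(axis=1)

    present = [g for g in config.igh_constant_genes if g in adata.var_names]
    missing = [g for g in config.igh_constant_genes if g not in adata.var_names]
    if missing:
        import warnings

        warnings.warn(f"IGH constant genes absent from matrix: {missing}")
    if not present:
        raise AnalysisError("none of the IGH constant genes are in the matrix")

    logc = log2_cpm(adata, exclude_spikeins=True)
    igh_idx = [logc.var_names.get_loc(g) for g in present]
    igh_sum = np.asarray(logc.X, dtype=float)[:, igh_idx].sum(axis=1)

    reasons = []
    for ng, ig in zip(n_genes, igh_sum):
        r = []
        if ng < config.min_genes:
            r.append("low_gene_count")
        if ng > config.max_genes:
            r.append("high_gene_count")
        if ig < config.ig_logcpm_min:
            r.append("low_ig_expression")
        reasons.append(";".join(r))

    ann = pd.DataFrame(
        {
            "n_genes_expressed": n_genes,
            "igh_logcpm_sum": igh_sum,
            "qc_pass": [r == "" for r in reasons],
            "fail_reasons": reasons,
        },
        index=adata.obs_names.copy(),
    )
    kept = adata[ann["qc_pass"].to_numpy()].copy()
    return ann, kept


def assign_isotype(
    adata: ad.AnnData, constant_genes: list[str] | None = None
) -> pd.DataFrame:
    """Per-cell isotype call as the most highly expressed constant gene.

    Ties resolve to the earliest gene in ``constant_genes`` and are flagged;
    a cell with zero expression across all constant genes is
    ``undetermined`` with no switch state.
    """
    if constant_genes is None:
        constant_genes = list(IGH_CONSTANT_GENES)
    present = [g for g in constant_genes if g in adata.var_names]
    if not present:
        raise AnalysisError("no constant-region gene present in matrix")
    idx = [adata.var_names.get_loc(g) for g in present]
    expr = np.asarray(adata.X, dtype=float)[:, idx]

    best = expr.argmax(axis=1)
    maxval = expr.max(axis=1)
    tie = (expr == maxval[:, None]).sum(axis=1) > 1
    isotype = np.array([present[i] for i in best], dtype=object)
    undetermined = maxval <= 0
    isotype[undetermined] = "undetermined"
    switch = np.where(
        undetermined,
        "undetermined",
        np.where(np.isin(isotype, list(UNSWITCHED_ISOTYPES)), "unswitched", "switched"),
    )
    return pd.DataFrame(
        {
            "isotype": isotype,
            "switch_state": switch,
            "isotype_tie": tie & ~undetermined,
        },
        index=adata.obs_names.copy(),
    )


def flag_plasma(
    adata: ad.AnnData,
    cluster_labels: pd.Series | None = None,
    marker_gene: str = "PRDM1",
    min_ratio: float = 2.0,
) -> pd.DataFrame:
    """Flag the plasma-cell cluster by marker expression.

    The cluster with the highest mean marker expression is called plasma only
    if that mean exceeds the runner-up cluster mean by ``min_ratio``; the
    call is per-cluster, so every member cell inherits ``is_plasma``.
    """
    if cluster_labels is None:
        if "cluster_label" not in adata.obs:
            raise AnalysisError("cluster labels required (obs['cluster_label'])")
        cluster_labels = adata.obs["cluster_label"]
    cluster_labels = pd.Series(
        np.asarray(cluster_labels, dtype=object), index=adata.obs_names
    )
    if cluster_labels.isna().any():
        raise AnalysisError("every cell needs a cluster label")
    if marker_gene not in adata.var_names:
        raise AnalysisError(f"marker gene {marker_gene!r} absent from matrix")

    marker = np.asarray(
        adata.X[:, adata.var_names.get_loc(marker_gene)], dtype=float
    ).ravel()
    means = pd.Series(marker).groupby(cluster_labels.to_numpy()).mean()
    means = means.sort_values(ascending=False)

    plasma_cluster = None
    if len(means) == 1:
        if means.iloc[0] > 0:
            plasma_cluster = means.index[0]
    else:
        top, second = means.iloc[0], means.iloc[1]
        if top > 0 and (second <= 0 or top / second >= min_ratio):
            plasma_cluster = means.index[0]

    return pd.DataFrame(
        {
            "cluster_label": cluster_labels,
            "is_plasma": (
                cluster_labels == plasma_cluster
                if plasma_cluster is not None
                else False
            ),
        },
        index=adata.obs_names.copy(),
    )
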