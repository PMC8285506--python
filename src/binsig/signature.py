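"""Covariant-gene signature derivation and gene-set enrichment.

A seed gene's expression profile across reference-atlas subsets defines a
covariant signature: every gene whose subset-mean profile has Pearson
r >= ``r_min`` (default 0.8) with the seed's profile.  The signature is
translated across species through an ortholog map (one-to-many expands,
many-to-one deduplicates) and tested for over-representation in gene
clusters with a one-sided hypergeometric test against a background
universe of all atlas-detected genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import AnalysisError


@dataclass
class Atlas:
    """Reference expression atlas: genes x replicate columns plus the
    replicate -> subset assignment.  Values are linear-scale, non-negative."""

    values: pd.DataFrame
    subset_map: pd.Series

    def __post_init__(self) -> None:
        missing = [c for c in self.values.columns if c not in self.subset_map.index]
        if missing:
            raise AnalysisError(f"replicates without subset assignment: {missing}")
        if self.values.index.duplicated().any():
            raise AnalysisError("duplicate gene ids in atlas")
        if self.subset_map.loc[self.values.columns].nunique() < 2:
            raise AnalysisError("atlas needs at least 2 subsets")

    @property
    def subsets(self) -> list[str]:
        return list(dict.fromkeys(self.subset_map.loc[self.values.columns]))

    def subset_means(self) -> pd.DataFrame:
        """Genes x subsets mean expression."""
        return (
            self.values.T.groupby(self.subset_map.loc[self.values.columns])
            .mean()
            .T[self.subsets]
        )

    def detected_genes(self) -> list[str]:
        """Genes with nonzero signal in at least one replicate (the
        enrichment background universe)."""
        return list(self.values.index[(self.values > 0).any(axis=1)])


def covariant_genes(
    atlas: Atlas,
    seed_gene: str,
    r_min: float = 0.8,
    level: str = "subset",
) -> tuple[list[str], pd.Series, list[str]]:
    """Genes correlating with the seed across subsets at Pearson r >= r_min.

    ``level="subset"`` (default) correlates subset-mean profiles;
    ``level="replicate"`` uses replicate-level values.  Returns
    ``(signature genes incl. seed, per-gene r, constant-profile genes
    excluded because r is undefined)``.
    """
    if seed_gene not in atlas.values.index:
        raise AnalysisError(f"seed gene {seed_gene!r} absent from atlas")
    if level == "subset":
        prof = atlas.subset_means()
        if prof.shape[1] < 3:
            raise AnalysisError("need >= 3 subsets for subset-level correlation")
    elif level == "replicate":
        prof = atlas.values
    else:
        raise AnalysisError(f"unknown level {level!r}")

    mat = prof.to_numpy(dtype=float)
    seed = prof.loc[seed_gene].to_numpy(dtype=float)
    if seed.std() == 0:
        raise AnalysisError(f"seed gene {seed_gene!r} has a constant profile")

    centered = mat - mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1)
    seed_c = seed - seed.mean()
    constant = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (centered @ seed_c) / (mat.shape[1] * sd * seed.std())
    r[constant] = np.nan
    r_series = pd.Series(r, index=prof.index, name="r")
    members = sorted(prof.index[(~constant) & (r >= r_min)])
    if seed_gene not in members:  # numerically r(seed)=1; keep explicit
        members = sorted(members + [seed_gene])
    excluded = list(prof.index[constant])
    return members, r_series, excluded


def map_orthologs(
    genes: list[str], ortholog_map: pd.DataFrame, direction: str = "mouse_to_human"
) -> tuple[list[str], list[str]]:
    """Translate a gene set through the ortholog table.

    One-to-many mappings expand, many-to-one deduplicate.  Returns
    ``(mapped genes sorted, unmapped input genes)``.
    """
    if ortholog_map.empty:
        raise AnalysisError("ortholog map is empty")
    if direction == "mouse_to_human":
        src, dst = "mouse_gene", "human_gene"
    elif direction == "human_to_mouse":
        src, dst = "human_gene", "mouse_gene"
    else:
        raise AnalysisError(f"unknown direction {direction!r}")
    lut: dict[str, set[str]] = {}
    for s, d in zip(ortholog_map[src], ortholog_map[dst]):
        lut.setdefault(s, set()).add(d)
    mapped: set[str] = set()
    unmapped: list[str] = []
    for g in dict.fromkeys(genes):
        if g in lut:
            mapped.update(lut[g])
        else:
            unmapped.append(g)
    if not mapped:
        import warnings

        warnings.warn("no input gene had an ortholog")
    return sorted(mapped), unmapped


def hypergeom_enrichment(
    signature: list[str],
    clusters: dict[str, list[str]] | pd.Series,
    universe: list[str],
    adjust: bool = True,
) -> pd.DataFrame:
    """One-sided over-representation test of the signature in each cluster.

    With universe size N, signature size K (after intersection with the
    universe), cluster size n and overlap k, p = P[X >= k] for
    X ~ Hypergeom(N, K, n).  Fold enrichment is (k/n)/(K/N).  ``adjust``
    adds BH-corrected q-values across clusters.
    """
    uni = set(universe)
    if not uni:
        raise AnalysisError("empty universe")
    sig = set(signature) & uni
    dropped = len(set(signature)) - len(sig)
    if dropped:
        import warnings

        warnings.warn(f"{dropped} signature gene(s) outside the universe dropped")
    if isinstance(clusters, pd.Series):
        clusters = {
            str(c): list(clusters.index[clusters == c])
            for c in sorted(clusters.unique())
        }
    N, K = len(uni), len(sig)
    rows = []
    for name, members in clusters.items():
        mem = set(members) & uni
        n, k = len(mem), len(mem & sig)
        p = float(hypergeom.sf(k - 1, N, K, n))
        fold = (k / n) / (K / N) if n and K else np.nan
        rows.append(
            {"cluster": name, "overlap_k": k, "cluster_n": n,
             "signature_K": K, "universe_N": N, "p_value": p,
             "fold_enrichment": fold}
        )
    out = pd.DataFrame(rows).set_index("cluster")
    if adjust and len(out):
        out["fdr"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


def signature_robustness(
    signature: list[str],
    seed_gene: str,
    clusters: dict[str, list[str]] | pd.Series,
    universe: list[str],
) -> pd.DataFrame:
    """Re-run the enrichment with the seed gene removed from the signature.

    Checks that enrichment does not hinge on the seed itself."""
    if seed_gene not in signature:
        raise AnalysisError("signature does not contain the seed gene")
    reduced = [g for g in signature if g != seed_gene]
    if not reduced:
        raise AnalysisError("signature is empty after removing the seed gene")
    return hypergeom_enrichment(reduced, clusters, universe)
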