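"""Post-search IP-MS analysis: protein-group filtering, median
normalization and fold-change ranking against negative-control antibodies.

Input is a protein-group LFQ intensity table (MaxQuant ``proteinGroups.txt``
dialect or the plain TSV produced by the synthetic generator): one row per
protein group, one intensity column per sample (0 = not detected) and
boolean contaminant / reverse / site_only flag columns.  Analysis steps:

1. drop flagged rows and proteins detected in fewer than two replicates of
   every condition (the per-condition reading is configurable);
2. divide each sample's nonzero intensities by that sample's median nonzero
   intensity (zeros encode non-detection and are preserved);
3. per test antibody, rank proteins by log2 of (mean test intensity +
   pseudocount) / (mean negative-control intensity + pseudocount).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AnalysisError, FormatError

FLAG_COLUMNS = ["contaminant", "reverse", "site_only"]


def read_protein_table(path: str | Path) -> pd.DataFrame:
    """Read a protein-group TSV; accepts MaxQuant-style '+' flag columns.

    Recognizes 'LFQ intensity <sample>' columns (renamed to the bare sample
    id) and the MaxQuant flag headers 'Potential contaminant', 'Reverse'
    and 'Only identified by site'.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    rename = {}
    for c in df.columns:
        if c.startswith("LFQ intensity "):
            rename[c] = c[len("LFQ intensity "):]
    alias = {
        "Potential contaminant": "contaminant",
        "Contaminant": "contaminant",
        "Reverse": "reverse",
        "Only identified by site": "site_only",
    }
    rename.update({c: alias[c] for c in df.columns if c in alias})
    df = df.rename(columns=rename)
    for c in FLAG_COLUMNS:
        if c not in df.columns:
            df[c] = False
        elif df[c].dtype == object:
            df[c] = df[c].fillna("") == "+"
        else:
            df[c] = df[c].fillna(False).astype(bool)
    return df


def _sample_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in FLAG_COLUMNS]


def filter_protein_groups(
    table: pd.DataFrame,
    condition_map: dict[str, list[str]],
    min_replicates: int = 2,
    every_condition: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove flagged rows and under-detected proteins.

    A protein is kept when it is detected (intensity > 0) in at least
    ``min_replicates`` replicates of *some* condition; set
    ``every_condition`` for the stricter conjunctive reading.  Returns
    ``(filtered table, removal log)``.
    """
    if not condition_map:
        raise AnalysisError("condition map is required")
    samples = _sample_columns(table)
    mapped = {s for cols in condition_map.values() for s in cols}
    missing = mapped - set(samples)
    if missing:
        raise FormatError(f"condition map names absent samples: {sorted(missing)}")

    flagged = table[FLAG_COLUMNS].any(axis=1)
    det_ok = pd.Series(every_condition, index=table.index)
    per_cond = []
    for cond, cols in condition_map.items():
        ok = (table[cols] > 0).sum(axis=1) >= min_replicates
        per_cond.append(ok)
    per_cond = pd.concat(per_cond, axis=1)
    det_ok = per_cond.all(axis=1) if every_condition else per_cond.any(axis=1)

    keep = ~flagged & det_ok
    log = pd.DataFrame(
        {
            "removed": ~keep,
            "reason": np.select(
                [flagged, ~det_ok],
                ["flagged", "insufficient_replicates"],
                default="",
            ),
        },
        index=table.index,
    )
    out = table[keep].copy()
    if out.empty:
        import warnings

        warnings.warn("no protein group survived filtering")
    return out, log


def median_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample so its median nonzero intensity becomes 1.

    Zeros are preserved (they encode non-detection, not low abundance).
    """
    out = table.copy()
    for c in _sample_columns(table):
        col = out[c].to_numpy(dtype=float)
        nz = col[col > 0]
        if nz.size == 0:
            raise AnalysisError(f"sample {c!r} has no nonzero intensity")
        out[c] = col / np.median(nz)
    return out


def ip_fold_change(
    table: pd.DataFrame,
    test_antibody: str,
    condition_map: dict[str, list[str]],
    controls: list[str],
    pseudocount: float | None = None,
    top_n: int = 10,
) -> pd.DataFrame:
    """Log2 fold change of each protein over the mean of negative controls.

    ``pseudocount=None`` uses the smallest nonzero intensity in the table
    (keeps zero-mean proteins finite without dominating detected ones).
    Returns the full ranked table; the top-``top_n`` rows carry
    ``in_top`` = True.
    """
    if test_antibody not in condition_map:
        raise AnalysisError(f"test antibody {test_antibody!r} not in condition map")
    missing = [c for c in controls if c not in condition_map]
    if missing or not controls:
        raise AnalysisError(f"controls missing from condition map: {missing}")

    test_cols = condition_map[test_antibody]
    ctrl_cols = [s for c in controls for s in condition_map[c]]
    vals = table[test_cols + ctrl_cols].to_numpy(dtype=float)
    if pseudocount is None:
        nz = vals[vals > 0]
        pseudocount = float(nz.min()) if nz.size else 1.0

    mean_test = table[test_cols].mean(axis=1)
    # mean of the per-control-antibody means, matching "mean of the
    # negative control antibodies" rather than a pooled replicate mean
    ctrl_means = pd.concat(
        [table[condition_map[c]].mean(axis=1) for c in controls], axis=1
    )
    mean_ctrl = ctrl_means.mean(axis=1)

    fc = np.log2((mean_test + pseudocount) / (mean_ctrl + pseudocount))
    out = pd.DataFrame(
        {
            "mean_test": mean_test,
            "mean_control": mean_ctrl,
            "log2_fold_change": fc,
        },
        index=table.index,
    )
    # descending fold change; ties broken by protein id for stable ranks
    out = out.iloc[
        np.lexsort((out.index.to_numpy(), -out["log2_fold_change"].to_numpy()))
    ]
    out["rank"] = np.arange(1, len(out) + 1)
    out["in_top"] = out["rank"] <= top_n
    return out
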