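"""HLA bead-assay analytics.

The screening readout is the normalized-background (NBG) ratio of bead i,

    NBG_i = (S_i - S_0) / (N_i - N_0),

where S are sample signals, N negative-serum signals, and subscript 0 the
negative-control bead of the panel.  A bead is positive at NBG >= 2.2
(inclusive); for plotting, ratios below 1 are floored at 1 before log2.
Polyreactive (serum-blockable) binding is detected by re-running the panel
with the antibody diluted in negative-control serum and comparing
class-wise maxima.  Single-antigen-bead (SAB) results use sample trimmed
MFI > 1,000 for hit status and the sample-minus-negative-serum delta for
ranking; eplet sharing across an antibody's top hits is a plain set
intersection over an allele -> eplets table.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .errors import AnalysisError, FormatError

NBG_POSITIVE_THRESHOLD = 2.2


def read_bead_panel(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"bead_id", "bead_class", "S", "N"}
    if not required <= set(df.columns):
        raise FormatError(f"bead panel needs columns {sorted(required)}")
    return df


def compute_nbg(
    panel: pd.DataFrame, threshold: float = NBG_POSITIVE_THRESHOLD
) -> dict:
    """NBG ratios, positivity and class-wise maxima for one bead panel.

    The panel must contain exactly one ``negative_control`` row supplying
    S_0/N_0.  Beads with non-positive denominator (negative-serum signal
    not above the negative bead) are flagged invalid and excluded from the
    class maxima.  Returns ``{"beads": DataFrame, "class_max": dict,
    "threshold": float}``.
    """
    nc = panel[panel["bead_class"] == "negative_control"]
    if len(nc) != 1:
        raise AnalysisError(
            f"panel must contain exactly one negative_control bead, found {len(nc)}"
        )
    s0 = float(nc["S"].iloc[0])
    n0 = float(nc["N"].iloc[0])
    beads = panel[panel["bead_class"] != "negative_control"].copy()
    if (beads[["S", "N"]] < 0).to_numpy().any():
        raise AnalysisError("negative signal values in panel")

    denom = beads["N"].to_numpy(dtype=float) - n0
    valid = denom > 0
    nbg = np.full(len(beads), np.nan)
    nbg[valid] = (beads["S"].to_numpy(dtype=float)[valid] - s0) / denom[valid]
    beads["nbg"] = nbg
    beads["valid"] = valid
    beads["positive"] = valid & (nbg >= threshold)
    beads["log2_floored"] = np.where(
        valid, np.log2(np.maximum(nbg, 1.0)), np.nan
    )

    class_max = {}
    for cls, sub in beads[beads["valid"]].groupby("bead_class"):
        class_max[cls] = float(sub["nbg"].max())
    return {"beads": beads, "class_max": class_max, "threshold": threshold}


def serum_block_compare(pbs: dict, blocked: dict) -> pd.DataFrame:
    """Pair the PBS and serum-blocked runs of one antibody.

    Panels must cover the same beads.  Reports per bead class the paired
    maxima and a ``lost_binding`` flag: positive in PBS (class max >=
    threshold) and negative when serum-blocked.
    """
    b_p, b_s = pbs["beads"], blocked["beads"]
    if set(b_p["bead_id"]) != set(b_s["bead_id"]):
        raise AnalysisError("PBS and blocked panels cover different beads")
    thr = pbs["threshold"]
    rows = []
    for cls in sorted(set(b_p["bead_class"])):
        mp = pbs["class_max"].get(cls, np.nan)
        ms = blocked["class_max"].get(cls, np.nan)
        pos_p = (not math.isnan(mp)) and mp >= thr
        pos_s = (not math.isnan(ms)) and ms >= thr
        rows.append(
            {
                "bead_class": cls,
                "max_nbg_pbs": mp,
                "max_nbg_blocked": ms,
                "positive_pbs": pos_p,
                "positive_blocked": pos_s,
                "lost_binding": pos_p and not pos_s,
            }
        )
    return pd.DataFrame(rows).set_index("bead_class")


def sab_call(
    sab: pd.DataFrame, mfi_min: float = 1000.0, top_n: int = 10
) -> dict:
    """Single-antigen-bead calls for one antibody.

    ``sab`` needs columns ``allele``, ``sample_mfi``, ``negative_mfi``
    (trimmed MFI).  A hit is sample trimmed MFI strictly above ``mfi_min``;
    ranking is by delta = sample - negative, descending, ties broken by
    allele name.  Returns ``{"table": DataFrame, "top_hits": list,
    "any_hit": bool}``.
    """
    required = {"allele", "sample_mfi", "negative_mfi"}
    if not required <= set(sab.columns):
        raise FormatError(f"SAB table needs columns {sorted(required)}")
    if sab["allele"].duplicated().any():
        raise AnalysisError("duplicate allele rows in SAB table")
    out = sab.copy()
    out["delta"] = out["sample_mfi"] - out["negative_mfi"]
    out["hit"] = out["sample_mfi"] > mfi_min
    out = out.sort_values(["delta", "allele"],
                          ascending=[False, True]).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    top = list(out["allele"].head(top_n))
    return {"table": out, "top_hits": top, "any_hit": bool(out["hit"].any())}


def read_eplet_table(path: str | Path) -> dict[str, set[str]]:
    """allele,eplets CSV (eplets semicolon-separated) -> dict of sets."""
    df = pd.read_csv(path)
    return {
        row.allele: {e for e in str(row.eplets).split(";") if e}
        for row in df.itertuples(index=False)
    }


def eplet_overlap(
    alleles: list[str], table: dict[str, set[str]]
) -> dict:
    """Eplets shared by *all* the given alleles, globally and per locus.

    The locus is the allele-name prefix before '*' (A, B, C, DRB1, ...).
    Alleles absent from the table are reported, not silently dropped.
    Returns ``{"shared": set, "per_locus": {locus: set}, "uncovered": list,
    "any_shared": bool}``.
    """
    if len(alleles) < 2:
        raise AnalysisError("eplet overlap needs at least 2 alleles")
    covered = [a for a in alleles if a in table]
    uncovered = [a for a in alleles if a not in table]
    shared: set[str] = (
        set.intersection(*(table[a] for a in covered)) if covered else set()
    )
    per_locus: dict[str, set[str]] = {}
    loci = {a.split("*")[0] for a in covered}
    for locus in sorted(loci):
        la = [a for a in covered if a.split("*")[0] == locus]
        if len(la) >= 2:
            per_locus[locus] = set.intersection(*(table[a] for a in la))
    return {
        "shared": shared,
        "per_locus": per_locus,
        "uncovered": uncovered,
        "any_shared": bool(shared),
    }


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def reactivity_frequency(
    calls: pd.Series | dict[str, bool],
    groups: pd.Series | dict[str, str] | None = None,
    yates: bool = True,
) -> dict:
    """Reactivity frequencies per group with a 2-group chi-squared test.

    ``calls`` maps antibody -> positive/negative; ``groups`` maps antibody
    -> group label (one group when omitted).  Percentages are rounded half
    up to the nearest integer; exact fractions are retained.  With exactly
    two groups a chi-squared test on the 2x2 table is run (Yates continuity
    correction by default; the choice is recorded in the output).
    """
    calls = pd.Series(calls, dtype=bool)
    if calls.empty:
        raise AnalysisError("no antibody calls provided")
    if groups is None:
        groups = pd.Series("all", index=calls.index)
    else:
        groups = pd.Series(groups).reindex(calls.index)

    rows = []
    for g, sub in calls.groupby(groups):
        n = len(sub)
        if n == 0:
            raise AnalysisError(f"group {g!r} is empty")
        k = int(sub.sum())
        rows.append(
            {"group": g, "k_positive": k, "n": n, "fraction": k / n,
             "percent": round_half_up(100.0 * k / n)}
        )
    table = pd.DataFrame(rows).set_index("group")

    result = {"table": table, "yates": yates}
    if len(table) == 2:
        cont = np.array(
            [
                [table["k_positive"].iloc[0], table["n"].iloc[0] - table["k_positive"].iloc[0]],
                [table["k_positive"].iloc[1], table["n"].iloc[1] - table["k_positive"].iloc[1]],
            ]
        )
        if table["k_positive"].sum() in (0, table["n"].sum()):
            # degenerate table: identical all-negative / all-positive groups
            result.update(chi2_statistic=0.0, p_value=1.0)
        else:
            chi2, p, _, _ = chi2_contingency(cont, correction=yates)
            result.update(chi2_statistic=float(chi2), p_value=float(p))
    return result
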