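"""Heavy-chain repertoire analysis: clonal families, mutation burden,
cross-compartment overlap and per-patient tallies.

Records follow the AIRR Rearrangement TSV dialect (``v_call``, ``d_call``,
``j_call``, ``junction_aa``, ...) extended with ``patient``,
``compartment`` (bcell / plasma), ``isotype``, ``switch_state`` and
``mutation_count`` columns.  A clonal family is the set of records from
one patient sharing V, D and J gene usage (allele suffixes stripped) and
CDR3 length; a family of two or more records is "expanded".
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AnalysisError

VALID_NT = set("ACGT")


def read_airr(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "mutation_count" in df.columns:
        df["mutation_count"] = pd.to_numeric(df["mutation_count"])
    if "cdr3_length" in df.columns:
        df["cdr3_length"] = pd.to_numeric(df["cdr3_length"])
    return df


def strip_allele(call) -> str:
    """Gene-level identifier: text before the '*' allele suffix."""
    if call is None or (isinstance(call, float) and np.isnan(call)):
        return ""
    return str(call).split("*")[0].strip()


def _cdr3_len(row: pd.Series, unit: str) -> int:
    if unit == "aa":
        if "cdr3_length" in row and not pd.isna(row["cdr3_length"]):
            return int(row["cdr3_length"])
        return len(str(row["junction_aa"]))
    if unit == "nt":
        if "junction" in row and isinstance(row["junction"], str):
            return len(row["junction"])
        return 3 * _cdr3_len(row, "aa")
    raise AnalysisError(f"unknown CDR3 unit {unit!r}")


def assign_clonal_families(
    records: pd.DataFrame, cdr3_unit: str = "aa"
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Partition records into clonal families within each patient.

    The clonal key is (patient, V gene, D gene, J gene, CDR3 length); a
    missing D call becomes ``"none"`` and matches only other D-less
    records.  Records lacking a V or J call are excluded with a reason.
    Family ids are deterministic: sorted by key, ``<patient>_CF<k>``.

    Returns ``(records with clone_id column, family table, excluded records)``.
    """
    req = {"v_call", "j_call", "patient"}
    missing_cols = req - set(records.columns)
    if missing_cols:
        raise AnalysisError(f"missing required columns: {sorted(missing_cols)}")

    recs = records.copy().reset_index(drop=True)
    v = recs["v_call"].map(strip_allele)
    j = recs["j_call"].map(strip_allele)
    d = (recs["d_call"].map(strip_allele) if "d_call" in recs.columns
         else pd.Series("", index=recs.index))
    d = d.replace("", "none").fillna("none")
    cdr3 = recs.apply(lambda r: _cdr3_len(r, cdr3_unit), axis=1)

    ok = (v != "") & (j != "")
    excluded = recs[~ok].copy()
    excluded["exclusion_reason"] = np.where(
        v[~ok] == "", "missing_v_call", "missing_j_call"
    )

    keys = pd.DataFrame(
        {"patient": recs["patient"], "v": v, "d": d, "j": j, "cdr3_length": cdr3}
    )[ok]
    uniq = keys.drop_duplicates().sort_values(
        ["patient", "v", "d", "j", "cdr3_length"]
    )
    fam_ids = {}
    counters: dict[str, int] = {}
    for row in uniq.itertuples(index=False):
        n = counters.get(row.patient, 0) + 1
        counters[row.patient] = n
        fam_ids[tuple(row)] = f"{row.patient}_CF{n:03d}"

    recs["clone_id"] = None
    recs.loc[ok, "clone_id"] = [
        fam_ids[tuple(r)] for r in keys.itertuples(index=False)
    ]

    fam_rows = []
    for key, fid in fam_ids.items():
        members = recs.index[(recs["clone_id"] == fid)]
        sub = recs.loc[members]
        fam_rows.append(
            {
                "clone_id": fid,
                "patient": key[0],
                "v_call": key[1],
                "d_call": key[2],
                "j_call": key[3],
                "cdr3_length": key[4],
                "size": len(members),
                "expanded": len(members) >= 2,
                "spans_compartments": (
                    sub["compartment"].nunique() > 1
                    if "compartment" in sub.columns
                    else False
                ),
            }
        )
    fam_cols = ["clone_id", "patient", "v_call", "d_call", "j_call",
                "cdr3_length", "size", "expanded", "spans_compartments"]
    families = (
        pd.DataFrame(fam_rows, columns=fam_cols).set_index("clone_id").sort_index()
    )
    return recs, families, excluded


def clonal_overlap(families: pd.DataFrame, records: pd.DataFrame) -> pd.DataFrame:
    """Per-patient families present in both the plasma and B-cell compartments."""
    if "compartment" not in records.columns:
        raise AnalysisError("records need a compartment column")
    rows = []
    for fid, fam in families.iterrows():
        comps = set(records.loc[records["clone_id"] == fid, "compartment"])
        if {"plasma", "bcell"} <= comps:
            rows.append({"patient": fam["patient"], "clone_id": fid,
                         "size": fam["size"]})
    out = pd.DataFrame(rows, columns=["patient", "clone_id", "size"])
    return out.sort_values(["patient", "clone_id"]).reset_index(drop=True)


def mutation_summary(
    records: pd.DataFrame,
    group_by: tuple[str, ...] = ("tissue", "switch_state"),
    high_threshold: int = 60,
) -> pd.DataFrame:
    """Mutation-burden distribution per group.

    Reports n, median, quartiles and the number of records with
    mutation_count strictly above ``high_threshold`` (default 60).
    """
    cols = [c for c in group_by if c in records.columns]
    if "mutation_count" not in records.columns:
        raise AnalysisError("records need a mutation_count column")
    if not cols:
        groups = [(("all",), records)]
    else:
        groups = records.groupby(list(cols), sort=True)
    rows = []
    for key, sub in groups:
        m = sub["mutation_count"].to_numpy(dtype=float)
        key = key if isinstance(key, tuple) else (key,)
        rows.append(
            dict(
                zip(cols or ["group"], key),
                n=len(m),
                median=float(np.median(m)),
                q1=float(np.percentile(m, 25)),
                q3=float(np.percentile(m, 75)),
                n_high_mutation=int((m > high_threshold).sum()),
            )
        )
    return pd.DataFrame(rows)


def recount_mutations(sequence: str, germline: str) -> int:
    """Nucleotide mismatches between an aligned sequence and its germline.

    Positions where either character is a gap or an N are ignored; the
    strings must be equal length.
    """
    if len(sequence) != len(germline):
        raise AnalysisError(
            f"aligned lengths differ: {len(sequence)} vs {len(germline)}"
        )
    n = 0
    for a, b in zip(sequence.upper(), germline.upper()):
        if a in VALID_NT and b in VALID_NT and a != b:
            n += 1
    return n


def repertoire_tally(
    records: pd.DataFrame, families: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-patient switched / unswitched / total counts, plus expanded
    clonal families when a family table is supplied.  The final column is
    the row-wise total."""
    if "switch_state" not in records.columns:
        raise AnalysisError("records need a switch_state column")
    tab = pd.crosstab(records["switch_state"], records["patient"])
    tab = tab.reindex(["switched", "unswitched"]).fillna(0).astype(int)
    tab.loc["total_sequenced"] = tab.sum(axis=0)
    if families is not None:
        exp = families[families["expanded"]].groupby("patient").size()
        tab.loc["expanded_clonal_families"] = (
            exp.reindex(tab.columns).fillna(0).astype(int)
        )
    tab["Total"] = tab.sum(axis=1)
    return tab


def isotype_tally(records: pd.DataFrame) -> pd.DataFrame:
    """Per-patient isotype counts with a row and column total."""
    if "isotype" not in records.columns:
        raise AnalysisError("records need an isotype column")
    tab = pd.crosstab(records["isotype"], records["patient"]).astype(int)
    tab.loc["Total"] = tab.sum(axis=0)
    tab["Total"] = tab.sum(axis=1)
    return tab
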