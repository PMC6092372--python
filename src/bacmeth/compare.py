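"""Cross-condition methylome comparison.

Combines per-condition occurrence-status tables over one shared occurrence
universe into three classes — conserved methylated (detected in every
condition), conserved unmethylated (detected in none; "protected" sites,
presumably occluded by DNA-binding proteins) and differential (anything in
between) — and provides pairwise mark-difference counting, fraction-stability
statistics (coefficient of variation) and the Dam-overexpression rescue
bookkeeping for protected sites.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Columns identifying one occurrence across condition tables.
OCC_KEY = ["motif", "contig", "methylated_position", "methylated_strand"]

CLASSES = ("conserved_methylated", "differential", "conserved_unmethylated")


def _check_universe(tables: Mapping[str, pd.DataFrame]) -> list[pd.DataFrame]:
    if not tables:
        raise ValueError("need at least one condition")
    frames = [t.sort_values(OCC_KEY).reset_index(drop=True) for t in tables.values()]
    ref = frames[0][OCC_KEY]
    for f in frames[1:]:
        if len(f) != len(ref) or not f[OCC_KEY].equals(ref):
            raise ValueError("condition tables cover different occurrence universes")
    return frames


def classify_across(tables: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Partition occurrences by how many conditions detected them.

    *tables* maps condition-id -> occurrence-status table (as produced by
    ``smrt.assign_calls`` / ``wgbs.assign_m5c``) over one shared universe.
    Returns one row per occurrence with n_conditions_detected and class.
    Occurrences with no qualifying call count as not-detected; a has_data
    column flags whether any condition carried a call at the site.
    """
    frames = _check_universe(tables)
    out = frames[0][OCC_KEY].copy()
    det = np.column_stack([f["detected"].to_numpy(bool) for f in frames])
    n_cond = det.shape[1]
    n_det = det.sum(axis=1)
    out["n_conditions_detected"] = n_det
    out["n_conditions"] = n_cond
    out["class"] = np.where(
        n_det == n_cond,
        "conserved_methylated",
        np.where(n_det == 0, "conserved_unmethylated", "differential"),
    )
    has_cov = np.column_stack(
        [f["coverage"].notna().to_numpy() | f["detected"].to_numpy(bool)
         for f in frames]
    )
    out["has_data"] = has_cov.any(axis=1)
    return out


def class_counts(classes: pd.DataFrame) -> pd.DataFrame:
    """Per-motif counts and percentages of the three cross-condition classes."""
    rows = []
    for motif, grp in classes.groupby("motif", sort=True):
        counts = grp["class"].value_counts()
        total = len(grp)
        row = {"motif": motif, "n_total": total}
        for cls in CLASSES:
            n = int(counts.get(cls, 0))
            row[cls] = n
            row[f"pct_{cls}"] = 100.0 * n / total if total else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def diff_pair(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    partner_pools: Mapping[str, str] | None = None,
) -> tuple[int, pd.Series, pd.DataFrame]:
    """Count occurrences whose detected flag differs between two conditions.

    Returns (total differing marks, per-motif breakdown, site list). The count
    is symmetric in the two arguments. *partner_pools* optionally maps motif
    names to a pooled label (e.g. both bipartite partner strings to one
    "motif III" group); the pooled breakdown is returned alongside the
    per-string one in the Series index.
    """
    a = table_a.sort_values(OCC_KEY).reset_index(drop=True)
    b = table_b.sort_values(OCC_KEY).reset_index(drop=True)
    if len(a) != len(b) or not a[OCC_KEY].equals(b[OCC_KEY]):
        raise ValueError("condition tables cover different occurrence universes")
    differ = a["detected"].to_numpy(bool) != b["detected"].to_numpy(bool)
    sites = a.loc[differ, OCC_KEY].copy()
    sites["detected_a"] = a.loc[differ, "detected"].to_numpy()
    sites["detected_b"] = b.loc[differ, "detected"].to_numpy()
    per_motif = sites.groupby("motif").size()
    # re-key over all motifs present in the universe so zeros are explicit
    per_motif = per_motif.reindex(sorted(a["motif"].unique()), fill_value=0)
    if partner_pools:
        pooled = (
            per_motif.groupby(
                [partner_pools.get(m, m) for m in per_motif.index]
            ).sum()
        )
        per_motif = pd.concat([per_motif, pooled[~pooled.index.isin(per_motif.index)]])
    return int(differ.sum()), per_motif, sites.reset_index(drop=True)


def stability_cv(summaries: pd.DataFrame) -> pd.Series:
    """Per-motif coefficient of variation of the detected fraction across
    conditions (population SD / mean). Requires >= 2 conditions per motif;
    a zero mean yields NaN (flagged as undefined)."""
    out = {}
    for motif, grp in summaries.groupby("motif", sort=True):
        fr = grp["fraction"].to_numpy(float)
        if len(fr) < 2:
            raise ValueError(f"motif {motif!r}: need >= 2 conditions for CV")
        mean = fr.mean()
        out[motif] = np.nan if mean == 0 else fr.std(ddof=0) / mean
    return pd.Series(out, name="cv")


def protected_sites(classes: pd.DataFrame, motif: str | None = None) -> pd.DataFrame:
    """Conserved-unmethylated occurrences (optionally restricted to one motif)."""
    sel = classes[classes["class"] == "conserved_unmethylated"]
    if motif is not None:
        sel = sel[sel["motif"] == motif]
    return sel.reset_index(drop=True)


def dam_rescue(
    protected: pd.DataFrame, dam_table: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split protected sites by their state in a Dam-overexpression condition.

    Returns (rescued, still_unmethylated): sites detected / not detected in
    the Dam+ condition. The two lists are disjoint and together cover the
    protected set.
    """
    dam = dam_table.set_index(
        ["motif", "contig", "methylated_position", "methylated_strand"]
    )
    keys = pd.MultiIndex.from_frame(protected[OCC_KEY])
    missing = keys.difference(dam.index)
    if len(missing):
        raise ValueError("protected sites absent from the Dam+ universe")
    det = dam.loc[keys, "detected"].to_numpy(bool)
    rescued = protected[det].reset_index(drop=True)
    still = protected[~det].reset_index(drop=True)
    return rescued, still


def total_marks(summaries: pd.DataFrame, motifs: Sequence[str] | None = None,
                condition: str | None = None) -> int:
    """Sum of n_detected over (a subset of) motif rows — the bookkeeping
    identity behind genome-wide modification-mark totals."""
    df = summaries
    if motifs is not None:
        df = df[df["motif"].isin(motifs)]
    if condition is not None:
        df = df[df["condition"] == condition]
    return int(df["n_detected"].sum())
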