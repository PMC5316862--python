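"""miRNA seed-family aggregation, polysome-shift ddCt, and ATP-linked OCR.

Seed families group miRNAs sharing nucleotides 2-8 of the mature sequence
(the 7-mer seed), hence largely overlapping target repertoires.  Family
statistics here treat the family as a pooled transcript: the cumulative
fold change is the log2 ratio of summed member means between groups, and
the pool contribution is the family's share of total miRNA counts.

Ct tables use long format with columns ``role`` ("target"/"reference"),
``condition`` ("treated"/"control") and ``ct``.  The ddCt displacement is
(target - reference) in treated minus the same in control; a positive value
means the target lost abundance in the assayed fraction under treatment.
OCR traces are long tables with ``phase`` and ``ocr``; ATP-linked OCR is
mean basal minus mean post-oligomycin OCR.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

_GROUP_PREFIXES = ("control", "disease")


def _group_columns(table: pd.DataFrame, group: str) -> list[str]:
    cols = [c for c in table.columns if c.startswith(f"{group}_")]
    if not cols:
        raise ValueError(f"no count columns found for group {group!r}")
    return cols


def assign_seed_family(
    table: pd.DataFrame, name_map: dict[str, str] | None = None
) -> pd.DataFrame:
    """Annotate a count table with 7-mer seeds and seed-family ids.

    The seed is positions 2-8 (1-based) of ``mature_sequence``; two miRNAs
    share a family iff their seeds are identical.  ``family_id`` is the
    seed string itself unless ``name_map`` supplies a friendlier name
    (e.g. ``{"AAAGUGC": "miR-17"}``).  Sequences shorter than 8 nt cannot
    carry a seed and are flagged with a missing family id.
    """
    out = table.copy()
    seqs = out["mature_sequence"].astype(str).str.upper().str.replace("T", "U")
    seeds = seqs.str.slice(1, 8)
    seeds = seeds.where(seqs.str.len() >= 8, other=pd.NA)
    out["seed_7mer"] = seeds
    if name_map:
        out["family_id"] = seeds.map(lambda s: name_map.get(s, s) if pd.notna(s) else pd.NA)
    else:
        out["family_id"] = seeds
    return out


def _family_rows(table: pd.DataFrame, family_id: str) -> pd.DataFrame:
    if "family_id" not in table.columns:
        raise ValueError("table has no family_id column; run assign_seed_family first")
    return table[table["family_id"] == family_id]


def family_cumulative_fold_change(
    table: pd.DataFrame,
    family_id: str,
    members: str = "significant_only",
    method: str = "pooled",
) -> float:
    """Cumulative log2 fold change of one seed family.

    With the default ``method="pooled"`` this is
    ``log2(sum of member disease means / sum of member control means)`` --
    the fold change of the family treated as one pooled transcript, which
    stays well defined when members differ in abundance.
    ``method="sum_log2fc"`` instead sums the members' individual log2 fold
    changes (provided for comparison).  ``members`` selects
    ``"significant_only"`` rows (``significant`` column truthy) or
    ``"all_expressed"``.
    """
    if members not in ("significant_only", "all_expressed"):
        raise ValueError("members must be 'significant_only' or 'all_expressed'")
    if method not in ("pooled", "sum_log2fc"):
        raise ValueError("method must be 'pooled' or 'sum_log2fc'")
    rows = _family_rows(table, family_id)
    if members == "significant_only":
        rows = rows[rows["significant"].astype(bool)]
    if rows.empty:
        raise ValueError(f"family {family_id!r} has no eligible members")
    if method == "sum_log2fc":
        return float(rows["log2_fc"].sum())
    ctrl = rows[_group_columns(rows, "control")].to_numpy(float).mean(axis=1).sum()
    dis = rows[_group_columns(rows, "disease")].to_numpy(float).mean(axis=1).sum()
    if ctrl <= 0:
        raise ValueError(f"family {family_id!r} has zero control total")
    return float(np.log2(dis / ctrl))


def family_pool_contribution(table: pd.DataFrame, family_id: str, group: str) -> float:
    """Percent of the total miRNA pool contributed by one family in one group.

    ``100 * (sum of the family's member mean counts) / (sum of all
    miRNAs' mean counts)`` in the chosen group ("control" or "disease").
    A family absent from the table contributes 0.
    """
    if group not in _GROUP_PREFIXES:
        raise ValueError(f"group must be one of {_GROUP_PREFIXES}")
    cols = _group_columns(table, group)
    means = table[cols].to_numpy(float).mean(axis=1)
    total = means.sum()
    if total <= 0:
        raise ValueError(f"group {group!r} has zero total counts")
    fam = means[(table["family_id"] == family_id).to_numpy()]
    return float(100.0 * fam.sum() / total)


def summarize_families(table: pd.DataFrame) -> pd.DataFrame:
    """Per-family summary: member counts, cumulative fold changes, pool shares."""
    rows = []
    for fam_id, fam in table.groupby("family_id", dropna=True):
        n_sig = int(fam["significant"].astype(bool).sum())
        rows.append(
            {
                "family_id": fam_id,
                "seed_7mer": fam["seed_7mer"].iloc[0] if "seed_7mer" in fam else pd.NA,
                "n_members_total": len(fam),
                "n_members_significant": n_sig,
                "cumulative_log2_fc_sig": (
                    family_cumulative_fold_change(table, fam_id, "significant_only")
                    if n_sig
                    else math.nan
                ),
                "cumulative_log2_fc_all": family_cumulative_fold_change(
                    table, fam_id, "all_expressed"
                ),
                "pool_pct_control": family_pool_contribution(table, fam_id, "control"),
                "pool_pct_disease": family_pool_contribution(table, fam_id, "disease"),
            }
        )
    return pd.DataFrame(rows).sort_values("pool_pct_disease", ascending=False, ignore_index=True)


def cross_model_correlation(fc_a: pd.Series, fc_b: pd.Series) -> float:
    """R^2 between two per-miRNA log2 fold-change vectors.

    Computed as the squared Pearson correlation over the intersection of
    miRNA ids with finite values in both vectors; needs at least 3 shared
    miRNAs.  Returns NaN (with a warning) when either vector is constant.
    """
    a = pd.Series(fc_a).dropna()
    b = pd.Series(fc_b).dropna()
    shared = a.index.intersection(b.index)
    x = a.loc[shared].to_numpy(float)
    y = b.loc[shared].to_numpy(float)
    finite = np.isfinite(x) & np.isfinite(y)
    x, y = x[finite], y[finite]
    if x.size < 3:
        raise ValueError("need >= 3 shared miRNAs with finite fold changes")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("zero variance in a fold-change vector; R^2 undefined")
        return math.nan
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def mipsa_displacement(table: pd.DataFrame) -> float:
    """Polysome-shift displacement in log2 units via the ddCt method.

    ``dCt(cond) = mean Ct(target, cond) - mean Ct(reference, cond)``;
    displacement ``= dCt(treated) - dCt(control)``.  Positive values mean
    the target was lost from the assayed (high-molecular-weight polysome)
    fraction under treatment.  A reference-gene shift common to both
    conditions cancels exactly.
    """
    dct = {}
    for condition in ("treated", "control"):
        cell = {}
        for role in ("target", "reference"):
            sel = table[(table["role"] == role) & (table["condition"] == condition)]
            if sel.empty:
                raise ValueError(f"missing Ct values for {role} / {condition}")
            cell[role] = float(sel["ct"].mean())
        dct[condition] = cell["target"] - cell["reference"]
    return dct["treated"] - dct["control"]


def atp_linked_ocr(trace: pd.DataFrame) -> float:
    """ATP-linked OCR: mean basal OCR minus mean post-oligomycin OCR.

    Oligomycin blocks ATP synthase, so the OCR drop it causes is the
    respiration that was driving ATP synthesis.  A negative result (post-
    oligomycin above basal) is returned as-is with a warning.
    """
    phases = trace["phase"]
    basal = trace.loc[phases == "basal", "ocr"]
    oligo = trace.loc[phases == "oligomycin", "ocr"]
    if basal.empty or oligo.empty:
        raise ValueError("trace must contain basal and oligomycin measurements")
    value = float(basal.mean() - oligo.mean())
    if value < 0:
        warnings.warn("post-oligomycin OCR exceeds basal; ATP-linked OCR is negative")
    return value
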