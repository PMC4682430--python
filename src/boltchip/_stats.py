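"""Shared differential-calling core for the expression and methylation arrays.

Both platforms call differential features the same way: a two-sample t-test on
log2 values between the sensitive (S) and resistant (R) genotype groups,
combined with a fold-change gate, optionally with Benjamini-Hochberg
adjustment. The expression and methylation front-ends differ only in their
direction labels and significance tiers, so the table-building logic lives
here once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


class StatsError(ValueError):
    pass


def split_groups(design: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Sample ids of the S and R conditions, in design order."""
    required = {"sample_id", "condition"}
    if not required.issubset(design.columns):
        raise StatsError(f"design table needs columns {sorted(required)}")
    s = design.loc[design["condition"] == "S", "sample_id"].tolist()
    r = design.loc[design["condition"] == "R", "sample_id"].tolist()
    if not s or not r:
        raise StatsError("both conditions (R and S) must have samples")
    return s, r


def differential_table(
    values: pd.DataFrame,
    design: pd.DataFrame,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
    adjust: str = "bh",
    equal_var: bool = True,
    label_high: str = "up_in_S",
    label_low: str = "up_in_R",
) -> pd.DataFrame:
    """Per-row S-vs-R differential test on a log2 value matrix.

    Parameters
    ----------
    values
        Rows are sequences/probes, columns are sample ids, entries are log2
        values (normalized signals or log ratios). NaN entries are omitted
        row-wise from the test.
    design
        Table with ``sample_id`` and ``condition`` (R/S) columns.
    fc_threshold
        Linear fold-change gate; a row is significant only if
        ``2**|mean_S - mean_R| >= fc_threshold``.
    alpha, adjust
        Significance level and whether it applies to BH-adjusted (``"bh"``)
        or raw (``"none"``) p-values. Adjusted p-values are reported either way.
    equal_var
        Pooled-variance (True) or Welch (False) t-test.

    Returns a DataFrame indexed like ``values`` with columns mean_S, mean_R,
    delta_log2, fold_change, t_stat, p_raw, p_adj, direction, significant.
    """
    if adjust not in ("bh", "none"):
        raise StatsError(f"unknown adjustment {adjust!r}")
    s_ids, r_ids = split_groups(design)
    if len(s_ids) < 2 or len(r_ids) < 2:
        raise StatsError("need >= 2 replicates per condition for the t-test")
    missing = [c for c in s_ids + r_ids if c not in values.columns]
    if missing:
        raise StatsError(f"samples missing from the value matrix: {missing}")

    s_vals = values[s_ids].to_numpy(dtype=float)
    r_vals = values[r_ids].to_numpy(dtype=float)
    mean_s = np.nanmean(s_vals, axis=1)
    mean_r = np.nanmean(r_vals, axis=1)
    delta = mean_s - mean_r

    with np.errstate(invalid="ignore", divide="ignore"):
        t_stat, p_raw = stats.ttest_ind(
            s_vals, r_vals, axis=1, equal_var=equal_var, nan_policy="omit"
        )
    t_stat = np.asarray(t_stat, dtype=float)
    p_raw = np.asarray(p_raw, dtype=float)
    # Zero within-group variance in both groups: equal means are a clean
    # "no evidence" case (p = 1); unequal means with zero variance are an
    # infinitely strong difference (p = 0).
    degenerate = ~np.isfinite(p_raw)
    if degenerate.any():
        equal = np.isclose(delta, 0.0) | ~np.isfinite(delta)
        p_raw[degenerate & equal] = 1.0
        t_stat[degenerate & equal] = 0.0
        p_raw[degenerate & ~equal] = 0.0
        t_stat[degenerate & ~equal] = np.sign(delta[degenerate & ~equal]) * np.inf

    p_adj = np.full_like(p_raw, np.nan)
    ok = np.isfinite(p_raw)
    if ok.any():
        p_adj[ok] = multipletests(p_raw[ok], method="fdr_bh")[1]

    fold_change = 2.0 ** np.abs(delta)
    direction = np.where(delta >= 0, label_high, label_low)
    p_gate = p_adj if adjust == "bh" else p_raw
    significant = (fold_change >= fc_threshold) & (p_gate < alpha)

    return pd.DataFrame(
        {
            "mean_S": mean_s,
            "mean_R": mean_r,
            "delta_log2": delta,
            "fold_change": fold_change,
            "t_stat": t_stat,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "direction": direction,
            "significant": significant,
        },
        index=values.index.rename("sequence_id"),
    )
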