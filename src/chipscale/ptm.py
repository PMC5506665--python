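"""Histone-PTM relative-abundance statistics from a peptide-species table.

Quantitative MS of histone H3 peptides yields, for each residue site
(H3K4, H3K9, H3K27, H3K36), the fraction of the peptide pool in each
modification state (me0/me1/me2/me3/ac) per replicate and condition.
This module compares conditions: per-state log2 ratios of condition
means, Welch two-sided t-tests across replicates, and a ranking by
effect size.  Upstream chromatographic peak integration is out of
scope; the input is the finished abundance table.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .genome import FormatError

logger = logging.getLogger("chipscale")

__all__ = [
    "load_ptm_table",
    "validate_ptm_table",
    "ptm_fractions",
    "compare_conditions",
]

SUM_TOL = 0.01  # per-site, per-replicate state fractions must sum to 1 +/- this

REQUIRED_COLUMNS = ["site", "state", "condition", "replicate", "abundance"]


def validate_ptm_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"PTM table missing columns: {missing}")
    if (table["abundance"] < 0).any():
        raise FormatError("PTM abundances must be non-negative")
    sums = table.groupby(["site", "condition", "replicate"])["abundance"].sum()
    bad = sums[(sums - 1.0).abs() > SUM_TOL]
    if len(bad):
        key = bad.index[0]
        raise FormatError(
            f"state fractions for {key} sum to {bad.iloc[0]:.4f}, expected 1 +/- {SUM_TOL}"
        )
    return table


def load_ptm_table(path: str | Path) -> pd.DataFrame:
    """Load and validate a PTM relative-abundance CSV.

    Columns: site, state, condition, replicate, abundance (fraction of
    the site's peptide pool).  Within each (site, condition, replicate)
    the state fractions must sum to 1 within tolerance.
    """
    return validate_ptm_table(pd.read_csv(path))


def ptm_fractions(table: pd.DataFrame, site: str, state: str) -> dict:
    """Replicate-level fractions and condition means (as percentages) for one cell."""
    sub = table[(table["site"] == site) & (table["state"] == state)]
    if sub.empty:
        raise KeyError(f"no rows for site={site!r} state={state!r}")
    out: dict = {}
    for cond, g in sub.groupby("condition"):
        pct = (g["abundance"] * 100).to_numpy()
        out[cond] = {"replicates_pct": pct, "mean_pct": float(pct.mean())}
    return out


def compare_conditions(
    table: pd.DataFrame,
    untreated: str = "untreated",
    treated: str = "treated",
) -> pd.DataFrame:
    """Per (site, state) condition comparison, ranked by |log2 ratio|.

    log2_ratio is the log2 of the ratio of condition means (treated over
    untreated); the mean of per-replicate ratios is reported alongside as
    ``mean_replicate_ratio``.  p-values are two-sided Welch t-tests across
    replicates (no multiple-testing correction, matching per-mark
    significance calls; a Benjamini-Hochberg column ``q_value`` is emitted
    for transparency).  With fewer than two replicates in either
    condition, p-values are omitted with a warning; ratios still reported.
    """
    validate_ptm_table(table)
    for cond in (untreated, treated):
        if cond not in set(table["condition"]):
            raise KeyError(f"condition {cond!r} not present in table")
    rows = []
    for (site, state), g in table.groupby(["site", "state"], sort=False):
        u = g.loc[g["condition"] == untreated, "abundance"].to_numpy()
        t = g.loc[g["condition"] == treated, "abundance"].to_numpy()
        mean_u, mean_t = float(u.mean()), float(t.mean())
        log2_ratio = float(np.log2(mean_t / mean_u)) if mean_u > 0 and mean_t > 0 else np.nan
        # diagnostic alternative aggregation: mean of per-replicate ratios
        # (defined only for equal replicate counts, paired by order)
        if len(u) == len(t) and (u > 0).all():
            mean_rep_ratio = float(np.mean(t / u))
        else:
            mean_rep_ratio = np.nan
        if len(u) >= 2 and len(t) >= 2:
            p = float(stats.ttest_ind(t, u, equal_var=False).pvalue)
        else:
            logger.warning(
                "%s %s: <2 replicates in a condition, p-value omitted", site, state
            )
            p = np.nan
        rows.append(
            {
                "site": site,
                "state": state,
                "mean_untreated": mean_u,
                "mean_treated": mean_t,
                "log2_ratio": log2_ratio,
                "mean_replicate_ratio": mean_rep_ratio,
                "n_untreated": len(u),
                "n_treated": len(t),
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows)
    # Benjamini-Hochberg over the valid p-values
    out["q_value"] = np.nan
    valid = out["p_value"].notna()
    if valid.any():
        out.loc[valid, "q_value"] = stats.false_discovery_control(
            out.loc[valid, "p_value"].to_numpy(), method="bh"
        )
    out = out.sort_values(
        "log2_ratio", key=lambda s: s.abs(), ascending=False, na_position="last"
    ).reset_index(drop=True)
    out["rank_abs_log2"] = np.arange(1, len(out) + 1)
    return out
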