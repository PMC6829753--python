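"""Non-CpG (mCH) methylation: global levels, the 12 CHN contexts, and the
mCH-expression relationship.

CH sites are strand-specific and never strand-merged; contexts are the 12
CHN trinucleotides (H = A/C/T; N = A/C/G/T excluding the CG dinucleotide at
the first position). CCG contains a CG at its second position and is treated
as a CG-adjacent context: it is displayed as its own axis but excluded from
the aggregate CHG mean by default (``ccg_in_chg`` restores the literal
trinucleotide classification). Sites enter the means only when covered at
least 10 times.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .genome import CH_CONTEXTS
from .io import ch_only, filter_by_coverage, levels

CHG_CONTEXTS = ("CAG", "CCG", "CTG")
CHH_CONTEXTS = tuple(c for c in CH_CONTEXTS if c not in CHG_CONTEXTS)


@dataclass
class ContextProfile:
    """Per-context mean mCH levels plus the aggregate CHG/CHH means."""

    context_levels: dict        # trinucleotide -> mean level (NaN if no sites)
    context_counts: dict        # trinucleotide -> site count entering the mean
    chg: float
    chh: float
    ccg_in_chg: bool = False

    def as_series(self) -> pd.Series:
        return pd.Series(self.context_levels).reindex(list(CH_CONTEXTS))

    def log2_percent(self) -> pd.Series:
        """log2 of the level in percent, for radar-style display axes."""
        s = self.as_series() * 100.0
        with np.errstate(divide="ignore"):
            return np.log2(s)


def mch_levels(sites: pd.DataFrame, min_coverage: int = 10,
               ccg_in_chg: bool = False) -> ContextProfile:
    """Unweighted per-context mean of CH site levels (coverage-filtered)."""
    ch = ch_only(filter_by_coverage(sites, ch_min=min_coverage))
    lv = levels(ch)
    ctx = ch["context"].to_numpy()
    context_levels, context_counts = {}, {}
    for c in CH_CONTEXTS:
        sel = ctx == c
        context_counts[c] = int(sel.sum())
        context_levels[c] = float(np.mean(lv[sel])) if sel.any() else float("nan")
    chg_set = CHG_CONTEXTS if ccg_in_chg else tuple(c for c in CHG_CONTEXTS
                                                    if c != "CCG")
    def agg(group):
        sel = np.isin(ctx, group)
        return float(np.mean(lv[sel])) if sel.any() else float("nan")
    return ContextProfile(context_levels, context_counts,
                          chg=agg(chg_set), chh=agg(CHH_CONTEXTS),
                          ccg_in_chg=ccg_in_chg)


def context_ranking(profile: ContextProfile) -> list:
    """Contexts by descending mean level; ties broken lexicographically."""
    s = profile.as_series()
    if s.isna().any():
        raise ValueError("profile incomplete: "
                         f"{sorted(s.index[s.isna()])} have no covered sites")
    return sorted(s.index, key=lambda c: (-s[c], c))


def mch_expression_correlation(feature_mch: pd.Series,
                               expression: pd.Series) -> dict:
    """Spearman correlation between per-gene mCH and expression.

    Both series are indexed by gene; the shared universe must hold >= 10
    genes. Degenerate (constant) inputs report NaN.
    """
    shared = feature_mch.index.intersection(expression.index)
    x = feature_mch.reindex(shared).to_numpy(float)
    y = expression.reindex(shared).to_numpy(float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 10:
        raise ValueError(f"shared gene universe too small ({len(x)} < 10)")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return {"rho": float("nan"), "p_value": float("nan"), "n": len(x)}
    rho, p = spearmanr(x, y)
    return {"rho": float(rho), "p_value": float(p), "n": len(x)}
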