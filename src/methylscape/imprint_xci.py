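"""Imprinted-DMR status and X-chromosome-inactivation classifiers.

Imprinted DMRs (iDMRs) normally sit at ~50% methylation because exactly one
parental allele is methylated; a sample-level call is "intermediate" inside a
configurable band (default [0.25, 0.75]), "hyper" above it and "hypo" below.

XCI calling works on TSS-proximal (TSS +/- 500 bp) methylation: a gene is a
candidate subject to XCI when male non-reprogrammed cells show <= 10% and
female non-reprogrammed cells 20-45% (the aggregate of an unmethylated active
and a methylated inactive allele). A candidate has escaped XCI in a
reprogrammed female lineage when its level drops to <= 5% in every
reprogrammed sample of that lineage. Escape-linked derepression is quantified
as log2((FPKM_a + c) / (FPKM_b + c)) with pseudocount c (default 0.01).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu


def idmr_status(idmr_levels: pd.DataFrame, intermediate_band=(0.25, 0.75)
                ) -> pd.DataFrame:
    """Per-iDMR, per-sample status from an iDMR x sample level matrix.

    Levels are fractions; NaN (no covered CpGs) yields "uncallable".
    """
    lo, hi = intermediate_band
    if not 0 <= lo < hi <= 1:
        raise ValueError("intermediate band must satisfy 0 <= lo < hi <= 1")
    vals = idmr_levels.to_numpy(float)
    status = np.where(np.isnan(vals), "uncallable",
                      np.where(vals > hi, "hyper",
                               np.where(vals < lo, "hypo", "intermediate")))
    return pd.DataFrame(status, index=idmr_levels.index,
                        columns=idmr_levels.columns)


def idmr_summary(status: pd.DataFrame) -> pd.DataFrame:
    """Counts and fractions of each status per sample (fractions of catalogue)."""
    n = len(status)
    rows = []
    for sample in status.columns:
        col = status[sample]
        rows.append({"sample": sample, "n_idmr": n,
                     "hyper": int((col == "hyper").sum()),
                     "hypo": int((col == "hypo").sum()),
                     "intermediate": int((col == "intermediate").sum()),
                     "uncallable": int((col == "uncallable").sum()),
                     "hyper_pct": 100.0 * (col == "hyper").sum() / n if n else 0.0})
    return pd.DataFrame(rows).set_index("sample")


def xci_candidates(tss_levels: pd.DataFrame, female_samples: Sequence[str],
                   male_samples: Sequence[str], male_max: float = 0.10,
                   female_band=(0.20, 0.45)) -> pd.DataFrame:
    """Classify X-linked genes as subject to XCI from non-reprogrammed samples.

    ``tss_levels`` is gene x sample TSS-region methylation (NaN = not enough
    coverage). A gene is callable when both group means exist; "XCI-subject"
    requires male mean <= male_max and female mean within female_band
    (inclusive bounds).
    """
    if not len(female_samples) or not len(male_samples):
        raise ValueError("need at least one female and one male sample")
    fmean = tss_levels[list(female_samples)].mean(axis=1)
    mmean = tss_levels[list(male_samples)].mean(axis=1)
    callable_ = ~(fmean.isna() | mmean.isna())
    lo, hi = female_band
    subject = callable_ & (mmean <= male_max) & (fmean >= lo) & (fmean <= hi)
    status = np.where(~callable_, "uncallable",
                      np.where(subject, "XCI-subject", "not-XCI"))
    out = pd.DataFrame({"gene": tss_levels.index, "male_mean": mmean.to_numpy(),
                        "female_mean": fmean.to_numpy(), "status": status})
    return out.set_index("gene")


def xci_subject_fraction(calls: pd.DataFrame) -> tuple[int, int, float]:
    """(n_subject, n_callable, percent subject among callable X-linked genes)."""
    callable_ = calls["status"] != "uncallable"
    n_call = int(callable_.sum())
    n_subj = int((calls["status"] == "XCI-subject").sum())
    return n_subj, n_call, (100.0 * n_subj / n_call if n_call else 0.0)


def xci_escape(calls: pd.DataFrame, reprogrammed_levels: pd.DataFrame,
               escape_max: float = 0.05, require_all: bool = True
               ) -> pd.DataFrame:
    """Escape calls for XCI-subject genes in one reprogrammed female lineage.

    ``reprogrammed_levels`` is gene x reprogrammed-sample TSS methylation.
    Escape requires level <= escape_max in ALL listed samples (the any-sample
    mode is available but off by default).
    """
    subjects = calls.index[calls["status"] == "XCI-subject"]
    if len(subjects) == 0:
        raise ValueError("no XCI-subject candidates to evaluate")
    lv = reprogrammed_levels.reindex(subjects)
    below = lv.le(escape_max)
    escaped = below.all(axis=1) if require_all else below.any(axis=1)
    escaped &= ~lv.isna().any(axis=1)
    out = calls.loc[subjects].copy()
    out["status"] = np.where(escaped, "XCI-escaped", "XCI-subject")
    for col in lv.columns:
        out[f"level_{col}"] = lv[col]
    return out


def expression_ratio(fpkm: pd.DataFrame, sample_a: str, sample_b: str,
                     pseudocount: float = 0.01) -> pd.Series:
    """Per-gene log2((FPKM_a + c) / (FPKM_b + c))."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    return np.log2((fpkm[sample_a] + pseudocount)
                   / (fpkm[sample_b] + pseudocount)).rename("log2_ratio")


def escape_derepression_test(ratios: pd.Series, escaped_genes: Sequence[str],
                             subject_genes: Sequence[str]) -> dict:
    """Rank-sum comparison of expression ratios: escaped vs still-subject genes."""
    a = ratios.reindex([g for g in escaped_genes if g in ratios.index]).dropna()
    b = ratios.reindex([g for g in subject_genes if g in ratios.index]).dropna()
    res = mannwhitneyu(a.to_numpy(), b.to_numpy(), alternative="two-sided")
    return {"escaped_median_log2": float(a.median()),
            "subject_median_log2": float(b.median()),
            "p_value": float(res.pvalue),
            "n_escaped": len(a), "n_subject": len(b)}
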