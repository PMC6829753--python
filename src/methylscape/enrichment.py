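"""Exact-test utilities: Fisher set overlap and GO-style gene-set enrichment.

Gene-set enrichment uses the classic per-term Fisher test with the standard
reporting filters: terms annotating fewer than 10 or more than 500 genes are
removed before testing, and a term is reported when p < 0.01 with an overlap
of at least 3 genes. Benjamini-Hochberg adjusted p-values are exported
alongside, but reporting is gated on the raw-p rule. DAG-aware decorrelation
(topGO's elim) is deliberately not implemented.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control, fisher_exact
from scipy.stats.contingency import odds_ratio as _odds_ratio


@dataclass
class EnrichmentResult:
    name: str
    table: tuple               # ((a, b), (c, d)) with consistent margins
    overlap: int
    odds_ratio: float          # conditional MLE
    sample_odds_ratio: float   # ad/bc
    p_value: float


def fisher_overlap(set_a: Sequence, set_b: Sequence,
                   universe: Sequence, name: str = "overlap") -> EnrichmentResult:
    """Two-sided Fisher exact test of association between two gene/interval sets.

    Both sets must be subsets of the universe. The 2x2 table counts members of
    the universe by (in A) x (in B).
    """
    u = set(universe)
    if not u:
        raise ValueError("empty universe")
    a, b = set(set_a), set(set_b)
    if not a <= u or not b <= u:
        raise ValueError("sets must be subsets of the universe")
    n11 = len(a & b)
    n12 = len(a - b)
    n21 = len(b - a)
    n22 = len(u) - n11 - n12 - n21
    tab = np.array([[n11, n12], [n21, n22]])
    sample_or, p = fisher_exact(tab, alternative="two-sided")
    cond = _odds_ratio(tab, kind="conditional")
    return EnrichmentResult(name=name, table=((n11, n12), (n21, n22)),
                            overlap=n11, odds_ratio=float(cond.statistic),
                            sample_odds_ratio=float(sample_or),
                            p_value=float(p))


def geneset_enrichment(genes: Sequence, annotation: Mapping[str, Sequence],
                       universe: Sequence, min_term_size: int = 10,
                       max_term_size: int = 500, p_threshold: float = 0.01,
                       min_overlap: int = 3) -> pd.DataFrame:
    """Classic Fisher enrichment of ``genes`` against term -> gene annotation.

    Terms are restricted to those annotating min_term_size..max_term_size
    genes within the universe. The ``reported`` flag applies the raw
    p < p_threshold AND overlap >= min_overlap rule; ``q_value`` is the BH
    adjustment over the tested terms.
    """
    u = set(universe)
    if not u:
        raise ValueError("empty universe")
    if not annotation:
        raise ValueError("empty annotation")
    query = set(genes) & u
    rows = []
    for term, members in annotation.items():
        m = set(members) & u
        if not min_term_size <= len(m) <= max_term_size:
            continue
        res = fisher_overlap(query, m, u, name=term)
        rows.append({"term": term, "term_size": len(m), "overlap": res.overlap,
                     "odds_ratio": res.odds_ratio, "p_value": res.p_value})
    if not rows:
        return pd.DataFrame(columns=["term", "term_size", "overlap", "odds_ratio",
                                     "p_value", "q_value", "reported"])
    df = pd.DataFrame(rows)
    df["q_value"] = false_discovery_control(df["p_value"].to_numpy(), method="bh")
    df["reported"] = (df["p_value"] < p_threshold) & (df["overlap"] >= min_overlap)
    return df.sort_values("p_value", kind="mergesort").reset_index(drop=True)


def read_gmt(path) -> dict:
    """GMT gene-set file: term <tab> description <tab> gene1 <tab> gene2 ..."""
    out = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                out[parts[0]] = parts[2:]
    return out
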