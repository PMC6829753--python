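"""DMR calling, filtering, k-means classification and origin/fate tracing.

Candidate regions between two sample groups are found by binary segmentation
of the per-CpG group-mean difference signal; each candidate is tested with a
two-sided Mann-Whitney U comparing the per-CpG levels of the two groups, and
p-values are Benjamini-Hochberg adjusted genome-wide. Reported DMRs satisfy
all of: number of CpGs >= 20, q < 0.01 and |group-mean difference| > 0.30.
Direction is "hyper" when group 1 exceeds group 2. Chromosomes X and Y are
excluded by default so sex differences cannot masquerade as DMRs.

Origin tracing compares a DMR's methylation in iPSC against an ESC reference:
similar levels mean the locus was properly reprogrammed and the DMR arose
during differentiation (demethylation error for hyper-DMRs; maintenance or
de-novo methylation error for hypo-DMRs depending on the pluripotent-state
level), whereas an iPSC-specific state transmitted to iRPE marks a
reprogramming error. Fate is "resolved-in-xRPE" when xenotransplantation
moved the region toward the native-RPE level by more than a margin.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control, fisher_exact, mannwhitneyu

from . import intervals as iv
from .io import cg_only, filter_by_coverage, levels
from .segmentation import binary_segmentation

DMR_MIN_CPG = 20
DMR_MAX_Q = 0.01
DMR_MIN_DELTA = 0.30

ORIGINS = ("demethylation-error", "maintenance-error", "de-novo-error",
           "reprogramming-error", "unclassified")


def _level_matrix(tables: Mapping[str, pd.DataFrame], chrom: str,
                  union_pos: np.ndarray) -> np.ndarray:
    """Sites x samples matrix of levels on a shared position index (NaN = uncovered)."""
    out = np.full((len(union_pos), len(tables)), np.nan)
    for j, tbl in enumerate(tables.values()):
        grp = tbl[tbl["chrom"] == chrom]
        grp = grp[grp["total"] > 0]
        pos = grp["pos"].to_numpy(np.int64)
        idx = np.searchsorted(union_pos, pos)
        ok = (idx < len(union_pos)) & (union_pos[np.minimum(idx, len(union_pos) - 1)]
                                       == pos)
        out[idx[ok], j] = levels(grp)[ok]
    return out


def call_dmrs(group1: Mapping[str, pd.DataFrame], group2: Mapping[str, pd.DataFrame],
              min_cpg: int = DMR_MIN_CPG, max_q: float = DMR_MAX_Q,
              min_delta: float = DMR_MIN_DELTA, penalty: float = 1.5,
              min_seg: int = 10, exclude_sex_chroms: bool = True,
              coverage_filter: bool = True) -> pd.DataFrame:
    """Call DMRs of group1 relative to group2.

    Returns intervals with per-group means, delta, U-test p, BH q, CpG count
    and direction; every row satisfies the three output filters.
    """
    if not group1 or not group2:
        raise ValueError("both groups need at least one sample")

    def prep(tables):
        out = {}
        for name, t in tables.items():
            if coverage_filter:
                t = filter_by_coverage(t)
            out[name] = cg_only(t)
        return out

    g1, g2 = prep(group1), prep(group2)
    chroms = sorted(set().union(*(set(t["chrom"].unique())
                                  for t in list(g1.values()) + list(g2.values()))))
    if exclude_sex_chroms:
        chroms = [c for c in chroms if c not in ("chrX", "chrY")]
    candidates = []
    for chrom in chroms:
        pools = [t.loc[t["chrom"] == chrom, "pos"].to_numpy(np.int64)
                 for t in list(g1.values()) + list(g2.values())]
        union_pos = np.unique(np.concatenate(pools)) if pools else np.array([], np.int64)
        if len(union_pos) < min_seg:
            continue
        m1 = _level_matrix(g1, chrom, union_pos)
        m2 = _level_matrix(g2, chrom, union_pos)
        with np.errstate(invalid="ignore"):
            mean1 = np.nanmean(m1, axis=1)
            mean2 = np.nanmean(m2, axis=1)
        ok = ~np.isnan(mean1) & ~np.isnan(mean2)
        pos, mean1, mean2 = union_pos[ok], mean1[ok], mean2[ok]
        m1, m2 = m1[ok], m2[ok]
        if len(pos) < min_seg:
            continue
        diff = mean1 - mean2
        cuts = binary_segmentation(diff, penalty, min_seg)
        bounds = [0, *cuts, len(pos)]
        for a, b in zip(bounds[:-1], bounds[1:]):
            v1 = m1[a:b][~np.isnan(m1[a:b])]
            v2 = m2[a:b][~np.isnan(m2[a:b])]
            if len(v1) == 0 or len(v2) == 0:
                continue
            delta = float(np.mean(mean1[a:b]) - np.mean(mean2[a:b]))
            res = mannwhitneyu(v1, v2, alternative="two-sided")
            candidates.append({
                "chrom": chrom, "start": int(pos[a]) - 1, "end": int(pos[b - 1]),
                "n_cpg": b - a, "mean_g1": float(np.mean(mean1[a:b])),
                "mean_g2": float(np.mean(mean2[a:b])), "delta": delta,
                "p_value": float(res.pvalue)})
    if not candidates:
        return _empty_dmr_frame()
    df = pd.DataFrame(candidates)
    df["q_value"] = false_discovery_control(df["p_value"].to_numpy(), method="bh")
    df["direction"] = np.where(df["delta"] > 0, "hyper", "hypo")
    out = df[(df["n_cpg"] >= min_cpg) & (df["q_value"] < max_q)
             & (df["delta"].abs() > min_delta)]
    return out.sort_values(["chrom", "start"]).reset_index(drop=True)


def _empty_dmr_frame() -> pd.DataFrame:
    return pd.DataFrame(columns=["chrom", "start", "end", "n_cpg", "mean_g1",
                                 "mean_g2", "delta", "p_value", "q_value",
                                 "direction"])


def read_metilene(path, min_cpg: int = DMR_MIN_CPG, max_q: float = DMR_MAX_Q,
                  min_delta: float = DMR_MIN_DELTA) -> pd.DataFrame:
    """Read metilene output (chrom start end q mean-diff nCpG ...) and apply
    the standard output filters. Mean difference is accepted as a percentage
    or a fraction (detected from its magnitude)."""
    df = pd.read_csv(path, sep="\t", header=None).iloc[:, :6]
    df.columns = ["chrom", "start", "end", "q_value", "delta", "n_cpg"]
    if df["delta"].abs().max() > 1.5:
        df["delta"] = df["delta"] / 100.0
    df["direction"] = np.where(df["delta"] > 0, "hyper", "hypo")
    out = df[(df["n_cpg"] >= min_cpg) & (df["q_value"] < max_q)
             & (df["delta"].abs() > min_delta)]
    return out.reset_index(drop=True)


def kmeans_dmrs(profiles: pd.DataFrame, k: int, seed: int = 0) -> pd.Series:
    """K-means on DMR x state mean-methylation profiles.

    Missing values are imputed by the state (column) mean. Cluster labels are
    renumbered 1..k by descending mean iPSC level (first column when no iPSC
    column exists) so the numbering is reproducible and puts the most
    pluripotent-hypermethylated cluster first.
    """
    from sklearn.cluster import KMeans
    X = profiles.to_numpy(float).copy()
    col_mean = np.nanmean(X, axis=0)
    nan_r, nan_c = np.where(np.isnan(X))
    X[nan_r, nan_c] = col_mean[nan_c]
    if k < 1:
        raise ValueError("k must be >= 1")
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    raw = km.fit_predict(X)
    order_col = list(profiles.columns).index("iPSC") if "iPSC" in profiles.columns \
        else 0
    centroid_key = km.cluster_centers_[:, order_col]
    order = np.argsort(-centroid_key, kind="mergesort")
    remap = {int(old): i + 1 for i, old in enumerate(order)}
    return pd.Series([remap[int(r)] for r in raw], index=profiles.index,
                     name="cluster")


def classify_origin_fate(state_levels: Mapping[str, float], direction: str,
                         similar_delta: float = 0.15,
                         fate_margin: float = 0.10) -> tuple[str, str]:
    """Origin and fate labels for one DMR from its per-state mean levels.

    Requires levels for iPSC, ESC, iRPE and nRPE (fate additionally needs
    xRPE); any missing value yields "unclassified" / "unknown".
    """
    need = ("iPSC", "ESC", "iRPE", "nRPE")
    vals = {s: state_levels.get(s) for s in ("iPSC", "ESC", "iRPE", "xRPE", "nRPE")}
    if any(vals[s] is None or (isinstance(vals[s], float) and np.isnan(vals[s]))
           for s in need):
        return "unclassified", "unknown"
    ipsc, esc, irpe, nrpe = vals["iPSC"], vals["ESC"], vals["iRPE"], vals["nRPE"]
    if abs(ipsc - esc) <= similar_delta:  # properly reprogrammed
        if direction == "hyper" and ipsc >= 0.5:
            origin = "demethylation-error"
        elif direction == "hypo" and ipsc >= 0.5:
            origin = "maintenance-error"
        elif direction == "hypo" and ipsc < 0.5:
            origin = "de-novo-error"
        else:
            origin = "unclassified"
    elif (ipsc >= 0.5) == (irpe >= 0.5):  # iPSC state transmitted to iRPE
        origin = "reprogramming-error"
    else:
        origin = "unclassified"
    xrpe = vals["xRPE"]
    if xrpe is None or (isinstance(xrpe, float) and np.isnan(xrpe)):
        fate = "unknown"
    elif abs(xrpe - nrpe) < abs(irpe - nrpe) - fate_margin:
        fate = "resolved-in-xRPE"
    else:
        fate = "persistent"
    return origin, fate


def classify_all(dmrs: pd.DataFrame, state_levels: pd.DataFrame,
                 similar_delta: float = 0.15,
                 fate_margin: float = 0.10) -> pd.DataFrame:
    """Vector wrapper: state_levels is DMR x state; returns dmrs + origin/fate."""
    out = dmrs.copy()
    origins, fates = [], []
    for idx, direction in zip(dmrs.index, dmrs["direction"]):
        o, f = classify_origin_fate(state_levels.loc[idx].to_dict(), direction,
                                    similar_delta, fate_margin)
        origins.append(o)
        fates.append(f)
    out["origin"] = origins
    out["fate"] = fates
    return out


def proximal_genes(dmrs: pd.DataFrame, genes: pd.DataFrame,
                   max_dist: int = 5_000) -> tuple[pd.DataFrame, dict]:
    """Genes within ``max_dist`` bp of a DMR (gap distance; 0 when overlapping).

    Returns (pairs, summary). The summary counts genes proximal to hyper-DMRs,
    to hypo-DMRs, to both, and the de-duplicated union.
    """
    if max_dist < 0:
        raise ValueError("max_dist must be >= 0")
    pairs = []
    for chrom, dgrp in dmrs.groupby("chrom", observed=True):
        ggrp = genes[genes["chrom"] == chrom]
        if len(ggrp) == 0:
            continue
        gs = ggrp["start"].to_numpy(np.int64)
        ge = ggrp["end"].to_numpy(np.int64)
        names = ggrp["name"].to_numpy()
        for r in dgrp.itertuples():
            gap = np.maximum(0, np.maximum(gs, r.start) - np.minimum(ge, r.end))
            hit = gap <= max_dist
            for name, dist in zip(names[hit], gap[hit]):
                pairs.append((getattr(r, "name", r.Index), name, int(dist),
                              getattr(r, "direction", "NA")))
    pairs = pd.DataFrame(pairs, columns=["dmr", "gene", "distance", "direction"])
    hyper = set(pairs.loc[pairs["direction"] == "hyper", "gene"])
    hypo = set(pairs.loc[pairs["direction"] == "hypo", "gene"])
    summary = {"hyper_genes": len(hyper), "hypo_genes": len(hypo),
               "both": len(hyper & hypo),
               "union": count_union(hyper, hypo)}
    return pairs, summary


def count_union(hyper_genes: Sequence, hypo_genes: Sequence) -> int:
    """De-duplicated DMR-proximal gene count: |hyper| + |hypo| - |both|."""
    return len(set(hyper_genes) | set(hypo_genes))


def cgi_flank_profile(sites: pd.DataFrame, cgis: pd.DataFrame, flank: int = 5_000,
                      flank_bins: int = 10, body_bins: int = 10,
                      merge_strands: bool = True) -> pd.DataFrame:
    """Average methylation profile across CGIs aligned on their boundaries.

    Bins: ``flank_bins`` upstream, ``body_bins`` across the (length-scaled)
    CGI body, ``flank_bins`` downstream. Returns bin index, relative
    coordinate label and mean level across CGIs.
    """
    if flank <= 0:
        raise ValueError("flank must be > 0")
    cg = cg_only(sites, merge_strands=merge_strands)
    cg = cg[cg["total"] > 0]
    n_bins = 2 * flank_bins + body_bins
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    for chrom, grp in cg.groupby("chrom", sort=False, observed=True):
        pos0 = grp["pos"].to_numpy(np.int64) - 1
        lv = levels(grp)
        for r in cgis[cgis["chrom"] == chrom].itertuples():
            lo = np.searchsorted(pos0, r.start - flank)
            hi = np.searchsorted(pos0, r.end + flank)
            p = pos0[lo:hi]
            v = lv[lo:hi]
            binidx = np.empty(len(p), dtype=np.int64)
            up = p < r.start
            down = p >= r.end
            body = ~up & ~down
            binidx[up] = ((p[up] - (r.start - flank)) * flank_bins // flank)
            size = max(r.end - r.start, 1)
            binidx[body] = flank_bins + (p[body] - r.start) * body_bins // size
            binidx[down] = (flank_bins + body_bins
                            + (p[down] - r.end) * flank_bins // flank)
            binidx = np.clip(binidx, 0, n_bins - 1)
            np.add.at(sums, binidx, v)
            np.add.at(counts, binidx, 1)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    zone = (["upstream"] * flank_bins + ["cgi"] * body_bins
            + ["downstream"] * flank_bins)
    return pd.DataFrame({"bin": np.arange(n_bins), "zone": zone,
                         "mean_level": mean, "n_sites": counts})


def cgi_pmd_cooccurrence(cgi_levels: pd.Series, cgis: pd.DataFrame,
                         pmds: pd.DataFrame, hyper_threshold: float = 0.5,
                         flank: int = 5_000,
                         min_flank_fraction: float = 0.5) -> dict:
    """Fisher test: is CGI hypermethylation associated with flanking PMDs?

    A CGI is "hypermethylated" when its mean level exceeds ``hyper_threshold``;
    its flank is "in a PMD" when at least ``min_flank_fraction`` of the
    +/- ``flank`` bp around it lies inside a PMD.
    """
    named = cgis.set_index("name")
    rows = []
    for name, level in cgi_levels.items():
        if name not in named.index or np.isnan(level):
            continue
        r = named.loc[name]
        fl = pd.DataFrame({"chrom": [r["chrom"], r["chrom"]],
                           "start": [max(0, r["start"] - flank), r["end"]],
                           "end": [r["start"], r["end"] + flank]})
        covered = iv.total_bp(iv.intersect(fl, pmds))
        frac = covered / max(iv.total_bp(fl), 1)
        rows.append((level > hyper_threshold, frac >= min_flank_fraction))
    tab = np.zeros((2, 2), dtype=int)
    for h, p in rows:
        tab[0 if h else 1, 0 if p else 1] += 1
    odds, p_value = fisher_exact(tab, alternative="two-sided")
    return {"table": tab, "odds_ratio": float(odds), "p_value": float(p_value),
            "n_cgis": len(rows)}
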