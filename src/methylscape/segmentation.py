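"""Methylome segmentation and PMD detection.

A methylome is segmented per chromosome by least-squares binary segmentation
on per-CpG methylation levels: a change-point is accepted when it reduces the
within-segment sum of squared deviations by more than a fixed penalty. The
default penalty (3.0) is set so that a 10-kb, 30-percentage-point step at
~10x depth is detected while depth noise alone is not. Runs of sites
separated by more than ``max_gap`` (default 100 kb) are segmented
independently so assembly gaps are never bridged.

Partially methylated domains (PMDs) are segments larger than 10 kb with mean
mCG below 70% (both bounds strict). The Methylated Domain Landscape (MDL)
representation plots each domain's mean level (percent) against log10 of its
size in bp.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import intervals as iv
from .io import cg_only, levels

DOMAIN_COLUMNS = ["chrom", "start", "end", "n_cpg", "mean_level"]
PMD_MIN_SIZE = 10_000
PMD_MAX_LEVEL = 0.70


def binary_segmentation(values: np.ndarray, penalty: float,
                        min_size: int) -> list:
    """Change-point indices by binary segmentation with bottom-up pruning.

    Phase 1 recursively places the least-squares-optimal split in every
    segment until no segment can be split (over-segmentation). Phase 2
    agglomeratively re-merges adjacent segments while the cheapest merge
    increases the total squared error by at most ``penalty``. The two-phase
    scheme detects short deviating intervals embedded in long segments, which
    a penalty-gated greedy descent misses. Deterministic; split ties resolve
    to the leftmost position, merge ties to the leftmost pair.
    """
    x = np.asarray(values, float)
    n = len(x)
    if n < 2 * min_size:
        return []
    csum = np.concatenate(([0.0], np.cumsum(x)))

    def best_split(a, b):
        ks = np.arange(a + min_size, b - min_size + 1)
        nl = ks - a
        nr = b - ks
        sl = csum[ks] - csum[a]
        sr = csum[b] - csum[ks]
        score = sl * sl / nl + sr * sr / nr  # maximize explained sum of squares
        i = int(np.argmax(score))
        s = csum[b] - csum[a]
        gain = score[i] - s * s / (b - a)
        return int(ks[i]), float(gain)

    # phase 1: overfit
    bounds = [0, n]
    stack = [(0, n)]
    while stack:
        a, b = stack.pop()
        if b - a < 2 * min_size:
            continue
        k, gain = best_split(a, b)
        if gain <= 1e-12:
            continue
        bounds.append(k)
        stack.append((a, k))
        stack.append((k, b))
    bounds = sorted(set(bounds))

    # phase 2: greedy agglomerative pruning with a lazy heap
    import heapq
    segs = [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]
    cnt = [b - a for a, b in segs]
    tot = [csum[b] - csum[a] for a, b in segs]
    prev_ = list(range(-1, len(segs) - 1))
    next_ = list(range(1, len(segs) + 1))
    next_[-1] = -1
    alive = [True] * len(segs)
    version = [0] * len(segs)

    def merge_cost(i, j):
        ni, nj = cnt[i], cnt[j]
        d = tot[i] / ni - tot[j] / nj
        return ni * nj / (ni + nj) * d * d

    heap = []
    for i in range(len(segs) - 1):
        heapq.heappush(heap, (merge_cost(i, i + 1), i, i + 1, version[i],
                              version[i + 1]))
    while heap:
        cost, i, j, vi, vj = heapq.heappop(heap)
        if cost > penalty:
            break
        if not (alive[i] and alive[j]) or version[i] != vi or version[j] != vj \
                or next_[i] != j:
            continue
        cnt[i] += cnt[j]
        tot[i] += tot[j]
        alive[j] = False
        version[i] += 1
        nj = next_[j]
        next_[i] = nj
        if nj != -1:
            prev_[nj] = i
            heapq.heappush(heap, (merge_cost(i, nj), i, nj, version[i],
                                  version[nj]))
        pi = prev_[i]
        if pi != -1:
            heapq.heappush(heap, (merge_cost(pi, i), pi, i, version[pi],
                                  version[i]))
    # reconstruct boundaries from the surviving segment chain
    i = 0
    while not alive[i]:
        i += 1
    starts = []
    while i != -1:
        starts.append(segs[i][0])
        i = next_[i]
    return [s for s in starts if s != 0]


def segment_methylome(sites: pd.DataFrame, penalty: float = 3.0,
                      min_sites: int = 20, max_gap: int = 100_000,
                      merge_strands: bool = True) -> pd.DataFrame:
    """Segment per-CpG levels into methylation domains (DomainSet).

    Domains tile the covered span of each chromosome: boundaries fall midway
    between the flanking CpGs of each change-point, and block edges at the
    first/last covered site. Chromosomes with fewer than ``min_sites`` covered
    CpGs are skipped with a warning.
    """
    cg = cg_only(sites, merge_strands=merge_strands)
    cg = cg[cg["total"] > 0]
    rows = []
    for chrom, grp in cg.groupby("chrom", sort=True, observed=True):
        pos = grp["pos"].to_numpy(np.int64)
        lv = levels(grp)
        if len(pos) < min_sites:
            warnings.warn(f"{chrom}: only {len(pos)} covered CpGs "
                          f"(< {min_sites}); skipped")
            continue
        block_breaks = np.flatnonzero(np.diff(pos) > max_gap) + 1
        for blk_pos, blk_lv in zip(np.split(pos, block_breaks),
                                   np.split(lv, block_breaks)):
            if len(blk_pos) < min_sites:
                continue
            cuts = binary_segmentation(blk_lv, penalty, min_sites)
            bounds = [0, *cuts, len(blk_pos)]
            for a, b in zip(bounds[:-1], bounds[1:]):
                start = int(blk_pos[0]) - 1 if a == 0 else \
                    int((blk_pos[a - 1] + blk_pos[a]) // 2)
                end = int(blk_pos[-1]) if b == len(blk_pos) else \
                    int((blk_pos[b - 1] + blk_pos[b]) // 2)
                rows.append((chrom, start, end, b - a, float(np.mean(blk_lv[a:b]))))
    return pd.DataFrame(rows, columns=DOMAIN_COLUMNS)


def call_pmds(domains: pd.DataFrame, min_size: int = PMD_MIN_SIZE,
              max_level: float = PMD_MAX_LEVEL) -> pd.DataFrame:
    """PMDs: domains strictly larger than min_size bp and strictly below max_level."""
    size = domains["end"] - domains["start"]
    sel = (size > min_size) & (domains["mean_level"] < max_level)
    return domains[sel].reset_index(drop=True)


def mdl_table(domains: pd.DataFrame) -> pd.DataFrame:
    """MDL plot points: (log10 size in bp, mean level in percent), one per domain."""
    if len(domains) == 0:
        raise ValueError("cannot build an MDL table from an empty domain set")
    size = (domains["end"] - domains["start"]).to_numpy(float)
    return pd.DataFrame({"log10_size": np.log10(size),
                         "level_pct": 100.0 * domains["mean_level"].to_numpy(float)})


def interval_overlap_mb(sets: dict) -> dict:
    """Basewise Venn partition sizes in Mb for up to three interval sets."""
    return iv.interval_overlap_mb(sets)


def pan_union(pmd_sets: list) -> pd.DataFrame:
    """Union of several PMD sets (e.g. pan-cRPE = union over cRPE1-4)."""
    return iv.union_all(pmd_sets)


def classify_pmds(irpe: pd.DataFrame, fib: pd.DataFrame, ipsc: pd.DataFrame,
                  pan_crpe: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Label iRPE PMD bases by lineage history.

    Bases shared with fibroblast PMDs are "persistent" when also PMD in iPSC
    (inherited through reprogramming) and "recurrent" otherwise (lost in iPSC,
    re-established on differentiation). Bases outside both fibroblast and
    pan-cRPE PMDs are "specific"; the remainder is "other". Returns the
    labeled intervals and basewise fractions of the iRPE PMD total.
    """
    shared_fib = iv.intersect(irpe, fib)
    persistent = iv.intersect(shared_fib, ipsc)
    recurrent = iv.subtract(shared_fib, ipsc)
    outside_fib = iv.subtract(irpe, fib)
    specific = iv.subtract(outside_fib, pan_crpe)
    other = iv.intersect(outside_fib, pan_crpe)
    parts = {"persistent": persistent, "recurrent": recurrent,
             "specific": specific, "other": other}
    labeled = []
    for label, df in parts.items():
        if len(df):
            d = df.copy()
            d["label"] = label
            labeled.append(d)
    labeled = pd.concat(labeled, ignore_index=True) if labeled else \
        pd.DataFrame(columns=iv.BED_COLUMNS + ["label"])
    total = iv.total_bp(irpe)
    fractions = {label: (iv.total_bp(df) / total if total else 0.0)
                 for label, df in parts.items()}
    return iv.sort_intervals(labeled), fractions


def pmd_prone_regions(fib_pmd_sets: list) -> pd.DataFrame:
    """PMD-prone regions: the union of fibroblast PMDs (used for masking)."""
    return iv.union_all(fib_pmd_sets)


def genome_pmd_fraction(pmds: pd.DataFrame, chrom_lengths: dict,
                        autosomes_only: bool = True) -> float:
    """Fraction of the genome covered by PMDs."""
    total = sum(v for c, v in chrom_lengths.items()
                if not (autosomes_only and c == "chrX"))
    if autosomes_only:
        pmds = pmds[pmds["chrom"] != "chrX"]
    return iv.total_bp(pmds) / total if total else 0.0
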