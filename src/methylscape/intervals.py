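"""Basewise interval arithmetic on BED-style (0-based, half-open) tables.

All functions operate on pandas DataFrames with at least ``chrom``, ``start``
and ``end`` columns. Intervals within one table may overlap unless stated;
set-algebra functions merge their inputs first so results are well defined.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

BED_COLUMNS = ["chrom", "start", "end"]


def _empty() -> pd.DataFrame:
    return pd.DataFrame({"chrom": pd.Series(dtype=object),
                         "start": pd.Series(dtype=np.int64),
                         "end": pd.Series(dtype=np.int64)})


def sort_intervals(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Union of intervals: sorted, non-overlapping, per chromosome."""
    if len(df) == 0:
        return _empty()
    out = []
    for chrom, grp in df.groupby("chrom", sort=True, observed=True):
        starts = grp["start"].to_numpy(np.int64)
        ends = grp["end"].to_numpy(np.int64)
        order = np.argsort(starts, kind="mergesort")
        starts, ends = starts[order], ends[order]
        run_end = np.maximum.accumulate(ends)
        # new run begins where start exceeds the running max end of predecessors
        new_run = np.ones(len(starts), dtype=bool)
        new_run[1:] = starts[1:] > run_end[:-1]
        run_id = np.cumsum(new_run) - 1
        ms = starts[new_run]
        me = np.zeros(run_id.max() + 1, dtype=np.int64)
        np.maximum.at(me, run_id, ends)
        out.append(pd.DataFrame({"chrom": chrom, "start": ms, "end": me}))
    return pd.concat(out, ignore_index=True)


def total_bp(df: pd.DataFrame) -> int:
    m = merge_intervals(df)
    return int((m["end"] - m["start"]).sum())


def _per_chrom(df: pd.DataFrame) -> dict:
    d = {}
    for chrom, grp in merge_intervals(df).groupby("chrom", observed=True):
        d[chrom] = (grp["start"].to_numpy(np.int64), grp["end"].to_numpy(np.int64))
    return d


def intersect(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Basewise intersection a ∩ b."""
    da, db = _per_chrom(a), _per_chrom(b)
    rows = []
    for chrom in sorted(set(da) & set(db)):
        sa, ea = da[chrom]
        sb, eb = db[chrom]
        i = j = 0
        while i < len(sa) and j < len(sb):
            lo, hi = max(sa[i], sb[j]), min(ea[i], eb[j])
            if lo < hi:
                rows.append((chrom, lo, hi))
            if ea[i] < eb[j]:
                i += 1
            else:
                j += 1
    if not rows:
        return _empty()
    return pd.DataFrame(rows, columns=BED_COLUMNS)


def subtract(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Basewise difference a \\ b."""
    da, db = _per_chrom(a), _per_chrom(b)
    rows = []
    for chrom, (sa, ea) in sorted(da.items()):
        sb, eb = db.get(chrom, (np.array([], np.int64), np.array([], np.int64)))
        for s, e in zip(sa, ea):
            cur = s
            k = np.searchsorted(eb, cur, side="right")
            while cur < e and k < len(sb):
                if sb[k] >= e:
                    break
                if sb[k] > cur:
                    rows.append((chrom, cur, min(sb[k], e)))
                cur = max(cur, eb[k])
                k += 1
            if cur < e:
                rows.append((chrom, cur, e))
    if not rows:
        return _empty()
    return pd.DataFrame(rows, columns=BED_COLUMNS)


def venn_basewise(sets: Mapping[str, pd.DataFrame]) -> dict:
    """Sizes (bp) of every non-empty region of the Venn diagram of up to N sets.

    Returns a dict mapping frozenset of set names -> base pairs covered by
    exactly that combination of sets.
    """
    names = list(sets)
    merged = {n: _per_chrom(sets[n]) for n in names}
    chroms = sorted({c for d in merged.values() for c in d})
    counts: dict = {}
    for chrom in chroms:
        bounds = [np.array([], np.int64)]
        for n in names:
            if chrom in merged[n]:
                s, e = merged[n][chrom]
                bounds.extend([s, e])
        pts = np.unique(np.concatenate(bounds))
        if len(pts) < 2:
            continue
        seg_s, seg_e = pts[:-1], pts[1:]
        member = np.zeros((len(names), len(seg_s)), dtype=bool)
        for k, n in enumerate(names):
            if chrom not in merged[n]:
                continue
            s, e = merged[n][chrom]
            idx = np.searchsorted(s, seg_s, side="right") - 1
            ok = idx >= 0
            member[k, ok] = e[idx[ok]] > seg_s[ok]
        widths = seg_e - seg_s
        if member.size:
            for row, w in zip(member.T, widths):  # segments x sets
                if not row.any():
                    continue
                key = frozenset(n for n, m in zip(names, row) if m)
                counts[key] = counts.get(key, 0) + int(w)
    return counts


def interval_overlap_mb(sets: Mapping[str, pd.DataFrame]) -> dict:
    """Venn partition sizes in Mb, keyed by frozenset of set names (Fig-1C style)."""
    if len(sets) > 3:
        raise ValueError("at most 3 sets supported for a Venn partition")
    return {k: v / 1e6 for k, v in venn_basewise(sets).items()}


def union_all(dfs: Iterable[pd.DataFrame]) -> pd.DataFrame:
    """Union of several interval tables (e.g. pan-cRPE = union of cRPE1-4 PMDs)."""
    dfs = [d[BED_COLUMNS] for d in dfs if len(d)]
    if not dfs:
        return _empty()
    return merge_intervals(pd.concat(dfs, ignore_index=True))


def sites_in_intervals(pos: np.ndarray, intervals: pd.DataFrame, chrom: str) -> np.ndarray:
    """Boolean mask: which 1-based site positions fall in the (merged) intervals."""
    mask = np.zeros(len(pos), dtype=bool)
    d = _per_chrom(intervals)
    if chrom not in d:
        return mask
    s, e = d[chrom]
    pos0 = np.asarray(pos, np.int64) - 1  # to 0-based
    idx = np.searchsorted(s, pos0, side="right") - 1
    ok = idx >= 0
    mask[ok] = e[idx[ok]] > pos0[ok]
    return mask


def gap_distance(a_start, a_end, b_start, b_end) -> int:
    """Gap in bp between two half-open intervals; 0 if they overlap or touch."""
    return max(0, max(a_start, b_start) - min(a_end, b_end))
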