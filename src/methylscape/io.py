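"""Per-cytosine methylation tables and annotation I/O.

The on-disk dialect is a Bismark-style cytosine report: tab-separated
``chrom, pos (1-based), strand, methylated count, unmethylated count,
context class (CG/CHG/CHH), trinucleotide``. In memory a SiteTable is a
pandas DataFrame with columns ``chrom, pos, strand, context, meth, total``
sorted by (chrom, pos); ``context`` is "CG" for CpG records and the literal
trinucleotide for CH records.

Coverage rules follow the analysis convention: CG sites are kept when covered
at least once, CH sites when covered at least 10 times. Symmetric-CpG strand
merging (counts summed onto the plus-strand coordinate) is available and is
the default for mCG analyses.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

SITE_COLUMNS = ["chrom", "pos", "strand", "context", "meth", "total"]


class ParseError(ValueError):
    """Malformed cytosine-report input; message carries the line number."""


def context_class(context: str) -> str:
    """CG / CHG / CHH class of a context string (trinucleotide or 'CG')."""
    if context == "CG":
        return "CG"
    if len(context) == 3 and context[0] == "C" and context[1] != "G":
        return "CHG" if context[2] == "G" else "CHH"
    raise ParseError(f"unknown context {context!r}")


def levels(sites: pd.DataFrame) -> np.ndarray:
    """Per-site methylation level meth/total; NaN where total == 0."""
    total = sites["total"].to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        lv = sites["meth"].to_numpy(float) / total
    lv[total == 0] = np.nan
    return lv


def write_cytosine_report(sites: pd.DataFrame, path) -> None:
    cls = sites["context"].map(lambda c: "CG" if c == "CG" else context_class(c))
    out = pd.DataFrame({
        "chrom": sites["chrom"], "pos": sites["pos"], "strand": sites["strand"],
        "meth": sites["meth"], "unmeth": sites["total"] - sites["meth"],
        "class": cls, "trinucleotide": sites["context"],
    })
    out.to_csv(path, sep="\t", header=False, index=False)


def read_cytosine_report(path) -> pd.DataFrame:
    """Read a cytosine report; malformed lines raise ParseError with line numbers."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "pos", "strand", "meth", "unmeth",
                                "class", "trinucleotide"],
                         dtype={"chrom": str, "strand": str, "class": str,
                                "trinucleotide": str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: {exc}") from exc
    bad = ~df["class"].isin(["CG", "CHG", "CHH"])
    if bad.any():
        raise ParseError(f"{path}: unknown context {df.loc[bad.idxmax(), 'class']!r} "
                         f"at line {int(bad.idxmax()) + 1}")
    for col in ("meth", "unmeth"):
        neg = pd.to_numeric(df[col], errors="coerce")
        if neg.isna().any() or (neg < 0).any():
            line = int((neg.isna() | (neg < 0)).idxmax()) + 1
            raise ParseError(f"{path}: invalid {col} count at line {line}")
    if (df["pos"] <= 0).any():
        line = int((df["pos"] <= 0).idxmax()) + 1
        raise ParseError(f"{path}: non-positive position at line {line}")
    context = np.where(df["class"] == "CG", "CG", df["trinucleotide"])
    sites = pd.DataFrame({"chrom": df["chrom"], "pos": df["pos"].astype(np.int64),
                          "strand": df["strand"], "context": context,
                          "meth": df["meth"].astype(np.int32),
                          "total": (df["meth"] + df["unmeth"]).astype(np.int32)})
    if not sites[["chrom", "pos"]].apply(tuple, axis=1).is_monotonic_increasing:
        warnings.warn(f"{path}: input not sorted by (chrom, pos); sorting on load")
        sites = sites.sort_values(["chrom", "pos"],
                                  kind="mergesort").reset_index(drop=True)
    return sites


def filter_by_coverage(sites: pd.DataFrame, cg_min: int = 1,
                       ch_min: int = 10) -> pd.DataFrame:
    """Keep CG sites with >= cg_min reads and CH sites with >= ch_min reads."""
    is_cg = sites["context"] == "CG"
    keep = np.where(is_cg, sites["total"] >= cg_min, sites["total"] >= ch_min)
    return sites[keep].reset_index(drop=True)


def merge_symmetric_cpg(sites: pd.DataFrame) -> pd.DataFrame:
    """Sum CG counts of both strands onto the plus-strand coordinate.

    CH records pass through untouched. Counts are conserved; applying the
    merge twice is a no-op.
    """
    is_cg = (sites["context"] == "CG").to_numpy()
    cg = sites[is_cg].copy()
    ch = sites[~is_cg]
    pos = cg["pos"].to_numpy(np.int64).copy()
    pos[(cg["strand"] == "-").to_numpy()] -= 1
    cg["pos"] = pos
    agg = (cg.groupby(["chrom", "pos"], sort=False, observed=True)[["meth", "total"]]
           .sum().reset_index())
    agg["strand"] = "+"
    agg["context"] = "CG"
    out = pd.concat([agg[SITE_COLUMNS], ch[SITE_COLUMNS]], ignore_index=True)
    out = out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    out["meth"] = out["meth"].astype(np.int32)
    out["total"] = out["total"].astype(np.int32)
    return out


def cg_only(sites: pd.DataFrame, merge_strands: bool = True) -> pd.DataFrame:
    cg = sites[sites["context"] == "CG"].reset_index(drop=True)
    return merge_symmetric_cpg(cg) if merge_strands else cg


def ch_only(sites: pd.DataFrame) -> pd.DataFrame:
    return sites[sites["context"] != "CG"].reset_index(drop=True)


def write_bedgraph(sites: pd.DataFrame, path) -> None:
    """Export site levels as bedGraph (chrom, start, end, level in percent)."""
    covered = sites[sites["total"] > 0]
    lv = 100.0 * covered["meth"].to_numpy(float) / covered["total"].to_numpy(float)
    out = pd.DataFrame({"chrom": covered["chrom"], "start": covered["pos"] - 1,
                        "end": covered["pos"], "level": np.round(lv, 2)})
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path, names_in_file: bool = True) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    cols = ["chrom", "start", "end", "name", "score", "strand"][:df.shape[1]]
    df.columns = cols + list(df.columns[len(cols):])
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    if (df["start"] >= df["end"]).any():
        raise ParseError(f"{path}: interval with start >= end")
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in ("chrom", "start", "end", "name", "score", "strand")
            if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)
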