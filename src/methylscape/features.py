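"""Feature x sample methylation matrices.

Features are genomic interval sets: tiling (optionally stepped) 100-kb
windows over the autosomes, promoters (2 kb upstream of the TSS on the coding
strand), gene bodies (TSS to transcript end), CpG islands, TSS-proximal
regions (TSS +/- 500 bp), and CGI-masked gene bodies. The value of a feature
in a sample is the unweighted mean of the covered site levels it contains;
features with fewer than ``min_sites`` covered sites are missing (NaN).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from . import intervals as iv
from .io import cg_only, ch_only, filter_by_coverage, levels


@dataclass
class FeatureMatrix:
    intervals: pd.DataFrame     # feature_id, chrom, start, end
    values: pd.DataFrame        # feature_id x sample, NaN = missing
    n_sites: pd.DataFrame       # covered sites per feature per sample

    @property
    def samples(self) -> list:
        return list(self.values.columns)

    def dropna_features(self) -> "FeatureMatrix":
        """Listwise deletion of features missing in any sample."""
        keep = self.values.dropna().index
        return FeatureMatrix(self.intervals.loc[self.intervals["feature_id"]
                                                .isin(keep)].reset_index(drop=True),
                             self.values.loc[keep], self.n_sites.loc[keep])

    def to_tsv(self, path) -> None:
        out = self.intervals.set_index("feature_id").join(self.values)
        out.to_csv(path, sep="\t")


def _interval_means(pos: np.ndarray, lv: np.ndarray, starts: np.ndarray,
                    ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean of site levels per interval; sites are 1-based, intervals 0-based."""
    c_lv = np.concatenate(([0.0], np.cumsum(lv)))
    lo = np.searchsorted(pos, starts + 1, side="left")
    hi = np.searchsorted(pos, ends, side="right")
    n = (hi - lo).astype(np.int64)
    with np.errstate(invalid="ignore"):
        means = np.where(n > 0, (c_lv[hi] - c_lv[lo]) / np.maximum(n, 1), np.nan)
    return means, n


def feature_means(site_tables: Mapping[str, pd.DataFrame],
                  intervals: pd.DataFrame, min_sites: int = 1,
                  context: str = "CG", merge_strands: bool = True,
                  coverage_filter: bool = True) -> FeatureMatrix:
    """Mean methylation of each interval in each sample.

    ``context`` is "CG" (strand-merged CpGs by default) or "CH" (strand-
    specific non-CpG sites, coverage-filtered at >= 10 reads).
    """
    if len(intervals) == 0:
        raise ValueError("empty interval set")
    if min_sites < 1:
        raise ValueError("min_sites must be >= 1")
    feats = intervals.reset_index(drop=True).copy()
    if "feature_id" not in feats.columns:
        feats.insert(0, "feature_id", [
            f"{r.chrom}:{r.start}-{r.end}" for r in feats.itertuples()])
    vals, ns = {}, {}
    for sample, tbl in site_tables.items():
        if coverage_filter:
            tbl = filter_by_coverage(tbl)
        sites = cg_only(tbl, merge_strands=merge_strands) if context == "CG" \
            else ch_only(tbl)
        sites = sites[sites["total"] > 0]
        mean_col = np.full(len(feats), np.nan)
        n_col = np.zeros(len(feats), dtype=np.int64)
        for chrom, grp in sites.groupby("chrom", sort=False, observed=True):
            sel = feats["chrom"] == chrom
            if not sel.any():
                continue
            m, n = _interval_means(grp["pos"].to_numpy(np.int64), levels(grp),
                                   feats.loc[sel, "start"].to_numpy(np.int64),
                                   feats.loc[sel, "end"].to_numpy(np.int64))
            mean_col[sel.to_numpy()] = m
            n_col[sel.to_numpy()] = n
        mean_col[n_col < min_sites] = np.nan
        vals[sample] = mean_col
        ns[sample] = n_col
    idx = feats["feature_id"]
    return FeatureMatrix(feats[["feature_id", "chrom", "start", "end"]],
                         pd.DataFrame(vals, index=idx),
                         pd.DataFrame(ns, index=idx))


def tiling_windows(chrom_lengths: Mapping[str, int], size: int = 100_000,
                   step: int | None = None,
                   autosomes_only: bool = True) -> pd.DataFrame:
    """Sliding windows; default step = size (non-overlapping tiling)."""
    step = step or size
    rows = []
    for chrom, length in chrom_lengths.items():
        if autosomes_only and chrom == "chrX":
            continue
        for start in range(0, length, step):
            rows.append((chrom, start, min(start + size, length)))
    return pd.DataFrame(rows, columns=iv.BED_COLUMNS)


def promoters(genes: pd.DataFrame, span: int = 2_000) -> pd.DataFrame:
    """Promoter = ``span`` bp upstream of the TSS on the coding strand."""
    if genes["strand"].isna().any() or (~genes["strand"].isin(["+", "-"])).any():
        raise ValueError("every gene must carry a strand")
    plus = genes["strand"] == "+"
    start = np.where(plus, genes["tss"] - span, genes["tss"] + 1)
    end = np.where(plus, genes["tss"], genes["tss"] + 1 + span)
    return pd.DataFrame({"feature_id": genes["name"], "chrom": genes["chrom"],
                         "start": np.maximum(start, 0), "end": end})


def tss_regions(genes: pd.DataFrame, flank: int = 500) -> pd.DataFrame:
    """TSS-proximal regions: TSS +/- ``flank`` bp (strand-symmetric)."""
    return pd.DataFrame({"feature_id": genes["name"], "chrom": genes["chrom"],
                         "start": np.maximum(genes["tss"] - flank, 0),
                         "end": genes["tss"] + flank + 1})


def gene_bodies(genes: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame({"feature_id": genes["name"], "chrom": genes["chrom"],
                         "start": genes["start"], "end": genes["end"]})


def mask_intervals(feats: pd.DataFrame, mask: pd.DataFrame) -> pd.DataFrame:
    """Subtract ``mask`` from each feature, keeping the feature_id on the pieces."""
    rows = []
    for r in feats.itertuples():
        one = pd.DataFrame({"chrom": [r.chrom], "start": [r.start], "end": [r.end]})
        left = iv.subtract(one, mask)
        fid = getattr(r, "feature_id", f"{r.chrom}:{r.start}-{r.end}")
        for piece in left.itertuples():
            rows.append((fid, piece.chrom, piece.start, piece.end))
    return pd.DataFrame(rows, columns=["feature_id", "chrom", "start", "end"])


def standard_features(genome, window_size: int = 100_000,
                      window_step: int | None = None,
                      autosomes_only: bool = True) -> dict:
    """The named feature sets used throughout the clustering analyses."""
    genes = genome.genes
    if autosomes_only:
        genes = genes[genes["chrom"] != "chrX"]
        cgis = genome.cgis[genome.cgis["chrom"] != "chrX"]
    else:
        cgis = genome.cgis
    cgi_feats = cgis.rename(columns={"name": "feature_id"})[
        ["feature_id", "chrom", "start", "end"]]
    bodies = gene_bodies(genes)
    return {
        "windows": tiling_windows(genome.chrom_lengths, window_size, window_step,
                                  autosomes_only=autosomes_only),
        "promoters": promoters(genes),
        "gene_bodies": bodies,
        "gene_bodies_cgi_masked": mask_intervals(bodies, cgis),
        "cgis": cgi_feats,
        "tss": tss_regions(genes),
    }
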