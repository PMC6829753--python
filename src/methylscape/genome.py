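"""Synthetic genome scaffold for methylome simulation.

The scaffold carries everything the downstream pipeline assumes about a real
genome annotation: chromosome sizes (autosomes plus one X), a CpG site
universe with CpG-island densification, a non-CpG (CH) site universe with
trinucleotide contexts, CpG islands, lamina-associated domains (LADs), gene
models with a unique TSS per gene, an imprinted-DMR catalogue, planted
differentially-methylated regions with known etiologies, and the gene subsets
(RPE signature, X-inactivation subjects, state-specific promoter programs)
that give the simulated cohort its biological structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import intervals as iv

CH_CONTEXTS = ("CAA", "CAC", "CAG", "CAT", "CCA", "CCC", "CCG", "CCT",
               "CTA", "CTC", "CTG", "CTT")

# rough human-like trinucleotide frequencies among non-CpG cytosines
_CH_WEIGHTS = {"CAA": 0.12, "CAC": 0.08, "CAG": 0.14, "CAT": 0.10,
               "CCA": 0.08, "CCC": 0.06, "CCG": 0.02, "CCT": 0.08,
               "CTA": 0.06, "CTC": 0.08, "CTG": 0.12, "CTT": 0.06}

DMR_ETIOLOGIES = ("demethylation-error", "maintenance-error",
                  "de-novo-error", "reprogramming-error")


class ConfigurationError(ValueError):
    """Raised for invalid scaffold parameters."""


@dataclass
class GenomeConfig:
    """Scaffold parameters. Lengths in bp, spacings are mean bp between sites."""

    n_autosomes: int = 3
    autosome_length: int = 10_000_000
    x_length: int = 5_000_000
    cpg_spacing: float = 120.0
    cgi_per_mb: float = 6.0
    cgi_size: int = 1_000
    cgi_cpg_spacing: float = 12.0
    genes_per_mb: float = 10.0
    x_genes_per_mb: float = 20.0
    promoter_cpg_spacing: float = 30.0
    lad_fraction: float = 0.35
    lad_mean_size: int = 500_000
    n_idmr: int = 50
    idmr_size: int = 1_500
    idmr_cpg_spacing: float = 40.0
    ch_spacing: float = 150.0
    n_dmr_demethylation: int = 40
    n_dmr_maintenance: int = 15
    n_dmr_denovo: int = 8
    n_dmr_reprogramming: int = 6
    dmr_size: int = 1_500
    dmr_cpg_spacing: float = 40.0
    resolved_fate_fraction: float = 0.30
    cgi_promoter_fraction: float = 0.6
    state_program_size: int = 25
    rpe_signature_size: int = 40
    n_error_prone_cgis: int = 30
    xci_subject_fraction: float = 0.5

    def validate(self) -> None:
        if self.n_autosomes < 1 or self.autosome_length < 1_000_000 \
                or self.x_length < 1_000_000:
            raise ConfigurationError("chromosome lengths must be >= 1 Mb")
        if self.cpg_spacing <= 0 or self.cgi_per_mb <= 0 or self.cgi_size <= 0:
            raise ConfigurationError("CpG density and CGI count must be positive")
        if not 0 <= self.lad_fraction < 1:
            raise ConfigurationError("lad_fraction must be in [0, 1)")
        if self.n_idmr < 0:
            raise ConfigurationError("n_idmr must be non-negative")


@dataclass
class GenomeSpec:
    """A fully materialized synthetic genome annotation universe."""

    chrom_lengths: dict                 # chrom -> bp
    cpg_pos: dict                       # chrom -> 1-based plus-strand C positions
    ch_sites: dict                      # chrom -> DataFrame(pos, strand, context)
    cgis: pd.DataFrame                  # chrom,start,end,name
    lads: pd.DataFrame
    genes: pd.DataFrame                 # name,chrom,start,end,strand,tss (0-based),...
    idmrs: pd.DataFrame
    planted_dmrs: pd.DataFrame          # chrom,start,end,name,etiology,direction,fate
    rpe_signature_genes: list
    xci_subject_genes: list
    state_programs: dict                # state -> list of gene names
    error_prone_cgis: list
    neutral_cgis: list = field(default_factory=list)  # eligible for errors
    config: GenomeConfig = field(repr=False, default=None)

    @property
    def autosomes(self) -> list:
        return [c for c in self.chrom_lengths if c != "chrX"]

    def n_cpg(self) -> int:
        return int(sum(len(p) for p in self.cpg_pos.values()))

    def write_annotations(self, outdir) -> None:
        """Write CGI/LAD/iDMR BED, BED12-like gene models and a JSON summary."""
        from pathlib import Path
        from .io import write_bed
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_bed(self.cgis, outdir / "cgis.bed")
        write_bed(self.lads, outdir / "lads.bed")
        write_bed(self.idmrs, outdir / "idmrs.bed")
        g = self.genes
        bed12 = pd.DataFrame({
            "chrom": g["chrom"], "start": g["start"], "end": g["end"],
            "name": g["name"], "score": 0, "strand": g["strand"],
            "thickStart": g["start"], "thickEnd": g["end"], "rgb": "0",
            "blockCount": 1, "blockSizes": (g["end"] - g["start"]).astype(str) + ",",
            "blockStarts": "0,",
        })
        bed12.to_csv(outdir / "genes.bed12", sep="\t", header=False, index=False)
        meta = {"chrom_lengths": self.chrom_lengths,
                "config": asdict(self.config) if self.config else None,
                "rpe_signature_genes": list(self.rpe_signature_genes),
                "xci_subject_genes": list(self.xci_subject_genes),
                "state_programs": {k: list(v) for k, v in self.state_programs.items()},
                "error_prone_cgis": list(self.error_prone_cgis)}
        (outdir / "genome.json").write_text(json.dumps(meta, indent=1, sort_keys=True))


def _place_lads(rng, length, cfg) -> list:
    out, pos = [], 0
    f = cfg.lad_fraction
    mean_gap = cfg.lad_mean_size * (1 - f) / max(f, 1e-9)
    while True:
        gap = int(rng.exponential(mean_gap)) + 50_000
        size = int(cfg.lad_mean_size * rng.uniform(0.6, 1.4))
        start = pos + gap
        end = start + size
        if end > length - 50_000:
            break
        out.append((start, end))
        pos = end
    return out


def _dense_positions(rng, start, end, spacing) -> np.ndarray:
    n = max(1, int((end - start) / spacing))
    gaps = rng.exponential(spacing, size=2 * n + 8)
    pos = start + np.cumsum(gaps)
    return pos[pos < end - 1].astype(np.int64)


def generate_genome(config: GenomeConfig | None = None, seed: int = 0) -> GenomeSpec:
    """Deterministically generate a GenomeSpec from scaffold parameters."""
    cfg = config or GenomeConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)

    chrom_lengths = {f"chr{i + 1}": cfg.autosome_length for i in range(cfg.n_autosomes)}
    chrom_lengths["chrX"] = cfg.x_length

    genes_rows, cgi_rows, lad_rows = [], [], []
    slot_pool = []  # candidate intergenic anchors for iDMR / planted DMR placement
    for chrom, length in chrom_lengths.items():
        is_x = chrom == "chrX"
        if not is_x:
            for s, e in _place_lads(rng, length, cfg):
                lad_rows.append((chrom, s, e))
        per_mb = cfg.x_genes_per_mb if is_x else cfg.genes_per_mb
        n_genes = int(per_mb * length / 1e6)
        spacing = length / max(n_genes, 1)
        for i in range(n_genes):
            tss = int(i * spacing + rng.uniform(0.15, 0.45) * spacing)
            strand = "+" if rng.random() < 0.5 else "-"
            glen = int(np.exp(rng.uniform(np.log(5_000), np.log(40_000))))
            if strand == "+":
                start, end = tss, min(tss + glen, length - 1)
            else:
                start, end = max(tss - glen, 0), tss + 1
            name = f"G{chrom[3:]}_{i:04d}"
            has_cgi = is_x or (rng.random() < cfg.cgi_promoter_fraction)
            genes_rows.append((name, chrom, start, end, strand, tss, has_cgi,
                               float(rng.lognormal(0.0, 0.4)),
                               float(rng.uniform(0.25, 0.42))))
            if has_cgi:
                cgi_rows.append((chrom, max(0, tss - cfg.cgi_size // 2),
                                 min(length, tss + cfg.cgi_size // 2)))
            if not is_x and i + 1 < n_genes:
                # mid-gap anchor, comfortably away from both promoters
                mid = int((i + 0.85) * spacing)
                slot_pool.append((chrom, mid))
        if not is_x:
            # intergenic CGIs up to the configured density
            want = int(cfg.cgi_per_mb * length / 1e6)
            have = sum(1 for c in cgi_rows if c[0] == chrom)
            for _ in range(max(0, want - have)):
                c = int(rng.uniform(1e5, length - 1e5))
                cgi_rows.append((chrom, c, c + cfg.cgi_size))

    genes = pd.DataFrame(genes_rows, columns=[
        "name", "chrom", "start", "end", "strand", "tss", "has_cgi_promoter",
        "mch_propensity", "xci_female_level"])
    cgis = iv.sort_intervals(pd.DataFrame(cgi_rows, columns=iv.BED_COLUMNS))
    # requested CGIs must be disjoint
    merged = iv.merge_intervals(cgis)
    if len(merged) < len(cgis):
        keep, last_end, last_chrom = [], -1, None
        for r in cgis.itertuples():
            if r.chrom != last_chrom or r.start >= last_end:
                keep.append(r.Index)
                last_end, last_chrom = r.end, r.chrom
        cgis = cgis.loc[keep].reset_index(drop=True)
    cgis["name"] = [f"CGI_{i:04d}" for i in range(len(cgis))]
    lads = pd.DataFrame(lad_rows, columns=iv.BED_COLUMNS)
    lads["name"] = [f"LAD_{i:03d}" for i in range(len(lads))]

    # iDMRs and planted DMRs from the intergenic slot pool
    n_dmr = (cfg.n_dmr_demethylation + cfg.n_dmr_maintenance
             + cfg.n_dmr_denovo + cfg.n_dmr_reprogramming)
    need = cfg.n_idmr + n_dmr
    if len(slot_pool) < need:
        raise ConfigurationError(
            f"genome too small: {len(slot_pool)} intergenic slots < {need} required")
    picks = rng.choice(len(slot_pool), size=need, replace=False)
    slots = [slot_pool[i] for i in picks]
    idmr_slots, dmr_slots = slots[:cfg.n_idmr], slots[cfg.n_idmr:]

    idmrs = pd.DataFrame(
        [(c, p, p + cfg.idmr_size, f"iDMR_{i:02d}")
         for i, (c, p) in enumerate(sorted(idmr_slots))],
        columns=iv.BED_COLUMNS + ["name"])

    etis = (["demethylation-error"] * cfg.n_dmr_demethylation
            + ["maintenance-error"] * cfg.n_dmr_maintenance
            + ["de-novo-error"] * cfg.n_dmr_denovo
            + ["reprogramming-error"] * cfg.n_dmr_reprogramming)
    dmr_rows = []
    for i, ((c, p), et) in enumerate(zip(sorted(dmr_slots), etis)):
        direction = "hypo" if et in ("maintenance-error", "de-novo-error") else "hyper"
        resolved = (et == "demethylation-error"
                    and rng.random() < cfg.resolved_fate_fraction)
        dmr_rows.append((c, p, p + cfg.dmr_size, f"DMR_{i:03d}", et, direction,
                         "resolved-in-xRPE" if resolved else "persistent"))
    planted_dmrs = pd.DataFrame(dmr_rows, columns=iv.BED_COLUMNS + [
        "name", "etiology", "direction", "fate"])

    # CpG site universe: background + densified CGIs, promoters, iDMRs, DMRs
    cpg_pos = {}
    for chrom, length in chrom_lengths.items():
        pos = [_dense_positions(rng, 2, length - 2, cfg.cpg_spacing)]
        for tbl, sp in ((cgis, cfg.cgi_cpg_spacing),
                        (idmrs, cfg.idmr_cpg_spacing),
                        (planted_dmrs, cfg.dmr_cpg_spacing)):
            for r in tbl[tbl["chrom"] == chrom].itertuples():
                pos.append(_dense_positions(rng, r.start, r.end, sp))
        for r in genes[genes["chrom"] == chrom].itertuples():
            pos.append(_dense_positions(rng, max(2, r.tss - 500),
                                        min(length - 2, r.tss + 500),
                                        cfg.promoter_cpg_spacing))
        p = np.unique(np.concatenate(pos))
        p = p[np.concatenate(([True], np.diff(p) >= 2))]  # CpGs cannot overlap
        cpg_pos[chrom] = p + 1  # 1-based position of the plus-strand C

    # CH site universe (strand-specific, fixed contexts)
    ctx = np.array(CH_CONTEXTS)
    w = np.array([_CH_WEIGHTS[c] for c in CH_CONTEXTS])
    w = w / w.sum()
    ch_sites = {}
    for chrom, length in chrom_lengths.items():
        p = _dense_positions(rng, 2, length - 2, cfg.ch_spacing) + 1
        ch_sites[chrom] = pd.DataFrame({
            "pos": p,
            "strand": np.where(rng.random(len(p)) < 0.5, "+", "-"),
            "context": ctx[rng.choice(len(ctx), size=len(p), p=w)],
        })

    # gene subsets driving the cohort's promoter-methylation structure
    auto_genes = genes.loc[genes["chrom"] != "chrX", "name"].tolist()
    pool = list(auto_genes)
    rng.shuffle(pool)

    def take(n):
        out, pool[:] = pool[:n], pool[n:]
        return sorted(out)

    rpe_signature = take(cfg.rpe_signature_size)
    states = ("Fibro", "iPSC", "iRPE", "xRPE", "cRPE", "nRPE")
    programs = {s: take(cfg.state_program_size) for s in states}

    # reprogramming errors hit "neutral" promoter CGIs: not state-program or
    # signature promoters, so planted error signal and planted state identity
    # stay separable
    special_genes = set(rpe_signature) | {g for p in programs.values() for g in p}
    cgi_promoter_names = []
    pgenes = genes[genes["has_cgi_promoter"] & (genes["chrom"] != "chrX")
                   & ~genes["name"].isin(special_genes)]
    for r in pgenes.itertuples():
        hits = cgis[(cgis["chrom"] == r.chrom) & (cgis["start"] <= r.tss)
                    & (cgis["end"] > r.tss)]
        if len(hits):
            cgi_promoter_names.append(hits.iloc[0]["name"])
    err_pool = sorted(cgi_promoter_names)
    rng.shuffle(err_pool)
    error_prone = sorted(err_pool[:cfg.n_error_prone_cgis])
    neutral_cgis = sorted(err_pool)

    x_genes = genes.loc[genes["chrom"] == "chrX", "name"].tolist()
    n_subj = int(round(cfg.xci_subject_fraction * len(x_genes)))
    xci_subject = sorted(rng.choice(x_genes, size=n_subj, replace=False).tolist())

    return GenomeSpec(chrom_lengths=chrom_lengths, cpg_pos=cpg_pos,
                      ch_sites=ch_sites, cgis=cgis, lads=lads, genes=genes,
                      idmrs=idmrs, planted_dmrs=planted_dmrs,
                      rpe_signature_genes=rpe_signature,
                      xci_subject_genes=xci_subject,
                      state_programs=programs, error_prone_cgis=error_prone,
                      neutral_cgis=neutral_cgis, config=cfg)
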