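"""End-to-end pipeline: simulate -> segment -> features -> cluster -> DMR ->
imprint/XCI -> mCH -> enrichment, with a JSON summary and full parameter
provenance. Every stage is also callable on its own through the library API.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, dmr as dmr_mod, enrichment, features, imprint_xci, mch
from . import segmentation as seg
from .genome import GenomeConfig, generate_genome
from .simulate import (ExpressionCoupling, cohort_lineages, simulate_cohort,
                       simulate_expression, simulate_methylome)
from .states import default_design, default_states


def paper_defaults() -> dict:
    """Every analysis threshold, named, in one place."""
    return {
        "pmd_min_size_bp": 10_000,        # PMD: size > 10 kb
        "pmd_max_level": 0.70,            # PMD: mean mCG < 70%
        "window_size_bp": 100_000,        # clustering windows
        "promoter_span_bp": 2_000,        # promoter = 2 kb upstream of TSS
        "tss_flank_bp": 500,              # TSS-proximal region = TSS +/- 500 bp
        "dmr_min_cpg": 20,                # DMR: >= 20 CpGs
        "dmr_max_q": 0.01,                # DMR: q < 0.01
        "dmr_min_delta": 0.30,            # DMR: methylation difference > 30%
        "proximal_max_dist_bp": 5_000,    # gene within 5 kb of a DMR
        "xci_male_max": 0.10,             # XCI subject: male <= 10%
        "xci_female_band": [0.20, 0.45],  # XCI subject: female 20-45%
        "xci_escape_max": 0.05,           # escape: <= 5% in all reprogrammed
        "cg_min_coverage": 1,             # CG sites covered at least once
        "ch_min_coverage": 10,            # CH sites covered at least 10 times
        "expression_pseudocount": 0.01,   # (FPKM + 0.01) ratio
        "ica_loading_threshold": 5.0,     # |loading| >= 5 contributors
        "kmeans_k_hyper": 5,              # hyper-DMRs -> clusters 1-5
        "kmeans_k_hypo": 2,               # hypo-DMRs -> clusters 6-7
        "go_min_term": 10,                # GO terms annotating 10-500 genes
        "go_max_term": 500,
        "go_p_threshold": 0.01,           # significance level for gene sets
        "go_min_overlap": 3,              # at least 3 annotated genes
    }


def small_genome_config() -> GenomeConfig:
    """A reduced scaffold for fast unit-scale runs."""
    return GenomeConfig(n_autosomes=2, autosome_length=3_000_000,
                        x_length=1_500_000, genes_per_mb=12, x_genes_per_mb=20,
                        cgi_per_mb=6, lad_mean_size=250_000, n_idmr=20,
                        n_dmr_demethylation=12, n_dmr_maintenance=6,
                        n_dmr_denovo=4, n_dmr_reprogramming=4,
                        state_program_size=12, rpe_signature_size=15,
                        n_error_prone_cgis=12)


@dataclass
class RunConfig:
    seed: int = 1
    outdir: str = "methylscape_out"
    scale: str = "small"              # "small" or "full" synthetic scaffold
    sample_paths: dict | None = None  # real data: sample -> cytosine report path
    thresholds: dict = field(default_factory=paper_defaults)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**{k: v for k, v in raw.items() if k in cls.__annotations__})
        th = paper_defaults()
        th.update(raw.get("thresholds") or {})
        cfg.thresholds = th
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.scale not in ("small", "full"):
            raise ValueError(f"unknown scale {self.scale!r}")
        for name, p in (self.sample_paths or {}).items():
            if not Path(p).exists():
                raise FileNotFoundError(f"sample {name!r}: missing path {p}")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Run the full synthetic-cohort analysis; returns the summary dict.

    Stage outputs (PMD BEDs, DMR tables, XCI calls, mCH profiles, dendrograms)
    and ``summary.json`` are written under ``config.outdir``.
    """
    if config.sample_paths:
        raise NotImplementedError(
            "file-based cohorts are consumed through the library API "
            "(io.read_cytosine_report + the stage functions); the orchestrated "
            "run operates on the synthetic cohort")
    th = config.thresholds
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    gcfg = small_genome_config() if config.scale == "small" else GenomeConfig()
    genome = generate_genome(gcfg, seed=config.seed)
    genome.write_annotations(out / "annotations")
    design = default_design()
    states = default_states()
    tables, manifest = simulate_cohort(genome, design, config.seed, states=states)
    (out / "manifest.json").write_text(json.dumps(_jsonable(manifest), indent=1))
    summary: dict = {"seed": config.seed, "scale": config.scale,
                     "thresholds": th, "n_samples": len(tables)}

    # --- segmentation & PMDs ---------------------------------------------
    pmd_sets, pmd_mb = {}, {}
    for name, tbl in tables.items():
        domains = seg.segment_methylome(tbl)
        pmds = seg.call_pmds(domains, min_size=th["pmd_min_size_bp"],
                             max_level=th["pmd_max_level"])
        pmd_sets[name] = pmds
        pmd_mb[name] = round(float((pmds["end"] - pmds["start"]).sum()) / 1e6, 3)
        pmds.to_csv(out / f"pmds_{name}.bed", sep="\t", header=False, index=False)
    summary["pmd_mb_per_sample"] = pmd_mb

    pan_crpe = seg.pan_union([pmd_sets[f"cRPE{i}"] for i in "1234"])
    _, fractions = seg.classify_pmds(pmd_sets["iRPE1"], pmd_sets["Fibro1"],
                                     pmd_sets["iPSC1"], pan_crpe)
    summary["irpe1_pmd_class_fractions"] = {k: round(v, 4)
                                            for k, v in fractions.items()}

    # --- promoter features & clustering ----------------------------------
    proms = features.promoters(genome.genes[genome.genes["chrom"] != "chrX"],
                               span=th["promoter_span_bp"])
    fm = features.feature_means(tables, proms)
    sample_states = {s.name: s.state for s in design.samples}
    results = {}
    for method in ("raw", "pca", "ica"):
        if method == "raw":
            Z, labels = clustering.cluster_raw(fm)
        else:
            dec = clustering.run_ica(fm, seed=config.seed) if method == "ica" \
                else clustering.run_pca(fm)
            Z, labels = clustering.cluster_components(dec)
        (out / f"dendrogram_{method}.nwk").write_text(
            clustering.linkage_to_newick(Z, labels))
        assign = clustering.cut_clusters(Z, labels, n_clusters=6)
        purity = _clade_purity(assign, sample_states)
        results[method] = purity
    summary["clustering_state_purity"] = results

    dec = clustering.run_ica(fm, seed=config.seed)
    reprog = [s.name for s in design.samples if s.reprogrammed]
    nonrep = [s.name for s in design.samples if not s.reprogrammed]
    disc = clustering.discriminating_components(dec, reprog, nonrep)
    summary["reprogramming_component"] = {
        "component": disc.iloc[0]["component"],
        "wilcoxon_p": float(disc.iloc[0]["p_value"])}

    # --- DMRs: call, cluster, origin/fate, proximal genes -----------------
    g1 = {k: tables[k] for k in ("iRPE1", "iRPE2")}
    g2 = {k: tables[k] for k in ("nRPE1", "nRPE2", "nRPE3", "nRPE4")}
    dmrs = dmr_mod.call_dmrs(g1, g2, min_cpg=th["dmr_min_cpg"],
                             max_q=th["dmr_max_q"], min_delta=th["dmr_min_delta"])
    dmrs.to_csv(out / "dmrs_irpe_vs_nrpe.tsv", sep="\t", index=False)
    summary["dmr_counts"] = {
        "hyper": int((dmrs["direction"] == "hyper").sum()),
        "hypo": int((dmrs["direction"] == "hypo").sum())}

    esc_tables = {
        f"ESC{i}": simulate_methylome(genome, states["ESC"], config.seed + 9000 + i,
                                      sex="M")
        for i in (1, 2)}
    state_levels = _dmr_state_levels(dmrs, tables | esc_tables, sample_states
                                     | {"ESC1": "ESC", "ESC2": "ESC"})
    if len(dmrs):
        classified = dmr_mod.classify_all(dmrs, state_levels)
        summary["dmr_origins"] = classified["origin"].value_counts().to_dict()
        hyper = classified[classified["direction"] == "hyper"]
        if len(hyper) >= th["kmeans_k_hyper"]:
            labels_km = dmr_mod.kmeans_dmrs(state_levels.loc[hyper.index],
                                            th["kmeans_k_hyper"], seed=config.seed)
            summary["hyper_dmr_cluster_sizes"] = \
                labels_km.value_counts().sort_index().to_dict()
        _, prox_summary = dmr_mod.proximal_genes(
            dmrs, genome.genes, max_dist=th["proximal_max_dist_bp"])
        summary["dmr_proximal_genes"] = prox_summary

    # --- imprinting --------------------------------------------------------
    idmr_fm = features.feature_means(
        tables, genome.idmrs.rename(columns={"name": "feature_id"}))
    status = imprint_xci.idmr_status(idmr_fm.values)
    summary["idmr_hyper_pct"] = {
        s: round(float(v), 2)
        for s, v in imprint_xci.idmr_summary(status)["hyper_pct"].items()}

    # --- XCI ----------------------------------------------------------------
    x_genes = genome.genes[genome.genes["chrom"] == "chrX"]
    tssf = features.tss_regions(x_genes, flank=th["tss_flank_bp"])
    tss_fm = features.feature_means(tables, tssf, min_sites=5)
    females = [s.name for s in design.samples
               if s.sex == "F" and not s.reprogrammed]
    males = [s.name for s in design.samples
             if s.sex == "M" and not s.reprogrammed]
    calls = imprint_xci.xci_candidates(tss_fm.values, females, males,
                                       male_max=th["xci_male_max"],
                                       female_band=tuple(th["xci_female_band"]))
    n_subj, n_call, pct = imprint_xci.xci_subject_fraction(calls)
    escape = imprint_xci.xci_escape(
        calls, tss_fm.values[["iPSC1", "iRPE1", "xRPE1"]],
        escape_max=th["xci_escape_max"])
    n_esc = int((escape["status"] == "XCI-escaped").sum())
    summary["xci"] = {"subject": n_subj, "callable": n_call,
                      "subject_pct": round(pct, 1), "escaped": n_esc,
                      "escaped_pct": round(100.0 * n_esc / max(n_subj, 1), 1)}
    escape.to_csv(out / "xci_calls.tsv", sep="\t")

    # --- expression coupling ----------------------------------------------
    fpkm = simulate_expression(genome, design, config.seed)
    ratios = imprint_xci.expression_ratio(fpkm, "iRPE1", "cRPE4",
                                          pseudocount=th["expression_pseudocount"])
    escaped_genes = escape.index[escape["status"] == "XCI-escaped"]
    subject_genes = escape.index[escape["status"] == "XCI-subject"]
    if len(escaped_genes) >= 3 and len(subject_genes) >= 3:
        summary["xci_derepression"] = imprint_xci.escape_derepression_test(
            ratios, escaped_genes, subject_genes)

    # --- mCH ----------------------------------------------------------------
    profiles = {}
    for name in ("Fibro1", "iPSC1", "iRPE1", "xRPE1", "cRPE1", "nRPE2"):
        prof = mch.mch_levels(tables[name], min_coverage=th["ch_min_coverage"])
        profiles[name] = {"chg": round(prof.chg, 5), "chh": round(prof.chh, 5),
                          "top_context": mch.context_ranking(prof)[0]}
    summary["mch"] = profiles
    pd.DataFrame({n: mch.mch_levels(tables[n]).as_series()
                  for n in profiles}).to_csv(out / "mch_contexts.tsv", sep="\t")

    gb = features.gene_bodies(genome.genes[genome.genes["chrom"] != "chrX"])
    gb_mch = features.feature_means({"nRPE2": tables["nRPE2"]}, gb, context="CH",
                                    min_sites=3)
    corr = mch.mch_expression_correlation(gb_mch.values["nRPE2"],
                                          np.log2(fpkm["nRPE2"] + 1))
    summary["nrpe_genebody_mch_expression_rho"] = round(corr["rho"], 3)

    # --- enrichment: RPE signature among RPE-component contributors --------
    rpe = [s.name for s in design.samples if sample_states[s.name]
           in ("iRPE", "xRPE", "cRPE", "nRPE")]
    nonrpe = [s.name for s in design.samples if s.name not in rpe]
    disc_rpe = clustering.discriminating_components(dec, rpe, nonrpe)
    comp = disc_rpe.iloc[0]["component"]
    contrib = clustering.top_contributors(dec, comp, top_n=25)
    universe = list(fm.dropna_features().values.index)
    sig = [g for g in genome.rpe_signature_genes if g in universe]
    res = enrichment.fisher_overlap(list(contrib["feature_id"]), sig, universe,
                                    name="rpe_signature_in_rpe_component")
    summary["rpe_signature_enrichment"] = {
        "component": comp, "n_contributors": len(contrib),
        "odds_ratio": round(res.odds_ratio, 2), "p_value": res.p_value}

    (out / "summary.json").write_text(json.dumps(_jsonable(summary), indent=1,
                                                 sort_keys=True))
    return summary


def _clade_purity(assign: dict, sample_states: dict) -> float:
    """Fraction of samples whose flat cluster is dominated by their own state."""
    df = pd.DataFrame({"cluster": pd.Series(assign),
                       "state": pd.Series(sample_states)}).dropna()
    correct = 0
    for _, grp in df.groupby("cluster"):
        correct += grp["state"].value_counts().iloc[0]
    return round(float(correct) / len(df), 4)


def _dmr_state_levels(dmrs: pd.DataFrame, tables: dict,
                      sample_states: dict) -> pd.DataFrame:
    """DMR x state mean methylation (state mean of per-sample feature means)."""
    if len(dmrs) == 0:
        return pd.DataFrame()
    feats = dmrs.reset_index()[["index", "chrom", "start", "end"]].rename(
        columns={"index": "feature_id"})
    fm = features.feature_means(tables, feats)
    by_state = {}
    for state in sorted(set(sample_states.values())):
        cols = [s for s, st in sample_states.items() if st == state
                and s in fm.values.columns]
        if cols:
            by_state[state] = fm.values[cols].mean(axis=1)
    out = pd.DataFrame(by_state)
    out.index = dmrs.index
    return out
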