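"""Cohort simulator: planted structure, error model, lineage memory,
determinism, and methylation-expression coupling."""

import numpy as np
import pandas as pd
import pytest

import methylscape.intervals as iv
from methylscape.genome import GenomeConfig, generate_genome
from methylscape.io import cg_only, levels
from methylscape.mch import context_ranking, mch_levels
from methylscape.simulate import (ExpressionCoupling, cohort_lineages,
                                  select_pmd_lads, simulate_cohort,
                                  simulate_expression, simulate_methylome,
                                  true_cg_levels)
from methylscape.states import (CellStateParams, CohortDesign, DesignError,
                                SampleSpec, default_design, default_states)


def test_fibroblast_pmd_depression_matches_planted_depth(genome_small):
    st = default_states()["Fibro"]
    tbl = simulate_methylome(genome_small, st, 42)
    pmds = select_pmd_lads(genome_small, st, 42)
    cg = cg_only(tbl)
    cg = cg[(cg["chrom"] != "chrX") & (cg["total"] > 0)]
    inside = outside = []
    mask = np.concatenate([
        iv.sites_in_intervals(grp["pos"].to_numpy(), pmds, chrom)
        for chrom, grp in cg.groupby("chrom", observed=True)])
    lv = levels(cg)
    # restrict outside to plain background (no CGI/promoter/planted regions)
    special = pd.concat([genome_small.cgis[iv.BED_COLUMNS],
                         genome_small.idmrs[iv.BED_COLUMNS],
                         genome_small.planted_dmrs[iv.BED_COLUMNS]])
    spec_mask = np.concatenate([
        iv.sites_in_intervals(grp["pos"].to_numpy(), special, chrom)
        for chrom, grp in cg.groupby("chrom", observed=True)])
    prom = np.concatenate([
        iv.sites_in_intervals(
            grp["pos"].to_numpy(),
            pd.DataFrame({"chrom": chrom,
                          "start": genome_small.genes.loc[
                              genome_small.genes["chrom"] == chrom, "tss"] - 600,
                          "end": genome_small.genes.loc[
                              genome_small.genes["chrom"] == chrom, "tss"] + 601}),
            chrom)
        for chrom, grp in cg.groupby("chrom", observed=True)])
    clean = ~spec_mask & ~prom
    drop = np.mean(lv[clean & ~mask]) - np.mean(lv[clean & mask])
    assert drop == pytest.approx(0.35, abs=0.02)


def test_nonconversion_floor_on_unmethylated_ch():
    cfg = GenomeConfig(n_autosomes=1, autosome_length=2_000_000,
                       x_length=1_000_000, n_idmr=5, n_dmr_demethylation=2,
                       n_dmr_maintenance=0, n_dmr_denovo=0,
                       n_dmr_reprogramming=0)
    g = generate_genome(cfg, seed=2)
    st = CellStateParams("flat", nonconversion=0.005)  # all mCH rates zero
    tbl = simulate_methylome(g, st, 3)
    ch = tbl[tbl["context"] != "CG"]
    obs = ch["meth"].sum() / ch["total"].sum()
    assert obs == pytest.approx(0.005, abs=0.0015)


def test_site_levels_converge_to_planted_truth(genome_small):
    st = default_states()["nRPE"]
    tbl = simulate_methylome(genome_small, st, 5)
    cg = tbl[(tbl["context"] == "CG") & (tbl["chrom"] == "chr1")
             & (tbl["strand"] == "+")]
    truth = true_cg_levels(genome_small, st, "chr1",
                           pmd_intervals=select_pmd_lads(genome_small, st, 5))
    covered = cg["total"].to_numpy() > 0
    obs = levels(cg)[covered]
    t = truth[covered]
    # aggregate check: mean deviation within 3 SE of the pooled binomial error
    n = cg["total"].to_numpy()[covered]
    se = np.sqrt(np.sum(t * (1 - t) / n)) / covered.sum()
    assert abs(np.mean(obs - t)) < 3 * se + 0.005  # + non-conversion offset


@pytest.mark.parametrize("state,first", [("nRPE", "CAC"), ("iPSC", "CAG")])
def test_planted_mch_context_ranking(genome_small, state, first):
    tbl = simulate_methylome(genome_small, default_states()[state], 7)
    assert context_ranking(mch_levels(tbl))[0] == first


def test_lineage_memory_shared_within_patient_absent_elsewhere(cohort):
    _, manifest = cohort
    errs = manifest["lineage_errors"]
    assert set(errs) == {"P1", "P2"}
    # every reprogrammed sample's patient has exactly one error set
    for s in manifest["samples"]:
        if s["reprogrammed"]:
            assert s["patient"] in errs
    # the two patients share the common error core but differ in extras
    e1, e2 = set(errs["P1"]["cgi_error_ids"]), set(errs["P2"]["cgi_error_ids"])
    assert e1 & e2
    assert e1 != e2
    # patient 2 carries the 13 extra hypermethylated iDMRs on top of the 6
    assert len(errs["P1"]["idmr_hyper_ids"]) == 6
    assert len(errs["P2"]["idmr_hyper_ids"]) == 19
    assert set(errs["P1"]["idmr_hyper_ids"]) <= set(errs["P2"]["idmr_hyper_ids"])


def test_errored_cgis_methylated_only_in_reprogrammed_lineage(genome_small,
                                                             cohort):
    tables, manifest = cohort
    err_ids = manifest["lineage_errors"]["P1"]["cgi_error_ids"]
    err = genome_small.cgis[genome_small.cgis["name"].isin(err_ids)]

    def cgi_level(sample):
        cg = cg_only(tables[sample])
        vals = []
        for chrom, grp in cg.groupby("chrom", observed=True):
            m = iv.sites_in_intervals(grp["pos"].to_numpy(), err, chrom)
            sel = grp[m & (grp["total"] > 0)]
            vals.append(levels(sel))
        return float(np.mean(np.concatenate(vals)))

    for s in ("iPSC1", "iRPE1", "xRPE1"):
        assert cgi_level(s) > 0.7
    for s in ("Fibro1", "cRPE1", "nRPE1"):
        assert cgi_level(s) < 0.2


def test_same_seed_identical_manifest_and_tables(genome_small, design):
    t1, m1 = simulate_cohort(genome_small, design, 99)
    t2, m2 = simulate_cohort(genome_small, design, 99)
    assert m1 == m2
    pd.testing.assert_frame_equal(t1["iRPE1"], t2["iRPE1"])


def test_single_state_single_sample_design(genome_small):
    d = CohortDesign([SampleSpec("only", "nRPE", "N9", "F", "in_vivo", False)])
    tables, manifest = simulate_cohort(genome_small, d, 4)
    assert list(tables) == ["only"]
    assert manifest["lineage_errors"] == {}


def test_unknown_state_raises_design_error(genome_small):
    d = CohortDesign([SampleSpec("s", "Plasma", "P", "F", "in_vitro", False)])
    with pytest.raises(DesignError, match="Plasma"):
        simulate_cohort(genome_small, d, 0)


def test_invalid_state_params_rejected():
    with pytest.raises(ValueError):
        CellStateParams("bad", baseline_mcg=1.2)
    with pytest.raises(ValueError):
        CellStateParams("bad", mean_depth=0)


class TestExpression:
    def test_escaped_genes_two_fold_derepressed(self, genome_small, design):
        lin = cohort_lineages(genome_small, design, 1)
        fpkm = simulate_expression(genome_small, design, 1, lineages=lin)
        ratio = np.log2((fpkm["iRPE1"] + 0.01) / (fpkm["cRPE4"] + 0.01))
        esc = lin["P1"].xci_escaped_genes
        assert ratio.reindex(esc).median() == pytest.approx(1.0, abs=0.35)
        others = [x for x in genome_small.xci_subject_genes if x not in esc]
        assert abs(ratio.reindex(others).median()) < 0.35
        assert (fpkm.to_numpy() >= 0).all()

    def test_zero_coupling_decouples_expression(self, genome_small, design):
        from scipy.stats import spearmanr
        fpkm = simulate_expression(genome_small, design, 1,
                                   coupling=ExpressionCoupling.zero())
        prop = genome_small.genes.set_index("name")["mch_propensity"]
        rho = spearmanr(fpkm["nRPE2"].reindex(prop.index), prop).statistic
        assert abs(rho) < 0.2

    def test_planted_inverse_gene_body_coupling_recovered(self):
        from methylscape import features
        from methylscape.mch import mch_expression_correlation
        cfg = GenomeConfig(n_autosomes=2, autosome_length=3_000_000,
                           x_length=1_000_000, genes_per_mb=40,
                           x_genes_per_mb=10, n_idmr=10,
                           n_dmr_demethylation=4, n_dmr_maintenance=0,
                           n_dmr_denovo=0, n_dmr_reprogramming=0,
                           state_program_size=5, rpe_signature_size=5,
                           n_error_prone_cgis=5)
        g = generate_genome(cfg, seed=6)
        design = CohortDesign([SampleSpec("nRPE1", "nRPE", "N1", "F",
                                          "in_vivo", False)])
        tbl = simulate_methylome(g, default_states()["nRPE"], 8)
        coupling = ExpressionCoupling(mch_slope_log2=-3.0)  # planted effect
        fpkm = simulate_expression(g, design, 8, coupling=coupling)
        gb = features.gene_bodies(g.genes[g.genes["chrom"] != "chrX"])
        m = features.feature_means({"nRPE1": tbl}, gb, context="CH",
                                   min_sites=3)
        corr = mch_expression_correlation(m.values["nRPE1"],
                                          np.log2(fpkm["nRPE1"] + 1))
        assert corr["rho"] < -0.15
        assert corr["p_value"] < 0.01
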