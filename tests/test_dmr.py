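"""DMR calling filters, k-means profiles, origin/fate rules, gene proximity,
CGI flank profiles and the hypermethylation/flank-PMD co-occurrence test."""

import numpy as np
import pandas as pd
import pytest

from methylscape import dmr as D

from conftest import make_sites


def _group(level_fn, n_samples, seed0, n_sites=400, spacing=60):
    pos = np.arange(1, n_sites + 1) * spacing
    return {f"s{seed0 + i}": make_sites("chr1", pos, level_fn(pos),
                                        depth=10, seed=seed0 + i)
            for i in range(n_samples)}


def test_planted_region_detected_with_direction():
    # 1-kb region (sites 100..130, ~30 CpGs) at +0.5 delta
    def hi(pos):
        lv = np.full(len(pos), 0.3)
        lv[(pos >= 6000) & (pos < 7800)] = 0.8
        return lv

    def lo(pos):
        return np.full(len(pos), 0.3)

    g1 = _group(hi, 2, 0)
    g2 = _group(lo, 2, 50)
    out = D.call_dmrs(g1, g2)
    assert len(out) == 1
    r = out.iloc[0]
    assert r["direction"] == "hyper"
    assert r["delta"] == pytest.approx(0.5, abs=0.08)
    assert r["start"] < 6000 + 600 and r["end"] > 7800 - 600
    # every emitted DMR satisfies the three output filters
    assert r["n_cpg"] >= 20 and r["q_value"] < 0.01 and abs(r["delta"]) > 0.30


def test_region_with_fifteen_cpgs_rejected():
    def hi(pos):
        lv = np.full(len(pos), 0.3)
        lv[(pos >= 6000) & (pos < 6900)] = 0.8  # 15 sites at spacing 60
        return lv

    g1 = _group(hi, 2, 0)
    g2 = _group(lambda p: np.full(len(p), 0.3), 2, 50)
    out = D.call_dmrs(g1, g2)
    assert len(out) == 0


def test_identical_groups_yield_no_dmrs():
    g1 = _group(lambda p: np.full(len(p), 0.5), 2, 0)
    g2 = _group(lambda p: np.full(len(p), 0.5), 4, 50)
    assert len(D.call_dmrs(g1, g2)) == 0


def test_sex_chromosomes_excluded_by_default():
    pos = np.arange(1, 401) * 60
    g1 = {"a": make_sites("chrX", pos, np.full(400, 0.9), seed=1)}
    g2 = {"b": make_sites("chrX", pos, np.full(400, 0.1), seed=2)}
    assert len(D.call_dmrs(g1, g2)) == 0
    assert len(D.call_dmrs(g1, g2, exclude_sex_chroms=False)) >= 1


def test_metilene_reader_applies_filters(tmp_path):
    path = tmp_path / "met.tsv"
    pd.DataFrame([
        ["chr1", 100, 900, 0.001, 45.0, 25],    # passes (percent delta)
        ["chr1", 2000, 2900, 0.001, 45.0, 10],  # too few CpGs
        ["chr1", 5000, 5900, 0.2, 45.0, 30],    # q too large
        ["chr1", 9000, 9900, 0.001, -35.0, 30],  # passes, hypo
    ]).to_csv(path, sep="\t", header=False, index=False)
    out = D.read_metilene(path)
    assert len(out) == 2
    assert list(out["direction"]) == ["hyper", "hypo"]


class TestKmeans:
    def test_two_archetypes_perfectly_separated(self):
        rng = np.random.default_rng(0)
        a = np.tile([0.9, 0.9, 0.1], (20, 1)) + rng.normal(0, 0.02, (20, 3))
        b = np.tile([0.1, 0.1, 0.9], (20, 1)) + rng.normal(0, 0.02, (20, 3))
        prof = pd.DataFrame(np.vstack([a, b]),
                            columns=["iPSC", "iRPE", "nRPE"])
        labels = D.kmeans_dmrs(prof, k=2, seed=0)
        assert set(labels.iloc[:20]) == {1}   # high-iPSC cluster numbered first
        assert set(labels.iloc[20:]) == {2}

    def test_k_one_single_cluster(self):
        prof = pd.DataFrame(np.random.default_rng(1).uniform(size=(10, 3)))
        labels = D.kmeans_dmrs(prof, k=1, seed=0)
        assert set(labels) == {1}

    def test_missing_values_imputed_by_state_mean(self):
        prof = pd.DataFrame({"iPSC": [0.9, np.nan, 0.1, 0.1],
                             "nRPE": [0.1, 0.1, 0.9, 0.9]})
        labels = D.kmeans_dmrs(prof, k=2, seed=0)
        assert labels.iloc[1] == labels.iloc[0]  # imputed toward column mean


@pytest.mark.parametrize("levels,direction,origin", [
    ({"iPSC": .8, "ESC": .8, "nRPE": .1, "iRPE": .8}, "hyper",
     "demethylation-error"),
    ({"iPSC": .8, "ESC": .8, "nRPE": .8, "iRPE": .1}, "hypo",
     "maintenance-error"),
    ({"iPSC": .1, "ESC": .1, "nRPE": .45, "iRPE": .1}, "hypo",
     "de-novo-error"),
    ({"iPSC": .85, "ESC": .1, "nRPE": .1, "iRPE": .85}, "hyper",
     "reprogramming-error"),
])
def test_origin_rules(levels, direction, origin):
    got, _ = D.classify_origin_fate(levels, direction)
    assert got == origin


def test_missing_state_gives_unclassified():
    got, fate = D.classify_origin_fate({"iPSC": .8, "nRPE": .1, "iRPE": .8},
                                       "hyper")
    assert got == "unclassified" and fate == "unknown"


def test_fate_resolved_when_xrpe_approaches_nrpe():
    base = {"iPSC": .8, "ESC": .8, "nRPE": .1, "iRPE": .8}
    _, fate = D.classify_origin_fate({**base, "xRPE": .15}, "hyper")
    assert fate == "resolved-in-xRPE"
    _, fate = D.classify_origin_fate({**base, "xRPE": .78}, "hyper")
    assert fate == "persistent"


class TestProximalGenes:
    genes = pd.DataFrame({"name": ["g1", "g2"], "chrom": ["chr1", "chr1"],
                          "start": [10_000, 50_000], "end": [20_000, 60_000]})

    def _dmrs(self, start, end, direction="hyper"):
        return pd.DataFrame({"chrom": ["chr1"], "start": [start],
                             "end": [end], "direction": [direction]})

    def test_distance_boundary_at_max_dist(self):
        pairs, _ = D.proximal_genes(self._dmrs(25_000, 26_000), self.genes)
        assert list(pairs["gene"]) == ["g1"]  # 5,000 away: proximal
        pairs, _ = D.proximal_genes(self._dmrs(25_001, 26_000), self.genes)
        assert list(pairs["gene"]) == []      # 5,001 away: not proximal

    def test_overlap_distance_zero(self):
        pairs, _ = D.proximal_genes(self._dmrs(15_000, 16_000), self.genes)
        assert pairs.iloc[0]["distance"] == 0

    def test_union_count_deduplicates(self):
        hyper = {f"g{i}" for i in range(1254)}
        hypo = {f"g{i}" for i in range(1222, 1427)}  # 32 shared with hyper
        assert len(hyper & hypo) == 32
        assert D.count_union(hyper, hypo) == 1427

    def test_matches_all_pairs_brute_force(self):
        rng = np.random.default_rng(8)
        genes = pd.DataFrame({
            "name": [f"g{i}" for i in range(40)], "chrom": "chr1",
            "start": rng.integers(0, 500_000, 40)})
        genes["end"] = genes["start"] + rng.integers(1_000, 30_000, 40)
        dmrs = pd.DataFrame({"chrom": "chr1",
                             "start": rng.integers(0, 500_000, 15)})
        dmrs["end"] = dmrs["start"] + rng.integers(500, 3_000, 15)
        dmrs["direction"] = "hyper"
        pairs, _ = D.proximal_genes(dmrs, genes, max_dist=5_000)
        got = set(zip(pairs["dmr"], pairs["gene"]))
        want = set()
        for di, d in dmrs.iterrows():
            for _, g in genes.iterrows():
                gap = max(0, max(d["start"], g["start"])
                          - min(d["end"], g["end"]))
                if gap <= 5_000:
                    want.add((di, g["name"]))
        assert got == want


class TestCgiFlank:
    def test_single_cgi_profile_equals_own_binned_levels(self):
        pos = np.arange(1, 201) * 100  # 20 kb of sites
        lv = np.linspace(0, 1, 200)
        sites = make_sites("chr1", pos, lv, depth=100, exact=True)
        cgis = pd.DataFrame({"chrom": ["chr1"], "start": [8_000],
                             "end": [12_000], "name": ["cgi1"]})
        prof = D.cgi_flank_profile(sites, cgis, flank=5_000, flank_bins=5,
                                   body_bins=4, merge_strands=False)
        body = prof[prof["zone"] == "cgi"]
        inside = (pos - 1 >= 8_000) & (pos - 1 < 12_000)
        assert body["mean_level"].mean() == pytest.approx(
            np.round(lv[inside] * 100).mean() / 100, abs=0.01)

    def test_planted_cooccurrence_detected(self):
        rng = np.random.default_rng(3)
        n = 60
        cgis = pd.DataFrame({"chrom": "chr1",
                             "start": np.arange(n) * 50_000 + 20_000})
        cgis["end"] = cgis["start"] + 1_000
        cgis["name"] = [f"c{i}" for i in range(n)]
        hyper = rng.random(n) < 0.4
        levels_ = np.where(hyper, 0.9, 0.05)
        # flank PMDs co-occur with hypermethylation
        pmd_rows = cgis[hyper]
        pmds = pd.DataFrame({"chrom": "chr1",
                             "start": pmd_rows["start"] - 5_000,
                             "end": pmd_rows["end"] + 5_000})
        res = D.cgi_pmd_cooccurrence(pd.Series(levels_, index=cgis["name"]),
                                     cgis, pmds)
        assert res["odds_ratio"] > 1
        assert res["p_value"] < 0.01

    def test_no_flank_effect_gives_no_association(self):
        n = 40
        cgis = pd.DataFrame({"chrom": "chr1",
                             "start": np.arange(n) * 50_000 + 20_000})
        cgis["end"] = cgis["start"] + 1_000
        cgis["name"] = [f"c{i}" for i in range(n)]
        levels_ = np.where(np.arange(n) % 2 == 0, 0.9, 0.05)
        # flank PMDs split evenly between hyper and non-hyper CGIs
        flanked = np.arange(n) % 4 < 2
        pmds = pd.DataFrame({"chrom": "chr1",
                             "start": cgis["start"][flanked] - 5_000,
                             "end": cgis["end"][flanked] + 5_000})
        res = D.cgi_pmd_cooccurrence(pd.Series(levels_, index=cgis["name"]),
                                     cgis, pmds)
        assert res["p_value"] > 0.05
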