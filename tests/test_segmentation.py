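"""Change-point segmentation, PMD calling, MDL points, interval Venn algebra
and PMD lineage classification."""

import numpy as np
import pandas as pd
import pytest

import methylscape.intervals as iv
from methylscape import segmentation as seg

from conftest import make_sites


def _three_block_sites(seed=0, n=500, depth=10):
    rng = np.random.default_rng(seed)
    pos = np.arange(1, 3 * n + 1) * 100  # one CpG per 100 bp
    truth = np.concatenate([np.full(n, 0.85), np.full(n, 0.45),
                            np.full(n, 0.85)])
    total = np.full(3 * n, depth)
    meth = rng.binomial(total, truth)
    return pd.DataFrame({"chrom": "chr1", "pos": pos, "strand": "+",
                         "context": "CG", "meth": meth, "total": total})


def test_planted_three_block_breakpoints_within_five_sites():
    sites = _three_block_sites()
    domains = seg.segment_methylome(sites, merge_strands=False)
    assert len(domains) == 3
    # breakpoints at site indices 500 and 1000 -> positions ~50000 and ~100000
    assert abs(domains.iloc[0]["end"] - 500 * 100) <= 5 * 100
    assert abs(domains.iloc[1]["end"] - 1000 * 100) <= 5 * 100
    assert domains.iloc[1]["mean_level"] == pytest.approx(0.45, abs=0.03)


def test_constant_methylome_single_domain():
    sites = make_sites("chr1", np.arange(1, 1001) * 50, np.full(1000, 0.8),
                       depth=10, seed=1)
    domains = seg.segment_methylome(sites, merge_strands=False)
    assert len(domains) == 1


def test_infinite_penalty_one_domain_per_chrom():
    sites = _three_block_sites()
    domains = seg.segment_methylome(sites, penalty=1e18, merge_strands=False)
    assert len(domains) == 1


def test_few_sites_chromosome_skipped_with_warning():
    sites = make_sites("chr9", [10, 20, 30], [0.5] * 3, exact=True)
    with pytest.warns(UserWarning, match="chr9"):
        domains = seg.segment_methylome(sites, merge_strands=False)
    assert len(domains) == 0


def test_domains_tile_and_weighted_mean_matches_site_mean():
    sites = _three_block_sites(seed=3)
    domains = seg.segment_methylome(sites, merge_strands=False)
    # non-overlapping tiling of the covered span
    assert (domains["start"].to_numpy()[1:] == domains["end"].to_numpy()[:-1]).all()
    w = domains["n_cpg"].to_numpy()
    weighted = np.sum(w * domains["mean_level"].to_numpy()) / w.sum()
    site_mean = (sites["meth"] / sites["total"]).mean()
    assert weighted == pytest.approx(site_mean, abs=1e-12)


@pytest.mark.parametrize("size,level,is_pmd", [
    (15_000, 0.55, True),    # larger than 10 kb, below 70%
    (10_000, 0.50, False),   # boundary: size must be strictly greater
    (50_000, 0.70, False),   # boundary: level must be strictly lower
])
def test_pmd_thresholds_strict(size, level, is_pmd):
    domains = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [size],
                            "n_cpg": [100], "mean_level": [level]})
    assert (len(seg.call_pmds(domains)) == 1) == is_pmd


def test_called_pmds_are_a_subset_with_verifiable_thresholds():
    rng = np.random.default_rng(4)
    domains = pd.DataFrame({
        "chrom": "chr1",
        "start": np.arange(20) * 50_000,
        "end": np.arange(1, 21) * 50_000 - rng.integers(0, 45_000, 20),
        "n_cpg": rng.integers(20, 500, 20),
        "mean_level": rng.uniform(0.3, 0.95, 20)})
    pmds = seg.call_pmds(domains)
    assert len(pmds) <= len(domains)
    assert ((pmds["end"] - pmds["start"]) > 10_000).all()
    assert (pmds["mean_level"] < 0.70).all()


def test_mdl_point_arithmetic_and_empty_error():
    domains = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100_000],
                            "n_cpg": [10], "mean_level": [0.5]})
    pt = seg.mdl_table(domains).iloc[0]
    assert pt["log10_size"] == pytest.approx(5.0)
    assert pt["level_pct"] == pytest.approx(50.0)
    with pytest.raises(ValueError):
        seg.mdl_table(domains.iloc[0:0])


class TestVenn:
    def test_two_set_example(self):
        a = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [100]})
        b = pd.DataFrame({"chrom": ["c"], "start": [50], "end": [150]})
        v = iv.venn_basewise({"A": a, "B": b})
        assert v == {frozenset("A"): 50, frozenset("B"): 50,
                     frozenset("AB"): 50}

    def test_identical_sets_no_symmetric_difference(self):
        a = pd.DataFrame({"chrom": ["c"], "start": [5], "end": [42]})
        v = iv.venn_basewise({"A": a, "B": a.copy()})
        assert v == {frozenset("AB"): 37}

    def test_matches_per_base_brute_force_on_random_sets(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            sets = {}
            for name in "ABC":
                s = np.sort(rng.integers(0, 500, 6))
                sets[name] = pd.DataFrame({
                    "chrom": "c", "start": s[::2],
                    "end": s[::2] + rng.integers(1, 80, 3)})
            got = iv.venn_basewise(sets)
            grid = np.zeros((3, 700), dtype=bool)
            for k, name in enumerate("ABC"):
                for r in sets[name].itertuples():
                    grid[k, r.start:r.end] = True
            want = {}
            for i in range(700):
                key = frozenset(n for n, m in zip("ABC", grid[:, i]) if m)
                if key:
                    want[key] = want.get(key, 0) + 1
            assert got == want
            union = iv.total_bp(iv.union_all(list(sets.values())))
            assert sum(got.values()) == union


class TestClassifyPmds:
    fib = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [100_000]})
    empty = fib.iloc[0:0]

    def test_recurrent_inside_fib_not_ipsc(self):
        irpe = pd.DataFrame({"chrom": ["c"], "start": [10_000],
                             "end": [30_000]})
        _, frac = seg.classify_pmds(irpe, self.fib, self.empty, self.empty)
        assert frac["recurrent"] == pytest.approx(1.0)

    def test_persistent_inside_fib_and_ipsc(self):
        irpe = pd.DataFrame({"chrom": ["c"], "start": [10_000],
                             "end": [30_000]})
        _, frac = seg.classify_pmds(irpe, self.fib, self.fib, self.empty)
        assert frac["persistent"] == pytest.approx(1.0)

    def test_specific_outside_fib_and_pan_crpe(self):
        irpe = pd.DataFrame({"chrom": ["c"], "start": [500_000],
                             "end": [520_000]})
        labeled, frac = seg.classify_pmds(irpe, self.fib, self.empty,
                                          self.empty)
        assert frac["specific"] == pytest.approx(1.0)
        assert set(labeled["label"]) == {"specific"}

    def test_mixed_fractions_sum_to_one(self):
        irpe = pd.DataFrame({"chrom": ["c", "c"], "start": [50_000, 500_000],
                             "end": [150_000, 520_000]})
        pan = pd.DataFrame({"chrom": ["c"], "start": [505_000],
                            "end": [510_000]})
        _, frac = seg.classify_pmds(irpe, self.fib, self.empty, pan)
        assert sum(frac.values()) == pytest.approx(1.0)


def test_pan_union_merges_overlaps():
    a = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [60]})
    b = pd.DataFrame({"chrom": ["c"], "start": [40], "end": [100]})
    u = seg.pan_union([a, b])
    assert iv.total_bp(u) == 100 and len(u) == 1
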