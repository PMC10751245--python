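import numpy as np
import pandas as pd
import pytest

import etgwas
from etgwas.bulking import BULK_ORDER, FilterConfig, round_half_up
from etgwas.errors import ConfigError, IdMismatchError


def make_pheno(values, prefix="a"):
    return etgwas.PhenotypeTable("SPY", pd.Series(values, index=[f"{prefix}{i:03d}" for i in range(len(values))]))


class TestBulkSizing:
    @pytest.mark.parametrize(
        "panel_n,fraction,expected_k",
        [(378, 0.20, 76), (389, 0.20, 78), (10, 0.20, 2), (377, 0.20, 75), (10, 0.25, 3)],
    )
    def test_round_half_up_sizing(self, panel_n, fraction, expected_k):
        rng = np.random.default_rng(panel_n)
        pheno = make_pheno(rng.normal(3.5, 1.9, panel_n))
        bulks = etgwas.assign_bulks(pheno, fraction, seed=1, match_random=False)
        assert bulks.bulk_size == expected_k
        assert round_half_up(fraction * panel_n) == expected_k

    def test_extremes_are_order_statistics(self):
        pheno = make_pheno(list(range(1, 11)))
        bulks = etgwas.assign_bulks(pheno, 0.2, seed=0, match_random=False)
        assert set(bulks.low) == {"a000", "a001"}
        assert set(bulks.high) == {"a008", "a009"}

    def test_low_max_below_high_min(self):
        rng = np.random.default_rng(3)
        pheno = make_pheno(rng.normal(0, 1, 101))
        bulks = etgwas.assign_bulks(pheno, 0.3, seed=4)
        assert max(pheno.values[bulks.low]) <= min(pheno.values[bulks.high])

    def test_overlapping_bulks_rejected(self):
        pheno = make_pheno(list(range(9)))
        with pytest.raises(ConfigError):
            etgwas.assign_bulks(pheno, 0.5, seed=0)  # k=5, 2k=10 > 9

    def test_too_small_panel_rejected(self):
        with pytest.raises(ConfigError):
            etgwas.assign_bulks(make_pheno([1.0] * 8), 0.2, seed=0)

    def test_determinism(self):
        rng = np.random.default_rng(9)
        pheno = make_pheno(rng.normal(3, 1, 150))
        b1 = etgwas.assign_bulks(pheno, 0.2, seed=42)
        b2 = etgwas.assign_bulks(pheno, 0.2, seed=42)
        assert (b1.low, b1.high, b1.random) == (b2.low, b2.high, b2.random)

    def test_boundary_ties_broken_lexically(self):
        # four accessions tie at the low-bulk boundary value
        vals = [1.0, 2.0, 2.0, 2.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0]
        pheno = make_pheno(vals)
        bulks = etgwas.assign_bulks(pheno, 0.2, seed=0, match_random=False)
        assert bulks.low == ["a000", "a001"]  # a001 < a002 < a003 lexically

    def test_random_bulk_moment_matching(self):
        rng = np.random.default_rng(21)
        pheno = make_pheno(rng.gamma(2.0, 2.0, 200))
        bulks = etgwas.assign_bulks(pheno, 0.2, seed=5, match_random=True)
        rv = pheno.values[bulks.random]
        assert abs(rv.mean() - pheno.mean) <= 0.25 * pheno.sd
        assert abs(rv.median() - pheno.median) <= 0.25 * pheno.sd
        # monotone ordering of bulk means
        assert (
            pheno.values[bulks.low].mean()
            <= rv.mean()
            <= pheno.values[bulks.high].mean()
        )

    def test_three_bulk_union_covers_40_to_60_percent(self):
        rng = np.random.default_rng(8)
        pheno = make_pheno(rng.normal(0, 1, 250))
        bulks = etgwas.assign_bulks(pheno, 0.2, seed=11)
        union = set(bulks.low) | set(bulks.high) | set(bulks.random)
        assert 0.40 * pheno.n <= len(union) <= 0.60 * pheno.n


class TestPooling:
    def test_simple_counts(self, toy_geno):
        pheno = etgwas.PhenotypeTable("SPY", pd.Series([1.0, 2.0, 3.0, 4.0], index=["a1", "a2", "a3", "a4"]))
        bulks = etgwas.BulkAssignment(0.25, 1, ["a1"], ["a3"], ["a2"], 0, 4)
        pooled = etgwas.pool_alleles(toy_geno, bulks)
        # site s1 dosages: low a1=0, random a2=1, high a3=2
        np.testing.assert_array_equal(pooled.alt_count[0], [0, 1, 2])
        np.testing.assert_array_equal(pooled.ref_count[0], [2, 1, 0])

    def test_missing_contributes_nothing(self, toy_geno):
        bulks = etgwas.BulkAssignment(0.5, 2, ["a1", "a4"], ["a2", "a3"], ["a1", "a2"], 0, 4)
        pooled = etgwas.pool_alleles(toy_geno, bulks)
        # site s3: low bulk = a1 (0) + a4 (MISSING) -> alt 0, called 1
        assert pooled.alt_count[2, 0] == 0
        assert pooled.n_called[2, 0] == 1
        assert pooled.ref_count[2, 0] == 2

    def test_absent_accession_raises(self, toy_geno):
        bulks = etgwas.BulkAssignment(0.25, 1, ["zz"], ["a3"], ["a2"], 0, 4)
        with pytest.raises(IdMismatchError):
            etgwas.pool_alleles(toy_geno, bulks)

    def test_counts_match_brute_force_tally(self, small_panel):
        _, geno, pheno, _ = small_panel
        bulks = etgwas.assign_bulks(pheno, 0.25, seed=13)
        pooled = etgwas.pool_alleles(geno, bulks)
        rng = np.random.default_rng(0)
        for j in rng.integers(0, geno.n_sites, 25):
            for b, bulk in enumerate(BULK_ORDER):
                alt = called = 0
                for acc in bulks.members(bulk):
                    d = geno.calls[geno.accessions.index(acc), j]
                    if d != etgwas.MISSING:
                        alt += int(d)
                        called += 1
                assert pooled.alt_count[j, b] == alt
                assert pooled.n_called[j, b] == called

    def test_allele_conservation(self, small_panel):
        _, geno, pheno, _ = small_panel
        bulks = etgwas.assign_bulks(pheno, 0.2, seed=2)
        pooled = etgwas.pool_alleles(geno, bulks)
        np.testing.assert_array_equal(pooled.ref_count + pooled.alt_count, 2 * pooled.n_called)
        assert (pooled.total_depth <= 6 * bulks.bulk_size).all()


class TestFilters:
    def _pooled(self, alt, called, k=10):
        alt = np.asarray(alt)
        called = np.asarray(called)
        m = alt.shape[0]
        return etgwas.PooledCounts(
            snp_ids=[f"s{i}" for i in range(m)],
            chroms=np.array(["1"] * m, dtype=object),
            positions=np.arange(1, m + 1) * 100,
            alt_count=alt,
            n_called=called,
            bulk_size=k,
        )

    def test_low_maf_removed_full_depth_retained(self):
        k = 10
        full = np.full((1, 3), k)
        pooled = self._pooled(
            alt=np.array([[1, 1, 0], [10, 10, 10]]),  # maf 2/60 = 0.033 ; 0.5
            called=np.vstack([full, full]),
            k=k,
        )
        kept = etgwas.filter_snps(pooled, FilterConfig(maf_min=0.05))
        assert list(kept) == [1]
        # total_depth = 6k >= k so the common SNP passes the depth rule
        assert pooled.total_depth[1] == 6 * k

    def test_depth_rule_default_is_bulk_size(self):
        pooled = self._pooled(alt=np.array([[1, 1, 1]]), called=np.array([[1, 1, 1]]), k=10)
        # depth 6 < bulk size 10 -> removed despite MAF 0.5
        assert len(etgwas.filter_snps(pooled)) == 0
        assert list(etgwas.filter_snps(pooled, FilterConfig(depth_min=6))) == [0]

    def test_retained_set_matches_rule_replay(self, small_panel):
        _, geno, pheno, _ = small_panel
        bulks = etgwas.assign_bulks(pheno, 0.2, seed=1)
        pooled = etgwas.pool_alleles(geno, bulks)
        cfg = FilterConfig(maf_min=0.05)
        kept = set(etgwas.filter_snps(pooled, cfg))
        for j in range(pooled.n_snps):
            depth = int(2 * pooled.n_called[j].sum())
            if depth == 0:
                assert j not in kept
                continue
            p = pooled.alt_count[j].sum() / depth
            expected = min(p, 1 - p) >= 0.05 and depth >= bulks.bulk_size
            assert (j in kept) == expected

    def test_filter_report_flags(self, small_panel):
        _, geno, pheno, _ = small_panel
        bulks = etgwas.assign_bulks(pheno, 0.2, seed=1)
        pooled = etgwas.pool_alleles(geno, bulks)
        report = etgwas.bulking.filter_report(pooled)
        assert report["retained"].sum() == len(etgwas.filter_snps(pooled))
        assert list(report.columns) == ["snp_id", "maf", "total_depth", "retained"]
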