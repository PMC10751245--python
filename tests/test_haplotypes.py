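import numpy as np
import pandas as pd
import pytest
from scipy.stats import studentized_range

import etgwas
from etgwas.errors import ConfigError, NoVariantError
from etgwas.haplotypes import (
    DuncanConfig,
    HaplotypeGroup,
    HaplotypeSequence,
    SuperiorRule,
    collapse_haplotypes,
    duncan_mrt,
    filter_haplotypes,
    list_donors,
    select_superior,
)

from .oracles import duncan_pairwise_oracle


def geno_from_strings(strings, start_pos=100, chrom="1"):
    """Accessions from haplotype strings over {R, H, A, .} (.=missing)."""
    code = {"R": 0, "H": 1, "A": 2, ".": etgwas.MISSING}
    n_sites = len(strings[0])
    sites = [etgwas.VariantSite(chrom, start_pos + 10 * i, f"s{i}", "A", "C") for i in range(n_sites)]
    calls = np.array([[code[c] for c in s] for s in strings], dtype=np.int16)
    return etgwas.GenotypeMatrix(sites, [f"a{i}" for i in range(len(strings))], calls)


def make_group(sym, values, gene="g"):
    seq = HaplotypeSequence(gene, sym, [etgwas.VariantSite("1", 10 * (i + 1), f"s{i}", "A", "C") for i in range(len(sym))])
    return HaplotypeGroup(seq, [f"m_{sym}_{i}" for i in range(len(values))], np.asarray(values, dtype=float))


class TestCollapse:
    def _pheno(self, geno, values=None):
        vals = values if values is not None else np.arange(len(geno.accessions), dtype=float)
        return etgwas.PhenotypeTable("SPY", pd.Series(vals, index=geno.accessions))

    def test_distinct_strings_form_groups(self):
        geno = geno_from_strings(["RRA", "RRA", "RAA", "ARA", "RAA"])
        gene = etgwas.GeneModel("g", "1", 90, 130)
        groups = collapse_haplotypes(geno, gene, self._pheno(geno))
        assert sorted(g.n for g in groups) == [1, 2, 2]
        assert {g.haplotype.symbols for g in groups} == {"RRA", "RAA", "ARA"}

    def test_identical_panel_single_group(self):
        geno = geno_from_strings(["RHA"] * 6)
        gene = etgwas.GeneModel("g", "1", 90, 130)
        groups = collapse_haplotypes(geno, gene, self._pheno(geno))
        assert len(groups) == 1 and groups[0].n == 6

    def test_missing_calls_excluded_and_partition_holds(self):
        geno = geno_from_strings(["RRA", "R.A", "RAA", "RAA", "ARA"])
        gene = etgwas.GeneModel("g", "1", 90, 130)
        groups = collapse_haplotypes(geno, gene, self._pheno(geno))
        members = [m for g in groups for m in g.members]
        assert sorted(members) == ["a0", "a2", "a3", "a4"]  # a1 has a missing call
        assert len(members) == len(set(members))

    def test_no_variants_in_gene(self):
        geno = geno_from_strings(["RA", "RR"])
        gene = etgwas.GeneModel("empty", "1", 5000, 6000)
        with pytest.raises(NoVariantError):
            collapse_haplotypes(geno, gene, self._pheno(geno))

    def test_planted_structure_recovered(self):
        rng = np.random.default_rng(12)
        truth = {"RRRR": 10, "RARA": 7, "AAAA": 3}
        strings = [s for s, n in truth.items() for _ in range(n)]
        order = rng.permutation(len(strings))
        geno = geno_from_strings([strings[i] for i in order])
        gene = etgwas.GeneModel("g", "1", 90, 140)
        groups = collapse_haplotypes(geno, gene, self._pheno(geno))
        assert {g.haplotype.symbols: g.n for g in groups} == truth

    def test_filter_drops_small_groups_and_commutes(self):
        geno = geno_from_strings(["RRA", "RRA", "RAA", "RAA", "ARA"])
        gene = etgwas.GeneModel("g", "1", 90, 130)
        groups = collapse_haplotypes(geno, gene, self._pheno(geno))
        kept = filter_haplotypes(groups, 2)
        assert sorted(g.n for g in kept) == [2, 2]
        # filtering after collapse equals collapsing only the accessions of kept groups
        kept_members = {m for g in kept for m in g.members}
        sub_pheno = etgwas.PhenotypeTable(
            "SPY", pd.Series(np.arange(5, dtype=float), index=geno.accessions)[list(kept_members)]
        )
        regroups = collapse_haplotypes(geno, gene, sub_pheno)
        assert {g.haplotype.symbols: g.n for g in regroups} == {g.haplotype.symbols: g.n for g in kept}

    def test_all_singletons_filter_to_empty(self):
        geno = geno_from_strings(["RRA", "RAA", "ARA"])
        gene = etgwas.GeneModel("g", "1", 90, 130)
        groups = filter_haplotypes(collapse_haplotypes(geno, gene, self._pheno(geno)))
        assert groups == []


class TestDuncan:
    def test_indistinguishable_means_share_letter(self):
        spread = np.array([-6.0, -3.0, 0.0, 0.0, 3.0, 6.0])
        g1 = make_group("R", 10.0 + spread)
        g2 = make_group("A", 10.001 + spread)
        out = duncan_mrt([g1, g2])
        assert out[0].letters == out[1].letters

    def test_separated_means_get_distinct_letters(self):
        rng = np.random.default_rng(1)
        g1 = make_group("R", rng.normal(0, 1, 5))
        g2 = make_group("A", rng.normal(10, 1, 5))
        out = duncan_mrt([g1, g2])
        assert out[0].letters == "a" and out[1].letters == "b"
        # with two groups the rule is a plain two-sample studentized-range test
        mse = (np.var(g1.values, ddof=1) * 4 + np.var(g2.values, ddof=1) * 4) / 8
        q = studentized_range.ppf(0.95, 2, 8)
        assert abs(g1.mean_pheno - g2.mean_pheno) > q * np.sqrt(mse / 5)

    def test_letters_agree_with_pairwise_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            k = int(rng.integers(3, 7))
            groups = [
                make_group(f"{'RA'[i % 2]}{i}", rng.normal(rng.uniform(0, 4), 1.0, int(rng.integers(4, 7))))
                for i in range(k)
            ]
            out = duncan_mrt(groups)
            means = [g.mean_pheno for g in out]
            sizes = [g.n for g in out]
            sep = duncan_pairwise_oracle(means, sizes, [g.values for g in out])
            for i in range(k):
                for j in range(i + 1, k):
                    share = bool(set(out[i].letters) & set(out[j].letters))
                    assert share == (not sep[i][j]), (means, sizes)

    def test_degenerate_zero_variance(self):
        g1 = make_group("R", [5.0, 5.0, 5.0])
        g2 = make_group("A", [7.0, 7.0, 7.0])
        g3 = make_group("H", [7.0, 7.0, 7.0])
        out = duncan_mrt([g1, g2, g3])
        by_sym = {g.haplotype.symbols: g.letters for g in out}
        assert by_sym["A"] == by_sym["H"]
        assert not set(by_sym["R"]) & set(by_sym["A"])

    def test_requires_two_groups_of_two(self):
        with pytest.raises(ConfigError):
            duncan_mrt([make_group("R", [1.0, 2.0])])
        with pytest.raises(ConfigError):
            duncan_mrt([make_group("R", [1.0, 2.0]), make_group("A", [3.0])])


class TestSuperior:
    def test_panel_sd_margin(self):
        # panel mean 3.5, sd 1.89 -> threshold 5.39; group mean 6.0 qualifies
        g = make_group("A", [6.0, 6.1, 5.9])
        g.letters = "a"
        rule = SuperiorRule(panel_mean=3.5, panel_sd=1.89, k_sd=1.0)
        assert select_superior([g], rule) == [g]
        assert g.superior

    def test_boundary_is_strict(self):
        g = make_group("A", [5.39, 5.39, 5.39])
        g.letters = "a"
        rule = SuperiorRule(panel_mean=3.5, panel_sd=1.89, k_sd=1.0)
        assert 3.5 + 1.89 == pytest.approx(g.mean_pheno)
        assert select_superior([g], rule) == []

    def test_infinite_margin_selects_nothing(self):
        g = make_group("A", [1e6] * 3)
        g.letters = "a"
        rule = SuperiorRule(panel_mean=0.0, panel_sd=1.0, k_sd=np.inf)
        assert select_superior([g], rule) == []

    def test_top_letter_required(self):
        hi = make_group("A", [10.0, 10.1, 9.9])
        lo = make_group("R", [8.0, 8.1, 7.9])
        hi.letters, lo.letters = "a", "b"
        rule = SuperiorRule(panel_mean=0.0, panel_sd=1.0, k_sd=1.0)
        assert select_superior([hi, lo], rule) == [hi]
        rule_any = SuperiorRule(panel_mean=0.0, panel_sd=1.0, k_sd=1.0, require_top_letter=False)
        assert select_superior([hi, lo], rule_any) == [hi, lo]

    def test_absolute_offset_mode(self):
        g = make_group("A", [4.8, 4.8, 4.8])
        g.letters = "a"
        rule = SuperiorRule(panel_mean=3.5, panel_sd=1.89, offset=1.0, mode="absolute")
        assert select_superior([g], rule) == [g]


class TestDonors:
    def test_donor_table_is_union_sorted_by_carriage(self):
        pheno = etgwas.PhenotypeTable(
            "SPY", pd.Series([9.0, 8.0, 7.0], index=["m_A_0", "m_A_1", "m_B_0"])
        )
        gA = make_group("A", [9.0, 8.0])
        gB = make_group("B", [9.0])
        gB.members = ["m_A_0"]
        gB.values = np.array([9.0])
        donors = list_donors({"gene1": [gA], "gene2": [gB]}, pheno)
        assert set(donors["accession"]) == {"m_A_0", "m_A_1"}
        assert donors.iloc[0]["accession"] == "m_A_0"
        assert donors.iloc[0]["n_superior_haps"] == 2

    def test_no_superior_haplotypes_empty_table(self):
        pheno = etgwas.PhenotypeTable("SPY", pd.Series([1.0], index=["x"]))
        assert len(list_donors({}, pheno)) == 0
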