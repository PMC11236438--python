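"""Diversity statistics: frequencies, heterozygosity, FIS, rarefied allelic
richness, private alleles, null-allele EM and the ENA FST correction."""

import math

import numpy as np
import pytest

from ssrpopgen import differentiation, diversity
from ssrpopgen.dataset import MISSING
from ssrpopgen.diversity import POOLED
from ssrpopgen.synthetic import generate_from_frequencies

from conftest import freq_table, make_dataset


class TestAlleleFrequencies:
    def test_simple_counts(self):
        ds = make_dataset([[(1, 1)], [(1, 2)]], ["A", "A"])
        t = diversity.allele_frequencies(ds)
        assert t.frequencies("A", "L0") == {1: 0.75, 2: 0.25}
        assert t.gene_count("A", "L0") == 4

    def test_all_missing_cell_absent(self):
        ds = make_dataset([[(MISSING, MISSING)], [(MISSING, MISSING)]], ["A", "A"])
        t = diversity.allele_frequencies(ds)
        assert not t.has_entry("A", "L0")
        with pytest.raises(KeyError):
            t.frequencies("A", "L0")

    def test_pooled_is_gene_count_weighted_mean(self, island_dataset):
        """Pooled frequencies equal a brute-force recount over all
        individuals, i.e. the gene-count-weighted mean of population
        frequencies."""
        t = diversity.allele_frequencies(island_dataset)
        for locus in island_dataset.loci:
            # brute-force recount ignoring population labels
            j = island_dataset.locus_index(locus)
            cell = island_dataset.genotypes[:, j, :]
            alleles = cell[cell != MISSING]
            vals, cnt = np.unique(alleles, return_counts=True)
            expect = dict(zip(vals.tolist(), (cnt / alleles.size).tolist()))
            got = t.frequencies(POOLED, locus)
            assert got == pytest.approx(expect)


class TestHeterozygosity:
    def test_all_heterozygotes(self):
        ds = make_dataset([[(1, 2)]] * 6, ["A"] * 6)
        assert diversity.observed_heterozygosity(ds, "A")["L0"] == 1.0

    def test_plain_he_half(self):
        ds = make_dataset([[(1, 1)], [(2, 2)], [(1, 2)], [(1, 2)]], ["A"] * 4)
        he = diversity.expected_heterozygosity(ds, "A", unbiased=False)
        assert he["L0"] == pytest.approx(0.5)

    def test_unbiased_correction_five_individuals(self):
        # 5 individuals, allele counts 5/5: He = (10/9) * 0.5
        ds = make_dataset([[(1, 2)]] * 5, ["A"] * 5)
        he = diversity.expected_heterozygosity(ds, "A", unbiased=True)
        assert he["L0"] == pytest.approx(10 / 9 * 0.5)

    def test_monomorphic_locus_is_zero_not_error(self):
        ds = make_dataset([[(7, 7)]] * 4, ["A"] * 4)
        assert diversity.expected_heterozygosity(ds, "A")["L0"] == 0.0
        assert diversity.observed_heterozygosity(ds, "A")["L0"] == 0.0

    def test_unbiased_at_least_plain_and_bounded(self, island_dataset):
        plain = diversity.expected_heterozygosity(island_dataset, "Pop1",
                                                  unbiased=False)
        unb = diversity.expected_heterozygosity(island_dataset, "Pop1",
                                                unbiased=True)
        for locus in plain:
            assert unb[locus] >= plain[locus]
            assert 0.0 <= plain[locus] <= 1.0
            assert 0.0 <= unb[locus] <= 1.0

    def test_global_level_reports_both_conventions(self, island_dataset):
        g = diversity.heterozygosity(island_dataset, level="global")
        assert set(g) == {"Ho", "He_pooled", "He_mean_within"}
        assert g["He_pooled"] >= g["He_mean_within"]  # Wahlund


class TestFis:
    def test_zero_when_ho_equals_hs(self):
        # large balanced heterozygote/homozygote mix engineered so the
        # observed fraction equals the unbiased gene diversity
        ds = make_dataset([[(1, 1)], [(2, 2)], [(1, 2)], [(1, 2)]] * 50,
                          ["A"] * 200)
        f = diversity.fis(ds)
        # Ho = 0.5, Hs = (400/399) * 0.5
        assert f["A"] == pytest.approx(1 - 0.5 / (400 / 399 * 0.5), abs=1e-12)
        assert abs(f["A"]) < 0.01

    def test_all_homozygotes_gives_one(self):
        ds = make_dataset([[(1, 1)], [(2, 2)]] * 10, ["A"] * 20)
        assert diversity.fis(ds)["A"] == pytest.approx(1.0)

    def test_matches_brute_force_per_locus(self, island_dataset):
        """FIS equals 1 - sum(Ho)/sum(Hs) computed long-hand per locus."""
        for pop in island_dataset.populations:
            idx = island_dataset.population_indices(pop)
            ho_sum = hs_sum = 0.0
            for j, locus in enumerate(island_dataset.loci):
                cell = island_dataset.genotypes[idx, j, :]
                cell = cell[np.all(cell != MISSING, axis=1)]
                if cell.shape[0] == 0:
                    continue
                n = cell.shape[0]
                ho = float((cell[:, 0] != cell[:, 1]).sum()) / n
                vals, cnt = np.unique(cell, return_counts=True)
                p = cnt / (2 * n)
                hs = (2 * n / (2 * n - 1)) * (1 - (p ** 2).sum())
                ho_sum += ho
                hs_sum += hs
            expect = 1 - ho_sum / hs_sum
            assert diversity.fis(island_dataset)[pop] == pytest.approx(expect)

    def test_sign_matches_hs_minus_ho(self, island_dataset):
        f = diversity.fis(island_dataset)
        for pop in island_dataset.populations:
            ho = np.mean(list(diversity.observed_heterozygosity(
                island_dataset, pop).values()))
            hs = np.mean(list(diversity.expected_heterozygosity(
                island_dataset, pop).values()))
            assert math.copysign(1, f[pop]) == math.copysign(1, hs - ho) or \
                abs(f[pop]) < 1e-9


class TestAllelicRichness:
    def test_full_depth_equals_allele_count(self):
        ds = make_dataset([[(1, 2)], [(2, 3)], [(3, 3)]], ["A"] * 3)
        _, per_cell, _ = diversity.allelic_richness(ds, g=6)
        assert per_cell[("A", "L0")] == pytest.approx(3.0)

    def test_monomorphic_is_one(self):
        ds = make_dataset([[(5, 5)]] * 5, ["A"] * 5)
        _, per_cell, _ = diversity.allelic_richness(ds, g=4)
        assert per_cell[("A", "L0")] == pytest.approx(1.0)

    def test_hand_computed_nine_one(self):
        # 10 genes, counts 9/1, g=2: Rs = 1 + [1 - C(9,2)/C(10,2)] = 1.2
        ds = make_dataset([[(1, 1)]] * 4 + [[(1, 2)]], ["A"] * 5)
        _, per_cell, _ = diversity.allelic_richness(ds, g=2)
        assert per_cell[("A", "L0")] == pytest.approx(1.2)

    def test_monotone_in_depth(self, island_dataset):
        values = []
        for g in (2, 6, 10, 14):
            per_pop, _, _ = diversity.allelic_richness(island_dataset, g=g)
            values.append(per_pop["Pop2"])
        assert all(a <= b + 1e-12 for a, b in zip(values, values[1:]))

    def test_depth_below_two_rejected(self, island_dataset):
        with pytest.raises(ValueError):
            diversity.allelic_richness(island_dataset, g=1)


class TestPrivateAlleles:
    def test_identical_populations_have_none(self):
        rows = [[(1, 2)], [(2, 2)]]
        ds = make_dataset(rows + rows, ["A", "A", "B", "B"])
        counts, frac = diversity.private_alleles(ds)
        assert counts == {"A": 0, "B": 0}
        assert frac == 0.0

    def test_single_private_allele_attributed(self):
        ds = make_dataset([[(1, 99)], [(1, 1)]], ["A", "B"])
        counts, _ = diversity.private_alleles(ds)
        assert counts == {"A": 1, "B": 0}

    def test_matches_set_algebra_oracle(self, island_dataset):
        t = diversity.allele_frequencies(island_dataset)
        pops = island_dataset.populations
        expect = {p: 0 for p in pops}
        for locus in island_dataset.loci:
            sets = {p: set(t.counts.get((p, locus), {})) for p in pops}
            for p in pops:
                others = set().union(*(sets[q] for q in pops if q != p))
                expect[p] += len(sets[p] - others)
        counts, _ = diversity.private_alleles(island_dataset)
        assert counts == expect

    def test_single_population_warns(self):
        ds = make_dataset([[(1, 2)]], ["A"])
        with pytest.warns(UserWarning, match="trivially private"):
            diversity.private_alleles(ds)


class TestNullAlleleEM:
    def test_exact_hwe_proportions_give_zero(self):
        ds = make_dataset([[(1, 1)]] * 2 + [[(2, 2)]] * 2 + [[(1, 2)]] * 4,
                          ["A"] * 8)
        per_locus, _ = diversity.null_allele_em(ds)
        assert per_locus["L0"] <= 1e-6

    def test_recovers_injected_null_frequency(self):
        table = freq_table({"P": {"LN": {1: 0.3, 2: 0.3, 3: 0.4}}})
        ds, _ = generate_from_frequencies(table, n_per_pop=200,
                                          null_freqs={"LN": 0.2}, seed=7)
        per_locus, per_cell = diversity.null_allele_em(ds)
        assert per_locus["LN"] == pytest.approx(0.2, abs=0.05)
        assert per_cell[("LN", "P")].converged


class TestFstEna:
    def test_no_nulls_corrected_equals_uncorrected(self):
        # exact HWE proportions in both pops: EM returns r = 0 everywhere
        block = [[(1, 1)]] * 2 + [[(2, 2)]] * 2 + [[(1, 2)]] * 4
        shifted = [[(1, 1)]] * 4 + [[(2, 2)]] * 1 + [[(1, 2)]] * 4
        rows = [r * 2 for r in block] + [r * 2 for r in shifted]
        rows = [[r[0], r[1]] for r in rows]
        ds = make_dataset(rows, ["A"] * 8 + ["B"] * 9)
        res = diversity.fst_ena(ds)
        assert res.fst_corrected == pytest.approx(res.fst_uncorrected, abs=1e-9)
        assert res.t_statistic == 0.0
        assert res.p_value == 1.0

    def test_correction_moves_toward_null_free_truth(self):
        rng = np.random.default_rng(11)
        loci = [f"L{i}" for i in range(9)]
        spec = {"A": {}, "B": {}}
        for l in loci:
            base = rng.dirichlet(np.ones(4) * 2)
            for pop in spec:
                f = rng.dirichlet(base * 15)
                spec[pop][l] = {100 + 2 * i: v for i, v in enumerate(f)}
        table = freq_table(spec)
        clean, _ = generate_from_frequencies(table, n_per_pop=100, seed=21)
        truth, _ = differentiation.multilocus_theta(clean)
        nulls = {l: 0.3 for l in loci[:4]}
        noisy, _ = generate_from_frequencies(table, n_per_pop=100,
                                             null_freqs=nulls, seed=21)
        res = diversity.fst_ena(noisy)
        assert abs(res.fst_corrected - truth) < abs(res.fst_uncorrected - truth)
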