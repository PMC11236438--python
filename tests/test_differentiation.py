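"""AMOVA, pairwise FST, Mantel test, directional relative migration."""

import itertools
import math

import numpy as np
import pytest

from ssrpopgen import differentiation
from ssrpopgen.dataset import DistanceMatrix, SSRDataset
from ssrpopgen.synthetic import generate_from_frequencies

from conftest import freq_table, make_dataset


def wc_theta_longhand(n_i, p_i, h_i):
    """Independent long-hand implementation of the W&C 1984 single-allele
    variance components (oracle; kept deliberately scalar and literal)."""
    r = len(n_i)
    n = np.asarray(n_i, float)
    p = np.asarray(p_i, float)
    h = np.asarray(h_i, float)
    nbar = n.mean()
    nc = (r * nbar - (n ** 2).sum() / (r * nbar)) / (r - 1)
    pbar = (n * p).sum() / (r * nbar)
    s2 = (n * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
    hbar = (n * h).sum() / (r * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
                       / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                               - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


class TestPairwiseFst:
    def test_fixed_different_alleles_is_one(self):
        ds = make_dataset([[(1, 1)]] * 5 + [[(2, 2)]] * 5, ["A"] * 5 + ["B"] * 5)
        fst = differentiation.pairwise_fst(ds)
        assert fst["A", "B"] == pytest.approx(1.0)

    def test_matches_longhand_variance_components(self):
        # A: {1,1},{1,1},{1,2},{1,2},{2,2}; B: {2,2},{2,2},{1,2},{2,2}
        ds = make_dataset([[(1, 1)], [(1, 1)], [(1, 2)], [(1, 2)], [(2, 2)],
                           [(2, 2)], [(2, 2)], [(1, 2)], [(2, 2)]],
                          ["A"] * 5 + ["B"] * 4)
        a1, b1, c1 = wc_theta_longhand([5, 4], [0.6, 0.125], [0.4, 0.25])
        a2, b2, c2 = wc_theta_longhand([5, 4], [0.4, 0.875], [0.4, 0.25])
        expect = (a1 + a2) / (a1 + b1 + c1 + a2 + b2 + c2)
        theta, _ = differentiation.multilocus_theta(ds)
        assert theta == pytest.approx(expect, abs=1e-12)

    def test_random_split_of_panmixia_near_zero(self):
        table = freq_table({"X": {f"L{j}": {100: 0.4, 102: 0.3, 104: 0.3}
                                  for j in range(9)}})
        pool, _ = generate_from_frequencies(table, n_per_pop=40, seed=5)
        ds = SSRDataset(pool.individual_ids, ["A"] * 20 + ["B"] * 20,
                        pool.loci, pool.genotypes)
        theta, _ = differentiation.multilocus_theta(ds)
        assert abs(theta) < 0.05

    def test_exact_duplication_slightly_negative(self, island_dataset):
        # two identical samples give a deterministic small negative theta
        idx = island_dataset.population_indices("Pop1")
        g = island_dataset.genotypes[idx]
        ds = SSRDataset([f"a{i}" for i in range(10)] + [f"b{i}" for i in range(10)],
                        ["X"] * 10 + ["Y"] * 10, island_dataset.loci,
                        np.vstack([g, g]))
        theta, _ = differentiation.multilocus_theta(ds)
        assert -0.12 < theta < 0.0

    def test_nei_gst_estimator_available(self, island_dataset):
        fst = differentiation.pairwise_fst(island_dataset, estimator="nei_gst")
        off = fst.condensed()
        assert np.all(off > 0) and np.all(off < 1)


class TestAmova:
    def test_percentages_sum_to_hundred(self, island_dataset):
        res = differentiation.amova(island_dataset, n_permutations=50, seed=0)
        assert res.pct_among + res.pct_within == pytest.approx(100.0, abs=0.01)
        assert 0 < res.p_value <= 1

    def test_fixed_populations_all_among(self):
        ds = make_dataset([[(1, 1)]] * 5 + [[(2, 2)]] * 5, ["A"] * 5 + ["B"] * 5)
        res = differentiation.amova(ds, n_permutations=100, seed=1)
        assert res.pct_among == pytest.approx(100.0)
        assert res.p_value < 0.05

    def test_panmictic_split_near_zero_among(self):
        table = freq_table({"X": {f"L{j}": {100: 0.4, 102: 0.3, 104: 0.3}
                                  for j in range(9)}})
        pool, _ = generate_from_frequencies(table, n_per_pop=40, seed=9)
        ds = SSRDataset(pool.individual_ids, ["A"] * 20 + ["B"] * 20,
                        pool.loci, pool.genotypes)
        res = differentiation.amova(ds, n_permutations=100, seed=3)
        assert res.pct_among < 5.0
        assert res.sigma_among >= 0.0  # truncated for reporting

    def test_p_invariant_to_population_relabeling(self, island_dataset):
        a = differentiation.amova(island_dataset, n_permutations=60, seed=7)
        relabeled = SSRDataset(
            island_dataset.individual_ids,
            [{"Pop1": "Z", "Pop2": "Q", "Pop3": "M", "Pop4": "W"}[p]
             for p in island_dataset.population_ids],
            island_dataset.loci, island_dataset.genotypes.copy())
        b = differentiation.amova(relabeled, n_permutations=60, seed=7)
        assert a.p_value == b.p_value
        assert a.phi_st == pytest.approx(b.phi_st)

    def test_matches_brute_force_variance_components(self):
        """Phi_ST equals a literal re-derivation of the one-level AMOVA sums
        of squares on a small two-population dataset."""
        ds = make_dataset(
            [[(1, 1), (3, 4)], [(1, 2), (3, 3)], [(2, 2), (4, 4)],
             [(2, 2), (4, 4)], [(1, 2), (4, 4)]],
            ["A", "A", "B", "B", "B"])
        res = differentiation.amova(ds, n_permutations=10, seed=0)
        # brute force: squared distance = allele mismatches summed over loci
        def d2(i, j):
            tot = 0
            for l in range(2):
                g1 = sorted(ds.genotypes[i, l]); g2 = sorted(ds.genotypes[j, l])
                shared = 0
                rem = list(g2)
                for x in g1:
                    if x in rem:
                        shared += 1
                        rem.remove(x)
                tot += 2 - shared
            return tot
        n, groups = 5, [0, 0, 1, 1, 1]
        ss_total = sum(d2(i, j) for i in range(n) for j in range(i + 1, n)) / n
        ss_within = (sum(d2(i, j) for i in [0, 1] for j in [1] if j > i) / 2
                     + sum(d2(i, j) for i in [2, 3, 4] for j in [3, 4] if j > i) / 3)
        ss_among = ss_total - ss_within
        ms_among = ss_among / 1
        ms_within = ss_within / 3
        n_prime = (5 - (4 + 9) / 5) / 1
        sigma_a = (ms_among - ms_within) / n_prime
        expect_phi = sigma_a / (sigma_a + ms_within)
        assert res.phi_st == pytest.approx(expect_phi, abs=1e-12)

    def test_invalid_permutation_count(self, island_dataset):
        with pytest.raises(ValueError):
            differentiation.amova(island_dataset, n_permutations=0)


class TestMantel:
    @staticmethod
    def matrices():
        rng = np.random.default_rng(8)
        m = rng.uniform(1, 5, size=(4, 4))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        m1 = DistanceMatrix(list("ABCD"), m)
        m2v = rng.uniform(1, 5, size=(4, 4))
        m2v = (m2v + m2v.T) / 2
        np.fill_diagonal(m2v, 0)
        return m1, DistanceMatrix(list("ABCD"), m2v)

    def test_perfect_linear_relation(self):
        m1, _ = self.matrices()
        m2 = DistanceMatrix(m1.labels, 3 * m1.values + 2 * (1 - np.eye(4)))
        r, p, nperm = differentiation.mantel(m1, m2)
        assert r == pytest.approx(1.0)
        assert nperm == 23  # all non-identity permutations of 4 labels
        assert p == pytest.approx(1 / 24)

    def test_exact_mode_equals_manual_enumeration(self):
        m1, m2 = self.matrices()
        r, p, nperm = differentiation.mantel(m1, m2, mode="exact_enumeration")
        x = m1.condensed()
        rs = []
        for perm in itertools.permutations(range(4)):
            mp = m2.values[np.ix_(perm, perm)]
            rs.append(np.corrcoef(x, mp[np.triu_indices(4, 1)])[0, 1])
        r_obs = rs[0]  # identity permutation
        expect_p = sum(1 for v in rs[1:] if v >= r_obs - 1e-12) + 1
        assert r == pytest.approx(r_obs)
        assert p == pytest.approx(expect_p / 24)

    def test_size_mismatch_rejected(self):
        m1, _ = self.matrices()
        m3 = DistanceMatrix(list("AB"), np.array([[0, 1], [1, 0.0]]))
        with pytest.raises(ValueError):
            differentiation.mantel(m1, m3)

    def test_zero_variance_reported_missing(self):
        m1, _ = self.matrices()
        flat = DistanceMatrix(m1.labels, np.ones((4, 4)) - np.eye(4))
        r, p, _ = differentiation.mantel(m1, flat)
        assert math.isnan(r) and math.isnan(p)


class TestRelativeMigration:
    def test_normalization_max_is_one(self, island_dataset):
        net = differentiation.relative_migration(island_dataset)
        off = net.values[~np.eye(4, dtype=bool)]
        assert off.max() == pytest.approx(1.0)
        assert np.all(np.diag(net.values) == 0)

    def test_scale_invariance_of_normalization(self, island_dataset):
        raw = differentiation._directional_matrix(island_dataset, "Nm")
        k = raw.shape[0]
        mask = ~np.eye(k, dtype=bool)
        for scale in (1.0, 3.7):
            scaled = raw * scale
            norm = scaled / scaled[mask & np.isfinite(scaled)].max()
            base = raw / raw[mask & np.isfinite(raw)].max()
            np.testing.assert_allclose(norm[mask], base[mask])

    def test_exchangeable_pair_roughly_symmetric(self):
        table = freq_table({"X": {f"L{j}": {100: 0.5, 102: 0.3, 104: 0.2}
                                  for j in range(9)}})
        pool, _ = generate_from_frequencies(table, n_per_pop=60, seed=2)
        ds = SSRDataset(pool.individual_ids, ["A"] * 30 + ["B"] * 30,
                        pool.loci, pool.genotypes)
        net = differentiation.relative_migration(ds, n_bootstrap=40, seed=4)
        # neither direction should dominate the bootstrap replicates
        assert 0.1 < net.bootstrap_support[0, 1] < 0.9

    def test_source_sink_directionality(self):
        rng = np.random.default_rng(4)
        spec = {"Src": {}, "Snk": {}}
        for j in range(9):
            fi = rng.dirichlet(np.ones(5))
            fj0 = rng.dirichlet(np.ones(5))
            fj = 0.7 * fi + 0.3 * fj0  # sink dominated by source migrants
            spec["Src"][f"L{j}"] = {100 + 2 * i: v for i, v in enumerate(fi)}
            spec["Snk"][f"L{j}"] = {100 + 2 * i: v for i, v in enumerate(fj)}
        ds, _ = generate_from_frequencies(freq_table(spec), n_per_pop=30, seed=11)
        net = differentiation.relative_migration(ds, n_bootstrap=50, seed=2)
        i, j = net.labels.index("Src"), net.labels.index("Snk")
        assert net.bootstrap_support[i, j] >= 0.9

    @pytest.mark.parametrize("statistic", ["Nm", "Gst", "D"])
    def test_all_statistics_produce_valid_networks(self, island_dataset,
                                                   statistic):
        net = differentiation.relative_migration(island_dataset,
                                                 statistic=statistic)
        off = net.values[~np.eye(4, dtype=bool)]
        assert np.all(off >= 0) and off.max() == pytest.approx(1.0)
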