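"""ABC engine: summary statistics, reference tables, scenario posteriors,
parameter estimation, model checking, error rates, scenario catalog."""

import warnings

import numpy as np
import pandas as pd
import pytest

from ssrpopgen import abc as abc_mod
from ssrpopgen import differentiation, diversity
from ssrpopgen.abc import (ISLANDS, PARAM_PREFIX, STAT_PREFIX,
                           build_reference_table, confidence_errors,
                           default_priors, estimate_parameters,
                           load_scenarios_stage, model_check, read_scenarios,
                           scenario_posterior, summary_stats, write_scenarios)
from ssrpopgen.coalescent import (Bottleneck, PriorSpec, Scenario, Split,
                                  draw_valid_params, simulate_scenario)

from conftest import make_dataset


def small_pair_of_scenarios():
    """Two single-sampled-deme scenarios: neutral vs severe bottleneck."""
    plain = Scenario("plain", {"anc": 2000.0, "D": 2000.0}, {"anc": 0, "D": 10},
                     events=[Split(200.0, "D", "anc")])
    bottl = Scenario("bottleneck", {"anc": 2000.0, "D": 2000.0},
                     {"anc": 0, "D": 10},
                     events=[Split(200.0, "D", "anc")],
                     bottlenecks=[Bottleneck("D", 200.0, 40.0, 5.0)])
    return [plain, bottl]


SMALL_PRIORS = PriorSpec({"mu": ("loguniform", 3e-4, 7e-4)})


@pytest.fixture(scope="module")
def small_table():
    return build_reference_table(small_pair_of_scenarios(), SMALL_PRIORS,
                                 300, n_loci=9, seed=5)


class TestSummaryStats:
    def test_monomorphic_dataset_convention(self):
        ds = make_dataset([[(7, 7)], [(7, 7)], [(7, 7)], [(7, 7)]],
                          ["A", "A", "B", "B"])
        s = summary_stats(ds)
        assert s["na_A"] == 1.0 and s["na_B"] == 1.0
        assert s["he_A"] == 0.0 and s["he_B"] == 0.0
        assert s["fst_A_B"] == 0.0  # undefined -> 0 by convention

    def test_equals_diversity_and_differentiation_modules(self, island_dataset):
        """Single source of truth: the stat vector equals direct calls into
        the diversity and differentiation modules."""
        s = summary_stats(island_dataset)
        table = diversity.allele_frequencies(island_dataset)
        for pop in island_dataset.populations:
            na = np.mean([len(table.counts.get((pop, l), {}))
                          for l in island_dataset.loci])
            he = np.mean([diversity.gene_diversity(
                table.frequencies(pop, l), table.gene_count(pop, l))
                for l in island_dataset.loci])
            assert s[f"na_{pop}"] == pytest.approx(na)
            assert s[f"he_{pop}"] == pytest.approx(he)
        theta, _ = differentiation.multilocus_theta(island_dataset,
                                                    ["Pop1", "Pop2"])
        assert s["fst_Pop1_Pop2"] == pytest.approx(theta)

    def test_invariant_to_individual_order_within_demes(self, island_dataset):
        rng = np.random.default_rng(0)
        idx = []
        for pop in island_dataset.populations:
            pidx = island_dataset.population_indices(pop)
            idx.extend(rng.permutation(pidx).tolist())
        shuffled = island_dataset.subset_individuals(np.asarray(idx))
        assert summary_stats(shuffled) == pytest.approx(
            summary_stats(island_dataset))


class TestReferenceTable:
    def test_row_count_and_schema(self, small_table):
        assert len(small_table) == 600
        assert set(small_table["scenario"]) == {"plain", "bottleneck"}
        stat_cols = [c for c in small_table.columns if c.startswith(STAT_PREFIX)]
        assert len(stat_cols) == 2  # one sampled deme: na + he
        assert small_table[stat_cols].notna().all().all()

    def test_same_seed_identical(self):
        scens = small_pair_of_scenarios()
        a = build_reference_table(scens, SMALL_PRIORS, 20, n_loci=4, seed=9)
        b = build_reference_table(scens, SMALL_PRIORS, 20, n_loci=4, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_needs_two_scenarios(self):
        with pytest.raises(ValueError):
            build_reference_table(small_pair_of_scenarios()[:1], SMALL_PRIORS,
                                  10)


class TestScenarioPosterior:
    def test_probabilities_sum_to_one(self, small_table):
        obs = {"na_D": 4.0, "he_D": 0.6}
        for method in ("rejection", "logistic"):
            post = scenario_posterior(small_table, obs, method=method)
            assert sum(post.probabilities.values()) == pytest.approx(1.0)

    def test_identical_scenarios_near_half(self):
        twin_a = small_pair_of_scenarios()[0]
        twin_b = Scenario("plain2", twin_a.deme_sizes, twin_a.sample_sizes,
                          twin_a.events, twin_a.bottlenecks)
        table = build_reference_table([twin_a, twin_b], SMALL_PRIORS, 250,
                                      n_loci=9, seed=3)
        ds = simulate_scenario(twin_a, {"mu": 5e-4}, n_loci=9, seed=77)
        post = scenario_posterior(table, summary_stats(ds), method="rejection",
                                  n_closest=100)
        assert post.probabilities["plain"] == pytest.approx(0.5, abs=0.2)

    def test_invariant_to_scenario_order(self, small_table):
        obs = {"na_D": 4.0, "he_D": 0.6}
        flipped = pd.concat([small_table[small_table["scenario"] == "bottleneck"],
                             small_table[small_table["scenario"] == "plain"]],
                            ignore_index=True)
        a = scenario_posterior(small_table, obs, method="rejection",
                               n_closest=60)
        b = scenario_posterior(flipped, obs, method="rejection", n_closest=60)
        for name in a.probabilities:
            assert a.probabilities[name] == pytest.approx(
                b.probabilities[name], abs=0.05)


class TestEstimateParameters:
    def test_quantiles_ordered(self, small_table):
        est = estimate_parameters(small_table, {"na_D": 4.0, "he_D": 0.6},
                                  "plain", n_closest=50, priors=SMALL_PRIORS)
        q = est.quantiles["mu"]
        assert q["q2.5"] <= q["q50"] <= q["q97.5"]

    def test_flat_likelihood_returns_prior(self):
        """Stats carrying no information about the parameter: the adjusted
        posterior quantiles reproduce the prior's."""
        rng = np.random.default_rng(4)
        n = 4000
        rows = pd.DataFrame({
            "scenario": "s",
            PARAM_PREFIX + "x": rng.uniform(0.0, 1.0, size=n),
            STAT_PREFIX + "a": rng.normal(size=n),
            STAT_PREFIX + "b": rng.normal(size=n),
        })
        priors = PriorSpec({"x": ("uniform", 0.0, 1.0)})
        est = estimate_parameters(rows, {"a": 0.0, "b": 0.0}, "s",
                                  n_closest=2000, priors=priors)
        q = est.quantiles["x"]
        assert q["q50"] == pytest.approx(0.5, abs=0.06)
        assert q["q2.5"] == pytest.approx(0.025, abs=0.06)
        assert q["q97.5"] == pytest.approx(0.975, abs=0.06)

    def test_bounded_adjustment_respects_prior_support(self, small_table):
        est = estimate_parameters(small_table, {"na_D": 2.0, "he_D": 0.2},
                                  "plain", n_closest=40, priors=SMALL_PRIORS)
        q = est.quantiles["mu"]
        assert 3e-4 <= q["q2.5"] and q["q97.5"] <= 7e-4


class TestModelCheck:
    def test_tail_probabilities_bounded(self, small_table):
        mc = model_check(small_table, {"na_D": 4.0, "he_D": 0.6})
        assert all(0.0 <= v <= 1.0 for v in mc.tail_probabilities.values())

    def test_pca_invariant_to_row_order(self, small_table):
        obs = {"na_D": 4.0, "he_D": 0.6}
        a = model_check(small_table, obs)
        shuffled = small_table.sample(frac=1.0, random_state=1)
        b = model_check(shuffled, obs)
        np.testing.assert_allclose(np.abs(a.pca_observed),
                                   np.abs(b.pca_observed), atol=1e-8)

    def test_self_consistent_observation_inside_cloud(self):
        scens = small_pair_of_scenarios()
        table = build_reference_table(scens, SMALL_PRIORS, 250, n_loci=9,
                                      seed=6)
        ds = simulate_scenario(scens[0], {"mu": 5e-4}, n_loci=9, seed=123)
        sub = table[table["scenario"] == "plain"]
        mc = model_check(table, summary_stats(ds), posterior_sims=sub)
        inside = [v > 0.05 for v in mc.tail_probabilities.values()]
        assert sum(inside) >= len(inside) - 1


class TestConfidenceErrors:
    def test_identical_scenarios_type1_half(self):
        twin_a = small_pair_of_scenarios()[0]
        twin_b = Scenario("plain2", twin_a.deme_sizes, twin_a.sample_sizes,
                          twin_a.events, twin_a.bottlenecks)
        table = build_reference_table([twin_a, twin_b], SMALL_PRIORS, 150,
                                      n_loci=9, seed=2)
        errs = confidence_errors([twin_a, twin_b], SMALL_PRIORS, 20, table,
                                 seed=3)
        assert errs.type_1["plain"] == pytest.approx(0.5, abs=0.3)

    def test_distinct_scenarios_low_type1(self, small_table):
        scens = small_pair_of_scenarios()
        errs = confidence_errors(scens, SMALL_PRIORS, 25, small_table, seed=8)
        assert errs.type_1["plain"] < 0.2
        assert errs.type_1["bottleneck"] < 0.2
        for name in ("plain", "bottleneck"):
            assert 0.0 <= errs.type_2_mean[name] <= 1.0
            lo, hi = errs.type_2_range[name]
            assert lo <= errs.type_2_mean[name] <= hi

    def test_interval_report_format(self, small_table):
        errs = confidence_errors(small_pair_of_scenarios(), SMALL_PRIORS, 10,
                                 small_table, seed=1)
        text = errs.formatted("plain")
        assert "type I" in text and "[" in text and "-" in text


class TestScenarioCatalog:
    @pytest.mark.parametrize("stage", [1, 2, 3])
    def test_catalog_scenarios_validate(self, stage):
        rng = np.random.default_rng(stage)
        for scn in load_scenarios_stage(stage):
            params = draw_valid_params(scn, default_priors(), rng)
            scn.bind(params).validate()

    def test_stage2_has_two_independent_mainland_introductions(self):
        winner = load_scenarios_stage(2)[0]
        mainland_children = [e.child for e in winner.events
                             if isinstance(e, Split) and e.parent == "Mainland"]
        assert sorted(mainland_children) == ["SanCristobal", "SantaCruz"]

    def test_stage3_origin_is_coast_to_san_cristobal(self):
        winner = load_scenarios_stage(3)[0]
        first = max(winner.events, key=lambda e: str(e.time))
        coast_children = [e.child for e in winner.events
                          if isinstance(e, Split) and e.parent == "Coast"]
        assert coast_children == ["SanCristobal"]

    def test_every_introduction_followed_by_bottleneck(self):
        for stage in (1, 2, 3):
            for scn in load_scenarios_stage(stage):
                intro = {e.child for e in scn.events if isinstance(e, Split)}
                bdemes = {b.deme for b in scn.bottlenecks}
                assert set(ISLANDS) & intro <= bdemes

    def test_unknown_stage_rejected(self):
        with pytest.raises(ValueError):
            load_scenarios_stage(4)

    def test_yaml_round_trip(self, tmp_path):
        scens = load_scenarios_stage(2)
        path = tmp_path / "catalog.yaml"
        write_scenarios(scens, path)
        back = read_scenarios(path)
        assert back == scens
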