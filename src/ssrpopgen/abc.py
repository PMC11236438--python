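"""Approximate Bayesian computation over demographic invasion scenarios.

Builds reference tables of (scenario, parameter draw, summary statistics)
by coalescent simulation, estimates scenario posterior probabilities by
rejection or local multinomial logistic regression, adjusts parameter
posteriors by Beaumont local-linear regression, and quantifies confidence
in scenario choice through type-I/type-II error rates on pseudo-observed
datasets. Summary statistics are the per-deme mean allele number, per-deme
mean gene diversity, and all pairwise Weir-Cockerham FST values.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.linear_model import LogisticRegression

from .coalescent import (Bottleneck, PriorSpec, Scenario, Split,
                         draw_valid_params, simulate_scenario)
from .dataset import SSRDataset
from .differentiation import multilocus_theta, pop_locus_stats
from .diversity import allele_frequencies, gene_diversity

PARAM_PREFIX = "param_"
STAT_PREFIX = "stat_"


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

def summary_stats(dataset: SSRDataset) -> dict[str, float]:
    """DIYABC-style summary statistic vector with a fixed key order.

    Per deme: mean number of alleles over loci and mean unbiased gene
    diversity over loci; then Weir-Cockerham FST for every deme pair in
    population order. Pairs where FST is undefined (monomorphic) report 0.
    """
    table = allele_frequencies(dataset)
    pops = dataset.populations
    out: dict[str, float] = {}
    for pop in pops:
        nas, hes = [], []
        for locus in dataset.loci:
            if table.has_entry(pop, locus):
                f = table.frequencies(pop, locus)
                nas.append(len(f))
                hes.append(gene_diversity(f, table.gene_count(pop, locus)))
            else:
                nas.append(0)
                hes.append(0.0)
        out[f"na_{pop}"] = float(np.mean(nas))
        out[f"he_{pop}"] = float(np.mean(hes))
    stats = pop_locus_stats(dataset)
    for a, b in itertools.combinations(pops, 2):
        theta, _ = multilocus_theta(dataset, [a, b], stats=stats)
        out[f"fst_{a}_{b}"] = 0.0 if math.isnan(theta) else float(theta)
    return out


# ---------------------------------------------------------------------------
# Reference table
# ---------------------------------------------------------------------------

def build_reference_table(scenarios: list[Scenario], priors: PriorSpec,
                          n_sims_per_scenario: int, n_loci: int = 9,
                          seed: int | None = None,
                          sample_sizes: dict[str, int] | None = None
                          ) -> pd.DataFrame:
    """Simulate the ABC reference table: prior draw -> simulate -> summarize.

    Returns a DataFrame with columns ``scenario``, ``param_*`` and
    ``stat_*``; the statistic schema must agree across scenarios, which
    requires every scenario to sample the same demes.
    """
    if len(scenarios) < 2:
        raise ValueError("need >= 2 scenarios")
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    for scn in scenarios:
        for _ in range(n_sims_per_scenario):
            params = draw_valid_params(scn, priors, rng)
            ds = simulate_scenario(scn, params, n_loci=n_loci,
                                   seed=int(rng.integers(2 ** 31)),
                                   sample_sizes=sample_sizes)
            row: dict = {"scenario": scn.name}
            row.update({PARAM_PREFIX + k: v for k, v in params.items()})
            row.update({STAT_PREFIX + k: v for k, v in summary_stats(ds).items()})
            rows.append(row)
    df = pd.DataFrame(rows)
    stat_cols = [c for c in df.columns if c.startswith(STAT_PREFIX)]
    if df[stat_cols].isna().any().any():
        raise RuntimeError("summary-statistic schema differs between scenarios")
    return df


def _stat_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c.startswith(STAT_PREFIX)]


def _standardize(table: pd.DataFrame, observed: dict[str, float],
                 method: str = "mad") -> tuple[np.ndarray, np.ndarray]:
    """Scale reference stats and observed vector by robust spread (MAD, with
    SD fallback for zero-MAD statistics); returns (scaled sims, scaled obs)."""
    cols = _stat_columns(table)
    x = table[cols].to_numpy(dtype=float)
    obs = np.array([observed[c[len(STAT_PREFIX):]] for c in cols], dtype=float)
    if method == "mad":
        scale = np.median(np.abs(x - np.median(x, axis=0)), axis=0)
        sd = x.std(axis=0)
        scale = np.where(scale > 0, scale, sd)
    elif method == "sd":
        scale = x.std(axis=0)
    else:
        raise ValueError(f"unknown standardization {method!r}")
    scale = np.where(scale > 0, scale, 1.0)
    return x / scale, obs / scale


@dataclass
class ScenarioPosterior:
    probabilities: dict[str, float]
    method: str
    n_closest: int


def scenario_posterior(table: pd.DataFrame, observed: dict[str, float],
                       n_closest: int | None = None, method: str = "logistic"
                       ) -> ScenarioPosterior:
    """Posterior probability of each scenario given observed summary stats.

    ``rejection``: scenario frequencies among the ``n_closest`` reference
    rows (Euclidean distance on standardized stats). ``logistic``:
    multinomial logistic regression of the scenario indicator on the
    (simulated - observed) statistic differences over the closest set,
    evaluated at a zero difference. ``n_closest`` defaults to 1% of rows.
    """
    if n_closest is None:
        n_closest = max(2, len(table) // 100)
    if n_closest > len(table):
        raise ValueError("n_closest exceeds table size")
    x, obs = _standardize(table, observed)
    dist = np.sqrt(((x - obs) ** 2).sum(axis=1))
    idx = np.argsort(dist, kind="stable")[:n_closest]
    names = list(pd.unique(table["scenario"]))
    labels = table["scenario"].to_numpy()[idx]
    if method == "rejection":
        probs = {n: float((labels == n).mean()) for n in names}
        missing = [n for n in names if probs[n] == 0.0]
        if missing:
            warnings.warn(f"scenarios absent from the closest set: {missing}")
    elif method == "logistic":
        present = [n for n in names if (labels == n).any()]
        if len(present) == 1:
            probs = {n: (1.0 if n == present[0] else 0.0) for n in names}
        else:
            feats = x[idx] - obs
            clf = LogisticRegression(max_iter=2000, C=1.0)
            clf.fit(feats, labels)
            p = clf.predict_proba(np.zeros((1, feats.shape[1])))[0]
            probs = {n: 0.0 for n in names}
            for cls, pv in zip(clf.classes_, p):
                probs[cls] = float(pv)
        tot = sum(probs.values())
        probs = {n: v / tot for n, v in probs.items()}
    else:
        raise ValueError(f"unknown method {method!r}")
    return ScenarioPosterior(probs, method, n_closest)


# ---------------------------------------------------------------------------
# Parameter estimation (Beaumont local-linear adjustment)
# ---------------------------------------------------------------------------

@dataclass
class ParameterPosterior:
    quantiles: dict[str, dict[str, float]]  # param -> {q2.5, q50, q97.5}
    adjusted: bool
    n_accepted: int


def _logit(u: np.ndarray) -> np.ndarray:
    return np.log(u / (1.0 - u))


def _expit(v: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-v))


def estimate_parameters(table: pd.DataFrame, observed: dict[str, float],
                        scenario: str, n_closest: int | None = None,
                        priors: PriorSpec | None = None) -> ParameterPosterior:
    """Posterior quantiles per parameter for one scenario.

    Accepted draws are the ``n_closest`` rows of that scenario; each
    parameter is regressed on the standardized statistic differences and
    adjusted to a zero difference (local-linear regression). When prior
    bounds are supplied the regression runs on the logit of the rescaled
    parameter so adjusted values respect the prior support. A singular
    regression falls back to the unadjusted rejection sample.
    """
    sub = table[table["scenario"] == scenario]
    if sub.empty:
        raise ValueError(f"no rows for scenario {scenario!r}")
    if n_closest is None:
        n_closest = max(2, len(sub) // 100)
    if n_closest > len(sub):
        raise ValueError("n_closest exceeds the scenario's row count")
    x, obs = _standardize(sub, observed)
    dist = np.sqrt(((x - obs) ** 2).sum(axis=1))
    idx = np.argsort(dist, kind="stable")[:n_closest]
    feats = x[idx] - obs
    design = np.column_stack([np.ones(len(idx)), feats])
    param_cols = [c for c in sub.columns
                  if c.startswith(PARAM_PREFIX) and sub[c].notna().all()]
    quantiles: dict[str, dict[str, float]] = {}
    adjusted_any = False
    for col in param_cols:
        name = col[len(PARAM_PREFIX):]
        vals = sub[col].to_numpy(dtype=float)[idx]
        bounds = None
        if priors is not None and name in priors.priors:
            bounds = priors.bounds(name)
        y, back = _transform(vals, bounds, priors, name)
        try:
            beta, *_ = np.linalg.lstsq(design, y, rcond=None)
            resid = y - design @ beta
            adj = beta[0] + resid  # value at zero statistic difference
            out_vals = back(adj)
            adjusted_any = True
        except np.linalg.LinAlgError:
            warnings.warn(f"singular regression for {name}; using rejection sample")
            out_vals = vals
        q = np.quantile(out_vals, [0.025, 0.5, 0.975])
        quantiles[name] = {"q2.5": float(q[0]), "q50": float(q[1]),
                           "q97.5": float(q[2])}
    return ParameterPosterior(quantiles, adjusted_any, n_closest)


def _transform(vals: np.ndarray, bounds: tuple[float, float] | None,
               priors: PriorSpec | None, name: str):
    if bounds is not None:
        lo, hi = bounds
        loguni = priors is not None and priors.priors[name][0] == "loguniform"
        if loguni:
            lo_l, hi_l = math.log(lo), math.log(hi)
            u = (np.log(vals) - lo_l) / (hi_l - lo_l)
        else:
            u = (vals - lo) / (hi - lo)
        u = np.clip(u, 1e-8, 1 - 1e-8)

        def back(v: np.ndarray) -> np.ndarray:
            w = _expit(v)
            if loguni:
                return np.exp(lo_l + w * (hi_l - lo_l))
            return lo + w * (hi - lo)

        return _logit(u), back
    return vals.copy(), lambda v: v


# ---------------------------------------------------------------------------
# Model checking
# ---------------------------------------------------------------------------

@dataclass
class ModelCheck:
    pca_reference: np.ndarray
    pca_observed: np.ndarray
    pca_posterior: np.ndarray | None
    tail_probabilities: dict[str, float]


def model_check(table: pd.DataFrame, observed: dict[str, float],
                posterior_sims: pd.DataFrame | None = None) -> ModelCheck:
    """Goodness-of-fit diagnostics for a fitted scenario.

    Projects the reference table, the observed vector, and (optionally)
    posterior-predictive simulations into the PCA space of the reference
    statistics; reports per-statistic two-sided tail probabilities of the
    observed value among the posterior predictions (or the whole reference
    table when none are given).
    """
    from sklearn.decomposition import PCA

    cols = _stat_columns(table)
    if len(cols) < 2:
        raise ValueError("need >= 2 summary statistics for PCA")
    x, obs = _standardize(table, observed)
    pca = PCA(n_components=min(len(cols), 5))
    ref_coords = pca.fit_transform(x - x.mean(axis=0))
    obs_coords = pca.transform((obs - x.mean(axis=0)).reshape(1, -1))
    post_coords = None
    pool = table if posterior_sims is None else posterior_sims
    xp, _ = _standardize(pool, observed) if posterior_sims is not None else (x, obs)
    if posterior_sims is not None:
        post_coords = pca.transform(xp - x.mean(axis=0))
    tails: dict[str, float] = {}
    raw = pool[cols].to_numpy(dtype=float)
    obs_raw = np.array([observed[c[len(STAT_PREFIX):]] for c in cols])
    for k, c in enumerate(cols):
        lo = float((raw[:, k] <= obs_raw[k]).mean())
        hi = float((raw[:, k] >= obs_raw[k]).mean())
        tails[c[len(STAT_PREFIX):]] = min(1.0, 2.0 * min(lo, hi))
    return ModelCheck(ref_coords, obs_coords, post_coords, tails)


# ---------------------------------------------------------------------------
# Confidence in scenario choice
# ---------------------------------------------------------------------------

@dataclass
class ConfidenceErrors:
    type_1: dict[str, float]                  # per scenario
    type_2_mean: dict[str, float]
    type_2_range: dict[str, tuple[float, float]]
    n_pseudo_per_scenario: int

    def formatted(self, scenario: str) -> str:
        lo, hi = self.type_2_range[scenario]
        return (f"type I {self.type_1[scenario]:.2f}, mean type II "
                f"{self.type_2_mean[scenario]:.2f} [{lo:.2f}-{hi:.2f}]")


def confidence_errors(scenarios: list[Scenario], priors: PriorSpec,
                      n_pseudo_per_scenario: int, table: pd.DataFrame,
                      seed: int | None = None, n_loci: int = 9,
                      n_closest: int | None = None,
                      sample_sizes: dict[str, int] | None = None,
                      method: str = "rejection") -> ConfidenceErrors:
    """Misclassification rates of scenario choice on pseudo-observed data.

    For each scenario, simulates pseudo-observed datasets from prior draws
    and classifies them against ``table``. Type-I error of a scenario is the
    fraction of its own pseudo-datasets not assigned to it; its type-II
    error against another scenario is the fraction of that scenario's
    pseudo-datasets assigned to it (mean and min-max range reported).
    """
    if n_pseudo_per_scenario < 10:
        warnings.warn("fewer than 10 pseudo-datasets per scenario: "
                      "error estimates will be unstable")
    rng = np.random.default_rng(seed)
    names = [s.name for s in scenarios]
    assigned: dict[str, list[str]] = {n: [] for n in names}
    for scn in scenarios:
        for _ in range(n_pseudo_per_scenario):
            params = draw_valid_params(scn, priors, rng)
            ds = simulate_scenario(scn, params, n_loci=n_loci,
                                   seed=int(rng.integers(2 ** 31)),
                                   sample_sizes=sample_sizes)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                post = scenario_posterior(table, summary_stats(ds),
                                          n_closest=n_closest, method=method)
            assigned[scn.name].append(max(post.probabilities,
                                          key=post.probabilities.get))
    t1 = {n: float(np.mean([a != n for a in assigned[n]])) for n in names}
    t2_mean: dict[str, float] = {}
    t2_range: dict[str, tuple[float, float]] = {}
    for focal in names:
        rates = [float(np.mean([a == focal for a in assigned[other]]))
                 for other in names if other != focal]
        t2_mean[focal] = float(np.mean(rates))
        t2_range[focal] = (min(rates), max(rates))
    return ConfidenceErrors(t1, t2_mean, t2_range, n_pseudo_per_scenario)


# ---------------------------------------------------------------------------
# Scenario catalog: published invasion topologies + user scenario files
# ---------------------------------------------------------------------------

ISLANDS = ["SantaCruz", "SanCristobal", "Isabela", "Floreana"]
_N_ISL = {"SantaCruz": "N2", "SanCristobal": "N3", "Isabela": "N4",
          "Floreana": "N5"}
_NB_ISL = {"SantaCruz": "N2b", "SanCristobal": "N3b", "Isabela": "N4b",
           "Floreana": "N5b"}


def _island_scenario(name: str, origin: str, intros: list[tuple[str, str, str]],
                     origin_sampled: bool) -> Scenario:
    """Build a scenario from (island, source, time-parameter) introductions.

    Every introduction is followed (forward in time) by a bottleneck in the
    introduced deme of size ``N?b`` lasting ``t_db`` generations.
    """
    sizes: dict[str, float | str] = {origin: "N1"}
    samples: dict[str, int] = {origin: 10 if origin_sampled else 0}
    events: list[Split] = []
    bots: list[Bottleneck] = []
    for isl in ISLANDS:
        sizes[isl] = _N_ISL[isl]
        samples[isl] = 10
    for isl, source, tname in intros:
        events.append(Split(tname, isl, source))
        bots.append(Bottleneck(isl, tname, "t_db", _NB_ISL[isl]))
    return Scenario(name, sizes, samples, events, bots)


def load_scenarios_stage(stage: int) -> list[Scenario]:
    """Competing invasion scenarios for one ABC stage.

    Each stage's first entry is the published best-supported topology:
    stage 1 — mainland to Floreana and Santa Cruz, Floreana to San
    Cristobal, San Cristobal to Isabela; stage 2 — two independent mainland
    introductions (Santa Cruz, San Cristobal), then San Cristobal to Isabela
    and Santa Cruz to Floreana; stage 3 — Coastal origin to San Cristobal,
    then San Cristobal to the other three islands. Two alternative
    topologies (a serial stepping-stone chain and four independent
    introductions) complete each stage's candidate set. Larger user-defined
    candidate sets load via :func:`read_scenarios`.
    """
    if stage == 1:
        origin, sampled = "Mainland", False
        winner = _island_scenario(
            "stage1_winner", origin,
            [("Floreana", origin, "t4"), ("SantaCruz", origin, "t4"),
             ("SanCristobal", "Floreana", "t2"), ("Isabela", "SanCristobal", "t1")],
            sampled)
    elif stage == 2:
        origin, sampled = "Mainland", True
        winner = _island_scenario(
            "stage2_winner", origin,
            [("SantaCruz", origin, "t4"), ("SanCristobal", origin, "t4"),
             ("Isabela", "SanCristobal", "t2"), ("Floreana", "SantaCruz", "t1")],
            sampled)
    elif stage == 3:
        origin, sampled = "Coast", True
        winner = _island_scenario(
            "stage3_winner", origin,
            [("SanCristobal", origin, "t4"), ("SantaCruz", "SanCristobal", "t2"),
             ("Isabela", "SanCristobal", "t2"), ("Floreana", "SanCristobal", "t2")],
            sampled)
    else:
        raise ValueError(f"unknown stage {stage!r}")
    serial = _island_scenario(
        f"stage{stage}_serial", origin,
        [("SantaCruz", origin, "t4"), ("SanCristobal", "SantaCruz", "t3"),
         ("Isabela", "SanCristobal", "t2"), ("Floreana", "Isabela", "t1")],
        sampled)
    independent = _island_scenario(
        f"stage{stage}_independent", origin,
        [(isl, origin, "t4") for isl in ISLANDS],
        sampled)
    return [winner, serial, independent]


def default_priors() -> PriorSpec:
    """Package default priors (the study does not publish its prior table).

    Log-uniform effective sizes, shallow uniform introduction times in
    generations (the colonization is historical, post-1940), a log-uniform
    mean SSR mutation rate, and short severe bottlenecks after each
    introduction. Times are constrained t1 < t2 < t3 < t4 by prior-draw
    rejection.
    """
    return PriorSpec({
        "N1": ("loguniform", 100.0, 100_000.0),
        "N2": ("loguniform", 10.0, 10_000.0),
        "N3": ("loguniform", 10.0, 10_000.0),
        "N4": ("loguniform", 10.0, 10_000.0),
        "N5": ("loguniform", 10.0, 10_000.0),
        "N2b": ("loguniform", 2.0, 100.0),
        "N3b": ("loguniform", 2.0, 100.0),
        "N4b": ("loguniform", 2.0, 100.0),
        "N5b": ("loguniform", 2.0, 100.0),
        "t1": ("uniform", 1.0, 125.0),
        "t2": ("uniform", 125.0, 250.0),
        "t3": ("uniform", 250.0, 375.0),
        "t4": ("uniform", 375.0, 500.0),
        "t_db": ("uniform", 1.0, 20.0),
        "mu": ("loguniform", 1e-4, 1e-3),
    })


def map_populations_to_demes(dataset: SSRDataset, scenario: Scenario
                             ) -> tuple[SSRDataset, dict[str, int]]:
    """Match a dataset's populations to a scenario's demes.

    Populations whose labels already are deme names are used directly;
    otherwise a four-population dataset is mapped onto the four islands in
    first-appearance order (with a warning). Returns the (possibly
    relabeled) dataset and the per-deme sample sizes, zero for unsampled
    demes.
    """
    pops = dataset.populations
    demes = set(scenario.deme_sizes)
    if set(pops) <= demes:
        mapping = {p: p for p in pops}
    elif len(pops) == len(ISLANDS):
        mapping = dict(zip(pops, ISLANDS))
        warnings.warn(f"population labels mapped onto islands in order: {mapping}")
    else:
        raise ValueError(
            f"cannot map populations {pops} onto scenario demes {sorted(demes)}")
    ds = SSRDataset(list(dataset.individual_ids),
                    [mapping[p] for p in dataset.population_ids],
                    list(dataset.loci), dataset.genotypes.copy())
    # order individuals so population order follows the scenario's deme order
    order = [d for d in scenario.sample_sizes if d in set(mapping.values())]
    idx = np.concatenate([ds.population_indices(d) for d in order])
    ds = ds.subset_individuals(idx)
    sizes = {d: 0 for d in scenario.sample_sizes}
    for d in order:
        sizes[d] = int(ds.population_indices(d).size)
    return ds, sizes


def read_scenarios(path: str | Path) -> list[Scenario]:
    """Load a user scenario catalog from a YAML file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return [Scenario.from_dict(d) for d in data["scenarios"]]


def write_scenarios(scenarios: list[Scenario], path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"scenarios": [s.to_dict() for s in scenarios]}, fh,
                       sort_keys=False)
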