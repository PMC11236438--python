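"""End-to-end analysis pipeline: diversity -> differentiation -> structure ->
tree -> ABC, with a JSON manifest as the single source of truth for every
reported number."""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import abc as abc_mod
from . import differentiation, diversity, genotype_io, phylo, structure
from .dataset import SSRDataset

logger = logging.getLogger("ssrpopgen")

STAGES = ["validate", "diversity", "differentiation", "structure", "tree", "abc"]


@dataclass
class PipelineConfig:
    input_path: str
    input_format: str = "genepop"          # genepop | table
    delimiter: str = ","
    output_dir: str = "ssrpopgen_out"
    seed: int = 0
    n_permutations: int = 10_000
    geographic_distances: str | None = None  # labeled CSV for the Mantel test
    tree_bootstraps: int = 1000
    nei_variant: str = "nei72"
    abc_stage: int = 1
    abc_sims_per_scenario: int = 1000
    abc_n_closest: int | None = None
    skip: list[str] = field(default_factory=list)
    verbose: bool = False

    def validate(self) -> None:
        if not Path(self.input_path).exists():
            raise FileNotFoundError(self.input_path)
        if self.geographic_distances and not Path(self.geographic_distances).exists():
            raise FileNotFoundError(self.geographic_distances)
        unknown = set(self.skip) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages to skip: {sorted(unknown)}")


def _load(config: PipelineConfig) -> SSRDataset:
    if config.input_format == "genepop":
        return genotype_io.read_genepop(config.input_path)
    if config.input_format == "table":
        return genotype_io.read_table(config.input_path, config.delimiter)
    raise ValueError(f"unknown input format {config.input_format!r}")


def run_all(config: PipelineConfig) -> dict:
    """Run every (non-skipped) stage; write artifacts and return the manifest.

    Each stage's outputs land in the output directory as CSV/JSON/Newick;
    the manifest records every statistic, seed and runtime. A stage failure
    is recorded and later stages still run; the manifest's ``status`` is
    then ``partial``.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.StreamHandler(sys.stderr)
    if config.verbose and not logger.handlers:
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    manifest: dict = {
        "config": asdict(config),
        "seed": config.seed,
        "stages": {},
        "status": "ok",
    }
    dataset = _load(config)
    manifest["dataset"] = {
        "individuals": dataset.n_individuals,
        "loci": dataset.loci,
        "populations": dataset.populations,
    }
    rng = np.random.default_rng(config.seed)
    stage_seeds = {s: int(rng.integers(2 ** 31)) for s in STAGES}
    manifest["stage_seeds"] = stage_seeds
    for stage in STAGES:
        if stage in config.skip:
            manifest["stages"][stage] = {"status": "skipped"}
            continue
        t0 = time.perf_counter()
        try:
            result = _RUNNERS[stage](dataset, config, stage_seeds[stage], out)
            result["status"] = "ok"
        except Exception as exc:  # noqa: BLE001 - stage isolation is the point
            logger.warning("stage %s failed: %s", stage, exc)
            result = {"status": "failed", "error": str(exc)}
            manifest["status"] = "partial"
        result["runtime_s"] = round(time.perf_counter() - t0, 3)
        manifest["stages"][stage] = result
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


# ---------------------------------------------------------------------------
# Stage runners
# ---------------------------------------------------------------------------

def _run_validate(ds: SSRDataset, config: PipelineConfig, seed: int,
                  out: Path) -> dict:
    rep = genotype_io.validate(ds)
    return {"valid": rep.valid, "violations": rep.violations,
            "warnings": rep.warnings,
            "missing_per_locus": rep.missing_per_locus}


def _run_diversity(ds: SSRDataset, config: PipelineConfig, seed: int,
                   out: Path) -> dict:
    per_locus = diversity.heterozygosity(ds, level="locus")
    per_pop = diversity.heterozygosity(ds, level="population")
    global_h = diversity.heterozygosity(ds, level="global")
    f = diversity.fis(ds)
    rs, _, g_used = diversity.allelic_richness(ds)
    priv, priv_frac = diversity.private_alleles(ds)
    table = diversity.allele_frequencies(ds)
    na_pop = {p: sum(len(table.counts.get((p, l), {})) for l in ds.loci)
              for p in ds.populations}
    rng = np.random.default_rng(seed)
    hwe = {}
    # HWE per locus on the pooled sample, as in the field's standard workflow
    pooled = SSRDataset(list(ds.individual_ids),
                        ["all"] * ds.n_individuals, list(ds.loci),
                        ds.genotypes.copy())
    for locus in ds.loci:
        res = diversity.hwe_test(pooled, locus, "all",
                                 seed=int(rng.integers(2 ** 31)))
        hwe[locus] = {"p": res.p_value, "se": res.se,
                      "applicable": res.applicable}
    null_locus, _ = diversity.null_allele_em(ds)
    ena = diversity.fst_ena(ds)
    rows = []
    for p in ds.populations:
        rows.append({"population": p, "Na": na_pop[p], "Ho": per_pop[p]["Ho"],
                     "He": per_pop[p]["He"], "FIS": f[p], "Rs": rs[p],
                     "Npa": priv[p]})
    pd.DataFrame(rows).to_csv(out / "diversity_per_population.csv", index=False)
    pd.DataFrame({"locus": ds.loci,
                  "Ho": [per_locus["Ho"].get(l) for l in ds.loci],
                  "He": [per_locus["He"].get(l) for l in ds.loci],
                  "No": [null_locus.get(l) for l in ds.loci],
                  "hwe_p": [hwe[l]["p"] for l in ds.loci],
                  }).to_csv(out / "diversity_per_locus.csv", index=False)
    return {
        "per_population": {p: {"Na": na_pop[p], "Ho": per_pop[p]["Ho"],
                               "He": per_pop[p]["He"], "FIS": f[p],
                               "Rs": rs[p], "Npa": priv[p]}
                           for p in ds.populations},
        "per_locus": {l: {"Ho": per_locus["Ho"].get(l),
                          "He": per_locus["He"].get(l),
                          "No": null_locus.get(l),
                          "hwe_p": hwe[l]["p"]} for l in ds.loci},
        "global": global_h, "fis_mean": f["mean"],
        "rarefaction_g": g_used, "private_fraction": priv_frac,
        "fst_ena": {"uncorrected": ena.fst_uncorrected,
                    "corrected": ena.fst_corrected,
                    "t": ena.t_statistic, "p": ena.p_value},
    }


def _run_differentiation(ds: SSRDataset, config: PipelineConfig, seed: int,
                         out: Path) -> dict:
    rng = np.random.default_rng(seed)
    fst = differentiation.pairwise_fst(ds)
    genotype_io.write_distance_csv(fst, out / "pairwise_fst.csv")
    am = differentiation.amova(ds, n_permutations=config.n_permutations,
                               seed=int(rng.integers(2 ** 31)))
    result = {
        "pairwise_fst": {"labels": fst.labels, "values": fst.values.tolist()},
        "amova": {"pct_among": am.pct_among, "pct_within": am.pct_within,
                  "phi_st": am.phi_st, "p": am.p_value,
                  "n_permutations": am.n_permutations},
    }
    if config.geographic_distances:
        geo = genotype_io.read_distance_csv(config.geographic_distances)
        r, p, nperm = differentiation.mantel(fst, geo,
                                             seed=int(rng.integers(2 ** 31)))
        result["mantel"] = {"r": r, "p": p, "n_permutations": nperm}
    net = differentiation.relative_migration(ds, statistic="Nm")
    pd.DataFrame(net.values, index=net.labels, columns=net.labels).to_csv(
        out / "relative_migration.csv")
    result["relative_migration"] = {"labels": net.labels,
                                    "values": net.values.tolist(),
                                    "statistic": net.statistic}
    return result


def _run_structure(ds: SSRDataset, config: PipelineConfig, seed: int,
                   out: Path) -> dict:
    sol = structure.find_clusters(ds, seed=seed)
    pd.DataFrame({"K": list(sol.bic_curve), "BIC": list(sol.bic_curve.values())}
                 ).to_csv(out / "bic_curve.csv", index=False)
    dap = structure.dapc(ds, clusters=sol.assignments)
    coords = pd.DataFrame(dap.coordinates,
                          columns=[f"LD{k + 1}" for k in
                                   range(dap.coordinates.shape[1])])
    coords.insert(0, "individual", dap.individual_ids)
    coords.to_csv(out / "dapc_coordinates.csv", index=False)
    fst = differentiation.pairwise_fst(ds, truncate=True)
    pc = structure.pcoa(fst)
    return {
        "selected_K": sol.K, "bic_curve": sol.bic_curve,
        "n_pcs": sol.n_pcs,
        "assignments": sol.assignments,
        "dapc_axis_variance": dap.axis_variance.tolist(),
        "pcoa_eigenvalues": pc.eigenvalues.tolist(),
    }


def _run_tree(ds: SSRDataset, config: PipelineConfig, seed: int,
              out: Path) -> dict:
    tree = phylo.bootstrap_tree(ds, n_boot=config.tree_bootstraps,
                                variant=config.nei_variant, seed=seed)
    phylo.write_newick(tree, out / "upgma_tree.nwk")
    supports = {",".join(sorted(n.leaves())): n.support
                for n in tree.walk() if not n.is_leaf}
    return {"newick": phylo.to_newick(tree), "supports": supports,
            "n_bootstraps": config.tree_bootstraps,
            "variant": config.nei_variant}


def _run_abc(ds: SSRDataset, config: PipelineConfig, seed: int,
             out: Path) -> dict:
    scenarios = abc_mod.load_scenarios_stage(config.abc_stage)
    priors = abc_mod.default_priors()
    # classify the *observed* data: sample sizes must match the input
    ds, sample_sizes = abc_mod.map_populations_to_demes(ds, scenarios[0])
    table = abc_mod.build_reference_table(
        scenarios, priors, config.abc_sims_per_scenario,
        n_loci=ds.n_loci, seed=seed, sample_sizes=sample_sizes)
    table.to_csv(out / "abc_reference_table.csv", index=False)
    obs = abc_mod.summary_stats(ds)
    post = abc_mod.scenario_posterior(table, obs,
                                      n_closest=config.abc_n_closest)
    best = max(post.probabilities, key=post.probabilities.get)
    est = abc_mod.estimate_parameters(table, obs, best,
                                      n_closest=config.abc_n_closest,
                                      priors=priors)
    check = abc_mod.model_check(table, obs)
    return {
        "stage": config.abc_stage,
        "scenarios": [s.name for s in scenarios],
        "posterior": post.probabilities,
        "best_scenario": best,
        "parameter_quantiles": est.quantiles,
        "tail_probabilities": check.tail_probabilities,
        "n_sims_per_scenario": config.abc_sims_per_scenario,
    }


_RUNNERS = {
    "validate": _run_validate,
    "diversity": _run_diversity,
    "differentiation": _run_differentiation,
    "structure": _run_structure,
    "tree": _run_tree,
    "abc": _run_abc,
}


# ---------------------------------------------------------------------------
# Human-readable report
# ---------------------------------------------------------------------------

def report_tables(manifest: dict) -> str:
    """Render the manifest as plain-text tables (2-decimal display)."""
    lines: list[str] = ["ssrpopgen analysis report", "=" * 25, ""]
    stages = manifest.get("stages", {})

    div = stages.get("diversity", {})
    if div.get("status") == "ok":
        lines.append("Per-population diversity")
        lines.append(f"{'population':<16}{'Na':>5}{'Ho':>7}{'He':>7}"
                     f"{'FIS':>7}{'Rs':>7}{'Npa':>5}")
        for pop, row in div["per_population"].items():
            lines.append(f"{pop:<16}{row['Na']:>5d}{row['Ho']:>7.2f}"
                         f"{row['He']:>7.2f}{row['FIS']:>7.2f}"
                         f"{row['Rs']:>7.2f}{row['Npa']:>5d}")
        g = div["global"]
        lines.append(f"global: Ho={g['Ho']:.2f} He(pooled)={g['He_pooled']:.2f} "
                     f"He(mean within)={g['He_mean_within']:.2f}")
        lines.append("")
    elif div.get("status") == "skipped":
        lines.append("[diversity stage skipped]\n")

    diff = stages.get("differentiation", {})
    if diff.get("status") == "ok":
        labels = diff["pairwise_fst"]["labels"]
        vals = diff["pairwise_fst"]["values"]
        lines.append("Pairwise FST")
        lines.append("\t" + "\t".join(labels))
        for i, lab in enumerate(labels):
            cells = ["—" if i == j else f"{vals[i][j]:.3f}"
                     for j in range(len(labels))]
            lines.append(lab + "\t" + "\t".join(cells))
        am = diff["amova"]
        lines.append(f"AMOVA: {am['pct_among']:.2f}% among / "
                     f"{am['pct_within']:.2f}% within populations "
                     f"(Phi_ST={am['phi_st']:.3f}, p={am['p']:.4f})")
        if "mantel" in diff:
            mt = diff["mantel"]
            lines.append(f"Mantel: r={mt['r']:.2f}, p={mt['p']:.3f} "
                         f"({mt['n_permutations']} permutations)")
        lines.append("")
    elif diff.get("status") == "skipped":
        lines.append("[differentiation stage skipped]\n")

    st = stages.get("structure", {})
    if st.get("status") == "ok":
        lines.append(f"Clusters: K={st['selected_K']} "
                     f"({st['n_pcs']} PCs retained)")
        lines.append("")

    ab = stages.get("abc", {})
    if ab.get("status") == "ok":
        lines.append("Scenario posterior probabilities")
        for name, p in ab["posterior"].items():
            lines.append(f"  {name:<24}{p:.4f}")
        lines.append(f"best: {ab['best_scenario']}")
        lines.append("")
    elif ab.get("status") == "skipped":
        lines.append("[abc stage skipped]\n")
    return "\n".join(lines)
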