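"""Within-population diversity statistics for SSR data.

Covers allele frequency tables, observed/expected heterozygosity (with the
Nei small-sample correction), inbreeding coefficients, hypergeometric
rarefied allelic richness, private alleles, the Guo & Thompson Markov-chain
exact test of Hardy-Weinberg proportions, a Dempster EM estimator of null
allele frequencies, and the "excluding null alleles" (ENA) correction to
Weir-Cockerham FST.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .dataset import MISSING, SSRDataset

POOLED = "__pooled__"


# ---------------------------------------------------------------------------
# Allele frequencies
# ---------------------------------------------------------------------------

@dataclass
class AlleleFreqTable:
    """Per-(population, locus) allele counts, frequencies and gene counts.

    Entries with zero observed genes are absent (never NaN-filled). The
    pooled sample over all populations is stored under the key
    :data:`POOLED`.
    """

    populations: list[str]
    loci: list[str]
    counts: dict[tuple[str, str], dict[int, int]] = field(default_factory=dict)

    def gene_count(self, population: str, locus: str) -> int:
        c = self.counts.get((population, locus))
        return sum(c.values()) if c else 0

    def frequencies(self, population: str, locus: str) -> dict[int, float]:
        c = self.counts.get((population, locus))
        if not c:
            raise KeyError(f"no observed genes for ({population!r}, {locus!r})")
        tot = sum(c.values())
        return {a: k / tot for a, k in c.items()}

    def has_entry(self, population: str, locus: str) -> bool:
        return bool(self.counts.get((population, locus)))

    def alleles(self, locus: str) -> list[int]:
        """All distinct alleles observed at a locus across populations."""
        seen: set[int] = set()
        for pop in self.populations:
            seen.update(self.counts.get((pop, locus), {}))
        return sorted(seen)


def allele_frequencies(dataset: SSRDataset) -> AlleleFreqTable:
    """Count alleles per population and locus (2 genes per scored genotype)."""
    table = AlleleFreqTable(dataset.populations, list(dataset.loci))
    for pop in dataset.populations + [POOLED]:
        idx = (np.arange(dataset.n_individuals) if pop == POOLED
               else dataset.population_indices(pop))
        for j, locus in enumerate(dataset.loci):
            cell = dataset.genotypes[idx, j, :]
            alleles = cell[cell != MISSING]
            if alleles.size:
                vals, cnt = np.unique(alleles, return_counts=True)
                table.counts[(pop, locus)] = dict(zip(vals.tolist(), cnt.tolist()))
    return table


# ---------------------------------------------------------------------------
# Heterozygosity, FIS
# ---------------------------------------------------------------------------

def gene_diversity(freqs: dict[int, float], n_genes: int, unbiased: bool = True) -> float:
    """Gene diversity 1 - sum p^2, with Nei's 2n/(2n-1) correction if asked."""
    h = 1.0 - sum(p * p for p in freqs.values())
    if unbiased and n_genes > 1:
        h *= n_genes / (n_genes - 1)
    return h


def observed_heterozygosity(dataset: SSRDataset, population: str | None = None
                            ) -> dict[str, float]:
    """Ho per locus: fraction of scored genotypes that are heterozygous."""
    idx = (np.arange(dataset.n_individuals) if population is None
           else dataset.population_indices(population))
    het = dataset.heterozygote_mask()[idx]
    scored = dataset.scored_mask[idx]
    out: dict[str, float] = {}
    for j, locus in enumerate(dataset.loci):
        n = int(scored[:, j].sum())
        if n:
            out[locus] = float(het[:, j].sum()) / n
    return out


def expected_heterozygosity(dataset: SSRDataset, population: str | None = None,
                            unbiased: bool = True) -> dict[str, float]:
    """He (gene diversity) per locus for one population or the pooled sample."""
    table = allele_frequencies(dataset)
    pop = POOLED if population is None else population
    out: dict[str, float] = {}
    for locus in dataset.loci:
        if table.has_entry(pop, locus):
            out[locus] = gene_diversity(table.frequencies(pop, locus),
                                        table.gene_count(pop, locus), unbiased)
    return out


def heterozygosity(dataset: SSRDataset, level: str = "population",
                   unbiased: bool = True) -> dict:
    """Ho and He at the requested level.

    ``locus``: per-locus values on the pooled sample. ``population``:
    per-population means over loci. ``global``: means over loci of the pooled
    He and of the across-population average Hs (both reported, the field's two
    common conventions), plus mean Ho.
    """
    if level == "locus":
        return {"Ho": observed_heterozygosity(dataset),
                "He": expected_heterozygosity(dataset, None, unbiased)}
    if level == "population":
        out: dict[str, dict[str, float]] = {}
        for pop in dataset.populations:
            ho = observed_heterozygosity(dataset, pop)
            he = expected_heterozygosity(dataset, pop, unbiased)
            out[pop] = {"Ho": float(np.mean(list(ho.values()))) if ho else math.nan,
                        "He": float(np.mean(list(he.values()))) if he else math.nan}
        return out
    if level == "global":
        pooled = expected_heterozygosity(dataset, None, unbiased)
        per_pop = [expected_heterozygosity(dataset, p, unbiased)
                   for p in dataset.populations]
        hs_by_locus = []
        for locus in dataset.loci:
            vals = [d[locus] for d in per_pop if locus in d]
            if vals:
                hs_by_locus.append(float(np.mean(vals)))
        ho = observed_heterozygosity(dataset)
        return {"Ho": float(np.mean(list(ho.values()))),
                "He_pooled": float(np.mean(list(pooled.values()))),
                "He_mean_within": float(np.mean(hs_by_locus))}
    raise ValueError(f"unknown level {level!r}")


def fis(dataset: SSRDataset, unbiased: bool = True) -> dict[str, float]:
    """Per-population FIS = 1 - mean(Ho)/mean(Hs) over loci, plus the mean.

    Ratio-of-averages over loci (the multilocus convention); populations where
    Hs is zero at every locus get NaN. The across-population mean is stored
    under ``"mean"``.
    """
    out: dict[str, float] = {}
    vals = []
    for pop in dataset.populations:
        ho = observed_heterozygosity(dataset, pop)
        hs = expected_heterozygosity(dataset, pop, unbiased)
        shared = [l for l in dataset.loci if l in ho and l in hs]
        hs_sum = sum(hs[l] for l in shared)
        if not shared or hs_sum <= 0:
            out[pop] = math.nan
            continue
        f = 1.0 - sum(ho[l] for l in shared) / hs_sum
        out[pop] = f
        vals.append(f)
    out["mean"] = float(np.mean(vals)) if vals else math.nan
    return out


# ---------------------------------------------------------------------------
# Rarefied allelic richness, private alleles
# ---------------------------------------------------------------------------

def _rarefied_count(counts: dict[int, int], g: int) -> float:
    n = sum(counts.values())
    if g > n:
        raise ValueError(f"rarefaction depth {g} exceeds gene count {n}")
    total = 0.0
    for ni in counts.values():
        # P(allele present in a hypergeometric subsample of g genes)
        if n - ni < g:
            total += 1.0
        else:
            total += 1.0 - math.comb(n - ni, g) / math.comb(n, g)
    return total


def allelic_richness(dataset: SSRDataset, g: int | None = None
                     ) -> tuple[dict[str, float], dict[tuple[str, str], float], int]:
    """Rarefied allelic richness Rs per population (mean over loci).

    ``g`` defaults to the minimum gene count over all (population, locus)
    cells with data, so every cell supports the rarefaction depth. Returns
    (per-population Rs, per-(population, locus) Rs, g used).
    """
    table = allele_frequencies(dataset)
    cells = [(p, l) for p in dataset.populations for l in dataset.loci
             if table.has_entry(p, l)]
    if g is None:
        g = min(table.gene_count(p, l) for p, l in cells)
    if g < 2:
        raise ValueError("rarefaction depth g must be >= 2")
    per_cell: dict[tuple[str, str], float] = {}
    for p, l in cells:
        if table.gene_count(p, l) >= g:
            per_cell[(p, l)] = _rarefied_count(table.counts[(p, l)], g)
    per_pop: dict[str, float] = {}
    for p in dataset.populations:
        vals = [v for (pp, _), v in per_cell.items() if pp == p]
        per_pop[p] = float(np.mean(vals)) if vals else math.nan
    return per_pop, per_cell, g


def private_alleles(dataset: SSRDataset) -> tuple[dict[str, int], float]:
    """Count alleles observed in exactly one population.

    Returns per-population counts and the fraction of all distinct
    (locus, allele) pairs that are private.
    """
    import warnings as _warnings

    table = allele_frequencies(dataset)
    pops = dataset.populations
    if len(pops) < 2:
        _warnings.warn("single population: every allele is trivially private")
    counts = {p: 0 for p in pops}
    n_total = 0
    for locus in dataset.loci:
        carriers: dict[int, list[str]] = {}
        for p in pops:
            for a in table.counts.get((p, locus), {}):
                carriers.setdefault(a, []).append(p)
        n_total += len(carriers)
        for a, who in carriers.items():
            if len(who) == 1:
                counts[who[0]] += 1
    frac = sum(counts.values()) / n_total if n_total else 0.0
    return counts, frac


# ---------------------------------------------------------------------------
# Guo-Thompson Markov-chain exact HWE test
# ---------------------------------------------------------------------------

@dataclass
class HWEResult:
    p_value: float
    se: float
    n_alleles: int
    n_individuals: int
    applicable: bool = True
    note: str = ""


def _log_table_weight(counts: np.ndarray) -> float:
    """log of 2^H / prod(n_ij!) — the table-dependent part of the HWE
    conditional probability given allele counts."""
    k = counts.shape[0]
    het = 0
    s = 0.0
    for i in range(k):
        for j in range(i, k):
            n = counts[i, j]
            s -= math.lgamma(n + 1)
            if i != j:
                het += n
    return s + het * math.log(2.0)


def hwe_test(dataset: SSRDataset, locus: str, population: str,
             dememorization: int = 1000, batches: int = 100,
             iterations: int = 1000, seed: int | None = None) -> HWEResult:
    """Markov-chain exact probability test of Hardy-Weinberg proportions.

    In the spirit of Guo & Thompson (1992): a Markov chain over genotype
    tables with the observed allele counts; the p-value is the chain
    fraction of tables no more probable than the observed one, and the
    standard error comes from the spread of per-batch p estimates. The
    chain state is the assignment of the 2n gene copies to ordered
    individual slots — conditional on allele counts every arrangement is
    equally likely under HWE, so swapping two random gene copies between
    two random individuals is a symmetric move accepted with probability
    one, and genotype tables are visited with probability proportional to
    n! 2^H / prod(n_ij!).
    """
    rng = np.random.default_rng(seed)
    idx = dataset.population_indices(population)
    j = dataset.locus_index(locus)
    cell = dataset.genotypes[idx, j, :]
    cell = cell[np.all(cell != MISSING, axis=1)]
    alleles = np.unique(cell)
    if alleles.size < 2 or cell.shape[0] < 3:
        return HWEResult(math.nan, math.nan, int(alleles.size), int(cell.shape[0]),
                         applicable=False, note="monomorphic or too few individuals")
    amap = {a: i for i, a in enumerate(alleles.tolist())}
    k = len(alleles)
    genos = np.array([[amap[a], amap[b]] for a, b in cell], dtype=np.intp)
    n = genos.shape[0]
    counts = np.zeros((k, k), dtype=np.int64)
    for a, b in genos:
        counts[min(a, b), max(a, b)] += 1
    obs_logw = _log_table_weight(counts)
    cur_logw = obs_logw

    def step() -> None:
        nonlocal cur_logw
        i1, i2 = rng.choice(n, size=2, replace=False)
        s1 = int(rng.integers(0, 2))
        s2 = int(rng.integers(0, 2))
        a1, a2 = genos[i1, s1], genos[i2, s2]
        if a1 == a2:
            return
        old_cells = (tuple(sorted(genos[i1])), tuple(sorted(genos[i2])))
        genos[i1, s1], genos[i2, s2] = a2, a1
        new_cells = (tuple(sorted(genos[i1])), tuple(sorted(genos[i2])))
        delta = 0.0
        for cell_ in old_cells:
            delta += math.log(counts[cell_])
            counts[cell_] -= 1
            if cell_[0] != cell_[1]:
                delta -= math.log(2.0)
        for cell_ in new_cells:
            counts[cell_] += 1
            delta -= math.log(counts[cell_])
            if cell_[0] != cell_[1]:
                delta += math.log(2.0)
        cur_logw += delta

    for _ in range(dememorization):
        step()
    tol = 1e-9
    batch_means = np.empty(batches)
    for b in range(batches):
        cur_logw = _log_table_weight(counts)  # re-anchor against float drift
        hits = 0
        for _ in range(iterations):
            step()
            if cur_logw <= obs_logw + tol:
                hits += 1
        batch_means[b] = hits / iterations
    p = float(batch_means.mean())
    se = float(batch_means.std(ddof=1) / math.sqrt(batches)) if batches > 1 else math.nan
    return HWEResult(p, se, k, n)


def hwe_exact_enumeration(dataset: SSRDataset, locus: str, population: str) -> float:
    """Exact HWE probability-test p-value by full enumeration (2 alleles only).

    Independent of the Markov chain: enumerates every genotype table with the
    observed allele counts via the heterozygote count.
    """
    idx = dataset.population_indices(population)
    j = dataset.locus_index(locus)
    cell = dataset.genotypes[idx, j, :]
    cell = cell[np.all(cell != MISSING, axis=1)]
    alleles = np.unique(cell)
    if alleles.size != 2:
        raise ValueError("enumeration oracle supports exactly 2 alleles")
    n = cell.shape[0]
    n1 = int((cell == alleles[0]).sum())
    h_obs = int((cell[:, 0] != cell[:, 1]).sum())
    hs = range(n1 % 2, min(n1, 2 * n - n1) + 1, 2)
    logw = {}
    for h in hs:
        n11 = (n1 - h) // 2
        n22 = n - n11 - h
        logw[h] = (h * math.log(2.0) - math.lgamma(n11 + 1)
                   - math.lgamma(h + 1) - math.lgamma(n22 + 1))
    m = max(logw.values())
    probs = {h: math.exp(v - m) for h, v in logw.items()}
    z = sum(probs.values())
    return sum(p for h, p in probs.items() if p <= probs[h_obs] * (1 + 1e-12)) / z


# ---------------------------------------------------------------------------
# Null allele EM (Dempster) and ENA-corrected FST
# ---------------------------------------------------------------------------

@dataclass
class NullAlleleEstimate:
    frequency: float
    visible_frequencies: dict[int, float]
    converged: bool
    iterations: int


def null_allele_em(dataset: SSRDataset, tol: float = 1e-8, max_iter: int = 10_000
                   ) -> tuple[dict[str, float], dict[tuple[str, str], NullAlleleEstimate]]:
    """EM estimate of null allele frequency per (locus, population).

    Model: apparent homozygotes at allele *i* are a mixture of true
    homozygotes (p_i^2) and heterozygotes carrying one null copy
    (2 p_i r); fully null individuals are unobservable and folded into
    missing data. Iterates expected gene counts until the null frequency
    moves by less than ``tol``. The per-locus summary is the mean over
    populations (populations with no data at the locus skipped).
    """
    per_cell: dict[tuple[str, str], NullAlleleEstimate] = {}
    for pop in dataset.populations:
        idx = dataset.population_indices(pop)
        for j, locus in enumerate(dataset.loci):
            cell = dataset.genotypes[idx, j, :]
            cell = cell[np.all(cell != MISSING, axis=1)]
            if cell.shape[0] == 0:
                continue
            per_cell[(locus, pop)] = _em_one_cell(cell, tol, max_iter)
    per_locus: dict[str, float] = {}
    for locus in dataset.loci:
        vals = [e.frequency for (l, _), e in per_cell.items() if l == locus]
        if vals:
            per_locus[locus] = float(np.mean(vals))
    return per_locus, per_cell


def _em_one_cell(cell: np.ndarray, tol: float, max_iter: int) -> NullAlleleEstimate:
    alleles = np.unique(cell).tolist()
    k = len(alleles)
    amap = {a: i for i, a in enumerate(alleles)}
    n = cell.shape[0]
    hom = np.zeros(k)       # apparent homozygote counts per allele
    het = np.zeros((k, k))  # heterozygote counts (upper triangle)
    for a, b in cell:
        ia, ib = amap[a], amap[b]
        if ia == ib:
            hom[ia] += 1
        else:
            het[min(ia, ib), max(ia, ib)] += 1
    het_genes = het.sum(axis=0) + het.sum(axis=1)
    if k == 1:
        return NullAlleleEstimate(0.0, {alleles[0]: 1.0}, True, 0)
    p = np.full(k, (1.0 - 0.05) / k)
    r = 0.05
    it = 0
    converged = False
    for it in range(1, max_iter + 1):
        # E-step: split apparent homozygotes into true homs vs null hets,
        # and impute the unobservable null-homozygote class (individuals
        # that drop out entirely): E[n_00] = n r^2 / (1 - r^2)
        denom = p + 2.0 * r
        w = np.divide(p, denom, out=np.ones_like(p), where=denom > 0)
        n00 = n * r * r / (1.0 - r * r) if r < 1.0 else 0.0
        # M-step gene counts: true hom 2 copies of i; null het 1 copy of i
        # plus 1 null; null homozygote 2 nulls
        gi = hom * (1.0 + w) + het_genes
        gnull = (hom * (1.0 - w)).sum() + 2.0 * n00
        total = 2.0 * (n + n00)
        p_new = gi / total
        r_new = gnull / total
        if abs(r_new - r) < tol and np.abs(p_new - p).max() < tol:
            p, r = p_new, r_new
            converged = True
            break
        p, r = p_new, r_new

    def loglik(pv: np.ndarray, rv: float) -> float:
        ll = 0.0
        for i in range(k):
            if hom[i]:
                ll += hom[i] * math.log(pv[i] * pv[i] + 2.0 * pv[i] * rv)
            for j in range(i + 1, k):
                if het[i, j]:
                    ll += het[i, j] * math.log(2.0 * pv[i] * pv[j])
        return ll - n * math.log(1.0 - rv * rv)

    # EM approaches the r = 0 boundary only geometrically; when the boundary
    # fit (raw frequencies, no nulls) is at least as likely, report it exactly
    p_raw = (2.0 * hom + het_genes) / (2.0 * n)
    if loglik(p_raw, 0.0) >= loglik(p, r) - 1e-9:
        return NullAlleleEstimate(0.0, {a: float(p_raw[amap[a]]) for a in alleles},
                                  True, it)
    return NullAlleleEstimate(float(r), {a: float(p[amap[a]]) for a in alleles},
                              converged, it)


@dataclass
class EnaFstResult:
    fst_uncorrected: float
    fst_corrected: float
    per_locus_uncorrected: dict[str, float]
    per_locus_corrected: dict[str, float]
    t_statistic: float
    p_value: float


def fst_ena(dataset: SSRDataset) -> EnaFstResult:
    """Global Weir-Cockerham FST with and without the ENA null-allele correction.

    The corrected estimate replaces each population's allele frequencies by
    the EM-corrected visible frequencies (which sum to 1 - r) and excludes
    the null-allele class from the sums over alleles, as in the "excluding
    null alleles" method. The two per-locus vectors are compared with a
    two-sided paired t-test; a zero-variance difference vector yields
    t = 0, p = 1 by convention.
    """
    from .differentiation import wc_variance_components

    _, per_cell = null_allele_em(dataset)
    pops = dataset.populations
    unc: dict[str, float] = {}
    cor: dict[str, float] = {}
    sum_a_u = sum_abc_u = sum_a_c = sum_abc_c = 0.0
    for j, locus in enumerate(dataset.loci):
        freqs_u, freqs_c, sizes, hets = {}, {}, {}, {}
        for pop in pops:
            idx = dataset.population_indices(pop)
            cell = dataset.genotypes[idx, j, :]
            cell = cell[np.all(cell != MISSING, axis=1)]
            if cell.shape[0] == 0:
                continue
            n = cell.shape[0]
            vals, cnt = np.unique(cell, return_counts=True)
            freqs_u[pop] = dict(zip(vals.tolist(), (cnt / (2 * n)).tolist()))
            est = per_cell[(locus, pop)]
            freqs_c[pop] = {a: f * (1.0 - est.frequency)
                            for a, f in est.visible_frequencies.items()}
            sizes[pop] = n
            hets[pop] = {a: float(((cell[:, 0] != cell[:, 1])
                                   & np.any(cell == a, axis=1)).sum()) / n
                         for a in vals.tolist()}
        if len(sizes) < 2:
            continue
        a_u, bc_u = wc_variance_components(freqs_u, sizes, hets)
        a_c, bc_c = wc_variance_components(freqs_c, sizes, hets)
        if a_u + bc_u > 0:
            unc[locus] = a_u / (a_u + bc_u)
        if a_c + bc_c > 0:
            cor[locus] = a_c / (a_c + bc_c)
        sum_a_u += a_u
        sum_abc_u += a_u + bc_u
        sum_a_c += a_c
        sum_abc_c += a_c + bc_c
    shared = [l for l in dataset.loci if l in unc and l in cor]
    if len(shared) >= 2:
        diff = np.array([cor[l] - unc[l] for l in shared])
        if np.allclose(diff.std(ddof=1), 0.0):
            t, p = 0.0, 1.0
        else:
            t, p = sps.ttest_rel([cor[l] for l in shared], [unc[l] for l in shared])
            t, p = float(t), float(p)
    else:
        t, p = math.nan, math.nan
    return EnaFstResult(
        sum_a_u / sum_abc_u if sum_abc_u > 0 else math.nan,
        sum_a_c / sum_abc_c if sum_abc_c > 0 else math.nan,
        unc, cor, t, p,
    )
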