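"""Between-population structure: Weir-Cockerham FST, AMOVA, Mantel test and
directional relative-migration networks."""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .dataset import MISSING, DistanceMatrix, SSRDataset


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984) theta
# ---------------------------------------------------------------------------

def wc_variance_components(freqs: dict[str, dict[int, float]],
                           sizes: dict[str, int],
                           hets: dict[str, dict[int, float]]) -> tuple[float, float]:
    """Single-locus Weir-Cockerham variance components summed over alleles.

    Parameters are per-population allele frequencies, sample sizes
    (individuals) and per-allele observed heterozygote proportions. Returns
    ``(sum_a, sum_b_plus_c)`` so theta = sum_a / (sum_a + sum_b_plus_c).
    Frequencies need not sum to one, which is what lets the ENA correction
    exclude the null-allele class.
    """
    pops = [p for p in freqs if sizes.get(p, 0) > 0]
    r = len(pops)
    if r < 2:
        raise ValueError("need >=2 populations with data")
    n = np.array([sizes[p] for p in pops], dtype=float)
    nbar = n.mean()
    if nbar <= 1:
        raise ValueError("need more than one individual per population on average")
    nc = (r * nbar - (n ** 2).sum() / (r * nbar)) / (r - 1)
    alleles = sorted({a for p in pops for a in freqs[p]})
    sum_a = sum_bc = 0.0
    for al in alleles:
        p_i = np.array([freqs[p].get(al, 0.0) for p in pops])
        h_i = np.array([hets[p].get(al, 0.0) for p in pops])
        pbar = (n * p_i).sum() / (r * nbar)
        s2 = (n * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n * h_i).sum() / (r * nbar)
        inner = pbar * (1 - pbar) - (r - 1) / r * s2
        a = (nbar / nc) * (s2 - (inner - hbar / 4.0) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2.0
        sum_a += a
        sum_bc += b + c
    return sum_a, sum_bc


def pop_locus_stats(dataset: SSRDataset
                    ) -> dict[tuple[str, int], tuple[int, dict, dict]]:
    """Per-(population, locus index): (n scored, allele freqs, per-allele
    observed heterozygote proportions). Computed once and reusable across
    many pairwise theta evaluations."""
    out: dict[tuple[str, int], tuple[int, dict, dict]] = {}
    for pop in dataset.populations:
        idx = dataset.population_indices(pop)
        for j in range(dataset.n_loci):
            cell = dataset.genotypes[idx, j, :]
            cell = cell[np.all(cell != MISSING, axis=1)]
            if cell.shape[0] == 0:
                continue
            nn = cell.shape[0]
            vals, cnt = np.unique(cell, return_counts=True)
            freqs = dict(zip(vals.tolist(), (cnt / (2 * nn)).tolist()))
            is_het = cell[:, 0] != cell[:, 1]
            hets = {a: float((is_het & np.any(cell == a, axis=1)).sum()) / nn
                    for a in vals.tolist()}
            out[(pop, j)] = (nn, freqs, hets)
    return out


def _locus_components(stats: dict, pops: list[str], j: int
                      ) -> tuple[float, float] | None:
    freqs: dict[str, dict[int, float]] = {}
    sizes: dict[str, int] = {}
    hets: dict[str, dict[int, float]] = {}
    for pop in pops:
        entry = stats.get((pop, j))
        if entry is None:
            continue
        sizes[pop], freqs[pop], hets[pop] = entry
    if len(sizes) < 2:
        return None
    if all(len(f) == 1 for f in freqs.values()) and len(
            {next(iter(f)) for f in freqs.values()}) == 1:
        return None  # monomorphic across these populations
    return wc_variance_components(freqs, sizes, hets)


def multilocus_theta(dataset: SSRDataset, pops: list[str] | None = None,
                     stats: dict | None = None
                     ) -> tuple[float, dict[str, float]]:
    """Multi-locus W&C theta (ratio of summed components) and per-locus values."""
    if pops is None:
        pops = dataset.populations
    if stats is None:
        stats = pop_locus_stats(dataset)
    sum_a = sum_abc = 0.0
    per_locus: dict[str, float] = {}
    for j, locus in enumerate(dataset.loci):
        comp = _locus_components(stats, pops, j)
        if comp is None:
            continue
        a, bc = comp
        if a + bc != 0:
            per_locus[locus] = a / (a + bc)
        sum_a += a
        sum_abc += a + bc
    theta = sum_a / sum_abc if sum_abc != 0 else math.nan
    return theta, per_locus


def nei_gst_pair(dataset: SSRDataset, pops: list[str]) -> float:
    """Nei's multilocus Gst = (Ht - Hs) / Ht over the given populations."""
    from .diversity import allele_frequencies, gene_diversity

    table = allele_frequencies(dataset)
    ht_sum = hs_sum = 0.0
    n_loci = 0
    for locus in dataset.loci:
        have = [p for p in pops if table.has_entry(p, locus)]
        if len(have) < 2:
            continue
        fr = [table.frequencies(p, locus) for p in have]
        hs = float(np.mean([1.0 - sum(v * v for v in f.values()) for f in fr]))
        mean_f: dict[int, float] = {}
        for f in fr:
            for a, v in f.items():
                mean_f[a] = mean_f.get(a, 0.0) + v / len(fr)
        ht = 1.0 - sum(v * v for v in mean_f.values())
        ht_sum += ht
        hs_sum += hs
        n_loci += 1
    if n_loci == 0 or ht_sum == 0:
        return math.nan
    return (ht_sum - hs_sum) / ht_sum


def pairwise_fst(dataset: SSRDataset, estimator: str = "weir_cockerham",
                 truncate: bool = False) -> DistanceMatrix:
    """Pairwise multilocus FST between all population pairs.

    Negative Weir-Cockerham estimates are reported as computed unless
    ``truncate`` is set.
    """
    pops = dataset.populations
    k = len(pops)
    if k < 2:
        raise ValueError("need >=2 populations")
    m = np.zeros((k, k))
    stats = pop_locus_stats(dataset) if estimator == "weir_cockerham" else None
    for i, jdx in itertools.combinations(range(k), 2):
        pair = [pops[i], pops[jdx]]
        if estimator == "weir_cockerham":
            theta, _ = multilocus_theta(dataset, pair, stats=stats)
        elif estimator == "nei_gst":
            theta = nei_gst_pair(dataset, pair)
        else:
            raise ValueError(f"unknown estimator {estimator!r}")
        if truncate and not math.isnan(theta):
            theta = max(theta, 0.0)
        m[i, jdx] = m[jdx, i] = theta
    # DistanceMatrix rejects negatives; allow small negative theta estimates
    dm = DistanceMatrix.__new__(DistanceMatrix)
    dm.labels = list(pops)
    dm.values = (m + m.T) / 2.0
    np.fill_diagonal(dm.values, 0.0)
    dm._tol = 1e-9
    return dm


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

@dataclass
class AmovaResult:
    sigma_among: float
    sigma_within: float
    sigma_among_raw: float
    pct_among: float
    pct_within: float
    phi_st: float
    p_value: float
    n_permutations: int


def _pairwise_allele_mismatch(dataset: SSRDataset) -> np.ndarray:
    """Squared inter-individual distance: allele-count mismatches (0/1/2)
    summed over loci scored in both individuals (the Arlequin default for
    codominant data)."""
    n = dataset.n_individuals
    g = dataset.genotypes
    scored = dataset.scored_mask
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = scored[i] & scored[j]
            if not ok.any():
                d[i, j] = d[j, i] = np.nan
                continue
            tot = 0
            for l in np.nonzero(ok)[0]:
                a1, b1 = g[i, l]
                a2, b2 = g[j, l]
                # multiset overlap of {a1,b1} and {a2,b2}
                if a1 == a2 and b1 == b2:
                    shared = 2
                elif a1 == a2 or a1 == b2 or b1 == a2 or b1 == b2:
                    shared = 1
                    if a1 == b1 and a2 == b2 and a1 != a2:
                        shared = 0
                else:
                    shared = 0
                tot += 2 - shared
            d[i, j] = d[j, i] = tot
    return d


def _amova_phi(d2: np.ndarray, groups: np.ndarray) -> tuple[float, float, float]:
    """One-level AMOVA variance components from a squared-distance matrix.

    Returns (sigma_among_raw, sigma_within, phi_st).
    """
    n = d2.shape[0]
    labels = np.unique(groups)
    k = labels.size
    iu = np.triu_indices(n, 1)
    ss_total = np.nansum(d2[iu]) / n
    ss_within = 0.0
    sizes = []
    for g in labels:
        idx = np.nonzero(groups == g)[0]
        sizes.append(idx.size)
        if idx.size > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += np.nansum(sub[np.triu_indices(idx.size, 1)]) / idx.size
    ss_among = ss_total - ss_within
    df_among, df_within = k - 1, n - k
    ms_among = ss_among / df_among
    ms_within = ss_within / df_within if df_within > 0 else math.nan
    sizes_arr = np.asarray(sizes, dtype=float)
    n_prime = (n - (sizes_arr ** 2).sum() / n) / (k - 1)
    sigma_w = ms_within
    sigma_a = (ms_among - ms_within) / n_prime
    denom = sigma_a + sigma_w
    phi = sigma_a / denom if denom > 0 else math.nan
    return sigma_a, sigma_w, phi


def amova(dataset: SSRDataset, n_permutations: int = 10_000,
          seed: int | None = None) -> AmovaResult:
    """One-level AMOVA (among vs within populations) with permutation test.

    Significance: individuals are randomly reassigned to populations
    (sizes preserved); p is the fraction of permuted Phi_ST >= observed,
    with the observed statistic included in numerator and denominator.
    Negative among-population components are truncated to 0 for the
    percentage report; the raw value is also returned.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    d2 = _pairwise_allele_mismatch(dataset)
    groups = np.asarray([dataset.populations.index(p) for p in dataset.population_ids])
    sigma_a_raw, sigma_w, phi_obs = _amova_phi(d2, groups)
    hits = 1
    for _ in range(n_permutations):
        perm = rng.permutation(groups)
        _, _, phi = _amova_phi(d2, perm)
        if phi >= phi_obs - 1e-12:
            hits += 1
    p = hits / (n_permutations + 1)
    sigma_a = max(sigma_a_raw, 0.0)
    tot = sigma_a + sigma_w
    return AmovaResult(
        sigma_among=sigma_a, sigma_within=sigma_w, sigma_among_raw=sigma_a_raw,
        pct_among=100.0 * sigma_a / tot, pct_within=100.0 * sigma_w / tot,
        phi_st=phi_obs, p_value=p, n_permutations=n_permutations,
    )


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

def mantel(m1: DistanceMatrix, m2: DistanceMatrix, mode: str = "auto",
           n_perm: int = 999, seed: int | None = None,
           alternative: str = "greater") -> tuple[float, float, int]:
    """Mantel test of matrix correlation.

    r is the Pearson correlation of off-diagonal upper triangles; p comes
    from permuting the labels of one matrix. With <= 7 labels (``auto`` or
    ``exact_enumeration``) all n! - 1 non-identity permutations are
    enumerated — 4 labels give the 23 permutations possible at this size.
    Returns (r, p, n_permutations_used).
    """
    if m1.labels != m2.labels:
        m2 = m2.reorder(m1.labels)
    n = len(m1.labels)
    if n < 3:
        raise ValueError("Mantel test needs >= 3 labels")
    x = m1.condensed()
    y = m2.condensed()
    if np.std(x) == 0 or np.std(y) == 0:
        return math.nan, math.nan, 0

    def corr(perm: np.ndarray) -> float:
        mp = m2.values[np.ix_(perm, perm)]
        yp = mp[np.triu_indices(n, 1)]
        return float(np.corrcoef(x, yp)[0, 1])

    r_obs = float(np.corrcoef(x, y)[0, 1])
    exact = mode == "exact_enumeration" or (mode == "auto" and n <= 7)
    if exact:
        perms = [np.asarray(p) for p in itertools.permutations(range(n))
                 if p != tuple(range(n))]
    else:
        if mode not in ("permutation", "auto"):
            raise ValueError(f"unknown mode {mode!r}")
        rng = np.random.default_rng(seed)
        perms = [rng.permutation(n) for _ in range(n_perm)]
    rs = np.array([corr(p) for p in perms])
    if alternative == "greater":
        hits = int((rs >= r_obs - 1e-12).sum())
    elif alternative == "two-sided":
        hits = int((np.abs(rs) >= abs(r_obs) - 1e-12).sum())
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    p = (hits + 1) / (len(perms) + 1)
    return r_obs, p, len(perms)


# ---------------------------------------------------------------------------
# Directional relative migration (divMigrate-style)
# ---------------------------------------------------------------------------

@dataclass
class MigrationNetwork:
    labels: list[str]
    values: np.ndarray        # m[i, j] = relative migration i -> j, max 1
    statistic: str
    bootstrap_support: np.ndarray | None = None  # P(m[i->j] > m[j->i])


def _pair_stat(freq_a: dict[int, float], freq_b: dict[int, float],
               statistic: str) -> float:
    """Two-deme differentiation between allele-frequency vectors (equal weights)."""
    alleles = set(freq_a) | set(freq_b)
    ha = 1.0 - sum(v * v for v in freq_a.values())
    hb = 1.0 - sum(v * v for v in freq_b.values())
    hs = (ha + hb) / 2.0
    ht = 1.0 - sum(((freq_a.get(a, 0.0) + freq_b.get(a, 0.0)) / 2) ** 2
                   for a in alleles)
    if ht <= 0:
        return math.nan
    gst = (ht - hs) / ht
    if statistic == "Gst":
        return gst
    if statistic == "Nm":
        # Nm from Gst for 2 demes (infinite-island rearrangement)
        if gst <= 0:
            return math.inf
        return 0.25 * (1.0 / gst - 1.0)
    if statistic == "D":
        if hs >= 1.0:
            return math.nan
        return (ht - hs) / (1.0 - hs) * 2.0
    raise ValueError(f"unknown statistic {statistic!r}")


def _directional_matrix(dataset: SSRDataset, statistic: str) -> np.ndarray:
    """Raw directional migration values before normalization.

    For each ordered pair (i, j): pool i and j into a hypothetical migrant
    pool (mean allele frequencies), measure differentiation between the
    *recipient* j and the pool across loci, and convert to a migration-like
    quantity (Nm directly, or 1/stat for Gst and D). A recipient of many
    migrants resembles the pool, giving low differentiation and a high value.
    """
    from .diversity import allele_frequencies

    table = allele_frequencies(dataset)
    pops = dataset.populations
    k = len(pops)
    m = np.zeros((k, k))
    for i, j in itertools.permutations(range(k), 2):
        vals = []
        for locus in dataset.loci:
            if not (table.has_entry(pops[i], locus) and table.has_entry(pops[j], locus)):
                continue
            fi = table.frequencies(pops[i], locus)
            fj = table.frequencies(pops[j], locus)
            pool = {a: (fi.get(a, 0.0) + fj.get(a, 0.0)) / 2.0
                    for a in set(fi) | set(fj)}
            s = _pair_stat(fj, pool, statistic)
            if not math.isnan(s):
                vals.append(s)
        if not vals:
            m[i, j] = np.nan
            continue
        stat = float(np.mean(vals))
        if statistic == "Nm":
            m[i, j] = stat
        else:
            m[i, j] = 1.0 / stat if stat > 0 else math.inf
    return m


def relative_migration(dataset: SSRDataset, statistic: str = "Nm",
                       n_bootstrap: int = 0, seed: int | None = None
                       ) -> MigrationNetwork:
    """Sundqvist-style directional relative migration network.

    The directed matrix is normalized by its maximum finite entry so the
    strongest edge equals 1. Optional bootstrap over individuals (within
    populations) reports, per ordered pair, the fraction of replicates in
    which m[i->j] > m[j->i].
    """
    raw = _directional_matrix(dataset, statistic)
    finite = raw[np.isfinite(raw) & ~np.eye(raw.shape[0], dtype=bool)]
    mx = finite.max() if finite.size else math.nan
    values = raw / mx if mx and not math.isnan(mx) else raw
    values = np.where(np.isinf(raw), 1.0, values)
    np.fill_diagonal(values, 0.0)
    support = None
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        k = len(dataset.populations)
        wins = np.zeros((k, k))
        for _ in range(n_bootstrap):
            idx = []
            for pop in dataset.populations:
                pidx = dataset.population_indices(pop)
                idx.extend(rng.choice(pidx, size=pidx.size, replace=True).tolist())
            boot = dataset.subset_individuals(np.asarray(idx))
            rb = _directional_matrix(boot, statistic)
            with np.errstate(invalid="ignore"):
                wins += (rb > rb.T).astype(float)
        support = wins / n_bootstrap
    return MigrationNetwork(list(dataset.populations), values, statistic, support)
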