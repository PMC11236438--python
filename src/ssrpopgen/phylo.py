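"""Population trees: Nei genetic distances, UPGMA with locus bootstrap,
and Newick output."""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dataset import DistanceMatrix, SSRDataset
from .diversity import AlleleFreqTable, allele_frequencies

#: Sentinel distance for population pairs sharing no alleles (I = 0).
INF_DISTANCE = math.inf


# ---------------------------------------------------------------------------
# Nei genetic distance
# ---------------------------------------------------------------------------

def nei_distance(freqs: AlleleFreqTable, variant: str = "nei72",
                 populations: list[str] | None = None) -> DistanceMatrix:
    """Nei's standard genetic distance D = -ln I over shared loci.

    I = Jxy / sqrt(Jx Jy), with each J the mean over loci of the summed
    (cross-)products of allele frequencies. ``nei78`` replaces the
    within-population J by its small-sample unbiased estimate
    (2n sum(p^2) - 1)/(2n - 1). Pairs with I = 0 get an infinite-distance
    sentinel.
    """
    if variant not in ("nei72", "nei78"):
        raise ValueError(f"unknown variant {variant!r}")
    pops = populations if populations is not None else list(freqs.populations)
    k = len(pops)
    m = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            m[i, j] = m[j, i] = _nei_pair(freqs, pops[i], pops[j], variant)
    dm = DistanceMatrix.__new__(DistanceMatrix)
    dm.labels = list(pops)
    dm.values = m
    dm._tol = 1e-9
    return dm


def _nei_pair(freqs: AlleleFreqTable, px: str, py: str, variant: str) -> float:
    jx = jy = jxy = 0.0
    n_loci = 0
    for locus in freqs.loci:
        if not (freqs.has_entry(px, locus) and freqs.has_entry(py, locus)):
            continue
        fx = freqs.frequencies(px, locus)
        fy = freqs.frequencies(py, locus)
        sx = sum(v * v for v in fx.values())
        sy = sum(v * v for v in fy.values())
        if variant == "nei78":
            nx = freqs.gene_count(px, locus)
            ny = freqs.gene_count(py, locus)
            sx = (nx * sx - 1.0) / (nx - 1.0) if nx > 1 else sx
            sy = (ny * sy - 1.0) / (ny - 1.0) if ny > 1 else sy
        jx += sx
        jy += sy
        jxy += sum(v * fy.get(a, 0.0) for a, v in fx.items())
        n_loci += 1
    if n_loci == 0:
        raise ValueError(f"populations {px!r} and {py!r} share no scored locus")
    jx, jy, jxy = jx / n_loci, jy / n_loci, jxy / n_loci
    if jxy <= 0:
        return INF_DISTANCE
    identity = jxy / math.sqrt(jx * jy)
    if identity >= 1.0:
        return 0.0
    return -math.log(identity)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """Node of a rooted ultrametric tree (leaf iff no children)."""

    label: str | None = None
    height: float = 0.0            # distance from this node down to its leaves
    children: list["TreeNode"] = field(default_factory=list)
    support: float | None = None   # bootstrap percent, internal nodes only

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]  # type: ignore[list-item]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def clades(self) -> list[frozenset[str]]:
        """Leaf sets of every internal node (including the root)."""
        out: list[frozenset[str]] = []
        if not self.is_leaf:
            out.append(frozenset(self.leaves()))
            for c in self.children:
                out.extend(c.clades())
        return out

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()


def upgma(dist: DistanceMatrix) -> TreeNode:
    """Average-linkage agglomerative clustering into an ultrametric tree.

    Node height is half the merge distance. Ties are broken by merging the
    pair whose lexicographically smallest member label is smallest (then by
    the second member), so the result is deterministic and invariant to the
    input label order.
    """
    if np.isnan(dist.values).any():
        raise ValueError("distance matrix contains NaN")
    labels = list(dist.labels)
    if len(labels) < 2:
        raise ValueError("need >= 2 labels")
    nodes: dict[str, TreeNode] = {l: TreeNode(label=l) for l in labels}
    sizes: dict[str, int] = {l: 1 for l in labels}
    # cluster key = lexicographically smallest member label
    d: dict[frozenset[str], float] = {}
    keys = sorted(labels)
    for i, a in enumerate(keys):
        for b in keys[i + 1:]:
            d[frozenset((a, b))] = dist[a, b]
    active = sorted(nodes)
    while len(active) > 1:
        best = None
        for i, a in enumerate(active):
            for b in active[i + 1:]:
                cand = (d[frozenset((a, b))], a, b)
                if best is None or cand < best:
                    best = cand
        dd, a, b = best  # type: ignore[misc]
        merged = TreeNode(height=dd / 2.0, children=[nodes[a], nodes[b]])
        key = min(a, b)
        na, nb = sizes[a], sizes[b]
        for other in active:
            if other in (a, b):
                continue
            dn = (na * d[frozenset((a, other))] + nb * d[frozenset((b, other))]) / (na + nb)
            d[frozenset((key, other))] = dn
        active = sorted([x for x in active if x not in (a, b)] + [key])
        nodes[key] = merged
        sizes[key] = na + nb
    return nodes[active[0]]


def _capped(dist: DistanceMatrix) -> DistanceMatrix:
    v = dist.values.copy()
    if np.isinf(v).any():
        finite = v[np.isfinite(v)]
        cap = 2.0 * finite.max() if finite.size else 1.0
        warnings.warn(f"infinite Nei distances capped at {cap:g} for tree building")
        v[np.isinf(v)] = cap
    dm = DistanceMatrix.__new__(DistanceMatrix)
    dm.labels = list(dist.labels)
    dm.values = v
    dm._tol = 1e-9
    return dm


def bootstrap_tree(dataset: SSRDataset, n_boot: int = 1000, variant: str = "nei72",
                   seed: int | None = None, by_individual: bool = False) -> TreeNode:
    """UPGMA tree on Nei distances with locus-bootstrap clade supports.

    Resamples loci with replacement, rebuilds the tree per replicate, and
    labels each internal node of the full-data tree with the percentage of
    replicates containing the same leaf set (the root always scores 100).
    ``by_individual`` treats every individual as a population of one.
    """
    if dataset.n_loci < 2:
        raise ValueError("bootstrap needs >= 2 loci")
    work = _as_individual_pops(dataset) if by_individual else dataset
    tree = upgma(_capped(nei_distance(allele_frequencies(work), variant)))
    target = tree.clades()
    hits = {cl: 0 for cl in target}
    rng = np.random.default_rng(seed)
    for _ in range(n_boot):
        idx = rng.integers(0, work.n_loci, size=work.n_loci)
        boot = work.subset_loci(idx)
        btree = upgma(_capped(nei_distance(allele_frequencies(boot), variant)))
        bclades = set(btree.clades())
        for cl in target:
            if cl in bclades:
                hits[cl] += 1
    for node in tree.walk():
        if not node.is_leaf:
            node.support = 100.0 * hits[frozenset(node.leaves())] / n_boot
    return tree


def _as_individual_pops(dataset: SSRDataset) -> SSRDataset:
    return SSRDataset(list(dataset.individual_ids), list(dataset.individual_ids),
                      list(dataset.loci), dataset.genotypes.copy())


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

_RESERVED = re.compile(r"[\s(),:;'\[\]]")


def _quote(label: str) -> str:
    if _RESERVED.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(tree: TreeNode) -> str:
    """Newick string with branch lengths; supports as internal node labels."""

    def render(node: TreeNode, parent_height: float) -> str:
        bl = parent_height - node.height
        if node.is_leaf:
            return f"{_quote(node.label or '')}:{bl:.10g}"
        inner = ",".join(render(c, node.height) for c in node.children)
        sup = "" if node.support is None else f"{node.support:.10g}"
        return f"({inner}){sup}:{bl:.10g}"

    if tree.is_leaf:
        return f"{_quote(tree.label or '')}:0;"
    inner = ",".join(render(c, tree.height) for c in tree.children)
    sup = "" if tree.support is None else f"{tree.support:.10g}"
    return f"({inner}){sup};"


def write_newick(tree: TreeNode, path: str | Path) -> None:
    Path(path).write_text(to_newick(tree) + "\n")
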