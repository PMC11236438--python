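"""Backward-in-time coalescent simulation of SSR data under demographic
invasion scenarios with a strict stepwise mutation model (SMM).

A :class:`Scenario` describes named demes with diploid effective sizes and an
ordered backward-in-time event list: SPLIT (a derived deme merges into its
source — forward in time, an introduction), ADMIXTURE (a deme's lineages trace
back to two sources), and BOTTLENECK intervals (a transient size reduction
after an introduction). Scenario fields may hold parameter names (strings)
to be bound from prior draws before simulation.

The simulator uses the continuous-time approximation: in a deme of diploid
size N, each pair of gene copies coalesces at rate 1/(2N) per generation.
Mutations fall on branches as Poisson(mu * length); each mutation shifts the
repeat count by +-1 with equal probability, and alleles are emitted as codes
around a base size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .dataset import SSRDataset

Param = float | str  # a number, or the name of a prior parameter


@dataclass(frozen=True)
class Split:
    """Backward in time at ``time``, all lineages of ``child`` move to
    ``parent`` and ``child`` ceases to exist (forward: an introduction)."""

    time: Param
    child: str
    parent: str


@dataclass(frozen=True)
class Admixture:
    """Backward in time at ``time``, each lineage of ``child`` moves to
    ``parent_a`` with probability ``prop_a``, else to ``parent_b``."""

    time: Param
    child: str
    parent_a: str
    parent_b: str
    prop_a: Param


@dataclass(frozen=True)
class Bottleneck:
    """Transient size reduction: the deme has size ``size`` during backward
    times [max(end - duration, 0), end].

    Anchoring on the *end* (in backward time) makes the common case direct:
    a bottleneck right after an introduction at backward time t is
    ``Bottleneck(deme, end=t, duration=t_db, size=Nb)``.
    """

    deme: str
    end: Param
    duration: Param
    size: Param


@dataclass
class Scenario:
    """Demographic model: demes, sample sizes, and backward-in-time events."""

    name: str
    deme_sizes: dict[str, Param]
    sample_sizes: dict[str, int]
    events: list[Split | Admixture] = field(default_factory=list)
    bottlenecks: list[Bottleneck] = field(default_factory=list)

    # -- parameter binding -------------------------------------------------

    def parameter_names(self) -> list[str]:
        names: list[str] = []

        def visit(v: Param) -> None:
            if isinstance(v, str) and v not in names:
                names.append(v)

        for v in self.deme_sizes.values():
            visit(v)
        for e in self.events:
            visit(e.time)
            if isinstance(e, Admixture):
                visit(e.prop_a)
        for b in self.bottlenecks:
            visit(b.end)
            visit(b.duration)
            visit(b.size)
        return names

    def bind(self, params: dict[str, float]) -> "Scenario":
        """Resolve every symbolic parameter to a number."""

        def res(v: Param) -> float:
            if isinstance(v, str):
                if v not in params:
                    raise KeyError(f"unbound parameter {v!r}")
                return float(params[v])
            return float(v)

        events: list[Split | Admixture] = []
        for e in self.events:
            if isinstance(e, Split):
                events.append(replace(e, time=res(e.time)))
            else:
                events.append(replace(e, time=res(e.time), prop_a=res(e.prop_a)))
        bots = [replace(b, end=res(b.end), duration=res(b.duration),
                        size=res(b.size)) for b in self.bottlenecks]
        return Scenario(self.name, {d: res(v) for d, v in self.deme_sizes.items()},
                        dict(self.sample_sizes), events, bots)

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        """Check event-order and structural invariants of a bound scenario."""
        if any(isinstance(v, str) for v in self.parameter_names()):
            if self.parameter_names():
                raise ValueError("scenario has unbound parameters "
                                 f"{self.parameter_names()}")
        for d, n in self.deme_sizes.items():
            if float(n) < 1:
                raise ValueError(f"deme {d!r} size {n} < 1")
        for d in self.sample_sizes:
            if d not in self.deme_sizes:
                raise ValueError(f"sampled deme {d!r} has no size")
        removed: set[str] = set()
        for e in sorted(self.events, key=lambda e: float(e.time)):
            if float(e.time) <= 0:
                raise ValueError("event times must be > 0")
            if e.child in removed:
                raise ValueError(f"deme {e.child!r} removed twice")
            parents = ([e.parent] if isinstance(e, Split)
                       else [e.parent_a, e.parent_b])
            for p in parents:
                if p in removed:
                    raise ValueError(
                        f"event at t={e.time} targets removed deme {p!r}")
                if p not in self.deme_sizes:
                    raise ValueError(f"unknown deme {p!r}")
            if isinstance(e, Admixture) and not (0.0 < float(e.prop_a) < 1.0):
                raise ValueError("admixture proportion must be in (0, 1)")
            removed.add(e.child)
        roots = set(self.deme_sizes) - removed
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root deme, got {sorted(roots)}")
        for b in self.bottlenecks:
            if float(b.end) < 0 or float(b.duration) < 0 or float(b.size) < 1:
                raise ValueError("bottleneck end/duration must be >= 0, size >= 1")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "deme_sizes": dict(self.deme_sizes),
            "sample_sizes": dict(self.sample_sizes),
            "events": [
                ({"type": "split", "time": e.time, "child": e.child,
                  "parent": e.parent} if isinstance(e, Split) else
                 {"type": "admixture", "time": e.time, "child": e.child,
                  "parent_a": e.parent_a, "parent_b": e.parent_b,
                  "prop_a": e.prop_a})
                for e in self.events
            ],
            "bottlenecks": [
                {"deme": b.deme, "end": b.end, "duration": b.duration,
                 "size": b.size} for b in self.bottlenecks
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        events: list[Split | Admixture] = []
        for e in d.get("events", []):
            if e["type"] == "split":
                events.append(Split(e["time"], e["child"], e["parent"]))
            elif e["type"] == "admixture":
                events.append(Admixture(e["time"], e["child"], e["parent_a"],
                                        e["parent_b"], e["prop_a"]))
            else:
                raise ValueError(f"unknown event type {e['type']!r}")
        bots = [Bottleneck(b["deme"], b["end"], b["duration"], b["size"])
                for b in d.get("bottlenecks", [])]
        return cls(d["name"], dict(d["deme_sizes"]), dict(d["sample_sizes"]),
                   events, bots)


# ---------------------------------------------------------------------------
# Priors
# ---------------------------------------------------------------------------

@dataclass
class PriorSpec:
    """Independent priors per parameter: ('uniform'|'loguniform', lo, hi).

    ``mu`` (the mean SSR mutation rate per generation) is a parameter like
    any other when present.
    """

    priors: dict[str, tuple[str, float, float]]

    def __post_init__(self) -> None:
        for name, (kind, lo, hi) in self.priors.items():
            if kind not in ("uniform", "loguniform"):
                raise ValueError(f"unknown prior kind {kind!r} for {name!r}")
            if not lo < hi:
                raise ValueError(f"prior for {name!r} needs lo < hi")
            if kind == "loguniform" and lo <= 0:
                raise ValueError(f"loguniform prior for {name!r} needs lo > 0")

    def draw(self, rng: np.random.Generator) -> dict[str, float]:
        out: dict[str, float] = {}
        for name, (kind, lo, hi) in self.priors.items():
            if kind == "uniform":
                out[name] = float(rng.uniform(lo, hi))
            else:
                out[name] = float(math.exp(rng.uniform(math.log(lo), math.log(hi))))
        return out

    def bounds(self, name: str) -> tuple[float, float]:
        _, lo, hi = self.priors[name]
        return lo, hi


def draw_valid_params(scenario: Scenario, priors: PriorSpec,
                      rng: np.random.Generator, max_tries: int = 1000
                      ) -> dict[str, float]:
    """Draw prior parameters until the bound scenario validates."""
    for _ in range(max_tries):
        params = priors.draw(rng)
        bound = scenario.bind(params)
        try:
            bound.validate()
            return params
        except ValueError:
            continue
    raise RuntimeError(
        f"no valid prior draw for scenario {scenario.name!r} in {max_tries} tries")


# ---------------------------------------------------------------------------
# Simulator
# ---------------------------------------------------------------------------

def _size_timeline(scn: Scenario) -> tuple[list[float], dict[str, list[float]]]:
    """Piecewise-constant deme sizes: breakpoints + per-deme size per interval."""
    points = {0.0}
    for e in scn.events:
        points.add(float(e.time))
    for b in scn.bottlenecks:
        points.add(max(float(b.end) - float(b.duration), 0.0))
        points.add(float(b.end))
    breaks = sorted(points)
    sizes: dict[str, list[float]] = {d: [] for d in scn.deme_sizes}
    for k in range(len(breaks)):
        mid_lo = breaks[k]
        for d, base in scn.deme_sizes.items():
            n = float(base)
            for b in scn.bottlenecks:
                start = max(float(b.end) - float(b.duration), 0.0)
                if b.deme == d and start <= mid_lo < float(b.end):
                    n = float(b.size)
            sizes[d].append(n)
    return breaks, sizes


def simulate_scenario(scenario: Scenario, params: dict[str, float] | None = None,
                      n_loci: int = 9, mutation_rate: float | None = None,
                      seed: int | None = None, base_allele: int = 200,
                      sample_sizes: dict[str, int] | None = None) -> SSRDataset:
    """Simulate a diploid SSR dataset under a demographic scenario.

    ``params`` binds any symbolic parameters; a ``mu`` entry provides the
    mutation rate unless ``mutation_rate`` is given explicitly. Sampled gene
    copies are paired consecutively into diploid individuals per deme.
    """
    params = dict(params or {})
    scn = scenario.bind(params)
    if sample_sizes is not None:
        unknown = [d for d, n in sample_sizes.items()
                   if n > 0 and d not in scn.deme_sizes]
        if unknown:
            raise ValueError(f"sampled demes {unknown} not in scenario "
                             f"{scenario.name!r}")
        scn.sample_sizes = {d: n for d, n in sample_sizes.items()
                            if d in scn.deme_sizes}
    scn.validate()
    if mutation_rate is None:
        if "mu" not in params:
            raise ValueError("mutation rate missing: pass mutation_rate or params['mu']")
        mutation_rate = params["mu"]
    if mutation_rate < 0:
        raise ValueError("mutation rate must be >= 0")
    rng = np.random.default_rng(seed)
    samples = {d: n for d, n in scn.sample_sizes.items() if n > 0}
    if not samples:
        raise ValueError("no sampled demes")
    n_copies = {d: 2 * n for d, n in samples.items()}
    total = sum(n_copies.values())

    breaks, interval_sizes = _size_timeline(scn)
    events_at: dict[float, list[Split | Admixture]] = {}
    for e in scn.events:
        events_at.setdefault(float(e.time), []).append(e)

    n_ind = sum(samples.values())
    genotypes = np.empty((n_ind, n_loci, 2), dtype=np.int64)
    for locus in range(n_loci):
        states, _ = _simulate_locus(scn, breaks, interval_sizes, events_at,
                                    n_copies, total, mutation_rate, rng)
        col = 0
        for d in samples:
            for i in range(samples[d]):
                genotypes[col + i, locus, 0] = base_allele + states[d][2 * i]
                genotypes[col + i, locus, 1] = base_allele + states[d][2 * i + 1]
            col += samples[d]
    ind_ids: list[str] = []
    pop_ids: list[str] = []
    for d in samples:
        for i in range(samples[d]):
            ind_ids.append(f"{d}_{i + 1:02d}")
            pop_ids.append(d)
    loci = [f"L{j + 1:02d}" for j in range(n_loci)]
    return SSRDataset(ind_ids, pop_ids, loci, genotypes)


def _simulate_locus(scn: Scenario, breaks: list[float],
                    interval_sizes: dict[str, list[float]],
                    events_at: dict[float, list[Split | Admixture]],
                    n_copies: dict[str, int], total: int,
                    mu: float, rng: np.random.Generator
                    ) -> tuple[dict[str, np.ndarray], float]:
    """One genealogy + SMM mutations.

    Returns (per-deme sampled repeat states, time of the last coalescence).
    """
    node_time = [0.0] * total
    parent = [-1] * total
    deme_lineages: dict[str, list[int]] = {d: [] for d in scn.deme_sizes}
    nid = 0
    sample_nodes: dict[str, list[int]] = {}
    for d, k in n_copies.items():
        sample_nodes[d] = list(range(nid, nid + k))
        deme_lineages[d].extend(sample_nodes[d])
        nid += k

    def coalesce(deme: str, t: float) -> None:
        nonlocal nid
        lin = deme_lineages[deme]
        m = len(lin)
        i = int(rng.integers(m))
        j = int(rng.integers(m - 1))
        if j >= i:
            j += 1
        if i < j:
            i, j = j, i
        a = lin.pop(i)
        b = lin.pop(j)
        node_time.append(t)
        parent.append(-1)
        parent[a] = nid
        parent[b] = nid
        lin.append(nid)
        nid += 1

    t = 0.0
    for k in range(len(breaks)):
        t_end = breaks[k + 1] if k + 1 < len(breaks) else math.inf
        while True:
            rates = []
            demes = []
            for d, lin in deme_lineages.items():
                m = len(lin)
                if m >= 2:
                    rates.append(m * (m - 1) / 2.0 / (2.0 * interval_sizes[d][k]))
                    demes.append(d)
            total_rate = sum(rates)
            n_left = sum(len(l) for l in deme_lineages.values())
            if total_rate == 0.0:
                if n_left == 1:
                    break
                t = t_end
                break
            wait = rng.exponential(1.0 / total_rate)
            if t + wait >= t_end:
                t = t_end
                break
            t += wait
            u = rng.random() * total_rate
            acc = 0.0
            for d, r in zip(demes, rates):
                acc += r
                if u <= acc:
                    coalesce(d, t)
                    break
        if sum(len(l) for l in deme_lineages.values()) == 1:
            break
        if k + 1 < len(breaks):
            for e in events_at.get(breaks[k + 1], []):
                lin = deme_lineages[e.child]
                if isinstance(e, Split):
                    deme_lineages[e.parent].extend(lin)
                else:
                    for x in lin:
                        dest = e.parent_a if rng.random() < e.prop_a else e.parent_b
                        deme_lineages[dest].append(x)
                deme_lineages[e.child] = []

    # mutations: root state 0; child = parent + net +-1 steps. A parent is
    # always created after its children, so iterating from the last node
    # downward assigns every parent state before it is needed.
    n_nodes = len(node_time)
    state = np.zeros(n_nodes, dtype=np.int64)
    for node in range(n_nodes - 1, -1, -1):
        p = parent[node]
        if p == -1:
            state[node] = 0
            continue
        length = node_time[p] - node_time[node]
        m = rng.poisson(mu * length) if mu > 0 else 0
        if m:
            up = rng.binomial(m, 0.5)
            state[node] = state[p] + 2 * up - m
        else:
            state[node] = state[p]
    states = {d: state[np.asarray(nodes)] for d, nodes in sample_nodes.items()}
    return states, max(node_time)


def pairwise_tmrca(deme_size: float, n_reps: int, seed: int | None = None
                   ) -> np.ndarray:
    """Simulated pairwise coalescence times for two gene copies in one deme.

    Runs the full event loop of the simulator (a one-deme scenario with a
    single diploid sample) and records the time of the root, for checking
    against the coalescent expectation E[T] = 2N generations.
    """
    scn = Scenario("one_deme", {"D": float(deme_size)}, {"D": 1}).bind({})
    scn.validate()
    breaks, sizes = _size_timeline(scn)
    rng = np.random.default_rng(seed)
    times = np.empty(n_reps)
    for r in range(n_reps):
        _, root_t = _simulate_locus(scn, breaks, sizes, {}, {"D": 2}, 2, 0.0, rng)
        times[r] = root_t
    return times
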