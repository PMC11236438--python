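"""Shared fixtures: small hand-checkable datasets and the island fixture."""

from __future__ import annotations

import numpy as np
import pytest

from ssrpopgen.dataset import SSRDataset
from ssrpopgen.diversity import AlleleFreqTable
from ssrpopgen.synthetic import generate_island_fixture


def make_dataset(genotypes, populations, loci=None, ids=None) -> SSRDataset:
    """Build an SSRDataset from a nested list [ind][locus] = (a, b)."""
    g = np.asarray(genotypes, dtype=np.int64)
    if g.ndim == 2:  # single locus: [ind] = (a, b)
        g = g[:, None, :]
    n, l, _ = g.shape
    return SSRDataset(
        ids or [f"ind{i}" for i in range(n)],
        list(populations),
        loci or [f"L{j}" for j in range(l)],
        g,
    )


def freq_table(spec: dict) -> AlleleFreqTable:
    """Build an AlleleFreqTable from {pop: {locus: {allele: freq}}}."""
    pops = list(spec)
    loci = sorted({l for by_locus in spec.values() for l in by_locus})
    table = AlleleFreqTable(pops, loci)
    for pop, by_locus in spec.items():
        for locus, fr in by_locus.items():
            table.counts[(pop, locus)] = dict(fr)
    return table


@pytest.fixture(scope="session")
def island_dataset():
    ds, _ = generate_island_fixture(seed=1)
    return ds


@pytest.fixture(scope="session")
def island_truth():
    _, truth = generate_island_fixture(seed=1)
    return truth
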