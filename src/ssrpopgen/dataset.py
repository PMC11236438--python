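"""Core containers for diploid microsatellite (SSR) genotype data.

An :class:`SSRDataset` holds a rectangular individuals x loci table of
unordered diploid allele pairs (allele codes are positive integers, typically
fragment sizes in base pairs). Missing genotypes are stored as the sentinel
:data:`MISSING` so that 0 can never be mistaken for an allele code.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Sentinel for a missing allele slot. Never a legal allele code.
MISSING: int = -1


@dataclass
class SSRDataset:
    """Diploid multi-locus genotype matrix with population labels.

    Parameters
    ----------
    individual_ids
        One id per individual, unique.
    population_ids
        Population label of each individual (same length as
        ``individual_ids``).
    loci
        Locus names, unique.
    genotypes
        Integer array of shape ``(n_individuals, n_loci, 2)``. Each cell is an
        unordered allele pair stored sorted ascending; both slots equal to
        :data:`MISSING` encode a missing genotype.
    """

    individual_ids: list[str]
    population_ids: list[str]
    loci: list[str]
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int64)
        n, l = len(self.individual_ids), len(self.loci)
        if self.genotypes.shape != (n, l, 2):
            raise ValueError(
                f"genotype array shape {self.genotypes.shape} does not match "
                f"{n} individuals x {l} loci x 2"
            )
        if len(self.population_ids) != n:
            raise ValueError("population_ids length mismatch")
        # canonical order: allele pairs sorted ascending, MISSING slots last
        g = self.genotypes
        key = np.where(g == MISSING, np.iinfo(np.int64).max, g)
        order = np.argsort(key, axis=2)
        self.genotypes = np.take_along_axis(g, order, axis=2)

    # -- basic structure ---------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def populations(self) -> list[str]:
        """Population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.population_ids:
            seen.setdefault(p)
        return list(seen)

    def population_indices(self, population: str) -> np.ndarray:
        idx = [i for i, p in enumerate(self.population_ids) if p == population]
        if not idx:
            raise KeyError(f"unknown population {population!r}")
        return np.asarray(idx, dtype=np.intp)

    def locus_index(self, locus: str) -> int:
        try:
            return self.loci.index(locus)
        except ValueError:
            raise KeyError(f"unknown locus {locus!r}") from None

    # -- masks -------------------------------------------------------------

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean ``(n, l)`` mask: True where the genotype is fully missing."""
        return np.all(self.genotypes == MISSING, axis=2)

    @property
    def scored_mask(self) -> np.ndarray:
        """Boolean ``(n, l)`` mask: True where both allele slots are scored."""
        return np.all(self.genotypes != MISSING, axis=2)

    def heterozygote_mask(self) -> np.ndarray:
        """Boolean ``(n, l)``: True where the genotype is a scored heterozygote."""
        g = self.genotypes
        return self.scored_mask & (g[:, :, 0] != g[:, :, 1])

    # -- manipulation ------------------------------------------------------

    def subset_loci(self, loci: list[str] | np.ndarray) -> "SSRDataset":
        """Dataset restricted to (possibly repeated) loci, e.g. a bootstrap draw."""
        if len(loci) and not isinstance(loci[0], str):
            idx = np.asarray(loci, dtype=np.intp)
            names = [f"{self.loci[j]}" if list(loci).count(j) == 1
                     else f"{self.loci[j]}.{k}"
                     for k, j in enumerate(idx)]
        else:
            idx = np.asarray([self.locus_index(l) for l in loci], dtype=np.intp)
            names = list(loci)
        return SSRDataset(
            list(self.individual_ids),
            list(self.population_ids),
            names,
            self.genotypes[:, idx, :].copy(),
        )

    def subset_individuals(self, indices: np.ndarray) -> "SSRDataset":
        indices = np.asarray(indices, dtype=np.intp)
        return SSRDataset(
            [self.individual_ids[i] for i in indices],
            [self.population_ids[i] for i in indices],
            list(self.loci),
            self.genotypes[indices].copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SSRDataset):
            return NotImplemented
        return (
            self.individual_ids == other.individual_ids
            and self.population_ids == other.population_ids
            and self.loci == other.loci
            and np.array_equal(self.genotypes, other.genotypes)
        )


@dataclass
class DistanceMatrix:
    """Labeled symmetric nonnegative distance matrix with zero diagonal."""

    labels: list[str]
    values: np.ndarray
    _tol: float = field(default=1e-9, repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        k = len(self.labels)
        if v.shape != (k, k):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=self._tol, equal_nan=True):
            raise ValueError("matrix is not symmetric")
        finite = v[np.isfinite(v)]
        if finite.size and finite.min() < -self._tol:
            raise ValueError("negative distances")
        v = (v + v.T) / 2.0
        np.fill_diagonal(v, 0.0)
        self.values = v

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries (row-major), scipy ``pdist`` ordering."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def reorder(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)])
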