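"""Readers and writers for SSR genotype tables and distance matrices.

Supports the GenePop 4.x text dialect (2- or 3-digit diploid allele coding)
and a delimited table layout with two allele columns per locus, plus labeled
square CSV distance matrices.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import MISSING, DistanceMatrix, SSRDataset


class ParseError(ValueError):
    """Raised when an input file cannot be parsed; message names the line."""


class ValidationError(ValueError):
    """Raised when a structurally readable dataset violates its invariants."""


# ---------------------------------------------------------------------------
# GenePop
# ---------------------------------------------------------------------------

def _split_genepop_cell(token: str, line_no: int) -> tuple[int, int, int]:
    """Return (allele_a, allele_b, digit_width) for one GenePop cell."""
    if not token.isdigit():
        raise ParseError(f"line {line_no}: non-numeric genotype token {token!r}")
    if len(token) % 2 != 0 or len(token) not in (4, 6):
        raise ParseError(
            f"line {line_no}: genotype token {token!r} must be 4 or 6 digits"
        )
    w = len(token) // 2
    a, b = int(token[:w]), int(token[w:])
    return a, b, w


def read_genepop(path: str | Path, population_names: list[str] | None = None) -> SSRDataset:
    """Read a GenePop 4.x file into an :class:`SSRDataset`.

    The first line is a title and is ignored. Locus names follow, one per
    line or comma-separated on a single line. Each ``Pop`` line starts a new
    population; by GenePop convention the population is named after the last
    individual label in its block unless ``population_names`` overrides this.
    Cells of all zeros (``0000``/``000000``) are missing; a single zero allele
    in a cell also marks the whole genotype missing.
    """
    lines = Path(path).read_text().splitlines()
    if len(lines) < 3:
        raise ParseError("file too short to be GenePop")
    # locus names: lines 2.. until first 'pop'
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        chunk = [t.strip() for t in lines[i].split(",") if t.strip()]
        loci.extend(chunk)
        i += 1
    if i == len(lines):
        raise ParseError("no 'Pop' separator found")
    if len(set(loci)) != len(loci):
        raise ValidationError("duplicate locus names")

    ind_ids: list[str] = []
    pop_of: list[int] = []
    rows: list[list[tuple[int, int]]] = []
    block_last_label: list[str] = []
    width: int | None = None
    pop_idx = -1
    while i < len(lines):
        line = lines[i]
        stripped = line.strip()
        i += 1
        if not stripped:
            continue
        if stripped.lower() == "pop":
            if pop_idx >= 0 and not block_last_label[pop_idx]:
                raise ValidationError(f"empty Pop block before line {i}")
            pop_idx += 1
            block_last_label.append("")
            continue
        if "," not in line:
            raise ParseError(f"line {i}: expected 'label , genotypes'")
        label, geno_part = line.split(",", 1)
        label = label.strip()
        tokens = geno_part.split()
        if len(tokens) != len(loci):
            raise ParseError(
                f"line {i}: expected {len(loci)} genotype tokens, got {len(tokens)}"
            )
        genos: list[tuple[int, int]] = []
        for tok in tokens:
            a, b, w = _split_genepop_cell(tok, i)
            if width is None:
                width = w
            elif w != width:
                raise ParseError(
                    f"line {i}: mixed {2 * width}- and {2 * w}-digit allele coding"
                )
            if a == 0 or b == 0:
                genos.append((MISSING, MISSING))
            else:
                genos.append((a, b))
        ind_ids.append(label)
        pop_of.append(pop_idx)
        rows.append(genos)
        block_last_label[pop_idx] = label
    if pop_idx < 0:
        raise ParseError("no 'Pop' separator found")
    if not block_last_label[pop_idx]:
        raise ValidationError("empty Pop block at end of file")

    if population_names is None:
        pop_names = list(block_last_label)
    else:
        if len(population_names) != len(block_last_label):
            raise ValidationError(
                f"{len(population_names)} population names given for "
                f"{len(block_last_label)} Pop blocks"
            )
        pop_names = list(population_names)
    genotypes = np.array(rows, dtype=np.int64)
    ds = SSRDataset(ind_ids, [pop_names[p] for p in pop_of], loci, genotypes)
    _check_structure(ds)
    return ds


def write_genepop(dataset: SSRDataset, path: str | Path, title: str = "ssrpopgen export",
                  digits: int = 3) -> None:
    """Write an :class:`SSRDataset` as a GenePop file (default 3-digit coding)."""
    if digits not in (2, 3):
        raise ValueError("GenePop allele coding must use 2 or 3 digits")
    hi = 10 ** digits - 1
    alleles = dataset.genotypes[dataset.genotypes != MISSING]
    if alleles.size and (alleles.max() > hi or alleles.min() < 1):
        raise ValueError(f"allele codes out of range 1..{hi} for {digits}-digit coding")
    out = io.StringIO()
    out.write(title + "\n")
    for locus in dataset.loci:
        out.write(locus + "\n")
    miss = "0" * digits
    current_pop: str | None = None
    for i, (ind, pop) in enumerate(zip(dataset.individual_ids, dataset.population_ids)):
        if pop != current_pop:
            out.write("Pop\n")
            current_pop = pop
        cells = []
        for j in range(dataset.n_loci):
            a, b = dataset.genotypes[i, j]
            if a == MISSING or b == MISSING:
                cells.append(miss + miss)
            else:
                cells.append(f"{a:0{digits}d}{b:0{digits}d}")
        out.write(f"{ind} , " + " ".join(cells) + "\n")
    Path(path).write_text(out.getvalue())


# ---------------------------------------------------------------------------
# Delimited tables
# ---------------------------------------------------------------------------

def read_table(path: str | Path, delimiter: str = ",",
               allele_columns_per_locus: int = 2,
               missing_tokens: tuple[str, ...] = ("NA", "na", "", "0", "-9")) -> SSRDataset:
    """Read a delimited genotype table.

    Layout: header row, first column individual id, second column population,
    then ``allele_columns_per_locus`` columns per locus. Locus names are taken
    from the header by stripping a trailing ``_1``/``_2`` (or ``.1``/``.2``)
    suffix when present; otherwise paired columns must repeat the same name.
    """
    if allele_columns_per_locus != 2:
        raise ValueError("only diploid two-column loci are supported")
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False,
                     skipinitialspace=True)
    if df.shape[1] < 4 or (df.shape[1] - 2) % 2 != 0:
        raise ParseError(
            f"expected 2 id columns plus 2 columns per locus, got {df.shape[1]} columns"
        )
    allele_cols = list(df.columns[2:])
    loci: list[str] = []
    for k in range(0, len(allele_cols), 2):
        a, b = allele_cols[k], allele_cols[k + 1]
        loci.append(_common_locus_name(a, b))
    if len(set(loci)) != len(loci):
        raise ValidationError("duplicate locus names in header")

    n = len(df)
    genotypes = np.full((n, len(loci), 2), MISSING, dtype=np.int64)
    for j in range(len(loci)):
        for s in range(2):
            col = df.iloc[:, 2 + 2 * j + s]
            for i, tok in enumerate(col):
                tok = tok.strip()
                if tok in missing_tokens:
                    continue
                try:
                    genotypes[i, j, s] = int(tok)
                except ValueError:
                    raise ParseError(
                        f"row {i + 2}, column {df.columns[2 + 2 * j + s]!r}: "
                        f"non-integer allele token {tok!r}"
                    ) from None
    # a half-missing cell is treated as missing, as in the GenePop reader
    half = (genotypes == MISSING).sum(axis=2) == 1
    genotypes[half] = MISSING
    ds = SSRDataset(list(df.iloc[:, 0].str.strip()), list(df.iloc[:, 1].str.strip()),
                    loci, genotypes)
    _check_structure(ds)
    return ds


def _common_locus_name(a: str, b: str) -> str:
    a, b = a.strip(), b.strip()
    if a == b:
        return a
    for sep in ("_", ".", "-"):
        pa, pb = a.rsplit(sep, 1), b.rsplit(sep, 1)
        if len(pa) == 2 and len(pb) == 2 and pa[0] == pb[0]:
            return pa[0]
    raise ParseError(f"cannot pair allele columns {a!r} and {b!r} into one locus")


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Outcome of :func:`validate`: violations, warnings and missingness."""

    violations: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    missing_per_locus: dict[str, int] = field(default_factory=dict)
    missing_per_population: dict[str, int] = field(default_factory=dict)

    @property
    def valid(self) -> bool:
        return not self.violations


def _check_structure(ds: SSRDataset) -> None:
    if ds.n_individuals < 1 or ds.n_loci < 1 or not ds.populations:
        raise ValidationError("dataset needs >=1 individual, locus and population")


def validate(dataset: SSRDataset) -> ValidationReport:
    """Check dataset invariants; reports rather than raises."""
    rep = ValidationReport()
    g = dataset.genotypes
    if len(set(dataset.individual_ids)) != len(dataset.individual_ids):
        rep.violations.append("duplicate individual ids")
    if len(set(dataset.loci)) != len(dataset.loci):
        rep.violations.append("duplicate locus names")
    half = (g == MISSING).sum(axis=2) == 1
    for i, j in zip(*np.nonzero(half)):
        rep.violations.append(
            f"haploid cell: individual {dataset.individual_ids[i]!r} "
            f"at locus {dataset.loci[j]!r}"
        )
    scored = dataset.scored_mask
    bad = scored & (g <= 0).any(axis=2)
    for i, j in zip(*np.nonzero(bad)):
        rep.violations.append(
            f"non-positive allele code: individual {dataset.individual_ids[i]!r} "
            f"at locus {dataset.loci[j]!r}"
        )
    miss = dataset.missing_mask
    for j, locus in enumerate(dataset.loci):
        rep.missing_per_locus[locus] = int(miss[:, j].sum())
        if miss[:, j].all():
            rep.warnings.append(f"uninformative locus {locus!r}: all genotypes missing")
    for pop in dataset.populations:
        idx = dataset.population_indices(pop)
        rep.missing_per_population[pop] = int(miss[idx].sum())
    return rep


# ---------------------------------------------------------------------------
# Distance matrices
# ---------------------------------------------------------------------------

def read_distance_csv(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, index_col=0)
    labels = [str(c) for c in df.columns]
    if labels != [str(r) for r in df.index]:
        raise ParseError("distance CSV row and column labels differ")
    return DistanceMatrix(labels, df.to_numpy(dtype=float))


def write_distance_csv(dm: DistanceMatrix, path: str | Path) -> None:
    pd.DataFrame(dm.values, index=dm.labels, columns=dm.labels).to_csv(path)
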