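"""Genotype I/O for the two text formats used throughout diploid
microsatellite work: STRUCTURE's whitespace table (one or two rows per
individual) and GenePop's 2/3-digit coding.

The in-memory currency of the whole package is :class:`GenotypeMatrix`:
an ``(n_individuals, n_loci, 2)`` integer array of allele codes plus
individual ids, population labels and locus names.  Allele codes are kept
verbatim (fragment sizes such as 230 are legal codes); a missing genotype
is the reserved sentinel :data:`MISSING` in *both* slots — half-calls are
rejected on construction and on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

#: Internal (and STRUCTURE-default) missing-data sentinel.
MISSING = -9


class GenotypeParseError(ValueError):
    """Raised when a genotype file violates its format contract."""


@dataclass
class GenotypeMatrix:
    """Diploid co-dominant genotypes for a set of individuals.

    Parameters
    ----------
    individual_ids
        Unique identifier per individual (whitespace-free tokens).
    population_labels
        One label per individual; populations are any grouping of rows.
    locus_names
        One name per locus.
    alleles
        Integer array ``(n_individuals, n_loci, 2)``.  Non-missing codes
        are positive integers; missing genotypes carry ``MISSING`` in
        both slots.
    """

    individual_ids: list[str]
    population_labels: list[str]
    locus_names: list[str]
    alleles: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int64)
        n, L = len(self.individual_ids), len(self.locus_names)
        if self.alleles.shape != (n, L, 2):
            raise ValueError(
                f"alleles shape {self.alleles.shape} != ({n}, {L}, 2)"
            )
        if len(self.population_labels) != n:
            raise ValueError("population_labels length != n_individuals")
        if len(set(self.individual_ids)) != n:
            raise ValueError("individual ids are not unique")
        valid = (self.alleles > 0) | (self.alleles == MISSING)
        if not valid.all():
            bad = np.argwhere(~valid)[0]
            raise ValueError(
                f"allele code must be a positive integer or {MISSING}: "
                f"individual {self.individual_ids[bad[0]]}, locus "
                f"{self.locus_names[bad[1]]}"
            )
        miss = self.alleles == MISSING
        half = miss[:, :, 0] != miss[:, :, 1]
        if half.any():
            i, j = np.argwhere(half)[0]
            raise ValueError(
                f"half-called genotype (one allele missing) for individual "
                f"{self.individual_ids[i]} at locus {self.locus_names[j]}"
            )

    # -- basic geometry -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_names)

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean ``(n, L)`` array: True where the genotype is missing."""
        return self.alleles[:, :, 0] == MISSING

    def populations(self) -> list[str]:
        """Distinct population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.population_labels:
            seen.setdefault(p)
        return list(seen)

    # -- subsetting ------------------------------------------------------
    def population_indices(self, population: str) -> np.ndarray:
        idx = np.array(
            [i for i, p in enumerate(self.population_labels) if p == population],
            dtype=int,
        )
        if idx.size == 0:
            raise KeyError(f"no individuals with population label {population!r}")
        return idx

    def subset(self, indices) -> "GenotypeMatrix":
        indices = np.asarray(indices, dtype=int)
        return GenotypeMatrix(
            [self.individual_ids[i] for i in indices],
            [self.population_labels[i] for i in indices],
            list(self.locus_names),
            self.alleles[indices],
        )

    def subset_population(self, population: str) -> "GenotypeMatrix":
        return self.subset(self.population_indices(population))

    def relabel(self, labels: list[str]) -> "GenotypeMatrix":
        return replace(self, population_labels=list(labels))


def concat(matrices: list[GenotypeMatrix]) -> GenotypeMatrix:
    """Stack matrices over individuals; locus names must agree."""
    first = matrices[0]
    for m in matrices[1:]:
        if m.locus_names != first.locus_names:
            raise ValueError("locus names differ between matrices")
    return GenotypeMatrix(
        [i for m in matrices for i in m.individual_ids],
        [p for m in matrices for p in m.population_labels],
        list(first.locus_names),
        np.concatenate([m.alleles for m in matrices], axis=0),
    )


# ---------------------------------------------------------------------------
# STRUCTURE format
# ---------------------------------------------------------------------------

def _read_lines(path) -> list[tuple[int, list[str]]]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            toks = line.split()
            if toks:
                out.append((lineno, toks))
    return out


def read_structure(
    path,
    dialect: str = "two-row",
    missing_code: int = -9,
) -> GenotypeMatrix:
    """Read a STRUCTURE-format genotype table.

    Column 1 is the individual id, column 2 the population token; an
    optional first line holds the locus names.  In the ``two-row``
    dialect each individual occupies two consecutive rows of one allele
    per locus; in ``one-row`` each individual has two adjacent columns
    per locus.
    """
    if dialect not in ("two-row", "one-row"):
        raise ValueError(f"unknown dialect {dialect!r}")
    lines = _read_lines(path)
    if not lines:
        return GenotypeMatrix([], [], [], np.zeros((0, 0, 2), dtype=int))

    per_locus = 1 if dialect == "two-row" else 2
    first = lines[0][1]
    if len(lines) == 1:
        # header-only file: an empty matrix with named loci
        return GenotypeMatrix(
            [], [], list(first), np.zeros((0, len(first), 2), dtype=int)
        )
    if len(first) == (len(lines[1][1]) - 2) // per_locus:
        locus_names = list(first)
        data = lines[1:]
    else:
        locus_names = None
        data = lines

    n_loci = None
    ids: list[str] = []
    pops: list[str] = []
    rows: list[np.ndarray] = []

    def parse_alleles(toks: list[str], lineno: int) -> np.ndarray:
        try:
            vals = np.array([int(t) for t in toks], dtype=np.int64)
        except ValueError as exc:
            raise GenotypeParseError(f"line {lineno}: non-integer allele") from exc
        vals[vals == missing_code] = MISSING
        return vals

    if dialect == "two-row":
        if len(data) % 2:
            raise GenotypeParseError(
                "two-row dialect requires an even number of data rows, "
                f"got {len(data)}"
            )
        for (ln1, r1), (ln2, r2) in zip(data[::2], data[1::2]):
            if len(r1) != len(r2):
                raise GenotypeParseError(
                    f"lines {ln1}/{ln2}: row pair with different lengths"
                )
            if r1[0] != r2[0]:
                raise GenotypeParseError(
                    f"lines {ln1}/{ln2}: consecutive rows belong to "
                    f"different individuals ({r1[0]!r} vs {r2[0]!r})"
                )
            if n_loci is None:
                n_loci = len(r1) - 2
            elif len(r1) - 2 != n_loci:
                raise GenotypeParseError(f"line {ln1}: ragged row")
            ids.append(r1[0])
            pops.append(r1[1])
            a = parse_alleles(r1[2:], ln1)
            b = parse_alleles(r2[2:], ln2)
            rows.append(np.stack([a, b], axis=1))
    else:
        for ln, r in data:
            if (len(r) - 2) % 2:
                raise GenotypeParseError(
                    f"line {ln}: odd number of allele columns"
                )
            if n_loci is None:
                n_loci = (len(r) - 2) // 2
            elif (len(r) - 2) // 2 != n_loci:
                raise GenotypeParseError(f"line {ln}: ragged row")
            ids.append(r[0])
            pops.append(r[1])
            vals = parse_alleles(r[2:], ln)
            rows.append(vals.reshape(n_loci, 2))

    assert n_loci is not None
    if locus_names is None:
        locus_names = [f"L{j + 1}" for j in range(n_loci)]
    if len(locus_names) != n_loci:
        raise GenotypeParseError(
            f"header names {len(locus_names)} loci but rows have {n_loci}"
        )
    alleles = (
        np.stack(rows, axis=0) if rows else np.zeros((0, n_loci, 2), dtype=int)
    )
    return GenotypeMatrix(ids, pops, locus_names, alleles)


def write_structure(
    gm: GenotypeMatrix,
    path,
    dialect: str = "two-row",
    missing_code: int = -9,
) -> None:
    """Write ``gm`` so that :func:`read_structure` recovers it exactly.

    Population labels are written verbatim when they are integer tokens,
    otherwise they are recoded 1..G in order of first appearance (the
    format's population column is conventionally an integer).
    """
    if dialect not in ("two-row", "one-row"):
        raise ValueError(f"unknown dialect {dialect!r}")
    labels = gm.population_labels
    if not all(lbl.lstrip("-").isdigit() for lbl in labels):
        code = {p: str(k + 1) for k, p in enumerate(gm.populations())}
        labels = [code[p] for p in labels]
    out = gm.alleles.copy()
    out[out == MISSING] = missing_code
    with open(path, "w") as fh:
        fh.write(" ".join(gm.locus_names) + "\n")
        for i in range(gm.n_individuals):
            if dialect == "two-row":
                for slot in (0, 1):
                    row = [gm.individual_ids[i], labels[i]] + [
                        str(v) for v in out[i, :, slot]
                    ]
                    fh.write(" ".join(row) + "\n")
            else:
                row = [gm.individual_ids[i], labels[i]] + [
                    str(v) for v in out[i].ravel()
                ]
                fh.write(" ".join(row) + "\n")


# ---------------------------------------------------------------------------
# GenePop format
# ---------------------------------------------------------------------------

def read_genepop(path) -> GenotypeMatrix:
    """Read a GenePop file with 2- or 3-digit allele coding.

    Populations are inferred from the ``Pop`` separators and labelled
    ``Pop1``, ``Pop2``, ...; the code ``00``/``000`` maps to missing.
    """
    with open(path) as fh:
        raw = fh.read().splitlines()
    if not raw:
        raise GenotypeParseError("empty GenePop file")
    body = raw[1:]  # first line is a free-form title

    locus_names: list[str] = []
    i = 0
    while i < len(body) and body[i].strip().lower() != "pop":
        chunk = body[i].strip()
        if chunk:
            locus_names.extend(t.strip() for t in chunk.split(",") if t.strip())
        i += 1
    if i == len(body):
        raise GenotypeParseError("no 'Pop' separator found")

    ids: list[str] = []
    pops: list[str] = []
    rows: list[list[str]] = []
    pop_idx = 0
    for lineno, line in enumerate(body[i:], start=i + 2):
        s = line.strip()
        if not s:
            continue
        if s.lower() == "pop":
            pop_idx += 1
            continue
        if "," not in s:
            raise GenotypeParseError(
                f"line {lineno}: expected 'id , genotypes' record"
            )
        name, _, geno = s.partition(",")
        toks = geno.split()
        if len(toks) != len(locus_names):
            raise GenotypeParseError(
                f"line {lineno}: {len(toks)} genotypes for "
                f"{len(locus_names)} loci"
            )
        ids.append(name.strip().replace(" ", "_"))
        pops.append(f"Pop{pop_idx}")
        rows.append(toks)

    widths = {len(t) for row in rows for t in row}
    if not widths:
        return GenotypeMatrix(
            ids, pops, locus_names, np.zeros((0, len(locus_names), 2), dtype=int)
        )
    if len(widths) != 1 or widths.pop() not in (4, 6):
        raise GenotypeParseError(
            "inconsistent allele digit width (expect uniform 2- or 3-digit coding)"
        )
    w = len(rows[0][0]) // 2

    alleles = np.zeros((len(rows), len(locus_names), 2), dtype=np.int64)
    for r, row in enumerate(rows):
        for l, tok in enumerate(row):
            a, b = int(tok[:w]), int(tok[w:])
            if (a == 0) != (b == 0):
                raise GenotypeParseError(
                    f"half-called genotype {tok!r} for individual {ids[r]}"
                )
            alleles[r, l] = (MISSING, MISSING) if a == 0 else (a, b)
    return GenotypeMatrix(ids, pops, locus_names, alleles)


def write_genepop(gm: GenotypeMatrix, path, digits: int = 3, title: str | None = None) -> None:
    """Write ``gm`` in GenePop format (one ``Pop`` block per population)."""
    if digits not in (2, 3):
        raise ValueError("digits must be 2 or 3")
    limit = 10**digits - 1
    nonmiss = gm.alleles[gm.alleles != MISSING]
    if nonmiss.size and nonmiss.max() > limit:
        raise ValueError(
            f"allele code {nonmiss.max()} does not fit {digits}-digit coding"
        )
    with open(path, "w") as fh:
        fh.write((title or "admixkit export") + "\n")
        for name in gm.locus_names:
            fh.write(name + "\n")
        for pop in gm.populations():
            fh.write("Pop\n")
            for i in gm.population_indices(pop):
                toks = []
                for l in range(gm.n_loci):
                    a, b = gm.alleles[i, l]
                    if a == MISSING:
                        a = b = 0
                    toks.append(f"{a:0{digits}d}{b:0{digits}d}")
                fh.write(f"{gm.individual_ids[i]} , " + " ".join(toks) + "\n")


def write_csv(table, path) -> None:
    """Write a result table (pandas DataFrame) as CSV with a header row."""
    table.to_csv(path, index=False)
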