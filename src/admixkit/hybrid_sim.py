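"""Hybrid-class genotype simulation by Mendelian crossing.

From two parental reference samples, allele frequencies are estimated and
a standard eight-class design is produced: the two pure classes, F1
(pure x pure), F2 (F1 x F1), first backcrosses of F1 to each parental
pool, and double backcrosses of those to the same pool.  Crossing uses
explicit simulated parent individuals with Mendelian gamete sampling —
not re-draws from class-level frequencies — because the between-individual
ancestry variance of backcross classes (the hard part of hybrid detection)
comes from segregation within pedigrees.

Parents for each offspring are drawn with replacement (pool sizes are
small); simulated genotypes contain no missing data.  When
``track_ancestry`` is on, every gene copy carries a provenance tag so the
true pool-A ancestry fraction of each individual is known exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .io_formats import MISSING, GenotypeMatrix
from .synthetic_pops import _as_rng


class HybridClass(str, Enum):
    PURE_A = "pure_A"
    PURE_B = "pure_B"
    F1 = "F1"
    F2 = "F2"
    BC_A = "BC_A"      # F1 x pure_A
    BC_B = "BC_B"      # F1 x pure_B
    BC2_A = "BC2_A"    # (F1 x pure_A) x pure_A
    BC2_B = "BC2_B"    # (F1 x pure_B) x pure_B


#: Expected fraction of ancestry from pool A for each class.
EXPECTED_ANCESTRY_A = {
    HybridClass.PURE_A: 1.0,
    HybridClass.PURE_B: 0.0,
    HybridClass.F1: 0.5,
    HybridClass.F2: 0.5,
    HybridClass.BC_A: 0.75,
    HybridClass.BC_B: 0.25,
    HybridClass.BC2_A: 0.875,
    HybridClass.BC2_B: 0.125,
}


@dataclass
class AlleleFrequencyTable:
    """Per-locus allele frequencies with the gene-copy counts behind them."""

    locus_names: list[str]
    alleles: list[np.ndarray]        # observed allele codes per locus
    frequencies: list[np.ndarray]    # matching frequency vectors
    gene_copies: np.ndarray          # non-missing gene copies per locus

    @property
    def n_loci(self) -> int:
        return len(self.locus_names)


def estimate_allele_frequencies(
    gm: GenotypeMatrix, population: str | None = None
) -> AlleleFrequencyTable:
    """Observed allele frequencies (counts over non-missing gene copies).

    ``population=None`` uses every individual in the matrix.
    """
    sub = gm if population is None else gm.subset_population(population)
    alleles, freqs, copies = [], [], np.zeros(gm.n_loci, dtype=int)
    for l, name in enumerate(gm.locus_names):
        col = sub.alleles[:, l, :].ravel()
        col = col[col != MISSING]
        if col.size == 0:
            raise ValueError(f"locus {name}: zero non-missing gene copies")
        codes, counts = np.unique(col, return_counts=True)
        alleles.append(codes)
        freqs.append(counts / col.size)
        copies[l] = col.size
    return AlleleFrequencyTable(list(gm.locus_names), alleles, freqs, copies)


def simulate_pure(
    freqs: AlleleFrequencyTable,
    n: int,
    seed=0,
    ancestry_tag: int | None = None,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Draw ``n`` individuals with both gene copies i.i.d. from the
    population frequencies (Hardy–Weinberg).

    Returns ``(genotypes, tags)`` with genotypes ``(n, L, 2)`` of allele
    codes; tags is an equal-shaped provenance array (all ``ancestry_tag``)
    or None.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _as_rng(seed)
    L = freqs.n_loci
    genos = np.zeros((n, L, 2), dtype=np.int64)
    for l in range(L):
        codes, p = freqs.alleles[l], freqs.frequencies[l]
        genos[:, l, :] = codes[rng.choice(codes.size, size=(n, 2), p=p)]
    tags = None
    if ancestry_tag is not None:
        tags = np.full((n, L, 2), ancestry_tag, dtype=np.int8)
    return genos, tags


def cross(
    parents_a: np.ndarray,
    parents_b: np.ndarray,
    n: int,
    seed=0,
    tags_a: np.ndarray | None = None,
    tags_b: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Mendelian cross: each offspring picks one parent uniformly (with
    replacement) from each pool and inherits one uniformly chosen allele
    per locus from each parent."""
    if len(parents_a) == 0 or len(parents_b) == 0:
        raise ValueError("both parent pools must be non-empty")
    rng = _as_rng(seed)
    L = parents_a.shape[1]
    ia = rng.integers(0, len(parents_a), size=n)
    ib = rng.integers(0, len(parents_b), size=n)
    slot_a = rng.integers(0, 2, size=(n, L))
    slot_b = rng.integers(0, 2, size=(n, L))
    rows = np.arange(n)[:, None]
    cols = np.arange(L)[None, :]
    genos = np.zeros((n, L, 2), dtype=np.int64)
    genos[:, :, 0] = parents_a[ia[:, None], cols, slot_a]
    genos[:, :, 1] = parents_b[ib[:, None], cols, slot_b]
    del rows
    tags = None
    if tags_a is not None and tags_b is not None:
        tags = np.zeros((n, L, 2), dtype=np.int8)
        tags[:, :, 0] = tags_a[ia[:, None], cols, slot_a]
        tags[:, :, 1] = tags_b[ib[:, None], cols, slot_b]
    return genos, tags


#: Canonical class order of the simulated design.
DESIGN_ORDER = [
    HybridClass.PURE_A,
    HybridClass.PURE_B,
    HybridClass.F1,
    HybridClass.F2,
    HybridClass.BC_A,
    HybridClass.BC_B,
    HybridClass.BC2_A,
    HybridClass.BC2_B,
]


@dataclass
class SimulatedDataset:
    """Simulated eight-class genotypes plus their ground-truth labels."""

    genotypes: GenotypeMatrix
    true_class: list[HybridClass]
    generation_seed: int
    ancestry_fraction: np.ndarray | None = None  # true fraction from pool A

    def truth_table(self):
        import pandas as pd

        data = {
            "individual_id": self.genotypes.individual_ids,
            "true_class": [c.value for c in self.true_class],
        }
        if self.ancestry_fraction is not None:
            data["ancestry_fraction_A"] = self.ancestry_fraction
        return pd.DataFrame(data)


def build_design(
    ref_a: GenotypeMatrix,
    ref_b: GenotypeMatrix,
    n_per_class: int = 60,
    seed: int = 0,
    track_ancestry: bool = True,
) -> SimulatedDataset:
    """Produce the eight-class simulated design (default 8 x 60 = 480).

    ``ref_a``/``ref_b`` are the two parental reference samples (already
    admixture-filtered in the real workflow).  Pure pools are drawn from
    the estimated reference frequencies; every hybrid class is produced
    by Mendelian crossing of simulated parents.
    """
    if ref_a.n_individuals < 2 or ref_b.n_individuals < 2:
        raise ValueError("each reference population needs >= 2 individuals")
    if ref_a.locus_names != ref_b.locus_names:
        raise ValueError("reference populations have different locus names")
    rng = np.random.default_rng(seed)
    fa = estimate_allele_frequencies(ref_a)
    fb = estimate_allele_frequencies(ref_b)

    tag_a = 1 if track_ancestry else None
    tag_b = 0 if track_ancestry else None
    pools: dict[HybridClass, tuple[np.ndarray, np.ndarray | None]] = {}
    pools[HybridClass.PURE_A] = simulate_pure(fa, n_per_class, rng, tag_a)
    pools[HybridClass.PURE_B] = simulate_pure(fb, n_per_class, rng, tag_b)

    def _cross(cls, a, b):
        ga, ta = pools[a]
        gb, tb = pools[b]
        pools[cls] = cross(ga, gb, n_per_class, rng, ta, tb)

    _cross(HybridClass.F1, HybridClass.PURE_A, HybridClass.PURE_B)
    _cross(HybridClass.F2, HybridClass.F1, HybridClass.F1)
    _cross(HybridClass.BC_A, HybridClass.F1, HybridClass.PURE_A)
    _cross(HybridClass.BC_B, HybridClass.F1, HybridClass.PURE_B)
    _cross(HybridClass.BC2_A, HybridClass.BC_A, HybridClass.PURE_A)
    _cross(HybridClass.BC2_B, HybridClass.BC_B, HybridClass.PURE_B)

    genos = np.concatenate([pools[c][0] for c in DESIGN_ORDER], axis=0)
    ids = [
        f"sim_{c.value}_{i + 1:03d}"
        for c in DESIGN_ORDER
        for i in range(n_per_class)
    ]
    labels = [c.value for c in DESIGN_ORDER for _ in range(n_per_class)]
    gm = GenotypeMatrix(ids, labels, list(ref_a.locus_names), genos)
    classes = [c for c in DESIGN_ORDER for _ in range(n_per_class)]
    anc = None
    if track_ancestry:
        anc = np.concatenate(
            [pools[c][1].mean(axis=(1, 2)) for c in DESIGN_ORDER]
        )
    return SimulatedDataset(gm, classes, seed, anc)
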