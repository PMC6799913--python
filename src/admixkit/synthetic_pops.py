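"""Synthetic parental populations under the Balding–Nichols model.

Two diverged populations are generated in three steps: (i) per-locus
ancestral allele frequencies from a symmetric Dirichlet; (ii) per-population
frequencies from a Dirichlet centred on the ancestral vector with
concentration ``(1 - F) / F`` (Balding–Nichols), so the expected
Weir–Cockerham FST between populations equals ``F``; (iii) diploid
genotypes drawn under Hardy–Weinberg proportions, optionally with an
inbreeding parameter ``f_is`` (probability the second gene copy duplicates
the first) and per-genotype missingness.

All draws are pure functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import MISSING, GenotypeMatrix, concat


@dataclass
class LocusSpec:
    """Ancestral description of one microsatellite locus."""

    n_alleles: int
    ancestral_frequencies: np.ndarray

    def __post_init__(self) -> None:
        self.ancestral_frequencies = np.asarray(
            self.ancestral_frequencies, dtype=float
        )
        if self.n_alleles < 2:
            raise ValueError("a locus needs at least 2 alleles")
        if len(self.ancestral_frequencies) != self.n_alleles:
            raise ValueError("frequency vector length != n_alleles")
        if (self.ancestral_frequencies < 0).any():
            raise ValueError("negative frequency")
        if abs(self.ancestral_frequencies.sum() - 1.0) > 1e-12:
            raise ValueError("frequencies must sum to 1")


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def draw_ancestral_frequencies(
    n_loci: int,
    allele_range: tuple[int, int] = (3, 17),
    concentration: float = 1.0,
    seed=0,
) -> list[LocusSpec]:
    """Draw per-locus allele counts (uniform on ``allele_range``, inclusive)
    and ancestral frequencies from a symmetric Dirichlet."""
    lo, hi = allele_range
    if not (2 <= lo <= hi):
        raise ValueError("need 2 <= min <= max allele count")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    rng = _as_rng(seed)
    specs = []
    for _ in range(n_loci):
        m = int(rng.integers(lo, hi + 1))
        freqs = rng.dirichlet(np.full(m, concentration))
        specs.append(LocusSpec(m, freqs))
    return specs


def draw_population_frequencies(
    spec: LocusSpec, fst: float, seed=0
) -> np.ndarray:
    """One population's frequency vector under Balding–Nichols drift.

    ``p_pop ~ Dirichlet(p_ancestral * (1 - fst) / fst)``, which has
    ``Var(p_i) = fst * p_i * (1 - p_i)``.
    """
    if not 0.0 < fst < 1.0:
        raise ValueError("fst must be in (0, 1)")
    rng = _as_rng(seed)
    conc = spec.ancestral_frequencies * (1.0 - fst) / fst
    # dirichlet via gamma draws to tolerate very small concentrations
    g = rng.gamma(np.maximum(conc, 1e-12))
    if g.sum() == 0.0:
        out = np.zeros_like(g)
        out[int(np.argmax(conc))] = 1.0
        return out
    return g / g.sum()


def sample_population(
    freqs: list[np.ndarray],
    n_individuals: int,
    missing_rate: float = 0.0,
    population_label: str = "pop",
    seed=0,
    f_is: float = 0.0,
    locus_names: list[str] | None = None,
    id_prefix: str | None = None,
) -> GenotypeMatrix:
    """Sample diploid genotypes from per-locus frequency vectors.

    Allele codes are 1-based indices into each frequency vector, shared
    across populations drawn from the same ancestral specs.  With
    ``f_is > 0`` the second gene copy duplicates the first with that
    probability, inflating homozygosity (heterozygote deficit) the way an
    inbreeding coefficient F_IS would.
    """
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must be in [0, 1)")
    if not 0.0 <= f_is <= 1.0:
        raise ValueError("f_is must be in [0, 1]")
    rng = _as_rng(seed)
    L = len(freqs)
    n = n_individuals
    alleles = np.zeros((n, L, 2), dtype=np.int64)
    for l, p in enumerate(freqs):
        p = np.asarray(p, dtype=float)
        if p.size == 0:
            raise ValueError(f"empty frequency vector at locus {l}")
        a = rng.choice(p.size, size=n, p=p) + 1
        b = rng.choice(p.size, size=n, p=p) + 1
        if f_is > 0:
            dup = rng.random(n) < f_is
            b = np.where(dup, a, b)
        alleles[:, l, 0] = a
        alleles[:, l, 1] = b
    if missing_rate > 0:
        drop = rng.random((n, L)) < missing_rate
        alleles[drop] = MISSING
    prefix = id_prefix if id_prefix is not None else population_label
    ids = [f"{prefix}_{i + 1:03d}" for i in range(n)]
    names = locus_names or [f"L{j + 1}" for j in range(L)]
    return GenotypeMatrix(ids, [population_label] * n, names, alleles)


@dataclass
class PopulationModel:
    """A pair of diverged populations sharing one ancestral frequency set."""

    fst_target: float
    locus_specs: list[LocusSpec]
    seed: int = 0

    @property
    def n_loci(self) -> int:
        return len(self.locus_specs)

    def population_frequencies(self, n_pops: int = 2) -> list[list[np.ndarray]]:
        """Independent Balding–Nichols draws for each population."""
        rng = np.random.default_rng(self.seed)
        return [
            [
                draw_population_frequencies(spec, self.fst_target, rng)
                for spec in self.locus_specs
            ]
            for _ in range(n_pops)
        ]

    def sample_pair(
        self,
        n_per_pop: tuple[int, int] = (30, 30),
        labels: tuple[str, str] = ("A", "B"),
        missing_rate: float = 0.0,
        f_is: float = 0.0,
    ) -> GenotypeMatrix:
        rng = np.random.default_rng(self.seed)
        pop_freqs = [
            [
                draw_population_frequencies(spec, self.fst_target, rng)
                for spec in self.locus_specs
            ]
            for _ in range(2)
        ]
        mats = [
            sample_population(
                pop_freqs[k],
                n_per_pop[k],
                missing_rate=missing_rate,
                population_label=labels[k],
                seed=rng,
                f_is=f_is,
            )
            for k in range(2)
        ]
        return concat(mats)


def simulate_parental_pair(
    n_loci: int = 27,
    allele_range: tuple[int, int] = (3, 17),
    fst: float = 0.165,
    n_per_pop: tuple[int, int] = (30, 30),
    concentration: float = 1.0,
    missing_rate: float = 0.0,
    f_is: float = 0.0,
    labels: tuple[str, str] = ("A", "B"),
    seed: int = 0,
) -> GenotypeMatrix:
    """Convenience wrapper: two reference populations with the study-like
    structure (27 loci, 3-17 alleles each, FST 0.165, 30 + 30 individuals)."""
    specs = draw_ancestral_frequencies(
        n_loci, allele_range, concentration, seed=np.random.default_rng(seed)
    )
    model = PopulationModel(fst, specs, seed=seed + 1)
    return model.sample_pair(
        n_per_pop, labels=labels, missing_rate=missing_rate, f_is=f_is
    )
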