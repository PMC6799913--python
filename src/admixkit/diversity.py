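"""Per-population diversity, identity and relatedness statistics.

The panel: mean alleles per locus (A), rarefied allelic richness (AR),
observed heterozygosity (Ho), unbiased expected heterozygosity (Hz, with
Nei's 2n/(2n-1) small-sample factor), private alleles between a pair of
populations (Np), the inbreeding coefficient FIS = (Hz - Ho)/Hz,
multilocus probability of identity (PID), and the Mxy genotype-sharing
relatedness index with simulated full-sib / half-sib / unrelated reference
distributions.

All statistics use locus-wise complete observations; missing genotypes are
excluded from denominators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .hybrid_sim import AlleleFrequencyTable, estimate_allele_frequencies
from .io_formats import MISSING, GenotypeMatrix
from .synthetic_pops import _as_rng


def _pop(gm: GenotypeMatrix, population: str | None) -> GenotypeMatrix:
    return gm if population is None else gm.subset_population(population)


# ---------------------------------------------------------------------------
# allele counts and heterozygosity
# ---------------------------------------------------------------------------

def mean_alleles_per_locus(gm: GenotypeMatrix, population: str | None = None) -> float:
    """A: mean over loci of the number of distinct non-missing alleles."""
    sub = _pop(gm, population)
    counts = []
    for l, name in enumerate(sub.locus_names):
        col = sub.alleles[:, l, :].ravel()
        col = col[col != MISSING]
        if col.size == 0:
            warnings.warn(f"locus {name}: all genotypes missing; counted as 0")
            counts.append(0)
        else:
            counts.append(np.unique(col).size)
    return float(np.mean(counts))


def allelic_richness(
    gm: GenotypeMatrix, population: str | None = None, g: int | None = None
) -> tuple[np.ndarray, float]:
    """Rarefied allelic richness at a standard sample of ``g`` gene copies.

    ``AR_locus = sum_i [1 - C(2n - N_i, g) / C(2n, g)]`` with ``N_i`` the
    count of allele i and 2n the non-missing gene copies at the locus.
    ``g=None`` uses the smallest per-locus copy count (the usual
    "adjust to the smallest sample" convention).  Returns the per-locus
    values and their mean.
    """
    sub = _pop(gm, population)
    copies = []
    tables = []
    for l in range(sub.n_loci):
        col = sub.alleles[:, l, :].ravel()
        col = col[col != MISSING]
        _, counts = np.unique(col, return_counts=True)
        tables.append(counts)
        copies.append(col.size)
    if g is None:
        g = int(min(copies))
    if g < 2:
        raise ValueError("g must be >= 2")
    if g > min(copies):
        raise ValueError(
            f"g={g} exceeds the smallest per-locus gene-copy count {min(copies)}"
        )
    per_locus = np.array([rarefied_allele_count(c, g) for c in tables])
    return per_locus, float(per_locus.mean())


def rarefied_allele_count(counts: np.ndarray, g: int) -> float:
    """Expected number of distinct alleles in a subsample of g gene copies."""
    counts = np.asarray(counts, dtype=int)
    total = counts.sum()
    # C(total - Ni, g) / C(total, g) via log-gamma for numerical range
    def log_comb(n, k):
        if k > n:
            return -np.inf
        return special.gammaln(n + 1) - special.gammaln(k + 1) - special.gammaln(n - k + 1)

    denom = log_comb(total, g)
    vals = [1.0 - np.exp(log_comb(total - ni, g) - denom) for ni in counts]
    return float(np.sum(vals))


def observed_heterozygosity(
    gm: GenotypeMatrix, population: str | None = None
) -> float:
    """Ho: fraction of heterozygous non-missing genotypes, averaged over loci."""
    sub = _pop(gm, population)
    vals = []
    for l in range(sub.n_loci):
        a = sub.alleles[:, l, :]
        keep = a[:, 0] != MISSING
        if not keep.any():
            continue
        vals.append(float(np.mean(a[keep, 0] != a[keep, 1])))
    return float(np.mean(vals)) if vals else np.nan


def unbiased_heterozygosity(
    gm: GenotypeMatrix, population: str | None = None
) -> float:
    """Hz: Nei's unbiased expected heterozygosity, averaged over loci.

    Per locus ``(2n / (2n - 1)) * (1 - sum p_i^2)`` with n the diploid
    individuals with data.
    """
    sub = _pop(gm, population)
    vals = []
    for l, name in enumerate(sub.locus_names):
        col = sub.alleles[:, l, :]
        keep = col[:, 0] != MISSING
        n = int(keep.sum())
        if n == 0:
            warnings.warn(f"locus {name}: no data; skipped in Hz")
            continue
        copies = col[keep].ravel()
        _, counts = np.unique(copies, return_counts=True)
        p = counts / (2 * n)
        if 2 * n < 2:
            continue
        vals.append((2 * n) / (2 * n - 1) * (1.0 - float(np.sum(p**2))))
    return float(np.mean(vals)) if vals else np.nan


def private_alleles(
    gm: GenotypeMatrix, population_pair: tuple[str, str]
) -> tuple[dict[str, int], pd.DataFrame]:
    """Alleles observed in exactly one of two populations.

    Returns per-population private counts and a table with columns
    ``population, locus, allele, frequency`` (frequency in the population
    holding the allele).
    """
    pa, pb = population_pair
    fa = estimate_allele_frequencies(gm, pa)
    fb = estimate_allele_frequencies(gm, pb)
    rows = []
    for l, name in enumerate(gm.locus_names):
        seen_a = dict(zip(fa.alleles[l].tolist(), fa.frequencies[l]))
        seen_b = dict(zip(fb.alleles[l].tolist(), fb.frequencies[l]))
        for allele, freq in seen_a.items():
            if allele not in seen_b:
                rows.append((pa, name, allele, float(freq)))
        for allele, freq in seen_b.items():
            if allele not in seen_a:
                rows.append((pb, name, allele, float(freq)))
    table = pd.DataFrame(rows, columns=["population", "locus", "allele", "frequency"])
    counts = {
        pa: int((table["population"] == pa).sum()),
        pb: int((table["population"] == pb).sum()),
    }
    return counts, table


def inbreeding_fis(
    gm: GenotypeMatrix,
    population: str | None = None,
    mode: str = "ratio-of-means",
) -> float:
    """FIS = (Hz - Ho) / Hz.

    ``ratio-of-means`` (default) computes the ratio of the multilocus mean
    heterozygosities; ``mean-of-ratios`` averages the per-locus F values
    over loci with Hz > 0.  The two differ on real data whenever diversity
    varies across loci.
    """
    sub = _pop(gm, population)
    if mode == "ratio-of-means":
        ho = observed_heterozygosity(sub)
        hz = unbiased_heterozygosity(sub)
        if not np.isfinite(hz) or hz == 0.0:
            return np.nan
        return float((hz - ho) / hz)
    if mode == "mean-of-ratios":
        vals = []
        for l in range(sub.n_loci):
            col = sub.alleles[:, l, :]
            keep = col[:, 0] != MISSING
            n = int(keep.sum())
            if n == 0:
                continue
            ho_l = float(np.mean(col[keep, 0] != col[keep, 1]))
            _, counts = np.unique(col[keep].ravel(), return_counts=True)
            p = counts / (2 * n)
            hz_l = (2 * n) / (2 * n - 1) * (1.0 - float(np.sum(p**2)))
            if hz_l > 0:
                vals.append((hz_l - ho_l) / hz_l)
        return float(np.mean(vals)) if vals else np.nan
    raise ValueError(f"unknown mode {mode!r}")


def diversity_summary(gm: GenotypeMatrix, g: int | None = None) -> pd.DataFrame:
    """The Table-3-style panel, one row per population."""
    rows = []
    for pop in gm.populations():
        sub = gm.subset_population(pop)
        _, ar = allelic_richness(sub, g=g)
        rows.append(
            {
                "population": pop,
                "n": sub.n_individuals,
                "A": mean_alleles_per_locus(sub),
                "AR": ar,
                "Hz": unbiased_heterozygosity(sub),
                "Ho": observed_heterozygosity(sub),
                "FIS": inbreeding_fis(sub),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# probability of identity
# ---------------------------------------------------------------------------

def probability_of_identity(
    freqs: AlleleFrequencyTable | list[np.ndarray],
) -> tuple[np.ndarray, float]:
    """PID per locus and combined over loci (product).

    ``PID_locus = sum_i p_i^4 + sum_{i<j} (2 p_i p_j)^2``: the probability
    that two random HWE genotypes at the locus are identical.
    """
    vectors = freqs.frequencies if isinstance(freqs, AlleleFrequencyTable) else freqs
    per_locus = []
    for p in vectors:
        p = np.asarray(p, dtype=float)
        hom = float(np.sum(p**4))
        outer = np.outer(p, p)
        het = float(np.sum((2.0 * outer[np.triu_indices(p.size, k=1)]) ** 2))
        per_locus.append(hom + het)
    per_locus = np.array(per_locus)
    return per_locus, float(np.prod(per_locus))


# ---------------------------------------------------------------------------
# Mxy genotype-sharing relatedness
# ---------------------------------------------------------------------------

def relatedness_mxy(ind_x: np.ndarray, ind_y: np.ndarray) -> float:
    """Genotype-sharing index between two individuals (arrays ``(L, 2)``).

    Per locus: shared-allele count of the two genotypes as multisets,
    divided by 2 (identical genotype 1, one shared copy 0.5, none 0);
    averaged over loci where both individuals have data.
    """
    x = np.sort(np.asarray(ind_x), axis=1)
    y = np.sort(np.asarray(ind_y), axis=1)
    usable = (x[:, 0] != MISSING) & (y[:, 0] != MISSING)
    if not usable.any():
        return np.nan
    x, y = x[usable], y[usable]
    per_locus = _shared_halfcount(x, y)
    return float(per_locus.mean())


def _shared_halfcount(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Multiset-intersection size / 2 for sorted genotype arrays (L, 2)."""
    full = (x[:, 0] == y[:, 0]) & (x[:, 1] == y[:, 1])
    any_match = (
        (x[:, 0] == y[:, 0])
        | (x[:, 0] == y[:, 1])
        | (x[:, 1] == y[:, 0])
        | (x[:, 1] == y[:, 1])
    )
    return np.where(full, 1.0, np.where(any_match, 0.5, 0.0))


def mxy_matrix(gm: GenotypeMatrix, population: str | None = None) -> pd.DataFrame:
    """Symmetric pairwise Mxy matrix (diagonal 1 where self-comparison is
    complete)."""
    sub = _pop(gm, population)
    n = sub.n_individuals
    out = np.ones((n, n))
    for i in range(n):
        for j in range(i, n):
            out[i, j] = out[j, i] = relatedness_mxy(sub.alleles[i], sub.alleles[j])
    return pd.DataFrame(out, index=sub.individual_ids, columns=sub.individual_ids)


@dataclass
class RelatednessResult:
    """Observed pairwise relatedness vs simulated pedigree references."""

    matrix: pd.DataFrame
    observed_mean: float
    reference_means: dict[str, float]
    p_values: dict[str, float]
    n_sim_pairs: int


def _mendelian_offspring(p1: np.ndarray, p2: np.ndarray, rng) -> np.ndarray:
    L = p1.shape[0]
    s1 = rng.integers(0, 2, size=L)
    s2 = rng.integers(0, 2, size=L)
    return np.stack([p1[np.arange(L), s1], p2[np.arange(L), s2]], axis=1)


def relatedness_reference_test(
    gm: GenotypeMatrix,
    population: str | None = None,
    n_sim_pairs: int = 1000,
    seed=0,
) -> RelatednessResult:
    """Compare a population's mean Mxy against simulated full-sib,
    half-sib and unrelated pair references.

    References are built from the population's own allele frequencies:
    full sibs share two HWE parents, half sibs one, unrelated pairs none;
    offspring genotypes are Mendelian.  Welch t-tests compare the observed
    pairwise values with each reference distribution.
    """
    sub = _pop(gm, population)
    if sub.n_individuals < 2:
        raise ValueError("population needs >= 2 individuals")
    freqs = estimate_allele_frequencies(sub)
    if all(f.size == 1 for f in freqs.frequencies):
        raise ValueError("panel is entirely monomorphic; Mxy is degenerate")
    rng = _as_rng(seed)
    L = freqs.n_loci

    def hwe_individual():
        g = np.zeros((L, 2), dtype=np.int64)
        for l in range(L):
            codes, p = freqs.alleles[l], freqs.frequencies[l]
            g[l] = codes[rng.choice(codes.size, size=2, p=p)]
        return g

    refs: dict[str, list[float]] = {"full_sib": [], "half_sib": [], "unrelated": []}
    for _ in range(n_sim_pairs):
        p1, p2, p3 = hwe_individual(), hwe_individual(), hwe_individual()
        o1 = _mendelian_offspring(p1, p2, rng)
        o2 = _mendelian_offspring(p1, p2, rng)
        refs["full_sib"].append(relatedness_mxy(o1, o2))
        h1 = _mendelian_offspring(p1, p2, rng)
        h2 = _mendelian_offspring(p1, p3, rng)
        refs["half_sib"].append(relatedness_mxy(h1, h2))
        refs["unrelated"].append(relatedness_mxy(hwe_individual(), hwe_individual()))

    matrix = mxy_matrix(sub)
    iu = np.triu_indices(sub.n_individuals, k=1)
    observed = matrix.to_numpy()[iu]
    observed = observed[np.isfinite(observed)]
    p_values = {}
    for name, vals in refs.items():
        res = stats.ttest_ind(observed, vals, equal_var=False)
        p_values[name] = float(res.pvalue)
    return RelatednessResult(
        matrix=matrix,
        observed_mean=float(observed.mean()),
        reference_means={k: float(np.mean(v)) for k, v in refs.items()},
        p_values=p_values,
        n_sim_pairs=n_sim_pairs,
    )
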