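"""Hardy–Weinberg and gametic-disequilibrium tests, multiple-testing
correction, and a null-allele screen.

The HWE test is the Monte-Carlo exact test of Guo & Thompson: a Metropolis
random walk over diploid genotype tables with fixed allele counts, using
allele-switch proposals, with the p-value the fraction of visited tables
whose Levene conditional probability does not exceed the observed table's.
For biallelic loci the full conditional distribution is small enough to
enumerate (:func:`hwe_enumeration_biallelic`), which this package uses as
an independent oracle in its tests.

The gametic-disequilibrium (LD) test is a permutation test on the
two-locus genotype contingency table with a log-likelihood-ratio (G)
statistic: single-locus genotype columns are shuffled between individuals,
which preserves both single-locus distributions while breaking any
between-locus association.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io_formats import MISSING, GenotypeMatrix


@dataclass
class TestResult:
    """Outcome of one equilibrium test."""

    name: str
    p_value: float
    mc_error: float
    statistic: float | None = None
    note: str = ""
    significant_after_correction: bool | None = None


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def _locus_genotypes(gm: GenotypeMatrix, population, locus) -> np.ndarray:
    sub = gm if population is None else gm.subset_population(population)
    if isinstance(locus, str):
        locus = gm.locus_names.index(locus)
    col = sub.alleles[:, locus, :]
    return col[col[:, 0] != MISSING]


def hwe_exact_test(
    gm: GenotypeMatrix,
    population: str | None,
    locus,
    chain_length: int = 100_000,
    dememorization: int = 100_000,
    seed=0,
    n_batches: int = 50,
) -> TestResult:
    """Guo–Thompson Monte-Carlo exact test for HWE at one locus.

    The chain state is the assignment of the fixed multiset of 2n gene
    copies to the 2n (individual, slot) positions; a step picks one gene
    copy in each of two random individuals and switches them.  Random
    switches are doubly stochastic, so the stationary distribution is
    uniform over assignments — which induces exactly the Levene
    conditional distribution on genotype tables (the 2^h heterozygote and
    multinomial factors are the assignment multiplicities).  The p-value
    is the post-dememorization fraction of states whose conditional table
    probability is <= the observed table's; its Monte-Carlo error comes
    from batch means.
    """
    locus_name = locus if isinstance(locus, str) else gm.locus_names[locus]
    genos = _locus_genotypes(gm, population, locus)
    n = len(genos)
    if np.unique(genos).size < 2:
        return TestResult(locus_name, 1.0, 0.0, note="monomorphic locus")
    if n < 3:
        raise ValueError(f"locus {locus_name}: need >= 3 individuals with data")

    rng = np.random.default_rng(seed)
    pairs = [list(g) for g in genos.tolist()]
    counts: dict[tuple[int, int], int] = {}
    h = 0
    logfac = 0.0  # sum over genotype cells of log(count!)
    for a, b in pairs:
        key = (a, b) if a <= b else (b, a)
        counts[key] = counts.get(key, 0) + 1
        logfac += math.log(counts[key])
        if a != b:
            h += 1
    log2 = math.log(2.0)
    logp_obs = h * log2 - logfac  # relative conditional log-probability
    logp = logp_obs

    total = dememorization + chain_length
    ii = rng.integers(0, n, size=total)
    jj = rng.integers(0, n, size=total)
    si = rng.integers(0, 2, size=total)
    sj = rng.integers(0, 2, size=total)

    tol = 1e-9
    hits = np.zeros(chain_length, dtype=np.int8)

    def key_of(g):
        return (g[0], g[1]) if g[0] <= g[1] else (g[1], g[0])

    def is_het(g):
        return g[0] != g[1]

    for t in range(total):
        i, j = ii[t], jj[t]
        if i != j:
            gi, gj = pairs[i], pairs[j]
            ai, aj = gi[si[t]], gj[sj[t]]
            if ai != aj:
                ki_old, kj_old = key_of(gi), key_of(gj)
                gi_new = list(gi)
                gj_new = list(gj)
                gi_new[si[t]] = aj
                gj_new[sj[t]] = ai
                ki_new, kj_new = key_of(gi_new), key_of(gj_new)
                # incremental update of sum log(count!) and het count
                delta_fac = 0.0
                c = counts[ki_old]
                delta_fac -= math.log(c)
                counts[ki_old] = c - 1
                c = counts[kj_old]
                delta_fac -= math.log(c)
                counts[kj_old] = c - 1
                c = counts.get(ki_new, 0) + 1
                counts[ki_new] = c
                delta_fac += math.log(c)
                c = counts.get(kj_new, 0) + 1
                counts[kj_new] = c
                delta_fac += math.log(c)
                dh = (
                    is_het(gi_new)
                    + is_het(gj_new)
                    - is_het(gi)
                    - is_het(gj)
                )
                pairs[i] = gi_new
                pairs[j] = gj_new
                logp += dh * log2 - delta_fac
        if t >= dememorization:
            hits[t - dememorization] = logp <= logp_obs + tol

    p = float(hits.mean())
    nb = min(n_batches, chain_length)
    batches = hits[: (chain_length // nb) * nb].reshape(nb, -1).mean(axis=1)
    mc_error = float(batches.std(ddof=1) / math.sqrt(nb))
    return TestResult(locus_name, p, mc_error, statistic=logp_obs)


def hwe_enumeration_biallelic(n11: int, n12: int, n22: int) -> float:
    """Exact HWE p-value for a biallelic genotype table by complete
    enumeration of the Levene conditional distribution.

    Serves as the independent oracle for the Monte-Carlo test: enumerate
    all tables with the observed allele counts, weight each by its
    conditional probability, and sum the probabilities of tables no more
    probable than the observed one.
    """
    n = n11 + n12 + n22
    nA = 2 * n11 + n12
    def log_prob(h):  # h = heterozygote count
        a = (nA - h) // 2
        b = (2 * n - nA - h) // 2
        return (
            -math.lgamma(a + 1)
            - math.lgamma(h + 1)
            - math.lgamma(b + 1)
            + h * math.log(2.0)
        )

    hs = [h for h in range(min(nA, 2 * n - nA) + 1) if (nA - h) % 2 == 0]
    logs = np.array([log_prob(h) for h in hs])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    p_obs = probs[hs.index(n12)]
    return float(probs[probs <= p_obs * (1 + 1e-12)].sum())


def hwe_panel(
    gm: GenotypeMatrix,
    population: str | None = None,
    chain_length: int = 100_000,
    dememorization: int = 100_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> list[TestResult]:
    """HWE test at every locus, with Bonferroni flags filled in."""
    results = [
        hwe_exact_test(
            gm, population, l, chain_length, dememorization, seed=seed + l
        )
        for l in range(gm.n_loci)
    ]
    flags, _ = bonferroni_adjust([r.p_value for r in results], alpha)
    for r, f in zip(results, flags):
        r.significant_after_correction = bool(f)
    return results


# ---------------------------------------------------------------------------
# gametic disequilibrium
# ---------------------------------------------------------------------------

def _g_statistic(codes_x: np.ndarray, codes_y: np.ndarray, nx: int, ny: int) -> float:
    obs = np.bincount(codes_x * ny + codes_y, minlength=nx * ny).reshape(nx, ny)
    total = obs.sum()
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expect = row * col / total
    mask = obs > 0
    return float(2.0 * np.sum(obs[mask] * np.log(obs[mask] / expect[mask])))


def ld_exact_test(
    gm: GenotypeMatrix,
    population: str | None,
    locus_pair: tuple,
    permutations: int = 10_000,
    seed=0,
) -> TestResult:
    """Permutation test for gametic disequilibrium between two loci.

    Statistic: G (log-likelihood ratio of association) on the two-locus
    genotype contingency table over individuals complete at both loci.
    Null distribution: one locus's genotypes shuffled between individuals.
    """
    la, lb = locus_pair
    ia = gm.locus_names.index(la) if isinstance(la, str) else la
    ib = gm.locus_names.index(lb) if isinstance(lb, str) else lb
    name = f"{gm.locus_names[ia]}x{gm.locus_names[ib]}"
    sub = gm if population is None else gm.subset_population(population)
    ga = np.sort(sub.alleles[:, ia, :], axis=1)
    gb = np.sort(sub.alleles[:, ib, :], axis=1)
    keep = (ga[:, 0] != MISSING) & (gb[:, 0] != MISSING)
    ga, gb = ga[keep], gb[keep]

    def encode(g):
        _, inv = np.unique(g, axis=0, return_inverse=True)
        return inv, int(inv.max()) + 1

    ca, na = encode(ga)
    cb, nb = encode(gb)
    if na < 2 or nb < 2:
        return TestResult(name, 1.0, 0.0, note="monomorphic locus in pair")

    rng = np.random.default_rng(seed)
    g_obs = _g_statistic(ca, cb, na, nb)
    count = 0
    for _ in range(permutations):
        perm = rng.permutation(cb)
        if _g_statistic(ca, perm, na, nb) >= g_obs - 1e-12:
            count += 1
    p = (1 + count) / (permutations + 1)
    mc_error = math.sqrt(p * (1 - p) / permutations)
    return TestResult(name, float(p), float(mc_error), statistic=g_obs)


# ---------------------------------------------------------------------------
# multiple testing and null alleles
# ---------------------------------------------------------------------------

def bonferroni_adjust(p_values, alpha: float = 0.05) -> tuple[np.ndarray, float]:
    """Bonferroni: significant iff p < alpha / m.  Returns (flags, threshold)."""
    p = np.asarray(p_values, dtype=float)
    if p.size < 1:
        raise ValueError("need at least one p-value")
    threshold = alpha / p.size
    return p < threshold, threshold


def null_allele_estimate(
    gm: GenotypeMatrix, population: str | None, locus
) -> float:
    """Brookfield-1 null-allele frequency estimate r = (He - Ho) / (1 + He),
    floored at zero.  He is the unbiased expected heterozygosity at the
    locus, Ho the observed."""
    if isinstance(locus, str):
        locus = gm.locus_names.index(locus)
    sub = gm if population is None else gm.subset_population(population)
    col = sub.alleles[:, locus, :]
    keep = col[:, 0] != MISSING
    n = int(keep.sum())
    if n == 0:
        return np.nan
    ho = float(np.mean(col[keep, 0] != col[keep, 1]))
    _, cnt = np.unique(col[keep].ravel(), return_counts=True)
    p = cnt / (2 * n)
    he = (2 * n) / (2 * n - 1) * (1.0 - float(np.sum(p**2)))
    return max(0.0, (he - ho) / (1.0 + he))
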