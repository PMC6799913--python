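"""HWE exact test vs enumeration oracle, LD permutation test, Bonferroni,
null-allele screen."""

import numpy as np
import pytest

import admixkit as ak
from admixkit.equilibrium import (
    bonferroni_adjust,
    hwe_enumeration_biallelic,
    hwe_exact_test,
    ld_exact_test,
    null_allele_estimate,
)
from admixkit.io_formats import MISSING

from conftest import make_gm


def _biallelic_gm(n11, n12, n22):
    genos = (
        [[[1, 1]]] * n11 + [[[1, 2]]] * n12 + [[[2, 2]]] * n22
    )
    return make_gm(genos)


def test_monomorphic_locus_gives_p_one():
    gm = make_gm([[[1, 1]]] * 5)
    res = hwe_exact_test(gm, None, 0, chain_length=100, dememorization=10)
    assert res.p_value == 1.0
    assert "monomorphic" in res.note


def test_hwe_requires_three_individuals():
    gm = make_gm([[[1, 2]], [[1, 2]]])
    with pytest.raises(ValueError, match=">= 3"):
        hwe_exact_test(gm, None, 0)


def test_enumeration_perfect_hwe_table_not_extreme():
    """A table at exact HWE proportions sits at the mode of the Levene
    distribution, so its exact p is large."""
    assert hwe_enumeration_biallelic(2, 4, 2) > 0.5
    assert hwe_enumeration_biallelic(4, 0, 4) < 0.05  # no heterozygotes


def test_enumeration_sums_full_distribution():
    # p over all tables with the same allele counts must total 1: check by
    # summing the probabilities of each achievable heterozygote count
    import math

    n11, n12, n22 = 3, 2, 3
    nA = 2 * n11 + n12
    n = n11 + n12 + n22
    hs = [h for h in range(min(nA, 2 * n - nA) + 1) if (nA - h) % 2 == 0]
    logs = []
    for h in hs:
        a = (nA - h) // 2
        b = (2 * n - nA - h) // 2
        logs.append(
            -math.lgamma(a + 1) - math.lgamma(h + 1) - math.lgamma(b + 1)
            + h * math.log(2)
        )
    probs = np.exp(np.array(logs) - max(logs))
    probs /= probs.sum()
    assert probs.sum() == pytest.approx(1.0)


def test_mc_matches_enumeration_on_sample_tables():
    for (n11, n12, n22) in [(3, 1, 3), (2, 4, 2), (5, 0, 3), (1, 6, 1)]:
        gm = _biallelic_gm(n11, n12, n22)
        res = hwe_exact_test(
            gm, None, 0, chain_length=20_000, dememorization=2_000, seed=7
        )
        exact = hwe_enumeration_biallelic(n11, n12, n22)
        assert res.p_value == pytest.approx(exact, abs=max(3 * res.mc_error, 0.01))


def test_hwe_type_one_error_calibrated():
    """Under HWE sampling the exact test rejects at ~ the nominal rate."""
    rng = np.random.default_rng(42)
    n, n_loci = 50, 500
    rejections = 0
    for l in range(n_loci):
        p = rng.uniform(0.2, 0.8)
        gm = ak.sample_population([np.array([p, 1 - p])], n, seed=rng)
        res = hwe_exact_test(
            gm, None, 0, chain_length=4000, dememorization=1000, seed=l
        )
        rejections += res.p_value <= 0.05
    rate = rejections / n_loci
    assert 0.03 <= rate <= 0.07


def test_ld_duplicated_locus_maximally_significant():
    rng = np.random.default_rng(0)
    col = rng.integers(1, 4, (40, 2))
    gm = make_gm(np.stack([col, col], axis=1))
    res = ld_exact_test(gm, None, (0, 1), permutations=199, seed=1)
    assert res.p_value <= 1.0 / 200.0 + 1e-12


def test_ld_monomorphic_partner_p_one():
    rng = np.random.default_rng(0)
    col = rng.integers(1, 4, (20, 2))
    mono = np.ones((20, 2), dtype=np.int64)
    gm = make_gm(np.stack([col, mono], axis=1))
    res = ld_exact_test(gm, None, (0, 1), permutations=99)
    assert res.p_value == 1.0


def test_ld_invariant_to_individual_reordering():
    gm = ak.sample_population([np.array([0.5, 0.5])] * 2, 40, seed=5)
    res1 = ld_exact_test(gm, None, (0, 1), permutations=499, seed=3)
    perm = np.random.default_rng(1).permutation(gm.n_individuals)
    res2 = ld_exact_test(gm.subset(perm), None, (0, 1), permutations=499, seed=3)
    assert res1.statistic == pytest.approx(res2.statistic)


def test_ld_null_p_values_uniform():
    """On independently simulated loci the permutation p-value is uniform
    (KS test over 200 replicates)."""
    from scipy import stats

    rng = np.random.default_rng(10)
    ps = []
    for _ in range(200):
        gm = ak.sample_population(
            [np.array([0.5, 0.3, 0.2]), np.array([0.6, 0.4])], 50, seed=rng
        )
        ps.append(ld_exact_test(gm, None, (0, 1), permutations=99, seed=rng.integers(2**31)).p_value)
    ks = stats.kstest(ps, "uniform")
    assert ks.pvalue > 0.001


def test_bonferroni_threshold_and_flags():
    flags, t = bonferroni_adjust([0.04], alpha=0.05)
    assert t == pytest.approx(0.05)
    assert flags.tolist() == [True]
    flags, t = bonferroni_adjust([0.001] + [0.5] * 26, alpha=0.05)
    assert t == pytest.approx(0.05 / 27)
    assert flags.sum() == 1
    flags, _ = bonferroni_adjust([0.01, 0.02, 0.03], alpha=0.05)
    assert flags.sum() == 1  # only p < 0.05/3 = 0.0167


def test_null_allele_estimator():
    # Ho == He -> 0; He 0.6 / Ho 0.4 -> 0.125; floored when Ho > He
    gm = make_gm([[[1, 2]], [[1, 2]], [[1, 1]], [[2, 2]]])
    he = ak.unbiased_heterozygosity(gm)
    ho = ak.observed_heterozygosity(gm)
    r = null_allele_estimate(gm, None, 0)
    assert r == pytest.approx(max(0.0, (he - ho) / (1 + he)))
    assert (0.6 - 0.4) / 1.6 == pytest.approx(0.125)
    all_het = make_gm([[[1, 2]], [[1, 2]], [[1, 2]]])
    assert null_allele_estimate(all_het, None, 0) == 0.0
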