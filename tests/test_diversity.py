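"""Diversity panel: hand-computed examples and enumeration oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import admixkit as ak
from admixkit.diversity import (
    allelic_richness,
    inbreeding_fis,
    mean_alleles_per_locus,
    observed_heterozygosity,
    private_alleles,
    probability_of_identity,
    rarefied_allele_count,
    relatedness_mxy,
    relatedness_reference_test,
    unbiased_heterozygosity,
)
from admixkit.io_formats import MISSING

from conftest import make_gm


def test_mean_alleles_hand_count():
    # locus 1: alleles {1,2,3}; locus 2: alleles {1..5}
    gm = make_gm(
        [
            [[1, 2], [1, 2]],
            [[3, 3], [3, 4]],
            [[1, 1], [5, 5]],
        ]
    )
    assert mean_alleles_per_locus(gm) == pytest.approx(4.0)


def test_mean_alleles_monomorphic_panel():
    gm = make_gm([[[2, 2], [7, 7]], [[2, 2], [7, 7]]])
    assert mean_alleles_per_locus(gm) == pytest.approx(1.0)


def test_allelic_richness_hand_value():
    """Counts {6, 2} at 2n = 8 rarefied to g = 4:
    AR = (1 - C(2,4)/C(8,4)) + (1 - C(6,4)/C(8,4)) = 1 + (1 - 15/70)."""
    assert rarefied_allele_count(np.array([6, 2]), 4) == pytest.approx(
        1.0 + (1.0 - 15.0 / 70.0)
    )


def test_allelic_richness_full_sample_equals_allele_count():
    gm = make_gm([[[1, 2]], [[3, 1]]])
    per_locus, mean = allelic_richness(gm, g=4)
    assert per_locus[0] == pytest.approx(3.0)
    assert mean == pytest.approx(3.0)


@settings(max_examples=50, deadline=None)
@given(
    counts=st.lists(st.integers(1, 10), min_size=2, max_size=6),
    g=st.integers(2, 6),
)
def test_allelic_richness_monotone_in_g(counts, g):
    total = sum(counts)
    if g + 1 > total:
        return
    c = np.array(counts)
    assert rarefied_allele_count(c, g + 1) >= rarefied_allele_count(c, g) - 1e-12


def test_observed_heterozygosity_hand_count():
    gm = make_gm(
        [[[1, 2]], [[1, 2]], [[1, 1]], [[MISSING, MISSING]]]
    )
    assert observed_heterozygosity(gm) == pytest.approx(2.0 / 3.0)


def test_observed_heterozygosity_all_homozygous():
    gm = make_gm([[[1, 1]], [[2, 2]]])
    assert observed_heterozygosity(gm) == 0.0


def test_unbiased_heterozygosity_hand_value():
    """n=2 with gene copies {A,A,B,B}: (4/3)(1 - 0.5) = 2/3."""
    gm = make_gm([[[1, 1]], [[2, 2]]])
    assert unbiased_heterozygosity(gm) == pytest.approx(2.0 / 3.0)


def test_unbiased_heterozygosity_monomorphic_is_zero():
    gm = make_gm([[[1, 1]], [[1, 1]]])
    assert unbiased_heterozygosity(gm) == 0.0


def test_unbiased_exceeds_raw_gene_diversity():
    rng = np.random.default_rng(0)
    a = rng.integers(1, 5, size=(10, 4, 2))
    gm = make_gm(a)
    hz = unbiased_heterozygosity(gm)
    raw = []
    for l in range(4):
        _, cnt = np.unique(a[:, l, :], return_counts=True)
        p = cnt / cnt.sum()
        raw.append(1 - np.sum(p**2))
    assert hz >= np.mean(raw)


def test_private_alleles_set_difference():
    gm = make_gm(
        [[[1, 2]], [[1, 1]], [[2, 3]], [[2, 2]]],
        pops=["x", "x", "y", "y"],
    )
    counts, table = private_alleles(gm, ("x", "y"))
    assert counts == {"x": 1, "y": 1}
    assert set(zip(table["population"], table["allele"])) == {("x", 1), ("y", 3)}


def test_private_alleles_identical_sets():
    gm = make_gm([[[1, 2]], [[1, 2]]], pops=["x", "y"])
    counts, table = private_alleles(gm, ("x", "y"))
    assert counts == {"x": 0, "y": 0}
    assert table.empty


def test_fis_hand_values():
    gm = make_gm([[[1, 2]], [[1, 2]]])
    assert inbreeding_fis(gm) == pytest.approx((2 / 3 - 1.0) / (2 / 3))
    assert inbreeding_fis(gm) < 0  # heterozygote excess
    # Ho = 0.57, Hz = 0.605 -> F = 0.0579 (ratio of multilocus means)
    assert (0.605 - 0.57) / 0.605 == pytest.approx(0.0579, abs=1e-4)


def test_fis_zero_when_ho_equals_hz():
    # 2 individuals, copies {A,A,B,B}, both heterozygous: Ho=1, Hz=2/3
    gm = make_gm([[[1, 1]], [[1, 2]], [[2, 2]], [[1, 2]]])
    ho = observed_heterozygosity(gm)
    hz = unbiased_heterozygosity(gm)
    assert inbreeding_fis(gm) == pytest.approx((hz - ho) / hz)


def test_fis_near_zero_under_hwe_sampling():
    gm = ak.sample_population(
        [np.array([0.4, 0.3, 0.2, 0.1])] * 10, 5000, seed=17
    )
    assert abs(inbreeding_fis(gm)) < 0.02


def _pid_enumeration(p):
    """Brute force: sum over ordered genotype pairs of P(both draws give
    the same unordered genotype)."""
    m = len(p)
    total = 0.0
    for a, b in itertools.product(range(m), repeat=2):
        if a == b:
            total += (p[a] * p[b]) ** 2
        elif a < b:
            total += (2 * p[a] * p[b]) ** 2
    return total


def test_pid_single_allele_locus():
    per_locus, combined = probability_of_identity([np.array([1.0])])
    assert per_locus[0] == pytest.approx(1.0)
    assert combined == pytest.approx(1.0)


def test_pid_biallelic_half():
    per_locus, _ = probability_of_identity([np.array([0.5, 0.5])])
    assert per_locus[0] == pytest.approx(0.375)
    assert per_locus[0] == pytest.approx(_pid_enumeration([0.5, 0.5]))


@settings(max_examples=50, deadline=None)
@given(
    raw=st.lists(st.floats(0.05, 1.0), min_size=2, max_size=4),
)
def test_pid_formula_matches_enumeration(raw):
    p = np.array(raw) / np.sum(raw)
    per_locus, _ = probability_of_identity([p])
    assert per_locus[0] == pytest.approx(_pid_enumeration(p), rel=1e-9)


def test_pid_combined_is_product():
    vecs = [np.array([0.5, 0.5]), np.array([0.9, 0.1])]
    per_locus, combined = probability_of_identity(vecs)
    assert combined == pytest.approx(np.prod(per_locus))


def test_mxy_sharing_rules():
    x = np.array([[1, 2]])
    assert relatedness_mxy(x, np.array([[1, 2]])) == 1.0
    assert relatedness_mxy(x, np.array([[1, 3]])) == 0.5
    assert relatedness_mxy(np.array([[1, 1]]), np.array([[2, 2]])) == 0.0
    assert relatedness_mxy(np.array([[1, 1]]), np.array([[1, 2]])) == 0.5


def test_mxy_symmetric_and_missing_skipped():
    rng = np.random.default_rng(1)
    x = rng.integers(1, 4, (8, 2))
    y = rng.integers(1, 4, (8, 2))
    assert relatedness_mxy(x, y) == relatedness_mxy(y, x)
    xm = x.copy()
    xm[0] = MISSING
    assert relatedness_mxy(xm, y) == relatedness_mxy(x[1:], y[1:])


def test_relatedness_reference_ordering(parental_pair):
    """Simulated pedigrees order full sib > half sib > unrelated."""
    res = relatedness_reference_test(parental_pair, "A", n_sim_pairs=500, seed=9)
    m = res.reference_means
    assert m["full_sib"] > m["half_sib"] > m["unrelated"]


def test_relatedness_clone_population_extreme():
    base = np.array([[1, 2], [3, 4], [5, 6]])
    gm = make_gm(np.tile(base[None, :, :], (6, 1, 1)))
    res = relatedness_reference_test(gm, None, n_sim_pairs=200, seed=2)
    assert res.observed_mean == pytest.approx(1.0)
    assert res.p_values["unrelated"] < 1e-6


def test_relatedness_unrelated_self_consistency():
    gm = ak.sample_population([np.array([0.25] * 4)] * 20, 40, seed=3)
    res = relatedness_reference_test(gm, None, n_sim_pairs=800, seed=4)
    ref = res.reference_means["unrelated"]
    assert res.observed_mean == pytest.approx(ref, abs=0.05)
    assert res.p_values["full_sib"] < 1e-6
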