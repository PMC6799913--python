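"""Shared fixtures: tiny hand-built genotype matrices and one
session-scoped admixture run on the full simulated design (it is the
expensive object several acceptance checks need)."""

from __future__ import annotations

import numpy as np
import pytest

import admixkit as ak
from admixkit.io_formats import MISSING, GenotypeMatrix


def make_gm(genos, pops=None, ids=None, locus_names=None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from a nested list (n, L, 2) of allele codes."""
    a = np.asarray(genos, dtype=np.int64)
    n, L = a.shape[0], a.shape[1]
    return GenotypeMatrix(
        ids or [f"ind{i}" for i in range(n)],
        pops or ["pop1"] * n,
        locus_names or [f"L{j + 1}" for j in range(L)],
        a,
    )


@pytest.fixture
def two_pop_fixed() -> GenotypeMatrix:
    """Two populations fixed for different alleles at every one of 10 loci."""
    L, n = 10, 8
    a = np.ones((2 * n, L, 2), dtype=np.int64)
    a[n:] = 2
    return GenotypeMatrix(
        [f"i{i}" for i in range(2 * n)],
        ["A"] * n + ["B"] * n,
        [f"L{j}" for j in range(L)],
        a,
    )


@pytest.fixture(scope="session")
def parental_pair() -> GenotypeMatrix:
    """Study-like reference pair: 27 loci, 3-17 alleles, FST 0.165, 30+30."""
    return ak.simulate_parental_pair(seed=11)


@pytest.fixture(scope="session")
def design(parental_pair) -> ak.SimulatedDataset:
    """The default eight-class design (480 individuals, 60 per class)."""
    return ak.build_design(
        parental_pair.subset_population("A"),
        parental_pair.subset_population("B"),
        n_per_class=60,
        seed=12,
    )


@pytest.fixture(scope="session")
def design_admixture(design) -> ak.AdmixtureResult:
    """Scaled-down admixture run (K=2, 20k reps / 5k burn-in) on the full
    simulated design; shared because it is the expensive step."""
    return ak.run_mcmc(design.genotypes, K=2, reps=20_000, burnin=5_000, seed=13)
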