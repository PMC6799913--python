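"""Between-population differentiation: Weir–Cockerham theta, two-level
AMOVA with a permutation test, and genotype PCA.

Theta follows Weir & Cockerham (1984): per locus and allele, the a/b/c
variance components from sample sizes, allele frequencies and observed
heterozygote frequencies; the multilocus estimate is the ratio of sums
over loci and alleles.  AMOVA partitions allele-identity distances
(number of differing gene copies per locus genotype, summed over loci)
into among- and within-group components; Phi_ST = among / (among +
within), with significance from permuting individuals across groups.
PCA runs on the column-centred allele-dosage matrix (0/1/2 per
locus-allele column; missing entries imputed with the column mean).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA as _SkPCA

from .io_formats import MISSING, GenotypeMatrix


# ---------------------------------------------------------------------------
# Weir-Cockerham theta
# ---------------------------------------------------------------------------

def weir_cockerham_theta(gm: GenotypeMatrix, populations: list[str]) -> float:
    """Multilocus Weir–Cockerham theta over ``r >= 2`` populations
    (ratio of summed variance components over loci and alleles)."""
    if len(populations) < 2:
        raise ValueError("need at least two populations")
    subs = [gm.subset_population(p) for p in populations]
    r = len(subs)
    num = 0.0
    den = 0.0
    for l in range(gm.n_loci):
        cols = [s.alleles[:, l, :] for s in subs]
        cols = [c[c[:, 0] != MISSING] for c in cols]
        n_i = np.array([len(c) for c in cols], dtype=float)
        if (n_i == 0).any():
            warnings.warn(
                f"locus {gm.locus_names[l]}: no data in some population; skipped"
            )
            continue
        alleles = np.unique(np.concatenate([c.ravel() for c in cols]))
        if alleles.size < 2:
            continue
        nbar = n_i.mean()
        if nbar <= 1:
            continue
        nc = (r * nbar - np.sum(n_i**2) / (r * nbar)) / (r - 1)
        for a in alleles:
            p_i = np.array([np.mean(c == a) for c in cols])
            h_i = np.array(
                [np.mean((c[:, 0] == a) != (c[:, 1] == a)) for c in cols]
            )
            pbar = np.sum(n_i * p_i) / (r * nbar)
            s2 = np.sum(n_i * (p_i - pbar) ** 2) / ((r - 1) * nbar)
            hbar = np.sum(n_i * h_i) / (r * nbar)
            a_comp = (nbar / nc) * (
                s2
                - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
            )
            b_comp = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar)
                - s2 * (r - 1) / r
                - hbar * (2 * nbar - 1) / (4 * nbar)
            )
            c_comp = hbar / 2
            num += a_comp
            den += a_comp + b_comp + c_comp
    if den == 0.0:
        return np.nan
    return float(num / den)


def pairwise_fst(gm: GenotypeMatrix, pop_a: str, pop_b: str) -> float:
    """Two-population multilocus Weir–Cockerham theta."""
    for p in (pop_a, pop_b):
        if len(gm.population_indices(p)) < 2:
            raise ValueError(f"population {p!r} needs >= 2 individuals")
    return weir_cockerham_theta(gm, [pop_a, pop_b])


def pairwise_fst_matrix(gm: GenotypeMatrix) -> pd.DataFrame:
    """Symmetric pairwise theta matrix over all populations (zero diagonal)."""
    pops = gm.populations()
    out = np.zeros((len(pops), len(pops)))
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            out[i, j] = out[j, i] = pairwise_fst(gm, pops[i], pops[j])
    return pd.DataFrame(out, index=pops, columns=pops)


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

@dataclass
class DifferentiationResult:
    """Two-level AMOVA summary."""

    phi_st: float
    var_among: float
    var_within: float
    p_value: float
    permutations: int
    note: str = ""


def _amova_components(
    allele_idx: list[np.ndarray],
    present: np.ndarray,
    group_ids: np.ndarray,
    n_groups: int,
) -> tuple[float, float, float]:
    """Summed variance components over loci for a gene-copy AMOVA.

    Each non-missing gene copy is one observation; the distance between
    copies is 0/1 allele identity, so sums of squares reduce to allele
    counts: sum_{i<j} d = C(N,2) - sum_a C(c_a,2).
    """
    var_a = 0.0
    var_w = 0.0
    for l, idx in enumerate(allele_idx):
        keep = present[:, l]
        if not keep.any():
            continue
        g = np.repeat(group_ids[keep], 2)
        a = idx[keep].ravel()
        m = int(a.max()) + 1
        c_ga = np.bincount(g * m + a, minlength=n_groups * m).reshape(n_groups, m)
        n_g = c_ga.sum(axis=1)
        live = n_g > 0
        if live.sum() < 2:
            continue
        c_a = c_ga.sum(axis=0)
        N = int(n_g.sum())
        pairs = lambda x: x * (x - 1) / 2.0
        ss_total = (pairs(N) - pairs(c_a).sum()) / N
        with np.errstate(invalid="ignore", divide="ignore"):
            per_group = pairs(n_g) - pairs(c_ga).sum(axis=1)
            ss_within = float(np.sum(per_group[live] / n_g[live]))
        g_count = int(live.sum())
        df_among = g_count - 1
        df_within = N - g_count
        if df_within < 1:
            continue
        ms_among = (ss_total - ss_within) / df_among
        ms_within = ss_within / df_within
        n0 = (N - np.sum(n_g[live] ** 2) / N) / df_among
        var_w += ms_within
        var_a += (ms_among - ms_within) / n0
    total = var_a + var_w
    phi = var_a / total if total != 0 else np.nan
    return phi, var_a, var_w


def amova(
    gm: GenotypeMatrix,
    grouping: list[str] | None = None,
    permutations: int = 1000,
    seed=0,
) -> DifferentiationResult:
    """Two-level AMOVA with permutation p-value.

    Gene copies are the observation unit with 0/1 allele-identity
    distances (the Arlequin-comparable FST AMOVA); variance components are
    summed over loci and Phi_ST = among / (among + within).  ``grouping``
    defaults to the matrix's population labels.  The permutation unit is
    the individual (both gene copies move together).  A negative
    among-group component is reported as-is (standard behaviour for
    near-zero differentiation), with a note.
    """
    groups = np.asarray(grouping if grouping is not None else gm.population_labels)
    labels, group_ids = np.unique(groups, return_inverse=True)
    if labels.size < 2:
        raise ValueError("need at least two groups")
    present = gm.alleles[:, :, 0] != MISSING
    allele_idx = []
    for l in range(gm.n_loci):
        col = gm.alleles[:, l, :]
        codes = np.unique(col[present[:, l]]) if present[:, l].any() else np.array([1])
        idx = np.searchsorted(codes, np.clip(col, codes[0], None))
        allele_idx.append(np.minimum(idx, codes.size - 1))
    phi, va, vw = _amova_components(allele_idx, present, group_ids, labels.size)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(permutations):
        perm = rng.permutation(group_ids)
        phi_p, _, _ = _amova_components(allele_idx, present, perm, labels.size)
        if phi_p >= phi - 1e-12:
            count += 1
    p = (1 + count) / (permutations + 1)
    note = "negative among-group variance component" if va < 0 else ""
    return DifferentiationResult(
        float(phi), float(va), float(vw), float(p), permutations, note
    )


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PcaResult:
    coordinates: np.ndarray        # (n_individuals, n_axes)
    percent_variance: np.ndarray   # per axis
    individual_ids: list[str]


def dosage_matrix(gm: GenotypeMatrix) -> tuple[np.ndarray, list[str]]:
    """Allele-dosage design matrix: one 0/1/2 column per (locus, allele),
    missing genotypes imputed with the column mean."""
    cols = []
    names = []
    for l, locus in enumerate(gm.locus_names):
        a = gm.alleles[:, l, :]
        present = a[:, 0] != MISSING
        codes = np.unique(a[present])
        for code in codes:
            dose = (a == code).sum(axis=1).astype(float)
            if present.all():
                col = dose
            else:
                mean = dose[present].mean() if present.any() else 0.0
                col = np.where(present, dose, mean)
            cols.append(col)
            names.append(f"{locus}:{code}")
    X = np.column_stack(cols) if cols else np.zeros((gm.n_individuals, 0))
    return X, names


def pca(gm: GenotypeMatrix, n_axes: int | None = None) -> PcaResult:
    """Genotype PCA on the centred dosage matrix."""
    if gm.n_individuals < 2:
        raise ValueError("PCA needs >= 2 individuals")
    X, _ = dosage_matrix(gm)
    keep = X.std(axis=0) > 0
    X = X[:, keep]
    k = min(gm.n_individuals - 1, X.shape[1])
    if n_axes is not None:
        k = min(k, n_axes)
    model = _SkPCA(n_components=k, svd_solver="full")
    coords = model.fit_transform(X - X.mean(axis=0))
    return PcaResult(
        coordinates=coords,
        percent_variance=model.explained_variance_ratio_ * 100.0,
        individual_ids=list(gm.individual_ids),
    )
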