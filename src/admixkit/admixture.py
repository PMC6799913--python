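"""Bayesian clustering with admixture for multi-allelic co-dominant data.

A from-scratch Gibbs sampler for the admixture model: each individual i
has a membership vector q_i on the K-simplex, each gene copy an origin
z ~ Categorical(q_i), and each cluster k per-locus allele frequencies
p_kl.  Conditionals:

* z for copy (i, l, c) with allele a:  Pr(z = k) ∝ q_ik · p_kla
* q_i | z ~ Dirichlet(alpha + per-cluster copy counts of i)
* p_kl | z ~ Dirichlet(prior + per-allele copy counts), where the prior is
  lambda (independent-frequencies model) or p_ancestral,l · (1 - F_k)/F_k
  (correlated-frequencies model, the drift parameterisation in which each
  cluster's frequencies are a Balding–Nichols perturbation of a shared
  ancestral vector with drift F_k).
* alpha, F_k and the ancestral frequencies are updated by Metropolis
  steps (uniform(0, 10) prior on alpha; uniform(0, 1) on F_k; Dirichlet
  (lambda) on the ancestral vector).

Missing genotypes are skipped in the likelihood and in all count vectors.
Reported Q and P are posterior means over post-burn-in thinned samples.
Model-order selection uses the harmonic estimator of ln Pr(X|K)
(mean minus half the variance of the data log-likelihood trace) and the
Evanno second-difference statistic; replicate Q matrices are aligned by
exhaustive label-permutation search maximising the G' similarity.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io_formats import MISSING, GenotypeMatrix


@dataclass
class AdmixtureResult:
    """Posterior summaries of one MCMC run."""

    Q: np.ndarray                       # (n, K) posterior-mean memberships
    P: list[np.ndarray]                 # per locus: (K, n_alleles) frequencies
    allele_codes: list[np.ndarray]      # allele codes matching P columns
    lnL_trace: np.ndarray               # post-burn-in data log-likelihoods
    ln_prob_data: float
    alpha: float
    F: np.ndarray                       # (K,) drift parameters (correlated)
    settings: dict = field(default_factory=dict)
    individual_ids: list[str] = field(default_factory=list)

    def q_table(self, population_labels=None) -> pd.DataFrame:
        cols = {f"q_{k + 1}": self.Q[:, k] for k in range(self.Q.shape[1])}
        data = {"individual_id": self.individual_ids}
        if population_labels is not None:
            data["population"] = list(population_labels)
        data.update(cols)
        return pd.DataFrame(data)


def _encode(gm: GenotypeMatrix):
    """Per-locus allele indexing plus a padded (n, L, 2) index array."""
    n, L = gm.n_individuals, gm.n_loci
    codes = []
    sizes = np.zeros(L, dtype=int)
    a_idx = np.zeros((n, L, 2), dtype=np.int64)
    valid = gm.alleles[:, :, 0] != MISSING
    for l in range(L):
        col = gm.alleles[:, l, :]
        obs = col[col[:, 0] != MISSING]
        cl = np.unique(obs) if obs.size else np.array([1])
        codes.append(cl)
        sizes[l] = cl.size
        idx = np.searchsorted(cl, col)
        idx[~valid[:, l]] = 0
        a_idx[:, l, :] = idx
    return codes, sizes, a_idx, np.repeat(valid[:, :, None], 2, axis=2)


def _log_dirichlet(x: np.ndarray, a: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Row-wise log Dirichlet density over the masked support.

    ``x``, ``a``, ``mask`` have shape (..., M); returns shape (...).
    """
    lx = np.log(np.maximum(x, 1e-300))
    am = np.where(mask, a, 0.0)
    term = np.where(mask, (am - 1.0) * lx - gammaln(np.maximum(am, 1e-300)), 0.0)
    return gammaln(am.sum(-1)) + term.sum(-1)


def run_mcmc(
    gm: GenotypeMatrix,
    K: int,
    reps: int = 700_000,
    burnin: int = 200_000,
    seed: int = 0,
    model: str = "correlated",
    thin: int = 10,
    alpha0: float = 1.0,
    lambda_: float = 1.0,
    alpha_max: float = 10.0,
    alpha_proposal_sd: float = 0.05,
    f_proposal_sd: float = 0.05,
    ancestral_proposal_concentration: float = 100.0,
) -> AdmixtureResult:
    """Run the admixture Gibbs sampler.

    ``reps`` is the total sweep count including ``burnin`` sweeps that are
    discarded; the data log-likelihood is recorded (and Q/P accumulated)
    every ``thin`` sweeps after burn-in.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if reps <= 0 or not reps > burnin or burnin < 0:
        raise ValueError("need reps > burnin >= 0")
    if model not in ("correlated", "independent"):
        raise ValueError(f"unknown model {model!r}")
    if K > gm.n_individuals:
        import warnings

        warnings.warn(
            f"K={K} exceeds the number of individuals ({gm.n_individuals}); "
            "the extra clusters cannot be populated"
        )

    rng = np.random.default_rng(seed)
    n, L = gm.n_individuals, gm.n_loci
    codes, sizes, a_idx, valid = _encode(gm)
    M = int(sizes.max())
    a_idx = np.minimum(a_idx, M - 1)
    maskM = np.arange(M)[None, :] < sizes[:, None]      # (L, M) allele support
    l_idx = np.broadcast_to(np.arange(L)[None, :, None], (n, L, 2))
    i_idx = np.broadcast_to(np.arange(n)[:, None, None], (n, L, 2))
    vflat = valid.ravel()
    a_flat = a_idx.ravel()
    l_flat = l_idx.ravel()
    i_flat = i_idx.ravel()

    # initial state: ancestral = observed overall frequencies
    p_anc = np.zeros((L, M))
    for l in range(L):
        col = gm.alleles[:, l, :]
        obs = col[col[:, 0] != MISSING]
        cnt = np.array([(obs == c).sum() for c in codes[l]], dtype=float)
        p_anc[l, : sizes[l]] = (cnt + lambda_) / (cnt.sum() + lambda_ * sizes[l])
    P = np.where(maskM[None], p_anc[None], 0.0).repeat(K, axis=0).reshape(K, L, M)
    g0 = rng.gamma(np.where(maskM[None], 50.0 * P, 0.0))
    P = g0 / np.maximum(g0.sum(-1, keepdims=True), 1e-300)
    Q = np.full((n, K), 1.0 / K)
    F = np.full(K, 0.01)
    alpha = float(alpha0)
    log_qsum = None  # filled lazily for alpha updates

    Q_sum = np.zeros_like(Q)
    P_sum = np.zeros_like(P)
    n_samples = 0
    trace = []

    def gather_P():
        # (K, n, L, 2): cluster frequency of each observed gene copy
        return P[:, l_idx, a_idx]

    for sweep in range(reps):
        # --- z: origins of every gene copy ------------------------------
        W = Q.T[:, :, None, None] * gather_P() + 1e-300
        cum = np.cumsum(W, axis=0)
        u = rng.random((n, L, 2)) * cum[-1]
        z = (cum[:-1] < u[None]).sum(axis=0) if K > 1 else np.zeros((n, L, 2), int)

        z_flat = z.ravel()
        # --- allele counts per cluster/locus/allele ---------------------
        flat = (z_flat * L + l_flat) * M + a_flat
        C = np.bincount(flat[vflat], minlength=K * L * M).reshape(K, L, M).astype(float)
        # --- Q update ---------------------------------------------------
        r = np.bincount(
            i_flat[vflat] * K + z_flat[vflat], minlength=n * K
        ).reshape(n, K)
        gq = rng.gamma(alpha + r)
        Q = gq / np.maximum(gq.sum(1, keepdims=True), 1e-300)
        # --- P update ---------------------------------------------------
        if model == "correlated":
            drift = ((1.0 - F) / F)[:, None, None]
            prior = p_anc[None] * drift
        else:
            prior = lambda_
        shape = np.where(maskM[None], prior + C, 0.0)
        gp = rng.gamma(shape)
        tot = gp.sum(-1, keepdims=True)
        bad = tot[..., 0] <= 0
        if bad.any():
            gp[bad] = maskM[None].repeat(K, 0).reshape(K, L, M)[bad].astype(float)
            tot = gp.sum(-1, keepdims=True)
        P = gp / tot

        if model == "correlated":
            # --- ancestral frequencies: per-locus MH --------------------
            conc = ancestral_proposal_concentration
            s_fwd = np.where(maskM, conc * p_anc + 0.5, 0.0)
            gprop = rng.gamma(s_fwd)
            prop = gprop / np.maximum(gprop.sum(-1, keepdims=True), 1e-300)
            drift_k = (1.0 - F) / F  # (K,)

            def loglik_anc(x):
                # sum over clusters of log Dir(P_kl ; drift_k * x_l)
                a = drift_k[:, None, None] * x[None]
                return _log_dirichlet(P, a, maskM[None]).sum(0)

            s_rev = np.where(maskM, conc * prop + 0.5, 0.0)
            log_ratio = (
                loglik_anc(prop)
                - loglik_anc(p_anc)
                + _log_dirichlet(p_anc, s_rev, maskM)
                - _log_dirichlet(prop, s_fwd, maskM)
            )
            if lambda_ != 1.0:
                lp = np.log(np.maximum(prop, 1e-300))
                lc = np.log(np.maximum(p_anc, 1e-300))
                log_ratio += (lambda_ - 1.0) * np.where(maskM, lp - lc, 0.0).sum(-1)
            acc = np.log(rng.random(L)) < log_ratio
            p_anc = np.where(acc[:, None], prop, p_anc)

            # --- F_k: reflective MH on (0,1) ----------------------------
            fprop = F + rng.normal(0.0, f_proposal_sd, size=K)
            fprop = np.abs(fprop)
            fprop = np.where(fprop > 1.0, 2.0 - fprop, fprop)
            fprop = np.clip(fprop, 1e-6, 1.0 - 1e-6)
            a_cur = ((1.0 - F) / F)[:, None, None] * p_anc[None]
            a_new = ((1.0 - fprop) / fprop)[:, None, None] * p_anc[None]
            ll_cur = _log_dirichlet(P, a_cur, maskM[None]).sum(-1)
            ll_new = _log_dirichlet(P, a_new, maskM[None]).sum(-1)
            facc = np.log(rng.random(K)) < (ll_new - ll_cur)
            F = np.where(facc, fprop, F)

        # --- alpha: MH with uniform(0, alpha_max) prior -----------------
        if K > 1:
            aprop = alpha + rng.normal(0.0, alpha_proposal_sd)
            if 0.0 < aprop < alpha_max:
                log_qsum = np.log(np.maximum(Q, 1e-300)).sum()
                def alpha_ll(a):
                    return n * (gammaln(K * a) - K * gammaln(a)) + (a - 1.0) * log_qsum
                if np.log(rng.random()) < alpha_ll(aprop) - alpha_ll(alpha):
                    alpha = float(aprop)

        # --- record ------------------------------------------------------
        if sweep >= burnin and (sweep - burnin) % thin == 0:
            mix = (Q.T[:, :, None, None] * gather_P()).sum(0)
            lnL = float(np.log(np.maximum(mix, 1e-300))[valid].sum())
            trace.append(lnL)
            Q_sum += Q
            P_sum += P
            n_samples += 1

    Q_mean = Q_sum / n_samples
    P_mean = P_sum / n_samples
    P_list = [P_mean[:, l, : sizes[l]] for l in range(L)]
    P_list = [p / p.sum(1, keepdims=True) for p in P_list]
    trace = np.asarray(trace)
    return AdmixtureResult(
        Q=Q_mean / Q_mean.sum(1, keepdims=True),
        P=P_list,
        allele_codes=codes,
        lnL_trace=trace,
        ln_prob_data=ln_prob_data(trace) if trace.size >= 2 else float(trace[0]),
        alpha=alpha,
        F=F,
        settings={
            "K": K,
            "reps": reps,
            "burnin": burnin,
            "seed": seed,
            "model": model,
            "thin": thin,
        },
        individual_ids=list(gm.individual_ids),
    )


def ln_prob_data(lnL_trace) -> float:
    """Harmonic-style estimate of ln Pr(X|K): mean(trace) - var(trace)/2
    (sample variance, n-1 denominator)."""
    t = np.asarray(lnL_trace, dtype=float)
    if t.size < 2:
        raise ValueError("trace must have length >= 2")
    return float(t.mean() - t.var(ddof=1) / 2.0)


# ---------------------------------------------------------------------------
# model-order selection (Evanno delta-K)
# ---------------------------------------------------------------------------

@dataclass
class ModelSelection:
    table: pd.DataFrame      # K, mean_ln_prob, sd_ln_prob, delta_k
    best_k: int | None


def evanno_delta_k(ln_probs: dict[int, list[float]]) -> ModelSelection:
    """Evanno's second-difference statistic.

    ``ln_probs`` maps each K to its replicate ln Pr(X|K) values; K values
    must be consecutive and at least three, with >= 2 replicates each so
    the replicate sd is defined.  ``delta_k(K) = |L(K+1) - 2 L(K) +
    L(K-1)| / sd(K)`` on replicate means; the argmax over interior K is
    reported.
    """
    ks = sorted(ln_probs)
    if len(ks) < 3 or ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("need >= 3 consecutive K values")
    means = {k: float(np.mean(ln_probs[k])) for k in ks}
    sds = {k: float(np.std(ln_probs[k], ddof=1)) for k in ks}
    rows = []
    for k in ks:
        dk = np.nan
        if ks[0] < k < ks[-1]:
            second = abs(means[k + 1] - 2 * means[k] + means[k - 1])
            if sds[k] == 0:
                import warnings

                warnings.warn(f"sd of ln Pr at K={k} is 0; delta-K undefined")
            else:
                dk = second / sds[k]
        rows.append(
            {"K": k, "mean_ln_prob": means[k], "sd_ln_prob": sds[k], "delta_k": dk}
        )
    table = pd.DataFrame(rows)
    interior = table["delta_k"].dropna()
    best = int(table.loc[interior.idxmax(), "K"]) if interior.size else None
    return ModelSelection(table, best)


# ---------------------------------------------------------------------------
# replicate alignment (label switching across runs)
# ---------------------------------------------------------------------------

def _g_prime(q1: np.ndarray, q2: np.ndarray) -> float:
    """G' similarity: one minus the normalised mean absolute difference."""
    return 1.0 - float(np.abs(q1 - q2).mean())


def align_replicates(
    q_matrices: list[np.ndarray],
) -> tuple[list[np.ndarray], np.ndarray]:
    """Align cluster labels across replicate Q matrices by exhaustive
    permutation search (FullSearch) against the first replicate, then
    return the aligned matrices and their mean."""
    qs = [np.asarray(q, dtype=float) for q in q_matrices]
    shape = qs[0].shape
    if any(q.shape != shape for q in qs):
        raise ValueError("replicate Q matrices must share a shape")
    K = shape[1]
    if K > 8:
        raise ValueError(
            "exhaustive label search is impractical for K > 8; align greedily "
            "or reduce K"
        )
    ref = qs[0]
    aligned = [ref]
    for q in qs[1:]:
        best_perm = max(
            itertools.permutations(range(K)),
            key=lambda perm: _g_prime(ref, q[:, perm]),
        )
        aligned.append(q[:, best_perm])
    return aligned, np.mean(aligned, axis=0)
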