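# Methods

## The problem

Two diverged lineages of the same species come into secondary contact
(here: deliberately or accidentally mixed captive stocks), and managers
must decide from a co-dominant marker panel whether an animal is
non-admixed or carries introgressed ancestry.  A Bayesian clustering
analysis yields, per individual, a membership coefficient *q_i* toward
each cluster; the operational question is which cut-off *t* on *q_i*
separates "non-admixed" from "admixed" with acceptable error on every
hybrid class — and that question can only be answered on simulated
hybrids of known pedigree, because real datasets carry no ground truth.
`admixkit` implements the whole loop: simulate reference populations,
breed the hybrid classes, estimate memberships, and score thresholds.

## Synthetic parental populations

The generator emulates the statistical structure of a pair of reference
groups rather than any particular species' mutation process:

* **Ancestral frequencies.**  Per locus, the allele count is uniform on
  3–17 and frequencies are a symmetric Dirichlet(λ_c) draw.  Default
  concentration λ_c = 1.0 (a flat prior over the simplex).
* **Divergence.**  Each population's frequencies are
  Dirichlet(p_anc · (1 − F)/F), the Balding–Nichols construction, with
  F the target F_ST (default 0.165).  This gives
  Var(p) = F · p(1 − p), so the multilocus Weir–Cockerham θ between two
  sampled populations is centred on F.
* **Genotypes.**  Hardy–Weinberg sampling; both gene copies i.i.d. from
  the population frequencies.  Options: per-genotype missingness (both
  slots together), and an inbreeding parameter `f_is` that duplicates the
  first gene copy with that probability (inflating homozygosity the way
  a within-population F_IS does); both default 0.

Calibration of λ_c: for an m-allele locus, E[1 − Σp²] under
Dirichlet(λ_c) is (m − 1)λ_c/(mλ_c + 1), and Balding–Nichols drift
shrinks expected heterozygosity by (1 − F).  With λ_c = 1, allele counts
uniform on 3–17 and F = 0.165 this puts expected population-level
heterozygosity near 0.63–0.66, inside the 0.60–0.71 band typical of the
reference groups this generator emulates; realised values per simulated
population vary around that.  λ_c is exposed for users who need other
diversity levels.

Defaults (27 loci, 3–17 alleles, F = 0.165, n = 30 + 30) are the study
conditions every downstream default assumes.

What the generator does **not** model: within-population substructure,
linkage between loci, mutation (no stepwise model), genotyping artefacts
other than simple missingness.  Tests passing on this generator
demonstrate the machinery is correct under its assumptions, not that any
particular empirical dataset satisfies them.

## Hybrid-class simulation

From each reference sample, allele frequencies are estimated (counts
over non-missing gene copies).  Pure-class pools are HWE draws from
those frequencies; every hybrid class is produced by **Mendelian
crossing of explicit simulated parents**: each offspring picks one
parent uniformly (with replacement — pool sizes are small and the
crossing software this emulates does not document its scheme) from each
pool and inherits one uniformly chosen gene copy per locus from each.
The eight classes are pure A, pure B, F1 = A×B, F2 = F1×F1, BC_A =
F1×A, BC_B = F1×B, BC2_A = BC_A×A, BC2_B = BC_B×B; default 60 each
(480 genotypes), no missing data.

Crossing real simulated parents (rather than redrawing from class-level
frequency tables) matters because the between-individual variance of
ancestry in F2 and backcross classes comes from Mendelian segregation
within pedigrees — exactly the variance that makes backcrosses hard to
detect.  With `track_ancestry=True` every gene copy carries a provenance
tag, so each individual's true pool-A ancestry fraction is known; class
means follow the pedigree expectations (1, 0, ½, ½, ¾, ¼, ⅞, ⅛) with
the appropriate segregation spread (F1 has none; F2/backcrosses do).

## The admixture model and sampler

The model is the standard admixture model for unlinked co-dominant loci
with the correlated-allele-frequencies extension.  Latent variables:
origins z for every gene copy, memberships Q (n × K), cluster
frequencies P (K × locus × allele), plus hyperparameters α (Dirichlet
parameter of Q rows), per-cluster drift F_k and ancestral frequencies
p_anc (correlated model).  One sweep:

1. z | Q, P — independent categorical draws,
   Pr(z = k) ∝ q_ik · p_k,l,a; missing copies excluded everywhere.
2. Q | z — rows Dirichlet(α + per-cluster copy counts).
3. P | z — rows Dirichlet(prior + per-allele counts); prior is λ = 1
   (independent model) or p_anc,l (1 − F_k)/F_k (correlated model).
4. p_anc — per-locus Metropolis–Hastings with a
   Dirichlet(c · p_anc + 0.5) proposal (c = 100; the +0.5 keeps reverse
   densities finite near the simplex boundary), target the product of
   the K cluster-frequency Dirichlet likelihoods times a Dirichlet(λ)
   prior.
5. F_k — reflective normal proposal (sd 0.05) on (0, 1), uniform prior.
   The prior on F_k is the one genuinely under-determined choice; with
   hundreds of individuals the likelihood dominates, and the sampler
   recovers F near the generator's divergence in calibration runs.
6. α — normal proposal (sd 0.05), uniform(0, 10) prior (one symmetric α).

Everything is vectorised over individuals, loci and copies; a sweep on
480 × 27 diploids takes ~2.5 ms, so the scaled-down defaults below run
in under a minute.  The sampler is replay-deterministic given (seed, K,
reps, burnin, model).

Reported quantities: posterior-mean Q and P over post-burn-in samples
thinned every 10 sweeps; the data log-likelihood trace at the same
points; ln Pr(X|K) estimated as mean(trace) − var(trace)/2.  Label
switching within a chain is left to the across-replicate aligner — on
informative data K = 2 chains essentially never switch; the aligner does
an exhaustive search over the K! column permutations maximising the G′
similarity (1 − mean |ΔQ|) to the first replicate and refuses K > 8.

**Chain lengths.**  Library defaults are the conventional long runs
(700,000 sweeps, 200,000 burn-in, 5 replicates).  The package's own
tests, examples and acceptance script run 20,000/5,000 with 1–3
replicates: with ≤ 480 individuals and 27 loci the posterior is simple
enough that longer chains change posterior-mean q_i by less than the
Monte-Carlo noise between replicate seeds, and the scaled-down setting
is part of the package's stated study conditions.

**K = 1** degenerates cleanly (every q_i exactly 1).  Model order is
chosen by Evanno's ΔK = |L(K+1) − 2L(K) + L(K−1)| / sd(K) on replicate
means (sd with n−1 denominator); ΔK is undefined at the scan edges and
where the replicate sd is zero (flagged, not fabricated).

## Threshold calibration

Classification rule (strict, following the *q_i* > t convention):
non-admixed toward a cluster iff its q_i strictly exceeds t; a value
exactly at the threshold is admixed.  Thresholds must lie in (0.5, 1).
Misassignment: pure classes err when called admixed **or** pure of the
wrong cluster; hybrid classes err when called non-admixed of either
cluster.  For any fixed Q these curves are monotone in t (pure
non-decreasing, hybrid non-increasing), which is the crossing structure
that forces a compromise threshold.

Selection rule: the **largest** candidate threshold at which pure, F1
and F2 misassignment are all exactly 0% — maximising backcross
detection subject to zero error on the classes the panel can separate;
if no candidate qualifies, the threshold minimising their summed error,
ties to the lower threshold.  The default grid is
{0.80, 0.85, 0.90, 0.95}; a step parameter turns it into a dense sweep
for plotting.

Membership coefficients for the simulated design are estimated by
running the sampler on the **whole 480-individual dataset at K = 2**
(the simulated pure classes anchor the clusters), not per-individual
against fixed references.

## Diversity, equilibrium and differentiation panel

* **A** — mean distinct non-missing alleles per locus.
* **AR** — rarefaction to g gene copies:
  Σ_i [1 − C(2n − N_i, g)/C(2n, g)]; g defaults to the smallest
  per-locus copy count; AR(g = 2n) equals the raw allele count and AR is
  non-decreasing in g.
* **Ho / Hz** — observed heterozygote fraction; Nei's unbiased expected
  heterozygosity (2n/(2n−1))(1 − Σp²); locus means.
* **F_IS** — (Hz − Ho)/Hz.  Default on multilocus means
  (ratio-of-means); a mean-of-ratios mode averages per-locus F instead.
  The two disagree on real data whenever diversity varies across loci,
  and published tables do not always say which was used — hence both.
* **Private alleles** — set difference of observed alleles between two
  populations, with the holder's frequency.
* **PID** — per locus Σp⁴ + Σ_{i<j}(2p_ip_j)², product over loci (the
  naive multilocus probability of identity; sib-corrected variants are
  out of scope).
* **Mxy relatedness** — per locus the multiset-intersection size of the
  two genotypes / 2 (1 / 0.5 / 0), averaged over mutually complete loci.
  Reference distributions are simulated from the population's own
  frequencies: full sibs (two shared HWE parents), half sibs (one),
  unrelated pairs; Welch t-tests compare the observed pairwise values to
  each reference.  Reference pair counts default to 1000.
* **HWE** — Guo–Thompson Monte-Carlo exact test.  The chain state is the
  assignment of the fixed gene copies to (individual, slot) positions;
  random two-individual switches are doubly stochastic, so the chain is
  uniform over assignments, which induces exactly the Levene conditional
  distribution over genotype tables.  p = fraction of post-dememorization
  states whose conditional table probability (∝ 2^h / Π n_g!) is ≤ the
  observed table's; Monte-Carlo error by batch means (50 batches).
  Defaults 100,000 chain / 100,000 dememorization steps.  For biallelic
  tables a full-enumeration exact p (`hwe_enumeration_biallelic`) serves
  as an independent oracle.
* **Gametic disequilibrium** — permutation test (default 10,000
  permutations) on the two-locus genotype table with a G statistic;
  one locus's genotypes are shuffled between individuals.  A cleaner
  design than the opaque "initial conditions / permutations" settings of
  legacy software, and calibrated: null p-values are uniform.
* **Bonferroni** — significant iff p < α/m; the adjusted threshold is
  returned.
* **Null alleles** — Brookfield-1 estimator (He − Ho)/(1 + He), floored
  at 0.  Size-range scoring artefacts and stutter diagnostics are out of
  scope.
* **θ (F_ST)** — Weir & Cockerham (1984) a/b/c variance components per
  locus and allele, ratio of sums; loci lacking data in a population are
  skipped with a warning.
* **AMOVA** — gene copies as observation units with 0/1 allele-identity
  distances (the Arlequin-comparable F_ST AMOVA); variance components
  summed over loci, Φ_ST = among/(among + within), permutation test with
  the individual as the permutation unit (both copies move together).
  Negative among-group components are reported as-is with a note.  On
  balanced HWE simulations Φ_ST and θ agree closely (an
  individual-genotype-distance AMOVA does not; it overweights the
  within-individual level, which is why the gene-copy formulation is
  used).
* **PCA** — allele-dosage matrix (one 0/1/2 column per locus-allele),
  column-mean imputation of missing genotypes, column centring, exact
  SVD; coordinates plus percent variance.

## Missing data

A genotype is missing as a whole (half-calls are rejected at I/O and
construction time).  Every statistic uses locus-wise or pairwise
complete observations and reports are based on the corresponding
denominators; the admixture sampler simply skips missing copies in all
counts and in the likelihood.

## Numerical choices

* Internal missing sentinel −9 (also the STRUCTURE read/write default).
* Dirichlet draws via gamma variables; degenerate shape vectors fall
  back to the valid-support uniform rather than producing NaNs.
* Log-densities floor their arguments at 1e-300.
* Permutation p-values use (1 + #{perm ≥ obs})/(B + 1); ties at the
  observed statistic count with a 1e-12 tolerance.
* Threshold rule uses strict > with exact float comparison; the
  accuracy table reports qi ranges toward each class's own parental
  cluster (cluster A for F1/F2 by convention).

## Known limitations

* The generator produces unlinked, HWE, substructure-free populations;
  heterozygote deficits can be emulated only through the scalar `f_is`.
* Later-generation hybrid swarms (F3+, triple backcrosses) and
  sex-linked inheritance are not modelled.
* The sampler implements the admixture model without prior population
  information; LOCPRIOR/USEPOPINFO-style variants and linkage models are
  out of scope.
* PID here is the naive estimator; with many loci it underestimates the
  sharing probability among relatives.
* Exhaustive replicate alignment is factorial in K and refuses K > 8.
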