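"""Quality-control panel: Hardy-Weinberg, gametic disequilibrium, null
alleles.

Runs the Guo-Thompson Monte-Carlo exact HWE test at every locus of one
simulated population (scaled-down chain), the G-statistic permutation
test for gametic disequilibrium on a few locus pairs, Bonferroni
correction, and the Brookfield-1 null-allele estimator.
"""

import admixkit as ak
from admixkit.equilibrium import (
    bonferroni_adjust,
    hwe_exact_test,
    ld_exact_test,
    null_allele_estimate,
)

gm = ak.simulate_parental_pair(n_loci=10, seed=1)

print("locus   HWE p   mc err   null-allele r")
pvals = []
for l, name in enumerate(gm.locus_names):
    r = hwe_exact_test(gm, "A", l, chain_length=20_000, dememorization=2_000, seed=l)
    null = null_allele_estimate(gm, "A", l)
    pvals.append(r.p_value)
    print(f"{name:6s} {r.p_value:6.3f} {r.mc_error:8.4f} {null:10.3f}")

flags, threshold = bonferroni_adjust(pvals, alpha=0.05)
print(f"\nBonferroni threshold 0.05/{len(pvals)} = {threshold:.5f}; "
      f"{int(flags.sum())} loci significant after correction")
# The generator samples genotypes under HWE, so p-values should look
# uniform and (almost) nothing should survive correction.

print("\ngametic disequilibrium (first three pairs):")
for pair in [(0, 1), (1, 2), (2, 3)]:
    r = ld_exact_test(gm, "A", pair, permutations=999, seed=7)
    print(f"  {r.name:12s} G = {r.statistic:6.2f}  p = {r.p_value:.3f}")
# Loci are simulated independently: no pair should show association.
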