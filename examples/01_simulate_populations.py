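"""Simulate two diverged parental populations and check their structure.

Builds a study-like reference pair — 27 microsatellite loci with 3-17
alleles each, Balding-Nichols divergence FST = 0.165, 30 diploids per
population — writes it in STRUCTURE format, and verifies the realised
differentiation and diversity.
"""

from pathlib import Path

import admixkit as ak

gm = ak.simulate_parental_pair(
    n_loci=27, allele_range=(3, 17), fst=0.165, n_per_pop=(30, 30), seed=1
)
out = Path("scratch_example_refs.str")
ak.write_structure(gm, out)

theta = ak.pairwise_fst(gm, "A", "B")
res = ak.amova(gm, permutations=199, seed=1)
print(f"wrote {gm.n_individuals} individuals x {gm.n_loci} loci to {out}")
print(f"Weir-Cockerham theta   : {theta:.3f}   (generator target 0.165)")
print(f"AMOVA Phi_ST           : {res.phi_st:.3f}  (p = {res.p_value:.3f})")
for pop in gm.populations():
    hz = ak.unbiased_heterozygosity(gm, pop)
    print(f"population {pop}: Hz = {hz:.3f}  (study band 0.60-0.71)")
# theta/Phi near the target confirm the two reference groups are as
# diverged as the empirical ones; Hz confirms realistic marker diversity.
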