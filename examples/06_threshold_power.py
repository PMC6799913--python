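"""Threshold power analysis: which qi cut-off separates hybrids from
non-admixed animals.

Runs the end-to-end pipeline at a reduced size (smaller design and chain
so it finishes in ~a minute): simulate references, build the eight-class
design, estimate memberships at K = 2, score per-class misassignment at
thresholds 0.80/0.85/0.90/0.95, and select the operating threshold.
"""

import pandas as pd

from admixkit.threshold_eval import run_full_pipeline

manifest = run_full_pipeline(
    {
        "seed": 1,
        "n_per_class": 20,
        "reps": 8000,
        "burnin": 2000,
        "replicates": 2,
    },
    "scratch_example_pipeline",
)

table = pd.read_csv("scratch_example_pipeline/accuracy.csv")
wide = table.pivot(
    index="hybrid_class", columns="threshold", values="percent_misassigned"
)
print("% misassigned per class and threshold:")
print(wide.to_string(float_format="%.1f"))
print(f"\nselected threshold: qi > {manifest['selected_threshold']}")
# The rule picks the largest threshold with zero pure/F1/F2 error, or —
# at this reduced size, where a few F2s stray — the one minimising their
# summed error.  Backcross (BC) and especially double-backcross (BC2)
# rows keep substantial error: the detection limit of the marker panel.
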