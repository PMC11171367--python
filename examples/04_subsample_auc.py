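"""Variant-count balancing: AUC distribution of random i-variant sub-scores.

A 50-variant score is repeatedly thinned to i variants without
replacement; the median AUC grows with i, quantifying how much of a
score's discrimination is just variant count.
"""

import pandas as pd

from smrprs import LdBlockSpec, PrsModel, make_cohort, make_reference_panel, subsample_auc

panel = make_reference_panel(
    LdBlockSpec(n_blocks=50, block_size=2, within_block_corr=0.3), 1500, seed=30
)
v = panel.variants.iloc[::2]
model = PrsModel(
    table=pd.DataFrame(
        {
            "snp": v["id"].to_numpy(),
            "effect_allele": v["a1"].to_numpy(),
            "other_allele": v["a2"].to_numpy(),
            "weight": 0.12,
        }
    ),
    label="full",
)
cohort = make_cohort(panel, model, "case_control", 1200, 1200, seed=31)

for i in (5, 10, 25, 50):
    s = subsample_auc(model, cohort, i=i, iterations=200, seed=32)
    print(
        f"i={i:3d}: median AUC {s.median:.3f} "
        f"(IQR {s.iqr[0]:.3f}-{s.iqr[1]:.3f}, range {s.range[0]:.3f}-{s.range[1]:.3f})"
    )
# at i=50 (the full model) every subsample is the same set of variants, so
# the distribution collapses to a single value.
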