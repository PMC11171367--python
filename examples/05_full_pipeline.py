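"""One-call end-to-end run: simulate -> scan -> PRS -> score -> evaluate.

Writes all artifacts (summary files, weight files, score files, reports,
provenance with content hashes) into ./pipeline_demo and prints the
headline comparison of the functional vs the GWAS-significance PRS.
"""

import json
from pathlib import Path

from smrprs import RunConfig, SimulateConfig, run_pipeline

cfg = RunConfig(out_dir=Path("pipeline_demo"), seed=1, simulate=SimulateConfig())
out = run_pipeline(cfg)

report = json.loads((out / "evaluation.json").read_text())
for name in ("functional", "gwas", "combined"):
    r = report["scores"][name]
    print(
        f"{name:10s} n_variants={r['n_variants_used']:3d} "
        f"AUC={r['auc']:.3f} ({r['auc_ci'][0]:.3f}-{r['auc_ci'][1]:.3f}) "
        f"OR/SD={r['or_per_sd']:.2f}"
    )
print("joint model AUC:", round(report["joint_gwas_functional"]["auc"], 3))
sub = json.loads((out / "subsample.json").read_text())
print(f"GWAS PRS thinned to {sub['i']} variants: median AUC {sub['median']:.3f}")
# a functional PRS built from the handful of SMR+HEIDI hits discriminates
# less well than the many-variant GWAS-significance PRS, and thinning the
# GWAS PRS to the same variant count closes part of that gap — variant
# count, not functional annotation, drives much of the difference.
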