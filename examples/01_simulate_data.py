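"""Generate a synthetic reference panel, QTL study and GWAS with known truth.

Builds a small LD-blocked panel, plants one pleiotropic variant (it raises
a molecular trait, and the trait raises disease risk), and prints the
recovered effect sizes next to the planted ones.
"""

from smrprs import (
    ArchitectureSpec,
    LdBlockSpec,
    ProbeMeta,
    make_gwas_study,
    make_qtl_study,
    make_reference_panel,
)

spec = LdBlockSpec(n_blocks=2, block_size=15, within_block_corr=0.6, maf_range=(0.15, 0.45))
panel = make_reference_panel(spec, n_individuals=2000, seed=1)
print(f"panel: {panel.n_individuals} individuals x {panel.n_variants} variants")

causal = panel.variants["id"].iloc[7]
arch = ArchitectureSpec(mode="pleiotropy", causal_variant_id=causal, b_zx=0.5, b_xy=0.3)
meta = ProbeMeta("probe1", "GENE1", "1", int(panel.variants["pos"].iloc[7]))

qtl = make_qtl_study(panel, arch, n_study=5000, probe_meta=meta, seed=2)
gwas = make_gwas_study(panel, arch, n_cases=10000, n_controls=10000, seed=3)

q = qtl.table.set_index("snp").loc[causal]
g = gwas.record(causal)
print(f"planted QTL effect b_zx = 0.5; estimated {q['b']:.3f} (SE {q['se']:.3f})")
print(
    "planted marginal disease effect b_zx*b_xy = 0.15; "
    f"estimated {g['b']:.3f} (SE {g['se']:.3f})"
)
# the GWAS beta at the causal variant should sit within ~2 SE of 0.15:
# the pleiotropic variant's disease effect is fully mediated by the trait.
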