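"""End-to-end orchestration: simulate -> SMR scan -> PRS -> score -> evaluate.

A run is described by a single validated config.  Inputs are either paths
to existing files or a simulation block that generates them; every stage's
outputs land in the run directory together with a provenance record
(config hash, seed, SHA-256 of every artifact) so a rerun with the same
config is bit-identical and verifiable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import io as sio
from .evaluate import evaluate_scores, joint_model_auc, overlap_analysis
from .prs import PrsModel, build_functional_model, combine_models, ld_prune, score_cohort
from .smr import HEIDI_P_THRESHOLD, SMR_P_THRESHOLD, HeidiConfig, run_smr_scan
from .subsample import subsample_auc
from .synth import (
    ArchitectureSpec,
    GwasSummary,
    LdBlockSpec,
    ProbeMeta,
    QtlDataset,
    _marginal_logit,
    make_cohort,
    make_qtl_study,
    make_reference_panel,
)

__all__ = ["SimulateConfig", "RunConfig", "simulate_inputs", "run_pipeline", "compare_weightings"]

logger = logging.getLogger(__name__)


class HeidiSettings(BaseModel):
    instrument_p_max: float = 1.57e-3
    r2_min: float = 0.05
    r2_max: float = 0.9
    max_instruments: int = 20
    min_instruments: int = 3

    def to_config(self) -> HeidiConfig:
        return HeidiConfig(**self.model_dump())


class SimulateConfig(BaseModel):
    """Desk-scale study conditions for a self-contained demonstration run.

    Defaults emulate the shape of the source study scaled to laptop size:
    a block-LD panel of a few hundred variants, a GWAS of ~20k subjects, a
    handful of pleiotropic / linkage / null probes, and a case-control
    cohort of a few thousand whose outcome follows the GWAS architecture.
    """

    n_blocks: int = 30
    block_size: int = 10
    within_block_corr: float = 0.55
    maf_range: tuple[float, float] = (0.1, 0.5)
    n_panel: int = 2000
    n_qtl_study: int = 5000
    n_gwas_cases: int = 10000
    n_gwas_controls: int = 10000
    n_cohort_cases: int = 1500
    n_cohort_controls: int = 1500
    n_pleiotropy_probes: int = 8
    n_linkage_probes: int = 4
    n_null_probes: int = 8
    b_zx: float = 0.5
    b_xy: float = 0.35
    b_zy_direct: float = 0.18
    gwas_background_frac: float = 0.5
    gwas_background_beta: float = 0.08


class RunConfig(BaseModel):
    """Paths, thresholds and seeds for one pipeline run."""

    out_dir: Path
    seed: int = 1
    gwas: Path | None = None
    qtl: Path | None = None
    panel: Path | None = None  # prefix of a dosage/variants TSV pair
    cohort: Path | None = None  # prefix of a dosage/variants TSV pair
    alt_weights: Path | None = None
    simulate: SimulateConfig | None = None
    smr_p_threshold: float = SMR_P_THRESHOLD
    heidi_p_threshold: float = HEIDI_P_THRESHOLD
    prune_r2: float = 0.9
    centile: float = 80.0
    heidi: HeidiSettings = Field(default_factory=HeidiSettings)
    subsample_iterations: int = 200

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        for name in ("smr_p_threshold", "heidi_p_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        if not 0.0 < self.prune_r2 <= 1.0:
            raise ValueError("prune_r2 must be in (0, 1]")
        if not 0.0 < self.centile < 100.0:
            raise ValueError("centile must be in (0, 100)")
        if self.simulate is None:
            for name in ("gwas", "qtl", "panel", "cohort"):
                p = getattr(self, name)
                if p is None:
                    raise ValueError(f"either provide 'simulate' or a path for {name!r}")
        return self

    def validate_inputs_exist(self) -> None:
        if self.simulate is not None:
            return
        for name, suffix in (
            ("gwas", None),
            ("qtl", None),
            ("panel", ".dosage.tsv"),
            ("cohort", ".dosage.tsv"),
        ):
            p = Path(getattr(self, name))
            probe = p.with_suffix(suffix) if suffix else p
            if not probe.exists():
                raise FileNotFoundError(f"{name} input not found: {probe}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def simulate_inputs(cfg: SimulateConfig, out_dir: Path, seed: int) -> dict[str, Path]:
    """Generate a full, internally consistent set of pipeline inputs.

    One reference panel underlies everything.  Pleiotropy probes drive a
    shared disease architecture (their causal variants carry GWAS effects
    b_zx*b_xy via mediation); linkage probes pair a QTL variant with a
    distinct disease variant in the same LD block; null probes carry no
    effects.  The GWAS additionally gives a fraction of non-QTL variants a
    polygenic background effect so an established "GWAS PRS" is buildable;
    the cohort outcome follows the same true per-variant effects.
    """
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    spec = LdBlockSpec(
        n_blocks=cfg.n_blocks,
        block_size=cfg.block_size,
        within_block_corr=cfg.within_block_corr,
        maf_range=cfg.maf_range,
    )
    panel = make_reference_panel(spec, cfg.n_panel, seed=seed + 1)

    n_probes = cfg.n_pleiotropy_probes + cfg.n_linkage_probes + cfg.n_null_probes
    if n_probes > cfg.n_blocks:
        raise ValueError("need at least one LD block per probe")
    blocks = rng.permutation(cfg.n_blocks)[:n_probes]

    # per-variant true disease effects accumulated for the cohort model
    true_beta = np.zeros(panel.n_variants)
    qtl_parts = []
    modes = (
        ["pleiotropy"] * cfg.n_pleiotropy_probes
        + ["linkage"] * cfg.n_linkage_probes
        + ["null"] * cfg.n_null_probes
    )
    for k, (mode, b) in enumerate(zip(modes, blocks)):
        in_block = panel.variants.index[panel.variants["block"] == b].to_numpy()
        causal = panel.variants.loc[rng.choice(in_block), "id"]
        center = int(panel.variants.loc[in_block, "pos"].median())
        meta = ProbeMeta(probe_id=f"probe{k:03d}", gene=f"GENE{k:03d}", chrom="1", position=center)
        if mode == "pleiotropy":
            sign = 1.0 if rng.random() < 0.5 else -1.0
            arch = ArchitectureSpec(
                mode="pleiotropy", causal_variant_id=causal, b_zx=cfg.b_zx, b_xy=sign * cfg.b_xy
            )
            true_beta[panel.variant_index(causal)] += cfg.b_zx * sign * cfg.b_xy
        elif mode == "linkage":
            others = [v for v in in_block if panel.variants.loc[v, "id"] != causal]
            direct = panel.variants.loc[rng.choice(others), "id"]
            arch = ArchitectureSpec(
                mode="linkage",
                causal_variant_id=causal,
                b_zx=cfg.b_zx,
                b_zy_direct=cfg.b_zy_direct,
                direct_variant_id=direct,
            )
            true_beta[panel.variant_index(direct)] += cfg.b_zy_direct
        else:
            arch = ArchitectureSpec(mode="null")
        qtl_parts.append(
            make_qtl_study(panel, arch, cfg.n_qtl_study, meta, seed=seed + 100 + k)
        )
    qtl = QtlDataset.concat(qtl_parts)

    # polygenic background on variants not already causal
    free = np.flatnonzero(true_beta == 0.0)
    n_bg = int(cfg.gwas_background_frac * free.size)
    bg = rng.choice(free, size=n_bg, replace=False)
    true_beta[bg] = rng.normal(0.0, cfg.gwas_background_beta, size=n_bg)

    # GWAS outcome follows the full true effect vector
    truth_model = PrsModel(
        table=pd.DataFrame(
            {
                "snp": panel.variants["id"],
                "effect_allele": panel.variants["a1"],
                "other_allele": panel.variants["a2"],
                "weight": true_beta,
            }
        ),
        label="truth",
    )

    gwas_cohort = make_cohort(
        panel,
        truth_model,
        design="case_control",
        n_cases=cfg.n_gwas_cases,
        n_noncases=cfg.n_gwas_controls,
        seed=seed + 2,
    )
    beta, se, p = _marginal_logit(gwas_cohort.labels.astype(float), gwas_cohort.dosages)
    gwas = GwasSummary(
        table=pd.DataFrame(
            {
                "snp": panel.variants["id"],
                "a1": panel.variants["a1"],
                "a2": panel.variants["a2"],
                "freq": gwas_cohort.dosages.mean(axis=0) / 2.0,
                "b": beta,
                "se": se,
                "p": p,
                "n": cfg.n_gwas_cases + cfg.n_gwas_controls,
            }
        ),
        truth={"true_beta": {s: float(v) for s, v in zip(panel.variants["id"], true_beta)}},
        seed=seed + 2,
    )

    cohort = make_cohort(
        panel,
        truth_model,
        design="case_control",
        n_cases=cfg.n_cohort_cases,
        n_noncases=cfg.n_cohort_controls,
        seed=seed + 3,
    )

    paths = {
        "gwas": out_dir / "gwas.ma.tsv",
        "qtl": out_dir / "qtl.tsv",
        "panel": out_dir / "panel",
        "cohort": out_dir / "cohort",
        "truth": out_dir / "truth.json",
    }
    sio.write_gwas_ma(gwas, paths["gwas"])
    sio.write_qtl_tsv(qtl, paths["qtl"])
    sio.write_panel_tsv(panel, paths["panel"])
    sio.write_cohort_tsv(cohort, paths["cohort"])
    paths["truth"].write_text(
        json.dumps(
            {
                "true_beta": gwas.truth["true_beta"],
                "probes": {p: {"mode": t["arch"].mode} for p, t in qtl.truth.items()},
            },
            indent=1,
            sort_keys=True,
        )
    )
    return paths


def _config_hash(cfg: RunConfig) -> str:
    payload = cfg.model_dump_json(exclude={"out_dir"})
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute every stage and return the run directory.

    Stages: (0) simulate inputs when configured, (1) SMR+HEIDI scan,
    (2) build the functional PRS and a GWAS-significance PRS, combine and
    prune, (3) score the cohort, (4) evaluate all scores (AUC, OR/SD,
    Youden, centile rule, joint model, overlap), (5) variant-count
    subsampling.  On any stage error a FAILED marker naming the stage is
    left in the run directory and the error propagates.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.validate_inputs_exist()
    stage = "setup"
    try:
        if cfg.simulate is not None:
            stage = "simulate"
            paths = simulate_inputs(cfg.simulate, out / "inputs", cfg.seed)
        else:
            paths = {
                "gwas": Path(cfg.gwas),
                "qtl": Path(cfg.qtl),
                "panel": Path(cfg.panel),
                "cohort": Path(cfg.cohort),
            }

        stage = "load"
        gwas = sio.read_gwas_ma(paths["gwas"])
        qtl = sio.read_qtl_tsv(paths["qtl"])
        panel = sio.read_panel_tsv(paths["panel"])
        cohort = sio.read_cohort_tsv(paths["cohort"])

        stage = "smr"
        scan = run_smr_scan(
            gwas,
            qtl,
            panel,
            smr_p_threshold=cfg.smr_p_threshold,
            heidi_p_threshold=cfg.heidi_p_threshold,
            cfg=cfg.heidi.to_config(),
        )
        scan_path = out / "smr_results.tsv"
        scan.to_csv(scan_path, sep="\t", index=False, float_format="%.10g")

        stage = "build-prs"
        if not scan["passed"].any():
            raise RuntimeError("no probes passed the SMR+HEIDI filters; nothing to score")
        functional = build_functional_model(scan, gwas, label="functional")
        # established-PRS stand-in: genome-wide-significant GWAS variants,
        # LD-pruned, weighted by their GWAS betas
        sig = gwas.table[gwas.table["p"] < cfg.smr_p_threshold]
        gwas_model = PrsModel(
            table=sig.rename(
                columns={"a1": "effect_allele", "a2": "other_allele", "b": "weight"}
            )[["snp", "effect_allele", "other_allele", "weight"]],
            label="gwas",
        )
        gwas_model = ld_prune(gwas_model, panel, cfg.prune_r2)
        combined = combine_models(gwas_model, functional, label="combined")
        functional_pruned = ld_prune(functional, panel, cfg.prune_r2)
        for model, name in (
            (functional, "functional"),
            (gwas_model, "gwas"),
            (combined, "combined"),
            (functional_pruned, "functional_pruned"),
        ):
            sio.write_weights(model, out / f"weights_{name}.tsv")

        stage = "score"
        scores = {
            name: score_cohort(model, cohort)
            for name, model in (
                ("functional", functional),
                ("gwas", gwas_model),
                ("combined", combined),
                ("functional_pruned", functional_pruned),
            )
        }
        for name, s in scores.items():
            sio.write_scores(s, out / f"scores_{name}.tsv")

        stage = "evaluate"
        reports = {name: evaluate_scores(s, cfg.centile).to_dict() for name, s in scores.items()}
        j_auc, j_lo, j_hi = joint_model_auc(scores["gwas"], scores["functional"])
        overlap = overlap_analysis(scores["gwas"], scores["functional"], cfg.centile)
        report = {
            "scores": reports,
            "joint_gwas_functional": {"auc": j_auc, "ci": [j_lo, j_hi]},
            "overlap_gwas_functional": overlap.to_dict(),
        }
        (out / "evaluation.json").write_text(json.dumps(report, indent=1, sort_keys=True))

        stage = "subsample"
        if len(gwas_model) >= len(functional):
            big, i = gwas_model, len(functional)
        else:
            big, i = functional, len(gwas_model)
        sub = subsample_auc(big, cohort, i=i, iterations=cfg.subsample_iterations, seed=cfg.seed + 7)
        (out / "subsample.json").write_text(json.dumps(sub.to_dict(), indent=1))

        stage = "provenance"
        artifacts = sorted(
            p for p in out.rglob("*") if p.is_file() and p.name != "provenance.json"
        )
        prov = {
            "config": json.loads(cfg.model_dump_json()),
            "config_hash": _config_hash(cfg),
            "seed": cfg.seed,
            "files": {str(p.relative_to(out)): _sha256(p) for p in artifacts},
        }
        (out / "provenance.json").write_text(json.dumps(prov, indent=1, sort_keys=True))
    except Exception as err:
        (out / "FAILED").write_text(f"stage={stage}\nerror={err}\n")
        raise
    return out


def compare_weightings(model: PrsModel, alt: PrsModel, cohort, centile: float = 80.0):
    """Score a cohort under two weightings of the same variant set.

    Returns (report_main, report_alt, overlap): the discrimination reports
    under each weighting plus the agreement of their high-risk calls —
    near-identical AUCs with discordant flags is the expected signature of
    correlated but non-identical weight sets.
    """
    sa, sb = set(model.snps), set(alt.snps)
    if sa != sb:
        diff = sorted(sa.symmetric_difference(sb))
        raise ValueError(f"weight sets cover different variants: {diff}")
    s1 = score_cohort(model, cohort)
    s2 = score_cohort(alt, cohort)
    return (
        evaluate_scores(s1, centile),
        evaluate_scores(s2, centile),
        overlap_analysis(s1, s2, centile),
    )
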