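"""Polygenic risk score construction, combination, LD pruning and scoring.

A PRS model is an ordered list of (variant, effect allele, other allele,
weight) entries; an individual's score is the weighted sum of effect-allele
dosages, PRS = sum_k beta_k * x_k with x_k in [0, 2] — plink's ``scoresum``
semantics, including mean-dosage (2*EAF) imputation of missing genotypes
and silent skipping (with a count) of model variants absent from the
cohort being scored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alleles import harmonize
from .synth import CohortData, GwasSummary, ReferencePanel

__all__ = [
    "PrsModel",
    "ScoreSet",
    "build_functional_model",
    "combine_models",
    "ld_prune",
    "score_cohort",
]

logger = logging.getLogger(__name__)

_MODEL_COLS = ["snp", "effect_allele", "other_allele", "weight"]


@dataclass
class PrsModel:
    """Variant weights (per effect allele, log-odds units) for one score."""

    table: pd.DataFrame
    label: str = "prs"

    def __post_init__(self) -> None:
        missing = [c for c in _MODEL_COLS if c not in self.table.columns]
        if missing:
            raise ValueError(f"model table missing columns {missing}")
        if self.table["snp"].duplicated().any():
            dup = self.table.loc[self.table["snp"].duplicated(), "snp"].tolist()
            raise ValueError(f"duplicate variants in model: {dup}")
        if not np.all(np.isfinite(self.table["weight"].to_numpy(dtype=float))):
            raise ValueError("model weights must be finite")
        self.table = self.table[_MODEL_COLS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def snps(self) -> list[str]:
        return list(self.table["snp"])


@dataclass
class ScoreSet:
    """Per-individual scores with outcome labels for one PRS model."""

    scores: np.ndarray
    labels: np.ndarray
    label: str = "prs"
    n_variants_used: int = 0
    iids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.scores.shape != self.labels.shape:
            raise ValueError("scores and labels must align")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")

    @property
    def case_scores(self) -> np.ndarray:
        return self.scores[self.labels == 1]

    @property
    def control_scores(self) -> np.ndarray:
        return self.scores[self.labels == 0]


def build_functional_model(
    scan: pd.DataFrame, gwas: GwasSummary, label: str = "functional"
) -> PrsModel:
    """Weight the SMR+HEIDI-passing top SNPs by their GWAS effects.

    ``scan`` may be the concatenation of several scans (e.g. an eQTL and an
    mQTL scan); a variant passing in more than one appears once.  Weights
    are the disease GWAS log-odds betas in the GWAS table's own allele
    orientation.
    """
    if scan.empty:
        raise ValueError("scan is empty")
    snps = list(dict.fromkeys(scan.loc[scan["passed"], "top_snp"]))
    gtab = gwas.table.set_index("snp")
    missing = [s for s in snps if s not in gtab.index]
    if missing:
        raise KeyError(f"passing variants missing from GWAS summary: {missing}")
    rows = [
        {
            "snp": s,
            "effect_allele": gtab.loc[s, "a1"],
            "other_allele": gtab.loc[s, "a2"],
            "weight": float(gtab.loc[s, "b"]),
        }
        for s in snps
    ]
    return PrsModel(table=pd.DataFrame(rows, columns=_MODEL_COLS), label=label)


def combine_models(a: PrsModel, b: PrsModel, label: str | None = None) -> PrsModel:
    """Set union of two models' variants; |a| + |b| - |overlap| entries.

    Shared variants must carry the same weight (after orienting to a common
    effect allele); a conflict raises rather than silently preferring one
    source, since a combined score is only meaningful under one weight
    scheme.
    """
    at = a.table.set_index("snp")
    overlap = [s for s in b.snps if s in at.index]
    for s in overlap:
        ra, rb = at.loc[s], b.table.set_index("snp").loc[s]
        wa, wb = float(ra["weight"]), float(rb["weight"])
        if rb["effect_allele"] == ra["other_allele"] and rb["other_allele"] == ra["effect_allele"]:
            wb = -wb
        elif rb["effect_allele"] != ra["effect_allele"]:
            raise ValueError(f"shared variant {s} has irreconcilable alleles")
        if not np.isclose(wa, wb, rtol=0, atol=1e-12):
            raise ValueError(f"shared variant {s} has conflicting weights ({wa} vs {wb})")
    extra = b.table[~b.table["snp"].isin(at.index)]
    out = pd.concat([a.table, extra], ignore_index=True)
    return PrsModel(table=out, label=label or f"{a.label}+{b.label}")


def ld_prune(model: PrsModel, panel: ReferencePanel, r2_threshold: float = 0.9) -> PrsModel:
    """Greedy LD pruning in genomic order.

    Scanning variants by (chrom, pos), a variant is dropped when its r^2
    with any already-retained variant exceeds the threshold; the earlier
    variant in genomic order is the one kept.  Idempotent and
    deterministic.
    """
    missing = [s for s in model.snps if s not in set(panel.variants["id"])]
    if missing:
        raise KeyError(f"model variants missing from panel: {missing}")
    vmeta = panel.variants.set_index("id")
    order = sorted(model.snps, key=lambda s: (str(vmeta.loc[s, "chrom"]), int(vmeta.loc[s, "pos"])))
    retained: list[str] = []
    for snp in order:
        if retained:
            r = panel.ld_r([snp], retained).ravel()
            if np.any(r**2 > r2_threshold):
                continue
        retained.append(snp)
    keep = model.table[model.table["snp"].isin(retained)].reset_index(drop=True)
    logger.info("LD prune (r2 > %g): %d -> %d variants", r2_threshold, len(model), len(keep))
    return PrsModel(table=keep, label=model.label)


def _aligned_dosages(
    model: PrsModel, cohort: CohortData
) -> tuple[np.ndarray, np.ndarray, int]:
    """Orient cohort dosages to the model's effect alleles.

    Returns (n x k effect-allele dosage matrix with missing entries imputed
    at twice the observed effect-allele frequency, length-k weight vector,
    count of model variants skipped because they are absent from the cohort
    or allele-irreconcilable).
    """
    cmeta = cohort.variants.set_index("id")
    cols, weights = [], []
    skipped = 0
    id_to_col = {v: j for j, v in enumerate(cohort.variants["id"])}
    for _, row in model.table.iterrows():
        snp = row["snp"]
        if snp not in id_to_col:
            skipped += 1
            continue
        ca1, ca2 = cmeta.loc[snp, "a1"], cmeta.loc[snp, "a2"]
        if row["other_allele"] in ("N", ".", ""):  # plink 3-column file: effect allele only
            if row["effect_allele"] == ca1:
                flip = False
            elif row["effect_allele"] == ca2:
                flip = True
            else:
                skipped += 1
                continue
        else:
            res = harmonize(
                row["effect_allele"], row["other_allele"], ca1, ca2, trust_strand=True
            )
            if not res.ok:
                skipped += 1
                continue
            flip = res.flip
        x = cohort.dosages[:, id_to_col[snp]].astype(float)
        if flip:
            x = 2.0 - x
        if np.isnan(x).any():
            # plink-style frequency imputation: 2 * effect-allele frequency
            # observed in the scoring cohort (= mean observed dosage)
            m = np.nanmean(x)
            x = np.where(np.isnan(x), m if np.isfinite(m) else 0.0, x)
        cols.append(x)
        weights.append(float(row["weight"]))
    if not cols:
        raise ValueError("no model variants present in the cohort")
    if skipped:
        logger.info("scoring %s: %d model variants absent from cohort, skipped", model.label, skipped)
    return np.column_stack(cols), np.asarray(weights), skipped


def score_cohort(model: PrsModel, cohort: CohortData) -> ScoreSet:
    """Score a cohort with scoresum semantics (see module docstring)."""
    X, w, skipped = _aligned_dosages(model, cohort)
    return ScoreSet(
        scores=X @ w,
        labels=cohort.labels,
        label=model.label,
        n_variants_used=X.shape[1],
        iids=list(cohort.iids),
    )
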