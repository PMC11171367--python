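"""Synthetic GWAS / molecular-QTL / cohort generators with known ground truth.

This module emulates, at desk scale, the data a blood-based
SMR-to-polygenic-score study consumes:

* a reference panel of genotype dosages with block-structured LD,
* per-probe cis-QTL summary statistics (marginal OLS of a simulated
  expression or methylation trait on dosage),
* disease GWAS summary statistics (marginal logistic regressions under a
  pleiotropy, linkage or null architecture),
* individual-level case-control or prospective cohorts whose outcome is
  driven by a known true polygenic score.

Every generator is a pure function of its inputs and an integer seed, and
records the ground-truth parameters it used, so downstream stages (SMR,
HEIDI, PRS scoring, discrimination metrics) can be tested against known
answers without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit, logit

from ._ld import calibrate_latent_rho, sample_block_genotypes

__all__ = [
    "LdBlockSpec",
    "ArchitectureSpec",
    "ProbeMeta",
    "ReferencePanel",
    "QtlDataset",
    "GwasSummary",
    "CohortData",
    "make_reference_panel",
    "make_qtl_study",
    "make_gwas_study",
    "make_cohort",
]

_BASES = ("A", "C", "G", "T")
_ALLELE_PAIRS = [(a, b) for a in _BASES for b in _BASES if a != b]


@dataclass(frozen=True)
class LdBlockSpec:
    """Block-structured LD layout for a synthetic reference panel.

    Variants within a block share a target pairwise dosage correlation
    ``within_block_corr``; variants in different blocks are independent.
    """

    n_blocks: int
    block_size: int
    within_block_corr: float = 0.0
    maf_range: tuple[float, float] = (0.05, 0.5)

    def __post_init__(self) -> None:
        if self.n_blocks < 1 or self.block_size < 1:
            raise ValueError("n_blocks and block_size must be positive")
        if not 0.0 <= self.within_block_corr < 1.0:
            raise ValueError("within_block_corr must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must be ordered and within (0, 0.5]")

    @property
    def n_variants(self) -> int:
        return self.n_blocks * self.block_size


@dataclass(frozen=True)
class ArchitectureSpec:
    """Causal architecture linking a molecular trait and disease liability.

    ``pleiotropy``: one causal variant drives the molecular trait
    (per-allele effect ``b_zx``) and the trait drives disease log-odds
    (``b_xy``), so the variant's marginal disease effect is ``b_zx*b_xy``
    by mediation.  ``linkage``: the trait-causal variant and the
    disease-causal variant (``direct_variant_id``, effect ``b_zy_direct``)
    are distinct variants in LD.  ``null``: no effects anywhere.
    """

    mode: Literal["pleiotropy", "linkage", "null"]
    causal_variant_id: str | None = None
    b_zx: float = 0.0
    b_xy: float = 0.0
    b_zy_direct: float = 0.0
    direct_variant_id: str | None = None
    trait_noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.mode == "null":
            if self.b_zx or self.b_xy or self.b_zy_direct:
                raise ValueError("null architecture must have all effects zero")
        elif self.mode == "pleiotropy":
            if self.causal_variant_id is None:
                raise ValueError("pleiotropy mode requires causal_variant_id")
        elif self.mode == "linkage":
            if self.causal_variant_id is None or self.direct_variant_id is None:
                raise ValueError("linkage mode requires causal and direct variant ids")
            if self.direct_variant_id == self.causal_variant_id:
                raise ValueError(
                    "linkage mode requires the disease variant to differ from the QTL variant"
                )
        else:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.trait_noise_sd < 0:
            raise ValueError("trait_noise_sd must be non-negative")


@dataclass(frozen=True)
class ProbeMeta:
    """Identity and genomic position of one expression/methylation probe."""

    probe_id: str
    gene: str
    chrom: str
    position: int


@dataclass
class ReferencePanel:
    """Allele-aligned genotype dosages used to estimate LD (and to resample).

    ``variants`` carries, besides identity columns (chrom, pos, id, a1
    effect allele, a2 other allele), the generative metadata (``block``,
    ``maf``, ``latent_rho``) needed to draw fresh individuals from the same
    haplotype model.
    """

    variants: pd.DataFrame
    dosages: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        ids = self.variants["id"]
        if ids.duplicated().any():
            raise ValueError("variant ids must be unique")
        if self.dosages.shape != (self.dosages.shape[0], len(self.variants)):
            raise ValueError("dosage matrix does not match variant table")
        freq = self.dosages.mean(axis=0) / 2.0
        if np.any(freq <= 0.0) or np.any(freq >= 1.0):
            raise ValueError("panel contains monomorphic variants")
        for _, grp in self.variants.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing or grp["pos"].duplicated().any():
                raise ValueError("positions must be strictly increasing within a chromosome")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def eaf(self) -> np.ndarray:
        """Empirical effect-allele (a1) frequency in the panel."""
        return self.dosages.mean(axis=0) / 2.0

    def variant_index(self, variant_id: str) -> int:
        idx = np.flatnonzero((self.variants["id"] == variant_id).to_numpy())
        if idx.size == 0:
            raise KeyError(f"variant {variant_id!r} not in panel")
        return int(idx[0])

    def ld_r(self, ids_a: Sequence[str], ids_b: Sequence[str] | None = None) -> np.ndarray:
        """Signed dosage correlation between two sets of panel variants."""
        ia = [self.variant_index(v) for v in ids_a]
        if ids_b is None:
            return np.atleast_2d(np.corrcoef(self.dosages[:, ia], rowvar=False))
        ib = [self.variant_index(v) for v in ids_b]
        c = np.corrcoef(self.dosages[:, ia + ib], rowvar=False)
        return np.atleast_2d(c)[: len(ia), len(ia):]

    def resample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n fresh individuals from the panel's haplotype model."""
        cols = []
        for _, grp in self.variants.groupby("block", sort=True):
            cols.append(
                sample_block_genotypes(
                    rng, n, grp["maf"].to_numpy(), float(grp["latent_rho"].iloc[0])
                )
            )
        return np.concatenate(cols, axis=1)


@dataclass
class QtlDataset:
    """Cis association summary statistics for one or more probes.

    ``table`` follows the SMR query layout: probe, probe_chr, probe_bp,
    gene, snp, snp_chr, snp_bp, a1, a2, freq, b, se, p.  ``truth`` maps
    probe id to the generating architecture parameters.
    """

    table: pd.DataFrame
    n_study: int
    truth: dict = field(default_factory=dict)
    seed: int | None = None

    @property
    def probes(self) -> list[str]:
        return list(self.table["probe"].unique())

    def probe_table(self, probe_id: str) -> pd.DataFrame:
        return self.table[self.table["probe"] == probe_id]

    @staticmethod
    def concat(datasets: Sequence["QtlDataset"]) -> "QtlDataset":
        truth: dict = {}
        for d in datasets:
            truth.update(d.truth)
        return QtlDataset(
            table=pd.concat([d.table for d in datasets], ignore_index=True),
            n_study=datasets[0].n_study,
            truth=truth,
            seed=datasets[0].seed,
        )


@dataclass
class GwasSummary:
    """Marginal disease association results, COJO ``.ma``-style.

    ``table`` columns: snp, a1, a2, freq, b, se, p, n — per-allele
    log-odds effects from single-variant logistic regressions.
    """

    table: pd.DataFrame
    truth: dict = field(default_factory=dict)
    seed: int | None = None

    def record(self, snp: str) -> pd.Series:
        rows = self.table[self.table["snp"] == snp]
        if rows.empty:
            raise KeyError(f"variant {snp!r} not in GWAS summary")
        return rows.iloc[0]


@dataclass
class CohortData:
    """Individual-level dosages with binary outcome labels.

    ``design`` distinguishes a prevalent case-control sample from a
    prospective cohort with incident cases; both are scored and evaluated
    identically downstream.
    """

    dosages: np.ndarray
    labels: np.ndarray
    variants: pd.DataFrame
    design: Literal["case_control", "prospective"]
    iids: list[str] = field(default_factory=list)
    truth: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")
        if (self.labels == 1).sum() < 1 or (self.labels == 0).sum() < 1:
            raise ValueError("cohort needs at least one case and one non-case")
        if not self.iids:
            self.iids = [f"I{i:06d}" for i in range(self.dosages.shape[0])]

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def eaf(self) -> np.ndarray:
        """Observed effect-allele frequency (ignoring missing entries)."""
        return np.nanmean(self.dosages, axis=0) / 2.0


def make_reference_panel(
    spec: LdBlockSpec,
    n_individuals: int,
    seed: int,
    chrom: str = "1",
    block_spacing: int = 5_000_000,
    variant_spacing: int = 2_000,
) -> ReferencePanel:
    """Simulate a reference panel with the requested block-LD structure.

    Blocks are laid out ``block_spacing`` bp apart on one chromosome so a
    conventional 2 Mb cis window around a block's centre covers exactly
    that block.  Blocks that come out monomorphic at small n are redrawn
    (bounded retries) so the panel always satisfies its own invariants.
    """
    if n_individuals < 2:
        raise ValueError("n_individuals must be at least 2")
    rng = np.random.default_rng(seed)
    mafs = rng.uniform(spec.maf_range[0], spec.maf_range[1], size=spec.n_variants)
    allele_idx = rng.integers(0, len(_ALLELE_PAIRS), size=spec.n_variants)

    rows = []
    for j in range(spec.n_variants):
        block, offset = divmod(j, spec.block_size)
        a1, a2 = _ALLELE_PAIRS[allele_idx[j]]
        rows.append(
            {
                "chrom": chrom,
                "pos": 1 + block * block_spacing + offset * variant_spacing,
                "id": f"rs{j + 1}",
                "a1": a1,
                "a2": a2,
                "maf": mafs[j],
                "block": block,
                "latent_rho": 0.0,
            }
        )
    variants = pd.DataFrame(rows)

    cols = []
    for b in range(spec.n_blocks):
        block_mafs = variants.loc[variants["block"] == b, "maf"].to_numpy()
        rho = calibrate_latent_rho(spec.within_block_corr, float(block_mafs.mean()))
        variants.loc[variants["block"] == b, "latent_rho"] = rho
        geno = sample_block_genotypes(rng, n_individuals, block_mafs, rho)
        for _ in range(50):  # redraw monomorphic blocks (only plausible at tiny n)
            f = geno.mean(axis=0) / 2.0
            if np.all((f > 0) & (f < 1)):
                break
            geno = sample_block_genotypes(rng, n_individuals, block_mafs, rho)
        cols.append(geno)

    return ReferencePanel(variants=variants, dosages=np.concatenate(cols, axis=1), seed=seed)


def _marginal_ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-column simple linear regression of y on X (vectorised)."""
    n = y.shape[0]
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sxx = (xc**2).sum(axis=0)
    sxy = xc.T @ yc
    syy = float(yc @ yc)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sxy / sxx
        rss = np.maximum(syy - beta * sxy, 0.0)
        se = np.sqrt(rss / (n - 2) / sxx)
        tstat = beta / se
    p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    mono = sxx <= 0
    beta[mono], se[mono], p[mono] = 0.0, np.inf, 1.0
    p[~np.isfinite(p)] = 1.0
    return beta, se, p


def make_qtl_study(
    panel: ReferencePanel,
    arch: ArchitectureSpec,
    n_study: int,
    probe_meta: ProbeMeta,
    seed: int,
    cis_window: int = 2_000_000,
    p_include: float | None = None,
) -> QtlDataset:
    """Simulate one probe's cis-QTL summary statistics.

    A molecular trait is simulated in an independent sample drawn from the
    panel's haplotype model (trait = b_zx * causal dosage + noise, or pure
    noise under the null/linkage-without-QTL settings) and regressed on
    each cis variant's dosage.  ``p_include`` optionally drops records
    above a p-value inclusion threshold, mimicking "lite" QTL releases
    that ship significant associations only.
    """
    if arch.mode != "null" and arch.causal_variant_id is not None:
        panel.variant_index(arch.causal_variant_id)  # raises KeyError if unknown

    rng = np.random.default_rng(seed)
    half = cis_window // 2
    in_cis = (panel.variants["chrom"] == probe_meta.chrom) & (
        (panel.variants["pos"] - probe_meta.position).abs() <= half
    )
    cis = panel.variants[in_cis]
    if cis.empty:
        raise ValueError(f"no panel variants in cis window of probe {probe_meta.probe_id}")

    geno = panel.resample(n_study, rng)
    trait = rng.normal(0.0, arch.trait_noise_sd, size=n_study)
    if arch.mode != "null" and arch.b_zx != 0.0:
        trait = trait + arch.b_zx * geno[:, panel.variant_index(arch.causal_variant_id)]

    cis_idx = np.flatnonzero(in_cis.to_numpy())
    beta, se, p = _marginal_ols(trait, geno[:, cis_idx])

    table = pd.DataFrame(
        {
            "probe": probe_meta.probe_id,
            "probe_chr": probe_meta.chrom,
            "probe_bp": probe_meta.position,
            "gene": probe_meta.gene,
            "snp": cis["id"].to_numpy(),
            "snp_chr": cis["chrom"].to_numpy(),
            "snp_bp": cis["pos"].to_numpy(),
            "a1": cis["a1"].to_numpy(),
            "a2": cis["a2"].to_numpy(),
            "freq": geno[:, cis_idx].mean(axis=0) / 2.0,
            "b": beta,
            "se": se,
            "p": p,
        }
    )
    if p_include is not None:
        table = table[table["p"] < p_include].reset_index(drop=True)
    truth = {probe_meta.probe_id: {"arch": arch, "n_study": n_study}}
    return QtlDataset(table=table, n_study=n_study, truth=truth, seed=seed)


def _marginal_logit(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-column logistic regression (intercept + dosage) via statsmodels."""
    m = X.shape[1]
    beta = np.zeros(m)
    se = np.full(m, np.inf)
    p = np.ones(m)
    for j in range(m):
        x = X[:, j]
        if x.std() == 0:
            continue  # monomorphic: p=1 sentinel, non-finite SE
        try:
            fit = sm.Logit(y, sm.add_constant(x)).fit(disp=0, maxiter=60)
            b_j, se_j = fit.params[1], fit.bse[1]
            if not np.isfinite(se_j) or se_j <= 0:
                continue
            beta[j], se[j] = b_j, se_j
            p[j] = 2.0 * stats.norm.sf(abs(b_j / se_j))
        except Exception:
            continue  # separation or non-convergence: keep sentinel
    return beta, se, p


def _sample_outcome_cohort(
    panel: ReferencePanel,
    eta_fn,
    n_cases: int,
    n_noncases: int,
    rng: np.random.Generator,
    base_rate: float = 0.5,
    max_batches: int = 40,
) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample individuals from the panel model until the requested
    case / non-case counts are met under a logistic outcome model."""
    alpha = float(logit(base_rate))
    # centre the linear predictor (estimated once, on the first batch) so the
    # realised prevalence stays near base_rate whatever the effect sizes
    mu = None
    batch = max(200, int(1.3 * (n_cases + n_noncases)))
    case_rows, ctrl_rows = [], []
    got_cases = got_ctrls = 0
    for _ in range(max_batches):
        geno = panel.resample(batch, rng)
        eta = eta_fn(geno, rng)
        if mu is None:
            mu = float(eta.mean())
        prob = expit(alpha + eta - mu)
        y = rng.random(batch) < prob
        if got_cases < n_cases:
            take = geno[y][: n_cases - got_cases]
            case_rows.append(take)
            got_cases += take.shape[0]
        if got_ctrls < n_noncases:
            take = geno[~y][: n_noncases - got_ctrls]
            ctrl_rows.append(take)
            got_ctrls += take.shape[0]
        if got_cases >= n_cases and got_ctrls >= n_noncases:
            geno_all = np.concatenate(case_rows + ctrl_rows, axis=0)
            labels = np.concatenate(
                [np.ones(n_cases, dtype=int), np.zeros(n_noncases, dtype=int)]
            )
            perm = rng.permutation(len(labels))
            return geno_all[perm], labels[perm]
    raise RuntimeError(
        "retry budget exceeded while sampling the requested case/non-case counts; "
        "effect sizes or base rate make the design infeasible"
    )


def make_gwas_study(
    panel: ReferencePanel,
    arch: ArchitectureSpec,
    n_cases: int,
    n_controls: int,
    seed: int,
    base_rate: float = 0.5,
) -> GwasSummary:
    """Simulate disease GWAS summary statistics under a causal architecture.

    Disease status follows a logistic model whose linear predictor is
    b_xy * (molecular trait) under pleiotropy — so the causal variant's
    marginal log-odds effect is approximately b_zx*b_xy by mediation — or
    b_zy_direct * (direct-variant dosage) under linkage.  Each panel
    variant is then tested by single-variant logistic regression in the
    realised case-control sample.
    """
    if n_cases < 50 or n_controls < 50:
        raise ValueError("need at least 50 cases and 50 controls for stable logistic fits")
    rng = np.random.default_rng(seed)

    if arch.mode == "pleiotropy":
        c_idx = panel.variant_index(arch.causal_variant_id)

        def eta_fn(geno, r):
            trait = arch.b_zx * geno[:, c_idx] + r.normal(
                0.0, arch.trait_noise_sd, size=geno.shape[0]
            )
            return arch.b_xy * trait

    elif arch.mode == "linkage":
        d_idx = panel.variant_index(arch.direct_variant_id)

        def eta_fn(geno, r):
            return arch.b_zy_direct * geno[:, d_idx]

    else:

        def eta_fn(geno, r):
            return np.zeros(geno.shape[0])

    geno, y = _sample_outcome_cohort(panel, eta_fn, n_cases, n_controls, rng, base_rate)
    beta, se, p = _marginal_logit(y.astype(float), geno)

    n_total = n_cases + n_controls
    table = pd.DataFrame(
        {
            "snp": panel.variants["id"].to_numpy(),
            "a1": panel.variants["a1"].to_numpy(),
            "a2": panel.variants["a2"].to_numpy(),
            "freq": geno.mean(axis=0) / 2.0,
            "b": beta,
            "se": se,
            "p": p,
            "n": n_total,
        }
    )
    truth = {"arch": arch, "n_cases": n_cases, "n_controls": n_controls}
    return GwasSummary(table=table, truth=truth, seed=seed)


def make_cohort(
    panel: ReferencePanel,
    true_weights,
    design: Literal["case_control", "prospective"],
    n_cases: int,
    n_noncases: int,
    seed: int,
    missing_rate: float = 0.0,
    base_rate: float | None = None,
) -> CohortData:
    """Simulate an individual-level cohort whose outcome follows a true PRS.

    ``true_weights`` is a PRS model (variant id, effect allele, weight);
    the outcome is drawn from a logistic model whose linear predictor is
    the true score.  ``base_rate`` defaults to 0.5 for case-control
    sampling efficiency and to a low incidence (n_cases/(n_cases+n_noncases))
    for prospective designs; case-control sampling leaves per-variant
    log-odds effects unchanged, only the intercept.  Missing dosages are
    inserted completely at random at ``missing_rate``.
    """
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)

    wtab = true_weights.table
    idx = np.array([panel.variant_index(s) for s in wtab["snp"]])
    flip = np.zeros(len(wtab), dtype=bool)
    for k, (_, row) in enumerate(wtab.iterrows()):
        pa1 = panel.variants.iloc[idx[k]]["a1"]
        pa2 = panel.variants.iloc[idx[k]]["a2"]
        if row["effect_allele"] == pa1:
            flip[k] = False
        elif row["effect_allele"] == pa2:
            flip[k] = True
        else:
            raise ValueError(f"effect allele of {row['snp']} not found in panel")
    w = wtab["weight"].to_numpy(dtype=float)

    def eta_fn(geno, r):
        x = geno[:, idx].copy()
        x[:, flip] = 2.0 - x[:, flip]
        return x @ w

    if base_rate is None:
        base_rate = 0.5 if design == "case_control" else max(
            0.01, n_cases / (n_cases + n_noncases)
        )
    geno, labels = _sample_outcome_cohort(panel, eta_fn, n_cases, n_noncases, rng, base_rate)

    if missing_rate > 0:
        mask = rng.random(geno.shape) < missing_rate
        geno = geno.astype(float)
        geno[mask] = np.nan

    truth = {
        "weights": {s: float(v) for s, v in zip(wtab["snp"], wtab["weight"])},
        "design": design,
        "base_rate": base_rate,
    }
    return CohortData(
        dosages=geno,
        labels=labels,
        variants=panel.variants[["chrom", "pos", "id", "a1", "a2"]].reset_index(drop=True),
        design=design,
        truth=truth,
        seed=seed,
    )
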