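"""Summary-data Mendelian randomization (SMR) with the HEIDI linkage filter.

For each molecular probe the scan takes the strongest cis-QTL variant as
the instrument and forms the ratio estimate b_smr = b_zy / b_zx of the
effect of the molecular trait on disease.  Its chi-square statistic

    T_smr = z_zy^2 * z_zx^2 / (z_zy^2 + z_zx^2),   z = b / se,

is referred to a 1-df chi-square.  HEIDI then asks whether the ratio
estimates from other cis-SNPs in LD with the top SNP are homogeneous:
under a single shared causal variant (pleiotropy) all instruments estimate
the same b_xy, whereas distinct causal variants in LD (linkage) make the
per-SNP deviations d_i = b_xy(i) - b_xy(top) systematically non-zero.
The HEIDI statistic sums the squared standardised deviations and is
referred to its correlated null, a weighted sum of 1-df chi-squares.

A probe is nominated as "functional" when p_smr < 5e-8 and p_heidi > 0.05,
the filter pair used throughout the downstream PRS construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .alleles import harmonize
from .synth import GwasSummary, QtlDataset, ReferencePanel
from .tail import weighted_chisq_tail

__all__ = [
    "SMR_P_THRESHOLD",
    "HEIDI_P_THRESHOLD",
    "HeidiConfig",
    "SmrStat",
    "compute_smr",
    "select_instruments",
    "compute_heidi",
    "run_smr_scan",
]

logger = logging.getLogger(__name__)

SMR_P_THRESHOLD = 5e-8
HEIDI_P_THRESHOLD = 0.05


@dataclass(frozen=True)
class HeidiConfig:
    """Instrument-selection settings for the HEIDI test.

    Defaults mirror the reference SMR implementation's documented
    behaviour: candidate instruments need QTL p < 1.57e-3 (z^2 > 10) and
    LD r^2 with the top SNP inside [0.05, 0.9]; between ``min_instruments``
    and ``max_instruments`` SNPs are used, ranked by QTL significance.
    """

    instrument_p_max: float = 1.57e-3
    r2_min: float = 0.05
    r2_max: float = 0.9
    max_instruments: int = 20
    min_instruments: int = 3

    def __post_init__(self) -> None:
        if not 0.0 < self.r2_min < self.r2_max <= 1.0:
            raise ValueError("need 0 < r2_min < r2_max <= 1")
        if not self.max_instruments >= self.min_instruments >= 1:
            raise ValueError("need max_instruments >= min_instruments >= 1")


@dataclass(frozen=True)
class SmrStat:
    """One SMR ratio test: estimate, delta-method SE, statistic and p."""

    ok: bool
    b_smr: float = np.nan
    se_smr: float = np.nan
    t_smr: float = np.nan
    p_smr: float = np.nan
    reason: str | None = None


def compute_smr(b_zy: float, se_zy: float, b_zx: float, se_zx: float) -> SmrStat:
    """SMR ratio test from one GWAS and one QTL effect at the same variant.

    Both effects must already be oriented to the same effect allele.
    A zero or non-finite QTL effect (or SE) makes the ratio undefined and
    is flagged rather than raised, so scans can skip such records.
    """
    vals = (b_zy, se_zy, b_zx, se_zx)
    if not all(np.isfinite(v) for v in vals) or se_zy <= 0 or se_zx <= 0:
        return SmrStat(ok=False, reason="non-finite effect or SE")
    if b_zx == 0.0:
        return SmrStat(ok=False, reason="zero QTL effect")
    z_zy2 = (b_zy / se_zy) ** 2
    z_zx2 = (b_zx / se_zx) ** 2
    b_smr = b_zy / b_zx
    if z_zy2 == 0.0:
        return SmrStat(ok=True, b_smr=0.0, se_smr=np.nan, t_smr=0.0, p_smr=1.0)
    t_smr = z_zy2 * z_zx2 / (z_zy2 + z_zx2)
    se_smr = abs(b_smr) / np.sqrt(t_smr)
    p_smr = float(chi2.sf(t_smr, df=1))
    return SmrStat(ok=True, b_smr=b_smr, se_smr=se_smr, t_smr=t_smr, p_smr=max(p_smr, 1e-300))


def select_instruments(
    probe_table: pd.DataFrame,
    panel: ReferencePanel,
    top_snp: str,
    cfg: HeidiConfig,
) -> list[str]:
    """Pick HEIDI instruments for one probe.

    Eligible variants have QTL p below ``cfg.instrument_p_max`` and squared
    correlation with the top SNP within [r2_min, r2_max]; the top SNP
    itself is excluded.  Instruments are ranked by ascending QTL p and
    truncated to ``cfg.max_instruments``.
    """
    panel.variant_index(top_snp)  # raises KeyError when absent
    cand = probe_table[(probe_table["snp"] != top_snp) & (probe_table["p"] < cfg.instrument_p_max)]
    cand = cand[cand["snp"].isin(set(panel.variants["id"]))]
    if cand.empty:
        return []
    r = panel.ld_r(list(cand["snp"]), [top_snp]).ravel()
    r2 = r**2
    keep = (r2 >= cfg.r2_min) & (r2 <= cfg.r2_max)
    cand = cand[keep].sort_values("p", kind="mergesort")
    return list(cand["snp"].head(cfg.max_instruments))


def _ratio_cov(
    b_zy: np.ndarray,
    se_zy: np.ndarray,
    b_zx: np.ndarray,
    se_zx: np.ndarray,
    r: np.ndarray,
) -> np.ndarray:
    """Delta-method covariance of the ratio estimates b_zy/b_zx across SNPs.

    GWAS and QTL samples are independent; within each study the covariance
    of marginal effect estimates at two SNPs is approximated by
    r_ij * se_i * se_j with r_ij the panel LD correlation.
    """
    inv_g = 1.0 / b_zx
    cov_f = r * np.outer(se_zy, se_zy)
    cov_g = r * np.outer(se_zx, se_zx)
    term1 = np.outer(inv_g, inv_g) * cov_f
    fac = b_zy / b_zx**2
    term2 = np.outer(fac, fac) * cov_g
    return term1 + term2


def compute_heidi(
    b_zy: np.ndarray,
    se_zy: np.ndarray,
    b_zx: np.ndarray,
    se_zx: np.ndarray,
    ld_r: np.ndarray,
) -> tuple[float, int]:
    """HEIDI heterogeneity p-value for one probe.

    Arrays are ordered with the top SNP first, followed by the
    instruments; ``ld_r`` is the signed dosage-correlation matrix in the
    same order.  Returns (p_heidi, number of instruments used).
    """
    b_zy = np.asarray(b_zy, float)
    se_zy = np.asarray(se_zy, float)
    b_zx = np.asarray(b_zx, float)
    se_zx = np.asarray(se_zx, float)
    ld_r = np.asarray(ld_r, float)
    m = b_zy.size
    if m < 2:
        raise ValueError("HEIDI needs the top SNP plus at least one instrument")
    if ld_r.shape != (m, m):
        raise ValueError("LD matrix shape does not match the SNP set")
    if np.any(b_zx == 0) or np.any(~np.isfinite(se_zx)) or np.any(~np.isfinite(se_zy)):
        raise ValueError("non-computable effect/SE among HEIDI SNPs")

    bxy = b_zy / b_zx
    cov_bxy = _ratio_cov(b_zy, se_zy, b_zx, se_zx, ld_r)

    # deviations of each instrument's ratio estimate from the top SNP's
    d = bxy[1:] - bxy[0]
    k = m - 1
    cov_d = (
        cov_bxy[1:, 1:]
        - cov_bxy[1:, [0]]
        - cov_bxy[[0], 1:]
        + cov_bxy[0, 0]
    )
    var_d = np.diag(cov_d).copy()
    if np.any(var_d <= 0) or np.any(~np.isfinite(var_d)):
        raise np.linalg.LinAlgError("degenerate deviation variance in HEIDI")
    sd = np.sqrt(var_d)
    z_d = d / sd
    corr_d = cov_d / np.outer(sd, sd)

    t_heidi = float(np.sum(z_d**2))
    weights = np.linalg.eigvalsh((corr_d + corr_d.T) / 2.0)
    weights = weights[weights > 1e-8 * max(1.0, weights.max())]
    if weights.size == 0:
        return 1.0, k
    p = weighted_chisq_tail(weights, t_heidi)
    return float(p), k


def _harmonized_probe(
    probe_table: pd.DataFrame, gwas_table: pd.DataFrame
) -> tuple[pd.DataFrame, int]:
    """Merge one probe's QTL records with the GWAS table on a common
    effect allele; returns the merged frame and the dropped-record count."""
    merged = probe_table.merge(
        gwas_table, on="snp", how="inner", suffixes=("_qtl", "_gwas")
    )
    if merged.empty:
        return merged, 0
    keep, b_gwas, f_gwas = [], [], []
    dropped = 0
    for _, row in merged.iterrows():
        res = harmonize(
            row["a1_gwas"],
            row["a2_gwas"],
            row["a1_qtl"],
            row["a2_qtl"],
            eaf=row["freq_gwas"],
            ref_eaf=row["freq_qtl"],
        )
        if not res.ok or not np.isfinite(row["se_gwas"]) or row["se_gwas"] <= 0:
            dropped += 1
            keep.append(False)
            b_gwas.append(np.nan)
            f_gwas.append(np.nan)
            continue
        keep.append(True)
        b_gwas.append(-row["b_gwas"] if res.flip else row["b_gwas"])
        f_gwas.append(1.0 - row["freq_gwas"] if res.flip else row["freq_gwas"])
    merged = merged.assign(b_zy=b_gwas, freq_zy=f_gwas)[keep].reset_index(drop=True)
    return merged, dropped


def run_smr_scan(
    gwas: GwasSummary,
    qtl: QtlDataset,
    panel: ReferencePanel,
    smr_p_threshold: float = SMR_P_THRESHOLD,
    heidi_p_threshold: float = HEIDI_P_THRESHOLD,
    cfg: HeidiConfig | None = None,
) -> pd.DataFrame:
    """Run the SMR + HEIDI scan over every probe in a QTL dataset.

    Per probe: the minimum-QTL-p variant shared with the GWAS is the top
    SNP; the SMR ratio test is computed there; HEIDI runs when enough
    instruments are available, otherwise its p is reported missing (NaN)
    and the probe cannot pass.  ``passed`` requires
    p_smr < smr_p_threshold and p_heidi > heidi_p_threshold.

    Returns a DataFrame with columns probe, gene, top_snp, b_smr, se_smr,
    p_smr, p_heidi, n_heidi_snps, passed; scan-level attrition counts are
    stored in ``result.attrs``.
    """
    cfg = cfg or HeidiConfig()
    rows = []
    n_skipped_no_shared = 0
    n_dropped_harmonize = 0
    gwas_by_snp = gwas.table

    for probe_id in qtl.probes:
        ptab = qtl.probe_table(probe_id)
        merged, dropped = _harmonized_probe(ptab, gwas_by_snp)
        n_dropped_harmonize += dropped
        merged = merged[merged["snp"].isin(set(panel.variants["id"]))]
        if merged.empty:
            n_skipped_no_shared += 1
            continue
        top = merged.loc[merged["p_qtl"].idxmin()]
        stat = compute_smr(top["b_zy"], top["se_gwas"], top["b_qtl"], top["se_qtl"])
        if not stat.ok:
            n_skipped_no_shared += 1
            continue

        qtl_for_sel = merged.rename(columns={"p_qtl": "p"})[["snp", "p"]]
        instruments = select_instruments(qtl_for_sel, panel, top["snp"], cfg)
        p_heidi = np.nan
        n_heidi = 0
        if len(instruments) >= cfg.min_instruments:
            sel = merged.set_index("snp").loc[[top["snp"], *instruments]]
            ld = panel.ld_r([top["snp"], *instruments])
            try:
                p_heidi, n_heidi = compute_heidi(
                    sel["b_zy"].to_numpy(),
                    sel["se_gwas"].to_numpy(),
                    sel["b_qtl"].to_numpy(),
                    sel["se_qtl"].to_numpy(),
                    ld,
                )
            except np.linalg.LinAlgError as err:
                raise np.linalg.LinAlgError(f"HEIDI failed for probe {probe_id}: {err}")
        passed = bool(
            stat.p_smr < smr_p_threshold
            and np.isfinite(p_heidi)
            and p_heidi > heidi_p_threshold
        )
        rows.append(
            {
                "probe": probe_id,
                "gene": ptab["gene"].iloc[0],
                "top_snp": top["snp"],
                "b_smr": stat.b_smr,
                "se_smr": stat.se_smr,
                "p_smr": stat.p_smr,
                "p_heidi": p_heidi,
                "n_heidi_snps": n_heidi,
                "passed": passed,
            }
        )

    out = pd.DataFrame(
        rows,
        columns=[
            "probe",
            "gene",
            "top_snp",
            "b_smr",
            "se_smr",
            "p_smr",
            "p_heidi",
            "n_heidi_snps",
            "passed",
        ],
    )
    out.attrs["n_probes_skipped_no_shared"] = n_skipped_no_shared
    out.attrs["n_records_dropped_harmonization"] = n_dropped_harmonize
    out.attrs["n_top_snps_passed_raw"] = int(out["passed"].sum())
    out.attrs["n_top_snps_passed_unique"] = int(out.loc[out["passed"], "top_snp"].nunique())
    if out.empty:
        logger.warning("SMR scan produced no results (no shared variants)")
    logger.info(
        "SMR scan: %d probes tested, %d skipped (no shared/computable variants), "
        "%d records dropped in harmonization, %d passed (%d unique top SNPs)",
        len(out),
        n_skipped_no_shared,
        n_dropped_harmonize,
        out.attrs["n_top_snps_passed_raw"],
        out.attrs["n_top_snps_passed_unique"],
    )
    return out
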