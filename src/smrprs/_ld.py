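"""Latent-Gaussian haplotype machinery shared by all synthetic generators.

Genotypes are sums of two independent haplotypes.  Within an LD block each
haplotype's alleles are thresholded from an equicorrelated (one-factor)
standard-normal vector; the latent correlation is calibrated numerically so
that the *binary allele* correlation — and hence the dosage correlation —
hits the requested target, which a naive copula would undershoot
(dichotomisation attenuates correlation).
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq
from scipy.special import ndtri, owens_t
from scipy.stats import norm

__all__ = ["allele_corr", "calibrate_latent_rho", "sample_block_genotypes"]


def _bvn_cdf_equal(h: float, rho: float) -> float:
    """P(X<=h, Y<=h) for standard bivariate normal with correlation rho."""
    if rho >= 1.0:
        return float(norm.cdf(h))
    a = np.sqrt((1.0 - rho) / (1.0 + rho))
    return float(norm.cdf(h) - 2.0 * owens_t(h, a))


def allele_corr(rho: float, maf: float) -> float:
    """Correlation of two Bernoulli(maf) alleles thresholded at latent corr rho."""
    t = float(ndtri(maf))
    p11 = _bvn_cdf_equal(t, rho)
    return (p11 - maf * maf) / (maf * (1.0 - maf))


def calibrate_latent_rho(target_r: float, maf: float) -> float:
    """Latent correlation giving allele correlation ``target_r`` at this MAF.

    The calibration uses a single representative MAF per block; with MAFs
    drawn from a narrow range the realised pairwise correlations are close
    to the target (exact when MAFs are equal).
    """
    if not 0.0 <= target_r < 1.0:
        raise ValueError(f"target correlation must be in [0, 1), got {target_r}")
    if target_r == 0.0:
        return 0.0
    lo, hi = 0.0, 0.999999
    f = lambda rho: allele_corr(rho, maf) - target_r
    if f(hi) < 0:  # target unreachable (can't happen for r<1 in practice)
        return hi
    return float(brentq(f, lo, hi, xtol=1e-10))


def sample_block_genotypes(
    rng: np.random.Generator, n: int, mafs: np.ndarray, latent_rho: float
) -> np.ndarray:
    """Draw an n x len(mafs) dosage matrix for one LD block (HWE by construction)."""
    mafs = np.asarray(mafs, dtype=float)
    t = ndtri(mafs)  # allele = 1 iff latent < t, so P(allele)=maf
    m = mafs.size
    geno = np.zeros((n, m), dtype=float)
    a = np.sqrt(latent_rho)
    b = np.sqrt(1.0 - latent_rho)
    for _hap in range(2):
        w = rng.standard_normal((n, 1))
        e = rng.standard_normal((n, m))
        z = a * w + b * e
        geno += (z < t).astype(float)
    return geno
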