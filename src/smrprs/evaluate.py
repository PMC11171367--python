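"""Discrimination metrics for polygenic risk scores.

Continuous scores are summarised by the AUC (Mann–Whitney probability that
a random case outscores a random control, ties counted half) with a DeLong
95% CI, and by the odds ratio per standard deviation of score from a
univariable logistic regression.  Two operating points are reported: the
Youden-optimal threshold, and the epidemiological 80th-centile rule, which
calls an individual high-risk when their score exceeds the 80th centile of
the *control* score distribution — fixing specificity at 0.8 by
construction.  For a binary classifier AUC = (sensitivity+specificity)/2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy.stats import norm, rankdata
from statsmodels.stats.contingency_tables import Table2x2

from .prs import ScoreSet

__all__ = [
    "Binary80",
    "EvalReport",
    "OverlapReport",
    "auc_ci",
    "or_per_sd",
    "youden_point",
    "binary_high_risk",
    "evaluate_scores",
    "joint_model_auc",
    "overlap_analysis",
]


@dataclass(frozen=True)
class Binary80:
    """High/low-risk dichotomisation at a control-score centile."""

    centile: float
    threshold: float
    sensitivity: float
    specificity: float
    auc_binary: float
    or_binary: float
    or_ci: tuple[float, float]


@dataclass(frozen=True)
class EvalReport:
    """Full discrimination report for one score set."""

    label: str
    n_cases: int
    n_controls: int
    n_variants_used: int
    auc: float
    auc_ci: tuple[float, float]
    or_per_sd: float
    or_per_sd_ci: tuple[float, float]
    youden: tuple[float, float, float]  # threshold, sensitivity, specificity
    binary80: Binary80

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
            "n_variants_used": self.n_variants_used,
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "or_per_sd": self.or_per_sd,
            "or_per_sd_ci": list(self.or_per_sd_ci),
            "youden": {
                "threshold": self.youden[0],
                "sensitivity": self.youden[1],
                "specificity": self.youden[2],
            },
            "binary": {
                "centile": self.binary80.centile,
                "threshold": self.binary80.threshold,
                "sensitivity": self.binary80.sensitivity,
                "specificity": self.binary80.specificity,
                "auc_binary": self.binary80.auc_binary,
                "or_binary": self.binary80.or_binary,
                "or_binary_ci": list(self.binary80.or_ci),
            },
        }


@dataclass(frozen=True)
class OverlapReport:
    """Cross-tabulation of two scores' high-risk flags, by case status."""

    centile: float
    cells: dict = field(default_factory=dict)  # stratum -> {both, only_a, only_b, neither}
    labels: tuple[str, str] = ("a", "b")

    def to_dict(self) -> dict:
        return {"centile": self.centile, "labels": list(self.labels), "cells": self.cells}


def _check_two_class(scores: ScoreSet) -> tuple[np.ndarray, np.ndarray]:
    cases = scores.case_scores
    controls = scores.control_scores
    if cases.size == 0 or controls.size == 0:
        raise ValueError("need at least one case and one control")
    return cases, controls


def _auc_mann_whitney(cases: np.ndarray, controls: np.ndarray) -> float:
    ranks = rankdata(np.concatenate([cases, controls]))
    r_cases = ranks[: cases.size].sum()
    n1, n0 = cases.size, controls.size
    return (r_cases - n1 * (n1 + 1) / 2.0) / (n1 * n0)


def _delong_variance(cases: np.ndarray, controls: np.ndarray) -> float:
    """DeLong's structural-component variance of the empirical AUC."""
    n1, n0 = cases.size, controls.size
    # V10_i = P(control < case_i) + 0.5 P(control == case_i), and symmetrically
    order = np.sort(controls)
    lo = np.searchsorted(order, cases, side="left")
    hi = np.searchsorted(order, cases, side="right")
    v10 = (lo + 0.5 * (hi - lo)) / n0
    order = np.sort(cases)
    lo = np.searchsorted(order, controls, side="right")
    hi = np.searchsorted(order, controls, side="left")
    v01 = ((n1 - lo) + 0.5 * (lo - hi)) / n1
    s10 = v10.var(ddof=1) if n1 > 1 else 0.0
    s01 = v01.var(ddof=1) if n0 > 1 else 0.0
    return s10 / n1 + s01 / n0


def auc_ci(scores: ScoreSet, alpha: float = 0.05) -> tuple[float, float, float]:
    """Empirical AUC with a DeLong 95% confidence interval."""
    cases, controls = _check_two_class(scores)
    auc = _auc_mann_whitney(cases, controls)
    se = float(np.sqrt(_delong_variance(cases, controls)))
    z = norm.ppf(1.0 - alpha / 2.0)
    return float(auc), float(max(0.0, auc - z * se)), float(min(1.0, auc + z * se))


def or_per_sd(
    scores: ScoreSet, alpha: float = 0.05, sd_from: str = "pooled"
) -> tuple[float, float, float]:
    """Odds ratio per standard deviation of score (univariable logistic fit).

    ``sd_from`` selects the standardising SD: the full pooled sample
    (default) or the controls only.
    """
    cases, controls = _check_two_class(scores)
    x = scores.scores
    sd = x.std(ddof=1) if sd_from == "pooled" else controls.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("score variance must be positive")
    xs = (x - x.mean()) / sd
    y = scores.labels.astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.Logit(y, sm.add_constant(xs)).fit(disp=0, maxiter=100)
    beta, se = fit.params[1], fit.bse[1]
    if not np.isfinite(se) or se <= 0 or se > 1e3:
        raise ValueError("logistic fit failed (complete separation?)")
    z = norm.ppf(1.0 - alpha / 2.0)
    return float(np.exp(beta)), float(np.exp(beta - z * se)), float(np.exp(beta + z * se))


def youden_point(scores: ScoreSet) -> tuple[float, float, float]:
    """Threshold maximising Youden's J = sensitivity + specificity - 1.

    Candidate thresholds are midpoints between adjacent distinct scores;
    classification is score > threshold.  On ties in J the smallest
    qualifying threshold is returned (maximal sensitivity).  All-identical
    scores are degenerate: J = 0 with a warning.
    """
    cases, controls = _check_two_class(scores)
    distinct = np.unique(scores.scores)
    if distinct.size == 1:
        warnings.warn("all scores identical; Youden point is degenerate")
        return float(distinct[0]), 1.0, 0.0
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    sens = (cases[None, :] > mids[:, None]).mean(axis=1)
    spec = (controls[None, :] <= mids[:, None]).mean(axis=1)
    j = sens + spec - 1.0
    best = int(np.argmax(j))  # argmax takes the first (smallest) threshold on ties
    return float(mids[best]), float(sens[best]), float(spec[best])


def _table2x2_or(
    n11: int, n10: int, n01: int, n00: int, alpha: float = 0.05
) -> tuple[float, tuple[float, float]]:
    table = np.array([[n11, n10], [n01, n00]], dtype=float)
    if (table == 0).any():
        table = table + 0.5  # Haldane-Anscombe correction
    t = Table2x2(table)
    ci = t.oddsratio_confint(alpha)
    return float(t.oddsratio), (float(ci[0]), float(ci[1]))


def binary_high_risk(scores: ScoreSet, centile: float = 80.0) -> Binary80:
    """Dichotomise at the given centile of the *control* score distribution.

    The threshold is the type-7 (linear-interpolation) centile of control
    scores; individuals strictly above it are high risk.  With distinct
    control scores and n_controls divisible by 100/(100-centile) the
    specificity is exact by construction (0.8 at the 80th centile).
    """
    if not 0.0 < centile < 100.0:
        raise ValueError("centile must be inside (0, 100)")
    cases, controls = _check_two_class(scores)
    if controls.size < 5:
        raise ValueError("need at least 5 controls to anchor the centile threshold")
    thr = float(np.quantile(controls, centile / 100.0))  # type-7 default
    sens = float((cases > thr).mean())
    spec = float((controls <= thr).mean())
    auc_b = (sens + spec) / 2.0
    n11 = int((cases > thr).sum())
    n10 = cases.size - n11
    n01 = int((controls > thr).sum())
    n00 = controls.size - n01
    or_b, or_ci = _table2x2_or(n11, n01, n10, n00)
    return Binary80(
        centile=float(centile),
        threshold=thr,
        sensitivity=sens,
        specificity=spec,
        auc_binary=auc_b,
        or_binary=or_b,
        or_ci=or_ci,
    )


def evaluate_scores(scores: ScoreSet, centile: float = 80.0) -> EvalReport:
    """Full report: AUC+CI, OR/SD+CI, Youden point and the centile rule."""
    cases, controls = _check_two_class(scores)
    auc, lo, hi = auc_ci(scores)
    orr, or_lo, or_hi = or_per_sd(scores)
    return EvalReport(
        label=scores.label,
        n_cases=int(cases.size),
        n_controls=int(controls.size),
        n_variants_used=scores.n_variants_used,
        auc=auc,
        auc_ci=(lo, hi),
        or_per_sd=orr,
        or_per_sd_ci=(or_lo, or_hi),
        youden=youden_point(scores),
        binary80=binary_high_risk(scores, centile),
    )


def _check_same_individuals(a: ScoreSet, b: ScoreSet) -> None:
    if a.scores.size != b.scores.size or not np.array_equal(a.labels, b.labels):
        raise ValueError("score sets must cover the same individuals in the same order")
    if a.iids and b.iids and a.iids != b.iids:
        raise ValueError("score sets must cover the same individuals in the same order")


def joint_model_auc(a: ScoreSet, b: ScoreSet, alpha: float = 0.05) -> tuple[float, float, float]:
    """AUC of the linear predictor from a logistic fit on both scores.

    A (near-)collinear second score adds nothing and is dropped before the
    fit so the joint AUC degrades gracefully to the single-score AUC.
    """
    _check_same_individuals(a, b)
    y = a.labels.astype(float)
    xa = (a.scores - a.scores.mean()) / (a.scores.std(ddof=1) or 1.0)
    xb = (b.scores - b.scores.mean()) / (b.scores.std(ddof=1) or 1.0)
    if b.scores.std(ddof=1) == 0 or abs(np.corrcoef(xa, xb)[0, 1]) > 1.0 - 1e-12:
        pred = xa if a.scores.std(ddof=1) > 0 else np.zeros_like(xa)
        fit = sm.Logit(y, sm.add_constant(pred)).fit(disp=0, maxiter=100)
        lp = fit.params[1] * pred
    else:
        X = sm.add_constant(np.column_stack([xa, xb]))
        fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
        lp = X[:, 1:] @ fit.params[1:]
    joint = ScoreSet(scores=lp, labels=a.labels, label=f"joint({a.label},{b.label})")
    return auc_ci(joint, alpha)


def overlap_analysis(a: ScoreSet, b: ScoreSet, centile: float = 80.0) -> OverlapReport:
    """Agreement of two scores' high-risk calls at the centile rule.

    Both scores are dichotomised independently at their own control-score
    centile; the four-cell agreement table is reported separately for
    cases and controls.
    """
    _check_same_individuals(a, b)
    thr_a = float(np.quantile(a.control_scores, centile / 100.0))
    thr_b = float(np.quantile(b.control_scores, centile / 100.0))
    flag_a = a.scores > thr_a
    flag_b = b.scores > thr_b
    cells = {}
    for stratum, mask in (("cases", a.labels == 1), ("controls", a.labels == 0)):
        fa, fb = flag_a[mask], flag_b[mask]
        cells[stratum] = {
            "both": int((fa & fb).sum()),
            "only_a": int((fa & ~fb).sum()),
            "only_b": int((~fa & fb).sum()),
            "neither": int((~fa & ~fb).sum()),
            "n": int(mask.sum()),
        }
    return OverlapReport(centile=float(centile), cells=cells, labels=(a.label, b.label))
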