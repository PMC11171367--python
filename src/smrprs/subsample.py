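"""Variant-count-balancing simulation.

When two risk scores differ in variant count, their AUCs are not directly
comparable; repeatedly subsampling i variants without replacement from the
larger model and rescoring yields the distribution of AUCs attainable with
i variants, against which the smaller model can be judged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evaluate import _auc_mann_whitney
from .prs import PrsModel, _aligned_dosages
from .synth import CohortData

__all__ = ["SubsampleSummary", "subsample_auc"]


@dataclass(frozen=True)
class SubsampleSummary:
    """AUC distribution over repeated i-variant subsamples of one model."""

    i: int
    iterations: int
    auc_values: np.ndarray
    median: float
    iqr: tuple[float, float]
    range: tuple[float, float]
    seed: int

    def to_dict(self) -> dict:
        return {
            "i": self.i,
            "iterations": self.iterations,
            "median": self.median,
            "iqr": list(self.iqr),
            "range": list(self.range),
            "seed": self.seed,
            "auc_values": [float(v) for v in self.auc_values],
        }


def subsample_auc(
    model: PrsModel, cohort: CohortData, i: int, iterations: int, seed: int
) -> SubsampleSummary:
    """AUC distribution of scores built from i-variant random subsets.

    Each iteration draws i distinct variants uniformly without replacement
    from the model, scores the cohort with just those weights, and records
    the AUC.  A master seed spawns one independent substream per iteration
    so results are reproducible regardless of execution order.
    """
    if not 1 <= i <= len(model):
        raise ValueError(f"subset size i={i} must be in [1, {len(model)}]")
    if iterations < 1:
        raise ValueError("iterations must be positive")

    X, w, _ = _aligned_dosages(model, cohort)
    case_mask = cohort.labels == 1
    k = X.shape[1]

    streams = np.random.SeedSequence(seed).spawn(iterations)
    aucs = np.empty(iterations)
    for it, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        # canonical column order keeps summation order (and hence exact score
        # ties) independent of the draw; the full-set draw must take the
        # uncopied path so i = |model| reproduces the full-model score exactly
        idx = np.sort(rng.choice(k, size=min(i, k), replace=False))
        s = X @ w if idx.size == k else X[:, idx] @ w[idx]
        aucs[it] = _auc_mann_whitney(s[case_mask], s[~case_mask])

    q25, q75 = np.quantile(aucs, [0.25, 0.75])
    return SubsampleSummary(
        i=i,
        iterations=iterations,
        auc_values=aucs,
        median=float(np.median(aucs)),
        iqr=(float(q25), float(q75)),
        range=(float(aucs.min()), float(aucs.max())),
        seed=seed,
    )
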