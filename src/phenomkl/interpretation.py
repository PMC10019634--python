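"""Histogram-of-projections confidence analysis.

Training samples are projected onto the separating hyperplane's normal
vector: the projection is the margin-scaled decision value f(x), so support
vectors fall in the band [-1, 1]. Samples with |f| at or below a confidence
threshold (default 0.5) form the low-confidence group; the rest are high
confidence. Features that differ between the groups are found with unpaired
two-sample Wilcoxon rank-sum tests, Benjamini-Hochberg adjusted across
features (significant at adjusted p <= 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .kernels import FeatureTable
from .mkl_model import SVMModel, decision_values

__all__ = ["ProjectionReport", "projection_histogram", "confidence_split",
           "feature_association"]

ALPHA = 0.05


@dataclass
class ProjectionReport:
    """Decision-value projections, confidence grouping and feature statistics."""

    sample_ids: tuple[str, ...]
    distances: np.ndarray
    threshold: float | None = None
    low_mask: np.ndarray | None = None
    feature_stats: pd.DataFrame | None = field(default=None)

    @property
    def low_indices(self) -> np.ndarray:
        if self.low_mask is None:
            raise ValueError("confidence groups not yet computed")
        return np.nonzero(self.low_mask)[0]

    @property
    def high_indices(self) -> np.ndarray:
        if self.low_mask is None:
            raise ValueError("confidence groups not yet computed")
        return np.nonzero(~self.low_mask)[0]


def projection_histogram(model: SVMModel, K_train: np.ndarray) -> ProjectionReport:
    """Decision values f(x_i) of the training samples (their signed,
    margin-scaled distance to the separating hyperplane)."""
    if model.alpha_signed is None or not len(model.alpha_signed):
        raise ValueError("model is not trained")
    K_train = np.asarray(K_train, dtype=float)
    if K_train.shape != (len(model.sample_ids),) * 2:
        raise ValueError("K_train must be the training-set Gram matrix")
    f = decision_values(model, K_train)
    return ProjectionReport(sample_ids=model.sample_ids, distances=f)


def confidence_split(report: ProjectionReport, threshold: float = 0.5) -> ProjectionReport:
    """Partition samples into low (|f| <= threshold) and high confidence."""
    low = np.abs(report.distances) <= threshold
    report.threshold = float(threshold)
    report.low_mask = low
    return report


def feature_association(features: FeatureTable, report: ProjectionReport,
                        alpha: float = ALPHA) -> ProjectionReport:
    """Per-feature Wilcoxon rank-sum between the confidence groups with BH
    adjustment. Features constant across both groups get p = 1 and a flag."""
    if report.low_mask is None:
        raise ValueError("run confidence_split first")
    lo, hi = report.low_indices, report.high_indices
    if lo.size == 0 or hi.size == 0:
        raise ValueError("both confidence groups must be nonempty")
    stats, pvals, flags = [], [], []
    for j, name in enumerate(features.feature_names):
        a = features.values[lo, j]
        b = features.values[hi, j]
        if np.ptp(np.concatenate([a, b])) == 0:
            stats.append(np.nan)
            pvals.append(1.0)
            flags.append(True)
            continue
        res = mannwhitneyu(a, b, alternative="two-sided", method="auto")
        stats.append(float(res.statistic))
        pvals.append(float(res.pvalue))
        flags.append(False)
    _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
    report.feature_stats = pd.DataFrame({
        "feature": list(features.feature_names),
        "statistic": stats,
        "p": pvals,
        "p_adj": p_adj,
        "constant": flags,
        "significant": p_adj <= alpha,
    })
    return report
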