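"""Metrics comparing estimated contributions against ground truth."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panel import ContributionTable

__all__ = ["EvaluationMetrics", "evaluate_estimates", "paired_error_test"]


@dataclass
class EvaluationMetrics:
    rmse: float
    pearson_r: float  # NaN = no-call (zero variance in either vector)
    spearman_rho: float
    n_pairs: int

    def as_dict(self) -> dict[str, float]:
        return {
            "rmse": self.rmse,
            "pearson_r": self.pearson_r,
            "spearman_rho": self.spearman_rho,
            "n_pairs": self.n_pairs,
        }


def _paired_vectors(
    estimates: ContributionTable | pd.DataFrame, truth: dict[tuple[str, str], float]
) -> tuple[np.ndarray, np.ndarray]:
    df = estimates.data if isinstance(estimates, ContributionTable) else estimates
    est = {(r.sink, r.source): r.proportion for r in df.itertuples()}
    missing = sorted(set(truth) - set(est))
    if missing:
        raise KeyError(f"estimate missing truth pair(s): {missing}")
    keys = sorted(truth)
    return (
        np.array([est[k] for k in keys]),
        np.array([truth[k] for k in keys]),
    )


def evaluate_estimates(
    estimates: ContributionTable | pd.DataFrame,
    truth: dict[tuple[str, str], float],
) -> EvaluationMetrics:
    """RMSE and rank/linear correlations over all (sink, source) truth pairs.

    ``truth`` maps (sink_name, source_name_or_'unknown') to the true
    proportion.  Every truth pair must be present among the estimates; extra
    estimate rows are ignored.  Correlations with a constant vector are
    undefined and reported as NaN (no-call).
    """
    a, b = _paired_vectors(estimates, truth)
    rmse = float(np.sqrt(np.mean((a - b) ** 2)))
    if a.size < 2 or np.std(a) == 0 or np.std(b) == 0:
        pearson = spearman = float("nan")
    else:
        pearson = float(stats.pearsonr(a, b).statistic)
        spearman = float(stats.spearmanr(a, b).statistic)
    return EvaluationMetrics(rmse=rmse, pearson_r=pearson, spearman_rho=spearman, n_pairs=a.size)


def paired_error_test(
    estimates_a: ContributionTable | pd.DataFrame,
    estimates_b: ContributionTable | pd.DataFrame,
    truth: dict[tuple[str, str], float],
) -> float:
    """Wilcoxon signed-rank p-value comparing two estimators' absolute errors.

    Errors are paired per (sink, source); the exact null distribution is used
    for fewer than 20 pairs (scipy falls back to the asymptotic test in the
    presence of ties).
    """
    a, t = _paired_vectors(estimates_a, truth)
    b, _ = _paired_vectors(estimates_b, truth)
    err_a, err_b = np.abs(a - t), np.abs(b - t)
    diff = err_a - err_b
    if np.allclose(diff, 0):
        return 1.0
    method = "exact" if diff.size < 20 and not _has_ties(diff) else "auto"
    return float(stats.wilcoxon(err_a, err_b, method=method).pvalue)


def _has_ties(diff: np.ndarray) -> bool:
    nz = diff[diff != 0]
    return (diff == 0).any() or np.unique(np.abs(nz)).size < nz.size
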