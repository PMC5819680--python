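"""Classifier evaluation for variant prioritization: ROC/AUC, Youden J
curves over normalized thresholds, clinical utility, call rates, and mean
score versus allele frequency.

Higher score means more pathogenic throughout, and a variant is called
pathogenic when its score is >= the threshold. Items a tool could not score
are excluded from ROC and J but count against clinical utility and appear
as "not scored" in call-rate tables.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve

PATHOGENIC = "pathogenic"
BENIGN = "benign"


@dataclass
class LabeledScore:
    score: Optional[float]  # None when the tool did not score the variant
    label: str              # pathogenic | benign
    group: Optional[str] = None
    frequency: Optional[float] = None
    rare: Optional[bool] = None

    def __post_init__(self):
        if self.label not in (PATHOGENIC, BENIGN):
            raise ValueError(f"label must be pathogenic or benign, got {self.label!r}")
        if self.rare is None and self.frequency is not None:
            self.rare = self.frequency < 1e-3


@dataclass
class EvalSummary:
    roc_points: list
    auc: float
    j_curve: list                    # (normalized threshold in [0,1], J)
    optimal_threshold: float         # raw score maximizing J (ties -> lowest)
    j_max: float
    accuracy_at: dict                # threshold -> (J+1)/2
    fraction_scored: float
    clinical_utility: float          # at the optimal threshold
    call_rates: dict                 # threshold -> (path%, benign%, not_scored%)
    n: int = 0


def _scored_arrays(data: Iterable[LabeledScore]):
    data = list(data)
    scored = [d for d in data if d.score is not None]
    y = np.array([1 if d.label == PATHOGENIC else 0 for d in scored])
    s = np.array([d.score for d in scored], float)
    if len(scored) == 0 or y.min() == y.max():
        raise ValueError("need scored items of both labels")
    return data, scored, y, s


def roc_auc(data: Iterable[LabeledScore]):
    """ROC points (FPR, TPR) over all distinct score thresholds, and the
    trapezoid AUC (equal to the tie-corrected rank-sum probability)."""
    _, _, y, s = _scored_arrays(data)
    fpr, tpr, _ = _roc_curve(y, s)
    return list(zip(fpr.tolist(), tpr.tolist())), float(_trapezoid_auc(fpr, tpr))


def youden_curve(data: Iterable[LabeledScore]):
    """J = Sn + Sp - 1 at every distinct score threshold.

    Returns (j_curve, optimal_threshold, j_max) with the curve plotted
    against (score - min)/(max - min) so any score range normalizes into
    [0, 1]; the optimal threshold is the lowest raw score attaining j_max.
    """
    _, _, y, s = _scored_arrays(data)
    fpr, tpr, thr = _roc_curve(y, s)
    finite = np.isfinite(thr)
    thr, j = thr[finite], (tpr - fpr)[finite]
    lo, hi = s.min(), s.max()
    span = hi - lo if hi > lo else 1.0
    order = np.argsort(thr)
    thr, j = thr[order], j[order]
    j_curve = [((t - lo) / span, float(jj)) for t, jj in zip(thr, j)]
    j_max = float(j.max())
    optimal = float(thr[j == j_max].min())
    return j_curve, optimal, j_max


def _sn_sp(y: np.ndarray, s: np.ndarray, threshold: float) -> tuple[float, float]:
    called = s >= threshold
    sn = called[y == 1].mean() if (y == 1).any() else float("nan")
    sp = (~called)[y == 0].mean() if (y == 0).any() else float("nan")
    return float(sn), float(sp)


def clinical_utility(data: Iterable[LabeledScore], threshold: float) -> float:
    """Accuracy (Sn+Sp)/2 over scored items at the threshold, multiplied by
    the fraction of items scored at all. A tool scoring nothing scores 0."""
    data = list(data)
    scored = [d for d in data if d.score is not None]
    if not scored:
        return 0.0
    y = np.array([1 if d.label == PATHOGENIC else 0 for d in scored])
    s = np.array([d.score for d in scored], float)
    sn, sp = _sn_sp(y, s, threshold)
    accuracy = (sn + sp) / 2.0
    return accuracy * len(scored) / len(data)


def call_rates(data: Iterable[LabeledScore], threshold: float,
               rare_only: bool = False) -> tuple[float, float, float]:
    """(pathogenic%, benign%, not_scored%) over all items (or the rare
    subset); the three percentages sum to 100."""
    data = list(data)
    if rare_only:
        data = [d for d in data if d.rare]
    n = len(data)
    if n == 0:
        return (0.0, 0.0, 0.0)
    path = sum(1 for d in data if d.score is not None and d.score >= threshold)
    unscored = sum(1 for d in data if d.score is None)
    benign = n - path - unscored
    return (100.0 * path / n, 100.0 * benign / n, 100.0 * unscored / n)


def score_vs_frequency(data: Iterable[LabeledScore], n_bins: int = 6) -> pd.DataFrame:
    """Mean score per logarithmic allele-frequency bin (empty bins omitted).

    Returns a frame with bin bounds, mean score and item count per bin.
    """
    items = [d for d in data if d.score is not None and d.frequency]
    if not items:
        return pd.DataFrame(columns=["bin_low", "bin_high", "mean_score", "n"])
    f = np.array([d.frequency for d in items])
    s = np.array([d.score for d in items], float)
    edges = np.logspace(math.log10(f.min()), math.log10(f.max()), n_bins + 1)
    edges[-1] = np.nextafter(edges[-1], np.inf)
    idx = np.clip(np.digitize(f, edges) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        mask = idx == b
        if mask.any():
            rows.append({"bin_low": edges[b], "bin_high": edges[b + 1],
                         "mean_score": float(s[mask].mean()), "n": int(mask.sum())})
    return pd.DataFrame(rows)


def evaluate(data: Iterable[LabeledScore],
             thresholds: Optional[list[float]] = None) -> EvalSummary:
    """Full evaluation summary; thresholds default to the J-optimal one."""
    data = list(data)
    roc_points, auc_value = roc_auc(data)
    j_curve, optimal, j_max = youden_curve(data)
    if thresholds is None:
        thresholds = [optimal]
    scored = [d for d in data if d.score is not None]
    y = np.array([1 if d.label == PATHOGENIC else 0 for d in scored])
    s = np.array([d.score for d in scored], float)
    accuracy_at = {}
    rates = {}
    for t in thresholds:
        sn, sp = _sn_sp(y, s, t)
        accuracy_at[t] = (sn + sp) / 2.0
        rates[t] = call_rates(data, t)
    return EvalSummary(
        roc_points=roc_points, auc=auc_value, j_curve=j_curve,
        optimal_threshold=optimal, j_max=j_max, accuracy_at=accuracy_at,
        fraction_scored=len(scored) / len(data),
        clinical_utility=clinical_utility(data, optimal),
        call_rates=rates, n=len(data))
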