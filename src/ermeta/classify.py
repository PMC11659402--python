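"""Cohort-level signature classification.

From a pair of activation/repression gene signatures (built from the
regulatory-percentile consensus, e.g. beyond +/-60), each cohort sample
gets an integrated score (activation minus repression single-sample
score); a univariate logistic model and an empirical ROC curve quantify
how well that score separates the classes (e.g. ESR1-mutant vs WT tumors).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata

from .enrichment import single_sample_score
from .ingest import ValidationError

__all__ = [
    "LogisticROC",
    "signature_from_percentiles",
    "integrated_score",
    "roc_curve_points",
    "auc_mann_whitney",
    "fit_logistic_roc",
]


@dataclass
class LogisticROC:
    """Univariate logistic fit plus the empirical ROC of the raw score."""

    coefficient: float
    intercept: float
    roc: pd.DataFrame  # columns: threshold, fpr, tpr
    auc: float
    converged: bool
    perfect_separation: bool


def signature_from_percentiles(
    avg_pct: pd.Series, cut: float = 60.0
) -> tuple[frozenset[str], frozenset[str]]:
    """Activation/repression signatures: average percentile beyond +/-cut."""
    up = frozenset(avg_pct.index[avg_pct > cut])
    down = frozenset(avg_pct.index[avg_pct < -cut])
    return up, down


def integrated_score(
    expr: pd.DataFrame,
    up_set: Iterable[str],
    down_set: Iterable[str],
    min_genes: int = 5,
) -> pd.Series:
    """Activation minus repression single-sample score, per sample."""
    up = single_sample_score(expr, up_set, min_genes=min_genes)
    down = single_sample_score(expr, down_set, min_genes=min_genes)
    return (up - down).rename("integrated_score")


def roc_curve_points(scores: Sequence[float], labels: Sequence[int]) -> pd.DataFrame:
    """Empirical ROC: one point per distinct score threshold (descending).

    A sample is called positive when score >= threshold.  Tied scores move
    together, producing the diagonal segments that make the trapezoidal
    area equal the tie-corrected rank statistic.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("both classes must be non-empty")
    order = np.argsort(-s, kind="stable")
    s, y = s[order], y[order]
    distinct = np.r_[np.diff(s) != 0, True]
    tp = np.cumsum(y == 1)[distinct]
    fp = np.cumsum(y == 0)[distinct]
    roc = pd.DataFrame(
        {
            "threshold": np.r_[np.inf, s[distinct]],
            "fpr": np.r_[0.0, fp / n_neg],
            "tpr": np.r_[0.0, tp / n_pos],
        }
    )
    return roc


def auc_mann_whitney(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUC as the tie-corrected Mann-Whitney U statistic, U / (n1 * n0)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("both classes must be non-empty")
    ranks = rankdata(s)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def fit_logistic_roc(
    scores: pd.Series | Sequence[float],
    labels: pd.Series | Sequence[int],
) -> LogisticROC:
    """Maximum-likelihood logistic fit of class on score, plus ROC and AUC.

    Perfect separation leaves the fit flagged (coefficients unreliable) but
    the rank-based ROC and AUC are always returned.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if min((y == 1).sum(), (y == 0).sum()) < 5:
        raise ValidationError("need >= 5 samples per class")
    roc = roc_curve_points(s, y)
    auc = auc_mann_whitney(s, y)
    x = sm.add_constant(s)
    coefficient = intercept = np.nan
    converged = False
    separated = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, x).fit(disp=False, maxiter=200)
        intercept, coefficient = float(fit.params[0]), float(fit.params[1])
        converged = bool(fit.mle_retvals.get("converged", True))
        separated = not converged and abs(coefficient) > 50
    except Exception:
        separated = True
    return LogisticROC(
        coefficient=coefficient,
        intercept=intercept,
        roc=roc,
        auc=auc,
        converged=converged,
        perfect_separation=separated,
    )
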