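"""Module expression scores and ROC/AUC evaluation of NE prediction.

A sample's module score is the mean of row-standardized (z-scored)
expression over the module's genes present in the tumor matrix.  Scores are
evaluated against binary NE labels with ROC curves; AUC uses the rank
(Mann-Whitney) formulation with ties counted one half.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.metrics import roc_curve as _sk_roc_curve

from .modules import ModuleAssignment

__all__ = ["RocResult", "module_scores", "roc_auc", "ModuleScorer"]

log = logging.getLogger(__name__)


@dataclass
class RocResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def module_scores(
    expression: pd.DataFrame,
    assignment: ModuleAssignment,
    fpkm: bool = False,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-sample mean z-score over each module's matched genes.

    FPKM-like inputs are offset by 0.5 and log2-transformed first when
    ``fpkm`` is set.  Gene rows are z-scored across samples (ddof=1);
    zero-variance rows become NaN and are excluded from module means.
    Returns (scores: samples x modules, matched_counts per module).
    A module with no matched gene scores NaN with a warning.
    """
    if expression.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    X = expression.astype(float)
    if fpkm:
        X = np.log2(X + 0.5)
    mu = X.mean(axis=1)
    sd = X.std(axis=1, ddof=1)
    Z = X.sub(mu, axis=0).div(sd.replace(0.0, np.nan), axis=0)

    modules = sorted(assignment.labels.unique())
    scores = {}
    matched = {}
    for m in modules:
        genes = assignment.genes_in(m)
        present = [g for g in genes if g in Z.index]
        n_unmatched = len(genes) - len(present)
        if n_unmatched:
            log.info("module %s: %d genes not in expression matrix", m, n_unmatched)
        matched[m] = len(present)
        if not present:
            log.warning("module %s has no matched genes; score is NaN", m)
            scores[m] = pd.Series(np.nan, index=Z.columns)
        else:
            scores[m] = Z.loc[present].mean(axis=0, skipna=True)
    return pd.DataFrame(scores), pd.Series(matched, name="matched_genes")


def roc_auc(scores: pd.Series | np.ndarray, labels: pd.Series | np.ndarray) -> RocResult:
    """ROC curve and rank-formulation AUC for a binary NE indicator.

    ``labels`` is boolean/0-1 with 1 = NE.  AUC is the Mann-Whitney
    probability that a random NE sample scores above a random non-NE
    sample, ties counting one half.  The curve comes from a threshold
    sweep over the observed scores.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(s)
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    fpr, tpr, thr = _sk_roc_curve(y.astype(int), s)
    return RocResult(thresholds=thr, fpr=fpr, tpr=tpr, auc=float(auc))


class ModuleScorer(BaseEstimator):
    """Score tumors for module expression and evaluate NE prediction.

    Parameters
    ----------
    fpkm : bool
        Apply the log2(x + 0.5) transform before z-scoring.

    Attributes (after ``fit``)
    --------------------------
    scores_ : samples x modules score matrix
    matched_counts_ : genes matched per module
    """

    def __init__(self, fpkm: bool = False):
        self.fpkm = fpkm

    def fit(self, expression: pd.DataFrame, assignment: ModuleAssignment):
        self.scores_, self.matched_counts_ = module_scores(
            expression, assignment, fpkm=self.fpkm
        )
        return self

    def evaluate(self, labels: pd.Series) -> dict:
        """Per-module RocResult against a binary NE indicator.

        Reports AUC for the higher-score-is-NE direction; ``1 - auc`` is
        the anti-correlated direction and is implied.
        """
        y = labels.reindex(self.scores_.index)
        out = {}
        for m in self.scores_.columns:
            s = self.scores_[m]
            ok = s.notna()
            out[m] = roc_auc(s[ok].to_numpy(), y[ok].to_numpy())
        return out
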