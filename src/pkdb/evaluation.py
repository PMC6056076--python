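"""Evaluation stack: zero-one loss, bias/variance, AUC, Friedman test.

The bias/variance estimates follow the Kohavi-Wolpert decomposition of the
zero-one loss under a deterministic-target assumption: repeated random
train/test splits yield, for each instance x, the empirical distribution
p_hat(y'|x) of predicted labels, from which

    bias(x)     = 1/2 * sum_y' (p_hat(y'|x) - 1{y' = y_x})^2
    variance(x) = 1/2 * (1 - sum_y' p_hat(y'|x)^2)

and bias(x) + variance(x) equals the expected zero-one loss at x. The
Friedman test ranks algorithms per dataset (rank 1 = lowest loss, average
ranks on ties) and compares

    X_F^2 = 12 / (N t (t+1)) * sum_j R_j^2 - 3 N (t+1)

with the upper-alpha chi-square quantile at t-1 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.stats import chi2, rankdata

from .data_io import Dataset, stratified_folds

__all__ = [
    "EvaluationReport",
    "FriedmanResult",
    "zero_one_loss",
    "bias_variance_decomposition",
    "roc_auc",
    "friedman_statistic",
    "friedman_critical_value",
    "friedman_test",
    "cross_validate",
]

# A learner maps a training Dataset to a scorer: rows -> (predictions, positive scores)
Learner = Callable[[Dataset], Callable[[np.ndarray], tuple[np.ndarray, np.ndarray | None]]]


def zero_one_loss(predictions: Sequence[int], truth: Sequence[int]) -> float:
    """Mean of per-instance 0/1 losses."""
    pred = np.asarray(predictions)
    true = np.asarray(truth)
    if pred.shape != true.shape or pred.size == 0:
        raise ValueError("prediction and truth vectors must match and be nonempty")
    return float(np.mean(pred != true))


def bias_variance_decomposition(
    learner: Learner,
    dataset: Dataset,
    n_repetitions: int = 10,
    train_fraction: float = 0.5,
    seed: int = 0,
) -> tuple[float, float]:
    """Kohavi-Wolpert bias and variance estimates for ``learner``.

    Runs ``n_repetitions`` random train/test splits; each instance's
    predicted-label distribution is accumulated over the repetitions in
    which it fell into the test half. Returns instance-averaged (bias,
    variance), each in [0, 1].
    """
    N = dataset.n_instances
    m = dataset.n_classes
    n_train = int(round(train_fraction * N))
    if n_repetitions < 1 or n_train < 1 or n_train >= N:
        raise ValueError("degenerate protocol")
    rng = np.random.default_rng(seed)
    votes = np.zeros((N, m))
    for _ in range(n_repetitions):
        perm = rng.permutation(N)
        train_idx, test_idx = perm[:n_train], perm[n_train:]
        scorer = learner(dataset.subset(train_idx))
        preds, _ = scorer(dataset.X[test_idx])
        votes[test_idx, np.asarray(preds, dtype=np.int64)] += 1
    predicted = votes.sum(axis=1)
    covered = predicted > 0
    p_hat = votes[covered] / predicted[covered, None]
    truth = np.zeros((int(covered.sum()), m))
    truth[np.arange(truth.shape[0]), dataset.y[covered]] = 1.0
    bias = float(np.mean(0.5 * ((p_hat - truth) ** 2).sum(axis=1)))
    variance = float(np.mean(0.5 * (1.0 - (p_hat**2).sum(axis=1))))
    return bias, variance


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based AUC (pair counting with ties worth one half).

    ``labels`` are binary with 1 the positive class; both classes must be
    present. Equivalent to the Mann-Whitney statistic with midranks.
    """
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels, dtype=np.int64)
    n_pos = int((lab == 1).sum())
    n_neg = int((lab == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(s)  # midranks for ties
    r_pos = ranks[lab == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


@dataclass
class FriedmanResult:
    rank_matrix: np.ndarray  # (N datasets, t algorithms)
    rank_sums: np.ndarray  # R_j
    statistic: float
    n_datasets: int
    n_algorithms: int
    critical_value: float | None = None
    alpha: float | None = None
    rejected: bool | None = None


def friedman_statistic(loss_matrix: np.ndarray | Sequence[Sequence[float]]) -> FriedmanResult:
    """Friedman rank statistic over a datasets x algorithms loss matrix.

    The best (lowest-loss) algorithm on each dataset receives rank 1; ties
    share average ranks. Rank sums always total N t (t+1) / 2.
    """
    losses = np.asarray(loss_matrix, dtype=float)
    if losses.ndim != 2 or losses.shape[0] < 2 or losses.shape[1] < 2:
        raise ValueError("need at least 2 datasets and 2 algorithms")
    N, t = losses.shape
    ranks = np.vstack([rankdata(row) for row in losses])
    rank_sums = ranks.sum(axis=0)
    statistic = 12.0 / (N * t * (t + 1)) * float((rank_sums**2).sum()) - 3.0 * N * (t + 1)
    return FriedmanResult(ranks, rank_sums, float(statistic), N, t)


def friedman_critical_value(t: int, alpha: float) -> float:
    """Upper-alpha chi-square quantile with t-1 degrees of freedom."""
    if t < 2:
        raise ValueError("need at least 2 algorithms")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return float(chi2.ppf(1.0 - alpha, df=t - 1))


def friedman_test(
    loss_matrix: np.ndarray | Sequence[Sequence[float]], alpha: float = 0.05
) -> FriedmanResult:
    """Friedman statistic plus the rejection decision at level ``alpha``."""
    result = friedman_statistic(loss_matrix)
    result.alpha = alpha
    result.critical_value = friedman_critical_value(result.n_algorithms, alpha)
    result.rejected = result.statistic > result.critical_value
    return result


@dataclass
class EvaluationReport:
    """Cross-validated metrics for one classifier on one dataset."""

    classifier: str
    per_fold_losses: list[float]
    per_fold_aucs: list[float] = field(default_factory=list)
    bias: float | None = None
    variance: float | None = None
    protocol: dict = field(default_factory=dict)

    @property
    def loss(self) -> float:
        return float(np.mean(self.per_fold_losses))

    @property
    def loss_std(self) -> float:
        return float(np.std(self.per_fold_losses))

    @property
    def auc(self) -> float | None:
        return float(np.mean(self.per_fold_aucs)) if self.per_fold_aucs else None

    @property
    def auc_std(self) -> float | None:
        return float(np.std(self.per_fold_aucs)) if self.per_fold_aucs else None


def cross_validate(
    learner: Learner,
    dataset: Dataset,
    name: str,
    n_folds: int = 10,
    seed: int = 0,
) -> EvaluationReport:
    """Stratified k-fold zero-one loss (and AUC when the scorer provides
    binary positive-class scores)."""
    plan = stratified_folds(dataset, n_folds, seed)
    losses: list[float] = []
    aucs: list[float] = []
    for fold in range(n_folds):
        train = dataset.subset(plan.train_indices(fold))
        test_idx = plan.test_indices(fold)
        scorer = learner(train)
        preds, scores = scorer(dataset.X[test_idx])
        truth = dataset.y[test_idx]
        losses.append(zero_one_loss(preds, truth))
        if scores is not None and dataset.n_classes == 2:
            if len(set(truth.tolist())) == 2:
                aucs.append(roc_auc(scores, truth))
    return EvaluationReport(
        classifier=name,
        per_fold_losses=losses,
        per_fold_aucs=aucs,
        protocol={"n_folds": n_folds, "seed": seed},
    )
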