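"""Model evaluation: confusion metrics, ROC/AUC, CV drivers, basic statistics.

The metric suite follows the usual binary-classification definitions:
SE = TP/(TP+FN), SP = TN/(TN+FP), Q_i = TP/(TP+FP), Q_ni = TN/(TN+FN),
Q = (TP+TN)/n and the Matthews correlation coefficient, with C = 0 when any
factor of its denominator vanishes.  AUC uses a trapezoidal threshold sweep,
so tied scores earn half credit and the value equals the normalized
Mann-Whitney pair count.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from fragbayes.errors import FitError, ParameterError


def round_half_up(x: float, ndigits: int = 3) -> float:
    """Half-up rounding as used when comparing against printed tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FN: int
    TN: int
    FP: int

    def __post_init__(self):
        if min(self.TP, self.FN, self.TN, self.FP) < 0:
            raise ParameterError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FN + self.TN + self.FP

    @classmethod
    def from_arrays(cls, y_true, y_pred) -> "ConfusionCounts":
        t = np.asarray(y_true, dtype=bool)
        p = np.asarray(y_pred, dtype=bool)
        if t.shape != p.shape:
            raise ParameterError("y_true and y_pred must have equal length")
        return cls(
            TP=int((p & t).sum()),
            FN=int((~p & t).sum()),
            TN=int((~p & ~t).sum()),
            FP=int((p & ~t).sum()),
        )

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.TP + other.TP, self.FN + other.FN, self.TN + other.TN, self.FP + other.FP
        )


@dataclass
class MetricsReport:
    SE: float | None
    SP: float | None
    Q_i: float | None
    Q_ni: float | None
    Q: float | None
    C: float
    AUC: float | None = None

    TABLE_COLUMNS = ("TP", "FN", "TN", "FP", "SE", "SP", "Q_i", "Q_ni", "C", "AUC")

    def row(self, counts: ConfusionCounts) -> list:
        """Row in the conventional table order TP FN TN FP SE SP Q_i Q_ni C AUC."""
        return [
            counts.TP,
            counts.FN,
            counts.TN,
            counts.FP,
            self.SE,
            self.SP,
            self.Q_i,
            self.Q_ni,
            self.C,
            self.AUC,
        ]


def compute_metrics(c: ConfusionCounts, scores=None, labels=None) -> MetricsReport:
    """Derive the metric suite from confusion counts.

    Metrics with a zero denominator are flagged ``None`` (except C, which is
    0 by convention).  Supplying per-compound ``scores`` and ``labels`` also
    fills in the AUC.
    """
    if c.total == 0:
        raise ParameterError("confusion counts are all zero")

    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    tp, fn, tn, fp = c.TP, c.FN, c.TN, c.FP
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom > 0 else 0.0
    auc = None
    if scores is not None:
        if labels is None:
            raise ParameterError("labels are required when scores are supplied")
        auc = roc_auc(scores, labels).auc
    return MetricsReport(
        SE=ratio(tp, tp + fn),
        SP=ratio(tn, tn + fp),
        Q_i=ratio(tp, tp + fp),
        Q_ni=ratio(tn, tn + fn),
        Q=ratio(tp + tn, c.total),
        C=mcc,
        AUC=auc,
    )


def write_metrics_table(path, rows: dict[str, tuple[ConfusionCounts, MetricsReport]]) -> None:
    """Dump named metric rows as TSV in the conventional column order."""
    with open(path, "w") as fh:
        fh.write("name\t" + "\t".join(MetricsReport.TABLE_COLUMNS) + "\n")
        for name, (cc, rep) in rows.items():
            cells = [
                "" if v is None else (str(v) if isinstance(v, int) else f"{v:.3f}")
                for v in rep.row(cc)
            ]
            fh.write(name + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------


@dataclass
class ROCCurve:
    points: list[tuple[float, float]]  # (FPR, TPR), monotone, (0,0) .. (1,1)
    auc: float


def roc_auc(scores, labels) -> ROCCurve:
    """ROC curve by threshold sweep over the distinct scores, trapezoidal AUC."""
    from fragbayes.nbayes import as_binary_labels

    s = np.asarray(scores, dtype=float)
    y = as_binary_labels(labels)
    if s.size != y.size:
        raise ParameterError("scores and labels must have equal length")
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ParameterError("both classes are required for a ROC curve")
    order = np.argsort(-s, kind="stable")
    ss = s[order]
    yy = y[order]
    points = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    while i < ss.size:
        j = i
        while j < ss.size and ss[j] == ss[i]:
            tp += int(yy[j])
            fp += int(not yy[j])
            j += 1
        points.append((fp / n_neg, tp / n_pos))
        i = j
    auc = 0.0
    for (x0, y0), (x1, y1) in zip(points, points[1:]):
        auc += (x1 - x0) * (y0 + y1) / 2.0
    return ROCCurve(points=points, auc=auc)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


def stratified_folds(labels, k: int, seed: int) -> list[np.ndarray]:
    """Deterministic stratified k-fold assignment (round-robin per class)."""
    from fragbayes.nbayes import as_binary_labels

    y = as_binary_labels(labels)
    if k < 2:
        raise ParameterError("k must be >= 2")
    for cls in (True, False):
        if (y == cls).sum() < k:
            name = "inhibitor" if cls else "non_inhibitor"
            raise ParameterError(f"class {name} has fewer than {k} examples; cannot stratify")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in (True, False):
        ix = np.flatnonzero(y == cls)
        rng.shuffle(ix)
        for pos, i in enumerate(ix):
            folds[pos % k].append(int(i))
    return [np.array(sorted(f)) for f in folds]


def random_folds(n: int, k: int, seed: int, labels=None, max_attempts: int = 5) -> list[np.ndarray]:
    """Plain random folds; redraws (with warning) folds leaving a single-class
    training part, erroring after ``max_attempts``."""
    from fragbayes.nbayes import as_binary_labels

    if k < 2:
        raise ParameterError("k must be >= 2")
    rng = np.random.default_rng(seed)
    y = as_binary_labels(labels) if labels is not None else None
    for attempt in range(max_attempts):
        perm = rng.permutation(n)
        folds = [np.array(sorted(perm[i::k].tolist())) for i in range(k)]
        if y is None:
            return folds
        ok = True
        for f in folds:
            mask = np.ones(n, dtype=bool)
            mask[f] = False
            if y[mask].all() or not y[mask].any():
                ok = False
                break
        if ok:
            return folds
        warnings.warn(f"fold draw {attempt + 1} left a single-class training part; redrawing")
    raise FitError(f"could not draw valid folds in {max_attempts} attempts")


def cross_validate(
    trainer: Callable,
    features: Sequence,
    labels,
    k: int = 5,
    seed: int = 0,
    stratified: bool = True,
) -> tuple[list[tuple[ConfusionCounts, MetricsReport]], ConfusionCounts, MetricsReport]:
    """k-fold cross-validation driver.

    ``trainer(train_features, train_labels)`` must return a callable mapping
    a feature item to a boolean/"inhibitor" prediction.  Returns per-fold
    (confusion, metrics), the pooled confusion (sum of folds) and its metrics.
    """
    from fragbayes.nbayes import as_binary_labels

    y = as_binary_labels(labels)
    n = y.size
    if len(features) != n:
        raise ParameterError("features and labels must have equal length")
    folds = stratified_folds(y, k, seed) if stratified else random_folds(n, k, seed, labels=y)
    per_fold = []
    pooled = ConfusionCounts(0, 0, 0, 0)
    for f in folds:
        test_mask = np.zeros(n, dtype=bool)
        test_mask[f] = True
        train_feats = [features[i] for i in range(n) if not test_mask[i]]
        predict_fn = trainer(train_feats, y[~test_mask])
        pred = as_binary_labels([predict_fn(features[i]) for i in f])
        cc = ConfusionCounts.from_arrays(y[f], pred)
        per_fold.append((cc, compute_metrics(cc)))
        pooled = pooled + cc
    return per_fold, pooled, compute_metrics(pooled)


def loo_bayes_scores(featuresets, labels) -> list[float]:
    """Leave-one-out Bayesian score per compound (count-decrement fast path)."""
    from fragbayes.nbayes import loo_scores

    return loo_scores(featuresets, labels)


# ---------------------------------------------------------------------------
# descriptor-vs-activity statistics
# ---------------------------------------------------------------------------


def welch_t_test(x, y, pooled: bool = False) -> tuple[float, float]:
    """Two-sided two-sample t test, Welch by default (pooled behind a flag)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ParameterError("each sample needs at least two observations")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0 and x.mean() == y.mean():
        return 0.0, 1.0
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        raise ParameterError("both samples are degenerate (zero variance)")
    res = stats.ttest_ind(x, y, equal_var=pooled)
    return float(res.statistic), float(res.pvalue)


def pearson_r(x, y) -> float:
    """Product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ParameterError("need equal-length samples of size >= 3")
    if x.var() == 0 or y.var() == 0:
        raise ParameterError("zero variance input")
    return float(stats.pearsonr(x, y).statistic)
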