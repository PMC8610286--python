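"""Classifier evaluation: confusion metrics, AUC, bootstrap errors,
reliability-index calibration curves, and the 5-fold cross-validation driver.

Point metrics follow the usual definitions: precision TP/(TP+FP), recall
TP/(TP+FN), specificity TN/(TN+FP), F1 the harmonic mean, and the Matthews
correlation coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).

Error bars are bootstrap standard deviations obtained conservatively by
resampling *without* replacement: 1000 half-sized subsamples of the
evaluation set, with the metric's spread across subsamples reported.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.stats import rankdata

from .graph import LinkDataset
from .rgcn import PredictionRecord

logger = logging.getLogger(__name__)


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricReport:
    precision: float
    recall: float
    specificity: float
    f1: float
    mcc: float
    auc: float | None = None
    #: metrics whose denominator vanished and were reported as 0
    degenerate: tuple[str, ...] = ()
    bootstrap_std: dict = field(default_factory=dict)


def confusion(
    preds: Sequence[PredictionRecord], truth: LinkDataset
) -> ConfusionCounts:
    """Tally the four confusion counts; predicted positive means RI >= 0."""
    by_pair = {(r.gene_a, r.gene_b): r for r in preds}
    tp = fp = tn = fn = 0
    for a, b, y in truth.records:
        r = by_pair.get((a, b))
        if r is None or not r.ok:
            raise ValueError(f"truth pair ({a}, {b}) was not scored")
        pos = r.ri >= 0
        if pos and y == 1:
            tp += 1
        elif pos and y == 0:
            fp += 1
        elif not pos and y == 0:
            tn += 1
        else:
            fn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: int, den: int, name: str, flags: list[str]) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def metrics(c: ConfusionCounts) -> MetricReport:
    """Point metrics from a confusion table; zero denominators yield 0 with
    the metric name recorded in ``degenerate`` (so resampling loops never
    raise)."""
    flags: list[str] = []
    precision = _ratio(c.tp, c.tp + c.fp, "precision", flags)
    recall = _ratio(c.tp, c.tp + c.fn, "recall", flags)
    specificity = _ratio(c.tn, c.tn + c.fp, "specificity", flags)
    if precision + recall == 0:
        flags.append("f1")
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    denom2 = (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    if denom2 == 0:
        flags.append("mcc")
        mcc = 0.0
    else:
        mcc = (c.tp * c.tn - c.fp * c.fn) / np.sqrt(float(denom2))
    return MetricReport(
        precision=precision,
        recall=recall,
        specificity=specificity,
        f1=f1,
        mcc=float(mcc),
        degenerate=tuple(flags),
    )


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve as the rank statistic: the probability that
    a random positive outscores a random negative, ties counted half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)  # average ranks handle ties
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def bootstrap_std(
    metric_fn: Callable[[Sequence, Sequence], float],
    preds: Sequence,
    truth: Sequence,
    n_boot: int = 1000,
    frac: float = 0.5,
    seed: int = 0,
) -> float:
    """Bootstrap (without replacement) standard deviation of a metric.

    Draws ``n_boot`` subsamples of size ``ceil(frac * N)`` without
    replacement from the paired (preds, truth) items and returns the
    standard deviation of ``metric_fn`` across them.  Subsamples on which
    the metric is degenerate (raises or returns NaN) are kept as NaN; if
    more than 10% are degenerate a warning is issued.
    """
    if len(preds) != len(truth):
        raise ValueError("preds and truth must be parallel sequences")
    n = len(preds)
    if n < 4:
        raise ValueError("bootstrap needs at least 4 items")
    m = int(np.ceil(frac * n))
    rng = np.random.default_rng(seed)
    vals = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.choice(n, size=m, replace=False)
        try:
            vals[b] = metric_fn([preds[i] for i in idx], [truth[i] for i in idx])
        except (ValueError, ZeroDivisionError):
            vals[b] = np.nan
    n_bad = int(np.isnan(vals).sum())
    if n_bad > 0.1 * n_boot:
        warnings.warn(
            f"metric degenerate in {n_bad}/{n_boot} bootstrap resamples",
            RuntimeWarning,
            stacklevel=2,
        )
    return float(np.nanstd(vals))


def evaluate(
    preds: Sequence[PredictionRecord],
    truth: LinkDataset,
    n_boot: int = 1000,
    seed: int = 0,
) -> MetricReport:
    """Full report: point metrics + AUC + bootstrap standard deviations."""
    c = confusion(preds, truth)
    rep = metrics(c)
    by_pair = {(r.gene_a, r.gene_b): r for r in preds}
    scored = [by_pair[(a, b)] for a, b, _ in truth.records]
    y = truth.labels()
    rep.auc = auc([r.p for r in scored], y)

    def make_fn(name: str):
        def fn(ps: Sequence[PredictionRecord], ys: Sequence[int]) -> float:
            if name == "auc":
                return auc([r.p for r in ps], ys)
            sub = LinkDataset(
                [(r.gene_a, r.gene_b, int(t)) for r, t in zip(ps, ys)]
            )
            m = metrics(confusion(ps, sub))
            return getattr(m, name)

        return fn

    for name in ("precision", "recall", "specificity", "f1", "mcc", "auc"):
        rep.bootstrap_std[name] = bootstrap_std(
            make_fn(name), scored, list(y), n_boot=n_boot, seed=seed
        )
    return rep


# ---------------------------------------------------------------------------
# reliability-index calibration


@dataclass
class CalibrationCurve:
    """Precision/coverage as the reliability-index threshold tightens.

    ``positive`` holds (threshold t >= 0, precision among predictions with
    RI >= t, fraction of all predictions with RI >= t); ``negative`` mirrors
    it for RI <= t <= 0, with precision measured for the negative class.
    """

    positive: list[tuple[int, float, float]]
    negative: list[tuple[int, float, float]]


def calibration(
    preds: Sequence[PredictionRecord], truth: LinkDataset, step: int = 5
) -> CalibrationCurve:
    by_pair = {(r.gene_a, r.gene_b): r for r in preds}
    ri = []
    y = []
    for a, b, lab in truth.records:
        r = by_pair.get((a, b))
        if r is None or not r.ok:
            raise ValueError(f"truth pair ({a}, {b}) was not scored")
        ri.append(r.ri)
        y.append(lab)
    ri = np.asarray(ri)
    y = np.asarray(y)
    n = len(ri)
    pos_curve = []
    for t in range(0, 101, step):
        sel = ri >= t
        if not sel.any():
            logger.info("calibration: empty positive bin at RI >= %d", t)
            continue
        pos_curve.append((t, float(y[sel].mean()), float(sel.sum() / n)))
    neg_curve = []
    for t in range(0, -101, -step):
        sel = ri <= t
        if not sel.any():
            logger.info("calibration: empty negative bin at RI <= %d", t)
            continue
        neg_curve.append((t, float(1 - y[sel].mean()), float(sel.sum() / n)))
    return CalibrationCurve(positive=pos_curve, negative=neg_curve)


def write_calibration(curve: CalibrationCurve, path) -> None:
    with open(path, "w") as fh:
        fh.write("side\tthreshold\tprecision\tcoverage\n")
        for t, p, c in curve.positive:
            fh.write(f"positive\t{t}\t{p:.6g}\t{c:.6g}\n")
        for t, p, c in curve.negative:
            fh.write(f"negative\t{t}\t{p:.6g}\t{c:.6g}\n")


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class CVFolds:
    """K disjoint folds plus the rotation layout.

    Each rotation is a (train, crosstrain, test) triple of index arrays:
    three folds train the model, one ("cross-training") drives
    hyperparameter/early-stop selection, and one is held out for testing,
    rotating cyclically so every link is tested exactly once.
    """

    folds: list[np.ndarray]
    rotations: list[tuple[np.ndarray, np.ndarray, np.ndarray]]


def crossval(links: LinkDataset, k: int = 5, seed: int = 0) -> CVFolds:
    n = len(links.records)
    if k > n:
        raise ValueError(f"k={k} exceeds dataset size {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = [np.sort(f) for f in np.array_split(order, k)]
    rotations = []
    for i in range(k):
        test = folds[i]
        cross = folds[(i + 1) % k]
        train_idx = np.sort(
            np.concatenate([folds[j] for j in range(k) if j not in (i, (i + 1) % k)])
        )
        rotations.append((train_idx, cross, test))
    return CVFolds(folds=folds, rotations=rotations)


def cross_validate(
    graph,
    features,
    links: LinkDataset,
    config,
    k: int = 5,
    seed: int = 0,
    n_boot: int = 200,
):
    """Run the k-fold rotation protocol; returns per-fold reports and the
    pooled report over all held-out predictions."""
    from .rgcn import train as _train, predict as _predict

    cv = crossval(links, k=k, seed=seed)
    fold_reports = []
    pooled_preds: list[PredictionRecord] = []
    pooled_truth: list[tuple[str, str, int]] = []
    for train_idx, cross_idx, test_idx in cv.rotations:
        model, _ = _train(
            graph, features, links.subset(train_idx), links.subset(cross_idx), config
        )
        test = links.subset(test_idx)
        preds = _predict(model, test.pairs(), graph, features)
        fold_reports.append(evaluate(preds, test, n_boot=n_boot, seed=seed))
        pooled_preds.extend(preds)
        pooled_truth.extend(test.records)
    pooled = evaluate(pooled_preds, LinkDataset(pooled_truth), n_boot=n_boot, seed=seed)
    return fold_reports, pooled
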