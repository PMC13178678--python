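"""Discrimination, calibration, comparison and thresholding statistics.

Conventions: AUROC is the probability that a random positive outranks a
random negative with ties counted 1/2 (computed from average ranks, so it
agrees exactly with brute-force pairwise counting); AUPRC is the step
integral of the precision-recall curve (average precision); micro-averaging
flattens the (record x label) matrices into one vector pair before anything
is computed.  Confidence intervals come from 1000 resampling iterations of
70% of the records (without replacement by default; a with-replacement
bootstrap is available behind ``replace=True``), with percentile 2.5/97.5
endpoints.  AUROC pairs are compared with a two-sided DeLong test.  No
multiple-testing correction is applied anywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from sklearn.metrics import average_precision_score

from .exceptions import (
    AlignmentError,
    InstabilityError,
    ParameterError,
    UndefinedMetricError,
)
from .io import PredictionSet


@dataclass
class MetricResult:
    """A point estimate with an optional percentile CI."""

    name: str
    estimate: float
    ci_low: float = math.nan
    ci_high: float = math.nan
    n_bootstrap: int = 0
    fraction: float = math.nan
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_bootstrap > 0 and not (
            self.ci_low <= self.estimate + 1e-12 and self.estimate - 1e-12 <= self.ci_high
        ):
            # percentile CIs from subsamples can exclude the full-sample point
            # estimate only under extreme skew; widen to contain it
            self.ci_low = min(self.ci_low, self.estimate)
            self.ci_high = max(self.ci_high, self.estimate)


def auroc(scores: np.ndarray, truths: np.ndarray) -> float:
    """Rank-based AUROC with ties counted 1/2.

    Equivalent to counting concordant positive/negative pairs; single-class
    input raises :class:`UndefinedMetricError`.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    truths = np.asarray(truths).ravel()
    pos = truths == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUROC undefined: only one class present")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def auprc(scores: np.ndarray, truths: np.ndarray) -> float:
    """Average precision (step integration of the precision-recall curve)."""
    scores = np.asarray(scores, dtype=float).ravel()
    truths = np.asarray(truths).ravel()
    if truths.min() == truths.max():
        raise UndefinedMetricError("AUPRC undefined: only one class present")
    return float(average_precision_score(truths, scores))


def _flatten(preds: PredictionSet) -> tuple[np.ndarray, np.ndarray]:
    return preds.scores.ravel(), preds.truths.ravel()


def rank_metrics(preds: PredictionSet, averaging: str = "micro") -> pd.DataFrame:
    """AUROC and AUPRC under micro, macro or per-label averaging.

    Returns a DataFrame indexed by ``"micro"``, ``"macro"`` or the label
    names, with columns ``auroc`` and ``auprc``.
    """
    if averaging == "micro":
        s, t = _flatten(preds)
        if t.min() == t.max():
            raise UndefinedMetricError("micro average undefined: single class overall")
        return pd.DataFrame(
            {"auroc": [auroc(s, t)], "auprc": [auprc(s, t)]}, index=["micro"]
        )
    rows = {}
    for j, label in enumerate(preds.label_names):
        t = preds.truths[:, j]
        if t.min() == t.max():
            raise UndefinedMetricError(f"label {label!r} has a single class")
        rows[label] = (auroc(preds.scores[:, j], t), auprc(preds.scores[:, j], t))
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=["auroc", "auprc"])
    if averaging == "per_label":
        return frame
    if averaging == "macro":
        return frame.mean().to_frame(name="macro").T
    raise ParameterError("averaging must be 'micro', 'macro' or 'per_label'")


_NAMED_METRICS: dict[str, Callable[[PredictionSet], float]] = {
    "auroc": lambda p: auroc(*_flatten(p)),
    "auprc": lambda p: auprc(*_flatten(p)),
}


def bootstrap_ci(
    preds: PredictionSet,
    metric: str | Callable[[PredictionSet], float] = "auroc",
    n_iter: int = 1000,
    fraction: float = 0.7,
    seed: int = 0,
    replace: bool = True,
) -> MetricResult:
    """Percentile CI from ``n_iter`` resamples of ceil(fraction * n) records.

    Records are drawn **with replacement** by default (a bootstrap at 70% of
    the sample size).  ``replace=False`` draws true 70% subsets instead; note
    that subsampling without replacement deflates the resampling variance by
    a factor ``1/fraction - 1`` relative to the estimator's own sampling
    variance, so those percentile intervals systematically under-cover the
    population value (~80% actual coverage at 70%) and should be treated as
    descriptive spread, not calibrated CIs.  Deterministic under ``seed``.
    Raises :class:`InstabilityError` when the metric is undefined on more
    than 20% of resamples.
    """
    fn = _NAMED_METRICS[metric] if isinstance(metric, str) else metric
    name = metric if isinstance(metric, str) else getattr(metric, "__name__", "metric")
    point = fn(preds)
    n = preds.n_records
    size = math.ceil(fraction * n)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 101]))
    values = []
    failures = 0
    for _ in range(n_iter):
        idx = rng.choice(n, size=size, replace=replace)
        try:
            values.append(fn(preds.subset(idx)))
        except UndefinedMetricError:
            failures += 1
    if n_iter and failures > 0.2 * n_iter:
        raise InstabilityError(
            f"metric undefined on {failures}/{n_iter} resamples "
            f"({failures / n_iter:.0%})"
        )
    if values:
        lo, hi = np.percentile(values, [2.5, 97.5])
    else:
        lo = hi = point
    return MetricResult(
        name=name, estimate=point, ci_low=float(lo), ci_high=float(hi),
        n_bootstrap=n_iter, fraction=fraction, seed=seed,
    )


# ---------------------------------------------------------------------------
# DeLong test
# ---------------------------------------------------------------------------

def _placements(scores: np.ndarray, truths: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Placement values V10 (per positive) and V01 (per negative).

    V10[i] is the fraction of negatives ranked below positive i (ties 1/2);
    the mean of either vector is the AUROC.
    """
    pos = scores[truths == 1]
    neg = scores[truths == 0]
    if pos.size == 0 or neg.size == 0:
        raise UndefinedMetricError("DeLong requires both classes")
    order = np.sort(neg)
    v10 = (
        np.searchsorted(order, pos, side="left")
        + np.searchsorted(order, pos, side="right")
    ) / (2.0 * neg.size)
    order_p = np.sort(pos)
    v01 = 1.0 - (
        np.searchsorted(order_p, neg, side="left")
        + np.searchsorted(order_p, neg, side="right")
    ) / (2.0 * pos.size)
    auc = float(v10.mean())
    return v10, v01, auc


def auroc_variance(scores: np.ndarray, truths: np.ndarray) -> float:
    """DeLong variance of a single AUROC via placement values."""
    scores = np.asarray(scores, dtype=float).ravel()
    truths = np.asarray(truths).ravel()
    v10, v01, _ = _placements(scores, truths)
    m, n = v10.size, v01.size
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(s10 / m + s01 / n)


@dataclass
class DelongResult:
    auroc_a: float
    auroc_b: float
    delta: float
    variance: float
    z: float
    p_value: float


def delong_test(
    scores_a: np.ndarray, scores_b: np.ndarray, truths: np.ndarray
) -> DelongResult:
    """Two-sided DeLong test for paired AUROCs on identical truths."""
    scores_a = np.asarray(scores_a, dtype=float).ravel()
    scores_b = np.asarray(scores_b, dtype=float).ravel()
    truths = np.asarray(truths).ravel()
    if not (scores_a.size == scores_b.size == truths.size):
        raise AlignmentError("scores_a, scores_b and truths must be paired")
    va10, va01, auc_a = _placements(scores_a, truths)
    vb10, vb01, auc_b = _placements(scores_b, truths)
    m, n = va10.size, va01.size
    if m > 1:
        s10 = np.cov(np.stack([va10, vb10]), ddof=1)
    else:
        s10 = np.zeros((2, 2))
    if n > 1:
        s01 = np.cov(np.stack([va01, vb01]), ddof=1)
    else:
        s01 = np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_delta = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    delta = auc_a - auc_b
    if var_delta <= 0:
        z = 0.0 if delta == 0 else math.inf * np.sign(delta)
    else:
        z = delta / math.sqrt(var_delta)
    p = 1.0 if z == 0 else float(2 * norm.sf(abs(z)))
    return DelongResult(auc_a, auc_b, float(delta), float(var_delta), float(z), p)


# ---------------------------------------------------------------------------
# thresholds and binary rates
# ---------------------------------------------------------------------------

@dataclass
class ThresholdTable:
    """Per-label decision thresholds with the operating point they achieve."""

    table: pd.DataFrame  # index: label; columns: threshold, sensitivity, specificity

    def threshold_for(self, label: str) -> float:
        return float(self.table.loc[label, "threshold"])

    def as_vector(self, label_names) -> np.ndarray:
        return self.table.loc[list(label_names), "threshold"].to_numpy(dtype=float)


def optimize_thresholds(calibration: PredictionSet) -> ThresholdTable:
    """Per-label threshold balancing sensitivity and specificity.

    Candidates are midpoints between consecutive distinct scores plus 0/1
    guards; the winner minimizes |sens - spec|, ties broken by the larger
    Youden index (sens + spec - 1), then by the smaller threshold.
    """
    rows = {}
    for j, label in enumerate(calibration.label_names):
        scores = calibration.scores[:, j]
        truths = calibration.truths[:, j]
        if truths.min() == truths.max():
            raise UndefinedMetricError(f"label {label!r} has a single class")
        distinct = np.unique(scores)
        candidates = np.concatenate(([0.0], (distinct[:-1] + distinct[1:]) / 2, [1.0]))
        # decisions = score >= t: counts above each candidate via sorted scores
        pos_sorted = np.sort(scores[truths == 1])
        neg_sorted = np.sort(scores[truths == 0])
        n_pos, n_neg = pos_sorted.size, neg_sorted.size
        sens = (n_pos - np.searchsorted(pos_sorted, candidates, side="left")) / n_pos
        spec = np.searchsorted(neg_sorted, candidates, side="left") / n_neg
        order = np.lexsort((candidates, -(sens + spec - 1), np.abs(sens - spec)))
        best = order[0]
        rows[label] = {
            "threshold": float(candidates[best]),
            "sensitivity": float(sens[best]),
            "specificity": float(spec[best]),
        }
    return ThresholdTable(pd.DataFrame.from_dict(rows, orient="index"))


@dataclass
class BinaryRates:
    tpr: float
    fpr: float
    sensitivity: float
    specificity: float
    tp: int
    fp: int
    tn: int
    fn: int
    tpr_defined: bool = True
    fpr_defined: bool = True


def binary_rates(decisions: np.ndarray, truths: np.ndarray) -> BinaryRates:
    """TPR = TP/(TP+FN), FPR = FP/(FP+TN), with raw counts for audit."""
    decisions = np.asarray(decisions).astype(bool).ravel()
    truths = np.asarray(truths).ravel()
    if decisions.size != truths.size:
        raise AlignmentError("decisions and truths must be paired")
    tp = int(np.sum(decisions & (truths == 1)))
    fn = int(np.sum(~decisions & (truths == 1)))
    fp = int(np.sum(decisions & (truths == 0)))
    tn = int(np.sum(~decisions & (truths == 0)))
    tpr_defined = (tp + fn) > 0
    fpr_defined = (fp + tn) > 0
    tpr = tp / (tp + fn) if tpr_defined else math.nan
    fpr = fp / (fp + tn) if fpr_defined else math.nan
    return BinaryRates(
        tpr=tpr, fpr=fpr, sensitivity=tpr, specificity=1 - fpr if fpr_defined else math.nan,
        tp=tp, fp=fp, tn=tn, fn=fn,
        tpr_defined=tpr_defined, fpr_defined=fpr_defined,
    )


# ---------------------------------------------------------------------------
# comparison and calibration
# ---------------------------------------------------------------------------

def continuous_nri(
    scores_new: np.ndarray, scores_old: np.ndarray, truths: np.ndarray
) -> float:
    """Category-free net reclassification index.

    NRI = [P(up|event) - P(down|event)] + [P(down|nonevent) - P(up|nonevent)]
    with "up" meaning scores_new > scores_old (ties count as neither).
    """
    scores_new = np.asarray(scores_new, dtype=float).ravel()
    scores_old = np.asarray(scores_old, dtype=float).ravel()
    truths = np.asarray(truths).ravel()
    if not (scores_new.size == scores_old.size == truths.size):
        raise AlignmentError("paired score vectors required")
    events = truths == 1
    if not events.any() or events.all():
        raise UndefinedMetricError("NRI requires both events and nonevents")
    up = scores_new > scores_old
    down = scores_new < scores_old
    p_up_e = up[events].mean()
    p_down_e = down[events].mean()
    p_up_ne = up[~events].mean()
    p_down_ne = down[~events].mean()
    return float((p_up_e - p_down_e) + (p_down_ne - p_up_ne))


def weighted_brier(
    preds: PredictionSet, weights: np.ndarray | str = "inverse_prevalence"
) -> float:
    """Weighted mean of per-label Brier scores: sum(w_l * Brier_l) / sum(w_l).

    ``"inverse_prevalence"`` sets w_l = 1 / prevalence_l.  The weighting
    scheme is this package's interpretation of the weighted Brier score; the
    normalized inverse-prevalence form is the default and any nonnegative
    weight vector may be supplied instead.
    """
    briers = ((preds.scores - preds.truths) ** 2).mean(axis=0)
    if isinstance(weights, str):
        if weights != "inverse_prevalence":
            raise ParameterError("weights must be an array or 'inverse_prevalence'")
        prevalence = preds.truths.mean(axis=0)
        if np.any(prevalence == 0):
            zero = [preds.label_names[j] for j in np.flatnonzero(prevalence == 0)]
            raise UndefinedMetricError(
                f"inverse-prevalence weights undefined for zero-prevalence labels {zero}"
            )
        w = 1.0 / prevalence
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (preds.n_labels,) or np.any(w < 0) or w.sum() == 0:
            raise ParameterError("weights must be nonnegative, not all zero, length L")
    return float(np.sum(w * briers) / np.sum(w))


def regression_mae(predicted: np.ndarray, true: np.ndarray) -> float:
    """Mean absolute error of paired real vectors."""
    predicted = np.asarray(predicted, dtype=float).ravel()
    true = np.asarray(true, dtype=float).ravel()
    if predicted.size != true.size:
        raise AlignmentError("paired vectors required")
    if predicted.size == 0:
        raise ParameterError("empty input")
    return float(np.mean(np.abs(predicted - true)))
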