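"""Model evaluation: AUROC with bootstrap CIs, averaging, calibration, cutoffs.

Uncertainty uses the reverse percentile bootstrap,
``[2*theta_hat - q_{0.975}, 2*theta_hat - q_{0.025}]`` over the bootstrap
distribution of the statistic; multi-class summaries report both macro
(unweighted mean of per-class metrics) and micro (metric on pooled
one-vs-rest rows) averages; recommended decision cutoffs maximize the
F_beta score (F_1 for gene-level models, F_0.2 — heavily favoring
precision — for gene-disease models).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from ._streams import stream

__all__ = [
    "auroc",
    "bootstrap_ci",
    "macro_micro",
    "calibration",
    "optimal_cutoff",
    "CalibrationResult",
    "CutoffResult",
    "EvaluationReport",
    "evaluation_report",
]


def auroc(scores, labels) -> float:
    """Probability a random positive outranks a random negative (ties = 1/2)."""
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def bootstrap_ci(metric: Callable[[np.ndarray, np.ndarray], float], scores, labels,
                 n_boot: int = 1000, level: float = 0.95, seed: int = 0,
                 max_retries: int = 100) -> tuple[float, float, float]:
    """Reverse percentile bootstrap interval for a (scores, labels) metric.

    Resampling unit is the (score, label) row.  Degenerate resamples on
    which the metric is undefined (e.g. single-class for AUROC) are
    redrawn up to ``max_retries`` times each, keeping ``n_boot`` fixed.

    Returns (point, lower, upper) with the interval
    [2*point - q_{1-alpha/2}, 2*point - q_{alpha/2}].
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n = len(scores)
    point = metric(scores, labels)
    rng = stream(seed, "bootstrap")
    stats = np.empty(n_boot)
    for b in range(n_boot):
        for attempt in range(max_retries + 1):
            idx = rng.integers(n, size=n)
            try:
                stats[b] = metric(scores[idx], labels[idx])
                break
            except ValueError:
                continue
        else:
            raise ValueError(f"metric undefined after {max_retries} bootstrap redraws")
    alpha = 1.0 - level
    q_lo, q_hi = np.quantile(stats, [alpha / 2, 1 - alpha / 2])
    return point, 2 * point - q_hi, 2 * point - q_lo


def macro_micro(per_class: dict[str, tuple[np.ndarray, np.ndarray]],
                metric: Callable = auroc) -> tuple[float, float]:
    """Macro (mean of per-class metrics) and micro (pooled rows) averages.

    ``per_class`` maps class name -> (scores, one-vs-rest labels); in the
    pooled computation every item contributes one row per class.
    """
    if not per_class:
        raise ValueError("need at least one class")
    macro = float(np.mean([metric(s, y) for s, y in per_class.values()]))
    pooled_s = np.concatenate([np.asarray(s, dtype=float) for s, _ in per_class.values()])
    pooled_y = np.concatenate([np.asarray(y) for _, y in per_class.values()])
    micro = float(metric(pooled_s, pooled_y))
    return macro, micro


@dataclass
class CalibrationResult:
    curve: pd.DataFrame  # bin, mean_predicted, observed_rate, count
    slope: float | None
    intercept: float | None
    flagged: bool  # True when the regression was undefined (single bin)


def calibration(predictions, labels, n_bins: int = 10) -> CalibrationResult:
    """Reliability curve over equal-width probability bins plus a linear fit.

    The slope/intercept come from a count-weighted least-squares fit of
    the observed positive rate on the mean prediction across non-empty
    bins (a calibrated model gives slope 1, intercept 0).  With a single
    occupied bin the regression is undefined and flagged.
    """
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(labels).astype(int)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("predictions must be probabilities in [0, 1]")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    which = np.clip(np.digitize(p, edges[1:-1]), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        mask = which == b
        if not mask.any():
            continue
        rows.append({"bin": b, "mean_predicted": float(p[mask].mean()),
                     "observed_rate": float(y[mask].mean()), "count": int(mask.sum())})
    curve = pd.DataFrame(rows)
    if len(curve) < 2:
        return CalibrationResult(curve=curve, slope=None, intercept=None, flagged=True)
    w = curve["count"].to_numpy(dtype=float)
    x = curve["mean_predicted"].to_numpy()
    obs = curve["observed_rate"].to_numpy()
    xbar = np.average(x, weights=w)
    obar = np.average(obs, weights=w)
    sxx = np.average((x - xbar) ** 2, weights=w)
    if sxx == 0:
        return CalibrationResult(curve=curve, slope=None, intercept=None, flagged=True)
    slope = float(np.average((x - xbar) * (obs - obar), weights=w) / sxx)
    intercept = float(obar - slope * xbar)
    return CalibrationResult(curve=curve, slope=slope, intercept=intercept, flagged=False)


@dataclass
class CutoffResult:
    threshold: float
    f_beta: float
    precision: float
    recall: float
    beta: float


def optimal_cutoff(predictions, labels, beta: float = 1.0) -> CutoffResult:
    """Threshold maximizing F_beta = (1+b^2) P R / (b^2 P + R).

    Every distinct prediction value is a candidate threshold (classify
    positive when prediction >= threshold); ties in F_beta break toward
    the smallest threshold, which maximizes recall at equal F.
    """
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(labels).astype(int)
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValueError("optimal_cutoff needs at least one positive label")
    order = np.argsort(-p, kind="mergesort")
    ps, ys = p[order], y[order]
    tp = np.cumsum(ys)
    npred = np.arange(1, len(ys) + 1)
    # last occurrence of each distinct value in the descending order =
    # counts for threshold "score >= value"
    last = np.flatnonzero(np.r_[ps[1:] != ps[:-1], True])
    tp_t, npred_t = tp[last], npred[last]
    prec = tp_t / npred_t
    rec = tp_t / n_pos
    b2 = beta * beta
    denom = b2 * prec + rec
    f = np.where(denom > 0, (1 + b2) * prec * rec / np.where(denom == 0, 1, denom), 0.0)
    best_f = f.max()
    candidates = np.flatnonzero(f == best_f)
    pick = candidates[-1]  # descending order: last candidate = smallest threshold
    return CutoffResult(threshold=float(ps[last][pick]), f_beta=float(best_f),
                        precision=float(prec[pick]), recall=float(rec[pick]), beta=float(beta))


@dataclass
class EvaluationReport:
    """Per-class and aggregate evaluation of holdout DOE predictions."""

    per_class: dict = field(default_factory=dict)
    macro_auroc: float | None = None
    micro_auroc: float | None = None
    n: int = 0

    def to_json(self, path=None) -> str:
        def _clean(v):
            if isinstance(v, dict):
                return {k: _clean(x) for k, x in v.items()}
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            return v
        payload = {"per_class": _clean(self.per_class), "macro_auroc": self.macro_auroc,
                   "micro_auroc": self.micro_auroc, "n": self.n}
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def evaluation_report(per_class: dict[str, tuple[np.ndarray, np.ndarray]],
                      beta: float = 1.0, n_boot: int = 1000, n_bins: int = 10,
                      seed: int = 0) -> EvaluationReport:
    """Full evaluation: per-class AUROC + CI, calibration, F_beta cutoff."""
    report = EvaluationReport()
    for cls, (scores, labels) in per_class.items():
        point, lo, hi = bootstrap_ci(auroc, scores, labels, n_boot=n_boot, seed=seed)
        cal = calibration(scores, labels)
        cut = optimal_cutoff(scores, labels, beta=beta)
        prev = float(np.mean(np.asarray(labels).astype(int)))
        report.per_class[cls] = {
            "auroc": point, "ci_lower": lo, "ci_upper": hi,
            "calibration_slope": cal.slope, "calibration_intercept": cal.intercept,
            "cutoff": asdict(cut), "prevalence": prev,
        }
        report.n = len(np.asarray(labels))
    macro, micro = macro_micro(per_class)
    report.macro_auroc, report.micro_auroc = macro, micro
    return report
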