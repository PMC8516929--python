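"""Slide-level metrics with percentile-bootstrap confidence intervals.

Metrics: ROC AUC (equivalently the Mann-Whitney pairwise statistic), log
loss, and threshold metrics (accuracy, sensitivity, specificity) at a fixed
probability threshold of 0.5. Confidence intervals are 95% percentile
bootstrap intervals over 1000 resamples drawn with replacement at the slide
level; resamples that lose a label category are redrawn so every metric is
computed on exactly ``n_bootstrap`` values.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = [
    "EvalConfig",
    "MetricEstimate",
    "EvalReport",
    "roc_auc",
    "log_loss",
    "threshold_metrics",
    "bootstrap_ci",
    "evaluate",
    "read_predictions_csv",
    "write_predictions_csv",
]

LOG_LOSS_EPS = 1e-15


@dataclass
class EvalConfig:
    threshold: float = 0.5
    n_bootstrap: int = 1000
    ci_level: float = 0.95
    seed: int = 0
    bootstrap_variant: str = "percentile"  # recorded in report metadata

    def validate(self) -> None:
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must lie strictly in (0, 1)")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must lie in (0, 1)")


def _check_inputs(labels, scores) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(labels, dtype=int).ravel()
    s = np.asarray(scores, dtype=np.float64).ravel()
    if y.shape != s.shape:
        raise ValueError(f"length mismatch: {y.shape} labels vs {s.shape} scores")
    return y, s


def roc_auc(labels, scores) -> float:
    """ROC AUC; equals the Mann-Whitney pairwise-comparison statistic."""
    y, s = _check_inputs(labels, scores)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC AUC needs both label categories")
    return float(roc_auc_score(y, s))


def log_loss(labels, probs) -> float:
    """Mean binary cross-entropy with probabilities clipped to [eps, 1-eps]."""
    y, p = _check_inputs(labels, probs)
    p = np.clip(p, LOG_LOSS_EPS, 1 - LOG_LOSS_EPS)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def threshold_metrics(labels, probs, threshold: float = 0.5) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) with positive iff prob >= threshold."""
    y, p = _check_inputs(labels, probs)
    pred = (p >= threshold).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("sensitivity/specificity need both label categories")
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    accuracy = (tp + tn) / len(y)
    sensitivity = tp / (tp + fn)
    specificity = tn / (tn + fp)
    return accuracy, sensitivity, specificity


def bootstrap_ci(
    metric: Callable[[np.ndarray, np.ndarray], float],
    labels,
    scores,
    cfg: EvalConfig,
) -> tuple[float, float]:
    """Percentile bootstrap interval for a slide-level metric.

    Slides are the resampling unit. Resamples on which the metric is
    undefined (e.g. a single label category for AUC) are redrawn; if no
    valid resample can be drawn the metric is reported as undefined.
    """
    cfg.validate()
    y, s = _check_inputs(labels, scores)
    if y.size < 2:
        raise ValueError("bootstrap needs at least two slides")
    rng = np.random.default_rng(cfg.seed)
    values = np.empty(cfg.n_bootstrap)
    max_attempts = 1000 * cfg.n_bootstrap
    attempts = 0
    for b in range(cfg.n_bootstrap):
        while True:
            attempts += 1
            if attempts > max_attempts:
                raise ValueError("metric undefined on all bootstrap resamples")
            idx = rng.integers(0, y.size, size=y.size)
            try:
                values[b] = metric(y[idx], s[idx])
                break
            except ValueError:
                continue
    alpha = 1.0 - cfg.ci_level
    lo, hi = np.quantile(values, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


@dataclass
class MetricEstimate:
    point: float
    ci_low: float
    ci_high: float


@dataclass
class EvalReport:
    """Point estimates and bootstrap CIs for one evaluation set."""

    auc: MetricEstimate
    log_loss: MetricEstimate
    accuracy: MetricEstimate
    sensitivity: MetricEstimate
    specificity: MetricEstimate
    n_positive: int
    n_negative: int
    config: dict = field(default_factory=dict)

    def to_json(self, uri: str | Path | None = None) -> str:
        payload = json.dumps(asdict(self), indent=2)
        if uri is not None:
            Path(uri).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, payload: str | Path) -> "EvalReport":
        if isinstance(payload, Path) or (
            isinstance(payload, str) and not payload.lstrip().startswith("{")
        ):
            payload = Path(payload).read_text()
        raw = json.loads(payload)
        metrics = {
            k: MetricEstimate(**raw[k])
            for k in ("auc", "log_loss", "accuracy", "sensitivity", "specificity")
        }
        return cls(
            **metrics,
            n_positive=raw["n_positive"],
            n_negative=raw["n_negative"],
            config=raw.get("config", {}),
        )

    def to_table_row(self) -> dict:
        def fmt(m: MetricEstimate) -> str:
            return f"{m.point:.4f} [{m.ci_low:.4f}, {m.ci_high:.4f}]"

        return {
            "ROC AUC": fmt(self.auc),
            "Log loss": fmt(self.log_loss),
            "Accuracy": fmt(self.accuracy),
            "Sensitivity": fmt(self.sensitivity),
            "Specificity": fmt(self.specificity),
        }


def evaluate(labels, probs, cfg: EvalConfig | None = None) -> EvalReport:
    """Full slide-level evaluation with bootstrap CIs for every metric."""
    cfg = cfg or EvalConfig()
    cfg.validate()
    y, p = _check_inputs(labels, probs)
    if len(np.unique(y)) < 2:
        raise ValueError("evaluation needs both positive and negative slides")

    def acc(yy, pp):
        return threshold_metrics(yy, pp, cfg.threshold)[0]

    def sens(yy, pp):
        return threshold_metrics(yy, pp, cfg.threshold)[1]

    def spec(yy, pp):
        return threshold_metrics(yy, pp, cfg.threshold)[2]

    estimates = {}
    for name, fn in [
        ("auc", roc_auc),
        ("log_loss", log_loss),
        ("accuracy", acc),
        ("sensitivity", sens),
        ("specificity", spec),
    ]:
        lo, hi = bootstrap_ci(fn, y, p, cfg)
        estimates[name] = MetricEstimate(float(fn(y, p)), lo, hi)
    return EvalReport(
        **estimates,
        n_positive=int(np.sum(y == 1)),
        n_negative=int(np.sum(y == 0)),
        config={
            "threshold": cfg.threshold,
            "n_bootstrap": cfg.n_bootstrap,
            "ci_level": cfg.ci_level,
            "seed": cfg.seed,
            "bootstrap_variant": cfg.bootstrap_variant,
        },
    )


def roc_points(labels, scores) -> list[tuple[float, float, float]]:
    """(fpr, tpr, threshold) points of the ROC curve, for plotting/export."""
    y, s = _check_inputs(labels, scores)
    fpr, tpr, thr = roc_curve(y, s)
    return list(zip(fpr.tolist(), tpr.tolist(), thr.tolist()))


def write_predictions_csv(
    rows: list[tuple[str, str, float]], uri: str | Path
) -> None:
    """Write (slide_id, label, probability) rows."""
    with open(uri, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["slide_id", "label", "probability"])
        writer.writerows(rows)


def read_predictions_csv(uri: str | Path) -> list[tuple[str, str, float]]:
    with open(uri, newline="") as fh:
        reader = csv.DictReader(fh)
        return [
            (row["slide_id"], row["label"], float(row["probability"]))
            for row in reader
        ]
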