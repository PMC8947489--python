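"""Slide-level classifier evaluation: ROC/AUC, log loss, confusion metrics,
and percentile-bootstrap confidence intervals.

The ROC curve is built by sweeping the decision threshold over every
distinct score (plus sentinels), calling a slide positive when its score is
>= the threshold, with TPR = TP/(TP+FN) and FPR = FP/(FP+TN) at each
threshold; the AUC is the trapezoidal area under that curve.  95% CIs come
from the percentile bootstrap with 1000 resamples of slides.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import substream


@dataclass
class ScoredCohort:
    """Slide ids, binary truth (1 = adenocarcinoma) and scores in [0, 1]."""

    slide_ids: list[str]
    labels: np.ndarray
    scores: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.scores.size and (self.scores.min() < 0 or self.scores.max() > 1):
            raise ValueError("scores must lie in [0, 1]")
        if len(self.labels) != len(self.scores):
            raise ValueError("labels and scores length mismatch")

    def __len__(self):
        return len(self.scores)

    def take(self, idx: np.ndarray) -> "ScoredCohort":
        return ScoredCohort(
            [self.slide_ids[i] for i in idx], self.labels[idx], self.scores[idx]
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "ScoredCohort":
        df = pd.read_csv(path)
        labels = (df["label"].astype(str) == "adenocarcinoma").astype(int).to_numpy()
        return cls(df["slide_id"].astype(str).tolist(), labels, df["score"].to_numpy())

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "slide_id": self.slide_ids,
                "label": np.where(self.labels == 1, "adenocarcinoma", "benign"),
                "score": self.scores,
            }
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def confusion_at_threshold(cohort: ScoredCohort, t: float) -> ConfusionCounts:
    """Counts with a slide called positive iff its score >= t."""
    call = cohort.scores >= t
    pos = cohort.labels == 1
    return ConfusionCounts(
        TP=int(np.sum(call & pos)),
        FP=int(np.sum(call & ~pos)),
        TN=int(np.sum(~call & ~pos)),
        FN=int(np.sum(~call & pos)),
    )


def tpr(c: ConfusionCounts) -> float:
    """True positive rate TP / (TP + FN)."""
    if c.TP + c.FN == 0:
        raise ZeroDivisionError("no positives in cohort")
    return c.TP / (c.TP + c.FN)


def fpr(c: ConfusionCounts) -> float:
    """False positive rate FP / (FP + TN)."""
    if c.FP + c.TN == 0:
        raise ZeroDivisionError("no negatives in cohort")
    return c.FP / (c.FP + c.TN)


def roc_curve(cohort: ScoredCohort) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Threshold sweep over all distinct scores plus sentinels.

    A slide is called positive at threshold t iff its score >= t.  The
    sweep runs over every distinct score plus a sentinel above the maximum
    (nothing positive, the (0,0) corner) and the sentinel 0 (everything
    positive, the (1,1) corner).  Implemented as one pass over the
    score-sorted cohort, which is algebraically identical to evaluating
    ``confusion_at_threshold`` at each threshold.

    Returns (fpr, tpr, thresholds) from the strictest threshold to 0.
    """
    labels, scores = cohort.labels, cohort.scores
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both labels in the cohort")
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    y_sorted = labels[order]
    # cumulative TP/FP counting all slides with score >= the block's score
    block_ends = np.r_[np.nonzero(np.diff(s_sorted))[0], len(s_sorted) - 1]
    tprs = np.cumsum(y_sorted)[block_ends] / n_pos
    fprs = np.cumsum(1 - y_sorted)[block_ends] / n_neg
    thresholds = s_sorted[block_ends]
    # sentinels: above-max threshold -> (0,0); threshold 0 -> (1,1)
    fprs = np.r_[0.0, fprs]
    tprs = np.r_[0.0, tprs]
    thresholds = np.r_[min(s_sorted[0] + 1e-9, 1.0 + 1e-9), thresholds]
    if thresholds[-1] > 0.0:
        fprs = np.r_[fprs, 1.0]
        tprs = np.r_[tprs, 1.0]
        thresholds = np.r_[thresholds, 0.0]
    return fprs, tprs, thresholds


def auc(fprs: np.ndarray, tprs: np.ndarray) -> float:
    """Trapezoidal area under a (FPR, TPR) curve."""
    order = np.lexsort((tprs, fprs))
    return float(np.trapezoid(tprs[order], fprs[order]))


def auc_score(cohort: ScoredCohort) -> float:
    f, t, _ = roc_curve(cohort)
    return auc(f, t)


def log_loss(cohort: ScoredCohort, eps: float = 1e-15) -> float:
    """Mean binary cross-entropy over slides, scores clipped to [eps, 1-eps]."""
    p = np.clip(cohort.scores, eps, 1.0 - eps)
    y = cohort.labels
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def summary_metrics(cohort: ScoredCohort, t: float = 0.5) -> dict[str, float]:
    """Accuracy, sensitivity, specificity and F1 at operating threshold t."""
    c = confusion_at_threshold(cohort, t)
    if c.TP + c.FN == 0 or c.FP + c.TN == 0:
        raise ZeroDivisionError("both labels required for summary metrics")
    return {
        "accuracy": (c.TP + c.TN) / c.total,
        "sensitivity": tpr(c),
        "specificity": c.TN / (c.TN + c.FP),
        "f1": 2 * c.TP / (2 * c.TP + c.FP + c.FN) if c.TP else 0.0,
    }


def bootstrap_ci(
    cohort: ScoredCohort,
    statistic,
    n_iter: int = 1000,
    seed: int = 0,
    _max_redraw: int = 1000,
) -> tuple[float, float]:
    """95% percentile-bootstrap CI of ``statistic`` over slide resamples.

    Slides are resampled with replacement n_iter times; resamples missing a
    label (on which ROC-style statistics are undefined) are re-drawn so the
    bootstrap distribution always holds n_iter values.
    """
    if len(cohort) < 2:
        raise ValueError("bootstrap needs at least 2 slides")
    rng = substream(seed, "bootstrap")
    n = len(cohort)
    values = np.empty(n_iter)
    failures = 0
    for i in range(n_iter):
        for _ in range(_max_redraw):
            idx = rng.integers(n, size=n)
            sub = cohort.take(idx)
            if len(np.unique(sub.labels)) == 2:
                break
        else:
            raise ValueError("statistic undefined on the vast majority of resamples")
        try:
            values[i] = statistic(sub)
        except (ValueError, ZeroDivisionError):
            failures += 1
            values[i] = np.nan
    if failures > n_iter / 2:
        raise ValueError("statistic undefined on more than half of the resamples")
    lo, hi = np.nanquantile(values, [0.025, 0.975])
    return float(lo), float(hi)


@dataclass
class MetricReport:
    """Point estimates with 95% bootstrap CIs for the six slide metrics."""

    auc: tuple[float, float, float]
    log_loss: tuple[float, float, float]
    accuracy: tuple[float, float, float]
    sensitivity: tuple[float, float, float]
    specificity: tuple[float, float, float]
    f1: tuple[float, float, float]
    threshold: float
    n_bootstrap: int
    seed: int

    def to_dict(self) -> dict:
        out = {}
        for name in ("auc", "log_loss", "accuracy", "sensitivity", "specificity", "f1"):
            point, lo, hi = getattr(self, name)
            out[name] = {"point": point, "ci_low": lo, "ci_high": hi}
        out["threshold"] = self.threshold
        out["n_bootstrap"] = self.n_bootstrap
        out["seed"] = self.seed
        return out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def summary(self) -> str:
        lines = [f"{'metric':<12} {'point':>8} {'95% CI':>19}"]
        for name in ("auc", "log_loss", "accuracy", "sensitivity", "specificity", "f1"):
            point, lo, hi = getattr(self, name)
            lines.append(f"{name:<12} {point:8.4f}   [{lo:.4f}, {hi:.4f}]")
        return "\n".join(lines)


def metric_report(
    cohort: ScoredCohort, threshold: float = 0.5, n_bootstrap: int = 1000, seed: int = 0
) -> MetricReport:
    """Compute the full metric suite with bootstrap CIs on one cohort."""
    stats = {
        "auc": auc_score,
        "log_loss": log_loss,
        "accuracy": lambda c: summary_metrics(c, threshold)["accuracy"],
        "sensitivity": lambda c: summary_metrics(c, threshold)["sensitivity"],
        "specificity": lambda c: summary_metrics(c, threshold)["specificity"],
        "f1": lambda c: summary_metrics(c, threshold)["f1"],
    }
    fields = {}
    for i, (name, fn) in enumerate(stats.items()):
        lo, hi = bootstrap_ci(cohort, fn, n_iter=n_bootstrap, seed=seed + i)
        fields[name] = (float(fn(cohort)), lo, hi)
    return MetricReport(
        **fields, threshold=threshold, n_bootstrap=n_bootstrap, seed=seed
    )


def write_roc_tsv(cohort: ScoredCohort, path: str | Path) -> None:
    f, t, thr = roc_curve(cohort)
    pd.DataFrame({"threshold": thr, "fpr": f, "tpr": t}).to_csv(path, sep="\t", index=False)


def plot_roc(cohort: ScoredCohort, path: str | Path, title: str = "ROC") -> None:
    """Save a ROC plot (AUC in the legend) as PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    f, t, _ = roc_curve(cohort)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(f, t, label=f"AUC = {auc(f, t):.4f}")
    ax.plot([0, 1], [0, 1], "k--", lw=0.5)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.set_title(title)
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
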