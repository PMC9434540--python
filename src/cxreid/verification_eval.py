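"""Verification-side evaluation.

Thresholded classification of pair scores, confusion-derived statistics
(accuracy, specificity, recall, precision, F1), ROC/AUC via the rank
statistic with tie correction, percentile-bootstrap confidence intervals,
and subgroup true-positive-rate analyses over positive pairs (age gap,
disease change, projection-view change).
"""

from __future__ import annotations

import dataclasses
import json
import math
import pathlib
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .cohort import Cohort
from .pairs import PairSet


@dataclasses.dataclass
class ScoredPairs:
    pairs: PairSet
    scores: np.ndarray

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if len(self.scores) != len(self.pairs):
            raise ValueError("scores not aligned to pairs")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("non-finite scores")

    @property
    def labels(self) -> np.ndarray:
        return self.pairs.labels()


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def p(self) -> int:
        return self.tp + self.fn

    @property
    def n(self) -> int:
        return self.tn + self.fp

    @classmethod
    def from_predictions(cls, predicted: np.ndarray, labels: np.ndarray
                         ) -> "ConfusionCounts":
        predicted = np.asarray(predicted).astype(bool)
        labels = np.asarray(labels).astype(bool)
        return cls(tp=int(np.sum(predicted & labels)),
                   fn=int(np.sum(~predicted & labels)),
                   tn=int(np.sum(~predicted & ~labels)),
                   fp=int(np.sum(predicted & ~labels)))


def classify(scored: ScoredPairs, threshold: float = 0.5) -> np.ndarray:
    """Predicted labels; a score equal to the threshold counts positive."""
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie inside (0, 1)")
    return (scored.scores >= threshold).astype(np.int64)


def confusion_metrics(c: ConfusionCounts) -> dict[str, float | None]:
    """Accuracy, specificity, recall, precision, F1 from confusion counts.

    A metric with zero denominator is reported as ``None`` rather than
    raising.
    """
    total = c.p + c.n
    out: dict[str, float | None] = {}
    out["accuracy"] = (c.tp + c.tn) / total if total else None
    out["specificity"] = c.tn / c.n if c.n else None
    out["recall"] = c.tp / c.p if c.p else None
    out["precision"] = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else None
    if out["precision"] is not None and out["recall"] is not None \
            and (out["precision"] + out["recall"]) > 0:
        out["f1"] = 2 * out["precision"] * out["recall"] / (out["precision"] + out["recall"])
    else:
        out["f1"] = None
    return out


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve via the two-sample rank statistic.

    Equivalent to the probability that a random positive outscores a random
    negative, counting ties as 1/2 (midrank tie correction).
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes present")
    ranks = rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def bootstrap_auc_ci(scores: Sequence[float], labels: Sequence[int],
                     n_boot: int = 10_000, level: float = 0.95,
                     seed: int = 0) -> tuple[float, float]:
    """Percentile bootstrap CI for the AUC, resampling scored pairs.

    Replicates that draw a single class are redrawn. The unit of resampling
    is the pair; pairs sharing an image are treated as independent, a caveat
    inherited from evaluating on pre-built pair sets.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(np.int64)
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    n = scores.size
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            lab = labels[idx]
            s = lab.sum()
            if 0 < s < n:
                break
        aucs[b] = roc_auc(scores[idx], lab)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(aucs, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


@dataclasses.dataclass
class VerificationReport:
    auc: float
    ci_low: float
    ci_high: float
    counts: ConfusionCounts
    metrics: dict[str, float | None]

    def to_dict(self) -> dict:
        d = {"auc": self.auc, "ci_low": self.ci_low, "ci_high": self.ci_high,
             "tp": self.counts.tp, "fn": self.counts.fn,
             "tn": self.counts.tn, "fp": self.counts.fp}
        d.update({k: (round(v, 4) if v is not None else None)
                  for k, v in self.metrics.items()})
        return d

    def to_json(self, path: str | pathlib.Path) -> None:
        pathlib.Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def evaluate_verification(scored: ScoredPairs, threshold: float = 0.5,
                          n_boot: int = 10_000, seed: int = 0) -> VerificationReport:
    labels = scored.labels
    predicted = classify(scored, threshold)
    counts = ConfusionCounts.from_predictions(predicted, labels)
    auc = roc_auc(scored.scores, labels)
    lo, hi = bootstrap_auc_ci(scored.scores, labels, n_boot=n_boot, seed=seed)
    return VerificationReport(auc, lo, hi, counts, confusion_metrics(counts))


# -- subgroup analyses over positive pairs ------------------------------------

def subgroup_tpr(scored: ScoredPairs, cohort: Cohort, attribute: str,
                 bins: Sequence[int] | None = None, threshold: float = 0.5
                 ) -> dict[str, dict]:
    """TPR of positive pairs grouped by an acquisition/biology attribute.

    ``attribute`` is one of ``age_gap_years`` (binned per supplied integer
    bin edges, right-open), ``disease_change`` (one bin per finding newly
    appearing in the later image of the pair; a pair with several new
    findings counts in each) and ``view_change``. Records with an unknown
    attribute are excluded; empty bins are omitted.
    """
    predicted = classify(scored, threshold)
    groups: dict[str, list[int]] = {}
    for sample, pred in zip(scored.pairs, predicted):
        if sample.label != 1:
            continue
        a, b = cohort[sample.first_id], cohort[sample.second_id]
        if attribute == "age_gap_years":
            gap = abs(a.age_years - b.age_years)
            edges = list(bins) if bins is not None else list(range(0, 13))
            key = None
            for lo, hi in zip(edges[:-1], edges[1:]):
                if lo <= gap < hi:
                    key = f"[{lo},{hi})"
                    break
            if key is None:
                continue
            groups.setdefault(key, []).append(int(pred))
        elif attribute == "disease_change":
            earlier, later = (a, b) if a.follow_up_index <= b.follow_up_index else (b, a)
            new_findings = later.findings - earlier.findings
            for label in sorted(new_findings):
                groups.setdefault(label, []).append(int(pred))
        elif attribute == "view_change":
            if a.view == "unknown" or b.view == "unknown":
                continue
            key = "changed" if a.view != b.view else "same"
            groups.setdefault(key, []).append(int(pred))
        else:
            raise ValueError(f"unknown attribute {attribute!r}")
    report = {}
    for key, preds in groups.items():
        p = len(preds)
        tp = int(sum(preds))
        report[key] = {"tpr": tp / p, "tp": tp, "p": p}
    return report


def read_score_file(csv_path: str | pathlib.Path) -> ScoredPairs:
    from .pairs import PairSample
    df = pd.read_csv(csv_path, dtype={"first_id": str, "second_id": str})
    pairs = PairSet([PairSample(r.first_id, r.second_id, int(r.label))
                     for r in df.itertuples(index=False)])
    return ScoredPairs(pairs, df["score"].to_numpy())


def write_score_file(scored: ScoredPairs, csv_path: str | pathlib.Path) -> None:
    pd.DataFrame([{"first_id": s.first_id, "second_id": s.second_id,
                   "label": s.label, "score": sc}
                  for s, sc in zip(scored.pairs, scored.scores)]
                 ).to_csv(csv_path, index=False)


def roc_curve_points(scores: Sequence[float], labels: Sequence[int]
                     ) -> pd.DataFrame:
    """ROC curve (FPR, TPR, threshold) over the distinct score thresholds."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc curve requires both classes present")
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    tp = np.cumsum(labels[order])
    fp = np.cumsum(~labels[order])
    distinct = np.r_[np.nonzero(np.diff(sorted_scores))[0], sorted_scores.size - 1]
    rows = {"threshold": np.r_[np.inf, sorted_scores[distinct]],
            "tpr": np.r_[0.0, tp[distinct] / n_pos],
            "fpr": np.r_[0.0, fp[distinct] / n_neg]}
    return pd.DataFrame(rows)


def round_half_up(x: float, digits: int = 4) -> float:
    """Decimal rounding matching printed tables (0.95545 -> 0.9555)."""
    factor = 10 ** digits
    return math.floor(x * factor + 0.5) / factor
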