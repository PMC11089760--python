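"""Evaluation of ranked lncRNA-disease predictions against a gold standard.

The gold standard holds only verified positive associations; every ranked
pair outside it is treated as negative (the standard, if imperfect, practice
when no verified negatives exist -- predictions counted as false positives
may simply be not-yet-verified).  Provided metrics: ROC/AUC, precision-
recall/AUPR, an F1 sweep over score thresholds, rank agreement (Jaccard on
the top fraction) and per-set recovery curves.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve

logger = logging.getLogger(__name__)

__all__ = [
    "GoldStandard",
    "label_rank",
    "roc_auc",
    "pr_aupr",
    "f1_sweep",
    "jaccard_top",
    "set_recovery",
    "evaluate_rank",
    "EvaluationReport",
]

Pair = tuple[str, str]


@dataclass(frozen=True)
class GoldStandard:
    """Set of externally verified (lncRNA, disease) pairs."""

    pairs: frozenset[Pair]

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError("gold standard is empty")

    @classmethod
    def from_pairs(cls, pairs) -> "GoldStandard":
        return cls(frozenset((str(a), str(b)) for a, b in pairs))


def label_rank(rank: pd.DataFrame, gold: GoldStandard) -> pd.DataFrame:
    """Tag each ranked triplet true iff its pair is in the gold standard."""
    universe = set(zip(rank["lncrna"], rank["disease"]))
    missing = len(gold.pairs - universe)
    if missing:
        logger.warning(
            "%d gold pair(s) never appear in the rank and cannot be recovered",
            missing,
        )
    out = rank.copy()
    out["label"] = [
        (l, d) in gold.pairs for l, d in zip(out["lncrna"], out["disease"])
    ]
    return out


def _labels_scores(labeled: pd.DataFrame):
    y = labeled["label"].to_numpy(dtype=bool)
    s = labeled["score"].to_numpy(dtype=float)
    return y, s


def roc_auc(labeled: pd.DataFrame):
    """ROC points and trapezoidal AUC; tied scores collapse to one step."""
    y, s = _labels_scores(labeled)
    if y.all() or not y.any():
        raise ValueError("ROC needs at least one positive and one negative label")
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    return list(zip(fpr.tolist(), tpr.tolist())), float(_trapezoid_auc(fpr, tpr))


def pr_aupr(labeled: pd.DataFrame):
    """Precision-recall points and AUPR.

    The curve is sampled at every threshold where recall increases, taking
    the precision attained there; the interpolated envelope (running maximum
    from high recall downwards) is integrated by trapezoid over recall, with
    an anchor at recall 0 carrying the first envelope precision.  With this
    construction AUPR is never below the positive prevalence.
    """
    y, s = _labels_scores(labeled)
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValueError("PR curve needs at least one positive label")
    order = np.argsort(-s, kind="mergesort")
    y_sorted, s_sorted = y[order], s[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(~y_sorted)
    # one point per distinct score (tie groups collapse to their last index)
    last_of_group = np.flatnonzero(np.r_[s_sorted[1:] != s_sorted[:-1], True])
    tp_g, fp_g = tp[last_of_group], fp[last_of_group]
    gained = np.r_[tp_g[0] > 0, tp_g[1:] > tp_g[:-1]]
    recall = tp_g[gained] / n_pos
    precision = tp_g[gained] / (tp_g[gained] + fp_g[gained])
    envelope = np.maximum.accumulate(precision[::-1])[::-1]
    r_pts = np.r_[0.0, recall]
    p_pts = np.r_[envelope[0], envelope]
    aupr = float(np.trapezoid(p_pts, r_pts))
    return list(zip(r_pts.tolist(), p_pts.tolist())), aupr


def f1_sweep(labeled: pd.DataFrame, thresholds=None) -> pd.DataFrame:
    """Precision, recall and F1 at each threshold (score >= t is positive).

    The default grid is {0.05, 0.10, ..., 0.95} plus every distinct score,
    so the true optimum is never missed.  F1 is defined as 0 when P + R = 0.
    """
    y, s = _labels_scores(labeled)
    if thresholds is None:
        grid = np.round(np.arange(0.05, 0.951, 0.05), 10)
        thresholds = np.unique(np.r_[grid, np.unique(s)])
    else:
        thresholds = np.unique(np.asarray(list(thresholds), dtype=float))
        if thresholds.size == 0:
            raise ValueError("threshold grid is empty")
    rows = []
    n_pos = int(y.sum())
    for t in thresholds:
        called = s >= t
        tp = int((called & y).sum())
        fp = int((called & ~y).sum())
        fn = n_pos - tp
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * p * r / (p + r) if p + r else 0.0
        rows.append((float(t), p, r, f1))
    return pd.DataFrame(rows, columns=["threshold", "precision", "recall", "f1"])


def max_f1(sweep: pd.DataFrame) -> tuple[float, float]:
    """(max F1, minimum threshold attaining it) from an f1_sweep table."""
    best = sweep["f1"].max()
    at = sweep.loc[np.isclose(sweep["f1"], best), "threshold"].min()
    return float(best), float(at)


def _top_pairs(rank: pd.DataFrame, fraction: float) -> set[Pair]:
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    n = math.ceil(fraction * len(rank))
    head = rank.head(n)
    return set(zip(head["lncrna"], head["disease"]))


def jaccard_top(rank_a: pd.DataFrame, rank_b: pd.DataFrame,
                fraction: float = 0.05) -> float:
    """Jaccard index of the two methods' top-fraction prediction sets."""
    ua = set(zip(rank_a["lncrna"], rank_a["disease"]))
    ub = set(zip(rank_b["lncrna"], rank_b["disease"]))
    if ua != ub:
        raise ValueError("ranks cover different pair universes")
    ta, tb = _top_pairs(rank_a, fraction), _top_pairs(rank_b, fraction)
    return len(ta & tb) / len(ta | tb)


def set_recovery(rank: pd.DataFrame, tagged_sets: dict[str, set],
                 fractions=(0.10, 0.20, 0.30, 0.50)) -> pd.DataFrame:
    """Fraction of each tagged pair set found in the top fractions of the rank.

    Rows are set labels, columns the rank fractions; each cell is the
    proportion of that set's pairs placed within the top ``ceil(f * n)``
    positions.  Cells are non-decreasing along each row.
    """
    universe = set(zip(rank["lncrna"], rank["disease"]))
    out = {}
    for label, pairs in tagged_sets.items():
        pairs = {(str(a), str(b)) for a, b in pairs}
        if not pairs:
            raise ValueError(f"tagged set {label!r} is empty")
        stray = pairs - universe
        if stray:
            raise ValueError(
                f"tagged set {label!r} has pairs outside the ranked universe: "
                f"{sorted(stray)[:3]}"
            )
        out[label] = [
            len(pairs & _top_pairs(rank, f)) / len(pairs) for f in fractions
        ]
    return pd.DataFrame(out, index=[f"top_{f:g}" for f in fractions]).T


@dataclass
class EvaluationReport:
    """Bundle of all metrics for one labeled rank."""

    roc_points: list
    auc: float
    pr_points: list
    aupr: float
    f1_table: pd.DataFrame
    max_f1: float
    argmax_threshold: float

    def summary(self) -> str:
        return (
            f"auc={self.auc:.4f}\taupr={self.aupr:.4f}\t"
            f"max_f1={self.max_f1:.4f}\tthreshold={self.argmax_threshold:g}"
        )

    def write(self, prefix) -> None:
        """Tab-separated metric tables plus a one-line summary."""
        pd.DataFrame(self.roc_points, columns=["fpr", "tpr"]).to_csv(
            f"{prefix}.roc.tsv", sep="\t", index=False
        )
        pd.DataFrame(self.pr_points, columns=["recall", "precision"]).to_csv(
            f"{prefix}.pr.tsv", sep="\t", index=False
        )
        self.f1_table.to_csv(f"{prefix}.f1.tsv", sep="\t", index=False)
        with open(f"{prefix}.summary.tsv", "w", encoding="utf-8") as fh:
            fh.write("auc\taupr\tmax_f1\tthreshold\n")
            fh.write(
                f"{self.auc:.6g}\t{self.aupr:.6g}\t{self.max_f1:.6g}\t"
                f"{self.argmax_threshold:.6g}\n"
            )


def evaluate_rank(rank: pd.DataFrame, gold: GoldStandard,
                  thresholds=None) -> EvaluationReport:
    """Label a rank against the gold standard and compute all metrics."""
    labeled = label_rank(rank, gold)
    roc_points, auc_val = roc_auc(labeled)
    pr_points, aupr_val = pr_aupr(labeled)
    sweep = f1_sweep(labeled, thresholds)
    best, at = max_f1(sweep)
    return EvaluationReport(roc_points, auc_val, pr_points, aupr_val,
                            sweep, best, at)
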