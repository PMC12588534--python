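"""Evaluation metrics and cross-validation / cross-dataset protocols.

Metrics follow the standard site-prediction conventions: sensitivity
SN = TP/(TP+FN), specificity SP = TN/(TN+FP), accuracy ACC = (TP+TN)/N,
Matthews correlation coefficient

    MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN))

(defined as 0 when any factor of the denominator vanishes), and AUC by the
Mann-Whitney rank statistic with ties credited ½ — identical to the
trapezoidal ROC area.  On an exactly balanced dataset ACC = (SN+SP)/2.

Cross-validation is stratified k-fold with seeded shuffling, and leakage is
controlled strictly: the propensity table, the FCM antecedents and the
consequent fit all see the training split of a fold only.  The cross-dataset
protocol trains the full pipeline on one dataset and evaluates once on
another; a matrix runner aggregates all ordered pairs into a long-format
table (heat-map-ready).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .config import RunConfig
from .pipeline import predict_pipeline, train_pipeline
from .sequence_io import LabelledDataset

logger = logging.getLogger(__name__)


@dataclass
class ConfusionCounts:
    """Standard 2×2 counts with +1 the positive class."""

    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class MetricReport:
    """SN/SP/ACC/MCC/AUC at a threshold, with per-fold breakdown when from CV."""

    SN: float
    SP: float
    ACC: float
    MCC: float
    AUC: float
    threshold: float = 0.0
    n: int = 0
    per_fold: list["MetricReport"] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "SN": self.SN,
            "SP": self.SP,
            "ACC": self.ACC,
            "MCC": self.MCC,
            "AUC": self.AUC,
            "threshold": self.threshold,
            "n": self.n,
        }
        if self.per_fold:
            d["per_fold"] = [f.to_dict() for f in self.per_fold]
        return d


def confusion(labels, predicted) -> ConfusionCounts:
    """Count TP/FP/TN/FN from ±1 truth and ±1 predictions."""
    labels = np.asarray(labels)
    predicted = np.asarray(predicted)
    if labels.shape != predicted.shape:
        raise ValueError(
            f"labels shape {labels.shape} != predictions shape {predicted.shape}"
        )
    return ConfusionCounts(
        TP=int(np.sum((labels == 1) & (predicted == 1))),
        FP=int(np.sum((labels == -1) & (predicted == 1))),
        TN=int(np.sum((labels == -1) & (predicted == -1))),
        FN=int(np.sum((labels == 1) & (predicted == -1))),
    )


def mcc_from_counts(c: ConfusionCounts) -> float:
    """MCC with the 0-on-zero-denominator convention (logged)."""
    num = c.TP * c.TN - c.FP * c.FN
    factors = [c.TP + c.FP, c.TP + c.FN, c.TN + c.FP, c.TN + c.FN]
    if any(f == 0 for f in factors):
        logger.debug("MCC denominator has a zero factor; returning 0")
        return 0.0
    denom = float(np.sqrt(np.prod([float(f) for f in factors])))
    return float(num) / denom


def auc_score(labels, scores) -> float:
    """AUC via the rank statistic, ties credited ½ (== trapezoidal ROC area)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == -1))
    if n_pos == 0 or n_neg == 0:
        warnings.warn("AUC undefined with a single class; returning NaN")
        return float("nan")
    ranks = rankdata(scores)  # average ranks handle ties as ½ credit
    rank_sum_pos = float(np.sum(ranks[labels == 1]))
    return (rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def metrics(labels, scores, threshold: float = 0.0) -> MetricReport:
    """Full metric report from ±1 labels and real-valued scores.

    Scores strictly above the threshold predict +1 (ties go to −1, matching
    the model's sign rule).  A single-class input yields NaN for the
    undefined rate, with a warning.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    predicted = np.where(scores > threshold, 1, -1)
    c = confusion(labels, predicted)
    if c.TP + c.FN == 0:
        warnings.warn("no positive labels; SN undefined (NaN)")
        sn = float("nan")
    else:
        sn = c.TP / (c.TP + c.FN)
    if c.TN + c.FP == 0:
        warnings.warn("no negative labels; SP undefined (NaN)")
        sp = float("nan")
    else:
        sp = c.TN / (c.TN + c.FP)
    acc = (c.TP + c.TN) / c.total if c.total else float("nan")
    return MetricReport(
        SN=sn,
        SP=sp,
        ACC=acc,
        MCC=mcc_from_counts(c),
        AUC=auc_score(labels, scores),
        threshold=threshold,
        n=c.total,
    )


def _mean_report(per_fold: list[MetricReport], threshold: float) -> MetricReport:
    def m(attr: str) -> float:
        return float(np.nanmean([getattr(f, attr) for f in per_fold]))

    return MetricReport(
        SN=m("SN"),
        SP=m("SP"),
        ACC=m("ACC"),
        MCC=m("MCC"),
        AUC=m("AUC"),
        threshold=threshold,
        n=sum(f.n for f in per_fold),
        per_fold=per_fold,
    )


def cross_validate(
    ds: LabelledDataset,
    config: RunConfig,
    folds: int | None = None,
    seed: int | None = None,
    pooling: str = "macro",
) -> MetricReport:
    """Stratified k-fold cross-validation with strict per-fold leakage control.

    Every trainable component (propensity table, antecedents, consequents)
    is fitted on the fold's training split only.  ``pooling="macro"``
    (default) averages per-fold metrics; ``"micro"`` pools all held-out
    scores into one report.
    """
    folds = folds if folds is not None else config.folds
    seed = seed if seed is not None else config.seed
    counts = (ds.n_positive, ds.n_negative)
    if min(counts) < folds:
        raise ValueError(
            f"{ds.name}: smallest class ({min(counts)}) has fewer samples "
            f"than folds ({folds})"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    per_fold: list[MetricReport] = []
    pooled_scores: list[np.ndarray] = []
    pooled_labels: list[np.ndarray] = []
    for fold_i, (train_idx, test_idx) in enumerate(
        skf.split(np.zeros(len(ds)), ds.labels)
    ):
        train = ds.subset(train_idx, name=f"{ds.name}/fold{fold_i}-train")
        test = ds.subset(test_idx, name=f"{ds.name}/fold{fold_i}-test")
        pm = train_pipeline(train, config)
        preds = predict_pipeline(pm, test.sequences)
        per_fold.append(metrics(test.labels, preds.score))
        pooled_scores.append(preds.score)
        pooled_labels.append(test.labels)
    if pooling == "micro":
        report = metrics(np.concatenate(pooled_labels), np.concatenate(pooled_scores))
        report.per_fold = per_fold
        return report
    if pooling != "macro":
        raise ValueError("pooling must be 'macro' or 'micro'")
    return _mean_report(per_fold, threshold=0.0)


def cross_dataset_eval(
    train_ds: LabelledDataset, test_ds: LabelledDataset, config: RunConfig
) -> MetricReport:
    """Train the full pipeline on one dataset, evaluate once on another."""
    if train_ds.window_length != test_ds.window_length:
        raise ValueError(
            f"window mismatch: train {train_ds.window_length} nt, "
            f"test {test_ds.window_length} nt"
        )
    pm = train_pipeline(train_ds, config)
    preds = predict_pipeline(pm, test_ds.sequences)
    return metrics(test_ds.labels, preds.score)


def cross_matrix(
    datasets: dict[str, LabelledDataset], config: RunConfig
) -> pd.DataFrame:
    """All ordered train/test dataset pairs as a long-format metric table."""
    rows = []
    for train_name, train_ds in datasets.items():
        pm = train_pipeline(train_ds, config)
        for test_name, test_ds in datasets.items():
            preds = predict_pipeline(pm, test_ds.sequences)
            rep = metrics(test_ds.labels, preds.score)
            rows.append(
                {
                    "train": train_name,
                    "test": test_name,
                    "ACC": rep.ACC,
                    "SN": rep.SN,
                    "SP": rep.SP,
                    "MCC": rep.MCC,
                    "AUC": rep.AUC,
                }
            )
    return pd.DataFrame(rows)


def report_to_tsv(report: MetricReport, path: str | Path, dataset: str = "dataset") -> None:
    """Tidy TSV: one row per fold plus the aggregate."""
    rows = []
    for i, f in enumerate(report.per_fold):
        rows.append(
            {"dataset": dataset, "fold": i, "SN": f.SN, "SP": f.SP, "ACC": f.ACC,
             "MCC": f.MCC, "AUC": f.AUC}
        )
    rows.append(
        {"dataset": dataset, "fold": "mean", "SN": report.SN, "SP": report.SP,
         "ACC": report.ACC, "MCC": report.MCC, "AUC": report.AUC}
    )
    pd.DataFrame(rows).to_csv(Path(path), sep="\t", index=False)


def report_to_json(report: MetricReport, path: str | Path) -> None:
    with open(Path(path), "w", encoding="utf-8", newline="\n") as fh:
        json.dump(report.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")
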