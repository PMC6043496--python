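"""Classifier evaluation: threshold metrics, ranking metrics, CV, holdout.

AUC is computed as the Mann-Whitney rank statistic (ties get average
rank), which equals the trapezoidal area under the ROC curve. AUPRC uses
the step-wise average-precision convention — no linear interpolation,
which would be optimistic under class imbalance. Threshold metrics use
0.5, with score == 0.5 counted as a positive prediction.

Degenerate ratios (0/0) are reported as 0 and flagged rather than raised,
so aggregate tables stay computable on small folds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import model as model_mod
from .datasets import (
    InteractionDataset,
    Split,
    sample_negatives,
    verify_c2,
)
from .features import PaacConfig

METRIC_COLUMNS = ["auc", "auprc", "acc", "f", "mcc", "precision", "recall", "fallout"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_at_threshold(scores, labels, threshold: float = 0.5) -> ConfusionCounts:
    """Binarize scores at ``threshold`` (score >= threshold => positive)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError(f"scores {scores.shape} and labels {labels.shape} differ in length")
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def _ratio(num: float, den: float, flags: list[str], name: str) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def classification_metrics(c: ConfusionCounts) -> dict:
    """ACC, precision, recall, fall-out, F score and MCC from counts.

    Returns a plain dict; the 'flags' entry lists metrics whose
    denominator was zero (value reported as 0).
    """
    flags: list[str] = []
    acc = _ratio(c.tp + c.tn, c.total, flags, "acc")
    precision = _ratio(c.tp, c.tp + c.fp, flags, "precision")
    recall = _ratio(c.tp, c.tp + c.fn, flags, "recall")
    fallout = _ratio(c.fp, c.fp + c.tn, flags, "fallout")
    f = _ratio(2 * precision * recall, precision + recall, flags, "f")
    mcc_den = np.sqrt(
        float(c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    mcc = _ratio(c.tp * c.tn - c.fp * c.fn, mcc_den, flags, "mcc")
    return {
        "acc": acc,
        "precision": precision,
        "recall": recall,
        "fallout": fallout,
        "f": f,
        "mcc": mcc,
        "flags": tuple(flags),
    }


def _check_both_classes(labels: np.ndarray) -> None:
    if labels.min() == labels.max():
        raise ValueError("ranking metrics require both classes present")


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve via the rank statistic.

    Equals the probability that a random positive outscores a random
    negative, ties counted 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels differ in length")
    _check_both_classes(labels)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    ranks = rankdata(scores)  # average ranks on ties
    rank_sum = ranks[labels == 1].sum()
    return (rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def pr_auc(scores, labels) -> float:
    """Area under the precision-recall curve, average-precision convention.

    AP = sum_i (R_i - R_{i-1}) * P_i over descending distinct score
    thresholds; tied scores enter as one block.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels differ in length")
    _check_both_classes(labels)
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    # block boundaries where the score value changes
    distinct = np.nonzero(np.diff(s))[0]
    cut = np.concatenate([distinct, [s.size - 1]])
    tp = np.cumsum(y)[cut].astype(float)
    fp = np.cumsum(1 - y)[cut].astype(float)
    n_pos = float(y.sum())
    precision = tp / (tp + fp)
    recall = tp / n_pos
    prev_recall = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - prev_recall) * precision))


def metrics_row(scores, labels, threshold: float = 0.5) -> dict:
    """All headline metrics for one scored set, as one flat row."""
    cm = classification_metrics(confusion_at_threshold(scores, labels, threshold))
    row = {
        "auc": roc_auc(scores, labels),
        "auprc": pr_auc(scores, labels),
        "acc": cm["acc"],
        "f": cm["f"],
        "mcc": cm["mcc"],
        "precision": cm["precision"],
        "recall": cm["recall"],
        "fallout": cm["fallout"],
    }
    return row


# ---------------------------------------------------------------------------
# report container


@dataclass
class EvaluationReport:
    """Per-repeat metric table plus exact mean/sd aggregation."""

    per_repeat: pd.DataFrame
    group_keys: tuple[str, ...] = ()

    def aggregate(self) -> pd.DataFrame:
        """Mean and sample sd of each metric, per group (or overall)."""
        metrics = [c for c in METRIC_COLUMNS if c in self.per_repeat.columns]
        if self.group_keys:
            g = self.per_repeat.groupby(list(self.group_keys))[metrics]
            return g.agg(["mean", "std"])
        agg = self.per_repeat[metrics].agg(["mean", "std"])
        return agg

    def summary(self) -> str:
        """Human-readable 'mean ± sd' lines per metric (and group)."""
        agg = self.aggregate()
        lines = []
        if self.group_keys:
            for key, row in agg.iterrows():
                label = ", ".join(
                    f"{k}={v}" for k, v in zip(self.group_keys, np.atleast_1d(key))
                )
                parts = [
                    f"{m}={row[(m, 'mean')]:.3f} ± {0.0 if np.isnan(row[(m, 'std')]) else row[(m, 'std')]:.3f}"
                    for m in {c[0] for c in agg.columns}
                ]
                lines.append(f"[{label}] " + "  ".join(sorted(parts)))
        else:
            for m in agg.columns:
                sd = agg.loc["std", m]
                sd = 0.0 if np.isnan(sd) else sd
                lines.append(f"{m}: {agg.loc['mean', m]:.3f} ± {sd:.3f}")
        return "\n".join(lines)

    def to_json(self, path) -> None:
        self.per_repeat.to_json(path, orient="records", indent=2)


# ---------------------------------------------------------------------------
# protocols


def cross_validate(
    dataset: InteractionDataset,
    cfg: PaacConfig,
    spec: "model_mod.ClassifierSpec",
    k: int = 10,
) -> EvaluationReport:
    """Stratified k-fold cross-validation at the pair level.

    This is the model-selection protocol: pairs (not proteins) are folded,
    so component overlap between folds is allowed by design; use the C2
    holdout for generalization estimates.
    """
    from sklearn.model_selection import StratifiedKFold

    if k < 2:
        raise ValueError("k must be >= 2")
    labels = np.array([r.label for r in dataset.records])
    if k > len(labels):
        raise ValueError(f"k={k} exceeds the {len(labels)} available pairs")
    if min(np.bincount(labels, minlength=2)) < k:
        raise ValueError("every fold needs both classes; dataset too small/imbalanced")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=spec.seed)
    rows = []
    records = np.array(dataset.records, dtype=object)
    for fold, (tr_idx, te_idx) in enumerate(skf.split(records, labels)):
        train = dataset.with_records(records[tr_idx].tolist())
        test = dataset.with_records(records[te_idx].tolist())
        trained = model_mod.train(train, cfg, spec)
        scores = model_mod.predict_dataset(trained, test, cfg)
        row = metrics_row(scores, labels[te_idx])
        row["fold"] = fold
        rows.append(row)
    return EvaluationReport(pd.DataFrame(rows))


def evaluate_holdout(
    splits: list[Split],
    cfg: PaacConfig,
    spec: "model_mod.ClassifierSpec",
    negative_ratios: tuple[float, ...] = (1,),
    seed: int = 0,
    known_positive_filter: set | None = None,
    n_draws: int = 1,
) -> EvaluationReport:
    """Train on each C2 train split and score its test split per imbalance ratio.

    ``splits`` carry positives only. For each repeat, training negatives
    are drawn degree-balanced inside the train partition; test negatives
    are drawn uniformly inside the test partition at each requested ratio
    (``n_draws`` independent draws per ratio, averaged into separate
    rows). The C2 property is re-verified after augmentation; violation
    is a hard error. Expected pattern on planted-signal data: AUC roughly
    invariant to the ratio, AUPRC falling as negatives are added.
    """
    rows = []
    for split in splits:
        verify_c2(split.train, split.test)
        train_neg = sample_negatives(
            split.train,
            ratio=1,
            mode="balanced",
            known_positive_filter=known_positive_filter,
            seed=seed + 31 * split.report.get("repeat", 0),
        )
        train_full = split.train.with_records(split.train.records + train_neg.records)
        verify_c2(train_full, split.test)
        trained = model_mod.train(train_full, cfg, spec)
        for ratio in negative_ratios:
            for draw in range(n_draws):
                test_neg = sample_negatives(
                    split.test,
                    ratio=ratio,
                    mode="random",
                    known_positive_filter=known_positive_filter,
                    seed=seed + 1009 * split.report.get("repeat", 0) + 7 * draw + int(ratio),
                    idps=sorted(split.test.idp_ids & set(split.test.sequence_store)),
                    partners=split.report.get("test_partner_ids"),
                )
                test_full = split.test.with_records(split.test.records + test_neg.records)
                verify_c2(train_full, test_full)
                scores = model_mod.predict_dataset(trained, test_full, cfg)
                labels = np.array([r.label for r in test_full.records])
                row = metrics_row(scores, labels)
                row["repeat"] = split.report.get("repeat", 0)
                row["ratio"] = ratio
                row["draw"] = draw
                rows.append(row)
    return EvaluationReport(pd.DataFrame(rows), group_keys=("ratio",))


def write_scores(dataset: InteractionDataset, scores, path) -> None:
    """Per-pair score file: idp_id, partner_id, label, score."""
    with open(path, "w") as fh:
        fh.write("idp_id\tpartner_id\tlabel\tscore\n")
        for rec, s in zip(dataset.records, scores):
            fh.write(f"{rec.idp_id}\t{rec.partner_id}\t{rec.label}\t{s:.6f}\n")
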