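"""Metrics, fold summaries, confidence intervals, and the k-fold CV driver.

Two tasks are evaluated side by side: pair-similarity classification (all
ordered distinct pairs over the held-out fold, thresholded at 0.5) and
per-peptide detection (aggregated ``rho`` thresholded at 0.5). Reports mirror
the usual layout: one row per fold with ACC / AUC-ROC / SPC / SEN, then an
AVG row (arithmetic mean) and an STD row (sample standard deviation, n-1
denominator). The 95% confidence half-width for a column is
``z * STD / sqrt(k)`` over the k folds.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from simpep.embedding import EmbeddingBackend, embed_set
from simpep.inference import classify, op_pre
from simpep.model import NetConfig, train_iterative
from simpep.pairing import sim_test_pairs, split_folds
from simpep.peptide_io import PeptideSet


class EvaluationError(Exception):
    """Metric undefined or evaluation contract violated."""


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN tallies for one binary evaluation."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise EvaluationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionCounts":
        t = np.asarray(y_true, dtype=int)
        p = np.asarray(y_pred, dtype=int)
        return cls(
            TP=int(np.sum((t == 1) & (p == 1))),
            TN=int(np.sum((t == 0) & (p == 0))),
            FP=int(np.sum((t == 0) & (p == 1))),
            FN=int(np.sum((t == 1) & (p == 0))),
        )


def metrics(counts: ConfusionCounts) -> dict:
    """ACC, SPC, SEN from confusion counts; undefined ratios come back as NaN.

    ACC = (TP+TN)/total, SPC = TN/(TN+FP), SEN = TP/(TP+FN).
    """

    def ratio(num: int, den: int) -> float:
        return num / den if den > 0 else float("nan")

    return {
        "ACC": ratio(counts.TP + counts.TN, counts.total),
        "SPC": ratio(counts.TN, counts.TN + counts.FP),
        "SEN": ratio(counts.TP, counts.TP + counts.FN),
    }


def auc_roc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC; ties count half. Needs both classes."""
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise EvaluationError("AUC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def fold_summary(per_fold: pd.DataFrame) -> pd.DataFrame:
    """Append AVG and STD (sample, n-1) rows to a per-fold metric table."""
    numeric = per_fold.select_dtypes(include=[np.number])
    if len(per_fold) < 2:
        raise EvaluationError("need at least 2 folds for a summary")
    avg = numeric.mean()
    std = numeric.std(ddof=1)
    out = per_fold.copy()
    out.loc["AVG"] = avg
    out.loc["STD"] = std
    if "fold" in out.columns:
        out.loc["AVG", "fold"] = "AVG"
        out.loc["STD", "fold"] = "STD"
    return out


def ci_halfwidth(std: float, k: int, z: float = 1.96) -> float:
    """Half-width of the z-based confidence interval over k folds: z*std/sqrt(k)."""
    if std < 0:
        raise EvaluationError("std must be non-negative")
    if k < 1:
        raise EvaluationError("k must be at least 1")
    return z * std / sqrt(k)


@dataclass
class CVResult:
    """Cross-validation outcome: per-fold + summary tables for both tasks."""

    ops_table: pd.DataFrame
    opd_table: pd.DataFrame
    fold_split: object
    seed: int

    def ci_row(self, table: str = "opd", z: float = 1.96) -> dict:
        frame = self.opd_table if table == "opd" else self.ops_table
        std = frame.loc["STD"]
        k = len(frame) - 2
        return {
            col: ci_halfwidth(float(std[col]), k, z)
            for col in frame.columns
            if col != "fold" and np.isfinite(std[col])
        }


def run_cv(
    pos_pool: PeptideSet,
    neg_pool: PeptideSet,
    backend: EmbeddingBackend,
    config: Optional[NetConfig] = None,
    k: int = 5,
    seed: int = 0,
    threshold: float = 0.5,
) -> CVResult:
    """Stratified k-fold cross-validation of both tasks.

    Per fold: train on the out-of-fold positives/negatives with the iterative
    strategy; evaluate pair-similarity metrics on all ordered distinct pairs
    of the held-out fold (thresholded at 0.5), and detection metrics on the
    aggregated per-peptide ``rho``. Fold assignment, training, and scoring
    are all seeded from ``seed``. Test peptides never appear in their own
    fold's training pools (asserted via the aggregation's leakage check).
    """
    config = config or NetConfig(input_dim=backend.dim)
    root = np.random.default_rng(seed)
    split = split_folds(pos_pool, neg_pool, k=k, seed=int(root.integers(2**31)))

    ops_rows, opd_rows = [], []
    for i in range(k):
        train_pos_ids, train_neg_ids = split.train_ids(i)
        test_pos_ids, test_neg_ids = split.test_ids(i)
        O = pos_pool.subset(train_pos_ids, name=f"O{i + 1}")
        N = neg_pool.subset(train_neg_ids, name=f"N{i + 1}")
        gamma = PeptideSet(
            f"gamma{i + 1}",
            [pos_pool[j] for j in test_pos_ids] + [neg_pool[j] for j in test_neg_ids],
        )
        labels = {pid: 1 for pid in test_pos_ids}
        labels.update({pid: 0 for pid in test_neg_ids})

        fold_config = NetConfig(**{**config.__dict__, "seed": int(root.integers(2**31))})
        model = train_iterative(O, N, backend, fold_config)

        # pair-similarity task on the held-out fold
        pairs = sim_test_pairs(gamma, labels)
        X_gamma = embed_set(gamma, backend)
        row_of = {pid: j for j, pid in enumerate(gamma.ids)}
        Xa = X_gamma[[row_of[p.left] for p in pairs]]
        Xb = X_gamma[[row_of[p.right] for p in pairs]]
        pair_scores = model.pair_similarity(Xa, Xb)
        pair_true = np.array([p.y for p in pairs])
        pair_pred = (pair_scores >= 0.5).astype(int)
        ops_m = metrics(ConfusionCounts.from_predictions(pair_true, pair_pred))
        ops_rows.append(
            {
                "fold": f"fold{i + 1}",
                "ACC": ops_m["ACC"],
                "AUC": auc_roc(pair_scores, pair_true),
                "SPC": ops_m["SPC"],
                "SEN": ops_m["SEN"],
            }
        )

        # detection task via similarity aggregation
        records = op_pre(model, gamma, O, N, backend)
        rho = np.array([r.rho for r in records])
        y_true = np.array([labels[r.peptide_id] for r in records])
        y_pred = np.array([1 if classify(r, threshold) == "OP" else 0 for r in records])
        opd_m = metrics(ConfusionCounts.from_predictions(y_true, y_pred))
        opd_rows.append(
            {
                "fold": f"fold{i + 1}",
                "ACC": opd_m["ACC"],
                "AUC": auc_roc(rho, y_true),
                "SPC": opd_m["SPC"],
                "SEN": opd_m["SEN"],
            }
        )

    return CVResult(
        ops_table=fold_summary(pd.DataFrame(ops_rows)),
        opd_table=fold_summary(pd.DataFrame(opd_rows)),
        fold_split=split,
        seed=int(seed),
    )
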