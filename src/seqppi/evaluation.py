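"""Performance metrics, cross-validation, and rank-based model comparison.

Per model/dataset the report carries per-class precision and recall plus one
model-level AUC for the interaction class (the rank-based Mann-Whitney AUC:
probability a random positive outscores a random negative, ties counting a
half). Feature-set comparisons run the two-sided Mann-Whitney U test on the
distributions of each metric across the per-dataset reports.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata
from sklearn.model_selection import StratifiedKFold

from .pair_encoding import LABEL_NO_PPI, LABEL_PPI, AttributeSchema
from .tree_learner import TreeParams, bag_train, dataset_to_matrix

SIGNIFICANCE_LEVEL = 0.05


@dataclass(frozen=True)
class PerformanceReport:
    """Cross-validated metrics for one model on one dataset."""

    dataset_id: str
    precision_ppi: Optional[float]
    recall_ppi: Optional[float]
    precision_no_ppi: Optional[float]
    recall_no_ppi: Optional[float]
    auc: float
    n_folds: int
    seed: int

    def metric(self, name: str) -> Optional[float]:
        return getattr(self, name)


def precision_recall(tp: int, fp: int, fn: int) -> tuple[Optional[float], Optional[float]]:
    """Precision TP/(TP+FP) and recall TP/(TP+FN); None flags an undefined ratio."""
    if min(tp, fp, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    precision = tp / (tp + fp) if tp + fp > 0 else None
    recall = tp / (tp + fn) if tp + fn > 0 else None
    return precision, recall


def auc(scores: Sequence[float], labels: Sequence[str]) -> float:
    """Rank-based (Mann-Whitney) AUC for the interaction class.

    Equals the fraction of (positive, negative) pairs in which the positive
    scores higher, counting ties as one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == LABEL_PPI
    neg = labels == LABEL_NO_PPI
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs at least one instance of each class")
    ranks = rankdata(scores[pos | neg])
    rank_sum_pos = ranks[pos[pos | neg]].sum()
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def cross_validate(
    dataset: pd.DataFrame,
    schema: AttributeSchema,
    params: TreeParams = TreeParams(),
    k: int = 10,
    n_bags: int = 10,
    seed: int = 0,
    dataset_id: str = "dataset",
) -> PerformanceReport:
    """Stratified k-fold CV of a bagged tree model; metrics pooled over folds.

    Each fold trains a fresh bagged model on the remaining folds and scores
    the held-out instances; the pooled held-out scores and labels give one
    confusion table (at the 0.5 threshold) and one AUC.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(dataset) < k:
        raise ValueError("dataset smaller than fold count")
    labels = dataset["label"].to_numpy()
    class_sizes = pd.Series(labels).value_counts()
    if (class_sizes < k).any():
        small = class_sizes[class_sizes < k]
        raise ValueError(
            f"classes with fewer than k={k} members: {small.to_dict()}; use a smaller k"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**32))
    pooled_scores = np.empty(len(dataset), dtype=float)
    for fold, (train_idx, test_idx) in enumerate(skf.split(np.zeros(len(dataset)), labels)):
        train = dataset.iloc[train_idx].reset_index(drop=True)
        model = bag_train(train, schema, params, n_bags=n_bags, seed=seed * 1000 + fold)
        X_test, _ = dataset_to_matrix(dataset.iloc[test_idx], schema)
        pooled_scores[test_idx] = model.predict_proba(X_test)

    pred_ppi = pooled_scores > 0.5
    actual_ppi = labels == LABEL_PPI
    tp = int((pred_ppi & actual_ppi).sum())
    fp = int((pred_ppi & ~actual_ppi).sum())
    fn = int((~pred_ppi & actual_ppi).sum())
    tn = int((~pred_ppi & ~actual_ppi).sum())
    p_ppi, r_ppi = precision_recall(tp, fp, fn)
    p_no, r_no = precision_recall(tn, fn, fp)
    return PerformanceReport(
        dataset_id=dataset_id,
        precision_ppi=p_ppi,
        recall_ppi=r_ppi,
        precision_no_ppi=p_no,
        recall_no_ppi=r_no,
        auc=auc(pooled_scores, labels),
        n_folds=k,
        seed=seed,
    )


def mann_whitney_u(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test: (U for group_a, p-value).

    Small tie-free samples (both n <= 8) use exact enumeration; otherwise
    the normal approximation with tie correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (max(len(a), len(b)) <= 8 and not has_ties) else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


_COMPARISON_METRICS = (
    ("Precision", "PPI", "precision_ppi"),
    ("Precision", "NO-PPI", "precision_no_ppi"),
    ("Recall", "PPI", "recall_ppi"),
    ("Recall", "NO-PPI", "recall_no_ppi"),
    ("AUC", "PPI", "auc"),
    ("AUC", "NO-PPI", "auc"),  # one model-level AUC, reported for both classes
)


def compare_feature_sets(
    reports_by_schema: dict[str, Sequence[PerformanceReport]]
) -> pd.DataFrame:
    """Pairwise Mann-Whitney comparison of schemas across per-dataset reports.

    For every schema pair and every metric (per-class precision and recall,
    plus the model-level AUC reported under both classes) the table carries
    the two-sided p-value, a significance flag at 0.05, and the schema with
    the higher median.
    """
    if len(reports_by_schema) < 2:
        raise ValueError("need at least two schemas to compare")
    counts = {s: len(r) for s, r in reports_by_schema.items()}
    if len(set(counts.values())) > 1:
        import warnings

        warnings.warn(f"unequal report counts across schemas: {counts}", stacklevel=2)
    rows = []
    for sa, sb in itertools.combinations(sorted(reports_by_schema), 2):
        for metric_name, cls, attr in _COMPARISON_METRICS:
            va = [r.metric(attr) for r in reports_by_schema[sa] if r.metric(attr) is not None]
            vb = [r.metric(attr) for r in reports_by_schema[sb] if r.metric(attr) is not None]
            u, p = mann_whitney_u(va, vb)
            med_a, med_b = float(np.median(va)), float(np.median(vb))
            rows.append(
                {
                    "comparison": f"{sa}x{sb}",
                    "metric": metric_name,
                    "class": cls,
                    "U": u,
                    "p_value": p,
                    "significant": p < SIGNIFICANCE_LEVEL,
                    "higher_median": sa if med_a > med_b else (sb if med_b > med_a else "tie"),
                }
            )
    return pd.DataFrame(rows)


# -- I/O --------------------------------------------------------------------

def write_reports(reports: Sequence[PerformanceReport], path: str | Path) -> None:
    suffix = Path(path).suffix
    frame = pd.DataFrame([asdict(r) for r in reports])
    if suffix == ".json":
        Path(path).write_text(json.dumps([asdict(r) for r in reports], indent=1))
    else:
        frame.to_csv(path, sep="\t", index=False)


def write_comparison_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)
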