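"""Case-level scoring rule, classification metrics, and cross-validation.

The case rule maps three per-slide infiltration scores (each 1-5, assigned at
the tumor/non-neoplastic-parenchyma interface) to one of three case classes by
their total: 3-6 -> IPS1, 7-9 -> IPS2, 10-15 -> IPS3.

Metrics are one-vs-rest precision/recall/F1 per class plus a class-frequency
weighted F1, reported in percent. Cross-validation splits at the *case* level
(all three slides of a case share a fold), stratified by IPS label.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence

import numpy as np
from sklearn.metrics import precision_recall_fscore_support

from .labels import (
    IPS_BANDS,
    IPS_CLASSES,
    N_SLIDES_PER_CASE,
    SLIDE_SCORE_MAX,
    SLIDE_SCORE_MIN,
)

__all__ = [
    "case_ips_from_slide_scores",
    "ScoreReport",
    "classification_report",
    "FoldPlan",
    "make_fold_plan",
    "run_cross_validation",
]


def case_ips_from_slide_scores(scores: Sequence[int]) -> str:
    """Map three per-slide scores (each in 1..5) to the case IPS label.

    The label is decided by the total: 3-6 IPS1, 7-9 IPS2, 10-15 IPS3.
    Raises ``ValueError`` on a wrong count or an out-of-range score.
    """
    scores = list(scores)
    if len(scores) != N_SLIDES_PER_CASE:
        raise ValueError(
            f"expected exactly {N_SLIDES_PER_CASE} slide scores, got {len(scores)}"
        )
    for s in scores:
        if int(s) != s or not (SLIDE_SCORE_MIN <= int(s) <= SLIDE_SCORE_MAX):
            raise ValueError(f"slide score {s!r} not an integer in "
                             f"{SLIDE_SCORE_MIN}..{SLIDE_SCORE_MAX}")
    total = int(sum(scores))
    for label, (lo, hi) in IPS_BANDS.items():
        if lo <= total <= hi:
            return label
    raise AssertionError(f"total {total} outside all bands")  # unreachable


@dataclass
class ScoreReport:
    """Per-class precision/recall/F1 and weighted F1, all in percent."""

    classes: List[str]
    precision: Dict[str, float]
    recall: Dict[str, float]
    f1: Dict[str, float]
    support: Dict[str, int]
    weighted_f1: float
    # Filled by run_cross_validation: per-run weighted F1 values.
    run_weighted_f1: List[float] = field(default_factory=list)
    weighted_f1_std: float = 0.0

    def to_dict(self) -> dict:
        return {
            "classes": self.classes,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "support": self.support,
            "weighted_f1": self.weighted_f1,
            "weighted_f1_std": self.weighted_f1_std,
            "run_weighted_f1": self.run_weighted_f1,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def __str__(self) -> str:  # human-readable report
        lines = [f"{'class':>8} {'prec':>7} {'recall':>7} {'F1':>7} {'n':>5}"]
        for c in self.classes:
            lines.append(
                f"{c:>8} {self.precision[c]:7.2f} {self.recall[c]:7.2f} "
                f"{self.f1[c]:7.2f} {self.support[c]:5d}"
            )
        lines.append(f"weighted F1: {self.weighted_f1:.2f}"
                     + (f" +/- {self.weighted_f1_std:.2f}"
                        if self.run_weighted_f1 else ""))
        return "\n".join(lines)


def classification_report(
    y_true: Sequence[str], y_pred: Sequence[str],
    classes: Sequence[str] = IPS_CLASSES,
) -> ScoreReport:
    """One-vs-rest precision/recall/F1 per class and weighted F1 (percent).

    F1 is defined as 0 when precision + recall is 0; weighted F1 is the
    support-weighted mean of the per-class F1 scores.
    """
    y_true = list(y_true)
    y_pred = list(y_pred)
    if not y_true:
        raise ValueError("empty label vectors")
    if len(y_true) != len(y_pred):
        raise ValueError("label vectors differ in length")
    classes = list(classes)
    prec, rec, f1, supp = precision_recall_fscore_support(
        y_true, y_pred, labels=classes, zero_division=0
    )
    n = len(y_true)
    weighted = float(np.sum(supp / n * f1) * 100.0)
    return ScoreReport(
        classes=classes,
        precision={c: float(p * 100) for c, p in zip(classes, prec)},
        recall={c: float(r * 100) for c, r in zip(classes, rec)},
        f1={c: float(v * 100) for c, v in zip(classes, f1)},
        support={c: int(s) for c, s in zip(classes, supp)},
        weighted_f1=weighted,
    )


@dataclass
class FoldPlan:
    """Case-level stratified fold assignment.

    ``assignment`` maps case_id -> fold index in [0, n_folds). Stratification
    is seeded round-robin within each IPS class, so per-fold class counts
    differ from the ideal by at most one case.
    """

    n_folds: int
    runs_per_fold: int
    assignment: Dict[str, int]
    seed: int

    def fold_cases(self, fold: int) -> List[str]:
        return [cid for cid, f in self.assignment.items() if f == fold]


def make_fold_plan(
    case_labels: Mapping[str, str],
    n_folds: int = 5,
    runs_per_fold: int = 3,
    seed: int = 0,
) -> FoldPlan:
    """Stratified case-level fold plan: shuffle within class, deal round-robin."""
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    rng = np.random.default_rng(seed)
    assignment: Dict[str, int] = {}
    offset = 0
    for label in IPS_CLASSES:
        cids = sorted(cid for cid, lab in case_labels.items() if lab == label)
        rng.shuffle(cids)
        for i, cid in enumerate(cids):
            assignment[cid] = (offset + i) % n_folds
        offset += len(cids)
    return FoldPlan(n_folds=n_folds, runs_per_fold=runs_per_fold,
                    assignment=assignment, seed=seed)


def run_cross_validation(
    case_bags: Mapping[str, list],
    case_labels: Mapping[str, str],
    plan: FoldPlan,
    gnn_config=None,
) -> ScoreReport:
    """Case-level stratified cross-validation of the cell-graph scorer.

    ``case_bags`` maps case_id to the case's bag of cell-graphs (from all of
    its slides, unstandardized). Per fold: feature-standardization statistics
    are fit on the training folds only, a GNN is trained ``runs_per_fold``
    times with distinct seeds, and test-fold cases are scored by bag voting.
    The report aggregates all runs jointly; per-run weighted F1 values and
    their std are attached.
    """
    from .cell_graph import fit_feature_stats, standardize_features
    from .gnn import GNNConfig, predict_case, train_gnn

    cfg = gnn_config if gnn_config is not None else GNNConfig()
    missing = [cid for cid in case_labels if cid not in case_bags or not case_bags[cid]]
    if missing:
        raise ValueError(f"cases without graphs: {missing[:5]}")

    all_true: List[str] = []
    all_pred: List[str] = []
    run_f1: List[float] = []
    for fold in range(plan.n_folds):
        test_cases = sorted(plan.fold_cases(fold))
        train_cases = sorted(set(case_labels) - set(test_cases))
        train_labels = {c: case_labels[c] for c in train_cases}
        present = set(train_labels.values())
        if present != set(IPS_CLASSES):
            raise ValueError(
                f"fold {fold}: training folds miss classes "
                f"{sorted(set(IPS_CLASSES) - present)}"
            )
        train_graphs = [g for c in train_cases for g in case_bags[c]]
        stats = fit_feature_stats(train_graphs)
        std_train = standardize_features(train_graphs, stats)
        std_test = {c: standardize_features(case_bags[c], stats) for c in test_cases}
        labels = [case_labels[c] for c in train_cases for _ in case_bags[c]]
        for run in range(plan.runs_per_fold):
            run_cfg = cfg.with_seed(cfg.seed + 1000 * fold + run)
            model, _ = train_gnn(std_train, labels, run_cfg)
            y_true = [case_labels[c] for c in test_cases]
            y_pred = [predict_case(model, std_test[c]).predicted_ips
                      for c in test_cases]
            all_true.extend(y_true)
            all_pred.extend(y_pred)
            run_f1.append(classification_report(y_true, y_pred).weighted_f1)

    report = classification_report(all_true, all_pred)
    report.run_weighted_f1 = run_f1
    report.weighted_f1 = float(np.mean(run_f1))
    report.weighted_f1_std = float(np.std(run_f1))
    return report
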