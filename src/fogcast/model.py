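"""Random-forest preFOG classifier with leave-one-patient-out evaluation.

The task is binary — prefog vs normal windows (freeze data never reach
the classifier).  Evaluation is patient-independent: one fold per
patient, the scaler fitted on the training rows of each fold only, so
nothing about the held-out patient leaks into training.  Window-level
scores are the single-class F1 of the prefog class and Cohen's kappa of
the 2x2 window-label confusion; fold confusions are pooled (micro) by
default, with per-fold macro averaging available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .features import FeatureMatrix, standardize
from .preprocess import LABEL_PREFOG

__all__ = [
    "RFParams",
    "FoldResult",
    "lopo_split",
    "train_and_eval",
    "f1_score",
    "kappa",
    "pooled_metrics",
    "macro_metrics",
    "topk_select",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RFParams:
    """Random-forest hyperparameters.

    Defaults are the optimized tuple (n_estimators, max_features,
    max_depth, min_samples_split, min_samples_leaf) = (800, 0.1, 4, 4, 4);
    max_features is a fraction, so 0.1 of 924 features gives 92
    candidates per split.
    """

    n_estimators: int = 800
    max_features: float = 0.1
    max_depth: int = 4
    min_samples_split: int = 4
    min_samples_leaf: int = 4
    seed: int = 0
    class_weight: str | None = None  # or "balanced"

    def __post_init__(self) -> None:
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be positive")
        if not 0 < self.max_features <= 1:
            raise ValueError("max_features must lie in (0, 1]")
        for name in ("max_depth", "min_samples_split", "min_samples_leaf"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    def candidate_features(self, n_features: int) -> int:
        """Per-split candidate count: floor(fraction x n_features), >= 1."""
        return max(1, int(self.max_features * n_features))

    def build(self) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=self.n_estimators,
            max_features=self.max_features,
            max_depth=self.max_depth,
            min_samples_split=self.min_samples_split,
            min_samples_leaf=self.min_samples_leaf,
            random_state=self.seed,
            class_weight=self.class_weight,
            n_jobs=1,
        )


@dataclass
class FoldResult:
    patient_id: str
    predictions: np.ndarray  # predicted labels for held-out windows
    tp: int
    fp: int
    fn: int
    tn: int
    f1: float
    kappa: float
    row_index: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    importances: np.ndarray | None = None

    @property
    def n_windows(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def f1_score(tp: int, fp: int, fn: int) -> float:
    """Single-class F1 = 2TP / (2TP + FN + FP); 0 when all counts vanish."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be nonnegative")
    denom = 2 * tp + fn + fp
    if denom == 0:
        logger.warning("F1 undefined (no positives anywhere); reporting 0")
        return 0.0
    return 2 * tp / denom


def kappa(tp: int, fp: int, fn: int, tn: int) -> float:
    """Cohen's kappa of a 2x2 confusion; 0 when chance agreement is 1."""
    n = tp + fp + fn + tn
    if n == 0:
        raise ValueError("empty confusion")
    po = (tp + tn) / n
    pe = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / (n * n)
    if pe == 1.0:
        return 0.0
    return (po - pe) / (1.0 - pe)


def lopo_split(fm: FeatureMatrix) -> list[tuple[np.ndarray, np.ndarray]]:
    """Leave-one-patient-out folds as (train_mask, test_mask) pairs."""
    pids = fm.patient_ids.to_numpy()
    unique = list(dict.fromkeys(pids))  # stable order of first appearance
    if len(unique) < 2:
        raise ValueError("leave-one-patient-out needs >= 2 patients")
    folds = []
    for pid in unique:
        test = pids == pid
        folds.append((~test, test))
    return folds


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[int, int, int, int]:
    pos_t = y_true == LABEL_PREFOG
    pos_p = y_pred == LABEL_PREFOG
    tp = int(np.sum(pos_t & pos_p))
    fp = int(np.sum(~pos_t & pos_p))
    fn = int(np.sum(pos_t & ~pos_p))
    tn = int(np.sum(~pos_t & ~pos_p))
    return tp, fp, fn, tn


def train_and_eval(
    fm: FeatureMatrix,
    p: RFParams,
    columns: list[str] | None = None,
    collect_importances: bool = False,
) -> list[FoldResult]:
    """Leave-one-patient-out training and window-level scoring.

    Per fold: standardize on the training rows, fit the forest, predict
    the held-out patient's windows.  A training fold containing a single
    class is skipped with a logged cause.  Deterministic given
    ``p.seed``.
    """
    sub = fm if columns is None else fm.subset_columns(columns)
    y = sub.labels.to_numpy()
    results: list[FoldResult] = []
    for train_mask, test_mask in lopo_split(sub):
        pid = sub.patient_ids.to_numpy()[test_mask][0]
        if len(np.unique(y[train_mask])) < 2:
            logger.warning("fold %s skipped: single-class training data", pid)
            continue
        z = standardize(sub, train_mask)
        X = z.features.to_numpy()
        clf = p.build()
        clf.fit(X[train_mask], y[train_mask])
        pred = clf.predict(X[test_mask])
        tp, fp, fn, tn = _confusion(y[test_mask], pred)
        results.append(
            FoldResult(
                patient_id=str(pid),
                predictions=pred,
                tp=tp, fp=fp, fn=fn, tn=tn,
                f1=f1_score(tp, fp, fn),
                kappa=kappa(tp, fp, fn, tn),
                row_index=np.flatnonzero(test_mask),
                importances=clf.feature_importances_ if collect_importances else None,
            )
        )
    return results


def pooled_metrics(folds: list[FoldResult]) -> tuple[float, float]:
    """Micro aggregation: pool confusion counts over folds, then score."""
    tp = sum(f.tp for f in folds)
    fp = sum(f.fp for f in folds)
    fn = sum(f.fn for f in folds)
    tn = sum(f.tn for f in folds)
    return f1_score(tp, fp, fn), kappa(tp, fp, fn, tn)


def macro_metrics(folds: list[FoldResult]) -> tuple[float, float]:
    """Mean of per-fold F1 and kappa."""
    return (
        float(np.mean([f.f1 for f in folds])),
        float(np.mean([f.kappa for f in folds])),
    )


def base_feature_importances(
    column_names: list[str], importances: np.ndarray
) -> dict[str, float]:
    """Aggregate column importances over sensors/channels by feature id.

    Keys are the bank identifiers ("F01" ... "F22") so a ranking can be
    reported per base feature, summing over all 42 channels.
    """
    agg: dict[str, float] = {}
    for name, imp in zip(column_names, importances):
        fid = name.rsplit("_", 1)[-1]
        agg[fid] = agg.get(fid, 0.0) + float(imp)
    return agg


@dataclass
class TopKResult:
    k: int
    columns: list[str]
    f1: float
    kappa: float
    base_feature_ranking: list[str]


def topk_select(
    fm: FeatureMatrix, p: RFParams, k_grid: list[int]
) -> tuple[TopKResult, list[TopKResult]]:
    """Top-K feature selection under leave-one-patient-out evaluation.

    Features are ranked by mean impurity importance across the LOPO
    folds of the full matrix (each fold's forest sees only its own
    training rows, so the ranking never uses held-out labels).  Each K
    in ``k_grid`` is then re-evaluated with the top-K columns; the
    winner maximizes pooled F1, ties broken by higher kappa, then
    smaller K.
    """
    if not k_grid:
        raise ValueError("k_grid must not be empty")
    if max(k_grid) > fm.n_features:
        raise ValueError("k_grid entries must not exceed the feature count")
    folds = train_and_eval(fm, p, collect_importances=True)
    imp = np.mean([f.importances for f in folds], axis=0)
    order = np.argsort(-imp, kind="stable")
    cols = list(fm.features.columns)
    ranked = [cols[i] for i in order]

    base = base_feature_importances(cols, imp)
    base_ranking = sorted(base, key=lambda fid: -base[fid])

    candidates: list[TopKResult] = []
    for k in sorted(set(int(k) for k in k_grid)):
        top = set(ranked[:k])
        # canonical column order, so K = n_features reproduces the full run
        sel = [c for c in cols if c in top]
        fold_k = train_and_eval(fm, p, columns=sel)
        f1, kap = pooled_metrics(fold_k)
        candidates.append(TopKResult(k, sel, f1, kap, base_ranking))
    best = max(candidates, key=lambda r: (r.f1, r.kappa, -r.k))
    return best, candidates
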