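"""Per-substrate-term random-forest classifiers and orphan scoring.

For each selected substrate term a binary random forest is trained on
the cargo-bearing transporters: positives are those whose ontology-term
closure contains the term, negatives are the remaining cargo-bearing
transporters.  Hyperparameters (mtry, ntree, class weighting) are chosen
by grid search maximizing the out-of-bag (OOB) F1 score, so no separate
validation split is needed.  The decision threshold is the score cut
giving maximum recall at a precision of at least 75%, and reported
scores are gamma-corrected so that the threshold maps to 0.5.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import average_precision_score, roc_auc_score

DEFAULT_MTRY = (20, 50, 100, 150, 200)
DEFAULT_NTREE = (300, 700, 1100, 1500)
DEFAULT_CLASSWT = ("unweighted", "balanced")
MIN_POSITIVES = 10
DEFAULT_MIN_PRECISION = 0.75


@dataclass
class HyperGrid:
    """Search grid; defaults span mtry 20-200, ntree 300-1500, and
    unweighted vs class-weighted fits."""

    mtry: tuple[int, ...] = DEFAULT_MTRY
    ntree: tuple[int, ...] = DEFAULT_NTREE
    classwt: tuple[str, ...] = DEFAULT_CLASSWT

    def cells(self, n_features: int):
        """(mtry, ntree, classwt) triples; mtry values are clipped to the
        feature count and deduplicated, preserving order."""
        seen = set()
        mtry_vals = []
        for m in self.mtry:
            m = min(m, n_features)
            if m not in seen:
                seen.add(m)
                mtry_vals.append(m)
        for wt in self.classwt:
            for nt in self.ntree:
                for m in mtry_vals:
                    yield m, nt, wt


@dataclass
class ClassifierSpec:
    """A trained per-term model with its OOB performance profile."""

    term_id: str
    term_label: str
    mtry: int
    ntree: int
    classwt: str
    n_pos: int
    n_neg: int
    oob_scores: np.ndarray
    labels: np.ndarray
    auroc: float
    auprc: float
    threshold: float
    precision: float
    recall: float
    specificity: float
    f1: float
    gamma: float
    threshold_fallback: bool = False
    feature_names: tuple[str, ...] = ()
    model: RandomForestClassifier | None = field(default=None, repr=False)

    def to_json_dict(self) -> dict:
        return {
            "term_id": self.term_id,
            "term_label": self.term_label,
            "hyperparams": {
                "mtry": self.mtry,
                "ntree": self.ntree,
                "classwt": self.classwt,
            },
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "metrics": {
                "auroc": round(self.auroc, 6),
                "auprc": round(self.auprc, 6),
                "precision": round(self.precision, 6),
                "recall": round(self.recall, 6),
                "specificity": round(self.specificity, 6),
                "f1": round(self.f1, 6),
            },
            "threshold": self.threshold,
            "threshold_fallback": self.threshold_fallback,
            "gamma": self.gamma,
        }


def _confusion_at(scores: np.ndarray, labels: np.ndarray, threshold: float):
    """TP, FP, FN, TN with predicted-positive meaning score >= threshold."""
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    return tp, fp, fn, tn


def _prf(tp: int, fp: int, fn: int, tn: int):
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    specificity = tn / (tn + fp) if tn + fp else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, specificity, f1


def select_threshold(
    oob_scores: np.ndarray,
    labels: np.ndarray,
    min_precision: float = DEFAULT_MIN_PRECISION,
) -> tuple[float, bool]:
    """Pick the score cut with maximum recall at precision >= *min_precision*.

    Candidates are the distinct observed score values.  Ties in recall go
    to the higher precision, then the higher threshold.  If no candidate
    reaches the precision floor, fall back to the precision-maximizing
    threshold and flag it (returned boolean True).
    """
    scores = np.asarray(oob_scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    candidates = np.unique(scores)
    best = None  # (recall, precision, threshold)
    best_any = None
    for t in candidates:
        tp, fp, fn, tn = _confusion_at(scores, labels, t)
        precision, recall, _, _ = _prf(tp, fp, fn, tn)
        key = (precision, recall, t)
        if best_any is None or key > best_any:
            best_any = key
        if precision >= min_precision:
            key2 = (recall, precision, t)
            if best is None or key2 > best:
                best = key2
    if best is not None:
        return float(best[2]), False
    return float(best_any[2]), True


def gamma_normalize(score, threshold: float):
    """Gamma-correct a probability so the decision threshold lands on 0.5.

    Returns ``score ** (ln 0.5 / ln threshold)``: a strictly increasing
    bijection of [0, 1] fixing 0 and 1 and mapping *threshold* to 0.5
    exactly.  Accepts scalars or arrays.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    gamma = math.log(0.5) / math.log(threshold)
    return np.power(score, gamma) if isinstance(score, np.ndarray) else score ** gamma


def _fit_forest(
    X: np.ndarray, y: np.ndarray, mtry: int, ntree: int, classwt: str, seed: int
) -> RandomForestClassifier:
    clf = RandomForestClassifier(
        n_estimators=ntree,
        max_features=mtry,
        class_weight="balanced" if classwt == "balanced" else None,
        oob_score=True,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    clf.fit(X, y)
    return clf


def _oob_positive_scores(clf: RandomForestClassifier) -> np.ndarray:
    """Per-sample OOB probability of the positive class.  A sample that
    ended up in every bootstrap (possible at tiny ntree) gets 0.5."""
    oob = clf.oob_decision_function_
    pos_col = int(np.where(clf.classes_ == 1)[0][0])
    scores = oob[:, pos_col]
    return np.nan_to_num(scores, nan=0.5)


def train_term_classifier(
    X: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    term_id: str,
    term_label: str = "",
    grid: HyperGrid | None = None,
    seed: int = 0,
    min_pos: int = MIN_POSITIVES,
    min_precision: float = DEFAULT_MIN_PRECISION,
    f1_at_threshold: bool = False,
) -> ClassifierSpec:
    """Grid-searched binary random forest for one substrate term.

    OOB probabilities drive both grid selection (F1 at the 0.5 cut by
    default; at the optimized cut if *f1_at_threshold*) and threshold
    selection.  Grid ties break to the smallest ntree, then the smallest
    mtry.  Requires at least *min_pos* positives and negatives.
    """
    grid = grid or HyperGrid()
    y = np.asarray(labels, dtype=int)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos < min_pos or n_neg < min_pos:
        raise ValueError(
            f"{term_id}: needs >= {min_pos} of each class, "
            f"got {n_pos} positives / {n_neg} negatives"
        )
    Xmat = np.asarray(X, dtype=float)
    n_features = Xmat.shape[1]

    best = None  # (f1, -ntree, -mtry) -> cell record
    for mtry, ntree, classwt in grid.cells(n_features):
        clf = _fit_forest(Xmat, y, mtry, ntree, classwt, seed)
        scores = _oob_positive_scores(clf)
        if f1_at_threshold:
            t, _ = select_threshold(scores, y, min_precision)
        else:
            t = 0.5
        _, _, _, f1 = _prf(*_confusion_at(scores, y, t))
        key = (f1, -ntree, -mtry)
        if best is None or key > best[0]:
            best = (key, (mtry, ntree, classwt, clf, scores))

    mtry, ntree, classwt, clf, scores = best[1]
    threshold, fallback = select_threshold(scores, y, min_precision)
    precision, recall, specificity, f1 = _prf(*_confusion_at(scores, y, threshold))
    auroc = float(roc_auc_score(y, scores))
    auprc = float(average_precision_score(y, scores))
    # a threshold of exactly 0 or 1 cannot be gamma-corrected; nudge inside
    t_for_gamma = min(max(threshold, 1e-9), 1 - 1e-9)
    gamma = math.log(0.5) / math.log(t_for_gamma)
    return ClassifierSpec(
        term_id=term_id,
        term_label=term_label or term_id,
        mtry=mtry,
        ntree=ntree,
        classwt=classwt,
        n_pos=n_pos,
        n_neg=n_neg,
        oob_scores=scores,
        labels=y,
        auroc=auroc,
        auprc=auprc,
        threshold=float(threshold),
        precision=precision,
        recall=recall,
        specificity=specificity,
        f1=f1,
        gamma=float(gamma),
        threshold_fallback=fallback,
        feature_names=tuple(X.columns) if hasattr(X, "columns") else (),
        model=clf,
    )


def labels_from_closures(
    closures: dict[str, set[str]], term_id: str, slc_ids: list[str]
) -> np.ndarray:
    """Positive = transporter whose term closure contains *term_id*;
    every other cargo-bearing transporter is a negative."""
    return np.array([1 if term_id in closures.get(s, set()) else 0 for s in slc_ids])


def predict_orphans(
    specs: list[ClassifierSpec], orphan_X: pd.DataFrame
) -> pd.DataFrame:
    """Score orphan transporters with every trained classifier.

    Returns a long-format frame (term_id, slc_id, raw_score,
    normalized_score, call) where the call is positive iff the
    gamma-normalized score reaches 0.5 (equivalently raw >= threshold).
    """
    rows = []
    for spec in specs:
        if spec.model is None:
            raise ValueError(f"{spec.term_id}: spec carries no fitted model")
        if spec.feature_names and tuple(orphan_X.columns) != spec.feature_names:
            raise ValueError(
                f"{spec.term_id}: orphan feature columns do not match training"
            )
        if len(orphan_X) == 0:
            continue
        pos_col = int(np.where(spec.model.classes_ == 1)[0][0])
        raw = spec.model.predict_proba(np.asarray(orphan_X, dtype=float))[:, pos_col]
        t = min(max(spec.threshold, 1e-9), 1 - 1e-9)
        norm = gamma_normalize(raw, t)
        for slc_id, r, s in zip(orphan_X.index, raw, norm):
            rows.append(
                {
                    "term_id": spec.term_id,
                    "term_label": spec.term_label,
                    "slc_id": slc_id,
                    "raw_score": float(r),
                    "normalized_score": float(s),
                    "call": bool(s >= 0.5),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["term_id", "term_label", "slc_id", "raw_score", "normalized_score", "call"],
    )


def write_specs_json(specs: list[ClassifierSpec], path) -> None:
    with open(path, "w") as fh:
        json.dump([s.to_json_dict() for s in specs], fh, indent=2)
        fh.write("\n")


def metrics_frame(specs: list[ClassifierSpec]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term_id": s.term_id,
                "term_label": s.term_label,
                "n_pos": s.n_pos,
                "n_neg": s.n_neg,
                "auroc": s.auroc,
                "auprc": s.auprc,
                "sensitivity": s.recall,
                "specificity": s.specificity,
                "precision": s.precision,
                "f1": s.f1,
                "threshold": s.threshold,
                "gamma": s.gamma,
            }
            for s in specs
        ]
    )
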