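"""Evaluation protocols and metrics for cleavage-site scorers.

Three protocols: 5-fold cross-validation with folds drawn over *substrates*
(never windows, so no same-substrate leakage), self-consistency (train and
test on the same windows; an upper bound that reveals fitting ability) and an
independent test on a disjoint substrate set.  Metrics are sensitivity,
specificity, accuracy, MCC and F-score from the confusion counts, plus ROC
and AUC; sensitivities can be tabulated at fixed specificity levels for
tool-to-tool comparison.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve as _sk_roc_curve

from .model import (
    CleavageSiteModel,
    CleavageSiteResults,
    ModelError,
    _rank_auc,
    threshold_at_specificity,
    DEFAULT_LEVELS,
)
from .substrates import ProteaseDataset, extract_windows

logger = logging.getLogger(__name__)


class EvaluationError(ValueError):
    pass


@dataclass
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise EvaluationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            tp=self.tp + other.tp, tn=self.tn + other.tn,
            fp=self.fp + other.fp, fn=self.fn + other.fn,
        )


def confusion(scores, labels, threshold: float = 0.0) -> ConfusionCounts:
    """Confusion counts for the decision rule ``score > threshold``."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    calls = scores > threshold
    return ConfusionCounts(
        tp=int((calls & labels).sum()),
        tn=int((~calls & ~labels).sum()),
        fp=int((calls & ~labels).sum()),
        fn=int((~calls & labels).sum()),
    )


def metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Sn, Sp, Acc, MCC and F-score from confusion counts.

    Undefined denominators follow a fixed convention: MCC is 0 when any
    marginal is zero, F is 0 when precision + recall is zero, and each rate is
    0 when its own denominator is zero.
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    if counts.total < 1:
        raise EvaluationError("empty confusion table")

    def ratio(num, den):
        return num / den if den else 0.0

    sn = ratio(tp, tp + fn)
    sp = ratio(tn, tn + fp)
    acc = (tp + tn) / counts.total
    marginals = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(marginals) if marginals else 0.0
    prec = ratio(tp, tp + fp)
    f = 2 * prec * sn / (prec + sn) if (prec + sn) else 0.0
    return {"sensitivity": sn, "specificity": sp, "accuracy": acc, "mcc": mcc, "f_score": f}


def roc_auc(scores, labels) -> tuple[pd.DataFrame, float]:
    """ROC curve points and AUC.

    The AUC is the midrank (Mann-Whitney) statistic, which equals the
    trapezoidal integral of the empirical ROC; the returned curve is the
    standard (fpr, tpr, threshold) sweep.
    """
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise EvaluationError("ROC needs both classes")
    fpr, tpr, thr = _sk_roc_curve(labels, np.asarray(scores, dtype=float))
    roc = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return roc, float(_rank_auc(scores, labels))


def sensitivity_at_specificity(
    scores, labels, levels: tuple[float, ...] = DEFAULT_LEVELS
) -> pd.DataFrame:
    """Sensitivity at fixed specificity levels (threshold per calibration rule)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    neg = scores[~labels]
    pos = scores[labels]
    if len(neg) == 0 or len(pos) == 0:
        raise EvaluationError("need both classes")
    rows = []
    for level in sorted(levels, reverse=True):
        t = threshold_at_specificity(neg, level)
        rows.append(
            {
                "level": level,
                "threshold": t,
                "sensitivity": float((pos > t).mean()),
                "empirical_specificity": float((neg <= t).mean()),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class EvaluationReport:
    """Pooled and per-fold evaluation of a cleavage scorer."""

    protocol: str
    pooled: ConfusionCounts
    pooled_metrics: dict[str, float]
    auc: float
    roc: pd.DataFrame
    per_fold: list[dict] = field(default_factory=list)
    sens_at_spec: pd.DataFrame | None = None
    scores: np.ndarray | None = None
    labels: np.ndarray | None = None

    @property
    def macro_metrics(self) -> dict[str, float]:
        """Unweighted mean of per-fold metrics (macro average)."""
        if not self.per_fold:
            return dict(self.pooled_metrics)
        keys = self.per_fold[0]["metrics"].keys()
        return {k: float(np.mean([f["metrics"][k] for f in self.per_fold])) for k in keys}

    def to_json(self, path) -> None:
        payload = {
            "protocol": self.protocol,
            "auc": self.auc,
            "pooled_counts": vars(self.pooled),
            "pooled_metrics": self.pooled_metrics,
            "macro_metrics": self.macro_metrics,
            "per_fold": [
                {"fold": f["fold"], "counts": vars(f["counts"]), "metrics": f["metrics"],
                 "auc": f["auc"]}
                for f in self.per_fold
            ],
        }
        if self.sens_at_spec is not None:
            payload["sensitivity_at_specificity"] = self.sens_at_spec.to_dict(orient="records")
        Path(path).write_text(json.dumps(payload, indent=2))

    def to_tsv(self, path_prefix) -> None:
        prefix = Path(path_prefix)
        self.roc.to_csv(prefix.with_suffix(".roc.tsv"), sep="\t", index=False)
        rows = [{"fold": "pooled", "auc": self.auc, **self.pooled_metrics, **vars(self.pooled)}]
        for f in self.per_fold:
            rows.append({"fold": f["fold"], "auc": f["auc"], **f["metrics"], **vars(f["counts"])})
        pd.DataFrame(rows).to_csv(prefix.with_suffix(".metrics.tsv"), sep="\t", index=False)


def _report(scores, labels, protocol, per_fold=None,
            decision_threshold: float = 0.0,
            levels: tuple[float, ...] = DEFAULT_LEVELS) -> EvaluationReport:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pooled = confusion(scores, labels, decision_threshold)
    roc, auc = roc_auc(scores, labels)
    return EvaluationReport(
        protocol=protocol,
        pooled=pooled,
        pooled_metrics=metrics(pooled),
        auc=auc,
        roc=roc,
        per_fold=per_fold or [],
        sens_at_spec=sensitivity_at_specificity(scores, labels, levels),
        scores=scores,
        labels=labels,
    )


def _fold_substrates(dataset: ProteaseDataset, n_folds: int, seed: int,
                     max_retries: int = 5) -> list[list[str]]:
    """Seeded partition of substrate ids into folds, each containing >=1 cleavage site."""
    ids = dataset.substrate_ids
    sites = {s.substrate_id: len(s.cleavage_p1_positions) for s in dataset.substrates}
    for attempt in range(max_retries):
        rng = np.random.default_rng(seed + attempt)
        order = list(rng.permutation(ids))
        folds = [order[k::n_folds] for k in range(n_folds)]
        if all(sum(sites[sid] for sid in fold) > 0 for fold in folds):
            if attempt:
                logger.warning("refolded %d time(s) to get positives in every fold", attempt)
            return folds
    raise EvaluationError("could not build folds with cleavage sites in each")


def cross_validate(
    dataset: ProteaseDataset,
    scheme: str = "ALL",
    span: tuple[int, int] = (4, 2),
    annotations: dict | None = None,
    negative_ratio: float = 3.0,
    n_folds: int = 5,
    grid: dict | None = None,
    svr_params: dict | None = None,
    select_features: bool = False,
    n_trees: int = 500,
    decision_threshold: float = 0.0,
    levels: tuple[float, ...] = DEFAULT_LEVELS,
    seed: int = 0,
) -> EvaluationReport:
    """K-fold cross-validation split by substrate.

    Windows are extracted once per run (seeded); folds partition the substrate
    ids, and for each fold the bi-profiles, optional feature mask and SVR are
    refit on the training windows only.  Pooled (micro) metrics are primary;
    per-fold metrics are also reported.
    """
    if dataset.n_substrates < n_folds:
        raise EvaluationError(f"need >= {n_folds} substrates for {n_folds}-fold CV")
    windows = extract_windows(dataset, span=span, negative_ratio=negative_ratio,
                              seed=seed, annotations=annotations)
    folds = _fold_substrates(dataset, n_folds, seed)

    all_scores, all_labels, per_fold = [], [], []
    for k, held_out in enumerate(folds):
        held = set(held_out)
        train_w = [w for w in windows if w.substrate_id not in held]
        test_w = [w for w in windows if w.substrate_id in held]
        if not test_w or not any(w.is_positive for w in test_w):
            raise EvaluationError(f"fold {k} lacks positive test windows")
        results = CleavageSiteModel(train_w, scheme=scheme, protease_id=dataset.protease_id).fit(
            grid=grid, svr_params=svr_params, select_features=select_features,
            n_trees=n_trees, levels=levels, seed=seed,
        )
        fold_scores = results.predict_scores(test_w)
        fold_labels = np.array([w.is_positive for w in test_w])
        counts = confusion(fold_scores, fold_labels, decision_threshold)
        fold_auc = _rank_auc(fold_scores, fold_labels) if len(np.unique(fold_labels)) == 2 else float("nan")
        per_fold.append({"fold": k, "counts": counts, "metrics": metrics(counts), "auc": fold_auc})
        all_scores.append(fold_scores)
        all_labels.append(fold_labels)

    return _report(np.concatenate(all_scores), np.concatenate(all_labels), "cv5",
                   per_fold=per_fold, decision_threshold=decision_threshold, levels=levels)


def self_consistency(
    dataset: ProteaseDataset,
    scheme: str = "ALL",
    span: tuple[int, int] = (4, 2),
    annotations: dict | None = None,
    negative_ratio: float = 3.0,
    grid: dict | None = None,
    svr_params: dict | None = None,
    select_features: bool = False,
    n_trees: int = 500,
    decision_threshold: float = 0.0,
    levels: tuple[float, ...] = DEFAULT_LEVELS,
    seed: int = 0,
) -> EvaluationReport:
    """Train and test on the same windows — an upper bound on attainable fit."""
    windows = extract_windows(dataset, span=span, negative_ratio=negative_ratio,
                              seed=seed, annotations=annotations)
    results = CleavageSiteModel(windows, scheme=scheme, protease_id=dataset.protease_id).fit(
        grid=grid, svr_params=svr_params, select_features=select_features,
        n_trees=n_trees, levels=levels, seed=seed,
    )
    scores = results.predict_scores(windows)
    labels = np.array([w.is_positive for w in windows])
    return _report(scores, labels, "self", decision_threshold=decision_threshold, levels=levels)


def independent_test(
    results: CleavageSiteResults,
    test_dataset: ProteaseDataset,
    annotations: dict | None = None,
    negative_ratio: float = 3.0,
    decision_threshold: float = 0.0,
    levels: tuple[float, ...] = DEFAULT_LEVELS,
    seed: int = 0,
) -> EvaluationReport:
    """Evaluate a fitted scorer on a substrate set disjoint from its training set."""
    if results.model is not None:
        train_ids = {w.substrate_id for w in results.model.windows}
        overlap = sorted(train_ids & set(test_dataset.substrate_ids))
        if overlap:
            raise EvaluationError(f"test substrates overlap training set: {overlap}")
    windows = extract_windows(test_dataset, span=results.scheme.span,
                              negative_ratio=negative_ratio, seed=seed,
                              annotations=annotations)
    scores = results.predict_scores(windows)
    labels = np.array([w.is_positive for w in windows])
    return _report(scores, labels, "independent",
                   decision_threshold=decision_threshold, levels=levels)
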