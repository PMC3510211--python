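"""SVR cleavage scorer: model fitting, scoring and specificity-calibrated thresholds.

:class:`CleavageSiteModel` holds labelled site windows and an encoding scheme;
``fit()`` fits the bi-profiles, optionally selects features by Gini Z-score,
tunes the RBF-kernel support vector regressor (targets +1 cleaved / -1
non-cleaved) by seeded internal cross-validation maximising AUC, refits on all
windows, calibrates decision thresholds to named specificity levels, and
returns a :class:`CleavageSiteResults` carrying everything needed to score new
candidate sites.  The raw SVR output is unbounded; decisions are made by
``score > threshold`` at a chosen specificity level, and a rank-percentile
against the training scores is reported alongside.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVR

from .encoding import BiProfile, EncodingScheme, encode, encode_windows, fit_profiles
from .selection import FeatureMask, apply_mask, compute_mdgi, select
from .substrates import LABEL_CLEAVED, SiteWindow

logger = logging.getLogger(__name__)

DEFAULT_GRID: dict[str, tuple[float, ...]] = {
    "C": (0.1, 1.0, 10.0, 100.0),
    "gamma": (0.001, 0.01, 0.1, 1.0),
}
#: reduced grid for routine runs; same shape of trade-offs, a quarter the fits
FAST_GRID: dict[str, tuple[float, ...]] = {"C": (1.0, 10.0, 100.0), "gamma": (0.01, 0.1)}

DEFAULT_EPSILON = 0.1
#: named specificity levels for threshold calibration
DEFAULT_LEVELS: tuple[float, ...] = (0.999, 0.998, 0.995, 0.99, 0.98)


class ModelError(ValueError):
    pass


def _rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC via the midrank (Mann-Whitney) statistic; ties get midranks."""
    from scipy.stats import rankdata

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ModelError("AUC needs both classes")
    ranks = rankdata(scores)
    return (ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def threshold_at_specificity(negative_scores: np.ndarray, level: float) -> float:
    """Smallest threshold whose empirical specificity on the negatives is >= level.

    With the decision rule ``score > threshold``, at most
    ``floor((1 - level) * n_neg)`` negatives may exceed the threshold; for
    ``level = 1.0`` the threshold is the maximum negative score (no negative
    strictly exceeds it).
    """
    neg = np.sort(np.asarray(negative_scores, dtype=float))[::-1]
    n = len(neg)
    if n == 0:
        raise ModelError("threshold calibration needs at least one negative score")
    if not 0 < level <= 1:
        raise ModelError("specificity level must be in (0, 1]")
    allowed_fp = int(math.floor((1.0 - level) * n + 1e-9))
    if allowed_fp >= n:
        return float(neg[-1]) - 1.0  # every negative may pass
    return float(neg[allowed_fp])


def calibrate_thresholds(
    scores: np.ndarray,
    labels: np.ndarray,
    levels: tuple[float, ...] = DEFAULT_LEVELS,
) -> dict[float, float]:
    """Per-level thresholds from scored labelled sites; monotone in the level.

    A warning is logged when the negatives cannot resolve a level (fewer than
    ``1 / (1 - level)`` negatives).
    """
    labels = np.asarray(labels).astype(bool)
    neg = np.asarray(scores, dtype=float)[~labels]
    if len(neg) == 0:
        raise ModelError("no negatives to calibrate on")
    for level in levels:
        if level < 1.0 and len(neg) < 1.0 / (1.0 - level):
            logger.warning(
                "only %d negatives: specificity level %.3f is below sampling resolution",
                len(neg), level,
            )
    ordered = sorted(levels)
    thresholds = [threshold_at_specificity(neg, lv) for lv in ordered]
    monotone = np.maximum.accumulate(thresholds)  # higher level => higher-or-equal threshold
    return {lv: float(t) for lv, t in zip(ordered, monotone)}


@dataclass
class SiteScore:
    """One scored candidate site; ``decision`` is ``score > threshold``."""

    p1_index: int
    score: float
    threshold: float | None = None
    level: float | None = None

    @property
    def decision(self) -> str:
        if self.threshold is None:
            raise ModelError("no threshold attached to this score")
        return LABEL_CLEAVED if self.score > self.threshold else "non-cleaved"


class CleavageSiteModel:
    """Cleavage-site scorer specification: labelled windows + encoding scheme.

    Parameters
    ----------
    windows
        Labelled :class:`~cleavesite.substrates.SiteWindow` objects (both
        classes must be present).
    scheme
        An :class:`~cleavesite.encoding.EncodingScheme` or a scheme name such
        as ``"ALL"`` or ``"BEAA+BPBSS"``.
    protease_id
        Identifier carried through to results and reports.
    """

    def __init__(self, windows: list[SiteWindow], scheme="ALL", protease_id: str = ""):
        if not windows:
            raise ModelError("no training windows")
        span = windows[0].span
        if any(w.span != span for w in windows):
            raise ModelError("all windows must share one span")
        if isinstance(scheme, str):
            scheme = EncodingScheme.from_name(scheme, span)
        elif scheme.span != span:
            raise ModelError("scheme span differs from window span")
        labels = np.array([w.is_positive for w in windows])
        if labels.all() or not labels.any():
            raise ModelError("training windows contain a single class")
        self.windows = list(windows)
        self.scheme = scheme
        self.protease_id = protease_id
        self.labels = labels

    @classmethod
    def from_dataset(
        cls,
        dataset,
        span: tuple[int, int] = (4, 2),
        scheme: str = "ALL",
        negative_ratio: float = 3.0,
        seed: int = 0,
        annotations: dict | None = None,
    ) -> "CleavageSiteModel":
        """Build from a :class:`~cleavesite.substrates.ProteaseDataset` by window extraction."""
        from .substrates import extract_windows

        windows = extract_windows(
            dataset, span=span, negative_ratio=negative_ratio, seed=seed, annotations=annotations
        )
        return cls(windows, scheme=scheme, protease_id=dataset.protease_id)

    # -- fitting ------------------------------------------------------------

    def fit(
        self,
        grid: dict | None = None,
        svr_params: dict | None = None,
        epsilon: float = DEFAULT_EPSILON,
        select_features: bool = False,
        z_threshold: float = 1.0,
        n_trees: int = 500,
        cv_folds: int = 5,
        levels: tuple[float, ...] = DEFAULT_LEVELS,
        pseudocount: float = 1.0,
        seed: int = 0,
    ) -> "CleavageSiteResults":
        """Fit profiles, (optionally) select features, tune and train the SVR.

        If ``svr_params`` (``{"C": ..., "gamma": ...}``) is given, the grid
        search is skipped.  Thresholds are calibrated on the training scores;
        :meth:`CleavageSiteResults.recalibrate` replaces them from held-out
        validation scores.
        """
        profiles = fit_profiles(self.windows, self.scheme, pseudocount=pseudocount)
        X, descriptors = encode_windows(self.windows, self.scheme, profiles)
        y = np.where(self.labels, 1.0, -1.0)

        mask: FeatureMask | None = None
        if select_features:
            importance = compute_mdgi(
                X, self.labels.astype(int), descriptors=descriptors,
                n_trees=n_trees, seed=seed,
            )
            mask = select(importance, z_threshold=z_threshold)
            X = apply_mask(X, mask)
            logger.info("feature selection kept %d/%d features (%.1f%% reduced)",
                        mask.n_selected, len(mask.selected), 100 * mask.reduction_fraction)

        if svr_params is not None:
            best_C, best_gamma = float(svr_params["C"]), float(svr_params["gamma"])
            grid_scores = None
        else:
            grid = grid or DEFAULT_GRID
            best_C, best_gamma, grid_scores = self._grid_search(
                X, y, grid, epsilon=epsilon, cv_folds=cv_folds, seed=seed
            )

        svr = SVR(kernel="rbf", C=best_C, gamma=best_gamma, epsilon=epsilon)
        svr.fit(X, y)
        train_scores = svr.predict(X)
        thresholds = calibrate_thresholds(train_scores, self.labels, levels=levels)

        return CleavageSiteResults(
            model=self,
            scheme=self.scheme,
            profiles=profiles,
            mask=mask,
            descriptors=descriptors,
            svr=svr,
            svr_params={"C": best_C, "gamma": best_gamma, "epsilon": epsilon},
            thresholds=thresholds,
            training_scores=train_scores,
            training_seed=seed,
            protease_id=self.protease_id,
            grid_scores=grid_scores,
        )

    def _grid_search(self, X, y, grid, epsilon, cv_folds, seed, max_retries: int = 5):
        labels01 = (y > 0).astype(int)
        counts = np.bincount(labels01)
        folds = min(cv_folds, int(counts.min()))
        if folds < 2:
            raise ModelError("too few samples in a class for internal cross-validation")
        splits = None
        for attempt in range(max_retries):
            kf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + attempt)
            candidate = list(kf.split(X, labels01))
            if all(len(np.unique(labels01[tr])) == 2 and len(np.unique(labels01[te])) == 2
                   for tr, te in candidate):
                splits = candidate
                break
        if splits is None:
            raise ModelError("could not form folds with both classes present")

        rows = []
        best = None
        for C, gamma in itertools.product(grid["C"], grid["gamma"]):
            aucs = []
            for tr, te in splits:
                svr = SVR(kernel="rbf", C=C, gamma=gamma, epsilon=epsilon)
                svr.fit(X[tr], y[tr])
                aucs.append(_rank_auc(svr.predict(X[te]), labels01[te]))
            mean_auc = float(np.mean(aucs))
            rows.append({"C": C, "gamma": gamma, "cv_auc": mean_auc})
            # deterministic tie-break: higher AUC, then smaller C, then smaller gamma
            key = (-mean_auc, C, gamma)
            if best is None or key < best[0]:
                best = (key, C, gamma)
        _, best_C, best_gamma = best
        logger.info("grid search selected C=%g gamma=%g", best_C, best_gamma)
        return float(best_C), float(best_gamma), pd.DataFrame(rows)


@dataclass
class CleavageSiteResults:
    """Fitted cleavage scorer: encoding, profiles, SVR and calibrated thresholds."""

    model: CleavageSiteModel | None
    scheme: EncodingScheme
    profiles: dict[str, BiProfile]
    mask: FeatureMask | None
    descriptors: list[str]
    svr: SVR
    svr_params: dict
    thresholds: dict[float, float]
    training_scores: np.ndarray
    training_seed: int
    protease_id: str = ""
    grid_scores: pd.DataFrame | None = None

    # -- scoring ------------------------------------------------------------

    def _design(self, windows: list[SiteWindow]) -> np.ndarray:
        for w in windows:
            if w.span != self.scheme.span:
                raise ModelError(
                    f"window span {w.span} does not match model span {self.scheme.span}"
                )
        X, _ = encode_windows(windows, self.scheme, self.profiles)
        if self.mask is not None:
            X = apply_mask(X, self.mask)
        return X

    def predict_scores(self, windows: list[SiteWindow]) -> np.ndarray:
        """Raw SVR scores for a batch of windows (deterministic)."""
        return self.svr.predict(self._design(windows))

    def predict_score(self, window: SiteWindow, level: float | None = None) -> SiteScore:
        """Score one candidate site, with a decision at the requested level."""
        score = float(self.predict_scores([window])[0])
        threshold = self.thresholds[level] if level is not None else None
        return SiteScore(p1_index=window.p1_index, score=score, threshold=threshold, level=level)

    def rank_percentile(self, score: float) -> float:
        """Percentile of a score against the training scores (display aid)."""
        return float(100.0 * np.mean(self.training_scores <= score))

    def recalibrate(self, scores: np.ndarray, labels: np.ndarray,
                    levels: tuple[float, ...] | None = None) -> dict[float, float]:
        """Replace thresholds using held-out validation scores."""
        levels = levels or tuple(sorted(self.thresholds))
        self.thresholds = calibrate_thresholds(scores, labels, levels=levels)
        return self.thresholds

    def scan(self, sequence: str, annotation=None, top_k: int | None = None, query_id: str = "query"):
        """Scan a full-length query; see :func:`cleavesite.scan.scan`."""
        from .scan import scan as _scan

        return _scan(self, sequence, annotation=annotation, top_k=top_k, query_id=query_id)

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        lines = [
            "Cleavage-site SVR model",
            "=" * 46,
            f"protease:        {self.protease_id or '(unnamed)'}",
            f"scheme:          {self.scheme.name}  span P{self.scheme.span[0]}-P{self.scheme.span[1]}'  (L={self.scheme.L})",
            f"features:        {self.scheme.vector_length}"
            + (f" -> {self.mask.n_selected} after Z>{self.mask.threshold:g} selection"
               if self.mask is not None else ""),
            f"SVR:             RBF kernel, C={self.svr_params['C']:g}, "
            f"gamma={self.svr_params['gamma']:g}, epsilon={self.svr_params['epsilon']:g}",
            f"support vectors: {len(self.svr.support_)}",
            f"training seed:   {self.training_seed}",
            "",
            "thresholds (score > t calls cleavage):",
        ]
        for level in sorted(self.thresholds, reverse=True):
            lines.append(f"  specificity {100 * level:5.1f}%  t = {self.thresholds[level]: .4f}")
        return "\n".join(lines)

    # -- persistence --------------------------------------------------------

    def save(self, directory) -> None:
        """Write a model bundle: manifest, profiles, mask, thresholds, SVR."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {
            "protease_id": self.protease_id,
            "scheme": self.scheme.name,
            "span": list(self.scheme.span),
            "svr_params": self.svr_params,
            "training_seed": self.training_seed,
            "levels": sorted(self.thresholds),
            "channels": sorted(self.profiles),
            "has_mask": self.mask is not None,
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
        for channel, profile in self.profiles.items():
            profile.to_tsv(directory / f"profile_{channel}.tsv")
        pd.DataFrame(
            {"level": sorted(self.thresholds), "threshold": [self.thresholds[lv] for lv in sorted(self.thresholds)]}
        ).to_csv(directory / "thresholds.tsv", sep="\t", index=False)
        if self.mask is not None:
            self.mask.to_tsv(directory / "mask.tsv")
        joblib.dump(
            {"svr": self.svr, "training_scores": self.training_scores, "descriptors": self.descriptors},
            directory / "svr.joblib",
        )

    @classmethod
    def load(cls, directory) -> "CleavageSiteResults":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        span = tuple(manifest["span"])
        scheme = EncodingScheme.from_name(manifest["scheme"], span)
        profiles = {
            ch: BiProfile.from_tsv(directory / f"profile_{ch}.tsv", span)
            for ch in manifest["channels"]
        }
        thresholds_df = pd.read_csv(directory / "thresholds.tsv", sep="\t")
        thresholds = dict(zip(thresholds_df["level"], thresholds_df["threshold"]))
        blob = joblib.load(directory / "svr.joblib")
        mask = None
        if manifest["has_mask"]:
            mask_df = pd.read_csv(directory / "mask.tsv", sep="\t")
            mask = FeatureMask(
                selected=mask_df["selected"].to_numpy(dtype=bool),
                threshold=1.0,
                descriptors=mask_df["descriptor"].tolist(),
            )
        return cls(
            model=None,
            scheme=scheme,
            profiles=profiles,
            mask=mask,
            descriptors=blob["descriptors"],
            svr=blob["svr"],
            svr_params=manifest["svr_params"],
            thresholds=thresholds,
            training_scores=np.asarray(blob["training_scores"]),
            training_seed=manifest["training_seed"],
            protease_id=manifest["protease_id"],
        )


def train(
    windows: list[SiteWindow],
    scheme="ALL",
    grid: dict | None = None,
    seed: int = 0,
    **fit_kwargs,
) -> CleavageSiteResults:
    """Convenience wrapper: build a :class:`CleavageSiteModel` and fit it."""
    return CleavageSiteModel(windows, scheme=scheme).fit(grid=grid, seed=seed, **fit_kwargs)
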