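"""Uniform fit / score / vote contract over the seven voting methods.

Five methods vote on a predicted probability of recurrence (RSVM, RF, NB,
LSVM, LR; vote 1 iff p >= 0.5), KNN votes its hard class assignment, and the
Cox risk-sum scorer (COX-RS) votes 1 iff a patient's risk sum exceeds the
training-median risk sum. The risk sum is built from one univariate
proportional-hazards fit per selected miRNA on standardized training
expression: RS_i = sum_j beta_j * z_ij.

All methods standardize features with constants estimated on the training
fold only, and are deterministic given a seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .core import METHOD_NAMES

logger = logging.getLogger("mirvote")

PROBABILITY_METHODS = ("RSVM", "RF", "NB", "LSVM", "LR")

#: Default hyperparameters; every entry is overridable via the YAML config.
DEFAULT_HYPERPARAMS: dict[str, dict] = {
    "RSVM": {"C": 1.0, "gamma": "median"},  # median-heuristic kernel width
    "LSVM": {"C": 1.0},
    "RF": {"n_estimators": 500, "max_features": "sqrt"},
    "NB": {},
    "KNN": {"n_neighbors": 5},  # odd k precludes ties
    "LR": {"C": 1.0},  # ridge: features can outnumber samples
    "COX-RS": {"ridge": 1e-6, "max_abs_beta": 20.0},
}


class TrainingError(ValueError):
    """Raised when a method cannot be fit (e.g. a class is absent)."""


@dataclass(frozen=True)
class RecurrenceScore:
    """A method's raw per-sample output before thresholding into a vote."""

    value: float
    kind: str  # probability | risk_sum | class

    def __post_init__(self) -> None:
        if self.kind == "probability" and not 0.0 <= self.value <= 1.0:
            raise ValueError(f"probability score {self.value} outside [0, 1]")
        if self.kind == "class" and self.value not in (0.0, 1.0):
            raise ValueError(f"class score must be 0 or 1, got {self.value}")
        if self.kind not in ("probability", "risk_sum", "class"):
            raise ValueError(f"unknown score kind {self.kind!r}")


@dataclass(frozen=True)
class FittedModel:
    """A trained method plus its training-fold standardization constants."""

    method: str
    feature_ids: tuple[str, ...]  # features actually used (zero-variance dropped)
    center: np.ndarray
    scale: np.ndarray
    kind: str
    seed: int
    estimator: Optional[object] = None  # sklearn estimator for the six ML methods
    cox_coefs: Optional[np.ndarray] = None  # per-feature univariate Cox betas
    threshold: Optional[float] = None  # training-median risk sum (COX-RS)

    def standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.center) / self.scale


def fit_classifier(
    method: str,
    X: np.ndarray,
    feature_ids: Sequence[str],
    labels: Sequence[int],
    survival: Optional[tuple[Sequence[float], Sequence[int]]] = None,
    seed: int = 0,
    hyperparams: Optional[Mapping[str, Mapping]] = None,
) -> FittedModel:
    """Fit one voting method on training expression (samples x features).

    ``labels`` are binary recurrence labels; ``survival`` supplies
    (time_months, event) and is required for COX-RS only. Features with zero
    training variance are dropped with a logged warning.
    """
    if method not in METHOD_NAMES:
        raise ValueError(f"unknown method {method!r}; expected one of {METHOD_NAMES}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.ndim != 2 or X.shape[0] != y.size or X.shape[1] != len(feature_ids):
        raise ValueError("X must be (n_samples, n_features) aligned with labels")
    counts = np.bincount(y, minlength=2)
    if counts[0] < 2 or counts[1] < 2:
        raise TrainingError(
            f"{method}: need at least 2 samples per class, got "
            f"{counts[1]} cases / {counts[0]} controls"
        )
    params = dict(DEFAULT_HYPERPARAMS[method])
    if hyperparams and method in hyperparams:
        params.update(hyperparams[method])

    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    keep = scale > 0
    if not keep.all():
        dropped = [f for f, k in zip(feature_ids, keep) if not k]
        logger.warning("%s: dropping zero-variance feature(s) %s", method, dropped)
    if not keep.any():
        raise TrainingError(f"{method}: all features have zero training variance")
    used_ids = tuple(f for f, k in zip(feature_ids, keep) if k)
    center, scale = center[keep], scale[keep]
    Z = (X[:, keep] - center) / scale

    if method == "COX-RS":
        if survival is None:
            raise TrainingError("COX-RS requires (time_months, event) survival data")
        times = np.asarray(survival[0], dtype=float)
        events = np.asarray(survival[1], dtype=int)
        coefs = _univariate_cox_coefs(Z, times, events, params)
        risk_sums = Z @ coefs
        threshold = float(np.median(risk_sums))
        return FittedModel(
            method=method,
            feature_ids=used_ids,
            center=center,
            scale=scale,
            kind="risk_sum",
            seed=seed,
            cox_coefs=coefs,
            threshold=threshold,
        )

    estimator = _build_estimator(method, params, Z, seed)
    estimator.fit(Z, y)
    kind = "class" if method == "KNN" else "probability"
    return FittedModel(
        method=method,
        feature_ids=used_ids,
        center=center,
        scale=scale,
        kind=kind,
        seed=seed,
        estimator=estimator,
    )


def _build_estimator(method: str, params: dict, Z: np.ndarray, seed: int):
    if method == "RSVM":
        gamma = params.get("gamma", "median")
        if gamma == "median":
            gamma = _median_heuristic_gamma(Z)
        svc = SVC(C=params.get("C", 1.0), kernel="rbf", gamma=gamma, random_state=seed)
        return _platt(svc)
    if method == "LSVM":
        svc = SVC(C=params.get("C", 1.0), kernel="linear", random_state=seed)
        return _platt(svc)
    if method == "RF":
        return RandomForestClassifier(
            n_estimators=params.get("n_estimators", 500),
            max_features=params.get("max_features", "sqrt"),
            random_state=seed,
        )
    if method == "NB":
        return GaussianNB()
    if method == "KNN":
        return KNeighborsClassifier(n_neighbors=params.get("n_neighbors", 5))
    if method == "LR":
        # default penalty is ridge (l2); C=1 keeps the fit defined when
        # features outnumber samples
        return LogisticRegression(
            C=params.get("C", 1.0),
            solver="lbfgs",
            max_iter=2000,
        )
    raise ValueError(method)


def _platt(svc: SVC) -> CalibratedClassifierCV:
    """Platt-scaled probabilities for a margin classifier (sigmoid on
    cross-validated decision values, deterministic unshuffled folds)."""
    return CalibratedClassifierCV(svc, method="sigmoid", cv=5, ensemble=False)


def _median_heuristic_gamma(Z: np.ndarray) -> float:
    """RBF width from the median pairwise distance: gamma = 1 / (2 * median^2)."""
    n = Z.shape[0]
    sq = np.sum(Z**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (Z @ Z.T)
    d2 = d2[np.triu_indices(n, k=1)]
    med2 = float(np.median(np.maximum(d2, 0.0)))
    if med2 <= 0:
        return 1.0 / Z.shape[1]
    return 1.0 / (2.0 * med2)


def _univariate_cox_coefs(
    Z: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    params: dict,
) -> np.ndarray:
    """One proportional-hazards coefficient per standardized feature.

    All features are fit simultaneously by Newton iteration on the Breslow
    partial likelihood (each feature enters its own univariate model, so the
    score and information are scalar per feature and vectorize across the
    feature axis). A tiny ridge term plus a coefficient bound keep the
    estimate finite when a feature perfectly separates event order
    (monotone likelihood).
    """
    ridge = params.get("ridge", 1e-6)
    bound = params.get("max_abs_beta", 20.0)
    n, p = Z.shape
    order = np.argsort(-times, kind="stable")
    Zs = Z[order]
    ts = times[order]
    ev = events[order].astype(bool)
    # risk set of an event at t_i is every sample with time >= t_i: with
    # descending sort that is the prefix ending at the last index tied with i
    _, inverse, counts = np.unique(-ts, return_inverse=True, return_counts=True)
    block_end = (np.cumsum(counts) - 1)[inverse]

    beta = np.zeros(p)
    for _ in range(60):
        eta = Zs * beta  # n x p
        eta = eta - eta.max(axis=0)  # ratios below are shift-invariant
        w = np.exp(eta)
        s0 = np.cumsum(w, axis=0)[block_end]
        s1 = np.cumsum(w * Zs, axis=0)[block_end]
        s2 = np.cumsum(w * Zs**2, axis=0)[block_end]
        mean = s1[ev] / s0[ev]
        score = (Zs[ev] - mean).sum(axis=0) - ridge * beta
        info = (s2[ev] / s0[ev] - mean**2).sum(axis=0) + ridge
        step = np.clip(score / np.maximum(info, 1e-12), -2.0, 2.0)
        beta_new = np.clip(beta + step, -bound, bound)
        if np.max(np.abs(beta_new - beta)) < 1e-10:
            beta = beta_new
            break
        beta = beta_new
    return beta


# ---------------------------------------------------------------------------
# Scoring and voting
# ---------------------------------------------------------------------------


def recurrence_score(
    model: FittedModel,
    sample: Mapping[str, float],
) -> RecurrenceScore:
    """Score one held-out sample given its expression over the model features."""
    values = np.empty(len(model.feature_ids))
    for i, fid in enumerate(model.feature_ids):
        try:
            values[i] = float(sample[fid])
        except (KeyError, IndexError):
            raise KeyError(f"sample is missing expression for feature {fid!r}") from None
    return _score_row(model, values)


def score_matrix(model: FittedModel, X: np.ndarray) -> list[RecurrenceScore]:
    """Score rows of a (samples x model-features) matrix."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(model.feature_ids):
        raise ValueError("X must be (n_samples, n_model_features)")
    Z = model.standardize(X)
    if model.kind == "risk_sum":
        vals = Z @ model.cox_coefs
        return [RecurrenceScore(float(v), "risk_sum") for v in vals]
    if model.kind == "class":
        vals = model.estimator.predict(Z)
        return [RecurrenceScore(float(v), "class") for v in vals]
    probs = model.estimator.predict_proba(Z)[:, list(model.estimator.classes_).index(1)]
    probs = np.clip(probs, 0.0, 1.0)
    return [RecurrenceScore(float(p), "probability") for p in probs]


def _score_row(model: FittedModel, values: np.ndarray) -> RecurrenceScore:
    return score_matrix(model, values[None, :])[0]


def cast_vote(score: RecurrenceScore, model: FittedModel) -> int:
    """Binary vote: probability >= 0.5, risk sum strictly above the training
    median, or the KNN class itself. A probability of exactly 0.5 votes 1
    (toward recurrence) — conservative for a treatment-sparing classifier."""
    if score.kind == "probability":
        return int(score.value >= 0.5)
    if score.kind == "risk_sum":
        return int(score.value > model.threshold)
    return int(score.value)
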