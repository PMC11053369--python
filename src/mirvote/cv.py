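"""Leave-one-pair-out cross-validation, vote aggregation and cohort transfer.

Each fold holds out one matched case-control pair; differential-expression
testing, FDR feature selection and classifier training all happen on the
remaining pairs only, so the held-out pair can never influence its own
feature set (the classical selection-bias leak in small expression studies).
Each method then votes on the two held-out samples; votes are summed into a
0..7 score per patient, from which risk groups are cut.

For external cohorts measured on a different miRNA panel, the feature space
is harmonized by intersection, per-method feature sets are preselected on
the reference cohort, and cross-validation inside the external cohort uses
those fixed sets (no per-fold re-selection).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .classifiers import FittedModel, cast_vote, fit_classifier, score_matrix
from .core import METHOD_NAMES, PairedCohort, RiskGroups, VoteTable
from .selection import FeatureSet, paired_differential_expression, select_features

logger = logging.getLogger("mirvote")


@dataclass(frozen=True)
class CVResult:
    """Held-out votes and scores of a cross-validation run."""

    vote_table: VoteTable
    scores: pd.DataFrame  # sample x method raw scores
    fold_features: tuple[FeatureSet, ...]  # one per fold (empty for fixed-set runs)
    config: dict = field(default_factory=dict)

    @property
    def n_folds(self) -> int:
        return int(self.config.get("n_folds", len(self.fold_features)))


def leave_one_pair_out_cv(
    cohort: PairedCohort,
    methods: Sequence[str] = METHOD_NAMES,
    fdr_threshold: float = 0.05,
    fallback_k: int = 10,
    seed: int = 0,
    hyperparams: Optional[Mapping[str, Mapping]] = None,
) -> CVResult:
    """LOPO-CV with per-fold FDR feature selection.

    For every pair p: (1) paired differential expression on all pairs except
    p, (2) FDR selection (top-k fallback), (3) fit every method on the
    training samples restricted to those features, (4) score and vote on the
    two held-out samples. Every sample is scored exactly once per method.
    """
    if cohort.pairs is None:
        raise ValueError(
            "cohort has no pairing; run match_pairs / supply pairs first"
        )
    if cohort.n_pairs < 4:
        raise ValueError(f"need at least 4 pairs for LOPO-CV, got {cohort.n_pairs}")
    methods = _check_methods(methods)

    n_pairs = cohort.n_pairs
    folds = []
    for p in range(n_pairs):
        train_pairs = [i for i in range(n_pairs) if i != p]
        test_ids = list(cohort.pairs[p])
        train_ids = [s for i in train_pairs for s in cohort.pairs[i]]
        folds.append((train_ids, test_ids, train_pairs))

    per_fold_features: list[FeatureSet] = []

    def feature_fn(fold_idx: int) -> FeatureSet:
        de = paired_differential_expression(cohort, pair_subset=folds[fold_idx][2])
        fs = select_features(de, fdr_threshold=fdr_threshold, fallback_k=fallback_k)
        per_fold_features.append(fs)
        return fs

    votes, scores = _run_folds(
        cohort,
        [(t, h) for t, h, _ in folds],
        methods,
        seed,
        hyperparams,
        feature_fn=feature_fn,
    )
    config = {
        "fdr_threshold": fdr_threshold,
        "fallback_k": fallback_k,
        "seed": seed,
        "methods": list(methods),
        "n_folds": n_pairs,
    }
    return CVResult(
        vote_table=aggregate_votes(votes),
        scores=scores,
        fold_features=tuple(per_fold_features),
        config=config,
    )


def _run_folds(
    cohort: PairedCohort,
    folds: Sequence[tuple[list[str], list[str]]],
    methods: Sequence[str],
    seed: int,
    hyperparams: Optional[Mapping[str, Mapping]],
    feature_fn=None,
    fixed_features: Optional[Mapping[str, FeatureSet]] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Shared fold loop; features come per-fold (feature_fn) or fixed per method."""
    clin = cohort.clinical_by_id()
    expr = cohort.expression
    col = {s: j for j, s in enumerate(expr.sample_ids)}
    feat_row = {f: i for i, f in enumerate(expr.feature_ids)}

    votes = pd.DataFrame(
        np.nan, index=list(expr.sample_ids), columns=list(methods), dtype=float
    )
    scores = votes.copy()

    for fold_idx, (train_ids, test_ids) in enumerate(folds):
        fold_seed = int((seed + 10007 * (fold_idx + 1)) % (2**31))
        labels = np.array([clin[s].event for s in train_ids])
        times = np.array([clin[s].time_months for s in train_ids])
        events = labels
        train_cols = [col[s] for s in train_ids]
        test_cols = [col[s] for s in test_ids]
        fold_fs = feature_fn(fold_idx) if feature_fn is not None else None

        for method in methods:
            fs = fold_fs if fold_fs is not None else fixed_features[method]
            rows = [feat_row[f] for f in fs.feature_ids]
            X_train = expr.values[np.ix_(rows, train_cols)].T
            model = fit_classifier(
                method,
                X_train,
                fs.feature_ids,
                labels,
                survival=(times, events),
                seed=fold_seed,
                hyperparams=hyperparams,
            )
            used_rows = [feat_row[f] for f in model.feature_ids]
            X_test = expr.values[np.ix_(used_rows, test_cols)].T
            for sid, sc in zip(test_ids, score_matrix(model, X_test)):
                if not np.isnan(votes.at[sid, method]):
                    raise RuntimeError(f"sample {sid!r} scored twice by {method}")
                votes.at[sid, method] = cast_vote(sc, model)
                scores.at[sid, method] = sc.value
    return votes, scores


def aggregate_votes(per_method: pd.DataFrame | Mapping[str, Mapping[str, int]]) -> VoteTable:
    """Sum per-method binary predictions into a vote table (validates 0/1,
    completeness, and canonical method order)."""
    if not isinstance(per_method, pd.DataFrame):
        per_method = pd.DataFrame(per_method)
    return VoteTable(per_method)


def assign_risk_groups(votes: VoteTable, mode: str = "fixed") -> RiskGroups:
    """Cut vote counts into ultralow / low / high groups.

    fixed: ultralow = {0}, low = {0, 1} — the reference-cohort rule.
    auto: with v_min the minimum observed vote count, ultralow = {v_min},
    low = {v_min, v_min + 1} — the dataset-adaptive rule used when no
    patient of a transferred cohort receives 0 or 1 votes.
    """
    totals = votes.votes
    if len(totals) == 0:
        raise ValueError("empty vote table")
    if mode == "fixed":
        ultralow, low = frozenset({0}), frozenset({0, 1})
    elif mode == "auto":
        v_min = int(totals.min())
        ultralow, low = frozenset({v_min}), frozenset({v_min, v_min + 1})
    else:
        raise ValueError(f"mode must be 'fixed' or 'auto', got {mode!r}")
    labels = totals.map(
        lambda v: "ultralow" if v in ultralow else ("low" if v in low else "high")
    )
    labels.name = "risk_group"
    return RiskGroups(labels=labels, ultralow_votes=ultralow, low_votes=low, mode=mode)


# ---------------------------------------------------------------------------
# External-cohort transfer
# ---------------------------------------------------------------------------


def harmonize_features(
    reference: PairedCohort, external: PairedCohort
) -> tuple[str, ...]:
    """Shared miRNA panel: intersection of feature ids, in reference order."""
    ext = set(external.expression.feature_ids)
    shared = tuple(f for f in reference.expression.feature_ids if f in ext)
    if not shared:
        raise ValueError("reference and external cohorts share no features")
    return shared


def preselect_method_features(
    reference: PairedCohort,
    method: str,
    shared_features: Sequence[str],
    k_grid: Sequence[int] = (5, 10, 20, 50),
    seed: int = 0,
    hyperparams: Optional[Mapping[str, Mapping]] = None,
) -> FeatureSet:
    """Choose a method's feature set on the reference cohort.

    Shared features are ranked by ascending paired-DE p-value in the
    reference cohort; each candidate top-k set is evaluated by the method's
    LOPO-CV accuracy on the reference, and the most accurate k wins
    (smallest k on ties).
    """
    if not shared_features:
        raise ValueError("shared feature list is empty")
    if method not in METHOD_NAMES:
        raise ValueError(f"unknown method {method!r}")
    de = paired_differential_expression(reference)
    ranked = [
        f
        for f in de.table.sort_values("p_value", kind="stable").index
        if f in set(shared_features)
    ]
    ks = []
    for k in k_grid:
        if k > len(ranked):
            logger.warning(
                "k=%d exceeds the %d shared features; clipping", k, len(ranked)
            )
            k = len(ranked)
        if k >= 1 and k not in ks:
            ks.append(k)
    ks.sort()

    truth = {r.sample_id: r.event for r in reference.clinical}
    best_k, best_acc = None, -1.0
    for k in ks:
        fs = FeatureSet(tuple(ranked[:k]), "preselected")
        result = _fixed_feature_cv(reference, {method: fs}, [method], seed, hyperparams)
        pred = result.vote_table.per_method[method]
        acc = float(np.mean([pred[s] == truth[s] for s in pred.index]))
        if acc > best_acc:  # strict: ties keep the smaller (earlier) k
            best_k, best_acc = k, acc
    return FeatureSet(tuple(ranked[:best_k]), "preselected")


def external_validation(
    external: PairedCohort,
    per_method_features: Mapping[str, FeatureSet],
    methods: Sequence[str] = METHOD_NAMES,
    seed: int = 0,
    mode: str = "auto",
    hyperparams: Optional[Mapping[str, Mapping]] = None,
) -> tuple[CVResult, RiskGroups]:
    """Cross-validated voting inside an external cohort with fixed features.

    Paired cohorts use leave-one-pair-out folds. Unpaired cohorts use
    stratified leave-two-out folds: cases and controls are shuffled (seeded)
    and zipped into one-case-plus-one-control folds; leftover samples of the
    larger class are held out in singleton folds, so every sample is voted
    exactly once.
    """
    methods = _check_methods(methods)
    missing = [m for m in methods if m not in per_method_features]
    if missing:
        raise ValueError(f"no preselected features for method(s) {missing}")
    result = _fixed_feature_cv(external, per_method_features, methods, seed, hyperparams)
    groups = assign_risk_groups(result.vote_table, mode=mode)
    return result, groups


def _fixed_feature_cv(
    cohort: PairedCohort,
    per_method_features: Mapping[str, FeatureSet],
    methods: Sequence[str],
    seed: int,
    hyperparams: Optional[Mapping[str, Mapping]],
) -> CVResult:
    all_ids = list(cohort.expression.sample_ids)
    clin = cohort.clinical_by_id()
    events = {s: clin[s].event for s in all_ids}
    if cohort.pairs is not None:
        held_out = [list(pair) for pair in cohort.pairs]
    else:
        rng = np.random.default_rng(seed)
        cases = [s for s in all_ids if events[s] == 1]
        controls = [s for s in all_ids if events[s] == 0]
        if not cases or not controls:
            raise ValueError("external cohort must contain both cases and controls")
        rng.shuffle(cases)
        rng.shuffle(controls)
        n = min(len(cases), len(controls))
        held_out = [[cases[i], controls[i]] for i in range(n)]
        held_out += [[s] for s in cases[n:] + controls[n:]]
    folds = [
        ([s for s in all_ids if s not in set(h)], h) for h in held_out
    ]
    votes, scores = _run_folds(
        cohort,
        folds,
        methods,
        seed,
        hyperparams,
        fixed_features=per_method_features,
    )
    config = {
        "seed": seed,
        "methods": list(methods),
        "n_folds": len(folds),
        "fixed_features": {
            m: list(per_method_features[m].feature_ids) for m in methods
        },
    }
    return CVResult(
        vote_table=aggregate_votes(votes),
        scores=scores,
        fold_features=(),
        config=config,
    )


def method_accuracies(result: CVResult, cohort: PairedCohort) -> pd.Series:
    """Held-out accuracy of each method against the true event labels."""
    truth = pd.Series(
        {r.sample_id: r.event for r in cohort.clinical}, name="event"
    ).reindex(result.vote_table.per_method.index)
    acc = (result.vote_table.per_method.eq(truth, axis=0)).mean(axis=0)
    acc.name = "accuracy"
    return acc


def majority_vote_accuracy(result: CVResult, cohort: PairedCohort) -> float:
    """Accuracy of the majority prediction (votes > half the methods)."""
    n_methods = result.vote_table.per_method.shape[1]
    pred = (result.vote_table.votes >= (n_methods // 2 + 1)).astype(int)
    truth = pd.Series({r.sample_id: r.event for r in cohort.clinical}).reindex(
        pred.index
    )
    return float((pred == truth).mean())


def _check_methods(methods: Sequence[str]) -> tuple[str, ...]:
    unknown = [m for m in methods if m not in METHOD_NAMES]
    if unknown:
        raise ValueError(f"unknown method(s): {unknown}")
    if not methods:
        raise ValueError("need at least one method")
    return tuple(m for m in METHOD_NAMES if m in set(methods))
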