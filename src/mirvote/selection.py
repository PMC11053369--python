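"""Paired differential expression and FDR-based feature selection.

Each cross-validation fold selects its own feature set from the training
pairs only: a two-sided paired t-test per miRNA on case-minus-control
differences, Benjamini-Hochberg adjustment, and selection at q < 0.05. When
no feature clears the FDR threshold (as happens on sparsely overlapping
external platforms) the fold falls back to the top-k smallest-p features so
cross-validation never aborts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import PairedCohort


@dataclass(frozen=True)
class DETable:
    """Per-feature paired test results: mean difference, t, p, BH q."""

    table: pd.DataFrame  # index feature_id; mean_diff, t_stat, p_value, q_value, zero_variance

    def __post_init__(self) -> None:
        required = {"mean_diff", "t_stat", "p_value", "q_value"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"DETable missing columns: {sorted(missing)}")
        q = self.table["q_value"].to_numpy()
        p = self.table["p_value"].to_numpy()
        if ((q < 0) | (q > 1)).any():
            raise ValueError("q-values must lie in [0, 1]")
        if (q + 1e-12 < p).any():
            raise ValueError("q-values cannot be smaller than p-values")

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "feature_id"
        out.to_csv(path, sep="\t", float_format="%.10g")


@dataclass(frozen=True)
class FeatureSet:
    """Ordered selected features and how they were chosen."""

    feature_ids: tuple[str, ...]
    selection_mode: str  # "fdr" | "fallback_topk"

    def __post_init__(self) -> None:
        if not self.feature_ids:
            raise ValueError("FeatureSet must be non-empty")
        if self.selection_mode not in ("fdr", "fallback_topk", "preselected"):
            raise ValueError(f"unknown selection mode {self.selection_mode!r}")

    def __len__(self) -> int:
        return len(self.feature_ids)


def paired_differential_expression(
    cohort: PairedCohort,
    pair_subset: Optional[Sequence[int]] = None,
) -> DETable:
    """Paired t-test per feature over the given pairs (default: all pairs).

    Differences are case minus control. A feature whose differences have zero
    variance is flagged and recorded with p = 1 rather than raising.
    """
    if cohort.pairs is None:
        raise ValueError("cohort has no pairing; run match_pairs first")
    pairs = cohort.pairs
    if pair_subset is not None:
        pairs = tuple(cohort.pairs[i] for i in pair_subset)
    n = len(pairs)
    if n < 3:
        raise ValueError(f"need at least 3 pairs for the paired test, got {n}")

    col = {s: j for j, s in enumerate(cohort.expression.sample_ids)}
    case_cols = [col[c] for c, _ in pairs]
    control_cols = [col[c] for _, c in pairs]
    diffs = (
        cohort.expression.values[:, case_cols]
        - cohort.expression.values[:, control_cols]
    )  # features x pairs

    mean_diff = diffs.mean(axis=1)
    sd = diffs.std(axis=1, ddof=1)
    zero_var = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = mean_diff / (sd / np.sqrt(n))
    t_stat = np.where(zero_var, 0.0, t_stat)
    p = 2.0 * stats.t.sf(np.abs(t_stat), df=n - 1)
    p = np.where(zero_var, 1.0, p)
    q = bh_adjust(p)

    table = pd.DataFrame(
        {
            "mean_diff": mean_diff,
            "t_stat": t_stat,
            "p_value": p,
            "q_value": q,
            "zero_variance": zero_var,
        },
        index=list(cohort.expression.feature_ids),
    )
    return DETable(table)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order.

    q_(i) = min over j >= i of p_(j) * m / j on the sorted p-values, clipped
    at 1 and mapped back to the original order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a non-empty 1-D sequence")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def select_features(
    de: DETable,
    fdr_threshold: float = 0.05,
    fallback_k: int = 10,
) -> FeatureSet:
    """Features with q < threshold ordered by ascending p; top-k fallback.

    If no feature clears the FDR threshold, returns the ``fallback_k``
    smallest-p features with selection_mode = "fallback_topk".
    """
    table = de.table.sort_values(["p_value", "q_value"], kind="stable")
    hits = table.index[table["q_value"] < fdr_threshold]
    if len(hits) > 0:
        return FeatureSet(tuple(hits), "fdr")
    k = min(fallback_k, len(table))
    return FeatureSet(tuple(table.index[:k]), "fallback_topk")
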