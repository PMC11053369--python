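"""Shared data model and file I/O.

The pipeline operates on matched case-control cohorts of lymph-node-negative
breast-cancer patients: a log-scale miRNA expression matrix (features x
samples), a clinical annotation table, and an explicit case/control pairing.
Expression values are assumed already normalized upstream; the package never
re-normalizes arrays, it only z-standardizes per training fold.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

#: Names of the seven voting methods, in fixed vote-table column order.
METHOD_NAMES = ("RSVM", "RF", "NB", "LSVM", "COX-RS", "KNN", "LR")

#: Cases are defined as regional/distant metastasis within 10 years.
CASE_HORIZON_MONTHS = 120.0

CLINICAL_COLUMNS = (
    "sample_id",
    "event",
    "time_months",
    "age_years",
    "tumor_size_mm",
    "er_status",
    "pr_status",
    "grade",
    "tumor_type",
    "year_of_surgery",
    "pair_id",
)


class FormatError(ValueError):
    """Malformed input file (duplicates, non-numeric cells, missing columns)."""


class ValidationError(ValueError):
    """Well-formed input violating a domain invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpressionMatrix:
    """Log-scale expression, features (miRNAs) x samples."""

    feature_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray  # shape (n_features, n_samples)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "feature_ids", tuple(self.feature_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        if len(set(self.feature_ids)) != len(self.feature_ids):
            dup = _first_duplicate(self.feature_ids)
            raise FormatError(f"duplicate feature id: {dup!r}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dup = _first_duplicate(self.sample_ids)
            raise FormatError(f"duplicate sample id: {dup!r}")
        if values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValidationError(
                f"values shape {values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if len(self.feature_ids) < 2 or len(self.sample_ids) < 4:
            raise ValidationError("need at least 2 features and 4 samples")
        if not np.all(np.isfinite(values)):
            raise ValidationError("expression values must all be finite")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.feature_ids), columns=list(self.sample_ids)
        )

    def subset_features(self, feature_ids: Sequence[str]) -> "ExpressionMatrix":
        index = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in feature_ids if f not in index]
        if missing:
            raise KeyError(f"features not in matrix: {missing[:5]}")
        rows = [index[f] for f in feature_ids]
        return ExpressionMatrix(tuple(feature_ids), self.sample_ids, self.values[rows])

    def sample_vector(self, sample_id: str) -> np.ndarray:
        try:
            j = self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample id: {sample_id!r}") from None
        return self.values[:, j]


@dataclass(frozen=True)
class ClinicalRecord:
    """One patient: outcome, follow-up and matching covariates.

    ``event`` is 1 for regional/distant metastasis within 10 years of
    diagnosis; ``time_months`` is time to metastasis for cases and follow-up
    time for recurrence-free controls.
    """

    sample_id: str
    event: int
    time_months: float
    age_years: float
    tumor_size_mm: float
    er_status: str  # pos / neg / na
    pr_status: str  # pos / neg / na
    grade: str  # 1 / 2 / 3 / na
    tumor_type: str
    year_of_surgery: int
    pair_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.event not in (0, 1):
            raise ValidationError(
                f"sample {self.sample_id!r}: event must be 0 or 1, got {self.event!r}"
            )
        if not self.time_months > 0:
            raise ValidationError(
                f"sample {self.sample_id!r}: time_months must be positive"
            )
        if self.event == 1 and self.time_months > CASE_HORIZON_MONTHS:
            raise ValidationError(
                f"sample {self.sample_id!r}: event=1 with time {self.time_months} "
                f"months violates the 10-year (120-month) case definition"
            )
        for name in ("er_status", "pr_status", "grade", "tumor_type"):
            object.__setattr__(self, name, str(getattr(self, name)).strip().lower())
        if self.er_status not in ("pos", "neg", "na"):
            raise ValidationError(
                f"sample {self.sample_id!r}: er_status must be pos/neg/na"
            )
        if self.pr_status not in ("pos", "neg", "na"):
            raise ValidationError(
                f"sample {self.sample_id!r}: pr_status must be pos/neg/na"
            )
        if self.grade not in ("1", "2", "3", "na"):
            raise ValidationError(f"sample {self.sample_id!r}: grade must be 1/2/3/na")


@dataclass(frozen=True)
class PairedCohort:
    """Expression + clinical + (optional) case-control pairing.

    When pairing is present every sample belongs to exactly one pair and each
    pair holds one case (event=1) and one control (event=0).
    """

    expression: ExpressionMatrix
    clinical: tuple[ClinicalRecord, ...]
    pairs: Optional[tuple[tuple[str, str], ...]] = None  # (case_id, control_id)

    def __post_init__(self) -> None:
        object.__setattr__(self, "clinical", tuple(self.clinical))
        clin_ids = [r.sample_id for r in self.clinical]
        if len(set(clin_ids)) != len(clin_ids):
            raise ValidationError(
                f"duplicate sample in clinical table: {_first_duplicate(clin_ids)!r}"
            )
        if set(clin_ids) != set(self.expression.sample_ids):
            only_expr = set(self.expression.sample_ids) - set(clin_ids)
            only_clin = set(clin_ids) - set(self.expression.sample_ids)
            raise ValidationError(
                "expression and clinical sample ids differ "
                f"(expression-only: {sorted(only_expr)[:5]}, "
                f"clinical-only: {sorted(only_clin)[:5]})"
            )
        if self.pairs is not None:
            pairs = tuple((str(a), str(b)) for a, b in self.pairs)
            object.__setattr__(self, "pairs", pairs)
            by_id = self.clinical_by_id()
            seen: set[str] = set()
            for case_id, control_id in pairs:
                for sid in (case_id, control_id):
                    if sid not in by_id:
                        raise ValidationError(f"pair references unknown sample {sid!r}")
                    if sid in seen:
                        raise ValidationError(
                            f"sample {sid!r} appears in more than one pair"
                        )
                    seen.add(sid)
                if by_id[case_id].event != 1 or by_id[control_id].event != 0:
                    raise ValidationError(
                        f"pair ({case_id!r}, {control_id!r}) must hold exactly one "
                        "case (event=1, first) and one control (event=0, second)"
                    )
            if seen != set(clin_ids):
                missing = sorted(set(clin_ids) - seen)
                raise ValidationError(
                    f"samples not covered by any pair: {missing[:5]}"
                )

    def clinical_by_id(self) -> dict[str, ClinicalRecord]:
        return {r.sample_id: r for r in self.clinical}

    @property
    def n_pairs(self) -> int:
        return 0 if self.pairs is None else len(self.pairs)

    def clinical_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.clinical]).set_index("sample_id")


@dataclass(frozen=True)
class VoteTable:
    """Per-sample binary votes of each method plus their sum (0..n_methods)."""

    per_method: pd.DataFrame  # index sample_id, one 0/1 column per method

    def __post_init__(self) -> None:
        unknown = [c for c in self.per_method.columns if c not in METHOD_NAMES]
        if unknown:
            raise ValidationError(f"unknown method columns: {unknown}")
        if self.per_method.isna().any().any():
            bad = self.per_method.columns[self.per_method.isna().any()][0]
            sid = self.per_method.index[self.per_method[bad].isna()][0]
            raise ValidationError(f"sample {sid!r} is missing a vote for {bad!r}")
        vals = self.per_method.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValidationError("per-method votes must be 0 or 1")
        # canonical column order and index name
        ordered = [m for m in METHOD_NAMES if m in self.per_method.columns]
        df = self.per_method[ordered].astype(int).rename_axis("sample_id")
        object.__setattr__(self, "per_method", df)

    @property
    def votes(self) -> pd.Series:
        s = self.per_method.sum(axis=1)
        s.name = "votes"
        return s

    @property
    def methods(self) -> tuple[str, ...]:
        return tuple(self.per_method.columns)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.per_method.index)


@dataclass(frozen=True)
class RiskGroups:
    """ultralow / low / high labels from vote counts under a cutoff rule.

    ``low`` in reports means "low but not ultralow"; as vote sets the
    ultralow cutoff is a subset of the low cutoff.
    """

    labels: pd.Series  # sample_id -> ultralow | low | high
    ultralow_votes: frozenset[int]
    low_votes: frozenset[int]
    mode: str  # fixed | auto

    def __post_init__(self) -> None:
        if not self.ultralow_votes <= self.low_votes:
            raise ValidationError("ultralow vote set must be a subset of low")
        bad = set(self.labels.unique()) - {"ultralow", "low", "high"}
        if bad:
            raise ValidationError(f"invalid risk labels: {sorted(bad)}")


# ---------------------------------------------------------------------------
# I/O operations
# ---------------------------------------------------------------------------


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a tab-separated expression file (header: feature_id + sample ids)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.columns[0] != "feature_id":
        raise FormatError(
            f"{path.name}: first header column must be 'feature_id', "
            f"got {df.columns[0]!r}"
        )
    feature_ids = df["feature_id"].tolist()
    dup = _first_duplicate(feature_ids)
    if dup is not None:
        raise FormatError(f"{path.name}: duplicate feature id {dup!r}")
    sample_ids = df.columns[1:].tolist()
    raw = df.iloc[:, 1:]
    values = raw.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise FormatError(
            f"{path.name}: non-numeric value {raw.iat[i, j]!r} at feature "
            f"{feature_ids[i]!r}, sample {sample_ids[j]!r}"
        )
    return ExpressionMatrix(tuple(feature_ids), tuple(sample_ids), values)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = matrix.to_frame()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_clinical(path: str | Path) -> list[ClinicalRecord]:
    """Read the clinical CSV; see CLINICAL_COLUMNS for the required header."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CLINICAL_COLUMNS if c != "pair_id" and c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing mandatory column(s) {missing}")
    records = []
    for _, row in df.iterrows():
        pair_id = row.get("pair_id", "")
        records.append(
            ClinicalRecord(
                sample_id=row["sample_id"],
                event=int(row["event"]),
                time_months=float(row["time_months"]),
                age_years=float(row["age_years"]),
                tumor_size_mm=float(row["tumor_size_mm"]),
                er_status=row["er_status"],
                pr_status=row["pr_status"],
                grade=row["grade"],
                tumor_type=row["tumor_type"],
                year_of_surgery=int(row["year_of_surgery"]),
                pair_id=pair_id if pair_id not in ("", "na") else None,
            )
        )
    return records


def write_clinical(records: Iterable[ClinicalRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        d = dict(vars(r))
        d["pair_id"] = d["pair_id"] if d["pair_id"] is not None else ""
        rows.append(d)
    pd.DataFrame(rows, columns=list(CLINICAL_COLUMNS)).to_csv(path, index=False)


def read_votes(path: str | Path) -> tuple[VoteTable, Optional[pd.Series]]:
    """Read a vote TSV; returns the table and risk-group labels if present."""
    df = pd.read_csv(path, sep="\t").set_index("sample_id")
    methods = [m for m in METHOD_NAMES if m in df.columns]
    table = VoteTable(df[methods])
    groups = df["risk_group"] if "risk_group" in df.columns else None
    return table, groups


def write_votes(
    table: VoteTable,
    path: str | Path,
    risk_groups: Optional[RiskGroups] = None,
) -> None:
    df = table.per_method.copy()
    df["votes"] = table.votes
    if risk_groups is not None:
        df["risk_group"] = risk_groups.labels.reindex(df.index)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def assemble_cohort(
    expression: ExpressionMatrix,
    clinical: Sequence[ClinicalRecord],
    pairs: Optional[Sequence[tuple[str, str]]] = None,
) -> PairedCohort:
    """Join expression, clinical records and an optional pairing into a cohort.

    Clinical records are sorted into expression column order, so the result
    is independent of clinical row order. Without ``pairs`` the cohort is
    unpaired and pair-based cross-validation will be refused downstream.
    """
    by_id = {r.sample_id: r for r in clinical}
    if len(by_id) != len(clinical):
        raise ValidationError("duplicate sample ids in clinical records")
    missing = [s for s in expression.sample_ids if s not in by_id]
    if missing:
        raise ValidationError(
            f"samples in expression but not clinical: {missing[:5]}"
        )
    extra = [s for s in by_id if s not in expression.sample_ids]
    if extra:
        raise ValidationError(f"samples in clinical but not expression: {extra[:5]}")
    ordered = tuple(by_id[s] for s in expression.sample_ids)
    return PairedCohort(
        expression=expression,
        clinical=ordered,
        pairs=tuple(pairs) if pairs is not None else None,
    )


def pairs_from_clinical(clinical: Sequence[ClinicalRecord]) -> list[tuple[str, str]]:
    """Recover (case, control) pairs from shared pair_id annotations."""
    groups: dict[str, list[ClinicalRecord]] = {}
    for r in clinical:
        if r.pair_id is not None:
            groups.setdefault(r.pair_id, []).append(r)
    pairs = []
    for pid in sorted(groups):
        members = groups[pid]
        if len(members) != 2:
            raise ValidationError(f"pair {pid!r} has {len(members)} members, need 2")
        cases = [r for r in members if r.event == 1]
        controls = [r for r in members if r.event == 0]
        if len(cases) != 1 or len(controls) != 1:
            raise ValidationError(
                f"pair {pid!r} must hold one case and one control"
            )
        pairs.append((cases[0].sample_id, controls[0].sample_id))
    return pairs


def _first_duplicate(items: Sequence[str]) -> Optional[str]:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None
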