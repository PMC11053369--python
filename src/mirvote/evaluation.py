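"""Evaluation statistics: classification metrics, one-tailed Fisher tests,
Kaplan-Meier curves, Cox hazard ratios, and the logistic independence check.

The Fisher test asks whether recurrence-free patients are enriched in a risk
group beyond chance, with all 2x2 margins fixed (upper hypergeometric tail).
The independence check is a multivariable logistic regression of risk-group
membership on the classical clinical markers (ER status, age, tumor size,
grade) plus outcome: a classifier worth deploying must not simply re-encode
the markers patients are already stratified by.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats

from .core import ClinicalRecord, RiskGroups
from .cv import CVResult


@dataclass(frozen=True)
class ConfusionMetrics:
    """2x2 classification counts and rates; case = recurrence."""

    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    @property
    def binomial_p(self) -> float:
        """One-sided exact binomial test of accuracy against chance (0.5)."""
        correct = self.tp + self.tn
        return float(
            stats.binomtest(correct, self.n, 0.5, alternative="greater").pvalue
        )


@dataclass(frozen=True)
class SurvivalSummary:
    """Per-group KM estimates plus the high-vs-rest hazard ratio."""

    km: dict[str, pd.DataFrame]  # group -> columns time, survival, at_risk
    hazard_ratio: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    p_value: Optional[float]
    monotone_likelihood: bool = False


def confusion_metrics(
    predictions: Sequence[int], truth: Sequence[int]
) -> ConfusionMetrics:
    """Counts and rates of binary recurrence predictions against outcomes."""
    pred = np.asarray(predictions, dtype=int)
    y = np.asarray(truth, dtype=int)
    if pred.size == 0 or pred.shape != y.shape:
        raise ValueError("predictions and truth must be non-empty and aligned")
    return ConfusionMetrics(
        tp=int(np.sum((pred == 1) & (y == 1))),
        fn=int(np.sum((pred == 0) & (y == 1))),
        tn=int(np.sum((pred == 0) & (y == 0))),
        fp=int(np.sum((pred == 1) & (y == 0))),
    )


def fisher_exact_one_tailed(a: int, b: int, c: int, d: int) -> float:
    """Upper-tail Fisher's exact p for the 2x2 table [[a, b], [c, d]].

    Layout: a = recurrence-free patients inside the risk group, b = recurrent
    patients inside it, c/d the remainder. Returns the hypergeometric
    probability of observing at least ``a`` recurrence-free patients in the
    group with all margins fixed.
    """
    for name, v in zip("abcd", (a, b, c, d)):
        if v < 0 or int(v) != v:
            raise ValueError(f"count {name} must be a nonnegative integer, got {v}")
    return float(
        stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1]
    )


def km_curve(
    time_months: Sequence[float],
    events: Sequence[int],
    groups: Sequence[str],
) -> dict[str, pd.DataFrame]:
    """Product-limit survival estimates per group.

    Returns, per group, a frame with the step times (event times only),
    the survival estimate and the at-risk count just before each step.
    """
    t = np.asarray(time_months, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(groups)
    if not (t > 0).all():
        raise ValueError("times must be positive")
    out: dict[str, pd.DataFrame] = {}
    for name in pd.unique(g):
        mask = g == name
        if mask.sum() == 0:
            warnings.warn(f"group {name!r} has no samples; omitted")
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(t[mask], e[mask])
        event_times = np.unique(t[mask][e[mask] == 1])
        surv = kmf.survival_function_at_times(event_times).to_numpy()
        at_risk = np.array([(t[mask] >= et).sum() for et in event_times])
        out[str(name)] = pd.DataFrame(
            {"time": event_times, "survival": surv, "at_risk": at_risk}
        )
    return out


def cox_hazard_ratio(
    time_months: Sequence[float],
    events: Sequence[int],
    group_indicator: Sequence[int],
) -> tuple[Optional[float], Optional[float], Optional[float], Optional[float], bool]:
    """Hazard ratio for a single binary covariate.

    Returns (HR, CI_low, CI_high, p, monotone_likelihood). When every event
    falls in one group the partial likelihood is monotone and no finite HR
    exists; the result is flagged and the HR/CI reported as unbounded (None).
    """
    t = np.asarray(time_months, dtype=float)
    e = np.asarray(events, dtype=int)
    x = np.asarray(group_indicator, dtype=int)
    if e.sum() == 0:
        raise ValueError("no events; hazard ratio undefined")
    if len(np.unique(x)) < 2:
        raise ValueError("both groups must be non-empty")
    # all events in a single group -> monotone likelihood, no finite MLE
    if len(np.unique(x[e == 1])) < 2:
        return None, None, None, None, True
    df = pd.DataFrame({"time": t, "event": e, "group": x})
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError:
        return None, None, None, None, True
    hr = float(np.exp(cph.params_.iloc[0]))
    ci = cph.confidence_intervals_
    ci_low = float(np.exp(ci.iloc[0, 0]))
    ci_high = float(np.exp(ci.iloc[0, 1]))
    p = float(cph.summary["p"].iloc[0])
    return hr, ci_low, ci_high, p, False


def survival_summary(
    clinical: Sequence[ClinicalRecord],
    risk_groups: RiskGroups,
    low_group: bool = False,
) -> SurvivalSummary:
    """KM curves per risk group plus the high-vs-(ultra)low hazard ratio.

    With ``low_group`` False the contrast is everyone-else vs ultralow;
    True compares against the combined low group (low or ultralow votes).
    """
    labels = risk_groups.labels
    t = np.array([r.time_months for r in clinical])
    e = np.array([r.event for r in clinical])
    g = np.array([labels[r.sample_id] for r in clinical])
    km = km_curve(t, e, g)
    member = (
        np.isin(g, ("ultralow", "low")) if low_group else (g == "ultralow")
    )
    hr = cox_hazard_ratio(t, e, (~member).astype(int))
    return SurvivalSummary(
        km=km,
        hazard_ratio=hr[0],
        ci_low=hr[1],
        ci_high=hr[2],
        p_value=hr[3],
        monotone_likelihood=hr[4],
    )


# ---------------------------------------------------------------------------
# Logistic independence of votes from clinical markers
# ---------------------------------------------------------------------------

#: default dichotomizations of the clinical covariates
COVARIATE_CODING = {
    "er_status": lambda r: {"pos": 1.0, "neg": 0.0}.get(r.er_status, np.nan),
    "age": lambda r: float(r.age_years > 50),
    "tumor_size": lambda r: float(r.tumor_size_mm >= 20),
    "grade": lambda r: (
        np.nan if r.grade == "na" else float(int(r.grade) >= 2)
    ),
    "outcome": lambda r: float(r.event),
}


def logistic_independence(
    membership: Mapping[str, int],
    clinical: Sequence[ClinicalRecord],
    coding: Optional[Mapping] = None,
) -> pd.DataFrame:
    """Multivariable logistic regression of group membership on clinical markers.

    One fit; rows report per-covariate odds ratio, 95% CI and Wald p. A
    covariate that perfectly predicts membership (e.g. outcome for an
    ultralow group containing no recurrences) is excluded from the fit and
    its row reported as n/a rather than raising.
    """
    coding = coding or COVARIATE_CODING
    rows = []
    y = []
    for r in clinical:
        if r.sample_id not in membership:
            continue
        rows.append({name: fn(r) for name, fn in coding.items()})
        y.append(int(membership[r.sample_id]))
    X = pd.DataFrame(rows)
    y = np.asarray(y)
    if len(y) < 20:
        raise ValueError("need at least 20 samples for the independence model")
    keep = X.notna().all(axis=1).to_numpy()
    X, y = X[keep], y[keep]

    separated = [c for c in X.columns if _perfectly_separates(X[c].to_numpy(), y)]
    fit_cols = [c for c in X.columns if c not in separated]
    table_rows = {}
    if fit_cols:
        design = sm.add_constant(X[fit_cols].astype(float), has_constant="add")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.Logit(y, design).fit(disp=0, maxiter=200)
        params = model.params
        ci = model.conf_int()
        for c in fit_cols:
            table_rows[c] = {
                "odds_ratio": float(np.exp(params[c])),
                "ci_low": float(np.exp(ci.loc[c, 0])),
                "ci_high": float(np.exp(ci.loc[c, 1])),
                "p_value": float(model.pvalues[c]),
                "flag": "",
            }
    for c in separated:
        table_rows[c] = {
            "odds_ratio": np.nan,
            "ci_low": np.nan,
            "ci_high": np.nan,
            "p_value": np.nan,
            "flag": "n/a (perfect separation)",
        }
    out = pd.DataFrame.from_dict(table_rows, orient="index").loc[list(X.columns)]
    out.index.name = "covariate"
    return out


def _perfectly_separates(x: np.ndarray, y: np.ndarray) -> bool:
    """True when a binary covariate level occurs in only one membership class."""
    for level in np.unique(x):
        if len(np.unique(y[x == level])) < 2 and (x == level).sum() > 0:
            # one covariate level maps to a single class
            if len(np.unique(y)) == 2 and (
                set(np.unique(y[x == level])) != set(np.unique(y))
            ):
                return True
    return False


# ---------------------------------------------------------------------------
# Report bundle
# ---------------------------------------------------------------------------


def build_report(
    result: CVResult,
    risk_groups: RiskGroups,
    clinical: Sequence[ClinicalRecord],
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write metrics.tsv, fisher.tsv, km_<group>.tsv, independence.tsv and a
    plain-text summary; returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_id = {r.sample_id: r for r in clinical}
    sample_ids = list(result.vote_table.per_method.index)
    truth = np.array([by_id[s].event for s in sample_ids])

    paths: dict[str, Path] = {}

    # per-method confusion metrics
    metric_rows = []
    for m in result.vote_table.methods:
        cm = confusion_metrics(result.vote_table.per_method[m].to_numpy(), truth)
        metric_rows.append(
            {
                "method": m,
                "tp": cm.tp,
                "fn": cm.fn,
                "tn": cm.tn,
                "fp": cm.fp,
                "accuracy": cm.accuracy,
                "sensitivity": cm.sensitivity,
                "specificity": cm.specificity,
                "binomial_p": cm.binomial_p,
            }
        )
    metrics = pd.DataFrame(metric_rows)
    paths["metrics"] = out_dir / "metrics.tsv"
    metrics.to_csv(paths["metrics"], sep="\t", index=False, float_format="%.6g")

    # Fisher 2x2 per risk group: enrichment of recurrence-free patients
    labels = risk_groups.labels
    fisher_rows = []
    for group, in_group in (
        ("ultralow", labels == "ultralow"),
        ("low", labels.isin(["ultralow", "low"])),
    ):
        member = in_group.reindex(sample_ids).to_numpy()
        a = int(np.sum(member & (truth == 0)))
        b = int(np.sum(member & (truth == 1)))
        c = int(np.sum(~member & (truth == 0)))
        d = int(np.sum(~member & (truth == 1)))
        fisher_rows.append(
            {
                "group": group,
                "norec_in_group": a,
                "rec_in_group": b,
                "norec_rest": c,
                "rec_rest": d,
                "p_one_tailed": fisher_exact_one_tailed(a, b, c, d),
            }
        )
    fisher = pd.DataFrame(fisher_rows)
    paths["fisher"] = out_dir / "fisher.tsv"
    fisher.to_csv(paths["fisher"], sep="\t", index=False, float_format="%.6g")

    # KM data per risk group
    times = np.array([by_id[s].time_months for s in sample_ids])
    groups = labels.reindex(sample_ids).to_numpy()
    km = km_curve(times, truth, groups)
    for group, frame in km.items():
        p = out_dir / f"km_{group}.tsv"
        frame.to_csv(p, sep="\t", index=False, float_format="%.6g")
        paths[f"km_{group}"] = p

    # independence of membership from clinical markers (low group)
    membership = {
        s: int(labels[s] in ("ultralow", "low")) for s in sample_ids
    }
    try:
        indep = logistic_independence(membership, clinical)
    except ValueError:
        indep = pd.DataFrame()
    paths["independence"] = out_dir / "independence.tsv"
    indep.to_csv(paths["independence"], sep="\t", float_format="%.6g")

    counts = labels.reindex(sample_ids).value_counts()
    summary = [
        f"samples: {len(sample_ids)}",
        f"methods: {', '.join(result.vote_table.methods)}",
        f"risk-group mode: {risk_groups.mode} "
        f"(ultralow votes {sorted(risk_groups.ultralow_votes)}, "
        f"low votes {sorted(risk_groups.low_votes)})",
        "group sizes: "
        + ", ".join(f"{g}={int(counts.get(g, 0))}" for g in ("ultralow", "low", "high")),
        "fisher p (ultralow, low): "
        + ", ".join(f"{p:.3g}" for p in fisher["p_one_tailed"]),
    ]
    paths["summary"] = out_dir / "summary.txt"
    paths["summary"].write_text("\n".join(summary) + "\n")
    return paths
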