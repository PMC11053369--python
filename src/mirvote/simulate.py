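"""Synthetic matched case-control cohorts with planted differential miRNAs.

The generator emulates the study design the pipeline is built for: 80
case-control pairs of systemically untreated, lymph-node-negative patients,
pair-matched on clinical covariates, profiled on 1212 mature miRNAs.
A small set of "informative" miRNAs carries a planted case-minus-control
shift of ``effect_size`` (in noise-SD units) driven by a per-sample latent
risk score; everything else is exchangeable noise, equicorrelated with
parameter ``feature_correlation``.

Case event times are concentrated within the 10-year case horizon (mean
about 58.5 months); controls carry long censored follow-up (mean about
250 months) — matching the cohort shape the pipeline targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import (
    CASE_HORIZON_MONTHS,
    ClinicalRecord,
    ExpressionMatrix,
    PairedCohort,
)

# Covariate distributions loosely follow the primary cohort's strata:
# mostly >50-year-old patients, 4-50 mm tumors, ER mostly positive,
# predominantly invasive ductal carcinomas, surgery 1980-2003.
_TUMOR_TYPES = ("idc", "ilc", "mucinous", "papillary", "metaplasia")
_TUMOR_TYPE_P = (0.79, 0.11, 0.035, 0.03, 0.035)
_ER_LEVELS = ("pos", "neg", "na")
_ER_P = (0.64, 0.29, 0.07)
_PR_P = (0.55, 0.35, 0.10)
_GRADE_LEVELS = ("1", "2", "3", "na")
_GRADE_P = (0.17, 0.33, 0.29, 0.21)


@dataclass(frozen=True)
class SimParams:
    """Knobs of the paired-cohort generator (defaults = study-shaped cohort)."""

    n_pairs: int = 80
    n_features: int = 1212
    n_informative: int = 50
    effect_size: float = 1.0  # planted case-control shift, noise-SD units
    indolent_fraction: float = 0.5  # controls with extra-low latent score
    indolence_shift: float = 1.0  # extra shift, multiples of effect_size
    feature_correlation: float = 0.2  # equicorrelation of the noise
    latent_sd: float = 0.5  # SD of the latent score around its group mean
    case_time_mean: float = 58.5  # months, before truncation at 120
    case_time_sigma: float = 0.55  # log-normal shape of event times
    control_followup_mean: float = 250.35  # months
    control_followup_sd: float = 30.0
    control_followup_min: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_informative <= self.n_features:
            raise ValueError(
                f"n_informative ({self.n_informative}) must lie in "
                f"[0, n_features={self.n_features}]"
            )
        if self.effect_size < 0:
            raise ValueError("effect_size must be nonnegative")
        if not 0 <= self.feature_correlation < 1:
            raise ValueError("feature_correlation must be in [0, 1)")
        if not 0 <= self.indolent_fraction <= 1:
            raise ValueError("indolent_fraction must be in [0, 1]")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of a simulated cohort, for recovery tests."""

    informative_feature_ids: tuple[str, ...]
    latent_scores: dict[str, float]  # sample_id -> latent risk score
    indolent_controls: tuple[str, ...]
    pair_covariates: dict[str, dict]  # pair_id -> covariate vector


@dataclass(frozen=True)
class MatchSpec:
    """Covariate constraints a case-control pair must satisfy.

    ``exact_on`` covariates must be equal; ``caliper_on`` maps continuous
    covariates to the maximum allowed absolute difference.
    """

    exact_on: tuple[str, ...] = ("tumor_type", "er_status", "grade")
    caliper_on: dict[str, float] = field(
        default_factory=lambda: {
            "age_years": 10.0,
            "tumor_size_mm": 10.0,
            "year_of_surgery": 5.0,
        }
    )

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.caliper_on.values()):
            raise ValueError("calipers must be positive")


def simulate_cohort(params: SimParams) -> tuple[PairedCohort, SimTruth]:
    """Draw a paired cohort and its ground truth; identical seed, identical output.

    Latent scores: cases get mean +delta/2 and controls -delta/2 where
    delta = effect_size; an ``indolent_fraction`` of controls is shifted
    further down by ``indolence_shift * delta``, giving the control
    population the graded structure that spreads votes over 0..7 instead of
    a binary split. Every shift scales with delta, so delta=0 yields a fully
    exchangeable null. Informative feature values are latent score plus
    equicorrelated noise of unit SD; other features are pure noise. The
    overall planted case-minus-control mean difference is therefore
    delta * (1 + indolent_fraction * indolence_shift).
    """
    rng = np.random.default_rng(params.seed)
    n_pairs, n_feat = params.n_pairs, params.n_features
    n_samples = 2 * n_pairs
    delta = params.effect_size

    feature_ids = tuple(f"mir-{i + 1:04d}" for i in range(n_feat))
    informative_idx = rng.choice(n_feat, size=params.n_informative, replace=False)
    informative_idx = np.sort(informative_idx)

    case_ids = tuple(f"CASE{i + 1:03d}" for i in range(n_pairs))
    control_ids = tuple(f"CTRL{i + 1:03d}" for i in range(n_pairs))
    sample_ids = case_ids + control_ids

    # latent risk scores
    f = params.indolent_fraction
    n_indolent = int(round(f * n_pairs))
    indolent = np.zeros(n_pairs, dtype=bool)
    if n_indolent:
        indolent[rng.choice(n_pairs, size=n_indolent, replace=False)] = True
    case_mean = np.full(n_pairs, delta / 2.0)
    # indolent controls sit further below the control mean; the shift scales
    # with delta so the delta=0 null stays exchangeable
    control_mean = -delta / 2.0 - np.where(
        indolent, params.indolence_shift * delta, 0.0
    )
    scores = np.concatenate(
        [
            case_mean + params.latent_sd * rng.standard_normal(n_pairs),
            control_mean + params.latent_sd * rng.standard_normal(n_pairs),
        ]
    )

    # equicorrelated noise of unit variance: shared per-sample factor + iid
    rho = params.feature_correlation
    shared = rng.standard_normal(n_samples)
    eps = math.sqrt(rho) * shared[None, :] + math.sqrt(1 - rho) * rng.standard_normal(
        (n_feat, n_samples)
    )
    values = eps
    values[informative_idx, :] += scores[None, :]

    pair_ids = tuple(f"P{i + 1:03d}" for i in range(n_pairs))
    pair_covariates: dict[str, dict] = {}
    case_times = _case_event_times(rng, params, n_pairs)
    control_times = _control_followup_times(rng, params, n_pairs)
    case_records, control_records = [], []
    for i in range(n_pairs):
        cov = _draw_pair_covariates(rng)
        pair_covariates[pair_ids[i]] = cov
        case_records.append(
            ClinicalRecord(
                sample_id=case_ids[i],
                event=1,
                time_months=case_times[i],
                pair_id=pair_ids[i],
                **cov,
            )
        )
        control_records.append(
            ClinicalRecord(
                sample_id=control_ids[i],
                event=0,
                time_months=control_times[i],
                pair_id=pair_ids[i],
                **cov,
            )
        )
    # clinical in expression column order (all cases, then all controls)
    clinical = case_records + control_records

    expression = ExpressionMatrix(feature_ids, sample_ids, values)
    pairs = tuple(zip(case_ids, control_ids))
    cohort = PairedCohort(expression=expression, clinical=tuple(clinical), pairs=pairs)
    truth = SimTruth(
        informative_feature_ids=tuple(feature_ids[i] for i in informative_idx),
        latent_scores=dict(zip(sample_ids, scores.tolist())),
        indolent_controls=tuple(
            control_ids[i] for i in range(n_pairs) if indolent[i]
        ),
        pair_covariates=pair_covariates,
    )
    return cohort, truth


def _case_event_times(
    rng: np.random.Generator, params: SimParams, n: int
) -> np.ndarray:
    """Log-normal event times resampled to stay within the 120-month horizon."""
    sigma = params.case_time_sigma
    mu = math.log(params.case_time_mean) - sigma**2 / 2.0
    times = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.lognormal(mu, sigma, size=2 * (n - filled))
        ok = draw[(draw <= CASE_HORIZON_MONTHS) & (draw > 0)]
        take = min(len(ok), n - filled)
        times[filled : filled + take] = ok[:take]
        filled += take
    return np.round(times, 1)


def _control_followup_times(
    rng: np.random.Generator, params: SimParams, n: int
) -> np.ndarray:
    times = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(params.control_followup_mean, params.control_followup_sd, 2 * (n - filled))
        ok = draw[draw >= params.control_followup_min]
        take = min(len(ok), n - filled)
        times[filled : filled + take] = ok[:take]
        filled += take
    return np.round(times, 1)


def _draw_pair_covariates(rng: np.random.Generator) -> dict:
    age = float(np.clip(round(rng.normal(61.0, 10.0)), 33, 88))
    size = float(np.clip(round(rng.normal(22.0, 9.0)), 4, 50))
    return {
        "age_years": age,
        "tumor_size_mm": size,
        "er_status": str(rng.choice(_ER_LEVELS, p=_ER_P)),
        "pr_status": str(rng.choice(_ER_LEVELS, p=_PR_P)),
        "grade": str(rng.choice(_GRADE_LEVELS, p=_GRADE_P)),
        "tumor_type": str(rng.choice(_TUMOR_TYPES, p=_TUMOR_TYPE_P)),
        "year_of_surgery": int(rng.integers(1980, 2004)),
    }


# ---------------------------------------------------------------------------
# Pair matching
# ---------------------------------------------------------------------------


def match_pairs(
    clinical: Sequence[ClinicalRecord],
    spec: Optional[MatchSpec] = None,
) -> tuple[list[tuple[str, str]], list[str]]:
    """Greedy nearest-neighbor matching of cases to controls.

    Cases are processed in input order. Each case is matched to the eligible
    control (equal on ``exact_on`` covariates, within every caliper) that
    minimizes the sum of caliper-normalized absolute differences; ties break
    by control input order; each control is used at most once. Returns the
    pairing and the ids left unmatched.
    """
    spec = spec or MatchSpec()
    cases = [r for r in clinical if r.event == 1]
    controls = [r for r in clinical if r.event == 0]
    if not cases or not controls:
        raise ValueError("need at least one case and one control to match")

    used: set[str] = set()
    pairing: list[tuple[str, str]] = []
    for case in cases:
        best: Optional[ClinicalRecord] = None
        best_dist = math.inf
        for control in controls:
            if control.sample_id in used:
                continue
            if any(
                getattr(case, c) != getattr(control, c) for c in spec.exact_on
            ):
                continue
            dist = 0.0
            ok = True
            for cov, caliper in spec.caliper_on.items():
                diff = abs(float(getattr(case, cov)) - float(getattr(control, cov)))
                if diff > caliper:
                    ok = False
                    break
                dist += diff / caliper
            if ok and dist < best_dist:  # strict: ties keep earlier control
                best, best_dist = control, dist
        if best is not None:
            used.add(best.sample_id)
            pairing.append((case.sample_id, best.sample_id))

    matched = {s for pair in pairing for s in pair}
    unmatched = [r.sample_id for r in clinical if r.sample_id not in matched]
    return pairing, unmatched
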