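import numpy as np
import pytest

from mirvote import (
    ClinicalRecord,
    ExpressionMatrix,
    PairedCohort,
    SimParams,
    assemble_cohort,
    simulate_cohort,
)


def make_record(sample_id, event, time_months=100.0, **overrides):
    """ClinicalRecord with sensible defaults for covariates not under test."""
    fields = dict(
        sample_id=sample_id,
        event=event,
        time_months=time_months,
        age_years=60.0,
        tumor_size_mm=20.0,
        er_status="pos",
        pr_status="neg",
        grade="2",
        tumor_type="idc",
        year_of_surgery=1995,
        pair_id=None,
    )
    fields.update(overrides)
    return ClinicalRecord(**fields)


def make_paired_cohort(case_values, control_values, feature_ids=None, seed=0):
    """Cohort from explicit per-pair expression (features x pairs arrays)."""
    case_values = np.asarray(case_values, dtype=float)
    control_values = np.asarray(control_values, dtype=float)
    n_feat, n_pairs = case_values.shape
    feature_ids = feature_ids or tuple(f"f{i}" for i in range(n_feat))
    case_ids = [f"CASE{i}" for i in range(n_pairs)]
    control_ids = [f"CTRL{i}" for i in range(n_pairs)]
    values = np.concatenate([case_values, control_values], axis=1)
    expr = ExpressionMatrix(tuple(feature_ids), tuple(case_ids + control_ids), values)
    rng = np.random.default_rng(seed)
    clinical = []
    for i in range(n_pairs):
        clinical.append(
            make_record(case_ids[i], 1, time_months=float(rng.uniform(10, 115)),
                        pair_id=f"P{i}")
        )
        clinical.append(
            make_record(control_ids[i], 0, time_months=float(rng.uniform(150, 320)),
                        pair_id=f"P{i}")
        )
    pairs = list(zip(case_ids, control_ids))
    return assemble_cohort(expr, clinical, pairs)


@pytest.fixture(scope="session")
def separable_cohort():
    """10 pairs x 60 features, strong planted signal: every method should win."""
    cohort, truth = simulate_cohort(
        SimParams(n_pairs=10, n_features=60, n_informative=15, effect_size=3.0, seed=7)
    )
    return cohort, truth


@pytest.fixture(scope="session")
def signal_cohort():
    """Moderate signal at the shape used for recovery-style checks."""
    cohort, truth = simulate_cohort(
        SimParams(n_pairs=20, n_features=150, n_informative=25, effect_size=2.0, seed=13)
    )
    return cohort, truth
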