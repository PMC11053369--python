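"""Cross-validation bookkeeping, the leakage ban, risk-group cutoffs and
external-cohort transfer."""

import numpy as np
import pandas as pd
import pytest

from mirvote import (
    METHOD_NAMES,
    ExpressionMatrix,
    SimParams,
    aggregate_votes,
    assemble_cohort,
    assign_risk_groups,
    external_validation,
    fisher_exact_one_tailed,
    harmonize_features,
    leave_one_pair_out_cv,
    method_accuracies,
    paired_differential_expression,
    preselect_method_features,
    select_features,
    simulate_cohort,
)
from mirvote.selection import FeatureSet

from conftest import make_paired_cohort, make_record


def subset_pairs(cohort, pair_indices, drop_pairing=False):
    """Sub-cohort containing only the given pairs."""
    keep_pairs = [cohort.pairs[i] for i in pair_indices]
    keep_ids = [s for p in keep_pairs for s in p]
    expr = cohort.expression
    cols = [expr.sample_ids.index(s) for s in keep_ids]
    sub_expr = ExpressionMatrix(expr.feature_ids, tuple(keep_ids),
                                expr.values[:, cols])
    clin = [r for r in cohort.clinical if r.sample_id in set(keep_ids)]
    return assemble_cohort(sub_expr, clin,
                           None if drop_pairing else keep_pairs)


class TestLeaveOnePairOut:
    def test_four_pairs_one_method_bookkeeping(self):
        rng = np.random.default_rng(0)
        cohort = make_paired_cohort(rng.standard_normal((8, 4)),
                                    rng.standard_normal((8, 4)))
        result = leave_one_pair_out_cv(cohort, methods=["NB"], seed=1)
        assert result.n_folds == 4
        assert len(result.fold_features) == 4
        votes = result.vote_table.per_method["NB"]
        assert len(votes) == 8  # every sample voted exactly once
        assert votes.isin([0, 1]).all()

    def test_unpaired_cohort_refused(self):
        rng = np.random.default_rng(1)
        expr = ExpressionMatrix(
            ("a", "b"), ("S1", "S2", "S3", "S4"), rng.standard_normal((2, 4))
        )
        clinical = [make_record(f"S{i}", i % 2, 100.0 if i % 2 else 300.0)
                    for i in range(1, 5)]
        cohort = assemble_cohort(expr, clinical, pairs=None)
        with pytest.raises(ValueError, match="pairing"):
            leave_one_pair_out_cv(cohort)

    def test_held_out_pair_cannot_steer_its_feature_set(self):
        """Corrupting the held-out pair's expression must leave that fold's
        selected features untouched: per-fold selection sees training pairs
        only."""
        cohort, _ = simulate_cohort(
            SimParams(n_pairs=8, n_features=50, n_informative=10,
                      effect_size=1.5, seed=3)
        )
        fold = 0
        train_pairs = [i for i in range(cohort.n_pairs) if i != fold]
        de = paired_differential_expression(cohort, pair_subset=train_pairs)
        fs_before = select_features(de)

        case_id, ctrl_id = cohort.pairs[fold]
        vals = cohort.expression.values.copy()
        cols = [cohort.expression.sample_ids.index(s) for s in (case_id, ctrl_id)]
        rng = np.random.default_rng(99)
        vals[:, cols] = rng.standard_normal((vals.shape[0], 2)) * 50
        corrupted = assemble_cohort(
            ExpressionMatrix(cohort.expression.feature_ids,
                             cohort.expression.sample_ids, vals),
            cohort.clinical,
            cohort.pairs,
        )
        de2 = paired_differential_expression(corrupted, pair_subset=train_pairs)
        fs_after = select_features(de2)
        assert fs_before.feature_ids == fs_after.feature_ids

    def test_strong_signal_all_methods_accurate(self, separable_cohort):
        cohort, _ = separable_cohort
        result = leave_one_pair_out_cv(cohort, seed=5)
        acc = method_accuracies(result, cohort)
        assert (acc >= 0.9).all()

    def test_deterministic(self, separable_cohort):
        cohort, _ = separable_cohort
        a = leave_one_pair_out_cv(cohort, methods=["NB", "KNN"], seed=5)
        b = leave_one_pair_out_cv(cohort, methods=["NB", "KNN"], seed=5)
        pd.testing.assert_frame_equal(a.vote_table.per_method,
                                      b.vote_table.per_method)
        pd.testing.assert_frame_equal(a.scores, b.scores)


class TestAggregateVotes:
    def test_sum_and_extremes(self):
        df = pd.DataFrame(
            [[1, 1, 0, 0, 0, 0, 0], [0] * 7, [1] * 7],
            index=["s1", "s2", "s3"],
            columns=list(METHOD_NAMES),
        )
        table = aggregate_votes(df)
        assert table.votes.tolist() == [2, 0, 7]

    def test_missing_vote_names_sample_and_method(self):
        df = pd.DataFrame(
            [[1, 1, 0, 0, 0, 0, 0], [0, 1, 0, 0, np.nan, 0, 0]],
            index=["s1", "s2"],
            columns=list(METHOD_NAMES),
        )
        with pytest.raises(Exception, match="s2.*COX-RS"):
            aggregate_votes(df)


class TestAssignRiskGroups:
    def _table(self, votes_per_sample):
        rows = [[1] * v + [0] * (7 - v) for v in votes_per_sample]
        df = pd.DataFrame(rows, columns=list(METHOD_NAMES),
                          index=[f"s{i}" for i in range(len(rows))])
        return aggregate_votes(df)

    def test_fixed_cutoffs(self):
        groups = assign_risk_groups(self._table([0, 1, 2, 5, 7, 0]), "fixed")
        assert groups.ultralow_votes == {0}
        assert groups.low_votes == {0, 1}
        assert groups.labels.tolist() == [
            "ultralow", "low", "high", "high", "high", "ultralow"
        ]

    def test_auto_min_zero_matches_fixed(self):
        auto = assign_risk_groups(self._table([0, 1, 2, 4]), "auto")
        assert auto.ultralow_votes == {0}
        assert auto.low_votes == {0, 1}

    def test_auto_min_two_regime(self):
        groups = assign_risk_groups(self._table([2, 3, 4, 7, 2]), "auto")
        assert groups.ultralow_votes == {2}
        assert groups.low_votes == {2, 3}
        assert groups.labels.tolist() == [
            "ultralow", "low", "high", "high", "ultralow"
        ]

    def test_degenerate_single_vote_value(self):
        groups = assign_risk_groups(self._table([3, 3, 3]), "auto")
        assert (groups.labels == "ultralow").all()


class TestHarmonize:
    def _cohort_with_features(self, feature_ids, seed=0):
        rng = np.random.default_rng(seed)
        n = len(feature_ids)
        return make_paired_cohort(rng.standard_normal((n, 3)),
                                  rng.standard_normal((n, 3)),
                                  feature_ids=feature_ids, seed=seed)

    def test_intersection_in_reference_order(self):
        ref = self._cohort_with_features(("A", "B", "C"))
        ext = self._cohort_with_features(("D", "C", "B"))
        assert harmonize_features(ref, ext) == ("B", "C")

    def test_disjoint_panels_error(self):
        ref = self._cohort_with_features(("A", "B"))
        ext = self._cohort_with_features(("C", "D"))
        with pytest.raises(ValueError, match="share no features"):
            harmonize_features(ref, ext)


class TestPreselection:
    def test_single_k_grid_returns_top_p_features(self, signal_cohort):
        cohort, _ = signal_cohort
        shared = cohort.expression.feature_ids
        fs = preselect_method_features(cohort, "NB", shared, k_grid=(5,), seed=1)
        de = paired_differential_expression(cohort)
        expected = tuple(de.table.sort_values("p_value", kind="stable").index[:5])
        assert fs.feature_ids == expected

    def test_accuracy_tie_prefers_smaller_k(self, separable_cohort):
        # clearly separable data: both candidate sizes classify perfectly,
        # so the tie rule must keep the smaller set
        cohort, _ = separable_cohort
        shared = cohort.expression.feature_ids
        fs = preselect_method_features(cohort, "NB", shared, k_grid=(5, 10), seed=1)
        assert len(fs) == 5

    def test_oversized_k_clipped(self, signal_cohort):
        cohort, _ = signal_cohort
        shared = cohort.expression.feature_ids[:8]
        fs = preselect_method_features(cohort, "KNN", shared, k_grid=(50,), seed=1)
        assert len(fs) == 8

    def test_preselected_set_recovers_planted_features(self, signal_cohort):
        cohort, truth = signal_cohort
        shared = cohort.expression.feature_ids
        fs = preselect_method_features(cohort, "NB", shared, k_grid=(25,), seed=1)
        planted = set(truth.informative_feature_ids)
        assert len(planted & set(fs.feature_ids)) / len(fs) >= 0.8


@pytest.fixture(scope="module")
def split_cohorts():
    """One simulated study split into reference and external halves, so
    both halves share the same planted informative miRNAs."""
    full, truth = simulate_cohort(
        SimParams(n_pairs=30, n_features=80, n_informative=15,
                  effect_size=2.5, seed=50)
    )
    ref = subset_pairs(full, range(15))
    ext = subset_pairs(full, range(15, 30))
    return ref, ext, truth


class TestExternalValidation:
    def _fixed_sets(self, cohort, k=10, methods=METHOD_NAMES):
        de = paired_differential_expression(cohort)
        top = tuple(de.table.sort_values("p_value", kind="stable").index[:k])
        return {m: FeatureSet(top, "preselected") for m in methods}

    def test_transfer_enriches_ultralow_for_nonrecurrent(self, split_cohorts):
        ref, ext, _ = split_cohorts
        sets = self._fixed_sets(ref)
        result, groups = external_validation(ext, sets, seed=2, mode="auto")
        truth = {r.sample_id: r.event for r in ext.clinical}
        sids = list(result.vote_table.per_method.index)
        member = groups.labels.reindex(sids).eq("ultralow").to_numpy()
        y = np.array([truth[s] for s in sids])
        a = int((member & (y == 0)).sum())
        b = int((member & (y == 1)).sum())
        c = int((~member & (y == 0)).sum())
        d = int((~member & (y == 1)).sum())
        assert fisher_exact_one_tailed(a, b, c, d) < 0.05

    def test_unbalanced_unpaired_cohort_every_sample_voted_once(self, split_cohorts):
        ref, ext, _ = split_cohorts
        # drop the pairing and most cases: 5 cases vs 15 controls
        keep = [r.sample_id for r in ext.clinical if r.event == 0]
        keep += [r.sample_id for r in ext.clinical if r.event == 1][:5]
        expr = ext.expression
        cols = [expr.sample_ids.index(s) for s in keep]
        sub = ExpressionMatrix(expr.feature_ids, tuple(keep), expr.values[:, cols])
        clin = [make_record(r.sample_id, r.event, r.time_months)
                for r in ext.clinical if r.sample_id in set(keep)]
        unpaired = assemble_cohort(sub, clin, pairs=None)
        sets = self._fixed_sets(ref, k=8, methods=("NB", "KNN"))
        result, _ = external_validation(unpaired, sets,
                                        methods=["NB", "KNN"], seed=3)
        votes = result.vote_table.per_method
        assert sorted(votes.index) == sorted(keep)
        assert votes.notna().all().all()
        assert result.config["n_folds"] == 15  # 5 mixed folds + 10 singletons

    def test_deterministic_across_runs(self, split_cohorts):
        ref, ext, _ = split_cohorts
        sets = self._fixed_sets(ref, k=6, methods=("NB",))
        r1, g1 = external_validation(ext, sets, methods=["NB"], seed=4)
        r2, g2 = external_validation(ext, sets, methods=["NB"], seed=4)
        pd.testing.assert_frame_equal(r1.vote_table.per_method,
                                      r2.vote_table.per_method)
        assert (g1.labels == g2.labels).all()
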