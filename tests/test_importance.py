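import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats

import drugresc as dr
from drugresc.enrichment import D2CMatrix
from drugresc.importance import drug_score_from_counts


def make_d2c(scores, prefix="i"):
    scores = np.asarray(scores, dtype=float)
    instances = [f"{prefix}{k}" for k in range(scores.shape[0])]
    cells = [f"c{j}" for j in range(scores.shape[1])]
    return D2CMatrix(instances, cells, scores)


def make_labels(y):
    return dr.CellLabels([f"c{j}" for j in range(len(y))], np.asarray(y))


@pytest.fixture()
def separable():
    """40 cells, 5 instances; instance 0 separates the classes cleanly."""
    rng = np.random.default_rng(11)
    y = np.array([1] * 12 + [0] * 28)
    scores = rng.uniform(-0.5, 0.5, size=(5, 40))
    scores[0] = np.where(y == 1, 1.5, -1.5) + rng.normal(0, 0.1, 40)
    return make_d2c(np.clip(scores, -2, 2)), make_labels(y)


class TestDrugScoreArithmetic:
    def test_forced_vote_counts(self):
        assert drug_score_from_counts([10, 8], [6, 8]) == 2.0

    def test_zero_when_counts_match(self):
        assert drug_score_from_counts([7, 5, 9], [7, 5, 9]) == 0.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            drug_score_from_counts([1, 2], [1])


class TestFitForest:
    def test_bootstrap_bookkeeping(self, separable):
        d2c, labels = separable
        model = dr.fit_forest(d2c, labels, ntree=20, seed=0)
        assert len(model.trees) == 20
        n = len(d2c.cells)
        for boot, oob in zip(model.bootstrap_indices, model.oob_indices):
            assert oob.size > 0
            assert set(boot) | set(oob) == set(range(n))
            assert set(boot) & set(oob) == set()

    def test_seed_determinism(self, separable):
        d2c, labels = separable
        m1 = dr.fit_forest(d2c, labels, ntree=10, seed=5)
        m2 = dr.fit_forest(d2c, labels, ntree=10, seed=5)
        for b1, b2 in zip(m1.bootstrap_indices, m2.bootstrap_indices):
            np.testing.assert_array_equal(b1, b2)

    def test_single_class_errors(self):
        d2c = make_d2c(np.zeros((2, 10)))
        labels = make_labels(np.ones(10, dtype=int))
        with pytest.raises(ValueError, match="both phenotype classes"):
            dr.fit_forest(d2c, labels)

    def test_mtry_out_of_range(self, separable):
        d2c, labels = separable
        with pytest.raises(ValueError, match="outside"):
            dr.fit_forest(d2c, labels, mtry=6)


class TestSelectMtry:
    def test_single_grid_value(self, separable):
        d2c, labels = separable
        assert dr.select_mtry(d2c, labels, grid=[3], ntree=10) == 3

    def test_out_of_range_grid(self, separable):
        d2c, labels = separable
        with pytest.raises(ValueError, match="outside"):
            dr.select_mtry(d2c, labels, grid=[1, 6], ntree=10)

    def test_argmin_contract(self, separable):
        d2c, labels = separable
        grid = [1, 2, 5]
        chosen = dr.select_mtry(d2c, labels, grid=grid, ntree=20, seed=1)
        X, y = d2c.scores.T, labels.phenotype
        errs = {
            m: dr.fit_forest(d2c, labels, ntree=20, mtry=m, seed=1).oob_error(X, y)
            for m in grid
        }
        assert errs[chosen] == min(errs.values())


class TestOOBPermutationImportance:
    def test_constant_column_scores_exactly_zero(self, separable):
        d2c, labels = separable
        scores = d2c.scores.copy()
        scores[3] = 0.7  # constant instance
        d2c_const = make_d2c(scores)
        model = dr.fit_forest(d2c_const, labels, ntree=20, seed=2)
        table = dr.oob_permutation_importance(model, d2c_const, labels, seed=3)
        assert table.loc[table["instance_id"] == "i3", "raw_score"].item() == 0.0

    def test_discriminative_instance_ranked_first(self, separable):
        d2c, labels = separable
        model = dr.fit_forest(d2c, labels, ntree=50, seed=4)
        table = dr.oob_permutation_importance(model, d2c, labels, seed=5)
        top = table.loc[table["rank"] == 1, "instance_id"].item()
        assert top == "i0"
        assert table.loc[table["instance_id"] == "i0", "raw_score"].item() > 0

    def test_bit_reproducible_under_seed(self, separable):
        d2c, labels = separable

        def run():
            model = dr.fit_forest(d2c, labels, ntree=15, seed=6)
            return dr.oob_permutation_importance(model, d2c, labels, seed=7)

        pd.testing.assert_frame_equal(run(), run())

    def test_rate_normalization_bounded(self, separable):
        d2c, labels = separable
        model = dr.fit_forest(d2c, labels, ntree=15, seed=8)
        table = dr.oob_permutation_importance(
            model, d2c, labels, seed=9, normalize="rate"
        )
        assert table["raw_score"].abs().max() <= 1.0


class TestStandardize:
    def test_examples(self):
        np.testing.assert_allclose(dr.standardize([1, 3, 5]), [0, 0.5, 1])
        np.testing.assert_allclose(dr.standardize([0, 1]), [0, 1])

    def test_constant_warns_half(self):
        with pytest.warns(UserWarning, match="all raw scores equal"):
            out = dr.standardize([2, 2, 2])
        np.testing.assert_allclose(out, 0.5)

    def test_affine_invariance(self):
        rng = np.random.default_rng(12)
        s = rng.normal(size=20)
        np.testing.assert_allclose(
            dr.standardize(3.7 * s + 11.0), dr.standardize(s), atol=1e-12
        )


class TestWilcoxonImportance:
    def test_identical_groups_zero(self):
        col = np.tile(np.array([0.1, 0.2, 0.3, 0.4]), 2)
        d2c = make_d2c(col[None, :])
        labels = make_labels([1] * 4 + [0] * 4)
        table = dr.wilcoxon_importance(d2c, labels)
        assert table["raw_score"].item() == pytest.approx(0.0, abs=1e-9)

    def test_full_separation_minimal_p(self):
        scores = np.concatenate([np.linspace(1, 2, 10), np.linspace(-2, -1, 10)])
        d2c = make_d2c(scores[None, :] / 2)
        labels = make_labels([1] * 10 + [0] * 10)
        table = dr.wilcoxon_importance(d2c, labels)
        p_min = 2 / math.comb(20, 10)  # exact rank-sum enumeration, no ties
        assert table["raw_score"].item() == pytest.approx(-np.log10(p_min), rel=1e-6)

    def test_constant_column_zero(self):
        d2c = make_d2c(np.full((1, 12), 0.5))
        labels = make_labels([1] * 5 + [0] * 7)
        table = dr.wilcoxon_importance(d2c, labels)
        assert table["raw_score"].item() == 0.0


class TestAnovaImportance:
    def test_equal_groups_near_zero(self):
        rng = np.random.default_rng(13)
        base = rng.normal(0, 0.3, 30)
        d2c = make_d2c(np.concatenate([base, base])[None, :])
        labels = make_labels([1] * 30 + [0] * 30)
        table = dr.anova_importance(d2c, labels)
        assert table["raw_score"].item() == pytest.approx(0.0, abs=1e-9)

    def test_matches_t_squared(self):
        rng = np.random.default_rng(14)
        a = rng.normal(0.0, 0.2, 50)
        b = rng.normal(1.0, 0.2, 50)
        d2c = make_d2c(np.concatenate([a, b])[None, :] / 2)
        labels = make_labels([1] * 50 + [0] * 50)
        table = dr.anova_importance(d2c, labels)
        t = scipy.stats.ttest_ind(a / 2, b / 2, equal_var=True).statistic
        assert table["raw_score"].item() == pytest.approx(t * t, rel=1e-9)

    def test_heteroskedastic_takes_welch_branch(self):
        rng = np.random.default_rng(15)
        a = rng.normal(0, 0.05, 60)
        b = rng.normal(0, 1.0, 60)
        d2c = make_d2c(np.clip(np.concatenate([a, b]), -2, 2)[None, :])
        labels = make_labels([1] * 60 + [0] * 60)
        table = dr.anova_importance(d2c, labels)
        assert bool(table["welch_branch"].item()) is True


class TestLogisticL1Importance:
    def test_informative_feature_largest_coefficient(self, separable):
        d2c, labels = separable
        table = dr.logistic_l1_importance(d2c, labels, seed=0)
        top = table.loc[table["raw_score"].idxmax(), "instance_id"]
        assert top == "i0"

    def test_seed_determinism(self, separable):
        d2c, labels = separable
        t1 = dr.logistic_l1_importance(d2c, labels, seed=3)
        t2 = dr.logistic_l1_importance(d2c, labels, seed=3)
        pd.testing.assert_frame_equal(t1, t2)


class TestEnsembleVote:
    def make_table(self, ranks):
        instances = sorted(ranks)
        raw = np.array([-float(ranks[i]) for i in instances])
        return pd.DataFrame(
            {
                "instance_id": instances,
                "raw_score": raw,
                "rank": [ranks[i] for i in instances],
            }
        )

    def test_unanimous_candidate(self):
        ranks = {"a": 1, "b": 2, "c": 3, "d": 4}
        tables = [self.make_table(ranks) for _ in range(6)]
        out = dr.ensemble_vote(tables, k=3)
        assert out.loc[out["instance_id"] == "a", "candidate"].item()
        assert out.loc[out["instance_id"] == "a", "votes"].item() == 6

    def test_two_of_six_votes_not_candidate(self):
        high = {"a": 1, "b": 2, "c": 3, "d": 4}
        low = {"a": 4, "b": 1, "c": 2, "d": 3}
        tables = [self.make_table(high)] * 2 + [self.make_table(low)] * 4
        out = dr.ensemble_vote(tables, k=3)
        assert not out.loc[out["instance_id"] == "a", "candidate"].item()
        assert out.loc[out["instance_id"] == "a", "votes"].item() == 2

    def test_k_exceeding_tables_errors(self):
        tables = [self.make_table({"a": 1, "b": 2})] * 2
        with pytest.raises(ValueError, match="exceeds"):
            dr.ensemble_vote(tables, k=3)
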