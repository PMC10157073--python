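"""Fold plans, min-max rescaling, linear SVM fits, greedy wrapper selection."""

import numpy as np
import pytest
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from wmpattern import (apply_scaler, build_cv_plan, fit_scaler,
                       greedy_forward_select, train_linear_svm)
from wmpattern.cv import inner_splits_for


# -- CV plans --------------------------------------------------------------

class TestCVPlan:

    def test_stratified_outer_folds_cover_and_balance(self):
        labels = np.array([1] * 14 + [-1] * 15)
        plan = build_cv_plan(labels, k_outer=10, r_outer=3,
                             k_inner=3, r_inner=2, seed=0)
        for rep in plan.outer_splits:
            all_test = np.concatenate([te for _, te in rep])
            assert sorted(all_test) == list(range(29))  # partition
            for tr, te in rep:
                assert 2 <= te.size <= 3
                # stratification: class ratio balanced to ±1 subject
                n_pos = np.sum(labels[te] == 1)
                assert abs(n_pos - te.size * 14 / 29) <= 1

    def test_identical_seed_identical_plan(self):
        labels = np.array([1] * 6 + [-1] * 6)
        a = build_cv_plan(labels, 3, 2, 2, 1, seed=5)
        b = build_cv_plan(labels, 3, 2, 2, 1, seed=5)
        for ra, rb in zip(a.outer_splits, b.outer_splits):
            for (tra, tea), (trb, teb) in zip(ra, rb):
                np.testing.assert_array_equal(tra, trb)
                np.testing.assert_array_equal(tea, teb)

    def test_k_exceeding_minority_count_suggests_smaller_k(self):
        labels = np.array([1] * 4 + [-1] * 10)
        with pytest.raises(ValueError, match="k <= 4"):
            build_cv_plan(labels, k_outer=5, r_outer=1, k_inner=2,
                          r_inner=1, seed=0)

    def test_leave_one_out_waives_stratification(self, caplog):
        labels = np.array([1] * 3 + [-1] * 3)
        with caplog.at_level("WARNING"):
            plan = build_cv_plan(labels, k_outer=6, r_outer=1,
                                 k_inner=2, r_inner=1, seed=0)
        assert all(te.size == 1 for _, te in plan.outer_splits[0])
        assert any("leave-one-out" in r.message for r in caplog.records)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            build_cv_plan(np.ones(6, int), 2, 1, 2, 1, seed=0)

    def test_inner_splits_deterministic_per_partition(self):
        labels = np.array([1] * 7 + [-1] * 7)
        plan = build_cv_plan(labels, 2, 1, 3, 2, seed=9)
        tr_labels = labels[:10]
        a = inner_splits_for(plan, tr_labels, 0, 1)
        b = inner_splits_for(plan, tr_labels, 0, 1)
        other = inner_splits_for(plan, tr_labels, 0, 0)
        assert len(a) == 6  # k_inner * r_inner
        for (tra, _), (trb, _) in zip(a, b):
            np.testing.assert_array_equal(tra, trb)
        assert any(not np.array_equal(x[0], y[0]) for x, y in zip(a, other))


# -- scaler ----------------------------------------------------------------

class TestScaler:

    def test_affine_mapping(self):
        state = fit_scaler(np.array([[2.0], [4.0], [6.0]]))
        out = apply_scaler(state, np.array([[2.0], [4.0], [6.0]]))
        np.testing.assert_allclose(out.ravel(), [0.0, 0.5, 1.0])

    def test_out_of_range_test_values_clipped(self):
        state = fit_scaler(np.array([[2.0], [6.0]]))
        out = apply_scaler(state, np.array([[8.0], [-1.0]]))
        np.testing.assert_allclose(out.ravel(), [1.0, 0.0])

    @pytest.mark.parametrize("const", [5.0, -3.0, 0.0])
    def test_constant_training_feature_maps_to_half(self, const, caplog):
        state = fit_scaler(np.full((3, 1), const))
        with caplog.at_level("WARNING"):
            out = apply_scaler(state, np.array([[const], [const + 1]]))
        np.testing.assert_allclose(out.ravel(), [0.5, 0.5])
        assert any("constant" in r.message for r in caplog.records)


# -- linear SVM ------------------------------------------------------------

class TestLinearSVM:

    def test_symmetric_separable_pair_boundary_at_midpoint(self):
        X = np.array([[0.0], [1.0]])
        y = np.array([-1, 1])
        w, b = train_linear_svm(X, y, C=1e6)
        assert -b / w[0] == pytest.approx(0.5, abs=1e-6)
        assert X[1] @ w + b > 0 > X[0] @ w + b

    def test_weight_norm_shrinks_with_decreasing_c(self):
        rng = np.random.default_rng(0)
        X = rng.random((10, 3))
        y = np.array([1, -1] * 5)
        X = np.vstack([X, X])          # duplicated contradictory points
        y = np.concatenate([y, -y])
        norms = [np.linalg.norm(train_linear_svm(X, y, C)[0])
                 for C in (4.0, 1.0, 0.25, 0.0625)]
        assert all(a >= b - 1e-9 for a, b in zip(norms, norms[1:]))

    def test_decision_scores_reproduce_linear_form(self):
        rng = np.random.default_rng(1)
        X = rng.random((12, 4))
        y = np.array([1] * 6 + [-1] * 6)
        w, b = train_linear_svm(X, y, C=1.0)
        ref = SVC(kernel="linear", C=1.0).fit(X, y)
        np.testing.assert_allclose(X @ w + b,
                                   ref.decision_function(X), atol=1e-8)

    def test_single_class_fold_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            train_linear_svm(np.ones((3, 1)), np.ones(3), 1.0)

    def test_matches_public_svc_across_random_problems(self):
        """The fast libsvm path must agree with sklearn's SVC estimator
        (weights, bias) across sizes, imbalance and penalties."""
        rng = np.random.default_rng(7)
        for _ in range(60):
            n = int(rng.integers(4, 28))
            d = int(rng.integers(1, 8))
            X = rng.random((n, d))
            y = rng.choice([-1, 1], size=n)
            if len(np.unique(y)) < 2:
                continue
            C = float(2.0 ** rng.integers(-6, 5))
            w, b = train_linear_svm(X, y, C)
            ref = SVC(kernel="linear", C=C).fit(X, y)
            np.testing.assert_allclose(w, ref.coef_.ravel(), atol=1e-5)
            assert b == pytest.approx(ref.intercept_[0], abs=1e-5)


# -- greedy wrapper --------------------------------------------------------

def _inner_bac(X, y, splits, cols, C):
    """Independent evaluation of a feature subset (plain sklearn)."""
    bacs = []
    for tr, va in splits:
        lo, hi = X[tr].min(axis=0), X[tr].max(axis=0)
        rng_ = np.where(hi - lo == 0, 1.0, hi - lo)
        Xtr = np.clip((X[tr] - lo) / rng_, 0, 1)
        Xva = np.clip((X[va] - lo) / rng_, 0, 1)
        Xtr[:, hi - lo == 0] = 0.5
        Xva[:, hi - lo == 0] = 0.5
        clf = SVC(kernel="linear", C=C).fit(Xtr[:, cols], y[tr])
        pred = np.where(clf.decision_function(Xva[:, cols]) > 0, 1, -1)
        yv = y[va]
        sens = np.mean(pred[yv == 1] == 1) if (yv == 1).any() else 0.0
        spec = np.mean(pred[yv == -1] == -1) if (yv == -1).any() else 0.0
        bacs.append(0.5 * (sens + spec))
    return float(np.mean(bacs))


@pytest.fixture(scope="module")
def informative_problem():
    rng = np.random.default_rng(3)
    n = 24
    y = np.array([1] * 12 + [-1] * 12)
    X = rng.standard_normal((n, 4))
    X[:, 2] += 1.4 * y  # single informative feature
    splits = list(StratifiedKFold(n_splits=4, shuffle=True,
                                  random_state=0).split(X, y))
    return X, y, splits


class TestGreedySelection:

    def test_greedy_path_matches_brute_force_per_cardinality(
            self, informative_problem):
        """On a one-informative-feature problem the greedy path must match
        the exhaustive best subset at each cardinality it visits."""
        X, y, splits = informative_problem
        c_grid = (0.25, 1.0, 4.0)
        res = greedy_forward_select(X, y, splits, c_grid)
        assert res.selected[0] == 2  # informative feature enters first

        # brute force: best subset of each cardinality (same tie-breaks)
        import itertools
        for size in range(1, len(res.selected) + 1):
            best = None
            for combo in itertools.combinations(range(4), size):
                for C in c_grid:
                    bac = _inner_bac(X, y, splits, list(combo), C)
                    key = (bac, [-c for c in combo])
                    if best is None or bac > best[0] + 1e-9:
                        best = (bac, combo)
            greedy_set = set(res.selected[:size])
            # the greedy prefix must achieve the brute-force optimum
            greedy_bac = max(_inner_bac(X, y, splits,
                                        sorted(greedy_set), C)
                             for C in c_grid)
            assert greedy_bac == pytest.approx(best[0], abs=1e-9)

    def test_all_noise_features_terminate_quickly(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((20, 4))
        y = np.array([1, -1] * 10)
        splits = list(StratifiedKFold(n_splits=4, shuffle=True,
                                      random_state=1).split(X, y))
        res = greedy_forward_select(X, y, splits, (1.0,))
        assert len(res.selected) <= 2
        assert res.bac <= 0.85  # nowhere near a confident fit on noise

    def test_duplicated_informative_columns_lower_index_wins(self):
        rng = np.random.default_rng(5)
        n = 20
        y = np.array([1] * 10 + [-1] * 10)
        base = rng.standard_normal(n) + 1.5 * y
        X = np.column_stack([rng.standard_normal(n), base, base.copy()])
        splits = list(StratifiedKFold(n_splits=4, shuffle=True,
                                      random_state=2).split(X, y))
        res = greedy_forward_select(X, y, splits, (1.0,))
        assert 1 in res.selected
        # the duplicate adds nothing, so it must not enter after its twin
        assert 2 not in res.selected

    def test_max_features_cap(self, informative_problem):
        X, y, splits = informative_problem
        res = greedy_forward_select(X, y, splits, (1.0,), max_features=1)
        assert len(res.selected) == 1
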