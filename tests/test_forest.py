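"""Forest backend: determinism, OOB bookkeeping, and importance contracts."""

import numpy as np
import pandas as pd
import pytest

from foreststab import ForestSpec, fit_forest, importances, oob_predict, predict_forest
from foreststab.exceptions import InputError, SchemaError
from foreststab.forest import per_tree_predictions


@pytest.fixture(scope="module")
def toy():
    rng = np.random.default_rng(42)
    X = pd.DataFrame(rng.integers(0, 3, size=(25, 8)).astype(float),
                     columns=[f"s{j}" for j in range(8)])
    y = X["s0"] * 2.0 + rng.normal(0, 0.5, size=25)
    return X, y


class TestFitAndPredict:
    def test_seed_determinism_bitwise(self, toy):
        X, y = toy
        spec = ForestSpec(num_trees=50, seed=1)
        p1 = predict_forest(fit_forest(X, y, spec), X)
        p2 = predict_forest(fit_forest(X, y, spec), X)
        assert np.array_equal(p1, p2)

    def test_different_seeds_differ(self, toy):
        X, y = toy
        p1 = predict_forest(fit_forest(X, y, ForestSpec(num_trees=20, seed=1)), X)
        p2 = predict_forest(fit_forest(X, y, ForestSpec(num_trees=20, seed=2)), X)
        assert not np.array_equal(p1, p2)

    def test_missing_values_rejected(self, toy):
        X, y = toy
        Xb = X.copy()
        Xb.iloc[0, 0] = np.nan
        with pytest.raises(InputError):
            fit_forest(Xb, y, ForestSpec(num_trees=5))

    def test_constant_response_predicts_constant(self, toy):
        X, _ = toy
        y = np.full(len(X), 3.25)
        forest = fit_forest(X, y, ForestSpec(num_trees=10, seed=0))
        assert np.allclose(predict_forest(forest, X), 3.25)

    def test_column_permutation_raises_schema_error(self, toy):
        X, y = toy
        forest = fit_forest(X, y, ForestSpec(num_trees=5))
        with pytest.raises(SchemaError):
            predict_forest(forest, X[list(X.columns[::-1])])

    def test_prediction_is_mean_of_per_tree_predictions(self, toy):
        X, y = toy
        forest = fit_forest(X, y, ForestSpec(num_trees=3, seed=9))
        per_tree = np.vstack([est.predict(X.to_numpy()) for est in forest.model.estimators_])
        assert np.allclose(predict_forest(forest, X), per_tree.mean(axis=0))

    def test_single_class_classification_rejected(self, toy):
        X, _ = toy
        with pytest.raises(InputError):
            fit_forest(X, np.full(len(X), "A"), ForestSpec(num_trees=5, task="classification"))


class TestOOB:
    def test_inbag_records_cover_all_trees(self, toy):
        X, y = toy
        forest = fit_forest(X, y, ForestSpec(num_trees=12, seed=0))
        assert forest.inbag.shape == (12, len(X))
        assert (forest.inbag.sum(axis=1) == len(X)).all()  # sample fraction 1.0

    def test_oob_regression_matches_enumeration_oracle(self, toy):
        X, y = toy
        forest = fit_forest(X, y, ForestSpec(num_trees=6, seed=2))
        got = oob_predict(forest, X)
        per_tree = per_tree_predictions(forest, X)
        for i in range(len(X)):
            oob_trees = [t for t in range(6) if forest.inbag[t, i] == 0]
            if not oob_trees:
                assert np.isnan(got[i])
            else:
                assert got[i] == pytest.approx(np.mean([per_tree[t, i] for t in oob_trees]))

    def test_oob_classification_is_modal_class(self, toy):
        X, _ = toy
        rng = np.random.default_rng(5)
        y = np.where(X["s0"] + rng.normal(0, 0.6, len(X)) > 1, "big", "small")
        forest = fit_forest(X, y, ForestSpec(num_trees=15, seed=3, task="classification"))
        got = oob_predict(forest, X)
        per_tree = per_tree_predictions(forest, X)
        for i in range(len(X)):
            oob_trees = np.nonzero(forest.inbag[:, i] == 0)[0]
            if len(oob_trees) == 0:
                assert got[i] is None
                continue
            counts = np.bincount(per_tree[oob_trees, i].astype(int),
                                 minlength=len(forest.classes))
            assert got[i] == forest.classes[np.argmax(counts)]

    def test_never_oob_individual_is_missing_with_warning(self, toy):
        X, y = toy
        forest = fit_forest(X, y, ForestSpec(num_trees=2, seed=1))
        never = np.nonzero((forest.inbag > 0).all(axis=0))[0]
        if len(never) == 0:
            pytest.skip("no individual in-bag for both trees under this seed")
        with pytest.warns(UserWarning, match="in-bag for every tree"):
            got = oob_predict(forest, X)
        assert np.isnan(got[never]).all()

    def test_oob_fraction_approaches_e_inverse(self, toy):
        X, y = toy
        forest = fit_forest(X, y, ForestSpec(num_trees=400, seed=7))
        frac = forest.oob_mask.mean()
        assert frac == pytest.approx(np.exp(-1), abs=0.02)


class TestImportances:
    def test_constant_column_has_zero_permutation_importance(self, toy):
        X, y = toy
        Xc = X.copy()
        Xc["s3"] = 1.0
        forest = fit_forest(Xc, y, ForestSpec(num_trees=20, seed=0))
        imp = importances(forest, Xc, y)
        assert imp[Xc.columns.get_loc("s3")] == 0.0

    def test_response_duplicated_as_predictor_ranks_first(self, toy):
        X, y = toy
        Xd = X.copy()
        Xd["leak"] = np.asarray(y)
        forest = fit_forest(Xd, y, ForestSpec(num_trees=100, seed=1))
        imp = importances(forest, Xd, y)
        assert int(np.argmax(imp)) == Xd.columns.get_loc("leak")

    def test_matches_naive_single_permutation_loop(self, toy):
        """Chunked vectorised permutation equals a per-feature loop with the same draws."""
        X, y = toy
        forest = fit_forest(X, y, ForestSpec(num_trees=10, seed=6))
        got = importances(forest, X, y, chunk_cells=500)  # force many chunks
        rng = np.random.default_rng(np.random.SeedSequence([6, 0x1B5]))
        Xm = X.to_numpy(dtype=float)
        n, p = Xm.shape
        perms = [rng.permutation(n) for _ in range(p)]
        base = -np.mean((np.asarray(y) - forest.model.predict(Xm)) ** 2)
        for j in range(p):
            X2 = Xm.copy()
            X2[:, j] = Xm[perms[j], j]
            score = -np.mean((np.asarray(y) - forest.model.predict(X2)) ** 2)
            assert got[j] == pytest.approx(base - score, abs=1e-12)

    def test_impurity_kind_uses_forest_importances(self, toy):
        X, y = toy
        forest = fit_forest(X, y, ForestSpec(num_trees=20, seed=0, importance_kind="impurity"))
        assert np.allclose(importances(forest), forest.model.feature_importances_)

    def test_two_seeds_generally_differ(self, toy):
        X, y = toy
        i1 = importances(fit_forest(X, y, ForestSpec(num_trees=10, seed=1)), X, y)
        i2 = importances(fit_forest(X, y, ForestSpec(num_trees=10, seed=2)), X, y)
        assert not np.allclose(i1, i2)

    def test_permutation_needs_evaluation_data(self, toy):
        X, y = toy
        forest = fit_forest(X, y, ForestSpec(num_trees=5))
        with pytest.raises(InputError):
            importances(forest)
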