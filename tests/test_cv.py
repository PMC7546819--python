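import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tissueclock as tc
from tissueclock.datamodel import ValidationError
from tissueclock.cv import TissueBlock


class TestKFoldSplit:
    def test_balanced_sizes_and_partition(self):
        folds = tc.kfold_split(103, 10, seed=0)
        sizes = sorted(len(f) for f in folds)
        assert sizes == [10] * 7 + [11] * 3
        union = np.concatenate(folds)
        assert sorted(union) == list(range(103))

    def test_deterministic_given_seed(self):
        a = tc.kfold_split(50, 10, seed=7)
        b = tc.kfold_split(50, 10, seed=7)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))
        c = tc.kfold_split(50, 10, seed=8)
        assert not all(np.array_equal(x, y) for x, y in zip(a, c))

    def test_n_equals_k_gives_singletons(self):
        folds = tc.kfold_split(10, 10, seed=1)
        assert all(len(f) == 1 for f in folds)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValidationError):
            tc.kfold_split(5, 10, seed=0)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.integers(min_value=4, max_value=200),
           st.integers(min_value=2, max_value=10),
           st.integers(min_value=0, max_value=1000))
    def test_partition_property(self, n, k, seed):
        if n < k:
            return
        folds = tc.kfold_split(n, k, seed)
        assert len(folds) == k
        assert max(len(f) for f in folds) - min(len(f) for f in folds) <= 1
        assert sorted(np.concatenate(folds)) == list(range(n))


def _toy_dataset(n=40, p=60, seed=0, signal=True):
    rng = np.random.default_rng(seed)
    ages = rng.uniform(20, 70, n)
    X = rng.normal(size=(n, p))
    if signal:
        X[:, :5] += np.outer((ages - 45) / 25, np.full(5, 2.0))
    block = TissueBlock("T", [f"g{i:03d}" for i in range(p)], X)
    return tc.CVDataset(blocks=[block], ages=ages,
                        unit_ids=[f"s{i:03d}" for i in range(n)])


class TestCVEvaluate:
    def test_repeat_average_is_mean_of_single_repeats(self):
        ds = _toy_dataset()
        r0, _ = tc.cv_evaluate(ds, 10, 0.0, 1.0, k=5, repeats=1, base_seed=100)
        r1, _ = tc.cv_evaluate(ds, 10, 0.0, 1.0, k=5, repeats=1, base_seed=101)
        r01, _ = tc.cv_evaluate(ds, 10, 0.0, 1.0, k=5, repeats=2, base_seed=100)
        assert r01 == pytest.approx((r0 + r1) / 2)

    def test_deterministic(self):
        ds = _toy_dataset()
        a = tc.cv_evaluate(ds, 10, 0.5, 1.0, k=5, repeats=2, base_seed=3)
        b = tc.cv_evaluate(ds, 10, 0.5, 1.0, k=5, repeats=2, base_seed=3)
        assert a == b

    def test_invariant_to_sample_order(self):
        ds = _toy_dataset()
        rng = np.random.default_rng(9)
        perm = rng.permutation(ds.n)
        shuffled = tc.CVDataset(
            blocks=[TissueBlock("T", ds.blocks[0].gene_ids, ds.blocks[0].X[perm])],
            ages=ds.ages[perm],
            unit_ids=ds.unit_ids[perm],
        )
        a = tc.cv_evaluate(ds, 10, 0.0, 1.0, k=5, repeats=2, base_seed=3)
        b = tc.cv_evaluate(shuffled, 10, 0.0, 1.0, k=5, repeats=2, base_seed=3)
        assert a == pytest.approx(b)

    def test_bootstrap_mode_differs_but_is_deterministic(self):
        ds = _toy_dataset()
        a = tc.cv_evaluate(ds, 10, 0.0, 1.0, k=5, repeats=2, base_seed=3,
                           resample="bootstrap")
        b = tc.cv_evaluate(ds, 10, 0.0, 1.0, k=5, repeats=2, base_seed=3,
                           resample="bootstrap")
        c = tc.cv_evaluate(ds, 10, 0.0, 1.0, k=5, repeats=2, base_seed=3)
        assert a == b
        assert a != c

    def test_fold_with_too_few_training_samples_rejected(self):
        ds = _toy_dataset(n=4)
        with pytest.raises(ValidationError, match="training samples"):
            tc.cv_evaluate(ds, 5, 0.0, 1.0, k=2, repeats=1, base_seed=0)

    def test_budget_must_match_blocks(self):
        ds = _toy_dataset()
        with pytest.raises(ValidationError, match="budgets"):
            tc.cv_evaluate(ds, (10, 10), 0.0, 1.0, k=5, repeats=1, base_seed=0)


class TestGridSearch:
    def test_single_combination_is_chosen(self):
        ds = _toy_dataset()
        grid = tc.ParamGrid(n_grid=[10], alpha_grid=[0.5], lambda_grid=[1.0])
        res = tc.grid_search(ds, grid, k=5, repeats=2, base_seed=0)
        assert res.chosen["n"] == 10
        assert res.chosen["alpha"] == 0.5
        assert res.chosen["lambda"] == 1.0
        assert len(res.table) == 1

    def test_intercept_only_cell_loses_on_signal_data(self):
        ds = _toy_dataset(signal=True)
        grid = tc.ParamGrid(n_grid=[10], alpha_grid=[0.0, 1.0],
                            lambda_grid=[1.0, 1e9])
        res = tc.grid_search(ds, grid, k=5, repeats=2, base_seed=0)
        assert not (res.chosen["alpha"] == 1.0 and res.chosen["lambda"] == 1e9)

    def test_final_model_refit_at_chosen_cell(self):
        ds = _toy_dataset()
        grid = tc.ParamGrid(n_grid=[10, 20], alpha_grid=[0.0], lambda_grid=[1.0])
        res = tc.grid_search(ds, grid, k=5, repeats=2, base_seed=0)
        model = res.final_model
        assert len(model.coefficients) == res.chosen["n"]
        assert model.alpha == res.chosen["alpha"]
        assert model.lam == res.chosen["lambda"]
        assert set(model.coefficients["tissue"]) == {"T"}

    def test_two_stage_agrees_with_joint_on_coarse_alphas(self):
        ds = _toy_dataset()
        grid = tc.ParamGrid(n_grid=[10], alpha_grid=[0.0, 0.5, 1.0],
                            lambda_grid=[1.0])
        joint = tc.grid_search(ds, grid, k=5, repeats=2, base_seed=0,
                               strategy="joint")
        staged = tc.grid_search(ds, grid, k=5, repeats=2, base_seed=0,
                                strategy="two_stage")
        assert joint.chosen == staged.chosen

    def test_grid_validation(self):
        with pytest.raises(ValidationError):
            tc.ParamGrid(lambda_grid=[0.0])
        with pytest.raises(ValidationError):
            tc.ParamGrid(alpha_grid=[1.5])
        with pytest.raises(ValidationError):
            tc.ParamGrid(n_grid=[])
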