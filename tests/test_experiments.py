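"""Enumeration combinatorics, split hygiene, training, and summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ehrfusion import (
    HyperparameterGrid,
    SourceRegistry,
    SourceSpec,
    enumerate_source_subsets,
    logistic_backend,
    make_splits,
    run_grid,
    summarize,
    train_eval_model,
)


@pytest.fixture(scope="module")
def toy_registry():
    return SourceRegistry(
        [
            SourceSpec("de", "tabular", 2),
            SourceSpec("ce", "time-series", 3),
            SourceSpec("vp", "image", 2),
        ]
    )


def brute_force_modality_groups(registry, excluded):
    """Independent subset scan counting distinct-modality coverage."""
    allowed = [n for n in registry.names if n not in excluded]
    counts = {}
    for r in range(1, len(allowed) + 1):
        for combo in itertools.combinations(allowed, r):
            m = len({registry.modality(n) for n in combo})
            counts[m] = counts.get(m, 0) + 1
    return counts


class TestEnumeration:
    def test_eleven_sources_yield_2047_subsets(self, registry):
        assert enumerate_source_subsets(registry).total == 2047

    def test_ten_sources_yield_1023_subsets(self, registry):
        assert enumerate_source_subsets(registry, excluded={"radn"}).total == 1023

    def test_ten_source_modality_groups_match_brute_force(self, registry):
        enum = enumerate_source_subsets(registry, excluded={"radn"})
        groups = enum.group_sizes_by_modality_count()
        assert groups == {1: 26, 2: 196, 3: 486, 4: 315}
        assert groups == brute_force_modality_groups(registry, {"radn"})

    def test_groups_partition_enumeration_for_all_prefixes(self, registry):
        for k in range(1, 12):
            sub = registry.restrict(registry.names[:k])
            enum = enumerate_source_subsets(sub)
            assert enum.total == 2**k - 1
            assert sum(enum.group_sizes_by_modality_count().values()) == enum.total
            assert sum(enum.group_sizes_by_source_count().values()) == enum.total

    def test_all_sources_excluded_rejected(self, registry):
        with pytest.raises(ValueError):
            enumerate_source_subsets(registry, excluded=set(registry.names))


class TestSplits:
    def _ids(self, n_patients, per_patient=3):
        ids = np.repeat([f"p{i}" for i in range(n_patients)], per_patient)
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, len(ids))
        y[:2] = [0, 1]  # both classes guaranteed
        return ids, y

    def test_no_patient_overlap_in_any_repetition(self):
        ids, y = self._ids(25)
        for train_idx, test_idx in make_splits(ids, y, n_rep=5, seed=3):
            assert not set(ids[train_idx]) & set(ids[test_idx])

    def test_ten_patients_give_two_test_patients(self):
        ids, y = self._ids(10)
        for train_idx, test_idx in make_splits(ids, y, test_frac=0.2, seed=0):
            assert len(set(ids[test_idx])) == 2

    def test_same_seed_gives_identical_plans(self):
        ids, y = self._ids(20)
        a = make_splits(ids, y, seed=11)
        b = make_splits(ids, y, seed=11)
        for (tr1, te1), (tr2, te2) in zip(a, b):
            np.testing.assert_array_equal(tr1, tr2)
            np.testing.assert_array_equal(te1, te2)

    def test_stratified_splits_cover_both_strata(self):
        ids = np.array([f"p{i}" for i in range(20)])
        y = np.array([1] * 4 + [0] * 16)
        for train_idx, test_idx in make_splits(
            ids, y, stratify_label=True, seed=2
        ):
            assert set(y[test_idx]) == {0, 1}
            assert set(y[train_idx]) == {0, 1}

    def test_single_class_task_rejected(self):
        ids = np.array(["a", "b", "c"])
        with pytest.raises(ValueError, match="single-class"):
            make_splits(ids, np.ones(3), seed=0)


class TestTrainEval:
    def test_linearly_separable_data_reaches_perfect_auroc(self):
        rng = np.random.default_rng(0)
        n = 200
        x = rng.normal(size=n)
        X = np.column_stack([x, rng.normal(size=n)])
        y = (x > 0).astype(int)
        split = (np.arange(0, 150), np.arange(150, n))
        result = train_eval_model(
            X, y, split, HyperparameterGrid.single(), logistic_backend()
        )
        assert result.test_auroc == 1.0

    def test_deterministic_given_seed_and_backend(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(120, 5))
        y = rng.integers(0, 2, 120)
        split = (np.arange(0, 90), np.arange(90, 120))
        grid = HyperparameterGrid(
            max_depth=(2, 3), n_estimators=(10,), learning_rate=(0.1, 0.3),
            cv_folds=3,
        )
        from ehrfusion import xgboost_backend

        a = train_eval_model(X, y, split, grid, xgboost_backend(seed=7), seed=7)
        b = train_eval_model(X, y, split, grid, xgboost_backend(seed=7), seed=7)
        assert a.test_auroc == b.test_auroc
        assert a.best_params == b.best_params

    def test_grid_selection_happens_inside_training_split(self):
        """Mutating test rows must not change normalizer or chosen model."""
        rng = np.random.default_rng(2)
        X = rng.normal(size=(150, 4))
        y = (X[:, 0] + rng.normal(scale=0.8, size=150) > 0).astype(int)
        split = (np.arange(0, 120), np.arange(120, 150))
        grid = HyperparameterGrid(
            max_depth=(2,), n_estimators=(10, 20), learning_rate=(0.1,), cv_folds=3
        )
        from ehrfusion import xgboost_backend

        base = train_eval_model(X, y, split, grid, xgboost_backend(seed=0), seed=0)
        X_mut = X.copy()
        X_mut[120:] += 1e6  # wildly perturb test rows only
        mut = train_eval_model(X_mut, y, split, grid, xgboost_backend(seed=0), seed=0)
        np.testing.assert_array_equal(base.normalizer.center, mut.normalizer.center)
        np.testing.assert_array_equal(base.normalizer.scale, mut.normalizer.scale)
        assert base.best_params == mut.best_params
        assert base.cv_scores == mut.cv_scores


@pytest.fixture(scope="module")
def toy_problem():
    rng = np.random.default_rng(0)
    n = 120
    z = rng.normal(size=n)
    X = {
        "de": np.column_stack([z + rng.normal(scale=1, size=n),
                               rng.normal(size=n)]),
        "ce": rng.normal(size=(n, 3)),
        "vp": np.column_stack([z + rng.normal(scale=1, size=n),
                               rng.normal(size=n)]),
    }
    y = (z + rng.normal(scale=0.5, size=n) > 0).astype(int)
    ids = np.repeat([f"p{i}" for i in range(n // 2)], 2)
    return X, y, ids


class TestRunGrid:
    def test_toy_three_source_registry_gives_seven_rows(
        self, toy_registry, toy_problem
    ):
        X, y, ids = toy_problem
        splits = make_splits(ids, y, n_rep=2, seed=0)
        table = run_grid(
            X, y, enumerate_source_subsets(toy_registry), splits,
            HyperparameterGrid.single(), logistic_backend(),
        )
        assert len(table) == 7
        assert table["auroc_mean"].between(0, 1).all()
        assert (table["auroc_sd"] >= 0).all()

    def test_rerun_with_same_seeds_is_identical(self, toy_registry, toy_problem):
        X, y, ids = toy_problem
        splits = make_splits(ids, y, n_rep=2, seed=1)
        kwargs = dict(
            embeddings=X, y=y,
            enumeration=enumerate_source_subsets(toy_registry),
            splits=splits, grid=HyperparameterGrid.single(),
            backend=logistic_backend(),
        )
        pd.testing.assert_frame_equal(run_grid(**kwargs), run_grid(**kwargs))

    def test_checkpoint_resume_skips_completed_cells(
        self, toy_registry, toy_problem, tmp_path
    ):
        X, y, ids = toy_problem
        splits = make_splits(ids, y, n_rep=2, seed=2)
        ckpt = tmp_path / "ckpt.csv"
        enum = enumerate_source_subsets(toy_registry)
        full = run_grid(
            X, y, enum, splits, HyperparameterGrid.single(),
            logistic_backend(), checkpoint_path=ckpt,
        )
        assert len(pd.read_csv(ckpt)) == 7
        resumed = run_grid(
            X, y, enum, splits, HyperparameterGrid.single(),
            logistic_backend(), checkpoint_path=ckpt,
        )
        np.testing.assert_allclose(
            full["auroc_mean"].to_numpy(), resumed["auroc_mean"].to_numpy()
        )
        assert len(pd.read_csv(ckpt)) == 7  # nothing recomputed or re-appended

    def test_missing_embedding_block_names_the_source(
        self, toy_registry, toy_problem
    ):
        X, y, ids = toy_problem
        splits = make_splits(ids, y, n_rep=1, seed=0)
        incomplete = {k: v for k, v in X.items() if k != "ce"}
        with pytest.raises(KeyError, match="ce"):
            run_grid(
                incomplete, y, enumerate_source_subsets(toy_registry), splits,
                HyperparameterGrid.single(), logistic_backend(),
            )


class TestSummarize:
    def _table(self, rows):
        return pd.DataFrame(
            rows,
            columns=["task", "subset", "n_sources", "n_modalities",
                     "auroc_mean", "auroc_sd", "chosen_depth",
                     "chosen_estimators", "chosen_lr"],
        )

    def test_constant_table_gives_zero_delta(self):
        table = self._table([
            ("t", "100", 1, 1, 0.7, 0.01, 5, 200, 0.1),
            ("t", "010", 1, 1, 0.7, 0.01, 5, 200, 0.1),
            ("t", "110", 2, 2, 0.7, 0.01, 5, 200, 0.1),
        ])
        summary = summarize(table)
        np.testing.assert_allclose(summary.delta["delta_pct_mean"], 0.0)

    def test_hand_arithmetic_on_toy_table(self):
        table = self._table([
            ("t", "100", 1, 1, 0.6, 0.01, 5, 200, 0.1),
            ("t", "010", 1, 1, 0.8, 0.01, 5, 200, 0.1),
            ("t", "110", 2, 2, 0.77, 0.01, 5, 200, 0.1),
        ])
        summary = summarize(table)
        assert summary.baseline_mean == pytest.approx(0.7)
        assert summary.baseline_best == pytest.approx(0.8)
        assert summary.delta["delta_pct_mean"].iloc[0] == pytest.approx(10.0)

    def test_single_source_cell_is_mean_of_singles(self):
        table = self._table([
            ("t", "100", 1, 1, 0.6, 0.0, 5, 200, 0.1),
            ("t", "010", 1, 1, 0.8, 0.0, 5, 200, 0.1),
            ("t", "110", 2, 2, 0.9, 0.0, 5, 200, 0.1),
        ])
        grid = summarize(table).mean_grid
        assert grid.loc[1, 1] == pytest.approx(0.7)
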