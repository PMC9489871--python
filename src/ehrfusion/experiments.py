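"""Exhaustive source-subset predictive experiments.

For a task with *k* allowable sources, every one of the 2^k − 1 non-empty
source subsets defines one model: the subset's fusion embedding is fed to a
gradient-boosted-tree classifier (pluggable backend), trained over 5
repetitions of patient-stratified 80/20 splits, with hyperparameters chosen
by fivefold cross-validated grid search inside each training split and the
test split touched exactly once per repetition for the reported AUROC.

The resulting table of (subset → mean test AUROC, SD) is both the summary
surface (AUROC by number of modalities/sources, ΔAUROC versus single-source
baselines) and the value function handed to the Shapley attribution module.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .fusion import (
    Normalizer,
    SourceSubset,
    apply_normalizer,
    fit_normalizer,
    stack_fusion_matrix,
)
from .registry import SourceRegistry

logger = logging.getLogger(__name__)

#: a backend maps a hyperparameter dict to an unfitted sklearn-style
#: classifier exposing fit(X, y) and predict_proba(X)
Backend = Callable[[Mapping[str, object]], object]


def xgboost_backend(seed: int = 0, n_jobs: int = 1) -> Backend:
    """Gradient-boosted decision trees (the default production backend)."""
    from xgboost import XGBClassifier

    def make(params: Mapping[str, object]):
        return XGBClassifier(
            max_depth=int(params.get("max_depth", 6)),
            n_estimators=int(params.get("n_estimators", 200)),
            learning_rate=float(params.get("learning_rate", 0.1)),
            eval_metric="logloss",
            tree_method="hist",
            n_jobs=n_jobs,
            random_state=seed,
            verbosity=0,
        )

    return make


def logistic_backend(max_iter: int = 500, C: float = 1.0) -> Backend:
    """L2 logistic regression: a fast deterministic backend for testing."""
    from sklearn.linear_model import LogisticRegression

    def make(params: Mapping[str, object]):
        return LogisticRegression(max_iter=max_iter, C=C)

    return make


# ---------------------------------------------------------------------------
# subset enumeration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubsetEnumeration:
    """All non-empty subsets of the allowed sources, annotated and grouped."""

    subsets: tuple[SourceSubset, ...]
    registry: SourceRegistry

    @property
    def total(self) -> int:
        return len(self.subsets)

    def group_sizes_by_modality_count(self) -> dict[int, int]:
        sizes: dict[int, int] = {}
        for s in self.subsets:
            m = s.n_modalities(self.registry)
            sizes[m] = sizes.get(m, 0) + 1
        return dict(sorted(sizes.items()))

    def group_sizes_by_source_count(self) -> dict[int, int]:
        sizes: dict[int, int] = {}
        for s in self.subsets:
            sizes[s.n_sources] = sizes.get(s.n_sources, 0) + 1
        return dict(sorted(sizes.items()))


def enumerate_source_subsets(
    registry: SourceRegistry, excluded: Iterable[str] = ()
) -> SubsetEnumeration:
    """Enumerate every non-empty subset of the allowed sources.

    Subsets are emitted in deterministic order: by size, then
    lexicographically by canonical member positions.
    """
    excluded = set(excluded)
    allowed = [n for n in registry.names if n not in excluded]
    if not allowed:
        raise ValueError("all sources excluded; nothing to enumerate")
    subsets = []
    for r in range(1, len(allowed) + 1):
        for combo in itertools.combinations(allowed, r):
            subsets.append(SourceSubset.from_names(combo, registry))
    return SubsetEnumeration(subsets=tuple(subsets), registry=registry)


# ---------------------------------------------------------------------------
# patient-stratified splitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitPlan:
    """Repeated disjoint train/test index partitions at patient granularity."""

    splits: tuple[tuple[np.ndarray, np.ndarray], ...]
    seed: int

    def __iter__(self):
        return iter(self.splits)

    def __len__(self) -> int:
        return len(self.splits)


def make_splits(
    patient_ids: Sequence[str],
    labels: Sequence[int],
    n_rep: int = 5,
    test_frac: float = 0.2,
    stratify_label: bool = False,
    seed: int = 0,
) -> SplitPlan:
    """Repeated 80/20 splits grouped by patient id.

    No patient contributes samples to both sides of any repetition.  With
    ``stratify_label`` the patient pool is split within label strata
    (patient stratum = majority label of the patient's samples), balancing
    target ratios approximately at patient granularity.
    """
    patient_ids = np.asarray(patient_ids)
    y = np.asarray(labels)
    if patient_ids.shape[0] != y.shape[0]:
        raise ValueError("patient_ids and labels must align")
    if len(np.unique(y)) < 2:
        raise ValueError("single-class task: AUROC is undefined")
    if not (0 < test_frac < 1):
        raise ValueError("test_frac must be in (0, 1)")

    unique_patients = np.unique(patient_ids)
    patient_label = {}
    for p in unique_patients:
        patient_label[p] = int(np.mean(y[patient_ids == p]) >= 0.5)

    splits = []
    for rep in range(n_rep):
        rng = np.random.default_rng([int(seed) % (2**31), rep])
        test_patients: set = set()
        if stratify_label:
            for stratum in (0, 1):
                pool = np.array(
                    [p for p in unique_patients if patient_label[p] == stratum]
                )
                if len(pool) < 2:
                    raise ValueError(
                        f"need >=2 patients in label stratum {stratum} to stratify"
                    )
                pool = pool[rng.permutation(len(pool))]
                n_test = max(1, round(test_frac * len(pool)))
                test_patients.update(pool[:n_test])
        else:
            pool = unique_patients[rng.permutation(len(unique_patients))]
            n_test = max(1, round(test_frac * len(pool)))
            test_patients.update(pool[:n_test])
        mask = np.isin(patient_ids, sorted(test_patients))
        test_idx = np.flatnonzero(mask)
        train_idx = np.flatnonzero(~mask)
        if len(train_idx) == 0 or len(test_idx) == 0:
            raise ValueError("degenerate split: empty train or test side")
        splits.append((train_idx, test_idx))
    return SplitPlan(splits=tuple(splits), seed=int(seed))


# ---------------------------------------------------------------------------
# model training and evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HyperparameterGrid:
    """Grid-search space; tie-breaks resolve to the first cell in
    lexicographic (max_depth, n_estimators, learning_rate) order."""

    max_depth: tuple[int, ...] = (5, 6, 7, 8)
    n_estimators: tuple[int, ...] = (200, 300)
    learning_rate: tuple[float, ...] = (0.05, 0.1, 0.3)
    cv_folds: int = 5

    def cells(self) -> list[dict[str, object]]:
        return [
            {"max_depth": d, "n_estimators": n, "learning_rate": lr}
            for d in self.max_depth
            for n in self.n_estimators
            for lr in self.learning_rate
        ]

    @classmethod
    def single(cls) -> "HyperparameterGrid":
        """Degenerate one-cell grid (no search; used with fixed backends)."""
        return cls(max_depth=(6,), n_estimators=(200,), learning_rate=(0.1,))


@dataclass
class TrainEvalResult:
    test_auroc: float
    best_params: dict[str, object]
    normalizer: Normalizer
    cv_scores: dict[tuple, float] = field(default_factory=dict)


def _cv_score(
    X: np.ndarray,
    y: np.ndarray,
    params: Mapping[str, object],
    backend: Backend,
    cv_folds: int,
    seed: int,
) -> Optional[float]:
    """Mean held-out AUROC of one grid cell; None if every fold degenerates."""
    kf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    scores = []
    for fold_train, fold_val in kf.split(X, y):
        y_tr, y_val = y[fold_train], y[fold_val]
        if len(np.unique(y_tr)) < 2 or len(np.unique(y_val)) < 2:
            warnings.warn("degenerate single-class CV fold skipped")
            continue
        model = backend(params)
        model.fit(X[fold_train], y_tr)
        prob = model.predict_proba(X[fold_val])[:, 1]
        scores.append(roc_auc_score(y_val, prob))
    if not scores:
        return None
    return float(np.mean(scores))


def train_eval_model(
    X: np.ndarray,
    y: Sequence[int],
    split: tuple[np.ndarray, np.ndarray],
    grid: HyperparameterGrid,
    backend: Backend,
    seed: int = 0,
) -> TrainEvalResult:
    """Grid-search on the training split, then score the test split once.

    The feature normalizer and every model-selection statistic are computed
    from training rows only; the test rows are used exactly once, for the
    reported AUROC.
    """
    y = np.asarray(y)
    train_idx, test_idx = split
    X_train, y_train = X[train_idx], y[train_idx]
    X_test, y_test = X[test_idx], y[test_idx]
    if len(np.unique(y_test)) < 2:
        raise ValueError("test split is single-class: AUROC undefined")

    normalizer = fit_normalizer(X_train)
    Z_train = apply_normalizer(normalizer, X_train)

    cells = grid.cells()
    cv_scores: dict[tuple, float] = {}
    if len(cells) == 1:
        best_params = cells[0]
    else:
        best_params, best_score = None, -np.inf
        for params in cells:
            score = _cv_score(
                Z_train, y_train, params, backend, grid.cv_folds, seed
            )
            if score is None:
                warnings.warn(f"grid cell {params} skipped: all folds degenerate")
                continue
            cv_scores[tuple(sorted(params.items()))] = score
            if score > best_score:  # strict: first cell wins ties
                best_params, best_score = params, score
        if best_params is None:
            raise ValueError("all grid cells degenerate; cannot select a model")

    model = backend(best_params)
    model.fit(Z_train, y_train)
    prob = model.predict_proba(apply_normalizer(normalizer, X_test))[:, 1]
    auroc = float(roc_auc_score(y_test, prob))
    return TrainEvalResult(
        test_auroc=auroc,
        best_params=dict(best_params),
        normalizer=normalizer,
        cv_scores=cv_scores,
    )


# ---------------------------------------------------------------------------
# the exhaustive grid of subset experiments
# ---------------------------------------------------------------------------

AUROC_TABLE_COLUMNS = (
    "task",
    "subset",
    "n_sources",
    "n_modalities",
    "auroc_mean",
    "auroc_sd",
    "chosen_depth",
    "chosen_estimators",
    "chosen_lr",
)


def run_grid(
    embeddings: Mapping[str, np.ndarray],
    y: Sequence[int],
    enumeration: SubsetEnumeration,
    splits: SplitPlan,
    grid: HyperparameterGrid,
    backend: Backend,
    task: str = "task",
    checkpoint_path: Optional[str | Path] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """One (mean AUROC, SD) row per source subset.

    ``embeddings`` maps source name → (n_samples × dim) matrix aligned with
    ``y``.  With ``checkpoint_path`` the run is resumable: completed subsets
    found in the checkpoint CSV are skipped and new rows appended after each
    subset.  Execution order does not affect results.
    """
    y = np.asarray(y)
    registry = enumeration.registry
    done: dict[str, pd.Series] = {}
    checkpoint = Path(checkpoint_path) if checkpoint_path is not None else None
    if checkpoint is not None and checkpoint.exists():
        prior = pd.read_csv(checkpoint, dtype={"subset": str})
        for _, row in prior[prior["task"] == task].iterrows():
            done[row["subset"]] = row

    rows = []
    for subset in enumeration.subsets:
        bits = subset.bitmask(registry)
        if bits in done:
            rows.append(done[bits].to_dict())
            continue
        X = stack_fusion_matrix(embeddings, subset, registry)
        aurocs, params_used = [], []
        for rep, split in enumerate(splits):
            result = train_eval_model(
                X, y, split, grid, backend, seed=int(seed) % (2**31) + rep
            )
            aurocs.append(result.test_auroc)
            params_used.append(result.best_params)
        chosen = params_used[-1]
        row = {
            "task": task,
            "subset": bits,
            "n_sources": subset.n_sources,
            "n_modalities": subset.n_modalities(registry),
            "auroc_mean": float(np.mean(aurocs)),
            "auroc_sd": float(np.std(aurocs, ddof=1)) if len(aurocs) > 1 else 0.0,
            "chosen_depth": chosen.get("max_depth"),
            "chosen_estimators": chosen.get("n_estimators"),
            "chosen_lr": chosen.get("learning_rate"),
        }
        rows.append(row)
        if checkpoint is not None:
            header = not checkpoint.exists()
            pd.DataFrame([row]).to_csv(
                checkpoint, mode="a", header=header, index=False
            )
        logger.debug("subset %s: AUROC %.3f", bits, row["auroc_mean"])
    return pd.DataFrame(rows, columns=list(AUROC_TABLE_COLUMNS))


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

@dataclass
class Summary:
    """Aggregated AUROC grids and per-subset improvement percentages."""

    mean_grid: pd.DataFrame      # mean AUROC by (n_modalities, n_sources)
    sd_grid: pd.DataFrame        # mean of per-subset SDs, same cells
    delta: pd.DataFrame          # per multimodal subset: ΔAUROC% vs baselines
    baseline_mean: float         # mean AUROC over single-source models
    baseline_best: float         # best single-source AUROC


def summarize(table: pd.DataFrame) -> Summary:
    """Aggregate an AUROC table the way the headline figures are read.

    ``delta_pct_mean`` compares each multi-source subset with the mean of
    all single-source models, ``delta_pct_best`` with the best one:
    100·(AUROC_subset − baseline)/baseline.
    """
    if table.empty:
        raise ValueError("cannot summarize an empty AUROC table")
    mean_grid = table.pivot_table(
        index="n_modalities", columns="n_sources", values="auroc_mean", aggfunc="mean"
    )
    sd_grid = table.pivot_table(
        index="n_modalities", columns="n_sources", values="auroc_sd", aggfunc="mean"
    )
    singles = table[table["n_sources"] == 1]
    if singles.empty:
        raise ValueError("AUROC table has no single-source rows to baseline against")
    baseline_mean = float(singles["auroc_mean"].mean())
    baseline_best = float(singles["auroc_mean"].max())
    multi = table[table["n_sources"] >= 2].copy()
    multi["delta_pct_mean"] = (
        100.0 * (multi["auroc_mean"] - baseline_mean) / baseline_mean
    )
    multi["delta_pct_best"] = (
        100.0 * (multi["auroc_mean"] - baseline_best) / baseline_best
    )
    return Summary(
        mean_grid=mean_grid,
        sd_grid=sd_grid,
        delta=multi,
        baseline_mean=baseline_mean,
        baseline_best=baseline_best,
    )
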