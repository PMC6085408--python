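"""Outcome classification from LFP features.

The core model is L1-penalized (lasso) logistic regression evaluated by
stratified, animal-grouped 4-fold cross-validation repeated 100 times.
Both recording sessions of an animal enter the design matrix as separate
rows but always share a fold, so no animal leaks between train and test.
Within each training fold, features are standardized from training rows
only and the penalty is chosen by an inner cross-validation minimizing
held-out deviance.  Feature "% survival" is the percentage of fitted fold
models in which a feature keeps a nonzero coefficient.

Chance performance is estimated by rerunning the whole procedure on label
permutations applied at the animal level; observed and permuted accuracy
distributions are compared with a Mann-Whitney U test whose statistic is
converted to a Cohen's d through the normal approximation
(z -> r = z / sqrt(N) -> d = 2 r / sqrt(1 - r^2)).

Single-feature information content is measured with unpenalized logistic
models under exhaustive leave-one-animal-out cross-validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn import config_context
from sklearn.linear_model import LogisticRegression

logger = logging.getLogger(__name__)

#: inner-CV penalty grid (sklearn C = inverse penalty strength)
DEFAULT_C_GRID: tuple[float, ...] = tuple(np.logspace(-2.0, 1.0, 7))


@dataclass
class DesignMatrix:
    """Feature rows (animal-sessions), binary labels, animal grouping."""

    X: pd.DataFrame
    y: np.ndarray
    groups: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y).astype(int)
        self.groups = np.asarray(self.groups)
        if not (len(self.X) == len(self.y) == len(self.groups)):
            raise ValueError("X, y and groups must have equal length")
        if self.X.isna().any().any():
            raise ValueError("design matrix contains missing values")
        if set(np.unique(self.y)) != {0, 1}:
            raise ValueError("labels must contain both classes, coded 0/1")
        for g in np.unique(self.groups):
            if len(set(self.y[self.groups == g])) != 1:
                raise ValueError(f"animal {g!r} has inconsistent labels across sessions")

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    def animal_labels(self) -> tuple[np.ndarray, np.ndarray]:
        animals, idx = np.unique(self.groups, return_index=True)
        return animals, self.y[idx]


def make_design_matrix(
    features: pd.DataFrame, labels: Mapping[str, int]
) -> DesignMatrix:
    """Assemble a design matrix from a feature table and per-animal labels.

    ``features`` must carry ``animal_id`` (and optionally ``session_id``)
    metadata columns; animals absent from ``labels`` are dropped.
    """
    meta = [c for c in ("animal_id", "session_id", "group") if c in features.columns]
    if "animal_id" not in meta:
        raise ValueError("feature table needs an animal_id column")
    kept = features[features["animal_id"].isin(labels)].reset_index(drop=True)
    if kept.empty:
        raise ValueError("no feature rows match the supplied labels")
    return DesignMatrix(
        X=kept.drop(columns=meta),
        y=np.array([labels[a] for a in kept["animal_id"]]),
        groups=kept["animal_id"].to_numpy(),
    )


@dataclass
class CVResult:
    accuracies: np.ndarray  # one pooled accuracy per repetition
    survival_pct: pd.Series  # per-feature % of fold models with nonzero coef
    n_models: int  # reps * k fitted fold models

    @property
    def mean(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def sd(self) -> float:
        return float(np.std(self.accuracies, ddof=1)) if len(self.accuracies) > 1 else 0.0


@dataclass
class PermutationResult:
    per_permutation: list[CVResult]

    @property
    def pooled_accuracies(self) -> np.ndarray:
        return np.concatenate([r.accuracies for r in self.per_permutation])


@dataclass(frozen=True)
class EffectSizeReport:
    U: float
    n1: int
    n2: int
    z: float
    d: float
    direction: str  # "observed>null" | "observed<null" | "none"
    degenerate: bool = False


# ------------------------------------------------------------------ folds

def _stratified_animal_folds(
    animals: np.ndarray, labels: np.ndarray, k: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Deal animals into k folds, stratified by class label."""
    folds: list[list] = [[] for _ in range(k)]
    offset = 0
    for cls in (0, 1):
        members = animals[labels == cls].copy()
        rng.shuffle(members)
        for i, a in enumerate(members):
            folds[(i + offset) % k].append(a)
        offset += len(members)
    return [np.array(f, dtype=animals.dtype) for f in folds]


#: disables redundant per-fit input validation inside the CV hot loops
_fast_sklearn = dict(assume_finite=True, skip_parameter_validation=True)


def _fit_l1(X: np.ndarray, y: np.ndarray, C: float) -> LogisticRegression:
    clf = LogisticRegression(
        l1_ratio=1.0, C=C, solver="liblinear", max_iter=2000, tol=1e-4, random_state=0
    )
    clf.fit(X, y)
    return clf


def _prob_class1(clf: LogisticRegression, X: np.ndarray) -> np.ndarray:
    z = X @ clf.coef_[0] + clf.intercept_[0]
    p = 1.0 / (1.0 + np.exp(-z))
    if clf.classes_[1] != 1:  # liblinear orders classes ascending; 0/1 labels
        p = 1.0 - p
    return p


def _deviance(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _standardize(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    sd = np.where(sd < 1e-12, 1.0, sd)  # constant columns stay at 0 after centering
    return (train - mu) / sd, (test - mu) / sd


def _select_penalty(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    c_grid: Sequence[float],
    rng: np.random.Generator,
    k_inner: int = 4,
) -> float:
    """Inner animal-grouped CV: penalty minimizing mean held-out deviance."""
    animals, idx = np.unique(groups, return_index=True)
    labels = y[idx]
    k = min(k_inner, int((labels == 0).sum()), int((labels == 1).sum()))
    if k < 2:
        logger.warning("too few animals for inner CV; using mid-grid penalty")
        return c_grid[len(c_grid) // 2]
    folds = _stratified_animal_folds(animals, labels, k, rng)
    deviance = np.zeros(len(c_grid))
    for fold in folds:
        test_mask = np.isin(groups, fold)
        Xtr, Xte = _standardize(X[~test_mask], X[test_mask])
        ytr, yte = y[~test_mask], y[test_mask]
        for ci, C in enumerate(c_grid):
            clf = _fit_l1(Xtr, ytr, C)
            deviance[ci] += _deviance(yte, _prob_class1(clf, Xte))
    return c_grid[int(np.argmin(deviance))]  # ties -> strongest penalty (grid ascends)


def fit_lasso_repeated_cv(
    dm: DesignMatrix,
    k: int = 4,
    reps: int = 100,
    seed: int = 0,
    c_grid: Sequence[float] = DEFAULT_C_GRID,
    max_reshuffles: int = 20,
) -> CVResult:
    """Repeated stratified, animal-grouped k-fold lasso cross-validation.

    Per repetition the pooled held-out accuracy over all k folds is
    recorded; per fold model, nonzero coefficients count toward feature
    survival.  A repetition whose training split degenerates to one class
    is reshuffled (logged) up to ``max_reshuffles`` times.
    """
    animals, labels = dm.animal_labels()
    if (labels == 0).sum() < 2 or (labels == 1).sum() < 2:
        raise ValueError("need >= 2 animals per class")
    if k > len(animals):
        raise ValueError(f"k={k} exceeds number of animals ({len(animals)})")
    X = dm.X.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    accuracies = np.empty(reps)
    selections = np.zeros(X.shape[1])
    n_models = 0
    for rep in range(reps):
        for attempt in range(max_reshuffles):
            folds = _stratified_animal_folds(animals, labels, k, rng)
            ok = all(
                len(set(dm.y[~np.isin(dm.groups, fold)])) == 2 for fold in folds
            )
            if ok:
                break
            logger.warning("repetition %d: single-class training fold, reshuffling", rep)
        else:
            raise RuntimeError("could not build two-class training folds")
        correct = 0
        with config_context(**_fast_sklearn):
            for fold in folds:
                test_mask = np.isin(dm.groups, fold)
                Xtr, Xte = _standardize(X[~test_mask], X[test_mask])
                ytr, yte = dm.y[~test_mask], dm.y[test_mask]
                C = _select_penalty(Xtr, ytr, dm.groups[~test_mask], c_grid, rng)
                clf = _fit_l1(Xtr, ytr, C)
                pred = (_prob_class1(clf, Xte) > 0.5).astype(int)
                correct += int((pred == yte).sum())
                selections += (np.abs(clf.coef_[0]) > 0).astype(float)
                n_models += 1
        accuracies[rep] = correct / len(dm.y)
    survival = pd.Series(100.0 * selections / n_models, index=dm.feature_names)
    return CVResult(accuracies=accuracies, survival_pct=survival, n_models=n_models)


def permutation_null(
    dm: DesignMatrix,
    n_perms: int = 10,
    k: int = 4,
    reps: int = 100,
    seed: int = 0,
    c_grid: Sequence[float] = DEFAULT_C_GRID,
) -> PermutationResult:
    """Rerun the repeated CV on animal-level label permutations.

    Every permutation shuffles the animal -> label assignment (all of an
    animal's sessions move together), preserving the label marginals.
    """
    if n_perms < 1:
        raise ValueError("need at least one permutation")
    animals, labels = dm.animal_labels()
    rng = np.random.default_rng(seed)
    results = []
    for p in range(n_perms):
        permuted = labels.copy()
        rng.shuffle(permuted)
        lab_map = dict(zip(animals, permuted))
        dm_p = DesignMatrix(
            X=dm.X, y=np.array([lab_map[g] for g in dm.groups]), groups=dm.groups
        )
        child = int(rng.integers(0, 2**31 - 1))
        results.append(fit_lasso_repeated_cv(dm_p, k=k, reps=reps, seed=child, c_grid=c_grid))
    return PermutationResult(per_permutation=results)


# ------------------------------------------------------------ effect size

def compare_distributions(
    observed: Sequence[float], null: Sequence[float]
) -> EffectSizeReport:
    """Mann-Whitney U with midranks, converted to Cohen's d.

    z uses the tie-corrected normal approximation; r = z / sqrt(N);
    d = 2 r / sqrt(1 - r^2).  d is positive when the observed sample
    stochastically dominates the null.
    """
    x = np.asarray(list(observed), dtype=float)
    y = np.asarray(list(null), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    U = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    mu = n1 * n2 / 2
    N = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (N * (N - 1)) if N > 1 else 0.0
    sigma2 = n1 * n2 / 12 * ((N + 1) - tie_term)
    if sigma2 <= 0:
        return EffectSizeReport(U=U, n1=n1, n2=n2, z=0.0, d=0.0, direction="none", degenerate=True)
    z = (U - mu) / np.sqrt(sigma2)
    r = z / np.sqrt(N)
    d = 2 * r / np.sqrt(max(1e-12, 1 - r**2))
    direction = "observed>null" if U > mu else ("observed<null" if U < mu else "none")
    return EffectSizeReport(U=U, n1=n1, n2=n2, z=float(z), d=float(d), direction=direction)


# ------------------------------------------------- univariate feature models

def univariate_logistic_loocv(
    feature: Sequence[float], y: Sequence[int], groups: Sequence
) -> tuple[float, str]:
    """Single-feature logistic model under leave-one-animal-out CV.

    Both sessions of the held-out animal leave together.  Returns the mean
    held-out accuracy over splits and the direction arrow (up if the
    class-1 mean exceeds the class-0 mean).  Fits use a very light L2
    ridge so separated training splits stay well-defined.
    """
    x = np.asarray(list(feature), dtype=float).reshape(-1, 1)
    y = np.asarray(list(y)).astype(int)
    groups = np.asarray(list(groups))
    animals, idx = np.unique(groups, return_index=True)
    alab = y[idx]
    if (alab == 0).sum() < 3 or (alab == 1).sum() < 3:
        raise ValueError("need >= 3 animals per class for leave-one-animal-out")
    accs = []
    for animal in animals:
        mask = groups == animal
        Xtr, Xte = _standardize(x[~mask], x[mask])
        clf = LogisticRegression(l1_ratio=0.0, C=1e6, solver="lbfgs", max_iter=1000)
        clf.fit(Xtr, y[~mask])
        accs.append(float((clf.predict(Xte) == y[mask]).mean()))
    direction = "↑" if x[y == 1].mean() > x[y == 0].mean() else "↓"
    return float(np.mean(accs)), direction


@dataclass
class FeatureReport:
    """Table-style top-k feature rankings for one model type."""

    logistic_top: pd.DataFrame  # direction, feature, pct_accuracy
    lasso_top: pd.DataFrame  # direction, feature, pct_survival
    univariate: pd.DataFrame  # full per-feature table


def build_feature_report(
    cv: CVResult,
    univariate: Mapping[str, tuple[float, str]],
    k: int = 5,
) -> FeatureReport:
    """Rank features by univariate % accuracy and by lasso % survival.

    Ties break by the other metric (descending) then by feature name, so
    the tables are deterministic.
    """
    names = list(cv.survival_pct.index)
    table = pd.DataFrame(
        {
            "feature": names,
            "pct_accuracy": [100.0 * univariate[n][0] for n in names],
            "direction": [univariate[n][1] for n in names],
            "pct_survival": [float(cv.survival_pct[n]) for n in names],
        }
    )
    if k > len(names):
        logger.warning("top-%d requested but only %d features; truncating", k, len(names))
        k = len(names)
    by_acc = table.sort_values(
        ["pct_accuracy", "pct_survival", "feature"], ascending=[False, False, True]
    ).head(k)
    by_surv = table.sort_values(
        ["pct_survival", "pct_accuracy", "feature"], ascending=[False, False, True]
    ).head(k)
    return FeatureReport(
        logistic_top=by_acc[["direction", "feature", "pct_accuracy"]].reset_index(drop=True),
        lasso_top=by_surv[["direction", "feature", "pct_survival"]].reset_index(drop=True),
        univariate=table,
    )
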