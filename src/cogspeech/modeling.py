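"""Modeling stage: ATN biomarker labeling, matched stratified splitting,
wrapper feature selection (NSGA-II and variable-length PSO), TPE
hyperparameter search, model fitting/evaluation, and the task registry.

Classification performance is optimized as balanced accuracy (BA), the
mean of sensitivity and specificity; regression as mean absolute error.
Feature selection and hyperparameter search see only the training set:
the split result carries a provenance token that evaluation verifies.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.metrics import (
    accuracy_score,
    balanced_accuracy_score,
    mean_absolute_error,
    precision_score,
    r2_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from ._types import CohortTable, CSFPanel

__all__ = [
    "ATN_ABETA_RATIO",
    "ATN_PTAU181",
    "ATN_TTAU",
    "label_atn",
    "SplitResult",
    "stratified_matched_split",
    "make_model",
    "cv_objective",
    "SelectionResult",
    "NSGA2FeatureSelector",
    "VLPSOFeatureSelector",
    "tpe_hyperparameter_search",
    "load_search_space",
    "EvalReport",
    "fit_and_evaluate",
    "TaskSpec",
    "build_task_registry",
    "run_task_suite",
]

# CSF positivity thresholds (strict inequalities)
ATN_ABETA_RATIO = 0.069  # A+ below
ATN_PTAU181 = 54.0       # T+ above (pg/mL)
ATN_TTAU = 412.0         # N+ above (pg/mL)


def label_atn(csf: CSFPanel | tuple) -> tuple[Optional[bool], Optional[bool], Optional[bool]]:
    """Dichotomize CSF analytes into (A, T, N) positivity flags.

    A+ iff the Aβ1-42/Aβ1-40 ratio is strictly below 0.069; T+ iff
    P-tau181 strictly exceeds 54 pg/mL; N+ iff T-tau strictly exceeds
    412 pg/mL. A missing analyte yields a None flag.
    """
    if not isinstance(csf, CSFPanel):
        csf = CSFPanel(*csf)
    a = None if csf.abeta_ratio is None else bool(csf.abeta_ratio < ATN_ABETA_RATIO)
    t = None if csf.ptau181 is None else bool(csf.ptau181 > ATN_PTAU181)
    n = None if csf.ttau is None else bool(csf.ttau > ATN_TTAU)
    return a, t, n


# ---------------------------------------------------------------------------
# Split


@dataclass
class SplitResult:
    train_ids: list[str]
    test_ids: list[str]
    seed_used: int
    n_attempts: int
    balanced: bool
    balance_pvalues: dict[str, float]

    @property
    def provenance_token(self) -> str:
        h = hashlib.sha256(
            ("|".join(sorted(self.test_ids)) + f"#{self.seed_used}").encode()
        )
        return h.hexdigest()[:16]


def _balance_pvalues(subjects: pd.DataFrame, train_ids: Sequence[str],
                     test_ids: Sequence[str], stratify_col: str) -> dict[str, float]:
    pvals: dict[str, float] = {}
    tr = subjects.loc[list(train_ids)]
    te = subjects.loc[list(test_ids)]
    for g in subjects[stratify_col].unique():
        a = tr[tr[stratify_col] == g]
        b = te[te[stratify_col] == g]
        if len(a) < 2 or len(b) < 2:
            continue
        for col in ("age", "education"):
            try:
                p = stats.mannwhitneyu(a[col], b[col],
                                       alternative="two-sided").pvalue
            except ValueError:
                p = 1.0
            pvals[f"{g}_{col}"] = float(p)
        tab = pd.crosstab(
            pd.Series(["train"] * len(a) + ["test"] * len(b)),
            pd.concat([a["sex"], b["sex"]]).values,
        )
        if tab.shape == (2, 2) and (tab.values.sum(axis=0) > 0).all():
            try:
                p = stats.chi2_contingency(tab.values)[1]
            except ValueError:
                p = 1.0
            pvals[f"{g}_sex"] = float(p)
    return pvals


def stratified_matched_split(
    table: CohortTable | pd.DataFrame,
    test_fraction: float = 0.2,
    seed: int = 0,
    max_retries: int = 25,
    stratify_col: str = "diagnosis",
) -> SplitResult:
    """80/20 split stratified by diagnosis with demographic matching.

    After each candidate split, per-group Mann-Whitney U tests (age,
    education) and chi-square tests (sex) compare train vs test;
    Bonferroni-corrected alpha 0.05. Failing splits are reshuffled with
    an incremented seed up to ``max_retries``; if exhausted, the
    best-seen split is returned with ``balanced=False`` and a warning.
    """
    subjects = table.subject_frame() if isinstance(table, CohortTable) else table
    counts = subjects[stratify_col].value_counts()
    small = counts[counts < 5]
    if not small.empty:
        raise ValueError(
            f"strata too small for a stratified split: {dict(small)}"
        )
    best: Optional[SplitResult] = None
    best_minp = -1.0
    for attempt in range(max_retries + 1):
        cur_seed = seed + attempt
        rng = np.random.default_rng(cur_seed)
        train_ids: list[str] = []
        test_ids: list[str] = []
        for g, idx in subjects.groupby(stratify_col).groups.items():
            ids = sorted(map(str, idx))
            n_test = max(1, int(round(test_fraction * len(ids))))
            perm = rng.permutation(len(ids))
            test_ids += [ids[i] for i in perm[:n_test]]
            train_ids += [ids[i] for i in perm[n_test:]]
        pvals = _balance_pvalues(subjects, train_ids, test_ids, stratify_col)
        alpha = 0.05 / max(1, len(pvals))
        ok = all(p > alpha for p in pvals.values())
        minp = min(pvals.values()) if pvals else 1.0
        result = SplitResult(sorted(train_ids), sorted(test_ids), cur_seed,
                             attempt + 1, ok, pvals)
        if ok:
            return result
        if minp > best_minp:
            best, best_minp = result, minp
    warnings.warn(
        "stratified split: demographic balance not achieved within "
        f"{max_retries} retries; returning best-seen split",
        stacklevel=2,
    )
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# Models


_FAMILIES = ("rf", "xgb", "svm", "knn", "dt", "lr")


def make_model(family: str, kind: str = "classification",
               params: Optional[dict] = None, seed: int = 0):
    """Instantiate a model pipeline for one family.

    Distance/margin-based families (svm, knn, lr) are standardized
    inside a sklearn Pipeline; tree ensembles are not.
    """
    params = dict(params or {})
    clf = kind == "classification"
    if family == "rf":
        from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

        cls = RandomForestClassifier if clf else RandomForestRegressor
        model = cls(n_estimators=params.pop("n_estimators", 100),
                    random_state=seed, n_jobs=1, **params)
    elif family == "xgb":
        from xgboost import XGBClassifier, XGBRegressor

        cls = XGBClassifier if clf else XGBRegressor
        model = cls(n_estimators=params.pop("n_estimators", 100),
                    random_state=seed, n_jobs=1, tree_method="hist",
                    verbosity=0, **params)
    elif family == "svm":
        from sklearn.svm import SVC, SVR

        model = (SVC(kernel="rbf", random_state=seed, **params) if clf
                 else SVR(kernel="rbf", **params))
    elif family == "knn":
        from sklearn.neighbors import KNeighborsClassifier, KNeighborsRegressor

        cls = KNeighborsClassifier if clf else KNeighborsRegressor
        model = cls(n_neighbors=params.pop("n_neighbors", 5), **params)
    elif family == "dt":
        from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

        cls = DecisionTreeClassifier if clf else DecisionTreeRegressor
        model = cls(random_state=seed, **params)
    elif family == "lr":
        if clf:
            from sklearn.linear_model import LogisticRegression

            model = LogisticRegression(max_iter=2000, random_state=seed, **params)
        else:
            from sklearn.linear_model import LinearRegression

            params.pop("C", None)
            model = LinearRegression(**params)
    else:
        raise ValueError(f"unknown model family {family!r}; choose from {_FAMILIES}")
    if family in ("svm", "knn", "lr"):
        return Pipeline([("scale", StandardScaler()), ("model", model)])
    return model


def cv_objective(
    X: np.ndarray,
    y: np.ndarray,
    model_family: str = "svm",
    mask: Optional[np.ndarray] = None,
    k: int = 5,
    seed: int = 0,
    kind: str = "classification",
    params: Optional[dict] = None,
) -> float:
    """Mean k-fold cross-validated balanced accuracy (classification,
    stratified folds) or mean absolute error (regression, plain folds)
    of a model restricted to the masked features."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("feature mask selects no features")
        X = X[:, mask]
    if kind == "classification":
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    scores = []
    for tr, va in splitter.split(X, y if kind == "classification" else None):
        model = make_model(model_family, kind, params, seed)
        model.fit(X[tr], y[tr])
        pred = model.predict(X[va])
        if kind == "classification":
            scores.append(balanced_accuracy_score(y[va], pred))
        else:
            scores.append(mean_absolute_error(y[va], pred))
    return float(np.mean(scores))


# ---------------------------------------------------------------------------
# Wrapper feature selection


@dataclass
class SelectionResult:
    mask: np.ndarray
    front: list[tuple[float, int, np.ndarray]]  # (performance, n_features, mask)
    selector: str
    seed: int
    cv_score: float
    n_evaluations: int = 0

    def __post_init__(self) -> None:
        if not np.any(self.mask):
            raise ValueError("chosen mask is empty")


def _pareto_front(points: list[tuple[float, int, np.ndarray]],
                  maximize_perf: bool) -> list[tuple[float, int, np.ndarray]]:
    """Non-dominated subset of (perf, count, mask) with unique (perf, count)."""
    front = []
    for p in points:
        dominated = False
        for q in points:
            better_perf = q[0] > p[0] if maximize_perf else q[0] < p[0]
            geq_perf = q[0] >= p[0] if maximize_perf else q[0] <= p[0]
            if (geq_perf and q[1] <= p[1]) and (better_perf or q[1] < p[1]):
                dominated = True
                break
        if not dominated:
            front.append(p)
    seen = set()
    out = []
    for p in sorted(front, key=lambda t: (t[1], -t[0] if maximize_perf else t[0])):
        key = (round(p[0], 12), p[1])
        if key not in seen:
            seen.add(key)
            out.append(p)
    return out


class _MaskEvaluator:
    """Caches objective evaluations keyed by the boolean mask."""

    def __init__(self, X, y, family, k, seed, kind, params=None):
        self.X, self.y = np.asarray(X, float), np.asarray(y)
        self.family, self.k, self.seed, self.kind = family, k, seed, kind
        self.params = params
        self.cache: dict[bytes, float] = {}

    def __call__(self, mask: np.ndarray) -> float:
        key = np.asarray(mask, bool).tobytes()
        if key not in self.cache:
            self.cache[key] = cv_objective(
                self.X, self.y, self.family, mask, self.k, self.seed,
                self.kind, self.params,
            )
        return self.cache[key]

    @property
    def n_evaluations(self) -> int:
        return len(self.cache)


def _repair(mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if not mask.any():
        mask = mask.copy()
        mask[rng.integers(mask.size)] = True
    return mask


def _fast_nondominated_sort(objs: np.ndarray) -> list[list[int]]:
    n = objs.shape[0]
    dominates = [[] for _ in range(n)]
    dominated_count = np.zeros(n, dtype=int)
    fronts: list[list[int]] = [[]]
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if np.all(objs[i] <= objs[j]) and np.any(objs[i] < objs[j]):
                dominates[i].append(j)
            elif np.all(objs[j] <= objs[i]) and np.any(objs[j] < objs[i]):
                dominated_count[i] += 1
        if dominated_count[i] == 0:
            fronts[0].append(i)
    f = 0
    while fronts[f]:
        nxt = []
        for i in fronts[f]:
            for j in dominates[i]:
                dominated_count[j] -= 1
                if dominated_count[j] == 0:
                    nxt.append(j)
        f += 1
        fronts.append(nxt)
    return fronts[:-1]


def _crowding_distance(objs: np.ndarray, front: list[int]) -> np.ndarray:
    dist = np.zeros(len(front))
    for m in range(objs.shape[1]):
        vals = objs[front, m]
        order = np.argsort(vals)
        dist[order[0]] = dist[order[-1]] = np.inf
        span = vals[order[-1]] - vals[order[0]]
        if span <= 0:
            continue
        for r in range(1, len(front) - 1):
            dist[order[r]] += (vals[order[r + 1]] - vals[order[r - 1]]) / span
    return dist


class NSGA2FeatureSelector(SelectorMixin, BaseEstimator):
    """Multi-objective wrapper feature selection with NSGA-II.

    Chromosomes are boolean feature masks; the two objectives are the
    cross-validated performance of an inner model (balanced accuracy
    maximized for classification, MAE minimized for regression) and the
    number of selected features (minimized). The chosen mask is the
    front member with the best performance, ties broken toward fewer
    features. Fitted attributes: ``support_``, ``pareto_front_``,
    ``selection_result_``.
    """

    def __init__(self, inner_family: str = "svm", kind: str = "classification",
                 pop_size: int = 100, n_gen: int = 50, cv: int = 5,
                 crossover_p: float = 0.9, mutation_p: Optional[float] = None,
                 random_state: int = 0):
        self.inner_family = inner_family
        self.kind = kind
        self.pop_size = pop_size
        self.n_gen = n_gen
        self.cv = cv
        self.crossover_p = crossover_p
        self.mutation_p = mutation_p
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y)
        n_features = X.shape[1]
        if n_features < 2:
            raise ValueError("need at least 2 features for wrapper selection")
        self.n_features_in_ = n_features
        rng = np.random.default_rng(self.random_state)
        evaluate = _MaskEvaluator(X, y, self.inner_family, self.cv,
                                  self.random_state, self.kind)
        maximize = self.kind == "classification"
        p_mut = self.mutation_p if self.mutation_p is not None else 1.0 / n_features

        def objs_of(mask: np.ndarray) -> tuple[float, float]:
            perf = evaluate(mask)
            return (-perf if maximize else perf, float(mask.sum()))

        pop = []
        for _ in range(self.pop_size):
            p = rng.uniform(0.1, 0.9)
            pop.append(_repair(rng.random(n_features) < p, rng))
        pop_objs = np.array([objs_of(m) for m in pop])

        for _gen in range(self.n_gen):
            fronts = _fast_nondominated_sort(pop_objs)
            rank = np.empty(len(pop), dtype=int)
            crowd = np.empty(len(pop))
            for fi, front in enumerate(fronts):
                rank[front] = fi
                crowd[front] = _crowding_distance(pop_objs, front)

            def tournament() -> int:
                i, j = rng.integers(len(pop)), rng.integers(len(pop))
                if rank[i] != rank[j]:
                    return i if rank[i] < rank[j] else j
                return i if crowd[i] >= crowd[j] else j

            children = []
            while len(children) < self.pop_size:
                a, b = pop[tournament()], pop[tournament()]
                if rng.random() < self.crossover_p:
                    take = rng.random(n_features) < 0.5
                    c1 = np.where(take, a, b)
                    c2 = np.where(take, b, a)
                else:
                    c1, c2 = a.copy(), b.copy()
                for c in (c1, c2):
                    flip = rng.random(n_features) < p_mut
                    c = np.logical_xor(c, flip)
                    children.append(_repair(c, rng))
            children = children[: self.pop_size]
            child_objs = np.array([objs_of(m) for m in children])

            union = pop + children
            union_objs = np.vstack([pop_objs, child_objs])
            fronts = _fast_nondominated_sort(union_objs)
            new_pop, new_objs = [], []
            for front in fronts:
                if len(new_pop) + len(front) <= self.pop_size:
                    new_pop += [union[i] for i in front]
                    new_objs += [union_objs[i] for i in front]
                else:
                    cd = _crowding_distance(union_objs, front)
                    order = np.argsort(-cd)
                    for r in order[: self.pop_size - len(new_pop)]:
                        new_pop.append(union[front[r]])
                        new_objs.append(union_objs[front[r]])
                    break
            pop, pop_objs = new_pop, np.array(new_objs)

        points = [
            ((-o[0] if maximize else o[0]), int(o[1]), m)
            for m, o in zip(pop, pop_objs)
        ]
        front = _pareto_front(points, maximize_perf=maximize)
        best = max(front, key=lambda t: (t[0], -t[1])) if maximize else \
            min(front, key=lambda t: (t[0], t[1]))
        self.support_ = best[2].astype(bool)
        self.pareto_front_ = front
        self.selection_result_ = SelectionResult(
            mask=self.support_, front=front, selector="nsga2",
            seed=self.random_state, cv_score=best[0],
            n_evaluations=evaluate.n_evaluations,
        )
        return self

    def _get_support_mask(self):
        return self.support_


class VLPSOFeatureSelector(SelectorMixin, BaseEstimator):
    """Variable-length particle swarm wrapper feature selection.

    Features are ranked by relevance (ANOVA F for classification,
    absolute correlation for regression); the swarm is split into
    divisions whose particle lengths cover increasing prefixes of the
    ranking. Particles use comprehensive learning (each dimension learns
    from a tournament-selected personal best), and when the global best
    stagnates the maximum length is renewed around the best particle's
    length. Fitness is the inner-model CV performance with a
    fewer-features tie-break.
    """

    def __init__(self, inner_family: str = "knn", kind: str = "classification",
                 swarm: int = 30, iters: int = 40, n_divisions: int = 6,
                 cv: int = 5, threshold: float = 0.6, stagnation: int = 7,
                 random_state: int = 0):
        self.inner_family = inner_family
        self.kind = kind
        self.swarm = swarm
        self.iters = iters
        self.n_divisions = n_divisions
        self.cv = cv
        self.threshold = threshold
        self.stagnation = stagnation
        self.random_state = random_state

    def _rank_features(self, X, y):
        if self.kind == "classification":
            from sklearn.feature_selection import f_classif

            f, _p = f_classif(X, y)
            f = np.nan_to_num(f)
        else:
            f = np.abs([stats.pearsonr(X[:, j], y)[0] if X[:, j].std() > 0 else 0.0
                        for j in range(X.shape[1])])
            f = np.nan_to_num(np.asarray(f))
        return np.argsort(-f)

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y)
        d = X.shape[1]
        if d < 2:
            raise ValueError("need at least 2 features for wrapper selection")
        self.n_features_in_ = d
        rng = np.random.default_rng(self.random_state)
        ranking = self._rank_features(X, y)
        evaluate = _MaskEvaluator(X, y, self.inner_family, self.cv,
                                  self.random_state, self.kind)
        maximize = self.kind == "classification"
        sign = 1.0 if maximize else -1.0

        def full_mask(pos: np.ndarray) -> np.ndarray:
            mask = np.zeros(d, dtype=bool)
            sel = pos > self.threshold
            mask[ranking[: pos.size][sel]] = True
            return _repair(mask, rng)

        def fitness(pos: np.ndarray) -> tuple[float, float]:
            mask = full_mask(pos)
            return sign * evaluate(mask), -float(mask.sum())

        ps = self.swarm
        ndiv = min(self.n_divisions, ps)
        lengths = [max(2, math.ceil(d * (j + 1) / ndiv)) for j in range(ndiv)]
        part_len = [lengths[min(j * ndiv // ps, ndiv - 1)] for j in range(ps)]
        pos = [rng.random(part_len[i]) for i in range(ps)]
        vel = [np.zeros(part_len[i]) for i in range(ps)]
        pbest = [p.copy() for p in pos]
        pbest_fit = [fitness(p) for p in pos]
        g = int(np.argmax([f[0] + 1e-9 * f[1] for f in pbest_fit]))
        gbest, gbest_fit = pbest[g].copy(), pbest_fit[g]
        pc = np.array([
            0.05 + 0.45 * (np.exp(10 * i / max(1, ps - 1)) - 1) / (np.exp(10) - 1)
            for i in range(ps)
        ])
        stagnant = 0
        c = 1.49445
        for it in range(self.iters):
            w = 0.9 - 0.5 * it / max(1, self.iters - 1)
            for i in range(ps):
                exemplar = np.empty(part_len[i])
                for k in range(part_len[i]):
                    if rng.random() < pc[i]:
                        a, b = rng.integers(ps), rng.integers(ps)
                        pick = a if pbest_fit[a] >= pbest_fit[b] else b
                    else:
                        pick = i
                    src = pbest[pick]
                    exemplar[k] = src[k] if k < src.size else pbest[i][k]
                vel[i] = w * vel[i] + c * rng.random(part_len[i]) * (exemplar - pos[i])
                np.clip(vel[i], -0.2, 0.2, out=vel[i])
                pos[i] = np.clip(pos[i] + vel[i], 0.0, 1.0)
                fit = fitness(pos[i])
                if fit > pbest_fit[i]:
                    pbest[i], pbest_fit[i] = pos[i].copy(), fit
            g = int(np.argmax([f[0] + 1e-9 * f[1] for f in pbest_fit]))
            if pbest_fit[g] > gbest_fit:
                gbest, gbest_fit = pbest[g].copy(), pbest_fit[g]
                stagnant = 0
            else:
                stagnant += 1
            if stagnant >= self.stagnation and it < self.iters - 1:
                # length renewal: re-center the division lengths on the
                # best particle's length and re-initialize exploration
                stagnant = 0
                lmax = max(2, gbest.size)
                lengths = [max(2, math.ceil(lmax * (j + 1) / ndiv))
                           for j in range(ndiv)]
                for i in range(ps):
                    newlen = lengths[min(i * ndiv // ps, ndiv - 1)]
                    old = pbest[i]
                    part_len[i] = newlen
                    pos[i] = rng.random(newlen)
                    pos[i][: min(newlen, old.size)] = old[: min(newlen, old.size)]
                    vel[i] = np.zeros(newlen)
                    pbest[i] = pos[i].copy()
                    pbest_fit[i] = fitness(pbest[i])

        mask = full_mask(gbest)
        perf = sign * gbest_fit[0]
        points = [(sign * f[0], int(-f[1]), full_mask(p))
                  for p, f in zip(pbest, pbest_fit)]
        self.support_ = mask
        self.pareto_front_ = _pareto_front(points, maximize_perf=maximize)
        self.selection_result_ = SelectionResult(
            mask=mask, front=self.pareto_front_, selector="vlpso",
            seed=self.random_state, cv_score=perf,
            n_evaluations=evaluate.n_evaluations,
        )
        return self

    def _get_support_mask(self):
        return self.support_


# ---------------------------------------------------------------------------
# TPE hyperparameter search


def load_search_space(family: str) -> dict:
    import importlib.resources

    import yaml

    text = (importlib.resources.files("cogspeech") / "resources"
            / "search_spaces.yaml").read_text()
    spaces = yaml.safe_load(text)
    if family not in spaces:
        raise ValueError(f"no search space defined for family {family!r}")
    return spaces[family]


def _sample_param(spec: dict, rng: np.random.Generator):
    if spec["type"] == "categorical":
        return spec["choices"][int(rng.integers(len(spec["choices"])))]
    lo, hi = float(spec["low"]), float(spec["high"])
    if spec.get("log"):
        v = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    else:
        v = float(rng.uniform(lo, hi))
    return int(round(v)) if spec["type"] == "int" else v


def _tpe_propose(spec: dict, good: list, bad: list,
                 rng: np.random.Generator, n_candidates: int = 24):
    """Propose one value maximizing the good/bad density ratio."""
    if spec["type"] == "categorical":
        choices = spec["choices"]
        gw = np.array([1.0 + sum(1 for v in good if v == c) for c in choices])
        bw = np.array([1.0 + sum(1 for v in bad if v == c) for c in choices])
        score = (gw / gw.sum()) / (bw / bw.sum())
        probs = gw / gw.sum()
        cand = rng.choice(len(choices), size=min(n_candidates, 4 * len(choices)),
                          p=probs)
        best = max(cand, key=lambda i: score[i])
        return choices[int(best)]
    lo, hi = float(spec["low"]), float(spec["high"])
    log = bool(spec.get("log"))
    tf = np.log if log else (lambda x: np.asarray(x, float))
    inv = np.exp if log else (lambda x: x)
    glo, ghi = tf(lo), tf(hi)
    gv = tf(np.asarray([float(v) for v in good]))
    bv = tf(np.asarray([float(v) for v in bad]))

    def kde_logpdf(x, obs):
        if obs.size == 0:
            return np.full(np.shape(x), -np.log(ghi - glo))
        bw = max(1.06 * (obs.std() + 1e-12) * obs.size ** (-0.2),
                 (ghi - glo) / 20)
        z = (np.asarray(x)[:, None] - obs[None, :]) / bw
        dens = np.exp(-0.5 * z**2).sum(axis=1) / (obs.size * bw * np.sqrt(2 * np.pi))
        return np.log(dens + 1e-300)

    if gv.size == 0:
        x = rng.uniform(glo, ghi, size=1)
    else:
        centers = gv[rng.integers(gv.size, size=n_candidates)]
        bw = max(1.06 * (gv.std() + 1e-12) * gv.size ** (-0.2), (ghi - glo) / 20)
        x = np.clip(centers + rng.normal(0, bw, size=n_candidates), glo, ghi)
    score = kde_logpdf(x, gv) - kde_logpdf(x, bv)
    v = float(inv(x[int(np.argmax(score))]))
    return int(round(v)) if spec["type"] == "int" else v


def tpe_hyperparameter_search(
    model_family: str,
    X: np.ndarray,
    y: np.ndarray,
    mask: Optional[np.ndarray] = None,
    n_iter: int = 1000,
    n_random: int = 500,
    cv: int = 5,
    seed: int = 0,
    kind: str = "classification",
    gamma: float = 0.25,
) -> tuple[dict, float]:
    """Sequential hyperparameter search with a tree-structured Parzen
    estimator surrogate.

    The first ``n_random`` iterations sample uniformly; afterwards each
    parameter is proposed by maximizing the density ratio between the
    top ``gamma`` quantile of observed configurations and the rest.
    Defaults are 1000 iterations with 500 random (budget-reducible).
    Returns (best_params, best_cv_score).
    """
    space = load_search_space(model_family)
    rng = np.random.default_rng(seed)
    maximize = kind == "classification"
    history: list[tuple[dict, float]] = []
    best_params: dict = {}
    best_score = -np.inf if maximize else np.inf
    for it in range(n_iter):
        if it < n_random or len(history) < 8:
            params = {name: _sample_param(spec, rng) for name, spec in space.items()}
        else:
            scores = np.array([s for _p, s in history])
            order = np.argsort(-scores if maximize else scores)
            n_good = max(1, int(np.ceil(gamma * len(history))))
            good_idx = set(order[:n_good].tolist())
            params = {}
            for name, spec in space.items():
                good = [history[i][0][name] for i in good_idx]
                bad = [history[i][0][name] for i in range(len(history))
                       if i not in good_idx]
                params[name] = _tpe_propose(spec, good, bad, rng)
        score = cv_objective(X, y, model_family, mask, cv, seed, kind, params)
        history.append((params, score))
        if (maximize and score > best_score) or (not maximize and score < best_score):
            best_params, best_score = dict(params), score
    return best_params, float(best_score)


# ---------------------------------------------------------------------------
# Evaluation


@dataclass
class EvalReport:
    task_name: str
    kind: str
    metrics: dict[str, float]
    predictions: pd.DataFrame  # index subject_id; columns y_true, y_pred[, score]
    model_family: str = ""
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind == "classification":
            for key in ("accuracy", "precision", "sensitivity", "specificity",
                        "auc", "balanced_accuracy"):
                v = self.metrics.get(key)
                if v is not None and not np.isnan(v) and not (0 <= v <= 1):
                    raise ValueError(f"metric {key}={v} outside [0, 1]")


def _decision_scores(model, X) -> np.ndarray:
    est = model.named_steps["model"] if isinstance(model, Pipeline) else model
    if hasattr(est, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    if hasattr(est, "decision_function"):
        return model.decision_function(X)
    return model.predict(X).astype(float)


def fit_and_evaluate(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    model_family: str = "svm",
    kind: str = "classification",
    mask: Optional[np.ndarray] = None,
    params: Optional[dict] = None,
    seed: int = 0,
    train_ids: Optional[Sequence[str]] = None,
    test_ids: Optional[Sequence[str]] = None,
    task_name: str = "",
) -> EvalReport:
    """Retrain on the full training set and evaluate on the held-out
    test set. Classification reports Acc/Pre/Sen/Spe/AUC (rank-based,
    midrank ties)/BA with sensitivity on the positive (more impaired /
    biomarker-positive) class; regression reports MAE/R²/Pearson r.
    Overlapping train and test ids are a hard error.
    """
    if train_ids is not None and test_ids is not None:
        overlap = set(train_ids) & set(test_ids)
        if overlap:
            raise ValueError(
                f"train/test provenance violation: shared subjects {sorted(overlap)[:5]}"
            )
    X_train = np.asarray(X_train, float)
    X_test = np.asarray(X_test, float)
    if mask is not None:
        mask = np.asarray(mask, bool)
        X_train, X_test = X_train[:, mask], X_test[:, mask]
    model = make_model(model_family, kind, params, seed)
    model.fit(X_train, y_train)
    pred = model.predict(X_test)
    index = list(test_ids) if test_ids is not None else list(range(len(y_test)))
    if kind == "classification":
        scores = _decision_scores(model, X_test)
        metrics = {
            "accuracy": float(accuracy_score(y_test, pred)),
            "precision": float(precision_score(y_test, pred, zero_division=0)),
            "sensitivity": float(recall_score(y_test, pred, pos_label=1,
                                              zero_division=0)),
            "specificity": float(recall_score(y_test, pred, pos_label=0,
                                              zero_division=0)),
            "balanced_accuracy": float(balanced_accuracy_score(y_test, pred)),
        }
        metrics["auc"] = (
            float(roc_auc_score(y_test, scores))
            if len(np.unique(y_test)) == 2 else float("nan")
        )
        preds = pd.DataFrame({"y_true": y_test, "y_pred": pred, "score": scores},
                             index=index)
    else:
        r = (stats.pearsonr(y_test, pred)[0]
             if np.std(pred) > 0 and np.std(y_test) > 0 else 0.0)
        metrics = {
            "mae": float(mean_absolute_error(y_test, pred)),
            "r2": float(r2_score(y_test, pred)),
            "pearson_r": float(r),
        }
        preds = pd.DataFrame({"y_true": y_test, "y_pred": pred}, index=index)
    return EvalReport(task_name=task_name, kind=kind, metrics=metrics,
                      predictions=preds, model_family=model_family,
                      params=dict(params or {}))


# ---------------------------------------------------------------------------
# Task registry and suite


@dataclass(frozen=True)
class TaskSpec:
    name: str
    kind: str  # classification | regression
    #: diagnosis labels forming the negative (less impaired) class
    negative: tuple[str, ...] = ()
    #: labels forming the positive class (classification)
    positive: tuple[str, ...] = ()
    #: ATN axis ("A"|"T"|"N") for biomarker tasks
    atn_axis: str = ""
    #: composite domain for regression tasks
    composite: str = ""
    baseline: bool = True


def build_task_registry(composites: Sequence[str] = ("memory",)) -> list[TaskSpec]:
    """The study's task registry: cognitive-impairment contrasts, ATN
    status prediction, and cognitive-composite regression."""
    ci = ("naMCI", "aMCI", "ADD")
    mci = ("naMCI", "aMCI")
    tasks = [
        TaskSpec("SCD_vs_CI", "classification", negative=("SCD",), positive=ci),
        TaskSpec("SCD_vs_ADD", "classification", negative=("SCD",), positive=("ADD",)),
        TaskSpec("MCI_vs_ADD", "classification", negative=mci, positive=("ADD",)),
        TaskSpec("SCD_vs_MCI", "classification", negative=("SCD",), positive=mci),
        TaskSpec("naMCI_vs_aMCI", "classification", negative=("naMCI",),
                 positive=("aMCI",)),
        TaskSpec("A_pos", "classification", atn_axis="A"),
        TaskSpec("T_pos", "classification", atn_axis="T"),
        TaskSpec("N_pos", "classification", atn_axis="N"),
    ]
    tasks += [TaskSpec(f"composite:{c}", "regression", composite=c)
              for c in composites]
    return tasks


def _task_labels(task: TaskSpec, table: CohortTable) -> tuple[np.ndarray, np.ndarray]:
    """Return (row_selector, y) for one task over the cohort table."""
    subj = table.subject_frame()
    if task.kind == "regression":
        y = np.array([r.composites.get(task.composite, np.nan)
                      for r in table.records])
        keep = ~np.isnan(y)
        return keep, y[keep]
    if task.atn_axis:
        flags = []
        for r in table.records:
            a, t, n = label_atn(r.csf) if r.csf else (None, None, None)
            flags.append({"A": a, "T": t, "N": n}[task.atn_axis])
        keep = np.array([f is not None for f in flags])
        y = np.array([1 if f else 0 for f, k in zip(flags, keep) if k])
        return keep, y
    dx = subj["diagnosis"].to_numpy()
    keep = np.isin(dx, task.negative + task.positive)
    y = np.isin(dx[keep], task.positive).astype(int)
    return keep, y


def run_task_suite(
    table: CohortTable,
    tasks: Optional[Sequence[TaskSpec]] = None,
    scopes: Sequence[str] = ("combined",),
    selectors: Sequence[str] = ("nsga2",),
    families: Sequence[str] = ("svm",),
    seed: int = 0,
    selection_budget: tuple[int, int] = (40, 20),
    tpe_budget: tuple[int, int] = (50, 25),
    cv: int = 5,
) -> dict:
    """Run the registered tasks over feature scopes, selectors and model
    families; emits per-run evaluation reports, selection results and a
    summary table. Tasks with a stratum below the split minimum are
    skipped with a warning.
    """
    tasks = list(tasks) if tasks is not None else build_task_registry()
    reports: dict[str, EvalReport] = {}
    selections: dict[str, SelectionResult] = {}
    rows = []
    for task in tasks:
        keep, y = _task_labels(task, table)
        if task.kind == "classification" and min(
            np.bincount(y, minlength=2)
        ) < 10:
            warnings.warn(f"task {task.name}: a class has <10 subjects; skipped",
                          stacklevel=2)
            continue
        records = [r for r, k in zip(table.records, keep) if k]
        ids = [r.subject_id for r in records]
        for scope in scopes:
            feat_names = [
                n for n in table.feature_names
                if scope == "combined" or table.feature_meta[n][1] == scope
            ]
            if not feat_names:
                continue
            X = table.features.loc[ids, feat_names].to_numpy(float)
            X = np.nan_to_num(X)
            subj = table.subject_frame().loc[ids]
            if task.kind == "classification":
                strat = pd.Series(y, index=ids, name="diagnosis")
                split_frame = subj.copy()
                split_frame["diagnosis"] = strat.astype(str).values
            else:
                split_frame = subj
            try:
                split = stratified_matched_split(split_frame, seed=seed)
            except ValueError as e:
                warnings.warn(f"task {task.name}: {e}", stacklevel=2)
                continue
            tr_idx = [ids.index(i) for i in split.train_ids]
            te_idx = [ids.index(i) for i in split.test_ids]
            for selector in selectors:
                sel_cls = (NSGA2FeatureSelector if selector == "nsga2"
                           else VLPSOFeatureSelector)
                if selector == "nsga2":
                    sel = sel_cls(kind=task.kind, pop_size=selection_budget[0],
                                  n_gen=selection_budget[1], cv=cv,
                                  random_state=seed)
                else:
                    sel = sel_cls(kind=task.kind, swarm=selection_budget[0],
                                  iters=selection_budget[1], cv=cv,
                                  random_state=seed)
                sel.fit(X[tr_idx], y[tr_idx])
                mask = sel.support_
                for family in families:
                    params, cv_score = tpe_hyperparameter_search(
                        family, X[tr_idx], y[tr_idx], mask,
                        n_iter=tpe_budget[0], n_random=tpe_budget[1],
                        cv=cv, seed=seed, kind=task.kind,
                    )
                    report = fit_and_evaluate(
                        X[tr_idx], y[tr_idx], X[te_idx], y[te_idx],
                        model_family=family, kind=task.kind, mask=mask,
                        params=params, seed=seed,
                        train_ids=split.train_ids, test_ids=split.test_ids,
                        task_name=task.name,
                    )
                    key = f"{task.name}|{scope}|{selector}|{family}"
                    reports[key] = report
                    selections[key] = sel.selection_result_
                    rows.append({
                        "task": task.name, "scope": scope,
                        "selector": selector, "model": family,
                        "n_features": int(mask.sum()),
                        "cv_score": cv_score, **report.metrics,
                    })
    return {
        "reports": reports,
        "selections": selections,
        "summary": pd.DataFrame(rows),
    }
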