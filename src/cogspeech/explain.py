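"""Shapley-value attribution, domain-normalized importance, and
demographic bias auditing.

Tree models (decision tree, random forest) get exact path-dependent
Shapley attributions computed over the tree structure with cover
weighting (base value + attributions reproduce the model output per
sample); gradient-boosted trees use the booster's native contribution
computation (margin space); kernel/distance models (SVM, KNN, logistic
regression) fall back to seeded permutation-sampling Shapley values
against a background sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.pipeline import Pipeline

from ._types import SubjectRecord

__all__ = [
    "AttributionReport",
    "BiasAudit",
    "shapley_attributions",
    "domain_importance",
    "bias_audit",
    "tree_shap_values",
]


@dataclass
class AttributionReport:
    values: np.ndarray  # (n_samples, n_features)
    base_value: float
    feature_names: list[str]
    method: str
    sample_ids: list = field(default_factory=list)

    def mean_abs(self) -> np.ndarray:
        return np.abs(self.values).mean(axis=0)

    def check_additivity(self, predictions: np.ndarray, atol: float = 1e-6) -> bool:
        return bool(np.allclose(self.base_value + self.values.sum(axis=1),
                                predictions, atol=atol))


# ---------------------------------------------------------------------------
# Exact path-dependent Shapley values for sklearn trees


class _Path:
    """Feature path bookkeeping for the polynomial-time tree algorithm.

    Each element tracks a feature on the current decision path: its
    index ``d``, the fraction of cover-weighted paths flowing through
    when the feature is unknown (``z``) or known (``o``), and the
    permutation weight ``w``.
    """

    __slots__ = ("d", "z", "o", "w")

    def __init__(self, d, z, o, w):
        self.d, self.z, self.o, self.w = d, z, o, w

    def copy(self):
        return _Path(self.d, self.z, self.o, self.w)


def _extend(m: list[_Path], pz: float, po: float, pi: int) -> list[_Path]:
    ln = len(m)
    m = [e.copy() for e in m]
    m.append(_Path(pi, pz, po, 1.0 if ln == 0 else 0.0))
    for i in range(ln - 1, -1, -1):
        m[i + 1].w += po * m[i].w * (i + 1) / (ln + 1)
        m[i].w = pz * m[i].w * (ln - i) / (ln + 1)
    return m


def _unwind(m: list[_Path], i: int) -> list[_Path]:
    ln = len(m)
    z, o = m[i].z, m[i].o
    n = m[ln - 1].w
    m = [e.copy() for e in m]
    for j in range(ln - 2, -1, -1):
        if o != 0:
            t = m[j].w
            m[j].w = n * ln / ((j + 1) * o)
            n = t - m[j].w * z * (ln - 1 - j) / ln
        else:
            m[j].w = m[j].w * ln / (z * (ln - 1 - j))
    for j in range(i, ln - 1):
        m[j].d, m[j].z, m[j].o = m[j + 1].d, m[j + 1].z, m[j + 1].o
    return m[: ln - 1]


def _unwound_sum(m: list[_Path], i: int) -> float:
    return float(sum(e.w for e in _unwind(m, i)))


def _single_tree_shap(x: np.ndarray, left, right, feature, threshold,
                      cover, values, n_features: int) -> np.ndarray:
    phi = np.zeros(n_features)

    def recurse(j: int, m: list[_Path], pz: float, po: float, pi: int) -> None:
        m = _extend(m, pz, po, pi)
        if left[j] < 0:  # leaf
            for i in range(1, len(m)):
                w = _unwound_sum(m, i)
                phi[m[i].d] += w * (m[i].o - m[i].z) * values[j]
            return
        d = feature[j]
        hot, cold = (left[j], right[j]) if x[d] <= threshold[j] else (right[j], left[j])
        iz = io = 1.0
        k = next((idx for idx in range(1, len(m)) if m[idx].d == d), None)
        if k is not None:
            iz, io = m[k].z, m[k].o
            m = _unwind(m, k)
        recurse(hot, m, iz * cover[hot] / cover[j], io, d)
        recurse(cold, m, iz * cover[cold] / cover[j], 0.0, d)

    recurse(0, [], 1.0, 1.0, -1)
    return phi


def _tree_arrays(decision_tree, classification: bool):
    t = decision_tree.tree_
    if classification:
        counts = t.value[:, 0, :]
        vals = counts[:, 1] / np.maximum(counts.sum(axis=1), 1e-300)
    else:
        vals = t.value[:, 0, 0]
    return (t.children_left, t.children_right, t.feature, t.threshold,
            t.weighted_n_node_samples, vals)


def _tree_expected(left, right, cover, values, j: int = 0) -> float:
    if left[j] < 0:
        return float(values[j])
    lw = cover[left[j]] / cover[j]
    return lw * _tree_expected(left, right, cover, values, left[j]) + \
        (1 - lw) * _tree_expected(left, right, cover, values, right[j])


def tree_shap_values(model, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Exact path-dependent Shapley values for sklearn tree models.

    Returns (phi, base) with ``base + phi.sum(axis=1)`` equal to the
    model output (class-1 probability for classifiers, prediction for
    regressors) per sample.
    """
    from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
    from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

    X = np.asarray(X, float)
    if isinstance(model, (DecisionTreeClassifier, DecisionTreeRegressor)):
        trees = [model]
        classification = isinstance(model, DecisionTreeClassifier)
    elif isinstance(model, (RandomForestClassifier, RandomForestRegressor)):
        trees = list(model.estimators_)
        classification = isinstance(model, RandomForestClassifier)
    else:
        raise TypeError(f"unsupported tree model {type(model).__name__}")
    n, m = X.shape
    phi = np.zeros((n, m))
    base = 0.0
    for tr in trees:
        left, right, feat, thr, cover, vals = _tree_arrays(tr, classification)
        base += _tree_expected(left, right, cover, vals)
        for i in range(n):
            phi[i] += _single_tree_shap(X[i], left, right, feat, thr, cover,
                                        vals, m)
    phi /= len(trees)
    base /= len(trees)
    return phi, float(base)


# ---------------------------------------------------------------------------
# Sampling Shapley for arbitrary models


def _model_output(model, X: np.ndarray) -> np.ndarray:
    est = model.named_steps["model"] if isinstance(model, Pipeline) else model
    if hasattr(est, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    if hasattr(est, "decision_function"):
        return model.decision_function(X)
    return np.asarray(model.predict(X), float)


def _sampling_shap(model, X: np.ndarray, background: np.ndarray,
                   n_permutations: int, rng: np.random.Generator
                   ) -> tuple[np.ndarray, float]:
    n, m = X.shape
    base = float(_model_output(model, background).mean())
    phi = np.zeros((n, m))
    for _ in range(n_permutations):
        perm = rng.permutation(m)
        bg = background[rng.integers(background.shape[0], size=n)]
        cur = bg.copy()
        prev_out = _model_output(model, cur)
        for j in perm:
            cur[:, j] = X[:, j]
            out = _model_output(model, cur)
            phi[:, j] += out - prev_out
            prev_out = out
    return phi / n_permutations, base


def shapley_attributions(
    model,
    X_test: np.ndarray,
    feature_names: Optional[Sequence[str]] = None,
    seed: int = 0,
    background: Optional[np.ndarray] = None,
    n_permutations: int = 30,
    sample_ids: Optional[Sequence] = None,
) -> AttributionReport:
    """Per-sample per-feature Shapley attributions for a fitted model.

    Decision trees and random forests use the exact path-dependent tree
    algorithm; gradient-boosted trees use the booster's native
    contributions (margin space); other models use permutation-sampling
    Shapley values against a background sample capped at 100 rows
    (default: the explained set itself).
    """
    X_test = np.asarray(X_test, float)
    if X_test.size == 0:
        raise ValueError("empty test set")
    names = (list(feature_names) if feature_names is not None
             else [f"x{j}" for j in range(X_test.shape[1])])
    inner = model.named_steps["model"] if isinstance(model, Pipeline) else model
    cls_name = type(inner).__name__
    if cls_name in ("DecisionTreeClassifier", "DecisionTreeRegressor",
                    "RandomForestClassifier", "RandomForestRegressor"):
        phi, base = tree_shap_values(inner, X_test)
        method = "tree_path_dependent"
    elif cls_name in ("XGBClassifier", "XGBRegressor"):
        import xgboost

        dm = xgboost.DMatrix(X_test)
        contribs = inner.get_booster().predict(dm, pred_contribs=True)
        phi, base = contribs[:, :-1], float(contribs[0, -1])
        method = "tree_path_dependent_margin"
    elif cls_name in ("SVC", "SVR", "KNeighborsClassifier",
                      "KNeighborsRegressor", "LogisticRegression",
                      "LinearRegression"):
        rng = np.random.default_rng(seed)
        bg = np.asarray(background, float) if background is not None else X_test
        if bg.shape[0] > 100:
            bg = bg[rng.choice(bg.shape[0], size=100, replace=False)]
        phi, base = _sampling_shap(model, X_test, bg, n_permutations, rng)
        method = "permutation_sampling"
    else:
        raise TypeError(
            f"unsupported model {cls_name}; supported: tree ensembles, "
            "XGB, SVC/SVR, KNN, logistic/linear regression"
        )
    return AttributionReport(values=phi, base_value=base, feature_names=names,
                             method=method,
                             sample_ids=list(sample_ids or range(X_test.shape[0])))


def domain_importance(report: AttributionReport,
                      groups: dict[str, str]) -> dict[str, float]:
    """Domain-normalized Shapley importance.

    For each domain, the mean |phi| of its features (across samples) is
    summed and divided by the number of features in the domain, so
    larger groups do not accumulate importance merely by size.
    """
    unmapped = [n for n in report.feature_names if n not in groups]
    if unmapped:
        raise ValueError(f"features without a domain mapping: {unmapped[:5]}")
    mean_abs = report.mean_abs()
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for name, v in zip(report.feature_names, mean_abs):
        d = groups[name]
        sums[d] = sums.get(d, 0.0) + float(v)
        counts[d] = counts.get(d, 0) + 1
    return {d: sums[d] / counts[d] for d in sums}


# ---------------------------------------------------------------------------
# Bias audit


@dataclass
class BiasAudit:
    sex_chi2: float
    sex_p: float
    sex_proportions: dict[str, float]
    age_t: float
    age_p: float
    age_means: tuple[float, float]  # (misclassified, correct)
    education_t: float
    education_p: float
    education_means: tuple[float, float]
    domain_sex_tests: dict[str, tuple[float, float]]  # domain -> (t, p)
    flags: dict[str, bool] = field(default_factory=dict)
    skipped: bool = False

    def __post_init__(self) -> None:
        for p in (self.sex_p, self.age_p, self.education_p,
                  *(p for _t, p in self.domain_sex_tests.values())):
            if not (np.isnan(p) or 0 <= p <= 1):
                raise ValueError(f"p-value {p} outside [0, 1]")


def bias_audit(
    predictions: pd.DataFrame,
    records: Sequence[SubjectRecord],
    attributions: Optional[AttributionReport] = None,
    feature_domains: Optional[dict[str, str]] = None,
    alpha: float = 0.05,
) -> BiasAudit:
    """Demographic bias audit of a classification evaluation.

    Sex: chi-square goodness-of-fit of the misclassified samples' sex
    counts against the full-dataset proportions. Age and education:
    Welch t-tests, misclassified vs correctly classified. Attribution
    bias: per-domain per-sample total |phi| compared between sexes with
    Welch t-tests. Flags are raised at the (unadjusted) alpha level.
    Fewer than two misclassified samples skips the tests.
    """
    by_id = {r.subject_id: r for r in records}
    ids = [str(i) for i in predictions.index]
    recs = [by_id[i] for i in ids]
    correct = (predictions["y_true"].to_numpy()
               == predictions["y_pred"].to_numpy())
    mis = ~correct
    nan = float("nan")
    if mis.sum() < 2:
        return BiasAudit(nan, nan, {}, nan, nan, (nan, nan), nan, nan,
                         (nan, nan), {}, {}, skipped=True)

    sexes = np.array([r.sex for r in recs])
    p_f_all = float(np.mean(sexes == "F"))
    mis_sex = sexes[mis]
    obs = np.array([(mis_sex == "F").sum(), (mis_sex == "M").sum()], float)
    exp = np.array([p_f_all, 1 - p_f_all]) * obs.sum()
    if (exp > 0).all():
        chi2, sex_p = stats.chisquare(obs, exp)
    else:
        chi2, sex_p = nan, nan
    ages = np.array([r.age for r in recs])
    edus = np.array([r.education for r in recs])

    def welch(a, b):
        if len(a) < 2 or len(b) < 2 or (np.std(a) == 0 and np.std(b) == 0):
            return nan, nan
        t, p = stats.ttest_ind(a, b, equal_var=False)
        return float(t), float(p)

    age_t, age_p = welch(ages[mis], ages[correct])
    edu_t, edu_p = welch(edus[mis], edus[correct])

    domain_tests: dict[str, tuple[float, float]] = {}
    if attributions is not None and feature_domains is not None:
        female = sexes == "F"
        doms = sorted(set(feature_domains.values()))
        for d in doms:
            cols = [j for j, n in enumerate(attributions.feature_names)
                    if feature_domains[n] == d]
            if not cols:
                continue
            totals = np.abs(attributions.values[:, cols]).sum(axis=1)
            domain_tests[d] = welch(totals[female], totals[~female])

    flags = {
        "sex": bool(sex_p < alpha) if not np.isnan(sex_p) else False,
        "age": bool(age_p < alpha) if not np.isnan(age_p) else False,
        "education": bool(edu_p < alpha) if not np.isnan(edu_p) else False,
    }
    for d, (_t, p) in domain_tests.items():
        flags[f"domain_{d}"] = bool(p < alpha) if not np.isnan(p) else False
    return BiasAudit(
        sex_chi2=float(chi2), sex_p=float(sex_p),
        sex_proportions={"dataset_F": p_f_all,
                         "misclassified_F": float(np.mean(mis_sex == "F"))},
        age_t=age_t, age_p=age_p,
        age_means=(float(ages[mis].mean()), float(ages[correct].mean())),
        education_t=edu_t, education_p=edu_p,
        education_means=(float(edus[mis].mean()), float(edus[correct].mean())),
        domain_sex_tests=domain_tests, flags=flags,
    )
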