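import math
from itertools import combinations
from math import factorial

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeRegressor

from cogspeech._types import SubjectRecord
from cogspeech.explain import (
    AttributionReport,
    bias_audit,
    domain_importance,
    shapley_attributions,
    tree_shap_values,
    _tree_arrays,
)


# --- brute-force Shapley oracle over the tree's conditional expectation -----

def cond_exp(x, S, left, right, feat, thr, cover, vals, j=0):
    if left[j] < 0:
        return vals[j]
    if feat[j] in S:
        nxt = left[j] if x[feat[j]] <= thr[j] else right[j]
        return cond_exp(x, S, left, right, feat, thr, cover, vals, nxt)
    lw = cover[left[j]] / cover[j]
    return lw * cond_exp(x, S, left, right, feat, thr, cover, vals, left[j]) \
        + (1 - lw) * cond_exp(x, S, left, right, feat, thr, cover, vals, right[j])


def brute_shapley(x, arrays, M):
    phi = np.zeros(M)
    for i in range(M):
        rest = [f for f in range(M) if f != i]
        for r in range(M):
            for S in combinations(rest, r):
                w = factorial(len(S)) * factorial(M - len(S) - 1) / factorial(M)
                phi[i] += w * (cond_exp(x, set(S) | {i}, *arrays)
                               - cond_exp(x, set(S), *arrays))
    return phi


class TestTreeShap:
    def test_matches_bruteforce_enumeration(self, rng):
        X = rng.normal(size=(150, 4))
        y = 2 * X[:, 0] + 3 * (X[:, 1] > 0) + rng.normal(0, 0.1, 150)
        tree = DecisionTreeRegressor(max_depth=4, random_state=0).fit(X, y)
        phi, base = tree_shap_values(tree, X[:5])
        arrays = _tree_arrays(tree, False)
        for i in range(5):
            want = brute_shapley(X[i], arrays, 4)
            assert np.allclose(phi[i], want, atol=1e-10)

    def test_additivity_for_forest(self, rng):
        X = rng.normal(size=(200, 5))
        y = (X[:, 0] + X[:, 2] > 0).astype(int)
        rf = RandomForestClassifier(n_estimators=15, max_depth=4,
                                    random_state=0).fit(X, y)
        rep = shapley_attributions(rf, X[:30], seed=0)
        proba = rf.predict_proba(X[:30])[:, 1]
        assert rep.check_additivity(proba, atol=1e-6)

    def test_dummy_feature_gets_zero(self, rng):
        from sklearn.tree import DecisionTreeClassifier

        X = rng.normal(size=(300, 3))
        y = (X[:, 0] > 0).astype(int)
        # greedy tree on a target that is a pure function of feature 0
        # never splits elsewhere, so other features must attribute ~0
        dt = DecisionTreeClassifier(random_state=0).fit(X, y)
        phi, _ = tree_shap_values(dt, X[:20])
        assert np.abs(phi[:, 1:]).max() <= 1e-6

    def test_xgboost_margin_additivity(self, rng):
        from xgboost import XGBClassifier

        X = rng.normal(size=(150, 4))
        y = (X[:, 0] - X[:, 3] > 0).astype(int)
        xgb = XGBClassifier(n_estimators=20, max_depth=3, random_state=0,
                            verbosity=0).fit(X, y)
        rep = shapley_attributions(xgb, X[:20], seed=0)
        import xgboost as xgblib

        margin = xgb.get_booster().predict(xgblib.DMatrix(X[:20]),
                                           output_margin=True)
        assert rep.check_additivity(margin, atol=1e-4)


class TestSamplingShap:
    def test_symmetric_duplicate_features_equal_in_expectation(self, rng):
        X = rng.normal(size=(120, 3))
        X[:, 1] = X[:, 0]  # exact duplicate
        y = (X[:, 0] > 0).astype(int)
        model = Pipeline([("s", StandardScaler()),
                          ("model", SVC(kernel="rbf", random_state=0))])
        model.fit(X, y)
        rep = shapley_attributions(model, X[:25], seed=0, n_permutations=60)
        a, b = np.abs(rep.values[:, 0]).mean(), np.abs(rep.values[:, 1]).mean()
        assert a == pytest.approx(b, rel=0.35)
        assert np.abs(rep.values[:, 2]).mean() < min(a, b)

    def test_seeded_reproducibility(self, rng):
        X = rng.normal(size=(60, 3))
        y = (X[:, 0] > 0).astype(int)
        model = Pipeline([("s", StandardScaler()),
                          ("model", SVC(random_state=0))]).fit(X, y)
        r1 = shapley_attributions(model, X[:10], seed=4, n_permutations=10)
        r2 = shapley_attributions(model, X[:10], seed=4, n_permutations=10)
        assert np.array_equal(r1.values, r2.values)

    def test_unsupported_model_rejected(self, rng):
        from sklearn.naive_bayes import GaussianNB

        X = rng.normal(size=(40, 2))
        y = (X[:, 0] > 0).astype(int)
        with pytest.raises(TypeError, match="supported"):
            shapley_attributions(GaussianNB().fit(X, y), X[:5])


class TestDomainImportance:
    def test_normalized_arithmetic(self):
        rep = AttributionReport(
            values=np.array([[2.0, 2.0, 1.5], [-2.0, 2.0, -1.5]]),
            base_value=0.0, feature_names=["a1", "a2", "b1"], method="t")
        scores = domain_importance(rep, {"a1": "A", "a2": "A", "b1": "B"})
        assert scores["A"] == pytest.approx(2.0)  # (2+2)/2 features
        assert scores["B"] == pytest.approx(1.5)

    def test_zero_attributions(self):
        rep = AttributionReport(np.zeros((3, 2)), 0.0, ["x", "y"], "t")
        scores = domain_importance(rep, {"x": "A", "y": "B"})
        assert scores == {"A": 0.0, "B": 0.0}

    def test_order_invariance(self, rng):
        vals = rng.normal(size=(10, 4))
        names = ["a", "b", "c", "d"]
        groups = {"a": "u", "b": "u", "c": "v", "d": "v"}
        rep1 = AttributionReport(vals, 0.0, names, "t")
        perm = [3, 1, 0, 2]
        rep2 = AttributionReport(vals[::-1][:, perm], 0.0,
                                 [names[i] for i in perm], "t")
        s1, s2 = domain_importance(rep1, groups), domain_importance(rep2, groups)
        for k in s1:
            assert s1[k] == pytest.approx(s2[k])

    def test_unmapped_feature_rejected(self):
        rep = AttributionReport(np.zeros((1, 2)), 0.0, ["x", "y"], "t")
        with pytest.raises(ValueError):
            domain_importance(rep, {"x": "A"})


def null_cohort(rng, n=120, p_correct=0.7):
    recs = [SubjectRecord(f"S{i}", "SCD", float(rng.normal(70, 7)),
                          "F" if rng.random() < 0.5 else "M",
                          float(rng.normal(11, 3)), 28.0) for i in range(n)]
    y = rng.integers(0, 2, n)
    correct = rng.random(n) < p_correct
    pred = np.where(correct, y, 1 - y)
    preds = pd.DataFrame({"y_true": y, "y_pred": pred},
                         index=[r.subject_id for r in recs])
    vals = rng.normal(0, 1, (n, 4))
    rep = AttributionReport(vals, 0.0, ["f1", "f2", "f3", "f4"], "t",
                            [r.subject_id for r in recs])
    doms = {"f1": "acoustic", "f2": "acoustic", "f3": "lexical", "f4": "lexical"}
    return recs, preds, rep, doms


class TestBiasAudit:
    def test_uniform_errors_no_sex_flag(self, rng):
        recs, preds, rep, doms = null_cohort(rng, n=400)
        audit = bias_audit(preds, recs, rep, doms)
        assert not audit.skipped
        assert audit.sex_p > 0.05 or math.isnan(audit.sex_p)

    def test_planted_age_effect_flagged(self, rng):
        n = 200
        recs = [SubjectRecord(f"S{i}", "SCD",
                              55.0 + (i >= n // 2) * 25.0 + float(rng.normal(0, 2)),
                              "F" if i % 2 else "M", 11.0, 28.0)
                for i in range(n)]
        y = np.zeros(n, int)
        pred = y.copy()
        pred[n // 2:] = 1  # all errors in the older half
        preds = pd.DataFrame({"y_true": y, "y_pred": pred},
                             index=[r.subject_id for r in recs])
        audit = bias_audit(preds, recs)
        assert audit.flags["age"]
        assert audit.age_means[0] > audit.age_means[1]

    def test_too_few_errors_skipped(self, rng):
        recs, preds, rep, doms = null_cohort(rng, n=30, p_correct=1.0)
        audit = bias_audit(preds, recs, rep, doms)
        assert audit.skipped

    def test_identical_attribution_distributions_rarely_flag(self, rng):
        flags = 0
        n_sims = 100
        for _ in range(n_sims):
            recs, preds, rep, doms = null_cohort(rng)
            audit = bias_audit(preds, recs, rep, doms)
            flags += audit.flags.get("domain_acoustic", False)
        assert flags / n_sims < 0.12
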