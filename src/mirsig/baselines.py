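"""Baseline classifiers trained with the protocol's fixed hyperparameters.

Stepwise procedures (backward-elimination LDA with an F-to-remove of 5,
backward stepwise logistic regression at p < 0.15 with second-order
interactions) are implemented natively; the base learners delegate to
scikit-learn / statsmodels.  Every trained model exposes a continuous
decision score where higher means more cancer-like, plus the list of
features actually retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import ElasticNet
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC

from .containers import ExpressionMatrix
from .evaluation import mann_whitney_auc

BASELINE_KINDS = ("lda", "logistic", "naive_bayes", "svm", "elastic_net", "random_forest")


@dataclass
class ZooModel:
    kind: str
    feature_names: list
    retained: list
    estimator: object
    params: dict = field(default_factory=dict)
    _score_fn: callable = None

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        cols = [self.feature_names.index(f) for f in self.retained]
        scores = self._score_fn(np.asarray(X, dtype=float)[:, cols])
        if not np.isfinite(scores).all():
            raise ValueError("non-finite decision scores")
        return scores


def _stepwise_lda(X: np.ndarray, y: np.ndarray, f_to_remove: float = 5.0) -> list:
    """Backward elimination by partial F (two-group discriminant analysis).

    For two groups the partial F of a variable given the others equals the
    squared t statistic of that variable in the least-squares regression of
    the group indicator on the variables, which is what is tested here.
    """
    keep = list(range(X.shape[1]))
    while len(keep) > 1:
        Xk = sm.add_constant(X[:, keep])
        fit = sm.OLS(y, Xk).fit()
        f_vals = fit.tvalues[1:] ** 2
        worst = int(np.argmin(f_vals))
        if f_vals[worst] >= f_to_remove:
            break
        keep.pop(worst)
    if len(keep) == 1:
        Xk = sm.add_constant(X[:, keep])
        f_last = sm.OLS(y, Xk).fit().tvalues[1] ** 2
        if f_last < f_to_remove:
            raise ValueError(
                "backward stepwise eliminated all features "
                f"(last partial F = {f_last:.3g} < {f_to_remove})"
            )
    return keep


def _stepwise_logistic(
    X: np.ndarray, y: np.ndarray, p_max: float = 0.15, interactions: bool = True
):
    """Backward stepwise logistic regression retaining terms with p < p_max.

    Candidate terms are the main effects plus, when the sample budget allows
    (terms <= n/3), all pairwise products.  Terms are removed one at a time
    by largest Wald p until all are below the threshold.
    """
    n, p = X.shape
    terms = [(j,) for j in range(p)]
    if interactions:
        inter = [(i, j) for i in range(p) for j in range(i + 1, p)]
        if p + len(inter) <= n // 3:
            terms += inter

    def design(term_list):
        cols = [X[:, t[0]] if len(t) == 1 else X[:, t[0]] * X[:, t[1]] for t in term_list]
        return sm.add_constant(np.column_stack(cols)) if cols else np.ones((n, 1))

    while terms:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fit = sm.Logit(y, design(terms)).fit(disp=0, maxiter=200)
                pvals = fit.pvalues[1:]
            except Exception:  # separation: fall back to regularized fit, keep all
                fit = sm.Logit(y, design(terms)).fit_regularized(alpha=1e-3, disp=0)
                break
        worst = int(np.argmax(pvals))
        if pvals[worst] < p_max or len(terms) == 1:
            break
        terms.pop(worst)
    if not terms:
        raise ValueError("backward stepwise eliminated all terms")
    return terms, fit


def train_baseline(
    kind: str,
    em_train: ExpressionMatrix,
    features,
    labels=None,
    params: dict | None = None,
    seed: int = 0,
) -> ZooModel:
    """Fit one baseline classifier on log-scale expression.

    Defaults per kind: LDA backward stepwise with F-to-remove 5; logistic
    backward stepwise at p < 0.15 with second-order interactions; Gaussian
    naive Bayes with empirical priors on log10 TPM; SVM grid over linear,
    polynomial (2nd/3rd) and RBF (gamma 0.1..1.0 step 0.1) kernels chosen by
    training AUC; elastic net used as classification-via-regression with
    mixing parameter 0.001; random forest with 100 trees considering
    K = int(1 + log2(p)) features per split.
    """
    if kind not in BASELINE_KINDS:
        raise ValueError(f"unknown baseline kind {kind!r}; expected one of {BASELINE_KINDS}")
    params = dict(params or {})
    sub = em_train.subset_features(features)
    X = sub.values.to_numpy().T
    y = (
        em_train.invasive_labels().to_numpy() if labels is None else np.asarray(labels)
    ).astype(int)
    names = list(features)

    if kind == "lda":
        keep = _stepwise_lda(X, y, params.get("f_to_remove", 5.0))
        retained = [names[j] for j in keep]
        est = LinearDiscriminantAnalysis().fit(X[:, keep], y)
        score = lambda Xr: est.decision_function(Xr)
    elif kind == "logistic":
        terms, fit = _stepwise_logistic(
            X, y, params.get("p_max", 0.15), params.get("interactions", True)
        )
        used = sorted({j for t in terms for j in t})
        retained = [names[j] for j in used]

        def score(Xr, _terms=terms, _fit=fit, _used=used):
            full = np.empty((len(Xr), X.shape[1]))
            full[:, _used] = Xr
            cols = [
                full[:, t[0]] if len(t) == 1 else full[:, t[0]] * full[:, t[1]]
                for t in _terms
            ]
            return sm.add_constant(np.column_stack(cols), has_constant="add") @ _fit.params

        est = fit
    elif kind == "naive_bayes":
        est = GaussianNB().fit(X, y)  # empirical priors by default
        retained = names
        score = lambda Xr: est.predict_proba(Xr)[:, 1]
    elif kind == "svm":
        grid = [{"kernel": "linear"}]
        grid += [{"kernel": "poly", "degree": d} for d in (2, 3)]
        grid += [{"kernel": "rbf", "gamma": round(g, 1)} for g in np.arange(0.1, 1.05, 0.1)]
        best, best_auc = None, -np.inf
        for g in grid:
            cand = SVC(C=params.get("C", 1.0), **g).fit(X, y)
            auc = mann_whitney_auc(cand.decision_function(X), y)
            if auc > best_auc:
                best, best_auc = cand, auc
        est = best
        retained = names
        score = lambda Xr: est.decision_function(Xr)
        params["kernel"] = est.kernel
    elif kind == "elastic_net":
        # classification via regression: one linear model per binarized class;
        # with a binary 0/1 target the two fits have opposite coefficients
        alpha_mix = params.get("l1_ratio", 0.001)
        lam = params.get("lam", 0.01)
        est = ElasticNet(alpha=lam, l1_ratio=alpha_mix, max_iter=50000).fit(X, y)
        neg = ElasticNet(alpha=lam, l1_ratio=alpha_mix, max_iter=50000).fit(X, 1 - y)
        retained = names
        params["coef_positive_class"] = est.coef_.tolist()
        params["coef_negative_class"] = neg.coef_.tolist()
        score = lambda Xr: est.predict(Xr)
    elif kind == "random_forest":
        k = int(1 + np.log2(X.shape[1]))
        est = RandomForestClassifier(
            n_estimators=params.get("n_trees", 100),
            max_features=min(k, X.shape[1]),
            random_state=seed,
        ).fit(X, y)
        retained = names
        params["max_features"] = min(k, X.shape[1])
        score = lambda Xr: est.predict_proba(Xr)[:, 1]

    return ZooModel(kind, names, retained, est, params, score)


def zoo_scores(model: ZooModel, em: ExpressionMatrix) -> pd.Series:
    missing = [f for f in model.feature_names if f not in em.values.index]
    if missing:
        raise KeyError(f"model features missing from input: {missing}")
    X = em.values.loc[model.feature_names].to_numpy().T
    return pd.Series(model.decision_scores(X), index=em.values.columns, name="score")
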