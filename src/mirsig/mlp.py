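"""Multilayer-perceptron restart search, prediction, and sensitivity pruning.

The diagnostic model is a single-hidden-layer perceptron over standardized
miRNA expression.  Architecture and link functions are sampled per restart:
hidden size uniformly from [ceil(n/3), ceil(1.5 n)] for n input features,
and hidden/output links independently from {linear, logistic, tanh,
exponential}.  Weights are fitted by BFGS on the back-propagated gradient
(cross-entropy loss for a logistic output, squared error otherwise, plus a
small L2 penalty for numerical stability).  Across restarts the network
with the best selection-set AUC is retained; ties break toward the smaller
hidden layer, then the earlier restart.

Selection policy: by default an internal validation split of the training
data is used for retention ("internal_validation"), because selecting on
the test set leaks information; the test-set policy used historically for
this kind of search is available as "test_set".
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

from .containers import ExpressionMatrix
from .evaluation import mann_whitney_auc

LINKS = ("linear", "logistic", "tanh", "exponential")


def _act(name: str, z: np.ndarray):
    """Activation value and derivative."""
    if name == "linear":
        return z, np.ones_like(z)
    if name == "logistic":
        s = expit(z)
        return s, s * (1 - s)
    if name == "tanh":
        t = np.tanh(z)
        return t, 1 - t**2
    if name == "exponential":
        e = np.exp(np.clip(z, -30.0, 30.0))
        return e, e
    raise ValueError(f"unknown link function {name!r}")


@dataclass
class MLPModel:
    """A trained network plus its input contract (features and standardizer)."""

    feature_names: list
    mu: np.ndarray
    sd: np.ndarray
    W1: np.ndarray  # h x n
    b1: np.ndarray  # h
    w2: np.ndarray  # h
    b2: float
    hidden_link: str
    output_link: str
    platform: str = "sequencing"  # "sequencing" | "qpcr" | "external"
    provenance: dict = field(default_factory=dict)

    @property
    def hidden_size(self) -> int:
        return self.W1.shape[0]

    def decision(self, X: np.ndarray) -> np.ndarray:
        Z = (X - self.mu) / self.sd
        H, _ = _act(self.hidden_link, Z @ self.W1.T + self.b1)
        return H @ self.w2 + self.b2

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        out, _ = _act(self.output_link, self.decision(np.asarray(X, dtype=float)))
        return np.clip(out, 0.0, 1.0)


def _pack(W1, b1, w2, b2):
    return np.concatenate([W1.ravel(), b1, w2, [b2]])


def _unpack(theta, h, n):
    i = h * n
    W1 = theta[:i].reshape(h, n)
    b1 = theta[i : i + h]
    w2 = theta[i + h : i + 2 * h]
    b2 = theta[i + 2 * h]
    return W1, b1, w2, b2


def _loss_grad(theta, Z, y, h, hidden_link, output_link, alpha):
    n = Z.shape[1]
    W1, b1, w2, b2 = _unpack(theta, h, n)
    pre_h = Z @ W1.T + b1
    H, dH = _act(hidden_link, pre_h)
    s = H @ w2 + b2
    N = len(y)
    if output_link == "logistic":
        # cross-entropy with logits, numerically stable
        loss = np.mean(np.logaddexp(0.0, s) - y * s)
        ds = (expit(s) - y) / N
    else:
        out, dout = _act(output_link, s)
        loss = np.mean((out - y) ** 2)
        ds = 2 * (out - y) * dout / N
    loss += 0.5 * alpha * (np.sum(W1**2) + np.sum(w2**2))
    gw2 = H.T @ ds + alpha * w2
    gb2 = ds.sum()
    dh = ds[:, None] * w2[None, :] * dH
    gW1 = dh.T @ Z + alpha * W1
    gb1 = dh.sum(axis=0)
    return loss, _pack(gW1, gb1, gw2, gb2)


def _bfgs(fun, x0, args, gtol: float = 1e-6, maxiter: int = 500):
    """Minimize fun (returning value and gradient) by BFGS.

    Dense inverse-Hessian update with Armijo backtracking; the update is
    skipped when the curvature condition fails, keeping the approximation
    positive definite.  Stops when the gradient's max-norm falls below
    ``gtol`` or after ``maxiter`` iterations.
    """
    x = np.asarray(x0, dtype=float)
    f, g = fun(x, *args)
    H = np.eye(len(x))
    for _ in range(maxiter):
        if np.abs(g).max(initial=0.0) < gtol:
            break
        p = -H @ g
        gp = g @ p
        if gp >= 0:  # numerical loss of descent direction: restart from steepest
            H = np.eye(len(x))
            p = -g
            gp = -(g @ g)
            if gp == 0:
                break
        alpha = 1.0
        for _ in range(30):
            xn = x + alpha * p
            fn, gn = fun(xn, *args)
            if np.isfinite(fn) and fn <= f + 1e-4 * alpha * gp:
                break
            alpha *= 0.5
        else:
            break  # line search failed
        s = xn - x
        yv = gn - g
        x, f, g = xn, fn, gn
        sy = s @ yv
        if sy > 1e-12:
            Hy = H @ yv
            H += ((sy + yv @ Hy) / sy**2) * np.outer(s, s)
            H -= (np.outer(Hy, s) + np.outer(s, Hy)) / sy
    return x


def hidden_size_bounds(n_features: int) -> tuple:
    """[ceil(n/3), ceil(1.5 n)] neurons for n input features."""
    return int(np.ceil(n_features / 3)), int(np.ceil(1.5 * n_features))


@dataclass
class SearchConfig:
    """Restart-search settings; ``restarts=5000`` reproduces full scale."""

    restarts: int = 200
    links: tuple = LINKS
    hidden_range: tuple | None = None  # default: rule from the feature count
    selection_policy: str = "internal_validation"  # or "test_set"
    val_fraction: float = 0.25
    max_iter: int = 500
    gtol: float = 1e-6
    alpha: float = 1e-3
    seed: int = 0


class MLPSearchClassifier(ClassifierMixin, BaseEstimator):
    """scikit-learn estimator running the restart search.

    With ``selection_policy="internal_validation"`` the training data are
    split into a fit and a validation part and the network with the best
    validation AUC is retained; any (X_select, y_select) passed to fit is
    scored in the log but never drives retention.  With
    ``"test_set"`` retention maximizes AUC on the supplied
    selection set.
    """

    def __init__(
        self,
        restarts: int = 200,
        links: tuple = LINKS,
        hidden_range: tuple | None = None,
        selection_policy: str = "internal_validation",
        val_fraction: float = 0.25,
        max_iter: int = 500,
        gtol: float = 1e-6,
        alpha: float = 1e-3,
        random_state: int = 0,
    ):
        self.restarts = restarts
        self.links = links
        self.hidden_range = hidden_range
        self.selection_policy = selection_policy
        self.val_fraction = val_fraction
        self.max_iter = max_iter
        self.gtol = gtol
        self.alpha = alpha
        self.random_state = random_state

    def fit(self, X, y, X_select=None, y_select=None, feature_names=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        if X.shape[1] == 0:
            raise ValueError("no input features")
        if len(np.unique(y)) < 2:
            raise ValueError("degenerate labels: both classes required")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")

        if self.selection_policy == "test_set":
            if X_select is None:
                raise ValueError("test_set policy needs a selection set")
            X_fit, y_fit = X, y
            X_sel = np.asarray(X_select, dtype=float)
            y_sel = np.asarray(y_select).astype(int)
        elif self.selection_policy == "internal_validation":
            X_fit, X_sel, y_fit, y_sel = train_test_split(
                X,
                y,
                test_size=self.val_fraction,
                stratify=y,
                random_state=self.random_state % (2**32),
            )
        else:
            raise ValueError(f"unknown selection policy {self.selection_policy!r}")
        if len(np.unique(y_sel)) < 2 or len(np.unique(y_fit)) < 2:
            raise ValueError("both classes required in fit and selection parts")

        n = X.shape[1]
        h_lo, h_hi = self.hidden_range or hidden_size_bounds(n)
        mu = X_fit.mean(axis=0)
        sd = X_fit.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        Z_fit = (X_fit - mu) / sd

        names = list(feature_names) if feature_names is not None else list(range(n))
        if X_select is not None and self.selection_policy == "internal_validation":
            ext = np.asarray(X_select, dtype=float)

        records = []
        best = None  # (selection_auc, -h, -restart) maximized
        for r in range(self.restarts):
            rng = np.random.default_rng([self.random_state, r])
            h = int(rng.integers(h_lo, h_hi + 1))
            hidden_link = str(rng.choice(self.links))
            output_link = str(rng.choice(self.links))
            theta0 = _pack(
                rng.normal(0, 1 / np.sqrt(n), size=(h, n)),
                np.zeros(h),
                rng.normal(0, 1 / np.sqrt(h), size=h),
                0.0,
            )
            theta = _bfgs(
                _loss_grad,
                theta0,
                args=(Z_fit, y_fit, h, hidden_link, output_link, self.alpha),
                gtol=self.gtol,
                maxiter=self.max_iter,
            )
            W1, b1, w2, b2 = _unpack(theta, h, n)
            model = MLPModel(
                names, mu, sd, W1, b1, w2, float(b2), hidden_link, output_link
            )
            train_auc = _safe_auc(model.predict_proba(X_fit), y_fit)
            sel_auc = _safe_auc(model.predict_proba(X_sel), y_sel)
            records.append(
                {
                    "restart": r,
                    "hidden_size": h,
                    "hidden_link": hidden_link,
                    "output_link": output_link,
                    "train_auc": train_auc,
                    "selection_auc": sel_auc,
                }
            )
            key = (sel_auc, -h, -r)
            if best is None or key > best[0]:
                best = (key, model)

        self.model_ = best[1]
        self.model_.provenance = {
            "seed": self.random_state,
            "restarts": self.restarts,
            "selection_policy": self.selection_policy,
            "hidden_range": [h_lo, h_hi],
        }
        self.search_log_ = pd.DataFrame(records)
        self.retained_index_ = int(
            self.search_log_.sort_values(
                ["selection_auc", "hidden_size", "restart"],
                ascending=[False, True, True],
                kind="stable",
            ).index[0]
        )
        self.selection_auc_ = float(self.search_log_.loc[self.retained_index_, "selection_auc"])
        if X_select is not None and self.selection_policy == "internal_validation":
            self.external_auc_ = _safe_auc(
                self.model_.predict_proba(ext), np.asarray(y_select).astype(int)
            )
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = n
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        p = self.model_.predict_proba(np.asarray(X, dtype=float))
        return np.column_stack([1 - p, p])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] > 0.5).astype(int)


def _safe_auc(scores, y) -> float:
    try:
        return mann_whitney_auc(scores, y)
    except ValueError:
        return 0.5


# ---------------------------------------------------------------------------
# functional wrappers on ExpressionMatrix


def _matrix_to_xy(em: ExpressionMatrix, labels, features):
    sub = em.subset_features(features)
    y = em.invasive_labels().to_numpy() if labels is None else np.asarray(labels)
    return sub.values.to_numpy().T, y.astype(int)


def mlp_search(
    em_train: ExpressionMatrix,
    em_select: ExpressionMatrix,
    features,
    cfg: SearchConfig,
    labels_train=None,
    labels_select=None,
):
    """Run the restart search; returns (MLPModel, search log DataFrame)."""
    X, y = _matrix_to_xy(em_train, labels_train, features)
    Xs, ys = _matrix_to_xy(em_select, labels_select, features)
    clf = MLPSearchClassifier(
        restarts=cfg.restarts,
        links=cfg.links,
        hidden_range=cfg.hidden_range,
        selection_policy=cfg.selection_policy,
        val_fraction=cfg.val_fraction,
        max_iter=cfg.max_iter,
        gtol=cfg.gtol,
        alpha=cfg.alpha,
        random_state=cfg.seed,
    ).fit(X, y, X_select=Xs, y_select=ys, feature_names=features)
    return clf.model_, clf.search_log_


def mlp_predict(model: MLPModel, em: ExpressionMatrix) -> pd.Series:
    """Probability of invasive cancer per sample."""
    missing = [f for f in model.feature_names if f not in em.values.index]
    if missing:
        raise KeyError(f"model features missing from input: {missing}")
    X = em.values.loc[model.feature_names].to_numpy().T
    return pd.Series(model.predict_proba(X), index=em.values.columns, name="probability")


def sensitivity_prune(
    model: MLPModel,
    em_train: ExpressionMatrix,
    em_select: ExpressionMatrix,
    cfg: SearchConfig,
    tolerance: float = 0.05,
    min_features: int = 2,
    labels_train=None,
    labels_select=None,
):
    """Iteratively drop the least informative input and retrain.

    Sensitivity of a feature is the ratio of the selection-set error
    (1 - AUC) when that feature is replaced by its training mean to the
    full-model error; the minimum-sensitivity feature is dropped and a
    fresh restart search is run on the reduced set.  Pruning continues
    while the selection AUC stays within ``tolerance`` of the incumbent
    best and more than ``min_features`` remain; a failing step is reverted.
    Returns (pruned model, trace DataFrame).
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    if len(model.feature_names) < 2:
        raise ValueError("model must have at least 2 features")

    def select_auc(m: MLPModel) -> float:
        X, y = _matrix_to_xy(em_select, labels_select, m.feature_names)
        return _safe_auc(m.predict_proba(X), y)

    current = model
    incumbent_auc = select_auc(model)
    trace = []
    step = 0
    while len(current.feature_names) > min_features:
        Xt, _ = _matrix_to_xy(em_train, labels_train, current.feature_names)
        Xs, ys = _matrix_to_xy(em_select, labels_select, current.feature_names)
        base_err = max(1.0 - _safe_auc(current.predict_proba(Xs), ys), 1e-9)
        train_means = Xt.mean(axis=0)
        sens = []
        for j in range(Xs.shape[1]):
            X_abl = Xs.copy()
            X_abl[:, j] = train_means[j]
            err = 1.0 - _safe_auc(current.predict_proba(X_abl), ys)
            sens.append(err / base_err)
        drop_j = int(np.argmin(sens))
        dropped = current.feature_names[drop_j]
        reduced = [f for f in current.feature_names if f != dropped]
        new_model, _ = mlp_search(
            em_train,
            em_select,
            reduced,
            replace(cfg, seed=cfg.seed + step + 1),
            labels_train,
            labels_select,
        )
        new_model.platform = model.platform
        new_auc = select_auc(new_model)
        accepted = incumbent_auc - new_auc <= tolerance
        trace.append(
            {
                "step": step,
                "dropped": dropped,
                "sensitivity": float(sens[drop_j]),
                "n_features": len(reduced),
                "selection_auc": new_auc,
                "accepted": accepted,
            }
        )
        if not accepted:
            break
        current = new_model
        incumbent_auc = max(incumbent_auc, new_auc)
        step += 1
    return current, pd.DataFrame(trace)
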