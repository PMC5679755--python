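"""The three variable-selection strategies and reference-gene stability.

* significance filter: per-miRNA Welch t-test with Benjamini-Hochberg FDR,
  keeping features with p < 0.05 and q < 0.05;
* convergent fold-change filter: linear fold change (invasive mean over
  non-invasive mean) outside the (0.8, 1.2) null band, in the same
  direction in every dataset;
* CFS: correlation-based feature-subset selection by best-first forward
  search over the merit k * r_cf / sqrt(k + k(k-1) * r_ff);
* NormFinder-style stability ranking: model-based decomposition of
  intra-group variance and shrunken inter-group difference, lower = more
  stable, used to pick qPCR reference assays.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix


@dataclass
class FeatureSelectionResult:
    method: str  # "significance" | "fold_change" | "cfs"
    selected: list
    stats: pd.DataFrame
    provenance: dict = field(default_factory=dict)


def _binary_labels(y) -> np.ndarray:
    y = np.asarray(y)
    if y.dtype == bool:
        return y.astype(int)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"expected two classes, got {classes.tolist()}")
    return (y == classes[1]).astype(int)


class TTestFDRSelector(SelectorMixin, BaseEstimator):
    """Welch two-sample t-test per feature with BH adjustment.

    Selects features with raw p < ``p_max`` AND BH-adjusted q < ``q_max``.
    Expects log-scale expression, samples x features.
    """

    def __init__(self, p_max: float = 0.05, q_max: float = 0.05):
        self.p_max = p_max
        self.q_max = q_max

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = _binary_labels(y)
        if min((y == 1).sum(), (y == 0).sum()) < 2:
            raise ValueError("each class needs at least 2 samples")
        with np.errstate(invalid="ignore", divide="ignore"):
            t, p = stats.ttest_ind(X[y == 1], X[y == 0], axis=0, equal_var=False)
        p = np.where(np.isnan(p), 1.0, p)
        _, q, _, _ = multipletests(p, method="fdr_bh")
        self.pvalues_ = p
        self.qvalues_ = q
        self.tvalues_ = np.where(np.isnan(t), 0.0, t)
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "pvalues_")
        return (self.pvalues_ < self.p_max) & (self.qvalues_ < self.q_max)


class FoldChangeSelector(SelectorMixin, BaseEstimator):
    """Convergent linear fold-change filter across datasets.

    Fold change is mean(X | positive) / mean(X | negative) per feature and
    dataset (linear TPM).  A feature is selected iff its fold change is
    strictly below ``low`` in every dataset, or strictly above ``high`` in
    every dataset.  Features with a zero negative-class mean in any dataset
    are skipped with a warning.
    """

    def __init__(self, low: float = 0.8, high: float = 1.2):
        self.low = low
        self.high = high

    def fit(self, X, y, *, dataset=None):
        X = np.asarray(X, dtype=float)
        y = _binary_labels(y)
        dataset = np.zeros(len(y), dtype=int) if dataset is None else np.asarray(dataset)
        fcs = []
        for d in pd.unique(dataset):
            m = dataset == d
            yd = y[m]
            if min((yd == 1).sum(), (yd == 0).sum()) < 1:
                raise ValueError(f"dataset {d!r} lacks one of the classes")
            pos = X[m][yd == 1].mean(axis=0)
            neg = X[m][yd == 0].mean(axis=0)
            with np.errstate(divide="ignore", invalid="ignore"):
                fcs.append(np.where(neg > 0, pos / np.where(neg > 0, neg, 1.0), np.nan))
        fc = np.stack(fcs, axis=0)  # datasets x features
        undefined = np.isnan(fc).any(axis=0)
        if undefined.any():
            warnings.warn(
                f"{int(undefined.sum())} feature(s) with zero negative-class mean skipped"
            )
        with np.errstate(invalid="ignore"):
            down = (fc < self.low).all(axis=0)
            up = (fc > self.high).all(axis=0)
        self.fold_changes_ = fc
        self.support_ = (down | up) & ~undefined
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


def cfs_merit(sum_rcf: float, sum_rff: float, k: int) -> float:
    """CFS merit k*r_cf / sqrt(k + k(k-1)*r_ff) from pair/feature sums."""
    if k == 0:
        return 0.0
    rcf = sum_rcf / k
    rff = sum_rff / (k * (k - 1) / 2) if k > 1 else 0.0
    return k * rcf / np.sqrt(k + k * (k - 1) * rff)


class CFSSelector(SelectorMixin, BaseEstimator):
    """Correlation-based feature-subset selection with best-first search.

    Relevance is the absolute point-biserial correlation between each
    (continuous) feature and the binary class; redundancy is the mean
    absolute Pearson correlation between selected features.  Best-first
    forward search starts from the empty set and stops after ``max_fails``
    consecutive expansions that fail to improve the best merit.  Ties are
    broken deterministically by feature index.  Constant features have
    correlation 0 by convention.
    """

    def __init__(self, max_fails: int = 5):
        self.max_fails = max_fails

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = _binary_labels(y).astype(float)
        n, p = X.shape
        if p < 1:
            raise ValueError("need at least one feature")

        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        xs = np.sqrt((Xc**2).sum(axis=0))
        ys = np.sqrt((yc**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r_cf = np.abs(Xc.T @ yc) / np.where(xs > 0, xs, 1.0) / (ys if ys > 0 else 1.0)
        r_cf = np.where((xs > 0) & (ys > 0), r_cf, 0.0)

        ff_cache: dict[int, np.ndarray] = {}

        def ff_col(f: int) -> np.ndarray:
            if f not in ff_cache:
                if xs[f] == 0:
                    ff_cache[f] = np.zeros(p)
                else:
                    with np.errstate(invalid="ignore", divide="ignore"):
                        col = np.abs(Xc.T @ Xc[:, f]) / np.where(xs > 0, xs, 1.0) / xs[f]
                    ff_cache[f] = np.where(xs > 0, col, 0.0)
            return ff_cache[f]

        # nodes: (subset tuple, sum r_cf, sum pairwise r_ff)
        best_set: tuple = ()
        best_merit = 0.0
        visited = {()}
        heap: list = [(-0.0, (), 0.0, 0.0)]
        fails = 0
        while heap and fails < self.max_fails:
            _, S, s_rcf, s_rff = heapq.heappop(heap)
            improved = False
            in_S = set(S)
            pair_sums = np.zeros(p)
            for g in S:
                pair_sums += ff_col(g)
            for f in range(p):
                if f in in_S:
                    continue
                S2 = tuple(sorted(S + (f,)))
                if S2 in visited:
                    continue
                visited.add(S2)
                m2 = cfs_merit(s_rcf + r_cf[f], s_rff + pair_sums[f], len(S2))
                heapq.heappush(heap, (-m2, S2, s_rcf + r_cf[f], s_rff + pair_sums[f]))
                if m2 > best_merit + 1e-12:
                    best_merit, best_set = m2, S2
                    improved = True
            fails = 0 if improved else fails + 1

        self.merit_ = float(best_merit)
        self.support_ = np.zeros(p, dtype=bool)
        self.support_[list(best_set)] = True
        self.class_correlations_ = r_cf
        self.n_features_in_ = p
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


class NormFinder(BaseEstimator):
    """Model-based reference-gene stability ranking.

    For each feature the per-group intra-group variance (after removing
    per-sample loading effects) and the inter-group mean difference are
    estimated; the difference is shrunk toward zero by the Bayesian factor
    gamma^2 / (gamma^2 + sigma^2/n), where gamma^2 is the across-feature
    variance of group differences.  Stability = mean over groups of
    |shrunken difference| + its posterior standard error; lower is more
    stable.  Invariant to per-feature location shifts and to per-sample
    global shifts.
    """

    def fit(self, X, groups):
        """X: samples x features (log scale or Cq); groups: per-sample labels."""
        X = np.asarray(X, dtype=float)
        groups = np.asarray(groups)
        levels = pd.unique(groups)
        if len(levels) < 2:
            raise ValueError("need at least two groups")
        Y = X.T  # features x samples
        G, _ = Y.shape
        if G < 2:
            raise ValueError("need at least two features")

        sigma2 = np.empty((G, len(levels)))
        group_means = np.empty((G, len(levels)))
        ns = np.empty(len(levels))
        for j, lev in enumerate(levels):
            m = groups == lev
            n_g = int(m.sum())
            if n_g < 2:
                raise ValueError(f"group {lev!r} has fewer than 2 samples")
            Yg = Y[:, m]
            row = Yg.mean(axis=1, keepdims=True)
            col = Yg.mean(axis=0, keepdims=True)
            R = Yg - row - col + Yg.mean()
            sigma2[:, j] = (R**2).sum(axis=1) / ((n_g - 1) * (G - 1) / G)
            group_means[:, j] = row[:, 0]
            ns[j] = n_g

        d = group_means - group_means.mean(axis=1, keepdims=True)
        d -= d.mean(axis=0, keepdims=True)
        nb = len(levels)
        gamma2 = max(
            0.0,
            (d**2).sum() / ((G - 1) * (nb - 1)) - (sigma2 / ns[None, :]).mean(),
        )
        se2 = sigma2 / ns[None, :]
        shrink = gamma2 / (gamma2 + se2) if gamma2 > 0 else np.zeros_like(se2)
        d_tilde = d * shrink
        post_var = se2 * shrink if gamma2 > 0 else np.zeros_like(se2)
        self.stability_ = (np.abs(d_tilde) + np.sqrt(post_var)).mean(axis=1)
        self.group_differences_ = d
        self.intra_group_variance_ = sigma2
        self.n_features_in_ = G
        return self

    def rank(self) -> np.ndarray:
        check_is_fitted(self, "stability_")
        return np.argsort(self.stability_, kind="stable")


# ---------------------------------------------------------------------------
# thin functional wrappers operating on ExpressionMatrix objects


def ttest_fdr_select(
    em: ExpressionMatrix, labels=None, p_max: float = 0.05, q_max: float = 0.05
) -> FeatureSelectionResult:
    if em.scale != "log10":
        raise ValueError("significance filter expects log-scale expression")
    y = em.invasive_labels().to_numpy() if labels is None else np.asarray(labels)
    sel = TTestFDRSelector(p_max=p_max, q_max=q_max).fit(em.values.to_numpy().T, y)
    table = pd.DataFrame(
        {"t": sel.tvalues_, "p": sel.pvalues_, "q": sel.qvalues_}, index=em.values.index
    )
    selected = list(em.values.index[sel.get_support()])
    return FeatureSelectionResult(
        "significance", selected, table, {"p_max": p_max, "q_max": q_max}
    )


def foldchange_select(
    em_by_dataset: list[ExpressionMatrix],
    labels_by_dataset=None,
    low: float = 0.8,
    high: float = 1.2,
) -> FeatureSelectionResult:
    if not em_by_dataset:
        raise ValueError("empty dataset list")
    index = em_by_dataset[0].values.index
    Xs, ys, ds = [], [], []
    for d, em in enumerate(em_by_dataset):
        if em.scale != "linear":
            raise ValueError("fold-change filter expects linear TPM")
        if not em.values.index.equals(index):
            raise ValueError("datasets must share the feature universe")
        y = (
            em.invasive_labels().to_numpy()
            if labels_by_dataset is None
            else np.asarray(labels_by_dataset[d])
        )
        Xs.append(em.values.to_numpy().T)
        ys.append(y.astype(int))
        ds.append(np.full(len(y), d))
    sel = FoldChangeSelector(low=low, high=high).fit(
        np.vstack(Xs), np.concatenate(ys), dataset=np.concatenate(ds)
    )
    table = pd.DataFrame(
        sel.fold_changes_.T, index=index, columns=[f"fc_dataset{d}" for d in range(len(Xs))]
    )
    selected = list(index[sel.get_support()])
    return FeatureSelectionResult("fold_change", selected, table, {"low": low, "high": high})


def cfs_select(em: ExpressionMatrix, labels=None, max_fails: int = 5) -> FeatureSelectionResult:
    if em.values.shape[0] < 2:
        raise ValueError("need at least two features")
    y = em.invasive_labels().to_numpy() if labels is None else np.asarray(labels)
    sel = CFSSelector(max_fails=max_fails).fit(em.values.to_numpy().T, y)
    table = pd.DataFrame({"r_cf": sel.class_correlations_}, index=em.values.index)
    selected = list(em.values.index[sel.get_support()])
    return FeatureSelectionResult("cfs", selected, table, {"merit": sel.merit_})


def normfinder_rank(em, groups=None, top_k: int = 2):
    """Rank features by stability (lowest first); returns (table, top-k ids).

    Accepts a log-scale ExpressionMatrix or a plain DataFrame (e.g. Cq
    values), features x samples.
    """
    if isinstance(em, ExpressionMatrix):
        if em.scale == "linear":
            raise ValueError("stability ranking expects log-scale expression")
        values = em.values
        if groups is None:
            groups = em.invasive_labels().to_numpy()
    else:
        values = em
        if groups is None:
            raise ValueError("groups required for plain matrices")
    nf = NormFinder().fit(values.to_numpy().T, np.asarray(groups))
    table = pd.DataFrame({"stability": nf.stability_}, index=values.index).sort_values(
        "stability", kind="stable"
    )
    return table, list(table.index[:top_k])
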