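"""Counts -> analysis-ready expression: TPM, log transform, prevalence
filtering, empirical-Bayes batch adjustment, and the stratified train/test
split.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import CountMatrix, ExpressionMatrix, SplitAssignment


def tpm_normalize(cm: CountMatrix) -> ExpressionMatrix:
    """Tags per million: reads for a miRNA / total mapped reads x 1e6."""
    zero = cm.total_reads <= 0
    if zero.any():
        raise ValueError(
            f"zero total mapped reads for samples: {cm.total_reads.index[zero].tolist()}"
        )
    values = cm.counts.div(cm.total_reads, axis=1) * 1e6
    return ExpressionMatrix(values, scale="linear")


def log_transform(em: ExpressionMatrix) -> ExpressionMatrix:
    """log10(TPM + 1); refuses to double-transform."""
    if em.scale != "linear":
        raise ValueError("matrix is already log scale")
    return ExpressionMatrix(np.log10(em.values + 1.0), scale="log10", sheet=em.sheet)


def filter_prevalence(
    em_by_dataset: list[ExpressionMatrix],
    threshold: float = 10.0,
    min_fraction: float = 0.5,
) -> list:
    """Features detected (TPM >= threshold) in >= min_fraction of samples of
    EVERY dataset; order follows the first dataset's feature order."""
    if not em_by_dataset:
        raise ValueError("empty dataset list")
    for em in em_by_dataset:
        if em.scale != "linear":
            raise ValueError("prevalence filter expects linear TPM")
    keep = None
    for em in em_by_dataset:
        frac = (em.values >= threshold).mean(axis=1)
        ok = frac[frac >= min_fraction].index
        keep = ok if keep is None else keep.intersection(ok, sort=False)
    first = em_by_dataset[0].values.index
    return [f for f in first if f in set(keep)]


def combat_adjust(em: ExpressionMatrix, batch) -> ExpressionMatrix:
    """Parametric empirical-Bayes location/scale batch adjustment.

    Per feature the data are standardized against the library-size-weighted
    grand mean and pooled variance; per-batch additive (location) and
    multiplicative (scale) effects are estimated and shrunk toward
    batch-level priors (normal for location, inverse gamma for scale) by the
    usual iterative conditional-posterior solution, then removed.  After
    back-transformation each feature is re-centred on its original grand
    mean.  Constant features are passed through unchanged with a warning.
    """
    if em.scale != "log10":
        raise ValueError("batch adjustment expects a log-scale matrix")
    batch = pd.Series(batch, index=em.values.columns) if not isinstance(batch, pd.Series) else batch
    batch = batch.reindex(em.values.columns)
    if batch.isna().any():
        raise ValueError("batch label missing for some samples")
    levels = batch.unique().tolist()
    sizes = batch.value_counts()
    if (sizes < 2).any():
        small = sizes.index[sizes < 2].tolist()
        raise ValueError(f"batches with fewer than 2 samples: {small}")
    if len(levels) == 1:
        return ExpressionMatrix(em.values.copy(), em.scale, em.sheet)

    X = em.values.to_numpy(dtype=float)
    adjusted = _combat_array(X, batch.to_numpy(), levels)
    return ExpressionMatrix(
        pd.DataFrame(adjusted, index=em.values.index, columns=em.values.columns),
        scale=em.scale,
        sheet=em.sheet,
    )


def _combat_array(X: np.ndarray, batch: np.ndarray, levels: list) -> np.ndarray:
    G, N = X.shape
    masks = [batch == b for b in levels]
    n_b = np.array([m.sum() for m in masks])

    batch_means = np.stack([X[:, m].mean(axis=1) for m in masks], axis=1)  # G x B
    grand_mean = batch_means @ (n_b / N)
    resid = X.copy()
    for i, m in enumerate(masks):
        resid[:, m] -= batch_means[:, [i]]
    var_pooled = (resid**2).sum(axis=1) / N

    constant = var_pooled <= 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant feature(s) passed through unadjusted",
            UserWarning,
            stacklevel=3,
        )
    sd = np.sqrt(np.where(constant, 1.0, var_pooled))

    Z = (X - grand_mean[:, None]) / sd[:, None]
    gamma_hat = np.stack([Z[:, m].mean(axis=1) for m in masks], axis=1)
    delta_hat = np.stack([Z[:, m].var(axis=1, ddof=1) for m in masks], axis=1)

    gamma_bar = gamma_hat.mean(axis=0)
    tau2 = gamma_hat.var(axis=0, ddof=1)
    d_mean = delta_hat.mean(axis=0)
    d_var = delta_hat.var(axis=0, ddof=1)
    a_prior = (2 * d_var + d_mean**2) / np.where(d_var > 0, d_var, 1.0)
    b_prior = (d_mean * d_var + d_mean**3) / np.where(d_var > 0, d_var, 1.0)

    gamma_star = np.empty_like(gamma_hat)
    delta_star = np.empty_like(delta_hat)
    for i, m in enumerate(masks):
        g_new = gamma_hat[:, i].copy()
        d_new = delta_hat[:, i].copy()
        n = n_b[i]
        Zb = Z[:, m]
        for _ in range(100):
            g_old, d_old = g_new, d_new
            g_new = (tau2[i] * n * gamma_hat[:, i] + d_old * gamma_bar[i]) / (
                tau2[i] * n + d_old
            )
            sum2 = ((Zb - g_new[:, None]) ** 2).sum(axis=1)
            d_new = (0.5 * sum2 + b_prior[i]) / (n / 2 + a_prior[i] - 1)
            if max(
                np.abs(g_new - g_old).max(initial=0), np.abs(d_new - d_old).max(initial=0)
            ) < 1e-4:
                break
        gamma_star[:, i] = g_new
        delta_star[:, i] = d_new

    Z_adj = Z.copy()
    for i, m in enumerate(masks):
        Z_adj[:, m] = (Z[:, m] - gamma_star[:, [i]]) / np.sqrt(delta_star[:, [i]])
    out = Z_adj * sd[:, None] + grand_mean[:, None]
    # EB shrinkage leaves a small residual offset; restore each feature's grand mean
    out += (grand_mean - out.mean(axis=1))[:, None]
    out[constant] = X[constant]
    return out


class CombatAdjuster(TransformerMixin, BaseEstimator):
    """scikit-learn transformer facade over :func:`combat_adjust`.

    Operates on X of shape (n_samples, n_features); the batch vector is a
    fit parameter.  Adjustment is computed on the fitted data itself
    (``fit_transform``); there is no out-of-sample transform, matching how
    batch adjustment is used in this pipeline.
    """

    def fit(self, X, y=None, *, batch=None):
        self.fit_transform(X, y, batch=batch)
        return self

    def fit_transform(self, X, y=None, *, batch=None):
        if batch is None:
            raise ValueError("CombatAdjuster requires a batch vector")
        X = np.asarray(X, dtype=float)
        batch = np.asarray(batch)
        levels = pd.unique(batch).tolist()
        if len(levels) == 1:
            self.adjusted_ = X.copy()
            return self.adjusted_
        sizes = pd.Series(batch).value_counts()
        if (sizes < 2).any():
            raise ValueError("batches with fewer than 2 samples")
        self.adjusted_ = _combat_array(X.T, batch, levels).T
        return self.adjusted_

    def transform(self, X):
        raise NotImplementedError("batch adjustment has no out-of-sample transform")


def stratified_split(
    sheet: pd.DataFrame, ratio: float = 0.75, seed: int = 0
) -> SplitAssignment:
    """Randomize samples into train/test within each pathology stratum.

    Each stratum contributes round(ratio * n) training samples, so the
    per-stratum train fraction is within one sample of the global ratio.
    Strata smaller than two samples go wholly to train with a warning.
    """
    if "pathology" not in sheet.columns:
        raise ValueError("sample sheet lacks pathology classes")
    if not 0 < ratio <= 1:
        raise ValueError("ratio must be in (0, 1]")
    rng = np.random.default_rng(seed)
    assignment = pd.Series(index=sheet.index, dtype=object)
    rows = []
    for cls, grp in sheet.groupby("pathology", sort=True):
        ids = np.array(grp.index)
        if len(ids) < 2:
            warnings.warn(f"stratum {cls!r} has <2 samples; placed wholly in train")
            assignment[ids] = "train"
            rows.append((cls, len(ids), 0))
            continue
        perm = rng.permutation(len(ids))
        n_train = int(round(ratio * len(ids)))
        n_train = min(max(n_train, 1), len(ids) if ratio == 1.0 else len(ids) - 1)
        train_ids = ids[perm[:n_train]]
        assignment[ids] = "test"
        assignment[train_ids] = "train"
        rows.append((cls, n_train, len(ids) - n_train))
    report = pd.DataFrame(rows, columns=["pathology", "train", "test"]).set_index("pathology")
    return SplitAssignment(assignment=assignment, ratio=ratio, seed=seed, stratum_counts=report)
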