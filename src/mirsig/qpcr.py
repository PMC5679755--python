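"""qPCR QC, delta-Cq normalization, and cross-platform recalibration.

QC rules mirror the vendor workflow: reactions with aberrant melt curves,
amplification efficiency below 1.6, or a Cq within 5 cycles of the
assay's no-template negative control are removed.  Undetected reactions
get the 37-cycle detection floor imputed.  Delta-Cq is computed either
against the per-sample global mean of universally detected assays or
against the average of two stable reference assays; in both cases the sign
convention is reference minus target, so higher delta-Cq means more
abundant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CqMatrix, ExpressionMatrix
from .mlp import MLPModel, SearchConfig, mlp_search
from .selection import normfinder_rank


def qc_filter(cq: CqMatrix):
    """Remove failing reactions; returns (filtered CqMatrix, removal log).

    Rules are applied in order — melt flag, efficiency < 1.6, Cq within 5
    cycles of the negative control — and each removed reaction is counted
    once, under the first rule it violates.
    """
    for name in ("efficiency", "melt_flag", "negctrl_cq"):
        ann = getattr(cq, name)
        if np.asarray(pd.isna(ann)).any():
            raise ValueError(f"missing QC annotation {name!r}")
    out = cq.copy()
    detected = out.cq.notna().to_numpy()
    melt = out.melt_flag.to_numpy(dtype=bool) & detected
    eff = (out.efficiency.to_numpy() < 1.6) & detected & ~melt
    with np.errstate(invalid="ignore"):
        neg = (
            (out.cq.to_numpy() >= out.negctrl_cq.to_numpy()[:, None] - 5.0)
            & detected
            & ~melt
            & ~eff
        )
    removed = melt | eff | neg
    vals = out.cq.to_numpy(dtype=float).copy()
    vals[removed] = np.nan
    out.cq = pd.DataFrame(vals, index=cq.cq.index, columns=cq.cq.columns)
    log = {
        "melt": int(melt.sum()),
        "efficiency": int(eff.sum()),
        "negative_control": int(neg.sum()),
    }
    return out, log


def impute_undetected(cq: CqMatrix, floor: float = 37.0) -> CqMatrix:
    """Set undetected reactions to the detection floor; clamp later Cqs to it."""
    out = cq.copy()
    vals = out.cq.to_numpy(dtype=float)
    vals = np.where(np.isnan(vals), floor, np.minimum(vals, floor))
    out.cq = pd.DataFrame(vals, index=cq.cq.index, columns=cq.cq.columns)
    return out


def global_mean_normalize(cq: CqMatrix):
    """Per-sample global-mean delta-Cq.

    dCq[a, s] = mean over universally detected assays of Cq[., s] - Cq[a, s].
    Returns (delta-Cq DataFrame, list of universal assays).
    """
    detected_everywhere = cq.cq.notna().all(axis=1)
    universal = list(cq.cq.index[detected_everywhere])
    if not universal:
        raise ValueError("no assay detected in every sample")
    sample_mean = cq.cq.loc[universal].mean(axis=0)
    dcq = sample_mean - cq.cq
    return dcq, universal


@dataclass
class ReferenceSet:
    candidates: list
    chosen: list  # the two most stable
    stability: pd.DataFrame


def choose_references(cq: CqMatrix, candidates, groups, n_refs: int = 2) -> ReferenceSet:
    """Rank candidate reference assays by stability on Cq values."""
    missing = [c for c in candidates if c not in cq.cq.index]
    if missing:
        raise KeyError(f"candidate assays not measured: {missing}")
    table, top = normfinder_rank(cq.cq.loc[list(candidates)], groups=groups, top_k=n_refs)
    return ReferenceSet(list(candidates), top, table)


def reference_dcq(cq: CqMatrix, refs: ReferenceSet) -> pd.DataFrame:
    """dCq[a, s] = mean(Cq of reference pair in s) - Cq[a, s].

    Samples in which a reference assay is unmeasured are dropped with a
    warning.
    """
    for r in refs.chosen:
        if r not in cq.cq.index:
            raise KeyError(f"reference assay {r} not in Cq table")
    ref_cq = cq.cq.loc[refs.chosen]
    good = ref_cq.notna().all(axis=0)
    if not good.all():
        warnings.warn(
            f"dropping {int((~good).sum())} sample(s) lacking a reference measurement"
        )
    ref_mean = ref_cq.loc[:, good].mean(axis=0)
    return ref_mean - cq.cq.loc[:, good]


def dcq_expression(dcq: pd.DataFrame, sheet=None) -> ExpressionMatrix:
    """Wrap a delta-Cq table as a log-scale expression matrix (platform qPCR)."""
    return ExpressionMatrix(dcq, scale="log10", sheet=sheet)


def recalibrate_signature(
    signature,
    dcq_train: ExpressionMatrix,
    dcq_select: ExpressionMatrix,
    cfg: SearchConfig,
    labels_train=None,
    labels_select=None,
):
    """Refit the network on delta-Cq inputs restricted to the signature."""
    available = [f for f in signature if f in dcq_train.values.index]
    if len(available) < 2:
        raise ValueError(
            f"need >= 2 signature features on the qPCR platform, have {len(available)}"
        )
    model, log = mlp_search(
        dcq_train, dcq_select, available, cfg, labels_train, labels_select
    )
    model.platform = "qpcr"
    return model, log


def map_external_platform(
    external: ExpressionMatrix, model: MLPModel
) -> ExpressionMatrix:
    """Bridge an external platform's matrix into the model's input space.

    Every signature feature must be present (1:1 mapping).  Each feature is
    z-scored against the external cohort and re-expressed on the model's
    training scale (mu + sigma * z), so the model's own standardizer maps it
    back to z-scores.  Rank order within each feature is preserved, so ROC
    ordering is invariant to per-feature affine differences between
    platforms.
    """
    missing = [f for f in model.feature_names if f not in external.values.index]
    if missing:
        raise KeyError(f"signature features missing from external matrix: {missing}")
    sub = external.values.loc[model.feature_names].to_numpy(dtype=float)
    mu_ext = sub.mean(axis=1, keepdims=True)
    sd_ext = sub.std(axis=1, keepdims=True)
    sd_ext = np.where(sd_ext > 0, sd_ext, 1.0)
    z = (sub - mu_ext) / sd_ext
    mapped = np.asarray(model.mu)[:, None] + np.asarray(model.sd)[:, None] * z
    return ExpressionMatrix(
        pd.DataFrame(mapped, index=model.feature_names, columns=external.values.columns),
        scale="log10",
        sheet=external.sheet,
    )
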