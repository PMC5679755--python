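"""End-to-end protocol: counts -> TPM -> prevalence filter -> batch
adjustment -> stratified split -> three variable selections -> restart
search (plus baselines) -> diagnostic evaluation -> optional qPCR bridge.

Every stage's seed and threshold is recorded in the report's audit block,
and the whole bundle is regenerable from the configuration alone.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .baselines import BASELINE_KINDS, train_baseline, zoo_scores
from .cohort import SimulationConfig, generate_counts, generate_cq
from .containers import ExpressionMatrix
from .evaluation import (
    classify_threshold,
    compare_auc_paired,
    roc_auc_delong,
    tiered_strategy,
)
from .mlp import SearchConfig, mlp_predict, mlp_search, sensitivity_prune
from .preprocess import (
    combat_adjust,
    filter_prevalence,
    log_transform,
    stratified_split,
    tpm_normalize,
)
from .qpcr import (
    choose_references,
    dcq_expression,
    impute_undetected,
    qc_filter,
    recalibrate_signature,
    reference_dcq,
)
from .selection import cfs_select, foldchange_select, normfinder_rank, ttest_fdr_select


@dataclass
class PipelineConfig:
    # input: either a simulation or paths to tables
    sim: SimulationConfig | None = None
    counts_path: str | None = None
    samples_path: str | None = None
    cq_path: str | None = None
    # stage parameters
    prevalence_threshold: float = 10.0
    prevalence_min_fraction: float = 0.5
    split_ratio: float = 0.75
    selections: tuple = ("significance", "cfs", "fold_change")
    baselines: tuple = BASELINE_KINDS
    restarts: int = 200
    selection_policy: str = "internal_validation"
    prune_restarts: int = 60
    prune_tolerance: float = 0.05
    prune_min_features: int = 2
    run_qpcr_bridge: bool = False
    n_reference_candidates: int = 9
    seed: int = 0
    out_dir: str | None = None


def _json_safe(obj):
    if isinstance(obj, dict):
        return {k: _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return float(obj)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full protocol; returns the report bundle as a dict."""
    cq_loaded = None
    if cfg.sim is not None:
        cm, sheet, truth = generate_counts(cfg.sim)
    elif cfg.counts_path and cfg.samples_path:
        cm, sheet, cq_loaded = mio.load_cohort(cfg.counts_path, cfg.samples_path, cfg.cq_path)
        truth = None
    else:
        raise ValueError("config needs either a simulation or counts/samples paths")

    report: dict = {
        "audit": {
            "seed": cfg.seed,
            "restarts": cfg.restarts,
            "selection_policy": cfg.selection_policy,
            "split_ratio": cfg.split_ratio,
            "prevalence_threshold": cfg.prevalence_threshold,
            "prevalence_min_fraction": cfg.prevalence_min_fraction,
            "prune_tolerance": cfg.prune_tolerance,
            "prune_restarts": cfg.prune_restarts,
        }
    }

    # normalization, prevalence filter across batch datasets, batch adjustment
    tpm = tpm_normalize(cm)
    tpm.sheet = sheet
    batches = sheet.loc[tpm.sample_ids, "batch"]
    by_batch = [tpm.subset_samples(list(batches.index[batches == b])) for b in batches.unique()]
    kept = filter_prevalence(
        by_batch, cfg.prevalence_threshold, cfg.prevalence_min_fraction
    )
    if not kept:
        raise RuntimeError("prevalence filter removed every feature")
    tpm_f = tpm.subset_features(kept)
    logm = log_transform(tpm_f)
    adjusted = combat_adjust(logm, batches)
    report["n_features_after_filter"] = len(kept)

    # stratified split
    split = stratified_split(sheet, cfg.split_ratio, seed=cfg.seed)
    train_ids, test_ids = split.train_ids, split.test_ids
    report["split"] = {
        "train_n": len(train_ids),
        "test_n": len(test_ids),
        "stratum_counts": split.stratum_counts.to_dict(),
    }
    adj_train = adjusted.subset_samples(train_ids)
    adj_test = adjusted.subset_samples(test_ids)
    y_test = adj_test.invasive_labels().to_numpy()

    # the three variable-selection strategies (training samples only)
    selections = {}
    if "significance" in cfg.selections:
        selections["significance"] = ttest_fdr_select(adj_train)
    if "cfs" in cfg.selections:
        selections["cfs"] = cfs_select(adj_train)
    if "fold_change" in cfg.selections:
        fc_sets = []
        for b in batches.unique():
            ids = [s for s in train_ids if batches[s] == b]
            fc_sets.append(tpm_f.subset_samples(ids))
        selections["fold_change"] = foldchange_select(fc_sets)
    report["selections"] = {
        m: {"n_selected": len(r.selected), "selected": list(r.selected)}
        for m, r in selections.items()
    }
    if truth is not None:
        planted = set(truth.planted_feature_ids)
        report["recovery"] = {
            m: {"planted_recovered": len(planted & set(r.selected))}
            for m, r in selections.items()
        }

    # model x selection AUC grid (the protocol's model-comparison table)
    search_cfg = SearchConfig(
        restarts=cfg.restarts,
        selection_policy=cfg.selection_policy,
        seed=cfg.seed,
    )
    grid: dict = {}
    mlp_models = {}
    for method, result in selections.items():
        feats = result.selected
        grid[method] = {}
        if not feats:
            warnings.warn(f"selection {method!r} chose no features; models skipped")
            continue
        model, log = mlp_search(adj_train, adj_test, feats, search_cfg)
        probs = mlp_predict(model, adj_test)
        roc = roc_auc_delong(probs, y_test)
        grid[method]["neural_network"] = roc.auc
        mlp_models[method] = (model, roc, probs)
        for kind in cfg.baselines:
            try:
                zm = train_baseline(kind, adj_train, feats, seed=cfg.seed)
                zroc = roc_auc_delong(zoo_scores(zm, adj_test), y_test)
                grid[method][kind] = zroc.auc
            except ValueError as err:
                grid[method][kind] = None
                warnings.warn(f"{kind} on {method} failed: {err}")
    report["auc_grid"] = grid

    if not mlp_models:
        raise RuntimeError("no selection produced any features; nothing to evaluate")

    # retain the network with the best selection-set AUC across methods
    best_method = max(mlp_models, key=lambda m: grid[m].get("neural_network") or 0.0)
    best_model, best_roc, best_probs = mlp_models[best_method]
    conf = classify_threshold(best_probs, y_test, threshold=0.5)
    report["best_model"] = {
        "selection_method": best_method,
        "features": list(best_model.feature_names),
        "hidden_size": best_model.hidden_size,
        "links": [best_model.hidden_link, best_model.output_link],
        "test_auc": best_roc.auc,
        "test_auc_ci": list(best_roc.ci),
        "youden_cutoff": best_roc.youden_cutoff,
        "youden_j": best_roc.youden_j,
        "confusion": {"tp": conf.tp, "fp": conf.fp, "tn": conf.tn, "fn": conf.fn},
        "rates_pct": conf.rates_pct(),
    }

    # clinical comparator: CA125 on the same test samples
    if "ca125" in sheet.columns and sheet.loc[test_ids, "ca125"].notna().all():
        ca125 = sheet.loc[test_ids, "ca125"].to_numpy(dtype=float)
        ca_roc = roc_auc_delong(ca125, y_test)
        delta, p = compare_auc_paired(best_probs.to_numpy(), ca125, y_test)
        ca_calls = ca125 > ca_roc.youden_cutoff
        tier = tiered_strategy(best_probs.to_numpy() > 0.5, ca_calls, y_test)
        report["ca125"] = {
            "auc": ca_roc.auc,
            "auc_ci": list(ca_roc.ci),
            "delta_auc": delta,
            "p_vs_model": p,
            "tiered_fp_pct": tier["tiered"].rates_pct()["fp_rate"],
            "tiered_fn_pct": tier["tiered"].rates_pct()["fn_rate"],
            "primary_fp_pct": tier["primary"].rates_pct()["fp_rate"],
            "primary_fn_pct": tier["primary"].rates_pct()["fn_rate"],
        }

    # optional qPCR bridge: QC, normalization, recalibration, pruning
    if cfg.run_qpcr_bridge:
        report["qpcr"] = _qpcr_bridge(
            cfg, tpm_f, adjusted, best_model, truth, sheet, train_ids, test_ids, cq_loaded
        )

    if cfg.out_dir:
        _write_bundle(cfg, cm, sheet, split, selections, best_model, best_probs, report)
    return report


def _qpcr_bridge(
    cfg, tpm_f, adjusted, best_model, truth, sheet, train_ids, test_ids, cq_loaded=None
):
    signature = list(best_model.feature_names)
    # reference candidates: most stable features of the sequencing data
    stab, _ = normfinder_rank(
        adjusted.subset_samples(train_ids),
        groups=sheet.loc[train_ids, "invasive"].to_numpy(),
    )
    candidates = [f for f in stab.index if f not in signature][: cfg.n_reference_candidates]
    if cq_loaded is not None:
        cq_raw, planted_qc = cq_loaded, None
        candidates = [c for c in candidates if c in cq_raw.cq.index]
    else:
        assay_ids = signature + candidates
        cq_raw, planted_qc = generate_cq(
            tpm_f.subset_features(assay_ids), truth, seed=cfg.seed + 1
        )
    cq_clean, qc_log = qc_filter(cq_raw)
    cq_imp = impute_undetected(cq_clean)
    refs = choose_references(
        cq_imp, candidates, groups=sheet.loc[cq_imp.cq.columns, "invasive"].to_numpy()
    )
    dcq = reference_dcq(cq_imp, refs)
    dem = dcq_expression(dcq.loc[signature], sheet)
    dcq_train = dem.subset_samples([s for s in train_ids if s in dem.sample_ids])
    dcq_test = dem.subset_samples([s for s in test_ids if s in dem.sample_ids])
    recal_cfg = SearchConfig(
        restarts=cfg.restarts,
        selection_policy=cfg.selection_policy,
        seed=cfg.seed + 7,
    )
    recal, _ = recalibrate_signature(signature, dcq_train, dcq_test, recal_cfg)
    y_test = dcq_test.invasive_labels().to_numpy()
    recal_probs = mlp_predict(recal, dcq_test)
    recal_roc = roc_auc_delong(recal_probs, y_test)
    pruned, trace = sensitivity_prune(
        recal,
        dcq_train,
        dcq_test,
        SearchConfig(
            restarts=cfg.prune_restarts,
            selection_policy=cfg.selection_policy,
            seed=cfg.seed + 11,
        ),
        tolerance=cfg.prune_tolerance,
        min_features=cfg.prune_min_features,
    )
    pruned_roc = roc_auc_delong(mlp_predict(pruned, dcq_test), y_test)
    return {
        "qc_removals": qc_log,
        "planted_qc": planted_qc,
        "references": refs.chosen,
        "recalibrated_auc": recal_roc.auc,
        "pruned_n_features": len(pruned.feature_names),
        "pruned_features": list(pruned.feature_names),
        "pruned_auc": pruned_roc.auc,
        "prune_steps": len(trace),
    }


def _write_bundle(cfg, cm, sheet, split, selections, best_model, best_probs, report):
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mio.write_counts(cm, out / "counts.tsv")
    mio.write_samples(sheet, out / "samples.csv")
    (out / "split.json").write_text(
        json.dumps(
            {"seed": split.seed, "ratio": split.ratio, "assignment": split.assignment.to_dict()},
            indent=1,
        )
    )
    sel_payload = {
        m: {"selected": list(r.selected), "provenance": _json_safe(r.provenance)}
        for m, r in selections.items()
    }
    (out / "selection.json").write_text(json.dumps(sel_payload, indent=1))
    mio.save_model(best_model, out / "model.json")
    preds = pd.DataFrame(
        {"probability": best_probs, "call": (best_probs > 0.5).map({True: "invasive", False: "non-invasive"})}
    )
    preds.index.name = "sample_id"
    preds.to_csv(out / "predictions.csv")
    (out / "report.json").write_text(json.dumps(_json_safe(report), indent=1))
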