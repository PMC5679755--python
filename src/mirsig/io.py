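"""On-disk formats: counts.tsv, samples.csv, cq.tsv, model.json.

Matrices are stored features x samples (first column the feature id), the
sample sheet as CSV with a ``sample_id`` column, and models as portable
JSON so predictions can be re-run from any language.  Loading validates
schemas and reports offending ids/lines instead of propagating NaNs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CountMatrix, CqMatrix, SchemaError, validate_sample_sheet
from .mlp import MLPModel

#: Normalization of human-readable pathology labels to canonical strata.
CLASS_LABEL_MAP = {
    "control": "control",
    "controls": "control",
    "healthy control": "control",
    "benign": "benign",
    "benign lesions": "benign",
    "benign lesion": "benign",
    "borderline": "borderline",
    "borderline tumors": "borderline",
    "borderline tumor": "borderline",
    "stage i/ii invasive cancers": "stageI_II",
    "stage i/ii invasive cancer": "stageI_II",
    "stagei_ii": "stageI_II",
    "stage iii/iv invasive cancers": "stageIII_IV",
    "stage iii/iv invasive cancer": "stageIII_IV",
    "stageiii_iv": "stageIII_IV",
}


def normalize_class_label(label: str) -> str:
    key = str(label).strip().lower()
    if key in CLASS_LABEL_MAP:
        return CLASS_LABEL_MAP[key]
    raise SchemaError(f"unknown pathology label {label!r}")


def write_counts(cm: CountMatrix, path) -> None:
    df = cm.counts.copy()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t")


def write_samples(sheet: pd.DataFrame, path) -> None:
    out = sheet.copy()
    out.index.name = "sample_id"
    out.to_csv(path)


def read_samples(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, index_col="sample_id")
    if "pathology" in sheet.columns:
        sheet["pathology"] = [normalize_class_label(c) for c in sheet["pathology"]]
    return validate_sample_sheet(sheet)


def read_counts(path, sheet: pd.DataFrame) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col="feature_id")
    bad = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if bad:
        raise SchemaError(f"non-numeric count columns: {bad}")
    missing = [s for s in df.columns if s not in sheet.index]
    if missing:
        raise SchemaError(f"samples in counts but not in sample sheet: {missing}")
    if "total_mapped_reads" not in sheet.columns:
        raise SchemaError("sample sheet lacks total_mapped_reads")
    totals = sheet.loc[df.columns, "total_mapped_reads"]
    return CountMatrix(df.astype(np.int64), totals.astype(np.int64))


def write_cq(cq: CqMatrix, path) -> None:
    """Long-format TSV: assay, sample, cq (empty = undetected), QC columns."""
    rows = []
    for a in cq.cq.index:
        for s in cq.cq.columns:
            v = cq.cq.loc[a, s]
            rows.append(
                {
                    "assay": a,
                    "sample": s,
                    "cq": "" if pd.isna(v) else v,
                    "efficiency": cq.efficiency.loc[a, s],
                    "melt_flag": int(cq.melt_flag.loc[a, s]),
                    "negctrl_cq": cq.negctrl_cq.loc[a],
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_cq(path) -> CqMatrix:
    df = pd.read_csv(path, sep="\t")
    cq = df.pivot(index="assay", columns="sample", values="cq")
    eff = df.pivot(index="assay", columns="sample", values="efficiency")
    melt = df.pivot(index="assay", columns="sample", values="melt_flag").astype(bool)
    neg = df.groupby("assay")["negctrl_cq"].first()
    return CqMatrix(cq.astype(float), eff, melt, neg)


def load_cohort(counts_path, samples_path, cq_path=None):
    """Load and validate (CountMatrix, sample sheet, optional CqMatrix)."""
    sheet = read_samples(samples_path)
    cm = read_counts(counts_path, sheet)
    cq = read_cq(cq_path) if cq_path else None
    return cm, sheet, cq


# ---------------------------------------------------------------------------
# model serialization


def save_model(model: MLPModel, path) -> None:
    payload = {
        "kind": "mlp",
        "feature_names": list(model.feature_names),
        "mu": np.asarray(model.mu).tolist(),
        "sd": np.asarray(model.sd).tolist(),
        "W1": np.asarray(model.W1).tolist(),
        "b1": np.asarray(model.b1).tolist(),
        "w2": np.asarray(model.w2).tolist(),
        "b2": float(model.b2),
        "hidden_link": model.hidden_link,
        "output_link": model.output_link,
        "platform": model.platform,
        "provenance": model.provenance,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path) -> MLPModel:
    d = json.loads(Path(path).read_text())
    if d.get("kind") != "mlp":
        raise SchemaError(f"unsupported model kind {d.get('kind')!r}")
    return MLPModel(
        feature_names=d["feature_names"],
        mu=np.asarray(d["mu"], dtype=float),
        sd=np.asarray(d["sd"], dtype=float),
        W1=np.asarray(d["W1"], dtype=float),
        b1=np.asarray(d["b1"], dtype=float),
        w2=np.asarray(d["w2"], dtype=float),
        b2=float(d["b2"]),
        hidden_link=d["hidden_link"],
        output_link=d["output_link"],
        platform=d.get("platform", "sequencing"),
        provenance=d.get("provenance", {}),
    )
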