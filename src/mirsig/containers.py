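"""Light in-memory containers shared across the pipeline.

Matrices are pandas DataFrames oriented features x samples (the orientation
GEO series matrices use on disk).  The sample sheet is a plain DataFrame
indexed by sample id.  Wrappers stay thin on purpose: every numeric routine
works on the underlying arrays and the wrappers only carry the metadata the
pipeline needs to refuse invalid inputs (scale mix-ups, duplicated ids,
count/library-size inconsistencies).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical pathology strata, from healthy controls to advanced invasive cancer.
PATHOLOGY_CLASSES = ("control", "benign", "borderline", "stageI_II", "stageIII_IV")

#: Strata counted as invasive disease (the positive diagnostic class).
INVASIVE_CLASSES = ("stageI_II", "stageIII_IV")


class SchemaError(ValueError):
    """A table violated the documented on-disk or in-memory schema."""


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a sample sheet.

    Required columns: ``batch`` and ``pathology``; the index holds sample ids.
    Adds/refreshes the derived boolean ``invasive`` column.
    """
    if sheet.index.has_duplicates:
        dup = sheet.index[sheet.index.duplicated()].unique().tolist()
        raise SchemaError(f"duplicate sample ids in sample sheet: {dup}")
    for col in ("batch", "pathology"):
        if col not in sheet.columns:
            raise SchemaError(f"sample sheet missing required column {col!r}")
    bad = sorted(set(sheet["pathology"]) - set(PATHOLOGY_CLASSES))
    if bad:
        raise SchemaError(
            f"unknown pathology classes {bad}; expected one of {PATHOLOGY_CLASSES}"
        )
    if sheet["batch"].isna().any() or (sheet["batch"].astype(str) == "").any():
        raise SchemaError("empty batch labels in sample sheet")
    sheet = sheet.copy()
    sheet["invasive"] = sheet["pathology"].isin(INVASIVE_CLASSES)
    return sheet


@dataclass
class CountMatrix:
    """Integer miRNA read counts plus per-sample total mapped reads."""

    counts: pd.DataFrame  # features x samples, non-negative integers
    total_reads: pd.Series  # per sample, positive

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise SchemaError("duplicate feature ids in count matrix")
        if self.counts.columns.has_duplicates:
            raise SchemaError("duplicate sample ids in count matrix")
        self.total_reads = self.total_reads.reindex(self.counts.columns)
        if self.total_reads.isna().any():
            missing = self.total_reads.index[self.total_reads.isna()].tolist()
            raise SchemaError(f"total mapped reads missing for samples: {missing}")
        if (np.asarray(self.counts.values) < 0).any():
            raise SchemaError("negative counts")
        colsum = self.counts.sum(axis=0)
        over = colsum > self.total_reads
        if over.any():
            raise SchemaError(
                "per-sample count sum exceeds total mapped reads for: "
                f"{colsum.index[over].tolist()}"
            )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class ExpressionMatrix:
    """TPM (linear) or log10(TPM+1) expression with an explicit scale marker."""

    values: pd.DataFrame  # features x samples
    scale: str = "linear"  # "linear" | "log10"
    sheet: pd.DataFrame | None = None  # optional attached sample sheet

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log10"):
            raise ValueError(f"unknown scale marker {self.scale!r}")
        if self.scale == "linear" and (np.asarray(self.values.values) < 0).any():
            raise ValueError("linear expression values must be non-negative")
        if self.sheet is not None:
            missing = [s for s in self.values.columns if s not in self.sheet.index]
            if missing:
                raise SchemaError(f"samples absent from sample sheet: {missing}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_features(self, feature_ids) -> "ExpressionMatrix":
        missing = [f for f in feature_ids if f not in self.values.index]
        if missing:
            raise KeyError(f"features not in matrix: {missing}")
        return ExpressionMatrix(self.values.loc[list(feature_ids)], self.scale, self.sheet)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        sheet = self.sheet.loc[list(sample_ids)] if self.sheet is not None else None
        return ExpressionMatrix(self.values[list(sample_ids)], self.scale, sheet)

    def invasive_labels(self) -> pd.Series:
        if self.sheet is None:
            raise ValueError("no sample sheet attached")
        return self.sheet.loc[self.values.columns, "invasive"].astype(bool)


@dataclass
class CqMatrix:
    """qPCR quantification cycles with per-cell QC annotations.

    ``cq`` holds NaN for undetected reactions (no amplification before the
    detection bound).  The three QC layers mirror the vendor export: one
    amplification-efficiency value and one melt flag per assay x sample
    reaction, and one no-template negative-control Cq per assay.
    """

    cq: pd.DataFrame  # assays x samples, NaN = undetected
    efficiency: pd.DataFrame  # assays x samples
    melt_flag: pd.DataFrame  # assays x samples, bool
    negctrl_cq: pd.Series  # per assay

    def __post_init__(self) -> None:
        for name in ("efficiency", "melt_flag"):
            ann = getattr(self, name)
            if not ann.index.equals(self.cq.index) or not ann.columns.equals(self.cq.columns):
                raise SchemaError(f"QC annotation {name!r} not aligned with Cq table")
        self.negctrl_cq = self.negctrl_cq.reindex(self.cq.index)
        if self.negctrl_cq.isna().any():
            raise SchemaError("negative-control Cq missing for some assays")
        vals = np.asarray(self.cq.values, dtype=float)
        finite = np.isfinite(vals)
        if finite.any() and vals[finite].min() <= 0:
            raise SchemaError("Cq values must be positive")

    def copy(self) -> "CqMatrix":
        return CqMatrix(
            self.cq.copy(), self.efficiency.copy(), self.melt_flag.copy(), self.negctrl_cq.copy()
        )


@dataclass
class SplitAssignment:
    """Train/test partition of samples, reproducible from (strata, ratio, seed)."""

    assignment: pd.Series  # sample_id -> "train" | "test"
    ratio: float
    seed: int
    stratum_counts: pd.DataFrame = field(default=None)  # per-stratum train/test report

    @property
    def train_ids(self) -> list[str]:
        return list(self.assignment.index[self.assignment == "train"])

    @property
    def test_ids(self) -> list[str]:
        return list(self.assignment.index[self.assignment == "test"])
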