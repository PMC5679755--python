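import numpy as np
import pandas as pd
import pytest

from mirsig import (
    SimulationConfig,
    combat_adjust,
    filter_prevalence,
    generate_counts,
    log_transform,
    stratified_split,
    tpm_normalize,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A quick 120-sample, 300-feature cohort with default class structure."""
    cfg = SimulationConfig(n_samples=120, n_features=300, seed=11)
    cm, sheet, truth = generate_counts(cfg)
    return cfg, cm, sheet, truth


@pytest.fixture(scope="session")
def processed_cohort(small_cohort):
    """The small cohort taken through TPM -> filter -> log -> batch adjustment
    and split, shared by selection/model tests."""
    cfg, cm, sheet, truth = small_cohort
    tpm = tpm_normalize(cm)
    tpm.sheet = sheet
    batches = sheet["batch"]
    by_batch = [
        tpm.subset_samples(list(batches.index[batches == b])) for b in batches.unique()
    ]
    kept = filter_prevalence(by_batch)
    tpm_f = tpm.subset_features(kept)
    adjusted = combat_adjust(log_transform(tpm_f), batches)
    split = stratified_split(sheet, seed=cfg.seed)
    return {
        "config": cfg,
        "sheet": sheet,
        "truth": truth,
        "tpm": tpm_f,
        "adjusted": adjusted,
        "split": split,
        "batches": batches,
    }


def make_expression(values, scale="linear", labels=None, batches=None):
    """Build a small ExpressionMatrix (features x samples) with a sheet."""
    from mirsig import ExpressionMatrix, validate_sample_sheet

    values = pd.DataFrame(
        np.asarray(values, dtype=float),
        index=[f"f{i}" for i in range(np.shape(values)[0])],
        columns=[f"s{j}" for j in range(np.shape(values)[1])],
    )
    sheet = None
    if labels is not None:
        labels = np.asarray(labels)
        sheet = pd.DataFrame(
            {
                "batch": batches if batches is not None else ["b0"] * len(labels),
                "pathology": np.where(labels.astype(bool), "stageIII_IV", "benign"),
            },
            index=values.columns,
        )
        sheet = validate_sample_sheet(sheet)
    return ExpressionMatrix(values, scale=scale, sheet=sheet)
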