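"""Synthetic serum small-RNA cohorts with planted ground truth.

The generator emulates the statistical structure a circulating-miRNA
discovery study assumes: a few hundred serum samples drawn from several
study populations (batches), five pathology strata from healthy control to
advanced invasive cancer, negative-binomial read counts whose expected
log10-TPM is baseline + class effect + batch shift, a planted signature of
differentially expressed miRNAs in invasive disease, a handful of stable
candidate reference miRNAs, serum CA125 of limited discriminative power,
and matched qPCR readouts with realistic QC failures.

Every generator is a pure function of (config, seed): identical inputs give
bitwise-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .containers import CountMatrix, CqMatrix, ExpressionMatrix, validate_sample_sheet

#: Pathology mix of the default cohort (proportions of a 179-subject study
#: population: 15 controls, 45 benign, 21 borderline, 53 stage I/II, 45 stage III/IV).
DEFAULT_CLASS_MIX = {
    "control": 15 / 179,
    "benign": 45 / 179,
    "borderline": 21 / 179,
    "stageI_II": 53 / 179,
    "stageIII_IV": 45 / 179,
}

INVASIVE = ("stageI_II", "stageIII_IV")


class ConfigurationError(ValueError):
    """A simulation configuration violated its invariants."""


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort.

    Fold-change ranges are on the linear scale and must lie outside the
    (0.8, 1.2) null band used by the convergent fold-change filter, so a
    planted feature is by construction selectable.  ``dispersion`` is the
    negative-binomial dispersion (variance = mu + dispersion * mu^2).
    ``batch_shift_sd`` is in log10-TPM units.
    """

    n_samples: int = 180
    n_features: int = 1500
    class_mix: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    n_batches: int = 3
    batch_shift_sd: float = 0.15
    signature_size: int = 14
    n_reference: int = 9
    up_fc_range: tuple = (2.0, 3.0)
    down_fc_range: tuple = (1 / 3, 0.5)
    dispersion: float = 0.2
    libsize_range: tuple = (5e6, 15e6)
    ca125_auc_target: float = 0.74
    seed: int = 0

    def validate(self) -> None:
        mix_sum = float(sum(self.class_mix.values()))
        if abs(mix_sum - 1.0) > 1e-9:
            raise ConfigurationError(f"class_mix sums to {mix_sum!r}, not 1")
        if any(p < 0 for p in self.class_mix.values()):
            raise ConfigurationError("negative class proportions")
        if self.n_features < self.signature_size + self.n_reference:
            raise ConfigurationError(
                "n_features must be at least signature_size + n_reference "
                f"({self.signature_size} + {self.n_reference})"
            )
        if not (self.up_fc_range[0] >= 1.2 or self.up_fc_range == (1.0, 1.0)):
            raise ConfigurationError("up_fc_range must not enter the (0.8, 1.2) null band")
        if not (self.down_fc_range[1] <= 0.8 or self.down_fc_range == (1.0, 1.0)):
            raise ConfigurationError("down_fc_range must not enter the (0.8, 1.2) null band")
        if not 0.5 <= self.ca125_auc_target < 1.0:
            raise ConfigurationError("ca125_auc_target must be in [0.5, 1)")
        if self.n_batches < 1 or self.n_samples < self.n_batches * 2:
            raise ConfigurationError("need at least two samples per batch")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort, for recovery testing."""

    planted_feature_ids: list
    true_fc: pd.DataFrame  # planted features x pathology classes, linear scale
    batch_shifts: pd.Series  # per batch, log10 units
    batch_multipliers: pd.Series  # per feature
    stable_reference_ids: list
    baseline_log10_tpm: pd.Series  # per feature

    def __post_init__(self) -> None:
        overlap = set(self.planted_feature_ids) & set(self.stable_reference_ids)
        if overlap:
            raise ConfigurationError(f"planted and reference sets overlap: {sorted(overlap)}")


def _class_counts(mix: dict, n: int) -> dict:
    """Largest-remainder rounding of class proportions to integer counts."""
    raw = {c: p * n for c, p in mix.items()}
    counts = {c: int(np.floor(v)) for c, v in raw.items()}
    short = n - sum(counts.values())
    order = sorted(mix, key=lambda c: (-(raw[c] - counts[c]), c))
    for c in order[:short]:
        counts[c] += 1
    return counts


def generate_counts(config: SimulationConfig):
    """Generate (CountMatrix, sample sheet, SyntheticTruth) for one cohort.

    Counts are negative-binomial with
    ``log10 E[TPM] = baseline + class effect + multiplier * batch shift``;
    the class effect (log10 of the configured fold change) applies to the
    planted signature features in invasive strata only.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, g = config.n_samples, config.n_features

    feature_ids = [f"miR-{i:04d}" for i in range(g)]
    sample_ids = [f"S{i:03d}" for i in range(n)]

    # pathology strata and batches
    counts_by_class = _class_counts(config.class_mix, n)
    classes = np.concatenate([[c] * k for c, k in counts_by_class.items()])
    rng.shuffle(classes)
    batches = np.tile(np.arange(config.n_batches), n // config.n_batches + 1)[:n]
    rng.shuffle(batches)
    batch_labels = np.array([f"batch{b}" for b in batches])

    # per-feature baseline abundance (log10 TPM); skewed toward low expression
    baseline = rng.uniform(0.0, 3.0, size=g)

    # choose planted signature among mid/high-abundance features and
    # references among high-abundance features, disjointly; fall back to the
    # most abundant remaining features when the preferred windows are small
    order = np.argsort(baseline)[::-1]  # descending abundance
    high = [i for i in order if baseline[i] > 2.5]
    if len(high) < config.n_reference:
        high = list(order[: max(config.n_reference * 2, config.n_reference)])
    ref_idx = rng.choice(high, size=config.n_reference, replace=False)
    taken = set(ref_idx)
    mid = [i for i in order if 1.5 <= baseline[i] <= 2.5 and i not in taken]
    if len(mid) < config.signature_size:
        mid = [i for i in order if i not in taken][
            : max(config.signature_size * 2, config.signature_size)
        ]
    planted_idx = rng.choice(mid, size=config.signature_size, replace=False)

    n_up = int(np.ceil(config.signature_size / 2))
    fc = np.ones(config.signature_size)
    fc[:n_up] = rng.uniform(*config.up_fc_range, size=n_up)
    fc[n_up:] = rng.uniform(*config.down_fc_range, size=config.signature_size - n_up)

    # batch model: additive on log10 with feature-specific multipliers;
    # reference features are exempt (they are stable by construction)
    shifts = rng.normal(0.0, config.batch_shift_sd, size=config.n_batches)
    multipliers = rng.normal(1.0, 0.3, size=g)
    multipliers[ref_idx] = 0.0

    log_tpm = np.tile(baseline[:, None], (1, n))
    invasive_mask = np.isin(classes, INVASIVE)
    for j, fi in enumerate(planted_idx):
        log_tpm[fi, invasive_mask] += np.log10(fc[j])
    log_tpm += multipliers[:, None] * shifts[batches][None, :]

    libsize = rng.uniform(*config.libsize_range, size=n)
    mu = 10.0 ** log_tpm / 1e6 * libsize[None, :]

    disp = np.full(g, config.dispersion)
    disp[ref_idx] = config.dispersion / 4  # low-variance reference candidates
    if config.dispersion > 0:
        r = 1.0 / disp[:, None]
        p = r / (r + mu)
        counts = rng.negative_binomial(r, p)
    else:
        counts = rng.poisson(mu)

    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=feature_ids, columns=sample_ids),
        total_reads=pd.Series(np.round(libsize).astype(np.int64), index=sample_ids),
    )

    sheet = pd.DataFrame(
        {
            "batch": batch_labels,
            "pathology": classes,
            "age": np.round(rng.normal(57, 9, size=n), 1),
            "total_mapped_reads": np.round(libsize).astype(np.int64),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    sheet = validate_sample_sheet(sheet)
    sheet["ca125"] = generate_ca125(
        sheet, config.ca125_auc_target, seed=int(rng.integers(0, 2**31 - 1))
    )

    true_fc = pd.DataFrame(
        1.0,
        index=[feature_ids[i] for i in planted_idx],
        columns=list(config.class_mix),
    )
    for cls in INVASIVE:
        true_fc[cls] = fc

    truth = SyntheticTruth(
        planted_feature_ids=[feature_ids[i] for i in planted_idx],
        true_fc=true_fc,
        batch_shifts=pd.Series(shifts, index=[f"batch{b}" for b in range(config.n_batches)]),
        batch_multipliers=pd.Series(multipliers, index=feature_ids),
        stable_reference_ids=[feature_ids[i] for i in ref_idx],
        baseline_log10_tpm=pd.Series(baseline, index=feature_ids),
    )
    return cm, sheet, truth


def generate_ca125(sheet: pd.DataFrame, target_auc: float, seed: int) -> pd.Series:
    """Simulate serum CA125 (U/ml) at a chosen discriminative operating point.

    Values are lognormal; the invasive-vs-rest location shift on the latent
    normal scale is solved from the binormal identity AUC = Phi(delta / sqrt(2)),
    so the large-sample AUC of the simulated marker equals ``target_auc``.
    Benign, borderline and control samples share one distribution (they form
    the single non-invasive outcome class).
    """
    if not 0.5 <= target_auc < 1.0:
        raise ValueError(f"target_auc must be in [0.5, 1), got {target_auc}")
    if "invasive" not in sheet.columns:
        raise ValueError("sample sheet lacks invasive labels")
    rng = np.random.default_rng(seed)
    delta = norm.ppf(target_auc) * np.sqrt(2.0)
    z = rng.normal(0.0, 1.0, size=len(sheet))
    z[sheet["invasive"].to_numpy(dtype=bool)] += delta
    return pd.Series(np.round(np.exp(np.log(35.0) + 0.9 * z), 1), index=sheet.index)


def generate_cq(
    expr: ExpressionMatrix,
    truth: SyntheticTruth | None,
    seed: int,
    intercept: float = 38.0,
    slope: float = 1.0,
    noise_sd: float = 0.3,
    reference_noise_sd: float = 0.1,
    detection_bound: float = 37.0,
    frac_efficiency_fail: float = 0.05,
    frac_melt_fail: float = 0.02,
    frac_negctrl_fail: float = 0.02,
):
    """Simulate a qPCR readout of an expression matrix.

    Measurement model: ``Cq = intercept - slope * log2(TPM + 1) + noise``;
    reactions whose Cq exceeds the detection bound are undetected (NaN).
    Stable reference assays get reduced noise.  QC annotations (amplification
    efficiency, melt-curve flag, per-assay negative-control Cq) are populated
    so configured fractions of reactions violate each downstream QC rule, in
    disjoint cells.

    Returns ``(CqMatrix, planted_qc)`` where ``planted_qc`` counts the
    reactions each QC rule should remove (melt first, then efficiency, then
    negative-control proximity — the same precedence ``qc_filter`` applies).
    """
    if expr.scale != "linear":
        raise ValueError("generate_cq expects a linear-TPM matrix")
    vals = expr.values.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("negative TPM")
    rng = np.random.default_rng(seed)
    g, n = vals.shape

    sd = np.full(g, noise_sd)
    if truth is not None:
        ref_rows = expr.values.index.isin(truth.stable_reference_ids)
        sd[ref_rows] = reference_noise_sd
    cq = intercept - slope * np.log2(vals + 1.0) + rng.normal(0.0, sd[:, None], size=(g, n))

    # QC planting: pick disjoint random cells for melt and efficiency failures
    ncell = g * n
    flat = rng.permutation(ncell)
    n_melt = int(round(frac_melt_fail * ncell))
    n_eff = int(round(frac_efficiency_fail * ncell))
    melt_cells = flat[:n_melt]
    eff_cells = flat[n_melt : n_melt + n_eff]

    efficiency = rng.uniform(1.8, 2.0, size=(g, n))
    efficiency.ravel()[eff_cells] = rng.uniform(1.3, 1.59, size=n_eff)
    melt = np.zeros((g, n), dtype=bool)
    melt.ravel()[melt_cells] = True

    # negative-control planting is per assay: failed assays get a low
    # no-template Cq so their late reactions fall within 5 cycles of it
    negctrl = np.full(g, 60.0)
    n_bad_assays = int(round(frac_negctrl_fail * g))
    bad_assays = rng.choice(g, size=n_bad_assays, replace=False)
    negctrl[bad_assays] = detection_bound + 4.0  # removal threshold at bound - 1

    detected = cq <= detection_bound
    cq_table = np.where(detected, cq, np.nan)

    out = CqMatrix(
        cq=pd.DataFrame(cq_table, index=expr.values.index, columns=expr.values.columns),
        efficiency=pd.DataFrame(efficiency, index=expr.values.index, columns=expr.values.columns),
        melt_flag=pd.DataFrame(melt, index=expr.values.index, columns=expr.values.columns),
        negctrl_cq=pd.Series(negctrl, index=expr.values.index),
    )

    # expected removals under qc_filter precedence, among detected reactions
    melt_rm = melt & detected
    eff_rm = (efficiency < 1.6) & detected & ~melt_rm
    neg_rm = (cq_table >= negctrl[:, None] - 5.0) & detected & ~melt_rm & ~eff_rm
    planted_qc = {
        "melt": int(melt_rm.sum()),
        "efficiency": int(eff_rm.sum()),
        "negative_control": int(np.nansum(neg_rm)),
    }
    return out, planted_qc
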