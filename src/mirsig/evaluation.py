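"""ROC/AUC inference and the diagnostic statistics used to judge models.

AUC follows the Mann-Whitney identity with ties counting one half; its
variance and confidence interval come from the DeLong structural-components
estimator, which also yields the paired test for comparing two markers
measured on the same patients.  Operating points use the Youden index
J = sensitivity + specificity - 1.  Screening-style combination of two
markers, exact Fisher and signed-rank tests, and the AUC-superiority sample
size calculation round out the toolbox.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats


# ---------------------------------------------------------------------------
# AUC / DeLong


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def mann_whitney_auc(scores, labels) -> float:
    """AUC via the tie-corrected Mann-Whitney identity (ties count 1/2)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    r = _midrank(scores)
    return float((r[y].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _delong_components(scores: np.ndarray, y: np.ndarray):
    """Structural components V10 (cases) and V01 (controls), plus the AUC."""
    cases = scores[y]
    controls = scores[~y]
    m, n = len(cases), len(controls)
    all_r = _midrank(scores)
    case_r = _midrank(cases)
    control_r = _midrank(controls)
    auc = (all_r[y].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (all_r[y] - case_r) / n
    v01 = 1.0 - (all_r[~y] - control_r) / m
    return v10, v01, float(auc)


@dataclass
class RocCurve:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_var: float
    ci: tuple  # 95% DeLong
    youden_cutoff: float
    youden_j: float


def roc_auc_delong(scores, labels) -> RocCurve:
    """Full ROC sweep with DeLong AUC variance and 95% CI.

    The threshold sweep uses the ">= threshold is positive" convention over
    all distinct score values (plus +inf for the empty-call point).
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if y.all() or (~y).all():
        raise ValueError("both classes must be present")
    v10, v01, auc = _delong_components(scores, y)
    m, n = int(y.sum()), int((~y).sum())
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    half = 1.959963984540054 * np.sqrt(max(var, 0.0))
    ci = (max(0.0, auc - half), min(1.0, auc + half))

    thr = np.concatenate(([np.inf], np.unique(scores)[::-1]))
    pos = scores[y]
    neg = scores[~y]
    sens = np.array([(pos >= t).mean() for t in thr])
    spec = np.array([(neg < t).mean() for t in thr])
    cutoff, j = youden_from_sweep(thr, sens, spec)
    return RocCurve(thr, sens, spec, auc, float(var), ci, cutoff, j)


def youden_from_sweep(thresholds, sensitivity, specificity):
    """Argmax of J = sens + spec - 1; ties resolved toward higher specificity."""
    j = np.asarray(sensitivity) + np.asarray(specificity) - 1.0
    best = np.flatnonzero(j >= j.max() - 1e-12)
    order = best[np.argsort(-np.asarray(specificity)[best], kind="stable")]
    i = order[0]
    return float(np.asarray(thresholds)[i]), float(j[i])


def youden_cutoff(roc: RocCurve) -> float:
    return roc.youden_cutoff


def compare_auc_paired(scores_a, scores_b, labels):
    """DeLong paired two-sided test for a difference in AUC.

    Returns (delta_auc, p).  Both score vectors must be measured on the same
    samples.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels).astype(bool)
    if len(scores_a) != len(scores_b) or len(scores_a) != len(y):
        raise ValueError("score vectors and labels must have equal length")
    va10, va01, auc_a = _delong_components(scores_a, y)
    vb10, vb01, auc_b = _delong_components(scores_b, y)
    m, n = int(y.sum()), int((~y).sum())
    s10 = np.cov(np.stack([va10, vb10]), ddof=1) / m
    s01 = np.cov(np.stack([va01, vb01]), ddof=1) / n
    cov = s10 + s01
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    delta = auc_a - auc_b
    if var <= 0:
        return float(delta), 1.0 if abs(delta) < 1e-12 else 0.0
    z = delta / np.sqrt(var)
    return float(delta), float(2 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# confusion tables


def _pct(x: float) -> float:
    """Percentage with half-away-from-zero rounding to 1 decimal place."""
    return float(np.floor(abs(x) * 1000 + 0.5) / 10 * np.sign(x))


@dataclass
class Confusion:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    @property
    def ppv(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else float("nan")

    @property
    def npv(self) -> float:
        return self.tn / (self.tn + self.fn) if self.tn + self.fn else float("nan")

    @property
    def fp_rate_overall(self) -> float:
        """False positives as a fraction of all subjects."""
        return self.fp / self.n

    @property
    def fn_rate_overall(self) -> float:
        return self.fn / self.n

    def rates_pct(self) -> dict:
        """All rates as 1-dp percentages (half away from zero)."""
        return {
            "sensitivity": _pct(self.sensitivity),
            "specificity": _pct(self.specificity),
            "ppv": _pct(self.ppv),
            "npv": _pct(self.npv),
            "fp_rate": _pct(self.fp_rate_overall),
            "fn_rate": _pct(self.fn_rate_overall),
        }


def classify_threshold(probabilities, labels, threshold: float = 0.5) -> Confusion:
    """Strictly-greater-than-threshold rule: p > threshold calls invasive."""
    p = np.asarray(probabilities, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    y = np.asarray(labels).astype(bool)
    call = p > threshold
    return Confusion(
        tp=int((call & y).sum()),
        fp=int((call & ~y).sum()),
        tn=int((~call & ~y).sum()),
        fn=int((~call & y).sum()),
    )


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p by the probability-mass method."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (t < 0).any():
        raise ValueError("negative cell counts")
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def tiered_strategy(primary_calls, secondary_calls, labels) -> dict:
    """Two-stage screening: secondary review of primary-negative subjects.

    Combined call = primary positive OR (primary negative AND secondary
    positive).  Returns confusions for primary alone, secondary alone, and
    the tiered strategy, plus the change in overall FP/FN percentage.
    """
    a = np.asarray(primary_calls).astype(bool)
    b = np.asarray(secondary_calls).astype(bool)
    y = np.asarray(labels).astype(bool)
    if not (len(a) == len(b) == len(y)):
        raise ValueError("prediction vectors and labels must have equal length")

    def conf(call):
        return Confusion(
            tp=int((call & y).sum()),
            fp=int((call & ~y).sum()),
            tn=int((~call & ~y).sum()),
            fn=int((~call & y).sum()),
        )

    tiered = conf(a | b)
    primary = conf(a)
    secondary = conf(b)
    return {
        "primary": primary,
        "secondary": secondary,
        "tiered": tiered,
        "delta_fp_pct": _pct(tiered.fp_rate_overall) - _pct(primary.fp_rate_overall),
        "delta_fn_pct": _pct(tiered.fn_rate_overall) - _pct(primary.fn_rate_overall),
    }


# ---------------------------------------------------------------------------
# paired pre/post test


def wilcoxon_paired(pre, post, exact_max_n: int = 25) -> float:
    """Wilcoxon matched-pairs signed-rank two-sided p.

    Zero differences are dropped.  For n <= ``exact_max_n`` the null
    distribution of W+ is enumerated exactly (by convolution over the 2^n
    sign patterns, handling midranks from ties); above that, the normal
    approximation with tie correction is used.
    """
    d = np.asarray(post, dtype=float) - np.asarray(pre, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        warnings.warn("all paired differences are zero; p = 1")
        return 1.0
    ranks = stats.rankdata(np.abs(d), method="average")
    w_plus = ranks[d > 0].sum()
    if n <= exact_max_n:
        # distribution of 2*W+ over all sign assignments, by polynomial product
        units = np.round(2 * ranks).astype(int)
        total = units.sum()
        dist = np.zeros(total + 1)
        dist[0] = 1.0
        for u in units:
            nxt = dist.copy()
            nxt[u:] += dist[: total + 1 - u]
            dist = nxt
        dist /= dist.sum()
        w2 = int(round(2 * w_plus))
        p_low = dist[: w2 + 1].sum()
        p_high = dist[w2:].sum()
        return float(min(1.0, 2 * min(p_low, p_high)))
    mu = n * (n + 1) / 4
    tie_term = sum(
        c**3 - c for c in np.unique(ranks, return_counts=True)[1]
    )
    sigma2 = n * (n + 1) * (2 * n + 1) / 24 - tie_term / 48
    z = (w_plus - mu) / np.sqrt(sigma2)
    return float(2 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# sample size for AUC superiority


@dataclass
class PowerSpec:
    auc_null: float = 0.75
    auc_alt: float = 0.85
    alpha: float = 0.05
    power: float = 0.80
    allocation: float = 1.0  # cases per control
    correlation: float | None = None  # with the comparator marker
    training_multiplier: float = 3.0

    def validate(self) -> None:
        if not 0.5 <= self.auc_null < self.auc_alt < 1.0:
            raise ValueError("need 0.5 <= auc_null < auc_alt < 1")
        for name in ("alpha", "power"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")


def hanley_mcneil_var(auc: float, n_cases: int, n_controls: int) -> float:
    """Hanley-McNeil variance of a nonparametric AUC estimate."""
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    return (
        auc * (1 - auc) + (n_cases - 1) * (q1 - auc**2) + (n_controls - 1) * (q2 - auc**2)
    ) / (n_cases * n_controls)


def power_auc_superiority(spec: PowerSpec, n_max: int = 100000) -> dict:
    """Smallest per-arm n for the chosen power against a fixed null AUC.

    Normal-approximation test with Hanley-McNeil variances evaluated at the
    null and alternative AUC; when a comparator correlation r is supplied
    the variance of the difference is reduced by 2 r sqrt(V_model V_comp),
    with the comparator variance taken at the null AUC.  Returns the per-arm
    and total testing-set sizes plus the total with the training multiplier.
    """
    spec.validate()
    z_a = stats.norm.ppf(1 - spec.alpha / 2)
    z_b = stats.norm.ppf(spec.power)
    delta = spec.auc_alt - spec.auc_null

    def var_pair(n_cases, n_controls):
        v0 = hanley_mcneil_var(spec.auc_null, n_cases, n_controls)
        v1 = hanley_mcneil_var(spec.auc_alt, n_cases, n_controls)
        if spec.correlation is not None:
            r = spec.correlation
            v0, v1 = (
                v0 + v0 - 2 * r * v0,
                v1 + v0 - 2 * r * np.sqrt(v1 * v0),
            )
        return v0, v1

    for n in range(2, n_max + 1):
        n_cases = n
        n_controls = max(2, int(np.ceil(n / spec.allocation)))
        v0, v1 = var_pair(n_cases, n_controls)
        if z_a * np.sqrt(v0) + z_b * np.sqrt(v1) <= delta:
            total = n_cases + n_controls
            return {
                "n_cases": n_cases,
                "n_controls": n_controls,
                "n_test_total": total,
                "n_total_with_training": int(np.ceil(total * (1 + spec.training_multiplier))),
            }
    raise ValueError("no n up to n_max achieves the requested power")
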