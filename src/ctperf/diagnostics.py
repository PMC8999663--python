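"""Diagnostic-accuracy statistics, implemented from first principles.

Everything needed to evaluate a continuous perfusion parameter against a
binary segment-level reference standard: empirical ROC/AUC with DeLong
variance and the paired DeLong test, Youden-index cutoff selection,
confusion-matrix metrics with Wilson score intervals, the Mann-Whitney U
test, Cohen's kappa, the two-way random-effects single-measure
absolute-agreement ICC, the paired t-test, and the DLP-to-effective-dose
conversion.

Only distribution functions (normal, t, F) are taken from scipy; the
statistics themselves are computed here.  No multiplicity correction is
applied; per-segment analyses ignore within-patient clustering (flagged in
the report metadata).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import special
from scipy import stats as _sps  # distribution quantiles/CDFs only

from .errors import DegenerateStatisticError, InputError

__all__ = [
    "ROCResult",
    "DeLongResult",
    "ConfusionMatrix",
    "ProportionCI",
    "AgreementResult",
    "DiagnosticReport",
    "round_half_up",
    "empirical_auc",
    "delong_paired_test",
    "youden_cutoff",
    "wilson_ci",
    "confusion_metrics",
    "reconstruct_confusion",
    "mann_whitney_u",
    "cohen_kappa",
    "icc_absolute_agreement",
    "paired_t_test",
    "effective_dose",
    "evaluate_parameters",
]

_DIRECTIONS = ("lower_is_abnormal", "higher_is_abnormal")


def round_half_up(x: float) -> int:
    """Round to nearest integer with halves going up (0.5 -> 1)."""
    return int(math.floor(x + 0.5))


def _midranks(x: np.ndarray) -> np.ndarray:
    """Midranks (average ranks for ties), 1-based."""
    order = np.argsort(x, kind="mergesort")
    sx = x[order]
    ranks = np.empty(x.size, dtype=float)
    i = 0
    while i < x.size:
        j = i
        while j + 1 < x.size and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _oriented(scores, labels, direction: str):
    """Return (pos_scores, neg_scores) oriented so higher = more abnormal."""
    if direction not in _DIRECTIONS:
        raise InputError(f"direction must be one of {_DIRECTIONS}, got '{direction}'")
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if s.ndim != 1 or y.shape != s.shape:
        raise InputError("scores and labels must be 1-D and the same length")
    if direction == "lower_is_abnormal":
        s = -s
    pos, neg = s[y], s[~y]
    if pos.size == 0 or neg.size == 0:
        raise InputError("both classes must be nonempty")
    return pos, neg


def _delong_components(pos: np.ndarray, neg: np.ndarray):
    """AUC plus DeLong structural components (V10 per positive, V01 per
    negative), computed with midranks (Sun & Xu formulation)."""
    m, n = pos.size, neg.size
    tz = _midranks(np.concatenate([pos, neg]))
    tx = _midranks(pos)
    ty = _midranks(neg)
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    return auc, v10, v01


# ---------------------------------------------------------------------------
# Proportions and confusion matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProportionCI:
    """A proportion with a two-sided confidence interval."""

    estimate: float
    lower: float
    upper: float
    n: int

    def __post_init__(self):
        if not (-1e-12 <= self.lower <= self.estimate + 1e-12
                and self.estimate <= self.upper + 1e-12 <= 1.0 + 2e-12):
            raise InputError(
                f"interval must satisfy 0 <= lower <= estimate <= upper <= 1, "
                f"got ({self.lower}, {self.estimate}, {self.upper})")


def wilson_ci(successes: int, trials: int, level: float = 0.95) -> ProportionCI:
    """Wilson score interval for a binomial proportion."""
    if trials < 1:
        raise InputError(f"trials must be >= 1, got {trials}")
    if not 0 <= successes <= trials:
        raise InputError(f"successes must be in [0, {trials}], got {successes}")
    if not 0.0 < level < 1.0:
        raise InputError(f"level must be in (0, 1), got {level}")
    z = special.ndtri(0.5 + level / 2.0)
    p = successes / trials
    denom = 1.0 + z * z / trials
    center = (p + z * z / (2 * trials)) / denom
    half = (z / denom) * math.sqrt(p * (1 - p) / trials + z * z / (4 * trials * trials))
    return ProportionCI(estimate=p, lower=max(0.0, center - half),
                        upper=min(1.0, center + half), n=trials)


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be nonnegative")

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.fp + self.tn


def confusion_metrics(cm: ConfusionMatrix, level: float = 0.95) -> dict:
    """Sensitivity, specificity, PPV and NPV with Wilson CIs.

    A metric whose denominator is zero is returned as ``None`` (undefined)
    without affecting the others.
    """
    pairs = {
        "sensitivity": (cm.tp, cm.tp + cm.fn),
        "specificity": (cm.tn, cm.tn + cm.fp),
        "ppv": (cm.tp, cm.tp + cm.fp),
        "npv": (cm.tn, cm.tn + cm.fn),
    }
    return {
        name: (wilson_ci(k, n, level) if n > 0 else None)
        for name, (k, n) in pairs.items()
    }


def reconstruct_confusion(sens_pct: float, spec_pct: float,
                          n_pos: int, n_neg: int) -> ConfusionMatrix:
    """Rebuild the confusion matrix implied by printed sensitivity and
    specificity percentages and the class totals (round half up)."""
    if not (0 <= sens_pct <= 100 and 0 <= spec_pct <= 100):
        raise InputError("percentages must be in [0, 100]")
    if n_pos < 1 or n_neg < 1:
        raise InputError("class totals must be >= 1")
    tp = round_half_up(sens_pct / 100.0 * n_pos)
    tn = round_half_up(spec_pct / 100.0 * n_neg)
    return ConfusionMatrix(tp=tp, fp=n_neg - tn, fn=n_pos - tp, tn=tn)


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

@dataclass
class ROCResult:
    auc: float
    auc_ci: tuple
    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    youden_cutoff: float
    youden_j: float
    direction: str = "lower_is_abnormal"


def _roc_curve(scores, labels, direction):
    """Sens/spec swept over candidate cutoffs (midpoints plus extremes).

    Calls are abnormal strictly beyond the cutoff (value < cutoff for
    ``lower_is_abnormal``); a value at the cutoff is called normal.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    distinct = np.unique(s)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    span = max(distinct[-1] - distinct[0], 1.0)
    cands = np.concatenate([[distinct[0] - span], mids, [distinct[-1] + span]])
    sens = np.empty(cands.size)
    spec = np.empty(cands.size)
    for i, c in enumerate(cands):
        call = s < c if direction == "lower_is_abnormal" else s > c
        sens[i] = (call & y).sum() / y.sum()
        spec[i] = (~call & ~y).sum() / (~y).sum()
    return cands, sens, spec


def empirical_auc(scores, labels, direction: str = "lower_is_abnormal",
                  level: float = 0.95) -> ROCResult:
    """Empirical AUC (Mann-Whitney probability with midrank tie handling),
    oriented so the configured direction indicates abnormality, with a
    DeLong-variance normal-approximation confidence interval."""
    pos, neg = _oriented(scores, labels, direction)
    auc, v10, v01 = _delong_components(pos, neg)
    var = 0.0
    if pos.size > 1:
        var += np.var(v10, ddof=1) / pos.size
    if neg.size > 1:
        var += np.var(v01, ddof=1) / neg.size
    z = special.ndtri(0.5 + level / 2.0)
    half = z * math.sqrt(max(var, 0.0))
    ci = (max(0.0, auc - half), min(1.0, auc + half))
    cutoff, j, sens_c, spec_c = youden_cutoff(scores, labels, direction)
    thresholds, sens, spec = _roc_curve(scores, labels, direction)
    return ROCResult(auc=float(auc), auc_ci=ci, thresholds=thresholds,
                     sensitivities=sens, specificities=spec,
                     youden_cutoff=cutoff, youden_j=j, direction=direction)


@dataclass(frozen=True)
class DeLongResult:
    auc_a: float
    auc_b: float
    difference: float
    variance: float
    z: float
    p_value: float


def delong_paired_test(scores_a, scores_b, labels,
                       direction: str = "lower_is_abnormal") -> DeLongResult:
    """DeLong's test for two correlated AUCs measured on the same segments.

    Uses the structural-components estimator of the covariance of the two
    AUCs; the two-sided p-value comes from the normal distribution.
    """
    pos_a, neg_a = _oriented(scores_a, labels, direction)
    pos_b, neg_b = _oriented(scores_b, labels, direction)
    if pos_a.size != pos_b.size or neg_a.size != neg_b.size:
        raise InputError("scores_a and scores_b must share the same labels")
    auc_a, v10_a, v01_a = _delong_components(pos_a, neg_a)
    auc_b, v10_b, v01_b = _delong_components(pos_b, neg_b)
    m, n = pos_a.size, neg_a.size
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = float(cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1])
    diff = float(auc_a - auc_b)
    if var_diff <= 0:
        if abs(diff) < 1e-12:
            return DeLongResult(float(auc_a), float(auc_b), diff, 0.0, 0.0, 1.0)
        raise DegenerateStatisticError(
            "zero estimated variance of the AUC difference with unequal AUCs")
    z = diff / math.sqrt(var_diff)
    p = 2.0 * (1.0 - special.ndtr(abs(z)))
    return DeLongResult(float(auc_a), float(auc_b), diff, var_diff, z, min(p, 1.0))


def youden_cutoff(scores, labels, direction: str = "lower_is_abnormal"):
    """Cutoff maximizing Youden's J = sensitivity + specificity - 1.

    Candidate thresholds are midpoints between adjacent distinct observed
    values, plus the degenerate all-normal cutoff (so J is never below 0);
    ties in J are broken toward higher specificity.  When all scores are
    equal there is no informative cutoff and J = 0.

    Returns ``(cutoff, J, sensitivity_at_cutoff, specificity_at_cutoff)``.
    """
    _oriented(scores, labels, direction)  # validation
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    distinct = np.unique(s)
    if distinct.size == 1:
        return float(distinct[0]), 0.0, 0.0, 1.0
    span = distinct[-1] - distinct[0]
    all_normal = (distinct[0] - span if direction == "lower_is_abnormal"
                  else distinct[-1] + span)
    cands = np.r_[all_normal, (distinct[:-1] + distinct[1:]) / 2.0]
    best = None
    for c in cands:
        call = s < c if direction == "lower_is_abnormal" else s > c
        sens = (call & y).sum() / y.sum()
        spec = (~call & ~y).sum() / (~y).sum()
        j = sens + spec - 1.0
        key = (j, spec)
        if best is None or key > best[0]:
            best = (key, float(c), float(sens), float(spec))
    (j, spec), cutoff, sens, spec_ = best
    return cutoff, float(j), sens, spec_


# ---------------------------------------------------------------------------
# Rank and agreement statistics
# ---------------------------------------------------------------------------

def mann_whitney_u(group_a, group_b):
    """Mann-Whitney U (midranks) with the tie-corrected, continuity-corrected
    normal approximation for the two-sided p-value.

    Returns ``(U, p)`` where U counts pairs won by ``group_a`` (ties half).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InputError("both groups must be nonempty")
    na, nb = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    u = float(ranks[:na].sum() - na * (na + 1) / 2.0)
    mu = na * nb / 2.0
    n = na + nb
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum())) / (n * (n - 1)) if n > 1 else 0.0
    var = na * nb / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return u, 1.0
    z = (abs(u - mu) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    p = 2.0 * (1.0 - special.ndtr(z))
    return u, min(p, 1.0)


@dataclass(frozen=True)
class AgreementResult:
    """Inter-observer agreement statistic (kappa or ICC)."""

    statistic_name: str
    value: float
    ci: tuple | None = None
    undefined: bool = False


def cohen_kappa(calls_a, calls_b) -> AgreementResult:
    """Cohen's kappa for two raters' categorical calls on the same items."""
    a = np.asarray(calls_a)
    b = np.asarray(calls_b)
    if a.shape != b.shape or a.ndim != 1:
        raise InputError("call vectors must be 1-D and the same length")
    if a.size < 2:
        raise InputError("at least 2 items are required")
    cats = np.unique(np.concatenate([a, b]))
    n = a.size
    p_o = float((a == b).sum()) / n
    p_e = sum(
        ((a == c).sum() / n) * ((b == c).sum() / n) for c in cats
    )
    if abs(1.0 - p_e) < 1e-12:
        return AgreementResult("kappa", float("nan"), undefined=True)
    kappa = (p_o - p_e) / (1.0 - p_e)
    return AgreementResult("kappa", float(kappa))


def icc_absolute_agreement(ratings, level: float = 0.95) -> AgreementResult:
    """ICC(2,1): two-way random effects, single measure, absolute agreement.

    ``ratings`` is an (n_targets, n_raters) array with no missing cells.
    The confidence interval follows McGraw & Wong via F-distribution bounds.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise InputError("ratings must be (n_targets, n_raters>=2)")
    n, k = x.shape
    if n < 5:
        raise InputError(f"at least 5 targets are required, got {n}")
    if np.isnan(x).any():
        raise InputError("missing cells are not allowed")
    if np.ptp(x) == 0:
        return AgreementResult("icc", float("nan"), undefined=True)
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * ((row_means - grand) ** 2).sum() / (n - 1)
    msc = n * ((col_means - grand) ** 2).sum() / (k - 1)
    sse = ((x - row_means[:, None] - col_means[None, :] + grand) ** 2).sum()
    mse = sse / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)

    alpha = 1.0 - level
    if 1.0 - icc < 1e-12:
        return AgreementResult("icc", 1.0, ci=(1.0, 1.0))
    a_ = (k * icc) / (n * (1.0 - icc))
    b_ = 1.0 + (k * icc * (n - 1.0)) / (n * (1.0 - icc))
    denom_v = ((a_ * msc) ** 2 / (k - 1)) + ((b_ * mse) ** 2 / ((n - 1) * (k - 1)))
    if denom_v <= 0:
        return AgreementResult("icc", float(icc))
    v = (a_ * msc + b_ * mse) ** 2 / denom_v
    f_l = _sps.f.ppf(1.0 - alpha / 2.0, n - 1, v)
    f_u = _sps.f.ppf(1.0 - alpha / 2.0, v, n - 1)
    lower = n * (msr - f_l * mse) / (
        f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f_u * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_u * msr)
    return AgreementResult("icc", float(icc),
                           ci=(float(max(-1.0, lower)), float(min(1.0, upper))))


def paired_t_test(a, b):
    """Paired t-test (two-sided), e.g. rest vs stress heart rate.

    A zero-variance nonzero difference is degenerate (infinite t) and
    raises; identical vectors return ``(0.0, 1.0)``.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("paired samples must be 1-D and the same length")
    if x.size < 2:
        raise InputError("at least 2 pairs are required")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return 0.0, 1.0
        raise DegenerateStatisticError(
            "zero variance of paired differences with nonzero mean (infinite t)")
    t = d.mean() / (sd / math.sqrt(d.size))
    p = 2.0 * _sps.t.sf(abs(t), d.size - 1)
    return float(t), float(min(p, 1.0))


def effective_dose(dlp: float, conversion_factor: float = 0.014) -> float:
    """Effective dose (mSv) from the dose-length product (mGy*cm)."""
    if dlp < 0:
        raise InputError(f"dlp must be nonnegative, got {dlp}")
    return dlp * conversion_factor


# ---------------------------------------------------------------------------
# Cohort-level report
# ---------------------------------------------------------------------------

@dataclass
class DiagnosticReport:
    """Per-parameter diagnostic accuracy against the reference standard."""

    n_pos: int
    n_neg: int
    parameters: dict = field(default_factory=dict)
    delong_pairwise: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        def _clean(obj):
            if isinstance(obj, dict):
                return {k: _clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_clean(v) for v in obj]
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            if isinstance(obj, (ProportionCI, DeLongResult, AgreementResult)):
                return _clean(asdict(obj))
            return obj

        payload = _clean({
            "n_pos": self.n_pos, "n_neg": self.n_neg,
            "parameters": self.parameters,
            "delong_pairwise": self.delong_pairwise,
            "metadata": self.metadata,
        })
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def summary_frame(self) -> pd.DataFrame:
        """Flat summary: one row per parameter, percentage cells rounded
        half-up with their 95% CI bounds."""
        rows = []
        for name, p in self.parameters.items():
            row = {"parameter": name,
                   "auc": p["auc"],
                   "auc_ci_lower": p["auc_ci"][0],
                   "auc_ci_upper": p["auc_ci"][1],
                   "cutoff": p["cutoff"]}
            for metric in ("sensitivity", "specificity", "ppv", "npv"):
                ci = p["metrics"][metric]
                if ci is None:
                    row[f"{metric}_pct"] = None
                    continue
                row[f"{metric}_pct"] = round_half_up(100 * ci["estimate"])
                row[f"{metric}_ci_lower_pct"] = round_half_up(100 * ci["lower"])
                row[f"{metric}_ci_upper_pct"] = round_half_up(100 * ci["upper"])
            rows.append(row)
        return pd.DataFrame(rows)


def evaluate_parameters(table: pd.DataFrame, truth_col: str = "abnormal",
                        parameter_cols: dict | None = None,
                        level: float = 0.95) -> DiagnosticReport:
    """Full diagnostic evaluation of perfusion parameters on a segment table.

    Parameters
    ----------
    table : DataFrame
        One row per segment; needs a boolean ``truth_col`` and one column
        per parameter.
    parameter_cols : dict
        Mapping ``name -> column``; all parameters are oriented
        lower-is-abnormal.  Defaults to ``{"mpr": "mpr", "tpr": "tpr",
        "endo_hu": "endo_hu"}``.

    For each parameter: ROC/AUC with DeLong CI, Youden-optimal cutoff,
    confusion matrix and Wilson-CI metrics at that cutoff, and the
    Mann-Whitney comparison of normal vs abnormal segments.  All parameter
    pairs are compared with DeLong's test.
    """
    if parameter_cols is None:
        parameter_cols = {"mpr": "mpr", "tpr": "tpr", "endo_hu": "endo_hu"}
    y = table[truth_col].to_numpy().astype(bool)
    report = DiagnosticReport(
        n_pos=int(y.sum()), n_neg=int((~y).sum()),
        metadata={
            "within_patient_clustering_corrected": False,
            "ci_method": "wilson",
            "direction": "lower_is_abnormal",
            "level": level,
        },
    )
    for name, col in parameter_cols.items():
        scores = table[col].to_numpy(dtype=float)
        roc = empirical_auc(scores, y, level=level)
        call = scores < roc.youden_cutoff
        cm = ConfusionMatrix(
            tp=int((call & y).sum()), fp=int((call & ~y).sum()),
            fn=int((~call & y).sum()), tn=int((~call & ~y).sum()))
        metrics = confusion_metrics(cm, level=level)
        u, p_u = mann_whitney_u(scores[~y], scores[y])
        abn = scores[y]
        nrm = scores[~y]
        report.parameters[name] = {
            "auc": roc.auc,
            "auc_ci": list(roc.auc_ci),
            "cutoff": roc.youden_cutoff,
            "youden_j": roc.youden_j,
            "confusion": asdict(cm),
            "metrics": {k: (asdict(v) if v is not None else None)
                        for k, v in metrics.items()},
            "mann_whitney": {"U": u, "p": p_u},
            "median_iqr_normal": [float(np.percentile(nrm, q)) for q in (50, 25, 75)],
            "median_iqr_abnormal": [float(np.percentile(abn, q)) for q in (50, 25, 75)],
            "mean_sd_normal": [float(nrm.mean()), float(nrm.std(ddof=1))],
            "mean_sd_abnormal": [float(abn.mean()), float(abn.std(ddof=1))],
        }
    names = list(parameter_cols)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            res = delong_paired_test(
                table[parameter_cols[a]].to_numpy(dtype=float),
                table[parameter_cols[b]].to_numpy(dtype=float), y)
            report.delong_pairwise[f"{a}_vs_{b}"] = asdict(res)
    return report
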