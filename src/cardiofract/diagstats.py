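"""Diagnostic-accuracy and reproducibility statistics for continuous markers.

Accuracy: nonparametric ROC AUC with Hanley–McNeil standard error, the
Youden index J = max_c (sensitivity_c + specificity_c - 1) over all
candidate thresholds, and sensitivity/specificity/predictive values with
exact (Clopper–Pearson) 95% confidence intervals.

Reproducibility: Bland–Altman bias and 95% limits of agreement, the
repeatability coefficient RC = 1.96 sqrt(sum(D_i^2) / (n - 1)) over the
absolute paired differences D_i, a coefficient of variation, the
intraclass correlation coefficient (two-way random effects, absolute
agreement, single measures, ICC(2,1)) and Fleiss' kappa for binary
classification concordance.

Convention throughout: higher marker values indicate disease, and a
subject is classified positive when its score is >= the threshold.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ROCResult",
    "DiagnosticResult",
    "BlandAltmanResult",
    "hanley_auc",
    "youden_threshold",
    "exact_ci_proportion",
    "diagnostic_accuracy",
    "evaluate_marker",
    "bland_altman",
    "icc_single",
    "fleiss_kappa",
]

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclasses.dataclass(frozen=True)
class ROCResult:
    auc: float
    auc_se: float
    youden_threshold: float
    j: float
    sens_at_c: float
    spec_at_c: float


@dataclasses.dataclass(frozen=True)
class DiagnosticResult:
    """2x2 accuracy summary; rates in percent with exact 95% CIs."""

    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    ci_95: dict[str, tuple[float, float]]


@dataclasses.dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    loa_95: tuple[float, float]
    rc: float
    cov_pct: float
    n: int


def _as_groups(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must be paired")
    cases, controls = scores[labels], scores[~labels]
    if cases.size == 0 or controls.size == 0:
        raise ValueError("need both cases and controls")
    return cases, controls


def hanley_auc(
    scores_cases: Sequence[float], scores_controls: Sequence[float]
) -> tuple[float, float]:
    """Nonparametric AUC = P(case > control) + P(tie)/2, with Hanley SE.

    The AUC is computed by midranks (identical to averaging over all
    case-control pairs); the standard error uses Hanley & McNeil's
    exponential approximation Q1 = A/(2-A), Q2 = 2A^2/(1+A).
    """
    cases = np.asarray(scores_cases, dtype=float)
    controls = np.asarray(scores_controls, dtype=float)
    if cases.size == 0 or controls.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n0 = cases.size, controls.size
    ranks = stats.rankdata(np.concatenate([cases, controls]))
    # Mann-Whitney U of the cases from their rank sum
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    auc = u / (n1 * n0)
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1.0 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2)
    ) / (n1 * n0)
    return float(auc), float(np.sqrt(max(var, 0.0)))


def _sens_spec(cases: np.ndarray, controls: np.ndarray, c: float) -> tuple[float, float]:
    sens = float(np.mean(cases >= c))
    spec = float(np.mean(controls < c))
    return sens, spec


def youden_threshold(scores: Sequence[float], labels: Sequence[int]) -> ROCResult:
    """Optimal threshold by the Youden index.

    Candidates are the midpoints between adjacent distinct sorted scores,
    plus sentinels below the minimum and above the maximum; J ties are
    broken toward the higher-specificity (larger) threshold.
    """
    cases, controls = _as_groups(scores, labels)
    distinct = np.unique(np.concatenate([cases, controls]))
    mids = (distinct[:-1] + distinct[1:]) / 2.0 if distinct.size > 1 else np.array([])
    candidates = np.concatenate([[distinct[0] - 1.0], mids, [distinct[-1] + 1.0]])
    best = None
    for c in candidates:  # increasing order: later ties = higher specificity
        sens, spec = _sens_spec(cases, controls, float(c))
        j = sens + spec - 1.0
        if best is None or j >= best[0] - 1e-12:
            best = (j, float(c), sens, spec)
    auc, se = hanley_auc(cases, controls)
    j, c, sens, spec = best
    return ROCResult(
        auc=auc, auc_se=se, youden_threshold=c, j=j, sens_at_c=sens, spec_at_c=spec
    )


def exact_ci_proportion(
    x: int, n: int, level: float = 0.95
) -> tuple[float, float]:
    """Clopper–Pearson exact CI for a binomial proportion, in percent."""
    if not (0 <= x <= n and n >= 1):
        raise ValueError(f"invalid counts x={x}, n={n}")
    alpha = 1.0 - level
    lower = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    upper = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return 100.0 * lower, 100.0 * upper


def diagnostic_accuracy(tp: int, fp: int, fn: int, tn: int) -> DiagnosticResult:
    """Sensitivity/specificity/PPV/NPV (percent) with exact 95% CIs."""
    counts = {"tp": tp, "fp": fp, "fn": fn, "tn": tn}
    if any(v < 0 for v in counts.values()):
        raise ValueError("counts must be non-negative")

    def rate(x: int, n: int) -> tuple[float, tuple[float, float]]:
        if n == 0:
            return float("nan"), (float("nan"), float("nan"))
        return 100.0 * x / n, exact_ci_proportion(x, n)

    sens, ci_sens = rate(tp, tp + fn)
    spec, ci_spec = rate(tn, tn + fp)
    ppv, ci_ppv = rate(tp, tp + fp)
    npv, ci_npv = rate(tn, tn + fn)
    return DiagnosticResult(
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        ci_95={
            "sensitivity": ci_sens,
            "specificity": ci_spec,
            "ppv": ci_ppv,
            "npv": ci_npv,
        },
    )


def evaluate_marker(
    scores: Sequence[float], labels: Sequence[int], threshold: float
) -> DiagnosticResult:
    """2x2 accuracy of the rule ``score >= threshold`` against truth."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    positive = scores >= threshold
    return diagnostic_accuracy(
        tp=int(np.sum(positive & labels)),
        fp=int(np.sum(positive & ~labels)),
        fn=int(np.sum(~positive & labels)),
        tn=int(np.sum(~positive & ~labels)),
    )


def bland_altman(
    reads_a: Sequence[float], reads_b: Sequence[float]
) -> BlandAltmanResult:
    """Bland–Altman agreement of paired repeat measurements.

    bias = mean(a - b); 95% limits of agreement = bias +/- 1.96 sd(a - b);
    RC = 1.96 sqrt(sum(D_i^2)/(n - 1)) with D_i the absolute differences
    and n the number of measurement pairs; CoV (percent) = 100 sd(a - b) /
    grand mean of all readings.
    """
    a = np.asarray(reads_a, dtype=float)
    b = np.asarray(reads_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("reads must be equal-length 1-D paired arrays")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    rc = 1.96 * float(np.sqrt(np.sum(np.abs(d) ** 2) / (n - 1)))
    grand_mean = float(np.concatenate([a, b]).mean())
    cov = 100.0 * sd / grand_mean if grand_mean != 0 else float("inf")
    return BlandAltmanResult(
        bias=bias,
        loa_95=(bias - 1.96 * sd, bias + 1.96 * sd),
        rc=rc,
        cov_pct=float(cov),
        n=n,
    )


def icc_single(ratings: np.ndarray) -> tuple[float, tuple[float, float]]:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    ``ratings`` is an (n subjects x k raters/readings) matrix with no
    missing cells.  The 95% CI comes from the F-distribution bounds.
    """
    import pingouin as pg

    ratings = np.asarray(ratings, dtype=float)
    if ratings.ndim != 2 or ratings.shape[0] < 2 or ratings.shape[1] < 2:
        raise ValueError("ratings must be an n x k matrix, n,k >= 2")
    if np.any(~np.isfinite(ratings)):
        raise ValueError("missing cells are not allowed")
    n, k = ratings.shape
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), k),
            "rater": np.tile(np.arange(k), n),
            "value": ratings.ravel(),
        }
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        # perfect agreement gives MSE = 0; pingouin still returns ICC = 1
        table = pg.intraclass_corr(
            data=long, targets="subject", raters="rater", ratings="value"
        ).set_index("Type")
    # label differs across pingouin versions: ICC(A,1) == Shrout-Fleiss ICC2
    label = "ICC(A,1)" if "ICC(A,1)" in table.index else "ICC2"
    row = table.loc[label]
    ci_col = "CI95" if "CI95" in table.columns else "CI95%"
    lo, hi = (float(v) for v in row[ci_col])
    return float(row["ICC"]), (lo, hi)


def fleiss_kappa(
    ratings: np.ndarray, level: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Fleiss' kappa for m raters' categorical ratings of n subjects.

    ``ratings`` is an (n subjects x m raters) array of category labels.
    The CI is the large-sample Wald interval using the Fleiss–Nee–Landis
    standard error; like the source tables it is not clipped to [-1, 1].
    """
    from statsmodels.stats import inter_rater

    ratings = np.asarray(ratings)
    if ratings.ndim != 2 or ratings.shape[1] < 2:
        raise ValueError("ratings must be n subjects x (m >= 2) raters")
    n, m = ratings.shape
    cats = np.unique(ratings)
    if cats.size < 2:
        raise ValueError(
            "kappa undefined: all ratings fall in a single category"
        )
    table = np.stack([(ratings == c).sum(axis=1) for c in cats], axis=1)
    kappa = float(inter_rater.fleiss_kappa(table, method="fleiss"))

    p = table.sum(axis=0) / (n * m)  # category marginals
    q = 1.0 - p
    spq = float(np.sum(p * q))
    se = np.sqrt(2.0 / (n * m * (m - 1))) * np.sqrt(
        spq**2 - float(np.sum(p * q * (q - p)))
    ) / spq
    z = stats.norm.ppf(0.5 + level / 2.0)
    return kappa, (kappa - z * se, kappa + z * se)
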