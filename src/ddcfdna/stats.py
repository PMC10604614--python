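"""Cohort statistics for the dichotomised dd-cfDNA analysis.

Group comparisons at the 1.0% cutoff (Mann-Whitney U for continuous rows,
Pearson chi-square for binary rows), ROC curves with DeLong confidence
intervals for the outcome discriminations, and a Firth-penalised logistic
fit as the covariate-adjusted association analogue.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_curve


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n_per_group: tuple[int, ...]

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")


@dataclass(frozen=True)
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    p_value: float
    n_pos: int
    n_neg: int
    curve_points: tuple[tuple[float, float], ...]  # (FPR, TPR)

    def __post_init__(self) -> None:
        if not self.ci_low <= self.auc <= self.ci_high:
            raise ValueError("CI must bracket the AUC")


@dataclass(frozen=True)
class EffectEstimate:
    """Adjusted-association analogue: Firth-penalised logistic odds ratio.

    This is an analogue of an adjusted risk estimate, not a reproduction of
    any particular cohort's hazard ratio; the penalty keeps small, sparse
    2x2 structures estimable.
    """

    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    method: str = "firth_logistic"


# ---------------------------------------------------------------------------
# descriptive statistics and two-group tests
# ---------------------------------------------------------------------------

def median_iqr(values: Sequence[float], method: str = "linear") -> tuple[float, float, float]:
    """(median, Q1, Q3) by linear interpolation (default) or Tukey hinges."""
    x = np.asarray(list(values), dtype=float)
    if x.size == 0:
        raise ValueError("median_iqr of empty input")
    if method == "linear":
        q1, med, q3 = np.percentile(x, [25, 50, 75])
    elif method == "tukey":
        s = np.sort(x)
        n = s.size
        med = float(np.median(s))
        half = (n + 1) // 2
        q1 = float(np.median(s[:half]))
        q3 = float(np.median(s[n - half:]))
    else:
        raise ValueError(f"unknown quartile method {method!r}")
    return float(med), float(q1), float(q3)


def mann_whitney(
    group_a: Sequence[float], group_b: Sequence[float], method: str = "auto"
) -> TestResult:
    """Two-sided Mann-Whitney U test.

    ``auto`` uses exact enumeration for small untied samples
    (n_a + n_b <= 12) and the tie-corrected normal approximation with
    continuity correction otherwise.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if method == "auto":
        no_ties = np.unique(np.concatenate([a, b])).size == a.size + b.size
        method = "exact" if (a.size + b.size <= 12 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method=f"mann_whitney_{method}",
        n_per_group=(int(a.size), int(b.size)),
    )


def chi_square_2x2(
    table: Sequence[Sequence[float]], continuity_correction: bool = False
) -> TestResult:
    """Pearson chi-square on a 2x2 contingency table, df = 1.

    The continuity (Yates) correction is off by default: the uncorrected
    statistic is what reproduces the printed association p-values from
    small transplant-cohort tables.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("counts must be non-negative integers")
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("both margins must be positive")
    expected = np.outer(row, col) / t.sum()
    dev = np.abs(t - expected)
    if continuity_correction:
        dev = np.maximum(dev - 0.5, 0.0)
    chi2 = float((dev**2 / expected).sum())
    p = float(sps.chi2.sf(chi2, df=1))
    return TestResult(
        statistic=chi2,
        p_value=p,
        method="chi_square_yates" if continuity_correction else "chi_square_pearson",
        n_per_group=tuple(int(c) for c in row),
    )


# ---------------------------------------------------------------------------
# ROC analysis
# ---------------------------------------------------------------------------

def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Midrank placement values used by the DeLong variance estimator."""
    m, n = pos.size, neg.size
    combined = np.concatenate([pos, neg])
    ranks = sps.rankdata(combined)
    ranks_pos, ranks_neg = ranks[:m], ranks[m:]
    v10 = (ranks_pos - sps.rankdata(pos)) / n          # P(neg < pos) per positive
    v01 = 1.0 - (ranks_neg - sps.rankdata(neg)) / m    # per negative
    return v10, v01


def roc_auc_ci(
    scores: Sequence[float],
    labels: Sequence[int],
    ci_method: str = "delong",
    alpha: float = 0.05,
) -> RocResult:
    """ROC curve, AUC and confidence interval for a binary discrimination.

    AUC via the rank (Mann-Whitney) identity; the CI and the p-value of the
    AUC = 0.5 test come from the DeLong covariance estimator by default,
    with Hanley-McNeil available as ``ci_method="hanley"``. The CI is
    clipped to [0, 1].
    """
    y = np.asarray(list(labels), dtype=int)
    x = np.asarray(list(scores), dtype=float)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    pos, neg = x[y == 1], x[y == 0]
    m, n = pos.size, neg.size
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")

    v10, v01 = _placements(pos, neg)
    auc = float(v10.mean())

    if ci_method == "delong":
        var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
            np.var(v01, ddof=1) / n if n > 1 else 0.0
        )
    elif ci_method == "hanley":
        q1 = auc / (2 - auc)
        q2 = 2 * auc**2 / (1 + auc)
        var = (auc * (1 - auc) + (m - 1) * (q1 - auc**2) + (n - 1) * (q2 - auc**2)) / (m * n)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    se = float(np.sqrt(max(var, 0.0)))
    z = sps.norm.ppf(1 - alpha / 2)
    lo = float(np.clip(auc - z * se, 0.0, 1.0))
    hi = float(np.clip(auc + z * se, 0.0, 1.0))
    p = 1.0 if se == 0 and auc == 0.5 else float(2 * sps.norm.sf(abs(auc - 0.5) / se)) if se > 0 else 0.0

    fpr, tpr, _ = roc_curve(y, x)
    return RocResult(
        auc=auc,
        ci_low=min(lo, auc),
        ci_high=max(hi, auc),
        p_value=min(p, 1.0),
        n_pos=m,
        n_neg=n,
        curve_points=tuple(zip(fpr.tolist(), tpr.tolist())),
    )


# ---------------------------------------------------------------------------
# Firth-penalised logistic adjusted association
# ---------------------------------------------------------------------------

def _firth_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 200, tol: float = 1e-8):
    """Firth-penalised logistic regression (Jeffreys-prior score correction).

    Returns (beta, covariance). Newton iterations on the modified score
    U*(b) = X'(y - p + h*(0.5 - p)) with h the hat-matrix diagonal.
    """
    n, k = X.shape
    beta = np.zeros(k)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        XW = X * w[:, None]
        info = X.T @ XW
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError("Fisher information singular; fit not estimable") from exc
        h = np.einsum("ij,jk,ik->i", XW, info_inv, X)
        score = X.T @ (y - p + h * (0.5 - p))
        step = info_inv @ score
        # dampen large steps for stability on near-separated data
        norm = np.linalg.norm(step)
        if norm > 5.0:
            step *= 5.0 / norm
        beta = beta + step
        if np.linalg.norm(score) < tol:
            break
    else:
        raise RuntimeError("Firth logistic fit did not converge")
    eta = np.clip(X @ beta, -30, 30)
    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1.0 - p)
    cov = np.linalg.inv(X.T @ (X * w[:, None]))
    return beta, cov


def adjusted_association(
    outcome: Sequence[int],
    exposure: Sequence[int],
    covariate: Sequence[float],
    alpha: float = 0.05,
) -> EffectEstimate:
    """Exposure effect on a binary outcome, adjusted for one covariate.

    Firth-penalised logistic regression of ``outcome`` on intercept,
    ``exposure`` (e.g. the elevated dd-cfDNA flag) and ``covariate`` (e.g.
    eGFR, standardised internally). Returns the exposure odds ratio with a
    Wald confidence interval. This is a labelled analogue of an adjusted
    risk model, not a survival fit.
    """
    y = np.asarray(list(outcome), dtype=float)
    e = np.asarray(list(exposure), dtype=float)
    c = np.asarray(list(covariate), dtype=float)
    if y.size < 10:
        raise ValueError("need at least 10 observations")
    if len({0.0, 1.0} & set(np.unique(y))) < 2 or np.unique(y).size < 2:
        raise ValueError("outcome must not be constant")
    c_std = (c - c.mean()) / (c.std() if c.std() > 0 else 1.0)
    X = np.column_stack([np.ones_like(y), e, c_std])
    beta, cov = _firth_logistic(X, y)
    b, se = float(beta[1]), float(np.sqrt(cov[1, 1]))
    z = sps.norm.ppf(1 - alpha / 2)
    p = float(2 * sps.norm.sf(abs(b) / se)) if se > 0 else 0.0
    return EffectEstimate(
        odds_ratio=float(np.exp(b)),
        ci_low=float(np.exp(b - z * se)),
        ci_high=float(np.exp(b + z * se)),
        p_value=min(p, 1.0),
    )


# ---------------------------------------------------------------------------
# group-comparison tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariableSpec:
    column: str
    label: str
    kind: str  # "continuous" | "binary"


#: default rows of the clinical comparison table (columns of the joined
#: per-patient frame produced by the pipeline)
DEFAULT_TABLE1_VARIABLES: tuple[VariableSpec, ...] = (
    VariableSpec("abmr", "1-month AbMR", "binary"),
    VariableSpec("acute_rejection", "1-month acute rejection", "binary"),
    VariableSpec("troubled_graft", "1-month troubled graft", "binary"),
    VariableSpec("first_year_rejection", "First year acute rejection", "binary"),
    VariableSpec("egfr", "First month eGFR (mL/min/1.73 m2)", "continuous"),
    VariableSpec("albuminuria", "First month albuminuria (mg/g)", "continuous"),
    VariableSpec("ttr_8_12", "TTR 8-12 at month 1 (%)", "continuous"),
    VariableSpec("ttr_above_12", "TTR > 12 at month 1 (%)", "continuous"),
    VariableSpec("mean_level", "Mean tacrolimus trough level month 1 (ng/mL)", "continuous"),
    VariableSpec("trough_month1", "Tacrolimus trough level at month 1 (ng/mL)", "continuous"),
    VariableSpec("mpa_trough", "Mycophenolic acid trough level at month 1 (mg/L)", "continuous"),
    VariableSpec("any_below_5", "Any tacrolimus level < 5 at month 1", "binary"),
    VariableSpec("any_below_6", "Any tacrolimus level < 6 at month 1", "binary"),
    VariableSpec("cv_percent", "Coefficient of variability at month 1 (%)", "continuous"),
    VariableSpec("cd_ratio", "Tacrolimus trough level/dose at month 1", "continuous"),
    VariableSpec("fast_metabolizer", "Fast tacrolimus metabolizers", "binary"),
)

DEFAULT_TABLE2_VARIABLES: tuple[VariableSpec, ...] = (
    VariableSpec("antigen_mm_total", "Antigen HLA class I and II mismatches", "continuous"),
    VariableSpec("classI_eplet_load", "All HLA class I eplet mismatch load", "continuous"),
    VariableSpec("classII_eplet_load", "All HLA class II eplet mismatch load", "continuous"),
    VariableSpec("drb1_eplet_load", "HLA-DRB1 eplet mismatch load", "continuous"),
    VariableSpec("dqb1_eplet_load", "HLA-DQB1 eplet mismatch load", "continuous"),
    VariableSpec("dqa1_eplet_load", "HLA-DQA1 eplet mismatch load", "continuous"),
)


def _fmt_median_iqr(values: np.ndarray) -> str:
    med, q1, q3 = median_iqr(values)
    return f"{med:.1f} [{q1:.1f}-{q3:.1f}]"


def _fmt_percent(values: np.ndarray) -> str:
    return f"{100.0 * np.mean(values):.1f}%"


def build_group_comparison(
    df: pd.DataFrame,
    variables: Iterable[VariableSpec],
    score_column: str = "dd_fraction_percent",
    cutoff: float = 1.0,
) -> pd.DataFrame:
    """Comparison table of the cohort split at the dd-cfDNA cutoff.

    One row per variable: overall / elevated-group / low-group summaries
    (median [IQR] for continuous rows, % for binary rows) and the
    Mann-Whitney or uncorrected chi-square p-value. Binary rows with an
    empty margin (e.g. an event observed in neither group) get a NaN
    p-value rather than an error.
    """
    variables = list(variables)
    missing = [v.column for v in variables if v.column not in df.columns]
    if missing:
        raise ValueError(f"missing variables: {missing}")
    if score_column not in df.columns:
        raise ValueError(f"missing score column {score_column!r}")
    high = df[df[score_column] >= cutoff]
    low = df[df[score_column] < cutoff]
    rows = []
    for v in variables:
        x_all = df[v.column].to_numpy(dtype=float)
        x_hi = high[v.column].to_numpy(dtype=float)
        x_lo = low[v.column].to_numpy(dtype=float)
        if v.kind == "continuous":
            p = (
                mann_whitney(x_hi, x_lo).p_value
                if x_hi.size > 0 and x_lo.size > 0
                else float("nan")
            )
            overall, s_hi, s_lo = _fmt_median_iqr(x_all), (
                _fmt_median_iqr(x_hi) if x_hi.size else "-"
            ), (_fmt_median_iqr(x_lo) if x_lo.size else "-")
        elif v.kind == "binary":
            tab = [
                [int(x_hi.sum()), int(x_hi.size - x_hi.sum())],
                [int(x_lo.sum()), int(x_lo.size - x_lo.sum())],
            ]
            try:
                p = chi_square_2x2(tab).p_value
            except ValueError:
                p = float("nan")
            overall, s_hi, s_lo = _fmt_percent(x_all), (
                _fmt_percent(x_hi) if x_hi.size else "-"
            ), (_fmt_percent(x_lo) if x_lo.size else "-")
        else:
            raise ValueError(f"unknown variable kind {v.kind!r}")
        rows.append(
            {
                "variable": v.label,
                "overall": overall,
                "elevated": s_hi,
                "low": s_lo,
                "p_value": round(p, 3) if np.isfinite(p) else p,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["n_elevated"] = int(len(high))
    out.attrs["n_low"] = int(len(low))
    out.attrs["cutoff"] = cutoff
    return out
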