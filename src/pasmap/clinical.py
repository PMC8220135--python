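"""Clinical/demographic group comparisons and symptom correlations.

Group comparisons of scalar variables use the equal-variance pooled
two-sample t (reproducible from printed group means/SDs/ns alone; Welch is
available by flag) and the Pearson chi-square for categorical tables.
Associations between per-region mean PAS and symptom scores use Pearson
correlation with Bonferroni correction over the full (region x score)
family — e.g. 7 regions x 3 obsessive-compulsive subscores = 21 tests at
alpha/21.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class SummaryStats:
    """Group summary of one variable: mean, SD, and sample size."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")
        if self.n < 2:
            raise ValueError("n must be at least 2")

    @classmethod
    def from_data(cls, x) -> "SummaryStats":
        x = np.asarray(x, dtype=float)
        return cls(mean=float(x.mean()), sd=float(x.std(ddof=1)), n=int(x.size))


@dataclass(frozen=True)
class CorrelationResult:
    region: str
    score: str
    r: float
    p_uncorrected: float
    m_tests: int
    bonferroni_alpha: float
    significant: bool
    n: int


def pooled_t_from_summary(
    a: SummaryStats, b: SummaryStats, welch: bool = False
) -> tuple[float, float]:
    """Two-sample t from group summaries; pooled equal-variance by default.

    Returns ``(t, df)`` with t oriented as ``a - b``.
    """
    if welch:
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        se = np.sqrt(va + vb)
        if se == 0:
            raise ValueError("zero variance in both groups")
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
        return float((a.mean - b.mean) / se), float(df)
    df = a.n + b.n - 2
    sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
    if sp2 == 0:
        raise ValueError("zero pooled variance")
    se = np.sqrt(sp2 * (1 / a.n + 1 / b.n))
    return float((a.mean - b.mean) / se), float(df)


def summary_p_value(t: float, df: float) -> float:
    return float(2 * stats.t.sf(abs(t), df))


def chi_square_counts(table, correction: bool = False) -> tuple[float, int]:
    """Pearson chi-square on a 2x2 count table (optional Yates correction)."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero margin in contingency table")
    res = stats.chi2_contingency(table, correction=correction)
    expected = res.expected_freq
    if np.any(expected <= 0):
        raise ValueError("expected counts must be positive")
    return float(res.statistic), 1


def pearson_with_bonferroni(
    features: pd.DataFrame, scores: pd.DataFrame, alpha: float = 0.05
) -> list[CorrelationResult]:
    """Pearson r for every (region, score) pair, Bonferroni-corrected.

    ``features`` columns are regions (per-subject cluster mean PAS),
    ``scores`` columns are clinical scores, rows aligned by subject.
    ``m_tests = n_regions * n_scores``; a pair is significant when its
    uncorrected p is below ``alpha / m_tests``. Constant columns yield an
    undefined (NaN) r, flagged not-significant.
    """
    if len(features) != len(scores):
        raise ValueError("features and scores must have the same subjects")
    if len(features) < 3:
        raise ValueError("need at least 3 paired observations")
    m_tests = features.shape[1] * scores.shape[1]
    thr = alpha / m_tests
    out: list[CorrelationResult] = []
    for region in features.columns:
        for score in scores.columns:
            x = features[region].to_numpy(dtype=float)
            y = scores[score].to_numpy(dtype=float)
            keep = np.isfinite(x) & np.isfinite(y)
            x, y = x[keep], y[keep]
            if x.size < 3 or np.std(x) == 0 or np.std(y) == 0:
                r, p = float("nan"), float("nan")
            else:
                res = stats.pearsonr(x, y)  # p via exact t transform, df = n - 2
                r, p = float(res.statistic), float(res.pvalue)
            out.append(
                CorrelationResult(
                    region=str(region), score=str(score), r=r, p_uncorrected=p,
                    m_tests=m_tests, bonferroni_alpha=thr,
                    significant=bool(np.isfinite(p) and p < thr), n=int(x.size),
                )
            )
    return out


def correlation_results_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def group_summary_table(
    manifest: pd.DataFrame, variables: list[str] | None = None
) -> pd.DataFrame:
    """Per-variable group summaries and pooled t from a cohort manifest."""
    variables = variables or [
        c for c in manifest.columns
        if c not in ("subject_id", "group", "seed", "bold_path", "motion_path")
        and np.issubdtype(manifest[c].dtype, np.number)
    ]
    rows = []
    for var in variables:
        summaries = {
            g: SummaryStats.from_data(manifest.loc[manifest.group == g, var])
            for g in ("patients", "controls")
        }
        try:
            t, df = pooled_t_from_summary(summaries["patients"], summaries["controls"])
        except ValueError:  # zero pooled variance (e.g. a constant variable)
            t, df = float("nan"), summaries["patients"].n + summaries["controls"].n - 2
        rows.append(
            {
                "variable": var,
                "patients_mean": summaries["patients"].mean,
                "patients_sd": summaries["patients"].sd,
                "controls_mean": summaries["controls"].mean,
                "controls_sd": summaries["controls"].sd,
                "t": t,
                "df": df,
                "p": summary_p_value(t, df) if np.isfinite(t) else float("nan"),
            }
        )
    return pd.DataFrame(rows)
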