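"""Inferential statistics for the force-discrimination analysis.

The layer mirrors the study's analysis plan: per-participant linear
regressions of baseline-normalized PSE on movement-time fraction,
normality-gated paired comparisons (paired t or Wilcoxon signed-rank,
selected by a Shapiro-Wilk test on the differences) with Benjamini-Hochberg
FDR correction and Cohen's d / matched-pairs rank-biserial effect sizes,
fully-within repeated-measures ANOVA with Greenhouse-Geisser correction and
partial eta-squared, and Pearson/Kendall and Pearson partial correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

ALPHA = 0.05


# ---------------------------------------------------------------------------
# per-participant time regressions

@dataclass
class TimeRegression:
    participant_id: str
    session: str
    slope: float  # N per % movement duration
    intercept: float  # N
    n_points: int
    group_times: dict[str, float] = field(default_factory=dict)


def group_mean_fractions(kept: pd.DataFrame) -> pd.DataFrame:
    """Mean realized test fraction per participant x session x final group.

    Target trials enter at their realized (tap-synchronous, ~100%) fraction.
    """
    reach = kept[kept["final_group"] != "baseline"]
    out = (
        reach.groupby(["participant_id", "session", "final_group"])["test_fraction"]
        .mean()
        .reset_index()
        .rename(columns={"final_group": "group", "test_fraction": "mean_fraction"})
    )
    return out


def fit_time_regression(
    normalized_pse: pd.DataFrame, mean_fractions: pd.DataFrame
) -> pd.DataFrame:
    """OLS of delta PSE on the per-group mean test fraction, per participant-session.

    Uses the (<= 4) points (group mean time, delta_pse); participant-sessions
    with fewer than three points are flagged and excluded from slope tests.
    """
    merged = normalized_pse.merge(
        mean_fractions, on=["participant_id", "session", "group"], how="inner"
    )
    rows = []
    for (pid, session), cell in merged.groupby(["participant_id", "session"]):
        x = cell["mean_fraction"].to_numpy(dtype=float)
        y = cell["delta_pse"].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        if x.size < 3:
            rows.append(
                {
                    "participant_id": pid,
                    "session": session,
                    "slope": np.nan,
                    "intercept": np.nan,
                    "n_points": int(x.size),
                    "valid": False,
                }
            )
            continue
        slope, intercept = np.polyfit(x, y, 1)
        rows.append(
            {
                "participant_id": pid,
                "session": session,
                "slope": float(slope),
                "intercept": float(intercept),
                "n_points": int(x.size),
                "valid": True,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# paired comparisons

@dataclass
class PairedTestResult:
    test_used: str  # {"paired_t", "wilcoxon"}
    statistic: float  # t, or W = sum of positive ranks
    p_raw: float
    ci95: tuple[float, float]
    effect_name: str  # {"cohens_d", "rank_biserial"}
    effect: float
    n: int
    shapiro_p: float
    p_fdr: Optional[float] = None


def _signed_rank_cdf_table(n: int) -> np.ndarray:
    """Exact null PMF of the signed-rank statistic T+ for sample size n."""
    max_t = n * (n + 1) // 2
    counts = np.zeros(max_t + 1)
    counts[0] = 1.0
    for r in range(1, n + 1):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:-r] if r > 0 else counts
        counts = counts + shifted
    return counts / counts.sum()


def _hodges_lehmann_ci(diff: np.ndarray, alpha: float = ALPHA) -> tuple[float, float]:
    """Pseudomedian (Hodges-Lehmann) confidence interval from Walsh averages."""
    d = np.sort(diff)
    n = d.size
    walsh = np.sort([(d[i] + d[j]) / 2.0 for i in range(n) for j in range(i, n)])
    m = walsh.size
    if n <= 25:
        pmf = _signed_rank_cdf_table(n)
        cdf = np.cumsum(pmf)
        # largest k with P(T <= k) <= alpha/2
        k = int(np.searchsorted(cdf, alpha / 2.0, side="right")) - 1
        k = max(k, 0)
    else:
        mu = n * (n + 1) / 4.0
        sd = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
        k = int(np.floor(mu - sps.norm.ppf(1 - alpha / 2.0) * sd))
        k = max(k, 0)
    lo = walsh[min(k, m - 1)]
    hi = walsh[max(m - 1 - k, 0)]
    return float(lo), float(hi)


def paired_compare(
    a: Sequence[float], b: Sequence[float], alpha: float = ALPHA
) -> PairedTestResult:
    """Paired comparison of two per-participant value vectors (a - b).

    A Shapiro-Wilk test on the differences selects between a paired t-test
    (normality not rejected at ``alpha``) and a Wilcoxon signed-rank test.
    The Wilcoxon path drops zero differences, uses the exact null
    distribution for n <= 25 and a continuity-corrected normal approximation
    above, reports W = T+ (sum of positive ranks) and the matched-pairs
    rank-biserial correlation (T+ - T-)/(T+ + T-), and a Hodges-Lehmann
    pseudomedian interval as the CI.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1D and equal length")
    diff = a - b
    n = diff.size
    if n < 5:
        raise ValueError("need at least 5 pairs")
    if np.allclose(diff, diff[0]):
        raise ValueError("zero-variance differences: effect size undefined")

    shapiro_p = float(sps.shapiro(diff).pvalue)
    if shapiro_p >= alpha:
        t = sps.ttest_rel(a, b)
        sd = diff.std(ddof=1)
        d = float(diff.mean() / sd)
        sem = sd / np.sqrt(n)
        tcrit = sps.t.ppf(1 - alpha / 2.0, n - 1)
        ci = (float(diff.mean() - tcrit * sem), float(diff.mean() + tcrit * sem))
        return PairedTestResult(
            test_used="paired_t",
            statistic=float(t.statistic),
            p_raw=float(t.pvalue),
            ci95=ci,
            effect_name="cohens_d",
            effect=d,
            n=n,
            shapiro_p=shapiro_p,
        )

    nz = diff[diff != 0.0]
    if nz.size == 0:
        raise ValueError("all paired differences are zero")
    ranks = sps.rankdata(np.abs(nz))
    t_plus = float(ranks[nz > 0].sum())
    t_minus = float(ranks[nz < 0].sum())
    rrb = (t_plus - t_minus) / (t_plus + t_minus)
    method = "exact" if nz.size <= 25 else "approx"
    res = sps.wilcoxon(nz, correction=True, method=method)
    return PairedTestResult(
        test_used="wilcoxon",
        statistic=t_plus,
        p_raw=float(res.pvalue),
        ci95=_hodges_lehmann_ci(nz, alpha),
        effect_name="rank_biserial",
        effect=float(rrb),
        n=n,
        shapiro_p=shapiro_p,
    )


def fdr_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# repeated-measures ANOVA

@dataclass
class AnovaResult:
    effect_name: str
    F: float
    df_num: float
    df_den: float
    epsilon_gg: float
    p: float
    partial_eta_sq: float
    mauchly_p: float
    sphericity_violated: bool


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k, k-1) normalized Helmert contrasts, orthonormal and mean-free."""
    C = np.zeros((k, k - 1))
    for j in range(1, k):
        norm = np.sqrt(j * (j + 1))
        C[:j, j - 1] = 1.0 / norm
        C[j, j - 1] = -j / norm
    return C


def _effect_from_scores(name: str, Z: np.ndarray, alpha: float) -> AnovaResult:
    """Univariate within-subject F test from orthonormal contrast scores.

    ``Z`` is (n subjects, d) where d is the effect's degrees of freedom.
    SS_effect = n * ||mean(Z)||^2 and SS_error = sum ||Z_i - mean(Z)||^2
    reproduce the classical partitioned sums of squares; the
    Greenhouse-Geisser epsilon and Mauchly test come from the covariance of
    the scores.
    """
    n, d = Z.shape
    zbar = Z.mean(axis=0)
    ss_eff = n * float(zbar @ zbar)
    resid = Z - zbar
    ss_err = float((resid**2).sum())
    df_num, df_den = float(d), float(d * (n - 1))
    F = (ss_eff / df_num) / (ss_err / df_den)

    if d == 1:
        eps, mauchly_p, violated = 1.0, 1.0, False
    else:
        S = np.cov(Z, rowvar=False, ddof=1)
        tr = np.trace(S)
        eps = float(tr**2 / (d * (S * S).sum()))
        eps = min(max(eps, 1.0 / d), 1.0)
        det = float(np.linalg.det(S))
        if det <= 0:
            mauchly_p = 0.0
        else:
            W = det / (tr / d) ** d
            c = 1.0 - (2 * d**2 + d + 2) / (6.0 * d * (n - 1))
            chi2 = -(n - 1) * c * np.log(W)
            dof = d * (d + 1) / 2.0 - 1.0
            mauchly_p = float(sps.chi2.sf(chi2, dof))
        violated = mauchly_p < alpha

    if violated:
        df_num_c, df_den_c = eps * df_num, eps * df_den
    else:
        df_num_c, df_den_c = df_num, df_den
    p = float(sps.f.sf(F, df_num_c, df_den_c))
    return AnovaResult(
        effect_name=name,
        F=float(F),
        df_num=df_num_c,
        df_den=df_den_c,
        epsilon_gg=float(eps),
        p=p,
        partial_eta_sq=ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0,
        mauchly_p=float(mauchly_p),
        sphericity_violated=bool(violated),
    )


def rm_anova_oneway(Y: np.ndarray, effect_name: str = "condition", alpha: float = ALPHA) -> AnovaResult:
    """One-way fully-within ANOVA on an (n subjects, k conditions) matrix."""
    Y = np.asarray(Y, dtype=float)
    n, k = Y.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 conditions")
    if not np.all(np.isfinite(Y)):
        raise ValueError("missing cells: fully balanced designs only")
    C = _orthonormal_contrasts(k)
    return _effect_from_scores(effect_name, Y @ C, alpha)


def rm_anova_twoway(
    Y: np.ndarray,
    factor_names: tuple[str, str] = ("A", "B"),
    alpha: float = ALPHA,
) -> list[AnovaResult]:
    """Two-way fully-within ANOVA on an (n, a, b) cell-mean array.

    Returns main effects of both factors and their interaction, each tested
    against its own subject-by-effect error term.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 3:
        raise ValueError("Y must be (subjects, levels_a, levels_b)")
    n, a, b = Y.shape
    if not np.all(np.isfinite(Y)):
        raise ValueError("missing cells: fully balanced designs only")
    flat = Y.reshape(n, a * b)
    Ca, Cb = _orthonormal_contrasts(a), _orthonormal_contrasts(b)
    ones_a = np.full((a, 1), 1.0 / np.sqrt(a))
    ones_b = np.full((b, 1), 1.0 / np.sqrt(b))
    effects = {
        factor_names[0]: np.kron(Ca, ones_b),
        factor_names[1]: np.kron(ones_a, Cb),
        f"{factor_names[0]} x {factor_names[1]}": np.kron(Ca, Cb),
    }
    return [
        _effect_from_scores(name, flat @ C, alpha) for name, C in effects.items()
    ]


def rm_anova(
    data: pd.DataFrame,
    dv: str,
    within: Sequence[str],
    subject: str,
    alpha: float = ALPHA,
) -> list[AnovaResult]:
    """Repeated-measures ANOVA from a long table (one or two within factors)."""
    within = list(within)
    if len(within) == 1:
        wide = data.pivot_table(index=subject, columns=within[0], values=dv)
        if wide.isna().any().any():
            raise ValueError("missing cells: fully balanced designs only")
        return [rm_anova_oneway(wide.to_numpy(), effect_name=within[0], alpha=alpha)]
    if len(within) == 2:
        f1, f2 = within
        levels1 = sorted(data[f1].unique())
        levels2 = sorted(data[f2].unique())
        wide = data.pivot_table(index=subject, columns=[f1, f2], values=dv)
        cols = pd.MultiIndex.from_product([levels1, levels2])
        wide = wide.reindex(columns=cols)
        if wide.isna().any().any():
            raise ValueError("missing cells: fully balanced designs only")
        Y = wide.to_numpy().reshape(len(wide), len(levels1), len(levels2))
        return rm_anova_twoway(Y, factor_names=(f1, f2), alpha=alpha)
    raise ValueError("rm_anova supports one or two within factors")


# ---------------------------------------------------------------------------
# correlations

@dataclass
class CorrelationResult:
    method: str  # {"pearson", "kendall"}
    coefficient: float
    p: float
    n: int
    partialled: Optional[str] = None


def correlation(x, y, method: str = "pearson") -> CorrelationResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "kendall":
        r, p = sps.kendalltau(x, y)
    else:
        raise ValueError("method must be 'pearson' or 'kendall'")
    return CorrelationResult(method=method, coefficient=float(r), p=float(p), n=x.size)


def partial_correlation(x, y, covariate, covariate_name: str = "covariate") -> CorrelationResult:
    """Pearson partial correlation of x and y controlling for one covariate.

    Both variables are residualized on the covariate (with intercept); the
    p-value uses the t transform with n - 3 degrees of freedom.  A constant
    covariate falls back to the simple correlation with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(covariate, dtype=float)
    n = x.size
    if not (x.shape == y.shape == z.shape):
        raise ValueError("x, y and covariate must have equal length")
    if np.allclose(z, z[0]):
        warnings.warn("constant covariate: falling back to simple correlation", stacklevel=2)
        return correlation(x, y, "pearson")
    Z = np.column_stack([np.ones(n), z])
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    # a variable fully explained by the covariate has no partial association
    if np.linalg.norm(rx) <= 1e-10 * max(1.0, np.linalg.norm(x)) or np.linalg.norm(
        ry
    ) <= 1e-10 * max(1.0, np.linalg.norm(y)):
        return CorrelationResult(
            method="pearson", coefficient=0.0, p=1.0, n=n, partialled=covariate_name
        )
    r = float(np.corrcoef(rx, ry)[0, 1])
    dof = n - 3
    t = r * np.sqrt(dof / (1.0 - r**2))
    p = float(2.0 * sps.t.sf(abs(t), dof))
    return CorrelationResult(
        method="pearson", coefficient=r, p=p, n=n, partialled=covariate_name
    )


def one_sample_against_zero(values: Sequence[float], alpha: float = ALPHA) -> PairedTestResult:
    """Normality-gated one-sample comparison of values against zero."""
    v = np.asarray(values, dtype=float)
    return paired_compare(v, np.zeros_like(v), alpha=alpha)
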