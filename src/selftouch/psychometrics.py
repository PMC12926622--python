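"""Psychometric-function fitting and derived indices.

Responses are fit with a two-parameter logistic by maximum likelihood,

    P(comparison stronger | x) = 1 / (1 + exp(-(b0 + b1 x))),

using Newton-Raphson iterations on the exact gradient and Hessian.  From the
fit we extract the point of subjective equality PSE = -b0/b1 (the comparison
intensity judged stronger with probability 0.5), the just noticeable
difference JND = ln(3)/b1 (the 0.5-to-0.75 distance), and McFadden's pseudo
R^2 = 1 - ll_model/ll_null as the goodness-of-fit gate.  Participants with a
poor fit (R^2 < 0.2) or a non-converged fit in any trial-group cell are
excluded.  Normalized PSEs subtract each participant-session's baseline PSE
from the reaching-group PSEs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import DEFAULT_INTENSITIES
from .observer import LOG3
from .trials import rebin_comparison

MAX_ITER = 100
GRADIENT_TOL = 1e-8
SEPARATION_SLOPE = 50.0  # |b1| beyond this flags quasi-separation


@dataclass
class PsychometricFit:
    beta0: float
    beta1: float
    pse: float
    jnd: float
    mcfadden_r2: float
    n_trials: int
    converged: bool
    loglik_model: float
    loglik_null: float


def _loglik(beta: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    eta = X @ beta
    # log(1+e^eta) computed stably
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def fit_psychometric(intensities, responses) -> PsychometricFit:
    """Maximum-likelihood logistic fit of binary 2AFC responses.

    ``intensities`` are comparison forces in N, ``responses`` the binary
    "comparison felt stronger" judgements.  Degenerate inputs (a single
    intensity, single-category responses) and separated fits return a
    non-converged fit with NaN derived quantities rather than raising, so
    downstream exclusion rules can handle them uniformly.
    """
    x = np.asarray(intensities, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("intensities and responses must be 1D and equal length")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("responses must be binary")
    n = x.size

    pbar = y.mean()
    if pbar in (0.0, 1.0):
        ll_null = 0.0
    else:
        ll_null = float(n * (pbar * np.log(pbar) + (1 - pbar) * np.log(1 - pbar)))

    def degenerate(note_ll: float) -> PsychometricFit:
        return PsychometricFit(
            beta0=np.nan, beta1=np.nan, pse=np.nan, jnd=np.nan,
            mcfadden_r2=np.nan, n_trials=n, converged=False,
            loglik_model=note_ll, loglik_null=ll_null,
        )

    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return degenerate(ll_null)

    X = np.column_stack([np.ones(n), x])
    beta = np.zeros(2)
    converged = False
    for _ in range(MAX_ITER):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (y - p)
        if np.max(np.abs(grad)) < GRADIENT_TOL:
            converged = True
            break
        w = p * (1.0 - p)
        H = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            return degenerate(_loglik(beta, X, y))
        # dampen oversized Newton steps to keep the iteration stable
        norm = np.max(np.abs(step))
        if norm > 20.0:
            step *= 20.0 / norm
        beta = beta + step
        if abs(beta[1]) > SEPARATION_SLOPE:
            return degenerate(_loglik(beta, X, y))

    ll_model = _loglik(beta, X, y)
    beta0, beta1 = float(beta[0]), float(beta[1])
    r2 = 1.0 - ll_model / ll_null if ll_null != 0.0 else np.nan
    return PsychometricFit(
        beta0=beta0,
        beta1=beta1,
        pse=-beta0 / beta1 if beta1 != 0 else np.nan,
        jnd=LOG3 / beta1 if beta1 != 0 else np.nan,
        mcfadden_r2=float(r2),
        n_trials=n,
        converged=converged,
        loglik_model=ll_model,
        loglik_null=ll_null,
    )


FIT_COLUMNS = (
    "participant_id",
    "session",
    "group",
    "beta0",
    "beta1",
    "pse",
    "jnd",
    "mcfadden_r2",
    "n_trials",
    "converged",
)


def fit_dataset(
    kept: pd.DataFrame,
    intensities=DEFAULT_INTENSITIES,
) -> pd.DataFrame:
    """Fit one psychometric function per participant x session x final group.

    Responses are pooled across instructed-finger (press) locations within
    each group, and measured comparison forces are rebinned to the nearest
    design intensity before fitting.
    """
    rows = []
    grid = tuple(intensities)
    for (pid, session, group), cell in kept.groupby(
        ["participant_id", "session", "final_group"], sort=True
    ):
        x = np.array([rebin_comparison(v, grid) for v in cell["comparison_measured"]])
        fit = fit_psychometric(x, cell["response_comparison_stronger"].to_numpy())
        rows.append(
            {
                "participant_id": pid,
                "session": session,
                "group": group,
                "beta0": fit.beta0,
                "beta1": fit.beta1,
                "pse": fit.pse,
                "jnd": fit.jnd,
                "mcfadden_r2": fit.mcfadden_r2,
                "n_trials": fit.n_trials,
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows, columns=list(FIT_COLUMNS))


def exclude_poor_fits(
    fits: pd.DataFrame, r2_threshold: float = 0.2
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop participants with any poor or non-converged trial-group fit.

    Returns ``(kept_fits, exclusion_report)``; the report lists each
    offending participant x session x group cell.
    """
    bad = fits[(~fits["converged"].astype(bool)) | (fits["mcfadden_r2"] < r2_threshold)]
    excluded = sorted(bad["participant_id"].unique())
    report = bad[["participant_id", "session", "group", "mcfadden_r2", "converged"]].copy()
    kept = fits[~fits["participant_id"].isin(excluded)].reset_index(drop=True)
    return kept, report


def normalize_pse(fits: pd.DataFrame) -> pd.DataFrame:
    """Baseline-normalized PSEs: PSE(reaching group) - PSE(baseline).

    One row per participant x session x reaching group; participant-sessions
    without a baseline fit are dropped with a warning.
    """
    rows = []
    for (pid, session), cell in fits.groupby(["participant_id", "session"]):
        base = cell[cell["group"] == "baseline"]
        if base.empty or not np.isfinite(base["pse"].iloc[0]):
            warnings.warn(
                f"{pid}/{session}: missing baseline fit; dropped", stacklevel=2
            )
            continue
        base_pse = float(base["pse"].iloc[0])
        for rec in cell[cell["group"] != "baseline"].itertuples(index=False):
            rows.append(
                {
                    "participant_id": pid,
                    "session": session,
                    "group": rec.group,
                    "delta_pse": rec.pse - base_pse,
                    "delta_jnd": rec.jnd - float(base["jnd"].iloc[0]),
                }
            )
    return pd.DataFrame(
        rows, columns=["participant_id", "session", "group", "delta_pse", "delta_jnd"]
    )
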