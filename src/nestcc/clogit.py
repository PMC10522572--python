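"""Conditional logistic regression for 1:m matched sets.

The likelihood is the standard one for matched case-control sets with
exactly one case per set: each set contributes

    exp(x_case . beta) / sum_j exp(x_j . beta)

over its members, i.e. a per-set softmax.  The log-likelihood, its analytic
gradient (sum over sets of x_case minus the softmax-weighted mean covariate)
and Hessian (minus the sum of softmax-weighted covariate covariances) are
computed with per-set max-subtraction for overflow safety.  Maximization is
Newton-Raphson from beta = 0 with step-halving; standard errors come from
the inverse observed information at the optimum, and odds ratios with 95%
Wald intervals use the fixed normal quantile 1.959964.

No ties are possible by construction (one case per set), so Breslow/Efron
distinctions do not arise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .config import COVARIATE_NAMES

Z975 = 1.959964
SEPARATION_BETA = 15.0


@dataclass
class MatchedDesign:
    """Stacked member rows grouped into matched sets.

    Rows must be ordered so each set is contiguous; ``group_starts`` indexes
    the first row of each set.
    """

    X: np.ndarray  # (N, p)
    is_case: np.ndarray  # (N,) bool, exactly one per set
    group_starts: np.ndarray  # (S,)
    names: list[str]

    def __post_init__(self) -> None:
        if not np.isfinite(self.X).all():
            raise ValueError("design matrix contains non-finite values")
        sizes = np.diff(np.append(self.group_starts, len(self.X)))
        if (sizes < 2).any():
            raise ValueError("every matched set needs at least 2 members")
        cases_per_set = np.add.reduceat(self.is_case.astype(int), self.group_starts)
        if (cases_per_set != 1).any():
            raise ValueError("every matched set must contain exactly one case")

    @property
    def n_sets(self) -> int:
        return len(self.group_starts)

    def informative_mask(self) -> np.ndarray:
        """Per-set flag: does any regressor vary within the set?"""
        group_id = np.repeat(np.arange(self.n_sets), np.diff(np.append(self.group_starts, len(self.X))))
        first = self.X[self.group_starts][group_id]
        varies = (self.X != first).any(axis=1)
        return np.add.reduceat(varies.astype(int), self.group_starts) > 0


@dataclass
class FitResult:
    beta: np.ndarray
    se: np.ndarray
    or_point: np.ndarray
    ci95: np.ndarray  # (p, 2)
    loglik: float
    n_sets: int
    n_informative: int
    converged: bool
    flag: str  # "converged" | "max_iterations" | "suspect_separation"
    iterations: int
    names: list[str] = field(default_factory=list)


ANALYSIS_ONE_EXPOSURE_TERMS = [
    "flupentixol_366_1825",
    "flupentixol_1826+",
    "other_antipsychotics_366_1825",
    "other_antipsychotics_1826+",
]
ANALYSIS_TWO_EXPOSURE_TERMS = ["any_antipsychotics_366_1825", "any_antipsychotics_1826+"]


def _cat_indicators(cat: pd.Series, prefix: str) -> pd.DataFrame:
    mid = cat.str.endswith("-1825").astype(float)
    high = cat.str.endswith("+").astype(float)
    return pd.DataFrame({f"{prefix}_366_1825": mid, f"{prefix}_1826+": high})


def build_design(
    matched_sets: pd.DataFrame,
    exposures: pd.DataFrame,
    covariates: pd.DataFrame,
    model_spec: str,
) -> MatchedDesign:
    """Assemble the regression design for one analysis.

    ``model_spec`` is ``"analysis_one"`` (two flupentixol-category indicators
    plus two other-antipsychotic indicators, both referenced at 0-365 days,
    plus the 21 confounders; 25 columns) or ``"analysis_two"`` (two
    any-antipsychotic indicators referenced at 1-365 days plus the 21
    confounders; 23 columns).
    """
    if model_spec not in ("analysis_one", "analysis_two"):
        raise ValueError(f"unknown model_spec {model_spec!r}")
    df = matched_sets[["set_id", "patient_id", "role"]].merge(
        exposures, on=["set_id", "patient_id", "role"], how="left", validate="one_to_one"
    )
    if df[["cat_any", "cat_flupentixol", "cat_other"]].isna().any().any():
        raise ValueError("matched-set member lacks exposure data")
    df = df.merge(
        covariates.drop(columns=["index_date"]), on=["set_id", "patient_id"], how="left", validate="one_to_one"
    )
    cov_cols = list(COVARIATE_NAMES)
    if df[cov_cols].isna().any().any():
        raise ValueError("matched-set member lacks covariate data")

    if model_spec == "analysis_one":
        blocks = [
            _cat_indicators(df["cat_flupentixol"], "flupentixol"),
            _cat_indicators(df["cat_other"], "other_antipsychotics"),
        ]
    else:
        blocks = [_cat_indicators(df["cat_any"], "any_antipsychotics")]
    Xdf = pd.concat(blocks + [df[cov_cols].astype(float)], axis=1)

    df = df.sort_values(["set_id", "role", "patient_id"], kind="stable")
    Xdf = Xdf.loc[df.index]
    set_ids = df["set_id"].to_numpy()
    group_starts = np.flatnonzero(np.concatenate(([True], set_ids[1:] != set_ids[:-1])))
    return MatchedDesign(
        X=Xdf.to_numpy(dtype=float),
        is_case=(df["role"] == "case").to_numpy(),
        group_starts=group_starts,
        names=list(Xdf.columns),
    )


def drop_inestimable_columns(design: MatchedDesign) -> tuple[MatchedDesign, list[str]]:
    """Remove regressors with no within-set variation.

    Such columns contribute nothing to the conditional likelihood (the
    per-set softmax is invariant to covariates constant within a set), so
    their coefficients are structurally inestimable; dropping them leaves
    every other estimate unchanged.
    """
    gs = design.group_starts
    sizes = np.diff(np.append(gs, len(design.X)))
    group_id = np.repeat(np.arange(design.n_sets), sizes)
    first = design.X[gs][group_id]
    varies = (design.X != first).any(axis=0)
    if varies.all():
        return design, []
    dropped = [n for n, v in zip(design.names, varies) if not v]
    kept = MatchedDesign(
        X=design.X[:, varies],
        is_case=design.is_case,
        group_starts=design.group_starts,
        names=[n for n, v in zip(design.names, varies) if v],
    )
    return kept, dropped


def conditional_loglik(design: MatchedDesign, beta: np.ndarray):
    """(loglik, gradient, hessian) of the conditional likelihood at beta."""
    beta = np.asarray(beta, dtype=float)
    if not np.isfinite(beta).all():
        raise ValueError("beta must be finite")
    X = design.X
    gs = design.group_starts
    n_sets = design.n_sets
    sizes = np.diff(np.append(gs, len(X)))
    group_id = np.repeat(np.arange(n_sets), sizes)

    eta = X @ beta
    eta_max = np.maximum.reduceat(eta, gs)
    z = np.exp(eta - eta_max[group_id])
    denom = np.add.reduceat(z, gs)
    w = z / denom[group_id]

    loglik = float(np.sum(eta[design.is_case] - (np.log(denom) + eta_max)))
    mean_x = np.empty((n_sets, X.shape[1]))
    wX = w[:, None] * X
    for j in range(X.shape[1]):
        mean_x[:, j] = np.add.reduceat(wX[:, j], gs)
    grad = X[design.is_case].sum(axis=0) - mean_x.sum(axis=0)
    hess = -(wX.T @ X - mean_x.T @ mean_x)
    return loglik, grad, hess


def _collinear_columns(design: MatchedDesign) -> list[str]:
    """Name columns implicated in a rank deficiency of the centered design."""
    gs = design.group_starts
    sizes = np.diff(np.append(gs, len(design.X)))
    group_id = np.repeat(np.arange(design.n_sets), sizes)
    means = np.empty((design.n_sets, design.X.shape[1]))
    for j in range(design.X.shape[1]):
        means[:, j] = np.add.reduceat(design.X[:, j], gs) / sizes
    centered = design.X - means[group_id]
    from scipy.linalg import qr

    _, r, piv = qr(centered, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(centered.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    return [design.names[j] for j in sorted(piv[rank:])]


def fit(design: MatchedDesign, tol: float = 1e-8, max_iter: int = 50, max_halvings: int = 10) -> FitResult:
    """Newton-Raphson maximum conditional likelihood from beta = 0."""
    informative = design.informative_mask()
    n_informative = int(informative.sum())
    if n_informative == 0:
        raise ValueError("no informative sets: every set is concordant on all regressors")

    p = design.X.shape[1]
    beta = np.zeros(p)
    ll, grad, hess = conditional_loglik(design, beta)
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        if np.max(np.abs(grad)) < tol:
            converged = True
            iterations -= 1
            break
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            cols = _collinear_columns(design)
            raise np.linalg.LinAlgError(
                f"singular information matrix; collinear columns: {cols}"
            ) from None
        new_beta = beta + step
        new_ll, new_grad, new_hess = conditional_loglik(design, new_beta)
        halvings = 0
        while new_ll < ll and halvings < max_halvings:
            step = step / 2.0
            new_beta = beta + step
            new_ll, new_grad, new_hess = conditional_loglik(design, new_beta)
            halvings += 1
        beta, ll, grad, hess = new_beta, new_ll, new_grad, new_hess
    else:
        converged = np.max(np.abs(grad)) < tol

    if np.max(np.abs(grad)) < tol:
        converged = True
    try:
        cov = np.linalg.inv(-hess)
    except np.linalg.LinAlgError:
        cols = _collinear_columns(design)
        raise np.linalg.LinAlgError(
            f"singular information matrix at optimum; collinear columns: {cols}"
        ) from None
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    flag = "converged" if converged else "max_iterations"
    if np.any(np.abs(beta) > SEPARATION_BETA):
        flag = "suspect_separation"
    with np.errstate(over="ignore"):
        ci = np.column_stack([np.exp(beta - Z975 * se), np.exp(beta + Z975 * se)])
    return FitResult(
        beta=beta,
        se=se,
        or_point=np.exp(beta),
        ci95=ci,
        loglik=ll,
        n_sets=design.n_sets,
        n_informative=n_informative,
        converged=converged,
        flag=flag,
        iterations=iterations,
        names=list(design.names),
    )


def wald_summary(result: FitResult) -> pd.DataFrame:
    """Odds-ratio table: term, OR, 95% CI bounds, two-sided p, significance."""
    z = np.divide(result.beta, result.se, out=np.zeros_like(result.beta), where=result.se > 0)
    pvals = 2.0 * norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "term": result.names,
            "OR": result.or_point,
            "ci_low": result.ci95[:, 0],
            "ci_high": result.ci95[:, 1],
            "p": pvals,
            "significant": pvals <= 0.05,
        }
    )
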