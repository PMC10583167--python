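"""Multiple imputation and Rubin's-rules pooling.

The chained-equations imputer here is a deliberately simple engine: binary
fields are completed by ridge-logistic posterior draws, ordinal fields by
proportional-odds draws (with a rounded-linear fallback when the ordinal
fit fails), and continuous fields by Bayesian linear draws with
posterior-predictive noise. All outcomes, the survey weight, race and the
other analysis variables enter every component model as predictors; weights
enter as a predictor rather than as fitting weights. The pooling rules,
which drive every reported interval, are implemented exactly:

    T = W + (1 + 1/M) B,   nu_j = (M - 1) (1 + W_jj / ((1 + 1/M) B_jj))^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import (
    ACE_COLUMNS,
    BIOMARKER_COLUMNS,
    DESIGN_COLUMNS,
    OUTCOMES,
    SUPPORT_COLUMNS,
    TRACT_COLUMNS,
)
from .glm import ModelFit

__all__ = ["ImputationSet", "PooledFit", "impute", "rubin_pool"]

#: df sentinel when the between-imputation variance of a term is degenerate.
LARGE_DF = 1e12

_BINARY_FIELDS = set(ACE_COLUMNS) | set(OUTCOMES) | {
    "dx_hypertension", "med_hypertension", "dx_diabetes", "med_diabetes", "pregnant",
}
_ORDINAL_FIELDS = {"parent1_education": (1, 5), "parent2_education": (1, 5)} | {
    c: (1, 5) for c in SUPPORT_COLUMNS
}
# post-draw constraints for continuous fields
_CONTINUOUS_BOUNDS = {c: (0.0, 1.0) for c in TRACT_COLUMNS}
_CONTINUOUS_BOUNDS["household_income"] = (0.0, np.inf)
_CONTINUOUS_BOUNDS["household_size"] = (1.0, np.inf)

#: complete base predictors used by every component model
_BASE_PREDICTORS = ("weight", "age")


@dataclass
class ImputationSet:
    """M completed cohort copies plus per-copy provenance."""

    copies: list[pd.DataFrame]
    seeds: list[int]
    n_iter: int
    imputed_fields: tuple[str, ...]

    @property
    def m(self) -> int:
        return len(self.copies)

    def __iter__(self):
        return iter(self.copies)


@dataclass
class PooledFit:
    """Rubin-pooled coefficients with within/between/total covariance."""

    params: pd.Series
    within: pd.DataFrame
    between: pd.DataFrame
    cov: pd.DataFrame  # total covariance T
    df: pd.Series
    m: int
    spec: object = None
    meta: dict = field(default_factory=dict)

    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov.to_numpy())), index=self.params.index)


# ---------------------------------------------------------------------------
# component draws


def _ridge_logistic_draw(
    X: np.ndarray, y: np.ndarray, X_mis: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Posterior-style logistic draw: Newton fit with a light ridge, a normal
    parameter draw from the penalized information, then Bernoulli draws."""
    n, p = X.shape
    lam = 1e-3 * n / max(p, 1)
    beta = np.zeros(p)
    for _ in range(25):
        eta = X @ beta
        mu = expit(eta)
        wdiag = np.maximum(mu * (1 - mu), 1e-10)
        info = X.T @ (X * wdiag[:, None]) + lam * np.eye(p)
        score = X.T @ (y - mu) - lam * beta
        step = np.linalg.solve(info, score)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-8:
            break
    cov = np.linalg.inv(info)
    beta_star = rng.multivariate_normal(beta, cov, method="cholesky")
    probs = expit(X_mis @ beta_star)
    return (rng.random(X_mis.shape[0]) < probs).astype(float)


def _bayes_linear_draw(
    X: np.ndarray, y: np.ndarray, X_mis: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Normal linear draw with posterior-predictive noise (the standard
    "norm" method): sigma^2 from a scaled inverse chi-square, coefficients
    from their conditional normal, then new residual noise."""
    n, p = X.shape
    lam = 1e-8
    gram = X.T @ X + lam * np.eye(p)
    beta_hat = np.linalg.solve(gram, X.T @ y)
    resid = y - X @ beta_hat
    dof = max(n - p, 2)
    sigma2 = float(resid @ resid) / rng.chisquare(dof)
    cov = sigma2 * np.linalg.inv(gram)
    beta_star = rng.multivariate_normal(beta_hat, cov, method="cholesky")
    return X_mis @ beta_star + rng.normal(0.0, np.sqrt(sigma2), size=X_mis.shape[0])


def _propodds_draw(
    X: np.ndarray, y: np.ndarray, X_mis: np.ndarray, levels: tuple[int, int],
    rng: np.random.Generator,
) -> np.ndarray:
    """Proportional-odds draw via the ordinal regression model; falls back to
    a rounded linear draw when the ordinal fit is degenerate."""
    lo, hi = levels
    observed_levels = np.unique(y)
    if observed_levels.size < 2:
        return np.full(X_mis.shape[0], observed_levels[0])
    try:
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        codes = np.searchsorted(observed_levels, y)
        # OrderedModel parameterizes its own thresholds: no constant column
        keep = np.std(np.vstack([X, X_mis]), axis=0) > 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = OrderedModel(codes, X[:, keep], distr="logit")
            res = model.fit(method="lbfgs", maxiter=200, disp=False)
            cov = np.asarray(res.cov_params())
            if not np.all(np.isfinite(cov)):
                raise ValueError("non-finite covariance")
            params_star = rng.multivariate_normal(np.asarray(res.params), _nearest_psd(cov))
            probs = np.asarray(model.predict(params_star, exog=X_mis[:, keep]))
        cum = np.cumsum(probs, axis=1)
        u = rng.random(X_mis.shape[0])
        idx = (u[:, None] > cum).sum(axis=1)
        return observed_levels[np.clip(idx, 0, observed_levels.size - 1)].astype(float)
    except Exception:  # degenerate fit: fall back, preserving determinism
        warnings.warn("proportional-odds fit failed; using rounded linear draw", stacklevel=2)
        draw = _bayes_linear_draw(X, y, X_mis, rng)
        return np.clip(np.rint(draw), lo, hi)


def _nearest_psd(mat: np.ndarray) -> np.ndarray:
    sym = (mat + mat.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    return (vecs * np.maximum(vals, 1e-12)) @ vecs.T


# ---------------------------------------------------------------------------
# chained equations


def _predictor_matrix(frame: pd.DataFrame, target: str, fields: Sequence[str]) -> np.ndarray:
    """Numeric predictor matrix for one component model: intercept, weight,
    age, sex and race indicators, plus current values of every other
    analysis field (including all outcomes)."""
    cols = [np.ones(len(frame))]
    for c in _BASE_PREDICTORS:
        if c in frame.columns:
            cols.append(frame[c].to_numpy(dtype=float))
    if "sex" in frame.columns:
        cols.append((frame["sex"].to_numpy() == "male").astype(float))
    if "race" in frame.columns:
        race = frame["race"].to_numpy()
        for g in pd.unique(race)[1:]:
            cols.append((race == g).astype(float))
    for c in fields:
        if c != target and c not in _BASE_PREDICTORS:
            cols.append(frame[c].to_numpy(dtype=float))
    X = np.column_stack(cols)
    # standardize non-intercept columns for numerical stability
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X[:, 1:] = (X[:, 1:] - X[:, 1:].mean(axis=0)) / sd[1:]
    return X


def _draw_field(
    frame: pd.DataFrame, target: str, fields: Sequence[str], missing: np.ndarray,
    rng: np.random.Generator, ordinal_method: str,
) -> np.ndarray:
    X = _predictor_matrix(frame, target, fields)
    obs = ~missing
    y = frame.loc[obs, target].to_numpy(dtype=float)
    X_obs, X_mis = X[obs], X[missing]
    if target in _BINARY_FIELDS:
        if np.unique(y).size < 2:
            return np.full(int(missing.sum()), float(y[0]))
        return _ridge_logistic_draw(X_obs, y, X_mis, rng)
    if target in _ORDINAL_FIELDS:
        levels = _ORDINAL_FIELDS[target]
        if ordinal_method == "propodds":
            return _propodds_draw(X_obs, y, X_mis, levels, rng)
        draw = _bayes_linear_draw(X_obs, y, X_mis, rng)
        return np.clip(np.rint(draw), *levels)
    draw = _bayes_linear_draw(X_obs, y, X_mis, rng)
    lo, hi = _CONTINUOUS_BOUNDS.get(target, (-np.inf, np.inf))
    if target == "household_size":
        draw = np.rint(draw)
    return np.clip(draw, lo, hi)


def impute(
    cohort: pd.DataFrame,
    m: int = 20,
    seed: int = 0,
    n_iter: int = 5,
    ordinal_method: str = "propodds",
) -> ImputationSet:
    """Chained-equations multiple imputation of every field with missingness.

    Returns ``m`` completed copies sharing the row ids and schema of the
    input; design variables must be complete on entry and are never imputed.
    Each copy runs an independent chain (its own seed stream), initialized
    by hot-deck draws from the observed marginals and cycled ``n_iter``
    times (capped at 10).
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    n_iter = min(int(n_iter), 10)
    for c in DESIGN_COLUMNS:
        if c in cohort.columns and cohort[c].isna().any():
            raise ValueError(f"design variable {c!r} has missing values")

    candidates = [
        c for c in cohort.columns
        if c not in DESIGN_COLUMNS + ("pid", "race", "sex")
        and not isinstance(cohort[c].dtype, pd.CategoricalDtype)
        and cohort[c].dtype.kind in "fiub"
    ]
    missing_fields = tuple(c for c in candidates if cohort[c].isna().any())
    for c in missing_fields:
        if cohort[c].notna().sum() == 0:
            raise ValueError(f"field {c!r} has no observed values; cannot impute")

    copies: list[pd.DataFrame] = []
    seeds: list[int] = []
    for k in range(m):
        copy_seed = int(np.random.default_rng([int(seed), 7919, k]).integers(2**31 - 1))
        seeds.append(copy_seed)
        rng = np.random.default_rng(copy_seed)
        frame = cohort.copy()
        if not missing_fields:
            copies.append(frame)
            continue
        masks = {c: frame[c].isna().to_numpy() for c in missing_fields}
        # hot-deck initialization from observed marginals
        for c in missing_fields:
            observed = frame.loc[~masks[c], c].to_numpy(dtype=float)
            fill = rng.choice(observed, size=int(masks[c].sum()), replace=True)
            col = frame[c].to_numpy(dtype=float)
            col[masks[c]] = fill
            frame[c] = col
        for _ in range(n_iter):
            for c in missing_fields:
                draw = _draw_field(frame, c, candidates, masks[c], rng, ordinal_method)
                col = frame[c].to_numpy(dtype=float)
                col[masks[c]] = draw
                frame[c] = col
        copies.append(frame)

    return ImputationSet(copies=copies, seeds=seeds, n_iter=n_iter, imputed_fields=missing_fields)


# ---------------------------------------------------------------------------
# Rubin's rules


def rubin_pool(fits: Sequence[ModelFit | PooledFit], single_ok: bool = False) -> PooledFit:
    """Pool coefficient vectors and covariances across imputations.

    ``beta_bar`` is the mean coefficient vector, ``W`` the mean within-
    imputation covariance, ``B`` the between-imputation sample covariance,
    and ``T = W + (1 + 1/M) B``. Per-term degrees of freedom follow the
    standard small-sample formula; terms with degenerate ``B`` get a large
    sentinel so a normal reference applies.
    """
    if len(fits) == 0:
        raise ValueError("no fits to pool")
    m = len(fits)
    labels = list(fits[0].params.index)
    for f in fits[1:]:
        if list(f.params.index) != labels:
            raise ValueError("all fits must share identical term labels")
    if m < 2 and not single_ok:
        raise ValueError(
            "between-imputation variance undefined for M < 2; pass "
            "single_ok=True for single-imputation mode"
        )

    betas = np.vstack([f.params.to_numpy() for f in fits])
    beta_bar = betas.mean(axis=0)
    W = np.mean([f.cov.to_numpy() for f in fits], axis=0)
    if m >= 2:
        centered = betas - beta_bar
        B = centered.T @ centered / (m - 1)
        T = W + (1.0 + 1.0 / m) * B
    else:
        B = np.zeros_like(W)
        T = W.copy()

    b_diag = np.diag(B)
    w_diag = np.diag(W)
    df = np.full(len(labels), LARGE_DF)
    if m >= 2:
        scale = max(float(np.max(b_diag)), 1.0)
        nonzero = b_diag > 1e-12 * scale
        inflate = (1.0 + 1.0 / m) * b_diag[nonzero]
        df[nonzero] = (m - 1) * (1.0 + w_diag[nonzero] / inflate) ** 2

    T = (T + T.T) / 2.0
    spec = getattr(fits[0], "spec", None)
    return PooledFit(
        params=pd.Series(beta_bar, index=labels),
        within=pd.DataFrame(W, index=labels, columns=labels),
        between=pd.DataFrame(B, index=labels, columns=labels),
        cov=pd.DataFrame(T, index=labels, columns=labels),
        df=pd.Series(df, index=labels),
        m=m,
        spec=spec,
    )
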