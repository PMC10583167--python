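"""Effect surfaces on the relative and absolute scales.

From a pooled interaction model this module computes, per race group:

* the within-group risk ratio for elevated adversity,
  ``RR_g = exp(beta_exposure + beta_interaction_g)``;
* the multiplicative interaction ratio ``exp(beta_interaction_g)``, which
  by the model identity equals ``RR_g / RR_referent``;
* the relative excess risk due to interaction (RERI, also called the
  interaction contrast ratio),

      RERI_g = RR_g1 - RR_g0 - RR_ref1 + 1,

  where all three ratios share the doubly-unexposed (referent race, low
  adversity) baseline cell;
* the interaction contrast ``IC_g = RERI_g x R00`` with ``R00`` the
  model-based risk in that baseline cell, and excess cases per 1000
  ``= 1000 x IC_g``, with percentile confidence intervals from
  multivariate-normal resampling of the pooled coefficients.

Note on signs: the excess-case estimate is negative exactly when RERI is
negative; a multiplicative interaction ratio below 1 does not by itself
determine the sign of the additive interaction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .pool import LARGE_DF, PooledFit

__all__ = [
    "EstimateCI",
    "InteractionResult",
    "within_group_rr",
    "interaction_rr",
    "interaction_ratio_from_within",
    "excess_cases",
    "reri",
]


@dataclass(frozen=True)
class EstimateCI:
    estimate: float
    ci_low: float
    ci_high: float
    is_referent: bool = False


@dataclass(frozen=True)
class InteractionResult:
    """Full interaction summary for one (outcome, non-referent group)."""

    outcome: str
    group: str
    within_rr: EstimateCI
    interaction_rr: EstimateCI
    reri: float
    r00: float
    ic: float
    excess_per_1000: EstimateCI
    n_resamples: int
    seed: int


def _require(pooled: PooledFit, term: str) -> int:
    labels = list(pooled.params.index)
    if term not in labels:
        raise ValueError(f"model does not contain term {term!r}")
    return labels.index(term)


def _exposure_term(pooled: PooledFit) -> str:
    for term in ("elevated_aces", "ace_score"):
        if term in pooled.params.index:
            return term
    raise ValueError("model contains no exposure main-effect term")


def _referent_of(pooled: PooledFit) -> str | None:
    spec = getattr(pooled, "spec", None)
    return getattr(spec, "referent_race", None)


def _linear_ci(pooled: PooledFit, contrast: np.ndarray, level: float = 0.95,
               reference: str = "normal") -> tuple[float, float, float]:
    """Point estimate, CI half-width basis for a linear combination c'beta."""
    beta = pooled.params.to_numpy()
    T = pooled.cov.to_numpy()
    est = float(contrast @ beta)
    var = float(contrast @ T @ contrast)
    se = np.sqrt(max(var, 0.0))
    alpha = 1.0 - level
    if reference == "t":
        # conservative: smallest Rubin df among contributing terms
        dfs = pooled.df.to_numpy()[np.abs(contrast) > 0]
        df = float(np.min(dfs)) if dfs.size else LARGE_DF
        crit = stats.t.ppf(1 - alpha / 2, df) if df < LARGE_DF else stats.norm.ppf(1 - alpha / 2)
    else:
        crit = stats.norm.ppf(1 - alpha / 2)
    return est, est - crit * se, est + crit * se


def within_group_rr(pooled: PooledFit, group: str, referent: str | None = None,
                    reference: str = "normal") -> EstimateCI:
    """Within-group risk ratio for elevated adversity, with its CI.

    For the referent group this is ``exp(beta_exposure)``; for group ``g``
    it is ``exp(beta_exposure + beta_interaction_g)``, with the variance of
    the linear combination taken from the pooled total covariance.
    """
    referent = referent or _referent_of(pooled)
    exposure = _exposure_term(pooled)
    contrast = np.zeros(len(pooled.params))
    contrast[_require(pooled, exposure)] = 1.0
    if group != referent:
        contrast[_require(pooled, f"{exposure}:race[{group}]")] = 1.0
    est, lo, hi = _linear_ci(pooled, contrast, reference=reference)
    return EstimateCI(float(np.exp(est)), float(np.exp(lo)), float(np.exp(hi)))


def interaction_rr(pooled: PooledFit, group: str, referent: str | None = None,
                   reference: str = "normal") -> EstimateCI:
    """Exponentiated interaction coefficient ``exp(beta_interaction_g)``.

    Equals the ratio of the group's within-group RR to the referent's. The
    referent group returns the reference marker (estimate 1, degenerate CI).
    """
    referent = referent or _referent_of(pooled)
    if group == referent:
        return EstimateCI(1.0, 1.0, 1.0, is_referent=True)
    exposure = _exposure_term(pooled)
    contrast = np.zeros(len(pooled.params))
    contrast[_require(pooled, f"{exposure}:race[{group}]")] = 1.0
    est, lo, hi = _linear_ci(pooled, contrast, reference=reference)
    return EstimateCI(float(np.exp(est)), float(np.exp(lo)), float(np.exp(hi)))


def interaction_ratio_from_within(rr_group: float, rr_referent: float) -> float:
    """Model identity: the interaction ratio equals RR_group / RR_referent.

    Useful for checking published within-group RRs against published
    interaction ratios.
    """
    if rr_group <= 0 or rr_referent <= 0:
        raise ValueError("risk ratios must be positive")
    return rr_group / rr_referent


def _cell_log_risks(pooled: PooledFit, group: str, referent: str,
                    baseline_profile: dict[str, float]) -> np.ndarray:
    """Contrast matrix mapping beta to the four cell log risks
    (g=0,e=0), (g=0,e=1), (g=1,e=0), (g=1,e=1) at the baseline profile."""
    exposure = _exposure_term(pooled)
    labels = list(pooled.params.index)
    p = len(labels)

    base = np.zeros(p)
    for i, term in enumerate(labels):
        if term == "Intercept":
            base[i] = 1.0
        elif term in baseline_profile:
            base[i] = float(baseline_profile[term])
        elif term == exposure or term.startswith("race[") or ":race[" in term:
            base[i] = 0.0
        else:
            raise ValueError(f"baseline profile missing model term {term!r}")

    i_exp = _require(pooled, exposure)
    i_grp = _require(pooled, f"race[{group}]")
    i_int = _require(pooled, f"{exposure}:race[{group}]")

    rows = np.tile(base, (4, 1))
    rows[1, i_exp] += 1.0                       # referent, exposed
    rows[2, i_grp] += 1.0                       # group, unexposed
    rows[3, i_exp] += 1.0
    rows[3, i_grp] += 1.0
    rows[3, i_int] += 1.0                       # group, exposed
    return rows


def reri(pooled: PooledFit, group: str, referent: str | None = None,
         baseline_profile: dict[str, float] | None = None) -> float:
    """Relative excess risk due to interaction for one group."""
    referent = referent or _referent_of(pooled)
    rows = _cell_log_risks(pooled, group, referent, baseline_profile or {})
    r = np.exp(rows @ pooled.params.to_numpy())
    r00 = r[0]
    return float(r[3] / r00 - r[2] / r00 - r[1] / r00 + 1.0)


def excess_cases(
    pooled: PooledFit,
    group: str,
    baseline_profile: dict[str, float] | None = None,
    n_resamples: int = 10000,
    seed: int = 0,
    referent: str | None = None,
    level: float = 0.95,
    r00_rows: np.ndarray | None = None,
    r00_weights: np.ndarray | None = None,
) -> InteractionResult:
    """Excess cases per 1000 due to additive interaction, with resampling CI.

    The point estimate is ``1000 x RERI_g x R00`` where ``R00`` is the
    model-predicted risk in the doubly-unexposed baseline cell. By default
    ``R00`` is evaluated at the supplied ``baseline_profile`` (referent
    race, low adversity, covariates typically at their weighted sample
    means). Passing ``r00_rows`` (design-matrix rows of the doubly-unexposed
    subsample, with optional ``r00_weights``) switches to marginal
    standardization: ``R00`` becomes the weighted average predicted risk
    over those rows, recomputed for every resample.

    The CI is the 2.5/97.5 percentile interval of the same functional over
    ``n_resamples`` multivariate-normal draws of the coefficients with the
    pooled total covariance; it is deterministic given ``seed``.
    """
    referent = referent or _referent_of(pooled)
    if referent is None:
        raise ValueError("referent race not recoverable from fit; pass referent=")
    baseline_profile = baseline_profile or {}
    rows = _cell_log_risks(pooled, group, referent, baseline_profile)
    beta = pooled.params.to_numpy()
    T = pooled.cov.to_numpy()

    eigvals = np.linalg.eigvalsh((T + T.T) / 2.0)
    if eigvals.min() < -1e-8 * max(eigvals.max(), 1.0):
        raise ValueError("pooled covariance is not positive semi-definite")

    if r00_rows is not None:
        r00_rows = np.atleast_2d(np.asarray(r00_rows, dtype=float))
        if r00_weights is None:
            r00_weights = np.ones(r00_rows.shape[0])
        r00_weights = np.asarray(r00_weights, dtype=float) / np.sum(r00_weights)

    def r00_of(b: np.ndarray) -> np.ndarray | float:
        # b: (p,) or (n_draws, p); returns matching scalar or vector
        if r00_rows is None:
            cell = rows[0] @ (b.T if b.ndim > 1 else b)
            return np.exp(cell)
        pred = np.exp(r00_rows @ (b.T if b.ndim > 1 else b))
        return r00_weights @ pred

    def functional(b: np.ndarray) -> np.ndarray:
        risks = np.exp(rows @ (b.T if b.ndim > 1 else b))
        r00_cell, r01, r10, r11 = risks
        reri_val = (r11 - r10 - r01) / r00_cell + 1.0
        return 1000.0 * reri_val * r00_of(b)

    risks_hat = np.exp(rows @ beta)
    r00_cell = float(risks_hat[0])
    r00 = float(r00_of(beta))
    if r00 >= 1.0:
        raise ValueError(f"baseline-cell risk R00 = {r00:.4f} >= 1; check the profile")
    reri_hat = float(risks_hat[3] / r00_cell - risks_hat[2] / r00_cell - risks_hat[1] / r00_cell + 1.0)
    ic_hat = reri_hat * r00
    point = 1000.0 * ic_hat

    rng = np.random.default_rng(seed)
    sym = (T + T.T) / 2.0
    draws = rng.multivariate_normal(beta, sym, size=n_resamples, method="eigh")
    with np.errstate(over="ignore"):  # separated cells can overflow exp in the tails
        samples = functional(draws)
    alpha = 1.0 - level
    lo, hi = np.percentile(samples, [100 * alpha / 2, 100 * (1 - alpha / 2)])

    return InteractionResult(
        outcome=getattr(getattr(pooled, "spec", None), "outcome", ""),
        group=group,
        within_rr=within_group_rr(pooled, group, referent),
        interaction_rr=interaction_rr(pooled, group, referent),
        reri=reri_hat,
        r00=r00,
        ic=ic_hat,
        excess_per_1000=EstimateCI(point, float(lo), float(hi)),
        n_resamples=n_resamples,
        seed=seed,
    )
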