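"""Synthetic cohort generator.

Emulates the structural features the analysis pipeline assumes about the
restricted source data without mimicking its actual sampling frame:

* stratified cluster sampling with heterogeneous positive weights;
* five race groups with configurable population shares;
* ten exchangeable adversity (ACE) component indicators whose dichotomized
  sum reaches a race-specific prevalence of the elevated (>=4) exposure;
* six adjustment covariates and a biomarker panel;
* seven binary outcomes drawn from a log-linear (log-binomial) risk model,
  so configured risk ratios are exactly the estimand of the modified
  Poisson analysis model;
* configurable missingness (MCAR by default, an optional MAR mechanism
  driven by race and parental education).

Generation is a pure function of ``(config, seed)``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .config import (
    ACE_COLUMNS,
    BIOMARKER_COLUMNS,
    COVARIATE_COLUMNS,
    DESIGN_COLUMNS,
    EDUCATION_LEVELS,
    OUTCOMES,
    SUPPORT_COLUMNS,
    TRACT_COLUMNS,
    SimulationConfig,
)

__all__ = [
    "generate_cohort",
    "induce_missingness",
    "item_probability_for_prevalence",
    "cohort_columns",
]

_ACE_THRESHOLD = 4
_N_ACE_ITEMS = 10


def item_probability_for_prevalence(prevalence: float, n_items: int = _N_ACE_ITEMS,
                                    threshold: int = _ACE_THRESHOLD) -> float:
    """Per-item Bernoulli probability so that ``P(Binomial(n, p) >= threshold)``
    equals ``prevalence``, for exchangeable components.

    Solved by root finding on the binomial survival function; the map is
    strictly increasing in ``p`` so the root is unique.
    """
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError("prevalence must lie in [0, 1]")
    if prevalence == 0.0:
        return 0.0
    if prevalence == 1.0:
        return 1.0

    def tail(p: float) -> float:
        return stats.binom.sf(threshold - 1, n_items, p) - prevalence

    return float(optimize.brentq(tail, 1e-12, 1 - 1e-12, xtol=1e-12))


def cohort_columns() -> list[str]:
    """Full column schema of a generated cohort, in order."""
    return [
        "pid",
        *DESIGN_COLUMNS,
        "race",
        *ACE_COLUMNS,
        "age",
        "sex",
        *COVARIATE_COLUMNS,
        *BIOMARKER_COLUMNS,
        "pregnant",
        *OUTCOMES,
    ]


def _draw_weights(rng: np.random.Generator, strata: np.ndarray, dispersion: float) -> np.ndarray:
    """Log-normal weights with mean 1 within each stratum."""
    n = strata.shape[0]
    if dispersion == 0.0:
        return np.ones(n)
    w = rng.lognormal(mean=-0.5 * dispersion**2, sigma=dispersion, size=n)
    out = np.empty(n)
    for h in np.unique(strata):
        mask = strata == h
        out[mask] = w[mask] / w[mask].mean()
    return out


def _ordinal_draw(rng: np.random.Generator, probs: np.ndarray, size: int) -> np.ndarray:
    """1-based ordinal categories with the given marginal probabilities."""
    return rng.choice(np.arange(1, len(probs) + 1), size=size, p=probs / probs.sum())


def _covariate_multiplier(cohort: pd.DataFrame, outcome: str, params: dict) -> np.ndarray:
    """Row-wise multiplicative covariate effect exp(sum coef * centred value)."""
    spec = params.get("covariate_log_rr", {}).get(outcome, {})
    if not spec:
        return np.ones(len(cohort))
    log_mult = np.zeros(len(cohort))
    for column, coef in spec.items():
        values = cohort[column].to_numpy(dtype=float)
        log_mult += coef * (values - values.mean())
    return np.exp(log_mult)


def generate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Generate a synthetic cohort table, one row per participant.

    Raises ``ValueError`` naming the offending (outcome, race) cell if any
    implied risk exceeds 1.
    """
    config.validate()
    n = config.n_individuals
    rng = np.random.default_rng(config.seed)
    params = config.confounder_params

    if n == 0:
        return pd.DataFrame({c: pd.Series(dtype=float) for c in cohort_columns()})

    # -- survey design ---------------------------------------------------
    strata = rng.integers(1, config.n_strata + 1, size=n)
    cluster_within = rng.integers(1, config.clusters_per_stratum + 1, size=n)
    clusters = strata * 1000 + cluster_within  # each cluster nested in one stratum
    weights = _draw_weights(rng, strata, config.weight_dispersion)

    # -- race and ACE components ----------------------------------------
    races = np.array(list(config.race_proportions))
    props = np.array([config.race_proportions[r] for r in races])
    race = rng.choice(races, size=n, p=props)

    item_p = np.empty(n)
    for r in races:
        prevalence = config.ace_prevalence_by_race.get(r, 0.27)
        item_p[race == r] = item_probability_for_prevalence(prevalence)
    ace_items = (rng.random((n, _N_ACE_ITEMS)) < item_p[:, None]).astype(int)
    elevated = ace_items.sum(axis=1) >= _ACE_THRESHOLD

    # -- covariates ------------------------------------------------------
    age = rng.normal(params["age_mean"], params["age_sd"], size=n)
    sex = np.where(rng.random(n) < params["male_proportion"], "male", "female")
    edu_probs = np.asarray(params["education_probs"], dtype=float)
    parent1 = _ordinal_draw(rng, edu_probs, n)
    parent2 = _ordinal_draw(rng, edu_probs, n)
    income = rng.lognormal(params["log_income_mean"], params["log_income_sd"], size=n)
    size_hh = 1 + rng.poisson(params["household_size_rate"], size=n)
    support = np.clip(
        np.rint(rng.normal(params["support_mean"], params["support_sd"], size=(n, 5))), 1, 5
    ).astype(int)
    tract_mean = np.array(
        [params["tract_mean_by_race"].get(r, 0.15) for r in race]
    )
    conc = params["tract_concentration"]
    tract = rng.beta(tract_mean[:, None] * conc, (1 - tract_mean[:, None]) * conc, size=(n, 5))

    # -- biomarker panel -------------------------------------------------
    male = sex == "male"
    systolic = rng.normal(118, 12, size=n)
    diastolic = rng.normal(74, 9, size=n)
    waist = np.where(male, rng.normal(95, 12, size=n), rng.normal(88, 14, size=n))
    triglycerides = rng.lognormal(np.log(100), 0.5, size=n)
    hdl = np.where(male, rng.normal(48, 11, size=n), rng.normal(55, 12, size=n))
    hba1c = rng.normal(5.4, 0.4, size=n)
    dx_hypertension = (rng.random(n) < 0.08).astype(int)
    med_hypertension = (rng.random(n) < 0.05).astype(int)
    dx_diabetes = (rng.random(n) < 0.03).astype(int)
    med_diabetes = (rng.random(n) < 0.02).astype(int)
    pregnant = ((~male) & (rng.random(n) < params["pregnancy_rate"])).astype(int)

    cohort = pd.DataFrame(
        {
            "pid": np.arange(1, n + 1),
            "stratum": strata,
            "cluster": clusters,
            "weight": weights,
            "race": race,
            **{c: ace_items[:, i] for i, c in enumerate(ACE_COLUMNS)},
            "age": age,
            "sex": sex,
            "parent1_education": parent1,
            "parent2_education": parent2,
            "household_income": income,
            "household_size": size_hh,
            **{c: support[:, i] for i, c in enumerate(SUPPORT_COLUMNS)},
            **{c: tract[:, i] for i, c in enumerate(TRACT_COLUMNS)},
            "systolic": systolic,
            "diastolic": diastolic,
            "waist": waist,
            "triglycerides": triglycerides,
            "hdl": hdl,
            "hba1c": hba1c,
            "dx_hypertension": dx_hypertension,
            "med_hypertension": med_hypertension,
            "dx_diabetes": dx_diabetes,
            "med_diabetes": med_diabetes,
            "pregnant": pregnant,
        }
    )

    # -- outcomes under the log-linear risk model ------------------------
    for outcome in OUTCOMES:
        baseline = config.baseline_risk_by_outcome[outcome]
        race_rr = np.array(
            [config.race_main_rr.get(outcome, {}).get(r, 1.0) for r in race]
        )
        ace_rr = np.array(
            [config.true_rr.get(outcome, {}).get(r, 1.0) for r in race]
        )
        risk = baseline * race_rr * np.where(elevated, ace_rr, 1.0)
        risk = risk * _covariate_multiplier(cohort, outcome, params)
        if np.any(risk > 1.0):
            i = int(np.argmax(risk))
            raise ValueError(
                f"implied risk {risk[i]:.4f} > 1 for outcome={outcome!r}, "
                f"race={race[i]!r}, elevated_aces={bool(elevated[i])}"
            )
        cohort[outcome] = (rng.random(n) < risk).astype(int)

    return cohort[cohort_columns()]


_CLASS_COLUMNS: dict[str, tuple[str, ...]] = {
    "ace": ACE_COLUMNS,
    "covariate": COVARIATE_COLUMNS,
    "outcome": OUTCOMES,
    "biomarker": BIOMARKER_COLUMNS,
}


def induce_missingness(cohort: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Mask values per the configured class-level rates.

    A rate ``r`` for a class is the fraction of rows carrying at least one
    missing field of that class (matching how the source study reports its
    missingness burden). Selected rows have each field of the class masked
    independently with probability 1/2, forced to at least one.

    Mechanisms: ``mcar`` selects rows uniformly; ``mar`` tilts selection by
    race (non-White up) and low parental education while preserving the
    marginal rate. Design variables are never masked; requesting a class
    that touches them raises.
    """
    for cls in config.missing_rates:
        if cls not in _CLASS_COLUMNS:
            raise ValueError(
                f"unknown missingness class {cls!r}; design variables "
                f"{DESIGN_COLUMNS} cannot be masked"
            )
    out = cohort.copy()
    n = len(out)
    if n == 0:
        return out
    rng = np.random.default_rng([int(config.seed), 104729])

    if config.missing_mechanism == "mar":
        # Logistic tilt on race and parental education, rescaled to keep the
        # marginal selection rate at the configured value.
        tilt = np.zeros(n)
        tilt += np.where(out["race"].to_numpy() != "White", 0.8, 0.0)
        edu = np.maximum(
            out["parent1_education"].to_numpy(dtype=float),
            out["parent2_education"].to_numpy(dtype=float),
        )
        tilt += np.where(edu <= 2, 0.8, 0.0)
        rel = np.exp(tilt)
        rel = rel / rel.mean()
    else:
        rel = np.ones(n)

    for cls, rate in config.missing_rates.items():
        if rate == 0.0:
            continue
        columns = [c for c in _CLASS_COLUMNS[cls] if c in out.columns]
        if not columns:
            continue
        prob = np.clip(rate * rel, 0.0, 1.0)
        selected = np.flatnonzero(rng.random(n) < prob)
        if selected.size == 0:
            continue
        mask = rng.random((selected.size, len(columns))) < 0.5
        none = ~mask.any(axis=1)
        if none.any():
            forced = rng.integers(0, len(columns), size=int(none.sum()))
            mask[np.flatnonzero(none), forced] = True
        for j, col in enumerate(columns):
            rows = selected[mask[:, j]]
            if rows.size:
                values = out[col].astype(float).to_numpy()
                values[rows] = np.nan
                out[col] = values
    return out
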