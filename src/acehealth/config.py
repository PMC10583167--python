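"""Run and simulation configuration objects.

Central place for the category vocabularies (race groups, outcome names,
column classes) and for the two configuration dataclasses:

* :class:`SimulationConfig` — every knob of the synthetic cohort generator.
* :class:`RunConfig` — the end-to-end analysis configuration.

Both round-trip through YAML so that runs are fully declarative.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

#: Race categories produced by the generator and used in analysis models.
RACE_CATEGORIES: tuple[str, ...] = ("White", "Black", "Asian", "AI/NA", "Multiracial")

#: Categories admitted on ingest only, removed by the exclusion rules
#: (Hispanic/Latino because ethnicity and race are assessed independently in
#: the source study; "Other" alone because of its very small cell size).
INGEST_ONLY_CATEGORIES: tuple[str, ...] = ("Hispanic/Latino", "Other")

#: The seven binary outcomes, in reporting order.
OUTCOMES: tuple[str, ...] = (
    "mets",
    "hypertension",
    "asthma",
    "depression",
    "anxiety",
    "suicidal_ideation",
    "drug_use",
)

#: Outcomes whose biomarker basis is affected by pregnancy; pregnant
#: participants are excluded from these models only.
BIOMARKER_OUTCOMES: tuple[str, ...] = ("mets", "hypertension")

ACE_COLUMNS: tuple[str, ...] = tuple(f"ace_{i}" for i in range(1, 11))
SUPPORT_COLUMNS: tuple[str, ...] = tuple(f"support_{i}" for i in range(1, 6))
TRACT_COLUMNS: tuple[str, ...] = tuple(f"tract_{i}" for i in range(1, 6))

#: Raw covariate inputs eligible for masking under the "covariate" class.
COVARIATE_COLUMNS: tuple[str, ...] = (
    "parent1_education",
    "parent2_education",
    "household_income",
    "household_size",
    *SUPPORT_COLUMNS,
    *TRACT_COLUMNS,
)

BIOMARKER_COLUMNS: tuple[str, ...] = (
    "systolic",
    "diastolic",
    "waist",
    "triglycerides",
    "hdl",
    "hba1c",
    "dx_hypertension",
    "med_hypertension",
    "dx_diabetes",
    "med_diabetes",
)

#: Survey design variables: never masked, never imputed.
DESIGN_COLUMNS: tuple[str, ...] = ("stratum", "cluster", "weight")

#: Adjustment covariates of the main analysis (derived scale).
DEFAULT_ADJUSTMENT: tuple[str, ...] = (
    "age",
    "sex_male",
    "parental_education_max",
    "equivalized_income",
    "parental_support_index",
    "neighborhood_disadvantage",
)

#: Five-level ordinal coding of parental education (1 = lowest).
EDUCATION_LEVELS: tuple[str, ...] = (
    "less_than_hs",
    "vocational_or_ged",
    "hs_diploma",
    "some_college",
    "college_or_more",
)


def table1_race_proportions() -> dict[str, float]:
    """Published weighted race shares, rescaled to sum to exactly 1.

    The printed percentages (74, 17, 3.2, 0.6, 5.8) sum to 100.6 because of
    rounding; the generator requires an exact simplex.
    """
    raw = {"White": 0.74, "Black": 0.17, "Asian": 0.032, "AI/NA": 0.006, "Multiracial": 0.058}
    total = sum(raw.values())
    return {k: v / total for k, v in raw.items()}


def table1_ace_prevalence() -> dict[str, float]:
    """Published weighted prevalence of elevated (>=4) ACEs by race."""
    return {"White": 0.25, "Black": 0.33, "Asian": 0.21, "AI/NA": 0.40, "Multiracial": 0.35}


def _default_baseline_risks() -> dict[str, float]:
    # Referent-cell (Multiracial, <4 ACEs) risks chosen so that mixing over
    # the configured ACE prevalence approximately reproduces the published
    # marginal outcome prevalences.
    return {
        "mets": 0.29,
        "hypertension": 0.50,
        "asthma": 0.22,
        "depression": 0.33,
        "anxiety": 0.17,
        "suicidal_ideation": 0.095,
        "drug_use": 0.40,
    }


def _default_true_rr() -> dict[str, dict[str, float]]:
    # Within-group risk ratios for elevated ACEs (the published adjusted
    # estimates), per outcome and race.
    return {
        "mets": {"White": 1.03, "Black": 1.00, "Asian": 1.00, "AI/NA": 0.99, "Multiracial": 1.00},
        "hypertension": {"White": 0.99, "Black": 1.01, "Asian": 1.02, "AI/NA": 0.86, "Multiracial": 0.98},
        "asthma": {"White": 1.04, "Black": 1.02, "Asian": 1.00, "AI/NA": 1.15, "Multiracial": 1.13},
        "depression": {"White": 1.13, "Black": 1.13, "Asian": 1.10, "AI/NA": 1.21, "Multiracial": 1.14},
        "anxiety": {"White": 1.05, "Black": 1.03, "Asian": 0.98, "AI/NA": 0.99, "Multiracial": 1.12},
        "suicidal_ideation": {"White": 1.05, "Black": 1.05, "Asian": 1.08, "AI/NA": 1.07, "Multiracial": 1.05},
        "drug_use": {"White": 1.11, "Black": 1.08, "Asian": 1.08, "AI/NA": 1.30, "Multiracial": 1.13},
    }


def _default_race_main_rr() -> dict[str, dict[str, float]]:
    # Low-ACE risk ratios versus the Multiracial referent, set so marginal
    # prevalences track the published Table-1 pattern (e.g. asthma lower and
    # drug use similar for White vs Multiracial participants).
    return {
        "mets": {"White": 0.90, "Black": 1.25, "Asian": 0.90, "AI/NA": 1.60, "Multiracial": 1.0},
        "hypertension": {"White": 1.00, "Black": 1.08, "Asian": 0.92, "AI/NA": 1.25, "Multiracial": 1.0},
        "asthma": {"White": 0.63, "Black": 0.63, "Asian": 0.45, "AI/NA": 0.65, "Multiracial": 1.0},
        "depression": {"White": 1.00, "Black": 0.75, "Asian": 0.50, "AI/NA": 0.90, "Multiracial": 1.0},
        "anxiety": {"White": 0.83, "Black": 0.34, "Asian": 0.17, "AI/NA": 0.19, "Multiracial": 1.0},
        "suicidal_ideation": {"White": 0.73, "Black": 0.73, "Asian": 0.60, "AI/NA": 1.45, "Multiracial": 1.0},
        "drug_use": {"White": 0.97, "Black": 0.28, "Asian": 0.60, "AI/NA": 1.05, "Multiracial": 1.0},
    }


def _default_confounders() -> dict[str, Any]:
    return {
        "age_mean": 29.0,
        "age_sd": 1.8,
        "male_proportion": 0.51,
        # Marginal distribution over the five ordinal education levels.
        "education_probs": [0.06, 0.05, 0.34, 0.18, 0.37],
        "log_income_mean": 3.6,  # income in $1000s; median ~ exp(3.6) = 36.6
        "log_income_sd": 0.65,
        "household_size_rate": 2.2,  # size = 1 + Poisson(rate)
        "support_mean": 3.3,
        "support_sd": 1.0,
        # Neighborhood disadvantage Beta mean by race, concentration 20.
        "tract_mean_by_race": {
            "White": 0.12,
            "Black": 0.23,
            "Asian": 0.13,
            "AI/NA": 0.23,
            "Multiracial": 0.15,
        },
        "tract_concentration": 20.0,
        "pregnancy_rate": 0.07,
        # Optional per-outcome log-RR coefficients on centred covariates,
        # e.g. {"asthma": {"age": 0.02}}. Empty by default so that the
        # configured race/ACE risk ratios are exactly the model estimands.
        "covariate_log_rr": {},
    }


def _default_missing_rates() -> dict[str, float]:
    # Published fractions of observations missing at least one field of each
    # class: 55% an ACE component, 21% a covariate, 40% an outcome.
    return {"ace": 0.55, "covariate": 0.21, "outcome": 0.40, "biomarker": 0.0}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort generator.

    Defaults reproduce the study conditions: published weighted race shares,
    race-specific elevated-ACE prevalence, published adjusted within-group
    risk ratios as the generative truth, and the published missingness
    burden. Generation is a pure function of the config (including ``seed``).
    """

    n_individuals: int = 12000
    n_strata: int = 20
    clusters_per_stratum: int = 4
    race_proportions: dict[str, float] = field(default_factory=table1_race_proportions)
    ace_prevalence_by_race: dict[str, float] = field(default_factory=table1_ace_prevalence)
    baseline_risk_by_outcome: dict[str, float] = field(default_factory=_default_baseline_risks)
    true_rr: dict[str, dict[str, float]] = field(default_factory=_default_true_rr)
    race_main_rr: dict[str, dict[str, float]] = field(default_factory=_default_race_main_rr)
    confounder_params: dict[str, Any] = field(default_factory=_default_confounders)
    missing_rates: dict[str, float] = field(default_factory=_default_missing_rates)
    missing_mechanism: str = "mcar"  # "mcar" or "mar"
    weight_dispersion: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        if self.n_individuals < 0:
            raise ValueError("n_individuals must be a nonnegative count")
        if self.n_strata <= 0 or self.clusters_per_stratum <= 0:
            raise ValueError("n_strata and clusters_per_stratum must be positive")
        total = sum(self.race_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"race_proportions must sum to 1 (got {total!r}); "
                "use table1_race_proportions() for the published shares"
            )
        for name, p in self.race_proportions.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"race proportion for {name} outside [0, 1]")
        for name, p in self.ace_prevalence_by_race.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"ACE prevalence for {name} outside [0, 1]")
        for cls, p in self.missing_rates.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"missing rate for class {cls} outside [0, 1]")
        if self.missing_mechanism not in ("mcar", "mar"):
            raise ValueError("missing_mechanism must be 'mcar' or 'mar'")
        if self.weight_dispersion < 0:
            raise ValueError("weight_dispersion must be nonnegative")
        for outcome, risk in self.baseline_risk_by_outcome.items():
            if not 0.0 < risk < 1.0:
                raise ValueError(f"baseline risk for {outcome} must lie in (0, 1)")
        for table_name, table in (("true_rr", self.true_rr), ("race_main_rr", self.race_main_rr)):
            for outcome, by_race in table.items():
                for race, rr in by_race.items():
                    if rr <= 0:
                        raise ValueError(f"{table_name}[{outcome}][{race}] must be positive")
        # Implied cell risks must be valid probabilities for every race x
        # exposure cell the generator can produce (covariate multipliers are
        # re-checked row-wise at generation time).
        for outcome, baseline in self.baseline_risk_by_outcome.items():
            for race in self.race_proportions:
                main = self.race_main_rr.get(outcome, {}).get(race, 1.0)
                rr = self.true_rr.get(outcome, {}).get(race, 1.0)
                risk = baseline * main * max(1.0, rr)
                if risk > 1.0:
                    raise ValueError(
                        f"implied risk {risk:.3f} > 1 for outcome={outcome!r}, "
                        f"race={race!r} (baseline {baseline} x race RR {main} x ACE RR {rr})"
                    )

    # -- (de)serialization ----------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown SimulationConfig fields: {sorted(unknown)}")
        base = cls()
        merged: dict[str, Any] = {}
        for f in dataclasses.fields(cls):
            merged[f.name] = data.get(f.name, getattr(base, f.name))
        return cls(**merged)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class RunConfig:
    """End-to-end analysis configuration.

    Either ``cohort_path`` (a delimited cohort file) or ``simulation`` must
    be provided as the input source.
    """

    cohort_path: str | None = None
    simulation: SimulationConfig | None = None
    outcomes: tuple[str, ...] = OUTCOMES
    exposure: str = "elevated"  # "elevated" (>=4 ACEs) or "score" (0-10)
    referent_race: str = "Multiracial"
    covariates: tuple[str, ...] = DEFAULT_ADJUSTMENT
    n_imputations: int = 20
    imputation_iterations: int = 5
    n_resamples: int = 10000
    seed: int = 0
    #: Derive MetS/hypertension from biomarkers (True) or use the cohort's
    #: outcome indicator columns (False, the synthetic-cohort default).
    derive_biomarker_outcomes: bool = False
    #: Fit the additional no-interaction model behind the "Overall" column.
    fit_overall: bool = True
    #: Reference-cell standardization for the RERI -> IC conversion:
    #: "reference_profile" (covariates at weighted means) or "marginal".
    r00_method: str = "reference_profile"
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if isinstance(self.outcomes, list):
            self.outcomes = tuple(self.outcomes)
        if isinstance(self.covariates, list):
            self.covariates = tuple(self.covariates)
        unknown = set(self.outcomes) - set(OUTCOMES)
        if unknown:
            raise ValueError(f"unknown outcomes: {sorted(unknown)}; known: {OUTCOMES}")
        if self.referent_race not in RACE_CATEGORIES:
            raise ValueError(f"referent_race must be one of {RACE_CATEGORIES}")
        if self.exposure not in ("elevated", "score"):
            raise ValueError("exposure must be 'elevated' or 'score'")
        if self.r00_method not in ("reference_profile", "marginal"):
            raise ValueError("r00_method must be 'reference_profile' or 'marginal'")
        if self.simulation is not None and isinstance(self.simulation, dict):
            self.simulation = SimulationConfig.from_dict(self.simulation)

    def to_dict(self) -> dict[str, Any]:
        out = dataclasses.asdict(self)
        out["outcomes"] = list(self.outcomes)
        out["covariates"] = list(self.covariates)
        return out

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def config_hash(self) -> str:
        """Stable hash of the configuration for the run manifest."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def outcome_columns(outcomes: Sequence[str] = OUTCOMES) -> tuple[str, ...]:
    return tuple(outcomes)
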