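"""Construction of analysis variables from raw cohort fields.

Covers the adversity score and its dichotomized exposure, the metabolic
syndrome (MetS) and hypertension composites, and the six adjustment
covariates. All operations are pure column transformations; they are meant
to run on completed (post-imputation) data and raise on missing inputs so a
skipped imputation step is caught loudly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ACE_COLUMNS, SUPPORT_COLUMNS, TRACT_COLUMNS

__all__ = [
    "compute_ace",
    "weighted_quantile",
    "DecileCutoffs",
    "decile_cutoffs",
    "classify_mets",
    "classify_hypertension",
    "derive_covariates",
    "derive_all",
]

ACE_THRESHOLD = 4

# MetS decile conventions: triglycerides in the top 3 deciles for males and
# top 2 for females count as high; HDL in the bottom 2 deciles for males and
# bottom 3 for females counts as low.
_TRIG_QUANTILE = {"male": 0.7, "female": 0.8}
_HDL_QUANTILE = {"male": 0.2, "female": 0.3}
_WAIST_CUTOFF = {"male": 102.0, "female": 80.0}


def compute_ace(components: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sum ten binary adversity components into a 0-10 score and the
    elevated (>= 4) exposure indicator.

    Must be called on completed data: any missing component raises, since
    the score is only summed after imputation.
    """
    values = np.asarray(components, dtype=float)
    if values.ndim == 1:
        values = values[None, :]
    if values.shape[1] != len(ACE_COLUMNS):
        raise ValueError(f"expected {len(ACE_COLUMNS)} components, got {values.shape[1]}")
    if np.isnan(values).any():
        raise ValueError(
            "missing ACE component: components must be imputed before the "
            "score is summed and dichotomized"
        )
    if not np.isin(values, (0.0, 1.0)).all():
        raise ValueError("ACE components must be binary 0/1")
    score = values.sum(axis=1).astype(int)
    elevated = (score >= ACE_THRESHOLD).astype(int)
    return score, elevated


def weighted_quantile(values: np.ndarray, weights: np.ndarray, q: float | np.ndarray) -> np.ndarray:
    """Left-continuous inverse of the weighted empirical CDF.

    Returns the smallest observed value ``x`` with ``F(x) >= q``; with unit
    weights this is ``numpy.quantile(..., method="inverted_cdf")``. Invariant
    to rescaling all weights by a positive constant.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.shape != weights.shape:
        raise ValueError("values and weights must have the same shape")
    if values.size == 0:
        raise ValueError("cannot compute quantiles of an empty sample")
    if np.any(weights < 0):
        raise ValueError("weights must be nonnegative")
    order = np.argsort(values, kind="stable")
    v = values[order]
    cum = np.cumsum(weights[order])
    total = cum[-1]
    if total <= 0:
        raise ValueError("total weight must be positive")
    q_arr = np.atleast_1d(np.asarray(q, dtype=float))
    if np.any((q_arr < 0) | (q_arr > 1)):
        raise ValueError("quantile levels must lie in [0, 1]")
    # smallest index with cumweight >= q * total (tolerance for ties in
    # floating-point cumulative sums)
    idx = np.searchsorted(cum, q_arr * total - 1e-12 * total, side="left")
    idx = np.clip(idx, 0, v.size - 1)
    out = v[idx]
    return out if np.ndim(q) else float(out[0])


@dataclass(frozen=True)
class DecileCutoffs:
    """Sex-specific weighted decile boundaries for triglycerides and HDL.

    ``trig_deciles``/``hdl_deciles`` hold the nine interior decile
    boundaries (10th..90th percentile) per sex, computed on the analysis
    sample. The MetS-relevant cutoffs are exposed as accessors.
    """

    trig_deciles: dict[str, np.ndarray]
    hdl_deciles: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for table in (self.trig_deciles, self.hdl_deciles):
            for sex, bounds in table.items():
                if np.any(np.diff(bounds) < 0):
                    raise ValueError(f"decile boundaries for sex={sex!r} not non-decreasing")

    def trig_cutoff(self, sex: str) -> float:
        """High-triglyceride boundary (top 3 deciles male, top 2 female)."""
        q = _TRIG_QUANTILE[_check_sex(sex)]
        return float(self.trig_deciles[sex][int(round(q * 10)) - 1])

    def hdl_cutoff(self, sex: str) -> float:
        """Low-HDL boundary (bottom 2 deciles male, bottom 3 female)."""
        q = _HDL_QUANTILE[_check_sex(sex)]
        return float(self.hdl_deciles[sex][int(round(q * 10)) - 1])


def _check_sex(sex: str) -> str:
    if sex not in ("male", "female"):
        raise ValueError(f"unknown sex code {sex!r}; expected 'male' or 'female'")
    return sex


def decile_cutoffs(cohort: pd.DataFrame, weights: np.ndarray | None = None) -> DecileCutoffs:
    """Weighted decile boundaries of triglycerides and HDL per sex.

    Requires at least 10 non-missing values per sex for each analyte; the
    boundaries are sample-relative, so they are recomputed within each
    imputed dataset on the relevant analysis sample.
    """
    if weights is None:
        weights = cohort["weight"].to_numpy(dtype=float)
    weights = np.asarray(weights, dtype=float)
    qs = np.arange(1, 10) / 10.0
    trig: dict[str, np.ndarray] = {}
    hdl: dict[str, np.ndarray] = {}
    sex = cohort["sex"].to_numpy()
    for s in ("male", "female"):
        mask = sex == s
        for column, table in (("triglycerides", trig), ("hdl", hdl)):
            values = cohort.loc[mask, column].to_numpy(dtype=float)
            w = weights[mask]
            ok = ~np.isnan(values)
            if ok.sum() < 10:
                raise ValueError(
                    f"insufficient non-missing {column} values for sex={s!r} "
                    f"({int(ok.sum())} < 10)"
                )
            table[s] = np.asarray(weighted_quantile(values[ok], w[ok], qs))
    return DecileCutoffs(trig_deciles=trig, hdl_deciles=hdl)


def _hypertension_category(frame: pd.DataFrame) -> np.ndarray:
    required = ["systolic", "diastolic", "dx_hypertension", "med_hypertension"]
    sub = frame[required].astype(float)
    if sub.isna().any().any():
        raise ValueError("missing biomarker inputs: impute before classification")
    return (
        (sub["systolic"].to_numpy() >= 130.0)
        | (sub["diastolic"].to_numpy() >= 80.0)
        | (sub["dx_hypertension"].to_numpy() == 1)
        | (sub["med_hypertension"].to_numpy() == 1)
    )


def classify_hypertension(frame: pd.DataFrame) -> np.ndarray:
    """Hypertension indicator: systolic >= 130 mmHg, diastolic >= 80 mmHg,
    prior diagnosis, or current medication use. Identical to the blood
    pressure category of the MetS composite."""
    return _hypertension_category(frame).astype(int)


def classify_mets(frame: pd.DataFrame, cutoffs: DecileCutoffs) -> np.ndarray:
    """Metabolic-syndrome indicator: positive in >= 3 of 5 categories.

    Categories: (1) elevated blood pressure / hypertension as in
    :func:`classify_hypertension`; (2) waist circumference > 102 cm (male) /
    > 80 cm (female); (3) triglycerides at or above the sex-specific upper
    decile boundary; (4) HDL at or below the sex-specific lower decile
    boundary; (5) diabetes: HbA1c > 5.7%, anti-diabetic medication, or
    diagnosis.
    """
    sex = frame["sex"].to_numpy()
    for s in np.unique(sex):
        _check_sex(str(s))
    numeric = frame[["waist", "triglycerides", "hdl", "hba1c", "dx_diabetes", "med_diabetes"]].astype(float)
    if numeric.isna().any().any():
        raise ValueError("missing biomarker inputs: impute before classification")

    male = sex == "male"
    waist_cut = np.where(male, _WAIST_CUTOFF["male"], _WAIST_CUTOFF["female"])
    trig_cut = np.where(male, cutoffs.trig_cutoff("male"), cutoffs.trig_cutoff("female"))
    hdl_cut = np.where(male, cutoffs.hdl_cutoff("male"), cutoffs.hdl_cutoff("female"))

    categories = (
        _hypertension_category(frame).astype(int)
        + (numeric["waist"].to_numpy() > waist_cut).astype(int)
        + (numeric["triglycerides"].to_numpy() >= trig_cut).astype(int)
        + (numeric["hdl"].to_numpy() <= hdl_cut).astype(int)
        + (
            (numeric["hba1c"].to_numpy() > 5.7)
            | (numeric["dx_diabetes"].to_numpy() == 1)
            | (numeric["med_diabetes"].to_numpy() == 1)
        ).astype(int)
    )
    return (categories >= 3).astype(int)


def derive_covariates(frame: pd.DataFrame) -> pd.DataFrame:
    """Derive the six adjustment covariates from raw inputs.

    * ``equivalized_income`` — household income / sqrt(household size);
    * ``parental_education_max`` — the higher of the two parents' five-level
      ordinal education codes;
    * ``parental_support_index`` — mean of the five Likert (1-5) items;
    * ``neighborhood_disadvantage`` — mean of the five tract proportions;
    * ``sex_male`` — 0/1 recode of sex (``age`` passes through unchanged).
    """
    required = ["household_income", "household_size", "parent1_education", "parent2_education",
                *SUPPORT_COLUMNS, *TRACT_COLUMNS]
    sub = frame[required].astype(float)
    if sub.isna().any().any():
        raise ValueError("missing covariate inputs: impute before derivation")
    size = sub["household_size"].to_numpy()
    if np.any(size < 1):
        raise ValueError("household size must be >= 1")
    tract = sub[list(TRACT_COLUMNS)].to_numpy()
    if np.any((tract < 0) | (tract > 1)):
        raise ValueError("tract proportions must lie in [0, 1]")
    out = pd.DataFrame(index=frame.index)
    out["equivalized_income"] = sub["household_income"].to_numpy() / np.sqrt(size)
    out["parental_education_max"] = np.maximum(
        sub["parent1_education"].to_numpy(), sub["parent2_education"].to_numpy()
    )
    out["parental_support_index"] = sub[list(SUPPORT_COLUMNS)].to_numpy().mean(axis=1)
    out["neighborhood_disadvantage"] = tract.mean(axis=1)
    out["sex_male"] = (frame["sex"].to_numpy() == "male").astype(int)
    return out


def derive_all(frame: pd.DataFrame, derive_biomarker_outcomes: bool = False) -> pd.DataFrame:
    """Append all derived analysis columns to a completed cohort frame.

    Adds ``ace_score``, ``elevated_aces`` and the covariate bundle; when
    ``derive_biomarker_outcomes`` is set, recomputes the ``mets`` and
    ``hypertension`` columns from the biomarker panel, with the sex-specific
    decile cutoffs computed on the (weighted) frame itself.
    """
    out = frame.copy()
    score, elevated = compute_ace(out[list(ACE_COLUMNS)])
    out["ace_score"] = score
    out["elevated_aces"] = elevated
    cov = derive_covariates(out)
    for column in cov.columns:
        out[column] = cov[column]
    if derive_biomarker_outcomes:
        cuts = decile_cutoffs(out)
        out["mets"] = classify_mets(out, cuts)
        out["hypertension"] = classify_hypertension(out)
    return out
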