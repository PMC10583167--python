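"""Modified Poisson risk-ratio regression under a complex survey design.

Fits a log-link Poisson working model to a binary outcome by weighted IRLS,
so that exponentiated coefficients are risk ratios, and pairs it with a
design-based linearized (Taylor) sandwich covariance: the "bread" is the
inverse weighted information and the "meat" is the between-cluster
covariance of weighted score totals within strata, with the standard
``n_h / (n_h - 1)`` cluster correction and no finite-population correction.

The race-by-exposure interaction model of the analysis is expressed through
:class:`ModelSpec`; :func:`fit_modified_poisson` builds the design matrix
with indicator contrasts against the configured referent race.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import RACE_CATEGORIES

__all__ = [
    "SurveyDesign",
    "ModelSpec",
    "ModelFit",
    "ConvergenceError",
    "build_design_matrix",
    "fit_poisson_glm",
    "fit_modified_poisson",
    "predict_risk",
]


class ConvergenceError(RuntimeError):
    """IRLS failed to converge; carries the iteration trace."""

    def __init__(self, message: str, trace: list[float]):
        super().__init__(message)
        self.trace = trace


@dataclass(frozen=True)
class SurveyDesign:
    """Stratum, primary-sampling-unit (cluster) and weight per row."""

    strata: np.ndarray
    clusters: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        strata = np.asarray(self.strata)
        clusters = np.asarray(self.clusters)
        weights = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "strata", strata)
        object.__setattr__(self, "clusters", clusters)
        object.__setattr__(self, "weights", weights)
        if not (strata.shape == clusters.shape == weights.shape):
            raise ValueError("strata, clusters and weights must share one length")
        if np.any(weights <= 0):
            raise ValueError("survey weights must be strictly positive")
        # each cluster must be nested in exactly one stratum
        frame = pd.DataFrame({"h": strata, "c": clusters})
        per_cluster = frame.groupby("c", sort=False)["h"].nunique()
        if (per_cluster > 1).any():
            bad = per_cluster[per_cluster > 1].index.tolist()[:3]
            raise ValueError(f"clusters appearing in more than one stratum: {bad}")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SurveyDesign":
        return cls(
            strata=frame["stratum"].to_numpy(),
            clusters=frame["cluster"].to_numpy(),
            weights=frame["weight"].to_numpy(dtype=float),
        )

    def subset(self, mask: np.ndarray) -> "SurveyDesign":
        return SurveyDesign(self.strata[mask], self.clusters[mask], self.weights[mask])

    def __len__(self) -> int:
        return int(self.weights.shape[0])


@dataclass(frozen=True)
class ModelSpec:
    """One outcome model: exposure coding, referent race, adjustment set."""

    outcome: str
    exposure: str = "elevated"  # "elevated" or "score"
    referent_race: str = "Multiracial"
    covariates: tuple[str, ...] = ()
    interaction: bool = True

    def __post_init__(self) -> None:
        if self.exposure not in ("elevated", "score"):
            raise ValueError("exposure must be 'elevated' or 'score'")
        if self.referent_race not in RACE_CATEGORIES:
            raise ValueError(f"referent race must be one of {RACE_CATEGORIES}")
        if isinstance(self.covariates, list):
            object.__setattr__(self, "covariates", tuple(self.covariates))

    @property
    def exposure_column(self) -> str:
        return "elevated_aces" if self.exposure == "elevated" else "ace_score"

    def race_groups(self, present: Sequence[str]) -> tuple[str, ...]:
        """Non-referent race groups in canonical order, restricted to data."""
        return tuple(r for r in RACE_CATEGORIES if r != self.referent_race and r in set(present))


@dataclass
class ModelFit:
    """Fitted coefficients on the log-RR scale with design-based covariance."""

    params: pd.Series
    cov: pd.DataFrame
    n: int
    converged: bool
    n_iter: int
    spec: ModelSpec | None = None
    trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.params.index)) != len(self.params.index):
            raise ValueError("term labels must be unique")
        v = self.cov.to_numpy()
        if not np.allclose(v, v.T, atol=1e-8):
            raise ValueError("covariance must be symmetric within 1e-8")

    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov.to_numpy())), index=self.params.index)


def build_design_matrix(frame: pd.DataFrame, spec: ModelSpec) -> tuple[pd.DataFrame, np.ndarray]:
    """Design matrix with labeled terms and the outcome vector.

    Terms: ``Intercept``; ``race[g]`` indicator contrasts against the
    referent; the exposure column; ``<exposure>:race[g]`` products when the
    interaction flag is set; then the adjustment covariates.
    """
    y = frame[spec.outcome].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError(f"outcome {spec.outcome!r} has missing values in fitting rows")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError(f"outcome {spec.outcome!r} must be binary 0/1")

    cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(frame))}
    race = frame["race"].to_numpy()
    exposure = frame[spec.exposure_column].to_numpy(dtype=float)
    if np.isnan(exposure).any():
        raise ValueError("exposure has missing values; impute first")
    groups = spec.race_groups(pd.unique(race))
    for g in groups:
        cols[f"race[{g}]"] = (race == g).astype(float)
    cols[spec.exposure_column] = exposure
    if spec.interaction:
        for g in groups:
            cols[f"{spec.exposure_column}:race[{g}]"] = exposure * (race == g)
    for c in spec.covariates:
        v = frame[c].to_numpy(dtype=float)
        if np.isnan(v).any():
            raise ValueError(f"covariate {c!r} has missing values; impute first")
        cols[c] = v
    X = pd.DataFrame(cols, index=frame.index)
    return X, y


def _check_rank(X: pd.DataFrame) -> None:
    mat = X.to_numpy()
    _, r = np.linalg.qr(mat)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(mat.shape) * np.finfo(float).eps * 10
    bad = [X.columns[i] for i in np.flatnonzero(diag < tol)]
    if bad:
        raise ValueError(f"design matrix rank-deficient; aliased terms: {bad}")


def fit_poisson_glm(
    X: pd.DataFrame,
    y: np.ndarray,
    design: SurveyDesign,
    *,
    tol: float = 1e-10,
    max_iter: int = 100,
    single_cluster: str = "certainty",
) -> ModelFit:
    """Weighted log-link Poisson IRLS plus the design-based sandwich.

    Starts from ``beta_0 = log(weighted mean of y)`` with the remaining
    coefficients at zero, and halves the Newton step (up to 10 times) when
    the weighted working objective increases — the log link on binary data
    can otherwise step outside the stable region. Convergence is declared
    when the relative coefficient change falls below ``tol``.

    ``single_cluster`` controls strata with one PSU: ``"certainty"``
    (default) treats them as certainty strata contributing zero variance,
    with a warning; ``"error"`` raises.
    """
    if np.all(y == 0):
        raise ValueError("outcome is identically zero; risk model is degenerate")
    _check_rank(X)
    labels = list(X.columns)
    mat = X.to_numpy(dtype=float)
    w = design.weights
    n, p = mat.shape

    beta = np.zeros(p)
    if "Intercept" in labels:
        prevalence = float(np.average(y, weights=w))
        beta[labels.index("Intercept")] = np.log(max(prevalence, 1e-12))

    def objective(b: np.ndarray) -> float:
        eta = mat @ b
        return float(np.sum(w * (np.exp(eta) - y * eta)))

    obj = objective(beta)
    trace = [obj]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = mat @ beta
        mu = np.exp(eta)
        info = mat.T @ (mat * (w * mu)[:, None])
        score = mat.T @ (w * (y - mu))
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular information at iteration {it}", trace) from exc
        new_beta = beta + step
        new_obj = objective(new_beta)
        halvings = 0
        while new_obj > obj + 1e-12 * (1 + abs(obj)) and halvings < 10:
            step *= 0.5
            new_beta = beta + step
            new_obj = objective(new_beta)
            halvings += 1
        rel_change = float(np.max(np.abs(new_beta - beta) / (np.abs(beta) + 1e-10)))
        obj_change = obj - new_obj
        beta, obj = new_beta, new_obj
        trace.append(obj)
        if rel_change < tol:
            converged = True
            break
        # quasi-separated cells (e.g. a zero-case race x exposure cell) drift
        # to -inf while the objective plateaus; stop on the plateau as
        # standard GLM deviance criteria do
        if 0 <= obj_change < 1e-12 * (1.0 + abs(obj)):
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"IRLS did not converge in {max_iter} iterations "
            f"(last objective {obj:.6g})", trace
        )

    cov = _sandwich_cov(mat, y, beta, design, single_cluster=single_cluster)
    cov = (cov + cov.T) / 2.0
    return ModelFit(
        params=pd.Series(beta, index=labels),
        cov=pd.DataFrame(cov, index=labels, columns=labels),
        n=n,
        converged=converged,
        n_iter=it,
        trace=trace,
    )


def _sandwich_cov(
    mat: np.ndarray,
    y: np.ndarray,
    beta: np.ndarray,
    design: SurveyDesign,
    single_cluster: str = "certainty",
) -> np.ndarray:
    """Stratified, clustered linearization variance of the IRLS solution."""
    w = design.weights
    mu = np.exp(mat @ beta)
    bread = np.linalg.inv(mat.T @ (mat * (w * mu)[:, None]))
    scores = mat * (w * (y - mu))[:, None]

    p = mat.shape[1]
    meat = np.zeros((p, p))
    strata = design.strata
    clusters = design.clusters
    for h in pd.unique(strata):
        in_h = strata == h
        cluster_ids = pd.unique(clusters[in_h])
        n_h = len(cluster_ids)
        if n_h < 2:
            if single_cluster == "error":
                raise ValueError(f"stratum {h!r} has a single cluster; variance undefined")
            warnings.warn(
                f"stratum {h!r} has a single cluster; treated as a certainty "
                "stratum contributing zero variance",
                stacklevel=3,
            )
            continue
        totals = np.vstack([scores[in_h & (clusters == c)].sum(axis=0) for c in cluster_ids])
        centered = totals - totals.mean(axis=0)
        meat += (n_h / (n_h - 1)) * centered.T @ centered
    # square-root form keeps the product PSD even when the information is
    # nearly singular (quasi-separated cells)
    vals, vecs = np.linalg.eigh((meat + meat.T) / 2.0)
    half = vecs * np.sqrt(np.maximum(vals, 0.0))
    root = bread @ half
    return root @ root.T


def fit_modified_poisson(
    frame: pd.DataFrame,
    spec: ModelSpec,
    design: SurveyDesign | None = None,
    **kwargs,
) -> ModelFit:
    """Fit one outcome's risk-ratio model on a completed analysis frame.

    ``frame`` must already carry the derived exposure and covariates; rows
    with a missing outcome are dropped (with their design rows) before
    fitting.
    """
    if design is None:
        design = SurveyDesign.from_frame(frame)
    if len(design) != len(frame):
        raise ValueError("design length must match frame length")
    keep = ~frame[spec.outcome].isna().to_numpy()
    sub = frame.loc[keep]
    X, y = build_design_matrix(sub, spec)
    fit = fit_poisson_glm(X, y, design.subset(keep), **kwargs)
    fit.spec = spec
    return fit


def predict_risk(fit: ModelFit, profile: Mapping[str, float]) -> float:
    """Predicted risk ``exp(x' beta)`` at a covariate profile.

    The profile must supply a value for every model term except the
    intercept (which is fixed at 1). Predictions above 1 are possible under
    the working model; they are flagged with a warning, never clipped.
    """
    x = np.empty(len(fit.params))
    for i, term in enumerate(fit.params.index):
        if term == "Intercept":
            x[i] = 1.0
        elif term in profile:
            x[i] = float(profile[term])
        else:
            raise ValueError(f"profile missing model term {term!r}")
    risk = float(np.exp(x @ fit.params.to_numpy()))
    if risk > 1.0:
        warnings.warn(f"predicted risk {risk:.4f} exceeds 1 (working-model artifact)", stacklevel=2)
    return risk
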