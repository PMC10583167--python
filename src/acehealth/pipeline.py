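"""End-to-end orchestration: exclusions, imputation, derivation, model
fitting, pooling, and the report tables.

The report bundle mirrors the published table shapes: weighted descriptives
by race (table 1 analog), adjusted overall and within-group risk ratios
(table 2 analog), exponentiated interaction terms (table 3 analog), and
excess cases per 1000 from the interaction contrast (table 4 analog), plus
a machine-readable run manifest. Every stage draws its randomness from
seeds derived deterministically from the run seed, so a run is fully
reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import __version__
from .config import (
    BIOMARKER_OUTCOMES,
    OUTCOMES,
    RACE_CATEGORIES,
    RunConfig,
)
from .derive import classify_hypertension, classify_mets, decile_cutoffs, derive_all
from .glm import ModelSpec, SurveyDesign, build_design_matrix, fit_modified_poisson
from .interaction import excess_cases, interaction_rr, within_group_rr
from .io import read_cohort
from .pool import ImputationSet, PooledFit, impute, rubin_pool
from .simulate import generate_cohort, induce_missingness

__all__ = ["ExclusionResult", "ReportBundle", "apply_exclusions", "run_analysis"]


@dataclass
class ExclusionResult:
    """Globally filtered cohort plus per-rule bookkeeping.

    Hispanic/Latino and "Other"-alone rows are removed for every model;
    pregnant participants are removed only from the biomarker-based
    (MetS, hypertension) models.
    """

    global_cohort: pd.DataFrame
    log: dict[str, int]

    def for_outcome(self, outcome: str, frame: pd.DataFrame | None = None) -> pd.DataFrame:
        frame = self.global_cohort if frame is None else frame
        if outcome in BIOMARKER_OUTCOMES:
            return frame.loc[frame["pregnant"] != 1]
        return frame


def apply_exclusions(cohort: pd.DataFrame) -> ExclusionResult:
    """Apply the row-level exclusion rules and count removals per rule."""
    race = cohort["race"].astype(str)
    hispanic = race == "Hispanic/Latino"
    other = race == "Other"
    kept = cohort.loc[~(hispanic | other)].copy()
    pregnant = int((kept["pregnant"] == 1).sum()) if "pregnant" in kept.columns else 0
    log = {
        "input_rows": int(len(cohort)),
        "excluded_hispanic_latino": int(hispanic.sum()),
        "excluded_other_alone": int(other.sum()),
        "analysis_rows": int(len(kept)),
        "pregnant_excluded_biomarker_models": pregnant,
    }
    return ExclusionResult(global_cohort=kept, log=log)


@dataclass
class ReportBundle:
    """All run outputs: the four report tables, pooled fits, and manifest."""

    table1: pd.DataFrame
    table2: pd.DataFrame
    table3: pd.DataFrame
    table4: pd.DataFrame
    pooled: dict[str, PooledFit]
    manifest: dict
    config: RunConfig

    def write(self, outdir: str | Path | None = None) -> Path:
        outdir = Path(outdir if outdir is not None else self.config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.table1.to_csv(outdir / "table1_descriptives.csv", index=False)
        self.table2.to_csv(outdir / "table2_within_group_rr.csv", index=False)
        self.table3.to_csv(outdir / "table3_interaction_rr.csv", index=False)
        self.table4.to_csv(outdir / "table4_excess_cases.csv", index=False)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)
        self.config.to_yaml(outdir / "run_config.yaml")
        return outdir


def _child_seed(seed: int, *tags: int) -> int:
    return int(np.random.default_rng([int(seed), *map(int, tags)]).integers(2**31 - 1))


def _load_input(config: RunConfig) -> pd.DataFrame:
    if config.cohort_path is not None:
        return read_cohort(config.cohort_path)
    if config.simulation is not None:
        cohort = generate_cohort(config.simulation)
        if any(r > 0 for r in config.simulation.missing_rates.values()):
            cohort = induce_missingness(cohort, config.simulation)
        return cohort
    raise ValueError("run config needs either cohort_path or simulation")


def _derive_copy(frame: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    out = derive_all(frame, derive_biomarker_outcomes=False)
    if config.derive_biomarker_outcomes:
        # decile cutoffs are sample-relative: computed within this imputed
        # dataset on the pregnancy-excluded analysis sample
        basis = out.loc[out["pregnant"] != 1]
        cuts = decile_cutoffs(basis)
        out["mets"] = classify_mets(out, cuts)
        out["hypertension"] = classify_hypertension(out)
    return out


def _weighted_profile(copies: list[pd.DataFrame], covariates: tuple[str, ...]) -> dict[str, float]:
    """Adjustment covariates at their survey-weighted means, averaged over
    the imputed copies (the reference-profile standardization for R00)."""
    profile: dict[str, float] = {}
    for c in covariates:
        vals = [float(np.average(cp[c], weights=cp["weight"])) for cp in copies]
        profile[c] = float(np.mean(vals))
    return profile


def _table1(copies: list[pd.DataFrame], excl: ExclusionResult) -> pd.DataFrame:
    """Weighted descriptives by race, pooled (averaged) over imputations."""
    base = copies[0]
    races = ["Overall"] + sorted(base["race"].unique().tolist())
    rows = []
    stats = [
        ("male_sex", lambda cp: cp["sex_male"]),
        ("age", lambda cp: cp["age"]),
        ("equivalized_income", lambda cp: cp["equivalized_income"]),
        ("parental_support_index", lambda cp: cp["parental_support_index"]),
        ("neighborhood_disadvantage", lambda cp: cp["neighborhood_disadvantage"]),
        ("elevated_aces", lambda cp: cp["elevated_aces"]),
        *[(o, lambda cp, o=o: cp[o]) for o in OUTCOMES if o in base.columns],
    ]
    for race in races:
        rec: dict[str, object] = {"race": race}
        mask = slice(None) if race == "Overall" else (base["race"] == race).to_numpy()
        rec["n_unweighted"] = int(len(base)) if race == "Overall" else int(mask.sum())
        for name, getter in stats:
            vals = []
            for cp in copies:
                sub = getter(cp)
                m = np.ones(len(cp), bool) if race == "Overall" else (cp["race"] == race).to_numpy()
                v = sub.to_numpy(dtype=float)[m]
                w = cp["weight"].to_numpy(dtype=float)[m]
                ok = ~np.isnan(v)
                vals.append(float(np.average(v[ok], weights=w[ok])) if ok.any() else np.nan)
            rec[name] = float(np.mean(vals))
        rows.append(rec)
    return pd.DataFrame(rows)


def run_analysis(config: RunConfig) -> ReportBundle:
    """Run the full pipeline and return the report bundle.

    Stage errors propagate with the stage name attached so a failing run
    identifies where it broke.
    """
    stage = "ingest"
    try:
        cohort = _load_input(config)
        stage = "exclusions"
        excl = apply_exclusions(cohort)

        stage = "imputation"
        imp: ImputationSet = impute(
            excl.global_cohort,
            m=config.n_imputations,
            seed=_child_seed(config.seed, 1),
            n_iter=config.imputation_iterations,
        )

        stage = "derivation"
        copies = [_derive_copy(cp, config) for cp in imp.copies]

        stage = "model fitting"
        pooled: dict[str, PooledFit] = {}
        pooled_overall: dict[str, PooledFit] = {}
        for outcome in config.outcomes:
            spec = ModelSpec(
                outcome=outcome,
                exposure=config.exposure,
                referent_race=config.referent_race,
                covariates=config.covariates,
                interaction=True,
            )
            fits = []
            for cp in copies:
                frame = excl.for_outcome(outcome, cp)
                fits.append(fit_modified_poisson(frame, spec, SurveyDesign.from_frame(frame)))
            pooled[outcome] = rubin_pool(fits, single_ok=config.n_imputations == 1)
            pooled[outcome].spec = spec
            if config.fit_overall:
                o_spec = ModelSpec(
                    outcome=outcome,
                    exposure=config.exposure,
                    referent_race=config.referent_race,
                    covariates=config.covariates,
                    interaction=False,
                )
                o_fits = []
                for cp in copies:
                    frame = excl.for_outcome(outcome, cp)
                    o_fits.append(fit_modified_poisson(frame, o_spec, SurveyDesign.from_frame(frame)))
                pooled_overall[outcome] = rubin_pool(o_fits, single_ok=config.n_imputations == 1)
                pooled_overall[outcome].spec = o_spec

        stage = "interaction surfaces"
        profile = _weighted_profile(copies, config.covariates)
        groups_present = [
            g for g in pd.unique(copies[0]["race"]) if g != config.referent_race
        ]
        groups = [g for g in RACE_CATEGORIES if g in groups_present]

        t2_rows, t3_rows, t4_rows = [], [], []
        for oi, outcome in enumerate(config.outcomes):
            fit = pooled[outcome]
            if config.fit_overall:
                exposure_term = "elevated_aces" if config.exposure == "elevated" else "ace_score"
                o_fit = pooled_overall[outcome]
                est = float(np.exp(o_fit.params[exposure_term]))
                se = float(o_fit.se()[exposure_term])
                crit = sps.norm.ppf(0.975)
                log_est = float(o_fit.params[exposure_term])
                t2_rows.append(
                    {"outcome": outcome, "group": "Overall", "estimate": est,
                     "ci_low": float(np.exp(log_est - crit * se)),
                     "ci_high": float(np.exp(log_est + crit * se))}
                )
            for gi, group in enumerate([*groups, config.referent_race]):
                rr = within_group_rr(fit, group, config.referent_race)
                t2_rows.append(
                    {"outcome": outcome, "group": group, "estimate": rr.estimate,
                     "ci_low": rr.ci_low, "ci_high": rr.ci_high}
                )
            for gi, group in enumerate(groups):
                ir = interaction_rr(fit, group, config.referent_race)
                t3_rows.append(
                    {"outcome": outcome, "group": group, "estimate": ir.estimate,
                     "ci_low": ir.ci_low, "ci_high": ir.ci_high}
                )
                ec_seed = _child_seed(config.seed, 2, oi, gi)
                kwargs = {}
                if config.r00_method == "marginal":
                    # design rows of the doubly-unexposed cell, stacked over copies
                    blocks, wts = [], []
                    exposure_col = fit.spec.exposure_column
                    for cp in copies:
                        frame = excl.for_outcome(outcome, cp)
                        sub = frame.loc[
                            (frame["race"] == config.referent_race) & (frame[exposure_col] == 0)
                        ]
                        if len(sub):
                            X, _ = build_design_matrix(sub, fit.spec)
                            blocks.append(X.to_numpy())
                            wts.append(sub["weight"].to_numpy(dtype=float))
                    kwargs["r00_rows"] = np.vstack(blocks)
                    kwargs["r00_weights"] = np.concatenate(wts)
                res = excess_cases(
                    fit, group, baseline_profile=profile,
                    n_resamples=config.n_resamples, seed=ec_seed,
                    referent=config.referent_race, **kwargs,
                )
                t4_rows.append(
                    {"outcome": outcome, "group": group,
                     "estimate": res.excess_per_1000.estimate,
                     "ci_low": res.excess_per_1000.ci_low,
                     "ci_high": res.excess_per_1000.ci_high,
                     "reri": res.reri, "r00": res.r00,
                     "n_resamples": res.n_resamples, "seed": res.seed}
                )

        stage = "reporting"
        t_cols2 = ["outcome", "group", "estimate", "ci_low", "ci_high"]
        t_cols4 = [*t_cols2, "reri", "r00", "n_resamples", "seed"]
        table1 = _table1(copies, excl) if config.outcomes else pd.DataFrame()
        table2 = pd.DataFrame(t2_rows, columns=t_cols2)
        table3 = pd.DataFrame(t3_rows, columns=t_cols2)
        table4 = pd.DataFrame(t4_rows, columns=t_cols4)

        manifest = {
            "package_version": __version__,
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "exclusions": excl.log,
            "n_imputations": imp.m,
            "imputation_seeds": imp.seeds,
            "imputed_fields": list(imp.imputed_fields),
            "outcomes": list(config.outcomes),
            "referent_race": config.referent_race,
            "exposure": config.exposure,
            "n_resamples": config.n_resamples,
            "note": "one model per outcome; no multiplicity adjustment (CI-based interpretation)",
        }
        return ReportBundle(
            table1=table1, table2=table2, table3=table3, table4=table4,
            pooled=pooled, manifest=manifest, config=config,
        )
    except Exception as exc:
        # attach the failing stage without changing the exception type
        exc.args = (f"[stage: {stage}] {exc}",)
        raise
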