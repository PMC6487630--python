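"""End-to-end analysis pipeline.

Stage order: estimated fetal weight -> internal reference charts and SDS ->
growth patterns -> conditional growth variables -> trajectory models ->
adiposity indices -> covariate imputation -> association models -> Rubin
pooling -> reports.  Deterministic given the configuration seed; every
stage logs its inclusion counts into a run log.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, anthro, association, conditional, indices, patterns, trajectories
from .association import BASIC_COVARIATES, MAIN_COVARIATES, results_frame
from .imputation import impute_covariates
from .io import PipelineConfig, read_cohort, read_observations
from .reference import ReferenceChart, classify_birth_size, fit_reference
from .synthetic import SimConfig, simulate_cohort

log = logging.getLogger(__name__)


def derive_efw(wide: pd.DataFrame) -> pd.DataFrame:
    """Estimated fetal weight (g) at the two ultrasound visits."""
    out = pd.DataFrame(index=wide.index)
    out["efw_20w_g"] = anthro.estimated_fetal_weight(
        wide["hc_20w_cm"], wide["ac_20w_cm"], wide["fl_20w_cm"], wide["ga_20w_wk"]
    )
    out["efw_30w_g"] = anthro.estimated_fetal_weight(
        wide["hc_30w_cm"], wide["ac_30w_cm"], wide["fl_30w_cm"], wide["ga_30w_wk"]
    )
    return out


def fit_charts(wide: pd.DataFrame, efw: pd.DataFrame, config: PipelineConfig) -> dict[str, ReferenceChart]:
    """Internal reference charts fitted on the cohort itself.

    Fetal EFW: log transform on gestational age, not sex adjusted.  Birth
    weight: by gestational age at birth, sex specific.  Infant weight: by
    age in months (all three visits stacked), sex specific.
    """
    fetal_sample = pd.DataFrame(
        {
            "age": pd.concat([wide["ga_20w_wk"], wide["ga_30w_wk"]], ignore_index=True),
            "value": pd.concat([efw["efw_20w_g"], efw["efw_30w_g"]], ignore_index=True),
        }
    )
    charts = {
        "efw": fit_reference(
            fetal_sample, "efw", "gestational-weeks", transform="log",
            n_bins=config.fetal_bins, min_per_bin=config.min_per_bin,
        ),
        "birth_weight": fit_reference(
            pd.DataFrame({"age": wide["birth_ga_wk"], "sex": wide["sex"], "value": wide["birth_weight_g"]}),
            "birth_weight", "gestational-weeks", sex_specific=True,
            n_bins=config.birth_bins, min_per_bin=config.min_per_bin,
        ),
        "infant_weight": fit_reference(
            pd.DataFrame(
                {
                    "age": pd.concat([wide["age_6mo_mo"], wide["age_12mo_mo"], wide["age_24mo_mo"]], ignore_index=True),
                    "sex": pd.concat([wide["sex"]] * 3, ignore_index=True),
                    "value": pd.concat(
                        [wide["weight_6mo_kg"], wide["weight_12mo_kg"], wide["weight_24mo_kg"]], ignore_index=True
                    ),
                }
            ),
            "infant_weight", "postnatal-months", sex_specific=True,
            n_bins=config.infant_bins, min_per_bin=config.min_per_bin,
            # bins must not straddle the empty gaps between visit clusters
            bin_edges=_infant_bin_edges(wide, max(config.infant_bins // 3, 1)),
        ),
    }
    return charts


def _infant_bin_edges(wide: pd.DataFrame, bins_per_visit: int) -> np.ndarray:
    """Quantile bin edges within each infant visit cluster, with cluster
    boundaries placed at the midpoint of the empty gap between visits."""
    out: list[float] = []
    prev_max = None
    for col in ("age_6mo_mo", "age_12mo_mo", "age_24mo_mo"):
        ages = wide[col].dropna().to_numpy(dtype=float)
        if ages.size == 0:
            continue
        e = np.quantile(ages, np.linspace(0, 1, bins_per_visit + 1))
        out.append(e[0] if prev_max is None else (prev_max + e[0]) / 2.0)
        out.extend(e[1:-1])
        prev_max = e[-1]
    out.append(prev_max)
    return np.unique(np.asarray(out, dtype=float))


def derive_sds(wide: pd.DataFrame, efw: pd.DataFrame, charts: dict[str, ReferenceChart]) -> pd.DataFrame:
    """Weight SDS at the six ordered time points."""
    sex = wide["sex"].to_numpy(dtype=object)
    out = pd.DataFrame(index=wide.index)
    out["sds_20w"] = charts["efw"].zscore(efw["efw_20w_g"], wide["ga_20w_wk"])
    out["sds_30w"] = charts["efw"].zscore(efw["efw_30w_g"], wide["ga_30w_wk"])
    out["sds_birth"] = charts["birth_weight"].zscore(wide["birth_weight_g"], wide["birth_ga_wk"], sex)
    out["sds_6mo"] = charts["infant_weight"].zscore(wide["weight_6mo_kg"], wide["age_6mo_mo"], sex)
    out["sds_12mo"] = charts["infant_weight"].zscore(wide["weight_12mo_kg"], wide["age_12mo_mo"], sex)
    out["sds_24mo"] = charts["infant_weight"].zscore(wide["weight_24mo_kg"], wide["age_24mo_mo"], sex)
    return out


def build_covariates(wide: pd.DataFrame) -> pd.DataFrame:
    """Numeric covariate design (binary covariates 0/1, NaN = missing)."""
    out = pd.DataFrame(index=wide.index)
    out["child_age_yr"] = wide["child_age_yr"]
    out["sex_boy"] = (wide["sex"].astype(str) == "boy").astype(float)
    out["maternal_age"] = wide["maternal_age"]
    out["education_low"] = wide["education"].map({"lower": 1.0, "higher": 0.0})
    out["prepregnancy_bmi"] = wide["prepregnancy_bmi"]
    out["smoking"] = wide["smoking"].map({"yes": 1.0, "no": 0.0})
    out["folic_acid"] = wide["folic_acid"].map({"yes": 1.0, "no": 0.0})
    out["parity_multi"] = wide["parity"].astype(float).clip(upper=1.0)
    out["non_european"] = wide["ethnicity"].map({"non_european": 1.0, "european": 0.0})
    out["breastfed_ever"] = wide["breastfeeding"].map({"ever": 1.0, "never": 0.0})
    return out


def build_body_composition(wide: pd.DataFrame) -> pd.DataFrame:
    """Childhood body-composition inputs for the adiposity indices."""
    out = pd.DataFrame(index=wide.index)
    out["height_cm"] = wide["height_cm"]
    out["weight_kg"] = wide["weight_kg"]
    out["fat_mass_kg"] = wide["fat_mass_kg"]
    out["fat_free_mass_kg"] = wide["fat_free_mass_kg"]
    out["visceral_fat_g"] = anthro.fat_volume_to_mass(wide["visceral_fat_vol_ml"])
    out["pericardial_fat_g"] = anthro.fat_volume_to_mass(wide["pericardial_fat_vol_ml"])
    samples = wide[["liver_fat_pct_s1", "liver_fat_pct_s2", "liver_fat_pct_s3", "liver_fat_pct_s4"]]
    with np.errstate(invalid="ignore"):
        out["liver_fat_pct"] = samples.mean(axis=1, skipna=True)
    return out


@dataclass
class PipelineResult:
    config: PipelineConfig
    wide: pd.DataFrame
    sds: pd.DataFrame
    charts: dict
    pattern_table: pd.DataFrame
    conditional_vars: pd.DataFrame | None
    derived: pd.DataFrame | None  # per-child PWV / AGEAP / BMIAP
    outcome_panel: pd.DataFrame
    results: dict = field(default_factory=dict)
    run_log: dict = field(default_factory=dict)
    paths: dict = field(default_factory=dict)


def _fmt_ci(r) -> str:
    if np.isnan(r.estimate):
        return "skipped"
    return f"{r.estimate:.2f} ({r.ci_low:.2f} to {r.ci_high:.2f})"


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run_log: dict = {
        "package_version": __version__,
        "versions": {m.__name__: m.__version__ for m in (np, pd)},
        "seed": config.seed,
        "stages": {},
    }
    paths: dict = {}

    # -- stage: input ------------------------------------------------------
    if config.simulate is not None:
        sim_kwargs = dict(config.simulate)
        sim_kwargs.setdefault("seed", config.seed)
        cohort = simulate_cohort(SimConfig(**sim_kwargs))
        wide, observations = cohort.wide, cohort.observations
        paths["cohort"] = str(outdir / "cohort.csv")
        paths["observations"] = str(outdir / "observations.csv")
        wide.to_csv(paths["cohort"], index=False)
        observations.to_csv(paths["observations"], index=False)
    else:
        wide = read_cohort(config.cohort_path)
        observations = read_observations(config.observations_path) if config.observations_path else None
    n = len(wide)
    run_log["stages"]["cohort"] = {"n_children": n}

    # -- stage: SDS --------------------------------------------------------
    efw = derive_efw(wide)
    if config.chart_source == "file":
        frame = pd.read_csv(config.chart_path)
        charts = {m: ReferenceChart.from_frame(g) for m, g in frame.groupby("measure")}
    elif config.chart_source == "generating":
        from .synthetic import true_reference_charts

        charts = true_reference_charts()
    else:
        charts = fit_charts(wide, efw, config)
    sds = derive_sds(wide, efw, charts)
    run_log["stages"]["sds"] = {c: int(sds[c].notna().sum()) for c in sds.columns}

    # -- stage: growth patterns -------------------------------------------
    pattern_tab = patterns.pattern_table(sds, threshold=config.centile_threshold)
    counts = patterns.pattern_counts(pattern_tab["pattern"])
    run_log["stages"]["patterns"] = {
        "eligible_n": int(pattern_tab["pattern"].notna().sum()),
        "group_counts": {k: int(v) for k, v in counts.items()},
        "infant_source": {str(k): int(v) for k, v in pattern_tab["infant_source"].value_counts().items()},
    }

    # -- stage: birth size -------------------------------------------------
    from scipy import stats as _st

    birth_size = classify_birth_size(
        sds["sds_birth"].to_numpy(),
        sga_cutoff=float(_st.norm.ppf(config.sga_percentile)),
        lga_cutoff=float(_st.norm.ppf(config.lga_percentile)),
    )
    run_log["stages"]["birth_size"] = {
        str(k): int(v) for k, v in pd.Series(birth_size).value_counts().items()
    }

    # -- stage: conditional growth ----------------------------------------
    cond = conditional.conditional_variables(sds) if config.run_conditional else None

    # -- stage: trajectories ----------------------------------------------
    derived = None
    if config.run_trajectories and observations is not None and not observations.empty:
        obs = observations.copy()
        obs["age_yr"] = obs["age_mo"] / 12.0
        reed_fit = trajectories.fit_reed1(obs, method=config.trajectory_method)
        pwv = trajectories.peak_weight_velocity(reed_fit)
        obs["bmi"] = anthro.bmi(obs["weight_kg"], obs["length_cm"])
        cubic_fit = trajectories.fit_logbmi_cubic(obs)
        peak = trajectories.adiposity_peak(cubic_fit)
        derived = pwv.merge(peak.drop(columns=["sex", "flag"]), on="child_id", how="outer")
        run_log["stages"]["trajectories"] = {
            "reed1_children": int(len(pwv)),
            "reed1_interior_peaks": int((pwv["flag"] == "interior").sum()),
            "reed1_converged": {k: bool(v) for k, v in reed_fit.converged.items()},
            "cubic_children": int(len(peak)),
            "cubic_interior_peaks": int((peak["flag"] == "interior").sum()),
            "cubic_converged": bool(cubic_fit.converged),
        }

    # -- stage: adiposity indices -----------------------------------------
    body = build_body_composition(wide)
    panel = indices.build_outcomes(body)
    powers = []
    for measure, col in (
        ("fat_mass", "fat_mass_kg"),
        ("fat_free_mass", "fat_free_mass_kg"),
        ("visceral_fat", "visceral_fat_g"),
        ("pericardial_fat", "pericardial_fat_g"),
    ):
        try:
            powers.append(indices.estimate_power(body[col], body["height_cm"] / 100.0, measure=measure))
        except Exception as exc:  # diagnostics only; small cohorts may lack data
            log.warning("estimate_power(%s) skipped: %s", measure, exc)
    run_log["stages"]["outcomes"] = {c: int(panel[c].notna().sum()) for c in panel.columns if c.endswith("_sds")}

    # -- stage: imputation + association models ----------------------------
    impute_seed = int(np.random.SeedSequence(config.seed).generate_state(1)[0] % (2**31))
    covs = build_covariates(wide)
    main_missing = [c for c in MAIN_COVARIATES if covs[c].isna().any()]
    if main_missing:
        imputed = impute_covariates(
            covs, covariates=main_missing, m=config.imputation_m,
            seed=impute_seed, burn_in=config.imputation_burn_in,
        )
    else:
        imputed = [covs.copy() for _ in range(config.imputation_m)]
    run_log["stages"]["imputation"] = {"m": config.imputation_m, "imputed_covariates": main_missing}

    def analysis_frame(cov_ds: pd.DataFrame) -> pd.DataFrame:
        parts = [panel.filter(like="_sds"), cov_ds]
        parts.append(pattern_tab[["fetal_delta", "infant_delta", "pattern"]])
        if cond is not None:
            parts.append(cond)
        if derived is not None:
            dmap = derived.set_index("child_id")[["pwv_kg_per_yr", "bmiap", "ageap_mo"]]
            parts.append(dmap.reindex(wide["child_id"]).set_axis(wide.index))
        frame = pd.concat(parts, axis=1)
        frame["birth_size"] = birth_size
        frame["birth_weight_g"] = wide["birth_weight_g"]
        return frame

    datasets = [analysis_frame(ds) for ds in imputed]
    adjust = BASIC_COVARIATES + MAIN_COVARIATES
    results: dict = {}

    if config.run_conditional and cond is not None:
        def fit_cond(ds):
            out = []
            for outcome in config.outcomes:
                out.extend(
                    conditional.critical_period_model(
                        ds[cond.columns], ds[outcome], ds[adjust], model_tag="conditional-main"
                    )
                )
            return out

        results["conditional"] = association.fit_pooled(datasets, fit_cond)

    if config.run_patterns:
        def fit_pat(ds):
            out = []
            for outcome in config.outcomes:
                out.extend(association.pattern_model(ds, outcome, covariates=adjust))
            return out

        results["patterns"] = association.fit_pooled(datasets, fit_pat)
        results["interaction_p"] = {
            outcome: association.interaction_test(datasets[0], outcome) for outcome in config.outcomes
        }

    if config.run_stratified and derived is not None:
        strat_cov = adjust + ["birth_weight_g"]

        def fit_strat(ds):
            out = []
            for outcome in config.outcomes:
                out.extend(
                    association.stratified_infant_models(
                        ds, outcome, covariates=strat_cov, min_stratum_n=config.min_stratum_n
                    )
                )
            return out

        results["stratified"] = association.fit_pooled(datasets, fit_strat)

    # -- reports -----------------------------------------------------------
    paths["sds"] = str(outdir / "sds.csv")
    sds_out = pd.concat([wide[["child_id"]], sds], axis=1)
    sds_out.to_csv(paths["sds"], index=False)
    paths["charts"] = str(outdir / "charts.csv")
    pd.concat([c.to_frame() for c in charts.values()], ignore_index=True).to_csv(paths["charts"], index=False)
    paths["patterns"] = str(outdir / "patterns.csv")
    pd.concat([wide[["child_id"]], pattern_tab], axis=1).to_csv(paths["patterns"], index=False)
    if cond is not None:
        paths["conditional"] = str(outdir / "conditional_variables.csv")
        pd.concat([wide[["child_id"]], cond], axis=1).to_csv(paths["conditional"], index=False)
    if derived is not None:
        paths["derived"] = str(outdir / "derived_trajectories.csv")
        derived.to_csv(paths["derived"], index=False)
    paths["outcomes"] = str(outdir / "outcome_panel.csv")
    pd.concat([wide[["child_id"]], panel], axis=1).to_csv(paths["outcomes"], index=False)
    if powers:
        paths["allometric_powers"] = str(outdir / "allometric_powers.csv")
        pd.DataFrame([vars(p) for p in powers]).to_csv(paths["allometric_powers"], index=False)

    for key in ("conditional", "patterns", "stratified"):
        if key in results:
            paths[f"results_{key}"] = str(outdir / f"results_{key}.csv")
            results_frame(results[key]).to_csv(paths[f"results_{key}"], index=False)

    if "conditional" in results:
        tab = results_frame(results["conditional"])
        tab["cell"] = [_fmt_ci(r) for r in results["conditional"]]
        wide_tab = tab.pivot(index="exposure", columns="outcome", values="cell")
        order = [c for c in ("cond_20w", "cond_30w", "cond_birth", "cond_6mo", "cond_12mo", "cond_24mo") if c in wide_tab.index]
        paths["table_critical_periods"] = str(outdir / "table_critical_periods.csv")
        wide_tab.loc[order].to_csv(paths["table_critical_periods"])
    if "patterns" in results:
        tab = results_frame(results["patterns"])
        tab["cell"] = [_fmt_ci(r) for r in results["patterns"]]
        wide_tab = tab.pivot(index="exposure", columns="outcome", values="cell")
        order = ["pat:" + lv for lv in patterns.PATTERN_LEVELS if lv != patterns.REFERENCE_PATTERN]
        wide_tab = wide_tab.loc[[o for o in order if o in wide_tab.index]]
        inter = pd.DataFrame(
            {k: [f"p={v:.3g}"] for k, v in results["interaction_p"].items()}, index=["interaction"]
        )
        paths["table_patterns"] = str(outdir / "table_patterns.csv")
        pd.concat([wide_tab, inter]).to_csv(paths["table_patterns"])
    if "stratified" in results:
        tab = results_frame(results["stratified"])
        tab["cell"] = [_fmt_ci(r) for r in results["stratified"]]
        tab["row"] = tab["stratum"] + " / " + tab["exposure"]
        paths["table_stratified"] = str(outdir / "table_stratified.csv")
        tab.pivot(index="row", columns="outcome", values="cell").to_csv(paths["table_stratified"])

    paths["run_log"] = str(outdir / "run_log.json")
    with open(paths["run_log"], "w") as fh:
        json.dump(run_log, fh, indent=2)

    return PipelineResult(
        config=config, wide=wide, sds=sds, charts=charts, pattern_table=pattern_tab,
        conditional_vars=cond, derived=derived, outcome_panel=panel,
        results=results, run_log=run_log, paths=paths,
    )
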