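"""End-to-end orchestration: traces -> metrics -> fish samples -> models -> community.

A single config (YAML or dict) drives the run.  Inputs are either a directory
of field CSVs (logger traces, surveys, length-weight coefficients, sediment)
or a synthetic-study block; exactly one of the two must be present.  Outputs
are plain CSV/JSON: per-transect complexity metrics, variograms, the
model-selection table in the long coefficient format, community-analysis
results, and a run manifest with seeds and warning counts.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import community_structure as cs
from . import complexity_metrics as cm
from . import fish_metrics as fm
from . import habitat_glm as hg
from . import synthetic_data as sd
from . import trace_processing as tp

log = logging.getLogger("reefscape")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    output_dir: str = "reefscape_out"
    input_dir: str | None = None         # field-data CSV directory
    synthetic: dict | None = None        # StudyConfig overrides
    seed: int = 0
    alpha: float = 0.05
    marginal_alpha: float = 0.10
    n_permutations: int = 1000
    nmds_restarts: int = 20
    richness_mode: str = "averaged"
    transect_length: float = 30.0

    def __post_init__(self):
        if (self.input_dir is None) == (self.synthetic is None):
            raise ValueError(
                "config must set exactly one of input_dir / synthetic")


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig(**raw)


# ---------------------------------------------------------------------------
# input validation

def validate_inputs(config: PipelineConfig) -> list[str]:
    """Schema, unit-sanity, and cross-file referential checks.

    All violations are aggregated and returned at once (empty list = clean).
    """
    violations: list[str] = []
    if config.synthetic is not None:
        return violations
    root = Path(config.input_dir)
    surveys = coeffs = None
    try:
        surveys = fm.read_survey_csv(root / "surveys.csv")
    except Exception as exc:
        violations.append(f"surveys.csv: {exc}")
    try:
        coeffs = fm.read_coefficients_csv(root / "coefficients.csv")
    except Exception as exc:
        violations.append(f"coefficients.csv: {exc}")
    trace_dir = root / "traces"
    trace_sites = set()
    if not trace_dir.is_dir():
        violations.append("traces/ directory missing")
    else:
        for f in sorted(trace_dir.glob("*.csv")):
            try:
                trace = tp.read_logger_csv(f)
                if np.any(trace.pressure_psi <= 10):
                    violations.append(f"{f.name}: pressure <= 10 PSI (unit error?)")
                trace_sites.add(f.stem.split("_")[0])
            except Exception as exc:
                violations.append(f"{f.name}: {exc}")
    if surveys is not None:
        bad = surveys[(surveys["length_cm_min"] < 1) | (surveys["count"] < 1)]
        for idx in bad.index:
            violations.append(f"surveys.csv row {idx}: length < 1 cm or count < 1")
        for site in sorted(set(surveys["site"]) - trace_sites):
            violations.append(f"survey site {site} has no logger trace")
        if coeffs is not None:
            known_fams = set(coeffs["family"])
            for fam in sorted(set(surveys["family"]) - known_fams):
                violations.append(f"family {fam} unresolvable from coefficients")
    return violations


# ---------------------------------------------------------------------------
# stages

def _load_inputs(config: PipelineConfig):
    if config.synthetic is not None:
        block = dict(config.synthetic)
        block.setdefault("seed", config.seed)
        study = sd.gen_study(sd.StudyConfig(**block))
        return study
    root = Path(config.input_dir)
    surveys = fm.read_survey_csv(root / "surveys.csv")
    coeffs = fm.read_coefficients_csv(root / "coefficients.csv")
    sediment_path = root / "sediment.csv"
    sediment = fm.read_sediment_csv(sediment_path) if sediment_path.exists() else pd.DataFrame()
    sites = pd.read_csv(root / "sites.csv")
    traces = {}
    for f in sorted((root / "traces").glob("*.csv")):
        site, season, tname = f.stem.rsplit("_", 2)
        traces[(site, season, int(tname.lstrip("T")))] = tp.read_logger_csv(f)
    env = pd.read_csv(root / "transect_env.csv") if (root / "transect_env.csv").exists() else None
    return sd.StudyData(sites=sites, traces=traces, true_profiles={},
                        surveys=surveys, sediment=sediment,
                        coefficients=coeffs, transect_env=env)


def process_traces_stage(study: sd.StudyData, config: PipelineConfig):
    """Trace -> profile -> complexity metrics + mean temperature per transect."""
    rows, profiles, variograms = [], {}, {}
    for key in sorted(study.traces):
        site, season, transect = key
        try:
            profile, _cal = tp.process_trace(study.traces[key],
                                             transect_length=config.transect_length)
            metrics = cm.compute_metrics(cm.resample_uniform(profile, 0.1))
            variograms[key] = cm.semivariogram(profile)
        except Exception as exc:
            raise PipelineError("trace_processing", f"{key}: {exc}") from exc
        profiles[key] = profile
        rows.append({"site": site, "season": season, "transect": transect,
                     "drr_m": metrics.drr, "c": metrics.c,
                     "relief_m": metrics.vertical_relief,
                     "depth_m": metrics.depth_mean,
                     "depth_min_m": metrics.depth_min,
                     "depth_max_m": metrics.depth_max,
                     "temp_c": tp.mean_temperature(study.traces[key])})
    metrics_df = pd.DataFrame(rows)
    site_info = study.sites[["site", "reef_type", "morphology"]]
    metrics_df = metrics_df.merge(site_info, on="site", how="left")
    return metrics_df, profiles, variograms


def fit_stage(samples: pd.DataFrame, config: PipelineConfig):
    """AIC model selection + pattern classification per response x reef type."""
    entries, selection = [], {}
    families = {"abundance": "negative_binomial", "biomass_kg": "gamma",
                "richness": "poisson"}
    for reef_type in ("natural", "artificial"):
        sub = samples[samples["reef_type"] == reef_type]
        drr_range = (sub["drr"].min(), sub["drr"].max())
        for response, family in families.items():
            specs = hg.candidate_specs(response, family, reef_type)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    best, table = hg.model_select(samples, specs)
            except (hg.ConvergenceError, ValueError) as exc:
                raise PipelineError("habitat_glm",
                                    f"{response}/{reef_type}: {exc}") from exc
            cls = hg.classify_pattern(best, drr_range, alpha=config.alpha,
                                      marginal_alpha=config.marginal_alpha)
            entries.append((response, reef_type, best, cls))
            selection[f"{response}_{reef_type}"] = {
                "best": "+".join(best.spec.predictors) or "intercept",
                "aic_table": table.to_dict(orient="records"),
            }
    return hg.results_table(entries), selection


def community_stage(study: sd.StudyData, env: pd.DataFrame,
                    config: PipelineConfig):
    """Bray-Curtis + PERMANOVA + nMDS + indicators + morphology ANOVAs."""
    sqrt_mat, groups = fm.family_abundance_matrix(study.surveys, env,
                                                  sqrt_transform=True)
    raw_mat, _ = fm.family_abundance_matrix(study.surveys, env,
                                            sqrt_transform=False)
    keep = sqrt_mat.sum(axis=1) > 0
    sqrt_mat, raw_mat, groups = sqrt_mat[keep], raw_mat[keep], groups[keep]
    D = cs.bray_curtis(sqrt_mat)
    perm = cs.permanova(D, groups.to_numpy(), n_perm=config.n_permutations,
                        seed=config.seed)
    ordination = cs.nmds(D, k=2, n_restarts=config.nmds_restarts,
                         seed=config.seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        indicators = cs.indicator_analysis(raw_mat, groups.to_numpy(),
                                           n_perm=config.n_permutations,
                                           seed=config.seed, max_combo_size=2)
    return D, perm, ordination, indicators, sqrt_mat.index


def anova_stage(samples: pd.DataFrame):
    out = {}
    for metric, transform in (("abundance", "log"), ("biomass_kg", "log"),
                              ("richness", "none")):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = cs.morphology_anova(samples[metric].to_numpy(),
                                      samples["morphology"].to_numpy(),
                                      transform=transform)
        out[metric] = {"f": res.f, "df": list(res.df), "p": res.p_value,
                       "posthoc": res.posthoc.to_dict(orient="records")}
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and write CSV/JSON outputs + a run manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": config.seed, "warnings": {}, "stages": []}

    study = _load_inputs(config)
    log.info("loaded inputs: %d traces, %d survey records",
             len(study.traces), len(study.surveys))
    manifest["stages"].append("load_inputs")

    if study.traces:
        metrics_df, profiles, variograms = process_traces_stage(study, config)
    elif study.transect_env is not None:
        metrics_df = study.transect_env.rename(columns={})
        profiles, variograms = {}, {}
    else:
        raise PipelineError("trace_processing", "no traces and no transect_env")
    log.info("trace processing: %d transects", len(metrics_df))
    manifest["stages"].append("trace_processing")
    metrics_df.to_csv(out / "transect_metrics.csv", index=False)
    for key, vg in variograms.items():
        cm.write_variogram_csv(vg, out / f"variogram_{key[0]}_{key[1]}_T{key[2]}.csv")

    env_cols = ["site", "season", "transect", "drr_m", "depth_m", "temp_c",
                "reef_type", "morphology"]
    env = metrics_df[env_cols]
    try:
        samples = fm.build_samples(study.surveys, study.coefficients, env,
                                   sediment=study.sediment if len(study.sediment) else None,
                                   richness_mode=config.richness_mode)
    except fm.UnresolvedTaxonError as exc:
        raise PipelineError("fish_metrics", str(exc)) from exc
    manifest["stages"].append("fish_metrics")
    samples.to_csv(out / "samples.csv", index=False)
    manifest["community_summary"] = fm.community_summary(study.surveys,
                                                         study.coefficients)
    manifest["warnings"]["family_fallback_records"] = int(
        samples["n_family_fallback"].sum())

    model_table, selection = fit_stage(samples, config)
    log.info("fitted %d response x reef-type model families", len(selection))
    manifest["stages"].append("habitat_glm")
    model_table.to_csv(out / "model_table.csv", index=False)
    with open(out / "model_selection.json", "w") as fh:
        json.dump(selection, fh, indent=2, default=float)

    D, perm, ordination, indicators, index = community_stage(study, env, config)
    manifest["stages"].append("community_structure")
    pd.DataFrame(D, index=index, columns=index).to_csv(out / "bray_curtis.csv")
    coords = pd.DataFrame(ordination.coordinates, index=index,
                          columns=["nmds1", "nmds2"])
    coords.to_csv(out / "ordination.csv")
    indicators.to_csv(out / "indicators.csv", index=False)
    anovas = anova_stage(samples)
    report = {
        "permanova": {"pseudo_f": perm.pseudo_f, "p": perm.p_value,
                      "df": [perm.df_between, perm.df_within]},
        "nmds_stress": ordination.stress,
        "anova": anovas,
    }
    with open(out / "community_report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)

    manifest["n_samples"] = int(len(samples))
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=float)
    return {"manifest": manifest, "samples": samples,
            "model_table": model_table, "community": report}
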