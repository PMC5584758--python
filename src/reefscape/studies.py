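"""Simulation studies validating the pipeline against planted ground truth.

These are the package's own calibration experiments: round-trip recovery of
rugosity through the logger-trace pipeline, power and type-I behaviour of the
unimodal pattern classification, exactness of the permutation machinery, and
calibration of the predictive-distribution goodness-of-fit P-values.  Both
the test suite and the reproduction script run them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import community_structure as cs
from . import habitat_glm as hg
from . import synthetic_data as sd
from .complexity_metrics import digital_reef_rugosity, resample_uniform
from .trace_processing import process_trace


# ---------------------------------------------------------------------------
# round-trip: profile -> logger trace -> recovered profile

def round_trip_drr(seeds=range(1, 21), pressure_noise_sd: float = 0.02,
                   swim_speed_sd: float = 1.5) -> pd.DataFrame:
    """Planted vs recovered DRR across morphologies, one transect per seed.

    The recovered profile comes from the full trace pipeline (spike detection,
    distance calibration, spike removal) applied to a generated 1 Hz trace
    with variable swim speed and hydrostatic pressure noise.
    """
    rows = []
    morphs = ["pavement_rubble", "ledge", "concrete", "ship"]
    for i, seed in enumerate(seeds):
        morph = morphs[i % len(morphs)]
        relief = {"pavement_rubble": 0.4, "ledge": 2.0,
                  "concrete": 1.0, "ship": 5.0}[morph]
        scen = sd.ReefScenario(morphology=morph, base_depth=20.0,
                               relief_amplitude=relief, roughness_sd=0.1,
                               seed=seed)
        profile = sd.gen_reef_profile(scen, resolution=0.1)
        trace = sd.gen_logger_trace(profile, swim_speed_sd=swim_speed_sd,
                                    pressure_noise_sd=pressure_noise_sd,
                                    seed=seed + 1000)
        recovered, _ = process_trace(trace)
        drr_true = digital_reef_rugosity(resample_uniform(profile, 0.1))
        drr_rec = digital_reef_rugosity(resample_uniform(recovered, 0.1))
        rows.append({"seed": seed, "morphology": morph, "drr_true": drr_true,
                     "drr_recovered": drr_rec,
                     "rel_error": abs(drr_rec - drr_true) / drr_true})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# GLM pattern recovery and type-I control

def simulate_abundance_samples(n_sites: int, model: sd.FishGenModel,
                               rng: np.random.Generator,
                               drr_range=(0.1, 1.0)) -> pd.DataFrame:
    """Replicate-level abundance samples from the planted count model.

    DRR spans the natural-reef range, depth and temperature their field
    ranges; the response is the negative-binomial total count.
    """
    drr = rng.uniform(*drr_range, size=n_sites)
    depth = rng.uniform(10.0, 30.0, size=n_sites)
    temp = rng.uniform(16.0, 27.0, size=n_sites)
    mu = np.array([model.mean(d, z, t) for d, z, t in zip(drr, depth, temp)])
    y = np.array([model.draw_total(m, rng) for m in mu])
    return pd.DataFrame({"drr": drr, "depth": depth, "temperature": temp,
                         "abundance": y, "reef_type": "natural",
                         "sediment_sd": np.nan})


_ABUNDANCE_SPEC = hg.ModelSpec(response="abundance", family="negative_binomial",
                               predictors=("drr", "drr2", "depth"),
                               reef_type="natural")


def unimodal_recovery(n_sites: int = 67, seeds=range(1, 51),
                      model: sd.FishGenModel | None = None) -> pd.DataFrame:
    """Classification and vertex recovery under a planted unimodal model."""
    if model is None:
        model = sd.FishGenModel(beta0=2.0, beta1=6.0, beta2=-6.0,
                                beta_depth=0.1, beta_temp=0.0)
    vertex = -model.beta1 / (2.0 * model.beta2)
    rows = []
    for seed in seeds:
        rng = np.random.default_rng(seed)
        samples = simulate_abundance_samples(n_sites, model, rng)
        fit = hg.fit_glm(samples, _ABUNDANCE_SPEC)
        cls = hg.classify_pattern(fit, (samples["drr"].min(), samples["drr"].max()))
        err = (abs(cls.inflection - vertex) / abs(vertex)
               if cls.inflection is not None else np.nan)
        rows.append({"seed": seed, "pattern": cls.pattern,
                     "inflection": cls.inflection, "rel_vertex_error": err})
    return pd.DataFrame(rows)


def null_unimodal_rate(n_sims: int = 500, n_sites: int = 67,
                       seed: int = 0) -> float:
    """Fraction of null simulations (beta1 = beta2 = 0) classified unimodal."""
    model = sd.FishGenModel(beta0=4.0, beta1=0.0, beta2=0.0,
                            beta_depth=0.05, beta_temp=0.0)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_sims):
        samples = simulate_abundance_samples(n_sites, model, rng)
        fit = hg.fit_glm(samples, _ABUNDANCE_SPEC)
        cls = hg.classify_pattern(fit, (samples["drr"].min(), samples["drr"].max()))
        hits += cls.pattern == "unimodal"
    return hits / n_sims


# ---------------------------------------------------------------------------
# predictive-fit calibration

def predictive_pvalue_calibration(n: int = 500, seed: int = 0,
                                  shape: float = 4.0) -> float:
    """KS uniformity P-value of assess_fit P-values under a correct model.

    Simulates gamma responses with a log-link mean model, refits, and tests
    the two-sided predictive P-values for uniformity.
    """
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, 1, size=n)
    depth = rng.uniform(10, 30, size=n)
    mu = np.exp(1.0 + 0.8 * x + 0.05 * depth)
    y = rng.gamma(shape, mu / shape)
    samples = pd.DataFrame({"drr": x, "depth": depth, "biomass": y,
                            "temperature": 20.0, "reef_type": "natural",
                            "sediment_sd": np.nan})
    spec = hg.ModelSpec(response="biomass", family="gamma",
                        predictors=("drr", "depth"), reef_type="natural")
    fit = hg.fit_glm(samples, spec)
    pvals, _ = hg.assess_fit(fit)
    return float(stats.kstest(pvals, "uniform").pvalue)


# ---------------------------------------------------------------------------
# community planted signal

def simulate_community(n_per_group: int = 8, seed: int = 0,
                       morphologies=("pavement_rubble", "ledge",
                                     "concrete", "ship")):
    """Family-abundance matrix with the generator's composition contrasts.

    Returns (matrix in sqrt scale, raw matrix, group labels).
    """
    rng = np.random.default_rng(seed)
    nat = sd.DEFAULT_NATURAL_MODEL
    art = sd.DEFAULT_ARTIFICIAL_MODEL
    rows, groups = [], []
    for morph in morphologies:
        model = nat if morph in sd.NATURAL else art
        drr_rng = (0.1, 1.0) if morph in sd.NATURAL else (0.3, 3.0)
        for _ in range(n_per_group):
            drr = rng.uniform(*drr_rng)
            depth = rng.uniform(12, 30)
            fish = sd.gen_fish_survey(drr, depth, 22.0, morph, model, rng)
            counts = fish.groupby("family")["count"].sum()
            rows.append(counts.reindex(sd.FAMILIES, fill_value=0))
            groups.append(morph)
    raw = pd.DataFrame(rows).reset_index(drop=True)
    return np.sqrt(raw), raw, np.asarray(groups)


def community_signal_detection(seeds=range(1, 21), n_per_group: int = 8,
                               n_perm: int = 199) -> pd.DataFrame:
    """PERMANOVA significance and top indicators for the planted contrast."""
    rows = []
    for seed in seeds:
        sqrt_mat, raw, groups = simulate_community(n_per_group, seed)
        D = cs.bray_curtis(sqrt_mat)
        res = cs.permanova(D, groups, n_perm=n_perm, seed=seed)
        ind = cs.indicator_analysis(raw, groups, n_perm=n_perm, seed=seed,
                                    max_combo_size=2)
        ship = ind[ind["group"] == "ship"].nlargest(3, "stat")["taxon"].tolist()
        rows.append({"seed": seed, "permanova_p": res.p_value,
                     "pseudo_f": res.pseudo_f,
                     "ship_indicators": ship,
                     "pelagic_top": bool(set(ship) & {"Lutjanidae", "Scombridae",
                                                      "Carangidae"})})
    return pd.DataFrame(rows)
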