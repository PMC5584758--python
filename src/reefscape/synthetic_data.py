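"""Synthetic reef profiles, logger traces, and fish surveys with known truth.

The generator emulates the four field data streams of a temperate-reef diver
survey so every downstream stage can be tested against planted parameters:

* reef depth profiles for four morphologies — pavement-and-rubble and ledge
  (natural), concrete and ship (artificial);
* 1 Hz pressure-logger traces of a diver towing the logger along the profile
  at ~10 cm/s, including the calibration spike groups (5 at the start, 3
  every 5 m, 5 at the end) and hydrostatic pressure noise;
* belt-transect fish records whose total count follows a negative-binomial
  distribution with log-mean linear in DRR, DRR^2, depth, and temperature (a
  plantable unimodal abundance-rugosity relationship), allocated to families
  by morphology-specific composition profiles (demersal-weighted concrete vs
  pelagic-weighted ships); and
* sediment-depth point measurements every 3 m on natural reefs.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .trace_processing import (ATMOSPHERIC_PSI, GRAVITY, PSI_TO_PA,
                               SEAWATER_DENSITY, SPIKE_GROUP_SPACING_M,
                               DepthTrace, TransectProfile)

MORPHOLOGIES = ("pavement_rubble", "ledge", "concrete", "ship")
NATURAL = ("pavement_rubble", "ledge")
ARTIFICIAL = ("concrete", "ship")

SIZE_CLASS_RANGES = {
    "small": (1, 10), "medium": (11, 29), "large": (30, 49), "extra_large": (50, 80),
}

#: species pool: (species, family, a, b, size-class weights, schooling)
#: `a`/`b` are synthetic length-weight coefficients in the realistic range for
#: warm-temperate reef fishes; Decapterus sp. deliberately lacks species-level
#: coefficients in the emitted table to exercise the family fallback.
SPECIES_POOL = [
    ("Mycteroperca microlepis", "Serranidae", 0.0110, 3.04, {"medium": .4, "large": .4, "extra_large": .2}, False),
    ("Centropristis striata", "Serranidae", 0.0124, 2.97, {"small": .2, "medium": .8}, False),
    ("Haemulon aurolineatum", "Haemulidae", 0.0132, 2.95, {"small": .6, "medium": .4}, True),
    ("Halichoeres bivittatus", "Labridae", 0.0099, 3.02, {"small": .7, "medium": .3}, False),
    ("Tautoga onitis", "Labridae", 0.0141, 3.00, {"medium": 1.0}, False),
    ("Chilomycterus schoepfii", "Diodontidae", 0.0390, 2.87, {"medium": 1.0}, False),
    ("Gymnothorax moringa", "Muraenidae", 0.0012, 3.12, {"large": .6, "extra_large": .4}, False),
    ("Ptereleotris calliura", "Ptereleotridae", 0.0050, 3.05, {"small": 1.0}, False),
    ("Balistes capriscus", "Balistidae", 0.0257, 2.93, {"medium": .6, "large": .4}, False),
    ("Stegastes variabilis", "Pomacentridae", 0.0210, 2.98, {"small": 1.0}, False),
    ("Scomberomorus maculatus", "Scombridae", 0.0065, 3.08, {"large": .5, "extra_large": .5}, False),
    ("Rhomboplites aurorubens", "Lutjanidae", 0.0131, 2.99, {"small": .4, "medium": .6}, True),
    ("Lutjanus campechanus", "Lutjanidae", 0.0161, 2.96, {"medium": .5, "large": .5}, False),
    ("Decapterus sp.", "Carangidae", 0.0090, 3.02, {"small": .5, "medium": .5}, True),
    ("Seriola dumerili", "Carangidae", 0.0182, 2.95, {"large": .4, "extra_large": .6}, False),
    ("Caranx crysos", "Carangidae", 0.0150, 2.99, {"medium": .5, "large": .5}, False),
    ("Sphyraena barracuda", "Sphyraenidae", 0.0040, 3.11, {"extra_large": 1.0}, False),
    ("Carcharias taurus", "Odontaspididae", 0.0030, 3.20, {"extra_large": 1.0}, False),
    ("Hypanus americanus", "Dasyatidae", 0.0380, 2.80, {"large": .5, "extra_large": .5}, False),
]

FAMILIES = ["Serranidae", "Haemulidae", "Labridae", "Diodontidae", "Muraenidae",
            "Ptereleotridae", "Balistidae", "Pomacentridae", "Scombridae",
            "Lutjanidae", "Carangidae", "Sphyraenidae", "Odontaspididae",
            "Dasyatidae"]

#: family relative-abundance profiles per morphology (rows sum to 1);
#: concrete is demersal-weighted and ship pelagic-weighted so community
#: analyses have a plantable signal
FAMILY_COMPOSITION = {
    "pavement_rubble": [.10, .22, .14, .02, .06, .08, .10, .12, .02, .06, .05, .01, .01, .01],
    "ledge":           [.12, .24, .12, .02, .03, .03, .10, .12, .03, .08, .07, .01, .02, .01],
    "concrete":        [.12, .18, .10, .10, .04, .03, .06, .14, .02, .06, .05, .03, .03, .04],
    "ship":            [.06, .14, .04, .01, .01, .01, .04, .06, .14, .22, .14, .06, .04, .03],
}


@dataclass
class ReefScenario:
    """Parameters of one synthetic reef transect."""

    morphology: str
    base_depth: float = 20.0        # seabed depth, m
    relief_amplitude: float = 1.0   # structure height, m
    roughness_sd: float = 0.1       # micro-roughness SD, m
    transect_length: float = 30.0   # m
    seed: int = 0

    def __post_init__(self):
        if self.morphology not in MORPHOLOGIES:
            raise ValueError(f"unknown morphology {self.morphology!r}")
        if self.transect_length <= 0:
            raise ValueError("transect_length must be positive")
        if self.relief_amplitude < 0 or self.roughness_sd < 0:
            raise ValueError("relief_amplitude and roughness_sd must be >= 0")


@dataclass
class FishGenModel:
    """Count model on the log-mean scale plus community composition.

    log mu = beta0 + beta1 DRR + beta2 DRR^2 + beta_depth depth + beta_temp T;
    the realized total is negative-binomial with size ``nb_dispersion``
    (Poisson in the infinite-dispersion limit).
    """

    beta0: float = 2.26
    beta1: float = 9.72
    beta2: float = -9.81
    beta_depth: float = 0.11
    beta_temp: float = 0.0
    nb_dispersion: float = 3.0
    composition: dict = field(default_factory=lambda: dict(FAMILY_COMPOSITION))
    length_distributions: dict = field(default_factory=lambda: dict(SIZE_CLASS_RANGES))
    seed: int = 0

    def __post_init__(self):
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        for morph, probs in self.composition.items():
            if not np.isclose(np.sum(probs), 1.0):
                raise ValueError(f"composition for {morph!r} must sum to 1")

    def mean(self, drr: float, depth: float, temperature: float) -> float:
        eta = (self.beta0 + self.beta1 * drr + self.beta2 * drr ** 2
               + self.beta_depth * depth + self.beta_temp * temperature)
        return float(np.exp(eta))

    def draw_total(self, mu: float, rng: np.random.Generator) -> int:
        if not np.isfinite(self.nb_dispersion) or self.nb_dispersion > 1e8:
            return int(rng.poisson(mu))
        theta = self.nb_dispersion
        return int(rng.negative_binomial(theta, theta / (theta + mu)))


#: planted models per reef type, mirroring the magnitudes of the fitted
#: abundance models (natural reefs have the stronger unimodal signal)
DEFAULT_NATURAL_MODEL = FishGenModel()
DEFAULT_ARTIFICIAL_MODEL = FishGenModel(beta0=4.37, beta1=1.31, beta2=-0.37,
                                        beta_depth=0.12, beta_temp=0.0)


# ---------------------------------------------------------------------------
# reef profiles

def gen_reef_profile(scenario: ReefScenario, resolution: float = 0.1) -> TransectProfile:
    """Generate a (distance, depth) profile for a reef morphology.

    Pavement-and-rubble is flat with micro-roughness; ledges contain a sharp
    or gradual drop of ``relief_amplitude``; concrete reefs carry a few
    low-lying blocks; ships are a rectangular superstructure with ramped ends.
    Depth is positive downward, so structure above the seabed reduces depth.
    """
    L = scenario.transect_length
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    if resolution > L / 10.0:
        raise ValueError("resolution too coarse (must be <= L/10)")
    rng = np.random.default_rng(scenario.seed)
    x = np.arange(0.0, L + resolution / 2, resolution)
    depth = np.full_like(x, scenario.base_depth)
    A = scenario.relief_amplitude
    if scenario.morphology == "pavement_rubble":
        # gentle undulation scaled to the micro-roughness so a zero-noise
        # pavement is exactly flat
        depth += 2.0 * scenario.roughness_sd * np.sin(
            2 * np.pi * x / L * rng.uniform(1.0, 2.0) + rng.uniform(0, 2 * np.pi))
    elif scenario.morphology == "ledge":
        x0 = rng.uniform(0.3, 0.7) * L
        width = rng.uniform(0.2, 1.0)  # sharp or gradual drop
        depth -= A / (1.0 + np.exp(-(x - x0) / width))
    elif scenario.morphology == "concrete":
        n_blocks = rng.integers(2, 5)
        heights = A * np.concatenate(([1.0], rng.uniform(0.4, 0.9, n_blocks - 1)))
        # clustered pipe/rubble piles several metres across
        for h in heights:
            c = rng.uniform(0.1, 0.9) * L
            w = rng.uniform(1.0, 2.0)
            depth = np.minimum(depth, scenario.base_depth - h * ((x > c - w) & (x < c + w)))
    else:  # ship
        length = rng.uniform(0.2, 0.3) * L
        c = rng.uniform(0.4, 0.6) * L
        # the towed logger follows the diver's path, which climbs a hull over
        # a horizontal run that grows with the superstructure height
        ramp = max(2.0, 0.8 * A)
        half = length / 2.0
        rel = np.clip((half + ramp - np.abs(x - c)) / ramp, 0.0, 1.0)
        depth -= A * rel
    if scenario.roughness_sd > 0:
        # micro-roughness with ~1 m correlation length: rubble and biogenic
        # relief vary over decimetres-to-metres, not sample-to-sample
        from scipy.ndimage import gaussian_filter1d
        white = rng.normal(0.0, 1.0, size=len(x))
        rough = gaussian_filter1d(white, sigma=1.0 / resolution, mode="wrap")
        rough *= scenario.roughness_sd / max(rough.std(), 1e-12)
        depth = depth + rough
    return TransectProfile(distance=x, depth=depth, transect_length=L)


# ---------------------------------------------------------------------------
# logger traces

SPIKES_PER_GROUP_END = 5
SPIKES_PER_GROUP_MID = 3
SPIKE_SPACING_S = 6.0     # within-group spike apex spacing
TRACE_PAD_S = 30.0        # baseline before the first / after the last group


def gen_logger_trace(profile: TransectProfile, swim_speed_mean: float = 10.0,
                     swim_speed_sd: float = 1.5, spike_height: float = 1.0,
                     pressure_noise_sd: float = 0.02, seed: int = 0,
                     water_temp: float = 22.0,
                     water_density: float = SEAWATER_DENSITY) -> DepthTrace:
    """Simulate the 1 Hz pressure-logger record of one transect swim.

    The diver moves at a per-5-m-segment realized speed drawn around
    ``swim_speed_mean`` (cm/s); calibration spike groups (logger raised
    ``spike_height`` m and lowered) are centred on the crossing time of each
    5 m mark — 5 spikes at the start and end, 3 at each interior mark.
    Hydrostatic pressure carries Gaussian noise of SD ``pressure_noise_sd``
    (PSI).
    """
    if swim_speed_mean <= 0:
        raise ValueError("swim_speed_mean must be positive")
    if spike_height <= 0:
        raise ValueError("spike_height must be positive")
    L = profile.transect_length
    if L < SPIKE_GROUP_SPACING_M:
        raise ValueError("profile shorter than one spike-group spacing (5 m)")
    n_seg = int(round(L / SPIKE_GROUP_SPACING_M))
    if not np.isclose(n_seg * SPIKE_GROUP_SPACING_M, L):
        raise ValueError("transect length must be a multiple of 5 m")
    rng = np.random.default_rng(seed)

    # realized per-segment speeds, cm/s, kept away from 0 and from speeds so
    # fast that adjacent spike groups would merge in time
    speeds = rng.normal(swim_speed_mean, swim_speed_sd, size=n_seg)
    speeds = np.clip(speeds, 0.4 * swim_speed_mean, 1.5 * swim_speed_mean)

    # crossing time of each 5 m mark
    centers = np.empty(n_seg + 1)
    centers[0] = TRACE_PAD_S
    centers[1:] = TRACE_PAD_S + np.cumsum(SPIKE_GROUP_SPACING_M * 100.0 / speeds)
    total = centers[-1] + TRACE_PAD_S
    time = np.arange(0.0, np.ceil(total) + 1.0)

    # distance along the transect (clamped to the ends before/after the swim)
    dist = np.interp(time, centers, np.arange(n_seg + 1) * SPIKE_GROUP_SPACING_M)
    depth = np.interp(dist, profile.distance, profile.depth)

    # superimpose spike groups
    for gi, c in enumerate(centers):
        k = SPIKES_PER_GROUP_END if gi in (0, n_seg) else SPIKES_PER_GROUP_MID
        offsets = (np.arange(k) - (k - 1) / 2.0) * SPIKE_SPACING_S
        for off in offsets:
            apex = int(round(c + off))
            depth[apex:apex + 2] -= spike_height

    pressure = ATMOSPHERIC_PSI + depth * water_density * GRAVITY / PSI_TO_PA
    if pressure_noise_sd > 0:
        pressure = pressure + rng.normal(0.0, pressure_noise_sd, size=len(time))
    temp = water_temp + rng.normal(0.0, 0.05, size=len(time))
    return DepthTrace(time=time, pressure_psi=pressure, temp_c=temp)


# ---------------------------------------------------------------------------
# fish surveys

def _species_records(species_row, n: int, model: FishGenModel,
                     rng: np.random.Generator) -> list[dict]:
    """Draw n individuals of one species and aggregate into survey records."""
    name, family, _a, _b, class_weights, schooling = species_row
    classes = list(class_weights)
    probs = np.array([class_weights[c] for c in classes])
    counts = rng.multinomial(n, probs / probs.sum())
    records = []
    for cls, n_cls in zip(classes, counts):
        if n_cls == 0:
            continue
        lo, hi = model.length_distributions[cls]
        hi = min(hi, 80)
        lengths = rng.integers(lo, int(hi) + 1, size=n_cls)
        if schooling and n_cls >= 10:
            # schools spanning a size range are recorded once with min-max
            records.append({"species": name, "family": family, "count": int(n_cls),
                            "length_cm_min": int(lengths.min()),
                            "length_cm_max": int(lengths.max())})
        else:
            for length, c in zip(*np.unique(lengths, return_counts=True)):
                records.append({"species": name, "family": family, "count": int(c),
                                "length_cm_min": int(length),
                                "length_cm_max": int(length)})
    return records


def gen_fish_survey(drr: float, depth: float, temperature: float,
                    morphology: str, model: FishGenModel,
                    rng: np.random.Generator) -> pd.DataFrame:
    """One belt transect of fish records for given habitat covariates.

    The total count is negative-binomial with log-mean linear in DRR, DRR^2,
    depth, and temperature; counts are allocated to families by the
    morphology's composition profile, then to species and lengths.
    """
    if morphology not in MORPHOLOGIES:
        raise ValueError(f"unknown morphology {morphology!r}")
    mu = model.mean(drr, depth, temperature)
    total = model.draw_total(mu, rng)
    comp = np.asarray(model.composition[morphology], dtype=float)
    fam_counts = rng.multinomial(total, comp)
    records = []
    for family, n_fam in zip(FAMILIES, fam_counts):
        if n_fam == 0:
            continue
        members = [s for s in SPECIES_POOL if s[1] == family]
        split = rng.multinomial(n_fam, np.full(len(members), 1.0 / len(members)))
        for sp, n_sp in zip(members, split):
            if n_sp:
                records.extend(_species_records(sp, int(n_sp), model, rng))
    cols = ["species", "family", "count", "length_cm_min", "length_cm_max"]
    return pd.DataFrame(records, columns=cols)


def length_weight_table(omit_species: tuple[str, ...] = ("Decapterus sp.",)) -> pd.DataFrame:
    """The length-weight coefficient table shipped with a synthetic study.

    ``omit_species`` are left out (identifiable only to family in the field),
    exercising the family-average fallback downstream.
    """
    rows = [{"species": s, "family": f, "a": a, "b": b}
            for s, f, a, b, _, _ in SPECIES_POOL if s not in omit_species]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full study

SEASONS = ("summer", "fall", "winter", "spring")
SEASON_TEMPS = {"summer": 27.0, "fall": 23.0, "winter": 17.0, "spring": 21.0}

#: sediment depth (cm) mean and within-transect SD by natural morphology:
#: pavements carry an ephemeral veneer (high SD), ledges little sediment
SEDIMENT_REGIMES = {"pavement_rubble": (4.0, 2.5), "ledge": (1.0, 0.5)}


@dataclass
class StudyConfig:
    n_natural_sites: int = 16
    n_artificial_sites: int = 14
    seasons: tuple = SEASONS
    transect_length: float = 30.0
    resolution: float = 0.1
    swim_speed_mean: float = 10.0
    swim_speed_sd: float = 1.5
    spike_height: float = 1.0
    pressure_noise_sd: float = 0.02
    weather_dropout: float = 0.0     # Bernoulli probability a site is single-season
    natural_model: FishGenModel = field(default_factory=lambda: replace(DEFAULT_NATURAL_MODEL))
    artificial_model: FishGenModel = field(default_factory=lambda: replace(DEFAULT_ARTIFICIAL_MODEL))
    generate_traces: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_natural_sites < 1 or self.n_artificial_sites < 1:
            raise ValueError("site counts must be >= 1")


@dataclass
class StudyData:
    sites: pd.DataFrame
    traces: dict               # (site, season, transect) -> DepthTrace
    true_profiles: dict        # (site, season, transect) -> TransectProfile
    surveys: pd.DataFrame
    sediment: pd.DataFrame
    coefficients: pd.DataFrame
    transect_env: pd.DataFrame  # true per-transect covariates (ground truth)


def _site_scenarios(config: StudyConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    n_pav = int(np.ceil(config.n_natural_sites * 0.55))
    n_con = int(np.ceil(config.n_artificial_sites * 0.3))
    for i in range(config.n_natural_sites):
        morph = "pavement_rubble" if i < n_pav else "ledge"
        relief = (rng.uniform(0.2, 0.6) if morph == "pavement_rubble"
                  else rng.uniform(1.0, 3.0))
        rough = 0.08 if morph == "pavement_rubble" else 0.15
        rows.append({"site": f"NAT{i+1:02d}", "reef_type": "natural",
                     "morphology": morph, "base_depth": rng.uniform(12, 35),
                     "relief_amplitude": relief, "roughness_sd": rough})
    for i in range(config.n_artificial_sites):
        morph = "concrete" if i < n_con else "ship"
        relief = (rng.uniform(0.5, 1.5) if morph == "concrete"
                  else rng.uniform(3.0, 8.0))
        rough = 0.10 if morph == "concrete" else 0.20
        rows.append({"site": f"ART{i+1:02d}", "reef_type": "artificial",
                     "morphology": morph, "base_depth": rng.uniform(12, 35),
                     "relief_amplitude": relief, "roughness_sd": rough})
    return pd.DataFrame(rows)


def gen_study(config: StudyConfig | None = None, **overrides) -> StudyData:
    """Generate a complete synthetic study: traces, surveys, sediment, temps.

    Two transects per site x season; sediment measurements every 3 m on
    natural sites only; optional weather dropout thins sites to one season.
    Identical config + seed reproduce byte-identical outputs.
    """
    if config is None:
        config = StudyConfig(**overrides)
    elif overrides:
        config = replace(config, **overrides)
    master = np.random.default_rng(config.seed)
    sites = _site_scenarios(config, master)
    from .complexity_metrics import compute_metrics  # local: avoid cycle at import

    traces, true_profiles = {}, {}
    survey_rows, sediment_rows, env_rows = [], [], []
    for si, site in enumerate(sites.itertuples(index=False)):
        seasons = list(config.seasons)
        if config.weather_dropout > 0 and master.uniform() < config.weather_dropout:
            seasons = [seasons[int(master.integers(len(seasons)))]]
        for season in seasons:
            ti_seed = np.random.SeedSequence(
                [config.seed, si, list(config.seasons).index(season)])
            season_rng = np.random.default_rng(ti_seed)
            temp = SEASON_TEMPS.get(season, 22.0) + season_rng.normal(0, 0.8)
            for transect in (1, 2):
                tseed = int(season_rng.integers(2 ** 31))
                scenario = ReefScenario(
                    morphology=site.morphology, base_depth=site.base_depth,
                    relief_amplitude=site.relief_amplitude,
                    roughness_sd=site.roughness_sd,
                    transect_length=config.transect_length, seed=tseed)
                profile = gen_reef_profile(scenario, config.resolution)
                metrics = compute_metrics(profile)
                key = (site.site, season, transect)
                true_profiles[key] = profile
                if config.generate_traces:
                    traces[key] = gen_logger_trace(
                        profile, config.swim_speed_mean, config.swim_speed_sd,
                        config.spike_height, config.pressure_noise_sd,
                        seed=tseed + 1, water_temp=temp)
                model = (config.natural_model if site.reef_type == "natural"
                         else config.artificial_model)
                fish = gen_fish_survey(metrics.drr, metrics.depth_mean, temp,
                                       site.morphology, model, season_rng)
                fish.insert(0, "transect", transect)
                fish.insert(0, "season", season)
                fish.insert(0, "site", site.site)
                survey_rows.append(fish)
                env_rows.append({"site": site.site, "season": season,
                                 "transect": transect, "drr_m": metrics.drr,
                                 "depth_m": metrics.depth_mean, "temp_c": temp,
                                 "reef_type": site.reef_type,
                                 "morphology": site.morphology})
                if site.reef_type == "natural":
                    mean_cm, sd_cm = SEDIMENT_REGIMES[site.morphology]
                    positions = np.arange(0.0, config.transect_length + 1e-9, 3.0)
                    values = np.clip(
                        season_rng.normal(mean_cm, sd_cm, size=len(positions)), 0, None)
                    for pos, val in zip(positions, values):
                        sediment_rows.append({"site": site.site, "season": season,
                                              "transect": transect,
                                              "position_m": pos,
                                              "depth_cm": round(float(val), 1)})
    surveys = (pd.concat(survey_rows, ignore_index=True) if survey_rows
               else pd.DataFrame())
    sediment = pd.DataFrame(sediment_rows)
    return StudyData(sites=sites, traces=traces, true_profiles=true_profiles,
                     surveys=surveys, sediment=sediment,
                     coefficients=length_weight_table(),
                     transect_env=pd.DataFrame(env_rows))


# ---------------------------------------------------------------------------
# writers (same delimited formats the readers consume)

def write_study(study: StudyData, outdir) -> None:
    """Write a synthetic study to CSVs consumable by the pipeline readers."""
    from pathlib import Path

    from .trace_processing import write_logger_csv
    out = Path(outdir)
    (out / "traces").mkdir(parents=True, exist_ok=True)
    for (site, season, transect), trace in study.traces.items():
        write_logger_csv(trace, out / "traces" / f"{site}_{season}_T{transect}.csv")
    study.surveys.to_csv(out / "surveys.csv", index=False)
    study.sediment.to_csv(out / "sediment.csv", index=False)
    study.coefficients.to_csv(out / "coefficients.csv", index=False)
    study.sites.to_csv(out / "sites.csv", index=False)
    study.transect_env.to_csv(out / "transect_env.csv", index=False)
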