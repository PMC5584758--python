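"""Fish community metrics from belt-transect surveys.

Divers record every fish on a 30 m x 4 m (120 m^2) belt transect: species,
family, count, and length to the nearest cm (a min-max range for schools).
This module converts those records into per-replicate abundance, biomass
(via the allometric length-weight relationship W = a L^b, g), species and
family richness, and size-class metrics, and attaches environmental
covariates (depth, temperature, sediment-depth variability).

Two transects surveyed at a reef in the same season are averaged into a
single replicate; averaged abundances are rounded to the nearest integer
(half away from zero) before entering count models, while biomass stays
continuous.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

TRANSECT_AREA_M2 = 120.0

SIZE_CLASSES = ("small", "medium", "large", "extra_large")
#: inclusive length bounds (cm); lengths are recorded to the nearest cm
SIZE_CLASS_BOUNDS = {
    "small": (1, 10),
    "medium": (11, 29),
    "large": (30, 49),
    "extra_large": (50, np.inf),
}


class UnresolvedTaxonError(KeyError):
    """No length-weight coefficients for a species and no family fallback."""


def size_class(length_cm: float) -> str:
    """Classify a fish length (cm) into small/medium/large/extra_large.

    Lengths are integer cm by protocol; non-integer inputs are floored with a
    warning so every fish falls in exactly one class.
    """
    if length_cm < 1:
        raise ValueError(f"fish length {length_cm} cm < 1 cm")
    L = float(length_cm)
    if L != np.floor(L):
        warnings.warn(f"non-integer length {L} cm floored", stacklevel=2)
        L = np.floor(L)
    for cls, (lo, hi) in SIZE_CLASS_BOUNDS.items():
        if lo <= L <= hi:
            return cls
    raise AssertionError("unreachable: size classes partition [1, inf)")


def observation_length(length_min: float, length_max: float) -> float:
    """Length used for biomass and size class: the midpoint for schools."""
    if length_min > length_max:
        raise ValueError("length_min > length_max")
    return (float(length_min) + float(length_max)) / 2.0


def family_fallback(coeffs: pd.DataFrame, family: str) -> tuple[float, float]:
    """Mean (a, b) over the family's known species (those observed on the reefs).

    Used when a fish is identified only to family, or its species has no
    published coefficients.
    """
    fam = coeffs[coeffs["family"] == family]
    if fam.empty:
        raise UnresolvedTaxonError(
            f"no length-weight coefficients for family {family!r}")
    return float(fam["a"].mean()), float(fam["b"].mean())


def resolve_coefficients(coeffs: pd.DataFrame, species: str,
                         family: str) -> tuple[float, float, str]:
    """Return (a, b, source) with source in {'species', 'family'}."""
    row = coeffs[coeffs["species"] == species]
    if not row.empty:
        return float(row["a"].iloc[0]), float(row["b"].iloc[0]), "species"
    a, b = family_fallback(coeffs, family)
    return a, b, "family"


def biomass_kg(count: int, length_min: float, length_max: float,
               a: float, b: float) -> float:
    """Biomass of one observation in kg: count x a L^b (g) / 1000."""
    L = observation_length(length_min, length_max)
    if L < 1:
        raise ValueError("fish length below 1 cm")
    return count * a * L ** b / 1000.0


def transect_metrics(records: pd.DataFrame, coeffs: pd.DataFrame) -> dict:
    """Metrics for a single belt transect.

    ``records`` columns: species, family, count, length_cm_min, length_cm_max.
    Returns abundance (fish / 120 m^2), biomass_kg, richness (species),
    family_richness, per-size-class abundance and biomass, and the count of
    family-fallback coefficient resolutions.
    """
    out = {"abundance": 0.0, "biomass_kg": 0.0,
           "richness": 0, "family_richness": 0, "n_family_fallback": 0}
    for cls in SIZE_CLASSES:
        out[f"abundance_{cls}"] = 0.0
        out[f"biomass_kg_{cls}"] = 0.0
    if records.empty:
        return out
    species_seen, families_seen = set(), set()
    for rec in records.itertuples(index=False):
        count = int(rec.count)
        if count < 1:
            raise ValueError("count must be >= 1")
        a, b, source = resolve_coefficients(coeffs, rec.species, rec.family)
        if source == "family":
            out["n_family_fallback"] += 1
        w = biomass_kg(count, rec.length_cm_min, rec.length_cm_max, a, b)
        # school midpoints ending in .5 are floored without comment: the
        # warning in size_class is for genuinely non-integer single lengths
        cls = size_class(np.floor(observation_length(rec.length_cm_min,
                                                     rec.length_cm_max)))
        out["abundance"] += count
        out["biomass_kg"] += w
        out[f"abundance_{cls}"] += count
        out[f"biomass_kg_{cls}"] += w
        species_seen.add(rec.species)
        families_seen.add(rec.family)
    out["richness"] = len(species_seen)
    out["family_richness"] = len(families_seen)
    return out


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero."""
    return int(np.sign(x) * np.floor(abs(x) + 0.5))


def replicate_average(transect_rows: list[dict], richness_mode: str = "averaged",
                      pooled_richness: int | None = None) -> dict:
    """Average 1-2 transect metric dicts into one site x season replicate.

    Abundance and richness are averaged then rounded half-away-from-zero (the
    count GLMs need integers); biomass stays continuous.  ``richness_mode``
    'averaged' takes the mean of per-transect richness; 'pooled' uses the
    richness of the pooled species set (``pooled_richness`` must be given).
    """
    if not transect_rows:
        raise ValueError("need at least one transect")
    if richness_mode not in ("averaged", "pooled"):
        raise ValueError("richness_mode must be 'averaged' or 'pooled'")
    keys = transect_rows[0].keys()
    out = {}
    for k in keys:
        vals = [r[k] for r in transect_rows]
        mean = float(np.mean(vals))
        if k.startswith("abundance"):
            out[k] = round_half_away(mean)
        elif k in ("richness", "family_richness"):
            if richness_mode == "pooled":
                if pooled_richness is None:
                    raise ValueError("pooled richness_mode requires pooled_richness")
                out[k] = pooled_richness if k == "richness" else round_half_away(mean)
            else:
                out[k] = round_half_away(mean)
        elif k == "n_family_fallback":
            out[k] = int(np.sum(vals))
        else:
            out[k] = mean
    return out


def sediment_sd(measurements_by_transect: list) -> float:
    """Sediment-depth variability (cm) for one site x season replicate.

    Sample SD of the point measurements within each transect, averaged across
    replicate transects.  Low SD = permanent cover, high SD = ephemeral.
    """
    sds = []
    for m in measurements_by_transect:
        m = np.asarray(m, dtype=float)
        if len(m) < 2:
            raise ValueError("need >= 2 sediment measurements per transect")
        sds.append(np.std(m, ddof=1))
    return float(np.mean(sds))


def sediment_positions(transect_length: float = 30.0, spacing: float = 3.0) -> np.ndarray:
    """Measurement positions along the transect, both endpoints included."""
    n = int(round(transect_length / spacing))
    return np.arange(n + 1) * spacing


def community_summary(surveys: pd.DataFrame, coeffs: pd.DataFrame) -> dict:
    """Study-wide totals over all transects (not replicate-averaged)."""
    if surveys.empty:
        return {"total_individuals": 0, "n_species": 0, "n_families": 0,
                "total_biomass_kg": 0.0}
    total_biomass = 0.0
    for rec in surveys.itertuples(index=False):
        a, b, _ = resolve_coefficients(coeffs, rec.species, rec.family)
        total_biomass += biomass_kg(int(rec.count), rec.length_cm_min,
                                    rec.length_cm_max, a, b)
    return {
        "total_individuals": int(surveys["count"].sum()),
        "n_species": int(surveys["species"].nunique()),
        "n_families": int(surveys["family"].nunique()),
        "total_biomass_kg": float(total_biomass),
    }


def build_samples(surveys: pd.DataFrame, coeffs: pd.DataFrame,
                  transect_env: pd.DataFrame,
                  sediment: pd.DataFrame | None = None,
                  richness_mode: str = "averaged") -> pd.DataFrame:
    """Assemble per-replicate (site x season) samples for the habitat models.

    Parameters
    ----------
    surveys
        Fish records: site, season, transect, species, family, count,
        length_cm_min, length_cm_max.
    transect_env
        Per-transect covariates: site, season, transect, drr_m, depth_m,
        temp_c, reef_type, morphology.
    sediment
        Optional point measurements: site, season, transect, position_m,
        depth_cm (natural reefs only).
    """
    rows = []
    for (site, season), env in transect_env.groupby(["site", "season"], sort=True):
        srows = surveys[(surveys["site"] == site) & (surveys["season"] == season)]
        tmetrics, pooled = [], set()
        for transect in sorted(env["transect"].unique()):
            rec = srows[srows["transect"] == transect]
            tmetrics.append(transect_metrics(rec, coeffs))
            pooled |= set(rec["species"])
        avg = replicate_average(tmetrics, richness_mode=richness_mode,
                                pooled_richness=len(pooled))
        row = {"site": site, "season": season,
               "reef_type": env["reef_type"].iloc[0],
               "morphology": env["morphology"].iloc[0],
               "drr": float(env["drr_m"].mean()),
               "depth": float(env["depth_m"].mean()),
               "temperature": float(env["temp_c"].mean()),
               **avg}
        if sediment is not None and row["reef_type"] == "natural":
            sed = sediment[(sediment["site"] == site) & (sediment["season"] == season)]
            if not sed.empty:
                per_transect = [g["depth_cm"].to_numpy()
                                for _, g in sed.groupby("transect")]
                row["sediment_sd"] = sediment_sd(per_transect)
        rows.append(row)
    df = pd.DataFrame(rows)
    if "sediment_sd" not in df.columns:
        df["sediment_sd"] = np.nan
    return df


def family_abundance_matrix(surveys: pd.DataFrame,
                            transect_env: pd.DataFrame,
                            sqrt_transform: bool = True) -> tuple[pd.DataFrame, pd.Series]:
    """Replicate x family abundance matrix for community analyses.

    Counts are averaged across the replicate transects of each site x season;
    square-root transformed by default (community ordination convention).
    Returns (matrix, morphology labels aligned to its rows).
    """
    merged = surveys.merge(
        transect_env[["site", "season", "transect", "morphology"]],
        on=["site", "season", "transect"], how="left")
    counts = (merged.groupby(["site", "season", "transect", "family"])["count"]
              .sum().unstack(fill_value=0))
    mat = counts.groupby(level=["site", "season"]).mean().astype(float)
    groups = (transect_env.groupby(["site", "season"])["morphology"].first()
              .reindex(mat.index))
    if sqrt_transform:
        mat = np.sqrt(mat)
    return mat, groups


# ---------------------------------------------------------------------------
# delimited-text IO

SURVEY_COLUMNS = ["site", "season", "transect", "species", "family",
                  "count", "length_cm_min", "length_cm_max"]


def read_survey_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(SURVEY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"survey CSV missing columns: {sorted(missing)}")
    return df


def read_coefficients_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"species", "family", "a", "b"} - set(df.columns)
    if missing:
        raise ValueError(f"coefficients CSV missing columns: {sorted(missing)}")
    if (df["a"] <= 0).any() or (df["b"] <= 0).any():
        raise ValueError("length-weight coefficients must be positive")
    return df


def read_sediment_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"site", "season", "transect", "position_m", "depth_cm"} - set(df.columns)
    if missing:
        raise ValueError(f"sediment CSV missing columns: {sorted(missing)}")
    return df
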