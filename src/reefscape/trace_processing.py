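"""Convert raw 1 Hz pressure-logger records into distance-referenced depth profiles.

A diver tows a pressure logger along a 30 m transect at a nominal 10 cm/s.
The logger records absolute pressure (PSI) and temperature once per second.
Calibration "spikes" — the logger raised ~1 m and rapidly lowered — mark the
start of the transect (5 spikes), every 5 m (3 spikes), and the end (5 spikes).
This module detects those spikes, converts pressure to depth, maps sample time
to along-transect distance via the spike groups, and removes the spike windows
to leave a clean (distance, depth) profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: 1 atm in PSI; the logger records absolute pressure.
ATMOSPHERIC_PSI = 14.696
#: pascal per PSI
PSI_TO_PA = 6894.757
#: default seawater density, kg/m^3
SEAWATER_DENSITY = 1025.0
GRAVITY = 9.81

#: spacing between spike groups along the transect, m
SPIKE_GROUP_SPACING_M = 5.0


class CalibrationError(ValueError):
    """Spike pattern inconsistent with the expected transect layout."""


class TraceQualityError(ValueError):
    """Too few samples survive spike removal for a trustworthy profile."""


@dataclass
class DepthTrace:
    """One transect swim: 1 Hz time (s), absolute pressure (PSI), temperature (degC)."""

    time: np.ndarray
    pressure_psi: np.ndarray
    temp_c: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.pressure_psi = np.asarray(self.pressure_psi, dtype=float)
        self.temp_c = np.asarray(self.temp_c, dtype=float)
        if self.time.ndim != 1 or len(self.time) != len(self.pressure_psi):
            raise ValueError("time and pressure must be 1-D and equal length")
        if len(self.time) > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(self.pressure_psi)):
            raise ValueError("non-finite pressure values")
        if np.any(self.pressure_psi <= 0):
            raise ValueError("absolute pressure must be positive")

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class TransectProfile:
    """Calibrated (distance, depth) series along one transect.

    Depth is positive downward, in metres; distance runs from 0 to the
    transect length ``transect_length``.
    """

    distance: np.ndarray
    depth: np.ndarray
    transect_length: float

    def __post_init__(self) -> None:
        self.distance = np.asarray(self.distance, dtype=float)
        self.depth = np.asarray(self.depth, dtype=float)
        if len(self.distance) != len(self.depth):
            raise ValueError("distance and depth must have equal length")
        if len(self.distance) > 1 and np.any(np.diff(self.distance) < 0):
            raise ValueError("distance must be monotone non-decreasing")

    def __len__(self) -> int:
        return len(self.distance)


@dataclass
class SpikeCalibration:
    """Detected calibration spikes clustered into groups at known distances."""

    spike_indices: np.ndarray          # sample index of each spike apex
    spike_windows: np.ndarray          # (n_spikes, 2) inclusive sample-index windows
    group_centers: np.ndarray          # time (s) of each spike-group centre
    group_distances: np.ndarray        # assigned distance (m): 0, 5, ..., L
    segment_speeds: np.ndarray = field(default_factory=lambda: np.empty(0))  # cm/s

    @property
    def n_groups(self) -> int:
        return len(self.group_centers)


def psi_to_depth(pressure_psi, atmospheric: float = ATMOSPHERIC_PSI,
                 water_density: float = SEAWATER_DENSITY) -> np.ndarray:
    """Convert absolute pressure (PSI) to hydrostatic depth (m, positive down).

    depth = (p - p_atm) * 6894.757 / (rho * g).  Depths that come out negative
    (pressure below 1 atm, e.g. sensor noise at the surface) are clipped to 0
    with a warning.
    """
    p = np.asarray(pressure_psi, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError("non-finite pressure values")
    depth = (p - atmospheric) * PSI_TO_PA / (water_density * GRAVITY)
    n_neg = int(np.sum(depth < 0))
    if n_neg:
        warnings.warn(f"clipped {n_neg} negative depth value(s) to 0", stacklevel=2)
        depth = np.clip(depth, 0.0, None)
    return depth


def _matched_spike_events(depth: np.ndarray, min_excursion: float,
                          max_width: int) -> tuple[list[int], list[tuple[int, int]]]:
    """Find rise-fall pairs: a shallowing of >= min_excursion within <= 2
    samples followed by an equal deepening within max_width samples.

    Reef features cannot mimic this signature: a narrow block rises but does
    not fall back within the window (the diver is still crossing it), and a
    ledge never falls back at all.
    """
    n = len(depth)
    spikes, windows = [], []
    i = 0
    while i < n - 2:
        rise_end = None
        for lag in (1, 2):
            if i + lag < n and depth[i] - depth[i + lag] > min_excursion:
                rise_end = i + lag
                break
        if rise_end is None:
            i += 1
            continue
        fall = None
        for k in range(rise_end, min(rise_end + max_width, n - 1)):
            for lag in (1, 2):
                if k + lag < n and depth[k + lag] - depth[k] > min_excursion:
                    fall = (k, min(k + lag, n - 1))
                    break
            if fall is not None:
                break
        if fall is None:
            i = rise_end
            continue
        s, e = i + 1, fall[0]
        apex = s + int(np.argmin(depth[s:e + 1]))
        spikes.append(apex)
        windows.append((s, e))
        i = fall[1] + 1
    return spikes, windows


def detect_spikes(depth: np.ndarray, transect_length: float = 30.0,
                  min_excursion: float = 0.5, max_width: float = 6.0,
                  group_gap: float = 12.0,
                  time: np.ndarray | None = None) -> SpikeCalibration:
    """Find calibration spikes (upward excursions) and cluster them into groups.

    A spike is an upward (shallower) excursion of at least ``min_excursion``
    m that returns to baseline within ``max_width`` seconds, detected as a
    matched rapid rise-fall pair.  Spikes separated by more than
    ``group_gap`` s fall into distinct groups; groups are assigned distances
    0, 5, ..., L in order.

    Raises
    ------
    CalibrationError
        If the number of groups found differs from L/5 + 1.
    """
    depth = np.asarray(depth, dtype=float)
    if time is None:
        time = np.arange(len(depth), dtype=float)
    spikes, windows = _matched_spike_events(depth, min_excursion, int(max_width))
    spikes = np.asarray(spikes, dtype=int)
    windows = np.asarray(windows, dtype=int).reshape(-1, 2)

    expected = int(round(transect_length / SPIKE_GROUP_SPACING_M)) + 1
    if len(spikes) == 0:
        raise CalibrationError(
            f"no calibration spikes found; expected {expected} groups")

    # cluster spike apices into groups separated by > group_gap seconds
    apex_times = time[spikes]
    breaks = np.flatnonzero(np.diff(apex_times) > group_gap)
    group_slices = np.split(np.arange(len(spikes)), breaks + 1)
    centers = np.array([apex_times[g].mean() for g in group_slices])

    if len(centers) != expected:
        raise CalibrationError(
            f"found {len(centers)} spike groups, expected {expected} "
            f"for a {transect_length:g} m transect")

    distances = np.arange(expected, dtype=float) * SPIKE_GROUP_SPACING_M
    dt = np.diff(centers)
    speeds = SPIKE_GROUP_SPACING_M * 100.0 / dt  # cm/s
    if np.any(speeds <= 0):
        raise CalibrationError("non-increasing spike group centers")
    return SpikeCalibration(spike_indices=spikes, spike_windows=windows,
                            group_centers=centers, group_distances=distances,
                            segment_speeds=speeds)


def calibrate_distance(cal: SpikeCalibration, transect_length: float):
    """Piecewise-linear time -> distance mapping anchored at spike-group centres.

    Per-segment diver speed is 5 m over the time between adjacent group
    centres; the mapping sends the first centre to 0 m and the last to L.
    Times outside the calibrated span clamp to the endpoints.
    """
    if cal.n_groups < 2:
        raise CalibrationError("need at least 2 spike groups to calibrate distance")
    centers = np.asarray(cal.group_centers, dtype=float)
    dists = np.asarray(cal.group_distances, dtype=float)
    if np.any(np.diff(centers) <= 0):
        raise CalibrationError("non-increasing group centers")
    if not np.isclose(dists[-1], transect_length):
        raise CalibrationError("last group distance does not equal transect length")

    def mapping(t):
        return np.interp(np.asarray(t, dtype=float), centers, dists)

    return mapping


def extract_profile(trace: DepthTrace, cal: SpikeCalibration, mapping,
                    transect_length: float = 30.0, margin: float = 1.0,
                    atmospheric: float = ATMOSPHERIC_PSI,
                    water_density: float = SEAWATER_DENSITY) -> TransectProfile:
    """Remove spike windows, map time to distance, and return the reef profile.

    Samples within ``margin`` seconds of a detected spike window are dropped;
    the remainder are assigned distances via ``mapping`` and restricted to
    [0, L].

    Raises
    ------
    TraceQualityError
        If fewer than half the samples survive removal.
    """
    depth = psi_to_depth(trace.pressure_psi, atmospheric, water_density)
    # restrict to the calibrated span (samples before the first / after the
    # last group are off-transect)
    in_span = (trace.time >= cal.group_centers[0]) & (trace.time <= cal.group_centers[-1])
    keep = in_span.copy()
    for s, e in cal.spike_windows:
        t0, t1 = trace.time[s] - margin, trace.time[e] + margin
        keep &= ~((trace.time >= t0) & (trace.time <= t1))
    if keep.sum() < 0.5 * in_span.sum():
        raise TraceQualityError(
            f"only {int(keep.sum())}/{int(in_span.sum())} on-transect samples "
            f"survive spike removal")
    dist = mapping(trace.time[keep])
    inside = (dist >= 0) & (dist <= transect_length)
    return TransectProfile(distance=dist[inside], depth=depth[keep][inside],
                           transect_length=transect_length)


def process_trace(trace: DepthTrace, transect_length: float = 30.0,
                  **detect_kwargs) -> tuple[TransectProfile, SpikeCalibration]:
    """Full trace pipeline: depth conversion, spike detection, profile extraction."""
    depth = psi_to_depth(trace.pressure_psi)
    cal = detect_spikes(depth, transect_length=transect_length,
                        time=trace.time, **detect_kwargs)
    mapping = calibrate_distance(cal, transect_length)
    profile = extract_profile(trace, cal, mapping, transect_length=transect_length)
    return profile, cal


def mean_temperature(trace: DepthTrace) -> float:
    """Arithmetic mean temperature over the transect (spike windows included)."""
    if len(trace) == 0:
        raise ValueError("empty trace")
    return float(np.mean(trace.temp_c))


# ---------------------------------------------------------------------------
# delimited-text IO

def read_logger_csv(path) -> DepthTrace:
    """Read a logger record (columns: timestamp, pressure_psi, temp_c)."""
    df = pd.read_csv(path)
    required = {"timestamp", "pressure_psi", "temp_c"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"logger CSV missing columns: {sorted(missing)}")
    t = pd.to_datetime(df["timestamp"])
    seconds = (t - t.iloc[0]).dt.total_seconds().to_numpy()
    return DepthTrace(time=seconds, pressure_psi=df["pressure_psi"].to_numpy(),
                      temp_c=df["temp_c"].to_numpy())


def write_logger_csv(trace: DepthTrace, path, start="2014-06-01T10:00:00") -> None:
    t0 = pd.Timestamp(start)
    stamps = t0 + pd.to_timedelta(trace.time, unit="s")
    pd.DataFrame({
        "timestamp": stamps.strftime("%Y-%m-%dT%H:%M:%S"),
        "pressure_psi": np.round(trace.pressure_psi, 5),
        "temp_c": np.round(trace.temp_c, 3),
    }).to_csv(path, index=False)


def write_profile_csv(profile: TransectProfile, path) -> None:
    pd.DataFrame({"distance_m": profile.distance,
                  "depth_m": profile.depth}).to_csv(path, index=False)


def read_profile_csv(path, transect_length: float | None = None) -> TransectProfile:
    df = pd.read_csv(path)
    L = transect_length if transect_length is not None else float(df["distance_m"].max())
    return TransectProfile(distance=df["distance_m"].to_numpy(),
                           depth=df["depth_m"].to_numpy(), transect_length=L)
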