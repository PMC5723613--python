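"""Synthetic multi-sensor foraging trips with known ground truth.

The generator emulates the data structure of a wing-propelled pursuit diver
(auk-like) foraging trip:

* a trip is a sequence of **dive bouts** separated by surface gaps > 300 s,
  each bout a run of dives with inter-dive gaps < 300 s;
* each dive has a trapezoidal time-depth profile (constant descent/ascent
  rate, flat bottom) sampled at 1 Hz;
* the number of prey pursuit-and-catching events (PCE) per dive is Poisson
  with log-mean eta(duration, depth) minus a within-bout depletion term, so
  bout-level gain saturates mechanistically as the patch is depleted;
* PCE appear in the 25 Hz tri-axial acceleration trace as high-amplitude
  broadband bursts over a regime-structured baseline (flight flapping,
  surface rest, underwater swim strokes) — four separable movement regimes;
* GPS fixes every 100 s; a smooth synthetic bathymetry field supports both
  benthic dives (bottom within 10 m of the charted seafloor, mixed profile
  only) and pelagic dives.

Everything is deterministic for a given :class:`SimConfig` (seed included).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from divebout.errors import CoverageError
from divebout.sensor_io import AccelTrace, BathymetryGrid, DepthTrace, GpsTrack

__all__ = [
    "SimConfig",
    "TruthRecord",
    "TrueDive",
    "simulate_bathymetry",
    "simulate_trip",
    "true_gain",
    "eta_true",
    "simulate_bout_pct",
    "simulate_species_bouts",
    "write_trip",
]

#: 1/8 arc minute in decimal degrees (~230 m at these latitudes).
DEFAULT_RESOLUTION_DEG = (1.0 / 60.0) / 8.0

DESCENT_RATE_M_S = 1.5  # also the ascent rate; trapezoid profile
BENTHIC_BUFFER_M = 10.0


def true_gain(t_underwater_s: np.ndarray | float, a: float, b: float) -> np.ndarray | float:
    """Saturating patch gain: expected cumulative capture time a*t/(b+t).

    ``a`` is the asymptotic gain (s of capture time), ``b`` the
    half-saturation residence time (s): at t = b the expected gain is a/2.
    """
    if a < 0:
        raise ValueError("asymptote a must be >= 0")
    if b <= 0:
        raise ValueError("half-saturation b must be > 0")
    t = np.asarray(t_underwater_s, dtype=float)
    if np.any(t < 0):
        raise ValueError("residence time must be >= 0")
    out = a * t / (b + t)
    return float(out) if np.ndim(t_underwater_s) == 0 else out


def eta_true(
    duration_s: np.ndarray | float,
    depth_m: np.ndarray | float,
    coeffs: dict[str, float],
    benthic: np.ndarray | bool = False,
) -> np.ndarray | float:
    """True log PCE-rate surface eta(duration, depth).

    A quadratic-with-interaction surface on scaled covariates
    s = duration/60 s, u = depth/30 m, plus an optional localized ridge
    (the product of Gaussian bumps in duration and depth — a prey-layer
    peak, genuinely non-additive on the log scale) and benthic-class shifts:

        eta = const + dur*s + depth*u + dur_depth*s*u + dur2*s^2 + depth2*u^2
              + peak_amp * exp(-(dur - peak_dur)^2 / (2 peak_dur_sd^2))
                         * exp(-(depth - peak_depth)^2 / (2 peak_depth_sd^2))
              + 1[benthic]*(benthic + dur_benthic*s + depth_benthic*u)

    Missing keys default to 0; ``const = -inf`` gives the zero-rate mode.
    """
    d = np.asarray(duration_s, dtype=float)
    z = np.asarray(depth_m, dtype=float)
    s = d / 60.0
    u = z / 30.0
    g = coeffs.get
    eta = (
        g("const", 0.0)
        + g("dur", 0.0) * s
        + g("depth", 0.0) * u
        + g("dur_depth", 0.0) * s * u
        + g("dur2", 0.0) * s**2
        + g("depth2", 0.0) * u**2
    )
    amp = g("peak_amp", 0.0)
    if amp:
        eta = eta + amp * np.exp(
            -((d - g("peak_dur", 30.0)) ** 2) / (2 * g("peak_dur_sd", 15.0) ** 2)
            - ((z - g("peak_depth", 7.0)) ** 2) / (2 * g("peak_depth_sd", 6.0) ** 2)
        )
    b = np.asarray(benthic, dtype=float)
    eta = eta + b * (
        g("benthic", 0.0) + g("dur_benthic", 0.0) * s + g("depth_benthic", 0.0) * u
    )
    if np.ndim(duration_s) == 0 and np.ndim(depth_m) == 0:
        return float(eta)
    return eta


@dataclass
class SimConfig:
    """Parameters of one synthetic deployment.

    Defaults give a shallow pelagic diver (razorbill-like): dives averaging
    ~36 s to ~8 m median depth, ~2 PCE per dive at the surface mean, within-
    bout depletion saturating bout gain on a ~700 s timescale.
    """

    seed: int = 0
    species_profile: str = "shallow_pelagic"  # or "mixed_benthic_pelagic"
    n_bouts: int = 10
    dives_per_bout_mean: float = 20.0
    inter_bout_gap_s: float = 600.0
    intra_bout_gap_range_s: tuple[float, float] = (30.0, 240.0)
    dive_duration_gamma: tuple[float, float] = (9.0, 4.0)  # shape, scale (s)
    depth_lognorm: tuple[float, float] = (np.log(8.0), 0.5)  # mu, sigma of log depth (m)
    benthic_fraction: float = 0.0  # >0 only for mixed profile
    # peaked capture-rate surface: highest for ~30 s dives in the top ~10 m,
    # ~2.5 expected events at the peak and ~0.6 elsewhere
    rate_coeffs: dict[str, float] = field(
        default_factory=lambda: {
            "const": -0.6, "dur": 0.3, "depth": 0.15,
            "peak_amp": 1.3, "peak_dur": 30.0, "peak_depth": 7.0,
            "peak_dur_sd": 15.0, "peak_depth_sd": 6.0,
        }
    )
    depletion_rate: float = 0.0015  # 1/s of cumulative within-bout underwater time
    pce_duration_gamma: tuple[float, float] = (3.0, 1.0)  # shape, scale (s)
    burst_ratio: float = 4.0  # PCE burst amplitude relative to swim-stroke amplitude
    flap_freq_hz: float = 8.0
    swim_freq_hz: float = 3.0
    swim_amp_g: float = 0.25
    flight_amp_g: float = 0.4
    rest_amp_g: float = 0.05
    noise_sd_g: float = 0.1
    gain_a_s: float = 300.0  # nominal gain asymptote carried into the truth record
    gain_b_s: float = 500.0
    grid_extent: tuple[float, float, float, float] = (-2.0, -1.0, 59.0, 59.5)
    grid_resolution: float = DEFAULT_RESOLUTION_DEG
    grid_depth_range: tuple[float, float] = (5.0, 260.0)

    def __post_init__(self) -> None:
        if self.species_profile not in ("shallow_pelagic", "mixed_benthic_pelagic"):
            raise ValueError(f"unknown species_profile {self.species_profile!r}")
        if self.inter_bout_gap_s <= 300:
            raise ValueError("inter_bout_gap_s must exceed the 300 s bout-gap threshold")
        for name in ("dive_duration_gamma", "pce_duration_gamma"):
            shape, scale = getattr(self, name)
            if shape <= 0 or scale <= 0:
                raise ValueError(f"{name} parameters must be > 0")
        if self.burst_ratio < 1:
            raise ValueError("burst_ratio must be >= 1")
        if self.species_profile == "shallow_pelagic" and self.benthic_fraction != 0:
            raise ValueError("shallow_pelagic profile cannot produce benthic dives")

    # -- presets -----------------------------------------------------------

    @classmethod
    def razorbill_like(cls, seed: int = 0, **kw) -> "SimConfig":
        """Shallow pelagic diver with saturating bout gain (the defaults)."""
        return cls(seed=seed, **kw)

    @classmethod
    def guillemot_like(cls, seed: int = 0, **kw) -> "SimConfig":
        """Mixed benthic/pelagic diver: deeper, longer dives, near-linear gain."""
        defaults = dict(
            species_profile="mixed_benthic_pelagic",
            n_bouts=8,
            dives_per_bout_mean=11.0,
            dive_duration_gamma=(16.0, 5.0),  # mean 80 s
            depth_lognorm=(np.log(30.0), 0.45),
            benthic_fraction=0.35,
            rate_coeffs={
                "const": -0.2,
                "dur": 0.35,
                "depth": 0.25,
                "benthic": 0.1,
                "depth_benthic": -0.45,
            },
            depletion_rate=0.0,
            grid_depth_range=(15.0, 90.0),
        )
        defaults.update(kw)
        return cls(seed=seed, **defaults)

    # -- serialization -----------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        def clean(v):
            if isinstance(v, (tuple, list)):
                return [clean(x) for x in v]
            if isinstance(v, dict):
                return {k: clean(x) for k, x in v.items()}
            if isinstance(v, np.generic):
                return v.item()
            return v

        Path(path).write_text(yaml.safe_dump(clean(asdict(self)), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        d = yaml.safe_load(Path(path).read_text())
        for k, v in list(d.items()):
            if isinstance(v, list):
                d[k] = tuple(v)
        d["rate_coeffs"] = dict(d.get("rate_coeffs") or {})
        return cls(**d)


@dataclass
class TrueDive:
    """Ground truth for one simulated dive."""

    start_s: float
    end_s: float
    max_depth_m: float
    bout_id: int
    dive_class: str  # benthic | pelagic
    seafloor_depth_m: float
    pce_intervals: list[tuple[float, float]]  # half-open, trip clock

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def n_pce(self) -> int:
        return len(self.pce_intervals)


@dataclass
class TruthRecord:
    """Full ground truth of a simulated trip."""

    dives: list[TrueDive]
    rate_coeffs: dict[str, float]
    depletion_rate: float
    gain_a_s: float
    gain_b_s: float

    @property
    def n_dives(self) -> int:
        return len(self.dives)

    def bout_members(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {}
        for i, d in enumerate(self.dives):
            out.setdefault(d.bout_id, []).append(i)
        return out

    def all_pce_intervals(self) -> np.ndarray:
        """(n_events, 2) array of all PCE intervals on the trip clock."""
        rows = [iv for d in self.dives for iv in d.pce_intervals]
        return np.array(rows, dtype=float).reshape(-1, 2)

    def window_pce_truth(self, centers: np.ndarray, width_s: float) -> np.ndarray:
        """True PCE indicator per analysis window (>=50% overlap rule)."""
        centers = np.asarray(centers, dtype=float)
        lo = centers - width_s / 2
        hi = centers + width_s / 2
        overlap = np.zeros_like(centers)
        for s, e in self.all_pce_intervals():
            overlap += np.clip(np.minimum(hi, e) - np.maximum(lo, s), 0, None)
        return overlap >= width_s / 2

    def to_json(self, path: str | Path) -> None:
        obj = {
            "rate_coeffs": self.rate_coeffs,
            "depletion_rate": self.depletion_rate,
            "gain_a_s": self.gain_a_s,
            "gain_b_s": self.gain_b_s,
            "dives": [
                {
                    "start_s": d.start_s,
                    "end_s": d.end_s,
                    "max_depth_m": d.max_depth_m,
                    "bout_id": d.bout_id,
                    "class": d.dive_class,
                    "seafloor_depth_m": d.seafloor_depth_m,
                    "pce_intervals": [list(iv) for iv in d.pce_intervals],
                }
                for d in self.dives
            ],
        }
        Path(path).write_text(json.dumps(obj, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthRecord":
        obj = json.loads(Path(path).read_text())
        dives = [
            TrueDive(
                start_s=d["start_s"],
                end_s=d["end_s"],
                max_depth_m=d["max_depth_m"],
                bout_id=d["bout_id"],
                dive_class=d["class"],
                seafloor_depth_m=d["seafloor_depth_m"],
                pce_intervals=[tuple(iv) for iv in d["pce_intervals"]],
            )
            for d in obj["dives"]
        ]
        return cls(
            dives,
            obj["rate_coeffs"],
            obj["depletion_rate"],
            obj["gain_a_s"],
            obj["gain_b_s"],
        )


# ---------------------------------------------------------------------------
# Bathymetry


def simulate_bathymetry(
    extent: tuple[float, float, float, float] = (-2.0, -1.0, 59.0, 59.5),
    resolution: float = DEFAULT_RESOLUTION_DEG,
    seed: int = 0,
    depth_range: tuple[float, float] = (5.0, 260.0),
    constant: float | None = None,
) -> BathymetryGrid:
    """Smooth positive seafloor-depth field over ``extent`` (degrees).

    The field is a Gaussian random surface (white noise smoothed with a
    Gaussian kernel) rescaled into ``depth_range``.  ``constant`` gives a
    flat bottom of that depth (degenerate mode used in tests).
    """
    from scipy.ndimage import gaussian_filter

    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    xmin, xmax, ymin, ymax = extent
    if xmax <= xmin or ymax <= ymin:
        raise ValueError(f"degenerate extent {extent}")
    ncols = max(int(np.ceil((xmax - xmin) / resolution)), 1)
    nrows = max(int(np.ceil((ymax - ymin) / resolution)), 1)
    if constant is not None:
        values = np.full((nrows, ncols), float(constant))
        return BathymetryGrid(xmin, ymin, resolution, values)
    rng = np.random.default_rng(seed)
    field_ = gaussian_filter(rng.standard_normal((nrows, ncols)), sigma=12, mode="reflect")
    lo, hi = field_.min(), field_.max()
    dmin, dmax = depth_range
    values = dmin + (field_ - lo) / (hi - lo) * (dmax - dmin)
    return BathymetryGrid(xmin, ymin, resolution, values)


# ---------------------------------------------------------------------------
# Trip simulation


def _trapezoid_depth(tau: np.ndarray, duration: float, max_depth: float) -> np.ndarray:
    """Trapezoidal profile: constant-rate descent/ascent, flat bottom, min 1 m while wet."""
    rate = DESCENT_RATE_M_S
    prof = np.minimum.reduce([rate * tau, np.full_like(tau, max_depth), rate * (duration - tau)])
    return np.clip(prof, 1.0, None)


def _place_events(
    rng: np.random.Generator,
    n: int,
    start: float,
    end: float,
    dur_gamma: tuple[float, float],
    edge_s: float = 1.5,
    min_gap_s: float = 2.0,
) -> list[tuple[float, float]]:
    """Place up to n non-overlapping event intervals inside [start+edge, end-edge)."""
    events: list[tuple[float, float]] = []
    for _ in range(n):
        dur = float(np.clip(rng.gamma(*dur_gamma), 1.0, 15.0))
        placed = False
        for _try in range(50):
            lo = start + edge_s
            hi = end - edge_s - dur
            if hi <= lo:
                break
            s = rng.uniform(lo, hi)
            e = s + dur
            if all(e + min_gap_s <= s2 or s >= e2 + min_gap_s for s2, e2 in events):
                events.append((s, e))
                placed = True
                break
        if not placed:
            continue
    return sorted(events)


def _sample_bout_position(
    rng: np.random.Generator,
    grid: BathymetryGrid,
    prev: tuple[float, float] | None,
    min_seafloor_m: float,
) -> tuple[float, float, float]:
    """Random-walk bout position constrained to cells at least ``min_seafloor_m`` deep."""
    xmin, xmax, ymin, ymax = grid.extent
    mx = 0.05 * (xmax - xmin)
    my = 0.05 * (ymax - ymin)
    for _ in range(200):
        if prev is None:
            lon = rng.uniform(xmin + mx, xmax - mx)
            lat = rng.uniform(ymin + my, ymax - my)
        else:
            lon = float(np.clip(prev[0] + rng.normal(0, 0.02), xmin + mx, xmax - mx))
            lat = float(np.clip(prev[1] + rng.normal(0, 0.01), ymin + my, ymax - my))
        row, col = grid.cell_index(lon, lat)
        seafloor = float(grid.values[row, col])
        if seafloor >= min_seafloor_m:
            return lon, lat, seafloor
    raise CoverageError(
        f"could not find a grid cell deeper than {min_seafloor_m} m for a bout position"
    )


def simulate_trip(
    config: SimConfig, grid: BathymetryGrid | None = None
) -> tuple[GpsTrack, DepthTrace, AccelTrace, TruthRecord]:
    """Simulate one deployment: GPS (100 s), depth (1 Hz), accel (25 Hz), truth.

    Dive start/end times fall on integer seconds and every in-dive depth
    sample exceeds the wet threshold, so segmentation recovers the true
    dive and bout structure exactly (a constructive guarantee the tests rely
    on).  PCE counts are Poisson with log-mean
    ``eta(duration, depth) - depletion_rate * cumulative bout underwater time``.
    """
    rng = np.random.default_rng(config.seed)
    if grid is None:
        grid = simulate_bathymetry(
            config.grid_extent,
            config.grid_resolution,
            seed=config.seed,
            depth_range=config.grid_depth_range,
        )
    mixed = config.species_profile == "mixed_benthic_pelagic"
    # shallow-pelagic bouts must sit over water deep enough that every dive
    # clears the benthic buffer; mixed bouts only need divable bottom
    min_seafloor = 25.0 if not mixed else max(12.0, config.grid_depth_range[0])

    zero_rate = np.isneginf(config.rate_coeffs.get("const", 0.0))
    t = 0.0
    pos: tuple[float, float] | None = None
    bout_positions: list[tuple[float, float]] = []
    bout_windows: list[tuple[float, float]] = []
    dives: list[TrueDive] = []
    for bout_id in range(config.n_bouts):
        if bout_id > 0:
            t += config.inter_bout_gap_s + float(rng.exponential(120.0))
        t = float(np.ceil(t))
        lon, lat, seafloor = _sample_bout_position(rng, grid, pos, min_seafloor)
        pos = (lon, lat)
        bout_positions.append(pos)
        bout_start = t
        n_dives = 1 + int(rng.poisson(max(config.dives_per_bout_mean - 1, 0)))
        cum_underwater = 0.0
        for j in range(n_dives):
            if j > 0:
                t += float(rng.integers(*[int(v) for v in config.intra_bout_gap_range_s]))
            start = float(np.ceil(t))
            if mixed and rng.uniform() < config.benthic_fraction:
                dive_class = "benthic"
                depth = seafloor - float(rng.uniform(0, 0.8 * BENTHIC_BUFFER_M))
            else:
                dive_class = "pelagic"
                mu, sigma = config.depth_lognorm
                depth = float(rng.lognormal(mu, sigma))
                depth = min(depth, seafloor - BENTHIC_BUFFER_M - 2.0)
            depth = max(depth, 1.0)
            duration = float(rng.gamma(*config.dive_duration_gamma))
            min_dur = 2.0 * depth / DESCENT_RATE_M_S + 2.0
            duration = float(np.ceil(max(duration, min_dur, 6.0)))
            end = start + duration
            if zero_rate:
                n_events = 0
            else:
                eta = eta_true(
                    duration, depth, config.rate_coeffs, benthic=(dive_class == "benthic")
                )
                lam = np.exp(eta - config.depletion_rate * cum_underwater)
                n_events = int(rng.poisson(lam))
            intervals = _place_events(rng, n_events, start, end, config.pce_duration_gamma)
            dives.append(
                TrueDive(
                    start_s=start,
                    end_s=end,
                    max_depth_m=depth,
                    bout_id=bout_id,
                    dive_class=dive_class,
                    seafloor_depth_m=seafloor,
                    pce_intervals=intervals,
                )
            )
            cum_underwater += duration
            t = end
        bout_windows.append((bout_start, t))

    total_s = int(np.ceil(t + 600.0))

    # --- depth trace (1 Hz) ------------------------------------------------
    time_1hz = np.arange(total_s, dtype=float)
    depth_trace = np.zeros(total_s)
    for d in dives:
        sel = (time_1hz >= d.start_s) & (time_1hz < d.end_s)
        depth_trace[sel] = _trapezoid_depth(
            time_1hz[sel] - d.start_s, d.duration_s, d.max_depth_m
        )

    # --- acceleration trace (25 Hz) ----------------------------------------
    fs = 25.0
    t_acc = np.arange(0.0, total_s, 1.0 / fs)
    n_acc = t_acc.size
    # regimes: 0 flight (between bouts), 1 rest (within-bout surface), 2 swim, 3 burst
    regime = np.zeros(n_acc, dtype=np.int8)
    for bs, be in bout_windows:
        regime[(t_acc >= bs) & (t_acc < be)] = 1
    for d in dives:
        regime[(t_acc >= d.start_s) & (t_acc < d.end_s)] = 2
        for s, e in d.pce_intervals:
            regime[(t_acc >= s) & (t_acc < e)] = 3
    amp = np.choose(regime, [config.flight_amp_g, config.rest_amp_g, config.swim_amp_g, 0.0])
    freq = np.choose(
        regime, [config.flap_freq_hz, 1.0, config.swim_freq_hz, config.swim_freq_hz]
    )
    phase = 2 * np.pi * np.cumsum(freq) / fs
    az = 1.0 + amp * np.sin(phase) + rng.normal(0, config.noise_sd_g, n_acc)
    ax = rng.normal(0, config.noise_sd_g, n_acc)
    ay = rng.normal(0, config.noise_sd_g, n_acc)
    burst = regime == 3
    if burst.any():
        sd_burst = config.burst_ratio * config.swim_amp_g / np.sqrt(2.0)
        nb = int(burst.sum())
        ax[burst] += rng.normal(0, sd_burst, nb)
        ay[burst] += rng.normal(0, sd_burst, nb)
        az[burst] += rng.normal(0, sd_burst, nb)

    # --- GPS (100 s lattice) -----------------------------------------------
    t_gps = np.arange(0.0, total_s + 1, 100.0)
    lon = np.empty_like(t_gps)
    lat = np.empty_like(t_gps)
    anchors_t = [0.0]
    anchors_ll = [bout_positions[0]]
    for (bs, be), p in zip(bout_windows, bout_positions):
        anchors_t += [bs, be]
        anchors_ll += [p, p]
    anchors_t.append(float(total_s))
    anchors_ll.append(bout_positions[-1])
    at = np.array(anchors_t)
    alon = np.array([p[0] for p in anchors_ll])
    alat = np.array([p[1] for p in anchors_ll])
    order = np.argsort(at, kind="stable")
    lon = np.interp(t_gps, at[order], alon[order])
    lat = np.interp(t_gps, at[order], alat[order])

    truth = TruthRecord(
        dives=dives,
        rate_coeffs=dict(config.rate_coeffs),
        depletion_rate=config.depletion_rate,
        gain_a_s=config.gain_a_s,
        gain_b_s=config.gain_b_s,
    )
    return (
        GpsTrack(t_gps, lon, lat),
        DepthTrace(time_1hz, depth_trace),
        AccelTrace(t_acc, ax, ay, az),
        truth,
    )


def write_trip(
    outdir: str | Path,
    gps: GpsTrack,
    depth: DepthTrace,
    accel: AccelTrace,
    truth: TruthRecord,
    config: SimConfig | None = None,
) -> None:
    """Write a simulated trip in the CSV dialects the readers accept, plus truth.json."""
    from divebout.sensor_io import write_accel_csv, write_depth_csv, write_gps_csv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_depth_csv(depth, outdir / "depth.csv")
    write_accel_csv(accel, outdir / "accel.csv")
    write_gps_csv(gps, outdir / "gps.csv")
    truth.to_json(outdir / "truth.json")
    if config is not None:
        config.to_yaml(outdir / "config.yaml")


# ---------------------------------------------------------------------------
# Bout-level study-condition generators


def simulate_bout_pct(
    n_bouts: int,
    a: float = 300.0,
    b: float = 500.0,
    seed: int = 0,
    linear_slope: float | None = None,
    time_range_s: tuple[float, float] = (100.0, 4500.0),
    gamma_shape: float = 10.0,
    animal_ids: int = 1,
) -> "pd.DataFrame":
    """Bout-level (time underwater, PCT) pairs from a known gain function.

    The mean is the saturating gain a*t/(b+t), or ``linear_slope * t`` when
    ``linear_slope`` is given (the no-plateau control); PCT is Gamma about
    that mean with shape ``gamma_shape`` (CV ~= 0.32), i.e. strictly
    positive, right-skewed residence-time noise.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    t = rng.uniform(*time_range_s, size=n_bouts)
    mean = linear_slope * t if linear_slope is not None else true_gain(t, a, b)
    pct = rng.gamma(gamma_shape, np.asarray(mean) / gamma_shape)
    return pd.DataFrame(
        {
            "time_underwater_s": t,
            "pct_s": pct,
            "animal_id": [f"A{i % animal_ids + 1}" for i in range(n_bouts)],
        }
    )


def simulate_species_bouts(
    n_per_species: int = 100,
    ratio: float = 2.0,
    seed: int = 0,
    base_rate: float = 0.08,
    sigma_log: float = 0.4,
) -> "pd.DataFrame":
    """Two-species bout table where species A's PCT/time ratio is ``ratio`` x species B's.

    log(PCT) = log(rate * t) + N(0, sigma_log), rate = base_rate * ratio for
    species A; a ratio of 1 is the null used for type-I calibration.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = []
    for species, rate in (("A", base_rate * ratio), ("B", base_rate)):
        t = rng.uniform(300.0, 4500.0, size=n_per_species)
        pct = rate * t * np.exp(rng.normal(0, sigma_log, n_per_species))
        rows.append(
            pd.DataFrame({"species": species, "time_underwater_s": t, "pct_s": pct})
        )
    return pd.concat(rows, ignore_index=True)
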