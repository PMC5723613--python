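"""Readers, writers and basic conversions for tag exports.

Formats handled (all plain text):

* ``depth.csv``  — columns ``time, pressure_mbar [, temp_c]`` or ``time, depth_m``
* ``accel.csv``  — columns ``time, ax_g, ay_g, az_g``
* ``gps.csv``    — columns ``time, lon, lat``
* bathymetry    — ESRI ASCII grid (``.asc``) or a minimally geo-referenced
  GeoTIFF; seafloor depth is stored positive-down (m below the surface).

``time`` may be numeric seconds or ISO-8601 timestamps; both occur in tag
exports and are auto-detected.  All in-memory times are seconds from the
first sample of the deployment.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from divebout.errors import CoverageError, DataError, FormatError, MatchError

__all__ = [
    "DepthTrace",
    "AccelTrace",
    "GpsTrack",
    "BathymetryGrid",
    "read_depth_csv",
    "read_accel_csv",
    "read_gps_csv",
    "write_depth_csv",
    "write_accel_csv",
    "write_gps_csv",
    "read_bathymetry_asc",
    "write_bathymetry_asc",
    "read_bathymetry_geotiff",
    "pressure_to_depth",
    "estimate_surface_offset",
    "interpolate_track",
    "locate_dive",
]

#: 1 m of seawater is close to 100 mbar; no latitude/density correction applied.
MBAR_PER_METRE = 100.0

#: Small negative depths are retained down to this floor (sensor noise around zero).
DEPTH_CLIP_M = -0.5


def _check_time(time_s: np.ndarray, what: str) -> None:
    if time_s.size == 0:
        raise DataError(f"{what}: empty trace")
    diffs = np.diff(time_s)
    bad = np.nonzero(diffs <= 0)[0]
    if bad.size:
        row = int(bad[0]) + 1
        kind = "duplicate" if diffs[bad[0]] == 0 else "decreasing"
        raise DataError(f"{what}: {kind} timestamp at row {row} (t={time_s[row]!r})")


@dataclass
class DepthTrace:
    """1 Hz (nominal) depth series for one deployment, seconds from trip start."""

    time_s: np.ndarray
    depth_m: np.ndarray
    sample_rate_hz: float = 1.0

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.depth_m = np.asarray(self.depth_m, dtype=float)
        if self.time_s.shape != self.depth_m.shape:
            raise DataError("DepthTrace: time and depth lengths differ")
        _check_time(self.time_s, "DepthTrace")

    def __len__(self) -> int:
        return self.time_s.size


@dataclass
class AccelTrace:
    """25 Hz (nominal) tri-axial acceleration in g, shared clock with depth."""

    time_s: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    sample_rate_hz: float = 25.0

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.ax = np.asarray(self.ax, dtype=float)
        self.ay = np.asarray(self.ay, dtype=float)
        self.az = np.asarray(self.az, dtype=float)
        n = self.time_s.size
        if not (self.ax.size == self.ay.size == self.az.size == n):
            raise DataError("AccelTrace: channel lengths differ")
        _check_time(self.time_s, "AccelTrace")

    def __len__(self) -> int:
        return self.time_s.size


@dataclass
class GpsTrack:
    """GPS fixes (WGS84 decimal degrees), nominally every 100 s."""

    time_s: np.ndarray
    lon: np.ndarray
    lat: np.ndarray

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        if not (self.lon.size == self.lat.size == self.time_s.size):
            raise DataError("GpsTrack: column lengths differ")
        _check_time(self.time_s, "GpsTrack")
        if np.any(np.abs(self.lat) > 90) or np.any(np.abs(self.lon) > 180):
            raise DataError("GpsTrack: coordinates outside WGS84 bounds")

    def __len__(self) -> int:
        return self.time_s.size


@dataclass
class BathymetryGrid:
    """Rectangular seafloor-depth raster, metres below surface (positive down).

    ``values[0, 0]`` is the north-west cell, matching ESRI ASCII row order.
    ``x0, y0`` are the coordinates of the lower-left corner of the grid and
    ``cell`` the square cell size, in the same units as query coordinates
    (degrees or metres — the grid is agnostic).
    """

    x0: float
    y0: float
    cell: float
    values: np.ndarray
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("BathymetryGrid: values must be 2-D")
        if self.cell <= 0:
            raise ValueError("BathymetryGrid: cell size must be > 0")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax)."""
        return (
            self.x0,
            self.x0 + self.ncols * self.cell,
            self.y0,
            self.y0 + self.nrows * self.cell,
        )

    def cell_index(self, x: float, y: float) -> tuple[int, int]:
        """Nearest-cell (row, col) for a point; edge ties go to the lower index."""
        xmin, xmax, ymin, ymax = self.extent
        if not (xmin <= x <= xmax and ymin <= y <= ymax):
            raise CoverageError(f"point ({x}, {y}) outside grid extent {self.extent}")
        u = (x - self.x0) / self.cell
        v = (y - self.y0) / self.cell
        col = int(np.ceil(u)) - 1 if u == int(u) and u > 0 else int(np.floor(u))
        vrow = int(np.ceil(v)) - 1 if v == int(v) and v > 0 else int(np.floor(v))
        col = min(max(col, 0), self.ncols - 1)
        vrow = min(max(vrow, 0), self.nrows - 1)
        return self.nrows - 1 - vrow, col  # row 0 is the northernmost


# ---------------------------------------------------------------------------
# CSV readers / writers


def _parse_time(series: pd.Series, path: str | Path) -> np.ndarray:
    """Numeric seconds or ISO-8601, auto-detected; returned as seconds from first sample."""
    numeric = pd.to_numeric(series, errors="coerce")
    if numeric.notna().all():
        return numeric.to_numpy(dtype=float)
    stamps = pd.to_datetime(series, errors="coerce", format="ISO8601")
    if stamps.isna().any():
        row = int(stamps.isna().to_numpy().argmax()) + 1
        raise FormatError(f"{path}: unparseable time at row {row}: {series.iloc[row - 1]!r}")
    return (stamps - stamps.iloc[0]).dt.total_seconds().to_numpy(dtype=float)


def _read_csv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}; found {list(df.columns)}")
    return df


def read_depth_csv(path: str | Path) -> DepthTrace:
    """Read a depth trace; accepts either raw pressure (mbar) or depth (m).

    Raw pressure is converted assuming the first sample is at the surface;
    use :func:`estimate_surface_offset` for drift-aware correction.
    """
    df = _read_csv(path, ["time"])
    t = _parse_time(df["time"], path)
    if "depth_m" in df.columns:
        depth = df["depth_m"].to_numpy(dtype=float)
    elif "pressure_mbar" in df.columns:
        p = df["pressure_mbar"].to_numpy(dtype=float)
        depth = pressure_to_depth(p, float(p[0]))
    else:
        raise FormatError(f"{path}: need a 'depth_m' or 'pressure_mbar' column")
    return DepthTrace(t, depth)


def read_accel_csv(path: str | Path) -> AccelTrace:
    df = _read_csv(path, ["time", "ax_g", "ay_g", "az_g"])
    t = _parse_time(df["time"], path)
    return AccelTrace(
        t,
        df["ax_g"].to_numpy(dtype=float),
        df["ay_g"].to_numpy(dtype=float),
        df["az_g"].to_numpy(dtype=float),
    )


def read_gps_csv(path: str | Path) -> GpsTrack:
    df = _read_csv(path, ["time", "lon", "lat"])
    t = _parse_time(df["time"], path)
    return GpsTrack(t, df["lon"].to_numpy(dtype=float), df["lat"].to_numpy(dtype=float))


def write_depth_csv(trace: DepthTrace, path: str | Path) -> None:
    pd.DataFrame({"time": trace.time_s, "depth_m": trace.depth_m}).to_csv(path, index=False)


def write_accel_csv(trace: AccelTrace, path: str | Path) -> None:
    pd.DataFrame(
        {"time": trace.time_s, "ax_g": trace.ax, "ay_g": trace.ay, "az_g": trace.az}
    ).to_csv(path, index=False)


def write_gps_csv(track: GpsTrack, path: str | Path) -> None:
    pd.DataFrame({"time": track.time_s, "lon": track.lon, "lat": track.lat}).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# Bathymetry rasters


def read_bathymetry_asc(path: str | Path) -> BathymetryGrid:
    """Read an ESRI ASCII grid; values are coerced positive-down."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise FormatError(f"{path}: ESRI ASCII header missing '{key}'")
    values = np.loadtxt(lines[i:].__iter__(), dtype=float)
    values = np.atleast_2d(values)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise FormatError(
            f"{path}: grid body shape {values.shape} does not match header "
            f"({int(header['nrows'])}, {int(header['ncols'])})"
        )
    nodata = header.get("nodata_value", -9999.0)
    mask = values != nodata
    # positive-down convention: elevation grids store seafloor as negative
    if mask.any() and np.nanmedian(values[mask]) < 0:
        values = np.where(mask, -values, values)
    return BathymetryGrid(
        header["xllcorner"], header["yllcorner"], header["cellsize"], values, nodata
    )


def write_bathymetry_asc(grid: BathymetryGrid, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"ncols {grid.ncols}\nnrows {grid.nrows}\n"
            f"xllcorner {grid.x0!r}\nyllcorner {grid.y0!r}\n"
            f"cellsize {grid.cell!r}\nNODATA_value {grid.nodata!r}\n"
        )
        np.savetxt(fh, grid.values, fmt="%.6g")


def read_bathymetry_geotiff(path: str | Path) -> BathymetryGrid:
    """Read a single-band GeoTIFF with ModelPixelScale + ModelTiepoint tags."""
    import tifffile

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray().astype(float)
        tags = page.tags
        try:
            scale = tags["ModelPixelScaleTag"].value
            tie = tags["ModelTiepointTag"].value
        except KeyError as exc:
            raise FormatError(f"{path}: GeoTIFF lacks geo-referencing tags") from exc
    if values.ndim != 2:
        raise FormatError(f"{path}: expected a single-band raster")
    sx, sy = float(scale[0]), float(scale[1])
    if not np.isclose(sx, sy):
        raise FormatError(f"{path}: non-square cells ({sx} x {sy}) not supported")
    # tiepoint maps raster (0, 0) upper-left corner to world (tie[3], tie[4])
    x0 = float(tie[3])
    ytop = float(tie[4])
    y0 = ytop - values.shape[0] * sy
    if np.nanmedian(values) < 0:
        values = -values
    return BathymetryGrid(x0, y0, sx, values)


# ---------------------------------------------------------------------------
# Conversions


def pressure_to_depth(
    pressure_mbar: np.ndarray | float, surface_offset_mbar: np.ndarray | float
) -> np.ndarray | float:
    """Hydrostatic conversion: depth = (p - p_surface) / 100 mbar per metre.

    Small negative values (sensor noise at the surface) are retained down to
    -0.5 m; anything below that is clipped.
    """
    depth = (np.asarray(pressure_mbar, dtype=float) - surface_offset_mbar) / MBAR_PER_METRE
    depth = np.maximum(depth, DEPTH_CLIP_M)
    if np.ndim(pressure_mbar) == 0:
        return float(depth)
    return depth


def estimate_surface_offset(
    pressure_mbar: np.ndarray, time_s: np.ndarray, window_s: float = 600.0
) -> np.ndarray:
    """Running-minimum surface-pressure estimate for zero-offset drift correction.

    The minimum pressure within a centered window tracks the surface reading
    as long as the animal surfaces at least once per window; a light boxcar
    smooth removes the staircase.  Subtracting the returned per-sample offset
    makes surface intervals read ~0 depth.
    """
    if window_s <= 0:
        raise ValueError("window_s must be > 0")
    p = np.asarray(pressure_mbar, dtype=float)
    t = np.asarray(time_s, dtype=float)
    if t[-1] - t[0] <= window_s:
        raise ValueError(
            f"trace span {t[-1] - t[0]:.0f} s is shorter than window_s={window_s:.0f} s"
        )
    dt = float(np.median(np.diff(t)))
    half = max(int(round(window_s / (2 * dt))), 1)
    from scipy.ndimage import minimum_filter1d, uniform_filter1d

    offset = minimum_filter1d(p, size=2 * half + 1, mode="nearest")
    return uniform_filter1d(offset, size=2 * half + 1, mode="nearest")


def interpolate_track(track: GpsTrack, interval_s: float = 100.0) -> GpsTrack:
    """Regularize a GPS track onto the exact ``interval_s`` lattice.

    Positions are linearly interpolated in lon/lat between fixes; the lattice
    runs over multiples of ``interval_s`` between the first and last original
    fix, with the original endpoints preserved.
    """
    if len(track) < 2:
        raise DataError("interpolate_track: need at least 2 fixes")
    t0, t1 = track.time_s[0], track.time_s[-1]
    first = np.ceil(t0 / interval_s) * interval_s
    lattice = np.arange(first, t1 + 1e-9, interval_s)
    times = np.unique(np.concatenate([[t0], lattice, [t1]]))
    lon = np.interp(times, track.time_s, track.lon)
    lat = np.interp(times, track.time_s, track.lat)
    return GpsTrack(times, lon, lat)


def locate_dive(
    dive_start_s: float, track: GpsTrack, max_gap_s: float = 100.0
) -> tuple[float, float]:
    """Position of the regularized fix nearest in time to the dive start.

    Ties between two equally near fixes resolve to the earlier one.  A dive
    starting more than ``max_gap_s`` beyond the track's coverage cannot be
    matched.
    """
    t = track.time_s
    if dive_start_s < t[0] - max_gap_s or dive_start_s > t[-1] + max_gap_s:
        raise MatchError(
            f"dive start {dive_start_s:.0f} s outside track coverage "
            f"[{t[0]:.0f}, {t[-1]:.0f}] by more than {max_gap_s:.0f} s"
        )
    dist = np.abs(t - dive_start_s)
    i = int(np.argmin(dist))  # argmin returns the first (earlier) on ties
    return float(track.lon[i]), float(track.lat[i])
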