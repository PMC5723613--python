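"""Benthic/pelagic dive classification against charted bathymetry.

A dive whose maximum depth comes within 10 m of the seafloor at its location
is benthic; anything else is pelagic.  Seafloor depth is taken from the
nearest raster cell (no interpolation — bilinear smoothing across shelf
breaks would blur exactly the contrast the buffer rule needs).
"""

from __future__ import annotations

import logging

import numpy as np

from divebout.segmentation import Dive
from divebout.sensor_io import BathymetryGrid, GpsTrack, locate_dive

__all__ = [
    "sample_bathymetry",
    "classify_dive",
    "benthic_proportion",
    "attach_habitat",
]

logger = logging.getLogger(__name__)

BENTHIC_BUFFER_M = 10.0


def sample_bathymetry(grid: BathymetryGrid, lon: float, lat: float) -> float:
    """Seafloor depth (m, positive down) of the nearest cell; NaN where no data."""
    row, col = grid.cell_index(lon, lat)
    value = float(grid.values[row, col])
    if value == grid.nodata:
        return float("nan")
    return value


def classify_dive(
    max_depth_m: float, seafloor_depth_m: float, buffer_m: float = BENTHIC_BUFFER_M
) -> str:
    """Classify one dive as ``benthic`` or ``pelagic`` with the buffer rule.

    A dive deeper than the charted seafloor is classed benthic with a logged
    warning: the bird demonstrably reached the bottom, so the chart is wrong.
    Unknown seafloor (no-data cell) yields ``unknown``.
    """
    if not np.isfinite(seafloor_depth_m):
        return "unknown"
    if max_depth_m > seafloor_depth_m:
        logger.warning(
            "dive max depth %.1f m exceeds charted seafloor %.1f m; "
            "classing benthic (bathymetry mismatch)",
            max_depth_m,
            seafloor_depth_m,
        )
        return "benthic"
    return "benthic" if seafloor_depth_m - max_depth_m <= buffer_m else "pelagic"


def benthic_proportion(dives: list[Dive]) -> float:
    """Fraction of classified dives that are benthic; NaN if none are classified."""
    classified = [d for d in dives if d.dive_class in ("benthic", "pelagic")]
    if not classified:
        return float("nan")
    return sum(d.dive_class == "benthic" for d in classified) / len(classified)


def attach_habitat(
    dives: list[Dive],
    track: GpsTrack,
    grid: BathymetryGrid,
    buffer_m: float = BENTHIC_BUFFER_M,
) -> list[Dive]:
    """Locate each dive on the regularized track, sample bathymetry, classify.

    Mutates and returns ``dives``.  Dives that cannot be located or fall on
    no-data cells keep class ``unknown`` (excluded from class-specific models).
    """
    from divebout.errors import CoverageError, MatchError

    for d in dives:
        try:
            d.lon, d.lat = locate_dive(d.start_s, track)
            d.seafloor_depth_m = sample_bathymetry(grid, d.lon, d.lat)
        except (MatchError, CoverageError) as exc:
            logger.warning("dive %d left unclassified: %s", d.dive_id, exc)
            continue
        d.dive_class = classify_dive(d.max_depth_m, d.seafloor_depth_m, buffer_m)
    return dives
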