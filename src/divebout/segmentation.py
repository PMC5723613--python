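"""Dive detection and bout segmentation from corrected depth traces.

A dive is a maximal submerged run (depth above the wet threshold) whose
maximum depth reaches at least 1 m; a dive bout is a maximal group of
consecutive dives whose inter-dive surface gaps are at most 300 s, so an
isolated dive forms a bout of one.  Thresholds are inclusive (>= 1 m,
<= 300 s) and the inter-dive gap is measured from the end of one dive to
the start of the next.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from divebout.errors import DataError
from divebout.sensor_io import DepthTrace

__all__ = ["Dive", "Bout", "detect_dives", "segment_bouts", "dive_metrics"]

DEPTH_THRESHOLD_M = 1.0   # minimum max depth for a submerged run to count as a dive
WET_THRESHOLD_M = 0.5     # submersion threshold defining dive start/end
BOUT_GAP_S = 300.0        # maximum inter-dive surface gap within a bout


@dataclass
class Dive:
    """One dive: half-open interval [start_s, end_s) on the deployment clock."""

    start_s: float
    end_s: float
    max_depth_m: float
    dive_id: int = -1
    bout_id: int = -1
    dive_class: str = "unknown"  # benthic | pelagic | unknown
    n_pce: int = 0
    lon: float = np.nan
    lat: float = np.nan
    seafloor_depth_m: float = np.nan

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class Bout:
    """A dive bout; may hold a single dive."""

    bout_id: int
    dives: list[Dive] = field(default_factory=list)
    pct_s: float = 0.0

    @property
    def n_dives(self) -> int:
        return len(self.dives)

    @property
    def time_underwater_s(self) -> float:
        return float(sum(d.duration_s for d in self.dives))

    @property
    def start_position(self) -> tuple[float, float]:
        return self.dives[0].lon, self.dives[0].lat


def detect_dives(
    trace: DepthTrace,
    depth_threshold_m: float = DEPTH_THRESHOLD_M,
    wet_threshold_m: float = WET_THRESHOLD_M,
) -> list[Dive]:
    """Detect dives as submerged runs reaching ``depth_threshold_m``.

    A run starts at the first sample with depth > ``wet_threshold_m`` and
    ends at the first sample back at or below it (half-open, so the end
    timestamp is the first dry sample).  Runs whose maximum depth stays below
    ``depth_threshold_m`` are discarded.  An unfinished run at the end of the
    trace is closed at one sample period past the last sample.
    """
    if len(trace) == 0:
        raise DataError("detect_dives: empty trace")
    depth = trace.depth_m
    t = trace.time_s
    wet = depth > wet_threshold_m
    # run boundaries via sign changes of the wet indicator
    padded = np.concatenate([[False], wet, [False]])
    edges = np.diff(padded.astype(np.int8))
    starts = np.nonzero(edges == 1)[0]
    ends = np.nonzero(edges == -1)[0]  # index of first dry sample (exclusive)
    dt = float(np.median(np.diff(t))) if len(trace) > 1 else 1.0
    dives: list[Dive] = []
    for s, e in zip(starts, ends):
        max_depth = float(depth[s:e].max())
        if max_depth >= depth_threshold_m:
            end_t = t[e] if e < t.size else t[-1] + dt
            dives.append(Dive(start_s=float(t[s]), end_s=float(end_t), max_depth_m=max_depth))
    for i, d in enumerate(dives):
        d.dive_id = i
    return dives


def segment_bouts(dives: list[Dive], gap_s: float = BOUT_GAP_S) -> list[Bout]:
    """Group sorted dives into bouts; a new bout opens when the surface gap exceeds ``gap_s``."""
    if not dives:
        return []
    for prev, nxt in zip(dives, dives[1:]):
        if nxt.start_s < prev.end_s:
            raise DataError(
                f"segment_bouts: dives overlap ({prev.end_s:.1f} > {nxt.start_s:.1f})"
            )
    bouts: list[Bout] = [Bout(bout_id=0, dives=[dives[0]])]
    for prev, nxt in zip(dives, dives[1:]):
        if nxt.start_s - prev.end_s > gap_s:
            bouts.append(Bout(bout_id=len(bouts), dives=[]))
        bouts[-1].dives.append(nxt)
    for bout in bouts:
        for d in bout.dives:
            d.bout_id = bout.bout_id
    return bouts


def dive_metrics(dive: Dive, trace: DepthTrace) -> tuple[float, float]:
    """(max_depth_m, duration_s) of a dive measured against its source trace."""
    sel = (trace.time_s >= dive.start_s) & (trace.time_s < dive.end_s)
    if not sel.any():
        raise DataError(
            f"dive_metrics: dive [{dive.start_s}, {dive.end_s}) outside trace "
            f"[{trace.time_s[0]}, {trace.time_s[-1]}]"
        )
    return float(trace.depth_m[sel].max()), dive.duration_s


def dives_to_frame(dives: list[Dive]) -> pd.DataFrame:
    """Tabular dive record matching the dives.csv dialect."""
    return pd.DataFrame(
        {
            "dive_id": [d.dive_id for d in dives],
            "start": [d.start_s for d in dives],
            "end": [d.end_s for d in dives],
            "duration_s": [d.duration_s for d in dives],
            "max_depth_m": [d.max_depth_m for d in dives],
            "class": [d.dive_class for d in dives],
            "n_pce": [d.n_pce for d in dives],
            "bout_id": [d.bout_id for d in dives],
            "lon": [d.lon for d in dives],
            "lat": [d.lat for d in dives],
            "seafloor_depth_m": [d.seafloor_depth_m for d in dives],
        }
    )


def bouts_to_frame(bouts: list[Bout]) -> pd.DataFrame:
    """Tabular bout record matching the bouts.csv dialect."""
    return pd.DataFrame(
        {
            "bout_id": [b.bout_id for b in bouts],
            "n_dives": [b.n_dives for b in bouts],
            "time_underwater_s": [b.time_underwater_s for b in bouts],
            "pct_s": [b.pct_s for b in bouts],
            "lon": [b.start_position[0] for b in bouts],
            "lat": [b.start_position[1] for b in bouts],
        }
    )
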