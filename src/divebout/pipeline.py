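"""End-to-end orchestration: raw traces -> dive/bout tables -> model suite."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from divebout.behavior import classify_behavior
from divebout.habitat import attach_habitat, benthic_proportion
from divebout.segmentation import bouts_to_frame, detect_dives, dives_to_frame, segment_bouts
from divebout.sensor_io import AccelTrace, BathymetryGrid, DepthTrace, GpsTrack, interpolate_track
from divebout.simulate import SimConfig, simulate_bathymetry, simulate_trip

logger = logging.getLogger(__name__)

__all__ = ["process_deployment", "run_two_species_demo"]


def process_deployment(
    gps: GpsTrack,
    depth: DepthTrace,
    accel: AccelTrace,
    grid: BathymetryGrid,
    animal_id: str,
    seed: int = 0,
    K: int = 4,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run segmentation, behavioral classification and habitat classification
    for one deployment; returns (dives, bouts) tables keyed by ``animal_id``."""
    dives = detect_dives(depth)
    bouts = segment_bouts(dives)
    classify_behavior(accel, dives, bouts, K=K, seed=seed)
    attach_habitat(dives, interpolate_track(gps), grid)
    dd = dives_to_frame(dives)
    bb = bouts_to_frame(bouts)
    dd["animal_id"] = animal_id
    bb["animal_id"] = animal_id
    # bout ids must be unique across deployments when pooled
    dd["bout_id"] = animal_id + "_" + dd["bout_id"].astype(str)
    bb["bout_id"] = animal_id + "_" + bb["bout_id"].astype(str)
    return dd, bb


def run_two_species_demo(
    outdir: Path | None = None,
    seed: int = 0,
    n_razorbills: int = 3,
    n_guillemots: int = 2,
    razorbill_kw: dict | None = None,
    guillemot_kw: dict | None = None,
) -> dict:
    """Simulate and analyse a two-species scenario end to end.

    A shallow pelagic species with within-bout depletion (saturating bout
    gain) and a deeper mixed benthic/pelagic species with near-linear gain
    are simulated, processed to dive and bout tables, and run through the
    dive-level model selection, the bout-level gain models and the species
    comparison.  Returns a summary dict of the headline quantities.
    """
    from divebout.foraging import (
        run_bout_models,
        run_guillemot_dive_models,
        run_razorbill_dive_models,
        run_species_comparison,
        render_outputs,
    )

    ss = np.random.SeedSequence(seed)
    child = ss.generate_state(2 * (n_razorbills + n_guillemots)) % (2**31)
    tables: dict[str, list] = {"razorbill": [], "guillemot": []}
    benthic_props: dict[str, float] = {}
    i = 0
    for species, n_birds in (("razorbill", n_razorbills), ("guillemot", n_guillemots)):
        for j in range(n_birds):
            kw = (razorbill_kw if species == "razorbill" else guillemot_kw) or {}
            cfg = (
                SimConfig.razorbill_like(seed=int(child[i]), **kw)
                if species == "razorbill"
                else SimConfig.guillemot_like(seed=int(child[i]), **kw)
            )
            grid = simulate_bathymetry(
                cfg.grid_extent, cfg.grid_resolution, cfg.seed, cfg.grid_depth_range
            )
            gps, depth, accel, _truth = simulate_trip(cfg, grid)
            aid = f"{species[:4].upper()}{j + 1}"
            dd, bb = process_deployment(
                gps, depth, accel, grid, aid, seed=int(child[i + 1]), K=4
            )
            benthic_props[aid] = float((dd["class"] == "benthic").mean())
            tables[species].append((dd, bb))
            i += 2

    razo_d = pd.concat([t[0] for t in tables["razorbill"]], ignore_index=True)
    razo_b = pd.concat([t[1] for t in tables["razorbill"]], ignore_index=True)
    gui_d = pd.concat([t[0] for t in tables["guillemot"]], ignore_index=True)
    gui_b = pd.concat([t[1] for t in tables["guillemot"]], ignore_index=True)

    razo_suite = run_razorbill_dive_models(razo_d[razo_d["class"] != "benthic"])
    gui_suite = run_guillemot_dive_models(gui_d)
    razo_bouts = run_bout_models(razo_b, "razorbill")
    gui_bouts = run_bout_models(gui_b, "guillemot")
    comparison = run_species_comparison(
        pd.concat(
            [razo_b.assign(species="razorbill"), gui_b.assign(species="guillemot")],
            ignore_index=True,
        )
    )
    species_row = [ix for ix in comparison.index if "species" in str(ix)][0]

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        razo_d.to_csv(outdir / "razorbill_dives.csv", index=False)
        razo_b.to_csv(outdir / "razorbill_bouts.csv", index=False)
        gui_d.to_csv(outdir / "guillemot_dives.csv", index=False)
        gui_b.to_csv(outdir / "guillemot_bouts.csv", index=False)
        render_outputs(razo_suite, outdir, prefix="dives_razorbill", seed=seed)
        render_outputs(gui_suite, outdir, prefix="dives_guillemot", seed=seed)
        render_outputs(razo_bouts, outdir, prefix="bouts_razorbill", seed=seed)
        render_outputs(gui_bouts, outdir, prefix="bouts_guillemot", seed=seed)
        comparison.to_csv(outdir / "species_comparison.csv")

    return {
        "n_dives": {"razorbill": len(razo_d), "guillemot": len(gui_d)},
        "n_bouts": {"razorbill": len(razo_b), "guillemot": len(gui_b)},
        "benthic_proportion": benthic_props,
        "razorbill_selected": razo_suite.selected,
        "guillemot_selected": gui_suite.selected,
        "razorbill_plateaus": razo_bouts.extras["plateaus"],
        "guillemot_plateaus": gui_bouts.extras["plateaus"],
        "species_coefficient": float(comparison.loc[species_row, "coef"]),
        "species_p": float(comparison.loc[species_row, "p"]),
    }
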