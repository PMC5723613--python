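"""The study's model suite: dive-level PCE models, bout-level PCT models,
and the between-species comparison.

Dive level (Poisson, log link, bout random effect, animal fixed effect):
six candidate structures for a pelagic-only species — individual-specific
or species-level smooths of dive duration and maximum depth, entering
additively, as an anisotropic tensor interaction, or both (basis dimension
5) — and three class-specific structures for a benthic/pelagic species with
a class-specific bathymetry slope (isotropic basis dimension 3, tensor 5).
Candidates are ranked by AIC; structures within 2 AIC units of the best are
treated as equally supported and the simplest (fewest effective degrees of
freedom) is selected.

Bout level: pursuit-and-catching time (PCT) against time underwater, as a
Tweedie (p = 1.05) GAM with individual-specific k=3 smooths for the
razorbill-like path, or a Gaussian model on log(PCT) vs log(time) for the
guillemot-like path.  The species comparison is an ordinary linear model of
log(PCT) on log(time underwater) plus a species indicator.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from divebout.errors import DataError, FitError
from divebout.gam import (
    FactorTerm,
    GamFit,
    GamSpec,
    Gaussian,
    LinearByFactorTerm,
    Poisson,
    RandomEffectTerm,
    SmoothTerm,
    Tweedie,
    fit_gam,
    predict,
    select_model,
)

__all__ = [
    "ModelSuiteResult",
    "run_razorbill_dive_models",
    "run_guillemot_dive_models",
    "run_bout_models",
    "run_species_comparison",
    "render_outputs",
    "select_with_parsimony",
]

logger = logging.getLogger(__name__)

AIC_EQUAL_SUPPORT = 2.0  # candidates within this many AIC units are "equally supported"
MIN_BOUTS_PER_ANIMAL = 5
TWEEDIE_P = 1.05


@dataclass
class ModelSuiteResult:
    """Fits, AIC ranking, the selected structure and its prediction products."""

    fits: dict[str, GamFit]
    aic_table: pd.DataFrame
    selected: str
    predictions: dict[str, pd.DataFrame] = field(default_factory=dict)
    extras: dict = field(default_factory=dict)

    @property
    def selected_fit(self) -> GamFit:
        return self.fits[self.selected]


def select_with_parsimony(fits: dict[str, GamFit]) -> tuple[str, pd.DataFrame]:
    """AIC ranking with the equal-support rule: within 2 AIC units of the
    best, prefer the structure with the fewest effective degrees of freedom."""
    table = select_model(list(fits.values()))
    near = table[table["delta_aic"] < AIC_EQUAL_SUPPORT]
    chosen = near.sort_values(["edf", "aic"], kind="stable").iloc[0]["label"]
    return str(chosen), table


def _check_dive_frame(dives: pd.DataFrame, need: list[str]) -> None:
    missing = [c for c in need if c not in dives.columns]
    if missing:
        raise DataError(f"dive table missing column(s) {missing}")


def run_razorbill_dive_models(
    dives: pd.DataFrame,
    k: int = 5,
    grid_size: int = 20,
    outer_maxiter: int = 60,
) -> ModelSuiteResult:
    """Dive-level PCE models for a pelagic-only species (six structures).

    ``dives`` needs n_pce, duration_s, max_depth_m, animal_id, bout_id, and
    must contain no benthic dives (the pelagic-only pathway).
    """
    _check_dive_frame(dives, ["n_pce", "duration_s", "max_depth_m", "animal_id", "bout_id"])
    if "class" in dives.columns and (dives["class"] == "benthic").any():
        raise DataError("pelagic-only model path received benthic dives")
    base = [FactorTerm("animal_id"), RandomEffectTerm("bout_id")]
    fam = Poisson()

    def smooth_set(by: str | None) -> dict[str, list]:
        sfx = "id" if by else "sp"
        return {
            f"additive_{sfx}": [
                SmoothTerm(("duration_s",), k=k, by=by),
                SmoothTerm(("max_depth_m",), k=k, by=by),
            ],
            f"interaction_{sfx}": [SmoothTerm(("duration_s", "max_depth_m"), k=(k, k), by=by)],
            f"both_{sfx}": [
                SmoothTerm(("duration_s",), k=k, by=by),
                SmoothTerm(("max_depth_m",), k=k, by=by),
                SmoothTerm(("duration_s", "max_depth_m"), k=(k, k), by=by),
            ],
        }

    candidates: dict[str, list] = {}
    candidates.update(smooth_set("animal_id"))
    candidates.update(smooth_set(None))
    fits: dict[str, GamFit] = {}
    for label, smooths in candidates.items():
        spec = GamSpec("n_pce", fam, smooths + base, label=label)
        fits[label] = fit_gam(spec, dives, outer_maxiter=outer_maxiter)
    selected, table = select_with_parsimony(fits)
    surface = _prediction_surface(fits[selected], dives, grid_size)
    return ModelSuiteResult(fits=fits, aic_table=table, selected=selected,
                            predictions={"surface": surface})


def run_guillemot_dive_models(
    dives: pd.DataFrame,
    k_iso: int = 3,
    k_tensor: int = 5,
    grid_size: int = 20,
    outer_maxiter: int = 60,
) -> ModelSuiteResult:
    """Dive-level PCE models with class-specific (benthic/pelagic) smooths.

    Three structures: class-specific additive smooths, class-specific tensor
    interaction, or both — all with a class-specific bathymetry slope,
    animal fixed effect and bout random effect.
    """
    _check_dive_frame(
        dives,
        ["n_pce", "duration_s", "max_depth_m", "animal_id", "bout_id", "class",
         "seafloor_depth_m"],
    )
    known = dives[dives["class"].isin(["benthic", "pelagic"])].copy()
    if known.empty:
        raise DataError("no dives with known benthic/pelagic class")
    if known["class"].nunique() == 1:
        logger.warning(
            "only %s dives present; class-specific terms degenerate to one level",
            known["class"].iloc[0],
        )
    base = [
        FactorTerm("class"),
        LinearByFactorTerm("seafloor_depth_m", by="class"),
        FactorTerm("animal_id"),
        RandomEffectTerm("bout_id"),
    ]
    candidates = {
        "additive_class": [
            SmoothTerm(("duration_s",), k=k_iso, by="class"),
            SmoothTerm(("max_depth_m",), k=k_iso, by="class"),
        ],
        "interaction_class": [
            SmoothTerm(("duration_s", "max_depth_m"), k=(k_tensor, k_tensor), by="class")
        ],
        "both_class": [
            SmoothTerm(("duration_s",), k=k_iso, by="class"),
            SmoothTerm(("max_depth_m",), k=k_iso, by="class"),
            SmoothTerm(("duration_s", "max_depth_m"), k=(k_tensor, k_tensor), by="class"),
        ],
    }
    fits: dict[str, GamFit] = {}
    for label, smooths in candidates.items():
        spec = GamSpec("n_pce", Poisson(), smooths + base, label=label)
        fits[label] = fit_gam(spec, known, outer_maxiter=outer_maxiter)
    selected, table = select_with_parsimony(fits)
    preds = {
        f"surface_{cls}": _prediction_surface(
            fits[selected], known[known["class"] == cls], grid_size, fixed={"class": cls}
        )
        for cls in known["class"].unique()
    }
    return ModelSuiteResult(fits=fits, aic_table=table, selected=selected, predictions=preds)


def _prediction_surface(
    fit: GamFit, dives: pd.DataFrame, grid_size: int, fixed: dict | None = None
) -> pd.DataFrame:
    """Response-scale PCE surface over the observed (duration, depth) box."""
    g1 = np.linspace(dives["duration_s"].min(), dives["duration_s"].max(), grid_size)
    g2 = np.linspace(dives["max_depth_m"].min(), dives["max_depth_m"].max(), grid_size)
    G1, G2 = np.meshgrid(g1, g2)
    nd = pd.DataFrame({"duration_s": G1.ravel(), "max_depth_m": G2.ravel()})
    # reference levels for factors not being varied
    nd["animal_id"] = dives["animal_id"].mode().iloc[0]
    nd["bout_id"] = "_new_"
    if "seafloor_depth_m" in dives.columns:
        nd["seafloor_depth_m"] = float(dives["seafloor_depth_m"].median())
    if "class" in dives.columns:
        nd["class"] = dives["class"].mode().iloc[0]
    for key, val in (fixed or {}).items():
        nd[key] = val
    pr = predict(fit, nd)
    out = nd[["duration_s", "max_depth_m"]].copy()
    out[["pce", "lo", "hi"]] = pr[["fit", "lo", "hi"]]
    return out


def run_bout_models(
    bouts: pd.DataFrame,
    species_path: str,
    k: int = 3,
    n_grid: int = 50,
    outer_maxiter: int = 60,
) -> ModelSuiteResult:
    """Bout-level PCT vs time-underwater model for one species.

    ``species_path='razorbill'``: Tweedie (p=1.05) with individual-specific
    k=3 smooths of time underwater (zero PCT allowed — the family's point
    mass at zero is the reason it is used).  ``species_path='guillemot'``:
    Gaussian on log(PCT) vs a smooth of log(time underwater) (zero-PCT bouts
    excluded with a logged count).  Individuals with fewer than 5 bouts are
    dropped with a warning.  Produces per-individual prediction curves with
    95% intervals and a plateau summary (maximum of the fitted curve and the
    time at which it is reached).
    """
    if species_path not in ("razorbill", "guillemot"):
        raise ValueError("species_path must be 'razorbill' or 'guillemot'")
    need = ["time_underwater_s", "pct_s", "animal_id"]
    _check_dive_frame(bouts, need)
    data = bouts.copy()
    counts = data["animal_id"].value_counts()
    thin = counts[counts < MIN_BOUTS_PER_ANIMAL].index.tolist()
    if thin:
        logger.warning("skipping individuals with <%d bouts: %s", MIN_BOUTS_PER_ANIMAL, thin)
        data = data[~data["animal_id"].isin(thin)]
    if data.empty:
        raise FitError("no individual has enough bouts to fit")
    multi = data["animal_id"].nunique() > 1
    by = "animal_id" if multi else None
    extra = [FactorTerm("animal_id")] if multi else []

    if species_path == "razorbill":
        spec = GamSpec(
            "pct_s",
            Tweedie(p=TWEEDIE_P),
            [SmoothTerm(("time_underwater_s",), k=k, by=by)] + extra,
            label="tweedie_bout",
        )
        fit = fit_gam(spec, data, outer_maxiter=outer_maxiter)
        xname = "time_underwater_s"
    else:
        nz = data["pct_s"] > 0
        if (~nz).any():
            logger.warning("guillemot path: excluding %d zero-PCT bouts", int((~nz).sum()))
        data = data[nz].copy()
        if data.empty:
            raise FitError("log-Gaussian bout model: no positive-PCT bouts")
        data["log_pct"] = np.log(data["pct_s"])
        data["log_time"] = np.log(data["time_underwater_s"])
        spec = GamSpec(
            "log_pct",
            Gaussian(),
            [SmoothTerm(("log_time",), k=k, by=by)] + extra,
            label="loggauss_bout",
        )
        fit = fit_gam(spec, data, outer_maxiter=outer_maxiter)
        xname = "log_time"

    curves = {}
    plateaus = {}
    for aid, sub in data.groupby("animal_id"):
        tt = np.linspace(sub[xname].min(), sub[xname].max(), n_grid)
        nd = pd.DataFrame({xname: tt, "animal_id": aid})
        pr = predict(fit, nd)
        if species_path == "guillemot":
            t_resp = np.exp(tt)
            curve = pd.DataFrame(
                {"time_underwater_s": t_resp, "pct": np.exp(pr["fit"]),
                 "lo": np.exp(pr["lo"]), "hi": np.exp(pr["hi"])}
            )
        else:
            curve = pd.DataFrame(
                {"time_underwater_s": tt, "pct": pr["fit"], "lo": pr["lo"], "hi": pr["hi"]}
            )
        curves[str(aid)] = curve
        imax = int(curve["pct"].to_numpy().argmax())
        plateaus[str(aid)] = {
            "plateau_pct_s": float(curve["pct"].iloc[imax]),
            "t_at_plateau_s": float(curve["time_underwater_s"].iloc[imax]),
            "rises_to_plateau": bool(
                np.all(np.diff(curve["pct"].to_numpy()[: imax + 1]) > -1e-9)
            ),
        }
    table = select_model([fit])
    return ModelSuiteResult(
        fits={spec.label: fit},
        aic_table=table,
        selected=spec.label,
        predictions=curves,
        extras={"plateaus": plateaus},
    )


def run_species_comparison(bouts_both: pd.DataFrame) -> pd.DataFrame:
    """Linear model of log(PCT) on log(time underwater) + species.

    Requires both species and strictly positive PCT and time (log scale).
    Returns the coefficient table (estimate, SE, t, p) from ordinary least
    squares; the species coefficient is the log ratio of PCT-per-time
    between the species.
    """
    import statsmodels.formula.api as smf

    need = ["species", "time_underwater_s", "pct_s"]
    _check_dive_frame(bouts_both, need)
    if bouts_both["species"].nunique() < 2:
        raise DataError("species comparison needs both species present")
    data = bouts_both[(bouts_both["pct_s"] > 0) & (bouts_both["time_underwater_s"] > 0)].copy()
    data["log_pct"] = np.log(data["pct_s"])
    data["log_time"] = np.log(data["time_underwater_s"])
    res = smf.ols("log_pct ~ log_time + C(species)", data=data).fit()
    out = pd.DataFrame(
        {"coef": res.params, "se": res.bse, "t": res.tvalues, "p": res.pvalues}
    )
    return out


def render_outputs(
    suite: ModelSuiteResult,
    outdir: str | Path,
    prefix: str = "suite",
    seed: int | None = None,
    config_hash: str | None = None,
    make_plots: bool = True,
) -> list[Path]:
    """Write AIC tables, prediction surfaces/curves (CSV + heatmap/curve PNGs)
    and a run log; returns the list of files written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    p = outdir / f"{prefix}_aic.csv"
    suite.aic_table.to_csv(p, index=False)
    written.append(p)
    for name, frame in suite.predictions.items():
        p = outdir / f"{prefix}_{name}.csv"
        frame.to_csv(p, index=False)
        written.append(p)
        if make_plots:
            written.append(_plot_prediction(frame, outdir / f"{prefix}_{name}.png"))
    log = {
        "selected": suite.selected,
        "seed": seed,
        "config_hash": config_hash,
        "aic": suite.aic_table.to_dict(orient="records"),
        "extras": suite.extras,
    }
    p = outdir / f"{prefix}_runlog.json"
    p.write_text(json.dumps(log, indent=1, default=str))
    written.append(p)
    return written


def _plot_prediction(frame: pd.DataFrame, path: Path) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    if {"duration_s", "max_depth_m", "pce"} <= set(frame.columns):
        n = int(np.sqrt(len(frame)))
        Z = frame["pce"].to_numpy().reshape(n, n)
        im = ax.imshow(
            Z,
            origin="lower",
            aspect="auto",
            extent=[frame["duration_s"].min(), frame["duration_s"].max(),
                    frame["max_depth_m"].min(), frame["max_depth_m"].max()],
        )
        fig.colorbar(im, ax=ax, label="predicted PCE per dive")
        ax.set_xlabel("dive duration (s)")
        ax.set_ylabel("max dive depth (m)")
    else:
        ax.plot(frame["time_underwater_s"], frame["pct"], "-")
        ax.fill_between(frame["time_underwater_s"], frame["lo"], frame["hi"], alpha=0.25)
        ax.set_xlabel("time underwater in bout (s)")
        ax.set_ylabel("predicted PCT (s)")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path
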