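"""Model comparison and collinearity diagnostics."""

from __future__ import annotations

import numpy as np
import pandas as pd

from divebout.errors import FitError
from divebout.gam.model import GamFit

__all__ = ["aic", "rsq_adj", "select_model", "compute_vif"]


def aic(fit: GamFit) -> float:
    """AIC on effective degrees of freedom (plus one for an estimated dispersion)."""
    return fit.aic


def rsq_adj(fit: GamFit) -> float:
    """Adjusted R-squared on the response scale with edf in the denominator."""
    return fit.rsq_adj


def select_model(fits: list[GamFit]) -> pd.DataFrame:
    """Rank candidate fits by AIC (ascending); ties break toward fewer edf.

    All fits must target the same response on data of the same size.
    """
    if not fits:
        raise FitError("select_model: no fits supplied")
    key = fits[0].data_shape_hash
    if any(f.data_shape_hash != key for f in fits):
        raise FitError("select_model: fits are not on identical data/response")
    rows = pd.DataFrame(
        {
            "label": [f.spec.label or f"model_{i}" for i, f in enumerate(fits)],
            "aic": [f.aic for f in fits],
            "edf": [f.edf_total for f in fits],
            "loglik": [f.loglik for f in fits],
            "rsq_adj": [f.rsq_adj for f in fits],
        }
    )
    rows = rows.sort_values(["aic", "edf"], kind="stable").reset_index(drop=True)
    rows["delta_aic"] = rows["aic"] - rows["aic"].iloc[0]
    return rows


def compute_vif(covariates: pd.DataFrame) -> pd.Series:
    """Variance inflation factors: VIF_j = 1 / (1 - R^2_j).

    Each covariate is regressed (with intercept) on all the others; exact
    collinearity yields infinity.
    """
    cols = list(covariates.columns)
    if len(cols) < 2:
        raise ValueError("compute_vif: need at least 2 covariates")
    Xall = covariates.to_numpy(dtype=float)
    n = Xall.shape[0]
    if n <= len(cols):
        raise ValueError("compute_vif: need more rows than covariates")
    out = {}
    for j, name in enumerate(cols):
        yj = Xall[:, j]
        Xo = np.column_stack([np.ones(n), np.delete(Xall, j, axis=1)])
        coef, *_ = np.linalg.lstsq(Xo, yj, rcond=None)
        resid = yj - Xo @ coef
        tss = float(((yj - yj.mean()) ** 2).sum())
        rss = float((resid**2).sum())
        if tss == 0:
            out[name] = np.inf
            continue
        r2 = 1.0 - rss / tss
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")
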