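"""Penalized IRLS fitting with Laplace-approximate ML smoothing selection.

For fixed smoothing parameters the coefficients minimize the penalized
deviance D(beta) + sum_j lambda_j beta' S_j beta (penalized iteratively
reweighted least squares, with step halving so the penalized deviance is
non-increasing).  The smoothing parameters maximize a Laplace approximation
to the marginal likelihood in which the penalties act as improper Gaussian
priors beta ~ N(0, phi S_lambda^-):

    ML(rho) = l(beta_hat; phi) - pen/(2 phi) + 1/2 log|S_lambda|_+
              - 1/2 log|X'WX + S_lambda| + ((q - r)/2) log(2 pi)
              + ((q - r)/2) log phi

with r = rank(S_lambda), q coefficients, pen = beta_hat' S_lambda beta_hat.
The outer optimizer is Nelder-Mead on log smoothing parameters started from
lambda = 1; the dispersion phi is profiled (closed form for Gaussian, 1-D
numerical profile for Tweedie, fixed at 1 for Poisson).

Effective degrees of freedom are the trace of (X'WX + S)^{-1} X'WX and
AIC = -2 loglik + 2 (edf + #dispersion parameters).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve

from divebout.errors import FitError
from divebout.gam.families import Family, Gaussian, Poisson, Tweedie
from divebout.gam.terms import InterceptTerm, Term

__all__ = ["GamSpec", "GamFit", "fit_gam", "predict"]

logger = logging.getLogger(__name__)


@dataclass
class GamSpec:
    """Response, family and term list of one model structure."""

    response: str
    family: Family
    terms: list[Term]
    include_intercept: bool = True
    label: str = ""

    def all_terms(self) -> list[Term]:
        base: list[Term] = [InterceptTerm()] if self.include_intercept else []
        return base + list(self.terms)

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        from divebout.gam import terms as T

        def describe(t: Term) -> dict:
            if isinstance(t, T.SmoothTerm):
                k = list(t.k) if isinstance(t.k, tuple) else t.k
                return {"type": "smooth", "covariates": list(t.covariates), "k": k,
                        "by": t.by}
            if isinstance(t, T.RandomEffectTerm):
                return {"type": "random_effect", "factor": t.factor}
            if isinstance(t, T.LinearByFactorTerm):
                return {"type": "linear_by", "name": t.name, "by": t.by}
            if isinstance(t, T.LinearTerm):
                return {"type": "linear", "name": t.name}
            if isinstance(t, T.FactorTerm):
                return {"type": "factor", "name": t.name}
            raise TypeError(f"cannot serialize term {t!r}")

        fam: dict = {"name": self.family.name}
        if isinstance(self.family, Tweedie):
            fam["p"] = self.family.p
        obj = {"response": self.response, "family": fam, "label": self.label,
               "include_intercept": self.include_intercept,
               "terms": [describe(t) for t in self.terms]}
        Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GamSpec":
        import yaml

        from divebout.gam import terms as T

        obj = yaml.safe_load(Path(path).read_text())
        fam_map = {"gaussian": Gaussian, "poisson": Poisson, "tweedie": Tweedie}
        fam_args = {k: v for k, v in obj["family"].items() if k != "name"}
        family = fam_map[obj["family"]["name"]](**fam_args)

        def build(d: dict) -> Term:
            kind = d["type"]
            if kind == "smooth":
                k = tuple(d["k"]) if isinstance(d["k"], list) else d["k"]
                return T.SmoothTerm(tuple(d["covariates"]), k=k, by=d.get("by"))
            if kind == "random_effect":
                return T.RandomEffectTerm(d["factor"])
            if kind == "linear_by":
                return T.LinearByFactorTerm(d["name"], d["by"])
            if kind == "linear":
                return T.LinearTerm(d["name"])
            if kind == "factor":
                return T.FactorTerm(d["name"])
            raise ValueError(f"unknown term type {kind!r}")

        return cls(response=obj["response"], family=family,
                   terms=[build(t) for t in obj["terms"]],
                   include_intercept=obj.get("include_intercept", True),
                   label=obj.get("label", ""))


@dataclass
class GamFit:
    """A fitted GAM: coefficients, smoothing parameters and diagnostics."""

    spec: GamSpec
    beta: np.ndarray
    lambdas: np.ndarray            # one per penalty
    phi: float
    term_slices: list[slice]
    term_labels: list[str]
    edf_by_term: dict[str, float]
    edf_total: float               # trace of the influence matrix
    loglik: float
    aic: float
    rsq_adj: float
    deviance: float
    null_deviance: float
    cov_beta: np.ndarray
    converged: bool
    n_obs: int
    penalized_deviance_path: np.ndarray = field(default_factory=lambda: np.array([]))
    ml_criterion: float = np.nan
    data_shape_hash: int = 0
    penalty_scales: np.ndarray = field(default_factory=lambda: np.array([]))
    penalty_labels: list[str] = field(default_factory=list)

    @property
    def edf_with_scale(self) -> float:
        return self.edf_total + (1.0 if self.spec.family.has_dispersion else 0.0)

    @property
    def lambdas_effective(self) -> np.ndarray:
        """Smoothing parameters on the raw (unscaled) penalty scale."""
        return self.lambdas * self.penalty_scales

    def variance_components(self) -> dict[str, float]:
        """Variance component phi / lambda_effective for each random-effect term."""
        out = {}
        for lab, lam_eff in zip(self.penalty_labels, self.lambdas_effective):
            if lab.startswith("re("):
                out[lab] = self.phi / lam_eff
        return out

    def fitted(self, data: pd.DataFrame) -> np.ndarray:
        X = _design(self.spec, data, fitting=False)[0]
        return self.spec.family.inv_link(X @ self.beta)

    def to_json(self, path: str | Path) -> None:
        obj = {
            "label": self.spec.label,
            "family": self.spec.family.name,
            "coefficients": self.beta.tolist(),
            "lambdas": self.lambdas.tolist(),
            "phi": self.phi,
            "edf_by_term": self.edf_by_term,
            "edf_total": self.edf_total,
            "loglik": self.loglik,
            "aic": self.aic,
            "rsq_adj": self.rsq_adj,
            "deviance": self.deviance,
            "converged": self.converged,
            "n_obs": self.n_obs,
        }
        Path(path).write_text(json.dumps(obj, indent=1))


def _design(
    spec: GamSpec, data: pd.DataFrame, fitting: bool
) -> tuple[np.ndarray, list[slice], list[str], list[tuple[slice, np.ndarray]]]:
    """Assemble the full design matrix, term slices and embedded penalties."""
    blocks, slices, labels, penalties, pen_labels = [], [], [], [], []
    col = 0
    for term in spec.all_terms():
        B = term.fit_build(data) if fitting else term.transform(data)
        sl = slice(col, col + B.shape[1])
        blocks.append(B)
        slices.append(sl)
        labels.append(term.label)
        if fitting:
            for S in term.penalties:
                penalties.append((sl, S))
                pen_labels.append(term.label)
        col += B.shape[1]
    return np.column_stack(blocks), slices, labels, penalties, pen_labels


def _assemble_S(q: int, penalties: list[tuple[slice, np.ndarray]], lams: np.ndarray) -> np.ndarray:
    S = np.zeros((q, q))
    for lam, (sl, Sj) in zip(lams, penalties):
        S[sl, sl] += lam * Sj
    return S


def _chol_solve(A: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, float]:
    """Solve A x = b (A SPSD) with jitter fallback; also return log|A|."""
    jitter = 0.0
    scale = float(np.trace(A)) / A.shape[0] or 1.0
    for _ in range(8):
        try:
            c, low = cho_factor(A + jitter * np.eye(A.shape[0]), lower=True)
            logdet = 2.0 * np.log(np.diag(c)).sum()
            return cho_solve((c, low), b), logdet
        except np.linalg.LinAlgError:
            jitter = max(jitter * 10, 1e-10 * scale)
    raise FitError("penalized normal equations not positive definite")


def _pirls(
    X: np.ndarray,
    y: np.ndarray,
    family: Family,
    S: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, float, list[float]]:
    """Penalized IRLS at fixed smoothing; penalized deviance non-increasing."""
    mu = family.initial_mu(y)
    mu = np.maximum(mu, 1e-8) if family.name != "gaussian" else mu
    eta = family.link(mu)
    beta = None
    pen_dev_prev = np.inf
    path: list[float] = []
    for _ in range(max_iter):
        w = np.maximum(family.fisher_weights(mu), 1e-12)
        dmu_deta = mu if family.name != "gaussian" else np.ones_like(mu)
        z = eta + (y - mu) / dmu_deta
        Xw = X * w[:, None]
        A = X.T @ Xw + S
        b = Xw.T @ z
        beta_new, _ = _chol_solve(A, b)
        step = 1.0
        beta_old = beta
        for _half in range(30):
            beta_try = beta_new if beta_old is None else beta_old + step * (beta_new - beta_old)
            eta_try = X @ beta_try
            mu_try = family.inv_link(eta_try)
            if family.name != "gaussian":
                mu_try = np.maximum(mu_try, 1e-10)
            pen_dev = family.deviance(y, mu_try) + float(beta_try @ S @ beta_try)
            if np.isfinite(pen_dev) and (pen_dev <= pen_dev_prev + 1e-10 or beta_old is None):
                break
            step /= 2.0
        beta, eta, mu = beta_try, eta_try, mu_try
        path.append(pen_dev)
        if abs(pen_dev_prev - pen_dev) < tol * (abs(pen_dev) + 1.0):
            break
        pen_dev_prev = pen_dev
    w = np.maximum(family.fisher_weights(mu), 1e-12)
    return beta, mu, w, path[-1], family.deviance(y, mu), path


def _penalty_blocks(
    q: int, penalties: list[tuple[slice, np.ndarray]]
) -> list[tuple[list[int], int]]:
    """Group penalty indices sharing a coefficient block; fixed ranks at lambda=1."""
    groups: dict[tuple[int, int], list[int]] = {}
    for j, (sl, _S) in enumerate(penalties):
        groups.setdefault((sl.start, sl.stop), []).append(j)
    out = []
    for (_a, _b), idx in groups.items():
        M = sum(penalties[j][1] for j in idx)
        ev = np.linalg.eigvalsh(M)
        rank = int((ev > ev.max() * 1e-9).sum()) if ev.max() > 0 else 0
        out.append((idx, rank))
    return out


def _logdet_S_plus(
    penalties: list[tuple[slice, np.ndarray]],
    blocks: list[tuple[list[int], int]],
    lams: np.ndarray,
) -> float:
    total = 0.0
    for idx, rank in blocks:
        if rank == 0:
            continue
        M = sum(lams[j] * penalties[j][1] for j in idx)
        ev = np.sort(np.linalg.eigvalsh(M))[::-1][:rank]
        total += float(np.log(np.maximum(ev, 1e-300)).sum())
    return total


def fit_gam(
    spec: GamSpec,
    data: pd.DataFrame,
    lambdas: np.ndarray | None = None,
    phi: float | None = None,
    optimize_smoothing: bool = True,
    outer_maxiter: int = 200,
    outer_xtol: float = 1e-2,
) -> GamFit:
    """Fit a penalized-spline GAM by ML smoothing selection.

    ``lambdas`` fixes the smoothing parameters (no outer optimization);
    ``phi`` fixes the dispersion.  Raises :class:`FitError` on non-convergent
    or degenerate fits.
    """
    for term in spec.terms:
        for c in getattr(term, "covariates", ()) or ():
            if c not in data.columns:
                raise FitError(f"covariate {c!r} not in data")
    if spec.response not in data.columns:
        raise FitError(f"response {spec.response!r} not in data")
    y = data[spec.response].to_numpy(dtype=float)
    X, slices, labels, penalties, pen_labels = _design(spec, data, fitting=True)
    n, q = X.shape
    npen = len(penalties)
    fam = spec.family
    # rescale each penalty to the magnitude of its design block, so smoothing
    # parameters are O(1) and the optimizer's search box covers both limits
    scaled = []
    penalty_scales = np.ones(npen)
    for j, (sl, Sj) in enumerate(penalties):
        Xb = X[:, sl]
        xs = float((Xb * Xb).sum()) / Xb.shape[1]
        ev = np.linalg.eigvalsh(Sj)
        rank = int((ev > ev.max() * 1e-9).sum()) if ev.max() > 0 else 0
        ss = float(ev[ev > ev.max() * 1e-9].mean()) if rank else 1.0
        penalty_scales[j] = xs / ss
        scaled.append((sl, Sj * penalty_scales[j]))
    penalties = scaled
    blocks = _penalty_blocks(q, penalties)
    rank_total = sum(r for _idx, r in blocks)

    def profile_phi(dev: float, pen: float, mu: np.ndarray) -> float:
        if phi is not None:
            return phi
        if not fam.has_dispersion:
            return 1.0
        if fam.name == "gaussian":
            denom = max(n - (q - rank_total), 1.0)
            return max((dev + pen) / denom, 1e-10)
        # Tweedie: 1-D profile of the criterion terms that involve phi
        def neg(lp: float) -> float:
            ph = np.exp(lp)
            return -(
                fam.loglik(y, mu, ph) - pen / (2 * ph) + (q - rank_total) / 2.0 * lp
            )
        res = optimize.minimize_scalar(neg, bounds=(-8, 8), method="bounded",
                                       options={"xatol": 1e-3})
        return float(np.exp(res.x))

    def criterion(lams: np.ndarray) -> tuple[float, dict]:
        S = _assemble_S(q, penalties, lams)
        beta, mu, w, pen_dev, dev, path = _pirls(X, y, fam, S)
        pen = float(beta @ S @ beta)
        ph = profile_phi(dev, pen, mu)
        Xw = X * w[:, None]
        XtWX = X.T @ Xw
        _sol, logdet_H = _chol_solve(XtWX + S, np.zeros(q))
        ll = fam.loglik(y, mu, ph)
        laml = (
            ll
            - pen / (2 * ph)
            + 0.5 * _logdet_S_plus(penalties, blocks, lams)
            - 0.5 * logdet_H
            + (q - rank_total) / 2.0 * (np.log(2 * np.pi) + np.log(ph))
        )
        state = dict(beta=beta, mu=mu, w=w, dev=dev, pen=pen, phi=ph, S=S,
                     XtWX=XtWX, loglik=ll, path=path)
        return laml, state

    if npen == 0 or (lambdas is not None) or not optimize_smoothing:
        lams = np.asarray(lambdas, dtype=float) if lambdas is not None else np.ones(npen)
        laml, st = criterion(lams)
        converged_outer = True
    else:
        def neg_laml(rho: np.ndarray) -> float:
            lams_ = np.exp(np.clip(rho, -25, 25))
            try:
                value, _ = criterion(lams_)
            except FitError:
                return 1e12
            return -value

        # explicit initial simplex: the default perturbation around a zero start
        # is far too small to explore log-smoothing space
        x0 = np.zeros(npen)
        simplex = np.vstack([x0] + [x0 + 3.0 * e for e in np.eye(npen)])
        res = optimize.minimize(
            neg_laml,
            x0=x0,
            method="Nelder-Mead",
            options={"maxiter": outer_maxiter * max(npen, 1), "xatol": outer_xtol,
                     "fatol": 1e-3, "adaptive": npen > 3,
                     "initial_simplex": simplex},
        )
        lams = np.exp(np.clip(res.x, -25, 25))
        laml, st = criterion(lams)
        converged_outer = bool(res.success or res.status == 1)

    beta, mu, ph, S, XtWX = st["beta"], st["mu"], st["phi"], st["S"], st["XtWX"]
    A = XtWX + S
    Ainv = np.linalg.inv(A + 1e-12 * np.eye(q) * (np.trace(A) / q))
    Fmat = Ainv @ XtWX
    edf_diag = np.diag(Fmat)
    edf_total = float(edf_diag.sum())
    edf_by_term = {lab: float(edf_diag[sl].sum()) for lab, sl in zip(labels, slices)}
    ll = st["loglik"]
    if fam.name == "gaussian":
        # report the likelihood at the ML dispersion so AIC agrees with the
        # classical closed form in the unpenalized limit
        ll = fam.loglik(y, mu, max(st["dev"] / n, 1e-12))
    n_scale = 1.0 if fam.has_dispersion else 0.0
    aic_val = -2.0 * ll + 2.0 * (edf_total + n_scale)
    tss = float(((y - y.mean()) ** 2).sum())
    rss = float(((y - mu) ** 2).sum())
    denom = max(n - edf_total - n_scale, 1.0)
    rsq = 1.0 - (rss / denom) / (tss / (n - 1)) if tss > 0 else np.nan
    mu0 = np.full(n, max(y.mean(), 1e-10))
    fit = GamFit(
        spec=spec,
        beta=beta,
        lambdas=lams,
        phi=ph,
        term_slices=slices,
        term_labels=labels,
        edf_by_term=edf_by_term,
        edf_total=edf_total,
        loglik=ll,
        aic=aic_val,
        rsq_adj=rsq,
        deviance=st["dev"],
        null_deviance=fam.deviance(y, mu0),
        cov_beta=ph * Ainv,
        converged=converged_outer,
        n_obs=n,
        penalized_deviance_path=np.asarray(st["path"]),
        ml_criterion=laml,
        data_shape_hash=hash((n, spec.response)),
        penalty_scales=penalty_scales,
        penalty_labels=pen_labels,
    )
    return fit


def predict(
    fit: GamFit,
    newdata: pd.DataFrame,
    interval: float = 0.95,
) -> pd.DataFrame:
    """Response-scale predictions with symmetric link-scale intervals.

    Returns a frame with ``fit``, ``se_link``, ``lo``, ``hi`` and an
    ``extrapolated`` flag marking rows with smooth covariates outside the
    training hull.
    """
    from scipy.stats import norm

    X, _slices, _labels, _pen, _pl = _design(fit.spec, newdata, fitting=False)
    eta = X @ fit.beta
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", X, fit.cov_beta, X), 0.0))
    zq = norm.ppf(0.5 + interval / 2.0)
    inv = fit.spec.family.inv_link
    extrap = np.zeros(len(newdata), dtype=bool)
    for term in fit.spec.terms:
        rng = getattr(term, "train_range_", None)
        if rng:
            for c, (lo, hi) in rng.items():
                v = newdata[c].to_numpy(dtype=float)
                extrap |= (v < lo) | (v > hi)
    return pd.DataFrame(
        {
            "fit": inv(eta),
            "se_link": se,
            "lo": inv(eta - zq * se),
            "hi": inv(eta + zq * se),
            "extrapolated": extrap,
        },
        index=newdata.index,
    )
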