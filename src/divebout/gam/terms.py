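"""Model terms: parametric effects, penalized smooths, random effects.

Each term knows how to build its design-matrix block from a data frame at
fit time (capturing knots, factor levels and the sum-to-zero constraint) and
how to rebuild the same block for new data at prediction time.  Penalized
terms expose one or more penalty matrices in block coordinates; each penalty
carries its own smoothing parameter in the fit.

Group-specific ("individual-specific" or class-specific) smooths are
replicate constrained bases per level of a ``by`` factor sharing one
smoothing parameter per marginal penalty across levels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from divebout.errors import FitError
from divebout.gam.basis import cr_basis, null_space_constraint, tensor_basis

__all__ = [
    "Term",
    "InterceptTerm",
    "LinearTerm",
    "FactorTerm",
    "LinearByFactorTerm",
    "SmoothTerm",
    "RandomEffectTerm",
    "random_effect_term",
]

logger = logging.getLogger(__name__)


class Term:
    """Interface: fit-time build then prediction-time transform."""

    label: str = ""
    penalized: bool = False

    def fit_build(self, data: pd.DataFrame) -> np.ndarray:
        raise NotImplementedError

    def transform(self, data: pd.DataFrame) -> np.ndarray:
        raise NotImplementedError

    @property
    def penalties(self) -> list[np.ndarray]:
        """Penalty matrices in this term's block coordinates (may be empty)."""
        return []


@dataclass
class InterceptTerm(Term):
    label: str = "intercept"

    def fit_build(self, data: pd.DataFrame) -> np.ndarray:
        return np.ones((len(data), 1))

    transform = fit_build


@dataclass
class LinearTerm(Term):
    name: str

    def __post_init__(self):
        self.label = self.name

    def fit_build(self, data: pd.DataFrame) -> np.ndarray:
        return data[self.name].to_numpy(dtype=float)[:, None]

    transform = fit_build


@dataclass
class FactorTerm(Term):
    """Fixed-effect factor, treatment (drop-first) coding."""

    name: str
    levels_: list = field(default_factory=list, repr=False)

    def __post_init__(self):
        self.label = self.name

    def fit_build(self, data: pd.DataFrame) -> np.ndarray:
        self.levels_ = sorted(pd.unique(data[self.name]).tolist())
        return self._encode(data)

    def _encode(self, data: pd.DataFrame) -> np.ndarray:
        g = data[self.name].to_numpy()
        known = set(self.levels_)
        unseen = {v for v in g if v not in known}
        if unseen:
            logger.warning("factor %s: unseen level(s) %s mapped to reference", self.name, unseen)
        X = np.zeros((len(g), len(self.levels_) - 1))
        for j, level in enumerate(self.levels_[1:]):
            X[:, j] = g == level
        return X

    def transform(self, data: pd.DataFrame) -> np.ndarray:
        return self._encode(data)


@dataclass
class LinearByFactorTerm(Term):
    """Factor-specific slopes: one column x * 1[g == level] per level."""

    name: str
    by: str
    levels_: list = field(default_factory=list, repr=False)

    def __post_init__(self):
        self.label = f"{self.name}:by:{self.by}"

    def fit_build(self, data: pd.DataFrame) -> np.ndarray:
        self.levels_ = sorted(pd.unique(data[self.by]).tolist())
        return self._encode(data)

    def _encode(self, data: pd.DataFrame) -> np.ndarray:
        x = data[self.name].to_numpy(dtype=float)
        g = data[self.by].to_numpy()
        X = np.zeros((len(x), len(self.levels_)))
        for j, level in enumerate(self.levels_):
            X[:, j] = x * (g == level)
        return X

    def transform(self, data: pd.DataFrame) -> np.ndarray:
        return self._encode(data)


@dataclass
class SmoothTerm(Term):
    """Penalized cubic regression spline smooth, univariate or tensor product.

    One covariate gives an isotropic cr smooth (one penalty); two covariates
    give an anisotropic tensor smooth (two marginal penalties, one smoothing
    parameter each).  A sum-to-zero constraint over the training rows is
    absorbed into the basis, and a ``by`` factor replicates the constrained
    basis per level (shared smoothing parameters across levels).
    """

    covariates: tuple[str, ...]
    k: int | tuple[int, int] = 5
    by: str | None = None
    penalized: bool = True
    # fit-time state
    knots_: list = field(default_factory=list, repr=False)
    Z_: np.ndarray | None = field(default=None, repr=False)
    levels_: list = field(default_factory=list, repr=False)
    S_: list = field(default_factory=list, repr=False)
    train_range_: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.covariates = tuple(self.covariates)
        if len(self.covariates) not in (1, 2):
            raise ValueError("SmoothTerm takes 1 or 2 covariates")
        base = f"s({', '.join(self.covariates)})"
        self.label = base if self.by is None else f"{base}:by:{self.by}"

    @property
    def kind(self) -> str:
        return "cr" if len(self.covariates) == 1 else "tensor"

    def _raw(self, data: pd.DataFrame, fitting: bool) -> tuple[np.ndarray, list[np.ndarray]]:
        if self.kind == "cr":
            x = data[self.covariates[0]].to_numpy(dtype=float)
            b = cr_basis(x, int(self.k), None if fitting else self.knots_[0])
            if fitting:
                self.knots_ = [b.knots]
            return b.X, [b.S]
        x1 = data[self.covariates[0]].to_numpy(dtype=float)
        x2 = data[self.covariates[1]].to_numpy(dtype=float)
        k1, k2 = self.k if isinstance(self.k, tuple) else (int(self.k), int(self.k))
        kn1, kn2 = (None, None) if fitting else self.knots_
        X, S1, S2, kn1, kn2 = tensor_basis(x1, x2, k1, k2, kn1, kn2)
        if fitting:
            self.knots_ = [kn1, kn2]
        return X, [S1, S2]

    def fit_build(self, data: pd.DataFrame) -> np.ndarray:
        for c in self.covariates:
            v = data[c].to_numpy(dtype=float)
            self.train_range_[c] = (float(v.min()), float(v.max()))
        Xraw, S_raw = self._raw(data, fitting=True)
        m = Xraw.mean(axis=0)
        self.Z_ = null_space_constraint(m)
        Xc = Xraw @ self.Z_
        S_c = [self.Z_.T @ S @ self.Z_ for S in S_raw]
        if self.by is None:
            self.S_ = S_c
            return Xc
        self.levels_ = sorted(pd.unique(data[self.by]).tolist())
        X = self._replicate(Xc, data)
        L = len(self.levels_)
        self.S_ = [_block_repeat(S, L) for S in S_c]
        return X

    def _replicate(self, Xc: np.ndarray, data: pd.DataFrame) -> np.ndarray:
        g = data[self.by].to_numpy()
        q = Xc.shape[1]
        X = np.zeros((len(g), q * len(self.levels_)))
        for j, level in enumerate(self.levels_):
            sel = g == level
            X[sel, j * q : (j + 1) * q] = Xc[sel]
        return X

    def transform(self, data: pd.DataFrame) -> np.ndarray:
        Xraw, _ = self._raw(data, fitting=False)
        Xc = Xraw @ self.Z_
        if self.by is None:
            return Xc
        return self._replicate(Xc, data)

    @property
    def penalties(self) -> list[np.ndarray]:
        return self.S_


def _block_repeat(S: np.ndarray, L: int) -> np.ndarray:
    return np.kron(np.eye(L), S)


@dataclass
class RandomEffectTerm(Term):
    """Random intercept as a ridge-penalized indicator basis.

    One column per factor level with an identity penalty; the single
    smoothing parameter is the inverse of the level-effect variance
    component (times the dispersion).  Unseen levels at prediction time get
    a zero effect.
    """

    factor: str
    penalized: bool = True
    levels_: list = field(default_factory=list, repr=False)

    def __post_init__(self):
        self.label = f"re({self.factor})"

    def fit_build(self, data: pd.DataFrame) -> np.ndarray:
        self.levels_ = sorted(pd.unique(data[self.factor]).tolist())
        if len(self.levels_) < 2:
            raise FitError(f"random effect {self.factor}: needs >= 2 levels")
        return self._encode(data)

    def _encode(self, data: pd.DataFrame) -> np.ndarray:
        g = data[self.factor].to_numpy()
        X = np.zeros((len(g), len(self.levels_)))
        for j, level in enumerate(self.levels_):
            X[:, j] = g == level
        return X

    def transform(self, data: pd.DataFrame) -> np.ndarray:
        return self._encode(data)

    @property
    def penalties(self) -> list[np.ndarray]:
        return [np.eye(len(self.levels_))]


def random_effect_term(factor_values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indicator basis and identity penalty for a factor (standalone helper)."""
    levels = sorted(pd.unique(np.asarray(factor_values)).tolist())
    if len(levels) < 2:
        raise FitError("random effect: needs >= 2 levels")
    X = np.zeros((len(factor_values), len(levels)))
    for j, level in enumerate(levels):
        X[:, j] = np.asarray(factor_values) == level
    return X, np.eye(len(levels))
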