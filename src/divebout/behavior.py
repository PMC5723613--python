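"""Behavioral partitioning of 25 Hz acceleration and PCE/PCT extraction.

Movement features (static and dynamic acceleration, VeDBA/ODBA, per-axis
variance, pitch) are computed over short windows, an expectation-maximization
(EM) Gaussian mixture partitions the windows into behavioral regimes, the
pursuit-and-catching regime is identified as the component with the highest
within-dive mean VeDBA ("fast and sharp" movement), and maximal runs of that
label become pursuit-and-catching events (PCE).  The per-dive event count
and the per-bout total event time (PCT) are the two downstream responses.

The EM is written in-house (it is the behavioral-classification core of the
pipeline); scikit-learn's GaussianMixture serves only as an independent
cross-check in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from divebout.errors import DataError, FitError
from divebout.segmentation import Bout, Dive
from divebout.sensor_io import AccelTrace

__all__ = [
    "FeatureSeries",
    "GmmModel",
    "PceEvent",
    "extract_features",
    "fit_em",
    "identify_pce_cluster",
    "extract_events",
    "count_pce",
    "compute_pct",
    "classify_behavior",
]

logger = logging.getLogger(__name__)

FEATURE_NAMES = (
    "static_x", "static_y", "static_z",
    "dyn_x", "dyn_y", "dyn_z",
    "vedba", "odba",
    "var_x", "var_y", "var_z",
    "pitch",
)
VEDBA_COL = FEATURE_NAMES.index("vedba")

MIN_EVENT_S = 0.2  # 5 samples at 25 Hz; suppresses single-window flicker


@dataclass
class FeatureSeries:
    """Per-window movement features tiling an acceleration trace."""

    centers_s: np.ndarray          # window centers on the deployment clock
    X: np.ndarray                  # (n_windows, n_features)
    window_s: float
    names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.X)):
            raise DataError("FeatureSeries: non-finite feature values")

    @property
    def vedba(self) -> np.ndarray:
        return self.X[:, VEDBA_COL]

    def __len__(self) -> int:
        return self.centers_s.size


def extract_features(
    accel: AccelTrace, static_window_s: float = 2.0, feature_window_s: float = 1.0
) -> FeatureSeries:
    """Windowed movement features from a tri-axial trace.

    Static acceleration is a centered running mean over ``static_window_s``
    (the gravity/posture component); dynamic acceleration is the residual.
    Per non-overlapping window of ``feature_window_s``: mean static per axis,
    mean |dynamic| per axis, mean VeDBA and ODBA, per-axis variance of the
    raw signal, and pitch from the static vector
    (atan2(static_x, ||(static_y, static_z)||)).
    """
    from scipy.ndimage import uniform_filter1d

    fs = accel.sample_rate_hz
    w_static = int(round(static_window_s * fs))
    w_feat = int(round(feature_window_s * fs))
    if w_static < 3 or w_feat < 3:
        raise ValueError("windows must span at least 3 samples")
    n = len(accel)
    if n < w_feat:
        raise DataError("trace shorter than one feature window")
    raw = np.stack([accel.ax, accel.ay, accel.az], axis=1)
    static = uniform_filter1d(raw, size=w_static, axis=0, mode="nearest")
    dyn = raw - static
    vedba = np.sqrt((dyn**2).sum(axis=1))
    odba = np.abs(dyn).sum(axis=1)

    n_win = n // w_feat
    end = n_win * w_feat

    def per_window(x: np.ndarray) -> np.ndarray:
        return x[:end].reshape(n_win, w_feat, -1)

    static_w = per_window(static).mean(axis=1)
    absdyn_w = per_window(np.abs(dyn)).mean(axis=1)
    vedba_w = per_window(vedba[:, None]).mean(axis=1)[:, 0]
    odba_w = per_window(odba[:, None]).mean(axis=1)[:, 0]
    var_w = per_window(raw).var(axis=1)
    pitch_w = np.arctan2(
        static_w[:, 0], np.hypot(static_w[:, 1], static_w[:, 2])
    )
    X = np.column_stack([static_w, absdyn_w, vedba_w, odba_w, var_w, pitch_w])
    centers = accel.time_s[:end].reshape(n_win, w_feat).mean(axis=1)
    return FeatureSeries(centers_s=centers, X=X, window_s=feature_window_s)


# ---------------------------------------------------------------------------
# Gaussian-mixture EM


@dataclass
class GmmModel:
    """K-component full-covariance Gaussian mixture fitted by EM."""

    weights: np.ndarray            # (K,), on the simplex
    means: np.ndarray              # (K, d)
    covariances: np.ndarray        # (K, d, d), SPD
    loglik: float
    n_iter: int
    converged: bool
    loglik_path: np.ndarray = field(default_factory=lambda: np.array([]))
    feature_names: tuple[str, ...] = FEATURE_NAMES

    @property
    def K(self) -> int:
        return self.weights.size

    def log_responsibilities(self, X: np.ndarray) -> np.ndarray:
        """(n, K) log posterior component probabilities."""
        from scipy.special import logsumexp

        logp = _log_gauss(X, self.means, self.covariances) + np.log(self.weights)
        return logp - logsumexp(logp, axis=1, keepdims=True)

    def predict_labels(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.log_responsibilities(X), axis=1)

    def to_dict(self) -> dict:
        return {
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
            "loglik": self.loglik,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "feature_names": list(self.feature_names),
        }


def _log_gauss(X: np.ndarray, means: np.ndarray, covs: np.ndarray) -> np.ndarray:
    """(n, K) log N(x | mu_k, Sigma_k) via Cholesky."""
    n, d = X.shape
    K = means.shape[0]
    out = np.empty((n, K))
    for k in range(K):
        L = np.linalg.cholesky(covs[k])
        diff = X - means[k]
        sol = np.linalg.solve(L, diff.T)
        maha = (sol**2).sum(axis=0)
        logdet = 2.0 * np.log(np.diag(L)).sum()
        out[:, k] = -0.5 * (d * np.log(2 * np.pi) + logdet + maha)
    return out


def fit_em(
    features: FeatureSeries | np.ndarray,
    K: int = 4,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    n_init: int = 5,
    ridge: float = 1e-6,
) -> GmmModel:
    """Fit a K-component Gaussian mixture by EM with seeded restarts.

    The best of ``n_init`` restarts (by final log-likelihood) is returned.
    Each restart initializes means at distinct random data points and
    covariances at the pooled sample covariance.  A ridge of
    ``ridge * mean(diag(pooled cov))`` is added to every covariance update,
    which also keeps nearly collinear features (ODBA/VeDBA) well conditioned.
    The per-iteration log-likelihood path is retained so monotonicity can be
    asserted.
    """
    from scipy.special import logsumexp

    X = features.X if isinstance(features, FeatureSeries) else np.asarray(features, float)
    n, d = X.shape
    if n <= K * (d + 1):
        raise FitError(f"too few windows ({n}) for K={K} components in {d} dims")
    pooled = np.cov(X.T).reshape(d, d)
    scale = float(np.mean(np.diag(pooled)))
    if scale <= 0 or not np.isfinite(scale):
        raise FitError("degenerate features: zero variance in every dimension")
    eps = ridge * scale * np.eye(d)

    rng = np.random.default_rng(seed)
    best: GmmModel | None = None
    for _init in range(n_init):
        idx = rng.choice(n, size=K, replace=False)
        means = X[idx].copy()
        covs = np.repeat((pooled + eps)[None], K, axis=0)
        weights = np.full(K, 1.0 / K)
        path = []
        prev = -np.inf
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            logp = _log_gauss(X, means, covs) + np.log(weights)
            norm = logsumexp(logp, axis=1)
            ll = float(norm.sum())
            path.append(ll)
            resp = np.exp(logp - norm[:, None])
            nk = resp.sum(axis=0) + 1e-300
            weights = nk / n
            means = (resp.T @ X) / nk[:, None]
            for k in range(K):
                diff = X - means[k]
                covs[k] = (resp[:, k][:, None] * diff).T @ diff / nk[k] + eps
            if ll - prev < tol * max(abs(ll), 1.0) and it > 1:
                converged = True
                break
            prev = ll
        model = GmmModel(
            weights=weights,
            means=means,
            covariances=covs,
            loglik=path[-1],
            n_iter=it,
            converged=converged,
            loglik_path=np.array(path),
        )
        if best is None or model.loglik > best.loglik:
            best = model
    assert best is not None
    return best


def identify_pce_cluster(
    model: GmmModel,
    features: FeatureSeries,
    dives: list[Dive] | None = None,
) -> int:
    """Index of the mixture component representing pursuit-and-catching.

    Operationalizes "fast and sharp movements": the component whose assigned
    within-dive windows have the highest mean VeDBA.  Ties break toward the
    higher VeDBA variance.  With K=1 the single component is returned with a
    warning (no partitioning happened).
    """
    if model.K == 1:
        logger.warning("identify_pce_cluster: single-component model, no partitioning")
        return 0
    labels = model.predict_labels(features.X)
    if dives:
        inside = np.zeros(len(features), dtype=bool)
        for d in dives:
            inside |= (features.centers_s >= d.start_s) & (features.centers_s < d.end_s)
    else:
        inside = np.ones(len(features), dtype=bool)
    if not inside.any():
        raise FitError("identify_pce_cluster: no analysis windows inside dives")
    vedba = features.vedba
    stats = []
    for k in range(model.K):
        sel = inside & (labels == k)
        if sel.any():
            stats.append((float(vedba[sel].mean()), float(vedba[sel].var())))
        else:
            stats.append((-np.inf, -np.inf))
    return max(range(model.K), key=lambda k: stats[k])


@dataclass
class PceEvent:
    """One pursuit-and-catching event, half-open interval within a dive."""

    start_s: float
    end_s: float
    dive_id: int

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def extract_events(
    labels: np.ndarray,
    features: FeatureSeries,
    dives: list[Dive],
    pce_component: int,
    min_event_s: float = MIN_EVENT_S,
) -> list[PceEvent]:
    """Turn PCE-labelled window runs into events clipped to dive boundaries.

    Maximal runs of the PCE label are merged when separated by less than one
    window, intersected with each dive's interval (runs outside any dive are
    discarded), and dropped if shorter than ``min_event_s``.
    """
    labels = np.asarray(labels)
    if labels.size != len(features):
        raise DataError("labels not aligned to feature windows")
    w = features.window_s
    is_pce = labels == pce_component
    padded = np.concatenate([[False], is_pce, [False]]).astype(np.int8)
    edges = np.diff(padded)
    starts = np.nonzero(edges == 1)[0]
    ends = np.nonzero(edges == -1)[0]
    # window i spans [center - w/2, center + w/2)
    intervals: list[tuple[float, float]] = []
    for s, e in zip(starts, ends):
        lo = features.centers_s[s] - w / 2
        hi = features.centers_s[e - 1] + w / 2
        if intervals and lo - intervals[-1][1] < w:
            intervals[-1] = (intervals[-1][0], hi)
        else:
            intervals.append((lo, hi))
    events: list[PceEvent] = []
    for lo, hi in intervals:
        for d in dives:
            s = max(lo, d.start_s)
            e = min(hi, d.end_s)
            if e - s >= min_event_s:
                events.append(PceEvent(start_s=s, end_s=e, dive_id=d.dive_id))
    return events


def count_pce(dive: Dive, events: list[PceEvent]) -> int:
    """Number of PCE in a dive."""
    return sum(ev.dive_id == dive.dive_id for ev in events)


def compute_pct(bout: Bout, events: list[PceEvent]) -> float:
    """Pursuit-and-catching time: summed event durations over the bout's dives."""
    member_ids = {d.dive_id for d in bout.dives}
    return float(sum(ev.duration_s for ev in events if ev.dive_id in member_ids))


def classify_behavior(
    accel: AccelTrace,
    dives: list[Dive],
    bouts: list[Bout] | None = None,
    K: int = 4,
    seed: int = 0,
    static_window_s: float = 2.0,
    feature_window_s: float = 1.0,
    min_event_s: float = MIN_EVENT_S,
) -> tuple[list[PceEvent], GmmModel, FeatureSeries]:
    """End-to-end behavioral classification for one deployment.

    Extracts features, fits the per-individual mixture, identifies the PCE
    component, extracts events, and writes ``n_pce`` onto the dives and
    ``pct_s`` onto the bouts (if given).  Returns (events, model, features).
    """
    features = extract_features(accel, static_window_s, feature_window_s)
    model = fit_em(features, K=K, seed=seed)
    pce_k = identify_pce_cluster(model, features, dives)
    labels = model.predict_labels(features.X)
    events = extract_events(labels, features, dives, pce_k, min_event_s)
    for d in dives:
        d.n_pce = count_pce(d, events)
    if bouts is not None:
        for b in bouts:
            b.pct_s = compute_pct(b, events)
    return events, model, features
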