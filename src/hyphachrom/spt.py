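"""Single-molecule tracking and diffusion-state mixture analysis.

Localizations from a PALM acquisition are linked into tracks with a
nearest-neighbour rule (0.6 um default radius, one missing frame allowed
for blinking), lag-1 squared displacements are pooled and fit with an
exponential mixture by EM — the likelihood-exact model for 2D Brownian
steps, where a step in state k has r^2 ~ Exponential with mean
4*D_k*dt + 4*loc_sigma^2 — and whole tracks are classified as confined,
free or mixed from the per-step state posteriors over sliding windows of
three consecutive steps (90 ms at 30 ms exposure).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator, DensityMixin

__all__ = [
    "TrackingConfig",
    "Track",
    "MobilityConfig",
    "DiffusionMixtureFit",
    "DiffusionMixtureEM",
    "link_tracks",
    "step_displacements",
    "pooled_steps",
    "fit_diffusion_mixture",
    "mobility_fractions",
    "classify_mobility",
    "tracks_to_frame",
]


@dataclass
class TrackingConfig:
    link_radius: float = 0.6  # um
    max_gap: int = 1  # frames of allowed disappearance
    dt: float = 0.03  # s per frame

    def __post_init__(self) -> None:
        if self.link_radius <= 0:
            raise ValueError("link_radius must be > 0")
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")


@dataclass
class Track:
    """One linked molecule trajectory (frames strictly increasing)."""

    track_id: int
    frames: np.ndarray  # int
    x: np.ndarray  # um
    y: np.ndarray  # um

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_steps(self) -> int:
        return max(len(self.frames) - 1, 0)


def _greedy_match(
    a_xy: np.ndarray, b_xy: np.ndarray, radius: float
) -> list[tuple[int, int]]:
    """Greedy distance-ascending partial matching between two point sets."""
    if len(a_xy) == 0 or len(b_xy) == 0:
        return []
    tree = cKDTree(b_xy)
    pairs = []
    for i, neighbours in enumerate(tree.query_ball_point(a_xy, radius)):
        for j in neighbours:
            d = float(np.hypot(*(a_xy[i] - b_xy[j])))
            pairs.append((d, i, j))
    pairs.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    out = []
    for _d, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        out.append((i, j))
    return out


def link_tracks(localizations: pd.DataFrame, config: TrackingConfig | None = None) -> list[Track]:
    """Link a localization table (frame, x_um, y_um) into tracks.

    Frame-to-frame assignment is a greedy partial matching in ascending
    distance within ``link_radius``; track ends unmatched at frame f are
    retried against frame f+1+g for gaps g up to ``max_gap`` (gap
    closing, same radius).  Every localization belongs to exactly one
    track; unlinked localizations become length-1 tracks.
    """
    config = config or TrackingConfig()
    req = {"frame", "x_um", "y_um"}
    if not req.issubset(localizations.columns):
        raise ValueError(f"localizations must have columns {sorted(req)}")
    if localizations[["x_um", "y_um"]].isna().any().any():
        raise ValueError("NaN coordinates rejected")

    frames = np.sort(localizations["frame"].unique())
    by_frame = {
        int(f): g[["x_um", "y_um"]].to_numpy(dtype=float)
        for f, g in localizations.groupby("frame")
    }

    # open tracks: list of [frames, xs, ys]; active index by last frame
    tracks: list[list[list]] = []
    open_by_frame: dict[int, list[int]] = {}

    for f in frames:
        f = int(f)
        pts = by_frame[f]
        unassigned = np.ones(len(pts), dtype=bool)
        # try previous frame first, then gap-close against older ends
        for gap in range(0, config.max_gap + 1):
            src = f - 1 - gap
            cand = [ti for ti in open_by_frame.get(src, []) if tracks[ti][0][-1] == src]
            if not cand:
                continue
            idx_un = np.flatnonzero(unassigned)
            if idx_un.size == 0:
                break
            a_xy = np.array([[tracks[ti][1][-1], tracks[ti][2][-1]] for ti in cand])
            matches = _greedy_match(a_xy, pts[idx_un], config.link_radius)
            for ai, bj in matches:
                ti = cand[ai]
                j = int(idx_un[bj])
                tracks[ti][0].append(f)
                tracks[ti][1].append(float(pts[j, 0]))
                tracks[ti][2].append(float(pts[j, 1]))
                unassigned[j] = False
                open_by_frame.setdefault(f, []).append(ti)
        for j in np.flatnonzero(unassigned):
            tracks.append([[f], [float(pts[j, 0])], [float(pts[j, 1])]])
            open_by_frame.setdefault(f, []).append(len(tracks) - 1)

    return [
        Track(i, np.array(fr, dtype=int), np.array(xs), np.array(ys))
        for i, (fr, xs, ys) in enumerate(tracks)
    ]


def tracks_to_frame(tracks: list[Track]) -> pd.DataFrame:
    """Flatten tracks to a (track_id, frame, x_um, y_um) table."""
    rows = []
    for t in tracks:
        for f, x, y in zip(t.frames, t.x, t.y):
            rows.append((t.track_id, int(f), x, y))
    return pd.DataFrame(rows, columns=["track_id", "frame", "x_um", "y_um"])


def step_displacements(track: Track, lag: int = 1) -> pd.DataFrame:
    """Squared displacements r^2 for all pairs exactly ``lag`` observed
    frames apart; gap-spanning steps carry their true frame separation.

    Returns columns r2 (um^2), dframes (true frame separation, equals
    ``lag`` for gap-free steps), gap (bool).
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    n = len(track)
    rows = []
    for i in range(n - lag):
        j = i + lag
        dfr = int(track.frames[j] - track.frames[i])
        r2 = float((track.x[j] - track.x[i]) ** 2 + (track.y[j] - track.y[i]) ** 2)
        rows.append((r2, dfr, dfr != lag))
    out = pd.DataFrame(rows, columns=["r2", "dframes", "gap"])
    return out.astype({"r2": float, "dframes": int, "gap": bool})


def pooled_steps(tracks: list[Track], lag: int = 1, include_gaps: bool = False) -> np.ndarray:
    """Pool lag-``lag`` squared displacements across tracks.

    Gap-spanning steps (true frame separation != lag) are excluded by
    default because their time base differs.
    """
    out = []
    for t in tracks:
        if len(t) <= lag:
            continue
        df = step_displacements(t, lag)
        if not include_gaps:
            df = df[~df["gap"]]
        out.append(df["r2"].to_numpy())
    return np.concatenate(out) if out else np.array([])


@dataclass
class DiffusionMixtureFit:
    """K-component diffusion mixture: apparent D and weight per state."""

    D_app: np.ndarray  # um^2/s, ascending
    weights: np.ndarray  # sum to 1
    log_likelihood: float
    posteriors: np.ndarray  # (n_steps, K) slow..fast ordering
    mean_D_app: float  # weight-averaged apparent D
    dt: float
    loc_sigma: float
    n_steps: int


class DiffusionMixtureEM(BaseEstimator, DensityMixin):
    """Exponential mixture over squared Brownian step lengths, fit by EM.

    For a molecule diffusing in 2D with coefficient D observed at
    interval dt with localization error loc_sigma per coordinate, the
    squared lag-1 displacement is exponential with mean
    4*D*dt + 4*loc_sigma^2.  A K-component exponential mixture on the
    pooled squared displacements therefore recovers the per-state
    apparent diffusion coefficients and state weights; per-step state
    posteriors fall out of the E-step.

    Parameters
    ----------
    n_components : number of diffusive states K (default 2).
    dt : frame interval in seconds.
    loc_sigma : localization error (um per coordinate) subtracted from
        the component means; 0 disables the correction.
    n_init : EM restarts; the best log-likelihood is kept.
    tol, max_iter : EM convergence controls.
    random_state : seed for restart initialisation.

    Attributes (after fit)
    ----------
    diffusion_coefficients_ : (K,) apparent D per state, ascending.
    weights_ : (K,) mixture weights.
    means_ : (K,) component means of r^2.
    log_likelihood_ : final total log-likelihood.
    mean_diffusion_coefficient_ : weight-averaged apparent D.
    """

    def __init__(
        self,
        n_components: int = 2,
        dt: float = 0.03,
        loc_sigma: float = 0.0,
        n_init: int = 10,
        tol: float = 1e-10,
        max_iter: int = 1000,
        min_steps: int = 50,
        random_state: int | None = 0,
    ):
        self.n_components = n_components
        self.dt = dt
        self.loc_sigma = loc_sigma
        self.n_init = n_init
        self.tol = tol
        self.max_iter = max_iter
        self.min_steps = min_steps
        self.random_state = random_state

    # -- internals ---------------------------------------------------------
    @staticmethod
    def _loglik(r2: np.ndarray, w: np.ndarray, m: np.ndarray) -> tuple[float, np.ndarray]:
        # log densities of Exp(mean m): -log m - r2/m
        logd = -np.log(m)[None, :] - r2[:, None] / m[None, :]
        logw = np.log(w)[None, :]
        a = logd + logw
        amax = a.max(axis=1, keepdims=True)
        lse = amax[:, 0] + np.log(np.exp(a - amax).sum(axis=1))
        post = np.exp(a - lse[:, None])
        return float(lse.sum()), post

    def _em_once(self, r2: np.ndarray, m0: np.ndarray) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
        K = self.n_components
        w = np.full(K, 1.0 / K)
        m = m0.copy()
        prev = -np.inf
        for _ in range(self.max_iter):
            ll, post = self._loglik(r2, w, m)
            nk = post.sum(axis=0)
            w = nk / nk.sum()
            m = (post * r2[:, None]).sum(axis=0) / np.maximum(nk, 1e-300)
            m = np.maximum(m, 1e-12)
            if ll - prev < self.tol * max(1.0, abs(ll)):
                prev = ll
                break
            prev = ll
        ll, post = self._loglik(r2, w, m)
        return ll, w, m, post

    # -- API ---------------------------------------------------------------
    def fit(self, X, y=None):
        """Fit the mixture to squared displacements.

        X : array-like of lag-1 squared displacements (um^2), or a list
            of :class:`Track` from which they are pooled.
        """
        if isinstance(X, (list, tuple)) and X and isinstance(X[0], Track):
            r2 = pooled_steps(list(X), lag=1)
        else:
            r2 = np.asarray(X, dtype=float).ravel()
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        r2 = r2[np.isfinite(r2)]
        if r2.size < self.min_steps:
            raise ValueError(
                f"need >= {self.min_steps} lag-1 steps, got {r2.size}"
            )
        if np.all(r2 <= 0):
            raise ValueError("all displacements are zero")
        r2 = np.maximum(r2, 1e-12)

        rng = np.random.default_rng(self.random_state)
        K = self.n_components
        best = None
        mean = r2.mean()
        for init in range(max(self.n_init, 1)):
            if init == 0:
                # spread initial means over quantiles
                qs = np.quantile(r2, (np.arange(K) + 0.5) / K)
                m0 = np.maximum(qs, 1e-10)
            else:
                m0 = mean * rng.uniform(0.05, 3.0, size=K)
            ll, w, m, post = self._em_once(r2, m0)
            if best is None or ll > best[0]:
                best = (ll, w, m, post)
        ll, w, m, post = best
        order = np.argsort(m)  # canonical: ascending D
        w, m, post = w[order], m[order], post[:, order]

        offset = 4.0 * self.loc_sigma**2
        D = np.maximum(m - offset, 0.0) / (4.0 * self.dt)
        self.means_ = m
        self.weights_ = w
        self.diffusion_coefficients_ = D
        self.log_likelihood_ = ll
        self.posteriors_ = post
        self.mean_diffusion_coefficient_ = float(np.dot(w, D))
        self.n_steps_ = int(r2.size)
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Posterior state probabilities for squared displacements."""
        r2 = np.maximum(np.asarray(X, dtype=float).ravel(), 1e-12)
        _, post = self._loglik(r2, self.weights_, self.means_)
        return post

    def predict(self, X) -> np.ndarray:
        """Maximum-posterior state index (0 = slowest)."""
        return np.argmax(self.predict_proba(X), axis=1)

    def score(self, X, y=None) -> float:
        r2 = np.maximum(np.asarray(X, dtype=float).ravel(), 1e-12)
        ll, _ = self._loglik(r2, self.weights_, self.means_)
        return ll / r2.size

    def result(self) -> DiffusionMixtureFit:
        return DiffusionMixtureFit(
            D_app=self.diffusion_coefficients_,
            weights=self.weights_,
            log_likelihood=self.log_likelihood_,
            posteriors=self.posteriors_,
            mean_D_app=self.mean_diffusion_coefficient_,
            dt=self.dt,
            loc_sigma=self.loc_sigma,
            n_steps=self.n_steps_,
        )


def fit_diffusion_mixture(
    tracks: list[Track] | np.ndarray,
    K: int = 2,
    dt: float = 0.03,
    loc_sigma: float = 0.0,
    n_init: int = 10,
    random_state: int | None = 0,
) -> DiffusionMixtureFit:
    """Fit a K-state diffusion mixture to lag-1 squared displacements."""
    est = DiffusionMixtureEM(
        n_components=K, dt=dt, loc_sigma=loc_sigma, n_init=n_init,
        random_state=random_state,
    ).fit(tracks)
    return est.result()


def msd_track_diffusion(tracks: list[Track], dt: float, K: int = 2,
                        min_steps: int = 3, random_state: int = 0):
    """Cross-check mode: per-track apparent D from the mean lag-1 squared
    displacement (D = <r^2>/(4 dt)), clustered with a Gaussian mixture on
    log D.  Returns (per-track D array, fitted sklearn GaussianMixture).
    """
    from sklearn.mixture import GaussianMixture

    Ds = []
    for t in tracks:
        r2 = step_displacements(t, 1)
        r2 = r2[~r2["gap"]]["r2"].to_numpy()
        if r2.size >= min_steps:
            Ds.append(max(r2.mean(), 1e-12) / (4.0 * dt))
    Ds = np.asarray(Ds)
    gm = GaussianMixture(n_components=K, random_state=random_state, n_init=5)
    gm.fit(np.log(Ds)[:, None])
    return Ds, gm


@dataclass
class MobilityConfig:
    window_steps: int = 3  # 90 ms at 30 ms per frame

    def __post_init__(self) -> None:
        if self.window_steps < 1:
            raise ValueError("window_steps must be >= 1")


def classify_mobility(
    tracks: list[Track],
    fit: DiffusionMixtureFit | DiffusionMixtureEM,
    config: MobilityConfig | None = None,
) -> pd.DataFrame:
    """Classify each track as confined, free or mixed.

    Each lag-1 step is assigned its maximum-posterior state under the
    two-state fit.  Only tracks with at least ``window_steps`` steps are
    classified: a track is confined if every sliding window of
    ``window_steps`` consecutive steps is entirely slow-state, free if
    entirely fast-state, and mixed otherwise.

    Returns a table (track_id, n_steps, mobility) for classifiable
    tracks; per-class fractions are just ``value_counts(normalize=True)``
    of the mobility column.
    """
    config = config or MobilityConfig()
    if isinstance(fit, DiffusionMixtureEM):
        fit = fit.result()
    if fit.D_app.shape[0] != 2:
        raise ValueError("mobility classification requires a K=2 fit")
    m = 4.0 * fit.D_app * fit.dt + 4.0 * fit.loc_sigma**2
    m = np.maximum(m, 1e-12)
    rows = []
    for t in tracks:
        sd = step_displacements(t, 1)
        sd = sd[~sd["gap"]]
        r2 = np.maximum(sd["r2"].to_numpy(), 1e-12)
        if r2.size < config.window_steps:
            continue
        logd = -np.log(m)[None, :] - r2[:, None] / m[None, :] + np.log(fit.weights)[None, :]
        slow = logd[:, 0] >= logd[:, 1]
        W = config.window_steps
        windows = np.lib.stride_tricks.sliding_window_view(slow, W)
        if windows.all():
            label = "confined"
        elif (~windows).all():
            label = "free"
        else:
            label = "mixed"
        rows.append((t.track_id, int(r2.size), label))
    return pd.DataFrame(rows, columns=["track_id", "n_steps", "mobility"])


def mobility_fractions(classes: pd.DataFrame) -> dict[str, float]:
    """Per-class fractions over classified tracks."""
    if len(classes) == 0:
        warnings.warn("no classifiable tracks")
        return {"confined": np.nan, "free": np.nan, "mixed": np.nan}
    frac = classes["mobility"].value_counts(normalize=True)
    return {k: float(frac.get(k, 0.0)) for k in ("confined", "free", "mixed")}
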