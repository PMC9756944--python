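"""Quantification of fluorescent foci and growth in hyphal time-lapse data.

Operates on 1D along-axis intensity profiles (position measured in um
from the hyphal tip) and per-frame tip/length records.  Provides peak
(focus) detection with SNIP-style background estimation, focus tracking
with duplication-event detection, tip-distance and inter-focus distance
metrics, loess trend smoothing, germination/stall phenotype rules and
the paired stalled-versus-growing sampling protocol.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

__all__ = [
    "PeakDetectConfig",
    "PhenotypeRules",
    "DuplicationEvent",
    "detect_foci",
    "detect_foci_all",
    "tip_distance_series",
    "interfocus_distances",
    "track_foci",
    "duplication_heatmap",
    "classify_phenotype",
    "branch_first_focus_time",
    "loess_trend",
    "stalled_vs_growing_sampling",
]


@dataclass
class PeakDetectConfig:
    smooth_sigma: float = 0.1  # um
    background_window: float = 2.0  # um
    snr_threshold: float = 5.0  # x robust noise sigma
    min_separation: float = 0.5  # um
    pixel_size: float = 0.065  # um

    def __post_init__(self) -> None:
        for name in ("smooth_sigma", "background_window", "snr_threshold",
                     "min_separation", "pixel_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def _snip_background(y: np.ndarray, half_width_px: int) -> np.ndarray:
    """SNIP-style background: iterative clipping against the mean of
    symmetric neighbours at increasing spans (decreasing-window variant)."""
    v = y.astype(float).copy()
    n = v.size
    for w in range(half_width_px, 0, -1):
        if 2 * w >= n:
            continue
        left = v[: n - 2 * w]
        right = v[2 * w :]
        mid = v[w : n - w]
        v[w : n - w] = np.minimum(mid, 0.5 * (left + right))
    return v


def detect_foci(
    positions: np.ndarray,
    intensities: np.ndarray,
    config: PeakDetectConfig | None = None,
) -> pd.DataFrame:
    """Detect fluorescent foci in a 1D intensity profile.

    Background is estimated by SNIP-style iterative clipping over
    ``background_window``; the background-subtracted signal is Gaussian
    smoothed (``smooth_sigma``); local maxima exceeding
    ``snr_threshold`` times a robust (MAD-based) noise sigma are kept;
    maxima closer than ``min_separation`` are resolved in favour of the
    higher; positions are refined by 3-point parabolic interpolation.

    Returns a DataFrame (position_um, intensity) sorted by position.
    """
    config = config or PeakDetectConfig()
    pos = np.asarray(positions, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite intensities")
    if y.size < 5:
        raise ValueError("profile must have at least 5 pixels")
    px = config.pixel_size

    bg = _snip_background(y, max(1, int(round(config.background_window / px / 2))))
    resid = y - bg
    sm = gaussian_filter1d(resid, sigma=max(config.smooth_sigma / px, 1e-6))
    # robust pixel noise from sigma-clipped first differences: peak slopes
    # are iteratively rejected, which a plain MAD cannot do on short
    # profiles where peaks cover a large fraction of the pixels
    d = np.diff(y)
    s = float(np.std(d)) if d.size else 0.0
    for _ in range(5):
        keep = np.abs(d - np.median(d)) < 3.0 * s
        if keep.sum() < 5 or s <= 0:
            break
        s_new = float(np.std(d[keep]))
        if abs(s_new - s) < 1e-3 * s:
            s = s_new
            break
        s = s_new
    sigma = s / np.sqrt(2.0)
    if sigma <= 0:
        sigma = max(np.std(resid), 1e-12)
    thr = config.snr_threshold * sigma

    cand = [
        i
        for i in range(1, y.size - 1)
        if sm[i] >= sm[i - 1] and sm[i] > sm[i + 1] and sm[i] > thr
    ]
    # min-separation: keep the higher of any pair closer than min_separation
    cand.sort(key=lambda i: -sm[i])
    kept: list[int] = []
    for i in cand:
        if all(abs(pos[i] - pos[j]) >= config.min_separation for j in kept):
            kept.append(i)
    rows = []
    for i in sorted(kept):
        denom = sm[i - 1] - 2 * sm[i] + sm[i + 1]
        delta = 0.5 * (sm[i - 1] - sm[i + 1]) / denom if denom != 0 else 0.0
        delta = float(np.clip(delta, -0.5, 0.5))
        rows.append((pos[i] + delta * px, float(resid[i])))
    return pd.DataFrame(rows, columns=["position_um", "intensity"])


def detect_foci_all(profiles: pd.DataFrame, config: PeakDetectConfig | None = None) -> pd.DataFrame:
    """Run :func:`detect_foci` on every (hypha_id, frame) profile group."""
    out = []
    for (hid, frame), g in profiles.groupby(["hypha_id", "frame"]):
        g = g.sort_values("position_um")
        try:
            foci = detect_foci(g["position_um"].to_numpy(), g["intensity"].to_numpy(), config)
        except ValueError:
            continue
        if len(foci) == 0:
            continue
        foci.insert(0, "frame", frame)
        foci.insert(0, "hypha_id", hid)
        out.append(foci)
    if not out:
        return pd.DataFrame(columns=["hypha_id", "frame", "position_um", "intensity"])
    return pd.concat(out, ignore_index=True)


def tip_distance_series(hypha: pd.DataFrame, foci: pd.DataFrame) -> pd.DataFrame:
    """Per-frame distance from the tip to the tip-proximal focus.

    ``hypha`` is the per-frame record of one hypha (frame, time_min);
    ``foci`` the detected foci of the same hypha with ``position_um``
    measured from the tip.  Frames with no focus get NaN and are counted
    in the ``focus_free`` attribute consumers can check via isna().
    """
    hf = hypha[["frame", "time_min"]].drop_duplicates().sort_values("frame")
    nearest = foci.groupby("frame")["position_um"].min()
    out = hf.copy()
    out["tip_distance_um"] = out["frame"].map(nearest)
    return out.reset_index(drop=True)


def interfocus_distances(positions: np.ndarray, mode: str = "adjacent") -> np.ndarray:
    """Distances between foci of one frame (positions along the axis).

    ``adjacent`` returns consecutive along-axis differences; ``all_pairs``
    every pairwise distance.  Fewer than two foci gives an empty array.
    """
    p = np.sort(np.asarray(positions, dtype=float))
    if p.size < 2:
        return np.array([])
    if mode == "adjacent":
        return np.diff(p)
    if mode == "all_pairs":
        return np.abs(p[:, None] - p[None, :])[np.triu_indices(p.size, k=1)]
    raise ValueError("mode must be 'adjacent' or 'all_pairs'")


@dataclass
class DuplicationEvent:
    hypha_id: object
    frame: int  # first frame with two sisters
    time_min: float
    sister_ids: tuple[int, int]
    # per 10-min interval after the split (up to 90 min): tip distances
    positions: pd.DataFrame  # columns interval, time_min, pos_a, pos_b, separation


def track_foci(
    foci: pd.DataFrame,
    max_move: float = 0.5,
    frame_interval: float = 10.0,
    n_intervals: int = 10,
    min_persist: int = 2,
    split_radius: float = 1.0,
) -> tuple[pd.DataFrame, list[DuplicationEvent]]:
    """Link detected foci of one hypha across frames; detect duplications.

    Foci are linked frame-to-frame by along-axis nearest neighbour
    within ``max_move`` (greedy in ascending distance; exact ties broken
    toward the tip-proximal candidate).  A focus that appears within
    ``split_radius`` of an existing trajectory while that trajectory
    continues starts a sister trajectory (sisters only become optically
    resolvable once separated, so the radius exceeds the per-frame
    movement bound); if the sister persists
    ``min_persist`` frames a :class:`DuplicationEvent` is recorded with
    the sister tip-distances at ``frame_interval`` spacing for
    ``n_intervals`` timepoints (90 min at 10-min imaging by default).

    Returns (trajectories table with traj_id per focus row, events).
    """
    foci = foci.sort_values(["frame", "position_um"]).reset_index(drop=True)
    frames = sorted(foci["frame"].unique())
    traj_of_row: dict[int, int] = {}
    last_pos: dict[int, float] = {}
    last_frame: dict[int, int] = {}
    parent: dict[int, int | None] = {}
    start_frame: dict[int, int] = {}
    length_of: dict[int, int] = {}
    next_traj = 0

    for f in frames:
        rows = foci.index[foci["frame"] == f].tolist()
        pts = foci.loc[rows, "position_um"].to_numpy()
        active = [t for t in last_frame if last_frame[t] == f - 1]
        pairs = []
        for ti in active:
            for k, p in enumerate(pts):
                d = abs(p - last_pos[ti])
                if d <= max_move:
                    # tie-break toward tip-proximal candidate (smaller p)
                    pairs.append((d, p, ti, k))
        pairs.sort()
        used_t: set[int] = set()
        used_k: set[int] = set()
        assigned: dict[int, int] = {}
        for _d, _p, ti, k in pairs:
            if ti in used_t or k in used_k:
                continue
            used_t.add(ti)
            used_k.add(k)
            assigned[k] = ti
        for k, row in enumerate(rows):
            p = float(pts[k])
            if k in assigned:
                ti = assigned[k]
            else:
                # unmatched focus: sister of the nearest continuing
                # trajectory within max_move, else a new trajectory
                best = None
                for ti2 in active:
                    d = abs(p - last_pos[ti2])
                    if d <= split_radius and ti2 in used_t:
                        if best is None or d < best[0] or (d == best[0] and last_pos[ti2] < best[1]):
                            best = (d, last_pos[ti2], ti2)
                ti = next_traj
                next_traj += 1
                parent[ti] = best[2] if best is not None else None
                start_frame[ti] = int(f)
                length_of[ti] = 0
            traj_of_row[row] = ti
            last_pos[ti] = p
            last_frame[ti] = int(f)
            length_of[ti] = length_of.get(ti, 0) + 1
            start_frame.setdefault(ti, int(f))
            parent.setdefault(ti, None)

    out = foci.copy()
    out["traj_id"] = out.index.map(traj_of_row)

    events: list[DuplicationEvent] = []
    for ti, par in parent.items():
        if par is None or length_of.get(ti, 0) < min_persist:
            continue
        f0 = start_frame[ti]
        a = out[out["traj_id"] == par].set_index("frame")["position_um"]
        b = out[out["traj_id"] == ti].set_index("frame")["position_um"]
        rows = []
        for i in range(n_intervals):
            f = f0 + i
            if f in a.index and f in b.index:
                rows.append((i, i * frame_interval, float(a[f]), float(b[f]),
                             abs(float(b[f]) - float(a[f]))))
        pos = pd.DataFrame(rows, columns=["interval", "time_min", "pos_a", "pos_b", "separation"])
        hid = out["hypha_id"].iloc[0] if "hypha_id" in out.columns else None
        events.append(DuplicationEvent(hid, int(f0), f0 * frame_interval, (par, ti), pos))
    return out, events


def duplication_heatmap(events: list[DuplicationEvent], n_intervals: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Stack sister tip-distances into an (2*events, n_intervals) matrix.

    Rows alternate sister A / sister B per event; missing timepoints are
    NaN.  Returns (matrix, column means ignoring NaN) — the column means
    are the average focus position trace.
    """
    M = np.full((2 * len(events), n_intervals), np.nan)
    for i, ev in enumerate(events):
        for _, r in ev.positions.iterrows():
            j = int(r["interval"])
            if j < n_intervals:
                M[2 * i, j] = r["pos_a"]
                M[2 * i + 1, j] = r["pos_b"]
    col_means = np.full(n_intervals, np.nan)
    if len(events):
        has_data = ~np.all(np.isnan(M), axis=0)
        col_means[has_data] = np.nanmean(M[:, has_data], axis=0)
    return M, col_means


@dataclass
class PhenotypeRules:
    total_observation: float = 960.0  # min (16 h)
    germ_inhibit_window: float = 60.0  # min: inhibited if pause > this
    branch_stall_window: float = 120.0  # min: stalled if pause >= this to end
    extension_epsilon: float = 0.2  # um minimum movement counted as extension

    def __post_init__(self) -> None:
        if max(self.germ_inhibit_window, self.branch_stall_window) > self.total_observation:
            raise ValueError("rule windows must not exceed total_observation")


def classify_phenotype(
    hypha: pd.DataFrame,
    rules: PhenotypeRules | None = None,
    kind: str = "spore",
) -> str:
    """Apply germination / growth-arrest phenotype rules to one series.

    ``hypha`` needs columns time_min and length_um covering the
    observation window.  For ``kind='spore'``: no emergence (length never
    exceeds extension_epsilon) during the whole observation ->
    ``nongerminating``; emergence followed by any pause in extension
    longer than ``germ_inhibit_window`` -> ``inhibited``; else
    ``germinated``.  For ``kind='branch'``: a pause of at least
    ``branch_stall_window`` with no re-initiation before the end of the
    series -> ``stalled_branch``; else ``growing``.  A series too short
    to apply the rule returns ``unclassifiable``.
    """
    rules = rules or PhenotypeRules()
    s = hypha.sort_values("time_min")
    t = s["time_min"].to_numpy(dtype=float)
    ln = s["length_um"].to_numpy(dtype=float)
    if t.size < 2:
        return "unclassifiable"
    span = t[-1] - t[0]
    eps = rules.extension_epsilon

    emerged = ln > eps
    if not emerged.any():
        if span >= rules.total_observation:
            return "nongerminating"
        return "unclassifiable"
    i0 = int(np.argmax(emerged))

    # times at which extension was observed (growth of > eps since the
    # previous recorded maximum)
    grow_times = [t[i0]]
    runmax = ln[i0]
    for i in range(i0 + 1, t.size):
        if ln[i] - runmax > eps:
            grow_times.append(t[i])
            runmax = ln[i]
    grow_times.append(None)  # sentinel for the tail pause
    pauses = []  # (duration, reaches_end)
    for a, b in zip(grow_times[:-1], grow_times[1:]):
        if b is None:
            pauses.append((t[-1] - a, True))
        else:
            pauses.append((b - a, False))

    if kind == "branch":
        if span < rules.branch_stall_window:
            return "unclassifiable"
        for dur, to_end in pauses:
            if dur >= rules.branch_stall_window and to_end:
                return "stalled_branch"
        return "growing"
    if kind == "spore":
        if span < rules.germ_inhibit_window:
            return "unclassifiable"
        for dur, _to_end in pauses:
            if dur > rules.germ_inhibit_window:
                return "inhibited"
        return "germinated"
    raise ValueError("kind must be 'spore' or 'branch'")


def branch_first_focus_time(
    branch_appear_time: float, foci: pd.DataFrame, frame_interval: float = 10.0
) -> float:
    """Minutes from branch appearance to its first detected focus.

    ``foci`` are the detected foci of the branch; returns NaN (flagging a
    focus-free branch) when no focus is ever seen.
    """
    if len(foci) == 0:
        return float("nan")
    if "time_min" in foci.columns:
        first = float(foci["time_min"].min())
    else:
        first = float(foci["frame"].min()) * frame_interval
    return first - branch_appear_time


def loess_trend(t: np.ndarray, y: np.ndarray, span: float = 0.5) -> np.ndarray:
    """Loess smooth (local linear regression, tricube weights) of y over t,
    evaluated at the input t."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size < 5:
        raise ValueError("need at least 5 points")
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    if np.all(t == t[0]):
        raise ValueError("degenerate input: all t identical")
    fitted = _sm_lowess(y, t, frac=span, it=0, return_sorted=False)
    return np.asarray(fitted, dtype=float)


def stalled_vs_growing_sampling(
    hyphae: pd.DataFrame,
    foci: pd.DataFrame,
    stall_events: pd.DataFrame,
    frame_interval: float = 10.0,
    length_tolerance: float = 1.0,
) -> pd.DataFrame:
    """Paired sampling protocol for stalled versus growing hyphae.

    For every stalled hypha the tip-proximal focus distance and focus
    count are measured one frame (10 min) before growth arrest; each is
    paired with measurements from normally growing hyphae at the frame
    where their length is closest to the stalled hypha's length at
    sampling (within ``length_tolerance`` um).  Returns a long table
    (group, hypha_id, frame, length_um, tip_distance_um, n_foci).
    """
    rows = []
    stalled_ids = set(stall_events["hypha_id"]) if len(stall_events) else set()
    lengths_at_sample = []
    for _, ev in stall_events.iterrows():
        hid = ev["hypha_id"]
        f = int(ev["frame"]) - 1
        h = hyphae[(hyphae["hypha_id"] == hid) & (hyphae["frame"] == f)]
        if len(h) == 0:
            continue
        fr_foci = foci[(foci["hypha_id"] == hid) & (foci["frame"] == f)]
        tipd = float(fr_foci["position_um"].min()) if len(fr_foci) else float("nan")
        length = float(h["length_um"].iloc[0])
        lengths_at_sample.append(length)
        rows.append(("stalled", hid, f, length, tipd, len(fr_foci)))
    # pair each stalled measurement with a distinct growing hypha sampled
    # at the frame where its length best matches the stalled length
    growing = {hid: g for hid, g in hyphae.groupby("hypha_id") if hid not in stalled_ids}
    used: set = set()
    for target in lengths_at_sample:
        best = None
        for hid, g in growing.items():
            if hid in used:
                continue
            diffs = (g["length_um"] - target).abs()
            i = diffs.idxmin()
            if diffs[i] > length_tolerance:
                continue
            if best is None or diffs[i] < best[0]:
                best = (float(diffs[i]), hid, i)
        if best is None:
            continue
        _, hid, i = best
        used.add(hid)
        g = growing[hid]
        f = int(g.loc[i, "frame"])
        fr_foci = foci[(foci["hypha_id"] == hid) & (foci["frame"] == f)]
        tipd = float(fr_foci["position_um"].min()) if len(fr_foci) else float("nan")
        rows.append(("growing", hid, f, float(g.loc[i, "length_um"]), tipd, len(fr_foci)))
    return pd.DataFrame(
        rows,
        columns=["group", "hypha_id", "frame", "length_um", "tip_distance_um", "n_foci"],
    )
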