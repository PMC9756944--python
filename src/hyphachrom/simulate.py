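"""Synthetic-data generators with known ground truth.

Every analysis stage in this package consumes one of four input classes:
single-molecule localization tables (PALM), per-hypha 1D intensity
profiles from time-lapse imaging, aligned ChIP fragment intervals plus a
genome, and optical-density growth curves.  The generators here emulate
the statistical structure those analyses assume — two-state Brownian
motion with localization error, blinking and bleaching; extending and
branching hyphae carrying duplicating fluorescent foci; negative-binomial
windowed fragment counts over AT-biased binding sites; noisy
log-logistic growth — and return the observable tables together with the
ground truth that produced them, so recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SPTSimConfig",
    "HyphaSimConfig",
    "ChIPSimConfig",
    "GrowthSimConfig",
    "simulate_spt",
    "simulate_hyphae",
    "simulate_chip",
    "simulate_growth",
]


# ---------------------------------------------------------------------------
# single-particle tracking (PALM)
# ---------------------------------------------------------------------------


@dataclass
class SPTSimConfig:
    """Two-state Brownian PALM acquisition.

    Molecules diffuse in 2D switching between a slow (DNA-bound) and a
    fast (freely diffusing) state.  Switching follows a two-state Markov
    chain parameterised so that its stationary slow-state occupancy is
    ``f_slow`` for any overall switching rate ``switch_prob``:
    p(slow->fast) = switch_prob*(1-f_slow), p(fast->slow) =
    switch_prob*f_slow.  Localization error is i.i.d. Gaussian per
    coordinate, applied after the trajectory is simulated.  Blinking
    removes single frames; bleaching terminates a molecule.
    """

    n_molecules: int = 200
    D_slow: float = 0.015  # um^2/s
    D_fast: float = 0.400  # um^2/s
    f_slow: float = 0.75
    switch_prob: float = 0.05  # per frame, overall switching rate scale
    dt: float = 0.03  # s per frame
    n_frames: int = 100
    loc_sigma: float = 0.02  # um localization error per coordinate
    p_bleach: float = 0.0  # per frame
    p_blink: float = 0.0  # per frame (single-frame dropout)
    fov: tuple[float, float] = (20.0, 20.0)  # um
    stagger: bool = False  # photoactivate molecules at random frames
    seed: int = 0

    def validate(self) -> None:
        for name in ("f_slow", "switch_prob", "p_bleach", "p_blink"):
            v = getattr(self, name)
            if not np.isfinite(v) or not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1], got {v}")
        if not (0.0 <= self.D_slow <= self.D_fast):
            raise ValueError("require 0 <= D_slow <= D_fast")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.n_molecules < 1 or self.n_frames < 1:
            raise ValueError("n_molecules and n_frames must be >= 1")
        if self.loc_sigma < 0:
            raise ValueError("loc_sigma must be >= 0")
        if len(self.fov) != 2 or min(self.fov) <= 0:
            raise ValueError("fov must be a positive (width, height)")


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflect coordinates into [lo, hi] (period 2*(hi-lo))."""
    span = hi - lo
    y = np.mod(x - lo, 2.0 * span)
    y = np.where(y > span, 2.0 * span - y, y)
    return y + lo


def simulate_spt(config: SPTSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a PALM acquisition.

    Returns
    -------
    localizations : DataFrame with columns frame, x_um, y_um, intensity —
        what a real experiment observes (no molecule identity).
    truth : DataFrame with columns molecule_id, frame, state, x_um, y_um —
        per-frame ground truth; state is "slow" or "fast".  Joins 1:1 to
        the localization table on (molecule_id implicit via row order is
        NOT assumed: both tables share frame/x/y).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    w, h = config.fov

    p_sf = config.switch_prob * (1.0 - config.f_slow)  # slow -> fast
    p_fs = config.switch_prob * config.f_slow  # fast -> slow
    sigma_step = np.sqrt(2.0 * np.array([config.D_slow, config.D_fast]) * config.dt)

    loc_rows = []
    truth_rows = []
    for mol in range(config.n_molecules):
        if config.stagger:
            start = int(rng.integers(0, config.n_frames))
        else:
            start = 0
        # bleach: geometric lifetime (in frames after appearance)
        if config.p_bleach > 0:
            life = 1 + int(rng.geometric(config.p_bleach))
        else:
            life = config.n_frames
        frames = np.arange(start, min(config.n_frames, start + life))
        n = frames.size
        if n == 0:
            continue
        states = np.empty(n, dtype=np.int8)
        states[0] = 0 if rng.random() < config.f_slow else 1
        u = rng.random(n)
        for i in range(1, n):
            p = p_sf if states[i - 1] == 0 else p_fs
            states[i] = (1 - states[i - 1]) if u[i] < p else states[i - 1]
        steps = rng.normal(0.0, 1.0, size=(n, 2)) * sigma_step[states][:, None]
        x0 = rng.uniform([0, 0], [w, h])
        pos = x0 + np.concatenate([[[0.0, 0.0]], np.cumsum(steps[1:], axis=0)])
        pos[:, 0] = _reflect(pos[:, 0], 0.0, w)
        pos[:, 1] = _reflect(pos[:, 1], 0.0, h)
        obs = pos + rng.normal(0.0, config.loc_sigma, size=pos.shape)
        obs[:, 0] = np.clip(obs[:, 0], 0.0, w)
        obs[:, 1] = np.clip(obs[:, 1], 0.0, h)
        visible = rng.random(n) >= config.p_blink
        intens = rng.lognormal(6.0, 0.3, size=n)
        for i in range(n):
            truth_rows.append(
                (mol, int(frames[i]), "slow" if states[i] == 0 else "fast",
                 obs[i, 0], obs[i, 1], bool(visible[i]))
            )
            if visible[i]:
                loc_rows.append((int(frames[i]), obs[i, 0], obs[i, 1], intens[i]))

    locs = pd.DataFrame(loc_rows, columns=["frame", "x_um", "y_um", "intensity"])
    locs = locs.sort_values(["frame", "x_um"], kind="stable").reset_index(drop=True)
    truth = pd.DataFrame(
        truth_rows,
        columns=["molecule_id", "frame", "state", "x_um", "y_um", "visible"],
    )
    return locs, truth


# ---------------------------------------------------------------------------
# hyphal time-lapse
# ---------------------------------------------------------------------------


@dataclass
class HyphaSimConfig:
    """Extending hyphae carrying fluorescent foci, observed as 1D profiles.

    Coordinates are distances from the current hyphal tip (um), matching
    how along-axis distances are measured in tip-growing filaments.  Foci
    are Gaussian intensity peaks of width ``peak_sigma`` on additive
    Gaussian noise.  The tip-proximal focus is anchored at the tip and
    drifts away at ``tip_drift`` per frame when anchorage is lost; body
    foci recede from the tip at the extension rate.  Duplication splits
    the tip-proximal focus; the new sister separates at ``split_rate``
    per frame up to ``split_max``.  Branches appear with ``branch_prob``
    per frame and acquire their first focus ``branch_focus_delay`` frames
    later.  A hypha stalls permanently with ``stall_prob`` per frame.
    """

    n_hyphae: int = 30
    frame_interval: float = 10.0  # min
    n_frames: int = 30
    extension_rate: float = 0.3  # um/frame
    branch_prob: float = 0.0  # per frame per hypha
    focus_spacing: float = 1.55  # um between body foci
    duplication_interval: int = 0  # frames between duplications; 0 = off
    tip_drift: float = 0.0  # um/frame tip-proximal anchorage loss
    stall_prob: float = 0.0  # per frame, permanent
    pixel_size: float = 0.065  # um
    peak_sigma: float = 0.15  # um
    peak_amplitude: float = 100.0  # a.u.
    noise_sigma: float = 10.0  # a.u.
    initial_length: float = 3.0  # um
    initial_tip_distance: float = 1.0  # um, tip-proximal focus at t=0
    split_rate: float = 0.3  # um/frame sister separation growth
    split_max: float = 1.75  # um plateau of sister separation
    branch_focus_delay: int = 3  # frames from branch appearance to focus
    seed: int = 0

    def validate(self) -> None:
        if self.frame_interval <= 0 or self.pixel_size <= 0:
            raise ValueError("frame_interval and pixel_size must be > 0")
        for name in ("extension_rate", "branch_prob", "tip_drift", "stall_prob",
                     "focus_spacing", "peak_sigma", "noise_sigma", "split_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.initial_length < 0 or self.initial_tip_distance < 0:
            raise ValueError("configs implying negative positions are invalid")
        if self.n_hyphae < 1 or self.n_frames < 1:
            raise ValueError("n_hyphae and n_frames must be >= 1")


@dataclass
class _Hypha:
    hypha_id: int
    parent_id: int | None
    appear_frame: int
    length: float
    foci: list[dict] = field(default_factory=list)  # {'d': tip distance, 'anchored': bool, 'split_age': int|None}
    stalled_at: int | None = None
    next_dup: int | None = None


def simulate_hyphae(
    config: HyphaSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a hyphal time-lapse.

    Returns
    -------
    hyphae : DataFrame (hypha_id, parent_id, appear_frame, frame, time_min,
        length_um) — per-frame tip/length record; tip position along the
        growth axis equals length.
    profiles : DataFrame (hypha_id, frame, position_um, intensity) —
        1D intensity profile, position measured from the tip.
    truth_foci : DataFrame (hypha_id, frame, focus_id, position_um) —
        ground-truth focus tip-distances.
    events : DataFrame (event, hypha_id, frame, time_min, detail) — log of
        duplication, branch, first_focus and stall events.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    hyphae: list[_Hypha] = []
    next_id = 0
    focus_counter = 0
    for _ in range(config.n_hyphae):
        h = _Hypha(next_id, None, 0, config.initial_length)
        d = config.initial_tip_distance
        while d <= h.length:
            h.foci.append({"d": d, "anchored": d == config.initial_tip_distance,
                           "split_age": None, "id": focus_counter})
            focus_counter += 1
            d += config.focus_spacing
        if config.duplication_interval > 0:
            h.next_dup = config.duplication_interval
        hyphae.append(h)
        next_id += 1

    hy_rows, prof_rows, truth_rows, event_rows = [], [], [], []

    for frame in range(config.n_frames):
        t = frame * config.frame_interval
        for h in list(hyphae):
            if frame < h.appear_frame:
                continue
            if frame > h.appear_frame:
                # growth step from previous frame
                if h.stalled_at is None and rng.random() < config.stall_prob:
                    h.stalled_at = frame
                    event_rows.append(("stall", h.hypha_id, frame, t, ""))
                growing = h.stalled_at is None
                ext = config.extension_rate if growing else 0.0
                h.length += ext
                for f in h.foci:
                    if f["split_age"] is not None:
                        f["split_age"] += 1  # schedule-positioned from tip
                    elif f["anchored"]:
                        f["d"] += config.tip_drift
                    else:
                        f["d"] += ext
                # duplication of the tip-proximal focus
                if h.next_dup is not None and frame - h.appear_frame >= h.next_dup:
                    h.next_dup += config.duplication_interval
                    if h.foci:
                        tipf = min(h.foci, key=lambda f: f["d"])
                        sister = {"d": tipf["d"], "anchored": False,
                                  "split_age": 0, "id": focus_counter}
                        focus_counter += 1
                        h.foci.append(sister)
                        event_rows.append(
                            ("duplication", h.hypha_id, frame, t,
                             f"parent={tipf['id']};sister={sister['id']}")
                        )
                # branching
                if h.stalled_at is None and rng.random() < config.branch_prob:
                    b = _Hypha(next_id, h.hypha_id, frame, 0.2)
                    hyphae.append(b)
                    event_rows.append(("branch", b.hypha_id, frame, t, f"parent={h.hypha_id}"))
                    next_id += 1
            # delayed first focus in branches
            if (h.parent_id is not None and not h.foci
                    and frame - h.appear_frame >= config.branch_focus_delay):
                h.foci.append({"d": min(config.initial_tip_distance, h.length),
                               "anchored": True, "split_age": None,
                               "id": focus_counter})
                focus_counter += 1
                event_rows.append(("first_focus", h.hypha_id, frame, t, ""))

            # sister separation schedule: freshly split focus recedes at
            # split_rate until the pair separation reaches split_max
            positions = []
            for f in h.foci:
                d = f["d"]
                if f["split_age"] is not None:
                    extra = min(config.split_rate * f["split_age"], config.split_max)
                    d = f["d"] + extra
                positions.append(max(0.0, min(d, h.length)))

            hy_rows.append((h.hypha_id, h.parent_id, h.appear_frame, frame, t, h.length))
            for f, d in zip(h.foci, positions):
                truth_rows.append((h.hypha_id, frame, f["id"], d))
            grid = np.arange(0.0, h.length + config.pixel_size / 2, config.pixel_size)
            signal = np.zeros_like(grid)
            for d in positions:
                signal += config.peak_amplitude * np.exp(
                    -0.5 * ((grid - d) / config.peak_sigma) ** 2
                )
            if config.noise_sigma > 0:
                signal = signal + rng.normal(0.0, config.noise_sigma, size=grid.size)
            for p, v in zip(grid, signal):
                prof_rows.append((h.hypha_id, frame, p, v))

    hyphae_df = pd.DataFrame(
        hy_rows,
        columns=["hypha_id", "parent_id", "appear_frame", "frame", "time_min", "length_um"],
    )
    profiles = pd.DataFrame(prof_rows, columns=["hypha_id", "frame", "position_um", "intensity"])
    truth = pd.DataFrame(truth_rows, columns=["hypha_id", "frame", "focus_id", "position_um"])
    events = pd.DataFrame(event_rows, columns=["event", "hypha_id", "frame", "time_min", "detail"])
    return hyphae_df, profiles, truth, events


# ---------------------------------------------------------------------------
# ChIP fragments
# ---------------------------------------------------------------------------


@dataclass
class ChIPSimConfig:
    """Windowed differential-binding design with AT-biased sites.

    The genome is random with per-base AT probability 1-gc_background,
    raised by ``site_at_boost`` inside binding sites.  Per sample,
    fragment counts for each site and each 1-kb background tile are
    Gamma-Poisson (negative binomial with dispersion ``dispersion``);
    the Gamma multiplier is shared by all fragments of a site/tile so
    windowed counts inherit the dispersion under thinning.  Site means
    scale with the per-condition enrichment fold and the library size.
    """

    genome_length: int = 100_000
    gc_background: float = 0.5
    n_sites: int = 20
    site_width: int = 200
    site_at_boost: float = 0.2
    enrichment_fold: float | dict[str, float] = 8.0
    fragment_length: int = 200
    library_sizes: int | dict[str, int] = 50_000
    dispersion: float = 0.1
    n_reps: int = 3
    conditions: tuple[str, str] = ("treated", "control")
    bg_tile: int = 1000
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.gc_background <= 1.0:
            raise ValueError("gc_background must be in [0, 1]")
        if self.n_sites * self.site_width >= self.genome_length:
            raise ValueError("n_sites * site_width must be < genome_length")
        folds = self._folds()
        if any(f < 1.0 for f in folds.values()):
            raise ValueError("enrichment_fold must be >= 1 at true sites")
        libs = self._libs()
        if any(v <= 0 for v in libs.values()):
            raise ValueError("library_sizes must be > 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")

    def _folds(self) -> dict[str, float]:
        if isinstance(self.enrichment_fold, dict):
            return {c: float(self.enrichment_fold.get(c, 1.0)) for c in self.conditions}
        return {self.conditions[0]: float(self.enrichment_fold), self.conditions[1]: 1.0}

    def _libs(self) -> dict[str, int]:
        if isinstance(self.library_sizes, dict):
            return {c: int(self.library_sizes[c]) for c in self.conditions}
        return {c: int(self.library_sizes) for c in self.conditions}


def _random_genome(rng, length: int, at_prob: np.ndarray) -> str:
    at = rng.random(length) < at_prob
    half = rng.random(length) < 0.5
    bases = np.where(at, np.where(half, "A", "T"), np.where(half, "G", "C"))
    return "".join(bases)


def simulate_chip(
    config: ChIPSimConfig,
) -> tuple[dict[str, pd.DataFrame], str, pd.DataFrame]:
    """Simulate a two-condition ChIP fragment dataset.

    Returns
    -------
    fragments : dict sample_name -> BED-like DataFrame (chrom, start, end,
        name, score, strand), sample names "<condition>_rep<i>".
    genome : genome sequence (single contig "chr").
    truth : DataFrame (site_id, start, end, fold_<cond>...) of planted sites.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    L = config.genome_length
    folds = config._folds()
    libs = config._libs()

    # non-overlapping site placement with retries
    starts: list[int] = []
    for _ in range(config.n_sites):
        ok = False
        for _try in range(1000):
            s = int(rng.integers(0, L - config.site_width))
            if all(abs(s - o) >= config.site_width for o in starts):
                ok = True
                starts.append(s)
                break
        if not ok:
            raise RuntimeError("could not place non-overlapping sites")
    starts.sort()
    sites = np.array(starts)

    at_prob = np.full(L, 1.0 - config.gc_background)
    for s in sites:
        at_prob[s : s + config.site_width] = np.minimum(
            1.0, 1.0 - config.gc_background + config.site_at_boost
        )
    genome = _random_genome(rng, L, at_prob)

    tile_starts = np.arange(0, L, config.bg_tile)
    tile_len = np.minimum(tile_starts + config.bg_tile, L) - tile_starts

    frag_len = config.fragment_length
    fragments: dict[str, pd.DataFrame] = {}
    for cond in config.conditions:
        fold = folds[cond]
        site_mass = config.site_width * fold * np.ones(len(sites))
        bg_mass = tile_len.astype(float)
        total_mass = site_mass.sum() + bg_mass.sum()
        lam_sites = libs[cond] * site_mass / total_mass
        lam_tiles = libs[cond] * bg_mass / total_mass
        for rep in range(1, config.n_reps + 1):
            name = f"{cond}_rep{rep}"
            phi = config.dispersion
            all_fs, all_fe = [], []
            for lam_vec, starts_vec, widths in (
                (lam_sites, sites, np.full(len(sites), config.site_width)),
                (lam_tiles, tile_starts, tile_len),
            ):
                if phi > 0:
                    gammas = rng.gamma(1.0 / phi, phi, size=lam_vec.size)
                else:
                    gammas = np.ones(lam_vec.size)
                counts = rng.poisson(lam_vec * gammas)
                # fragment centres uniform within their site/tile
                reg_start = np.repeat(starts_vec, counts).astype(float)
                reg_width = np.repeat(widths, counts).astype(float)
                centers = reg_start + rng.uniform(0.0, 1.0, reg_start.size) * reg_width
                fs = np.clip((centers - frag_len / 2).astype(int), 0, L - 1)
                all_fs.append(fs)
                all_fe.append(np.minimum(fs + frag_len, L))
            fs = np.concatenate(all_fs)
            fe = np.concatenate(all_fe)
            strands = np.where(rng.random(fs.size) < 0.5, "+", "-")
            df = pd.DataFrame({"chrom": "chr", "start": fs, "end": fe,
                               "name": [f"frag{i}" for i in range(fs.size)],
                               "score": 0, "strand": strands})
            df = df.sort_values(["start", "end"], kind="stable").reset_index(drop=True)
            fragments[name] = df

    truth = pd.DataFrame({"site_id": np.arange(len(sites)), "start": sites,
                          "end": sites + config.site_width})
    for cond in config.conditions:
        truth[f"fold_{cond}"] = folds[cond]
    return fragments, genome, truth


# ---------------------------------------------------------------------------
# growth curves
# ---------------------------------------------------------------------------


@dataclass
class GrowthSimConfig:
    """Noisy three-parameter log-logistic OD curves.

    OD(t) = d / (1 + exp(b * (log t - log e))) + N(0, noise_sigma);
    with the sign convention that negative b gives an increasing curve,
    d is the plateau (maximal OD) and e the ED50 (time of half-maximal OD).
    """

    b_true: float = -5.08
    d_true: float = 1.0
    e_true: float = 11.8  # h
    noise_sigma: float = 0.02  # OD units
    n_replicates: int = 5
    t_grid: np.ndarray = field(
        default_factory=lambda: np.arange(0.25, 48.0 + 1e-9, 0.25)
    )  # h; quarter-hour sampling over 48 h
    seed: int = 0

    def validate(self) -> None:
        t = np.asarray(self.t_grid, dtype=float)
        if t.ndim != 1 or t.size < 2:
            raise ValueError("t_grid must be a 1D grid of at least 2 points")
        if np.any(t <= 0):
            raise ValueError("all t_grid values must be > 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("t_grid must be strictly increasing")
        if self.e_true <= 0 or self.d_true <= 0:
            raise ValueError("e_true and d_true must be > 0")
        if self.noise_sigma < 0 or self.n_replicates < 1:
            raise ValueError("noise_sigma >= 0 and n_replicates >= 1 required")


def log_logistic(t: np.ndarray, b: float, d: float, e: float) -> np.ndarray:
    """Three-parameter log-logistic response d/(1+exp(b*(log t - log e)))."""
    t = np.asarray(t, dtype=float)
    return d / (1.0 + np.exp(b * (np.log(t) - np.log(e))))


def simulate_growth(config: GrowthSimConfig) -> pd.DataFrame:
    """Simulate replicate OD curves; columns time_h, rep1..repN."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    t = np.asarray(config.t_grid, dtype=float)
    mean = log_logistic(t, config.b_true, config.d_true, config.e_true)
    out = {"time_h": t}
    for r in range(1, config.n_replicates + 1):
        noise = rng.normal(0.0, config.noise_sigma, size=t.size) if config.noise_sigma > 0 else 0.0
        out[f"rep{r}"] = mean + noise
    return pd.DataFrame(out)
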