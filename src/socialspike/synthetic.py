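"""Synthetic colony trajectories and a behavior-coupled spike train.

The generator emulates the experimental setting — a 55 x 55 cm hive floor
tilted by 17 deg, tracked at 10 frames/s, one focal bee carrying the
electrode among freely moving hive mates — with planted, recoverable
effects so that every downstream stage can be tested by parameter recovery:

* locomotion: per-bee 2-state (stop/go) Markov chains; log-normal walking
  speed in "go", wrapped-normal heading persistence, reflecting arena walls;
* social episodes: scripted approach events producing ground-truth passive
  contacts (a hive mate approaches the motionless focal bee), active
  contacts (the focal bee starts walking toward the approaching bee within
  1 s of contact) and walking onsets, each satisfying the corresponding
  state-window definition exactly;
* firing rate: lambda(t) = [baseline + beta_dist * exp(-d(t)/d0)
  + alpha * g(t - t_contact)] * m(t), where d is the nearest-bee distance,
  g a raised-cosine bump centered ``lead_s`` before each planted active
  contact, and m a log-normal rate multiplier redrawn every ``block_s``
  (sub-block sd set by the enclosing window's social state) that plants a
  state-dependent within-window rate variance;
* spikes: inhomogeneous-Poisson thinning against lambda_max.

Outside scripted episodes a mutual 12 cm exclusion zone around the focal
bee guarantees that no unscripted approach crosses the 10 cm alone radius,
which makes the planted ground truth (including the alone-window tiling)
exact.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    FOCAL_ID,
    SpikeTrain,
    TrackTable,
    write_spikes,
    write_tracks,
)
from .social_states import SocialEvent, events_to_frame

DEFAULT_SIGMA_STATE = {
    "alone": 0.1,
    "random": 0.2,
    "walking_onset": 0.5,
    "passive_contact": 0.5,
    "active_contact": 1.0,
}


@dataclass
class SimConfig:
    """All knobs of the colony + spike-train simulation."""

    # arena and clock (experimental defaults)
    arena_width_cm: float = 55.0
    arena_height_cm: float = 55.0
    tilt_deg: float = 17.0
    frame_rate_hz: float = 10.0
    duration_s: float = 600.0
    n_other_bees: int = 5
    seed: int = 0

    # locomotion (stop/go Markov chain, per frame)
    p_stop_to_go: float = 0.02
    p_go_to_stop: float = 0.05
    mean_speed_cm_s: float = 1.5
    speed_log_sd: float = 0.4
    heading_sd_deg: float = 20.0
    focal_free_locomotion: bool = True

    # scripted social episodes
    passive_rate_per_min: float = 1.0
    active_rate_per_min: float = 1.0
    onset_rate_per_min: float = 0.0
    n_passive_events: int | None = None  # explicit counts override the rates
    n_active_events: int | None = None
    n_onset_events: int | None = None
    exclusion_radius_cm: float = 12.0
    min_event_separation_s: float = 16.0
    edge_margin_s: float = 12.0

    # firing-rate model
    baseline_hz: float = 3.0
    beta_dist_hz: float = 15.0
    dist_kernel_cm: float = 6.0  # d0 of exp(-d/d0)
    alpha_hz: float = 8.0
    lead_s: float = 1.2
    bump_width_s: float = 0.8
    sigma_state: dict = field(default_factory=lambda: dict(DEFAULT_SIGMA_STATE))
    sigma_background: float | None = None  # default: sigma_state["random"]
    block_s: float = 1.0  # multiplier sub-block length

    def __post_init__(self) -> None:
        for p in (self.p_stop_to_go, self.p_go_to_stop):
            if not 0.0 <= p <= 1.0:
                raise ValueError("transition probabilities must lie in [0, 1]")
        for r in (
            self.passive_rate_per_min,
            self.active_rate_per_min,
            self.onset_rate_per_min,
            self.baseline_hz,
            self.beta_dist_hz,
            self.alpha_hz,
        ):
            if r < 0:
                raise ValueError("rates must be nonnegative")
        if self.duration_s <= 16.0:
            raise ValueError(
                "duration_s must exceed 16 s to accommodate the +/-8 s perievent windows"
            )

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate_hz))


@dataclass
class TrueRate:
    """The planted firing rate lambda(t), piecewise constant on frames."""

    edges: np.ndarray  # bin left edges, s
    lam_hz: np.ndarray
    bin_w: float = 0.1


@dataclass
class GroundTruth:
    """Planted events, rate parameters, and bookkeeping for recovery tests."""

    events: list[SocialEvent]
    params: dict
    # frame spans (inclusive) during which some other bee is inside the
    # 10 cm alone radius; their complement defines the planted "alone"
    # tiling
    non_clear_spans: list[tuple[int, int]] = field(default_factory=list)
    rate: TrueRate | None = None

    def by_state(self, state: str) -> list[SocialEvent]:
        return [e for e in self.events if e.state == state]


# ---------------------------------------------------------------------------
# episode scripts (frame-level choreography of planted events)

_STAGE_F = 60  # episode starts this many frames before contact
_APPROACH_F = 20  # radial approach duration (frames) = the 2 s pre-contact
_HOLD_F = 10  # frames the pair stays in contact
_DEPART_F = 35  # frames for the partner to leave again
_D_STAGE = 10.8  # staging distance, just outside the alone radius (cm)
_D_CONTACT = 0.85  # contact distance, inside the 1 cm radius (cm)
_D_LEAVE = 13.0  # departure target distance (cm)
_ACTIVE_ONSET_F = 6  # focal starts walking this many frames before contact
_ACTIVE_WALK_F = 15  # focal walks 1.5 s (< 2 s: never counts as an onset)
# focal approach speed: clearly above the 0.5 cm/s moving threshold, but the
# total advance (1.5 s * 1.2 cm/s = 1.8 cm) stays below the 2 cm slack between
# the exclusion radius and the alone radius, so scripted focal motion can
# never drag an uninvolved bee inside 10 cm
_FOCAL_WALK_SPEED = 1.2  # cm/s
_ONSET_HOLD_F = 30  # scripted walking-onset: hold still 3 s ...
_ONSET_WALK_F = 30  # ... then walk 3 s
_ONSET_SPEED = 2.0  # cm/s


@dataclass
class _Episode:
    kind: str  # "passive", "active", "onset"
    sync_f: int  # contact frame / onset frame
    partner: int | None = None  # bee index, assigned at episode start
    u: np.ndarray | None = None  # approach bearing (unit vector)
    r0: float | None = None  # partner distance at episode start
    depart_dir: np.ndarray | None = None

    @property
    def start_f(self) -> int:
        return self.sync_f - (_STAGE_F if self.kind != "onset" else _ONSET_HOLD_F)

    @property
    def end_f(self) -> int:
        return self.sync_f + (_HOLD_F + _DEPART_F if self.kind != "onset" else _ONSET_WALK_F)

    def partner_distance(self, f: int) -> float:
        """Scripted partner-focal distance at frame f (contact episodes)."""
        c = self.sync_f
        if f <= c - _APPROACH_F:
            k = f - self.start_f
            K = _STAGE_F - _APPROACH_F
            return self.r0 + (_D_STAGE - self.r0) * k / K
        if f <= c:
            k = f - (c - _APPROACH_F)
            return _D_STAGE + (_D_CONTACT - _D_STAGE) * k / _APPROACH_F
        if f <= c + _HOLD_F:
            return _D_CONTACT
        k = f - (c + _HOLD_F)
        return _D_CONTACT + (_D_LEAVE - _D_CONTACT) * k / _DEPART_F


def _schedule_episodes(cfg: SimConfig, rng: np.random.Generator) -> list[_Episode]:
    counts = {}
    for kind, rate, explicit in (
        ("passive", cfg.passive_rate_per_min, cfg.n_passive_events),
        ("active", cfg.active_rate_per_min, cfg.n_active_events),
        ("onset", cfg.onset_rate_per_min, cfg.n_onset_events),
    ):
        n = explicit if explicit is not None else int(rng.poisson(rate * cfg.duration_s / 60.0))
        if kind in ("passive", "active") and cfg.n_other_bees == 0:
            n = 0
        counts[kind] = n
    lo, hi = cfg.edge_margin_s, cfg.duration_s - cfg.edge_margin_s
    if hi <= lo:
        raise ValueError("duration too short for any scripted episode")
    placed: list[tuple[str, float]] = []
    for kind in ("passive", "active", "onset"):
        for _ in range(counts[kind]):
            for _try in range(2000):
                t = float(rng.uniform(lo, hi))
                if all(abs(t - t0) >= cfg.min_event_separation_s for _, t0 in placed):
                    placed.append((kind, t))
                    break
            # if no placement was found the event is dropped (rare)
    placed.sort(key=lambda kt: kt[1])
    return [_Episode(kind, int(round(t * cfg.frame_rate_hz))) for kind, t in placed]


def _reflect(pos: np.ndarray, head: float, w: float, h: float) -> tuple[np.ndarray, float]:
    """Reflect a proposed position (and heading) off the arena walls."""
    x, y = pos
    hx, hy = np.cos(head), np.sin(head)
    for _ in range(4):
        if x < 0:
            x, hx = -x, -hx
        elif x > w:
            x, hx = 2 * w - x, -hx
        if y < 0:
            y, hy = -y, -hy
        elif y > h:
            y, hy = 2 * h - y, -hy
        if 0 <= x <= w and 0 <= y <= h:
            break
    return np.array([x, y]), float(np.arctan2(hy, hx))


def _toward_center(p: np.ndarray, center: np.ndarray) -> np.ndarray:
    vec = center - p
    n = float(np.hypot(*vec))
    return vec / n if n > 1e-9 else np.array([1.0, 0.0])


def simulate_colony(cfg: SimConfig) -> tuple[TrackTable, GroundTruth]:
    """Simulate the focal bee plus ``n_other_bees`` hive mates.

    Free motion is a correlated random walk with stop/go bouts; planted
    social episodes are scripted so that each satisfies the geometric and
    movement preconditions of its state definition exactly.  Reproducible
    bit-for-bit under a fixed (config, seed).
    """
    rng = np.random.default_rng(cfg.seed)
    fps = cfg.frame_rate_hz
    F = cfg.n_frames
    n_bees = 1 + cfg.n_other_bees  # index 0 = focal
    w, h = cfg.arena_width_cm, cfg.arena_height_cm
    center = np.array([w / 2, h / 2])
    excl = cfg.exclusion_radius_cm

    pos = np.empty((n_bees, 2))
    pos[0] = rng.uniform([0.25 * w, 0.25 * h], [0.75 * w, 0.75 * h])
    for i in range(1, n_bees):
        for _ in range(1000):
            p = rng.uniform([1.0, 1.0], [w - 1.0, h - 1.0])
            if float(np.hypot(*(p - pos[0]))) >= excl + 2.0:
                pos[i] = p
                break
        else:
            raise RuntimeError("could not place other bees outside the exclusion zone")
    heading = rng.uniform(0, 2 * np.pi, size=n_bees)
    going = np.zeros(n_bees, dtype=bool)
    theta = heading.copy()  # last body-axis angle (kept while stationary)

    episodes = _schedule_episodes(cfg, rng)
    ep_by_start = {e.start_f: e for e in episodes}
    active_ep: _Episode | None = None

    X = np.empty((F, n_bees))
    Y = np.empty((F, n_bees))
    TH = np.empty((F, n_bees))
    X[0], Y[0], TH[0] = pos[:, 0], pos[:, 1], theta % (2 * np.pi)
    mu_log = np.log(cfg.mean_speed_cm_s) - cfg.speed_log_sd**2 / 2
    head_sd = np.deg2rad(cfg.heading_sd_deg)

    def free_step(i: int, obstacles: np.ndarray) -> None:
        """One correlated-random-walk step for bee i.

        ``obstacles`` are positions the bee must not approach inside the
        exclusion radius (the focal bee for hive mates; all hive mates for
        the focal bee).  A blocked step is rejected and the bee turns away.
        """
        if going[i]:
            if rng.random() < cfg.p_go_to_stop:
                going[i] = False
        else:
            if rng.random() < cfg.p_stop_to_go:
                going[i] = True
        if not going[i]:
            return
        heading[i] = heading[i] + rng.normal(0.0, head_sd)
        speed = rng.lognormal(mu_log, cfg.speed_log_sd)
        step = speed / fps * np.array([np.cos(heading[i]), np.sin(heading[i])])
        new, heading[i] = _reflect(pos[i] + step, heading[i], w, h)
        if len(obstacles):
            d_new = np.hypot(*(obstacles - new).T)
            d_old = np.hypot(*(obstacles - pos[i]).T)
            jmin = int(np.argmin(d_new))
            if d_new[jmin] < excl and d_new[jmin] <= d_old[jmin]:
                away = pos[i] - obstacles[jmin]
                heading[i] = float(np.arctan2(away[1], away[0]))
                return
        pos[i] = new
        theta[i] = heading[i]

    for f in range(1, F):
        if active_ep is None and f in ep_by_start:
            active_ep = ep_by_start[f]
            if active_ep.kind in ("passive", "active"):
                others_d = np.hypot(*(pos[1:] - pos[0]).T)
                active_ep.partner = 1 + int(np.argmin(others_d))
                vec = pos[active_ep.partner] - pos[0]
                active_ep.r0 = float(np.hypot(*vec))
                active_ep.u = vec / active_ep.r0
            else:
                active_ep.u = _toward_center(pos[0], center)

        ep = active_ep
        scripted: set[int] = set()
        if ep is not None:
            c = ep.sync_f
            scripted.add(0)  # the focal bee is frozen unless walking below
            if ep.kind == "onset":
                if c <= f < c + _ONSET_WALK_F:
                    pos[0] = pos[0] + ep.u * (_ONSET_SPEED / fps)
                    theta[0] = float(np.arctan2(ep.u[1], ep.u[0]))
                    going[0] = False  # resume from "stop" after the script
            else:
                if (
                    ep.kind == "active"
                    and c - _ACTIVE_ONSET_F <= f < c - _ACTIVE_ONSET_F + _ACTIVE_WALK_F
                ):
                    pos[0] = pos[0] + ep.u * (_FOCAL_WALK_SPEED / fps)
                    theta[0] = float(np.arctan2(ep.u[1], ep.u[0]))
                    going[0] = False
                j = ep.partner
                scripted.add(j)
                d = ep.partner_distance(f)
                if f <= c + _HOLD_F:
                    direction = ep.u
                else:
                    if ep.depart_dir is None:
                        # leave along the approach bearing if there is room,
                        # else toward the arena center (provably in-arena:
                        # the target overshoots the center by < 14 cm)
                        room = _D_LEAVE + _ACTIVE_WALK_F * _FOCAL_WALK_SPEED / fps + 1.0
                        ep.depart_dir = ep.u if ep.r0 >= room else _toward_center(pos[0], center)
                    direction = ep.depart_dir
                pos[j] = pos[0] + d * direction
                face = -direction if f <= c + _HOLD_F else direction
                theta[j] = float(np.arctan2(face[1], face[0]))

        if 0 not in scripted and cfg.focal_free_locomotion:
            free_step(0, pos[1:])
        for i in range(1, n_bees):
            if i not in scripted:
                free_step(i, pos[0:1])

        X[f], Y[f], TH[f] = pos[:, 0], pos[:, 1], theta % (2 * np.pi)

        if ep is not None and f >= ep.end_f:
            active_ep = None

    # assemble the tracking table
    ids = [FOCAL_ID] + [f"bee{i:02d}" for i in range(1, n_bees)]
    frames = np.arange(F)
    records = []
    for b, bee in enumerate(ids):
        records.append(
            pd.DataFrame(
                {
                    "frame": frames,
                    "time_s": frames / fps,
                    "bee_id": bee,
                    "x_cm": X[:, b],
                    "y_cm": Y[:, b],
                    "theta_deg": np.rad2deg(TH[:, b]) % 360.0,
                }
            )
        )
    table = TrackTable(
        pd.concat(records, ignore_index=True)
        .sort_values(["frame", "bee_id"], kind="mergesort")
        .reset_index(drop=True),
        frame_rate_hz=fps,
    )

    # ground truth: planted events + the clear-interval tiling for "alone",
    # derived from the generator's own realized positions
    events: list[SocialEvent] = []
    sync_off = int(round(2.0 * fps))
    for ep in episodes:
        c = ep.sync_f
        if ep.kind == "onset":
            events.append(SocialEvent("walking_onset", (c - sync_off) / fps, c / fps))
        else:
            state = "passive_contact" if ep.kind == "passive" else "active_contact"
            events.append(
                SocialEvent(state, (c - sync_off) / fps, c / fps, partner_id=ids[ep.partner])
            )
    if n_bees > 1:
        dmin = np.min(np.hypot(X[:, 1:] - X[:, :1], Y[:, 1:] - Y[:, :1]), axis=1)
        inside = dmin < 10.0
    else:
        inside = np.zeros(F, dtype=bool)
    spans = _runs(inside)
    events.extend(_alone_tiling(F, spans, fps))
    truth = GroundTruth(
        events=sorted(events, key=lambda e: e.t_sync_s),
        params={
            "baseline_hz": cfg.baseline_hz,
            "beta_dist_hz": cfg.beta_dist_hz,
            "dist_kernel_cm": cfg.dist_kernel_cm,
            "alpha_hz": cfg.alpha_hz,
            "lead_s": cfg.lead_s,
            "bump_width_s": cfg.bump_width_s,
            "sigma_state": dict(cfg.sigma_state),
        },
        non_clear_spans=spans,
    )
    return table, truth


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Inclusive (start, stop) frame spans of True runs."""
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        return []
    edges = np.diff(m.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    stops = list(np.flatnonzero(edges == -1))
    if m[0]:
        starts.insert(0, 0)
    if m[-1]:
        stops.append(len(m) - 1)
    return list(zip(starts, stops))


def _alone_tiling(n_frames: int, non_clear: list[tuple[int, int]], fps: float) -> list[SocialEvent]:
    """Greedy 4 s tiling of the intervals where no bee is inside 10 cm."""
    clear = np.ones(n_frames, dtype=bool)
    for a, b in non_clear:
        clear[a : b + 1] = False
    win = int(round(4.0 * fps))
    sync = int(round(2.0 * fps))
    events = []
    for a, b in _runs(clear):
        for k in range((b - a + 1) // win):
            s = a + k * win
            events.append(SocialEvent("alone", s / fps, (s + sync) / fps))
    return events


# ---------------------------------------------------------------------------
# firing-rate model


def bump_kernel(u_s: np.ndarray, lead_s: float, width_s: float) -> np.ndarray:
    """Raised-cosine (Hann) bump centered ``lead_s`` before the event.

    ``u_s`` is time relative to the event (negative = before).  The bump has
    unit peak at u = -lead_s, full width ``width_s``, and is truncated at
    u = 0 (nothing after the event).
    """
    x = np.asarray(u_s, dtype=float) + lead_s
    g = np.where(np.abs(x) <= width_s / 2, np.cos(np.pi * x / width_s) ** 2, 0.0)
    return np.where(np.asarray(u_s) <= 0.0, g, 0.0)


def _block_multiplier(
    n_bins: int,
    bin_w: float,
    events: list[SocialEvent],
    sigma_state: dict,
    sigma_background: float,
    block_s: float,
    window_s: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Log-normal rate multiplier, redrawn per sub-block.

    Background blocks tile the whole recording at ``sigma_background``;
    blocks inside a planted event window are overridden with the state's
    sigma (aligned to the window start).  Multipliers are exp(sigma * Z),
    i.e. median 1.
    """
    bpb = int(round(block_s / bin_w))  # bins per block
    n_blocks = int(np.ceil(n_bins / bpb))
    m = np.repeat(np.exp(sigma_background * rng.standard_normal(n_blocks)), bpb)[:n_bins]
    wpb = int(round(window_s / block_s))  # blocks per window
    for ev in events:
        sig = sigma_state.get(ev.state)
        if sig is None:
            continue
        i0 = int(np.floor(ev.t_start_s / bin_w + 1e-9))
        if i0 < 0 or i0 >= n_bins:
            continue
        draws = np.repeat(np.exp(sig * rng.standard_normal(wpb)), bpb)
        i1 = min(i0 + len(draws), n_bins)
        m[i0:i1] = draws[: i1 - i0]
    return m


def compute_rate(tracks: TrackTable, truth: GroundTruth, cfg: SimConfig) -> TrueRate:
    """The planted rate lambda(t) on the 100 ms grid (clipped at 0).

    Deterministic given the config seed: the multiplier stream is drawn from
    a seed derived from ``cfg.seed`` independently of the trajectory stream,
    so changing a rate parameter never changes the trajectories.
    """
    from .behavior import nearest_bee

    bin_w = 1.0 / cfg.frame_rate_hz
    d = nearest_bee(tracks)["distance_cm"].to_numpy(dtype=float)
    n_bins = len(d)
    kernel = np.where(
        np.isfinite(d), np.exp(-np.nan_to_num(d, nan=np.inf) / cfg.dist_kernel_cm), 0.0
    )
    lam = cfg.baseline_hz + cfg.beta_dist_hz * kernel
    t_centers = (np.arange(n_bins) + 0.5) * bin_w
    for ev in truth.by_state("active_contact"):
        lam = lam + cfg.alpha_hz * bump_kernel(
            t_centers - ev.t_sync_s, cfg.lead_s, cfg.bump_width_s
        )
    rng = np.random.default_rng([cfg.seed, 7919])
    sigma_bg = (
        cfg.sigma_background
        if cfg.sigma_background is not None
        else cfg.sigma_state.get("random", 0.0)
    )
    m = _block_multiplier(
        n_bins, bin_w, truth.events, cfg.sigma_state, sigma_bg, cfg.block_s, 4.0, rng
    )
    lam = np.clip(lam * m, 0.0, None)
    rate = TrueRate(edges=np.arange(n_bins) * bin_w, lam_hz=lam, bin_w=bin_w)
    truth.rate = rate
    return rate


def simulate_spikes(true_rate: TrueRate, seed) -> SpikeTrain:
    """Inhomogeneous-Poisson spike times by thinning against lambda_max."""
    lam = np.asarray(true_rate.lam_hz, dtype=float)
    if len(lam) == 0 or lam.max() <= 0:
        return SpikeTrain(np.empty(0))
    rng = np.random.default_rng(seed)
    t0 = float(true_rate.edges[0])
    T = len(lam) * true_rate.bin_w
    lam_max = float(lam.max())
    n_cand = rng.poisson(lam_max * T)
    cand = np.sort(rng.uniform(0.0, T, size=n_cand))
    idx = np.minimum((cand / true_rate.bin_w).astype(int), len(lam) - 1)
    keep = rng.uniform(0.0, lam_max, size=n_cand) < lam[idx]
    return SpikeTrain(t0 + cand[keep])


# ---------------------------------------------------------------------------
# controlled-rate builders for recovery experiments


def planted_bump_rate(
    event_syncs_s,
    duration_s: float,
    baseline_hz: float,
    alpha_hz: float,
    lead_s: float,
    width_s: float = 0.8,
    bin_w: float = 0.1,
) -> TrueRate:
    """Constant-baseline rate with a pre-event bump at each planted event."""
    n_bins = int(round(duration_s / bin_w))
    t = (np.arange(n_bins) + 0.5) * bin_w
    lam = np.full(n_bins, float(baseline_hz))
    for ts in np.atleast_1d(np.asarray(event_syncs_s, dtype=float)):
        lam += alpha_hz * bump_kernel(t - ts, lead_s, width_s)
    return TrueRate(np.arange(n_bins) * bin_w, lam, bin_w)


def planted_state_windows(
    n_windows: dict[str, int],
    sigma_state: dict[str, float],
    baseline_hz: float,
    rng: np.random.Generator,
    gap_s: float = 1.0,
    window_s: float = 4.0,
    block_s: float = 1.0,
    bin_w: float = 0.1,
) -> tuple[TrueRate, dict[str, np.ndarray]]:
    """Back-to-back state windows with per-state multiplier sigmas.

    Windows of all states are shuffled along the timeline (separated by
    ``gap_s`` of plain baseline) so state is not confounded with time.
    Returns the rate and, per state, the window start times.
    """
    states = [s for s, n in n_windows.items() for _ in range(n)]
    order = rng.permutation(len(states))
    slot = window_s + gap_s
    duration = len(states) * slot + gap_s
    n_bins = int(round(duration / bin_w))
    lam = np.full(n_bins, float(baseline_hz))
    starts: dict[str, list[float]] = {s: [] for s in n_windows}
    wpb = int(round(window_s / block_s))
    bpb = int(round(block_s / bin_w))
    for k, oi in enumerate(order):
        state = states[oi]
        t_start = gap_s + k * slot
        starts[state].append(t_start)
        i0 = int(round(t_start / bin_w))
        m = np.repeat(np.exp(sigma_state[state] * rng.standard_normal(wpb)), bpb)
        lam[i0 : i0 + len(m)] *= m
    return (
        TrueRate(np.arange(n_bins) * bin_w, lam, bin_w),
        {s: np.array(v) for s, v in starts.items()},
    )


# ---------------------------------------------------------------------------
# fixture files


def make_fixture(cfg: SimConfig, out_dir) -> dict[str, Path]:
    """Write tracks CSV, spike text file and ground-truth JSON to a directory.

    The files round-trip losslessly through the readers and are
    byte-identical across runs with the same (config, seed).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tracks, truth = simulate_colony(cfg)
    rate = compute_rate(tracks, truth, cfg)
    spikes = simulate_spikes(rate, [cfg.seed, 104729])
    paths = {
        "tracks": out / "tracks.csv",
        "spikes": out / "spikes.txt",
        "truth": out / "truth.json",
    }
    try:
        write_tracks(tracks, paths["tracks"])
        write_spikes(spikes, paths["spikes"])
        payload = {
            "events": events_to_frame(truth.events).to_dict(orient="records"),
            "params": truth.params,
            "non_clear_spans": [list(map(int, s)) for s in truth.non_clear_spans],
            "config": asdict(cfg),
        }
        paths["truth"].write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
    except OSError as exc:
        raise OSError(f"failed writing fixture under {out}: {exc}") from exc
    return paths
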