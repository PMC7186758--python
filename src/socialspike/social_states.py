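"""Detection of 4 s social-state windows from the behavioral series.

Five states are labeled, each a 4 s window with a synchronization point at
its 2 s mark:

* ``alone`` — no other bee closer than 10 cm for the whole window,
  regardless of walking.
* ``random`` — software-selected control windows, count-matched to the
  passive contacts.
* ``walking_onset`` — the focal bee moved less than 1 mm for 2 s, then moved
  continuously for at least 2 s; sync at the onset.
* ``passive_contact`` — focal alone at the window start (no bee within
  10 cm), exactly one bee closer than 1 cm at the 2 s mark, and the focal
  bee either did not move for the whole window or moved for the whole
  window.
* ``active_contact`` — same geometry, but the focal bee was standing still
  initially and started walking between the 1 s and 2 s marks.

The distance/displacement thresholds (10 cm, 1 cm, 1 mm over 2 s) are fixed
by the state definitions; "moving continuously" additionally needs a
frame-level speed threshold the definitions leave open — default 0.5 cm/s
sustained in at least 90% of the span's frames (tracker-jitter tolerance).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STATE_NAMES = ("alone", "random", "walking_onset", "passive_contact", "active_contact")


@dataclass
class StateConfig:
    """Thresholds and windows of the social-state definitions."""

    window_s: float = 4.0
    sync_mark_s: float = 2.0
    alone_radius_cm: float = 10.0
    contact_radius_cm: float = 1.0
    still_displacement_mm: float = 1.0
    still_span_s: float = 2.0
    active_onset_min_s: float = 1.0  # earliest onset mark within the window
    active_onset_max_s: float = 2.0  # latest onset mark (= contact moment)
    moving_speed_threshold_cm_s: float = 0.5
    moving_fraction: float = 0.9
    random_overlap_allowed: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.sync_mark_s < self.window_s:
            raise ValueError("need 0 < sync_mark_s < window_s")
        if not self.contact_radius_cm < self.alone_radius_cm:
            raise ValueError("contact radius must be smaller than alone radius")

    def frames(self, frame_rate_hz: float) -> dict[str, int]:
        f = frame_rate_hz
        return {
            "window": int(round(self.window_s * f)),
            "sync": int(round(self.sync_mark_s * f)),
            "still": int(round(self.still_span_s * f)),
            "onset_min": int(round(self.active_onset_min_s * f)),
            "onset_max": int(round(self.active_onset_max_s * f)),
        }


@dataclass
class SocialEvent:
    """A labeled 4 s window; ``t_sync`` is the 2 s mark."""

    state: str
    t_start_s: float
    t_sync_s: float
    partner_id: str | None = None

    def __post_init__(self) -> None:
        if self.state not in STATE_NAMES:
            raise ValueError(f"unknown state {self.state!r}")


def events_to_frame(events: list[SocialEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "state": e.state,
                "t_start_s": e.t_start_s,
                "t_sync_s": e.t_sync_s,
                "partner_id": e.partner_id if e.partner_id is not None else "",
            }
            for e in events
        ],
        columns=["state", "t_start_s", "t_sync_s", "partner_id"],
    )


def movement_flags(
    speed_cm_s: np.ndarray, frame_rate_hz: float, cfg: StateConfig
) -> pd.DataFrame:
    """Per-frame movement predicates.

    ``moving``: speed at or above the frame-level threshold.
    ``still_end``: the 2 s span ending *just before* this frame covered less
    than 1 mm of path, i.e. the bee was "not moving" right up to this frame.
    The frame's own displacement is excluded so that a movement onset at
    frame t can satisfy still_end[t] and moving[t] simultaneously.
    """
    speed = np.asarray(speed_cm_s, dtype=float)
    nf = cfg.frames(frame_rate_hz)
    disp = speed / frame_rate_hz  # cm moved into each frame
    moving = speed >= cfg.moving_speed_threshold_cm_s
    k = nf["still"]
    n = len(speed)
    csum = np.concatenate([[0.0], np.cumsum(disp)])
    path = np.full(n, np.inf)
    t = np.arange(k, n)
    path[k:] = csum[t] - csum[t - k]  # steps t-k .. t-1
    still_end = path < cfg.still_displacement_mm / 10.0  # mm -> cm
    return pd.DataFrame({"moving": moving, "still_end": still_end, "path_cm": path})


def _moving_fraction(moving: np.ndarray, a: int, b: int) -> float:
    seg = moving[a:b]
    return float(seg.mean()) if len(seg) else 0.0


def detect_alone(
    distance_cm: np.ndarray, frame_rate_hz: float, cfg: StateConfig
) -> list[SocialEvent]:
    """Tile maximal no-bee-within-10-cm runs into non-overlapping 4 s windows.

    A frame counts as "clear" when the nearest-bee distance is strictly
    greater than the alone radius or undefined (no other bee tracked).
    Windows are tiled greedily from each run's start.
    """
    d = np.asarray(distance_cm, dtype=float)
    clear = np.isnan(d) | (d > cfg.alone_radius_cm)
    nf = cfg.frames(frame_rate_hz)
    events: list[SocialEvent] = []
    n = len(clear)
    i = 0
    while i < n:
        if not clear[i]:
            i += 1
            continue
        j = i
        while j < n and clear[j]:
            j += 1
        run = j - i
        for k in range(run // nf["window"]):
            start = i + k * nf["window"]
            events.append(
                SocialEvent(
                    "alone",
                    start / frame_rate_hz,
                    (start + nf["sync"]) / frame_rate_hz,
                )
            )
        i = j
    return events


def detect_walking_onset(
    flags: pd.DataFrame, n_frames: int, frame_rate_hz: float, cfg: StateConfig
) -> list[SocialEvent]:
    """Onsets: 2 s of <1 mm displacement, then >=2 s of continuous movement.

    Sync is the onset frame.  Overlapping candidates are resolved by keeping
    the earliest and skipping one full window.
    """
    moving = flags["moving"].to_numpy()
    still_end = flags["still_end"].to_numpy()
    nf = cfg.frames(frame_rate_hz)
    events: list[SocialEvent] = []
    t = nf["sync"]  # first frame whose window fits the recording
    last_kept = -(10**9)
    while t + (nf["window"] - nf["sync"]) <= n_frames:
        ok = (
            t - last_kept >= nf["window"]
            and still_end[t]
            and moving[t]
            and t + nf["still"] <= n_frames
            and _moving_fraction(moving, t, t + nf["still"]) >= cfg.moving_fraction
        )
        if ok:
            events.append(
                SocialEvent(
                    "walking_onset",
                    (t - nf["sync"]) / frame_rate_hz,
                    t / frame_rate_hz,
                )
            )
            last_kept = t
            t += nf["window"]
        else:
            t += 1
    return events


def detect_contacts(
    distance_cm: np.ndarray,
    partner_id: np.ndarray,
    n_within_contact: np.ndarray,
    flags: pd.DataFrame,
    frame_rate_hz: float,
    cfg: StateConfig,
) -> tuple[list[SocialEvent], list[SocialEvent], int]:
    """Passive and active contact events.

    A contact frame is the first frame with a bee inside the contact radius;
    the window start (2 s earlier) must be clear of bees within the alone
    radius, and exactly one bee must be inside the contact radius at the
    contact moment.  Classification by the focal bee's movement:

    * active — a movement onset (2 s still then sustained walking up to the
      contact) falls between the 1 s and 2 s marks of the window;
    * passive — the focal bee did not move at any frame of the window, or
      moved in at least ``moving_fraction`` of them.

    Returns (passive, active, n_unclassified); windows that exceed the
    recording are dropped silently, geometric contacts matching neither
    movement pattern are counted in ``n_unclassified``.
    """
    d = np.asarray(distance_cm, dtype=float)
    moving = flags["moving"].to_numpy()
    still_end = flags["still_end"].to_numpy()
    nf = cfg.frames(frame_rate_hz)
    n = len(d)
    inside = np.nan_to_num(d, nan=np.inf) < cfg.contact_radius_cm
    crossings = np.flatnonzero(inside & ~np.concatenate([[False], inside[:-1]]))
    passive: list[SocialEvent] = []
    active: list[SocialEvent] = []
    unclassified = 0
    for t in crossings:
        ws = t - nf["sync"]
        we = ws + nf["window"]
        if ws < 0 or we > n:
            continue
        d_start = d[ws]
        if not (np.isnan(d_start) or d_start > cfg.alone_radius_cm):
            continue  # not alone at the window start
        if int(n_within_contact[t]) != 1:
            continue  # "only one bee" rule
        event = None
        # active: onset between the 1 s and 2 s marks, still before it,
        # sustained walking from the onset through the contact moment
        for o in range(ws + nf["onset_min"], ws + nf["onset_max"] + 1):
            if o >= n or not still_end[o]:
                continue
            span_end = min(max(t + 1, o + 1), n)
            if moving[o] and _moving_fraction(moving, o, span_end) >= cfg.moving_fraction:
                event = "active"
                break
        if event is None:
            frac = _moving_fraction(moving, ws, we)
            never = not moving[ws:we].any()
            if never or frac >= cfg.moving_fraction:
                event = "passive"
        if event is None:
            unclassified += 1
            continue
        ev = SocialEvent(
            "active_contact" if event == "active" else "passive_contact",
            ws / frame_rate_hz,
            t / frame_rate_hz,
            partner_id=str(partner_id[t]) if partner_id is not None else None,
        )
        (active if event == "active" else passive).append(ev)
    return passive, active, unclassified


def sample_random_windows(
    n_frames: int, n: int, frame_rate_hz: float, cfg: StateConfig, seed
) -> list[SocialEvent]:
    """``n`` uniformly placed 4 s control windows, snapped to the frame grid.

    Overlap with real-state windows is permitted (documented decision);
    windows may also overlap each other.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    nf = cfg.frames(frame_rate_hz)
    if n_frames < nf["window"]:
        raise ValueError("recording shorter than one state window")
    rng = np.random.default_rng(seed)
    starts = rng.integers(0, n_frames - nf["window"] + 1, size=n)
    return [
        SocialEvent("random", s / frame_rate_hz, (s + nf["sync"]) / frame_rate_hz)
        for s in sorted(starts.tolist())
    ]


@dataclass
class EventCatalog:
    """All detected state windows plus bookkeeping counts."""

    events: list[SocialEvent]
    n_unclassified_contacts: int = 0
    cross_state_overlaps: int = 0

    def by_state(self, state: str) -> list[SocialEvent]:
        return [e for e in self.events if e.state == state]

    def to_frame(self) -> pd.DataFrame:
        return events_to_frame(self.events)


def classify_all(
    behavior: pd.DataFrame, frame_rate_hz: float, cfg: StateConfig, seed
) -> EventCatalog:
    """Run all detectors and add count-matched random windows.

    ``behavior`` is the per-frame table from
    :func:`socialspike.behavior.behavior_table`.  The number of random
    windows equals the number of passive contacts found.
    """
    speed = behavior["speed_cm_s"].to_numpy(dtype=float)
    dist = behavior["distance_cm"].to_numpy(dtype=float)
    partner = behavior["partner_id"].to_numpy(dtype=object)
    n = len(behavior)
    flags = movement_flags(speed, frame_rate_hz, cfg)
    # per-frame count of bees inside the contact radius: with only the
    # nearest distance available this is 1 when the nearest bee is inside;
    # callers with full multi-bee info may pass a finer count via
    # detect_contacts directly
    n_within = behavior["n_within_contact"].to_numpy() if "n_within_contact" in behavior else (
        np.nan_to_num(dist, nan=np.inf) < cfg.contact_radius_cm
    ).astype(int)

    alone = detect_alone(dist, frame_rate_hz, cfg)
    onsets = detect_walking_onset(flags, n, frame_rate_hz, cfg)
    passive, active, n_uncls = detect_contacts(
        dist, partner, n_within, flags, frame_rate_hz, cfg
    )
    randoms = sample_random_windows(n, len(passive), frame_rate_hz, cfg, seed)
    events = alone + onsets + passive + active + randoms

    overlaps = 0
    real = [e for e in events if e.state != "random"]
    for a, b in itertools.combinations(real, 2):
        if a.state != b.state and abs(a.t_start_s - b.t_start_s) < cfg.window_s:
            overlaps += 1
    return EventCatalog(events, n_unclassified_contacts=n_uncls, cross_state_overlaps=overlaps)


def count_within_contact(table, focal_id: str, cfg: StateConfig) -> np.ndarray:
    """Number of other bees within the contact radius, per focal frame.

    Used to enforce the "only one bee" rule exactly when more than one other
    bee can be close simultaneously.
    """
    focal = table.bee(focal_id)
    others = table.data[table.data["bee_id"] != focal_id]
    counts = np.zeros(len(focal), dtype=int)
    if len(others) == 0:
        return counts
    ids = sorted(others["bee_id"].unique())
    px = others.pivot(index="frame", columns="bee_id", values="x_cm").reindex(
        index=focal.index, columns=ids
    )
    py = others.pivot(index="frame", columns="bee_id", values="y_cm").reindex(
        index=focal.index, columns=ids
    )
    dx = px.to_numpy() - focal["x_cm"].to_numpy()[:, None]
    dy = py.to_numpy() - focal["y_cm"].to_numpy()[:, None]
    dist = np.hypot(dx, dy)
    return np.nansum(dist < cfg.contact_radius_cm, axis=1).astype(int)
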