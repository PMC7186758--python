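"""Behavioral covariates derived from the tracking table.

All series live on the 100 ms frame clock and are indexed by frame number.
Conventions (stated once, used everywhere):

* Walking speed at frame i is the centroid displacement from frame i-1 times
  the frame rate; the first tracked frame has speed 0.  No smoothing.
* Distances are centroid-to-centroid.  The 1 cm contact threshold is
  sensitive to this choice (the tracker reports no other body reference
  point), so it is worth restating: "within 1 cm" means centroids within
  1 cm.
* The arena is tilted; up-slope is the +y axis.  The gravity-relative body
  angle is measured from up-slope, so a bee pointing straight down-slope is
  at 180 deg.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .io import FOCAL_ID, TrackTable
from .stats import TestResult, rank_sum_test


def walking_speed(track: pd.DataFrame, frame_rate_hz: float = 10.0) -> pd.Series:
    """Per-frame walking speed (cm/s) of one bee.

    ``track`` is a single bee's rows indexed by frame (see
    :meth:`TrackTable.bee`).  Across tracker gaps the speed is the average
    speed over the gap.
    """
    if len(track) < 2:
        warnings.warn("walking_speed: fewer than 2 frames, returning empty", stacklevel=2)
        return pd.Series(dtype=float, name="speed_cm_s")
    frames = track.index.to_numpy()
    xy = track[["x_cm", "y_cm"]].to_numpy(dtype=float)
    step = np.hypot(*np.diff(xy, axis=0).T)
    dt = np.diff(frames) / frame_rate_hz
    speed = np.concatenate([[0.0], step / dt])
    return pd.Series(speed, index=frames, name="speed_cm_s")


def nearest_bee(table: TrackTable, focal_id: str = FOCAL_ID) -> pd.DataFrame:
    """Distance (cm) and identity of the closest other bee, per focal frame.

    Frames where no other bee is tracked get NaN distance and a missing id.
    Exact ties are broken toward the lexicographically smallest bee id.
    """
    focal = table.bee(focal_id)
    others = table.data[table.data["bee_id"] != focal_id]
    out = pd.DataFrame(
        {"distance_cm": np.nan, "partner_id": pd.Series(pd.NA, index=focal.index, dtype="string")},
        index=focal.index,
    )
    if len(others) == 0:
        return out
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
    any_def = ~np.all(np.isnan(dist), axis=1)
    # nanargmin returns the first minimum; columns are id-sorted, so exact
    # ties resolve to the lowest id
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        idx = np.where(any_def, np.nanargmin(np.where(np.isnan(dist), np.inf, dist), axis=1), 0)
    out.loc[any_def, "distance_cm"] = dist[np.arange(len(dist)), idx][any_def]
    out.loc[any_def, "partner_id"] = np.array(ids, dtype=object)[idx][any_def]
    return out


def orientation_to_gravity(theta_deg: pd.Series) -> pd.Series:
    """Body-axis angle relative to the slope, 0 = up-slope, 180 = down-slope.

    ``theta_deg`` is the tracked long-body-axis angle in arena coordinates
    (counterclockwise from +x); up-slope is +y, i.e. 90 deg in arena
    coordinates.
    """
    return ((theta_deg - 90.0) % 360.0).rename("gravity_angle_deg")


def relative_body_angle(theta_focal: pd.Series, theta_nearest: pd.Series) -> pd.Series:
    """Angle between the nearest bee's long axis and the focal bee's, mod 360."""
    return ((theta_nearest - theta_focal) % 360.0).rename("relative_angle_deg")


def approach_bearing(focal: pd.DataFrame, nearest_xy: pd.DataFrame) -> pd.Series:
    """Bearing of the nearest bee as seen from the focal body axis.

    0 deg means the other bee lies straight ahead along the focal long axis.
    This is the alternative reading of the "angle of the approaching bee";
    the body-axis difference (:func:`relative_body_angle`) is the default.
    """
    dx = nearest_xy["x_cm"] - focal["x_cm"]
    dy = nearest_xy["y_cm"] - focal["y_cm"]
    bearing = np.rad2deg(np.arctan2(dy, dx)) % 360.0
    return ((bearing - focal["theta_deg"]) % 360.0).rename("approach_bearing_deg")


def angular_rate_profile(
    angles_deg: np.ndarray, rates_hz: np.ndarray, bin_deg: float = 10.0
) -> pd.DataFrame:
    """Mean spike rate in angular bins of ``bin_deg`` (default 10 deg).

    Returns one row per bin [k*bin_deg, (k+1)*bin_deg) with the mean of the
    rates whose angle falls in the bin; empty bins are NaN.
    """
    if not np.isclose(360.0 % bin_deg, 0.0):
        raise ValueError(f"bin_deg={bin_deg} must divide 360")
    angles = np.asarray(angles_deg, dtype=float) % 360.0
    rates = np.asarray(rates_hz, dtype=float)
    ok = np.isfinite(angles) & np.isfinite(rates)
    n_bins = int(round(360.0 / bin_deg))
    which = np.floor(angles[ok] / bin_deg).astype(int)
    sums = np.bincount(which, weights=rates[ok], minlength=n_bins)
    counts = np.bincount(which, minlength=n_bins)
    mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame(
        {
            "bin_left_deg": bin_deg * np.arange(n_bins),
            "mean_rate_hz": mean,
            "n_frames": counts,
        }
    )


def quarter_split(obj):
    """Split a series/frame/array into 4 contiguous equal-duration quarters.

    Remainder frames go to the last quarter, so the concatenation of the
    quarters is exactly the original.
    """
    n = len(obj)
    if n < 4:
        raise ValueError("need at least 4 frames to split into quarters")
    q = n // 4
    bounds = [0, q, 2 * q, 3 * q, n]
    if isinstance(obj, np.ndarray):
        return [obj[bounds[i] : bounds[i + 1]] for i in range(4)]
    return [obj.iloc[bounds[i] : bounds[i + 1]] for i in range(4)]


def compare_focal_vs_others_speed(focal_speeds, other_speeds) -> TestResult:
    """Rank-sum test of the focal bee's walking-speed distribution against
    the speeds of the co-tracked comparison bees (the closest other bees)."""
    x = np.asarray(focal_speeds, dtype=float)
    y = np.asarray(other_speeds, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    return rank_sum_test(x, y)


def behavior_table(table: TrackTable, focal_id: str = FOCAL_ID) -> pd.DataFrame:
    """Assemble the per-frame behavioral covariate table for the focal bee.

    Columns: time_s, x_cm, y_cm, theta_deg, speed_cm_s, distance_cm,
    partner_id, gravity_angle_deg, relative_angle_deg, approach_bearing_deg.
    """
    focal = table.bee(focal_id)
    speed = walking_speed(focal, table.frame_rate_hz)
    near = nearest_bee(table, focal_id)
    out = focal[["time_s", "x_cm", "y_cm", "theta_deg"]].copy()
    out["speed_cm_s"] = speed.reindex(out.index).fillna(0.0)
    out["distance_cm"] = near["distance_cm"]
    out["partner_id"] = near["partner_id"]
    out["gravity_angle_deg"] = orientation_to_gravity(focal["theta_deg"])

    theta_near = pd.Series(np.nan, index=out.index)
    near_xy = pd.DataFrame(np.nan, index=out.index, columns=["x_cm", "y_cm"])
    has = near["partner_id"].notna()
    if has.any():
        others = table.data[table.data["bee_id"] != focal_id].set_index(["frame", "bee_id"])
        keys = list(zip(near.index[has], near["partner_id"][has]))
        sel = others.loc[keys]
        theta_near[has] = sel["theta_deg"].to_numpy()
        near_xy.loc[has, ["x_cm", "y_cm"]] = sel[["x_cm", "y_cm"]].to_numpy()
    out["relative_angle_deg"] = relative_body_angle(out["theta_deg"], theta_near)
    out["approach_bearing_deg"] = approach_bearing(out, near_xy)
    return out
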