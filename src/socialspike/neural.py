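"""Event-aligned and covariate-resolved spike-rate analyses.

* Perievent time histogram (PETH): event-aligned average of relative spike
  rates on +/-8 s of lag in 100 ms bins.
* Pre-event peak latency: lag of the smoothed PETH maximum in the 4 s before
  the event — the "phasic lead" of a rate increase anticipating an active
  contact.
* Window variance: population variance of the 40 in-window 100 ms rates,
  the single-parameter proxy for within-window rate restructuring.
* Distance analyses: spike-rate deciles vs. nearest-bee distance, and
  near/far (5 cm) rate distributions per data quarter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import RateSeries
from .stats import TestResult, rank_sum_test


@dataclass
class PETH:
    """Perievent time histogram of relative spike rates."""

    lags_s: np.ndarray  # bin centers, symmetric about 0
    mean_relative_rate: np.ndarray
    n_events: int
    per_event: np.ndarray  # (n_events, n_lags) relative-rate matrix
    n_dropped_context: int = 0  # events without a full +/-half_span context
    n_dropped_zero_rate: int = 0  # events with zero spikes in the span


def peth(
    rate: RateSeries,
    event_syncs_s,
    half_span_s: float = 8.0,
    state: str = "events",
    normalize: str = "per_event",
) -> PETH:
    """Average event-aligned relative spike rate over +/-``half_span_s``.

    Each event's lag vector is normalized by that event's own mean rate over
    the span (``normalize="per_event"``, the default) or by the grand mean
    across events (``"grand"``).  Events whose span does not fit in the
    recording, or with zero spikes in the span (per-event mode), are dropped
    and counted.
    """
    k = int(round(half_span_s / rate.bin_w))
    rates = rate.rates
    rows = []
    n_ctx = n_zero = 0
    for t in np.atleast_1d(np.asarray(event_syncs_s, dtype=float)):
        i = int(np.floor((t - rate.edges[0]) / rate.bin_w + 1e-9))
        if i - k < 0 or i + k > len(rates):
            n_ctx += 1
            continue
        rows.append(rates[i - k : i + k])
    if normalize not in ("per_event", "grand"):
        raise ValueError(f"unknown normalization {normalize!r}")
    mat = np.array(rows, dtype=float)
    if normalize == "per_event" and len(mat):
        means = mat.mean(axis=1)
        n_zero = int(np.sum(means == 0))
        mat = mat[means > 0] / means[means > 0, None]
    elif len(mat):
        grand = mat.mean()
        if grand == 0:
            n_zero = len(mat)
            mat = mat[:0]
        else:
            mat = mat / grand
    if len(mat) == 0:
        raise ValueError(f"no usable events for PETH of state {state!r}")
    lags = (np.arange(-k, k) + 0.5) * rate.bin_w
    return PETH(
        lags_s=lags,
        mean_relative_rate=mat.mean(axis=0),
        n_events=len(mat),
        per_event=mat,
        n_dropped_context=n_ctx,
        n_dropped_zero_rate=n_zero,
    )


def peak_pre_event_latency(
    p: PETH,
    search_s: tuple[float, float] = (-4.0, 0.0),
    smooth_s: float = 0.3,
    flat_tol: float = 0.05,
) -> float | None:
    """Latency (positive seconds before the event) of the pre-event peak.

    The mean relative rate is boxcar-smoothed over ``smooth_s`` and the
    maximum is taken within ``search_s``.  A flat PETH — maximum within
    ``flat_tol`` (relative) of the overall mean — yields ``None``
    ("no phasic peak").
    """
    bin_w = float(p.lags_s[1] - p.lags_s[0])
    w = max(1, int(round(smooth_s / bin_w)))
    kernel = np.ones(w) / w
    smoothed = np.convolve(p.mean_relative_rate, kernel, mode="same")
    sel = (p.lags_s >= search_s[0]) & (p.lags_s <= search_s[1])
    if not sel.any():
        raise ValueError("empty search interval")
    seg = smoothed[sel]
    lags = p.lags_s[sel]
    peak = float(seg.max())
    if peak <= smoothed.mean() * (1 + flat_tol):
        return None
    return float(-lags[int(np.argmax(seg))])


def window_variance(
    rate: RateSeries, t_start_s: float, window_s: float = 4.0
) -> float:
    """Population variance (Hz^2) of the in-window 100 ms rates.

    The "average of the squared differences from the mean" — variance with
    the population denominator n (= 40 bins for a 4 s window).
    """
    n_bins = int(round(window_s / rate.bin_w))
    i = int(np.floor((t_start_s - rate.edges[0]) / rate.bin_w + 1e-9))
    if i < 0 or i + n_bins > len(rate):
        raise ValueError(
            f"window [{t_start_s}, {t_start_s + window_s}) s not fully inside the recording"
        )
    return float(np.var(rate.rates[i : i + n_bins]))


def window_variances(rate: RateSeries, t_starts_s, window_s: float = 4.0) -> np.ndarray:
    return np.array([window_variance(rate, t, window_s) for t in np.atleast_1d(t_starts_s)])


@dataclass
class DecileResult:
    """Frame-wise rates split into 10 equal-count rate groups."""

    summary: pd.DataFrame  # per group: rate range, distance quartiles
    group_of_frame: np.ndarray
    test_top_vs_bottom: TestResult


def decile_distance_analysis(
    rates_hz, distances_cm, tie_break: str = "permute", seed: int = 0
) -> DecileResult:
    """Distance distributions across 10 equal-sized spike-rate groups.

    Frames (with a defined nearest-bee distance) are sorted by rate and
    split into 10 equal-count groups; the remainder is spread over the last
    groups.  Group 1 holds the lowest rates, group 10 the highest.  The
    rank-sum test contrasts the distance distributions of group 10 against
    group 1.

    100 ms spike counts are small integers, so rate ties are massive and the
    tie-break decides which tied frames land in which group.  The default
    breaks ties by a seeded random permutation: membership among tied frames
    is then independent of time, which keeps the top-vs-bottom test valid
    when the distance series is autocorrelated (breaking ties by frame index
    — available as ``tie_break="index"`` — silently turns the test into an
    early-vs-late comparison and inflates its false-positive rate).
    """
    rates = np.asarray(rates_hz, dtype=float)
    dist = np.asarray(distances_cm, dtype=float)
    ok = np.isfinite(rates) & np.isfinite(dist)
    rates, dist = rates[ok], dist[ok]
    n = len(rates)
    if n < 10:
        raise ValueError(f"need at least 10 frames with defined distance, got {n}")
    if tie_break == "permute":
        key = np.random.default_rng(seed).permutation(n)
    elif tie_break == "index":
        key = np.arange(n)
    else:
        raise ValueError(f"unknown tie_break {tie_break!r}")
    order = np.lexsort((key, rates))
    base, rem = divmod(n, 10)
    sizes = [base] * (10 - rem) + [base + 1] * rem
    group = np.empty(n, dtype=int)
    start = 0
    for g, size in enumerate(sizes, start=1):
        group[order[start : start + size]] = g
        start += size
    rows = []
    for g in range(1, 11):
        dg = dist[group == g]
        rg = rates[group == g]
        q1, med, q3 = np.percentile(dg, [25, 50, 75])
        rows.append(
            {
                "group": g,
                "n": len(dg),
                "rate_min_hz": rg.min(),
                "rate_max_hz": rg.max(),
                "dist_q1_cm": q1,
                "dist_median_cm": med,
                "dist_q3_cm": q3,
            }
        )
    test = rank_sum_test(dist[group == 10], dist[group == 1])
    return DecileResult(pd.DataFrame(rows), group, test)


def distance_split_profiles(
    rates_hz, distances_cm, cut_cm: float = 5.0
) -> pd.DataFrame:
    """Near/far (<= cut vs. > cut) rate distributions per data quarter.

    A distance exactly at the cut goes to the near stratum.  Empty strata
    are flagged (``empty=True``) rather than fatal.  Returns one row per
    (quarter, stratum) with rate summary statistics.
    """
    from .behavior import quarter_split

    rates = np.asarray(rates_hz, dtype=float)
    dist = np.asarray(distances_cm, dtype=float)
    if len(rates) != len(dist):
        raise ValueError("rates and distances must be aligned")
    rows = []
    for q, (rq, dq) in enumerate(zip(quarter_split(rates), quarter_split(dist)), start=1):
        ok = np.isfinite(rq) & np.isfinite(dq)
        for name, mask in (("near", dq <= cut_cm), ("far", dq > cut_cm)):
            sel = rq[ok & mask]
            rows.append(
                {
                    "quarter": q,
                    "stratum": name,
                    "n": len(sel),
                    "empty": len(sel) == 0,
                    "rate_mean_hz": sel.mean() if len(sel) else np.nan,
                    "rate_median_hz": np.median(sel) if len(sel) else np.nan,
                }
            )
    return pd.DataFrame(rows)
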