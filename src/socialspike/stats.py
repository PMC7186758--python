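"""Statistical tests for the social-state analyses.

The two workhorse tests are implemented here rather than imported so that
they can be verified against closed forms and brute-force enumeration:

* Wilcoxon rank-sum — exact null enumeration (dynamic programming over rank
  subsets) for small untied samples, tie-corrected normal approximation with
  continuity correction otherwise.
* Rayleigh test of circular uniformity, generalized to nonnegative weights
  (each frame's body-axis angle weighted by its spike count).

Multiple comparisons across social-state pairs use Bonferroni correction
with a 6-pair family (the four non-alone states), matching the alpha/6
star thresholds used throughout the variance analysis.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: social states forming the Bonferroni-corrected comparison family
VARIANCE_FAMILY = ("random", "walking_onset", "passive_contact", "active_contact")


@dataclass
class TestResult:
    name: str
    statistic: float
    p: float
    n_x: int
    n_y: int
    sided: str = "two-sided"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p-value {self.p} outside [0, 1]")


TestResult.__test__ = False  # not a pytest class despite the name


def _ranksum_exact_cdf(n_x: int, n_y: int) -> np.ndarray:
    """PMF of the rank-sum W of the x-sample under H0 (no ties).

    ``pmf[w]`` is the number of size-``n_x`` subsets of ranks 1..N with sum
    ``w``, for w = 0..n_x*N; divide by C(N, n_x) for probabilities.
    """
    N = n_x + n_y
    max_w = n_x * N
    # counts[k][w]: subsets of size k with rank-sum w, ranks added one at a time
    counts = np.zeros((n_x + 1, max_w + 1), dtype=float)
    counts[0, 0] = 1.0
    for r in range(1, N + 1):
        for k in range(min(r, n_x), 0, -1):
            counts[k, r:] += counts[k - 1, : max_w + 1 - r]
    return counts[n_x] / math.comb(N, n_x)


def rank_sum_test(x, y, exact_max_n: int = 20) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses exact enumeration of the rank-sum null distribution when
    ``n_x + n_y <= exact_max_n`` and there are no ties; otherwise the normal
    approximation with midranks, tie-corrected variance and a 0.5 continuity
    correction.  Degenerate all-equal samples give p = 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank_sum_test requires two nonempty samples")
    n_x, n_y = x.size, y.size
    N = n_x + n_y
    pooled = np.concatenate([x, y])
    # midranks
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(N, dtype=float)
    sorted_vals = pooled[order]
    i = 0
    while i < N:
        j = i
        while j + 1 < N and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    W = float(np.sum(ranks[:n_x]))
    has_ties = len(np.unique(pooled)) < N

    if not has_ties and N <= exact_max_n:
        pmf = _ranksum_exact_cdf(n_x, n_y)
        w = int(round(W))
        p_low = float(pmf[: w + 1].sum())
        p_high = float(pmf[w:].sum())
        p = min(1.0, 2.0 * min(p_low, p_high))
        return TestResult("rank-sum (exact)", W, p, n_x, n_y)

    mu = n_x * (N + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n_x * n_y / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    if var <= 0:  # all observations equal
        return TestResult("rank-sum (normal)", 0.0, 1.0, n_x, n_y)
    d = W - mu
    d_cc = d - 0.5 * np.sign(d)
    z = d_cc / math.sqrt(var)
    p = float(min(1.0, 2.0 * _norm_sf(abs(z))))
    return TestResult("rank-sum (normal)", z, p, n_x, n_y)


def _norm_sf(z: float) -> float:
    return 0.5 * math.erfc(z / math.sqrt(2.0))


def rayleigh_test(angles_deg, weights=None) -> TestResult:
    """Weighted Rayleigh test of circular uniformity.

    With weights w_i (e.g. spike counts per frame) and angles theta_i, the
    mean resultant length is Rbar = |sum w e^{i theta}| / sum w, the effective
    sample size n = sum w, and Z = n * Rbar^2.  The p-value uses the standard
    finite-n correction p = exp(-Z) * [1 + (2Z - Z^2) / (4n)], clipped to
    [0, 1].  Invariant under global rotation of all angles.
    """
    theta = np.deg2rad(np.asarray(angles_deg, dtype=float))
    if weights is None:
        w = np.ones_like(theta)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != theta.shape:
            raise ValueError("weights must match angles in shape")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
    n_eff = float(w.sum())
    if n_eff <= 0:
        raise ValueError("sum of weights must be positive")
    C = float(np.sum(w * np.cos(theta)))
    S = float(np.sum(w * np.sin(theta)))
    rbar = math.hypot(C, S) / n_eff
    Z = n_eff * rbar**2
    p = math.exp(-Z) * (1.0 + (2.0 * Z - Z**2) / (4.0 * n_eff))
    p = float(min(1.0, max(0.0, p)))
    return TestResult("rayleigh", rbar, p, int(round(n_eff)), 0, sided="uniformity")


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-comparison significance threshold alpha/m."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def star_level(p: float, alpha: float = 0.05, m: int = 6) -> str:
    """Star annotation at Bonferroni-corrected thresholds.

    One star at alpha/m, two at (alpha/5)/m, three at (alpha/10)/m — with the
    defaults these are the familiar 0.0083 / 0.0017 / 0.00083 levels.
    """
    if p <= bonferroni_threshold(alpha / 10, m):
        return "***"
    if p <= bonferroni_threshold(alpha / 5, m):
        return "**"
    if p <= bonferroni_threshold(alpha, m):
        return "*"
    return ""


def pairwise_variance_comparisons(
    samples: dict[str, np.ndarray],
    alpha: float = 0.05,
    include_alone: bool = False,
) -> pd.DataFrame:
    """Rank-sum tests between per-state spike-rate-variance samples.

    The corrected family is the 6 pairs among the four non-alone states
    (random, walking onset, passive contact, active contact); pairs involving
    "alone" are reported but not star-annotated unless ``include_alone`` is
    set, in which case the family grows to all 10 pairs and the correction
    becomes alpha/10.  Missing states are skipped (pair omitted).
    """
    family = list(VARIANCE_FAMILY) + (["alone"] if include_alone else [])
    m = len(family) * (len(family) - 1) // 2
    states = [s for s in list(VARIANCE_FAMILY) + ["alone"] if s in samples]
    rows = []
    for a, b in itertools.combinations(states, 2):
        xa = np.asarray(samples[a], dtype=float)
        xb = np.asarray(samples[b], dtype=float)
        if xa.size < 2 or xb.size < 2:
            continue
        res = rank_sum_test(xa, xb)
        in_family = a in family and b in family
        rows.append(
            {
                "state_a": a,
                "state_b": b,
                "n_a": res.n_x,
                "n_b": res.n_y,
                "statistic": res.statistic,
                "p": res.p,
                "in_family": in_family,
                "significant": in_family and res.p <= bonferroni_threshold(alpha, m),
                "stars": star_level(res.p, alpha, m) if in_family else "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "state_a",
            "state_b",
            "n_a",
            "n_b",
            "statistic",
            "p",
            "in_family",
            "significant",
            "stars",
        ],
    )
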