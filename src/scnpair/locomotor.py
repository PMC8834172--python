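"""Locomotor assay analysis: habituation trimming, activity, bursts, statistics.

Tracks are per-animal time-binned distance/peak-velocity series (the export
shape of automated larval tracking chambers). The analysis drops a
habituation period (default first 30 min of a 90-min recording in 10-min
bins), totals per-bin distances for overall activity, counts high-velocity
burst movements above a 50 mm/s cut-off (contiguous supra-threshold runs of
bins counted once), and compares groups with a two-sided Mann-Whitney U test
whose p-value is exact — full permutation distribution of midrank sums, so
ties are handled exactly — whenever the smaller group has at most
``exact_max_n`` animals (default 12, i.e. C(24,12) ~ 2.7M labelings resolved
by a rank-sum counting recursion, not enumeration).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

BURST_CUTOFF_MM_S = 50.0
DEFAULT_ALPHA = 0.01


class TrackError(ValueError):
    """Raised for malformed tracks or cohorts."""


@dataclass(frozen=True)
class LocomotorTrack:
    """One animal's binned movement series.

    ``bins`` is an ordered list of (bin_index, distance_mm, max_velocity_mm_s)
    with contiguous 0-based indices; bin start time is bin_index*bin_minutes.
    """

    animal_id: str
    group: str
    bins: tuple[tuple[int, float, float], ...]
    bin_minutes: float = 10.0

    def __post_init__(self) -> None:
        if not self.bins:
            raise TrackError(f"animal {self.animal_id!r}: empty track")
        idx = [b[0] for b in self.bins]
        if idx != list(range(idx[0], idx[0] + len(idx))):
            raise TrackError(f"animal {self.animal_id!r}: bin indices not contiguous")
        if any(b[1] < 0 for b in self.bins):
            raise TrackError(f"animal {self.animal_id!r}: negative distance")

    @property
    def distances(self) -> np.ndarray:
        return np.array([b[1] for b in self.bins])

    @property
    def max_velocities(self) -> np.ndarray:
        return np.array([b[2] for b in self.bins])


@dataclass(frozen=True)
class GroupComparison:
    """Result of a two-sided Mann-Whitney U comparison."""

    statistic_U: float
    n1: int
    n2: int
    p_two_sided: float
    alpha: float = DEFAULT_ALPHA
    method: str = "exact"

    def __post_init__(self) -> None:
        if not 0 <= self.statistic_U <= self.n1 * self.n2:
            raise TrackError("U outside [0, n1*n2]")

    @property
    def significant(self) -> bool:
        return self.p_two_sided <= self.alpha


def trim_habituation(track: LocomotorTrack, trim_min: float = 30.0) -> LocomotorTrack:
    """Drop bins whose start time falls before ``trim_min`` minutes."""
    kept = tuple(b for b in track.bins if b[0] * track.bin_minutes >= trim_min)
    if not kept:
        raise TrackError(
            f"animal {track.animal_id!r}: habituation trim of {trim_min} min "
            f"removes the whole recording"
        )
    return LocomotorTrack(
        animal_id=track.animal_id,
        group=track.group,
        bins=kept,
        bin_minutes=track.bin_minutes,
    )


def activity_total(track: LocomotorTrack) -> tuple[float, np.ndarray]:
    """Total distance moved (mm) and the per-bin series it sums."""
    series = track.distances
    return float(series.sum()), series


def count_bursts(track: LocomotorTrack, cutoff_mm_s: float = BURST_CUTOFF_MM_S) -> int:
    """Burst movements: runs of bins with max velocity strictly above cut-off.

    Contiguous supra-threshold bins are counted as one burst so a single
    movement spanning a bin boundary is not double-counted.
    """
    v = track.max_velocities
    above = v > cutoff_mm_s
    return int(np.sum(above & ~np.concatenate(([False], above[:-1]))))


def _exact_ranksum_tail(
    doubled_ranks: np.ndarray, n1: int, observed_doubled_sum: int
) -> tuple[float, float]:
    """P(R <= obs) and P(R >= obs) for the rank sum of a random size-n1 subset.

    Midranks are doubled so all values are integers; the distribution of the
    subset rank sum is built by a counting recursion over items (exact under
    ties, equivalent to enumerating all C(N, n1) labelings).
    """
    total = int(doubled_ranks.sum())
    # dp[k, s]: number of size-k subsets with doubled rank sum s
    dp = np.zeros((n1 + 1, total + 1))
    dp[0, 0] = 1.0
    for r in doubled_ranks:
        r = int(r)
        for k in range(n1, 0, -1):  # descending: each item used at most once
            dp[k, r:] += dp[k - 1, : total + 1 - r]
    counts = dp[n1]
    n_total = counts.sum()
    ple = counts[: observed_doubled_sum + 1].sum() / n_total
    pge = counts[observed_doubled_sum:].sum() / n_total
    return float(ple), float(pge)


def mann_whitney_u(
    a: list[float] | np.ndarray,
    b: list[float] | np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    exact_max_n: int = 12,
) -> GroupComparison:
    """Two-sided Mann-Whitney U test with midrank ties.

    U is computed for group ``a`` from rank sums. When min(n1, n2) is at most
    ``exact_max_n`` the two-sided p is exact over the permutation distribution
    of midrank sums (doubling the smaller tail, capped at 1); otherwise a
    normal approximation with tie correction and continuity correction is
    used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise TrackError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    order = pooled.argsort(kind="mergesort")
    ranks = np.empty(len(pooled))
    # midranks: average rank within tied blocks
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0

    if min(n1, n2) <= exact_max_n:
        doubled = np.rint(2.0 * ranks).astype(int)
        obs = int(round(2.0 * r1))
        ple, pge = _exact_ranksum_tail(doubled, n1, obs)
        p = min(1.0, 2.0 * min(ple, pge))
        method = "exact"
    else:
        mu = n1 * n2 / 2.0
        n = n1 + n2
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float(np.sum(tie_counts**3 - tie_counts))
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var == 0:
            p = 1.0
        else:
            z = (abs(u1 - mu) - 0.5) / math.sqrt(var)
            p = min(1.0, 2.0 * norm.sf(max(z, 0.0)))
        method = "normal"
    return GroupComparison(
        statistic_U=u1, n1=n1, n2=n2, p_two_sided=p, alpha=alpha, method=method
    )


def compare_groups(
    cohort_a: list[LocomotorTrack],
    cohort_b: list[LocomotorTrack],
    metric: str = "activity_total",
    trim_min: float = 30.0,
    cutoff_mm_s: float = BURST_CUTOFF_MM_S,
    alpha: float = DEFAULT_ALPHA,
) -> tuple[GroupComparison, pd.DataFrame]:
    """Per-animal metric after habituation trim, then Mann-Whitney U.

    ``metric`` is ``activity_total`` (mm moved) or ``burst_count``.
    """
    if len(cohort_a) < 2 or len(cohort_b) < 2:
        raise TrackError("need at least 2 animals per group")
    if metric not in {"activity_total", "burst_count"}:
        raise TrackError(f"unknown metric {metric!r}")

    rows = []
    values: dict[str, list[float]] = {"a": [], "b": []}
    for key, cohort in (("a", cohort_a), ("b", cohort_b)):
        for track in cohort:
            trimmed = trim_habituation(track, trim_min)
            if metric == "activity_total":
                val = activity_total(trimmed)[0]
            else:
                val = float(count_bursts(trimmed, cutoff_mm_s))
            values[key].append(val)
            rows.append(
                {
                    "animal_id": track.animal_id,
                    "group": track.group,
                    "metric": metric,
                    "value": val,
                }
            )
    comparison = mann_whitney_u(values["a"], values["b"], alpha=alpha)
    return comparison, pd.DataFrame(rows)


def read_cohort_csv(path: str | Path, bin_minutes: float = 10.0) -> list[LocomotorTrack]:
    """Read per-animal tracks from a cohort CSV.

    Columns: animal_id,group,bin_index,distance_mm,max_velocity_mm_s.
    """
    df = pd.read_csv(path)
    required = {"animal_id", "group", "bin_index", "distance_mm", "max_velocity_mm_s"}
    missing = required - set(df.columns)
    if missing:
        raise TrackError(f"cohort CSV missing columns: {sorted(missing)}")
    if df.empty:
        raise TrackError(f"cohort CSV {path} contains no animals")
    tracks = []
    for (animal, group), sub in df.groupby(["animal_id", "group"], sort=True):
        sub = sub.sort_values("bin_index")
        tracks.append(
            LocomotorTrack(
                animal_id=str(animal),
                group=str(group),
                bins=tuple(
                    (int(r.bin_index), float(r.distance_mm), float(r.max_velocity_mm_s))
                    for r in sub.itertuples()
                ),
                bin_minutes=bin_minutes,
            )
        )
    return tracks


def write_cohort_csv(tracks: list[LocomotorTrack], path: str | Path) -> None:
    rows = [
        {
            "animal_id": t.animal_id,
            "group": t.group,
            "bin_index": b[0],
            "distance_mm": b[1],
            "max_velocity_mm_s": b[2],
        }
        for t in tracks
        for b in t.bins
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.3f")
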