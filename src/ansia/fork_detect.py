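"""Detection of invasive forks (leader-cell protrusions) on front profiles.

A fork shows up as a localized peak of the smoothed depth profile. The rule:
at each interface position x, the smoothed profile value is compared with the
mean of the profile over flanking side windows (40 px on either side, raw
profile by default); x qualifies when the smoothed value strictly exceeds
both side means. Contiguous runs of qualifying positions collapse to a single
peak at the run's argmax of the smoothed profile (leftmost on ties).
Consecutive peaks then partition the profile into half-open intervals split
at the floor midpoints between neighbours, and each fork's depth is read off
the raw profile within its interval.

Side windows exclude the focal position: left = [x - w, x), right =
[x + 1, x + 1 + w) for side window w. At the profile edges the windows
truncate; a truncated or invalid-heavy window must retain at least w/2 valid
pixels for x to remain a candidate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._stats import significance_stars, welch_ttest
from .errors import ConfigError, DataError
from .front_quant import FrontProfile

__all__ = [
    "ForkCall",
    "ForkDepthDistribution",
    "DepthComparison",
    "detect_peaks",
    "assign_intervals",
    "fork_depth",
    "call_forks",
    "compare_depth_distributions",
]


@dataclass
class ForkCall:
    """One detected invasive protrusion on a single frame."""

    peak_x: int
    depth: float
    interval: tuple[int, int]  # half-open [start_x, end_x)
    frame_index: int = 0

    def __post_init__(self) -> None:
        start, end = self.interval
        if not start <= self.peak_x < end:
            raise DataError(
                f"peak {self.peak_x} outside its interval [{start}, {end})"
            )


@dataclass
class ForkDepthDistribution:
    """Fork depths pooled for one condition."""

    depths: np.ndarray
    condition: str = ""

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        if (self.depths < 0).any():
            raise DataError("fork depths must be non-negative")

    @property
    def n(self) -> int:
        return self.depths.size

    def quantiles(self, q=(0.25, 0.5, 0.75)) -> np.ndarray:
        if self.n == 0:
            return np.full(len(q), np.nan)
        return np.quantile(self.depths, q)


@dataclass
class DepthComparison:
    """Two-sample comparison of fork-depth distributions.

    Welch t-test is the primary statistic; Mann-Whitney U is reported
    alongside. With fewer than 2 depths in either sample only descriptive
    quantiles are produced (statistics are NaN).
    """

    t_statistic: float
    p_value: float
    mannwhitney_u: float
    mannwhitney_p: float
    stars: str
    quantiles_a: np.ndarray
    quantiles_b: np.ndarray
    n_a: int
    n_b: int


# ---------------------------------------------------------------------------
# peak rule
# ---------------------------------------------------------------------------

def _as_depth(profile) -> np.ndarray:
    if isinstance(profile, FrontProfile):
        return profile.depth
    return np.asarray(profile, dtype=float)


def _side_means(values: np.ndarray, side_window: int):
    """Mean and valid-pixel count over [x-w, x) and [x+1, x+1+w) per position."""
    n = values.size
    valid = np.isfinite(values)
    filled = np.where(valid, values, 0.0)
    csum = np.concatenate([[0.0], np.cumsum(filled)])
    ccnt = np.concatenate([[0.0], np.cumsum(valid.astype(float))])
    idx = np.arange(n)
    ls, le = np.maximum(idx - side_window, 0), idx
    rs, re = np.minimum(idx + 1, n), np.minimum(idx + 1 + side_window, n)
    lcnt = ccnt[le] - ccnt[ls]
    rcnt = ccnt[re] - ccnt[rs]
    with np.errstate(invalid="ignore"):
        lmean = np.where(lcnt > 0, (csum[le] - csum[ls]) / np.maximum(lcnt, 1),
                         np.nan)
        rmean = np.where(rcnt > 0, (csum[re] - csum[rs]) / np.maximum(rcnt, 1),
                         np.nan)
    return lmean, lcnt, rmean, rcnt


def detect_peaks(
    smoothed,
    raw,
    side_window: int = 40,
    compare: str = "raw",
) -> np.ndarray:
    """Positions of fork peaks on a smoothed front profile.

    A position qualifies when the smoothed value strictly exceeds the mean of
    the comparison profile over both flanking side windows (``compare="raw"``
    uses the raw profile in the flanks, the literal reading; ``"smoothed"``
    compares smoothed against smoothed). Qualifying runs collapse to the
    argmax of the smoothed profile, leftmost on ties. Returns sorted integer
    positions; consecutive peaks are always >= 2 px apart.
    """
    s = _as_depth(smoothed)
    r = _as_depth(raw)
    if s.size != r.size:
        raise DataError("smoothed and raw profiles differ in length")
    if side_window < 1:
        raise ConfigError("side_window must be >= 1")
    if s.size < side_window:
        raise ConfigError(
            f"profile of length {s.size} shorter than side window {side_window}"
        )
    if compare == "raw":
        ref = r
    elif compare == "smoothed":
        ref = s
    else:
        raise ConfigError(f"unknown compare mode {compare!r}")

    lmean, lcnt, rmean, rcnt = _side_means(ref, side_window)
    min_valid = side_window / 2
    with np.errstate(invalid="ignore"):
        candidate = (
            np.isfinite(s)
            & (lcnt >= min_valid)
            & (rcnt >= min_valid)
            & (s > lmean)
            & (s > rmean)
        )

    peaks: list[int] = []
    i = 0
    n = s.size
    while i < n:
        if candidate[i]:
            j = i
            while j + 1 < n and candidate[j + 1]:
                j += 1
            run = s[i : j + 1]
            peaks.append(i + int(np.argmax(run)))  # argmax -> leftmost tie
            i = j + 1
        else:
            i += 1
    return np.asarray(peaks, dtype=int)


def assign_intervals(peaks, profile_length: int) -> list[tuple[int, int]]:
    """Partition [0, profile_length) into one half-open interval per peak.

    Boundaries are the floor midpoints between consecutive peaks (the
    boundary pixel goes to the right interval); the first interval starts at
    0 and the last ends at ``profile_length``. An empty peak list yields an
    empty interval list.
    """
    peaks = np.asarray(peaks, dtype=int)
    if peaks.size == 0:
        return []
    if profile_length <= int(peaks.max()):
        raise DataError("peak position beyond profile length")
    if np.any(np.diff(peaks) <= 0):
        raise DataError("peaks must be sorted strictly ascending")
    bounds = [0]
    for a, b in zip(peaks[:-1], peaks[1:]):
        bounds.append((int(a) + int(b)) // 2)
    bounds.append(int(profile_length))
    return [(bounds[i], bounds[i + 1]) for i in range(len(peaks))]


def fork_depth(
    interval: tuple[int, int],
    raw,
    reference: str = "initial_interface",
) -> float:
    """Depth of one fork within its interval, read off the raw profile.

    ``initial_interface`` (default): the maximum depth in the interval; the
    profile is already measured from the fixed frame-0 interface line.
    ``local_baseline``: that maximum minus the smaller of the two
    interval-boundary depths, i.e. protrusion height above the local front.
    """
    r = _as_depth(raw)
    start, end = int(interval[0]), int(interval[1])
    if not (0 <= start < end <= r.size):
        raise DataError(f"interval [{start}, {end}) outside profile")
    seg = r[start:end]
    if not np.isfinite(seg).any():
        raise DataError("all positions in interval are invalid")
    peak = float(np.nanmax(seg))
    if reference == "initial_interface":
        return peak
    if reference == "local_baseline":
        edges = np.array([seg[0], seg[-1]])
        if np.isfinite(edges).any():
            base = float(np.nanmin(edges))
        else:  # both boundary pixels invalid: fall back to interval minimum
            base = float(np.nanmin(seg))
        return peak - base
    raise ConfigError(f"unknown depth reference {reference!r}")


def call_forks(
    smoothed,
    raw,
    side_window: int = 40,
    reference: str = "initial_interface",
    compare: str = "raw",
    frame_index: int = 0,
) -> list[ForkCall]:
    """Full fork calling on one frame: peaks -> intervals -> depths."""
    s = _as_depth(smoothed)
    peaks = detect_peaks(s, raw, side_window=side_window, compare=compare)
    intervals = assign_intervals(peaks, s.size)
    calls = []
    for p, iv in zip(peaks, intervals):
        calls.append(
            ForkCall(
                peak_x=int(p),
                depth=fork_depth(iv, raw, reference=reference),
                interval=iv,
                frame_index=frame_index,
            )
        )
    return calls


def compare_depth_distributions(
    a: ForkDepthDistribution, b: ForkDepthDistribution
) -> DepthComparison:
    """Welch t-test (primary) and Mann-Whitney U between two depth samples."""
    if a.n == 0 or b.n == 0:
        raise DataError("both depth samples must be non-empty")
    if a.n < 2 or b.n < 2:
        # descriptive-only output
        return DepthComparison(
            t_statistic=float("nan"), p_value=float("nan"),
            mannwhitney_u=float("nan"), mannwhitney_p=float("nan"),
            stars="n.s.", quantiles_a=a.quantiles(), quantiles_b=b.quantiles(),
            n_a=a.n, n_b=b.n,
        )
    t, p = welch_ttest(a.depths, b.depths)
    mw = stats.mannwhitneyu(a.depths, b.depths, alternative="two-sided")
    return DepthComparison(
        t_statistic=t,
        p_value=p,
        mannwhitney_u=float(mw.statistic),
        mannwhitney_p=float(mw.pvalue),
        stars=significance_stars(p),
        quantiles_a=a.quantiles(),
        quantiles_b=b.quantiles(),
        n_a=a.n,
        n_b=b.n,
    )
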