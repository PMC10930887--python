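"""Shared fixtures and independent oracles used across the suite."""

from __future__ import annotations

import numpy as np
import pytest


def smooth_oracle(depth: np.ndarray, window: int) -> np.ndarray:
    """Brute-force truncated centered moving average, NaN-aware.

    Window for position i covers [i - (w-1)//2, i + w//2], clipped to the
    array; independent of the cumulative-sum implementation under test.
    """
    n = len(depth)
    out = np.full(n, np.nan)
    for i in range(n):
        lo = max(0, i - (window - 1) // 2)
        hi = min(n, i + window // 2 + 1)
        seg = depth[lo:hi]
        seg = seg[np.isfinite(seg)]
        if seg.size:
            out[i] = seg.mean()
    return out


def peak_rule_oracle(smoothed: np.ndarray, raw: np.ndarray,
                     side_window: int) -> list[int]:
    """Exhaustive per-position evaluation of the side-window peak rule.

    A position qualifies iff the smoothed value strictly exceeds the mean of
    the raw profile over both flanks [x-w, x) and [x+1, x+1+w), each flank
    retaining at least w/2 valid pixels after truncation. Qualifying runs
    collapse to the argmax of the smoothed profile, leftmost on ties.
    """
    n = len(smoothed)
    qualifies = []
    for x in range(n):
        if not np.isfinite(smoothed[x]):
            qualifies.append(False)
            continue
        left = raw[max(0, x - side_window):x]
        right = raw[x + 1:x + 1 + side_window]
        left = left[np.isfinite(left)]
        right = right[np.isfinite(right)]
        ok = (
            left.size >= side_window / 2
            and right.size >= side_window / 2
            and smoothed[x] > left.mean()
            and smoothed[x] > right.mean()
        )
        qualifies.append(bool(ok))
    peaks = []
    x = 0
    while x < n:
        if qualifies[x]:
            j = x
            while j + 1 < n and qualifies[j + 1]:
                j += 1
            run = smoothed[x:j + 1]
            best = x
            for k in range(x, j + 1):
                if smoothed[k] > smoothed[best]:
                    best = k
            peaks.append(best)
            x = j + 1
        else:
            x += 1
    return peaks


def random_profile(rng: np.random.Generator, n: int,
                   nan_fraction: float = 0.0) -> np.ndarray:
    """Random piecewise-smooth profile with optional invalid positions."""
    base = np.cumsum(rng.normal(0, 1.0, n))
    bumps = np.zeros(n)
    for _ in range(rng.integers(0, 4)):
        x0 = rng.uniform(0, n)
        amp = rng.uniform(5, 40)
        sig = rng.uniform(3, 15)
        bumps += amp * np.exp(-0.5 * ((np.arange(n) - x0) / sig) ** 2)
    prof = base + bumps + rng.normal(0, 0.5, n)
    if nan_fraction > 0:
        prof[rng.random(n) < nan_fraction] = np.nan
    return prof


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def band_mask():
    """Factory: binary band mask with the epithelium occupying the top rows.

    ``front_row[x]`` gives the furthest epithelium row in column x.
    """

    def make(height: int, width: int, front_row) -> np.ndarray:
        front_row = np.broadcast_to(np.asarray(front_row), (width,))
        rows = np.arange(height)[:, None]
        return rows <= front_row[None, :]

    return make
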