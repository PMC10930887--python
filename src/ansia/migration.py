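"""Per-cell motility metrics from trajectory tables.

For a track with positions p_0 .. p_n at times t_0 .. t_n:

* displacement  = |p_n - p_0|                    (straight-line, px or um)
* path_length   = sum_i |p_i - p_{i-1}|
* velocity      = path_length / (t_n - t_0)      (mean speed; ``net`` mode
                  uses displacement / elapsed instead)
* directionality = displacement / path_length    (confinement ratio in [0,1])

Directionality here is the confinement ratio; the mean cosine of turning
angles is computed alongside as ``directionality_cos`` for users who prefer
the angular reading. Missing frames contribute their actual time gap; no
interpolation is performed.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ._stats import sem, significance_stars, welch_ttest
from .errors import ConfigError, DataError
from .io_formats import TrajectoryTable

__all__ = ["track_metrics", "compare_conditions"]

_METRICS = ("displacement", "path_length", "velocity", "directionality")


def _single_track_metrics(xy: np.ndarray, t: np.ndarray,
                          velocity_mode: str) -> dict:
    steps = np.diff(xy, axis=0)
    step_len = np.hypot(steps[:, 0], steps[:, 1])
    path = float(step_len.sum())
    disp = float(np.hypot(*(xy[-1] - xy[0])))
    elapsed = float(t[-1] - t[0])
    if elapsed <= 0:
        raise DataError("zero elapsed time on track")
    if velocity_mode == "path":
        velocity = path / elapsed
    elif velocity_mode == "net":
        velocity = disp / elapsed
    else:
        raise ConfigError(f"unknown velocity mode {velocity_mode!r}")
    directionality = disp / path if path > 0 else np.nan

    # mean cosine of turning angles between consecutive non-zero steps
    nz = step_len > 0
    cos = np.nan
    if nz.sum() >= 2:
        unit = steps[nz] / step_len[nz, None]
        cos = float(np.sum(unit[1:] * unit[:-1], axis=1).mean())
    return {
        "displacement": disp,
        "path_length": path,
        "velocity": velocity,
        "directionality": directionality,
        "directionality_cos": cos,
        "n_steps": len(step_len),
        "elapsed_min": elapsed,
    }


def track_metrics(
    traj: TrajectoryTable,
    velocity_mode: str = "path",
    pixel_size: float | None = None,
) -> pd.DataFrame:
    """Motility metrics, one row per track (index: track_id).

    Tracks with fewer than 2 points are skipped with a warning. Lengths are
    in pixels unless ``pixel_size`` (um/px) converts them.
    """
    scale = 1.0 if pixel_size is None else float(pixel_size)
    rows = {}
    for tid, grp in traj.data.groupby("track_id", sort=True):
        if len(grp) < 2:
            continue
        xy = grp[["x", "y"]].to_numpy(float) * scale
        t = grp["time_min"].to_numpy(float)
        rows[tid] = _single_track_metrics(xy, t, velocity_mode)
    if traj.short_tracks:
        warnings.warn(
            f"skipped {len(traj.short_tracks)} track(s) with <2 points",
            stacklevel=2,
        )
    if not rows:
        raise DataError("no track has >= 2 points")
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "track_id"
    return df


def compare_conditions(
    metrics_by_condition: dict[str, pd.DataFrame],
    metric_name: str,
) -> pd.DataFrame:
    """Pairwise Welch t-tests on one motility metric across conditions.

    Returns a table with one row per condition pair: means +- s.e.m., the
    t statistic, p-value and star annotation. Every condition needs at least
    2 tracks.
    """
    if metric_name not in _METRICS and metric_name != "directionality_cos":
        raise ConfigError(
            f"unknown metric {metric_name!r}; choose from {_METRICS}"
        )
    names = list(metrics_by_condition)
    if len(names) < 2:
        raise ConfigError("need at least two conditions to compare")
    samples = {}
    for name in names:
        vals = metrics_by_condition[name][metric_name].dropna().to_numpy(float)
        if vals.size < 2:
            raise DataError(f"condition {name!r} has fewer than 2 tracks")
        samples[name] = vals
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            t, p = welch_ttest(samples[a], samples[b])
            rows.append({
                "metric": metric_name,
                "condition_a": a,
                "condition_b": b,
                "mean_a": samples[a].mean(),
                "sem_a": sem(samples[a]),
                "n_a": samples[a].size,
                "mean_b": samples[b].mean(),
                "sem_b": sem(samples[b]),
                "n_b": samples[b].size,
                "t_statistic": t,
                "p_value": p,
                "stars": significance_stars(p),
            })
    return pd.DataFrame(rows)
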