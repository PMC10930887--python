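"""End-to-end orchestration: simulate -> quantify -> summarize -> report.

A run is described by a :class:`RunConfig` (YAML-serializable). The invasion
pipeline simulates (or loads) one stack per condition and replicate, extracts
masks, front profiles and forks, computes the normalized invasion extent per
frame, and — with exactly two conditions — the fold change and fork-depth
comparison. Everything is written as CSV plus a provenance JSON (parameters,
seeds, package version, input hashes) from which the run can be reproduced
byte-identically for its deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, DataError
from .fork_detect import (
    ForkDepthDistribution,
    call_forks,
    compare_depth_distributions,
)
from .front_quant import (
    combine_summaries,
    extract_front,
    fold_change,
    mask_from_stack,
    normalized_extent,
    smooth_profile,
)
from .synthetic_data import FrontSimConfig, simulate_front_stack

__all__ = ["RunConfig", "run_invasion_pipeline", "make_report", "reproduce"]

_FLOAT_FMT = "%.6g"  # fixed format => byte-identical CSV on rerun


@dataclass
class RunConfig:
    """Configuration of one invasion pipeline run.

    ``conditions`` maps condition names to simulation parameter overrides
    (:class:`FrontSimConfig` fields) — or to ``{"stack": path}`` entries for
    real data. Analysis parameters default to the study's stated values:
    20 px smoothing window, 40 px side windows, 60 min invasion frame
    interval.
    """

    conditions: dict = field(default_factory=dict)
    replicates: int = 3
    window: int = 20
    side_window: int = 40
    depth_reference: str = "initial_interface"
    compare: str = "raw"
    interface_row: int | None = None
    seed: int = 0
    out_dir: str = "ansia_run"

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")
        if not self.conditions:
            raise ConfigError("at least one condition is required")
        if self.window < 1 or self.side_window < 1:
            raise ConfigError("window and side_window must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path} is not a mapping")
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(f"bad config {path}: {exc}") from exc

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _replicate_seed(base_seed: int, condition: str, replicate: int) -> int:
    """Stable per-replicate sub-seed derived from the run seed."""
    digest = hashlib.sha256(
        f"{base_seed}:{condition}:{replicate}".encode()
    ).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def run_invasion_pipeline(cfg: RunConfig) -> dict:
    """Run the full invasion analysis and write the result bundle.

    Writes ``extent.csv`` (condition, replicate, frame, time_min, extent_px),
    ``forks.csv`` (final-frame fork calls), ``comparison.csv`` (fold change
    and fork-depth test when exactly two conditions are present) and
    ``provenance.json`` into ``cfg.out_dir``. Returns the bundle in memory.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    extent_rows = []
    fork_rows = []
    summaries: dict[str, list] = {}
    depths: dict[str, list] = {}
    input_hashes: dict[str, str] = {}

    for cond_name, params in cfg.conditions.items():
        summaries[cond_name] = []
        depths[cond_name] = []
        for rep in range(cfg.replicates):
            if "stack" in params:
                from .io_formats import read_image_stack

                stack_path = Path(params["stack"])
                if not stack_path.exists():
                    raise DataError(f"missing input file: {stack_path}")
                input_hashes[str(stack_path)] = _hash_file(stack_path)
                stack = read_image_stack(stack_path)
                interface_row = cfg.interface_row
                if interface_row is None:
                    raise ConfigError(
                        "interface_row is required for real stacks"
                    )
            else:
                sim_cfg = FrontSimConfig(
                    seed=_replicate_seed(cfg.seed, cond_name, rep),
                    **{k: v for k, v in params.items() if k != "stack"},
                )
                stack = simulate_front_stack(sim_cfg).stack
                interface_row = sim_cfg.interface_row

            try:
                masks = mask_from_stack(stack)
                summary = normalized_extent(
                    masks, interface_row,
                    frame_interval=stack.frame_interval,
                    condition=cond_name,
                )
                final_profile = extract_front(
                    masks[-1], interface_row,
                    frame_index=stack.n_frames - 1,
                )
                smoothed = smooth_profile(final_profile, window=cfg.window)
                calls = call_forks(
                    smoothed, final_profile,
                    side_window=cfg.side_window,
                    reference=cfg.depth_reference,
                    compare=cfg.compare,
                    frame_index=stack.n_frames - 1,
                )
            except (ConfigError, DataError) as exc:
                raise type(exc)(
                    f"[{cond_name} replicate {rep}] {exc}"
                ) from exc

            summaries[cond_name].append(summary)
            for t, e in enumerate(summary.extent[0]):
                extent_rows.append(
                    (cond_name, rep, t, t * summary.frame_interval, e)
                )
            for c in calls:
                fork_rows.append(
                    (cond_name, rep, c.frame_index, c.peak_x,
                     c.interval[0], c.interval[1], c.depth)
                )
                depths[cond_name].append(c.depth)

    extent_df = pd.DataFrame(
        extent_rows,
        columns=["condition", "replicate", "frame", "time_min", "extent_px"],
    )
    forks_df = pd.DataFrame(
        fork_rows,
        columns=["condition", "replicate", "frame", "peak_x",
                 "start_x", "end_x", "depth_px"],
    )

    comparison_rows = []
    cond_names = list(cfg.conditions)
    if len(cond_names) == 2:
        test, control = cond_names[1], cond_names[0]
        fc = fold_change(
            combine_summaries(summaries[test]),
            combine_summaries(summaries[control]),
        )
        comparison_rows.append({
            "measure": "extent_fold_change",
            "test": test, "control": control,
            "value": fc.fold_change, "p_value": fc.p_value,
            "stars": fc.stars,
        })
        if len(depths[test]) >= 2 and len(depths[control]) >= 2:
            cmp_res = compare_depth_distributions(
                ForkDepthDistribution(np.array(depths[test]), test),
                ForkDepthDistribution(np.array(depths[control]), control),
            )
            comparison_rows.append({
                "measure": "fork_depth_welch_t",
                "test": test, "control": control,
                "value": cmp_res.t_statistic, "p_value": cmp_res.p_value,
                "stars": cmp_res.stars,
            })
    comparison_df = pd.DataFrame(
        comparison_rows,
        columns=["measure", "test", "control", "value", "p_value", "stars"],
    )

    extent_df.to_csv(out / "extent.csv", index=False, float_format=_FLOAT_FMT)
    forks_df.to_csv(out / "forks.csv", index=False, float_format=_FLOAT_FMT)
    comparison_df.to_csv(out / "comparison.csv", index=False,
                         float_format=_FLOAT_FMT)

    provenance = {
        "tool": "ansia",
        "version": __version__,
        "numpy_version": np.__version__,
        "config": cfg.to_dict(),
        "input_hashes": input_hashes,
    }
    (out / "provenance.json").write_text(
        json.dumps(provenance, indent=2, sort_keys=True) + "\n"
    )

    return {
        "extent": extent_df,
        "forks": forks_df,
        "comparison": comparison_df,
        "summaries": summaries,
        "provenance": provenance,
        "out_dir": out,
    }


def reproduce(provenance_path: str | Path, out_dir: str | Path) -> dict:
    """Re-run a pipeline from its provenance record alone."""
    record = json.loads(Path(provenance_path).read_text())
    cfg_dict = dict(record["config"])
    cfg_dict["out_dir"] = str(out_dir)
    return run_invasion_pipeline(RunConfig(**cfg_dict))


def make_report(bundle_dir: str | Path, fig_dir: str | Path | None = None) -> list[Path]:
    """Render summary figures from a written result bundle.

    Plots E(t) curves per condition (mean +- s.e.m. across replicates) and a
    fork-depth histogram per condition. Re-rendering the same bundle never
    recomputes analysis; it only reads the CSVs. Returns the written paths.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    bundle_dir = Path(bundle_dir)
    extent_path = bundle_dir / "extent.csv"
    if not extent_path.exists():
        raise DataError(f"no result bundle at {bundle_dir}")
    extent = pd.read_csv(extent_path)
    if extent.empty:
        raise DataError("empty results; nothing to plot")
    forks = pd.read_csv(bundle_dir / "forks.csv")
    fig_dir = Path(fig_dir) if fig_dir else bundle_dir
    fig_dir.mkdir(parents=True, exist_ok=True)
    written = []

    fig, ax = plt.subplots(figsize=(5, 4))
    for cond, grp in extent.groupby("condition"):
        stats = grp.groupby("time_min")["extent_px"].agg(["mean", "sem"])
        ax.errorbar(stats.index / 60.0, stats["mean"], yerr=stats["sem"],
                    label=cond, capsize=2)
    ax.set_xlabel("time (h)")
    ax.set_ylabel("normalized invasion extent (px)")
    ax.legend()
    fig.tight_layout()
    path = fig_dir / "extent_curves.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)

    if forks.empty:
        print("fork table empty; histogram skipped")
    else:
        fig, ax = plt.subplots(figsize=(5, 4))
        for cond, grp in forks.groupby("condition"):
            ax.hist(grp["depth_px"], bins=15, alpha=0.6, label=cond)
        ax.set_xlabel("fork depth (px)")
        ax.set_ylabel("count")
        ax.legend()
        fig.tight_layout()
        path = fig_dir / "fork_depths.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written
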