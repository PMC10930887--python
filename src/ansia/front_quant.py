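"""Invasion-front extraction and the normalized invasion extent statistic.

The assay geometry is a fluorescently labeled epithelial monolayer abutting an
unlabeled stromal monolayer along a straight interface. Directional cues make
the invasion quasi one-dimensional, so the front reduces to a depth profile
d(x): for each position x along the interface, how far the labeled epithelium
has advanced past the initial interface line (axis-0 row ``interface_row``,
fixed at frame 0 and held constant over time).

The headline statistic is the normalized extent of invasion

    E(t) = (A(t) - A(t0)) / L0

where A(t) is the invaded area (labeled pixels beyond the interface line) and
L0 the initial length of the epithelium-stroma interface. E has units of
length (pixels, or microns when a pixel size is configured) and E(t0) = 0 by
construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from shapely.geometry import Polygon
from skimage import filters, morphology

from ._stats import sem as _sem
from ._stats import significance_stars, welch_ttest
from .errors import ConfigError, DataError
from .io_formats import ImageStack, RoiPolygon

__all__ = [
    "FrontProfile",
    "InvasionSummary",
    "FoldChangeResult",
    "mask_from_stack",
    "extract_front",
    "smooth_profile",
    "normalized_extent",
    "normalized_extent_from_rois",
    "combine_summaries",
    "fold_change",
]


@dataclass
class FrontProfile:
    """Quasi-1D invasion depth per interface position at one time point.

    ``depth[x]`` is the advance (pixels) of the furthest connected epithelium
    past the initial interface line in column x; NaN marks positions where
    the epithelium does not reach the interface (invalid, not zero).
    """

    depth: np.ndarray
    frame_index: int = 0
    interface_length: int = 0  # L0: valid interface positions at frame 0

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.ndim != 1 or self.depth.size == 0:
            raise DataError("profile depth must be a non-empty 1D array")

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.depth)

    def __len__(self) -> int:
        return self.depth.size


@dataclass
class InvasionSummary:
    """Per-frame normalized invasion extent for one condition.

    ``extent`` has shape (n_replicates, n_frames); replicates are independent
    assay locations. ``extent[:, 0]`` is 0 by construction.
    """

    extent: np.ndarray
    frame_interval: float = 60.0
    interface_length: float = 0.0
    condition: str = ""
    units: str = "px"

    def __post_init__(self) -> None:
        self.extent = np.atleast_2d(np.asarray(self.extent, dtype=float))

    @property
    def n_replicates(self) -> int:
        return self.extent.shape[0]

    @property
    def n_frames(self) -> int:
        return self.extent.shape[1]

    @property
    def final_extent(self) -> np.ndarray:
        """Final-frame extent per replicate location."""
        return self.extent[:, -1]

    @property
    def times_min(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    def mean(self) -> np.ndarray:
        return self.extent.mean(axis=0)

    def sem(self) -> np.ndarray:
        if self.n_replicates < 2:
            return np.full(self.n_frames, np.nan)
        return self.extent.std(axis=0, ddof=1) / np.sqrt(self.n_replicates)


@dataclass
class FoldChangeResult:
    """Ratio of mean final extents between two conditions, with Welch t-test."""

    fold_change: float
    p_value: float
    stars: str
    mean_test: float
    mean_control: float
    sem_test: float
    sem_control: float
    n_test: int
    n_control: int


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def mask_from_stack(
    stack: ImageStack,
    threshold_method: str = "otsu",
    min_object_size: int = 64,
    fill_holes: bool = True,
) -> np.ndarray:
    """Threshold each frame into an epithelium mask (True = labeled cells).

    Small-object removal (< ``min_object_size`` px) and hole filling clean up
    the binary mask. A frame that thresholds to all-background or
    all-foreground is a degenerate segmentation and raises.
    """
    masks = np.empty(stack.frames.shape, dtype=bool)
    for t, frame in enumerate(stack.frames):
        frame = np.asarray(frame, dtype=float)
        if np.ptp(frame) == 0:
            raise DataError(f"degenerate segmentation: frame {t} is uniform")
        if threshold_method == "otsu":
            thr = filters.threshold_otsu(frame)
        elif threshold_method == "mean":
            thr = frame.mean()
        else:
            raise ConfigError(f"unknown threshold_method {threshold_method!r}")
        mask = frame > thr
        if mask.all() or not mask.any():
            raise DataError(f"degenerate segmentation: frame {t}")
        # drop objects below min_object_size px (max_size is inclusive)
        mask = morphology.remove_small_objects(mask, max_size=min_object_size - 1)
        if fill_holes:
            mask = ndimage.binary_fill_holes(mask)
        if not mask.any():
            raise DataError(f"degenerate segmentation: frame {t}")
        masks[t] = mask
    return masks


# ---------------------------------------------------------------------------
# front extraction
# ---------------------------------------------------------------------------

def _main_front_mask(mask: np.ndarray, interface_row: int) -> np.ndarray:
    """Connected components attached to the epithelial side of the interface.

    Detached clusters entirely beyond the interface line (disseminated cells)
    are excluded from the depth profile; they still count toward area in
    :func:`normalized_extent`.
    """
    labels, n = ndimage.label(mask)
    if n <= 1:
        return mask
    attached = np.unique(labels[: interface_row + 1, :])
    attached = attached[attached != 0]
    return np.isin(labels, attached)


def extract_front(
    mask: np.ndarray,
    interface_row: int,
    frame_index: int = 0,
    interface_length: int | None = None,
) -> FrontProfile:
    """Convert an epithelium mask into a per-column depth profile.

    For each column x, depth d(x) is the furthest epithelium row at or beyond
    ``interface_row`` minus ``interface_row``, using only epithelium connected
    to the interface. Columns where the connected epithelium does not reach
    the interface are invalid (NaN). ``interface_length`` (L0) defaults to the
    number of columns spanned by the epithelial monolayer in this mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise DataError("mask must be 2D")
    if not mask.any():
        raise DataError("empty mask")
    if not 0 <= interface_row < mask.shape[0]:
        raise DataError(
            f"interface_row {interface_row} outside image of height {mask.shape[0]}"
        )

    main = _main_front_mask(mask, interface_row)
    h, w = main.shape
    depth = np.full(w, np.nan)
    reaches = main[interface_row, :]
    beyond = main[interface_row:, :]
    # furthest True row per column among rows >= interface_row
    rows = np.arange(beyond.shape[0])[:, None]
    furthest = np.where(beyond, rows, -1).max(axis=0)
    depth[reaches] = furthest[reaches].astype(float)

    if not np.isfinite(depth).any():
        warnings.warn(
            "epithelium does not reach the interface anywhere; "
            "all profile positions invalid",
            stacklevel=2,
        )
    if interface_length is None:
        spanned = mask[: interface_row + 1, :].any(axis=0)
        interface_length = int(spanned.sum())
    return FrontProfile(depth, frame_index=frame_index,
                        interface_length=interface_length)


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------

def _window_bounds(n: int, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Centered window [i-(w-1)//2, i+w//2] inclusive, truncated at the edges."""
    idx = np.arange(n)
    start = np.maximum(idx - (window - 1) // 2, 0)
    stop = np.minimum(idx + window // 2 + 1, n)  # exclusive
    return start, stop


def smooth_profile(profile: FrontProfile, window: int = 20) -> FrontProfile:
    """Centered moving average of the depth profile.

    Edges use the truncated (shrinking) window — no padding, so no phantom
    mass. Invalid (NaN) positions are excluded from every average and stay
    invalid where an entire window is invalid. ``window=1`` is the identity.
    """
    if window < 1:
        raise ConfigError("window must be >= 1")
    n = len(profile)
    if window > n:
        raise ConfigError(f"window {window} larger than profile length {n}")
    d = profile.depth
    if window == 1:
        return FrontProfile(d.copy(), frame_index=profile.frame_index,
                            interface_length=profile.interface_length)
    valid = np.isfinite(d)
    filled = np.where(valid, d, 0.0)
    csum = np.concatenate([[0.0], np.cumsum(filled)])
    ccnt = np.concatenate([[0.0], np.cumsum(valid.astype(float))])
    start, stop = _window_bounds(n, window)
    total = csum[stop] - csum[start]
    count = ccnt[stop] - ccnt[start]
    with np.errstate(invalid="ignore"):
        out = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return FrontProfile(out, frame_index=profile.frame_index,
                        interface_length=profile.interface_length)


# ---------------------------------------------------------------------------
# normalized extent
# ---------------------------------------------------------------------------

def _area_beyond(mask: np.ndarray, interface_row: int) -> float:
    """Invaded area: labeled pixels strictly beyond the interface line.

    All labeled pixels count, including detached clusters ahead of the
    connected front ("aerial invasion" is area-faithful).
    """
    return float(mask[interface_row + 1:, :].sum())


def normalized_extent(
    masks: np.ndarray,
    interface_row: int,
    interface_length: float | None = None,
    frame_interval: float = 60.0,
    pixel_size: float | None = None,
    condition: str = "",
) -> InvasionSummary:
    """Normalized invasion extent E(t) from per-frame epithelium masks.

    E(t) = (A(t) - A(t0)) / L0 with A(t) the labeled area beyond the fixed
    frame-0 interface line and L0 the initial interface length (defaults to
    the monolayer span of frame 0). Reported in pixels, or microns when
    ``pixel_size`` is given.
    """
    masks = np.asarray(masks, dtype=bool)
    if masks.ndim != 3 or masks.shape[0] < 1:
        raise DataError("masks must be a (T, H, W) array with T >= 1")
    if interface_length is None:
        spanned = masks[0][: interface_row + 1, :].any(axis=0)
        interface_length = float(spanned.sum())
    if interface_length <= 0:
        raise DataError("interface length L0 must be positive")
    areas = np.array([_area_beyond(m, interface_row) for m in masks])
    extent = (areas - areas[0]) / interface_length
    units = "px"
    if pixel_size is not None:
        extent = extent * pixel_size
        units = "um"
    return InvasionSummary(extent[None, :], frame_interval=frame_interval,
                           interface_length=interface_length,
                           condition=condition, units=units)


def normalized_extent_from_rois(
    rois: list[RoiPolygon],
    interface_length: float,
    frame_interval: float = 60.0,
    pixel_size: float | None = None,
    condition: str = "",
) -> InvasionSummary:
    """Normalized extent from traced invaded-region polygons (shoelace areas)."""
    if not rois:
        raise DataError("no ROI polygons supplied")
    if interface_length <= 0:
        raise DataError("interface length L0 must be positive")
    rois = sorted(rois, key=lambda r: r.frame_index)
    areas = np.array([Polygon(r.vertices).area for r in rois])
    extent = (areas - areas[0]) / interface_length
    units = "px"
    if pixel_size is not None:
        extent = extent * pixel_size
        units = "um"
    return InvasionSummary(extent[None, :], frame_interval=frame_interval,
                           interface_length=interface_length,
                           condition=condition, units=units)


def combine_summaries(summaries: list[InvasionSummary]) -> InvasionSummary:
    """Stack per-location summaries of one condition into replicate rows."""
    if not summaries:
        raise DataError("no summaries to combine")
    n_frames = {s.n_frames for s in summaries}
    if len(n_frames) != 1:
        raise DataError("replicate summaries have differing frame counts")
    first = summaries[0]
    return InvasionSummary(
        np.vstack([s.extent for s in summaries]),
        frame_interval=first.frame_interval,
        interface_length=first.interface_length,
        condition=first.condition,
        units=first.units,
    )


def fold_change(
    summary_test: InvasionSummary, summary_control: InvasionSummary
) -> FoldChangeResult:
    """Fold change of mean final-frame extent (test / control), Welch t-test.

    Requires at least 2 replicate locations per condition and a positive
    control mean.
    """
    a = summary_test.final_extent
    b = summary_control.final_extent
    if a.size < 2 or b.size < 2:
        raise DataError("fold change needs >= 2 replicate locations per condition")
    mean_control = float(b.mean())
    if mean_control <= 0:
        raise DataError("control mean extent <= 0; fold change undefined")
    _, p = welch_ttest(a, b)
    ratio = float(a.mean()) / mean_control
    return FoldChangeResult(
        fold_change=ratio,
        p_value=p,
        stars=significance_stars(p),
        mean_test=float(a.mean()),
        mean_control=mean_control,
        sem_test=_sem(a),
        sem_control=_sem(b),
        n_test=int(a.size),
        n_control=int(b.size),
    )
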