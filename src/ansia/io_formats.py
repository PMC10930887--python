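"""Readers and writers for every external representation the pipeline touches.

Conventions (fixed once, used everywhere downstream):

* Image coordinates are 0-based pixel indices. Axis 0 ("y", rows) increases
  *into* the stromal compartment; axis 1 ("x", columns) runs along the
  initial epithelium-stroma interface.
* Canonical row order for tabular data is frame-major, then track / vertex
  index; readers re-sort into that order and never reorder silently beyond it.
* Every reader/writer pair is a lossless round trip for in-range data.

File dialects:

* image stacks   — multi-page grayscale TIFF,
* ROI polygons   — CSV with columns ``frame,vertex_index,x,y``,
* trajectories   — CSV with columns ``track_id,frame,x,y[,time_min]``; the
  TrackMate "spots" export spelling (``TRACK_ID,FRAME,POSITION_X,POSITION_Y``)
  is accepted via a column-mapping table,
* expression     — matrix-market coordinate file (genes x cells) with sidecar
  one-ID-per-line gene and cell lists, or a dense CSV with genes as rows,
* gene sets      — plain text, one gene identifier per line, ``#`` comments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import io as sio
from scipy import sparse

from .errors import DataError

#: default frame spacing for invasion time-lapses (1 h acquisition cadence)
INVASION_FRAME_INTERVAL_MIN = 60.0
#: default frame spacing for migration time-lapses (10 min cadence)
MIGRATION_FRAME_INTERVAL_MIN = 10.0

# TrackMate "spots" export -> canonical column names
_TRACKMATE_COLUMNS = {
    "TRACK_ID": "track_id",
    "FRAME": "frame",
    "POSITION_X": "x",
    "POSITION_Y": "y",
    "POSITION_T": "time_min",
}


# ---------------------------------------------------------------------------
# image stacks
# ---------------------------------------------------------------------------

@dataclass
class ImageStack:
    """Time-lapse of single-channel intensity frames.

    ``frames`` has shape (T, H, W). Axis 0 of each frame is the invasion
    direction (positive = into stroma); axis 1 runs along the interface.
    """

    frames: np.ndarray
    pixel_size: float | None = None      # microns per pixel, optional
    frame_interval: float = INVASION_FRAME_INTERVAL_MIN  # minutes

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise DataError(
                f"stack must be (T, H, W), got shape {self.frames.shape}"
            )
        if self.frame_interval <= 0:
            raise DataError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(H, W) of a single frame."""
        return self.frames.shape[1:]

    def require_time_resolved(self) -> None:
        """Raise for single-frame stacks when a time-resolved op is requested."""
        if self.n_frames < 2:
            raise DataError(
                "time-resolved operation requires at least 2 frames, "
                f"stack has {self.n_frames}"
            )


def read_image_stack(
    path: str | Path,
    pixel_size: float | None = None,
    frame_interval: float = INVASION_FRAME_INTERVAL_MIN,
) -> ImageStack:
    """Read a multi-page grayscale TIFF into an :class:`ImageStack`.

    Frames are kept in file order. Frames of unequal shape are an error.
    """
    try:
        frames = tifffile.imread(str(path))
    except (OSError, ValueError, tifffile.TiffFileError) as exc:
        raise DataError(f"unreadable stack {path}: {exc}") from exc
    frames = np.asarray(frames)
    if frames.size == 0:
        raise DataError(f"unreadable stack {path}: no image pages found")
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise DataError(
            f"expected single-channel pages in {path}, got shape {frames.shape}"
        )
    return ImageStack(frames, pixel_size=pixel_size, frame_interval=frame_interval)


def write_image_stack(stack: ImageStack, path: str | Path) -> None:
    tifffile.imwrite(str(path), stack.frames, photometric="minisblack")


# ---------------------------------------------------------------------------
# ROI polygons
# ---------------------------------------------------------------------------

@dataclass
class RoiPolygon:
    """Manually traced invasion-boundary polygon for one frame.

    Vertices are (x_along_interface, y_into_stroma) pixel coordinates.
    """

    vertices: np.ndarray  # (n, 2) float
    frame_index: int
    closed: bool = True

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise DataError("vertices must be an (n, 2) array")
        if self.closed and len(self.vertices) < 3:
            raise DataError("closed polygon needs at least 3 vertices")


def read_roi_csv(path: str | Path) -> list[RoiPolygon]:
    """Read traced ROI polygons, one per frame, vertices ordered by index.

    Expects columns ``frame,vertex_index,x,y``; extra columns are ignored.
    """
    df = pd.read_csv(path)
    required = {"frame", "vertex_index", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"ROI CSV {path} missing columns: {sorted(missing)}")
    for col in ("x", "y"):
        if not np.issubdtype(df[col].dtype, np.number):
            raise DataError(f"ROI CSV column {col!r} is not numeric")
    polygons = []
    for frame, grp in df.groupby("frame", sort=True):
        grp = grp.sort_values("vertex_index")
        polygons.append(
            RoiPolygon(grp[["x", "y"]].to_numpy(float), frame_index=int(frame))
        )
    return polygons


def write_roi_csv(polygons: Sequence[RoiPolygon], path: str | Path) -> None:
    rows = []
    for poly in polygons:
        for i, (x, y) in enumerate(poly.vertices):
            rows.append((poly.frame_index, i, x, y))
    pd.DataFrame(rows, columns=["frame", "vertex_index", "x", "y"]).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

@dataclass
class TrajectoryTable:
    """Time-ordered planar positions of tracked cells.

    ``data`` holds columns ``track_id, frame, x, y, time_min`` sorted by
    (track_id, frame). Tracks with fewer than 2 points are retained but
    listed in :attr:`short_tracks`; metric computation skips them.
    """

    data: pd.DataFrame
    frame_interval: float = MIGRATION_FRAME_INTERVAL_MIN
    short_tracks: list = field(default_factory=list)

    def __post_init__(self) -> None:
        df = self.data
        required = {"track_id", "frame", "x", "y"}
        missing = required - set(df.columns)
        if missing:
            raise DataError(f"trajectory table missing columns: {sorted(missing)}")
        if df[["x", "y"]].isna().any().any():
            raise DataError("trajectory table has missing coordinates")
        dup = df.duplicated(subset=["track_id", "frame"])
        if dup.any():
            first = df.loc[dup, ["track_id", "frame"]].iloc[0]
            raise DataError(
                "duplicate (track_id, frame) pair: "
                f"({first['track_id']}, {first['frame']})"
            )
        df = df.sort_values(["track_id", "frame"], kind="mergesort").reset_index(
            drop=True
        )
        if "time_min" not in df.columns:
            df["time_min"] = df["frame"] * float(self.frame_interval)
        counts = df.groupby("track_id").size()
        self.short_tracks = list(counts.index[counts < 2])
        self.data = df

    @property
    def track_ids(self) -> list:
        return list(self.data["track_id"].unique())

    def __len__(self) -> int:
        return len(self.data)


def read_trajectories(
    path: str | Path,
    frame_interval: float | None = None,
    column_map: dict[str, str] | None = None,
) -> TrajectoryTable:
    """Read a cell-track CSV (canonical or TrackMate spots dialect).

    ``column_map`` maps file column names onto the canonical
    ``track_id/frame/x/y/time_min``; the TrackMate spots spelling is applied
    automatically. Either a ``time_min`` column or ``frame_interval`` must
    provide timing (default: 10 min frame spacing).
    """
    df = pd.read_csv(path)
    mapping = dict(_TRACKMATE_COLUMNS)
    if column_map:
        mapping.update(column_map)
    df = df.rename(columns={k: v for k, v in mapping.items() if k in df.columns})
    interval = frame_interval
    if interval is None:
        interval = MIGRATION_FRAME_INTERVAL_MIN
    return TrajectoryTable(df, frame_interval=interval)


def write_trajectories(table: TrajectoryTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# expression matrices and gene sets
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Gene x cell numeric matrix with stable identifier ordering.

    ``cell_groups`` optionally labels each cell with a group (for example a
    tumor subtype: ER, HER2, TNBC).
    """

    genes: list[str]
    cells: list[str]
    values: np.ndarray  # (n_genes, n_cells)
    cell_groups: pd.Series | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.cells)):
            raise DataError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if len(set(self.genes)) != len(self.genes):
            dupes = pd.Index(self.genes)
            raise DataError(
                "duplicate gene identifiers: "
                f"{sorted(dupes[dupes.duplicated()].unique())[:5]}"
            )
        if self.cell_groups is not None:
            self.cell_groups = pd.Series(
                np.asarray(self.cell_groups), index=self.cells
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def gene_index(self) -> pd.Index:
        return pd.Index(self.genes)


@dataclass
class GeneSet:
    """Named list of gene identifiers; duplicates removed on construction."""

    name: str
    genes: list[str]

    def __post_init__(self) -> None:
        seen: dict[str, None] = {}
        for g in self.genes:
            seen.setdefault(g, None)
        self.genes = list(seen)
        if not self.genes:
            raise DataError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)


def _read_id_list(path: str | Path) -> list[str]:
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def read_gene_set(path: str | Path, name: str | None = None) -> GeneSet:
    return GeneSet(name=name or Path(path).stem, genes=_read_id_list(path))


def write_gene_set(gene_set: GeneSet, path: str | Path) -> None:
    Path(path).write_text("\n".join(gene_set.genes) + "\n")


def read_expression(
    path_matrix: str | Path,
    path_genes: str | Path | None = None,
    path_cells: str | Path | None = None,
    cell_groups: str | Path | None = None,
) -> ExpressionMatrix:
    """Read a genes x cells matrix.

    Matrix-market files need sidecar gene and cell ID lists; a dense CSV
    carries gene IDs as its index column and cell IDs as its header.
    ``cell_groups`` optionally points to a two-column CSV ``cell,group``.
    """
    path_matrix = Path(path_matrix)
    if path_matrix.suffix == ".mtx":
        if path_genes is None or path_cells is None:
            raise DataError("matrix-market input needs gene and cell ID files")
        try:
            mat = sio.mmread(str(path_matrix))
        except ValueError as exc:
            raise DataError(f"unreadable matrix {path_matrix}: {exc}") from exc
        if sparse.issparse(mat):
            mat = mat.toarray()
        genes = _read_id_list(path_genes)
        cells = _read_id_list(path_cells)
        if mat.shape != (len(genes), len(cells)):
            raise DataError(
                f"matrix shape {mat.shape} does not match ID lists "
                f"({len(genes)} genes, {len(cells)} cells)"
            )
    else:
        df = pd.read_csv(path_matrix, index_col=0)
        genes = [str(g) for g in df.index]
        cells = [str(c) for c in df.columns]
        mat = df.to_numpy(float)
    groups = None
    if cell_groups is not None:
        gdf = pd.read_csv(cell_groups)
        if not {"cell", "group"} <= set(gdf.columns):
            raise DataError("cell-group CSV needs columns cell,group")
        groups = gdf.set_index("cell")["group"].reindex(cells)
    return ExpressionMatrix(genes, cells, np.asarray(mat, float), cell_groups=groups)


def write_expression(
    matrix: ExpressionMatrix,
    path_matrix: str | Path,
    path_genes: str | Path | None = None,
    path_cells: str | Path | None = None,
) -> None:
    """Write matrix-market (+ ID sidecars) or dense CSV, by file extension."""
    path_matrix = Path(path_matrix)
    if path_matrix.suffix == ".mtx":
        if path_genes is None or path_cells is None:
            raise DataError("matrix-market output needs gene and cell ID paths")
        sio.mmwrite(str(path_matrix), sparse.coo_matrix(matrix.values))
        Path(path_genes).write_text("\n".join(matrix.genes) + "\n")
        Path(path_cells).write_text("\n".join(matrix.cells) + "\n")
    else:
        pd.DataFrame(
            matrix.values, index=matrix.genes, columns=matrix.cells
        ).to_csv(path_matrix)
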