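"""Per-cell gene-set module scores and cross-set correlations.

A module score is the per-cell mean of gene-wise z-scaled expression over the
genes of a set: genes are centered and scaled to unit variance across *all*
cells once, and the score of a cell for a set is the mean of the scaled
values of the set genes present in the matrix. Scores of two sets are then
correlated (Pearson) within each cell group — e.g. within each breast tumor
subtype (ER, HER2, TNBC) — with the two-sided p-value from the t distribution
with n-2 degrees of freedom.

Scaling across all cells with within-group correlation is the default; pass
``scale_within_group=True`` to :func:`module_scores` pipelines that need the
alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError
from .io_formats import ExpressionMatrix, GeneSet

__all__ = [
    "ModuleScoreTable",
    "CorrelationResult",
    "scale_genes",
    "module_score",
    "module_scores",
    "correlate_scores",
]


@dataclass
class ModuleScoreTable:
    """Per-cell module scores, one column per gene set.

    A set with zero overlap with the matrix yields a column of NaN (missing,
    not zero). ``n_matched`` records how many set genes were found.
    """

    scores: pd.DataFrame  # index: cells, columns: set names
    groups: pd.Series | None = None
    n_matched: dict = field(default_factory=dict)


@dataclass
class CorrelationResult:
    """Pearson correlation of two module scores within one cell group."""

    set_a: str
    set_b: str
    group: str
    r: float
    p_value: float
    n_cells: int


def scale_genes(
    matrix: ExpressionMatrix,
    normalize_raw: bool = False,
    target_sum: float = 1e4,
) -> ExpressionMatrix:
    """Center each gene to mean 0 and unit variance across cells.

    Input is assumed already normalized (log scale); with
    ``normalize_raw=True`` raw counts are first library-size normalized to
    ``target_sum`` counts per cell and log1p transformed. Zero-variance genes
    carry no information after scaling and are dropped with a warning.
    Re-scaling an already scaled matrix is idempotent.
    """
    if len(matrix.cells) < 2:
        raise DataError("scaling needs at least 2 cells")
    values = matrix.values
    if normalize_raw:
        libsize = values.sum(axis=0)
        if (libsize <= 0).any():
            raise DataError("cell with zero total counts")
        values = np.log1p(values / libsize * target_sum)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True, ddof=0)
    keep = sd[:, 0] > 0
    if not keep.all():
        dropped = [g for g, k in zip(matrix.genes, keep) if not k]
        warnings.warn(
            f"dropped {len(dropped)} zero-variance gene(s): {dropped[:5]}",
            stacklevel=2,
        )
    if not keep.any():
        raise DataError("all genes have zero variance")
    scaled = (values[keep] - mean[keep]) / sd[keep]
    return ExpressionMatrix(
        [g for g, k in zip(matrix.genes, keep) if k],
        list(matrix.cells),
        scaled,
        cell_groups=matrix.cell_groups,
    )


def module_score(scaled: ExpressionMatrix, gene_set: GeneSet) -> tuple[np.ndarray, int]:
    """Per-cell mean scaled expression over the set genes present.

    Returns (scores, n_matched); with zero overlap the scores are all-NaN
    (missing) and a warning names the set.
    """
    idx = scaled.gene_index().get_indexer(gene_set.genes)
    idx = idx[idx >= 0]
    if idx.size == 0:
        warnings.warn(
            f"gene set {gene_set.name!r} has no overlap with the matrix",
            stacklevel=2,
        )
        return np.full(len(scaled.cells), np.nan), 0
    return scaled.values[idx].mean(axis=0), int(idx.size)


def module_scores(
    scaled: ExpressionMatrix, gene_sets: list[GeneSet]
) -> ModuleScoreTable:
    """Score several gene sets into one table (cells x sets)."""
    if not gene_sets:
        raise ConfigError("no gene sets supplied")
    cols = {}
    matched = {}
    for gs in gene_sets:
        cols[gs.name], matched[gs.name] = module_score(scaled, gs)
    df = pd.DataFrame(cols, index=list(scaled.cells))
    return ModuleScoreTable(df, groups=scaled.cell_groups, n_matched=matched)


def correlate_scores(
    table: ModuleScoreTable,
    set_a: str,
    set_b: str,
    by_group: bool = True,
    min_cells: int = 3,
) -> list[CorrelationResult]:
    """Pearson correlation between two score columns, per cell group.

    Groups with fewer than ``min_cells`` cells are skipped with a warning;
    a zero-variance score vector makes r undefined (NaN) for that group.
    With ``by_group=False`` (or no group labels) all cells form one group.
    """
    for name in (set_a, set_b):
        if name not in table.scores.columns:
            raise ConfigError(f"unknown gene set column {name!r}")
        if table.scores[name].isna().all():
            raise DataError(f"score column {name!r} is missing (no gene overlap)")

    if by_group and table.groups is not None:
        grouping = table.groups
    else:
        grouping = pd.Series("all", index=table.scores.index)

    results = []
    for group, members in table.scores.groupby(grouping):
        a = members[set_a].to_numpy(float)
        b = members[set_b].to_numpy(float)
        ok = np.isfinite(a) & np.isfinite(b)
        a, b = a[ok], b[ok]
        if a.size < min_cells:
            warnings.warn(
                f"group {group!r} has {a.size} cells (< {min_cells}); skipped",
                stacklevel=2,
            )
            continue
        if np.std(a) == 0 or np.std(b) == 0:
            warnings.warn(
                f"zero-variance score in group {group!r}; r undefined",
                stacklevel=2,
            )
            results.append(CorrelationResult(set_a, set_b, str(group),
                                             float("nan"), float("nan"),
                                             int(a.size)))
            continue
        res = stats.pearsonr(a, b)
        results.append(
            CorrelationResult(set_a, set_b, str(group),
                              float(res.statistic), float(res.pvalue),
                              int(a.size))
        )
    return results
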