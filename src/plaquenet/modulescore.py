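"""Per-cell module scores with expression-bin-matched control genes.

The score of a gene set in a cell is the mean expression of the set's genes
minus the mean expression of a pooled control set.  Controls are matched on
overall expression level: all genes are placed into equal-occupancy bins by
their average expression across cells, and for every set gene a fixed number
of control genes is sampled from its bin (without replacement when the bin
is large enough).  Subtracting bin-matched controls removes the component of
the score explained by expression magnitude alone, so a positive score means
the set is expressed above comparable genes in that cell.

Scores are comparable only within one normalization of the input matrix;
normalizing the cell x gene matrix is the caller's responsibility.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["ModuleScoreParams", "module_score", "aggregate_by_group"]


@dataclass(frozen=True)
class ModuleScoreParams:
    """Control-matching parameters for the module score."""

    n_bins: int = 24
    n_control_per_gene: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.n_control_per_gene < 1:
            raise ValueError("n_control_per_gene must be >= 1")


def module_score(
    cell_expr: pd.DataFrame,
    gene_set: list[str] | set[str],
    params: ModuleScoreParams | None = None,
) -> pd.Series:
    """Per-cell score of a gene set against bin-matched controls.

    Parameters
    ----------
    cell_expr
        Normalized cell x gene matrix (cells as rows).
    gene_set
        Genes to score; members absent from the matrix are dropped with a
        warning, a fully absent set raises.

    Returns
    -------
    Per-cell scores (index = cells), deterministic given ``params.seed``.
    """
    params = params or ModuleScoreParams()
    genes = list(cell_expr.columns)
    gene_pos = {g: i for i, g in enumerate(genes)}
    present = sorted(set(gene_set) & set(genes))
    missing = sorted(set(gene_set) - set(genes))
    if not present:
        raise ValueError("gene set has no members in the matrix")
    if missing:
        logger.warning(
            "module_score: %d set genes absent from the matrix", len(missing)
        )
    X = cell_expr.to_numpy(dtype=float)
    mean_expr = X.mean(axis=0)
    # equal-occupancy bins on average expression; ties and pools are ordered
    # by gene name so results do not depend on input gene order
    names = np.asarray(genes, dtype=object)
    order = np.lexsort((names, mean_expr))
    bin_of = np.empty(len(genes), dtype=int)
    bin_of[order] = np.minimum(
        (np.arange(len(genes)) * params.n_bins) // len(genes), params.n_bins - 1
    )
    bins: dict[int, np.ndarray] = {}
    for b in range(params.n_bins):
        members = np.flatnonzero(bin_of == b)
        bins[b] = members[np.argsort(names[members], kind="mergesort")]
    rng = np.random.default_rng(params.seed)
    control_idx: list[np.ndarray] = []
    for g in present:
        b = bin_of[gene_pos[g]]
        pool = bins[b]
        pool = pool[pool != gene_pos[g]]
        if pool.size == 0:
            continue
        if pool.size >= params.n_control_per_gene:
            chosen = rng.choice(pool, size=params.n_control_per_gene, replace=False)
        else:
            logger.info(
                "module_score: bin %d has %d genes; sampling controls with "
                "replacement",
                b,
                pool.size,
            )
            chosen = rng.choice(pool, size=params.n_control_per_gene, replace=True)
        control_idx.append(chosen)
    set_idx = np.array([gene_pos[g] for g in present], dtype=int)
    set_mean = X[:, set_idx].mean(axis=1)
    if control_idx:
        pooled = np.concatenate(control_idx)
        control_mean = X[:, pooled].mean(axis=1)
    else:
        control_mean = np.zeros(X.shape[0])
    return pd.Series(set_mean - control_mean, index=cell_expr.index, name="score")


def aggregate_by_group(scores: pd.Series, labels: pd.Series) -> pd.DataFrame:
    """Per-group mean, median and rank of module scores.

    ``labels`` maps every cell to its group (e.g. cell type); empty groups
    are excluded with a warning.  Sorted by mean score descending; ``rank``
    is 1 for the highest-scoring group.
    """
    missing = scores.index.difference(labels.index)
    if len(missing):
        raise ValueError(f"cells without labels: {list(missing[:5])}")
    lab = labels.loc[scores.index]
    grouped = scores.groupby(lab, observed=True)
    table = pd.DataFrame(
        {
            "group": grouped.mean().index,
            "mean": grouped.mean().to_numpy(),
            "median": grouped.median().to_numpy(),
            "n_cells": grouped.size().to_numpy(),
        }
    )
    empty = set(labels.unique()) - set(table["group"])
    if empty:
        logger.warning("aggregate_by_group: empty groups excluded: %s", sorted(empty))
    table = table.sort_values(
        ["mean", "group"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table
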