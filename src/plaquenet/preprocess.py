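"""Count correction, depth normalization and quality filters for bulk UMI counts.

The bulk protocol tags each transcript molecule with one of ``B = 4096``
unique molecular identifier (UMI) barcodes.  When many molecules of the same
gene are present, distinct molecules collide on the same barcode and the raw
barcode count undercounts the true molecule number.  Under uniform random
barcode assignment the expected number of observed barcodes for ``t`` true
molecules is ``B * (1 - exp(-t/B))``; inverting gives the saturation
correction applied to every raw count ``r``::

    corrected = -B * ln(1 - r / B)

Corrected counts are depth-normalized (each sample scaled to the median
sample depth) and log-transformed with ``log(1 + x)``.  Quality control
removes samples with fewer than 10 000 detected genes or fewer than 18 000
total reads, and genes whose mean count per sample is not strictly above 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "UMICorrectionParams",
    "QCThresholds",
    "correct_umi_counts",
    "normalize_and_log",
    "filter_genes",
    "filter_samples",
    "preprocess_counts",
]


@dataclass(frozen=True)
class UMICorrectionParams:
    """Parameters of the UMI saturation correction."""

    barcode_space: int = 4096

    def __post_init__(self) -> None:
        if self.barcode_space <= 0:
            raise ValueError("barcode_space must be positive")


@dataclass(frozen=True)
class QCThresholds:
    """Sample- and gene-level quality-control thresholds.

    ``min_genes_per_sample`` and ``min_reads_per_sample`` are inclusive
    (a sample exactly at the threshold passes); ``min_mean_count_per_gene``
    is exclusive (a gene with mean exactly at the threshold is removed).
    """

    min_genes_per_sample: int = 10_000
    min_reads_per_sample: int = 18_000
    min_mean_count_per_gene: float = 1.0

    def __post_init__(self) -> None:
        if (
            self.min_genes_per_sample < 0
            or self.min_reads_per_sample < 0
            or self.min_mean_count_per_gene < 0
        ):
            raise ValueError("QC thresholds must be nonnegative")


def correct_umi_counts(
    raw: pd.DataFrame, params: UMICorrectionParams | None = None
) -> pd.DataFrame:
    """Invert UMI barcode saturation: ``c = -B * ln(1 - r/B)``.

    Strictly increasing and convex in the raw count; ``c >= r`` with equality
    only at 0.  A raw count at or above the barcode space ``B`` is impossible
    under the sampling model and raises.
    """
    params = params or UMICorrectionParams()
    B = float(params.barcode_space)
    values = raw.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValueError("raw counts must be nonnegative")
    saturated = np.argwhere(values >= B)
    if saturated.size:
        i, j = saturated[0]
        raise ValueError(
            f"raw count {values[i, j]} at gene {raw.index[i]!r}, sample "
            f"{raw.columns[j]!r} is >= barcode space {params.barcode_space}; "
            "the saturation correction is undefined at or beyond saturation"
        )
    corrected = -B * np.log1p(-values / B)
    return pd.DataFrame(corrected, index=raw.index, columns=raw.columns)


def normalize_and_log(mat: pd.DataFrame) -> pd.DataFrame:
    """Scale every sample to the median sample depth, then apply log1p."""
    values = mat.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValueError("expected nonnegative entries")
    depths = values.sum(axis=0)
    zero = np.flatnonzero(depths == 0)
    if zero.size:
        raise ValueError(
            f"all-zero samples cannot be depth-normalized: {list(mat.columns[zero])}"
        )
    target = np.median(depths)
    scaled = values * (target / depths)
    return pd.DataFrame(np.log1p(scaled), index=mat.index, columns=mat.columns)


def filter_genes(
    mat: pd.DataFrame, thresholds: QCThresholds | None = None
) -> pd.DataFrame:
    """Keep genes whose mean count per sample is strictly above the threshold."""
    thresholds = thresholds or QCThresholds()
    means = mat.to_numpy(dtype=float).mean(axis=1)
    keep = means > thresholds.min_mean_count_per_gene
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("filter_genes: removed %d of %d genes", n_removed, len(mat))
    if not keep.any():
        logger.warning("filter_genes: no genes pass the mean-count threshold")
    return mat.loc[keep]


def filter_samples(
    mat: pd.DataFrame, thresholds: QCThresholds | None = None
) -> pd.DataFrame:
    """Keep samples with enough detected genes and enough total reads.

    A gene is "detected" in a sample when its count is > 0.  Both cuts are
    exclusive removals: equality with the threshold passes.
    """
    thresholds = thresholds or QCThresholds()
    values = mat.to_numpy(dtype=float)
    detected = (values > 0).sum(axis=0)
    reads = values.sum(axis=0)
    keep = (detected >= thresholds.min_genes_per_sample) & (
        reads >= thresholds.min_reads_per_sample
    )
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info(
            "filter_samples: removed %d of %d samples", n_removed, mat.shape[1]
        )
    return mat.loc[:, keep]


def preprocess_counts(
    raw: pd.DataFrame,
    umi_params: UMICorrectionParams | None = None,
    thresholds: QCThresholds | None = None,
) -> pd.DataFrame:
    """Full preprocessing chain on a raw gene x sample count matrix.

    Order: UMI correction -> sample filter -> gene filter -> depth
    normalization + log1p.  The sample filter uses the *raw* counts (detected
    genes and read totals are library properties), the gene filter the
    corrected counts.
    """
    umi_params = umi_params or UMICorrectionParams()
    thresholds = thresholds or QCThresholds()
    corrected = correct_umi_counts(raw, umi_params)
    kept_samples = filter_samples(raw, thresholds).columns
    corrected = corrected.loc[:, kept_samples]
    corrected = filter_genes(corrected, thresholds)
    if corrected.empty:
        raise ValueError("no genes or samples survive quality control")
    return normalize_and_log(corrected)
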