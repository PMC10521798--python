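"""Readers, writers and run configuration.

Formats: dense TSV gene x sample matrices, MatrixMarket triples (matrix +
gene list + sample list), GMT gene sets, BED-like locus intervals (0-based
half-open) with a gene-coordinate table, and plain-TSV result tables whose
header comment records the config hash and seed for audit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "read_expression",
    "write_expression",
    "read_gene_sets",
    "write_gene_sets",
    "read_loci",
    "read_table",
    "write_table",
]


@dataclass
class RunConfig:
    """Run-level configuration; defaults are the published analysis settings.

    Soft-threshold grid 2..30 with scale-free R^2 cutoff 0.8 and median
    connectivity below 100; tree cut deepSplit 3, minimum module size 20; 20
    permutations with KD significance at FDR < 0.1.
    """

    seed: int = 0
    power_grid: list[int] = field(default_factory=lambda: list(range(2, 31)))
    power: int | None = None
    r2_cutoff: float = 0.8
    median_k_max: float = 100.0
    deep_split: int = 3
    min_cluster_size: int = 20
    n_permutations: int = 20
    fdr_threshold: float = 0.1
    bias_alpha: float = 0.05
    overlap_alpha: float = 0.05
    gwas_alpha: float = 0.05
    barcode_space: int = 4096
    paths: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("r2_cutoff", "fdr_threshold", "bias_alpha",
                     "overlap_alpha", "gwas_alpha"):
            value = getattr(self, name)
            if not 0.0 < value < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {value}")
        grid = self.power_grid
        if (
            not grid
            or any(int(g) != g or g <= 0 for g in grid)
            or sorted(set(grid)) != list(grid)
        ):
            raise ValueError("power_grid must be strictly increasing positive integers")
        if self.deep_split not in (0, 1, 2, 3, 4):
            raise ValueError("deep_split must be in 0..4")
        if self.min_cluster_size < 1 or self.n_permutations < 1:
            raise ValueError("counts must be positive")
        if self.median_k_max <= 0 or self.barcode_space <= 0:
            raise ValueError("median_k_max and barcode_space must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def digest(self) -> str:
        """Stable short hash of the configuration, recorded in every output."""
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def _check_unique(values: pd.Index, what: str) -> None:
    if values.has_duplicates:
        dups = values[values.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what} identifiers: {dups[:10]}")


def read_expression(
    path: str | Path, format: str = "tsv", count_mode: bool = False
) -> pd.DataFrame:
    """Read a gene x sample matrix.

    ``tsv``: genes as rows with a header of sample names.  ``mtx``: a
    MatrixMarket file ``<path>`` with sidecars ``<stem>.genes.txt`` and
    ``<stem>.samples.txt`` (one identifier per line).  With ``count_mode``
    negative entries are rejected.
    """
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    elif format == "mtx":
        matrix = np.asarray(mmread(str(path)).todense(), dtype=float)
        stem = path.with_suffix("")
        genes = stem.with_suffix(".genes.txt").read_text().split()
        samples = stem.with_suffix(".samples.txt").read_text().split()
        if matrix.shape != (len(genes), len(samples)):
            raise ValueError(
                f"MTX dimension mismatch: matrix {matrix.shape} vs "
                f"{len(genes)} genes x {len(samples)} samples"
            )
        df = pd.DataFrame(matrix, index=genes, columns=samples)
    else:
        raise ValueError(f"unknown format {format!r}")
    _check_unique(df.index, "gene")
    _check_unique(df.columns, "sample")
    if count_mode and (df.to_numpy() < 0).any():
        raise ValueError("negative entries in count-mode matrix")
    return df


def write_expression(
    mat: pd.DataFrame, path: str | Path, format: str = "tsv"
) -> None:
    """Write a gene x sample matrix as TSV or a MatrixMarket triple."""
    path = Path(path)
    if format == "tsv":
        mat.to_csv(path, sep="\t", float_format="%.10g")
    elif format == "mtx":
        mmwrite(str(path), csr_matrix(mat.to_numpy(dtype=float)))
        stem = path.with_suffix("")
        stem.with_suffix(".genes.txt").write_text("\n".join(mat.index) + "\n")
        stem.with_suffix(".samples.txt").write_text("\n".join(mat.columns) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gene_sets(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file: name, description, then tab-separated members.

    Duplicate members within a set are deduplicated (order preserved,
    logged); empty sets and malformed lines raise with the line number.
    """
    sets: dict[str, list[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(
                f"{path}:{lineno}: malformed GMT line (<3 fields)"
            )
        name = fields[0]
        members = [m for m in fields[2:] if m]
        if not members:
            raise ValueError(f"{path}:{lineno}: empty gene set {name!r}")
        unique = list(dict.fromkeys(members))
        if len(unique) < len(members):
            logger.info(
                "read_gene_sets: set %s had %d duplicate members",
                name,
                len(members) - len(unique),
            )
        if name in sets:
            raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
        sets[name] = unique
    return sets


def write_gene_sets(sets: dict[str, list[str]], path: str | Path) -> None:
    lines = [
        "\t".join([name, "na", *members]) for name, members in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# loci (BED-like, 0-based half-open)
# ---------------------------------------------------------------------------

def read_loci(path: str | Path, gene_coords: pd.DataFrame) -> set[str]:
    """Genes overlapping any locus interval.

    The BED-like file has columns chrom, start, end (0-based half-open, no
    header); ``gene_coords`` is indexed by gene with columns ``chrom``,
    ``start``, ``end`` in the same convention.  Two half-open intervals
    overlap iff ``start_a < end_b and start_b < end_a``.
    """
    loci = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end"], usecols=[0, 1, 2],
    )
    bad = loci[loci["start"] >= loci["end"]]
    if len(bad):
        row = bad.iloc[0]
        raise ValueError(
            f"locus with start >= end: {row['chrom']}:{row['start']}-{row['end']}"
        )
    for col in ("chrom", "start", "end"):
        if col not in gene_coords.columns:
            raise ValueError(f"gene_coords missing column {col!r}")
    hits: set[str] = set()
    for chrom, group in loci.groupby("chrom"):
        genes = gene_coords[gene_coords["chrom"] == chrom]
        if genes.empty:
            continue
        gs = genes["start"].to_numpy()
        ge = genes["end"].to_numpy()
        for _, locus in group.iterrows():
            overlap = (gs < locus["end"]) & (locus["start"] < ge)
            hits.update(genes.index[overlap])
    return hits


# ---------------------------------------------------------------------------
# audited result tables
# ---------------------------------------------------------------------------

def write_table(
    df: pd.DataFrame, path: str | Path, config: RunConfig | None = None
) -> None:
    """Write a result table as TSV with an audit header comment."""
    path = Path(path)
    header = ""
    if config is not None:
        header = f"# config_hash={config.digest()} seed={config.seed}\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
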