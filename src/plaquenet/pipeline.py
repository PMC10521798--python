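"""End-to-end orchestration: preprocess, build, compare, drive, prioritize.

The pipeline runs the sex-stratified analysis on two expression matrices
(stratum A is the focal stratum).  Outputs are plain TSV tables whose header
comment records the configuration hash and seed; given identical inputs,
configuration and seed the outputs are byte-identical.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .diffconn import StratifiedConnectivityTest
from .io import RunConfig, read_expression, read_gene_sets, read_loci, write_table
from .keydrivers import KeyDriverAnalysis, StructureSearchParams
from .network import CoexpressionNetwork
from .preprocess import QCThresholds, UMICorrectionParams, preprocess_counts
from .prioritize import gene_set_overlap_test, gwas_loci_enrichment, prioritize_modules

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


@_stage("load")
def _load_stratum(config: RunConfig, key: str) -> pd.DataFrame:
    paths = config.paths
    if f"counts_{key}" in paths:
        raw = read_expression(paths[f"counts_{key}"], count_mode=True)
        return preprocess_counts(
            raw,
            UMICorrectionParams(barcode_space=config.barcode_space),
            QCThresholds(),
        )
    if f"expr_{key}" in paths:
        return read_expression(paths[f"expr_{key}"])
    raise ValueError(f"config.paths needs counts_{key} or expr_{key}")


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict[str, Path]:
    """Run every stage and write the report bundle under ``out_dir``.

    Expected ``config.paths`` keys: ``counts_a``/``expr_a`` and
    ``counts_b``/``expr_b`` (strata), optional ``reference_gmt`` (reference
    gene sets for the overlap criterion), optional ``loci_bed`` +
    ``gene_coords`` (GWAS loci).  Returns a mapping of output names to
    written files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    expr_a = _load_stratum(config, "a")
    expr_b = _load_stratum(config, "b")
    shared = expr_a.index.intersection(expr_b.index)
    expr_a, expr_b = expr_a.loc[shared], expr_b.loc[shared]

    @_stage("netbuild")
    def _netbuild():
        model = CoexpressionNetwork(
            expr_a,
            power=config.power,
            power_grid=config.power_grid,
            r2_cutoff=config.r2_cutoff,
            median_k_max=config.median_k_max,
            deep_split=config.deep_split,
            min_cluster_size=config.min_cluster_size,
        )
        return model.fit()

    results = _netbuild()
    modules = results.partition.modules
    outputs: dict[str, Path] = {}

    def _emit(name: str, df: pd.DataFrame) -> None:
        path = out / f"{name}.tsv"
        write_table(df, path, config)
        outputs[name] = path

    _emit(
        "modules",
        pd.DataFrame(
            {"gene": results.partition.labels.index,
             "module": results.partition.labels.to_numpy()}
        ),
    )
    if results.soft_threshold is not None:
        _emit("soft_threshold", results.soft_threshold.table)
    eigs = results.eigengenes.reset_index()
    _emit("eigengenes", eigs)

    @_stage("diffconn")
    def _diffconn() -> pd.DataFrame:
        test = StratifiedConnectivityTest(
            expr_a, expr_b, modules, beta=results.power,
            bias_alpha=config.bias_alpha,
        )
        return test.fit()

    bias = _diffconn()
    _emit("bias", bias)

    @_stage("keydrivers")
    def _keydrivers() -> pd.DataFrame:
        kda = KeyDriverAnalysis(
            expr_a,
            modules,
            universe=list(expr_a.index),
            params=StructureSearchParams(),
            n_permutations=config.n_permutations,
            fdr_threshold=config.fdr_threshold,
            seed=config.seed,
        )
        return kda.fit()

    _emit("key_drivers", _keydrivers())

    @_stage("prioritize")
    def _prioritize() -> pd.DataFrame:
        universe = set(expr_a.index)
        reference: set[str] = set()
        if "reference_gmt" in config.paths:
            sets = read_gene_sets(config.paths["reference_gmt"])
            reference = set().union(*sets.values()) & universe
        locus_genes: set[str] = set()
        if "loci_bed" in config.paths and "gene_coords" in config.paths:
            coords = pd.read_csv(
                config.paths["gene_coords"], sep="\t", index_col=0
            )
            locus_genes = read_loci(config.paths["loci_bed"], coords) & universe
        overlap_p = {
            m: gene_set_overlap_test(g, reference, universe) if reference else 1.0
            for m, g in modules.items()
        }
        gwas_p = {
            m: gwas_loci_enrichment(g, locus_genes, universe) if locus_genes else 1.0
            for m, g in modules.items()
        }
        report = prioritize_modules(
            bias, overlap_p, gwas_p,
            overlap_alpha=config.overlap_alpha, gwas_alpha=config.gwas_alpha,
        )
        return report.table

    _emit("prioritization", _prioritize())
    logger.info("pipeline complete: %d outputs in %s", len(outputs), out)
    return outputs
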