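"""Synthetic data with planted ground truth for the whole pipeline.

Bulk expression is generated from a single-latent-factor model per module:
for module ``m`` each sample carries a factor ``f_m ~ N(0, 1)`` and gene
``g`` in ``m`` is::

    x_g = lambda_g * f_m + sqrt(1 - lambda_g^2) * eps,   eps ~ N(0, 1)

so every gene has unit variance and the population correlation of two genes
in the same module is exactly ``lambda_i * lambda_j`` — a closed-form truth
that the recovery tests lean on.  Background genes are pure noise.  The two
strata share the factor structure but stratum A's loadings are multiplied by
a connectivity multiplier (clipped at 1), emulating a sex-biased increase in
module coherence.  Hub genes get a boosted loading, emulating key drivers.

Also provided: the UMI barcode-saturation map (the exact inverse of the
correction in :mod:`plaquenet.preprocess`), traits correlated with a module
factor, linear-Gaussian data from a user-specified DAG, and a
negative-binomial single-cell matrix in which designated cell types
over-express designated module gene sets.

All generators are deterministic given their seed and return a
:class:`SyntheticTruth` sidecar describing what was planted.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationDesign",
    "SyntheticTruth",
    "generate_two_strata_expression",
    "saturate_umi",
    "generate_trait",
    "generate_dag_data",
    "generate_single_cell",
]

BACKGROUND = "background"


@dataclass(frozen=True)
class SimulationDesign:
    """Study-scale defaults for the two-stratum bulk simulation.

    The defaults mirror the matched carotid-plaque cohort design at round
    numbers: 150 samples per stratum, five planted modules of 60 genes
    (comfortably above the minimum module size of 20) on a background of
    300 unstructured genes, base loading 0.6 (mean within-module correlation
    0.36), one hub per module with loading 0.9, and a 1.5-fold loading
    multiplier in stratum A producing the planted connectivity bias.

    ``loading_spread`` scatters per-gene loadings uniformly around the base
    (default 0.15): genes in real coexpression modules vary in membership
    strength, and that heterogeneity is what gives the connectivity
    distribution its heavy tail (approximate scale-free topology).  Set it
    to 0 for the exchangeable-gene model with closed-form correlations
    ``lambda_i * lambda_j`` all equal.
    """

    n_modules: int = 5
    genes_per_module: int = 60
    n_background_genes: int = 300
    n_samples_per_stratum: int = 150
    base_loading: float = 0.6
    loading_spread: float = 0.15
    stratum_a_multiplier: float = 1.5
    hubs_per_module: int = 1
    hub_loading: float = 0.9
    noise_sd: float = 1.0
    trait_target_r: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.base_loading <= 1.0 or not 0.0 < self.hub_loading <= 1.0:
            raise ValueError("loadings must lie in (0, 1]")
        if self.loading_spread < 0 or self.base_loading - self.loading_spread <= 0:
            raise ValueError("loading_spread must keep loadings in (0, 1]")
        if self.stratum_a_multiplier <= 0:
            raise ValueError("multiplier must be positive")
        if min(self.n_modules, self.genes_per_module, self.n_samples_per_stratum) <= 0:
            raise ValueError("design counts must be positive")


@dataclass
class SyntheticTruth:
    """What was planted: memberships, hubs, loadings, coefficients, seed."""

    module_map: dict[str, str]
    hubs: list[str] = field(default_factory=list)
    loadings: pd.DataFrame | None = None  # gene x [stratum_a, stratum_b]
    trait_coefficients: dict[str, float] = field(default_factory=dict)
    dag_edges: list[tuple[str, str, float]] = field(default_factory=list)
    seed: int = 0

    def module_labels(self, genes: list[str]) -> pd.Series:
        return pd.Series([self.module_map[g] for g in genes], index=genes)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "module_map": self.module_map,
            "hubs": self.hubs,
            "loadings": None
            if self.loadings is None
            else self.loadings.round(10).to_dict(orient="index"),
            "trait_coefficients": self.trait_coefficients,
            "dag_edges": [[a, b, c] for a, b, c in self.dag_edges],
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _module_name(i: int) -> str:
    return f"M{i + 1}"


def generate_two_strata_expression(
    design: SimulationDesign,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Two gene x sample matrices (strata A and B) with planted modules.

    Stratum A loadings are ``min(1, multiplier * lambda)``; a warning is
    logged when clipping occurs.  Hub genes take ``hub_loading`` as their
    base loading.  Matrices share the gene index; samples are disjoint.
    """
    rng = np.random.default_rng(design.seed)
    n_mod_genes = design.n_modules * design.genes_per_module
    n_genes = n_mod_genes + design.n_background_genes
    genes = [f"g{i + 1:04d}" for i in range(n_genes)]
    module_map: dict[str, str] = {}
    hubs: list[str] = []
    lam_b = np.zeros(n_genes)
    for m in range(design.n_modules):
        start = m * design.genes_per_module
        for j in range(design.genes_per_module):
            g = genes[start + j]
            module_map[g] = _module_name(m)
            if j < design.hubs_per_module:
                hubs.append(g)
                lam_b[start + j] = design.hub_loading
            else:
                lam_b[start + j] = np.clip(
                    design.base_loading
                    + design.loading_spread * rng.uniform(-1.0, 1.0),
                    1e-3,
                    1.0,
                )
    for g in genes[n_mod_genes:]:
        module_map[g] = BACKGROUND
    lam_a = lam_b * design.stratum_a_multiplier
    if np.any(lam_a > 1.0):
        logger.warning(
            "generate_two_strata_expression: %d stratum-A loadings clipped to 1",
            int((lam_a > 1.0).sum()),
        )
        lam_a = np.minimum(lam_a, 1.0)

    def _stratum(lam: np.ndarray, prefix: str) -> pd.DataFrame:
        n = design.n_samples_per_stratum
        factors = rng.standard_normal((design.n_modules, n))
        X = np.empty((n_genes, n))
        for i, g in enumerate(genes):
            eps = rng.standard_normal(n) * design.noise_sd
            if i < n_mod_genes:
                m = i // design.genes_per_module
                X[i] = lam[i] * factors[m] + np.sqrt(1.0 - lam[i] ** 2) * eps
            else:
                X[i] = eps
        samples = [f"{prefix}{s + 1:03d}" for s in range(n)]
        df = pd.DataFrame(X, index=genes, columns=samples)
        df.attrs["factors"] = pd.DataFrame(
            factors,
            index=[_module_name(m) for m in range(design.n_modules)],
            columns=samples,
        )
        return df

    expr_a = _stratum(lam_a, "A")
    expr_b = _stratum(lam_b, "B")
    loadings = pd.DataFrame(
        {"stratum_a": lam_a, "stratum_b": lam_b}, index=genes
    )
    truth = SyntheticTruth(
        module_map=module_map, hubs=hubs, loadings=loadings, seed=design.seed
    )
    return expr_a, expr_b, truth


def saturate_umi(
    true_counts: pd.DataFrame | np.ndarray, barcode_space: int = 4096
) -> pd.DataFrame | np.ndarray:
    """Forward UMI barcode-collision map: ``r = round(B * (1 - exp(-t/B)))``.

    The exact inverse of the saturation correction; ``r < B`` always.
    """
    B = float(barcode_space)
    values = np.asarray(true_counts, dtype=float)
    if np.any(values < 0):
        raise ValueError("true counts must be nonnegative")
    raw = np.rint(B * -np.expm1(-values / B))
    raw = np.minimum(raw, B - 1)  # rounding may not cross the asymptote
    if isinstance(true_counts, pd.DataFrame):
        return pd.DataFrame(
            raw, index=true_counts.index, columns=true_counts.columns
        )
    return raw


def generate_trait(
    factor: pd.Series | np.ndarray, target_r: float, seed: int
) -> np.ndarray:
    """A trait with population correlation ``target_r`` to a latent factor.

    ``trait = r * z(f) + sqrt(1 - r^2) * noise``; at |r| = 1 the trait is
    exactly proportional to the factor.
    """
    if not -1.0 <= target_r <= 1.0:
        raise ValueError("target correlation must lie in [-1, 1]")
    f = np.asarray(factor, dtype=float)
    z = (f - f.mean()) / f.std()
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(f.size)
    return target_r * z + np.sqrt(1.0 - target_r**2) * noise


def generate_dag_data(
    edges: list[tuple[str, str, float]],
    n: int,
    seed: int,
    nodes: list[str] | None = None,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Linear-Gaussian structural-equation data from a DAG.

    Each node is the coefficient-weighted sum of its parents plus unit
    Gaussian noise, evaluated in topological order.  Raises on cycles.
    Returns a gene x sample matrix (nodes as rows).
    """
    import networkx as nx

    g = nx.DiGraph()
    if nodes:
        g.add_nodes_from(nodes)
    for a, b, c in edges:
        g.add_edge(a, b, coef=float(c))
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("edge list contains a cycle")
    order = list(nx.topological_sort(g))
    rng = np.random.default_rng(seed)
    data: dict[str, np.ndarray] = {}
    for node in order:
        x = rng.standard_normal(n)
        for parent in g.predecessors(node):
            x = x + g.edges[parent, node]["coef"] * data[parent]
        data[node] = x
    all_nodes = nodes if nodes else order
    expr = pd.DataFrame(
        {node: data[node] for node in all_nodes},
        index=[f"s{i + 1:04d}" for i in range(n)],
    ).T
    truth = SyntheticTruth(
        module_map={node: "dag" for node in all_nodes},
        dag_edges=[(a, b, float(c)) for a, b, c in edges],
        seed=seed,
    )
    return expr, truth


def generate_single_cell(
    cell_types: dict[str, int],
    module_genes: dict[str, list[str]],
    programs: dict[str, dict[str, float]],
    n_background_genes: int = 100,
    base_mean: float = 1.0,
    dispersion: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, SyntheticTruth]:
    """Cell x gene negative-binomial counts with cell-type module programs.

    ``programs[cell_type][module]`` multiplies the base mean of that module's
    genes in cells of that type.  Dispersion is the negative-binomial
    overdispersion phi (variance = mu + phi * mu^2).  Returns the count
    matrix (cells as rows), per-cell type labels, and the planted truth.
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    rng = np.random.default_rng(seed)
    genes: list[str] = []
    module_map: dict[str, str] = {}
    for mod, members in module_genes.items():
        for gene in members:
            if gene in module_map:
                raise ValueError(f"gene {gene!r} assigned to two modules")
            genes.append(gene)
            module_map[gene] = mod
    for i in range(n_background_genes):
        gene = f"bg{i + 1:04d}"
        genes.append(gene)
        module_map[gene] = BACKGROUND
    cells, labels = [], []
    for ctype, count in cell_types.items():
        for j in range(len(labels), len(labels) + count):
            cells.append(f"c{j + 1:05d}")
            labels.append(ctype)
    size = 1.0 / dispersion  # NB shape parameter
    counts = np.empty((len(cells), len(genes)), dtype=np.int64)
    mu_by_type = {}
    for ctype in cell_types:
        mu = np.full(len(genes), base_mean)
        for gi, gene in enumerate(genes):
            mod = module_map[gene]
            mult = programs.get(ctype, {}).get(mod, 1.0)
            mu[gi] = base_mean * mult
        mu_by_type[ctype] = mu
    for ci, ctype in enumerate(labels):
        mu = mu_by_type[ctype]
        p = size / (size + mu)
        counts[ci] = rng.negative_binomial(size, p)
    matrix = pd.DataFrame(counts, index=cells, columns=genes)
    label_series = pd.Series(labels, index=cells, name="cell_type")
    truth = SyntheticTruth(module_map=module_map, seed=seed)
    return matrix, label_series, truth
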