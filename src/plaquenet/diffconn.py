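"""Stratified "network activity": intramodular connectivity per stratum and
the sex-bias test.

A module's activity in a stratum is summarized by its genes' intramodular
connectivity: each stratum's expression, restricted to the module's genes,
is turned into a signed adjacency at the shared soft power, and each gene's
connectivity is the sum of its adjacency weights within the module.  The
bias test compares the paired per-gene connectivities between strata with a
two-sided unpaired Student t test (a paired option is exposed); a module is
flagged biased toward the focal stratum A when the test is significant and
the mean connectivity is higher in A.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .network import bicor_matrix, signed_adjacency

logger = logging.getLogger(__name__)

__all__ = [
    "StratifiedConnectivity",
    "BiasResult",
    "stratified_connectivity",
    "sex_bias_test",
    "bias_table",
    "StratifiedConnectivityTest",
]


@dataclass
class StratifiedConnectivity:
    """Per-gene intramodular connectivity in two strata of one module."""

    module: str
    k_a: pd.Series
    k_b: pd.Series

    def __post_init__(self) -> None:
        if not self.k_a.index.equals(self.k_b.index):
            raise ValueError("strata must cover identical gene lists")

    @property
    def n_genes(self) -> int:
        return len(self.k_a)


@dataclass
class BiasResult:
    """Outcome of the stratum-bias test for one module."""

    module: str
    mean_k_a: float
    mean_k_b: float
    t_statistic: float
    p_value: float
    fraction_a_higher: float
    biased: bool


def stratified_connectivity(
    expr_a: pd.DataFrame,
    expr_b: pd.DataFrame,
    module_genes: list[str],
    beta: int,
    module: str = "module",
) -> StratifiedConnectivity:
    """Module-restricted connectivity of each gene in each stratum.

    Both strata use the shared soft power ``beta``; the adjacency is built
    only over the module's genes (activity of the module itself, not
    genome-wide connectivity).
    """
    missing = sorted(
        set(module_genes) - set(expr_a.index) | set(module_genes) - set(expr_b.index)
    )
    if missing:
        raise KeyError(f"module genes missing from a stratum: {missing[:10]}")
    if expr_a.shape[1] < 30 or expr_b.shape[1] < 30:
        logger.warning("stratified_connectivity: a stratum has fewer than 30 samples")

    def _k(expr: pd.DataFrame) -> pd.Series:
        sub = expr.loc[module_genes]
        adj = signed_adjacency(bicor_matrix(sub), beta).to_numpy()
        np.fill_diagonal(adj, 0.0)
        return pd.Series(adj.sum(axis=1), index=module_genes)

    return StratifiedConnectivity(module=module, k_a=_k(expr_a), k_b=_k(expr_b))


def sex_bias_test(
    sc: StratifiedConnectivity, bias_alpha: float = 0.05, paired: bool = False
) -> BiasResult:
    """Two-sided Student t test of stratum-A vs stratum-B connectivity.

    Unpaired by default (a paired alternative over the shared gene list is
    available).  ``biased`` is true when p < ``bias_alpha`` *and* the mean
    connectivity is higher in stratum A, the focal stratum.  Degenerate
    (zero-variance) comparisons are reported as not biased with a warning.
    """
    ka = sc.k_a.to_numpy(dtype=float)
    kb = sc.k_b.to_numpy(dtype=float)
    if len(ka) < 20:
        logger.warning(
            "sex_bias_test: module %s has fewer than 20 genes", sc.module
        )
    mean_a, mean_b = float(ka.mean()), float(kb.mean())
    frac = float((ka > kb).mean())
    if np.allclose(ka, ka[0]) and np.allclose(kb, kb[0]) or np.array_equal(ka, kb):
        logger.warning("sex_bias_test: degenerate connectivity in %s", sc.module)
        return BiasResult(sc.module, mean_a, mean_b, 0.0, 1.0, frac, False)
    if paired:
        res = stats.ttest_rel(ka, kb)
    else:
        res = stats.ttest_ind(ka, kb)
    t = float(res.statistic)
    p = float(res.pvalue)
    if not np.isfinite(t):
        logger.warning("sex_bias_test: undefined t statistic in %s", sc.module)
        return BiasResult(sc.module, mean_a, mean_b, 0.0, 1.0, frac, False)
    biased = bool(p < bias_alpha and mean_a > mean_b)
    return BiasResult(sc.module, mean_a, mean_b, t, p, frac, biased)


def bias_table(results: list[BiasResult]) -> pd.DataFrame:
    """Per-module bias results with a Benjamini-Hochberg column for audit.

    The bias criterion itself uses the per-module p (the flag is already set
    in each result); the adjusted column is reported for transparency only.
    """
    df = pd.DataFrame(
        [
            {
                "module": r.module,
                "mean_k_a": r.mean_k_a,
                "mean_k_b": r.mean_k_b,
                "t": r.t_statistic,
                "p": r.p_value,
                "fraction_a_higher": r.fraction_a_higher,
                "biased": r.biased,
            }
            for r in results
        ]
    )
    if len(df):
        df["p_bh"] = multipletests(df["p"], method="fdr_bh")[1]
    return df


class StratifiedConnectivityTest:
    """Model-style facade: stratified connectivity + bias test per module.

    Parameters
    ----------
    expr_a, expr_b
        Normalized gene x sample matrices of the focal stratum (A) and the
        comparison stratum (B).
    modules
        Mapping module name -> gene list (grey already excluded).
    beta
        Shared soft power.
    """

    def __init__(
        self,
        expr_a: pd.DataFrame,
        expr_b: pd.DataFrame,
        modules: dict[str, list[str]],
        beta: int,
        bias_alpha: float = 0.05,
        paired: bool = False,
    ) -> None:
        self.expr_a = expr_a
        self.expr_b = expr_b
        self.modules = modules
        self.beta = beta
        self.bias_alpha = bias_alpha
        self.paired = paired

    def fit(self) -> pd.DataFrame:
        results = []
        self.connectivities: dict[str, StratifiedConnectivity] = {}
        for name, genes in self.modules.items():
            sc = stratified_connectivity(
                self.expr_a, self.expr_b, genes, self.beta, module=name
            )
            self.connectivities[name] = sc
            results.append(sex_bias_test(sc, self.bias_alpha, paired=self.paired))
        return bias_table(results)
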