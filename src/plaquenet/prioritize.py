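"""Three-criterion module prioritization.

A module is prioritized on up to three criteria: (1) biased network activity
in the focal stratum (from the stratified-connectivity test), (2)
significant overlap of its genes with a reference gene set, and (3)
enrichment for genes inside disease-associated (GWAS) loci.  Overlap and
locus enrichment both use the one-sided hypergeometric upper-tail test
against the gene universe that entered network construction.  The number of
criteria met maps onto a tier color: 0 -> none, 1 -> yellow, 2 -> orange,
3 -> red.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

__all__ = [
    "gene_set_overlap_test",
    "gwas_loci_enrichment",
    "prioritize_modules",
    "PrioritizationReport",
    "TIER_COLORS",
]

TIER_COLORS = {0: "none", 1: "yellow", 2: "orange", 3: "red"}


def gene_set_overlap_test(
    module_genes: set[str] | list[str],
    reference: set[str] | list[str],
    universe: set[str] | list[str],
) -> float:
    """One-sided hypergeometric upper-tail p for a gene-set overlap.

    ``P(X >= k)`` for the observed overlap ``k`` when ``n = |module|`` genes
    are drawn without replacement from a universe of ``N`` genes containing
    ``K = |reference|`` successes.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    module = set(module_genes)
    ref = set(reference)
    outside = (module | ref) - universe
    if outside:
        raise ValueError(
            f"genes outside the universe: {sorted(outside)[:10]}"
        )
    k = len(module & ref)
    return float(stats.hypergeom.sf(k - 1, len(universe), len(ref), len(module)))


def gwas_loci_enrichment(
    module_genes: set[str] | list[str],
    locus_genes: set[str] | list[str],
    universe: set[str] | list[str],
) -> float:
    """Enrichment of a module for genes inside GWAS loci.

    Identical machinery to :func:`gene_set_overlap_test` with the locus gene
    set (from interval overlap of loci with gene coordinates) as reference.
    """
    return gene_set_overlap_test(module_genes, locus_genes, universe)


@dataclass
class PrioritizationReport:
    """Tiered per-module prioritization table."""

    table: pd.DataFrame
    overlap_alpha: float
    gwas_alpha: float

    def summary(self) -> str:
        lines = ["Module prioritization", "====================="]
        for _, row in self.table.iterrows():
            lines.append(
                f"  {row['module']:<14s} criteria {row['criteria_met']}/3"
                f"  tier {row['tier']:<7s} (bias p={row['bias_p']:.3g}, "
                f"overlap p={row['overlap_p']:.3g}, gwas p={row['gwas_p']:.3g})"
            )
        return "\n".join(lines)


def prioritize_modules(
    bias: pd.DataFrame,
    overlap_p: dict[str, float],
    gwas_p: dict[str, float],
    overlap_alpha: float = 0.05,
    gwas_alpha: float = 0.05,
) -> PrioritizationReport:
    """Combine the three criteria into the tiered ranking.

    Parameters
    ----------
    bias
        Per-module bias table with columns ``module``, ``p``, ``biased``.
    overlap_p, gwas_p
        Per-module hypergeometric p-values for the reference-set overlap and
        the GWAS-locus enrichment.  All three inputs must cover the same
        module set.
    """
    modules = list(bias["module"])
    for name, mapping in (("overlap", overlap_p), ("gwas", gwas_p)):
        missing = [m for m in modules if m not in mapping]
        if missing:
            raise ValueError(f"modules missing from {name} p-values: {missing}")
    rows = []
    for _, brow in bias.iterrows():
        mod = brow["module"]
        met = (
            int(bool(brow["biased"]))
            + int(overlap_p[mod] < overlap_alpha)
            + int(gwas_p[mod] < gwas_alpha)
        )
        rows.append(
            {
                "module": mod,
                "bias_p": float(brow["p"]),
                "biased": bool(brow["biased"]),
                "overlap_p": float(overlap_p[mod]),
                "gwas_p": float(gwas_p[mod]),
                "criteria_met": met,
                "tier": TIER_COLORS[met],
            }
        )
    table = (
        pd.DataFrame(rows)
        .sort_values(["criteria_met", "bias_p"], ascending=[False, True],
                     kind="mergesort")
        .reset_index(drop=True)
    )
    return PrioritizationReport(
        table=table, overlap_alpha=overlap_alpha, gwas_alpha=gwas_alpha
    )
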