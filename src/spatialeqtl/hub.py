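"""Second-pass discovery of the co-regulated gene hub.

Every variant with a significant first-pass association to the focal gene
is re-mapped spatially against *all* annotated genes (same contact set) and
re-tested; the second pass forms its own Benjamini-Hochberg family.  The
hub is the set of genes, excluding the focal gene itself, with at least one
significant second-pass association — genes sharing regulatory variants
with the focal gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from .digest import FragmentLibrary
from .eqtl import SpatialEQTL, SpatialEQTLResults
from .spatial import CIS_WINDOW_DEFAULT, map_spatial_pairs

__all__ = ["HubResult", "second_pass", "summarize_hub"]

logger = logging.getLogger(__name__)


@dataclass
class HubResult:
    """Hub of genes co-regulated with the focal gene.

    ``results`` is the full second-pass association table (the focal gene's
    own re-tests included); ``hub_genes`` excludes the focal gene.
    """

    focal_gene: str
    results: SpatialEQTLResults
    hub_genes: list[str]
    summary_table: pd.DataFrame
    edges: pd.DataFrame

    def summary(self) -> str:
        lines = [
            f"Co-regulation hub around {self.focal_gene}",
            "=" * 48,
            f"second-pass tests     {self.results.n_tests}",
            f"hub genes (excl. focal) {len(self.hub_genes)}",
        ]
        if len(self.summary_table):
            lines += ["", self.summary_table.to_string(index=False)]
        return "\n".join(lines)

    def to_tsv(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        self.summary_table.to_csv(outdir / "hub_summary.tsv", sep="\t", index=False)
        self.edges.to_csv(outdir / "hub_edges.tsv", sep="\t", index=False)


def second_pass(
    significant_variants: list[str],
    variants: pd.DataFrame,
    genes: pd.DataFrame,
    fragment_library: FragmentLibrary,
    contacts: pd.DataFrame,
    genotypes: pd.DataFrame,
    expression_by_tissue: Mapping[str, pd.DataFrame],
    focal_gene: str,
    maf_min: float = 0.05,
    alpha: float = 0.05,
    cis_window: int = CIS_WINDOW_DEFAULT,
) -> HubResult:
    """Re-map and re-test the focal gene's significant regulators genome-wide."""
    if not significant_variants:
        logger.info("no significant first-pass variants; hub is empty")
        empty = SpatialEQTL(
            pd.DataFrame(columns=["rsid", "gene_id", "category", "distance",
                                  "n_libraries", "libraries"]),
            genotypes, expression_by_tissue, maf_min=maf_min,
        ).fit(alpha=alpha)
        return HubResult(focal_gene, empty, [], _empty_summary(), _empty_edges())

    subset = variants[variants["rsid"].isin(significant_variants)]
    pairs = map_spatial_pairs(subset, genes, fragment_library, contacts,
                              cis_window=cis_window)
    model = SpatialEQTL(pairs, genotypes, expression_by_tissue, maf_min=maf_min)
    results = model.fit(alpha=alpha)  # fresh BH family for this pass
    hub_genes = sorted(set(results.significant["gene_id"]) - {focal_gene})
    summary_table, edges = summarize_hub(results, focal_gene)
    return HubResult(focal_gene, results, hub_genes, summary_table, edges)


def _empty_summary() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["gene_id", "n_snps", "categories", "tissues", "min_p_adj"]
    )


def _empty_edges() -> pd.DataFrame:
    return pd.DataFrame(columns=["rsid", "gene_id", "category", "tissue_id", "p_adj"])


def summarize_hub(
    second_pass_results: SpatialEQTLResults, focal_gene: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-hub-gene summary plus the SNP -> gene edge list for export.

    One summary row per hub gene: supporting SNP count, spatial categories
    and tissues present, minimum adjusted p.  Edges carry every significant
    (SNP, gene, tissue) triple (focal gene excluded).
    """
    sig = second_pass_results.significant
    sig = sig[sig["gene_id"] != focal_gene]
    if len(sig) == 0:
        return _empty_summary(), _empty_edges()
    edges = (
        sig[["rsid", "gene_id", "category", "tissue_id", "p_adj"]]
        .sort_values(["gene_id", "rsid", "tissue_id"])
        .reset_index(drop=True)
    )
    summary = (
        sig.groupby("gene_id")
        .agg(
            n_snps=("rsid", "nunique"),
            categories=("category", lambda s: ",".join(sorted(set(s)))),
            tissues=("tissue_id", lambda s: ",".join(sorted(set(s)))),
            min_p_adj=("p_adj", "min"),
        )
        .reset_index()
        .sort_values("gene_id")
        .reset_index(drop=True)
    )
    return summary, edges
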