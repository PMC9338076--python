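"""Gene-set statistics on the hub: motif and LoF-constraint enrichment.

Two questions about a discovered hub of co-regulated genes:

* are their promoters (TSS +/- 1 kb) enriched for a transcription-factor
  binding motif? — one-sided hypergeometric upper-tail test per motif,
  Benjamini-Hochberg across motifs;
* is the set enriched for loss-of-function-intolerant genes? — one-sided
  Fisher exact test on the 2x2 of {in set / not} x {intolerant / not},
  where intolerance is pLI >= 0.9 (gnomAD convention).  Genes with missing
  pLI are "undetermined" and counted as not-intolerant, and the study set
  stays inside the universe, which makes the test exactly hypergeometric.

LOEUF (the 90% upper bound of the observed/expected loss-of-function
ratio) is additionally reported at the conventional reference points:
< 0.35 (LoF-intolerant), < 0.63 (mean of essential genes), > 1.34 (mean of
non-essential genes).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .eqtl import bh_adjust

__all__ = [
    "EnrichmentResult",
    "promoter_windows",
    "motif_enrichment",
    "constraint_classify",
    "constraint_enrichment",
    "constraint_report",
    "round_percent",
]

PLI_INTOLERANT = 0.9
LOEUF_INTOLERANT = 0.35
LOEUF_ESSENTIAL_MEAN = 0.63
LOEUF_NONESSENTIAL_MEAN = 1.34


@dataclass(frozen=True)
class EnrichmentResult:
    """Outcome of a gene-set overrepresentation test."""

    set_size: int
    set_hits: int
    universe_size: int
    universe_hits: int
    odds_ratio: float
    p_value: float
    test_name: str
    alternative: str

    def __post_init__(self) -> None:
        if self.set_hits > self.set_size:
            raise ValueError("set_hits exceeds set_size")
        if self.universe_hits > self.universe_size:
            raise ValueError("universe_hits exceeds universe_size")
        if self.set_size > self.universe_size:
            raise ValueError("set not contained in universe")


def round_percent(hits: int, size: int) -> float:
    """hits/size as a percentage, round-half-up to one decimal."""
    if size <= 0:
        raise ValueError("size must be positive")
    pct = Decimal(hits) / Decimal(size) * 100
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def promoter_windows(genes: pd.DataFrame, half_width: int = 1000,
                     chromosome_lengths: dict[str, int] | None = None) -> pd.DataFrame:
    """Promoter interval [tss - half_width, tss + half_width) per gene.

    Strand enters only through TSS placement; windows are clipped to
    chromosome bounds when lengths are supplied.
    """
    if half_width <= 0:
        raise ValueError("half_width must be positive")
    out = genes[["gene_id", "chromosome", "tss"]].copy()
    out["promoter_start"] = (out["tss"] - half_width).clip(lower=0)
    out["promoter_end"] = out["tss"] + half_width
    if chromosome_lengths:
        limits = out["chromosome"].map(chromosome_lengths)
        out["promoter_end"] = np.minimum(out["promoter_end"], limits)
    return out[["gene_id", "chromosome", "promoter_start", "promoter_end"]]


def motif_enrichment(
    gene_set: Iterable[str], motif_table: pd.DataFrame, universe: Iterable[str]
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of promoter-motif hits, per motif.

    ``motif_table`` columns: gene_id, motif_id, hit (0/1).  Returns one row
    per motif with the hypergeometric upper-tail p and BH adjustment across
    motifs.
    """
    gene_set = set(gene_set)
    universe = set(universe)
    unknown = gene_set - universe
    if unknown:
        raise KeyError(f"gene set contains genes outside the universe: {sorted(unknown)[:5]}")
    tbl = motif_table[motif_table["gene_id"].isin(universe) & (motif_table["hit"] == 1)]
    hits_by_motif = tbl.groupby("motif_id")["gene_id"].agg(set)
    N, n = len(universe), len(gene_set)
    rows = []
    for motif_id in sorted(set(motif_table["motif_id"])):
        hit_genes = hits_by_motif.get(motif_id, set())
        K = len(hit_genes)
        k = len(gene_set & hit_genes)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((motif_id, n, k, N, K, p))
    out = pd.DataFrame(
        rows, columns=["motif_id", "set_size", "set_hits", "universe_size",
                       "universe_hits", "p_value"],
    )
    out["p_adj"] = bh_adjust(out["p_value"]) if len(out) else pd.Series(dtype=float)
    return out


def constraint_classify(pli: float | None, pli_threshold: float = PLI_INTOLERANT) -> str:
    """Tolerance class from pLI: intolerant (>= threshold), tolerant, undetermined."""
    if pli is None or (isinstance(pli, float) and np.isnan(pli)):
        return "undetermined"
    if not 0 <= pli <= 1:
        raise ValueError(f"pLI {pli} outside [0, 1]")
    return "intolerant" if pli >= pli_threshold else "tolerant"


def constraint_enrichment(
    gene_set: Iterable[str],
    constraint_table: pd.DataFrame,
    pli_threshold: float = PLI_INTOLERANT,
    alternative: str = "greater",
) -> EnrichmentResult:
    """Fisher exact test for LoF-intolerance enrichment of a gene set.

    The universe is every gene in the constraint table; undetermined pLI
    counts as not-intolerant.  The default alternative "greater" tests for
    overrepresentation of intolerant genes in the set.
    """
    gene_set = set(gene_set)
    if not gene_set:
        raise ValueError("gene set is empty")
    universe = set(constraint_table["gene_id"])
    unknown = gene_set - universe
    if unknown:
        raise KeyError(f"gene set contains genes outside the constraint table: {sorted(unknown)[:5]}")
    intolerant = {
        row.gene_id
        for row in constraint_table.itertuples(index=False)
        if constraint_classify(row.pli, pli_threshold) == "intolerant"
    }
    set_hits = len(gene_set & intolerant)
    table = [
        [set_hits, len(gene_set) - set_hits],
        [len(intolerant) - set_hits, len(universe) - len(intolerant) - (len(gene_set) - set_hits)],
    ]
    odds, p = stats.fisher_exact(table, alternative=alternative)
    return EnrichmentResult(
        set_size=len(gene_set),
        set_hits=set_hits,
        universe_size=len(universe),
        universe_hits=len(intolerant),
        odds_ratio=float(odds),
        p_value=float(p),
        test_name="fisher_exact",
        alternative=alternative,
    )


def constraint_report(
    gene_set: Iterable[str], constraint_table: pd.DataFrame,
    pli_threshold: float = PLI_INTOLERANT,
) -> dict:
    """Per-gene tolerance classes plus counts/percentages at reference thresholds.

    Reports, for the set and the universe: pLI >= threshold, LOEUF < 0.35,
    LOEUF < 0.63, LOEUF > 1.34.
    """
    gene_set = sorted(set(gene_set))
    ct = constraint_table.set_index("gene_id")
    unknown = set(gene_set) - set(ct.index)
    if unknown:
        raise KeyError(f"gene set contains genes outside the constraint table: {sorted(unknown)[:5]}")

    per_gene = pd.DataFrame(
        {
            "gene_id": gene_set,
            "pli": [ct.at[g, "pli"] for g in gene_set],
            "loeuf": [ct.at[g, "loeuf"] for g in gene_set],
        }
    )
    per_gene["tolerance_class"] = [
        constraint_classify(v, pli_threshold) for v in per_gene["pli"]
    ]

    def _counts(pli: pd.Series, loeuf: pd.Series) -> dict:
        n = len(pli)
        n_int = int((pli.fillna(-1) >= pli_threshold).sum())
        n_035 = int((loeuf < LOEUF_INTOLERANT).sum())
        n_063 = int((loeuf < LOEUF_ESSENTIAL_MEAN).sum())
        n_134 = int((loeuf > LOEUF_NONESSENTIAL_MEAN).sum())
        return {
            "n_genes": n,
            "n_pli_intolerant": n_int,
            "pct_pli_intolerant": round_percent(n_int, n),
            "n_loeuf_lt_0.35": n_035,
            "pct_loeuf_lt_0.35": round_percent(n_035, n),
            "n_loeuf_lt_0.63": n_063,
            "pct_loeuf_lt_0.63": round_percent(n_063, n),
            "n_loeuf_gt_1.34": n_134,
            "pct_loeuf_gt_1.34": round_percent(n_134, n),
        }

    return {
        "per_gene": per_gene,
        "set": _counts(per_gene["pli"], per_gene["loeuf"]),
        "universe": _counts(constraint_table["pli"], constraint_table["loeuf"]),
    }
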