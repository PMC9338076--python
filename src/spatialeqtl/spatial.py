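"""Spatial confirmation of variant-gene pairs from Hi-C contact records.

A variant and a gene form a *spatial pair* when the variant's restriction
fragment is observed in contact with a fragment overlapping the gene's
transcript span in at least one Hi-C library — or when the variant sits on a
gene-overlapping fragment itself (a fragment trivially contacts itself).
Gene overlap is exact interval intersection of the transcript span with the
fragment, with no binning or padding.

Pairs are classified by genomic relationship: ``cis`` (same chromosome,
variant within ``cis_window`` of the TSS), ``trans_intra`` (same chromosome,
beyond the window), ``trans_inter`` (different chromosomes).
"""

from __future__ import annotations

import math
from typing import Mapping

import pandas as pd

from .digest import FragmentLibrary

__all__ = [
    "CIS_WINDOW_DEFAULT",
    "SELF_MARKER",
    "assign_variants_to_fragments",
    "assign_genes_to_fragments",
    "resolve_contacts",
    "find_spatial_pairs",
    "classify_pair",
    "classify_pairs",
]

#: cis window in bases, variant position to TSS (the GTEx cis-eQTL convention)
CIS_WINDOW_DEFAULT = 1_000_000

#: pseudo-library recorded when a variant shares a fragment with the gene
SELF_MARKER = "self"

FragKey = tuple[str, int]  # (chromosome, fragment_id)


def assign_variants_to_fragments(
    variants: pd.DataFrame, library: FragmentLibrary
) -> pd.DataFrame:
    """Map every variant to the unique fragment containing its position.

    Returns a frame with columns ``rsid, chromosome, fragment_id``.
    """
    unknown = sorted(set(variants["chromosome"]) - set(library.chromosomes))
    if unknown:
        offenders = variants.loc[variants["chromosome"].isin(unknown), "rsid"].tolist()
        raise KeyError(
            f"variants on chromosomes absent from the fragment library {unknown}: {offenders}"
        )
    fids = [
        library.locate(chrom, pos).fragment_id
        for chrom, pos in zip(variants["chromosome"], variants["position"])
    ]
    return pd.DataFrame(
        {"rsid": variants["rsid"].to_numpy(),
         "chromosome": variants["chromosome"].to_numpy(),
         "fragment_id": fids}
    )


def assign_genes_to_fragments(
    genes: pd.DataFrame, library: FragmentLibrary
) -> dict[str, list[FragKey]]:
    """Map each gene to the fragments overlapping its span by >= 1 base."""
    unknown = sorted(set(genes["chromosome"]) - set(library.chromosomes))
    if unknown:
        raise KeyError(f"genes on chromosomes absent from the fragment library: {unknown}")
    out: dict[str, list[FragKey]] = {}
    for row in genes.itertuples(index=False):
        frs = library.overlapping(row.chromosome, int(row.start), int(row.end))
        out[row.gene_id] = [(row.chromosome, f.fragment_id) for f in frs]
    return out


def _canonical(a: FragKey, b: FragKey) -> tuple[FragKey, FragKey]:
    return (a, b) if a <= b else (b, a)


def resolve_contacts(
    contacts: pd.DataFrame, library: FragmentLibrary
) -> dict[tuple[FragKey, FragKey], set[str]]:
    """Resolve BEDPE-style records to canonical fragment pairs -> library ids.

    Each endpoint interval must coincide with a fragment of the library;
    anything else indicates contacts digested with a different enzyme.
    """
    pairs: dict[tuple[FragKey, FragKey], set[str]] = {}
    for row in contacts.itertuples(index=False):
        key_parts = []
        for chrom, start, end in (
            (row.chrom_a, row.start_a, row.end_a),
            (row.chrom_b, row.start_b, row.end_b),
        ):
            if chrom not in library.chromosomes:
                raise KeyError(f"contact endpoint on unknown chromosome {chrom!r}")
            frag = library.locate(chrom, int(start) + 1)
            if (frag.start, frag.end) != (int(start), int(end)):
                raise ValueError(
                    f"contact endpoint {chrom}:{start}-{end} is not a library fragment "
                    f"(nearest fragment [{frag.start}, {frag.end}))"
                )
            key_parts.append((chrom, frag.fragment_id))
        key = _canonical(key_parts[0], key_parts[1])
        pairs.setdefault(key, set()).add(str(row.library_id))
    return pairs


def find_spatial_pairs(
    variant_fragments: pd.DataFrame,
    gene_fragments: Mapping[str, list[FragKey]],
    contacts: dict[tuple[FragKey, FragKey], set[str]],
) -> dict[tuple[str, str], set[str]]:
    """Confirm (variant, gene) pairs with contact or self-fragment support.

    Returns ``{(rsid, gene_id): supporting library ids}`` where the pseudo
    library ``"self"`` marks variants on a gene-overlapping fragment.
    """
    # fragment -> genes overlapping it
    frag_to_genes: dict[FragKey, set[str]] = {}
    for gene_id, frs in gene_fragments.items():
        for fk in frs:
            frag_to_genes.setdefault(fk, set()).add(gene_id)
    # fragment -> {other fragment: libraries}
    adjacency: dict[FragKey, dict[FragKey, set[str]]] = {}
    for (a, b), libs in contacts.items():
        adjacency.setdefault(a, {}).setdefault(b, set()).update(libs)
        adjacency.setdefault(b, {}).setdefault(a, set()).update(libs)

    support: dict[tuple[str, str], set[str]] = {}
    for row in variant_fragments.itertuples(index=False):
        vf: FragKey = (row.chromosome, int(row.fragment_id))
        for gene_id in frag_to_genes.get(vf, ()):
            support.setdefault((row.rsid, gene_id), set()).add(SELF_MARKER)
        for other, libs in adjacency.get(vf, {}).items():
            for gene_id in frag_to_genes.get(other, ()):
                support.setdefault((row.rsid, gene_id), set()).update(libs)
    return support


def classify_pair(
    variant_chromosome: str,
    variant_position: int,
    gene_chromosome: str,
    gene_tss: int,
    cis_window: int = CIS_WINDOW_DEFAULT,
) -> tuple[str, float]:
    """Classify one pair; returns (category, distance), distance NaN for trans_inter.

    ``variant_position`` is 1-based, ``gene_tss`` 0-based; the distance is
    between the variant's 0-based position and the TSS.
    """
    if cis_window <= 0:
        raise ValueError("cis_window must be positive")
    if variant_chromosome != gene_chromosome:
        return "trans_inter", math.nan
    distance = abs((variant_position - 1) - gene_tss)
    return ("cis" if distance <= cis_window else "trans_intra"), float(distance)


def classify_pairs(
    support: Mapping[tuple[str, str], set[str]],
    variants: pd.DataFrame,
    genes: pd.DataFrame,
    cis_window: int = CIS_WINDOW_DEFAULT,
) -> pd.DataFrame:
    """Build the SpatialPair table from confirmed support sets.

    Columns: rsid, gene_id, category, distance, n_libraries, libraries
    (comma-joined, sorted; includes the "self" marker when applicable).
    """
    v = variants.set_index("rsid")
    g = genes.set_index("gene_id")
    rows = []
    for (rsid, gene_id), libs in sorted(support.items()):
        category, distance = classify_pair(
            v.at[rsid, "chromosome"], int(v.at[rsid, "position"]),
            g.at[gene_id, "chromosome"], int(g.at[gene_id, "tss"]),
            cis_window,
        )
        rows.append(
            (rsid, gene_id, category, distance, len(libs), ",".join(sorted(libs)))
        )
    return pd.DataFrame(
        rows,
        columns=["rsid", "gene_id", "category", "distance", "n_libraries", "libraries"],
    )


def map_spatial_pairs(
    variants: pd.DataFrame,
    genes: pd.DataFrame,
    library: FragmentLibrary,
    contacts: pd.DataFrame,
    focal_gene: str | None = None,
    cis_window: int = CIS_WINDOW_DEFAULT,
) -> pd.DataFrame:
    """End-to-end spatial mapping: fragments -> contact query -> classified pairs.

    With ``focal_gene`` set, only pairs involving that gene are returned
    (first-pass mapping against the focal gene).
    """
    if focal_gene is not None:
        if focal_gene not in set(genes["gene_id"]):
            raise KeyError(f"focal gene {focal_gene!r} not in annotation")
        genes = genes[genes["gene_id"] == focal_gene]
    vf = assign_variants_to_fragments(variants, library)
    gf = assign_genes_to_fragments(genes, library)
    resolved = resolve_contacts(contacts, library)
    support = find_spatial_pairs(vf, gf, resolved)
    return classify_pairs(support, variants, genes, cis_window)
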