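"""Readers and writers for the pipeline's file formats.

One TSV dialect everywhere: tab-separated, UTF-8, header row, '.' decimal,
no quoting — so identical runs produce byte-identical outputs.

Canonical in-memory containers:

* genome — ``dict[str, str]`` of chromosome name -> sequence
* genes — ``pandas.DataFrame`` with columns
  ``gene_id, symbol, chromosome, strand, start, end, tss``
  (0-based half-open span; tss = start on '+', end - 1 on '-')
* variants — ``pandas.DataFrame`` with columns
  ``rsid, chromosome, position, ref, alt, maf`` (position is 1-based)
* dosages — ``pandas.DataFrame``, samples x variants, values in {0, 1, 2}
  (NaN for missing genotypes)
* expression — ``dict[str, pandas.DataFrame]``, tissue -> samples x genes
* contacts — ``pandas.DataFrame`` with columns
  ``chrom_a, start_a, end_a, chrom_b, start_b, end_b, library_id, count``
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd
import pysam

__all__ = [
    "write_fasta",
    "read_fasta",
    "write_vcf",
    "read_vcf",
    "write_gtf",
    "read_gtf",
    "write_expression",
    "read_expression",
    "write_contacts",
    "read_contacts",
    "write_tsv",
]

_FASTA_WIDTH = 70


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- FASTA

def write_fasta(genome: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), _FASTA_WIDTH):
                fh.write(seq[i : i + _FASTA_WIDTH] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    from pyfaidx import Fasta

    fa = Fasta(str(path))
    return {name: str(fa[name][:]) for name in fa.keys()}


# ------------------------------------------------------------------ VCF

def write_vcf(
    variants: pd.DataFrame,
    genotypes: pd.DataFrame,
    path: str | Path,
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write biallelic SNPs with GT genotypes as VCF v4.2.

    ``genotypes`` is samples x rsid with dosage values 0/1/2; dosage d is
    written as the unphased genotype with d alternate alleles.
    """
    samples = list(genotypes.index)
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if contig_lengths:
            for name, length in contig_lengths.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##INFO=<ID=MAF,Number=1,Type=Float,Description="Realized minor allele frequency">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for row in variants.itertuples(index=False):
            gts = "\t".join(gt_map[int(d)] for d in genotypes[row.rsid])
            fh.write(
                f"{row.chromosome}\t{row.position}\t{row.rsid}\t{row.ref}\t{row.alt}"
                f"\t.\tPASS\tMAF={row.maf:.6g}\tGT\t{gts}\n"
            )


def read_vcf(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a VCF into (variants, dosages).

    Keeps biallelic SNPs only. Dosage is the alternate-allele count per
    sample; missing genotypes become NaN. MAF is taken from the INFO field
    when present, else computed from the genotypes (folded to <= 0.5).
    """
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    rows = []
    dosage_cols: dict[str, list[float]] = {}
    for rec in vf:
        if len(rec.alts or ()) != 1:
            continue
        if len(rec.ref) != 1 or len(rec.alts[0]) != 1:
            continue
        dosages = []
        for s in samples:
            gt = rec.samples[s].get("GT")
            if gt is None or any(a is None for a in gt):
                dosages.append(float("nan"))
            else:
                dosages.append(float(sum(gt)))
        maf = rec.info.get("MAF")
        if maf is None:
            vals = [d for d in dosages if d == d]
            f = sum(vals) / (2 * len(vals)) if vals else float("nan")
            maf = min(f, 1 - f)
        rows.append((rec.id, rec.chrom, rec.pos, rec.ref, rec.alts[0], float(maf)))
        dosage_cols[rec.id] = dosages
    variants = pd.DataFrame(
        rows, columns=["rsid", "chromosome", "position", "ref", "alt", "maf"]
    )
    dosage = pd.DataFrame(dosage_cols, index=pd.Index(samples, name="sample"))
    return variants, dosage


# ------------------------------------------------------------------ GTF

def write_gtf(genes: pd.DataFrame, path: str | Path, source: str = "spatialeqtl") -> None:
    """Write gene models as GTF (1-based inclusive coordinates on disk)."""
    with open(path, "w") as fh:
        for row in genes.itertuples(index=False):
            attrs = f'gene_id "{row.gene_id}"; gene_name "{row.symbol}";'
            for feature in ("gene", "transcript"):
                fh.write(
                    f"{row.chromosome}\t{source}\t{feature}\t{row.start + 1}\t{row.end}"
                    f"\t.\t{row.strand}\t.\t{attrs}\n"
                )


def _gtf_attr(attrs: str, key: str) -> str:
    for field in attrs.strip().split(";"):
        field = field.strip()
        if field.startswith(key + " "):
            return field.split(" ", 1)[1].strip('"')
    raise ValueError(f"attribute {key!r} missing in GTF attributes: {attrs!r}")


def read_gtf(path: str | Path) -> pd.DataFrame:
    """Read gene records from a GTF into the canonical genes frame."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, _, feature, start, end, _, strand, _, attrs = line.rstrip("\n").split("\t")
            if feature != "gene":
                continue
            start0, end0 = int(start) - 1, int(end)
            tss = start0 if strand == "+" else end0 - 1
            rows.append(
                (_gtf_attr(attrs, "gene_id"), _gtf_attr(attrs, "gene_name"),
                 chrom, strand, start0, end0, tss)
            )
    return pd.DataFrame(
        rows, columns=["gene_id", "symbol", "chromosome", "strand", "start", "end", "tss"]
    )


# ----------------------------------------------------------- expression

def write_expression(expression: Mapping[str, pd.DataFrame], outdir: str | Path) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for tissue, mat in expression.items():
        p = outdir / f"expression_{tissue}.tsv"
        mat.to_csv(p, sep="\t", index_label="sample")
        paths.append(p)
    return paths


def read_expression(dirpath: str | Path) -> dict[str, pd.DataFrame]:
    out = {}
    for p in sorted(Path(dirpath).glob("expression_*.tsv")):
        tissue = p.stem.removeprefix("expression_")
        out[tissue] = pd.read_csv(p, sep="\t", index_col="sample")
    if not out:
        raise FileNotFoundError(f"no expression_*.tsv files in {dirpath}")
    return out


# -------------------------------------------------------------- contacts

CONTACT_COLUMNS = [
    "chrom_a", "start_a", "end_a", "chrom_b", "start_b", "end_b", "library_id", "count",
]


def write_contacts(contacts: pd.DataFrame, path: str | Path) -> None:
    contacts[CONTACT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_contacts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(CONTACT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"contact table missing columns {sorted(missing)}")
    return df
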