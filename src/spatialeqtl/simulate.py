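"""Synthetic study generator with the statistical structure the pipeline assumes.

Every input the analysis consumes — genome, gene annotation, biallelic SNP
genotypes, per-tissue expression, fragment-level Hi-C contacts, gene
constraint scores, promoter motif hits — is generated here with a known
planted truth, so recovery and calibration are testable without any
external download.

Statistical structure:

* genotypes: biallelic SNPs, allele frequency drawn from ``maf_range``,
  genotypes under Hardy-Weinberg (no LD, no population structure);
* expression: ``y = alpha + beta * dosage + Normal(0, noise_sd)`` with
  nonzero beta only at the planted (variant, gene, tissue) triples;
* contacts: background fragment pairs sampled uniformly at
  ``contact_background_rate`` per library, plus planted pairs guaranteed
  present — planted regulator loci are therefore enriched for contacts;
* constraint: an exact ``constraint_intolerant_fraction`` of genes receive
  pLI >= 0.9 (with correspondingly low LOEUF);
* motifs: target-set genes carry the focus motif with
  ``motif_hit_prob_in_set``, all other gene/motif combinations with
  ``motif_hit_prob_background``.

One global seed drives named per-component substreams, so changing one
component's parameters does not perturb another component's draws.
"""

from __future__ import annotations

import dataclasses
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .digest import FragmentLibrary, build_fragment_library, get_enzyme

__all__ = [
    "PlantedEffect",
    "PlantedContact",
    "SimulationConfig",
    "StudyData",
    "make_genome",
    "make_annotation",
    "make_variants_and_genotypes",
    "make_expression",
    "make_contacts",
    "make_constraint_table",
    "make_motif_table",
    "simulate_study",
    "simulate_focal_study",
]

_BASES = np.array(list("ACGT"))

# fixed substream labels: component draws are independent of one another
_STREAMS = {
    "genome": 11, "annotation": 12, "variants": 13, "expression": 14,
    "contacts": 15, "constraint": 16, "motifs": 17, "design": 18,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[stream], seed])


@dataclass(frozen=True)
class PlantedEffect:
    """A true eQTL: beta expression units per alternate allele at one triple."""

    rsid: str
    gene_id: str
    tissue_id: str
    beta: float


@dataclass(frozen=True)
class PlantedContact:
    """A fragment pair guaranteed present in the named Hi-C library."""

    chrom_a: str
    fragment_a: int
    chrom_b: str
    fragment_b: int
    library_id: str


@dataclass
class SimulationConfig:
    """Parameters of one synthetic study.

    Defaults give a desk-scale study (2 chromosomes x 500 kb, 200 genes,
    2,000 SNPs, 100 samples, 3 tissues) that runs the full pipeline in
    well under a minute.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length: int = 500_000
    site_density: float = 4.0          # expected recognition sites per kb (MboI-like)
    enzyme: str = "MboI"
    n_genes: int = 200
    n_variants: int = 2_000
    n_samples: int = 100
    n_tissues: int = 3
    n_libraries: int = 3
    maf_range: tuple[float, float] = (0.05, 0.5)
    planted_effects: list[PlantedEffect] = field(default_factory=list)
    expression_baseline: float = 10.0  # alpha, arbitrary expression units
    noise_sd: float = 1.0
    contact_background_rate: float = 1e-5
    planted_contact_pairs: list[PlantedContact] = field(default_factory=list)
    constraint_intolerant_fraction: float = 0.155
    motif_hit_prob_in_set: float = 0.9
    motif_hit_prob_background: float = 0.05
    n_motifs: int = 5
    focus_motif: str = "SP2"

    def __post_init__(self) -> None:
        if self.chromosome_length < 1_000:
            raise ValueError("chromosome_length must be >= 1 kb")
        if self.n_chromosomes < 1 or self.n_genes < 1 or self.n_variants < 1:
            raise ValueError("counts must be positive")
        if self.n_samples < 10:
            raise ValueError("need n_samples >= 10")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.site_density < 0 or self.noise_sd < 0:
            raise ValueError("site_density and noise_sd must be non-negative")
        if not 0 <= self.constraint_intolerant_fraction <= 1:
            raise ValueError("constraint_intolerant_fraction must lie in [0, 1]")
        for p in (self.motif_hit_prob_in_set, self.motif_hit_prob_background):
            if not 0 <= p <= 1:
                raise ValueError("motif hit probabilities must lie in [0, 1]")

    @property
    def chromosomes(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    @property
    def tissues(self) -> list[str]:
        return [f"tissue{i + 1}" for i in range(self.n_tissues)]

    @property
    def libraries(self) -> list[str]:
        return [f"hic{i + 1}" for i in range(self.n_libraries)]


# ----------------------------------------------------------------- genome


def _disrupt_sites(seq: np.ndarray, word: str, rng: np.random.Generator) -> None:
    """Mutate one base inside every occurrence of ``word`` until none remain."""
    pattern = re.compile(f"(?={word})")
    while True:
        starts = [m.start() for m in pattern.finditer("".join(seq))]
        if not starts:
            return
        for s in starts:
            pos = s + len(word) // 2
            current = seq[pos]
            choices = [b for b in "ACGT" if b != current]
            seq[pos] = choices[rng.integers(len(choices))]


def make_genome(config: SimulationConfig) -> dict[str, str]:
    """Random chromosomes with recognition sites planted at ``site_density``.

    Accidental occurrences of the recognition word are removed first, then
    a Poisson number of sites (mean ``site_density`` per kb) is planted at
    uniform positions, so a density of zero yields a site-free sequence.
    """
    enzyme = get_enzyme(config.enzyme)
    word = enzyme.recognition
    if any(c not in "ACGT" for c in word):
        raise ValueError("genome simulation needs a concrete (unambiguous) recognition word")
    rng = _rng(config.seed, "genome")
    genome: dict[str, str] = {}
    for chrom in config.chromosomes:
        L = config.chromosome_length
        seq = _BASES[rng.integers(0, 4, size=L)]
        _disrupt_sites(seq, word, rng)
        n_sites = int(rng.poisson(config.site_density * L / 1000))
        if n_sites > 0:
            # non-overlapping placement: sorted distinct draws shifted by i*|word|
            w = len(word)
            space = L - n_sites * w
            if space <= 0:
                raise ValueError("site_density too high for chromosome_length")
            draws = np.sort(rng.choice(space, size=n_sites, replace=False))
            for i, pos in enumerate(draws + np.arange(n_sites) * w):
                seq[pos : pos + w] = list(word)
        genome[chrom] = "".join(seq)
    return genome


# ------------------------------------------------------------- annotation


def make_annotation(config: SimulationConfig, genome: dict[str, str]) -> pd.DataFrame:
    """Non-overlapping gene models, one per equal-width slot per chromosome."""
    rng = _rng(config.seed, "annotation")
    chroms = list(genome)
    per_chrom = np.zeros(len(chroms), dtype=int)
    for i in range(config.n_genes):
        per_chrom[i % len(chroms)] += 1
    rows = []
    gene_idx = 0
    min_len, max_len = 1_000, 5_000
    for chrom, n in zip(chroms, per_chrom):
        L = len(genome[chrom])
        if n == 0:
            continue
        slot = L // n
        if slot < min_len + 2:
            raise ValueError(
                f"cannot place {n} non-overlapping genes of >= {min_len} bp on "
                f"{chrom} ({L} bp)"
            )
        for j in range(n):
            lo = j * slot
            length = int(rng.integers(min_len, min(max_len, slot - 1)))
            start = lo + int(rng.integers(0, slot - length))
            strand = "+" if rng.random() < 0.5 else "-"
            end = start + length
            gene_idx += 1
            rows.append(
                (f"GENE{gene_idx:04d}", f"G{gene_idx}", chrom, strand, start, end,
                 start if strand == "+" else end - 1)
            )
    return pd.DataFrame(
        rows, columns=["gene_id", "symbol", "chromosome", "strand", "start", "end", "tss"]
    )


# --------------------------------------------------- variants & genotypes


def make_variants_and_genotypes(
    config: SimulationConfig, genome: dict[str, str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Biallelic SNPs with HWE genotypes; realized MAF recorded per variant.

    Returns (variants, dosages): the variant table carries the realized
    (sample) minor allele frequency; dosages is samples x rsid in {0,1,2}.
    """
    rng = _rng(config.seed, "variants")
    chroms = list(genome)
    seen: set[tuple[str, int]] = set()
    lo, hi = config.maf_range
    samples = [f"S{i + 1:04d}" for i in range(config.n_samples)]
    var_rows = []
    dosage_cols: dict[str, np.ndarray] = {}
    i = 0
    while i < config.n_variants:
        chrom = chroms[int(rng.integers(len(chroms)))]
        pos = int(rng.integers(1, len(genome[chrom]) + 1))  # 1-based
        if (chrom, pos) in seen:
            continue
        seen.add((chrom, pos))
        ref = genome[chrom][pos - 1]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        freq = float(rng.uniform(lo, hi))
        dosage = rng.binomial(2, freq, size=config.n_samples).astype(float)
        f_hat = dosage.sum() / (2 * config.n_samples)
        i += 1
        rsid = f"rs{i:06d}"
        var_rows.append((rsid, chrom, pos, ref, alt, min(f_hat, 1 - f_hat)))
        dosage_cols[rsid] = dosage
    variants = pd.DataFrame(
        var_rows, columns=["rsid", "chromosome", "position", "ref", "alt", "maf"]
    ).sort_values(["chromosome", "position"]).reset_index(drop=True)
    dosages = pd.DataFrame(dosage_cols, index=pd.Index(samples, name="sample"))
    return variants, dosages[variants["rsid"]]


# ------------------------------------------------------------- expression


def make_expression(
    config: SimulationConfig, genotypes: pd.DataFrame, annotation: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """Per-tissue samples x genes matrices: alpha + noise, plus planted beta*dosage."""
    gene_ids = list(annotation["gene_id"])
    gene_set = set(gene_ids)
    tissue_set = set(config.tissues)
    for eff in config.planted_effects:
        if eff.gene_id not in gene_set:
            raise KeyError(f"planted effect on unknown gene {eff.gene_id!r}")
        if eff.rsid not in genotypes.columns:
            raise KeyError(f"planted effect on unknown variant {eff.rsid!r}")
        if eff.tissue_id not in tissue_set:
            raise KeyError(f"planted effect in unknown tissue {eff.tissue_id!r}")
    rng = _rng(config.seed, "expression")
    out = {}
    for tissue in config.tissues:
        mat = config.expression_baseline + rng.normal(
            0.0, config.noise_sd, size=(config.n_samples, len(gene_ids))
        )
        df = pd.DataFrame(mat, index=genotypes.index, columns=gene_ids)
        for eff in config.planted_effects:
            if eff.tissue_id == tissue:
                df[eff.gene_id] += eff.beta * genotypes[eff.rsid].to_numpy()
        out[tissue] = df
    return out


# ---------------------------------------------------------------- contacts


def make_contacts(config: SimulationConfig, library: FragmentLibrary) -> pd.DataFrame:
    """Fragment-pair contact records: uniform background plus planted pairs.

    Background: per Hi-C library, Poisson(rate x n_candidate_pairs) draws of
    uniform fragment pairs, aggregated to (pair, library) counts.  Every
    planted pair is guaranteed present in its named library.
    """
    frags = [
        (chrom, f.fragment_id, f.start, f.end)
        for chrom in library.chromosomes
        for f in library.fragments(chrom)
    ]
    F = len(frags)
    n_candidates = F * (F - 1) // 2
    rng = _rng(config.seed, "contacts")
    counts: dict[tuple[int, int, str], int] = {}
    for lib_id in config.libraries:
        n_bg = rng.poisson(config.contact_background_rate * n_candidates)
        for _ in range(int(n_bg)):
            a = int(rng.integers(F))
            b = int(rng.integers(F))
            while b == a:
                b = int(rng.integers(F))
            key = (min(a, b), max(a, b), lib_id)
            counts[key] = counts.get(key, 0) + 1
    index = {(chrom, fid): k for k, (chrom, fid, _, _) in enumerate(frags)}
    for pc in config.planted_contact_pairs:
        for chrom, fid in ((pc.chrom_a, pc.fragment_a), (pc.chrom_b, pc.fragment_b)):
            if (chrom, fid) not in index:
                raise KeyError(f"planted contact references missing fragment {chrom}:{fid}")
        a, b = index[(pc.chrom_a, pc.fragment_a)], index[(pc.chrom_b, pc.fragment_b)]
        key = (min(a, b), max(a, b), pc.library_id)
        counts[key] = counts.get(key, 0) + 1
    rows = []
    for (a, b, lib_id), count in sorted(counts.items()):
        ca, fa, sa, ea = frags[a]
        cb, fb, sb, eb = frags[b]
        rows.append((ca, sa, ea, cb, sb, eb, lib_id, count))
    return pd.DataFrame(rows, columns=io.CONTACT_COLUMNS)


# -------------------------------------------------------------- constraint


def make_constraint_table(config: SimulationConfig, annotation: pd.DataFrame) -> pd.DataFrame:
    """pLI/LOEUF per gene with an exact intolerant fraction (pLI >= 0.9)."""
    rng = _rng(config.seed, "constraint")
    gene_ids = list(annotation["gene_id"])
    n = len(gene_ids)
    n_intolerant = int(round(config.constraint_intolerant_fraction * n))
    order = rng.permutation(n)
    intolerant = set(np.array(gene_ids)[order[:n_intolerant]])
    rows = []
    for gid in gene_ids:
        if gid in intolerant:
            pli = float(rng.uniform(0.9, 1.0))
            loeuf = float(rng.uniform(0.1, 0.35))
        else:
            pli = float(rng.uniform(0.0, 0.9))
            loeuf = float(rng.uniform(0.35, 2.0))
        rows.append((gid, pli, loeuf))
    return pd.DataFrame(rows, columns=["gene_id", "pli", "loeuf"])


# ------------------------------------------------------------------ motifs


def make_motif_table(
    config: SimulationConfig, annotation: pd.DataFrame, target_set: set[str] | list[str]
) -> pd.DataFrame:
    """Promoter motif hit table: focus motif enriched in the target set.

    The focus motif hits target-set genes with ``motif_hit_prob_in_set`` and
    all other genes with ``motif_hit_prob_background``; the remaining motifs
    hit every gene at the background rate.
    """
    target_set = set(target_set)
    gene_ids = list(annotation["gene_id"])
    unknown = target_set - set(gene_ids)
    if unknown:
        raise KeyError(f"target set contains unannotated genes: {sorted(unknown)[:5]}")
    rng = _rng(config.seed, "motifs")
    motifs = [config.focus_motif] + [f"MOTIF{i + 1}" for i in range(config.n_motifs - 1)]
    rows = []
    for motif in motifs:
        for gid in gene_ids:
            p = (
                config.motif_hit_prob_in_set
                if (motif == config.focus_motif and gid in target_set)
                else config.motif_hit_prob_background
            )
            rows.append((gid, motif, int(rng.random() < p)))
    return pd.DataFrame(rows, columns=["gene_id", "motif_id", "hit"])


# ------------------------------------------------------------ orchestration


@dataclass
class StudyData:
    """All artifacts of one synthetic study, in memory, plus its planted truth."""

    config: SimulationConfig
    genome: dict[str, str]
    library: FragmentLibrary
    genes: pd.DataFrame
    variants: pd.DataFrame
    dosages: pd.DataFrame
    expression: dict[str, pd.DataFrame]
    contacts: pd.DataFrame
    constraint: pd.DataFrame
    motifs: pd.DataFrame
    manifest: dict

    def write(self, outdir: str | Path) -> dict[str, str]:
        """Write every artifact in its standard format; returns the path map."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": str(outdir / "genome.fa"),
            "fragments": str(outdir / "fragments.tsv"),
            "genes": str(outdir / "genes.gtf"),
            "vcf": str(outdir / "variants.vcf"),
            "expression_dir": str(outdir),
            "contacts": str(outdir / "contacts.tsv"),
            "constraint": str(outdir / "constraint.tsv"),
            "motifs": str(outdir / "motifs.tsv"),
            "manifest": str(outdir / "manifest.json"),
        }
        io.write_fasta(self.genome, paths["genome"])
        self.library.to_tsv(paths["fragments"])
        io.write_gtf(self.genes, paths["genes"])
        io.write_vcf(
            self.variants, self.dosages, paths["vcf"],
            contig_lengths={c: len(s) for c, s in self.genome.items()},
        )
        io.write_expression(self.expression, outdir)
        io.write_contacts(self.contacts, paths["contacts"])
        io.write_tsv(self.constraint, paths["constraint"])
        io.write_tsv(self.motifs, paths["motifs"])
        with open(paths["manifest"], "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return paths


def _config_manifest(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["planted_effects"] = [dataclasses.asdict(e) for e in config.planted_effects]
    d["planted_contact_pairs"] = [
        dataclasses.asdict(c) for c in config.planted_contact_pairs
    ]
    d["maf_range"] = list(config.maf_range)
    return d


def simulate_study(
    config: SimulationConfig,
    target_set: set[str] | None = None,
    extra_manifest: dict | None = None,
) -> StudyData:
    """Generate every artifact of one study from a config.

    ``target_set`` seeds the motif table's enriched set (defaults to the
    genes carrying planted effects).
    """
    genome = make_genome(config)
    library = build_fragment_library(genome, get_enzyme(config.enzyme))
    genes = make_annotation(config, genome)
    variants, dosages = make_variants_and_genotypes(config, genome)
    expression = make_expression(config, dosages, genes)
    contacts = make_contacts(config, library)
    constraint = make_constraint_table(config, genes)
    if target_set is None:
        target_set = {e.gene_id for e in config.planted_effects}
    motifs = make_motif_table(config, genes, target_set)
    manifest = {
        "config": _config_manifest(config),
        "planted_effects": [dataclasses.asdict(e) for e in config.planted_effects],
        "motif_target_set": sorted(target_set),
    }
    if extra_manifest:
        manifest.update(extra_manifest)
    return StudyData(
        config, genome, library, genes, variants, dosages, expression,
        contacts, constraint, motifs, manifest,
    )


def _gene_free_variants(
    variants: pd.DataFrame, library: FragmentLibrary, genes: pd.DataFrame
) -> pd.DataFrame:
    """Variants whose fragment overlaps no annotated gene (non-coding loci)."""
    gene_frags: set[tuple[str, int]] = set()
    for row in genes.itertuples(index=False):
        for f in library.overlapping(row.chromosome, int(row.start), int(row.end)):
            gene_frags.add((row.chromosome, f.fragment_id))
    keep = []
    for row in variants.itertuples(index=False):
        frag = library.locate(row.chromosome, int(row.position))
        keep.append((row.chromosome, frag.fragment_id) not in gene_frags)
    return variants[np.array(keep)]


def _exclusive_gene_fragment(
    gene_id: str, genes: pd.DataFrame, library: FragmentLibrary
) -> tuple[str, int]:
    """A fragment overlapping this gene and no other (first fragment fallback).

    Planted contacts anchor here so spatial support is unambiguous when a
    boundary fragment spans two adjacent genes.
    """
    g = genes.set_index("gene_id")
    chrom = str(g.at[gene_id, "chromosome"])
    frags = library.overlapping(chrom, int(g.at[gene_id, "start"]), int(g.at[gene_id, "end"]))
    others = genes[(genes["chromosome"] == chrom) & (genes["gene_id"] != gene_id)]
    for f in frags:
        touched = others[(others["start"] < f.end) & (others["end"] > f.start)]
        if len(touched) == 0:
            return chrom, f.fragment_id
    return chrom, frags[0].fragment_id


def simulate_focal_study(
    seed: int = 0,
    n_regulator_snps: int = 8,
    beta: float = 1.5,
    n_coregulated: int = 3,
    snps_per_coregulated: int = 3,
    config: SimulationConfig | None = None,
) -> StudyData:
    """A full focal-gene study with planted regulators and a co-regulated hub.

    Emulates the study design the pipeline targets: non-coding regulator
    SNPs (fragments overlapping no gene) with planted effects on one focal
    gene, a subset of which also regulate ``n_coregulated`` further genes
    (the planted hub).  Planted contacts connect each regulator's fragment
    to a gene-exclusive fragment of its target, in a library chosen
    round-robin.  About 20% of the regulators are drawn from other
    chromosomes, giving trans-interchromosomal pairs alongside the cis
    majority.

    The regulator count is kept modest because the regulators of one gene
    share its expression variance: with k independent regulators of effect
    beta each, the per-SNP share of variance shrinks as 1/k, so very large
    k makes individual effects undetectable at any sample size — a property
    of the model, not of the implementation.
    """
    base = config if config is not None else SimulationConfig(seed=seed)
    base = dataclasses.replace(
        base, seed=seed, planted_effects=[], planted_contact_pairs=[]
    )
    genome = make_genome(base)
    library = build_fragment_library(genome, get_enzyme(base.enzyme))
    genes = make_annotation(base, genome)
    variants, _ = make_variants_and_genotypes(base, genome)

    rng = _rng(seed, "design")
    focal_candidates = genes[genes["chromosome"] == base.chromosomes[0]]
    focal_gene = str(focal_candidates.iloc[len(focal_candidates) // 2]["gene_id"])
    focal_chrom = str(genes.set_index("gene_id").at[focal_gene, "chromosome"])

    candidates = _gene_free_variants(variants, library, genes)
    same = candidates[candidates["chromosome"] == focal_chrom]
    other = candidates[candidates["chromosome"] != focal_chrom]
    n_trans = min(len(other), max(0, int(round(0.2 * n_regulator_snps))))
    n_cis = n_regulator_snps - n_trans
    if len(same) < n_cis:
        raise ValueError("not enough gene-free variants on the focal chromosome")
    chosen = pd.concat(
        [
            same.iloc[rng.choice(len(same), size=n_cis, replace=False)],
            other.iloc[rng.choice(len(other), size=n_trans, replace=False)],
        ]
    )
    regulator_rsids = list(chosen["rsid"])

    coreg_pool = genes[genes["gene_id"] != focal_gene]
    coreg = list(
        coreg_pool.iloc[rng.choice(len(coreg_pool), size=n_coregulated, replace=False)]["gene_id"]
    )

    tissues = base.tissues
    effects = [
        PlantedEffect(rsid, focal_gene, tissues[int(rng.integers(len(tissues)))], beta)
        for rsid in regulator_rsids
    ]
    for gid in coreg:
        picks = rng.choice(len(regulator_rsids), size=min(snps_per_coregulated, len(regulator_rsids)), replace=False)
        for k in picks:
            effects.append(
                PlantedEffect(regulator_rsids[int(k)], gid,
                              tissues[int(rng.integers(len(tissues)))], beta)
            )

    planted_contacts = _contacts_for_effects(effects, variants, genes, library, base)
    full = dataclasses.replace(
        base, planted_effects=effects, planted_contact_pairs=planted_contacts
    )
    return simulate_study(
        full,
        target_set=set(coreg) | {focal_gene},
        extra_manifest={
            "focal_gene": focal_gene,
            "regulator_rsids": sorted(regulator_rsids),
            "coregulated_genes": sorted(coreg),
            "planted_pairs": sorted({(e.rsid, e.gene_id) for e in effects}),
        },
    )


def _contacts_for_effects(
    effects: list[PlantedEffect],
    variants: pd.DataFrame,
    genes: pd.DataFrame,
    library: FragmentLibrary,
    config: SimulationConfig,
) -> list[PlantedContact]:
    """One planted contact per distinct planted (variant, gene) pair."""
    vpos = variants.set_index("rsid")
    libs = config.libraries
    contacts = []
    gene_anchor: dict[str, tuple[str, int]] = {}
    for i, (rsid, gene_id) in enumerate(sorted({(e.rsid, e.gene_id) for e in effects})):
        vchrom = str(vpos.at[rsid, "chromosome"])
        vfrag = library.locate(vchrom, int(vpos.at[rsid, "position"])).fragment_id
        if gene_id not in gene_anchor:
            gene_anchor[gene_id] = _exclusive_gene_fragment(gene_id, genes, library)
        gchrom, gfrag = gene_anchor[gene_id]
        contacts.append(PlantedContact(vchrom, vfrag, gchrom, gfrag, libs[i % len(libs)]))
    return contacts


def simulate_planted_pairs_study(
    seed: int = 0,
    n_pairs: int = 50,
    beta: float = 1.5,
    all_tissues: bool = False,
    config: SimulationConfig | None = None,
) -> StudyData:
    """A study with planted effects spread over ``n_pairs`` distinct genes.

    One non-coding regulator SNP per gene, each the sole signal in its
    gene's expression, so per-pair detection power depends only on beta,
    the noise level and the sample size.  With ``all_tissues`` the effect
    is planted in every tissue (unambiguous truth for false-discovery
    accounting); otherwise in one tissue drawn at random.
    """
    base = config if config is not None else SimulationConfig(seed=seed)
    base = dataclasses.replace(
        base, seed=seed, planted_effects=[], planted_contact_pairs=[]
    )
    genome = make_genome(base)
    library = build_fragment_library(genome, get_enzyme(base.enzyme))
    genes = make_annotation(base, genome)
    variants, _ = make_variants_and_genotypes(base, genome)

    rng = _rng(seed, "design")
    candidates = _gene_free_variants(variants, library, genes)
    if len(candidates) < n_pairs or len(genes) < n_pairs:
        raise ValueError("not enough gene-free variants or genes for the requested pairs")
    snps = candidates.iloc[rng.choice(len(candidates), size=n_pairs, replace=False)]
    targets = genes.iloc[rng.choice(len(genes), size=n_pairs, replace=False)]

    tissues = base.tissues
    effects = []
    for rsid, gene_id in zip(snps["rsid"], targets["gene_id"]):
        if all_tissues:
            effects.extend(PlantedEffect(rsid, gene_id, t, beta) for t in tissues)
        else:
            effects.append(
                PlantedEffect(rsid, gene_id, tissues[int(rng.integers(len(tissues)))], beta)
            )
    planted_contacts = _contacts_for_effects(effects, variants, genes, library, base)
    full = dataclasses.replace(
        base, planted_effects=effects, planted_contact_pairs=planted_contacts
    )
    return simulate_study(
        full,
        extra_manifest={
            "planted_pairs": sorted({(e.rsid, e.gene_id) for e in effects}),
        },
    )
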