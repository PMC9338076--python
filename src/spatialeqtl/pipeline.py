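"""End-to-end orchestration: simulate -> digest -> spatialmap -> eqtl -> hub -> enrich.

A single config file (YAML) drives a run; every stage writes its TSVs into
the run directory plus a JSON run-manifest (versions, seed, parameters, row
counts, skipped-test counts).  Re-running with an identical config
reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, enrich, io
from .digest import build_fragment_library, get_enzyme
from .eqtl import SpatialEQTL, export_manhattan
from .hub import second_pass
from .simulate import SimulationConfig, StudyData, simulate_focal_study, simulate_study
from .spatial import CIS_WINDOW_DEFAULT, map_spatial_pairs

__all__ = ["run_all", "load_config"]

logger = logging.getLogger(__name__)

STAGES = ["simulate", "digest", "spatialmap", "eqtl", "hub", "enrich"]


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} did not parse to a mapping")
    return cfg


def _simulate_stage(cfg: dict) -> StudyData:
    sim = dict(cfg.get("simulate", {}))
    scenario = sim.pop("scenario", "focal")
    scenario_keys = {
        k: sim.pop(k)
        for k in ("n_regulator_snps", "beta", "n_coregulated", "snps_per_coregulated")
        if k in sim
    }
    seed = sim.pop("seed", 0)
    base = SimulationConfig(seed=seed, **sim)
    if scenario == "focal":
        return simulate_focal_study(seed=seed, config=base, **scenario_keys)
    if scenario == "plain":
        return simulate_study(base)
    raise ValueError(f"unknown simulate scenario {scenario!r}")


def run_all(config_path: str | Path, outdir: str | Path | None = None) -> Path:
    """Execute the full pipeline; returns the run directory.

    Stages read the previous stage's in-memory outputs; every stage also
    persists its table(s) so any stage can be re-run standalone from files.
    """
    cfg = load_config(config_path)
    outdir = Path(outdir if outdir is not None else cfg.get("outdir", "spatialeqtl_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "versions": _versions(),
        "config": cfg,
        "stages": {},
    }

    def record(stage: str, **counts) -> None:
        manifest["stages"][stage] = counts
        logger.info("[%s] %s", stage, counts)

    try:
        # -- simulate ---------------------------------------------------
        study = _simulate_stage(cfg)
        data_dir = outdir / "data"
        paths = study.write(data_dir)
        focal_gene = cfg.get("spatialmap", {}).get(
            "focal_gene", study.manifest.get("focal_gene")
        )
        record(
            "simulate",
            seed=study.config.seed,
            n_variants=len(study.variants),
            n_genes=len(study.genes),
            n_samples=study.config.n_samples,
            n_tissues=study.config.n_tissues,
            n_planted_effects=len(study.config.planted_effects),
        )

        # -- digest -----------------------------------------------------
        enzyme = get_enzyme(cfg.get("digest", {}).get("enzyme", study.config.enzyme))
        library = build_fragment_library(study.genome, enzyme)
        library.to_tsv(outdir / "fragments.tsv")
        record("digest", enzyme=enzyme.name, n_fragments=library.n_fragments())

        # -- spatialmap -------------------------------------------------
        cis_window = int(cfg.get("spatialmap", {}).get("cis_window", CIS_WINDOW_DEFAULT))
        pairs = map_spatial_pairs(
            study.variants, study.genes, library, study.contacts,
            focal_gene=focal_gene, cis_window=cis_window,
        )
        io.write_tsv(pairs, outdir / "spatial_pairs.tsv")
        record(
            "spatialmap",
            focal_gene=focal_gene,
            cis_window=cis_window,
            n_pairs=len(pairs),
            by_category=pairs["category"].value_counts().to_dict(),
        )

        # -- eqtl -------------------------------------------------------
        ecfg = cfg.get("eqtl", {})
        maf_min = float(ecfg.get("maf_min", 0.05))
        alpha = float(ecfg.get("alpha", 0.05))
        model = SpatialEQTL(
            pairs, study.dosages, study.expression,
            maf_min=maf_min, transform=ecfg.get("transform", "inverse_normal"),
        )
        results = model.fit(alpha=alpha, bh_family=ecfg.get("bh_family", "pooled"))
        results.variants = study.variants
        results.to_tsv(outdir / "eqtl_results.tsv")
        io.write_tsv(results.manhattan(), outdir / "manhattan.tsv")
        record(
            "eqtl",
            maf_min=maf_min, alpha=alpha,
            n_tests=results.n_tests, n_skipped=results.n_skipped,
            n_maf_filtered=results.n_maf_filtered,
            n_significant=int(results.significant.shape[0]),
            n_significant_variants=len(results.significant_variants),
        )

        # -- hub --------------------------------------------------------
        hub_res = second_pass(
            results.significant_variants, study.variants, study.genes, library,
            study.contacts, study.dosages, study.expression,
            focal_gene=focal_gene, maf_min=maf_min, alpha=alpha,
            cis_window=cis_window,
        )
        hub_res.results.to_tsv(outdir / "second_pass_results.tsv")
        hub_res.to_tsv(outdir)
        record(
            "hub",
            n_second_pass_tests=hub_res.results.n_tests,
            n_hub_genes=len(hub_res.hub_genes),
            hub_genes=hub_res.hub_genes,
        )

        # -- enrich -----------------------------------------------------
        ncfg = cfg.get("enrich", {})
        pli_threshold = float(ncfg.get("pli_threshold", 0.9))
        analysis_set = sorted(set(hub_res.hub_genes) | {focal_gene})
        universe = sorted(study.constraint["gene_id"])
        enrich_rows = []
        if analysis_set:
            cres = enrich.constraint_enrichment(
                analysis_set, study.constraint, pli_threshold=pli_threshold
            )
            enrich_rows.append({"test": "constraint_pli", **dataclasses.asdict(cres)})
            report = enrich.constraint_report(analysis_set, study.constraint, pli_threshold)
            io.write_tsv(report["per_gene"], outdir / "constraint_classes.tsv")
            with open(outdir / "constraint_report.json", "w") as fh:
                json.dump(
                    {"set": report["set"], "universe": report["universe"]},
                    fh, indent=2, sort_keys=True,
                )
                fh.write("\n")
            motif_res = enrich.motif_enrichment(analysis_set, study.motifs, universe)
            io.write_tsv(motif_res, outdir / "motif_enrichment.tsv")
        pd.DataFrame(enrich_rows).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        record(
            "enrich",
            set_size=len(analysis_set),
            pli_threshold=pli_threshold,
            constraint_p=(enrich_rows[0]["p_value"] if enrich_rows else None),
        )
    except Exception as exc:
        done = set(manifest["stages"])
        stage = next((s for s in STAGES if s not in done), "unknown")
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    manifest["input_paths"] = paths
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return outdir


def _versions() -> dict:
    import numpy
    import scipy
    import statsmodels

    return {
        "numpy": numpy.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
    }
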