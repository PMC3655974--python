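"""Pipeline orchestration: simulate -> curate -> map -> enrich -> sensitivity.

Each stage persists its intermediates in the documented flat-file
formats so stages are individually re-runnable; the final report (a
results TSV plus JSON sidecar) embeds the fully resolved configuration
and master seed, and is byte-identical across runs with the same seed.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from pathlib import Path
from typing import Dict, List, Mapping, Optional

from . import io as cio
from .curation import curate_interactome
from .enrichment import EnrichmentConfig, run_enrichment, sensitivity_scan
from .errors import ConfigError
from .mapping import score_significant_genes
from .simulate import SimConfig, generate_dataset, write_dataset

logger = logging.getLogger("candidate_interactome.pipeline")

ALL_STAGES = ("simulate", "curate", "map", "enrich", "sensitivity")

_SIM_FIELDS = {f.name for f in dataclasses.fields(SimConfig)}
_ENRICH_KEYS = {
    "pcut",
    "n_replicates",
    "n_studies",
    "alpha_category",
    "size_weighted",
    "window_bp",
    "r2_max",
    "dist_bp",
}


def validate_config(config: Mapping) -> dict:
    """Schema-check a pipeline configuration.

    Required top-level fields: ``seed`` (int) and ``outdir`` (str).
    Optional sections: ``simulate`` (SimConfig fields), ``enrich``
    (EnrichmentConfig fields), ``sensitivity`` (``pcuts``,
    ``scan_all``), ``inputs`` (paths overriding simulated files),
    ``curate`` (``name``).  Unknown fields raise :class:`ConfigError`
    naming the offender.
    """
    if not isinstance(config, Mapping):
        raise ConfigError("configuration must be a mapping")
    resolved: dict = {}
    for required in ("seed", "outdir"):
        if required not in config:
            raise ConfigError(f"missing required config field: {required!r}")
    try:
        resolved["seed"] = int(config["seed"])
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"config field 'seed' must be an integer: {exc}") from exc
    resolved["outdir"] = str(config["outdir"])

    known_sections = {"simulate", "enrich", "sensitivity", "inputs", "curate", "stages"}
    for key in config:
        if key not in known_sections | {"seed", "outdir"}:
            raise ConfigError(f"unknown config field: {key!r}")

    sim = dict(config.get("simulate") or {})
    for key in sim:
        if key not in _SIM_FIELDS:
            raise ConfigError(f"unknown simulate field: {key!r}")
    resolved["simulate"] = sim

    enr = dict(config.get("enrich") or {})
    for key in enr:
        if key not in _ENRICH_KEYS:
            raise ConfigError(f"unknown enrich field: {key!r}")
    resolved["enrich"] = enr

    sens = dict(config.get("sensitivity") or {})
    for key in sens:
        if key not in {"pcuts", "scan_all"}:
            raise ConfigError(f"unknown sensitivity field: {key!r}")
    resolved["sensitivity"] = sens

    resolved["inputs"] = dict(config.get("inputs") or {})
    resolved["curate"] = dict(config.get("curate") or {})
    stages = config.get("stages", list(ALL_STAGES))
    for s in stages:
        if s not in ALL_STAGES:
            raise ConfigError(f"unknown stage: {s!r}")
    resolved["stages"] = list(stages)
    return resolved


def run_pipeline(config: Mapping, stages: Optional[List[str]] = None) -> Dict[str, Path]:
    """Execute the requested stages in order; returns artifact paths.

    Stage failures propagate as exceptions prefixed with the stage name.
    """
    cfg = validate_config(config)
    stages = list(stages) if stages is not None else cfg["stages"]
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = cfg["seed"]
    artifacts: Dict[str, Path] = {}
    inputs = dict(cfg["inputs"])

    def _input(name: str, default: Path) -> Path:
        return Path(inputs.get(name, default))

    def _stage(name):
        logger.info("stage %s: starting", name)
        return time.perf_counter()

    def _done(name, t0):
        logger.info("stage %s: finished in %.2fs", name, time.perf_counter() - t0)

    if "simulate" in stages:
        t0 = _stage("simulate")
        try:
            sim_cfg = SimConfig(**{**cfg["simulate"], "seed": seed})
            dataset = generate_dataset(sim_cfg)
            paths = write_dataset(dataset, outdir)
        except Exception as exc:
            raise type(exc)(f"simulate stage failed: {exc}") from exc
        artifacts.update(paths)
        _done("simulate", t0)

    gwas_path = _input("gwas", outdir / "gwas.tsv")
    genes_path = _input("genes", outdir / "genes.bed")
    ld_path = _input("ld", outdir / "ld.tsv")
    sets_path = _input("sets", outdir / "sets.gmt")
    mask_path = _input("mask", outdir / "mask.bed")
    evidence_path = _input("evidence", outdir / "evidence.tsv")

    if "curate" in stages:
        t0 = _stage("curate")
        evidence = cio.read_evidence_table(evidence_path)
        name = cfg["curate"].get("name", "CURATED")
        interactome = curate_interactome(evidence, name)
        curated_path = outdir / "curated.gmt"
        cio.write_gene_sets([interactome], curated_path)
        artifacts["curated"] = curated_path
        logger.info("curate: %d gene(s) kept for %s", len(interactome), name)
        _done("curate", t0)

    enr_cfg = EnrichmentConfig(**{**cfg["enrich"], "seed": seed})

    snps = genes = ld = mask = None
    if {"map", "enrich", "sensitivity"} & set(stages):
        snps = cio.read_gwas_summary(gwas_path)
        genes = cio.read_gene_annotation(genes_path)
        ld = cio.read_ld_table(ld_path)
        mask = (
            cio.read_region_mask(mask_path)
            if Path(mask_path).exists()
            else None
        )

    if "map" in stages:
        t0 = _stage("map")
        pruned, _ = score_significant_genes(
            snps,
            genes,
            ld,
            enr_cfg.pcut,
            mask=None,
            window_bp=enr_cfg.window_bp,
            r2_max=enr_cfg.r2_max,
            dist_bp=enr_cfg.dist_bp,
        )
        siglist_path = outdir / "siglist.tsv"
        with open(siglist_path, "w") as fh:
            fh.write("gene\tindex_rsid\tindex_p\n")
            for gene, rsid, pval in pruned.entries:
                fh.write(f"{gene}\t{rsid}\t{pval:.17g}\n")
        artifacts["siglist"] = siglist_path
        logger.info("map: %d independent significant gene(s)", len(pruned))
        _done("map", t0)

    if "enrich" in stages:
        t0 = _stage("enrich")
        sets = cio.read_gene_sets(sets_path)
        run = run_enrichment(snps, genes, ld, sets, enr_cfg, mask=mask)
        results_path = outdir / "results.tsv"
        parameters = {
            "seed": seed,
            "enrichment": dataclasses.asdict(enr_cfg),
            "simulate": cfg["simulate"],
        }
        study = {
            "unmasked": _study_dict(run.study_unmasked),
        }
        if run.study_masked is not None:
            study["masked"] = _study_dict(run.study_masked)
        cio.write_results_table(run.results, results_path, parameters=parameters, study=study)
        artifacts["results"] = results_path
        _done("enrich", t0)

    if "sensitivity" in stages:
        t0 = _stage("sensitivity")
        sets = cio.read_gene_sets(sets_path)
        pcuts = cfg["sensitivity"].get("pcuts", [0.005, 0.03, 0.05])
        scan_all = bool(cfg["sensitivity"].get("scan_all", False))
        table = sensitivity_scan(
            snps, genes, ld, sets, enr_cfg, mask=mask, pcuts=pcuts, scan_all=scan_all
        )
        sens_path = outdir / "sensitivity.tsv"
        table.to_csv(sens_path, sep="\t", index=False, float_format="%.6g")
        artifacts["sensitivity"] = sens_path
        _done("sensitivity", t0)

    return artifacts


def _study_dict(study) -> dict:
    return {
        "observed_n_significant_categories": study.observed_n_significant_categories,
        "expected_n_significant_categories": study.expected_n_significant_categories,
        "study_p": study.study_p,
    }
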