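"""End-to-end orchestration: simulate -> filter -> concord -> correct ->
map -> scan -> extremes, with per-stage accounting in one machine-readable
run report. Identical configuration and seed give an identical report;
every intermediate artifact is written so any stage can be audited.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import correct as corr
from . import filters, linkage, qc, qtl, synth
from . import io as fio
from .correct import CorrectionConfig
from .extremes import ExtremesConfig, select_extremes, segregating_variants
from .filters import FilterConfig
from .linkage import LinkageConfig
from .qtl import ScanConfig

log = logging.getLogger("f2radmap")


@dataclass
class ScenarioConfig:
    """Synthetic-scenario parameters (ignored when a VCF is supplied)."""

    n_chromosomes: int = 19
    markers_per_chromosome: int = 100
    chromosome_cM: float = 200.0
    chromosome_bp: int = 40_000_000
    n_progeny: int = 192
    n_rep_p1: int = 4
    n_rep_p2: int = 3
    u_het_to_hom: float = 0.12
    e_hom_to_het: float = 0.065
    p_missing: float = 0.20
    qtl_chromosome: str = "chr2"
    qtl_cM: float = 60.0
    qtl_additive: float = 5.0
    qtl_dominance: float = 0.0
    qtl_pve: float = 0.09
    trait_baseline: float = 132.0


@dataclass
class RunConfig:
    seed: int = 0
    vcf: str | None = None  # observed data instead of simulation
    phenotypes: str | None = None
    roles: dict[str, str] | None = None
    genes_bed: str | None = None
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    correction: CorrectionConfig = field(default_factory=CorrectionConfig)
    linkage: LinkageConfig = field(default_factory=LinkageConfig)
    scan: ScanConfig = field(default_factory=ScanConfig)
    extremes: ExtremesConfig = field(default_factory=ExtremesConfig)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        for key in ("seed", "vcf", "phenotypes", "roles", "genes_bed"):
            if key in raw:
                kwargs[key] = raw[key]
        for key, klass in (
            ("scenario", ScenarioConfig),
            ("filters", FilterConfig),
            ("correction", CorrectionConfig),
            ("linkage", LinkageConfig),
            ("scan", ScanConfig),
            ("extremes", ExtremesConfig),
        ):
            if key in raw:
                kwargs[key] = klass(**raw[key])
        return cls(**kwargs)


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.time()
            log.info("stage %s ...", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s done in %.1fs", name, time.time() - t0)
            return out
        return inner
    return wrap


def run_all(config: RunConfig, outdir: str | os.PathLike) -> dict:
    """Execute every stage in fixed order and return the combined report
    (also written to ``<outdir>/run_report.json``)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed}
    rng_seed = config.seed

    # -- simulate (or load) --------------------------------------------
    @_stage("simulate")
    def do_simulate():
        sc = config.scenario
        if config.vcf is not None:
            if config.roles is None:
                raise ValueError("vcf input needs sample roles")
            matrix = fio.read_vcf(config.vcf, config.roles)
            pheno = (
                synth.read_phenotypes(config.phenotypes)
                if config.phenotypes is not None
                else None
            )
            return matrix, pheno
        sim_map = synth.SimMap.uniform(
            sc.n_chromosomes,
            sc.markers_per_chromosome,
            sc.chromosome_cM,
            sc.chromosome_bp,
        )
        error = synth.ErrorModel(
            u_het_to_hom=sc.u_het_to_hom,
            e_hom_to_het=sc.e_hom_to_het,
            p_missing=sc.p_missing,
        )
        qtl_spec = synth.QTLSpec(
            chromosome=sc.qtl_chromosome,
            cM=sc.qtl_cM,
            additive=sc.qtl_additive,
            dominance=sc.qtl_dominance,
            target_pve=sc.qtl_pve,
            baseline=sc.trait_baseline,
        )
        bundle = synth.simulate_bundle(
            sim_map, sc.n_progeny, error, qtl_spec,
            sc.n_rep_p1, sc.n_rep_p2, seed=rng_seed,
        )
        synth.emit_vcf(bundle, outdir / "simulated.vcf")
        synth.write_phenotypes(bundle.phenotypes, outdir / "phenotypes.tsv")
        report["simulate"] = {
            "n_markers": bundle.truth.n_markers,
            "n_progeny": sc.n_progeny,
            "qtl_chromosome": sc.qtl_chromosome,
            "qtl_cM": sc.qtl_cM,
        }
        return bundle.observed, bundle.phenotypes

    matrix, phenotypes = do_simulate()

    # -- filter cascade ------------------------------------------------
    @_stage("filter")
    def do_filter():
        m, cascade = filters.run_cascade(matrix, config.roles, config.filters)
        cascade.write(outdir / "filter_cascade.tsv")
        fio.write_matrix(m, outdir / "matrix_filtered.tsv")
        report["filter"] = {
            "stages": cascade.stages,
            "snps_out": m.n_markers,
            "individuals_out": m.n_samples,
        }
        return m

    filtered = do_filter()

    # -- concordance ---------------------------------------------------
    @_stage("concord")
    def do_concord():
        # discordance is measured after the basic site filters but before
        # parental-het exclusion, which would remove the discordant sites
        pre, _ = filters.basic_filters(matrix, config.filters)
        block = {}
        for role in ("parent1", "parent2"):
            rep = qc.pairwise_discordance(pre, role)
            block[role] = {
                "mean_discordance": rep.mean_discordance,
                "estimated_error_rate": rep.estimated_error_rate,
                "category_fractions": rep.category_fractions(),
            }
        het = qc.heterozygosity(filtered)
        block["mean_progeny_heterozygosity"] = float(
            het.iloc[filtered.progeny_index].mean()
        )
        report["concord"] = block

    do_concord()

    # -- correction ----------------------------------------------------
    @_stage("correct")
    def do_correct():
        fixed, crep = corr.correct_and_impute(filtered, config.correction)
        fio.write_matrix(fixed, outdir / "matrix_corrected.tsv")
        crep.type_frame().to_csv(outdir / "correction_types.tsv", sep="\t")
        report["correct"] = {
            "corrected_fraction": crep.corrected_fraction,
            "imputed_fraction": crep.imputed_fraction,
            "markers_removed_by_binning": len(crep.markers_removed),
        }
        return fixed

    corrected = do_correct()

    # -- linkage map ---------------------------------------------------
    @_stage("map")
    def do_map():
        calls = corrected.calls[corrected.progeny_index]
        r, lod, _ = linkage.pairwise_rf(calls)
        groups, discarded = linkage.group_markers(r, lod, config.linkage)
        bp = corrected.markers["bp"].to_numpy()
        ordered = [
            linkage.order_markers(g, r, config.linkage, bp) for g in groups
        ]
        ordered, removed = linkage.remove_outlier_markers(
            corrected, ordered, r, config.linkage
        )
        gmap = linkage.build_map(corrected, ordered, r)
        gmap.write(outdir / "genetic_map.tsv")
        xo = linkage.count_crossovers(corrected, gmap)
        rho = linkage.order_correlation(gmap)
        report["map"] = {
            "n_groups": len(gmap.groups),
            "n_markers": gmap.n_markers,
            "total_length_cM": gmap.total_length_cM,
            "discarded_small_groups": len(discarded),
            "outliers_removed": len(removed),
            "mean_crossovers_per_group": float(xo.mean().mean()) if len(xo) else None,
            "mean_order_rho": float(rho.mean()) if len(rho) else None,
        }
        return gmap

    gmap = do_map()

    # -- QTL scan ------------------------------------------------------
    @_stage("scan")
    def do_scan():
        if phenotypes is None:
            raise ValueError("no phenotypes available")
        cfg = ScanConfig(
            model=config.scan.model,
            n_permutations=config.scan.n_permutations,
            alpha=config.scan.alpha,
            lod_drop=config.scan.lod_drop,
            seed=rng_seed,
        )
        res = qtl.run_scan(corrected, phenotypes, cfg, gmap)
        res.table.to_csv(outdir / "scan.tsv", sep="\t", index=False)
        report["scan"] = {
            "threshold": res.threshold,
            "peaks": [asdict(p) for p in res.peaks],
        }
        return res

    do_scan()

    # -- extremes ------------------------------------------------------
    @_stage("extremes")
    def do_extremes():
        low, high = select_extremes(phenotypes, config.extremes)
        block = {"n_low": len(low), "n_high": len(high)}
        if len(low) and len(high):
            variants = segregating_variants(corrected, low, high, config.extremes)
            if config.genes_bed:
                from .extremes import annotate_proximity
                variants = annotate_proximity(
                    variants, fio.read_intervals(config.genes_bed),
                    config.extremes.proximity_bp,
                )
            variants.to_csv(outdir / "segregating_variants.tsv", sep="\t", index=False)
            block["n_segregating"] = len(variants)
        report["extremes"] = block

    do_extremes()

    with open(outdir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_jsonable)
    return report


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
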