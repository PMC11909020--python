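"""End-to-end orchestration: simulate -> qc -> prune -> score -> associate.

Each stage writes its outputs under the run directory and contributes row
counts to a manifest; re-running with the same config reproduces
byte-identical outputs (all randomness derives from the one seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml

from . import io, qc, associate
from .prune import prune as _prune
from . import score as score_mod
from .config import (
    PruneConfig,
    QCThresholds,
    SimulationConfig,
    ThresholdSet,
)
from .errors import StageError, ValidationError

STAGES = ("simulate", "qc", "prune", "score", "associate")


@dataclass
class RunConfig:
    """Everything one reproducible run needs.

    Either a :class:`SimulationConfig` (synthetic cohort) or the four
    input paths must be supplied per data role, never both.
    """

    out_dir: str = "prsdiff_run"
    sim: Optional[SimulationConfig] = None
    sumstats_path: Optional[str] = None
    vcf_path: Optional[str] = None
    phenotypes_path: Optional[str] = None
    covariates_path: Optional[str] = None
    sumstats_columns: dict = field(default_factory=dict)
    qc_thresholds: QCThresholds = field(default_factory=QCThresholds)
    prune_config: PruneConfig = field(default_factory=PruneConfig)
    thresholds: ThresholdSet = field(default_factory=ThresholdSet)
    alpha: float = 0.05

    def __post_init__(self):
        paths = (self.sumstats_path, self.vcf_path,
                 self.phenotypes_path, self.covariates_path)
        have_paths = any(p is not None for p in paths)
        if self.sim is not None and have_paths:
            raise ValidationError("supply either a simulation config or input "
                                  "paths, not both")
        if self.sim is None and not all(p is not None for p in paths):
            raise ValidationError("without a simulation config, all four input "
                                  "paths are required")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "sim" in kwargs and kwargs["sim"] is not None:
            sim = dict(kwargs["sim"])
            if "qc_plant_counts" in sim and isinstance(sim["qc_plant_counts"], dict):
                from .config import QCPlantCounts
                sim["qc_plant_counts"] = QCPlantCounts(**sim["qc_plant_counts"])
            for key in ("maf_range", "age_range", "affected_regions"):
                if key in sim and isinstance(sim[key], list):
                    sim[key] = tuple(sim[key])
            kwargs["sim"] = SimulationConfig(**sim)
        for key, klass in (("qc_thresholds", QCThresholds),
                           ("prune_config", PruneConfig)):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = klass(**kwargs[key])
        if "thresholds" in kwargs and isinstance(kwargs["thresholds"], (list, tuple)):
            kwargs["thresholds"] = ThresholdSet(tuple(kwargs["thresholds"]))
        return cls(**kwargs)


def fixture_run_config(seed: int = 1, out_dir: str = "prsdiff_run") -> RunConfig:
    """A run shaped like the intended target study: 168 samples, 5,000
    SNPs, cognition assessed in 145 and imaging in 126, a standardized
    effect of 0.21 planted on working memory and the left medial
    orbitofrontal surface area."""
    sim = SimulationConfig(
        seed=seed, n_target=168, n_blocks=100, snps_per_block=50,
        causal_fraction=0.1, effect_sd=0.1, prs_effect=0.21,
        affected_regions=("WM", "lh_medialorbitofrontal_area"),
        n_cognition=145, n_imaging=126,
    )
    return RunConfig(out_dir=out_dir, sim=sim)


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage name
                raise StageError(name, exc) from exc
        return inner
    return wrap


def run_pipeline(config: RunConfig) -> dict:
    """Execute all five stages; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": [], "seed": config.sim.seed if config.sim else None,
                      "config": _config_echo(config)}
    files: dict[str, Path] = {}

    # -- stage 1: simulate or load ------------------------------------
    @_stage("simulate")
    def stage_simulate():
        if config.sim is not None:
            from .simulate import simulate_cohort
            cohort = simulate_cohort(config.sim)
            files["genotypes"] = io.write_vcf(cohort["genotypes"],
                                              cohort["variants"],
                                              out / "genotypes.vcf")
            files["variants"] = io.write_table(cohort["variants"],
                                               out / "variants.tsv")
            files["truth"] = io.write_table(cohort["truth"], out / "truth.tsv")
            files["sumstats"] = io.write_table(cohort["sumstats"],
                                               out / "sumstats.tsv")
            files["phenotypes"] = io.write_table(cohort["phenotypes"],
                                                 out / "phenotypes.tsv")
            files["covariates"] = io.write_table(cohort["covariates"],
                                                 out / "covariates.tsv")
            sumstats = cohort["sumstats"].rename(columns=str)
            sumstats["chrom"] = sumstats["chrom"].astype(str)
            return cohort["genotypes"], cohort["variants"], sumstats, \
                cohort["phenotypes"], cohort["covariates"]
        genotypes, variants = io.read_vcf(config.vcf_path)
        sumstats = qc.parse_sumstats(config.sumstats_path,
                                     config.sumstats_columns)
        phenotypes = io.read_table(config.phenotypes_path)
        covariates = io.read_table(config.covariates_path)
        return genotypes, variants, sumstats, phenotypes, covariates

    genotypes, variants, sumstats, phenotypes, covariates = stage_simulate()
    manifest["stages"].append({"name": "simulate",
                               "samples": genotypes.n_samples,
                               "variants_out": genotypes.n_variants})

    # -- stage 2: QC + harmonization ----------------------------------
    @_stage("qc")
    def stage_qc():
        stats = qc.variant_stats(genotypes, variants)
        stats["chrom"] = stats["chrom"].astype(str)
        ss = sumstats.copy()
        ss["chrom"] = ss["chrom"].astype(str)
        kept, report = qc.filter_variants(stats, ss, config.qc_thresholds)
        weights, counts = qc.harmonize_alleles(ss, kept)
        io.write_table(report.to_frame(), out / "qc_report.tsv")
        io.write_table(weights, out / "weights.tsv")
        files["qc_report"] = out / "qc_report.tsv"
        files["weights"] = out / "weights.tsv"
        return kept, weights, report, counts

    kept_variants, weights, report, harmon_counts = stage_qc()
    manifest["stages"].append({"name": "qc",
                               "variants_in": report.variants_in,
                               "variants_out": report.variants_out,
                               "removed": report.counts,
                               "harmonization": harmon_counts})

    # -- stage 3: LD pruning -------------------------------------------
    @_stage("prune")
    def stage_prune():
        g_kept = genotypes.subset_variants(list(kept_variants["variant_id"]))
        kept_sorted = kept_variants.sort_values(
            ["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        g_sorted = g_kept.subset_variants(list(kept_sorted["variant_id"]))
        kept_ids, log = _prune(g_sorted, kept_sorted, weights,
                               config.prune_config)
        (out / "pruned_keep.txt").write_text("\n".join(kept_ids) + "\n")
        io.write_table(log, out / "prune_log.tsv")
        files["pruned_keep"] = out / "pruned_keep.txt"
        files["prune_log"] = out / "prune_log.tsv"
        return kept_ids

    kept_ids = stage_prune()
    manifest["stages"].append({"name": "prune",
                               "variants_in": len(kept_variants),
                               "variants_out": len(kept_ids)})

    # -- stage 4: scoring ----------------------------------------------
    @_stage("score")
    def stage_score():
        w = weights[weights["variant_id"].isin(kept_ids)]
        g = genotypes.subset_variants(kept_ids)
        prs = score_mod.build_prs_matrix(g, w, config.thresholds)
        files["prs"] = io.write_table(prs, out / "prs.tsv")
        return prs

    prs = stage_score()
    manifest["stages"].append({"name": "score",
                               "samples": len(prs),
                               "thresholds": list(config.thresholds.cutoffs)})

    # -- stage 5: association -------------------------------------------
    @_stage("associate")
    def stage_associate():
        cog = associate.run_cognitive_scan(phenotypes, prs, covariates,
                                           config.thresholds, config.alpha)
        cort = associate.run_cortical_scan(phenotypes, prs, covariates,
                                           config.thresholds, config.alpha)
        files["associations_cognitive"] = io.write_table(
            cog, out / "associations_cognitive.tsv")
        files["associations_cortical"] = io.write_table(
            cort, out / "associations_cortical.tsv")
        return cog, cort

    cog, cort = stage_associate()
    manifest["stages"].append({
        "name": "associate",
        "cognitive_tests": len(cog),
        "cortical_tests": len(cort),
        "bonferroni_significant": int(cort["significant_bonferroni"].sum()),
        "nominal_significant": int(cort["significant_nominal"].sum()),
    })

    manifest["checksums"] = {k: io.file_sha256(p) for k, p in sorted(files.items())}
    io.write_manifest(manifest, out / "manifest.json")
    return manifest


def _config_echo(config: RunConfig) -> dict:
    echo = {
        "out_dir": config.out_dir,
        "alpha": config.alpha,
        "thresholds": list(config.thresholds.cutoffs),
        "qc_thresholds": asdict(config.qc_thresholds),
        "prune_config": asdict(config.prune_config),
    }
    if config.sim is not None:
        echo["sim"] = asdict(config.sim)
    else:
        echo["inputs"] = {
            "sumstats": config.sumstats_path,
            "vcf": config.vcf_path,
            "phenotypes": config.phenotypes_path,
            "covariates": config.covariates_path,
        }
    return echo
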