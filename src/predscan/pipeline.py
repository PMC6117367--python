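"""End-to-end driver: simulate -> residualize -> fit -> project -> PheWAS.

One global seed fans out to per-stage seeds through a stage-name CRC32
derivation, so every stage is individually reproducible and reruns with
the same configuration are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from predscan import io as psio
from predscan.bslmm import MCMCConfig, compute_weights, fit_bslmm, residualize
from predscan.genotypes import GenotypeMatrix
from predscan.phewas import (
    PhecodeDefinition,
    PhenotypeRejected,
    PositiveControlSpec,
    adjust_multiplicity,
    assemble_case_control,
    compute_skewness,
    evaluate_positive_controls,
    results_to_frame,
    run_phewas,
)
from predscan.projection import align_alleles, project_scores
from predscan.simulate import (
    ArchitectureSpec,
    DiagnosisSpec,
    random_snp_panel,
    simulate_biomarker,
    simulate_covariates,
    simulate_diagnoses,
    simulate_genotypes,
)
from predscan.utils import derive_seed

logger = logging.getLogger("predscan")

CONFIG_SCHEMA: dict[str, Any] = {
    "$schema": "https://json-schema.org/draft/2020-12/schema",
    "title": "predscan pipeline configuration",
    "type": "object",
    "required": ["biomarker"],
    "properties": {
        "biomarker": {"type": "string"},
        "seed": {"type": "integer"},
        "adjust": {"type": "array", "items": {"type": "string"}},
        "mcmc": {
            "type": "object",
            "properties": {
                "n_steps": {"type": "integer", "minimum": 2},
                "n_burn": {"type": "integer", "minimum": 0},
                "thin": {"type": "integer", "minimum": 1},
            },
        },
        "thresholds": {
            "type": "object",
            "properties": {
                "alpha": {"type": "number", "exclusiveMinimum": 0, "maximum": 1},
                "fdr_q": {"type": "number", "exclusiveMinimum": 0, "maximum": 1},
                "min_cases": {"type": "integer", "minimum": 1},
                "min_site_cases": {"type": "integer", "minimum": 0},
                "rank_cutoff": {"type": "integer", "minimum": 1},
                "p_filter": {"type": "number", "exclusiveMinimum": 0, "maximum": 1},
                "n_biomarkers": {"type": "integer", "minimum": 1},
            },
        },
        "fdr_family": {"enum": ["per_biomarker", "global"]},
        "simulate": {"type": "object"},
        "inputs": {"type": "object"},
    },
}


@dataclass
class PipelineConfig:
    biomarker: str = "biomarker"
    seed: int = 0
    adjust: tuple[str, ...] = ("age", "sex", "pc1", "pc2")
    mcmc: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)
    fdr_family: str = "per_biomarker"
    simulate: dict | None = None
    inputs: dict | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw, base_dir=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict, base_dir: Path | None = None) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**{k: v for k, v in raw.items() if k in known})
        if isinstance(cfg.adjust, list):
            cfg.adjust = tuple(cfg.adjust)
        cfg.validate(base_dir)
        return cfg

    def validate(self, base_dir: Path | None = None) -> None:
        if self.simulate is None and self.inputs is None:
            raise ValueError("config needs either a 'simulate' or an 'inputs' section")
        th = self.thresholds
        for key, lo, hi in (
            ("alpha", 0.0, 1.0),
            ("fdr_q", 0.0, 1.0),
            ("p_filter", 0.0, 1.0),
        ):
            if key in th and not lo < th[key] <= hi:
                raise ValueError(f"threshold {key}={th[key]} outside ({lo}, {hi}]")
        if self.fdr_family not in ("per_biomarker", "global"):
            raise ValueError(f"bad fdr_family {self.fdr_family!r}")
        if self.inputs is not None:
            for key, p in self.inputs.items():
                path = Path(p)
                if base_dir is not None and not path.is_absolute():
                    path = base_dir / path
                if not path.exists():
                    raise ValueError(f"input path for {key!r} does not exist: {path}")
                self.inputs[key] = str(path)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


@dataclass
class RunManifest:
    config: dict
    package_version: str
    stage_seconds: dict[str, float]
    input_hashes: dict[str, str]
    warnings: list[str]

    def write(self, path: Path) -> None:
        tmp = path.with_suffix(".tmp")
        tmp.write_text(
            json.dumps(
                {
                    "config": self.config,
                    "package_version": self.package_version,
                    "stage_seconds": self.stage_seconds,
                    "input_hashes": self.input_hashes,
                    "warnings": self.warnings,
                },
                indent=2,
                sort_keys=True,
                default=str,
            )
            + "\n"
        )
        tmp.replace(path)


def _simulate_inputs(cfg: PipelineConfig, out: Path) -> dict:
    """Generate measurement and target cohorts per the simulate block."""
    sim = cfg.simulate
    seed = cfg.seed
    n_meas = int(sim.get("n_measurement", 1000))
    n_target = int(sim.get("n_target", 2000))
    n_snps = int(sim.get("n_snps", 500))
    arch_cfg = sim.get("architecture", {})
    arch = ArchitectureSpec(
        pve=float(arch_cfg.get("pve", 0.5)),
        pge=float(arch_cfg.get("pge", 0.8)),
        n_large=int(arch_cfg.get("n_large", 10)),
        n_poly=int(arch_cfg.get("n_poly", 100)),
        seed=derive_seed(seed, "biomarker"),
    )
    panel = random_snp_panel(n_snps, derive_seed(seed, "panel"))
    g_meas = simulate_genotypes(n_meas, panel, derive_seed(seed, "genotypes_meas"))
    g_target = simulate_genotypes(n_target, panel, derive_seed(seed, "genotypes_target"))
    cov_meas = simulate_covariates(g_meas.samples, derive_seed(seed, "cov_meas"))
    cov_target = simulate_covariates(
        [f"T{s}" for s in g_target.samples], derive_seed(seed, "cov_target")
    )
    g_target = GenotypeMatrix(
        samples=list(cov_target["sample_id"]), snps=g_target.snps, dosages=g_target.dosages
    )
    trait, truth = simulate_biomarker(g_meas, arch)

    # diagnoses in the target cohort share the biomarker's genetic effects
    Xt = g_target.mean_imputed()
    g_true_target = (Xt - Xt.mean(axis=0)) @ truth.effects

    specs = []
    for ph in sim.get("phenotypes", []):
        specs.append(
            DiagnosisSpec(
                phecode=str(ph["phecode"]),
                prevalence=float(ph.get("prevalence", 0.1)),
                genetic_log_or=float(ph.get("genetic_log_or", 0.0)),
                exclusion_codes=tuple(str(c) for c in ph.get("exclusion_codes", [])),
                sex_restriction=ph.get("sex_restriction", "both"),
            )
        )
    occurrences = simulate_diagnoses(
        g_true_target, specs, cov_target, derive_seed(seed, "diagnoses")
    )
    definitions = [
        PhecodeDefinition(
            phecode=s.phecode,
            label=f"simulated {s.phecode}",
            exclusion_codes=s.exclusion_codes,
            sex_restriction=s.sex_restriction,
        )
        for s in specs
    ]
    controls = [
        PositiveControlSpec(
            biomarker=cfg.biomarker,
            control_phecodes=tuple(str(c) for c in sim.get("positive_controls", [])),
        )
    ] if sim.get("positive_controls") else []

    sim_dir = out / "simulated"
    sim_dir.mkdir(parents=True, exist_ok=True)
    psio.write_dosage_tsv(g_meas, sim_dir / "measurement.dosage.tsv")
    psio.write_dosage_tsv(g_target, sim_dir / "target.dosage.tsv")
    pd.DataFrame({"sample_id": g_meas.samples, cfg.biomarker: trait}).to_csv(
        sim_dir / "biomarker.tsv", sep="\t", index=False
    )
    psio.write_covariates(cov_meas, sim_dir / "covariates_measurement.tsv")
    psio.write_covariates(cov_target, sim_dir / "covariates_target.tsv")
    psio.write_occurrences(occurrences, sim_dir / "occurrences.csv")
    psio.write_definitions(definitions, sim_dir / "definitions.csv")
    if controls:
        psio.write_positive_controls(controls, sim_dir / "positive_controls.csv")
    return {
        "g_meas": g_meas,
        "trait": trait,
        "cov_meas": cov_meas,
        "g_target": g_target,
        "cov_target": cov_target,
        "occurrences": occurrences,
        "definitions": definitions,
        "controls": controls,
        "truth": truth,
    }


def _load_inputs(cfg: PipelineConfig) -> dict:
    paths = cfg.inputs
    g_meas = psio.read_genotypes(paths["measurement_genotypes"])
    trait_df = pd.read_csv(paths["trait"], sep="\t", dtype={"sample_id": str})
    cov_meas = psio.read_covariates(paths["measurement_covariates"])
    g_target = psio.read_genotypes(paths["target_genotypes"])
    cov_target = psio.read_covariates(paths["target_covariates"])
    occurrences = psio.read_occurrences(paths["occurrences"])
    definitions = psio.read_definitions(paths["definitions"])
    controls = (
        psio.read_positive_controls(paths["positive_controls"])
        if "positive_controls" in paths
        else []
    )
    trait_col = cfg.biomarker if cfg.biomarker in trait_df.columns else trait_df.columns[1]
    trait = (
        trait_df.set_index("sample_id")[trait_col].reindex(g_meas.samples).to_numpy()
    )
    return {
        "g_meas": g_meas,
        "trait": trait,
        "cov_meas": cov_meas,
        "g_target": g_target,
        "cov_target": cov_target,
        "occurrences": occurrences,
        "definitions": definitions,
        "controls": controls,
        "truth": None,
    }


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> RunManifest:
    """Execute the full paradigm and write every stage output under out_dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    th = {
        "alpha": 0.05,
        "fdr_q": 0.1,
        "min_cases": 300,
        "min_site_cases": 10,
        "rank_cutoff": 5,
        "p_filter": 0.1,
        "n_biomarkers": 1,
        **config.thresholds,
    }
    stage_seconds: dict[str, float] = {}
    warnings_log: list[str] = []

    def stage(name):
        logger.info("[%s] start", name)
        stage_seconds[name] = time.perf_counter()
        return name

    def done(name):
        stage_seconds[name] = round(time.perf_counter() - stage_seconds[name], 3)
        logger.info("[%s] done in %.3fs", name, stage_seconds[name])

    s = stage("inputs")
    data = _simulate_inputs(config, out) if config.simulate else _load_inputs(config)
    done(s)

    s = stage("residualize")
    cov_meas = data["cov_meas"]
    adjust = [c for c in config.adjust if c in cov_meas.columns]
    y = residualize(data["trait"], cov_meas[adjust] if adjust else None)
    done(s)

    s = stage("fit_bslmm")
    mcmc = MCMCConfig(
        n_steps=int(config.mcmc.get("n_steps", 100_000)),
        n_burn=config.mcmc.get("n_burn"),
        thin=int(config.mcmc.get("thin", 10)),
        seed=derive_seed(config.seed, "bslmm"),
    )
    fit = fit_bslmm(data["g_meas"], y, mcmc)
    if fit.dropped_snps:
        warnings_log.append(f"dropped {len(fit.dropped_snps)} constant SNPs during fit")
    psio.write_fit_report(fit, out / "fit.json", seed=config.seed)
    done(s)

    s = stage("compute_weights")
    weights = compute_weights(fit, data["g_meas"].snps)
    psio.write_weights(weights, out / "weights.tsv")
    done(s)

    s = stage("align_alleles")
    aligned, report = align_alleles(weights, data["g_target"].snps)
    (out / "alignment.json").write_text(json.dumps(report.to_dict(), indent=2) + "\n")
    if report.n_dropped_ambiguous:
        warnings_log.append(f"{report.n_dropped_ambiguous} strand-ambiguous SNPs dropped")
    done(s)

    s = stage("project_scores")
    scores = project_scores(
        data["g_target"], aligned, biomarker=config.biomarker, alignment=report
    )
    psio.write_scores(scores, out / "scores.tsv")
    done(s)

    s = stage("case_control")
    cov_target = data["cov_target"]
    assignments = []
    rejected = {}
    for d in data["definitions"]:
        try:
            assignments.append(
                assemble_case_control(
                    data["occurrences"],
                    d,
                    cov_target,
                    min_cases=th["min_cases"],
                    min_site_cases=th["min_site_cases"],
                )
            )
        except PhenotypeRejected as exc:
            rejected[d.phecode] = exc.reason
    if rejected:
        warnings_log.append(f"{len(rejected)} phenotypes rejected")
    if not assignments:
        raise RuntimeError("case_control: every phenotype was rejected")
    done(s)

    s = stage("phewas")
    defs_by_code = {d.phecode: d for d in data["definitions"]}
    results = run_phewas(scores, assignments, cov_target, defs_by_code)
    n_nonconv = sum(not r.converged for r in results)
    if n_nonconv:
        warnings_log.append(f"{n_nonconv} non-converged logistic fits")
    results, thresholds = adjust_multiplicity(
        results,
        n_biomarkers=th["n_biomarkers"],
        n_phenotypes=len(results),
        alpha=th["alpha"],
        fdr_q=th["fdr_q"],
        fdr_family=config.fdr_family,
    )
    frame = results_to_frame(results)
    frame.to_csv(out / "results.tsv", sep="\t", index=False, float_format="%.10g")
    (out / "thresholds.json").write_text(json.dumps(thresholds, indent=2) + "\n")
    done(s)

    s = stage("positive_controls")
    if data["controls"]:
        categories, summary = evaluate_positive_controls(
            results, data["controls"], rank_cutoff=th["rank_cutoff"], fdr_q=th["fdr_q"]
        )
        (out / "positive_controls.json").write_text(
            json.dumps(
                {"categories": {k: sorted(v) for k, v in categories.items()},
                 "summary": summary},
                indent=2,
            )
            + "\n"
        )
    done(s)

    s = stage("skewness")
    try:
        skew = compute_skewness(results, min_cases=min(th["min_cases"], 150), fdr_q=th["fdr_q"])
    except ValueError as exc:
        skew = None
        warnings_log.append(f"skewness undefined: {exc}")
    (out / "skewness.json").write_text(
        json.dumps({"skewness": skew, "rejected_phenotypes": rejected}, indent=2) + "\n"
    )
    done(s)

    input_hashes = {
        p.name: _sha256(p)
        for p in sorted(out.glob("simulated/*"))
        if p.is_file()
    }
    if config.inputs:
        input_hashes.update({k: _sha256(Path(v)) for k, v in config.inputs.items()})
    manifest = RunManifest(
        config={
            "biomarker": config.biomarker,
            "seed": config.seed,
            "adjust": list(config.adjust),
            "mcmc": dict(config.mcmc),
            "thresholds": th,
            "fdr_family": config.fdr_family,
            "simulate": config.simulate,
            "inputs": config.inputs,
        },
        package_version=_package_version(),
        stage_seconds=stage_seconds,
        input_hashes=input_hashes,
        warnings=warnings_log,
    )
    manifest.write(out / "manifest.json")
    return manifest


def _package_version() -> str:
    from predscan import __version__

    return __version__
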