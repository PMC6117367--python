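"""Readers and writers for the pipeline's on-disk formats.

Formats: dosage TSV (samples x SNPs matrix plus a SNP metadata sidecar),
minimal VCF 4.2 with a DS FORMAT field (GT fallback on read), long
occurrence CSV (sample_id, phecode, count), phecode definition CSV, weight
TSV in the fitter's dialect, and score TSV.  Dosage TSV round-trips
losslessly with the writer.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from predscan.bslmm import BslmmFit, SnpWeightSet
from predscan.genotypes import GenotypeMatrix, SnpRecord
from predscan.phewas import PhecodeDefinition, PositiveControlSpec
from predscan.projection import ScoreVector

META_COLUMNS = ["snp_id", "chrom", "pos", "coded_allele", "other_allele", "maf"]


def _meta_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.tsv")


# ---------------------------------------------------------------------------
# dosage TSV


def write_dosage_tsv(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Matrix TSV (header of snp_ids, one row per sample) plus metadata sidecar."""
    path = Path(path)
    df = pd.DataFrame(genotypes.dosages, columns=genotypes.snp_ids)
    df.insert(0, "sample_id", genotypes.samples)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g", na_rep="NA")
    meta = pd.DataFrame(
        [
            {
                "snp_id": s.snp_id,
                "chrom": s.chrom,
                "pos": s.pos,
                "coded_allele": s.coded_allele,
                "other_allele": s.other_allele,
                "maf": s.maf,
            }
            for s in genotypes.snps
        ],
        columns=META_COLUMNS,
    )
    meta.to_csv(_meta_path(path), sep="\t", index=False, float_format="%.17g")


def read_dosage_tsv(path: str | Path) -> GenotypeMatrix:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta_path = _meta_path(path)
    if not meta_path.exists():
        raise FileNotFoundError(f"metadata sidecar missing: {meta_path}")
    meta = pd.read_csv(
        meta_path, sep="\t", dtype={"chrom": str, "snp_id": str},
        float_precision="round_trip",
    )
    snps = [
        SnpRecord(
            snp_id=r.snp_id,
            chrom=str(r.chrom),
            pos=int(r.pos),
            coded_allele=r.coded_allele,
            other_allele=r.other_allele,
            maf=float(r.maf),
        )
        for r in meta.itertuples(index=False)
    ]
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "sample_id":
            raise ValueError(f"{path}:1: first column must be sample_id")
        snp_ids = header[1:]
        n_cols = len(header)
        samples = []
        rows = []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != n_cols:
                raise ValueError(
                    f"{path}:{lineno}: expected {n_cols} fields, got {len(fields)}"
                )
            samples.append(fields[0])
            try:
                rows.append(
                    [np.nan if v == "NA" else float(v) for v in fields[1:]]
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad dosage value ({exc})") from None
    if snp_ids != [s.snp_id for s in snps]:
        raise ValueError(f"{path}: header snp_ids disagree with sidecar {meta_path}")
    dosages = np.array(rows, dtype=float) if rows else np.empty((0, len(snps)))
    return GenotypeMatrix(samples=samples, snps=snps, dosages=dosages)


# ---------------------------------------------------------------------------
# VCF


def write_vcf(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Minimal VCF 4.2 with DS (coded-allele dosage) as the ALT allele dose."""
    path = Path(path)
    order = sorted(
        range(genotypes.n_snps),
        key=lambda j: (genotypes.snps[j].chrom, genotypes.snps[j].pos),
    )
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Coded allele dosage">\n'
        )
        for chrom in sorted({s.chrom for s in genotypes.snps}):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.samples)
            + "\n"
        )
        for j in order:
            s = genotypes.snps[j]
            col = genotypes.dosages[:, j]
            ds = "\t".join("." if np.isnan(v) else f"{v:.6g}" for v in col)
            fh.write(
                f"{s.chrom}\t{s.pos}\t{s.snp_id}\t{s.other_allele}\t"
                f"{s.coded_allele}\t.\t.\t.\tDS\t{ds}\n"
            )


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read dosages from DS, falling back to GT coded-allele counts.

    The ALT allele is taken as the coded allele; ``maf`` on each record is
    the folded sample allele frequency.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snps: list[SnpRecord] = []
    cols: list[np.ndarray] = []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(f"{path}: {var.ID}: multi-allelic records unsupported")
        ds = None
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            col = np.asarray(ds, dtype=float).reshape(-1)
            col = np.where((col < 0) | (col > 2), np.nan, col)
        else:
            gts = var.genotype.array()
            if gts is None:
                raise ValueError(f"{path}: {var.ID}: neither DS nor GT present")
            alleles = gts[:, :2].astype(float)
            alleles[alleles < 0] = np.nan
            col = alleles.sum(axis=1)
        freq = float(np.nanmean(col) / 2.0) if np.isfinite(col).any() else 0.0
        snps.append(
            SnpRecord(
                snp_id=var.ID or f"{var.CHROM}:{var.POS}",
                chrom=str(var.CHROM),
                pos=int(var.POS),
                coded_allele=var.ALT[0],
                other_allele=var.REF,
                maf=min(freq, 1.0 - freq),
            )
        )
        cols.append(col)
    dosages = (
        np.column_stack(cols) if cols else np.empty((len(samples), 0))
    )
    return GenotypeMatrix(samples=samples, snps=snps, dosages=dosages)


def read_genotypes(path: str | Path, fmt: str | None = None) -> GenotypeMatrix:
    """Dispatch on declared or inferred format (vcf | dosage_tsv)."""
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix == ".vcf" else "dosage_tsv"
    if fmt == "vcf":
        return read_vcf(path)
    if fmt == "dosage_tsv":
        return read_dosage_tsv(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


# ---------------------------------------------------------------------------
# tables


def write_occurrences(occ: pd.DataFrame, path: str | Path) -> None:
    occ[["sample_id", "phecode", "count"]].to_csv(path, index=False)


def read_occurrences(path: str | Path) -> pd.DataFrame:
    occ = pd.read_csv(path, dtype={"sample_id": str, "phecode": str})
    missing = {"sample_id", "phecode", "count"} - set(occ.columns)
    if missing:
        raise ValueError(f"{path}: occurrence table missing columns {sorted(missing)}")
    return occ


def write_definitions(defs: list[PhecodeDefinition], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "phecode": d.phecode,
                "label": d.label,
                "exclusion_codes": ";".join(d.exclusion_codes),
                "sex_restriction": d.sex_restriction,
            }
            for d in defs
        ]
    ).to_csv(path, index=False)


def read_definitions(path: str | Path) -> list[PhecodeDefinition]:
    df = pd.read_csv(path, dtype=str).fillna("")
    missing = {"phecode", "label", "exclusion_codes", "sex_restriction"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: definition table missing columns {sorted(missing)}")
    return [
        PhecodeDefinition(
            phecode=r.phecode,
            label=r.label,
            exclusion_codes=tuple(c for c in r.exclusion_codes.split(";") if c),
            sex_restriction=r.sex_restriction or "both",
        )
        for r in df.itertuples(index=False)
    ]


def write_positive_controls(specs: list[PositiveControlSpec], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"biomarker": s.biomarker, "control_phecodes": ";".join(s.control_phecodes)}
            for s in specs
        ]
    ).to_csv(path, index=False)


def read_positive_controls(path: str | Path) -> list[PositiveControlSpec]:
    df = pd.read_csv(path, dtype=str).fillna("")
    return [
        PositiveControlSpec(
            biomarker=r.biomarker,
            control_phecodes=tuple(c for c in r.control_phecodes.split(";") if c),
        )
        for r in df.itertuples(index=False)
    ]


def write_covariates(cov: pd.DataFrame, path: str | Path) -> None:
    cov.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_covariates(path: str | Path) -> pd.DataFrame:
    cov = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in cov.columns:
        raise ValueError(f"{path}: covariate table needs a sample_id column")
    return cov.set_index("sample_id", drop=False)


# ---------------------------------------------------------------------------
# weights, scores, fit report


def write_weights(weights: SnpWeightSet, path: str | Path) -> None:
    weights.table.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_weights(path: str | Path) -> SnpWeightSet:
    df = pd.read_csv(
        path, sep="\t", dtype={"snp_id": str, "chrom": str},
        float_precision="round_trip",
    )
    return SnpWeightSet(df)


def write_scores(scores: ScoreVector, path: str | Path) -> None:
    scores.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_scores(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample_id": str})


def write_fit_report(fit: BslmmFit, path: str | Path, seed: int | None = None) -> None:
    cfg = fit.config
    report = {
        "pve": {"median": fit.pve.median, "ci": [fit.pve.ci_low, fit.pve.ci_high]},
        "pge": {"median": fit.pge.median, "ci": [fit.pge.ci_low, fit.pge.ci_high]},
        "n_gamma": {
            "median": fit.n_gamma.median,
            "ci": [fit.n_gamma.ci_low, fit.n_gamma.ci_high],
        },
        "acceptance": fit.acceptance,
        "ess": fit.ess,
        "dropped_snps": fit.dropped_snps,
        "config": {
            "n_steps": cfg.n_steps,
            "n_burn": cfg.burn,
            "thin": cfg.thin,
            "seed": cfg.seed,
        }
        if cfg
        else None,
        "seed": seed,
    }
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
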