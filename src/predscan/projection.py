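"""Project SNP weights onto a target cohort: allele alignment and scoring.

The genetically predicted biomarker for sample j is

    raw_j = sum_i w_i * dosage_ji

over aligned SNPs, with the dosage counting the weight's coded allele.  The
standardized score is centered and scaled to unit standard deviation in the
target cohort, so downstream odds ratios are per SD of predicted biomarker.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from predscan.bslmm import SnpWeightSet
from predscan.genotypes import COMPLEMENT, GenotypeMatrix, SnpRecord

__all__ = ["AlignmentReport", "ScoreVector", "align_alleles", "project_scores"]


@dataclass
class AlignmentReport:
    """Per-SNP disposition of a weight set against a target panel."""

    n_matched: int
    n_flipped: int
    n_dropped_ambiguous: int
    n_missing_in_target: int
    n_incompatible: int
    dispositions: pd.DataFrame = field(repr=False)  # snp_id, disposition

    def to_dict(self) -> dict:
        return {
            "n_matched": self.n_matched,
            "n_flipped": self.n_flipped,
            "n_dropped_ambiguous": self.n_dropped_ambiguous,
            "n_missing_in_target": self.n_missing_in_target,
            "n_incompatible": self.n_incompatible,
        }


@dataclass
class ScoreVector:
    samples: list[str]
    raw: np.ndarray
    standardized: np.ndarray
    biomarker: str = "biomarker"
    weight_hash: str = ""
    alignment: AlignmentReport | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.samples, "raw": self.raw, "standardized": self.standardized}
        )


def align_alleles(
    weights: SnpWeightSet,
    target_snps: list[SnpRecord],
    maf_ambiguity_window: tuple[float, float] = (0.4, 0.6),
) -> tuple[SnpWeightSet, AlignmentReport]:
    """Reconcile weight-set alleles with the target panel.

    Matching is by snp_id with allele verification.  Same pair, swapped
    order: the weight flips sign (the target's coded allele is the weight's
    other allele).  Strand complements are resolved by complementing the
    weight alleles first.  A/T and C/G SNPs are strand-ambiguous — for
    those, when the target MAF falls inside ``maf_ambiguity_window`` the
    orientation cannot be resolved by frequency and the SNP is dropped.
    Allele pairs compatible with no orientation are dropped, not fatal.
    """
    target_by_id = {}
    for rec in target_snps:
        if rec.snp_id in target_by_id:
            raise ValueError(f"duplicate snp_id in target panel: {rec.snp_id}")
        target_by_id[rec.snp_id] = rec

    lo, hi = maf_ambiguity_window
    rows = []
    dispo = []
    n_flipped = n_ambig = n_missing = n_incomp = 0
    for row in weights.table.itertuples(index=False):
        tgt = target_by_id.get(row.snp_id)
        if tgt is None:
            n_missing += 1
            dispo.append((row.snp_id, "missing_in_target"))
            continue
        a, b = row.coded_allele, row.other_allele
        ambiguous = COMPLEMENT[a] == b
        if ambiguous:
            # target MAF refers to the minor allele; the window is symmetric
            if lo <= tgt.maf <= hi or lo <= 1 - tgt.maf <= hi:
                n_ambig += 1
                dispo.append((row.snp_id, "dropped_ambiguous"))
                continue
        if (tgt.coded_allele, tgt.other_allele) == (a, b):
            flip = False
        elif (tgt.coded_allele, tgt.other_allele) == (b, a):
            flip = True
        elif (tgt.coded_allele, tgt.other_allele) == (COMPLEMENT[a], COMPLEMENT[b]):
            flip = False  # other strand, same orientation
        elif (tgt.coded_allele, tgt.other_allele) == (COMPLEMENT[b], COMPLEMENT[a]):
            flip = True
        else:
            n_incomp += 1
            dispo.append((row.snp_id, "incompatible_alleles"))
            continue
        w = -row.w if flip else row.w
        alpha = -row.alpha if flip else row.alpha
        beta = -row.beta if flip else row.beta
        if flip:
            n_flipped += 1
        dispo.append((row.snp_id, "flipped" if flip else "matched"))
        rows.append(
            {
                "snp_id": row.snp_id,
                "chrom": tgt.chrom,
                "pos": tgt.pos,
                "coded_allele": tgt.coded_allele,
                "other_allele": tgt.other_allele,
                "alpha": alpha,
                "beta": beta,
                "gamma": row.gamma,
                "w": w,
            }
        )
    aligned = SnpWeightSet(pd.DataFrame(rows, columns=SnpWeightSet.COLUMNS))
    report = AlignmentReport(
        n_matched=len(rows),
        n_flipped=n_flipped,
        n_dropped_ambiguous=n_ambig,
        n_missing_in_target=n_missing,
        n_incompatible=n_incomp,
        dispositions=pd.DataFrame(dispo, columns=["snp_id", "disposition"]),
    )
    return aligned, report


def project_scores(
    target: GenotypeMatrix,
    aligned: SnpWeightSet,
    biomarker: str = "biomarker",
    alignment: AlignmentReport | None = None,
) -> ScoreVector:
    """Weighted dosage sum per sample, then center and scale to SD 1.

    Missing target dosages are mean-imputed (2 x target allele frequency),
    which preserves the score expectation.  Centering is included so the
    standardized score is invariant to which allele each weight codes.
    """
    if len(aligned) == 0:
        raise ValueError("no aligned SNPs to project")
    idx = {sid: i for i, sid in enumerate(target.snp_ids)}
    missing = [s for s in aligned.table["snp_id"] if s not in idx]
    if missing:
        raise ValueError(f"aligned SNPs absent from target genotypes: {missing[:5]}")
    cols = [idx[s] for s in aligned.table["snp_id"]]
    X = target.mean_imputed()[:, cols]
    for j, (sid, coded) in enumerate(
        zip(aligned.table["snp_id"], aligned.table["coded_allele"])
    ):
        rec = target.snps[cols[j]]
        if rec.coded_allele != coded:
            # aligned table carries the target orientation; a mismatch means
            # the caller skipped align_alleles
            raise ValueError(f"{sid}: weight coded allele differs from target dosage allele")
    w = aligned.table["w"].to_numpy()
    raw = X @ w
    sd = raw.std()
    if sd == 0:
        raise ValueError("raw scores are constant; standardization undefined")
    std = (raw - raw.mean()) / sd
    h = hashlib.sha256(
        pd.util.hash_pandas_object(aligned.table, index=False).to_numpy().tobytes()
    ).hexdigest()[:16]
    return ScoreVector(
        samples=list(target.samples),
        raw=raw,
        standardized=std,
        biomarker=biomarker,
        weight_hash=h,
        alignment=alignment,
    )
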