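"""Dosage matrices and per-SNP metadata shared by both cohorts."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

VALID_BASES = frozenset("ACGT")

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Sentinel for a missing dosage inside the float matrix.
MISSING = np.nan


@dataclass(frozen=True)
class SnpRecord:
    """Identity metadata for one biallelic SNP.

    The coded allele is the allele counted by the 0/1/2 dosage; ``maf`` is
    the design minor-allele frequency used by the simulator and by the
    strand-ambiguity rule during allele alignment.
    """

    snp_id: str
    chrom: str
    pos: int
    coded_allele: str
    other_allele: str
    maf: float

    def __post_init__(self) -> None:
        if self.coded_allele not in VALID_BASES or self.other_allele not in VALID_BASES:
            raise ValueError(
                f"{self.snp_id}: alleles must be single bases, got "
                f"{self.coded_allele!r}/{self.other_allele!r}"
            )
        if self.coded_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: coded and other allele are identical")
        if not 0.0 <= self.maf <= 0.5:
            raise ValueError(f"{self.snp_id}: maf {self.maf} outside [0, 0.5]")
        if self.pos < 1:
            raise ValueError(f"{self.snp_id}: pos must be >= 1")

    @property
    def is_strand_ambiguous(self) -> bool:
        """A/T and C/G pairs read the same on both strands."""
        return COMPLEMENT[self.coded_allele] == self.other_allele


@dataclass
class GenotypeMatrix:
    """Samples x SNPs dosage matrix with per-SNP allele metadata.

    Dosages count copies of each SNP's coded allele: integers for hard
    calls, fractional values in [0, 2] for imputed dosages, NaN for missing.
    """

    samples: list[str]
    snps: list[SnpRecord]
    dosages: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} snps"
            )
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate snp_id in panel")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample identifiers")
        finite = self.dosages[np.isfinite(self.dosages)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValueError("dosages outside [0, 2]")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def sample_allele_freqs(self) -> np.ndarray:
        """Coded-allele frequency per SNP from non-missing dosages."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def mean_imputed(self) -> np.ndarray:
        """Dosage matrix with missing entries replaced by 2 * allele freq."""
        if not np.isnan(self.dosages).any():
            return self.dosages.copy()
        out = self.dosages.copy()
        fill = 2.0 * self.sample_allele_freqs()
        idx = np.where(np.isnan(out))
        out[idx] = fill[idx[1]]
        return out

    def subset_samples(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = list(indices)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            snps=list(self.snps),
            dosages=self.dosages[idx, :],
        )

    def subset_snps(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = list(indices)
        return GenotypeMatrix(
            samples=list(self.samples),
            snps=[self.snps[i] for i in idx],
            dosages=self.dosages[:, idx],
        )
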