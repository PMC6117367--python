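"""Synthetic cohorts with the statistical structure the paradigm assumes.

The generator produces biallelic dosages in linkage equilibrium, a
quantitative biomarker with a controlled sparse-plus-polygenic architecture
(PVE = proportion of trait variance from all SNPs, PGE = proportion of the
genetic variance from the large-effect SNPs), binary diagnoses from a
logistic liability model sharing the biomarker's true genetic value, and a
covariate table (sex, birth decade, site, platform, principal components).
Every stage is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from predscan.genotypes import GenotypeMatrix, SnpRecord

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class ArchitectureSpec:
    """Target genetic architecture for a simulated biomarker.

    pve: trait variance fraction explained by all SNPs jointly, in [0, 1].
    pge: fraction of the genetic variance carried by the ``n_large``
        large-effect SNPs, in [0, 1].
    n_large / n_poly: counts of large-effect and small-effect causal SNPs.
    rescale: "exact" scales the realized components so the in-sample
        variance fractions equal pve/pge to machine precision (sharp test
        oracles); "sampled" draws effects from the implied normal priors so
        realized fractions fluctuate around the targets.
    """

    pve: float
    pge: float
    n_large: int
    n_poly: int
    seed: int
    rescale: str = "exact"

    def __post_init__(self) -> None:
        if not 0.0 <= self.pve <= 1.0:
            raise ValueError(f"pve {self.pve} outside [0, 1]")
        if not 0.0 <= self.pge <= 1.0:
            raise ValueError(f"pge {self.pge} outside [0, 1]")
        if self.n_large < 0 or self.n_poly < 0:
            raise ValueError("n_large and n_poly must be >= 0")
        if self.pve > 0 and self.pge > 0 and self.n_large < 1:
            raise ValueError("pge > 0 requires at least one large-effect SNP")
        if self.pve > 0 and self.pge < 1 and self.n_poly < 1:
            raise ValueError("pge < 1 requires at least one polygenic SNP")
        if self.rescale not in ("exact", "sampled"):
            raise ValueError("rescale must be 'exact' or 'sampled'")


@dataclass(frozen=True)
class DiagnosisSpec:
    """One simulated phecode phenotype.

    ``genetic_log_or`` couples case liability to the biomarker's true
    genetic value (per SD) through a logistic model, so planted log-odds
    ratios are recoverable on the same scale the downstream PheWAS uses.
    ``exclusion_codes`` name closely related phecodes whose carriers must
    not serve as controls.
    """

    phecode: str
    prevalence: float
    genetic_log_or: float = 0.0
    exclusion_codes: tuple[str, ...] = ()
    sex_restriction: str = "both"

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError(f"{self.phecode}: prevalence {self.prevalence} outside (0, 1)")
        if self.sex_restriction not in ("both", "male", "female"):
            raise ValueError(f"{self.phecode}: bad sex_restriction {self.sex_restriction!r}")
        if self.phecode in self.exclusion_codes:
            raise ValueError(f"{self.phecode}: phecode listed in its own exclusion codes")


@dataclass
class BiomarkerTruth:
    """Ground truth behind a simulated biomarker.

    ``effects`` are per-SNP effects on the centered-dosage scale;
    ``genetic_value`` is the per-sample true genetic value (large + poly
    components); realized fractions are computed in-sample with ddof=0.
    """

    effects: np.ndarray
    large_idx: np.ndarray
    poly_idx: np.ndarray
    genetic_value: np.ndarray
    large_component: np.ndarray
    poly_component: np.ndarray
    realized_pve: float
    realized_pge: float


# ---------------------------------------------------------------------------
# genotype panel


def random_snp_panel(
    n_snps: int,
    seed: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    chrom: str = "1",
) -> list[SnpRecord]:
    """A panel of biallelic SNPs with MAFs uniform on ``maf_range``."""
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    rng = np.random.default_rng(seed)
    mafs = rng.uniform(*maf_range, size=n_snps)
    # strictly increasing positions without materializing the whole range
    positions = np.sort(rng.integers(1, 10**8 - n_snps, size=n_snps)) + np.arange(n_snps)
    records = []
    for i in range(n_snps):
        a, b = rng.choice(4, size=2, replace=False)
        records.append(
            SnpRecord(
                snp_id=f"rs{i + 1}",
                chrom=chrom,
                pos=int(positions[i]),
                coded_allele=str(_BASES[a]),
                other_allele=str(_BASES[b]),
                maf=float(mafs[i]),
            )
        )
    return records


def simulate_genotypes(
    n_samples: int, snp_specs: list[SnpRecord], seed: int
) -> GenotypeMatrix:
    """Draw hard-call dosages Binomial(2, maf) per SNP, no LD.

    Linkage equilibrium keeps downstream variance-decomposition oracles
    exact; LD structure is deliberately out of scope.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if not snp_specs:
        raise ValueError("snp_specs is empty")
    rng = np.random.default_rng(seed)
    mafs = np.array([s.maf for s in snp_specs])
    dosages = rng.binomial(2, mafs, size=(n_samples, len(snp_specs))).astype(float)
    samples = [f"S{i + 1:06d}" for i in range(n_samples)]
    return GenotypeMatrix(samples=samples, snps=list(snp_specs), dosages=dosages)


def inject_missing(genotypes: GenotypeMatrix, rate: float, seed: int) -> GenotypeMatrix:
    """Set a fraction ``rate`` of dosages to missing, completely at random."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    mask = rng.random(genotypes.dosages.shape) < rate
    dosages = genotypes.dosages.copy()
    dosages[mask] = np.nan
    return GenotypeMatrix(list(genotypes.samples), list(genotypes.snps), dosages)


# ---------------------------------------------------------------------------
# biomarker


def _var(x: np.ndarray) -> float:
    return float(np.var(x))  # ddof=0 throughout, matching the exactness contract


def simulate_biomarker(
    genotypes: GenotypeMatrix, arch: ArchitectureSpec
) -> tuple[np.ndarray, BiomarkerTruth]:
    """Simulate a biomarker with the requested sparse/polygenic architecture.

    The trait is ``large + poly + noise`` built from centered dosages.  In
    "exact" mode the three components are orthogonalized in-sample (the
    polygenic component is projected off the large-effect component — the
    projection lies in the span of the large-effect SNPs, so per-SNP effects
    stay exact — and the noise off both) and rescaled so that in-sample
    var(genetic)/var(trait) = pve and var(large)/var(genetic) = pge to
    machine precision, with total trait variance 1.
    """
    n, p = genotypes.n_samples, genotypes.n_snps
    if arch.n_large + arch.n_poly > p:
        raise ValueError(
            f"n_large + n_poly = {arch.n_large + arch.n_poly} exceeds panel size {p}"
        )
    rng = np.random.default_rng(arch.seed)
    X = genotypes.mean_imputed()
    Xc = X - X.mean(axis=0)

    causal = rng.choice(p, size=arch.n_large + arch.n_poly, replace=False)
    large_idx = np.sort(causal[: arch.n_large])
    poly_idx = np.sort(causal[arch.n_large :])

    effects = np.zeros(p)
    noise = rng.standard_normal(n)

    var_g = arch.pve
    var_large = arch.pge * var_g
    var_poly = (1.0 - arch.pge) * var_g
    var_noise = 1.0 - var_g

    b_large = np.zeros(arch.n_large)
    b_poly = np.zeros(arch.n_poly)
    if var_large > 0:
        b_large = rng.standard_normal(arch.n_large)
    if var_poly > 0:
        b_poly = rng.standard_normal(arch.n_poly)

    L = Xc[:, large_idx] @ b_large if arch.n_large else np.zeros(n)
    P = Xc[:, poly_idx] @ b_poly if arch.n_poly else np.zeros(n)

    if arch.rescale == "exact":
        if var_large > 0:
            if _var(L) == 0:
                raise ValueError("large-effect component degenerate (constant dosages?)")
            # orthogonalize poly against large; correction stays in the span
            # of the large-effect SNPs so it folds into their effects
            c = float(L @ (P - P.mean()) / (L @ (L - L.mean()))) if _var(P) > 0 else 0.0
            P = P - c * L
            b_poly_adj_on_large = -c * b_large
            s_l = np.sqrt(var_large / _var(L))
            L = s_l * L
            b_large_final = s_l * b_large
        else:
            b_large_final = np.zeros(arch.n_large)
            b_poly_adj_on_large = np.zeros(arch.n_large)
            L = np.zeros(n)
        if var_poly > 0:
            if _var(P) == 0:
                raise ValueError("polygenic component degenerate")
            s_p = np.sqrt(var_poly / _var(P))
            P = s_p * P
            b_poly_final = s_p * b_poly
            poly_on_large = s_p * b_poly_adj_on_large
        else:
            P = np.zeros(n)
            b_poly_final = np.zeros(arch.n_poly)
            poly_on_large = np.zeros(arch.n_large)
        g = L + P
        # noise orthogonal to the genetic value, exact variance
        e = noise - noise.mean()
        if _var(g) > 0:
            e = e - (e @ (g - g.mean())) / ((g - g.mean()) @ (g - g.mean())) * (g - g.mean())
        if var_noise > 0:
            e = e * np.sqrt(var_noise / _var(e))
        else:
            e = np.zeros(n)
        effects[large_idx] = b_large_final + poly_on_large
        effects[poly_idx] = b_poly_final
    else:  # sampled: effects drawn at the implied scale, no rescaling
        exp_var_l = float(np.sum(Xc[:, large_idx].var(axis=0))) if arch.n_large else 0.0
        exp_var_p = float(np.sum(Xc[:, poly_idx].var(axis=0))) if arch.n_poly else 0.0
        sc_l = np.sqrt(var_large / exp_var_l) if var_large > 0 and exp_var_l > 0 else 0.0
        sc_p = np.sqrt(var_poly / exp_var_p) if var_poly > 0 and exp_var_p > 0 else 0.0
        effects[large_idx] = sc_l * b_large
        effects[poly_idx] = sc_p * b_poly
        L = Xc[:, large_idx] @ effects[large_idx] if arch.n_large else np.zeros(n)
        P = Xc[:, poly_idx] @ effects[poly_idx] if arch.n_poly else np.zeros(n)
        g = L + P
        e = noise * np.sqrt(var_noise) if var_noise > 0 else np.zeros(n)

    trait = g + e
    vt = _var(trait)
    realized_pve = _var(g) / vt if vt > 0 else 0.0
    realized_pge = _var(L) / _var(g) if _var(g) > 0 else 0.0
    truth = BiomarkerTruth(
        effects=effects,
        large_idx=large_idx,
        poly_idx=poly_idx,
        genetic_value=g,
        large_component=L,
        poly_component=P,
        realized_pve=realized_pve,
        realized_pge=realized_pge,
    )
    return trait, truth


# ---------------------------------------------------------------------------
# covariates


def simulate_covariates(
    samples: list[str],
    seed: int,
    n_pcs: int = 3,
    n_sites: int = 3,
    n_platforms: int = 2,
    birth_decades: tuple[int, ...] = (1920, 1930, 1940, 1950, 1960, 1970, 1980),
) -> pd.DataFrame:
    """Covariate table: sex (1 = female), birth decade, site, platform, PCs.

    All subjects are born before 1990, mirroring the cohort-level filter the
    PheWAS applies before analysis.
    """
    rng = np.random.default_rng(seed)
    n = len(samples)
    df = pd.DataFrame(
        {
            "sample_id": samples,
            "sex": rng.integers(0, 2, size=n),
            "birth_decade": rng.choice(birth_decades, size=n),
            "site": [f"site_{i}" for i in rng.integers(0, n_sites, size=n)],
            "platform": [f"chip_{i}" for i in rng.integers(0, n_platforms, size=n)],
        }
    )
    for k in range(1, n_pcs + 1):
        df[f"pc{k}"] = rng.standard_normal(n)
    # age only matters for residualization of the measured biomarker
    df["age"] = rng.integers(40, 80, size=n).astype(float)
    return df.set_index("sample_id", drop=False)


# ---------------------------------------------------------------------------
# diagnoses


def _solve_intercept(z: np.ndarray, log_or: float, prevalence: float) -> float:
    """Intercept making mean logistic case probability equal prevalence."""

    def gap(b0: float) -> float:
        return float(np.mean(expit(b0 + log_or * z))) - prevalence

    return brentq(gap, -40.0, 40.0, xtol=1e-12)


def simulate_diagnoses(
    true_genetic_value: np.ndarray,
    specs: list[DiagnosisSpec],
    covariates: pd.DataFrame,
    seed: int,
    case_exclusion_rate: float = 0.3,
    carrier_exclusion_rate: float = 0.05,
) -> pd.DataFrame:
    """Draw phecode occurrences from a logistic liability on the genetic value.

    For each spec, case probability is ``expit(b0 + genetic_log_or * z)``
    with ``z`` the standardized true genetic value and ``b0`` solved so the
    expected case fraction (among sex-eligible samples) equals the spec's
    prevalence.  Exclusion codes are co-assigned to a fraction of cases and,
    at a lower rate, to non-cases, so control-exclusion logic is exercised.
    Returns a long table: sample_id, phecode, count.
    """
    if not specs:
        raise ValueError("specs is empty")
    g = np.asarray(true_genetic_value, dtype=float)
    n = g.size
    if len(covariates) != n:
        raise ValueError("covariates and genetic value length mismatch")
    sd = g.std()
    z = (g - g.mean()) / sd if sd > 0 else np.zeros(n)
    rng = np.random.default_rng(seed)
    sample_ids = covariates["sample_id"].to_numpy()
    sex = covariates["sex"].to_numpy()

    rows: list[tuple[str, str, int]] = []
    for spec in specs:
        if spec.sex_restriction == "female":
            eligible = sex == 1
        elif spec.sex_restriction == "male":
            eligible = sex == 0
        else:
            eligible = np.ones(n, dtype=bool)
        if not eligible.any():
            continue
        b0 = _solve_intercept(z[eligible], spec.genetic_log_or, spec.prevalence)
        prob = np.zeros(n)
        prob[eligible] = expit(b0 + spec.genetic_log_or * z[eligible])
        is_case = rng.random(n) < prob
        counts = 1 + rng.poisson(1.0, size=n)
        for i in np.where(is_case)[0]:
            rows.append((sample_ids[i], spec.phecode, int(counts[i])))
        for code in spec.exclusion_codes:
            case_hit = is_case & (rng.random(n) < case_exclusion_rate)
            carrier_hit = ~is_case & (rng.random(n) < carrier_exclusion_rate)
            for i in np.where(case_hit | carrier_hit)[0]:
                rows.append((sample_ids[i], code, 1))
    occ = pd.DataFrame(rows, columns=["sample_id", "phecode", "count"])
    # a sample may receive the same exclusion code through several specs
    return (
        occ.groupby(["sample_id", "phecode"], as_index=False)["count"]
        .sum()
        .sort_values(["sample_id", "phecode"], kind="stable")
        .reset_index(drop=True)
    )
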