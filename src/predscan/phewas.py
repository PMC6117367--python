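"""Phenome-wide association scanning of a genetically predicted biomarker.

Phenotypes are phecodes: a sample with one or more occurrences of the code
is a case; controls carry neither the code nor any closely related
exclusion code and their birth decade falls inside the range observed among
cases.  Sites contributing fewer than ``min_site_cases`` cases are excluded
wholesale for that phenotype, single-gender phenotypes are rejected, and a
phenotype enters the scan only with at least ``min_cases`` cases.  Each
phenotype is tested by multivariable logistic regression of case status on
the standardized score plus covariates; odds ratios are per SD of predicted
biomarker.  Selection uses a strict experiment-wide Bonferroni threshold
alongside Benjamini-Hochberg FDR q < 0.1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning, PerfectSeparationError

try:  # newer statsmodels also warns instead of raising
    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning
except ImportError:  # pragma: no cover
    class PerfectSeparationWarning(UserWarning):
        pass

from predscan.projection import ScoreVector

__all__ = [
    "PhecodeDefinition",
    "CaseControlAssignment",
    "AssociationResult",
    "PositiveControlSpec",
    "PhenotypeRejected",
    "LogisticFit",
    "assemble_case_control",
    "fit_logistic",
    "run_phewas",
    "adjust_multiplicity",
    "evaluate_positive_controls",
    "compute_skewness",
    "stratified_association",
    "direction_concordance",
]

DEFAULT_COVARIATE_COLS = ("sex", "birth_decade", "site", "platform", "pc1", "pc2", "pc3")

_Z975 = norm.ppf(0.975)


class PhenotypeRejected(ValueError):
    """A phenotype failed a cohort-assembly rule (too few cases, single
    gender, ...); carries the reason for logging."""

    def __init__(self, phecode: str, reason: str):
        super().__init__(f"phecode {phecode} rejected: {reason}")
        self.phecode = phecode
        self.reason = reason


@dataclass(frozen=True)
class PhecodeDefinition:
    phecode: str
    label: str = ""
    exclusion_codes: tuple[str, ...] = ()
    sex_restriction: str = "both"

    def __post_init__(self) -> None:
        if self.sex_restriction not in ("both", "male", "female"):
            raise ValueError(f"bad sex_restriction {self.sex_restriction!r}")


@dataclass(frozen=True)
class PositiveControlSpec:
    biomarker: str
    control_phecodes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.control_phecodes:
            raise ValueError(f"{self.biomarker}: empty positive-control phecode list")


@dataclass
class CaseControlAssignment:
    phecode: str
    status: pd.Series = field(repr=False)  # index sample_id -> case/control/excluded
    n_cases: int = 0
    n_controls: int = 0
    site_case_counts: dict[str, int] = field(default_factory=dict)
    case_birth_decades: tuple[int, int] = (0, 0)
    excluded_sites: tuple[str, ...] = ()

    def case_ids(self) -> pd.Index:
        return self.status.index[self.status == "case"]

    def control_ids(self) -> pd.Index:
        return self.status.index[self.status == "control"]


@dataclass
class LogisticFit:
    beta: float
    se: float
    p: float
    ci_low: float
    ci_high: float
    converged: bool
    separated: bool = False


@dataclass
class AssociationResult:
    biomarker: str
    phecode: str
    label: str
    beta: float
    se: float
    p: float
    n_cases: int
    n_controls: int
    converged: bool
    q: float = np.nan
    rank: float = np.nan
    bonferroni_significant: bool = False
    fdr_significant: bool = False

    @property
    def or_point(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci_low(self) -> float:
        return float(np.exp(self.beta - _Z975 * self.se))

    @property
    def ci_high(self) -> float:
        return float(np.exp(self.beta + _Z975 * self.se))


# ---------------------------------------------------------------------------
# case/control assembly


def assemble_case_control(
    occurrences: pd.DataFrame,
    definition: PhecodeDefinition,
    covariates: pd.DataFrame,
    min_cases: int = 300,
    min_site_cases: int = 10,
) -> CaseControlAssignment:
    """Assign case/control/excluded status for one phecode phenotype.

    Raises :class:`PhenotypeRejected` when the phenotype is single-gender,
    or has fewer than ``min_cases`` cases after site exclusion.
    """
    if covariates.empty:
        raise ValueError("empty cohort")
    if definition.sex_restriction != "both":
        raise PhenotypeRejected(definition.phecode, "single-gender phenotype")
    required = {"sample_id", "phecode"}
    if not required.issubset(occurrences.columns):
        raise ValueError("occurrence table must have sample_id and phecode columns")

    samples = covariates["sample_id"]
    occ = occurrences[occurrences["sample_id"].isin(samples)]
    case_ids = set(occ.loc[occ["phecode"] == definition.phecode, "sample_id"])
    excl_ids = set(
        occ.loc[occ["phecode"].isin(definition.exclusion_codes), "sample_id"]
    )

    status = pd.Series("control", index=pd.Index(samples, name="sample_id"))
    status.loc[status.index.isin(case_ids)] = "case"
    # exclusion-code carriers who are not cases sit out entirely
    status.loc[status.index.isin(excl_ids - case_ids)] = "excluded"

    # site exclusion: a site with < min_site_cases cases drops wholesale
    site = covariates.set_index("sample_id")["site"].reindex(status.index)
    case_mask = status == "case"
    site_counts = site[case_mask].value_counts().to_dict()
    all_sites = site.unique()
    bad_sites = tuple(
        sorted(s for s in all_sites if site_counts.get(s, 0) < min_site_cases)
    )
    if bad_sites:
        status.loc[site.isin(bad_sites)] = "excluded"

    case_mask = status == "case"
    n_cases = int(case_mask.sum())
    if n_cases < min_cases:
        raise PhenotypeRejected(
            definition.phecode, f"{n_cases} cases < required {min_cases}"
        )

    decade = covariates.set_index("sample_id")["birth_decade"].reindex(status.index)
    lo, hi = int(decade[case_mask].min()), int(decade[case_mask].max())
    out_of_range = (status == "control") & ((decade < lo) | (decade > hi))
    status.loc[out_of_range] = "excluded"

    return CaseControlAssignment(
        phecode=definition.phecode,
        status=status,
        n_cases=n_cases,
        n_controls=int((status == "control").sum()),
        site_case_counts={k: int(v) for k, v in site_counts.items()},
        case_birth_decades=(lo, hi),
        excluded_sites=bad_sites,
    )


# ---------------------------------------------------------------------------
# logistic regression


def _build_design(
    covariates: pd.DataFrame, cols: tuple[str, ...] = DEFAULT_COVARIATE_COLS
) -> pd.DataFrame:
    """Dummy-code categorical covariates; drop columns constant in-cohort.

    Birth decade, site and platform enter as categorical factors.
    """
    use = [c for c in cols if c in covariates.columns]
    parts = []
    for c in use:
        col = covariates[c]
        if col.nunique() <= 1:
            continue  # constant within the analysis cohort (e.g. one site)
        if c in ("site", "platform", "birth_decade"):
            parts.append(pd.get_dummies(col.astype(str), prefix=c, drop_first=True, dtype=float))
        else:
            parts.append(pd.to_numeric(col).astype(float).to_frame(c))
    if not parts:
        return pd.DataFrame(index=covariates.index)
    return pd.concat(parts, axis=1)


def fit_logistic(
    status: np.ndarray,
    score: np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> LogisticFit:
    """Maximum-likelihood logistic fit of status on the score plus covariates.

    Returns the Wald statistics for the score coefficient.  Complete or
    quasi-complete separation is flagged (``converged=False``) with the
    estimates withheld, matching plain-ML behaviour without a penalized
    fallback.
    """
    y = np.asarray(status, dtype=float)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("status has a single class")
    x = np.asarray(score, dtype=float)
    if covariates is not None and len(covariates):
        design = _build_design(covariates)
        X = np.column_stack([np.ones(y.size), x, design.to_numpy(dtype=float)])
    else:
        X = np.column_stack([np.ones(y.size), x])
    bad = LogisticFit(np.nan, np.nan, np.nan, np.nan, np.nan, False, True)
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=100)
        except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError):
            return bad
    params = res.params
    bse = res.bse
    converged = bool(res.mle_retvals.get("converged", False))
    if not np.all(np.isfinite(params)) or not np.all(np.isfinite(bse)):
        return bad
    if np.abs(params).max() > 1e3:  # numerically separated
        return bad
    beta, se = float(params[1]), float(bse[1])
    if not converged:
        return LogisticFit(np.nan, np.nan, np.nan, np.nan, np.nan, False, False)
    z = beta / se
    p = 2.0 * norm.sf(abs(z))
    return LogisticFit(
        beta=beta,
        se=se,
        p=float(p),
        ci_low=float(np.exp(beta - _Z975 * se)),
        ci_high=float(np.exp(beta + _Z975 * se)),
        converged=True,
    )


# ---------------------------------------------------------------------------
# the scan


def run_phewas(
    scores: ScoreVector,
    assignments: list[CaseControlAssignment],
    covariates: pd.DataFrame,
    definitions: dict[str, PhecodeDefinition] | None = None,
) -> list[AssociationResult]:
    """Serially test the standardized score against every phenotype.

    One result per assignment; non-converged fits are retained with the
    flag set and excluded from ranking.  Ranks (1 = smallest p) are per
    biomarker; ties break by |beta| descending then phecode.
    """
    if not assignments:
        raise ValueError("no case/control assignments")
    codes = [a.phecode for a in assignments]
    if len(set(codes)) != len(codes):
        raise ValueError("duplicate phecode among assignments")
    score_s = pd.Series(scores.standardized, index=pd.Index(scores.samples, name="sample_id"))
    cov = covariates.set_index("sample_id", drop=False)
    results = []
    for a in assignments:
        mask = a.status != "excluded"
        ids = a.status.index[mask]
        y = (a.status[mask] == "case").to_numpy(dtype=float)
        x = score_s.reindex(ids).to_numpy()
        c = cov.reindex(ids)
        fit = fit_logistic(y, x, c[list(DEFAULT_COVARIATE_COLS)].copy()
                           if set(DEFAULT_COVARIATE_COLS) & set(c.columns) else None)
        label = definitions[a.phecode].label if definitions and a.phecode in definitions else ""
        results.append(
            AssociationResult(
                biomarker=scores.biomarker,
                phecode=a.phecode,
                label=label,
                beta=fit.beta,
                se=fit.se,
                p=fit.p,
                n_cases=int(y.sum()),
                n_controls=int((1 - y).sum()),
                converged=fit.converged,
            )
        )
    _assign_ranks(results)
    return results


def _assign_ranks(results: list[AssociationResult]) -> None:
    for biomarker in {r.biomarker for r in results}:
        conv = [r for r in results if r.biomarker == biomarker and r.converged]
        conv.sort(key=lambda r: (r.p, -abs(r.beta), r.phecode))
        for i, r in enumerate(conv, start=1):
            r.rank = float(i)


def adjust_multiplicity(
    results: list[AssociationResult],
    n_biomarkers: int,
    n_phenotypes: int,
    alpha: float = 0.05,
    fdr_q: float = 0.1,
    fdr_family: str = "per_biomarker",
) -> tuple[list[AssociationResult], dict]:
    """Annotate results with Bonferroni and Benjamini-Hochberg selection.

    The Bonferroni threshold is ``alpha / (n_biomarkers * n_phenotypes)``
    (experiment-wide).  B-H step-up q-values are computed within the chosen
    family: per biomarker across its tested phenotypes (default) or
    globally across all results.
    """
    if not results:
        raise ValueError("no results to adjust")
    if n_biomarkers < 1 or n_phenotypes < 1:
        raise ValueError("n_biomarkers and n_phenotypes must be >= 1")
    if fdr_family not in ("per_biomarker", "global"):
        raise ValueError("fdr_family must be 'per_biomarker' or 'global'")
    threshold = alpha / (n_biomarkers * n_phenotypes)

    def families():
        if fdr_family == "global":
            yield [r for r in results if r.converged]
        else:
            for biomarker in sorted({r.biomarker for r in results}):
                yield [r for r in results if r.biomarker == biomarker and r.converged]

    for fam in families():
        if not fam:
            continue
        pvals = np.array([r.p for r in fam])
        _, qvals, _, _ = multipletests(pvals, alpha=fdr_q, method="fdr_bh")
        for r, q in zip(fam, qvals):
            r.q = float(q)
            r.fdr_significant = bool(q < fdr_q)
            r.bonferroni_significant = bool(r.p < threshold)
    thresholds = {
        "bonferroni_threshold": threshold,
        "alpha": alpha,
        "fdr_q": fdr_q,
        "fdr_family": fdr_family,
    }
    return results, thresholds


# ---------------------------------------------------------------------------
# evaluation


def evaluate_positive_controls(
    results: list[AssociationResult],
    specs: list[PositiveControlSpec],
    rank_cutoff: int = 5,
    fdr_q: float = 0.1,
) -> tuple[dict[str, set[str]], dict]:
    """Categorize each biomarker's positive-control pair.

    A pair is ``bonferroni`` if any of its control phecodes passes the
    experiment-wide threshold, ``top_rank`` if any has rank <= cutoff,
    ``fdr`` if any has q < fdr_q; categories are non-exclusive and a pair
    matching none is ``none``.  Pairs whose control phecodes are absent
    from the results are untestable and leave the denominator.
    """
    if not specs:
        raise ValueError("empty positive-control specification")
    by_key: dict[tuple[str, str], AssociationResult] = {
        (r.biomarker, r.phecode): r for r in results
    }
    categories: dict[str, set[str]] = {}
    untestable = []
    for spec in specs:
        hits = [
            by_key[(spec.biomarker, code)]
            for code in spec.control_phecodes
            if (spec.biomarker, code) in by_key
        ]
        if not hits:
            untestable.append(spec.biomarker)
            continue
        cats: set[str] = set()
        if any(r.bonferroni_significant for r in hits):
            cats.add("bonferroni")
        if any(r.converged and r.rank <= rank_cutoff for r in hits):
            cats.add("top_rank")
        if any(r.converged and r.q < fdr_q for r in hits):
            cats.add("fdr")
        if not cats:
            cats.add("none")
        categories[spec.biomarker] = cats
    n = len(categories)
    summary = {
        "n_testable": n,
        "n_untestable": len(untestable),
        "untestable": untestable,
    }
    for cat in ("bonferroni", "top_rank", "fdr", "none"):
        summary[f"pct_{cat}"] = (
            100.0 * sum(cat in c for c in categories.values()) / n if n else np.nan
        )
    return categories, summary


def compute_skewness(
    results: list[AssociationResult],
    min_cases: int = 150,
    exclude_fdr: bool = True,
    fdr_q: float = 0.1,
) -> float:
    """Skewness of the scan's regression coefficients.

        skewness = (sum(beta^3) / n) / (sum(beta^2) / n)^(3/2)

    over converged results with at least ``min_cases`` cases, excluding
    FDR-significant associations (q < fdr_q) so strong hits do not dominate
    the asymmetry measure.  Requires >= 3 retained coefficients; all-zero
    retained betas leave the statistic undefined (NaN).
    """
    retained = [
        r.beta
        for r in results
        if r.converged
        and r.n_cases >= min_cases
        and not (exclude_fdr and not np.isnan(r.q) and r.q < fdr_q)
    ]
    if len(retained) < 3:
        raise ValueError(f"only {len(retained)} betas retained; need >= 3")
    b = np.asarray(retained, dtype=float)
    m2 = float(np.sum(b**2)) / b.size
    if m2 == 0:
        warnings.warn("all retained betas are zero; skewness undefined", stacklevel=2)
        return float("nan")
    m3 = float(np.sum(b**3)) / b.size
    return m3 / m2**1.5


def stratified_association(
    scores: ScoreVector,
    assignment: CaseControlAssignment,
    covariates: pd.DataFrame,
    stratifier: pd.Series,
) -> dict[str, AssociationResult | None]:
    """Fit the phenotype association separately within each stratum.

    ``stratifier`` is a binary per-sample label (e.g. type 2 diabetes
    status) indexed by sample_id; it is removed from the adjustment set.  A
    stratum whose case/control set is single-class yields ``None``.
    """
    levels = pd.unique(stratifier.dropna())
    if len(levels) < 2:
        raise ValueError("stratifier is constant")
    if len(levels) > 2:
        raise ValueError("stratifier must be binary")
    score_s = pd.Series(scores.standardized, index=pd.Index(scores.samples, name="sample_id"))
    cov = covariates.set_index("sample_id", drop=False)
    out: dict[str, AssociationResult | None] = {}
    for level in sorted(levels, key=str):
        ids = stratifier.index[stratifier == level]
        sub = assignment.status.reindex(ids).dropna()
        sub = sub[sub != "excluded"]
        y = (sub == "case").to_numpy(dtype=float)
        if y.size == 0 or len(np.unique(y)) < 2:
            out[str(level)] = None
            continue
        x = score_s.reindex(sub.index).to_numpy()
        c = cov.reindex(sub.index)
        fit = fit_logistic(y, x, c[list(DEFAULT_COVARIATE_COLS)].copy())
        out[str(level)] = AssociationResult(
            biomarker=scores.biomarker,
            phecode=assignment.phecode,
            label=f"stratum={level}",
            beta=fit.beta,
            se=fit.se,
            p=fit.p,
            n_cases=int(y.sum()),
            n_controls=int((1 - y).sum()),
            converged=fit.converged,
        )
    return out


def direction_concordance(
    results_a: list[AssociationResult],
    results_b: list[AssociationResult],
    p_filter: float = 0.1,
) -> tuple[float, int]:
    """Fraction of sign-concordant associations between two cohorts.

    Results are joined on phecode; the denominator counts only pairs whose
    cohort-B association is nominally significant (p < ``p_filter``).
    Returns (fraction, n_pairs); an empty denominator yields (NaN, 0).
    """
    a_by_code = {r.phecode: r for r in results_a if r.converged}
    pairs = [
        (a_by_code[r.phecode], r)
        for r in results_b
        if r.converged and r.phecode in a_by_code and r.p < p_filter
    ]
    if not pairs:
        warnings.warn("no pairs pass the p filter; concordance undefined", stacklevel=2)
        return float("nan"), 0
    same = sum(np.sign(ra.beta) == np.sign(rb.beta) for ra, rb in pairs)
    return same / len(pairs), len(pairs)


def results_to_frame(results: list[AssociationResult]) -> pd.DataFrame:
    """Flatten association results to the canonical TSV column order."""
    return pd.DataFrame(
        [
            {
                "biomarker": r.biomarker,
                "phecode": r.phecode,
                "label": r.label,
                "beta": r.beta,
                "se": r.se,
                "or": r.or_point,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p": r.p,
                "q": r.q,
                "n_cases": r.n_cases,
                "n_controls": r.n_controls,
                "rank": r.rank,
                "bonferroni": r.bonferroni_significant,
                "fdr": r.fdr_significant,
                "converged": r.converged,
            }
            for r in results
        ]
    )
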