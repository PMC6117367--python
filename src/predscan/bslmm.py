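"""Bayesian sparse linear mixed model (BSLMM) for biomarker prediction.

Model, for a centered residualized biomarker y (n samples) and
column-standardized dosages X (n x p):

    y = X beta_tilde + u + eps
    beta_tilde_i ~ pi N(0, sigma_a^2 / tau) + (1 - pi) delta_0
    u ~ N(0, sigma_b^2 K / tau),   K = X X^T / p
    eps ~ N(0, I / tau)

Hyperparameters are re-expressed as (h, rho, log10 pi) with uniform priors:
h is the total genetic variance proportion, rho the fraction of genetic
variance carried by the sparse component, pi the prior inclusion
probability.  On the standardized scale

    sigma_a^2 = h rho / ((1 - h) pi p),   sigma_b^2 = h (1 - rho) / (1 - h).

The sampler is Metropolis-within-Gibbs: random-walk moves on (h, rho,
log10 pi) and add/remove/swap moves on the inclusion set, with effect sizes
and the residual precision tau integrated out of the acceptance ratio
(Jeffreys prior on tau).  Conditional effect draws at a thinning interval
provide the posterior PVE/PGE/|gamma| traces and Rao-Blackwellized per-SNP
posterior means alpha (polygenic), beta (sparse, conditional on inclusion)
and gamma (posterior inclusion probability).  Per-SNP projection weights are
w = alpha + beta * gamma, back-transformed to the raw 0/1/2 dosage scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from predscan.genotypes import GenotypeMatrix, SnpRecord

__all__ = [
    "MCMCConfig",
    "BslmmFit",
    "SnpWeightSet",
    "residualize",
    "fit_bslmm",
    "compute_weights",
    "estimate_pct_pve",
]

_H_EPS = 1e-4  # keep h, rho off the exact prior boundary


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler schedule and priors.

    The production default mirrors the published schedule (100,000 steps,
    summaries from the last 50,000); tests and the bundled demo use shorter
    chains.  ``fix_rho=0`` turns the sparse component off, reducing the
    model to the ridge/GBLUP limit.
    """

    n_steps: int = 100_000
    n_burn: int | None = None  # default: n_steps // 2
    seed: int = 0
    thin: int = 10
    max_included: int = 300
    h_step: float = 0.1
    rho_step: float = 0.1
    log10_pi_step: float = 0.3
    fix_h: float | None = None
    fix_rho: float | None = None
    fix_log10_pi: float | None = None

    def __post_init__(self) -> None:
        burn = self.n_burn if self.n_burn is not None else self.n_steps // 2
        if not 0 <= burn < self.n_steps:
            raise ValueError("n_burn must lie in [0, n_steps)")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def burn(self) -> int:
        return self.n_burn if self.n_burn is not None else self.n_steps // 2


@dataclass
class PosteriorSummary:
    median: float
    ci_low: float
    ci_high: float

    def contains(self, value: float) -> bool:
        return self.ci_low <= value <= self.ci_high


@dataclass
class BslmmFit:
    """Posterior summaries and per-SNP posterior means from one chain."""

    pve: PosteriorSummary
    pge: PosteriorSummary
    n_gamma: PosteriorSummary
    alpha: np.ndarray  # polygenic posterior mean, per-allele (raw dosage) scale
    beta: np.ndarray  # sparse effect posterior mean conditional on inclusion
    gamma: np.ndarray  # posterior inclusion probability
    snp_ids: list[str]
    dropped_snps: list[str]
    traces: pd.DataFrame = field(repr=False)
    acceptance: dict[str, float] = field(default_factory=dict)
    ess: dict[str, float] = field(default_factory=dict)
    config: MCMCConfig | None = None


@dataclass
class SnpWeightSet:
    """Per-SNP projection weights tied to a coded allele."""

    table: pd.DataFrame  # snp_id chrom pos coded_allele other_allele alpha beta gamma w

    COLUMNS = [
        "snp_id",
        "chrom",
        "pos",
        "coded_allele",
        "other_allele",
        "alpha",
        "beta",
        "gamma",
        "w",
    ]

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"weight table missing columns {missing}")
        self.table = self.table[self.COLUMNS].reset_index(drop=True)
        if self.table["snp_id"].duplicated().any():
            raise ValueError("duplicate snp_id in weight set")
        if len(self.table):
            resid = self.table["w"] - (
                self.table["alpha"] + self.table["beta"] * self.table["gamma"]
            )
            if np.abs(resid.to_numpy()).max() > 1e-9:
                raise ValueError("w != alpha + beta * gamma")

    def __len__(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# residualization


def residualize(trait: np.ndarray, covariates: pd.DataFrame | None) -> np.ndarray:
    """OLS residuals of the biomarker on an intercept plus covariates.

    Biomarkers are adjusted (typically for age, sex and leading principal
    components) before the mixed model sees them.  Residuals are orthogonal
    to every covariate column and to the intercept.
    """
    y = np.asarray(trait, dtype=float)
    if covariates is None or covariates.shape[1] == 0:
        return y - y.mean()
    C = covariates.apply(pd.to_numeric).to_numpy(dtype=float)
    if np.isnan(C).any() or np.isnan(y).any():
        raise ValueError("missing values in trait or covariates")
    design = np.column_stack([np.ones(len(y)), C])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        bad = _collinear_columns(design, list(covariates.columns))
        raise ValueError(f"covariate design is rank deficient; collinear: {bad}")
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ coef


def _collinear_columns(design: np.ndarray, names: list[str]) -> list[str]:
    """Name covariates whose removal restores full rank."""
    bad = []
    full_rank = np.linalg.matrix_rank(design)
    for j in range(1, design.shape[1]):
        sub = np.delete(design, j, axis=1)
        if np.linalg.matrix_rank(sub) == full_rank:
            bad.append(names[j - 1])
    return bad or names


# ---------------------------------------------------------------------------
# sampler internals


class _State:
    __slots__ = ("h", "rho", "log10_pi", "S", "logpost", "loglik")

    def __init__(self, h, rho, log10_pi, S):
        self.h = h
        self.rho = rho
        self.log10_pi = log10_pi
        self.S = S  # sorted int array of included SNPs
        self.logpost = -np.inf
        self.loglik = -np.inf


def _reflect(x: float, lo: float, hi: float) -> float:
    span = hi - lo
    x = (x - lo) % (2 * span)
    return lo + (span - abs(x - span) if x > span else x)


class _BslmmSampler:
    """One MCMC chain over (h, rho, log10 pi, inclusion set)."""

    def __init__(self, Xs: np.ndarray, y: np.ndarray, config: MCMCConfig):
        self.cfg = config
        self.n, self.p = Xs.shape
        self.rng = np.random.default_rng(config.seed)
        # eigendecomposition of K = Xs Xs^T / p rotates the polygenic term
        K = (Xs @ Xs.T) / self.p
        d, U = np.linalg.eigh(K)
        self.d = np.clip(d, 0.0, None)
        self.ystar = U.T @ y
        self.Xstar = U.T @ Xs
        self.ones_rot = U.T @ np.ones(self.n)
        self.log10_pi_min = np.log10(1.0 / self.p)
        self.sparse_off = config.fix_rho is not None and config.fix_rho == 0.0

    # -- marginal likelihood with effects and tau integrated out ----------

    def _variances(self, h: float, rho: float, log10_pi: float) -> tuple[float, float]:
        pi = 10.0**log10_pi
        sa2 = h * rho / ((1.0 - h) * pi * self.p) if rho > 0 else 0.0
        sb2 = h * (1.0 - rho) / (1.0 - h)
        return sa2, sb2

    def _loglik(self, h: float, rho: float, log10_pi: float, S: np.ndarray):
        """Integrated log-likelihood; returns (loglik, cached pieces)."""
        sa2, sb2 = self._variances(h, rho, log10_pi)
        D = sb2 * self.d + 1.0
        Dinv = 1.0 / D
        logdetD = float(np.log(D).sum())
        yDy = float(self.ystar @ (Dinv * self.ystar))
        k = len(S)
        if k == 0 or sa2 == 0.0:
            quad = yDy
            logdet = logdetD
            cache = (Dinv, None, None, sa2, sb2)
        else:
            Xs_S = self.Xstar[:, S]
            DX = Dinv[:, None] * Xs_S
            G = Xs_S.T @ DX  # k x k
            v = Xs_S.T @ (Dinv * self.ystar)
            M = G + np.eye(k) / sa2
            L = np.linalg.cholesky(M)
            w = np.linalg.solve(L, v)
            quad = yDy - float(w @ w)
            # |Sigma| = |D| * |I + sa2 G| = |D| * |M| * sa2^k
            logdet = logdetD + 2.0 * float(np.log(np.diag(L)).sum()) + k * np.log(sa2)
            cache = (Dinv, L, v, sa2, sb2)
        quad = max(quad, 1e-300)
        loglik = -0.5 * logdet - 0.5 * self.n * np.log(quad)
        return loglik, quad, cache

    def _logprior_S(self, log10_pi: float, k: int) -> float:
        pi = 10.0**log10_pi
        pi = min(max(pi, 1e-300), 1 - 1e-12)
        return k * np.log(pi) + (self.p - k) * np.log1p(-pi)

    def _logpost(self, st: _State):
        loglik, quad, cache = self._loglik(st.h, st.rho, st.log10_pi, st.S)
        return loglik + self._logprior_S(st.log10_pi, len(st.S)), loglik, quad, cache

    # -- proposal moves ----------------------------------------------------

    def _propose_hyper(self, st: _State) -> _State:
        cfg = self.cfg
        h = st.h if cfg.fix_h is not None else _reflect(
            st.h + cfg.h_step * self.rng.standard_normal(), _H_EPS, 1 - _H_EPS
        )
        rho = st.rho if cfg.fix_rho is not None else _reflect(
            st.rho + cfg.rho_step * self.rng.standard_normal(), 0.0, 1.0
        )
        lp = st.log10_pi if cfg.fix_log10_pi is not None else _reflect(
            st.log10_pi + cfg.log10_pi_step * self.rng.standard_normal(),
            self.log10_pi_min,
            0.0,
        )
        return _State(h, rho, lp, st.S)

    def _n_move_types(self, k: int) -> int:
        """How many move types (add/remove/swap) are available at set size k."""
        n = 0
        if k < min(self.cfg.max_included, self.p):
            n += 1  # add
        if k > 0:
            n += 1  # remove
        if k > 0 and self.p - k > 0:
            n += 1  # swap
        return n

    def _propose_set(self, st: _State) -> tuple[_State, float]:
        """Add/remove/swap one SNP; returns (proposal, log Hastings ratio).

        The Hastings ratio includes the move-type selection probability,
        which is asymmetric at the empty and full-set boundaries.
        """
        k = len(st.S)
        out_count = self.p - k
        moves = []
        if k < min(self.cfg.max_included, self.p):
            moves.append("add")
        if k > 0:
            moves.append("remove")
        if 0 < k and out_count > 0:
            moves.append("swap")
        move = moves[self.rng.integers(len(moves))]
        n_fwd = len(moves)
        in_set = np.zeros(self.p, dtype=bool)
        in_set[st.S] = True
        if move == "add":
            cand = self.rng.integers(out_count)
            j = np.flatnonzero(~in_set)[cand]
            S = np.sort(np.append(st.S, j))
            # forward: pick "add" then one of out_count; reverse: "remove"
            # then one of k+1
            log_hastings = (
                np.log(out_count) - np.log(k + 1)
                + np.log(n_fwd) - np.log(self._n_move_types(k + 1))
            )
        elif move == "remove":
            j = st.S[self.rng.integers(k)]
            S = st.S[st.S != j]
            log_hastings = (
                np.log(k) - np.log(out_count + 1)
                + np.log(n_fwd) - np.log(self._n_move_types(k - 1))
            )
        else:  # swap: symmetric, set size unchanged
            j_out = st.S[self.rng.integers(k)]
            j_in = np.flatnonzero(~in_set)[self.rng.integers(out_count)]
            S = np.sort(np.append(st.S[st.S != j_out], j_in))
            log_hastings = 0.0
        return _State(st.h, st.rho, st.log10_pi, S), log_hastings

    # -- conditional effect draw (for traces and posterior means) ----------

    def _draw_effects(self, st: _State, quad: float, cache):
        """Sample (tau, sparse effects, polygenic eigencomponents).

        Returns the per-draw PVE, PGE, and Rao-Blackwellized contributions
        to alpha (E[a | rest]) and beta (conditional posterior mean m_b).
        """
        Dinv, L, v, sa2, sb2 = cache
        n = self.n
        tau = self.rng.gamma(shape=0.5 * n, scale=2.0 / quad)
        sigma_e2 = 1.0 / tau
        k = len(st.S)
        if k and L is not None:
            m_b = np.linalg.solve(L.T, np.linalg.solve(L, v))
            z = self.rng.standard_normal(k)
            b = m_b + np.linalg.solve(L.T, z) / np.sqrt(tau)
            sparse_star = self.Xstar[:, st.S] @ b
        else:
            m_b = np.zeros(0)
            b = np.zeros(0)
            sparse_star = np.zeros(n)
        r = self.ystar - sparse_star
        shrink = sb2 * self.d / (sb2 * self.d + 1.0)
        mu_u = shrink * r
        u = mu_u + np.sqrt(shrink / tau) * self.rng.standard_normal(n)
        g_star = sparse_star + u
        # sample variance in the original basis (rotation preserves norms)
        g_mean = float(self.ones_rot @ g_star) / n
        var_g = float(g_star @ g_star) / n - g_mean * g_mean
        s_mean = float(self.ones_rot @ sparse_star) / n
        var_sparse = float(sparse_star @ sparse_star) / n - s_mean * s_mean
        pve = var_g / (var_g + sigma_e2) if var_g > 0 else 0.0
        pge = min(var_sparse / var_g, 1.0) if var_g > 0 else 0.0
        # Rao-Blackwellized polygenic effect: E[a | y, b] on standardized scale
        alpha_contrib = (sb2 / self.p) * (self.Xstar.T @ (Dinv * r))
        return pve, pge, m_b, alpha_contrib

    # -- main loop ----------------------------------------------------------

    def run(self):
        cfg = self.cfg
        st = _State(
            cfg.fix_h if cfg.fix_h is not None else 0.5,
            cfg.fix_rho if cfg.fix_rho is not None else 0.5,
            cfg.fix_log10_pi
            if cfg.fix_log10_pi is not None
            else 0.5 * self.log10_pi_min,
            np.empty(0, dtype=int),
        )
        st.logpost, st.loglik, quad, cache = self._logpost(st)

        n_rec_target = max(1, (cfg.n_steps - cfg.burn) // cfg.thin)
        pve_tr = np.empty(n_rec_target)
        pge_tr = np.empty(n_rec_target)
        ng_tr = np.empty(n_rec_target)
        h_tr = np.empty(n_rec_target)
        alpha_sum = np.zeros(self.p)
        beta_sum = np.zeros(self.p)
        gamma_sum = np.zeros(self.p)
        n_rec = 0
        acc = {"hyper": 0, "hyper_n": 0, "set": 0, "set_n": 0}

        for step in range(cfg.n_steps):
            # hyperparameter move
            if cfg.fix_h is None or cfg.fix_rho is None or cfg.fix_log10_pi is None:
                prop = self._propose_hyper(st)
                lp, ll, q2, c2 = self._logpost(prop)
                acc["hyper_n"] += 1
                if np.log(self.rng.random()) < lp - st.logpost:
                    prop.logpost, prop.loglik = lp, ll
                    st, quad, cache = prop, q2, c2
                    acc["hyper"] += 1
            # inclusion-set move
            if not self.sparse_off and self.p > 0:
                prop, log_hast = self._propose_set(st)
                lp, ll, q2, c2 = self._logpost(prop)
                acc["set_n"] += 1
                if np.log(self.rng.random()) < lp - st.logpost + log_hast:
                    prop.logpost, prop.loglik = lp, ll
                    st, quad, cache = prop, q2, c2
                    acc["set"] += 1
            if step >= cfg.burn and (step - cfg.burn) % cfg.thin == 0 and n_rec < n_rec_target:
                pve, pge, m_b, alpha_contrib = self._draw_effects(st, quad, cache)
                pve_tr[n_rec] = pve
                pge_tr[n_rec] = pge
                ng_tr[n_rec] = len(st.S)
                h_tr[n_rec] = st.h
                alpha_sum += alpha_contrib
                if len(st.S):
                    beta_sum[st.S] += m_b
                    gamma_sum[st.S] += 1.0
                n_rec += 1

        traces = pd.DataFrame(
            {
                "pve": pve_tr[:n_rec],
                "pge": pge_tr[:n_rec],
                "n_gamma": ng_tr[:n_rec],
                "h": h_tr[:n_rec],
            }
        )
        alpha = alpha_sum / n_rec
        gamma = gamma_sum / n_rec
        with np.errstate(invalid="ignore", divide="ignore"):
            beta = np.where(gamma_sum > 0, beta_sum / np.maximum(gamma_sum, 1), 0.0)
        acceptance = {
            "hyper": acc["hyper"] / max(acc["hyper_n"], 1),
            "set": acc["set"] / max(acc["set_n"], 1),
        }
        return traces, alpha, beta, gamma, acceptance


def _summary(x: np.ndarray) -> PosteriorSummary:
    return PosteriorSummary(
        median=float(np.median(x)),
        ci_low=float(np.quantile(x, 0.025)),
        ci_high=float(np.quantile(x, 0.975)),
    )


def _ess(x: np.ndarray) -> float:
    """Effective sample size from the initial positive autocorrelation sum."""
    x = np.asarray(x, float)
    n = x.size
    if n < 10 or x.std() == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1 :] / (xc @ xc)
    s = 0.0
    for t in range(1, min(n, 1000)):
        if acf[t] <= 0:
            break
        s += acf[t]
    return float(n / (1.0 + 2.0 * s))


def fit_bslmm(
    genotypes: GenotypeMatrix, y: np.ndarray, config: MCMCConfig | None = None
) -> BslmmFit:
    """Fit the BSLMM by MCMC and summarize the posterior.

    Reported PVE/PGE/|gamma| are medians (with central 95% credible
    intervals) over the post-burn-in thinned draws.  Per-SNP alpha/beta are
    back-transformed from the standardized-genotype scale to the per-allele
    scale, so exported weights apply directly to raw 0/1/2 dosages.
    Constant SNP columns are dropped with a warning and recorded on the fit.
    """
    config = config or MCMCConfig()
    y = np.asarray(y, dtype=float)
    if y.size != genotypes.n_samples:
        raise ValueError("y length does not match genotype sample count")
    if genotypes.n_snps < 2:
        raise ValueError("need at least 2 SNPs")
    if y.std() == 0:
        raise ValueError("y is constant")

    X = genotypes.mean_imputed()
    freqs = X.mean(axis=0) / 2.0
    sd = X.std(axis=0)
    keep = sd > 0
    dropped = [s.snp_id for s, k in zip(genotypes.snps, keep) if not k]
    if dropped:
        warnings.warn(f"dropping {len(dropped)} constant SNP columns", stacklevel=2)
    Xk = X[:, keep]
    Xs = (Xk - 2.0 * freqs[keep]) / sd[keep]
    yc = y - y.mean()

    sampler = _BslmmSampler(Xs, yc, config)
    traces, alpha_std, beta_std, gamma_k, acceptance = sampler.run()

    p = genotypes.n_snps
    alpha = np.zeros(p)
    beta = np.zeros(p)
    gamma = np.zeros(p)
    # back-transform: standardized-scale effect / column SD = per-allele effect
    alpha[keep] = alpha_std / sd[keep]
    beta[keep] = beta_std / sd[keep]
    gamma[keep] = gamma_k

    return BslmmFit(
        pve=_summary(traces["pve"].to_numpy()),
        pge=_summary(traces["pge"].to_numpy()),
        n_gamma=_summary(traces["n_gamma"].to_numpy()),
        alpha=alpha,
        beta=beta,
        gamma=gamma,
        snp_ids=genotypes.snp_ids,
        dropped_snps=dropped,
        traces=traces,
        acceptance=acceptance,
        ess={c: _ess(traces[c].to_numpy()) for c in ("pve", "pge", "n_gamma")},
        config=config,
    )


def compute_weights(fit: BslmmFit, snp_meta: list[SnpRecord]) -> SnpWeightSet:
    """Projection weights w = alpha + beta * gamma, tied to the coded allele."""
    if len(snp_meta) != len(fit.snp_ids):
        raise ValueError("fit and snp_meta cover different numbers of SNPs")
    for rec, sid in zip(snp_meta, fit.snp_ids):
        if rec.snp_id != sid:
            raise ValueError(f"SNP order mismatch: {rec.snp_id} vs {sid}")
    table = pd.DataFrame(
        {
            "snp_id": [s.snp_id for s in snp_meta],
            "chrom": [s.chrom for s in snp_meta],
            "pos": [s.pos for s in snp_meta],
            "coded_allele": [s.coded_allele for s in snp_meta],
            "other_allele": [s.other_allele for s in snp_meta],
            "alpha": fit.alpha,
            "beta": fit.beta,
            "gamma": fit.gamma,
        }
    )
    table["w"] = table["alpha"] + table["beta"] * table["gamma"]
    return SnpWeightSet(table)


def estimate_pct_pve(
    genotypes: GenotypeMatrix,
    y: np.ndarray,
    config: MCMCConfig | None = None,
    holdout_n: int = 500,
    seed: int = 0,
) -> dict:
    """Holdout estimate of the share of PVE captured by the predictor.

    Randomly removes ``holdout_n`` subjects, fits the model on the rest,
    projects weights onto the holdout and computes the R^2 of the holdout
    biomarker on the predicted score; %PVE = 100 * R^2 / posterior median
    PVE.  Flagged undefined when the PVE median is numerically zero.
    """
    from predscan.projection import project_scores

    y = np.asarray(y, dtype=float)
    n = genotypes.n_samples
    if holdout_n >= n - 50:
        raise ValueError("holdout_n must leave at least 50 training samples")
    rng = np.random.default_rng(seed)
    hold = np.sort(rng.choice(n, size=holdout_n, replace=False))
    train = np.setdiff1d(np.arange(n), hold)

    fit = fit_bslmm(genotypes.subset_samples(train), y[train], config)
    weights = compute_weights(fit, genotypes.snps)
    scores = project_scores(genotypes.subset_samples(hold), weights)

    yh = y[hold]
    pred = scores.raw
    vp = pred.std()
    r2 = float(np.corrcoef(yh, pred)[0, 1] ** 2) if vp > 0 else 0.0
    pve_med = fit.pve.median
    if pve_med < 1e-6:
        return {"pct_pve": np.nan, "r2": r2, "pve_median": pve_med, "defined": False}
    return {
        "pct_pve": 100.0 * r2 / pve_med,
        "r2": r2,
        "pve_median": pve_med,
        "defined": True,
    }
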