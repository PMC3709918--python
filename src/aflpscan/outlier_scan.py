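"""Bayesian FST-outlier scan for dominant biallelic markers.

The model is the Multinomial-Dirichlet island model with the
Beaumont-Balding decomposition of differentiation: at locus i in
population j the null-allele frequency q_ij is a Beta draw around the
migrant-pool frequency qbar_i with shape c_ij = (1 - F_ij) / F_ij, and

    logit(F_ij) = alpha_i * delta_i + beta_j,

where alpha_i is a locus-specific (selection) effect, beta_j a
population-specific (demographic) effect, and delta_i in {0, 1} an
indicator choosing between the neutral model and the selection model.
Band-absence counts are Binomial(N_ij, q_ij^2) under Hardy-Weinberg
equilibrium (exact dominant-data likelihood; no residual inbreeding).

A reversible-jump MCMC samples (qbar, q, alpha, beta, delta); the
posterior inclusion probability PIP_i = E[delta_i] measures support for
selection at locus i, positive posterior alpha indicating divergent and
negative balancing selection.  Q-values derive from posterior error
probabilities 1 - PIP, and candidate loci follow the replicated-pair
rule: flagged in at least one inter-host comparison and in no intra-host
comparison.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from .io_model import ComparisonPlan, DataError

logger = logging.getLogger("aflpscan")

__all__ = [
    "OutlierModelConfig",
    "fit_outlier_model",
    "compute_qvalues",
    "classify_candidates",
    "summarize_alpha",
]

_EPS = 1e-9


@dataclass
class OutlierModelConfig:
    """Priors and chain settings for the outlier scan.

    Defaults mirror the standard settings of Bayesian FST-outlier
    software: prior odds 10 for the neutral model, alpha ~ N(0, 1),
    beta ~ N(-1, 1.8); chain lengths are desk-scale and configurable.
    """

    prior_odds: float = 10.0
    alpha_sd: float = 1.0
    beta_mean: float = -1.0
    beta_sd: float = 1.8
    n_burnin: int = 5_000
    n_iter: int = 20_000   # post-burn-in iterations (before thinning)
    thin: int = 10
    maf_threshold: float = 0.05
    min_loci: int = 50
    adapt_interval: int = 100
    seed: int = 0

    def validate(self) -> None:
        if self.prior_odds <= 0:
            raise DataError("prior odds must be positive")
        if self.n_iter <= 0 or self.n_burnin < 0:
            raise DataError("chain length must exceed burn-in")
        if not (0 <= self.maf_threshold < 0.5):
            raise DataError("MAF threshold must lie in [0, 0.5)")


def _logit(x: np.ndarray) -> np.ndarray:
    return np.log(x) - np.log1p(-x)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30.0, 30.0)))


def _reflect01(x: np.ndarray) -> np.ndarray:
    x = np.abs(x) % 2.0
    return np.where(x > 1.0, 2.0 - x, x)


def _binom_loglik(q: np.ndarray, m: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Band-absence likelihood: m ~ Binomial(n, q^2), constants dropped."""
    return 2.0 * m * np.log(q) + (n - m) * np.log1p(-(q * q))


def _beta_logpdf(q: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return (a - 1.0) * np.log(q) + (b - 1.0) * np.log1p(-q) - special.betaln(a, b)


def _shapes(qbar: np.ndarray, logit_f: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    f = _sigmoid(logit_f)
    c = (1.0 - f) / f
    return c * qbar[:, None], c * (1.0 - qbar[:, None])


class _Adapt:
    """Robbins-Monro step-size adaptation toward a target acceptance rate."""

    def __init__(self, scale: float, target: float = 0.3):
        self.scale = scale
        self.target = target
        self.accepted = 0.0
        self.proposed = 0.0

    def update(self) -> None:
        if self.proposed == 0:
            return
        rate = self.accepted / self.proposed
        self.scale *= np.exp(0.6 * (rate - self.target))
        self.scale = float(np.clip(self.scale, 1e-4, 2.0))
        self.accepted = self.proposed = 0.0


def maf_filter(
    m: np.ndarray, n: np.ndarray, threshold: float
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled minor-allele-frequency filter across the two populations.

    Uses the ML frequency p = 1 - sqrt(m_pool / n_pool): the filter is a
    statement about the observed sample, so no posterior shrinkage.
    """
    m_pool = m.sum(axis=1)
    n_pool = n.sum(axis=1)
    p_plus = 1.0 - np.sqrt(m_pool / n_pool)
    maf = np.minimum(p_plus, 1.0 - p_plus)
    return maf >= threshold, maf


def fit_outlier_model(
    m: np.ndarray,
    n: np.ndarray,
    locus_ids: list[str] | None = None,
    config: OutlierModelConfig | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """RJ-MCMC outlier scan for one pair of populations.

    Parameters
    ----------
    m, n
        (L, 2) arrays of band-absence counts and sample sizes for the two
        populations.
    Returns a DataFrame with one row per locus: ``pip`` (posterior
    probability of the selection model), ``alpha`` (posterior mean of
    alpha_i given inclusion), ``qvalue``, posterior-mean ``fst_1`` /
    ``fst_2``, and the MAF-filter outcome.  Filtered loci carry NaN
    statistics.
    """
    config = config or OutlierModelConfig()
    config.validate()
    m = np.asarray(m, dtype=float)
    n = np.asarray(n, dtype=float)
    if m.ndim != 2 or m.shape[1] != 2 or m.shape != n.shape:
        raise DataError("m and n must be (L, 2) arrays for two populations")
    n_total = m.shape[0]
    if locus_ids is None:
        locus_ids = [f"L{i + 1:04d}" for i in range(n_total)]

    keep, maf = maf_filter(m, n, config.maf_threshold)
    if keep.sum() == 0:
        raise DataError("degenerate input: no polymorphic locus passes the MAF filter")
    if keep.sum() < config.min_loci:
        raise DataError(
            f"only {int(keep.sum())} loci pass the MAF filter "
            f"(minimum {config.min_loci}; lower config.min_loci to override)"
        )
    mk, nk = m[keep], n[keep]
    n_loci = mk.shape[0]

    rng = np.random.default_rng(config.seed if seed is None else seed)
    pi1 = 1.0 / (1.0 + config.prior_odds)  # prior P(selection model)
    log_prior_ratio = np.log(pi1) - np.log1p(-pi1)

    # Pilot per-locus moment estimate of logit(FST) for the jump proposal:
    # proposing alpha from its prior almost never reaches large planted
    # effects, so the reversible jump proposes from a data-informed normal
    # centred on the pilot contrast (with the proper Hastings correction).
    qh = np.sqrt(mk / nk)
    pilot_var = (1.0 - mk / nk) / (4.0 * nk)
    s2 = (qh[:, 0] - qh[:, 1]) ** 2 / 2.0 - pilot_var.mean(axis=1)
    qm = qh.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_pilot = s2 / np.clip(qm * (1.0 - qm), 1e-3, None)
    f_pilot = np.clip(np.nan_to_num(f_pilot), 5e-3, 0.9)
    pilot_logit_f = _logit(f_pilot)
    prop_sd = 1.0

    # initial state
    x = mk / nk
    qbar = np.clip(np.sqrt(x.mean(axis=1)), 0.02, 0.98)
    q = np.clip(np.sqrt(x), 0.02, 0.98)
    alpha = np.zeros(n_loci)
    delta = np.zeros(n_loci, dtype=bool)
    beta = np.full(2, config.beta_mean)

    def logit_f_mat(alpha_v: np.ndarray, delta_v: np.ndarray) -> np.ndarray:
        return (alpha_v * delta_v)[:, None] + beta[None, :]

    ad_q = _Adapt(0.1)
    ad_qbar = _Adapt(0.1)
    ad_alpha = _Adapt(0.4)
    ad_beta = _Adapt(0.15)

    sum_delta = np.zeros(n_loci)
    sum_alpha = np.zeros(n_loci)
    sum_f = np.zeros((n_loci, 2))
    half_delta = [np.zeros(n_loci), np.zeros(n_loci)]
    half_count = [0, 0]
    kept = 0

    lik = _binom_loglik(q, mk, nk)
    a_sh, b_sh = _shapes(qbar, logit_f_mat(alpha, delta))
    pbeta = _beta_logpdf(q, a_sh, b_sh)

    total_iter = config.n_burnin + config.n_iter
    for it in range(total_iter):
        burnin = it < config.n_burnin

        # --- update q_ij
        prop = np.clip(_reflect01(q + rng.normal(0.0, ad_q.scale, q.shape)),
                       _EPS, 1.0 - _EPS)
        lik_p = _binom_loglik(prop, mk, nk)
        pbeta_p = _beta_logpdf(prop, a_sh, b_sh)
        acc = np.log(rng.uniform(size=q.shape)) < (lik_p - lik + pbeta_p - pbeta)
        q = np.where(acc, prop, q)
        lik = np.where(acc, lik_p, lik)
        pbeta = np.where(acc, pbeta_p, pbeta)
        ad_q.accepted += acc.mean()
        ad_q.proposed += 1

        # --- update qbar_i (uniform prior)
        prop = np.clip(_reflect01(qbar + rng.normal(0.0, ad_qbar.scale, n_loci)),
                       _EPS, 1.0 - _EPS)
        a_p, b_p = _shapes(prop, logit_f_mat(alpha, delta))
        pbeta_p = _beta_logpdf(q, a_p, b_p)
        acc = np.log(rng.uniform(size=n_loci)) < (pbeta_p - pbeta).sum(axis=1)
        qbar = np.where(acc, prop, qbar)
        a_sh = np.where(acc[:, None], a_p, a_sh)
        b_sh = np.where(acc[:, None], b_p, b_sh)
        pbeta = np.where(acc[:, None], pbeta_p, pbeta)
        ad_qbar.accepted += acc.mean()
        ad_qbar.proposed += 1

        # --- update alpha_i where delta_i = 1
        if delta.any():
            prop_a = alpha + rng.normal(0.0, ad_alpha.scale, n_loci)
            a_p, b_p = _shapes(qbar, logit_f_mat(prop_a, delta))
            pbeta_p = _beta_logpdf(q, a_p, b_p)
            dprior = (alpha**2 - prop_a**2) / (2.0 * config.alpha_sd**2)
            ratio = (pbeta_p - pbeta).sum(axis=1) + dprior
            acc = delta & (np.log(rng.uniform(size=n_loci)) < ratio)
            alpha = np.where(acc, prop_a, alpha)
            a_sh = np.where(acc[:, None], a_p, a_sh)
            b_sh = np.where(acc[:, None], b_p, b_sh)
            pbeta = np.where(acc[:, None], pbeta_p, pbeta)
            ad_alpha.accepted += acc.sum() / max(delta.sum(), 1)
            ad_alpha.proposed += 1

        # --- update beta_j
        for j in (0, 1):
            prop_b = beta.copy()
            prop_b[j] += rng.normal(0.0, ad_beta.scale)
            lf = (alpha * delta)[:, None] + prop_b[None, :]
            a_p, b_p = _shapes(qbar, lf)
            pbeta_p = _beta_logpdf(q, a_p, b_p)
            dprior = ((beta[j] - config.beta_mean) ** 2
                      - (prop_b[j] - config.beta_mean) ** 2) / (2.0 * config.beta_sd**2)
            ratio = (pbeta_p[:, j] - pbeta[:, j]).sum() + dprior
            if np.log(rng.uniform()) < ratio:
                beta = prop_b
                a_sh, b_sh, pbeta = a_p, b_p, pbeta_p
                ad_beta.accepted += 1
            ad_beta.proposed += 1

        # --- reversible jump on delta_i: alpha proposed from a normal centred
        #     on the pilot contrast given the current beta; the acceptance
        #     ratio carries prior/proposal and prior-odds terms
        prop_mu = pilot_logit_f - beta.mean()
        alpha_new = np.where(delta, alpha, rng.normal(prop_mu, prop_sd))
        a_p, b_p = _shapes(qbar, logit_f_mat(alpha_new, ~delta))
        pbeta_p = _beta_logpdf(q, a_p, b_p)
        a_involved = np.where(delta, alpha, alpha_new)
        log_prior_alpha = -0.5 * (a_involved / config.alpha_sd) ** 2 - np.log(
            config.alpha_sd
        )
        log_prop_alpha = -0.5 * ((a_involved - prop_mu) / prop_sd) ** 2 - np.log(
            prop_sd
        )
        ratio = (pbeta_p - pbeta).sum(axis=1) + np.where(
            delta,
            -log_prior_ratio - log_prior_alpha + log_prop_alpha,
            log_prior_ratio + log_prior_alpha - log_prop_alpha,
        )
        acc = np.log(rng.uniform(size=n_loci)) < ratio
        delta = np.where(acc, ~delta, delta)
        alpha = np.where(acc & delta, alpha_new, np.where(delta, alpha, 0.0))
        a_sh = np.where(acc[:, None], a_p, a_sh)
        b_sh = np.where(acc[:, None], b_p, b_sh)
        pbeta = np.where(acc[:, None], pbeta_p, pbeta)

        if burnin:
            if (it + 1) % config.adapt_interval == 0:
                for ad in (ad_q, ad_qbar, ad_alpha, ad_beta):
                    ad.update()
            continue

        post_it = it - config.n_burnin
        if post_it % config.thin == 0:
            kept += 1
            sum_delta += delta
            sum_alpha += alpha * delta
            sum_f += _sigmoid(logit_f_mat(alpha, delta))
            h = 0 if post_it < config.n_iter // 2 else 1
            half_delta[h] += delta
            half_count[h] += 1

    pip = sum_delta / kept
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha_mean = np.where(sum_delta > 0, sum_alpha / np.maximum(sum_delta, 1), np.nan)
    fst_mean = sum_f / kept

    if min(half_count) > 0:
        disc = np.abs(half_delta[0] / half_count[0] - half_delta[1] / half_count[1])
        frac = float(np.mean(disc > 0.1))
        if frac > 0.05:
            logger.warning(
                "outlier-scan convergence heuristic: split-chain PIP discrepancy "
                "> 0.1 at %.1f%% of loci (max %.3f); consider longer chains",
                100 * frac, float(disc.max()),
            )

    out = pd.DataFrame(
        {
            "locus_id": locus_ids,
            "maf": maf,
            "maf_pass": keep,
            "pip": np.nan,
            "alpha": np.nan,
            "qvalue": np.nan,
            "fst_1": np.nan,
            "fst_2": np.nan,
        }
    )
    out.loc[keep, "pip"] = pip
    out.loc[keep, "alpha"] = alpha_mean
    out.loc[keep, "fst_1"] = fst_mean[:, 0]
    out.loc[keep, "fst_2"] = fst_mean[:, 1]
    out.loc[keep, "qvalue"] = compute_qvalues(pip)
    return out


def compute_qvalues(pip: np.ndarray) -> np.ndarray:
    """Bayesian q-values from posterior inclusion probabilities.

    With posterior error probability PEP_i = 1 - PIP_i, the q-value of
    locus i is the mean PEP over all loci at least as extreme
    (PEP <= PEP_i) -- the estimated FDR incurred when declaring locus i
    and everything stronger significant.
    """
    pip = np.asarray(pip, dtype=float)
    if pip.size == 0:
        return pip.copy()
    if ((pip < 0) | (pip > 1)).any():
        raise DataError("PIP values must lie in [0, 1]")
    pep = 1.0 - pip
    order = np.argsort(pep, kind="stable")
    running = np.cumsum(pep[order]) / np.arange(1, pep.size + 1)
    q = np.empty_like(pep)
    q[order] = running
    return q


def classify_candidates(
    scan_results: dict[str, pd.DataFrame],
    plan: ComparisonPlan,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Replicated-pair candidate rule at one FDR threshold.

    ``scan_results`` maps comparison id ("popA/popB") to the per-locus
    DataFrame of :func:`fit_outlier_model`.  A locus is a candidate when
    flagged (q-value <= threshold) in at least one inter-host comparison
    and in none of the intra-host comparisons; its summary alpha is the
    mean posterior alpha over the comparisons where it was flagged.
    """
    inter_ids = {plan.comparison_id(p) for p in plan.inter_host}
    intra_ids = {plan.comparison_id(p) for p in plan.intra_host}
    known = inter_ids | intra_ids
    for cid in scan_results:
        if cid not in known:
            raise DataError(f"comparison {cid!r} not in plan for {plan.country!r}")
    missing = known - set(scan_results)
    if missing:
        logger.warning(
            "missing scan results for comparisons %s: treated as not flagged",
            sorted(missing),
        )

    all_loci: list[str] = []
    for df in scan_results.values():
        for l in df["locus_id"]:
            if l not in all_loci:
                all_loci.append(l)

    rows = []
    for locus in all_loci:
        inter_flags, intra_flags, alphas = 0, 0, []
        for cid, df in scan_results.items():
            sub = df[df["locus_id"] == locus]
            if sub.empty or not np.isfinite(sub["qvalue"].iloc[0]):
                continue
            flagged = sub["qvalue"].iloc[0] <= fdr_threshold
            if not flagged:
                continue
            if cid in inter_ids:
                inter_flags += 1
                alphas.append(float(sub["alpha"].iloc[0]))
            else:
                intra_flags += 1
        candidate = inter_flags >= 1 and intra_flags == 0
        rows.append(
            {
                "locus_id": locus,
                "n_inter_flags": inter_flags,
                "n_intra_flags": intra_flags,
                "candidate": candidate,
                "alpha_mean": summarize_alpha(alphas) if candidate and alphas else np.nan,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["fdr_threshold"] = fdr_threshold
    out.attrs["country"] = plan.country
    return out


def summarize_alpha(alphas: list[float] | np.ndarray) -> float:
    """Mean locus effect over flagged comparisons, reported to 2 decimals.

    Rounds half away from zero (the usual print convention), not
    banker's rounding: mean(1.62, 1.95) = 1.785 reports as 1.79.
    """
    alphas = np.asarray(alphas, dtype=float)
    if alphas.size == 0:
        raise DataError("no flagged comparisons: mean alpha undefined")
    mean = float(np.mean(alphas))
    return math.copysign(math.floor(abs(mean) * 100 + 0.5) / 100, mean)
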