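"""Gametic disequilibrium between dominant loci.

With dominant markers only four joint band phenotype classes are
observable for a locus pair (presence/absence at A x presence/absence at
B).  Under Hardy-Weinberg equilibrium and random union of gametes the
class probabilities are determined by the null-allele frequencies q_A,
q_B and the double-null gamete frequency g: P(aa,bb) = g^2, P(absent at
A) = q_A^2, P(absent at B) = q_B^2.  The maximum-likelihood solution
matches cell frequencies (Hill's classic ML estimate for dominant data),
with g clamped into the feasible gamete-frequency interval; the
disequilibrium coefficient is D = g - q_A q_B and the gametic correlation
r = D / sqrt(p_A(1-p_A) p_B(1-p_B)) with p = 1 - q the dominant-allele
frequency.

Because phenotype randomization is not a valid null for dominant data
(band presence confounds +/+ and +/-), significance comes from an MCMC
randomization of the *underlying genotype frequencies*: a Metropolis
chain samples each locus's null-allele frequency from its Zhivotovsky
posterior, draws pseudo allele counts, pairs them into genotypes, and
recomputes r, giving the null distribution of r under linkage
equilibrium conditional on the observed phenotype counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .io_model import DataError

__all__ = [
    "PhenotypeCounts2x2",
    "LDEstimate",
    "LDTestResult",
    "phenotype_counts",
    "hill_ml_d",
    "mcmc_null_pvalue",
    "combine_pvalues_z",
    "bh_fdr",
]


@dataclass
class PhenotypeCounts2x2:
    """Joint band phenotype counts for a locus pair in one population.

    P = band presence, a = band absence; the first letter refers to locus
    A, the second to locus B.
    """

    n_pp: int
    n_pa: int  # present at A, absent at B
    n_ap: int  # absent at A, present at B
    n_aa: int

    def __post_init__(self) -> None:
        for v in (self.n_pp, self.n_pa, self.n_ap, self.n_aa):
            if v < 0:
                raise DataError("negative phenotype count")
        if self.total < 1:
            raise DataError("empty phenotype table (N = 0)")

    @property
    def total(self) -> int:
        return self.n_pp + self.n_pa + self.n_ap + self.n_aa


@dataclass
class LDEstimate:
    q_a: float
    q_b: float
    g_ab: float   # double-null gamete frequency
    d: float      # g_ab - q_a * q_b
    r: float      # gametic correlation; NaN when a locus is fixed
    clamped: bool


def phenotype_counts(pheno_a: np.ndarray, pheno_b: np.ndarray) -> PhenotypeCounts2x2:
    """Tabulate joint phenotypes, excluding individuals missing at either locus."""
    a = np.asarray(pheno_a, dtype=float)
    b = np.asarray(pheno_b, dtype=float)
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    return PhenotypeCounts2x2(
        n_pp=int(np.sum((a == 1) & (b == 1))),
        n_pa=int(np.sum((a == 1) & (b == 0))),
        n_ap=int(np.sum((a == 0) & (b == 1))),
        n_aa=int(np.sum((a == 0) & (b == 0))),
    )


def _loglik(counts: PhenotypeCounts2x2, q_a: float, q_b: float, g: float) -> float:
    # scalar hot path (called inside the constrained-ML refit): plain math
    cells = (
        1.0 - q_a * q_a - q_b * q_b + g * g,
        q_b * q_b - g * g,
        q_a * q_a - g * g,
        g * g,
    )
    ns = (counts.n_pp, counts.n_pa, counts.n_ap, counts.n_aa)
    total = 0.0
    for c, k in zip(cells, ns):
        if k > 0:
            if c <= 0.0:
                return -math.inf
            total += k * math.log(c)
    return total


def _best_g(counts: PhenotypeCounts2x2, q_a: float, q_b: float) -> tuple[float, float]:
    """Exact profile maximization over the gamete frequency g.

    For fixed marginals the log-likelihood's stationary points in
    z = g^2 are roots of a cubic; the maximum is among those roots and
    the feasibility endpoints.  Returns (g, max log-likelihood).
    """
    x, y = q_a * q_a, q_b * q_b
    w = 1.0 - x - y
    glo, ghi = max(0.0, q_a + q_b - 1.0), min(q_a, q_b)
    zlo, zhi = glo * glo, ghi * ghi
    cands = [zlo, zhi]
    if zhi - zlo > 1e-15:
        n_aa, n_ap, n_pa, n_pp = counts.n_aa, counts.n_ap, counts.n_pa, counts.n_pp
        a_sum, b_prod = x + y, x * y
        c3 = float(n_aa + n_ap + n_pa + n_pp)
        c2 = n_aa * (w - a_sum) - n_ap * (y - w) - n_pa * (x - w) - n_pp * a_sum
        c1 = n_aa * (b_prod - w * a_sum) - n_ap * y * w - n_pa * x * w + n_pp * b_prod
        c0 = n_aa * w * b_prod
        for r in np.roots([c3, c2, c1, c0]):
            if abs(r.imag) < 1e-9 and zlo < r.real < zhi:
                cands.append(float(r.real))
    best_g, best_ll = glo, -math.inf
    for z in cands:
        g = math.sqrt(max(z, 0.0))
        ll = _loglik(counts, q_a, q_b, g)
        if ll > best_ll:
            best_g, best_ll = g, ll
    return best_g, best_ll


def hill_ml_d(counts: PhenotypeCounts2x2, fast_refit: bool = False) -> LDEstimate:
    """ML estimate of gametic disequilibrium from a 2x2 phenotype table.

    The cell-matching solution q_A = sqrt((n_aP + n_aa)/N), q_B =
    sqrt((n_Pa + n_aa)/N), g = sqrt(n_aa/N) is the global multinomial ML
    whenever g lies in the feasible interval
    [max(0, q_A + q_B - 1), min(q_A, q_B)].  When the lower Frechet bound
    binds (possible with very few double-presence phenotypes), the
    marginals are re-fit numerically on the boundary g = q_A + q_B - 1 so
    the estimate remains the constrained ML.
    """
    n = counts.total
    q_a = float(np.sqrt((counts.n_ap + counts.n_aa) / n))
    q_b = float(np.sqrt((counts.n_pa + counts.n_aa) / n))
    g = float(np.sqrt(counts.n_aa / n))

    lo = max(0.0, q_a + q_b - 1.0)
    hi = min(q_a, q_b)
    clamped = False
    if g < lo - 1e-12 and hi - lo > 1e-12:
        clamped = True
        # The cell-matching solution is infeasible at the gamete level, so the
        # constrained optimum need not sit at the cell-matching marginals:
        # profile the likelihood over (q_a, q_b) with an inner exact 1-D
        # maximization over g inside its feasible interval (the log-likelihood
        # is concave in g^2, hence unimodal in g).
        nm_opts = (
            {"xatol": 1e-6, "fatol": 1e-9, "maxiter": 400}
            if fast_refit
            else {"xatol": 1e-10, "fatol": 1e-13, "maxiter": 4000}
        )

        def profile_neg(theta: np.ndarray) -> float:
            qa, qb = theta
            if not (0.0 < qa < 1.0 and 0.0 < qb < 1.0):
                return np.inf
            return -_best_g(counts, qa, qb)[1]

        res = optimize.minimize(
            profile_neg, x0=[q_a, q_b], method="Nelder-Mead", options=nm_opts,
        )
        q_a, q_b = (float(x) for x in res.x)
        g = _best_g(counts, q_a, q_b)[0]
    elif g < lo:  # degenerate interval: snap to the bound
        clamped = True
        g = lo
    elif g > hi:  # cannot occur for counts, kept as a guard for float edge cases
        clamped = True
        g = hi

    d = g - q_a * q_b
    if q_a in (0.0, 1.0) or q_b in (0.0, 1.0):
        r = float("nan")
    else:
        r = d / np.sqrt(q_a * (1 - q_a) * q_b * (1 - q_b))
    return LDEstimate(q_a=q_a, q_b=q_b, g_ab=g, d=float(d), r=float(r),
                      clamped=clamped)


# ---------------------------------------------------------------------------
# MCMC null distribution of the gametic correlation


@dataclass
class LDTestResult:
    r_obs: float
    p_value: float
    null_r: np.ndarray
    steps: int
    window: float
    seed: int
    two_sided: bool


def _zhiv_logpost(q: float, m: int, n: int, a: float = 1.0, b: float = 1.0) -> float:
    """Log posterior density of the null-allele frequency q (u = q^2 ~ Beta)."""
    if q <= 0.0 or q >= 1.0:
        return -np.inf
    return (2 * (m + a) - 1) * np.log(q) + (n - m + b - 1) * np.log1p(-(q * q))


def _reflect(x: float) -> float:
    # reflecting boundaries on [0, 1]
    x = x % 2.0
    return 2.0 - x if x > 1.0 else x


def mcmc_null_pvalue(
    m_a: int,
    n_a: int,
    m_b: int,
    n_b: int,
    r_obs: float,
    steps: int = 10_000,
    window: float = 0.15,
    seed: int = 0,
    two_sided: bool = False,
    prior: tuple[float, float] = (1.0, 1.0),
) -> LDTestResult:
    """Null distribution of r under linkage equilibrium, by genotype MCMC.

    ``m_a, n_a`` and ``m_b, n_b`` are the band-absence count and sample
    size at each locus.  The chain state is the pair of null-allele
    frequencies, initialised at the Zhivotovsky posterior means and
    updated by a uniform proposal of width ``window`` with reflection at
    [0, 1], accepted by the Metropolis ratio of the Zhivotovsky posterior
    at each locus independently.  At every step, 2N pseudo allele copies
    per locus are drawn Binomial(2N, q), randomly paired into N diploid
    genotypes, converted to band phenotypes, randomly paired across
    individuals, and one null r is computed.  The one-sided P-value is
    (1 + #{r_null >= r_obs}) / (steps + 1); with ``two_sided`` the
    comparison is on |r|.
    """
    if steps < 100:
        raise DataError("need >=100 MCMC steps")
    for m, n in ((m_a, n_a), (m_b, n_b)):
        if m == 0 or m == n:
            raise DataError("monomorphic locus in sample: LD P-value undefined")
    if n_a != n_b:
        raise DataError("locus sample sizes differ within one population")
    n_ind = n_a
    rng = np.random.default_rng(seed)

    from .dominant_freq import zhivotovsky_qhat

    q = [
        float(zhivotovsky_qhat(m_a, n_a, prior).qhat),
        float(zhivotovsky_qhat(m_b, n_b, prior).qhat),
    ]
    data = [(m_a, n_a), (m_b, n_b)]
    logp = [_zhiv_logpost(q[k], *data[k], *prior) for k in range(2)]

    # --- Metropolis chain on (q_A, q_B): cheap scalar loop
    half = window / 2.0
    unif = rng.uniform(-half, half, size=(steps, 2))
    log_u = np.log(rng.uniform(size=(steps, 2)))
    q_chain = np.empty((steps, 2))
    for t in range(steps):
        for k in range(2):
            prop = _reflect(q[k] + unif[t, k])
            lp = _zhiv_logpost(prop, *data[k], *prior)
            if lp - logp[k] > log_u[t, k]:
                q[k], logp[k] = prop, lp
        q_chain[t] = q

    # --- pseudo data under linkage equilibrium, vectorized across steps:
    # 2N allele copies per locus, randomly paired into N diploids (random
    # ranks below k are null), then phenotypes re-paired across individuals,
    # which makes the double-absence count hypergeometric given the margins.
    absent = np.empty((steps, 2), dtype=np.int64)
    for k in range(2):
        k_null = rng.binomial(2 * n_ind, q_chain[:, k])
        ranks = np.argsort(
            np.argsort(rng.random((steps, 2 * n_ind)), axis=1), axis=1
        )
        nulls = ranks < k_null[:, None]
        absent[:, k] = (nulls[:, :n_ind] & nulls[:, n_ind:]).sum(axis=1)
    n_aa = rng.hypergeometric(
        absent[:, 0], n_ind - absent[:, 0], np.maximum(absent[:, 1], 0)
    )
    # closed-form Hill estimate per step (cell matching); the rare tables
    # where the Frechet clamp binds go through the full constrained fit
    qa = np.sqrt(absent[:, 0] / n_ind)
    qb = np.sqrt(absent[:, 1] / n_ind)
    g = np.sqrt(n_aa / n_ind)
    lo = np.maximum(0.0, qa + qb - 1.0)
    d = g - qa * qb
    denom = qa * (1 - qa) * qb * (1 - qb)
    with np.errstate(invalid="ignore", divide="ignore"):
        null_r = np.where(denom > 0, d / np.sqrt(denom), np.nan)
    refit = (g < lo - 1e-12) & (np.minimum(qa, qb) - lo > 1e-12)
    for t in np.flatnonzero(refit):
        n_ab = int(absent[t, 0] - n_aa[t])
        n_ba = int(absent[t, 1] - n_aa[t])
        est = hill_ml_d(
            PhenotypeCounts2x2(
                int(n_ind - n_ab - n_ba - n_aa[t]), n_ba, n_ab, int(n_aa[t])
            ),
            fast_refit=True,
        )
        null_r[t] = est.r

    # a monomorphic pseudo-sample leaves r undefined; such draws count as
    # exceedances (conservative tie-breaking keeps P valid and equal to 1
    # when r_obs is below every null draw)
    n_undef = int(np.isnan(null_r).sum())
    finite = null_r[~np.isnan(null_r)]
    if two_sided:
        count = int(np.sum(np.abs(finite) >= abs(r_obs))) + n_undef
    else:
        count = int(np.sum(finite >= r_obs)) + n_undef
    p = (1.0 + count) / (steps + 1.0)
    return LDTestResult(
        r_obs=float(r_obs), p_value=float(p), null_r=null_r,
        steps=steps, window=window, seed=seed, two_sided=two_sided,
    )


# ---------------------------------------------------------------------------
# P-value combination and FDR


def combine_pvalues_z(
    pvalues: np.ndarray, weights: np.ndarray | None = None
) -> float:
    """Whitlock's weighted Z-transform combination of one-sided P-values.

    Z_i = Phi^-1(1 - P_i); Z = sum(w_i Z_i) / sqrt(sum(w_i^2)); combined
    P = 1 - Phi(Z).  Default weights are equal.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise DataError("no P-values to combine")
    if (p <= 0).any() or (p > 1).any():
        raise DataError("P-values must lie in (0, 1]")
    w = np.ones_like(p) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != p.shape or (w <= 0).any():
        raise DataError("weights must be positive and match P-values")
    z = stats.norm.isf(p)
    z_comb = float(np.sum(w * z) / np.sqrt(np.sum(w**2)))
    return float(stats.norm.sf(z_comb))


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P-values (monotone)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]
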