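"""Population differentiation for dominant data: FST, AMOVA, FST distributions.

FST follows the Lynch-Milligan variance-component approach for dominant
markers: per locus, the among-population variance of the null-allele
frequency estimates q_hat = sqrt(m/N) is corrected by subtracting the
mean sampling variance of those estimates, the within-population
variance is the mean gene variance q(1-q), and the multi-locus estimate
is the ratio of sums over loci.  The sampling variance of sqrt(m/N) is
computed exactly under the binomial law and averaged over the Jeffreys
posterior of the band-absence probability u (rather than the first-order
Taylor term (1-x)/4N), which keeps the correction honest at nearly fixed
loci where the Taylor expansion breaks down.  Negative per-locus values
are retained so that distribution-level summaries stay unbiased.

The hierarchical AMOVA is an expected-dosage surrogate: each individual's
unobservable null-allele dosage is replaced by its HWE expectation
conditional on the band phenotype (2 when the band is absent, 2q/(1+q)
when present), and variance components come from unbalanced nested
ANOVA mean squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dominant_freq import LocusFrequencies, population_frequencies, zhivotovsky_qhat
from .io_model import BandMatrix, DataError, SampleMap

__all__ = [
    "FstResult",
    "AmovaResult",
    "FstDistributionSummary",
    "pairwise_fst",
    "fst_matrix",
    "permutation_pvalue",
    "amova",
    "fst_distribution_stats",
]


@dataclass
class FstResult:
    multi_locus: float
    per_locus: np.ndarray
    among: np.ndarray   # corrected among-population variance per locus
    total: np.ndarray   # among + within per locus


@dataclass
class AmovaResult:
    """Nested variance components and coancestry coefficients.

    sigma2_c: between host types; sigma2_b: among populations within host
    types; sigma2_a: among individuals within populations.  theta_ct =
    sigma2_c / total, theta_st = (sigma2_c + sigma2_b) / total, theta_sc =
    sigma2_b / (sigma2_b + sigma2_a).  CIs are percentile bootstrap over
    loci.
    """

    sigma2_c: float
    sigma2_b: float
    sigma2_a: float
    theta_ct: float
    theta_sc: float
    theta_st: float
    ci: dict[str, tuple[float, float]]
    per_locus: pd.DataFrame  # columns sigma2_c, sigma2_b, sigma2_a


@dataclass
class FstDistributionSummary:
    mean: float
    kurtosis: float  # non-excess (normal = 3)
    n: int


# ---------------------------------------------------------------------------
# Lynch & Milligan FST

_VAR_CACHE: dict[tuple[int, int], np.ndarray] = {}


def sampling_var_sqrt(m: np.ndarray, n: np.ndarray, grid: int = 60) -> np.ndarray:
    """Sampling variance of q_hat = sqrt(m/N), exact in the binomial law.

    Var(sqrt(Bin(N, u)/N)) is evaluated on a quantile grid of the
    Jeffreys posterior u ~ Beta(m + 1/2, N - m + 1/2) and averaged,
    acknowledging that the true band-absence probability u is unknown;
    a point plug-in at m/N collapses to zero at fixed loci and the
    first-order Taylor term (1-x)/4N is badly biased there.
    Results are cached per sample size.
    """
    m = np.asarray(m, dtype=int)
    n = np.asarray(n, dtype=int)
    out = np.empty(m.shape, dtype=float)
    for size in np.unique(n):
        key = (int(size), grid)
        if key not in _VAR_CACHE:
            qs = (np.arange(grid) + 0.5) / grid
            k = np.arange(size + 1)
            sq = np.sqrt(k / size)
            table = np.empty(size + 1)
            for mi in range(size + 1):
                u = stats.beta.ppf(qs, mi + 0.5, size - mi + 0.5)
                pmf = stats.binom.pmf(k[None, :], size, u[:, None])
                e1 = (pmf * sq[None, :]).sum(axis=1)
                e2 = (pmf * (k / size)[None, :]).sum(axis=1)
                table[mi] = float(np.mean(e2 - e1**2))
            _VAR_CACHE[key] = table
        sel = n == size
        out[sel] = _VAR_CACHE[key][m[sel]]
    return out


def _fst_components(
    qhats: np.ndarray, variances: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus among (corrected) and total variance for J populations.

    ``qhats`` and ``variances`` are (J, L) arrays of frequency estimates
    and their sampling variances.
    """
    j = qhats.shape[0]
    if j < 2:
        raise DataError("need >=2 populations for FST")
    qbar = qhats.mean(axis=0)
    s2 = np.sum((qhats - qbar) ** 2, axis=0) / (j - 1)
    among = s2 - variances.mean(axis=0)
    within = np.mean(qhats * (1.0 - qhats), axis=0)
    return among, among + within


def pairwise_fst(
    freqs_a: LocusFrequencies, freqs_b: LocusFrequencies
) -> FstResult:
    """Multi-locus and per-locus FST between two populations.

    Raises when all loci are monomorphic in both populations (total
    variance zero, FST undefined).
    """
    return multipop_fst([freqs_a, freqs_b])


def multipop_fst(freqs: list[LocusFrequencies]) -> FstResult:
    qhats = np.vstack([np.sqrt(f.m / f.n) for f in freqs])
    variances = np.vstack([sampling_var_sqrt(f.m, f.n) for f in freqs])
    among, total = _fst_components(qhats, variances)
    denom = total.sum()
    if denom <= 0:
        raise DataError("FST undefined: all loci monomorphic in all populations")
    with np.errstate(divide="ignore", invalid="ignore"):
        per_locus = np.where(total > 0, among / np.where(total > 0, total, 1.0), np.nan)
    return FstResult(
        multi_locus=float(among.sum() / denom),
        per_locus=per_locus,
        among=among,
        total=total,
    )


def fst_matrix(
    band: BandMatrix,
    smap: SampleMap,
    prior: str | tuple[float, float] = "uniform",
    pairs: list[tuple[str, str]] | None = None,
) -> tuple[pd.DataFrame, dict[tuple[str, str], FstResult]]:
    """Symmetric pairwise multi-locus FST matrix over populations."""
    freqs = population_frequencies(band, smap, prior)
    pops = sorted(freqs)
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(pops) for b in pops[i + 1:]]
    mat = pd.DataFrame(0.0, index=pops, columns=pops)
    results: dict[tuple[str, str], FstResult] = {}
    for a, b in pairs:
        res = pairwise_fst(freqs[a], freqs[b])
        results[(a, b)] = res
        mat.loc[a, b] = mat.loc[b, a] = res.multi_locus
    return mat, results


def permutation_pvalue(
    band: BandMatrix,
    smap: SampleMap,
    pop_a: str,
    pop_b: str,
    n_permutations: int = 999,
    prior: str | tuple[float, float] = "uniform",
    seed: int = 0,
) -> tuple[float, float]:
    """Permutation P for pairwise FST: individuals shuffled between pops.

    P = (1 + #{FST_perm >= FST_obs}) / (n_permutations + 1).
    """
    ids = smap.samples_in(pop_a) + smap.samples_in(pop_b)
    n_a = len(smap.samples_in(pop_a))
    sub = band.subset_samples(ids)
    pheno = sub.phenotypes

    def fst_of(split: np.ndarray) -> float:
        res_parts = []
        for grp in (split[:n_a], split[n_a:]):
            block = pheno[grp, :]
            n = np.sum(~np.isnan(block), axis=0)
            m = np.sum(block == 0, axis=0)
            res_parts.append(zhivotovsky_qhat(m, np.maximum(n, 1), (1.0, 1.0)))
        return multipop_fst(res_parts).multi_locus

    order = np.arange(len(ids))
    obs = fst_of(order)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(order)
        if fst_of(perm) >= obs:
            count += 1
    return obs, (1.0 + count) / (n_permutations + 1.0)


# ---------------------------------------------------------------------------
# Hierarchical AMOVA (expected-dosage surrogate)


def expected_dosage(
    pheno: np.ndarray, qhat: np.ndarray
) -> np.ndarray:
    """Expected null-allele dosage per individual given phenotype and q.

    Band absent (-/-) has dosage 2; band present has the HWE conditional
    expectation E[dosage | not -/-] = 2pq / (1 - q^2) = 2q / (1 + q).
    ``pheno`` is (n, L); ``qhat`` is (L,).  Missing stays NaN.
    """
    present = 2.0 * qhat / (1.0 + qhat)
    return np.where(np.isnan(pheno), np.nan, np.where(pheno == 0, 2.0, present))


def _nested_components(
    y: np.ndarray, pop_codes: np.ndarray, group_codes: np.ndarray
) -> tuple[float, float, float]:
    """Unbalanced nested ANOVA components for one locus's dosage vector.

    y: (n,) with NaN allowed; levels group (host type) / population /
    individual.  Returns (sigma2_c, sigma2_b, sigma2_a).
    """
    keep = ~np.isnan(y)
    y, pop_codes, group_codes = y[keep], pop_codes[keep], group_codes[keep]
    n_tot = y.size
    groups = np.unique(group_codes)
    pops = np.unique(pop_codes)
    g, p = groups.size, pops.size
    if g < 2 or p <= g or n_tot <= p:
        raise DataError("AMOVA needs >=2 host types each with >=2 populations")

    grand = y.mean()
    ss_within = ss_pop = ss_group = 0.0
    sum_npg2_over_ng = 0.0
    sum_npg2 = 0.0
    sum_ng2 = 0.0
    for gc in groups:
        in_g = group_codes == gc
        y_g = y[in_g]
        n_g = y_g.size
        sum_ng2 += n_g**2
        ss_group += n_g * (y_g.mean() - grand) ** 2
        for pc in np.unique(pop_codes[in_g]):
            y_p = y[in_g][pop_codes[in_g] == pc]
            n_p = y_p.size
            sum_npg2 += n_p**2
            sum_npg2_over_ng += n_p**2 / n_g
            ss_pop += n_p * (y_p.mean() - y_g.mean()) ** 2
            ss_within += np.sum((y_p - y_p.mean()) ** 2)

    ms_within = ss_within / (n_tot - p)
    ms_pop = ss_pop / (p - g)
    ms_group = ss_group / (g - 1)
    # expected-mean-square coefficients for the unbalanced nested design
    n_b = (n_tot - sum_npg2_over_ng) / (p - g)
    n_b2 = (sum_npg2_over_ng - sum_npg2 / n_tot) / (g - 1)
    n_c = (n_tot - sum_ng2 / n_tot) / (g - 1)

    sigma2_a = ms_within
    sigma2_b = (ms_pop - ms_within) / n_b
    sigma2_c = (ms_group - ms_within - n_b2 * sigma2_b) / n_c
    return float(sigma2_c), float(sigma2_b), float(sigma2_a)


def amova(
    band: BandMatrix,
    smap: SampleMap,
    freqs: dict[str, LocusFrequencies] | None = None,
    locus_ids: list[str] | None = None,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> AmovaResult:
    """Three-level AMOVA: host type / population / individual.

    Components are estimated per locus from expected null-allele dosages
    and summed over loci; coancestry coefficients are ratios of summed
    components, with percentile bootstrap CIs over loci.
    """
    if freqs is None:
        freqs = population_frequencies(band, smap)
    sub = band if locus_ids is None else band.subset_loci(locus_ids)
    l_idx = [band.locus_ids.index(l) for l in sub.locus_ids]

    pop_tab = smap.population_table()
    per_host = pop_tab.groupby("host_type").size()
    if len(per_host) < 2 or (per_host < 2).any():
        raise DataError("AMOVA needs >=2 host types each with >=2 populations")

    pops = sorted(freqs)
    pop_of = smap.table.loc[sub.sample_ids, "population"].to_numpy()
    host_of = smap.table.loc[sub.sample_ids, "host_type"].to_numpy()
    pop_codes = np.searchsorted(np.array(pops), pop_of)
    host_codes = pd.factorize(host_of, sort=True)[0]

    qhat_mat = np.vstack([freqs[p].qhat[l_idx] for p in pops])  # (P, L)
    comps = np.zeros((sub.n_loci, 3))
    for j in range(sub.n_loci):
        q_ind = qhat_mat[pop_codes, j]
        y = expected_dosage(sub.phenotypes[:, j], q_ind)
        comps[j] = _nested_components(y, pop_codes, host_codes)

    def summarize(idx: np.ndarray) -> tuple[float, float, float]:
        c, b, a = comps[idx].sum(axis=0)
        tot = c + b + a
        if tot <= 0:
            raise DataError("AMOVA undefined: zero total variance")
        return c / tot, b / (b + a) if (b + a) > 0 else np.nan, (c + b) / tot

    all_idx = np.arange(sub.n_loci)
    theta_ct, theta_sc, theta_st = summarize(all_idx)
    sig_c, sig_b, sig_a = comps.sum(axis=0)

    rng = np.random.default_rng(seed)
    boots = {"theta_ct": [], "theta_sc": [], "theta_st": []}
    for _ in range(n_bootstrap):
        idx = rng.integers(0, sub.n_loci, size=sub.n_loci)
        try:
            ct, sc, st = summarize(idx)
        except DataError:
            continue
        boots["theta_ct"].append(ct)
        boots["theta_sc"].append(sc)
        boots["theta_st"].append(st)
    ci = {
        k: (float(np.nanpercentile(v, 2.5)), float(np.nanpercentile(v, 97.5)))
        if v else (np.nan, np.nan)
        for k, v in boots.items()
    }
    return AmovaResult(
        sigma2_c=float(sig_c),
        sigma2_b=float(sig_b),
        sigma2_a=float(sig_a),
        theta_ct=float(theta_ct),
        theta_sc=float(theta_sc),
        theta_st=float(theta_st),
        ci=ci,
        per_locus=pd.DataFrame(
            comps, index=sub.locus_ids, columns=["sigma2_c", "sigma2_b", "sigma2_a"]
        ),
    )


# ---------------------------------------------------------------------------
# FST distribution summaries


def fst_distribution_stats(
    fst_a: np.ndarray, fst_b: np.ndarray
) -> tuple[FstDistributionSummary, FstDistributionSummary, float, float]:
    """Mean and non-excess kurtosis per sample plus a two-sample KS test."""
    out = []
    clean = []
    for v in (fst_a, fst_b):
        v = np.asarray(v, dtype=float)
        v = v[~np.isnan(v)]
        if v.size < 8:
            raise DataError("need >=8 per-locus FST values")
        if np.std(v) == 0:
            raise DataError("kurtosis undefined for a constant FST vector")
        clean.append(v)
        out.append(
            FstDistributionSummary(
                mean=float(np.mean(v)),
                kurtosis=float(stats.kurtosis(v, fisher=False)),
                n=v.size,
            )
        )
    d, p = stats.ks_2samp(clean[0], clean[1], mode="asymp")
    return out[0], out[1], float(d), float(p)
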