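"""Bayesian allele-frequency estimation for dominant loci.

A dominant biallelic locus exposes only the recessive "-/-" homozygote
(band absence); under Hardy-Weinberg equilibrium the band-absence
probability is u = q**2, where q is the frequency of the non-amplifying
("null", "-") allele.  Zhivotovsky's Bayesian estimator places a Beta(a, b)
prior on u, so that with m band-absent individuals out of N scored the
posterior is u ~ Beta(m + a, N - m + b) and the posterior mean of q is the
Beta moment

    q_hat = E[sqrt(u)] = B(m + a + 1/2, N - m + b) / B(m + a, N - m + b).

Nei's gene diversity follows as He = 2 q (1 - q).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .io_model import BandMatrix, DataError, LocusMeta, SampleMap

__all__ = [
    "LocusFrequencies",
    "zhivotovsky_qhat",
    "empirical_prior",
    "counts_by_population",
    "population_frequencies",
    "nei_he",
    "he_summary",
    "classify_loci",
    "homoplasy_test",
]


@dataclass
class LocusFrequencies:
    """Posterior summaries of the null-allele frequency for a set of loci."""

    qhat: np.ndarray        # posterior mean of q = sqrt(u)
    alpha_post: np.ndarray  # posterior Beta shape for u
    beta_post: np.ndarray
    m: np.ndarray
    n: np.ndarray

    @property
    def phat(self) -> np.ndarray:
        """Dominant ("+") allele frequency estimate 1 - q_hat."""
        return 1.0 - self.qhat

    @property
    def he(self) -> np.ndarray:
        return nei_he(self.qhat)

    @property
    def var_q(self) -> np.ndarray:
        """Posterior variance of q: E[u] - q_hat**2."""
        e_u = self.alpha_post / (self.alpha_post + self.beta_post)
        return np.maximum(e_u - self.qhat**2, 0.0)


def zhivotovsky_qhat(
    m: np.ndarray | int,
    n: np.ndarray | int,
    prior: tuple[float, float] = (1.0, 1.0),
) -> LocusFrequencies:
    """Posterior-mean null-allele frequency for band-absence counts.

    Parameters
    ----------
    m, n
        Band-absent count and number of scored individuals (scalars or
        arrays, broadcast together).
    prior
        Beta shape parameters (a, b) of the prior on u = q**2.  The default
        (1, 1) is the uniform prior; see :func:`empirical_prior` for a
        data-driven alternative.
    """
    a, b = prior
    if a <= 0 or b <= 0:
        raise DataError("prior shapes must be positive")
    m = np.asarray(m, dtype=float)
    n = np.asarray(n, dtype=float)
    m, n = np.broadcast_arrays(m, n)
    if (n < 1).any():
        raise DataError("N = 0: no scored individuals at some locus")
    if ((m < 0) | (m > n)).any():
        raise DataError("band-absence count m outside [0, N]")
    ap = m + a
    bp = n - m + b
    qhat = np.exp(special.betaln(ap + 0.5, bp) - special.betaln(ap, bp))
    return LocusFrequencies(qhat=qhat, alpha_post=ap, beta_post=bp,
                            m=m.copy(), n=n.copy())


def empirical_prior(m: np.ndarray, n: np.ndarray) -> tuple[float, float]:
    """Method-of-moments Beta fit to the loci-wide distribution of m/N.

    Fits the prior on the band-absence probability u from the observed
    proportions; falls back to the uniform prior when the moments are
    degenerate (all proportions equal, or variance beyond the Beta bound).
    """
    x = np.asarray(m, dtype=float) / np.asarray(n, dtype=float)
    mu = float(np.mean(x))
    v = float(np.var(x, ddof=1)) if x.size > 1 else 0.0
    if v <= 0 or mu <= 0 or mu >= 1 or v >= mu * (1 - mu):
        return (1.0, 1.0)
    k = mu * (1 - mu) / v - 1.0
    return (max(mu * k, 1e-3), max((1 - mu) * k, 1e-3))


def counts_by_population(
    band: BandMatrix, smap: SampleMap
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per (population, locus) band-absence counts m and scored sizes N.

    Missing phenotypes reduce N pairwise (per locus and population).
    Returns two DataFrames indexed by population with locus columns.
    """
    frame = band.to_frame()
    pop = smap.table.loc[frame.index, "population"]
    scored = frame.notna().groupby(pop.values).sum()
    absent = (frame == 0).groupby(pop.values).sum()
    scored.index.name = absent.index.name = "population"
    return absent.sort_index(), scored.sort_index()


def population_frequencies(
    band: BandMatrix,
    smap: SampleMap,
    prior: str | tuple[float, float] = "uniform",
) -> dict[str, LocusFrequencies]:
    """Zhivotovsky estimates per population over all loci.

    ``prior`` is "uniform", "empirical" (method-of-moments fit on the whole
    dataset's m/N distribution) or an explicit (a, b) tuple.
    """
    absent, scored = counts_by_population(band, smap)
    if prior == "uniform":
        shapes = (1.0, 1.0)
    elif prior == "empirical":
        tot_m = absent.sum(axis=0).to_numpy()
        tot_n = scored.sum(axis=0).to_numpy()
        shapes = empirical_prior(tot_m, tot_n)
    else:
        shapes = prior  # type: ignore[assignment]
    out = {}
    for p in absent.index:
        n = scored.loc[p].to_numpy(dtype=float)
        m = absent.loc[p].to_numpy(dtype=float)
        if (n < 1).any():
            raise DataError(
                f"population {p!r} has a locus with no scored individuals"
            )
        out[str(p)] = zhivotovsky_qhat(m, n, shapes)
    return out


def nei_he(qhat: np.ndarray | float) -> np.ndarray | float:
    """Nei's gene diversity He = 2 q (1 - q) for a biallelic locus."""
    q = np.asarray(qhat, dtype=float)
    he = 2.0 * q * (1.0 - q)
    return he if he.ndim else float(he)


def he_summary(freqs: LocusFrequencies) -> tuple[float, float]:
    """Population mean He over loci with its standard error."""
    he = np.asarray(nei_he(freqs.qhat))
    return float(np.mean(he)), float(np.std(he, ddof=1) / np.sqrt(he.size))


def classify_loci(
    group_counts: dict[str, tuple[np.ndarray, np.ndarray]],
    maf_threshold: float = 0.05,
    fixation_threshold: float = 0.99,
) -> pd.DataFrame:
    """Polymorphic / private / monomorphic classification per locus.

    ``group_counts`` maps a group label (e.g. country) to pooled (m, N)
    arrays; pooling is by summed counts across the group's populations.
    Classification uses the maximum-likelihood frequency p = 1 - sqrt(m/N)
    rather than the Bayesian posterior mean: fixation (p > 0.99 or
    p < 0.01) is a statement about the observed sample, and posterior
    shrinkage would keep pooled estimates away from the bounds at any
    realistic sample size.  A locus is polymorphic when the pooled
    whole-dataset minor-allele frequency is at least ``maf_threshold``;
    it is private to group G when its "+" allele frequency is above
    ``fixation_threshold`` (or below 1 - threshold) in G but strictly
    between those bounds in the other group.  With a single group the
    private classification is skipped.
    """
    groups = sorted(group_counts)
    m_tot = np.sum([group_counts[g][0] for g in groups], axis=0)
    n_tot = np.sum([group_counts[g][1] for g in groups], axis=0)
    p_all = 1.0 - np.sqrt(m_tot / n_tot)
    maf = np.minimum(p_all, 1.0 - p_all)
    out = pd.DataFrame({"pooled_p": p_all, "maf": maf,
                        "polymorphic": maf >= maf_threshold})

    lo, hi = 1.0 - fixation_threshold, fixation_threshold
    p_by_group = {
        g: 1.0 - np.sqrt(group_counts[g][0] / group_counts[g][1])
        for g in groups
    }
    for g in groups:
        out[f"p_{g}"] = p_by_group[g]
    if len(groups) < 2:
        import logging

        logging.getLogger("aflpscan").warning(
            "single group: private-locus classification skipped"
        )
        out["private_to"] = ""
        return out

    private = np.full(len(p_all), "", dtype=object)
    for g in groups:
        others = [h for h in groups if h != g]
        fixed_g = (p_by_group[g] > hi) | (p_by_group[g] < lo)
        poly_other = np.all(
            [(p_by_group[h] > lo) & (p_by_group[h] < hi) for h in others], axis=0
        )
        private = np.where(fixed_g & poly_other & (private == ""), g, private)
    out["private_to"] = private
    return out


def homoplasy_test(
    pooled_p: np.ndarray, meta: LocusMeta, locus_ids: list[str]
) -> tuple[float, float]:
    """Size-homoplasy check: Pearson correlation of fragment size vs frequency.

    Two co-migrating AFLP fragments scored as one locus inflate the
    apparent frequency of short fragments, producing a negative size-
    frequency correlation; a non-significant correlation is evidence
    against widespread homoplasy.  Returns (r, two-sided P).
    """
    sizes = meta.fragment_sizes(locus_ids)
    p = np.asarray(pooled_p, dtype=float)
    keep = ~np.isnan(sizes)
    sizes, p = sizes[keep], p[keep]
    if sizes.size < 3:
        raise DataError("need >=3 loci with fragment sizes")
    if np.std(sizes) == 0 or np.std(p) == 0:
        raise DataError("undefined correlation: constant sizes or frequencies")
    r, pval = stats.pearsonr(sizes, p)
    return float(r), float(pval)
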