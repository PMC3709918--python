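"""FST estimator, hierarchical AMOVA, FST distribution summaries."""

import numpy as np
import pandas as pd
import pytest

from aflpscan.differentiation import (
    amova,
    expected_dosage,
    fst_distribution_stats,
    multipop_fst,
    pairwise_fst,
    sampling_var_sqrt,
)
from aflpscan.dominant_freq import population_frequencies, zhivotovsky_qhat
from aflpscan.io_model import BandMatrix, DataError
from aflpscan.synthetic import pair_preset, simulate_dataset, study_preset
from conftest import make_sample_map


def freqs_from_counts(m, n):
    return zhivotovsky_qhat(np.asarray(m), np.asarray(n))


def simulate_pair_counts(rng, fst, n_loci=500, n=24):
    """Two populations drawn independently around shared ancestral freqs."""
    qbar = np.clip(rng.beta(1.2, 0.5, n_loci), 1e-9, 1 - 1e-9)
    if fst == 0.0:
        q1 = q2 = qbar
    else:
        c = (1 - fst) / fst
        q1 = rng.beta(c * qbar, c * (1 - qbar))
        q2 = rng.beta(c * qbar, c * (1 - qbar))
    return rng.binomial(n, q1**2), rng.binomial(n, q2**2), np.full(n_loci, n)


class TestPairwiseFst:
    def test_no_true_differentiation_near_zero(self):
        rng = np.random.default_rng(10)
        m1, m2, n = simulate_pair_counts(rng, 0.0, n_loci=500)
        res = pairwise_fst(freqs_from_counts(m1, n), freqs_from_counts(m2, n))
        assert abs(res.multi_locus) < 0.01

    def test_recovery_of_fst_010(self):
        # scaled-down version of the full recovery check in the acceptance suite
        rng = np.random.default_rng(11)
        ests = []
        for _ in range(25):
            m1, m2, n = simulate_pair_counts(rng, 0.10, n_loci=684)
            res = pairwise_fst(freqs_from_counts(m1, n), freqs_from_counts(m2, n))
            ests.append(res.multi_locus)
        assert float(np.mean(ests)) == pytest.approx(0.10, abs=0.02)

    def test_hand_oracle_three_loci(self):
        # spreadsheet-style evaluation of the estimator formulas
        m_a, m_b = np.array([3, 10, 0]), np.array([12, 2, 6])
        n = np.array([24, 24, 24])
        qa, qb = np.sqrt(m_a / 24), np.sqrt(m_b / 24)
        va, vb = sampling_var_sqrt(m_a, n), sampling_var_sqrt(m_b, n)
        among = (qa - qb) ** 2 / 2 - (va + vb) / 2
        within = (qa * (1 - qa) + qb * (1 - qb)) / 2
        expected = among.sum() / (among + within).sum()
        res = pairwise_fst(freqs_from_counts(m_a, n), freqs_from_counts(m_b, n))
        assert res.multi_locus == pytest.approx(expected, abs=1e-12)
        np.testing.assert_allclose(res.per_locus, among / (among + within))

    def test_symmetry_and_locus_order_invariance(self):
        rng = np.random.default_rng(12)
        m1, m2, n = simulate_pair_counts(rng, 0.05, n_loci=80)
        a, b = freqs_from_counts(m1, n), freqs_from_counts(m2, n)
        assert pairwise_fst(a, b).multi_locus == pytest.approx(
            pairwise_fst(b, a).multi_locus
        )
        perm = rng.permutation(80)
        ap = freqs_from_counts(m1[perm], n[perm])
        bp = freqs_from_counts(m2[perm], n[perm])
        assert pairwise_fst(ap, bp).multi_locus == pytest.approx(
            pairwise_fst(a, b).multi_locus
        )

    def test_monotone_in_divergence(self):
        rng = np.random.default_rng(13)
        means = []
        for fst in (0.01, 0.05, 0.1, 0.2):
            ests = [
                pairwise_fst(
                    *(freqs_from_counts(m, n) for m in simulate_pair_counts(rng, fst)[:2])
                ).multi_locus
                for _ in range(20)
                for n in [np.full(500, 24)]
            ]
            means.append(np.mean(ests))
        assert all(x < y for x, y in zip(means, means[1:]))

    def test_all_monomorphic_rejected(self):
        n = np.full(5, 24)
        zeros = freqs_from_counts(np.zeros(5), n)
        with pytest.raises(DataError, match="monomorphic"):
            multipop_fst([zeros, zeros])


def _amova_dataset(seed=0, n_loci=40, delta=0.0):
    """2 host types x 2 populations x 12 individuals; optional host-level shift."""
    rng = np.random.default_rng(seed)
    smap = make_sample_map(
        {
            "M1": ("maize", "X", 12),
            "M2": ("maize", "X", 12),
            "D1": ("dicot", "X", 12),
            "D2": ("dicot", "X", 12),
        }
    )
    qbar = rng.uniform(0.2, 0.8, n_loci)
    pheno = []
    ids = []
    for pop in ("D1", "D2", "M1", "M2"):
        shift = delta if pop.startswith("M") else -delta
        q = np.clip(qbar + shift, 0.02, 0.98)
        nulls = rng.binomial(2, q, size=(12, n_loci))
        pheno.append((nulls < 2).astype(float))
        ids += [f"{pop}_{i}" for i in range(12)]
    band = BandMatrix(np.vstack(pheno), ids, [f"L{j}" for j in range(n_loci)])
    return band, smap


class TestAmova:
    def test_components_match_bruteforce_oracle(self):
        band, smap = _amova_dataset(seed=1, n_loci=3)
        freqs = population_frequencies(band, smap)
        res = amova(band, smap, freqs, n_bootstrap=10, seed=0)
        pops = sorted(freqs)
        # independent oracle: explicit nested sums on the dosage table
        for j, locus in enumerate(band.locus_ids):
            y, pop_lab, host_lab = [], [], []
            for i, sid in enumerate(band.sample_ids):
                pop = smap.table.loc[sid, "population"]
                q = freqs[pop].qhat[j]
                ph = band.phenotypes[i, j]
                y.append(2.0 if ph == 0 else 2 * q / (1 + q))
                pop_lab.append(pop)
                host_lab.append(smap.table.loc[sid, "host_type"])
            y = np.array(y)
            df = pd.DataFrame({"y": y, "pop": pop_lab, "host": host_lab})
            grand = df.y.mean()
            ss_g = sum(
                len(s) * (s.y.mean() - grand) ** 2 for _, s in df.groupby("host")
            )
            ss_p = sum(
                len(s) * (s.y.mean() - df[df.host == s.host.iloc[0]].y.mean()) ** 2
                for _, s in df.groupby("pop")
            )
            ss_w = sum(((s.y - s.y.mean()) ** 2).sum() for _, s in df.groupby("pop"))
            # balanced design: 2 hosts x 2 pops x 12
            ms_w = ss_w / (48 - 4)
            ms_p = ss_p / 2
            ms_g = ss_g / 1
            sig_a = ms_w
            sig_b = (ms_p - ms_w) / 12
            sig_c = (ms_g - ms_p) / 24
            row = res.per_locus.loc[locus]
            assert row["sigma2_a"] == pytest.approx(sig_a, abs=1e-8)
            assert row["sigma2_b"] == pytest.approx(sig_b, abs=1e-8)
            assert row["sigma2_c"] == pytest.approx(sig_c, abs=1e-8)

    def test_component_conservation(self):
        # total variance of the dosage table is conserved by the decomposition
        band, smap = _amova_dataset(seed=2, n_loci=5)
        freqs = population_frequencies(band, smap)
        res = amova(band, smap, freqs, n_bootstrap=10, seed=0)
        # for a balanced design, E-weighted components reconstruct the
        # corrected total sum of squares per locus
        pops = sorted(freqs)
        for j, locus in enumerate(band.locus_ids):
            q_by_pop = {p: freqs[p].qhat[j] for p in pops}
            y = np.array(
                [
                    2.0
                    if band.phenotypes[i, j] == 0
                    else 2 * q_by_pop[smap.table.loc[s, "population"]]
                    / (1 + q_by_pop[smap.table.loc[s, "population"]])
                    for i, s in enumerate(band.sample_ids)
                ]
            )
            ss_total = ((y - y.mean()) ** 2).sum()
            row = res.per_locus.loc[locus]
            # reconstruct SS from components via the balanced expected values
            ss_rebuilt = (
                row["sigma2_a"] * 44
                + (row["sigma2_a"] + 12 * row["sigma2_b"]) * 2
                + (row["sigma2_a"] + 12 * row["sigma2_b"] + 24 * row["sigma2_c"]) * 1
            )
            assert ss_rebuilt == pytest.approx(ss_total, abs=1e-8)

    def test_null_hierarchy_ci_covers_zero(self):
        covered = 0
        for seed in range(30):
            band, smap = _amova_dataset(seed=100 + seed, n_loci=60)
            res = amova(band, smap, n_bootstrap=200, seed=seed)
            lo, hi = res.ci["theta_ct"]
            covered += lo <= 0.0 <= hi or res.theta_ct < 0
        assert covered >= 27  # >= 90 % of seeds

    def test_planted_host_divergence_detected(self):
        hits = 0
        for seed in range(20):
            band, smap = _amova_dataset(seed=200 + seed, n_loci=60, delta=0.0)
            # overwrite 10 loci with host-level divergence
            band2, smap2 = _amova_dataset(seed=300 + seed, n_loci=10, delta=0.25)
            pheno = band.phenotypes.copy()
            pheno[:, :10] = band2.phenotypes
            band = BandMatrix(pheno, band.sample_ids, band.locus_ids)
            res_sel = amova(band, smap, locus_ids=band.locus_ids[:10],
                            n_bootstrap=10, seed=seed)
            res_neu = amova(band, smap, locus_ids=band.locus_ids[10:],
                            n_bootstrap=10, seed=seed)
            hits += res_sel.theta_ct > res_neu.theta_ct
        assert hits >= 19  # >= 95 % of seeds

    def test_single_population_per_host_rejected(self):
        band, smap = _amova_dataset(seed=3, n_loci=4)
        keep = [s for s in band.sample_ids if not s.startswith(("M2", "D2"))]
        sub = band.subset_samples(keep)
        from aflpscan.io_model import SampleMap

        smap_sub = SampleMap(smap.table.loc[keep])
        with pytest.raises(DataError, match=">=2"):
            amova(sub, smap_sub, n_bootstrap=10)

    def test_dosage_formula(self):
        q = np.array([0.5])
        # band present: E[dosage | not -/-] = 2q/(1+q)
        assert expected_dosage(np.array([1.0]), q)[0] == pytest.approx(2 / 3)
        assert expected_dosage(np.array([0.0]), q)[0] == 2.0
        assert np.isnan(expected_dosage(np.array([np.nan]), q)[0])


class TestFstDistribution:
    def test_identical_samples_ks_zero(self):
        rng = np.random.default_rng(0)
        v = rng.normal(0.05, 0.02, 100)
        s1, s2, d, p = fst_distribution_stats(v, v)
        assert d == 0.0
        assert s1.mean == pytest.approx(s2.mean)

    def test_normal_kurtosis_three(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=100_000)
        s1, _, _, _ = fst_distribution_stats(v, rng.normal(size=100))
        assert s1.kurtosis == pytest.approx(3.0, abs=0.1)

    def test_ks_power_on_shifted_samples(self):
        rng = np.random.default_rng(2)
        rejected = 0
        for _ in range(50):
            a = rng.normal(0, 1, 1000)
            b = rng.normal(1, 1, 1000)
            *_, p = fst_distribution_stats(a, b)
            rejected += p < 1e-5
        assert rejected >= 50 * 0.99

    def test_constant_vector_rejected(self):
        with pytest.raises(DataError, match="kurtosis"):
            fst_distribution_stats(np.full(10, 0.1), np.full(10, 0.1))
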