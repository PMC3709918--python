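"""End-to-end orchestration: data -> frequencies -> FST/AMOVA -> outlier scan
-> candidate table -> LD on candidate pairs -> combined and FDR-adjusted P.

One :class:`RunConfig` and one global seed drive the whole analysis; each
stage draws a deterministic substream seed from the stage name, so stage
outputs are pure functions of (inputs, config, seed) and a rerun with the
same seed is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .differentiation import amova, fst_distribution_stats, fst_matrix
from .dominant_freq import (
    classify_loci,
    counts_by_population,
    homoplasy_test,
    population_frequencies,
    zhivotovsky_qhat,
)
from .io_model import (
    BandMatrix,
    DataError,
    LocusMeta,
    SampleMap,
    enumerate_comparisons,
    enumerate_locus_pairs,
    read_dataset,
    write_dataset,
)
from .ld_test import bh_fdr, combine_pvalues_z, hill_ml_d, mcmc_null_pvalue, phenotype_counts
from .outlier_scan import OutlierModelConfig, classify_candidates, fit_outlier_model
from .synthetic import SimConfig, simulate_dataset, study_preset

logger = logging.getLogger("aflpscan")

__all__ = [
    "RunConfig",
    "RunReport",
    "StageError",
    "run_pipeline",
    "ld_jobs",
    "stage_seed",
    "mean_marker_spacing_kb",
    "percent_polymorphic",
]


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are persisted."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    out_dir: str | Path = "aflpscan_run"
    sim: SimConfig | None = None
    input_dir: str | Path | None = None
    prior: str = "uniform"
    fdr_thresholds: tuple[float, ...] = (0.05, 0.10)
    scan: OutlierModelConfig = field(default_factory=OutlierModelConfig)
    ld_steps: int = 10_000
    ld_window: float = 0.15
    amova_bootstrap: int = 1000
    maf_threshold: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if (self.sim is None) == (self.input_dir is None):
            raise DataError("exactly one of sim / input_dir must be set")
        for t in self.fdr_thresholds:
            if not (0.0 < t < 1.0):
                raise DataError("FDR thresholds must lie in (0, 1)")


@dataclass
class RunReport:
    population_summary: pd.DataFrame
    homoplasy: tuple[float, float] | None
    locus_classes: pd.DataFrame
    fst: pd.DataFrame
    fst_distribution: pd.DataFrame | None
    amova_tables: dict[str, pd.DataFrame]
    scan_tables: dict[str, dict[str, pd.DataFrame]]   # country -> comparison -> table
    candidates: dict[str, dict[float, pd.DataFrame]]  # country -> threshold -> table
    ld: pd.DataFrame | None
    ld_combined: pd.DataFrame | None
    provenance: dict


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed (< 2**31)."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def ld_jobs(
    cand_sets: dict[str, list[str]], pop_tab: pd.DataFrame
) -> list[tuple[tuple[str, str], str]]:
    """(locus pair, population) LD jobs from per-country candidate sets.

    Within-country candidate pairs are tested in that country's
    populations; with two countries, cross pairs (one candidate from
    each) are tested in every population.
    """
    countries = sorted(cand_sets)
    jobs: list[tuple[tuple[str, str], str]] = []
    for country in countries:
        for pair in enumerate_locus_pairs(cand_sets[country]):
            for pop in pop_tab[pop_tab["country"] == country].index:
                jobs.append((pair, pop))
    if len(countries) == 2:
        a, b = countries
        if cand_sets[a] and cand_sets[b]:
            for pair in enumerate_locus_pairs(cand_sets[a], cand_sets[b]):
                for pop in pop_tab.index:
                    jobs.append((pair, pop))
    return jobs


def mean_marker_spacing_kb(genome_size_bp: float, n_markers: int) -> float:
    """Average spacing between markers assumed uniform across the genome."""
    if n_markers < 1:
        raise DataError("need >=1 marker")
    return genome_size_bp / n_markers / 1_000.0


def percent_polymorphic(n_polymorphic: int, n_total: int) -> float:
    """Percentage of polymorphic loci, rounded to one decimal."""
    return round(100.0 * n_polymorphic / n_total, 1)


def _population_summary(
    band: BandMatrix, smap: SampleMap, freqs, maf_threshold: float
) -> pd.DataFrame:
    rows = []
    pop_tab = smap.population_table()
    for pop in sorted(freqs):
        f = freqs[pop]
        p = 1.0 - np.sqrt(f.m / f.n)  # ML convention, as in the MAF filter
        pl = int(np.sum(np.minimum(p, 1 - p) >= maf_threshold))
        he = np.asarray(2.0 * f.qhat * (1.0 - f.qhat))
        rows.append(
            {
                "population": pop,
                "host_type": pop_tab.loc[pop, "host_type"],
                "country": pop_tab.loc[pop, "country"],
                "n": int(pop_tab.loc[pop, "n"]),
                "pl": pl,
                "pct_pl": percent_polymorphic(pl, band.n_loci),
                "he_mean": float(np.mean(he)),
                "he_se": float(np.std(he, ddof=1) / np.sqrt(he.size)),
            }
        )
    return pd.DataFrame(rows).set_index("population")


def run_pipeline(config: RunConfig) -> RunReport:
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seedof = lambda stage: stage_seed(config.seed, stage)  # noqa: E731

    # ----- stage: data -------------------------------------------------
    stage = "data"
    try:
        if config.sim is not None:
            band, smap, meta, truth = simulate_dataset(config.sim, seedof("simulate"))
            write_dataset(out / "data", band, smap, meta)
            truth.write(out / "data")
        else:
            base = Path(config.input_dir)
            meta_path = base / "locus_meta.tsv"
            band, smap, meta = read_dataset(
                base / "band_matrix.tsv",
                base / "sample_map.tsv",
                meta_path if meta_path.exists() else None,
            )
        plans = enumerate_comparisons(smap)
    except Exception as exc:  # pragma: no cover - error path
        raise StageError(stage, exc) from exc

    # ----- stage: frequencies ------------------------------------------
    stage = "freqs"
    try:
        freqs = population_frequencies(band, smap, config.prior)
        pop_summary = _population_summary(band, smap, freqs, config.maf_threshold)
        pop_summary.to_csv(out / "population_summary.tsv", sep="\t")

        absent, scored = counts_by_population(band, smap)
        pop_country = smap.population_table()["country"]
        group_counts = {
            c: (
                absent.loc[pop_country[pop_country == c].index].sum(axis=0).to_numpy(),
                scored.loc[pop_country[pop_country == c].index].sum(axis=0).to_numpy(),
            )
            for c in sorted(pop_country.unique())
        }
        classes = classify_loci(group_counts, config.maf_threshold)
        classes.insert(0, "locus_id", band.locus_ids)
        classes.to_csv(out / "locus_classes.tsv", sep="\t", index=False)

        homoplasy = None
        if meta is not None:
            m_tot = absent.sum(axis=0).to_numpy()
            n_tot = scored.sum(axis=0).to_numpy()
            pooled_p = zhivotovsky_qhat(m_tot, n_tot).phat
            homoplasy = homoplasy_test(pooled_p, meta, band.locus_ids)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ----- stage: FST ---------------------------------------------------
    stage = "fst"
    try:
        fst, per_pair = fst_matrix(band, smap, config.prior)
        fst.to_csv(out / "fst_matrix.tsv", sep="\t")
        fst_dist = None
        countries = sorted({p.country for _, p in smap.population_table().iterrows()})
        if len(countries) == 2 and all(len(plans[c].inter_host) > 0 for c in countries):
            vecs = {}
            for c in countries:
                vals = [per_pair[p].per_locus for p in plans[c].inter_host if p in per_pair]
                vecs[c] = np.concatenate(vals)
            s_a, s_b, d, p = fst_distribution_stats(vecs[countries[0]], vecs[countries[1]])
            fst_dist = pd.DataFrame(
                {
                    "country": countries,
                    "mean_fst": [s_a.mean, s_b.mean],
                    "kurtosis": [s_a.kurtosis, s_b.kurtosis],
                    "ks_d": [d, d],
                    "ks_p": [p, p],
                }
            )
            fst_dist.to_csv(out / "fst_distribution.tsv", sep="\t", index=False)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ----- stage: outlier scan -----------------------------------------
    stage = "scan"
    scan_tables: dict[str, dict[str, pd.DataFrame]] = {}
    candidates: dict[str, dict[float, pd.DataFrame]] = {}
    try:
        for country, plan in plans.items():
            if not plan.pairs:
                continue
            scan_tables[country] = {}
            for pair in plan.pairs:
                cid = plan.comparison_id(pair)
                m = np.column_stack(
                    [absent.loc[pair[0]].to_numpy(), absent.loc[pair[1]].to_numpy()]
                )
                n = np.column_stack(
                    [scored.loc[pair[0]].to_numpy(), scored.loc[pair[1]].to_numpy()]
                )
                table = fit_outlier_model(
                    m, n, band.locus_ids, config.scan,
                    seed=seedof(f"scan:{country}:{cid}"),
                )
                table.insert(0, "comparison", cid)
                scan_tables[country][cid] = table
            candidates[country] = {
                thr: classify_candidates(scan_tables[country], plan, thr)
                for thr in config.fdr_thresholds
            }
        if scan_tables:
            pd.concat(
                [t for c in scan_tables.values() for t in c.values()],
                ignore_index=True,
            ).to_csv(out / "scan.tsv", sep="\t", index=False)
            cand_frames = []
            for country, by_thr in candidates.items():
                for thr, tab in by_thr.items():
                    t = tab.copy()
                    t.insert(0, "country", country)
                    t.insert(1, "fdr_threshold", thr)
                    cand_frames.append(t)
            pd.concat(cand_frames, ignore_index=True).to_csv(
                out / "candidates.tsv", sep="\t", index=False
            )
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ----- stage: AMOVA (all loci, outlier and neutral sets) ------------
    stage = "amova"
    amova_tables: dict[str, pd.DataFrame] = {}
    try:
        thr_max = max(config.fdr_thresholds)
        for country in plans:
            pop_tab = smap.population_table()
            pops_c = pop_tab[pop_tab["country"] == country]
            per_host = pops_c.groupby("host_type").size()
            if len(per_host) < 2 or (per_host < 2).any():
                logger.warning("AMOVA skipped for %r: needs >=2 pops per host type", country)
                continue
            samples = [
                s for s in band.sample_ids
                if smap.table.loc[s, "country"] == country
            ]
            band_c = band.subset_samples(samples)
            smap_c = SampleMap(smap.table.loc[samples])
            freqs_c = population_frequencies(band_c, smap_c, config.prior)
            cand_ids: list[str] = []
            if country in candidates:
                tab = candidates[country][thr_max]
                cand_ids = list(tab.loc[tab["candidate"], "locus_id"])
            sets = {"all": None}
            if cand_ids:
                sets["outliers"] = cand_ids
                sets["neutral"] = [l for l in band.locus_ids if l not in cand_ids]
            rows = []
            for label, loci in sets.items():
                res = amova(
                    band_c, smap_c, freqs_c, locus_ids=loci,
                    n_bootstrap=config.amova_bootstrap,
                    seed=seedof(f"amova:{country}:{label}"),
                )
                rows.append(
                    {
                        "set": label,
                        "n_loci": band.n_loci if loci is None else len(loci),
                        "sigma2_c": res.sigma2_c,
                        "sigma2_b": res.sigma2_b,
                        "sigma2_a": res.sigma2_a,
                        "theta_ct": res.theta_ct,
                        "theta_sc": res.theta_sc,
                        "theta_st": res.theta_st,
                        "theta_ct_lo": res.ci["theta_ct"][0],
                        "theta_ct_hi": res.ci["theta_ct"][1],
                    }
                )
            amova_tables[country] = pd.DataFrame(rows)
            amova_tables[country].to_csv(
                out / f"amova_{country}.tsv", sep="\t", index=False
            )
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ----- stage: LD on candidate pairs ---------------------------------
    stage = "ld"
    ld_table = ld_combined = None
    try:
        thr_max = max(config.fdr_thresholds)
        cand_sets = {
            country: list(
                candidates[country][thr_max].loc[
                    candidates[country][thr_max]["candidate"], "locus_id"
                ]
            )
            for country in candidates
        }
        ld_rows = []
        pop_tab = smap.population_table()
        jobs = ld_jobs(cand_sets, pop_tab)
        if not jobs:
            logger.info("LD stage: no candidate pairs")
        for pair, pop in jobs:
            ids = smap.samples_in(pop)
            sub = band.subset_samples(ids).subset_loci(list(pair))
            counts = phenotype_counts(sub.phenotypes[:, 0], sub.phenotypes[:, 1])
            est = hill_ml_d(counts)
            row = {
                "locus_a": pair[0],
                "locus_b": pair[1],
                "population": pop,
                "country": pop_tab.loc[pop, "country"],
                "host_type": pop_tab.loc[pop, "host_type"],
                "d": est.d,
                "r": est.r,
                "p_value": np.nan,
            }
            m_a = counts.n_ap + counts.n_aa
            m_b = counts.n_pa + counts.n_aa
            n_tot = counts.total
            if (
                np.isfinite(est.r)
                and 0 < m_a < n_tot
                and 0 < m_b < n_tot
            ):
                res = mcmc_null_pvalue(
                    m_a, n_tot, m_b, n_tot, est.r,
                    steps=config.ld_steps, window=config.ld_window,
                    seed=seedof(f"ld:{pair[0]}:{pair[1]}:{pop}"),
                )
                row["p_value"] = res.p_value
            ld_rows.append(row)
        if ld_rows:
            ld_table = pd.DataFrame(ld_rows)
            ld_table.to_csv(out / "ld.tsv", sep="\t", index=False)
            comb_rows = []
            for (country, host), sub in ld_table.groupby(["country", "host_type"]):
                for (la, lb), pairsub in sub.groupby(["locus_a", "locus_b"]):
                    p = pairsub["p_value"].dropna().to_numpy()
                    if p.size == 0:
                        continue
                    comb_rows.append(
                        {
                            "category": f"{country}-{host}",
                            "locus_a": la,
                            "locus_b": lb,
                            "n_populations": p.size,
                            "combined_p": combine_pvalues_z(p),
                        }
                    )
            if comb_rows:
                ld_combined = pd.DataFrame(comb_rows)
                ld_combined["adjusted_p"] = np.nan
                for cat, sub in ld_combined.groupby("category"):
                    ld_combined.loc[sub.index, "adjusted_p"] = bh_fdr(
                        sub["combined_p"].to_numpy()
                    )
                ld_combined.to_csv(out / "ld_combined.tsv", sep="\t", index=False)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ----- stage: report -------------------------------------------------
    stage = "report"
    try:
        cfg_text = yaml.safe_dump(
            {
                "seed": config.seed,
                "prior": config.prior,
                "fdr_thresholds": list(config.fdr_thresholds),
                "ld_steps": config.ld_steps,
                "scan": asdict(config.scan),
                "sim": asdict(config.sim) if config.sim else None,
                "input_dir": str(config.input_dir) if config.input_dir else None,
            },
            sort_keys=True,
        )
        provenance = {
            "version": __version__,
            "seed": config.seed,
            "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        }
        (out / "provenance.json").write_text(json.dumps(provenance, indent=2, sort_keys=True))
        _write_summary(
            out / "summary.txt", band, pop_summary, homoplasy, classes,
            fst, candidates, ld_combined,
        )
    except Exception as exc:
        raise StageError(stage, exc) from exc

    return RunReport(
        population_summary=pop_summary,
        homoplasy=homoplasy,
        locus_classes=classes,
        fst=fst,
        fst_distribution=fst_dist,
        amova_tables=amova_tables,
        scan_tables=scan_tables,
        candidates=candidates,
        ld=ld_table,
        ld_combined=ld_combined,
        provenance=provenance,
    )


def _write_summary(path, band, pop_summary, homoplasy, classes, fst, candidates, ld_combined):
    lines = [
        f"aflpscan summary ({band.n_loci} loci, {band.n_samples} individuals)",
        "",
        "Per-population diversity:",
        pop_summary.round(3).to_string(),
        "",
        f"Polymorphic loci (pooled MAF filter): {int(classes['polymorphic'].sum())}"
        f" / {band.n_loci}"
        f" ({percent_polymorphic(int(classes['polymorphic'].sum()), band.n_loci)}%)",
    ]
    if homoplasy is not None:
        lines.append(
            f"Size-frequency homoplasy check: Pearson r = {homoplasy[0]:.3f}, "
            f"P = {homoplasy[1]:.3f}"
        )
    lines += ["", "Pairwise multi-locus FST:", fst.round(3).to_string(), ""]
    for country, by_thr in candidates.items():
        for thr, tab in by_thr.items():
            n_cand = int(tab["candidate"].sum())
            lines.append(
                f"Candidates in {country} at FDR {thr:g}: {n_cand}"
            )
            if n_cand:
                sub = tab[tab["candidate"]][["locus_id", "alpha_mean"]]
                lines.append(sub.to_string(index=False))
    if ld_combined is not None:
        lines += [
            "",
            "Combined LD P-values (per category, BH-adjusted):",
            ld_combined.round(4).to_string(index=False),
        ]
    Path(path).write_text("\n".join(lines) + "\n")


def default_study_config(out_dir: str | Path, seed: int = 0, **scan_overrides) -> RunConfig:
    """Study-scale synthetic run configuration (684 loci, 12 populations)."""
    return RunConfig(
        out_dir=out_dir,
        sim=study_preset(seed=seed),
        scan=OutlierModelConfig(**scan_overrides) if scan_overrides else OutlierModelConfig(),
        seed=seed,
    )
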