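"""Synthetic dominant-marker datasets with known ground truth.

The generator emulates the sampling design of a two-country host-race
study: populations nested in host-plant type nested in country, with
band phenotypes produced by random union of gametes under Hardy-Weinberg
equilibrium.  Allele frequencies follow a hierarchical Balding-Nichols
model: the frequency at each level is a Beta draw around the parent
frequency with shape c = (1 - F) / F, which is exactly the biallelic
Multinomial-Dirichlet island model assumed by the outlier scan, so the
scan's generative assumptions can be matched (or violated deliberately).

Selection is encoded only as an elevated locus-specific divergence between
host types: for a selected locus i in country c the host-level F is
logistic(alpha_i + logit(F_host_c)) -- the same locus/population
decomposition of logit(FST) the outlier scan estimates.  Gametic
disequilibrium can be planted per locus pair as a haplotype-level D.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_model import BandMatrix, DataError, LocusMeta, SampleMap

__all__ = [
    "PopulationSpec",
    "SelectedLocus",
    "PlantedLD",
    "SimConfig",
    "SimTruth",
    "study_preset",
    "pair_preset",
    "simulate_frequencies",
    "simulate_band_matrix",
    "simulate_dataset",
]


def _logit(x: float | np.ndarray) -> np.ndarray:
    return np.log(x) - np.log1p(-x)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class PopulationSpec:
    name: str
    country: str
    host_type: str
    n: int


@dataclass
class SelectedLocus:
    """A locus with host-type-level divergent selection in one country."""

    index: int
    country: str
    alpha: float  # additive effect on logit(host-level FST)


@dataclass
class PlantedLD:
    """Target haplotype disequilibrium D for one locus pair.

    Applied in the named populations (all populations when None); the
    double-null gamete frequency is q_A q_B + D, clamped to the feasible
    range.
    """

    locus_a: int
    locus_b: int
    d: float
    populations: list[str] | None = None


@dataclass
class SimConfig:
    """Study design and frequency-model parameters for one simulation."""

    populations: list[PopulationSpec]
    n_loci: int = 684
    # Beta prior on the ancestral null-allele frequency; skewed toward common
    # band absence so that mean Bayesian He lands near 0.245
    prior_a: float = 1.2
    prior_b: float = 0.5
    fst_country: float | None = 0.07   # country level; None disables the level
    fst_host: dict[str, float] | float = 0.05  # host-type level, per country
    fst_pop: float | None = 0.015      # population level; None disables
    selected: list[SelectedLocus] = field(default_factory=list)
    planted_ld: list[PlantedLD] = field(default_factory=list)
    fragment_size_range: tuple[int, int] = (80, 450)
    ld_clamp_tol: float = 0.1
    selected_qbar_range: tuple[float, float] = (0.2, 0.8)
    seed: int = 0

    def host_fst(self, country: str) -> float:
        if isinstance(self.fst_host, dict):
            return self.fst_host[country]
        return float(self.fst_host)

    def validate(self) -> None:
        if self.n_loci < 1 or not self.populations:
            raise DataError("need >=1 locus and >=1 population")
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise DataError("duplicate population names")
        for f in self._all_fst():
            if not (0.0 < f < 1.0):
                raise DataError(f"FST value {f} outside (0, 1)")
        for s in self.selected:
            if not (0 <= s.index < self.n_loci):
                raise DataError(f"selected locus index {s.index} out of range")
        for p in self.planted_ld:
            if p.locus_a == p.locus_b:
                raise DataError("planted LD pair must involve two distinct loci")

    def _all_fst(self) -> list[float]:
        out = []
        if self.fst_country is not None:
            out.append(self.fst_country)
        countries = {p.country for p in self.populations}
        out += [self.host_fst(c) for c in countries]
        if self.fst_pop is not None:
            out.append(self.fst_pop)
        return out


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset, for recovery tests."""

    qbar: np.ndarray                      # ancestral null-allele frequency per locus
    q_pop: pd.DataFrame                   # realized frequencies, population x locus
    host_fst: pd.DataFrame                # per-locus host-level FST, (country) columns
    selected: list[SelectedLocus]
    planted_ld: list[PlantedLD]
    locus_ids: list[str]

    def selected_ids(self) -> list[str]:
        return [self.locus_ids[s.index] for s in self.selected]

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        loci = pd.DataFrame({"locus_id": self.locus_ids, "qbar": self.qbar})
        loci["selected_country"] = ""
        loci["alpha"] = np.nan
        for s in self.selected:
            loci.loc[s.index, "selected_country"] = s.country
            loci.loc[s.index, "alpha"] = s.alpha
        loci.to_csv(out_dir / "truth_loci.tsv", sep="\t", index=False)
        self.q_pop.rename_axis("population").to_csv(
            out_dir / "truth_frequencies.tsv", sep="\t"
        )
        if self.planted_ld:
            rows = [
                {
                    "locus_a": self.locus_ids[p.locus_a],
                    "locus_b": self.locus_ids[p.locus_b],
                    "d": p.d,
                    "populations": ",".join(p.populations or []),
                }
                for p in self.planted_ld
            ]
            pd.DataFrame(rows).to_csv(out_dir / "truth_ld.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# Presets

# Host-level divergence and planted locus effects mirror the magnitudes the
# study design targets: weaker inter-host divergence in France than in China,
# and locus effects in the 1.1-1.8 range on the logit scale.
_FRANCE_ALPHAS = (1.60, 1.69)
_CHINA_ALPHAS = (1.35, 1.59, 1.59, 1.79, 1.14, 1.54, 1.46, 1.64, 1.45)


def study_preset(
    n_loci: int = 684,
    planted_ld: list[PlantedLD] | None = None,
    seed: int = 0,
) -> SimConfig:
    """Study-scale design: 684 loci, 12 populations, 2 countries x 2 hosts.

    Sample sizes (19-24 per population) and the number of selected loci
    (2 + 9) follow the study layout; locus effects use the 1.1-1.8 range.
    """
    pops = [
        PopulationSpec("BOV-M", "France", "maize", 24),
        PopulationSpec("GRI-M", "France", "maize", 24),
        PopulationSpec("WLA-M", "France", "maize", 24),
        PopulationSpec("BOV-mu", "France", "dicot", 24),
        PopulationSpec("GRI-ho", "France", "dicot", 24),
        PopulationSpec("WLA-mu", "France", "dicot", 24),
        PopulationSpec("SHG-M", "China", "maize", 21),
        PopulationSpec("WUH-M", "China", "maize", 23),
        PopulationSpec("ACA-M", "China", "maize", 19),
        PopulationSpec("SHG-ho", "China", "dicot", 22),
        PopulationSpec("WUH-mu", "China", "dicot", 21),
        PopulationSpec("ACA-ho", "China", "dicot", 21),
    ]
    rng = np.random.default_rng(seed)
    idx = rng.choice(n_loci, size=len(_FRANCE_ALPHAS) + len(_CHINA_ALPHAS), replace=False)
    selected = [
        SelectedLocus(int(i), "France", a)
        for i, a in zip(idx[: len(_FRANCE_ALPHAS)], _FRANCE_ALPHAS)
    ] + [
        SelectedLocus(int(i), "China", a)
        for i, a in zip(idx[len(_FRANCE_ALPHAS):], _CHINA_ALPHAS)
    ]
    return SimConfig(
        populations=pops,
        n_loci=n_loci,
        fst_country=0.07,
        fst_host={"France": 0.035, "China": 0.065},
        fst_pop=0.015,
        selected=selected,
        planted_ld=planted_ld or [],
        seed=seed,
    )


def pair_preset(
    n_loci: int = 684,
    n: int = 24,
    fst_background: float = 0.05,
    selected_indices: tuple[int, ...] = (),
    fst_selected: float = 0.5,
    seed: int = 0,
) -> SimConfig:
    """Two populations diverged at ``fst_background`` with planted loci.

    A flat design (no country or within-population level) used for
    estimator-recovery simulations: planted loci diverge at
    ``fst_selected`` instead of the background.
    """
    alpha = float(_logit(fst_selected) - _logit(fst_background))
    pops = [
        PopulationSpec("P1", "X", "maize", n),
        PopulationSpec("P2", "X", "dicot", n),
    ]
    selected = [SelectedLocus(int(i), "X", alpha) for i in selected_indices]
    return SimConfig(
        populations=pops,
        n_loci=n_loci,
        fst_country=None,
        fst_host=fst_background,
        fst_pop=None,
        selected=selected,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Simulation


def _bn_draw(rng: np.random.Generator, p: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Balding-Nichols Beta draw around parent frequencies p with FST f."""
    f = np.broadcast_to(np.asarray(f, dtype=float), p.shape)
    if ((f <= 0) | (f >= 1)).any():
        raise DataError("FST numerically 0 or 1 in Balding-Nichols draw")
    c = (1.0 - f) / f
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return rng.beta(c * p, c * (1.0 - p))


def simulate_frequencies(config: SimConfig, seed: int | None = None) -> SimTruth:
    """Draw ancestral and per-population null-allele frequencies.

    The hierarchy is ancestral -> country -> host type within country ->
    population; levels with ``None`` FST are skipped (frequencies copied).
    Selected loci redraw their ancestral frequency inside
    ``selected_qbar_range`` so the planted contrast segregates.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    qbar = rng.beta(config.prior_a, config.prior_b, size=config.n_loci)
    lo, hi = config.selected_qbar_range
    for s in config.selected:
        while not (lo <= qbar[s.index] <= hi):
            qbar[s.index] = rng.beta(config.prior_a, config.prior_b)

    locus_ids = [f"L{i + 1:04d}" for i in range(config.n_loci)]
    countries = sorted({p.country for p in config.populations})

    q_country: dict[str, np.ndarray] = {}
    for c in countries:
        q_country[c] = (
            _bn_draw(rng, qbar, config.fst_country)
            if config.fst_country is not None
            else qbar.copy()
        )

    host_fst = pd.DataFrame(index=locus_ids, columns=countries, dtype=float)
    q_host: dict[tuple[str, str], np.ndarray] = {}
    for c in countries:
        base = _logit(config.host_fst(c))
        logit_f = np.full(config.n_loci, base)
        for s in config.selected:
            if s.country == c:
                logit_f[s.index] += s.alpha
        f = _sigmoid(logit_f)
        host_fst[c] = f
        for h in sorted({p.host_type for p in config.populations if p.country == c}):
            q_host[(c, h)] = _bn_draw(rng, q_country[c], f)

    rows = {}
    for p in config.populations:
        parent = q_host[(p.country, p.host_type)]
        rows[p.name] = (
            _bn_draw(rng, parent, config.fst_pop)
            if config.fst_pop is not None
            else parent.copy()
        )
    q_pop = pd.DataFrame.from_dict(rows, orient="index", columns=locus_ids)
    return SimTruth(
        qbar=qbar,
        q_pop=q_pop,
        host_fst=host_fst,
        selected=list(config.selected),
        planted_ld=list(config.planted_ld),
        locus_ids=locus_ids,
    )


def feasible_d(q_a: float, q_b: float) -> tuple[float, float]:
    """Feasible range of the haplotype disequilibrium D given q_A, q_B."""
    lo = max(0.0, q_a + q_b - 1.0) - q_a * q_b
    hi = min(q_a, q_b) - q_a * q_b
    return lo, hi


def _ld_gametes(
    rng: np.random.Generator, q_a: float, q_b: float, d: float, n: int,
    tol: float, pair_label: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Phenotypes at a planted-LD locus pair for n diploid individuals."""
    lo, hi = feasible_d(q_a, q_b)
    d_eff = min(max(d, lo), hi)
    if abs(d_eff - d) > tol:
        raise DataError(
            f"planted D={d} infeasible for pair {pair_label} "
            f"(feasible range [{lo:.4f}, {hi:.4f}])"
        )
    g_ab = q_a * q_b + d_eff          # double-null gamete
    probs = np.array([
        g_ab,
        q_a - g_ab,                    # null at A, "+" at B
        q_b - g_ab,                    # "+" at A, null at B
        1.0 - q_a - q_b + g_ab,        # "+" at both
    ])
    probs = np.clip(probs, 0.0, None)
    probs /= probs.sum()
    gametes = rng.choice(4, size=(n, 2), p=probs)
    null_a = np.isin(gametes, (0, 1)).sum(axis=1)
    null_b = np.isin(gametes, (0, 2)).sum(axis=1)
    return (null_a < 2).astype(float), (null_b < 2).astype(float)


def simulate_band_matrix(
    truth: SimTruth, config: SimConfig, seed: int | None = None
) -> tuple[BandMatrix, SampleMap, LocusMeta]:
    """Draw band phenotypes by random union of gametes (HWE within pops).

    Non-LD loci: each individual carries two independent allele draws at
    the population frequency; the band is absent iff both are null.
    Planted-LD pairs: gametes come from the 2x2 gamete table with the
    target D (clamped to the feasible range), paired into diploids.
    """
    derived = (config.seed if seed is None else seed) + 1_000_003
    rng = np.random.default_rng(derived % (2**31))
    sample_ids, rows, map_rows = [], [], []
    for pop in config.populations:
        q = truth.q_pop.loc[pop.name].to_numpy(dtype=float)
        nulls = rng.binomial(2, np.clip(q, 0.0, 1.0), size=(pop.n, config.n_loci))
        pheno = (nulls < 2).astype(float)
        for planted in config.planted_ld:
            if planted.populations is not None and pop.name not in planted.populations:
                continue
            a, b = planted.locus_a, planted.locus_b
            pheno[:, a], pheno[:, b] = _ld_gametes(
                rng, float(q[a]), float(q[b]), planted.d, pop.n,
                config.ld_clamp_tol,
                f"({truth.locus_ids[a]}, {truth.locus_ids[b]}) in {pop.name}",
            )
        for i in range(pop.n):
            sid = f"{pop.name}_{i + 1:02d}"
            sample_ids.append(sid)
            map_rows.append(
                {"sample_id": sid, "population": pop.name,
                 "host_type": pop.host_type, "country": pop.country}
            )
        rows.append(pheno)

    band = BandMatrix(np.vstack(rows), sample_ids, truth.locus_ids)
    smap = SampleMap(pd.DataFrame(map_rows).set_index("sample_id"))
    lo, hi = config.fragment_size_range
    meta = LocusMeta(
        pd.DataFrame(
            {"fragment_size": rng.integers(lo, hi + 1, size=config.n_loci)},
            index=pd.Index(truth.locus_ids, name="locus_id"),
        )
    )
    return band, smap, meta


def simulate_dataset(
    config: SimConfig, seed: int | None = None
) -> tuple[BandMatrix, SampleMap, LocusMeta, SimTruth]:
    """Frequencies plus band matrix in one call (single seed)."""
    truth = simulate_frequencies(config, seed)
    band, smap, meta = simulate_band_matrix(truth, config, seed)
    return band, smap, meta, truth
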