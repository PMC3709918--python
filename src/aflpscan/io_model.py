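"""Data model and file I/O for dominant-marker (AFLP) band matrices.

AFLP loci are scored per individual as band presence (1) or absence (0);
band absence is the only directly observable genotype class (the recessive
"-/-" homozygote).  The dataset shape is a binary individual x locus matrix
plus a sample map (population, host-plant type, country) and optional locus
metadata (fragment size in base pairs).

Files are plain TSV with a header row; missing phenotypes are coded "NA".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("aflpscan")

MISSING_CODE = "NA"

__all__ = [
    "BandMatrix",
    "SampleMap",
    "LocusMeta",
    "ComparisonPlan",
    "DataError",
    "read_dataset",
    "write_dataset",
    "enumerate_comparisons",
    "enumerate_locus_pairs",
]


class DataError(ValueError):
    """Raised on malformed or inconsistent input data."""


@dataclass
class BandMatrix:
    """Binary individual x locus band phenotype matrix.

    ``phenotypes`` is a float array with entries 0.0 (band absent, the
    "-/-" genotype), 1.0 (band present, "+/+" or "+/-") or NaN (missing).
    """

    phenotypes: np.ndarray
    sample_ids: list[str]
    locus_ids: list[str]

    def __post_init__(self) -> None:
        self.phenotypes = np.asarray(self.phenotypes, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.locus_ids = [str(l) for l in self.locus_ids]
        self.validate()

    def validate(self) -> None:
        n, p = self.phenotypes.shape
        if n != len(self.sample_ids):
            raise DataError(
                f"phenotype matrix has {n} rows but {len(self.sample_ids)} sample ids"
            )
        if p != len(self.locus_ids):
            raise DataError(
                f"phenotype matrix has {p} columns but {len(self.locus_ids)} locus ids"
            )
        if len(set(self.sample_ids)) != n:
            raise DataError("duplicate sample ids")
        if len(set(self.locus_ids)) != p:
            raise DataError("duplicate locus ids")
        bad = ~(np.isnan(self.phenotypes) | (self.phenotypes == 0) | (self.phenotypes == 1))
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise DataError(
                f"non-binary phenotype entry {self.phenotypes[i, j]!r} at "
                f"sample {self.sample_ids[i]!r}, locus {self.locus_ids[j]!r}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.phenotypes, index=self.sample_ids, columns=self.locus_ids)

    def subset_samples(self, ids: Sequence[str]) -> "BandMatrix":
        idx = [self.sample_ids.index(s) for s in ids]
        return BandMatrix(self.phenotypes[idx, :], list(ids), list(self.locus_ids))

    def subset_loci(self, ids: Sequence[str]) -> "BandMatrix":
        idx = [self.locus_ids.index(l) for l in ids]
        return BandMatrix(self.phenotypes[:, idx], list(self.sample_ids), list(ids))


@dataclass
class SampleMap:
    """Per-sample population, host-plant type and country assignments."""

    table: pd.DataFrame  # index = sample_id; columns population, host_type, country

    REQUIRED = ("population", "host_type", "country")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise DataError(f"sample map missing required column {col!r}")
        self.table = self.table.copy()
        self.table.index = self.table.index.astype(str)
        if self.table.index.duplicated().any():
            dup = self.table.index[self.table.index.duplicated()][0]
            raise DataError(f"duplicate sample id in sample map: {dup!r}")
        # every population must map to exactly one (host_type, country)
        grp = self.table.groupby("population")[["host_type", "country"]].nunique()
        bad = grp[(grp > 1).any(axis=1)]
        if len(bad):
            raise DataError(
                f"population {bad.index[0]!r} maps to more than one (host_type, country)"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def populations(self) -> list[str]:
        return sorted(self.table["population"].unique())

    def population_of(self, sample_id: str) -> str:
        return str(self.table.loc[sample_id, "population"])

    def samples_in(self, population: str) -> list[str]:
        return list(self.table.index[self.table["population"] == population])

    def population_table(self) -> pd.DataFrame:
        """One row per population: host_type, country, n (sample count)."""
        tab = (
            self.table.groupby("population")
            .agg(host_type=("host_type", "first"), country=("country", "first"),
                 n=("host_type", "size"))
            .sort_index()
        )
        return tab

    def check_against(self, band: BandMatrix) -> None:
        missing = [s for s in band.sample_ids if s not in self.table.index]
        if missing:
            raise DataError(f"sample {missing[0]!r} in band matrix absent from sample map")
        extra = [s for s in self.table.index if s not in set(band.sample_ids)]
        if extra:
            raise DataError(f"sample {extra[0]!r} in sample map absent from band matrix")


@dataclass
class LocusMeta:
    """Optional per-locus metadata: fragment size (bp), primer pair."""

    table: pd.DataFrame  # index = locus_id; columns fragment_size[, primer_pair]

    def __post_init__(self) -> None:
        if "fragment_size" not in self.table.columns:
            raise DataError("locus meta missing required column 'fragment_size'")
        self.table = self.table.copy()
        self.table.index = self.table.index.astype(str)
        if self.table.index.duplicated().any():
            raise DataError("duplicate locus id in locus meta")
        sizes = self.table["fragment_size"].dropna()
        if (sizes <= 0).any():
            bad = sizes.index[sizes <= 0][0]
            raise DataError(f"non-positive fragment size at locus {bad!r}")

    def fragment_sizes(self, locus_ids: Sequence[str]) -> np.ndarray:
        return self.table.reindex(list(locus_ids))["fragment_size"].to_numpy(dtype=float)


@dataclass
class ComparisonPlan:
    """Within-country population pairs labelled inter-host or intra-host.

    A pair is inter-host iff the two populations were sampled from distinct
    host-plant types; the candidate rule downstream requires detection in at
    least one inter-host comparison and in no intra-host comparison.
    """

    country: str
    pairs: list[tuple[str, str]] = field(default_factory=list)
    kinds: list[str] = field(default_factory=list)  # "inter_host" | "intra_host"

    def __post_init__(self) -> None:
        if len(self.pairs) != len(self.kinds):
            raise DataError("pairs and kinds length mismatch")

    @property
    def inter_host(self) -> list[tuple[str, str]]:
        return [p for p, k in zip(self.pairs, self.kinds) if k == "inter_host"]

    @property
    def intra_host(self) -> list[tuple[str, str]]:
        return [p for p, k in zip(self.pairs, self.kinds) if k == "intra_host"]

    def comparison_id(self, pair: tuple[str, str]) -> str:
        return f"{pair[0]}/{pair[1]}"


# ---------------------------------------------------------------------------
# File I/O


def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataError(f"file not found: {path}")
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def read_band_matrix(path: str | Path) -> BandMatrix:
    raw = _read_tsv(path)
    if raw.shape[1] < 2:
        raise DataError(f"band matrix {path} needs an id column plus >=1 locus column")
    sample_ids = raw.iloc[:, 0].astype(str).tolist()
    locus_ids = [str(c) for c in raw.columns[1:]]
    values = np.full((len(sample_ids), len(locus_ids)), np.nan)
    for j, col in enumerate(raw.columns[1:]):
        for i, cell in enumerate(raw[col]):
            cell = cell.strip()
            if cell == MISSING_CODE or cell == "":
                continue
            if cell not in ("0", "1"):
                raise DataError(
                    f"non-binary phenotype entry {cell!r} at sample "
                    f"{sample_ids[i]!r}, locus {locus_ids[j]!r} in {path}"
                )
            values[i, j] = float(cell)
    return BandMatrix(values, sample_ids, locus_ids)


def read_sample_map(path: str | Path) -> SampleMap:
    raw = _read_tsv(path)
    if "sample_id" not in raw.columns:
        raise DataError(f"sample map {path} missing 'sample_id' column")
    return SampleMap(raw.set_index("sample_id"))


def read_locus_meta(path: str | Path) -> LocusMeta:
    raw = _read_tsv(path)
    if "locus_id" not in raw.columns:
        raise DataError(f"locus meta {path} missing 'locus_id' column")
    tab = raw.set_index("locus_id")
    tab["fragment_size"] = pd.to_numeric(tab["fragment_size"], errors="coerce")
    return LocusMeta(tab)


def read_dataset(
    band_matrix_path: str | Path,
    sample_map_path: str | Path,
    locus_meta_path: str | Path | None = None,
) -> tuple[BandMatrix, SampleMap, LocusMeta | None]:
    """Read and cross-validate the three dataset files."""
    band = read_band_matrix(band_matrix_path)
    smap = read_sample_map(sample_map_path)
    smap.check_against(band)
    meta = None
    if locus_meta_path is not None:
        meta = read_locus_meta(locus_meta_path)
    return band, smap, meta


def write_dataset(
    out_dir: str | Path,
    band: BandMatrix,
    smap: SampleMap,
    meta: LocusMeta | None = None,
) -> dict[str, Path]:
    """Write band_matrix.tsv / sample_map.tsv / locus_meta.tsv into *out_dir*."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    cells = np.where(
        np.isnan(band.phenotypes), MISSING_CODE,
        np.nan_to_num(band.phenotypes).astype(int).astype(str),
    )
    frame = pd.DataFrame(cells, columns=band.locus_ids)
    frame.insert(0, "sample_id", band.sample_ids)
    paths["band_matrix"] = out_dir / "band_matrix.tsv"
    frame.to_csv(paths["band_matrix"], sep="\t", index=False)

    paths["sample_map"] = out_dir / "sample_map.tsv"
    smap.table.rename_axis("sample_id").reset_index().to_csv(
        paths["sample_map"], sep="\t", index=False
    )

    if meta is not None:
        paths["locus_meta"] = out_dir / "locus_meta.tsv"
        meta.table.rename_axis("locus_id").reset_index().to_csv(
            paths["locus_meta"], sep="\t", index=False
        )
    return paths


# ---------------------------------------------------------------------------
# Comparison and locus-pair enumeration


def enumerate_comparisons(smap: SampleMap) -> dict[str, ComparisonPlan]:
    """All unordered within-country population pairs, labelled by host type.

    Returns one :class:`ComparisonPlan` per country (sorted country order,
    lexicographic pair order, so output is independent of input ordering).
    Countries with a single population yield an empty plan with a warning.
    """
    pops = smap.population_table()
    plans: dict[str, ComparisonPlan] = {}
    for country in sorted(pops["country"].unique()):
        sub = pops[pops["country"] == country]
        names = sorted(sub.index)
        if len(names) < 2:
            logger.warning("country %r has a single population; empty comparison plan", country)
            plans[country] = ComparisonPlan(country=country)
            continue
        pairs, kinds = [], []
        for a, b in combinations(names, 2):
            kind = (
                "inter_host"
                if sub.loc[a, "host_type"] != sub.loc[b, "host_type"]
                else "intra_host"
            )
            pairs.append((a, b))
            kinds.append(kind)
        plans[country] = ComparisonPlan(country=country, pairs=pairs, kinds=kinds)
    return plans


def enumerate_locus_pairs(
    a: Iterable[str], b: Iterable[str] | None = None
) -> list[tuple[str, str]]:
    """Unordered locus pairs: C(|A|,2) within one set, or |A|x|B| across sets.

    Cross mode (``b`` given) requires disjoint sets; no self-pairs or
    duplicates are produced, and the output is in canonical (sorted) order.
    """
    a_sorted = sorted({str(x) for x in a})
    if b is None:
        return list(combinations(a_sorted, 2))
    b_sorted = sorted({str(x) for x in b})
    overlap = set(a_sorted) & set(b_sorted)
    if overlap:
        raise DataError(f"locus sets overlap in cross mode: {sorted(overlap)[:3]}")
    return [(x, y) for x in a_sorted for y in b_sorted]
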