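"""Readers, writers and canonical in-memory containers.

Every downstream statistic operates on a :class:`HaplotypeMatrix` — a phased,
ancestral/derived-polarized 0/1 matrix with one row per haplotype (two per
diploid individual) and one column per biallelic SNP.  Polarization comes from
the VCF ``INFO/AA`` annotation; sites without a confidently inferred ancestral
allele are dropped at load time, as are indels and multiallelic records.

Coordinates are 1-based inclusive throughout (VCF convention).
"""

from __future__ import annotations

import dataclasses
import re
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "HaplotypeMatrix",
    "PopulationMeta",
    "GeneticMap",
    "GenotypeRecord",
    "read_vcf",
    "write_vcf",
    "downsample_individuals",
    "read_genetic_map",
    "average_maps",
    "read_population_table",
    "read_genotype_table",
]


@dataclasses.dataclass
class HaplotypeMatrix:
    """Phased haplotype-by-site matrix, polarized ancestral(0)/derived(1).

    Parameters
    ----------
    alleles
        ``(n_haplotypes, n_sites)`` int8 array of 0/1.
    positions
        Physical positions (bp, 1-based), strictly increasing.
    sample_ids
        Individual identifier per row; diploid individuals contribute two
        consecutive rows with the same identifier.
    population
        Population label per row.
    """

    alleles: np.ndarray
    positions: np.ndarray
    sample_ids: np.ndarray
    population: np.ndarray
    chrom: str = "chr"

    def __post_init__(self):
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.population = np.asarray(self.population, dtype=object)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be 2-D (haplotypes x sites)")
        n, m = self.alleles.shape
        if len(self.positions) != m:
            raise ValueError("positions length does not match site count")
        if len(self.sample_ids) != n or len(self.population) != n:
            raise ValueError("per-haplotype labels do not match row count")
        if m > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        if not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("alleles must be 0 (ancestral) or 1 (derived)")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def site_index(self, position: int) -> int:
        idx = np.searchsorted(self.positions, position)
        if idx >= len(self.positions) or self.positions[idx] != position:
            raise KeyError(f"position {position} not present in matrix")
        return int(idx)

    def rows_for_population(self, pop: str) -> np.ndarray:
        return np.flatnonzero(self.population == pop)

    def subset_rows(self, rows: Sequence[int]) -> "HaplotypeMatrix":
        rows = np.asarray(rows, dtype=int)
        return HaplotypeMatrix(
            self.alleles[rows], self.positions.copy(),
            self.sample_ids[rows], self.population[rows], self.chrom,
        )

    def subset_sites(self, cols: Sequence[int]) -> "HaplotypeMatrix":
        cols = np.asarray(cols, dtype=int)
        return HaplotypeMatrix(
            self.alleles[:, cols], self.positions[cols],
            self.sample_ids.copy(), self.population.copy(), self.chrom,
        )

    def derived_frequency(self, position: int, pop: Optional[str] = None) -> float:
        col = self.alleles[:, self.site_index(position)]
        if pop is not None:
            col = col[self.population == pop]
        return float(col.mean())


@dataclasses.dataclass
class PopulationMeta:
    """Per-population metadata row.

    ``latitude`` is stored as the absolute value in degrees (southern
    hemisphere folded), ``temperature`` is the annual mean in °C and
    ``fst_to_reference`` the genome-wide ratio-of-averages F_ST to the
    reference population (slightly negative values are legitimate for the
    Weir–Cockerham estimator).
    """

    name: str
    latitude: float
    longitude: float
    temperature: float
    n_individuals: int
    fst_to_reference: float = np.nan
    daf: float = np.nan
    continent: str = ""

    def __post_init__(self):
        if not 0.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} outside [0, 90]")
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")


class GeneticMap:
    """Piecewise-constant recombination-rate map.

    Built from HapMap-format rows ``(position bp, rate cM/Mb, map cM)``; the
    rate on ``[pos_i, pos_{i+1})`` is ``rate_i`` and the cumulative map
    position is the rectangular integral of the rates.  Beyond the last map
    point the last interval's rate is extended.
    """

    def __init__(self, positions: Sequence[float], rates: Sequence[float]):
        self.positions = np.asarray(positions, dtype=float)
        self.rates = np.asarray(rates, dtype=float)
        if len(self.positions) != len(self.rates):
            raise ValueError("positions and rates must have equal length")
        if len(self.positions) < 1:
            raise ValueError("empty map")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("map positions must be strictly increasing")
        if np.any(self.rates < 0):
            raise ValueError("negative recombination rate")
        # cumulative cM at each breakpoint (rectangular integration)
        seg = np.diff(self.positions) * self.rates[:-1] / 1e6 if len(self.rates) > 1 else np.array([])
        self.cumulative = np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def span(self) -> tuple:
        return float(self.positions[0]), float(self.positions[-1])

    def cm_at(self, pos) -> np.ndarray:
        """Cumulative genetic position (cM) at physical position(s)."""
        pos = np.atleast_1d(np.asarray(pos, dtype=float))
        idx = np.clip(np.searchsorted(self.positions, pos, side="right") - 1, 0, len(self.positions) - 1)
        out = self.cumulative[idx] + (pos - self.positions[idx]) * self.rates[idx] / 1e6
        # before the first map point: extend the first rate backwards
        before = pos < self.positions[0]
        out[before] = (pos[before] - self.positions[0]) * self.rates[0] / 1e6
        return out if out.size > 1 else out

    def rate_at(self, pos) -> np.ndarray:
        pos = np.atleast_1d(np.asarray(pos, dtype=float))
        idx = np.clip(np.searchsorted(self.positions, pos, side="right") - 1, 0, len(self.positions) - 1)
        return self.rates[idx]


@dataclasses.dataclass
class GenotypeRecord:
    """Diploid genotype of one individual at the focal SNP, with metadata."""

    individual_id: str
    population: str
    derived_count: int
    ancestral_count: int
    latitude: float = np.nan
    longitude: float = np.nan
    temperature: float = np.nan
    age_years: Optional[float] = None
    missing: bool = False

    def __post_init__(self):
        if not self.missing and self.derived_count + self.ancestral_count != 2:
            raise ValueError(
                f"{self.individual_id}: derived+ancestral counts must sum to 2 (diploid)"
            )


_REGION_RE = re.compile(r"^([^:]+):(\d+)-(\d+)$")


def _parse_region(region: str):
    m = _REGION_RE.match(region)
    if not m:
        raise ValueError(f"malformed region {region!r}; expected chrom:start-end")
    return m.group(1), int(m.group(2)), int(m.group(3))


def read_vcf(
    path,
    region: Optional[str] = None,
    focal_site: Optional[int] = None,
    sample_populations: Optional[dict] = None,
) -> HaplotypeMatrix:
    """Load a phased VCF into a polarized :class:`HaplotypeMatrix`.

    Only biallelic SNPs with a confidently inferred ancestral allele
    (``INFO/AA`` matching REF or ALT, case-insensitive) are retained.  When
    AA equals ALT the column is flipped so 1 always means *derived*.

    Parameters
    ----------
    region
        ``chrom:start-end``, 1-based inclusive.
    focal_site
        Position that must survive filtering; raises ``KeyError`` otherwise.
    sample_populations
        Optional mapping sample id -> population label (default ``"pop0"``).
    """
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    if region is not None:
        chrom, start, end = _parse_region(region)
        records = vf.fetch(chrom, start - 1, end) if vf.index is not None else (
            r for r in vf if r.chrom == chrom and start <= r.pos <= end
        )
    else:
        records = iter(vf)

    cols, positions, chrom_seen = [], [], None
    for rec in records:
        chrom_seen = rec.chrom
        if rec.alts is None or len(rec.alts) != 1:
            continue  # multiallelic or monomorphic record
        ref, alt = rec.ref, rec.alts[0]
        if len(ref) != 1 or len(alt) != 1:
            continue  # indel
        aa = rec.info.get("AA")
        if isinstance(aa, tuple):
            aa = aa[0]
        if aa is None:
            continue
        aa = str(aa).split("|")[0].strip().upper()
        if aa not in (ref.upper(), alt.upper()):
            continue  # unpolarizable
        flip = aa == alt.upper()
        col = np.empty(2 * len(samples), dtype=np.int8)
        for i, s in enumerate(samples):
            sample = rec.samples[s]
            if not sample.phased:
                raise ValueError(
                    f"unphased genotype for sample {s} at {rec.chrom}:{rec.pos}"
                )
            gt = sample["GT"]
            col[2 * i], col[2 * i + 1] = gt
        if flip:
            col = (1 - col).astype(np.int8)
        cols.append(col)
        positions.append(rec.pos)

    positions = np.asarray(positions, dtype=np.int64)
    alleles = np.column_stack(cols) if cols else np.empty((2 * len(samples), 0), np.int8)
    sample_ids = np.repeat(samples, 2)
    pops = np.array(
        [(sample_populations or {}).get(s, "pop0") for s in sample_ids], dtype=object
    )
    hm = HaplotypeMatrix(alleles, positions, sample_ids, pops, chrom_seen or "chr")
    if focal_site is not None and focal_site not in set(positions.tolist()):
        raise KeyError(f"focal site {focal_site} absent after filtering")
    return hm


def write_vcf(matrix: HaplotypeMatrix, path) -> None:
    """Write a :class:`HaplotypeMatrix` as a phased VCF (REF=ancestral A, ALT=derived G)."""
    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.contigs.add(matrix.chrom, length=int(matrix.positions[-1]) + 1 if matrix.n_sites else 2)
    individuals = list(dict.fromkeys(matrix.sample_ids.tolist()))
    for ind in individuals:
        header.add_sample(str(ind))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j in range(matrix.n_sites):
            rec = out.new_record(
                contig=matrix.chrom, start=int(matrix.positions[j]) - 1,
                alleles=("A", "G"), id=".",
            )
            rec.info["AA"] = "A"
            for ind in individuals:
                rows = np.flatnonzero(matrix.sample_ids == ind)
                rec.samples[str(ind)]["GT"] = tuple(int(matrix.alleles[r, j]) for r in rows)
                rec.samples[str(ind)].phased = True
            out.write(rec)


def downsample_individuals(matrix: HaplotypeMatrix, n: int, seed: int) -> HaplotypeMatrix:
    """Randomly retain exactly ``n`` individuals per population (both haplotypes).

    Deterministic given ``seed``; raises if any population has fewer than
    ``n`` individuals.
    """
    rng = np.random.default_rng(seed)
    keep_rows = []
    for pop in sorted(set(matrix.population.tolist())):
        rows = matrix.rows_for_population(pop)
        inds = list(dict.fromkeys(matrix.sample_ids[rows].tolist()))
        if len(inds) < n:
            raise ValueError(
                f"population {pop} has {len(inds)} individuals, fewer than {n}"
            )
        chosen = set(rng.choice(len(inds), size=n, replace=False).tolist())
        chosen_ids = {inds[i] for i in chosen}
        keep_rows.extend(r for r in rows if matrix.sample_ids[r] in chosen_ids)
    return matrix.subset_rows(sorted(keep_rows))


def read_genetic_map(path) -> GeneticMap:
    """Read a HapMap-format genetic map (position bp, rate cM/Mb, map cM)."""
    df = pd.read_csv(path, sep=r"\s+", comment="#")
    if df.shape[1] < 2:
        raise ValueError("genetic map needs at least position and rate columns")
    pos = df.iloc[:, 0].to_numpy(dtype=float)
    rate = df.iloc[:, 1].to_numpy(dtype=float)
    return GeneticMap(pos, rate)


def average_maps(maps: Sequence[GeneticMap]) -> GeneticMap:
    """Per-basepair arithmetic mean of rates on the union of breakpoints."""
    if not maps:
        raise ValueError("no maps given")
    starts = [m.span[0] for m in maps]
    ends = [m.span[1] for m in maps]
    if max(starts) >= min(ends):
        raise ValueError("maps do not share a common span")
    lo, hi = max(starts), min(ends)
    breaks = np.unique(np.concatenate([
        m.positions[(m.positions >= lo) & (m.positions <= hi)] for m in maps
    ] + [np.array([lo, hi])]))
    rates = np.mean([m.rate_at(breaks) for m in maps], axis=0)
    return GeneticMap(breaks, rates)


_MANDATORY_POP_COLS = ("population", "latitude", "longitude", "temperature")


def _fold_latitude(lat: float) -> float:
    return abs(float(lat))


def read_population_table(path) -> list:
    """Read a delimited per-population metadata table into ``PopulationMeta`` records."""
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    for col in _MANDATORY_POP_COLS:
        if col not in df.columns:
            raise ValueError(f"missing mandatory column {col!r}")
    out = []
    for _, row in df.iterrows():
        out.append(PopulationMeta(
            name=str(row["population"]),
            latitude=_fold_latitude(row["latitude"]),
            longitude=float(row["longitude"]),
            temperature=float(row["temperature"]),
            n_individuals=int(row.get("n_individuals", 1)),
            fst_to_reference=float(row["fst_to_reference"]) if "fst_to_reference" in df.columns else np.nan,
            daf=float(row["daf"]) if "daf" in df.columns else np.nan,
            continent=str(row["continent"]) if "continent" in df.columns else "",
        ))
    return out


def read_genotype_table(path) -> list:
    """Read a per-individual genotype table into ``GenotypeRecord`` rows.

    Expected columns: id, population, derived_count, ancestral_count,
    latitude, longitude, temperature, optionally age_years.  Rows with
    missing genotype are flagged (``missing=True``), not dropped.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("id", "population", "derived_count", "ancestral_count"):
        if col not in df.columns:
            raise ValueError(f"missing mandatory column {col!r}")
    out = []
    for _, row in df.iterrows():
        missing = pd.isna(row["derived_count"]) or pd.isna(row["ancestral_count"])
        out.append(GenotypeRecord(
            individual_id=str(row["id"]),
            population=str(row["population"]),
            derived_count=0 if missing else int(row["derived_count"]),
            ancestral_count=2 if missing else int(row["ancestral_count"]),
            latitude=_fold_latitude(row["latitude"]) if "latitude" in df.columns else np.nan,
            longitude=float(row["longitude"]) if "longitude" in df.columns else np.nan,
            temperature=float(row["temperature"]) if "temperature" in df.columns else np.nan,
            age_years=float(row["age_years"]) if "age_years" in df.columns and not pd.isna(row.get("age_years")) else None,
            missing=bool(missing),
        ))
    return out
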