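"""Selection-scan and diversity statistics.

Implements the Weir & Cockerham (1984) F_ST variance components (per-site and
the genome-wide "ratio of averages"), Tajima's D, Fay & Wu's H (unnormalized),
nucleotide diversity, EHH/iHH and the derived scores iHS and XP-EHH, and
rank-based empirical P-values against a genome-wide background.

The F_ST estimator uses observed heterozygote counts when genotypes are
available; when only allele frequencies are known (e.g. reproducing published
per-population frequencies) heterozygosity is imputed under Hardy–Weinberg
equilibrium, h_i = 2 p_i (1 - p_i).
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Iterable, Optional, Sequence

import numpy as np
from numba import njit

from .io_formats import GeneticMap, HaplotypeMatrix

__all__ = [
    "SiteCounts",
    "FstComponents",
    "EhhResult",
    "wc_fst_site",
    "wc_fst_from_freqs",
    "fst_ratio_of_averages",
    "fst_ratio_pair",
    "pairwise_fst_matrix",
    "tajimas_d",
    "fay_wu_h",
    "derived_sfs",
    "nucleotide_diversity",
    "ehh_curve",
    "ehh_and_ihh",
    "ihs_scan",
    "xpehh_scan",
    "empirical_pvalue",
]


@dataclasses.dataclass
class SiteCounts:
    """Per-population allele and heterozygote counts at one site.

    ``het_count`` is the number of heterozygous individuals; ``None`` means
    genotype data is absent and HWE imputation is used.
    """

    n: Sequence[int]                      # diploid sample sizes
    derived_count: Sequence[int]          # derived allele counts (0..2n)
    het_count: Optional[Sequence[float]] = None

    def __post_init__(self):
        self.n = np.asarray(self.n, dtype=float)
        self.derived_count = np.asarray(self.derived_count, dtype=float)
        if np.any(self.derived_count < 0) or np.any(self.derived_count > 2 * self.n):
            raise ValueError("derived count outside [0, 2n]")
        if self.het_count is not None:
            self.het_count = np.asarray(self.het_count, dtype=float)

    @property
    def freqs(self) -> np.ndarray:
        return self.derived_count / (2 * self.n)

    @property
    def het_freqs(self) -> np.ndarray:
        if self.het_count is None:
            p = self.freqs
            return 2 * p * (1 - p)
        return self.het_count / self.n


@dataclasses.dataclass
class FstComponents:
    """Weir–Cockerham variance components: a (among populations), b (among
    individuals within populations), c (within individuals)."""

    a: float
    b: float
    c: float
    defined: bool = True

    @property
    def theta(self) -> float:
        if not self.defined:
            return np.nan
        return self.a / (self.a + self.b + self.c)


def wc_fst_site(counts: SiteCounts) -> FstComponents:
    """Weir & Cockerham (1984) variance components for one site, r >= 2 populations."""
    n = counts.n
    r = len(n)
    if r < 2:
        raise ValueError("need at least two populations")
    p = counts.freqs
    h = counts.het_freqs
    nbar = n.mean()
    nc = (r * nbar - (n ** 2).sum() / (r * nbar)) / (r - 1)
    pbar = (n * p).sum() / (r * nbar)
    s2 = (n * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
    hbar = (n * h).sum() / (r * nbar)
    a = (nbar / nc) * (
        s2 - (1.0 / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
    )
    c = hbar / 2
    if a + b + c == 0:
        return FstComponents(a, b, c, defined=False)
    return FstComponents(a, b, c)


def wc_fst_from_freqs(p1: float, p2: float, n1: int, n2: int) -> FstComponents:
    """Pairwise F_ST components from allele frequencies with HWE heterozygosity."""
    return wc_fst_site(SiteCounts(
        n=[n1, n2],
        derived_count=[p1 * 2 * n1, p2 * 2 * n2],
    ))


def fst_ratio_of_averages(sites: Iterable[FstComponents]) -> float:
    """Genome-wide F_ST as the ratio of averages, sum(a) / sum(a+b+c).

    This is *not* the mean of per-site theta; monomorphic (undefined) sites
    are skipped.
    """
    num = den = 0.0
    k = 0
    for comp in sites:
        if not comp.defined:
            continue
        num += comp.a
        den += comp.a + comp.b + comp.c
        k += 1
    if k == 0:
        raise ValueError("no sites with defined F_ST components")
    return num / den


def _wc_pair_components_vec(p1, p2, n1, n2):
    """Vectorized WC components (a, a+b+c) for many sites of one population pair.

    HWE heterozygosity; algebra identical to :func:`wc_fst_site` with r=2
    (checked against it in the test suite).
    """
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    n = np.array([float(n1), float(n2)])
    r = 2
    nbar = n.mean()
    nc = (r * nbar - (n ** 2).sum() / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * 2 * p1 * (1 - p1) + n2 * 2 * p2 * (1 - p2)) / (r * nbar)
    a = (nbar / nc) * (s2 - (1.0 / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar))
    c = hbar / 2
    return a, a + b + c


def fst_ratio_pair(p1, p2, n1, n2) -> float:
    """Ratio-of-averages F_ST for one pair over sites polymorphic in that pair."""
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    poly = ~((p1 == p2) & ((p1 == 0.0) | (p1 == 1.0)))
    a, abc = _wc_pair_components_vec(p1[poly], p2[poly], n1, n2)
    if abc.size == 0:
        raise ValueError("no sites polymorphic in this pair")
    return float(a.sum() / abc.sum())


def pairwise_fst_matrix(freqs: np.ndarray, n_individuals: np.ndarray) -> np.ndarray:
    """Pairwise ratio-of-averages F_ST matrix from a (pops x sites) frequency table.

    Only sites polymorphic in a given pair contribute to that pair, matching
    the genome-wide background convention used for tree building.
    """
    freqs = np.asarray(freqs, dtype=float)
    n_individuals = np.asarray(n_individuals)
    npop = freqs.shape[0]
    out = np.zeros((npop, npop))
    for i in range(npop):
        for j in range(i + 1, npop):
            out[i, j] = out[j, i] = fst_ratio_pair(
                freqs[i], freqs[j], n_individuals[i], n_individuals[j]
            )
    return out


def _tajima_constants(n: int):
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i ** 2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n ** 2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return a1, e1, e2


def tajimas_d(S: int, pi: float, n: int) -> float:
    """Tajima (1989) D from segregating sites, mean pairwise differences and sample size.

    Returns NaN (flagged undefined) when S = 0.
    """
    if n < 4:
        raise ValueError("need at least 4 haplotypes")
    if S < 1:
        return np.nan
    a1, e1, e2 = _tajima_constants(n)
    return (pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def derived_sfs(matrix_or_alleles) -> np.ndarray:
    """Derived-allele site frequency spectrum S_1..S_{n-1} (length n-1)."""
    alleles = matrix_or_alleles.alleles if isinstance(matrix_or_alleles, HaplotypeMatrix) else np.asarray(matrix_or_alleles)
    n = alleles.shape[0]
    counts = alleles.sum(axis=0)
    sfs = np.bincount(counts[(counts > 0) & (counts < n)].astype(int), minlength=n)[1:n]
    return sfs


def fay_wu_h(sfs: Sequence[int], n: int) -> float:
    """Unnormalized Fay & Wu's H = theta_pi - theta_H from a polarized derived SFS."""
    sfs = np.asarray(sfs, dtype=float)
    if len(sfs) != n - 1:
        raise ValueError("polarized SFS must have length n-1")
    i = np.arange(1, n)
    denom = n * (n - 1)
    theta_pi = (2 * sfs * i * (n - i)).sum() / denom
    theta_h = (2 * sfs * i ** 2).sum() / denom
    return theta_pi - theta_h


def nucleotide_diversity(matrix_or_alleles, rows: Optional[Sequence[int]] = None) -> float:
    """Mean pairwise difference count over all haplotype pairs."""
    alleles = matrix_or_alleles.alleles if isinstance(matrix_or_alleles, HaplotypeMatrix) else np.asarray(matrix_or_alleles)
    if rows is not None:
        alleles = alleles[np.asarray(rows, dtype=int)]
    n = alleles.shape[0]
    if n < 2:
        raise ValueError("need at least 2 haplotypes")
    c = alleles.sum(axis=0, dtype=np.int64)
    return float((c * (n - c)).sum() / (n * (n - 1) / 2))


@njit(cache=True)
def _ehh_from_first_diffs(d: np.ndarray, m: int, n: int) -> np.ndarray:
    """EHH per column depth from adjacent first-difference columns.

    With rows in lexicographic walk order, haplotypes identical over columns
    [0, j] form runs of adjacent rows whose pairwise first-difference column
    exceeds j; EHH(j) is the within-run pair fraction.
    """
    npairs = n * (n - 1) / 2.0
    out = np.empty(m)
    for j in range(m):
        pairs = 0.0
        run = 1
        for i in range(n - 1):
            if d[i] > j:
                run += 1
            else:
                pairs += run * (run - 1) / 2.0
                run = 1
        pairs += run * (run - 1) / 2.0
        out[j] = pairs / npairs
    return out


def _homozygosity_walk(hap: np.ndarray):
    """EHH values walking outward over the columns of ``hap`` (carriers x sites).

    Column 0 is the first site away from the core; returns EHH after each
    column is appended to the extending haplotypes.
    """
    n, m = hap.shape
    if m == 0:
        return np.empty(0)
    order = np.lexsort(hap[:, ::-1].T)
    s = hap[order]
    neq = s[:-1] != s[1:]
    any_diff = neq.any(axis=1)
    d = np.where(any_diff, neq.argmax(axis=1), m).astype(np.int64)
    return _ehh_from_first_diffs(d, m, n)


@dataclasses.dataclass
class EhhResult:
    core_site: int
    ehh_positions: np.ndarray   # physical positions, ascending, includes core
    ehh_values: np.ndarray      # EHH at each position (1.0 at the core)
    ihh: float                  # cM-integrated homozygosity, both directions
    defined: bool = True


def ehh_curve(matrix: HaplotypeMatrix, core_site: int, core_allele: int,
              gmap: GeneticMap, cutoff: float = 0.05) -> EhhResult:
    """EHH around ``core_site`` among carriers of ``core_allele``.

    EHH(x) is the fraction of carrier pairs with identical haplotypes over
    [core, x]; the walk extends outward in each direction until EHH drops
    below ``cutoff`` or the region ends.  iHH is the trapezoid integral of
    EHH against genetic distance (cM), summed over both directions, with the
    curve truncated at the first point below the cutoff.
    """
    core = matrix.site_index(core_site)
    carriers = matrix.alleles[:, core] == core_allele
    if carriers.sum() < 2:
        return EhhResult(core_site, np.array([core_site]), np.array([1.0]), np.nan, defined=False)
    hap = matrix.alleles[carriers]
    cm = np.asarray(gmap.cm_at(matrix.positions.astype(float)))
    counts = matrix.alleles.sum(axis=0)
    poly = (counts > 0) & (counts < matrix.n_haplotypes)  # informative sites only

    pos_out, val_out = [core_site], [1.0]
    ihh = 0.0
    for direction in (+1, -1):
        cols = np.arange(core + 1, matrix.n_sites) if direction > 0 else np.arange(core - 1, -1, -1)
        cols = cols[poly[cols]]
        ehh = _homozygosity_walk(hap[:, cols]) if len(cols) else np.empty(0)
        below = np.flatnonzero(ehh < cutoff)
        stop = below[0] + 1 if len(below) else len(cols)
        seg_cols = cols[:stop]
        seg_ehh = ehh[:stop]
        x = np.abs(cm[seg_cols] - cm[core])
        prev_x, prev_e = 0.0, 1.0
        for xi, ei in zip(x, seg_ehh):
            ihh += 0.5 * (prev_e + ei) * (xi - prev_x)
            prev_x, prev_e = xi, ei
        if len(below) == 0:
            # cutoff never reached: extend flat to the region boundary
            edge = matrix.positions[-1] if direction > 0 else matrix.positions[0]
            x_edge = abs(float(gmap.cm_at(float(edge))[0]) - cm[core])
            if x_edge > prev_x:
                ihh += prev_e * (x_edge - prev_x)
        pos_out.extend(matrix.positions[seg_cols].tolist())
        val_out.extend(seg_ehh.tolist())
    order = np.argsort(pos_out)
    return EhhResult(core_site, np.asarray(pos_out)[order], np.asarray(val_out)[order], ihh)


def ehh_and_ihh(matrix: HaplotypeMatrix, core_site: int, gmap: GeneticMap,
                cutoff: float = 0.05):
    """(iHH_derived, iHH_ancestral) at ``core_site``; NaN when < 2 carriers."""
    d = ehh_curve(matrix, core_site, 1, gmap, cutoff)
    a = ehh_curve(matrix, core_site, 0, gmap, cutoff)
    return d.ihh, a.ihh


def _standardize_in_bins(values: np.ndarray, freqs: np.ndarray,
                         bg_values: np.ndarray, bg_freqs: np.ndarray,
                         bin_width: float) -> np.ndarray:
    out = np.full_like(values, np.nan, dtype=float)
    edges = np.arange(0.0, 1.0 + bin_width, bin_width)
    which = np.clip(np.digitize(freqs, edges) - 1, 0, len(edges) - 2)
    bg_which = np.clip(np.digitize(bg_freqs, edges) - 1, 0, len(edges) - 2)
    for b in np.unique(which):
        sel = which == b
        bg = bg_values[(bg_which == b) & np.isfinite(bg_values)]
        if len(bg) < 2 or np.std(bg) == 0:
            warnings.warn(f"no usable background in DAF bin {b}; iHS left NA")
            continue
        out[sel] = (values[sel] - bg.mean()) / bg.std()
    return out


def ihs_scan(matrix: HaplotypeMatrix, gmap: GeneticMap,
             maf_bounds=(0.05, 0.95), cutoff: float = 0.05,
             bin_width: float = 0.02,
             background: Optional[tuple] = None) -> dict:
    """Per-site iHS: ln(iHH_ancestral / iHH_derived), standardized within DAF bins.

    Sites with derived frequency outside ``maf_bounds`` are NA.  By default
    standardization uses the scanned sites themselves as background; pass
    ``background=(unstd_values, dafs)`` for an external (genome-wide) set.
    """
    n = matrix.n_haplotypes
    daf = matrix.alleles.mean(axis=0)
    unstd = np.full(matrix.n_sites, np.nan)
    ok = (daf > maf_bounds[0]) & (daf < maf_bounds[1])
    for j in np.flatnonzero(ok):
        ihh_d, ihh_a = ehh_and_ihh(matrix, int(matrix.positions[j]), gmap, cutoff)
        if np.isfinite(ihh_d) and np.isfinite(ihh_a) and ihh_d > 0 and ihh_a > 0:
            unstd[j] = math.log(ihh_a / ihh_d)
    if background is None:
        bg_values, bg_freqs = unstd, daf
    else:
        bg_values, bg_freqs = map(np.asarray, background)
    std = _standardize_in_bins(unstd, daf, bg_values, bg_freqs, bin_width)
    return {"positions": matrix.positions.copy(), "daf": daf,
            "ihs_unstd": unstd, "ihs_std": std}


def xpehh_scan(matrix_test: HaplotypeMatrix, matrix_ref: HaplotypeMatrix,
               gmap: GeneticMap, min_test_daf: float = 0.05,
               cutoff: float = 0.05,
               background: Optional[np.ndarray] = None,
               sites: Optional[Sequence[int]] = None) -> dict:
    """Per-site XP-EHH: ln(iHH_test / iHH_ref), EHH over *all* haplotypes.

    Positive values mean longer haplotypes in the test population.  Sites with
    test-population derived frequency <= ``min_test_daf`` or with iHH_ref = 0
    are NA.  Standardized to mean 0 / sd 1 over the background set (the
    scanned sites by default).
    """
    if not np.array_equal(matrix_test.positions, matrix_ref.positions):
        raise ValueError("test and reference matrices must share the site set")
    daf_test = matrix_test.alleles.mean(axis=0)
    positions = matrix_test.positions
    idx = range(matrix_test.n_sites) if sites is None else [matrix_test.site_index(s) for s in sites]
    unstd = np.full(matrix_test.n_sites, np.nan)
    for j in idx:
        if daf_test[j] <= min_test_daf:
            continue
        pos = int(positions[j])
        # EHH of the full panel (no allele split) from the core outward
        t = _panel_ihh(matrix_test, pos, gmap, cutoff)
        r = _panel_ihh(matrix_ref, pos, gmap, cutoff)
        if t > 0 and r > 0:
            unstd[j] = math.log(t / r)
    bg = unstd[np.isfinite(unstd)] if background is None else np.asarray(background, float)
    bg = bg[np.isfinite(bg)]
    if len(bg) >= 2 and bg.std() > 0:
        std = (unstd - bg.mean()) / bg.std()
    else:
        std = np.full_like(unstd, np.nan)
    return {"positions": positions.copy(), "daf_test": daf_test,
            "xpehh_unstd": unstd, "xpehh_std": std}


def _panel_ihh(matrix: HaplotypeMatrix, core_site: int, gmap: GeneticMap, cutoff: float) -> float:
    core = matrix.site_index(core_site)
    hap = matrix.alleles
    cm = np.asarray(gmap.cm_at(matrix.positions.astype(float)))
    counts = hap.sum(axis=0)
    poly = (counts > 0) & (counts < matrix.n_haplotypes)
    ihh = 0.0
    for direction in (+1, -1):
        cols = np.arange(core + 1, matrix.n_sites) if direction > 0 else np.arange(core - 1, -1, -1)
        cols = cols[poly[cols]]
        ehh = _homozygosity_walk(hap[:, cols]) if len(cols) else np.empty(0)
        below = np.flatnonzero(ehh < cutoff)
        stop = below[0] + 1 if len(below) else len(cols)
        x = np.abs(cm[cols[:stop]] - cm[core])
        prev_x, prev_e = 0.0, 1.0
        for xi, ei in zip(x, ehh[:stop]):
            ihh += 0.5 * (prev_e + ei) * (xi - prev_x)
            prev_x, prev_e = xi, ei
        if len(below) == 0:
            edge = matrix.positions[-1] if direction > 0 else matrix.positions[0]
            x_edge = abs(float(gmap.cm_at(float(edge))[0]) - cm[core])
            if x_edge > prev_x:
                ihh += prev_e * (x_edge - prev_x)
    return ihh


def empirical_pvalue(value: float, background: Sequence[float], tail: str = "upper") -> float:
    """Rank-based empirical P-value against a background distribution.

    Upper tail: fraction of background values >= ``value`` (plain proportion,
    no +1 smoothing); a value above all N background values gives 0.0 and the
    caller should report "< 1/N".
    """
    bg = np.asarray(background, dtype=float)
    bg = bg[np.isfinite(bg)]
    if len(bg) == 0:
        raise ValueError("empty background")
    if tail == "upper":
        return float((bg >= value).mean())
    if tail == "lower":
        return float((bg <= value).mean())
    raise ValueError("tail must be 'upper' or 'lower'")
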