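"""Approximate Bayesian computation on the locus simulations.

Fourteen summary statistics describe one dataset (observed or simulated): the
cross-population EHH score at the focal site computed over the whole region;
Tajima's D and Fay & Wu's H per deme for the central ~65 kb section and the
combined ~120 kb flanks; the mean per-SNP F_ST per section; the focal derived
allele frequency in each deme; and the focal-site F_ST.  Records where the
focal allele is at frequency <= 5% in the non-African *test* deme are
excluded (the cross-population EHH contrast is undefined there); the same
filter is applied to observations and simulations, and the realized prior
after filtering is reported.

The statistics are Box-Cox transformed (per-statistic ML lambda after a shift
to positivity), standardized, and projected onto partial-least-squares
components fitted by regressing the model parameters (pooled across models,
with parameters absent under a model coded as zero) on the statistics.
Rejection keeps the nearest simulations in PLS space; model posterior
probabilities are retained-count proportions corrected for unequal simulation
counts per model, and the Bayes factor is the posterior odds of the best
model against all alternatives combined, BF = PP/(1-PP).
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cross_decomposition import PLSRegression

from .io_formats import HaplotypeMatrix
from .locus_simulator import (Demography, SelectionModelSpec, sample_prior,
                              simulate_locus)
from . import sumstats as ss

__all__ = [
    "STAT_NAMES",
    "PARAM_NAMES",
    "compute_sumstat_vector",
    "simulate_reference",
    "BoxCoxPlsTransform",
    "fit_transform",
    "rmse_per_component",
    "abc_reject",
    "ModelChoiceResult",
    "model_posterior",
    "parameter_posterior",
    "cross_validation_power",
    "run_halted_comparison",
    "default_n_retain",
]

STAT_NAMES = [
    "xpehh_core",
    "tajd_afr_center", "tajd_afr_flank", "tajd_na_center", "tajd_na_flank",
    "fwh_afr_center", "fwh_afr_flank", "fwh_na_center", "fwh_na_flank",
    "fst_center", "fst_flank",
    "daf_afr", "daf_na", "fst_focal",
]
PARAM_NAMES = ["t_sel", "s_A", "s_NA", "f_sel"]


def _section_columns(positions: np.ndarray, L: float, center_kb: float = 65_000.0):
    lo = L / 2 - center_kb / 2
    hi = L / 2 + center_kb / 2
    center = (positions >= lo) & (positions <= hi)
    return center, ~center


def _deme_section_stats(alleles: np.ndarray):
    """(Tajima's D, Fay & Wu's H) for one deme over one section's columns."""
    n = alleles.shape[0]
    counts = alleles.sum(axis=0)
    seg = (counts > 0) & (counts < n)
    S = int(seg.sum())
    if S == 0:
        return np.nan, 0.0
    pi = ss.nucleotide_diversity(alleles[:, seg])
    d = ss.tajimas_d(S, pi, n)
    sfs = np.bincount(counts[seg].astype(int), minlength=n)[1:n]
    h = ss.fay_wu_h(sfs, n)
    return d, h


def compute_sumstat_vector(matrix: HaplotypeMatrix, focal_site: int,
                           L: float = 185_000.0, center_kb: float = 65_000.0,
                           min_test_daf: float = 0.05,
                           ehh_cutoff: float = 0.05) -> dict:
    """The 14-statistic summary of one two-deme dataset.

    Returns a dict of named statistics plus ``excluded`` (True when the
    non-African focal frequency is <= ``min_test_daf`` or any statistic is
    undefined, e.g. a monomorphic section).
    """
    pops = sorted(set(matrix.population.tolist()))
    if len(pops) != 2:
        raise ValueError("summary vector requires exactly two demes")
    afr_label = "AFR" if "AFR" in pops else pops[0]
    na_label = [p for p in pops if p != afr_label][0]
    rows_afr = matrix.rows_for_population(afr_label)
    rows_na = matrix.rows_for_population(na_label)
    try:
        fcol = matrix.site_index(focal_site)
    except KeyError as e:
        raise KeyError(f"focal site {focal_site} missing from matrix") from e

    daf_afr = float(matrix.alleles[rows_afr, fcol].mean())
    daf_na = float(matrix.alleles[rows_na, fcol].mean())
    out = {"daf_afr": daf_afr, "daf_na": daf_na}
    excluded = daf_na <= min_test_daf

    # whole-region cross-population EHH contrast at the focal site
    flat_map = None
    from .io_formats import GeneticMap
    flat_map = GeneticMap([1.0, float(L)], [1.0, 1.0])
    m_na = matrix.subset_rows(rows_na)
    m_afr = matrix.subset_rows(rows_afr)
    if not excluded:
        t = ss._panel_ihh(m_na, focal_site, flat_map, ehh_cutoff)
        r = ss._panel_ihh(m_afr, focal_site, flat_map, ehh_cutoff)
        out["xpehh_core"] = math.log(t / r) if (t > 0 and r > 0) else np.nan
    else:
        out["xpehh_core"] = np.nan

    center, flank = _section_columns(matrix.positions, L, center_kb)
    for deme, rows in (("afr", rows_afr), ("na", rows_na)):
        for sec, cols in (("center", center), ("flank", flank)):
            d, h = _deme_section_stats(matrix.alleles[np.ix_(rows, np.flatnonzero(cols))])
            out[f"tajd_{deme}_{sec}"] = d
            out[f"fwh_{deme}_{sec}"] = h

    n_afr, n_na = len(rows_afr) // 2, len(rows_na) // 2
    p_afr = matrix.alleles[rows_afr].mean(axis=0)
    p_na = matrix.alleles[rows_na].mean(axis=0)
    for sec, cols in (("center", center), ("flank", flank)):
        sel = np.flatnonzero(cols)
        poly = sel[~(((p_afr[sel] == p_na[sel]) & ((p_afr[sel] == 0) | (p_afr[sel] == 1))))]
        if len(poly) == 0:
            out[f"fst_{sec}"] = np.nan
        else:
            a, abc_ = ss._wc_pair_components_vec(p_afr[poly], p_na[poly], n_afr, n_na)
            with np.errstate(invalid="ignore", divide="ignore"):
                theta = a / abc_
            out[f"fst_{sec}"] = float(np.nanmean(theta))
    out["fst_focal"] = ss.wc_fst_from_freqs(p_afr[fcol], p_na[fcol], n_afr, n_na).theta

    vec = np.array([out[k] for k in STAT_NAMES], dtype=float)
    out["excluded"] = bool(excluded or not np.all(np.isfinite(vec)))
    return out


def simulate_reference(models: Sequence[str], n_per_model: int,
                       demography: Demography, seed: int,
                       rescale_q: float = 50.0, L: float = 185_000.0,
                       gmap=None, mu: float = 1.25e-8,
                       n_hap=(122, 122)) -> pd.DataFrame:
    """Reference table: prior draws, simulations and summary vectors per model.

    Excluded records (focal test-deme frequency <= 5% or undefined statistics)
    are kept in the table with ``excluded=True`` so the realized prior can be
    reported; inference uses the included subset.
    """
    from .locus_simulator import simulate_trajectory

    rows = []
    rng = np.random.default_rng(seed)
    for model in models:
        for _ in range(n_per_model):
            spec = sample_prior(model, rng)
            try:
                traj = simulate_trajectory(spec, demography, rng)
                x_na = traj.freq[1, 0]
                # certain exclusion (test-deme frequency filter) is decidable
                # from the trajectory alone; skip the haplotype phase then
                n_test = n_hap[1]
                thresh = 0.05 * n_test
                if (not np.isfinite(x_na)) or x_na == 0.0 or (
                        sps.binom.sf(thresh, n_test, x_na) < 1e-9):
                    stats = {k: np.nan for k in STAT_NAMES}
                    stats["excluded"] = True
                else:
                    hm, focal = simulate_locus(
                        spec, demography, gmap=gmap, L=L, mu=mu, n_hap=n_hap,
                        rng=rng, rescale_q=rescale_q, trajectory=traj)
                    stats = compute_sumstat_vector(hm, focal, L=L)
            except RuntimeError:
                stats = {k: np.nan for k in STAT_NAMES}
                stats["excluded"] = True
            rows.append({
                "model": model, "t_sel": spec.t_sel, "s_A": spec.s_A,
                "s_NA": spec.s_NA, "f_sel": spec.f_sel, **stats,
            })
    return pd.DataFrame(rows)


@dataclasses.dataclass
class BoxCoxPlsTransform:
    stat_names: list
    shifts: np.ndarray
    lambdas: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    pls: PLSRegression
    n_components: int

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Z = np.empty_like(X)
        for j in range(X.shape[1]):
            x = np.clip(X[:, j] + self.shifts[j], 1e-9, None)
            lam = self.lambdas[j]
            z = np.log(x) if abs(lam) < 1e-9 else (x ** lam - 1.0) / lam
            Z[:, j] = (z - self.means[j]) / self.sds[j]
        return self.pls.transform(Z)


def fit_transform(reference: pd.DataFrame, n_components: int = 5,
                  stat_names: Sequence[str] = STAT_NAMES) -> BoxCoxPlsTransform:
    """Fit the Box-Cox + PLS transform on the included reference rows.

    Parameters absent under a model (e.g. selection coefficients under the
    neutral model) are coded zero in the PLS response.  Constant statistics
    are dropped with a warning.
    """
    inc = reference[~reference["excluded"]]
    if len(inc) < 100:
        raise ValueError("need at least 100 included reference rows")
    names = [s for s in stat_names if inc[s].std() > 0]
    dropped = set(stat_names) - set(names)
    if dropped:
        warnings.warn(f"dropping constant statistics {sorted(dropped)}")
    if len(names) < n_components:
        raise ValueError("fewer usable statistics than PLS components")
    X = inc[names].to_numpy(dtype=float)
    shifts = 1.0 - X.min(axis=0)
    lambdas = np.empty(X.shape[1])
    Z = np.empty_like(X)
    for j in range(X.shape[1]):
        x = X[:, j] + shifts[j]
        if np.ptp(x) < 1e-12:
            lambdas[j] = 1.0
            Z[:, j] = x
            continue
        zt, lam = sps.boxcox(x)
        lambdas[j] = lam
        Z[:, j] = zt
    means, sds = Z.mean(axis=0), Z.std(axis=0)
    sds[sds == 0] = 1.0
    Z = (Z - means) / sds
    Y = inc[PARAM_NAMES].to_numpy(dtype=float)
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(Z, Y)
    return BoxCoxPlsTransform(names, shifts, lambdas, means, sds, pls, n_components)


def rmse_per_component(reference: pd.DataFrame, max_components: int = 8,
                       test_fraction: float = 0.3, seed: int = 0) -> pd.DataFrame:
    """Held-out RMSE of linear parameter prediction from the first c components."""
    inc = reference[~reference["excluded"]].reset_index(drop=True)
    rng = np.random.default_rng(seed)
    n = len(inc)
    test = np.zeros(n, dtype=bool)
    test[rng.choice(n, size=max(int(test_fraction * n), 1), replace=False)] = True
    tr = fit_transform(inc[~test].reset_index(drop=True),
                       n_components=min(max_components, len(STAT_NAMES)))
    Ztr = tr.transform(inc.loc[~test, tr.stat_names].to_numpy(float))
    Zte = tr.transform(inc.loc[test, tr.stat_names].to_numpy(float))
    rows = []
    for p in PARAM_NAMES:
        ytr = inc.loc[~test, p].to_numpy(float)
        yte = inc.loc[test, p].to_numpy(float)
        for c in range(1, tr.n_components + 1):
            A = np.column_stack([np.ones((~test).sum()), Ztr[:, :c]])
            coef, *_ = np.linalg.lstsq(A, ytr, rcond=None)
            pred = np.column_stack([np.ones(test.sum()), Zte[:, :c]]) @ coef
            rows.append({"parameter": p, "n_components": c,
                         "rmse": float(np.sqrt(np.mean((pred - yte) ** 2)))})
    return pd.DataFrame(rows)


def default_n_retain(n_reference: int, fraction: float = 1e-3,
                     floor: int = 50) -> int:
    """Retained-simulation count: a fixed acceptance fraction with a floor.

    The fraction mirrors the full-scale design (1,000 of 10^6); the floor
    keeps posterior summaries usable when the table is scaled down.
    """
    return min(max(int(round(fraction * n_reference)), floor), n_reference)


def abc_reject(observed: Dict[str, float] | np.ndarray, reference: pd.DataFrame,
               transform: BoxCoxPlsTransform,
               n_retain: Optional[int] = None) -> pd.DataFrame:
    """Nearest reference simulations to the observation in PLS space.

    Distances are Euclidean over the PLS components; ties break by simulation
    index.  Returns the retained rows with a ``distance`` column.
    """
    inc = reference[~reference["excluded"]].reset_index(drop=True)
    if n_retain is None:
        n_retain = default_n_retain(len(inc))
    if n_retain > len(inc):
        raise ValueError("reference table smaller than n_retain")
    if isinstance(observed, dict):
        if observed.get("excluded"):
            raise ValueError("observation is excluded by the frequency filter")
        obs = np.array([observed[s] for s in transform.stat_names], dtype=float)
    else:
        obs = np.asarray(observed, dtype=float)
    zobs = transform.transform(obs[None, :])
    Z = transform.transform(inc[transform.stat_names].to_numpy(float))
    d = np.sqrt(((Z - zobs) ** 2).sum(axis=1))
    order = np.argsort(d, kind="stable")[:n_retain]
    out = inc.iloc[order].copy()
    out["distance"] = d[order]
    return out


@dataclasses.dataclass
class ModelChoiceResult:
    posterior: Dict[str, float]
    best_model: str
    bayes_factor: float
    n_retained: Dict[str, int]


def model_posterior(retained: pd.DataFrame,
                    prior_counts: Dict[str, int]) -> ModelChoiceResult:
    """Retained-count model posterior, corrected for unequal simulation counts.

    PP(m) ∝ retained_m / simulated_m (equal model priors); ``prior_counts``
    are the usable table rows per model — the counts after the frequency
    filter, mirroring a reference table filtered before inference.  The
    Bayes factor is PP(best)/(1 - PP(best)), infinite when everything
    retained comes from one model.
    """
    if len(retained) == 0:
        raise ValueError("empty retained set")
    if any(v <= 0 for v in prior_counts.values()):
        raise ValueError("every model needs a positive simulation count")
    counts = {m: int((retained["model"] == m).sum()) for m in prior_counts}
    raw = {m: counts[m] / prior_counts[m] for m in prior_counts}
    tot = sum(raw.values())
    pp = {m: (raw[m] / tot if tot > 0 else 1.0 / len(raw)) for m in raw}
    best = max(pp, key=pp.get)
    bf = pp[best] / (1.0 - pp[best]) if pp[best] < 1.0 else math.inf
    return ModelChoiceResult(pp, best, bf, counts)


def parameter_posterior(retained: pd.DataFrame, model: str,
                        params: Sequence[str] = ("t_sel", "s_NA", "f_sel"),
                        min_rows: int = 20) -> pd.DataFrame:
    """Rejection-posterior quantiles (2.5%, median, 97.5%) per parameter."""
    sub = retained[retained["model"] == model]
    rows = []
    for p in params:
        v = sub[p].to_numpy(float)
        if len(v) == 0:
            rows.append({"parameter": p, "median": np.nan, "q025": np.nan,
                         "q975": np.nan, "low_confidence": True})
            continue
        rows.append({
            "parameter": p,
            "median": float(np.median(v)),
            "q025": float(np.quantile(v, 0.025)),
            "q975": float(np.quantile(v, 0.975)),
            "low_confidence": len(v) < min_rows,
        })
    return pd.DataFrame(rows)


def _knn_assign(Z: np.ndarray, labels: np.ndarray, prior_counts: Dict[str, int],
                zobs: np.ndarray, n_retain: int, exclude_idx: int) -> str:
    d = np.sqrt(((Z - zobs) ** 2).sum(axis=1))
    d[exclude_idx] = np.inf
    order = np.argsort(d, kind="stable")[:n_retain]
    lab = labels[order]
    raw = {m: (lab == m).sum() / prior_counts[m] for m in prior_counts}
    return max(raw, key=raw.get)


def cross_validation_power(reference: pd.DataFrame, n_pseudo: int,
                           n_retain: Optional[int] = None,
                           transform: Optional[BoxCoxPlsTransform] = None,
                           seed: int = 0,
                           models: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Leave-one-out model-choice power on pseudo-observations from the table.

    Each pseudo-observation is a reference row, excluded from the reference
    when scored, and assigned to the model with the highest posterior
    probability.  Returns per-model TP/FP/FN counts and the correctly
    assigned fraction.
    """
    inc = reference[~reference["excluded"]].reset_index(drop=True)
    models = list(models or inc["model"].unique())
    prior_counts = {m: int((inc["model"] == m).sum()) for m in models}
    tr = transform or fit_transform(inc)
    Z = tr.transform(inc[tr.stat_names].to_numpy(float))
    labels = inc["model"].to_numpy()
    if n_retain is None:
        n_retain = default_n_retain(len(inc))
    rng = np.random.default_rng(seed)
    assigned = {m: {"TP": 0, "FP": 0, "FN": 0, "n": 0} for m in models}
    for m in models:
        idx = np.flatnonzero(labels == m)
        chosen = rng.choice(idx, size=min(n_pseudo, len(idx)), replace=False)
        for i in chosen:
            call = _knn_assign(Z, labels, prior_counts, Z[i], n_retain, i)
            assigned[m]["n"] += 1
            if call == m:
                assigned[m]["TP"] += 1
            else:
                assigned[m]["FN"] += 1
                assigned[call]["FP"] += 1
    rows = []
    for m in models:
        a = assigned[m]
        rows.append({"model": m, "TP": a["TP"], "FP": a["FP"], "FN": a["FN"],
                     "n_pseudo": a["n"],
                     "fraction_correct": a["TP"] / a["n"] if a["n"] else np.nan})
    return pd.DataFrame(rows)


def run_halted_comparison(reference: pd.DataFrame, observed: Dict[str, float],
                          n_retain: Optional[int] = None) -> Dict[str, ModelChoiceResult]:
    """Model choice over the halted set and over all five models.

    ``reference`` must contain the halted variants; raises otherwise.
    """
    models = set(reference["model"].unique())
    if not {"SDN_halted", "SSV_halted"} <= models:
        raise ValueError("reference lacks halted-model simulations")
    out = {}
    for key, subset in (
        ("halted", ["SDN_halted", "SSV_halted", "NTR"]),
        ("all", ["SDN", "SSV", "NTR", "SDN_halted", "SSV_halted"]),
    ):
        sub = reference[reference["model"].isin(subset)].reset_index(drop=True)
        if set(sub["model"].unique()) < set(s for s in subset if s in models):
            continue
        tr = fit_transform(sub)
        ret = abc_reject(observed, sub, tr, n_retain)
        sub_inc = sub[~sub["excluded"]]
        prior = {m: int((sub_inc["model"] == m).sum()) for m in subset if m in models}
        out[key] = model_posterior(ret, prior)
    return out
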