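"""Synthetic inputs with the statistical structure the pipeline assumes.

The generators stand in for the real sampling design — 20 populations of 61
diploid individuals (the 1000 Genomes-style panel) or 110 populations of two
individuals (an SGDP-style panel) — so that every downstream stage is testable
without downloads:

* a focal SNP whose logit population frequency is linear in latitude (and
  optionally temperature), with Balding–Nichols drift noise;
* unlinked genome-wide background SNPs under the same drift model, supplying
  empirical null distributions and the pairwise F_ST matrix;
* ancient diploid genotypes drawn from a user-supplied allele-frequency
  trajectory over an age range;
* a small country-level prevalence table linear in derived-allele frequency.

Balding–Nichols is used for drift because the F parameter maps analytically
onto expected F_ST, giving closed-form oracles.  Temperature defaults to a
noisy monotone-decreasing function of latitude, mirroring the real-world
collinearity the regression model set has to disentangle.

:func:`table1_fixture` returns transcribed published per-population values
(latitude, temperature, derived allele frequency, F_ST and empirical
P-values), the published AIC model-comparison columns, and the published ABC
Bayes factors and posterior summaries, packaged for regression tests.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .io_formats import GenotypeRecord, PopulationMeta
from .sumstats import pairwise_fst_matrix

__all__ = [
    "ClineScenario",
    "generate_cline_panel",
    "generate_background",
    "generate_ancient_samples",
    "generate_prevalence_table",
    "table1_fixture",
]

# Published per-population overview (latitude/longitude degrees, annual mean
# temperature °C, derived allele frequency at the focal SNP, F_ST to the
# reference population and empirical P-values).  NaN marks the published NA
# rules: the reference population has no F_ST to itself, XP-EHH is not
# computed within Africa, and iHS needs 0.05 < DAF < 0.95.
_TABLE1 = [
    # pop, continent, lat, lon, temp, daf, fst, fst_p, xpehh_p, ihs_p
    ("FIN", "EUR", 60.25, 24.75, 5.7, 0.87, 0.805, 0.0002, 0.205, 0.166),
    ("GBR", "EUR", 54.75, -1.25, 10.0, 0.80, 0.724, 0.0006, 0.287, 0.304),
    ("CEU", "EUR", 50.75, 4.25, 10.7, 0.82, 0.751, 0.0004, 0.228, 0.36),
    ("TSI", "EUR", 43.25, 11.25, 14.2, 0.84, 0.778, 0.0002, 0.26, 0.622),
    ("IBS", "EUR", 40.25, -3.25, 14.9, 0.80, 0.733, 0.0004, 0.291, 0.656),
    ("CHB", "EAS", 39.75, 116.25, 13.4, 0.39, 0.279, 0.0550, 0.939, 0.219),
    ("JPT", "EAS", 35.25, 139.25, 14.8, 0.45, 0.349, 0.0356, 0.947, 0.593),
    ("PJL", "SAS", 31.25, 74.25, 25.3, 0.57, 0.472, 0.0066, 0.651, 0.869),
    ("BEB", "SAS", 23.25, 90.25, 26.1, 0.52, 0.428, 0.0102, 0.605, 0.8),
    ("GIH", "SAS", 23.25, 72.75, 27.7, 0.53, 0.437, 0.0101, 0.587, 0.821),
    ("CHS", "EAS", 22.25, 114.25, 23.4, 0.36, 0.254, 0.0666, 0.927, 0.161),
    ("CDX", "EAS", 22.25, 100.25, 19.2, 0.30, 0.184, 0.1051, 0.895, 0.926),
    ("ITU", "SAS", 16.75, 80.75, 28.6, 0.39, 0.278, 0.0367, 0.804, 0.952),
    ("GWD", "AFR", 13.25, -16.25, 27.2, 0.06, -0.007, 0.8610, np.nan, 0.39),
    ("KHV", "EAS", 10.25, 106.25, 28.2, 0.30, 0.193, 0.0953, 0.938, 0.69),
    ("ESN", "AFR", 6.75, 6.25, 27.0, 0.04, -0.007, 0.8046, np.nan, np.nan),
    ("STU", "SAS", 9.25, 80.25, 28.5, 0.37, 0.262, 0.0411, 0.866, 0.626),
    ("MSL", "AFR", 7.75, -11.25, 26.6, 0.03, -0.005, 0.6836, np.nan, np.nan),
    ("YRI", "AFR", 7.25, 3.75, 27.6, 0.05, np.nan, np.nan, np.nan, 0.699),
    ("LWK", "AFR", 0.75, 34.75, 20.5, 0.07, -0.002, 0.6912, np.nan, 0.901),
]

# Published model-comparison AIC columns: (label, AIC, k), per analysis.
_TABLE2 = {
    "1KGP_PGLS": [("Null+Lat.", -49.43, 5), ("Null+Temp.+Lat.", -49.186, 6),
                  ("Null+Temp.", -44.147, 5), ("Null", -42.255, 4)],
    "1KGP_GLMM": [("Null+Temp.+Lat.", 1929.2, 6), ("Null+Lat.", 1929.3, 5),
                  ("Null+Temp.", 1939.8, 5), ("Null", 1946.2, 4)],
    # delta-AIC values as printed (the absolute AICs round to one decimal)
    "1KGP_GLMM_DELTAS": [("Null+Temp.+Lat.", 0.0, 6), ("Null+Lat.", 0.09, 5),
                         ("Null+Temp.", 10.633, 5), ("Null", 16.964, 4)],
    "SGDP_GLMM": [("Null+Temp.+Lat.", 435.206, 6), ("Null+Lat.", 440.841, 5),
                  ("Null+Temp.", 451.699, 5), ("Null", 452.458, 4)],
    "SGDP_EURASIA_GLMM": [("Null+Lat.", 301.301, 5), ("Null+Temp.+Lat.", 302.35, 6),
                          ("Null+Temp.", 305.874, 5), ("Null", 308.611, 4)],
}

# Published ABC results of the standing-variation model, per population:
# Bayes factor, posterior probability, and posterior median / 2.5% / 97.5%
# for t0 (years), s_NA (%), f_sel (%).  Transcribed verbatim.
_TABLE3 = [
    ("FIN", 9.6, 0.906, 35055, 22052, 49881, 1.238, 0.304, 2.430, 0.078, 0.010, 0.189),
    ("GBR", 588.3, 0.998, 29783, 21384, 49231, 1.352, 0.333, 2.456, 0.075, 0.012, 0.182),
    ("CEU", 474.8, 0.998, 31390, 21311, 49593, 1.453, 0.346, 2.425, 0.080, 0.012, 0.187),
    ("TSI", 23.3, 0.959, 36789, 22088, 50000, 1.418, 0.304, 2.446, 0.111, 0.018, 0.194),
    ("IBS", 17.5, 0.946, 32558, 21520, 49666, 1.209, 0.250, 2.409, 0.090, 0.012, 0.191),
    ("CHB", 81.8, 0.988, 24529, 21067, 47771, 0.270, 0.045, 0.693, 0.081, 0.008, 0.191),
    ("JPT", 25.8, 0.963, 25509, 21103, 48685, 0.269, 0.050, 0.734, 0.080, 0.008, 0.193),
    ("PJL", 70.0, 0.986, 25017, 21101, 48055, 0.378, 0.109, 2.100, 0.077, 0.006, 0.192),
    ("BEB", 7.4, 0.882, 26887, 21118, 48393, 0.293, 0.075, 0.713, 0.082, 0.006, 0.193),
    ("GIH", 17.4, 0.946, 26298, 21122, 48234, 0.314, 0.087, 0.836, 0.079, 0.006, 0.192),
    ("CHS", 220.9, 0.996, 24407, 21047, 47586, 0.271, 0.049, 0.711, 0.079, 0.007, 0.189),
    ("CDX", 4.6, 0.823, 26438, 21088, 47862, 0.234, 0.033, 1.103, 0.075, 0.005, 0.187),
    ("ITU", 10.6, 0.914, 26297, 21100, 48424, 0.249, 0.041, 0.991, 0.073, 0.005, 0.189),
    ("KHV", 3.1, 0.755, 26399, 21110, 48452, 0.204, 0.025, 1.041, 0.075, 0.005, 0.186),
    ("STU", 14.4, 0.935, 26024, 21097, 48491, 0.249, 0.041, 0.009, 0.071, 0.005, 0.188),
]


def table1_fixture():
    """Published per-population overview, AIC lists and ABC columns.

    Returns
    -------
    metas : list of PopulationMeta (with ``daf`` filled)
    scan : pandas.DataFrame with the published F_ST and empirical P columns
    aic_tables : dict of analysis -> list of (model label, AIC, k)
    abc : pandas.DataFrame with Bayes factor, posterior probability and
        posterior medians / 95% intervals for the standing-variation model
    """
    metas = [
        PopulationMeta(name=p, latitude=lat, longitude=lon, temperature=t,
                       n_individuals=61, fst_to_reference=fst, daf=daf,
                       continent=cont)
        for p, cont, lat, lon, t, daf, fst, *_ in _TABLE1
    ]
    scan = pd.DataFrame(
        _TABLE1,
        columns=["population", "continent", "latitude", "longitude",
                 "temperature", "daf", "fst", "fst_p", "xpehh_p", "ihs_p"],
    )
    abc = pd.DataFrame(
        _TABLE3,
        columns=["population", "bayes_factor", "posterior_probability",
                 "t0_median", "t0_q025", "t0_q975",
                 "s_na_median", "s_na_q025", "s_na_q975",
                 "f_sel_median", "f_sel_q025", "f_sel_q975"],
    )
    return metas, scan, dict(_TABLE2), abc


def _default_latitudes(n_pops: int) -> np.ndarray:
    if n_pops == 20:
        return np.array([row[2] for row in _TABLE1])
    return np.linspace(0.75, 60.25, n_pops)


@dataclasses.dataclass
class ClineScenario:
    """Sampling design and effect sizes for the synthetic focal-SNP panel.

    Defaults follow the study design the generators emulate: 20 populations
    of 61 diploid individuals spanning latitudes 0.75°–60.25°, temperature a
    noisy decreasing function of latitude, logit-scale latitude effect of 1
    per z-unit, and a per-population Balding–Nichols drift parameter of 0.05
    (a typical between-continent human F_ST scale).
    """

    n_pops: int = 20
    n_individuals: int = 61
    latitudes: Optional[np.ndarray] = None
    temperatures: Optional[np.ndarray] = None
    beta_lat: float = 1.0
    beta_temp: float = 0.0
    base_logit: float = 0.0
    drift_fst: float = 0.05
    n_background_snps: int = 10_000
    temp_noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.drift_fst < 1.0:
            raise ValueError("drift_fst must be in [0, 1)")
        if self.n_individuals < 2:
            raise ValueError("need at least 2 individuals per population")
        if self.latitudes is None:
            self.latitudes = _default_latitudes(self.n_pops)
        self.latitudes = np.asarray(self.latitudes, dtype=float)
        if len(self.latitudes) != self.n_pops:
            raise ValueError("latitudes length must equal n_pops")
        if self.temperatures is not None:
            self.temperatures = np.asarray(self.temperatures, dtype=float)

    def realized_temperatures(self, rng: np.random.Generator) -> np.ndarray:
        if self.temperatures is not None:
            return self.temperatures
        # annual mean cooling ~0.4 °C per degree latitude, plus local noise
        return 28.0 - 0.4 * self.latitudes + rng.normal(0, self.temp_noise_sd, self.n_pops)


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    return (v - v.mean()) / sd if sd > 0 else v * 0.0


def _balding_nichols(rng: np.random.Generator, p, F):
    """Population frequency draw: Beta(p(1-F)/F, (1-p)(1-F)/F); F -> 0 is no drift."""
    p = np.asarray(p, dtype=float)
    if F < 1e-9:
        return p.copy()
    a = p * (1 - F) / F
    b = (1 - p) * (1 - F) / F
    return rng.beta(np.clip(a, 1e-9, None), np.clip(b, 1e-9, None))


def generate_cline_panel(scenario: ClineScenario):
    """Focal-SNP diploid genotypes whose logit frequency is linear in latitude.

    Population frequency: p_j = expit(base + beta_lat·z(lat_j) +
    beta_temp·z(temp_j)) perturbed by a Balding–Nichols draw with parameter
    ``drift_fst``; genotypes are Binomial(2, p_j) per individual.

    Returns (records, metas): per-individual :class:`GenotypeRecord` rows and
    per-population :class:`PopulationMeta` (``fst_to_reference`` prefilled
    with the drift parameter as a generator-level ancestry covariate; the
    pipeline replaces it with the realized genome-wide value when background
    SNPs are generated).
    """
    rng = np.random.default_rng(scenario.seed)
    lat = scenario.latitudes
    temp = scenario.realized_temperatures(rng)
    eta = (scenario.base_logit
           + scenario.beta_lat * _zscore(lat)
           + scenario.beta_temp * _zscore(temp))
    p_mean = expit(eta)
    p = _balding_nichols(rng, p_mean, scenario.drift_fst)
    p = np.clip(p, 1e-6, 1 - 1e-6)
    records, metas = [], []
    for j in range(scenario.n_pops):
        name = f"P{j:02d}"
        geno = rng.binomial(2, p[j], size=scenario.n_individuals)
        for i, g in enumerate(geno):
            records.append(GenotypeRecord(
                individual_id=f"{name}_{i:03d}", population=name,
                derived_count=int(g), ancestral_count=2 - int(g),
                latitude=lat[j], longitude=0.0, temperature=temp[j],
            ))
        metas.append(PopulationMeta(
            name=name, latitude=lat[j], longitude=0.0, temperature=temp[j],
            n_individuals=scenario.n_individuals,
            fst_to_reference=scenario.drift_fst,
            daf=float(geno.mean() / 2),
        ))
    return records, metas


def generate_background(scenario: ClineScenario):
    """Unlinked neutral background SNP frequencies under Balding–Nichols drift.

    Each SNP draws an ancestral frequency from U(0.05, 0.95) and independent
    per-population Balding–Nichols frequencies with parameter ``drift_fst``.

    Returns
    -------
    freqs : DataFrame (populations x SNPs) of population frequencies
    fst_matrix : realized pairwise ratio-of-averages F_ST matrix
    """
    rng = np.random.default_rng(scenario.seed + 1)
    anc = rng.uniform(0.05, 0.95, scenario.n_background_snps)
    freqs = np.empty((scenario.n_pops, scenario.n_background_snps))
    for j in range(scenario.n_pops):
        freqs[j] = _balding_nichols(rng, anc, scenario.drift_fst)
    pops = [f"P{j:02d}" for j in range(scenario.n_pops)]
    fst = pairwise_fst_matrix(freqs, np.full(scenario.n_pops, scenario.n_individuals))
    return pd.DataFrame(freqs, index=pops), pd.DataFrame(fst, index=pops, columns=pops)


def generate_ancient_samples(
    n: int,
    age_range=(3000.0, 8500.0),
    trajectory: Callable[[float], float] = lambda age: 0.7,
    latitude_range=(38.0, 62.0),
    missing_rate: float = 0.0,
    seed: int = 0,
) -> list:
    """Ancient diploid genotypes: genotype ~ Binomial(2, trajectory(age)).

    Ages and latitudes are uniform over their ranges; a ``missing_rate``
    fraction of samples is flagged missing (genotype unusable but row kept).
    """
    rng = np.random.default_rng(seed)
    ages = rng.uniform(*age_range, n)
    lats = rng.uniform(*latitude_range, n)
    out = []
    for i in range(n):
        p = float(np.clip(trajectory(ages[i]), 0.0, 1.0))
        miss = bool(rng.random() < missing_rate)
        g = int(rng.binomial(2, p))
        out.append(GenotypeRecord(
            individual_id=f"anc{i:03d}", population="ancient",
            derived_count=0 if miss else g, ancestral_count=2 if miss else 2 - g,
            latitude=float(lats[i]), longitude=0.0,
            temperature=np.nan, age_years=float(ages[i]), missing=miss,
        ))
    return out


def generate_prevalence_table(n_countries: int, daf_values: Sequence[float],
                              slope: float, noise_sd: float, seed: int = 0,
                              intercept: float = 0.05) -> pd.DataFrame:
    """Country-level table: prevalence = intercept + slope·DAF + noise, clipped to [0,1]."""
    rng = np.random.default_rng(seed)
    daf = np.asarray(daf_values, dtype=float)
    if len(daf) != n_countries:
        raise ValueError("daf_values length must equal n_countries")
    if np.any((daf < 0) | (daf > 1)):
        raise ValueError("DAF values must lie in [0, 1]")
    prev = np.clip(intercept + slope * daf + rng.normal(0, noise_sd, n_countries), 0.0, 1.0)
    return pd.DataFrame({
        "country": [f"C{i:02d}" for i in range(n_countries)],
        "daf": daf, "prevalence": prev,
    })
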