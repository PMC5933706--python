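"""Two-population haplotype simulation of a 185 kb locus under selection models.

Simulates an African and one non-African (European or East-Asian branch)
population under an out-of-Africa demography (ancestral expansion, bottleneck,
split with exponential growth and migration; parameter values follow the
standard three-population inference of Gravel and colleagues, collapsed to the
two sampled demes), with a focal allele evolving under one of five models:

* ``SDN`` — selection on a de novo mutation: the allele is born as a single
  copy 30–60 kya in Africa and is immediately advantageous (s_A in Africa,
  s_NA outside).
* ``SSV`` — selection on standing variation: a previously neutral allele at
  frequency f_sel becomes advantageous (s_NA, non-African deme only) at t_sel,
  between the out-of-Africa migration and the European–Asian split.
* ``NTR`` — fully neutral; the allele is born as in SDN with s = 0.
* ``SDN_halted`` / ``SSV_halted`` — as above, but selection ceases
  ``halt_age`` (default 3,000) years ago.

Engine
------
The allele-frequency trajectory is simulated per (unscaled) generation by
Wright–Fisher binomial sampling with additive fitness (1, 1+hs, 1+s; h=0.5)
and migration; trajectories losing the allele before the present are rejected
and redrawn.  Haplotypes are then generated by a rescaled forward
Wright–Fisher simulation *conditioned on that trajectory*: msprime provides
the whole-population neutral standing variation at the start of the
conditioned phase under the (rescaled) demography, and the forward engine
evolves the population to the present, fixing the focal-allele count in each
deme to the trajectory.  Because conditioning carries all the selection
information, the selection coefficient never enters the rescaled engine and
the usual s·Q constraint of rescaled forward simulation does not arise.

Recombination hotspots are handled by the extension trick: intervals with
rate above a threshold are replaced by proportionally longer stretches at the
baseline rate (total genetic length conserved); the inserted excess
contributes recombination but is masked for mutation, and surviving
coordinates are projected back onto the physical frame.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional, Sequence

import msprime
import numpy as np
from numba import njit

from .io_formats import GeneticMap, HaplotypeMatrix

__all__ = [
    "Demography",
    "gravel_demography",
    "SelectionModelSpec",
    "Trajectory",
    "sample_prior",
    "simulate_trajectory",
    "ExtendedMap",
    "apply_hotspot_extension",
    "simulate_locus",
    "MODELS",
]

MODELS = ("SDN", "SSV", "NTR", "SDN_halted", "SSV_halted")

_PRIORS = {
    # model -> (t_sel low/high in years, ...)
    "SDN": dict(t=(30_000, 60_000), s_A=(0.0, 0.015), s_NA=(0.005, 0.05)),
    "SSV": dict(t=(21_000, 51_000), f_sel=(0.0, 0.20), s_NA=(0.0, 0.05)),
    "NTR": dict(t=(30_000, 60_000)),
}


@dataclasses.dataclass
class Demography:
    """Two-sampled-deme out-of-Africa demography (diploid sizes, years).

    The non-African deme is the out-of-Africa bottleneck population until the
    European–Asian split, then the chosen daughter branch with exponential
    growth.  ``constant(N)`` gives a single constant-size deme for
    closed-form neutral checks.
    """

    generation_time: float = 25.0
    N_anc: int = 7310
    N_af: int = 14474
    t_af_years: float = 148_000.0
    N_b: int = 1861
    t_ooa_years: float = 51_000.0
    N_daughter0: int = 1032
    growth_rate: float = 0.0038       # per generation
    t_split_years: float = 23_000.0
    m_ooa: float = 15e-5              # per generation, AFR <-> bottleneck deme
    m_daughter: float = 2.5e-5        # per generation, AFR <-> daughter deme
    branch: str = "EUR"
    single_deme: bool = False

    @classmethod
    def constant(cls, N: int) -> "Demography":
        return cls(N_anc=N, N_af=N, t_af_years=1e12, single_deme=True)

    def gens(self, years: float) -> float:
        return years / self.generation_time

    @property
    def t_af(self) -> float:
        return self.gens(self.t_af_years)

    @property
    def t_ooa(self) -> float:
        return self.gens(self.t_ooa_years)

    @property
    def t_split(self) -> float:
        return self.gens(self.t_split_years)

    def size_afr(self, t_gens_ago: float) -> float:
        return float(self.N_af if t_gens_ago < self.t_af else self.N_anc)

    def size_nonafr(self, t_gens_ago: float) -> Optional[float]:
        """Diploid size of the non-African deme, or None before it exists."""
        if self.single_deme or t_gens_ago >= self.t_ooa:
            return None
        if t_gens_ago >= self.t_split:
            return float(self.N_b)
        return float(self.N_daughter0 * math.exp(self.growth_rate * (self.t_split - t_gens_ago)))

    def migration(self, t_gens_ago: float) -> float:
        if self.single_deme or t_gens_ago >= self.t_ooa:
            return 0.0
        return self.m_ooa if t_gens_ago >= self.t_split else self.m_daughter

    def arrays(self, t_max: int):
        """Vectorized (2N_af, 2N_na, m) per generation ago for t = 0..t_max."""
        t = np.arange(t_max + 1, dtype=float)
        N2_af = np.where(t < self.t_af, 2 * self.N_af, 2 * self.N_anc).astype(np.int64)
        if self.single_deme:
            N2_na = np.zeros(t_max + 1, dtype=np.int64)
            mig = np.zeros(t_max + 1)
        else:
            grown = 2 * self.N_daughter0 * np.exp(
                self.growth_rate * np.clip(self.t_split - t, 0, None))
            N2_na = np.where(t >= self.t_ooa, 0,
                             np.where(t >= self.t_split, 2 * self.N_b, grown)
                             ).astype(np.int64)
            mig = np.where(t >= self.t_ooa, 0.0,
                           np.where(t >= self.t_split, self.m_ooa, self.m_daughter))
        return N2_af, N2_na, mig


def gravel_demography(branch: str = "EUR") -> Demography:
    """Out-of-Africa demography for the chosen daughter branch.

    Branches differ only in the daughter deme's founding size, growth rate
    and migration rate with Africa.
    """
    if branch == "EUR":
        return Demography(branch="EUR", N_daughter0=1032, growth_rate=0.0038,
                          m_daughter=2.5e-5)
    if branch == "EAS":
        return Demography(branch="EAS", N_daughter0=554, growth_rate=0.0048,
                          m_daughter=0.78e-5)
    raise ValueError("branch must be 'EUR' or 'EAS'")


@dataclasses.dataclass
class SelectionModelSpec:
    """Model identity and parameters of the focal allele's history."""

    model: str
    t_sel: float                     # years ago: allele birth (SDN/NTR) or onset (SSV)
    s_A: float = 0.0                 # selection coefficient in Africa (SDN only)
    s_NA: float = 0.0                # selection coefficient outside Africa
    f_sel: float = 0.0               # standing frequency at onset (SSV only)
    halt_age: float = 0.0            # years ago selection ceases (halted variants)
    h: float = 0.5
    # SSV standing allele at onset: "both" demes at f_sel, or "africa" only
    # (the non-African deme then acquires the allele by migration)
    ssv_standing: str = "both"

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model}")
        for s in (self.s_A, self.s_NA):
            if not 0.0 <= s <= 0.05:
                raise ValueError("selection coefficients must lie in [0, 0.05]")
        if self.model.startswith("SSV") and not 0.0 < self.f_sel <= 0.2:
            raise ValueError("f_sel must lie in (0, 0.2]")

    @property
    def base_model(self) -> str:
        return self.model.split("_")[0]

    @property
    def halted(self) -> bool:
        return self.model.endswith("_halted")


def sample_prior(model: str, rng: np.random.Generator) -> SelectionModelSpec:
    """Draw model parameters from the uniform priors.

    SDN: t ~ U(30, 60) kya, s_A ~ U(0, 1.5%), s_NA ~ U(0.5%, 5%);
    SSV: t ~ U(21, 51) kya, f_sel ~ U(0, 20%), s_NA ~ U(0, 5%];
    NTR: t ~ U(30, 60) kya, neutral.  Halted variants add halt_age = 3,000 y.
    """
    base = model.split("_")[0]
    if base not in _PRIORS:
        raise ValueError(f"unknown model {model}")
    pr = _PRIORS[base]
    t = rng.uniform(*pr["t"])
    kw = dict(model=model, t_sel=t, halt_age=3000.0 if model.endswith("_halted") else 0.0)
    if base == "SDN":
        kw["s_A"] = rng.uniform(*pr["s_A"])
        kw["s_NA"] = rng.uniform(*pr["s_NA"])
    elif base == "SSV":
        f = 0.0
        while f <= 0.0:
            f = rng.uniform(*pr["f_sel"])
        s = 0.0
        while s <= 0.0:
            s = rng.uniform(*pr["s_NA"])
        kw["f_sel"] = f
        kw["s_NA"] = s
    return SelectionModelSpec(**kw)


@dataclasses.dataclass
class Trajectory:
    """Per-deme derived-allele frequency per (unscaled) generation ago.

    ``freq`` has shape (2, birth_gen + 1): row 0 Africa, row 1 the
    non-African deme (NaN where it does not yet exist); column t is the
    frequency t generations before the present.
    """

    freq: np.ndarray
    birth_gen: int
    onset_gen: int
    model: str
    n_rejected: int = 0

    def at(self, deme: int, t_gens_ago: float) -> float:
        t = int(min(round(t_gens_ago), self.birth_gen))
        return float(self.freq[deme, t])


def _sel_step(p: float, s: float, h: float) -> float:
    """One generation of deterministic selection, fitnesses (1, 1+hs, 1+s)."""
    if s == 0.0 or p in (0.0, 1.0):
        return p
    w1 = (1 - p) * (1 + h * s) + p * (1 + s)
    wbar = 1 + 2 * p * (1 - p) * h * s + p * p * s
    return p * w1 / wbar


@njit(cache=True)
def _reverse_kernel(f0, N2_af, N2_anc, t_af_minus_onset, max_len, seed):
    """Neutral absorption path from f0 into the past (African deme sizes)."""
    np.random.seed(seed)
    path = np.empty(max_len + 1)
    path[0] = f0
    y = f0
    k = 0
    while y > 0.0 and k < max_len:
        k += 1
        N2 = N2_af if k < t_af_minus_onset else N2_anc
        y = np.random.binomial(N2, y) / N2
        path[k] = y
    return path[:k + 1], y == 0.0


def _reverse_neutral_path(f0: float, demography: Demography,
                          onset_gen: int, rng, max_len: int = 200_000):
    """Neutral frequency path back from f0 at onset until loss into the past.

    Time-reversed neutral Wright–Fisher in the African deme: simulate
    absorption at zero from f0 with the deme sizes at increasing ages; the
    reversed path serves as the pre-onset standing-variation history.
    """
    N2_af = int(2 * demography.size_afr(onset_gen))
    N2_anc = int(2 * demography.N_anc)
    t_rel = max(int(demography.t_af) - onset_gen, 0)
    for _ in range(1000):
        path, lost = _reverse_kernel(f0, N2_af, N2_anc, t_rel, max_len,
                                     int(rng.integers(1, 2 ** 31 - 2)))
        if lost:
            return path
    raise RuntimeError("reverse neutral path failed to reach loss")


@njit(cache=True)
def _wf_kernel(freq, start_t, N2_af, N2_na, mig, s_af, s_na, h,
               deterministic, seed):
    """Forward Wright–Fisher step loop from start_t-1 down to the present.

    ``freq`` is the (2, T+1) trajectory array with initial conditions already
    set at start_t..T; N2_na[t] == 0 marks the non-African deme absent.
    Returns True when the allele is lost in every existing deme.
    """
    np.random.seed(seed)
    for t in range(start_t - 1, -1, -1):
        p_af = freq[0, t + 1]
        na_now = N2_na[t] > 0
        na_prev = N2_na[t + 1] > 0
        p_na = freq[1, t + 1] if na_prev else 0.0
        m = mig[t]
        if na_now and not na_prev:
            p_na = p_af  # founding of the non-African deme
        # Africa
        q = (1 - m) * p_af + m * p_na if na_now else p_af
        s = s_af[t]
        if s > 0.0 and 0.0 < q < 1.0:
            w1 = (1 - q) * (1 + h * s) + q * (1 + s)
            wbar = 1 + 2 * q * (1 - q) * h * s + q * q * s
            q = q * w1 / wbar
        freq[0, t] = q if deterministic else np.random.binomial(N2_af[t], q) / N2_af[t]
        # non-Africa
        if na_now:
            q = (1 - m) * p_na + m * p_af
            s = s_na[t]
            if s > 0.0 and 0.0 < q < 1.0:
                w1 = (1 - q) * (1 + h * s) + q * (1 + s)
                wbar = 1 + 2 * q * (1 - q) * h * s + q * q * s
                q = q * w1 / wbar
            freq[1, t] = q if deterministic else np.random.binomial(N2_na[t], q) / N2_na[t]
        else:
            freq[1, t] = np.nan
        tot = freq[0, t] + (freq[1, t] if na_now else 0.0)
        if tot == 0.0:
            return True
    return False


@njit(cache=True)
def _wf_reject_kernel(freq, start_t, N2_af, N2_na, mig, s_af, s_na, h,
                      max_rej, seed):
    """Repeat the step loop until a trajectory survives; returns the number of
    rejected attempts, or -1 when ``max_rej`` is exhausted."""
    np.random.seed(seed)
    for attempt in range(max_rej):
        lost = False
        for t in range(start_t - 1, -1, -1):
            p_af = freq[0, t + 1]
            na_now = N2_na[t] > 0
            na_prev = N2_na[t + 1] > 0
            p_na = freq[1, t + 1] if na_prev else 0.0
            m = mig[t]
            if na_now and not na_prev:
                p_na = p_af
            q = (1 - m) * p_af + m * p_na if na_now else p_af
            s = s_af[t]
            if s > 0.0 and 0.0 < q < 1.0:
                w1 = (1 - q) * (1 + h * s) + q * (1 + s)
                wbar = 1 + 2 * q * (1 - q) * h * s + q * q * s
                q = q * w1 / wbar
            freq[0, t] = np.random.binomial(N2_af[t], q) / N2_af[t]
            if na_now:
                q = (1 - m) * p_na + m * p_af
                s = s_na[t]
                if s > 0.0 and 0.0 < q < 1.0:
                    w1 = (1 - q) * (1 + h * s) + q * (1 + s)
                    wbar = 1 + 2 * q * (1 - q) * h * s + q * q * s
                    q = q * w1 / wbar
                freq[1, t] = np.random.binomial(N2_na[t], q) / N2_na[t]
            else:
                freq[1, t] = np.nan
            tot = freq[0, t] + (freq[1, t] if na_now else 0.0)
            if tot == 0.0:
                lost = True
                break
        if not lost:
            return attempt
    return -1


def simulate_trajectory(spec: SelectionModelSpec, demography: Demography,
                        rng: np.random.Generator,
                        deterministic: bool = False,
                        max_rejections: int = 100_000) -> Trajectory:
    """Per-generation allele-frequency trajectory under the model.

    Forward Wright–Fisher binomial sampling with selection and migration;
    SSV builds the pre-onset history backward from f_sel under neutrality.
    Trajectories losing the allele in every deme before the present are
    rejected and redrawn (the rejection count is recorded).
    """
    gens = demography.gens
    halt_gen = int(round(gens(spec.halt_age))) if spec.halted else -1
    n_rej = 0
    size_cache = {}

    def deme_arrays(birth, onset):
        key = birth
        if key not in size_cache:
            size_cache[key] = demography.arrays(birth)
        N2_af, N2_na, mig = size_cache[key]
        sel_on = np.ones(birth + 1, dtype=bool)
        if spec.halted:
            sel_on[:halt_gen] = False
        s_af = np.where(sel_on, spec.s_A if spec.base_model == "SDN" else 0.0, 0.0)
        t_arr = np.arange(birth + 1)
        s_na = np.where(sel_on & (t_arr <= onset), spec.s_NA, 0.0)
        return N2_af, N2_na, mig, s_af, s_na

    while True:
        if spec.base_model == "SSV":
            onset = int(round(gens(spec.t_sel)))
            pre = _reverse_neutral_path(spec.f_sel, demography, onset, rng) \
                if not deterministic else np.array([spec.f_sel, 0.0])
            birth = onset + len(pre) - 1
        else:
            birth = int(round(gens(spec.t_sel)))
            onset = birth
            pre = None
        freq = np.full((2, birth + 1), np.nan)
        N2_af, N2_na, mig, s_af, s_na = deme_arrays(birth, onset)
        if pre is not None:
            freq[0, onset:birth + 1] = pre[:birth - onset + 1]
            exists = N2_na[onset:birth + 1] > 0
            na_pre = pre[:birth - onset + 1] if spec.ssv_standing == "both" else 0.0
            freq[1, onset:birth + 1] = np.where(exists, na_pre, np.nan)
            start_t = onset
        else:
            # de novo birth: in the selected (non-African) deme once it
            # exists, otherwise in the ancestral African deme
            if N2_na[birth] > 0:
                freq[0, birth] = 0.0
                freq[1, birth] = 1.0 / N2_na[birth]
            else:
                freq[0, birth] = 1.0 / N2_af[birth]
                freq[1, birth] = np.nan
            start_t = birth
        if deterministic:
            lost = _wf_kernel(freq, start_t, N2_af, N2_na, mig, s_af, s_na,
                              spec.h, True, int(rng.integers(1, 2 ** 31 - 2)))
            if lost:
                raise RuntimeError("deterministic trajectory lost the allele")
            return Trajectory(freq, birth, onset, spec.model, 0)
        # SSV redraws the pre-onset path per attempt; SDN/NTR initial
        # conditions are fixed, so the whole rejection loop can run jitted
        budget = 1 if pre is not None else max(max_rejections - n_rej, 1)
        rej = _wf_reject_kernel(freq, start_t, N2_af, N2_na, mig, s_af, s_na,
                                spec.h, budget, int(rng.integers(1, 2 ** 31 - 2)))
        if rej >= 0:
            return Trajectory(freq, birth, onset, spec.model, n_rej + rej)
        n_rej += budget
        if n_rej >= max_rejections:
            raise RuntimeError(
                f"allele lost in {n_rej} consecutive trajectories for {spec}"
            )


# ---------------------------------------------------------------------------
# Hotspot extension
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ExtendedMap:
    """Uniform-rate coordinate frame with hotspots stretched and masked.

    ``segments`` rows: (orig_start, ext_start, ext_len, scale, masked) where
    ``scale`` maps extended offsets back to physical offsets (0 for masked
    excess).  Lengths are kept as floats so genetic length is conserved
    exactly.
    """

    L: float
    L_ext: float
    rho0: float                       # baseline rate, cM/Mb
    segments: np.ndarray
    masked: np.ndarray                # (start, end) intervals in extended coords

    @property
    def genetic_length_cm(self) -> float:
        return self.L_ext * self.rho0 / 1e6

    @property
    def unmasked_length(self) -> float:
        return self.L_ext - sum(e - s for s, e in self.masked)

    def project(self, ext_pos) -> np.ndarray:
        """Extended -> physical coordinates (masked positions -> NaN)."""
        ext_pos = np.atleast_1d(np.asarray(ext_pos, dtype=float))
        out = np.full_like(ext_pos, np.nan)
        for orig_start, ext_start, ext_len, scale, masked in self.segments:
            sel = (ext_pos >= ext_start) & (ext_pos < ext_start + ext_len)
            if masked:
                continue
            out[sel] = orig_start + (ext_pos[sel] - ext_start) * scale
        return out

    def lift(self, pos) -> np.ndarray:
        """Physical -> extended coordinates."""
        pos = np.atleast_1d(np.asarray(pos, dtype=float))
        out = np.full_like(pos, np.nan)
        for orig_start, ext_start, ext_len, scale, masked in self.segments:
            if masked or scale == 0:
                continue
            orig_len = ext_len * scale
            sel = (pos >= orig_start) & (pos <= orig_start + orig_len)
            out[sel] = ext_start + (pos[sel] - orig_start) / scale
        return out

    def sample_unmasked(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Uniform positions (extended coords) outside masked intervals."""
        segs = self.segments[self.segments[:, 4] == 0]
        lens = segs[:, 2]
        which = rng.choice(len(segs), size=n, p=lens / lens.sum())
        return segs[which, 1] + rng.random(n) * segs[which, 2]


def apply_hotspot_extension(gmap: Optional[GeneticMap], L: float,
                            threshold: float = 5.0) -> ExtendedMap:
    """Replace hotspots (rate > ``threshold`` cM/Mb) by baseline-rate stretches.

    Each hotspot of physical length l and rate rho_h becomes a stretch of
    length l·rho_h/rho0 at the baseline rate rho0 (the mean rate across the
    locus excluding hotspots); total genetic length is conserved, the
    inserted excess is masked for mutation, and surviving coordinates project
    back onto [0, L].  With no map (or no hotspots) the projection is the
    identity.
    """
    if gmap is None:
        seg = np.array([[0.0, 0.0, float(L), 1.0, 0.0]])
        return ExtendedMap(float(L), float(L), 1.3, seg, np.empty((0, 2)))
    lo = gmap.positions[0]
    breaks = np.unique(np.concatenate([gmap.positions - lo, [0.0, float(L)]]))
    breaks = breaks[(breaks >= 0) & (breaks <= L)]
    starts, ends = breaks[:-1], breaks[1:]
    rates = gmap.rate_at(starts + lo)
    hot = rates > threshold
    base_len = (ends - starts)[~hot].sum()
    if base_len == 0:
        raise ValueError("entire locus is hotspot; no baseline rate")
    rho0 = float(((ends - starts) * rates)[~hot].sum() / base_len)
    if rho0 == 0 and hot.any():
        raise ValueError("baseline rate is zero but hotspots are present")
    segments, masked = [], []
    ext_cursor = 0.0
    for s, e, r, is_hot in zip(starts, ends, rates, hot):
        phys_len = e - s
        if not is_hot:
            segments.append([s, ext_cursor, phys_len, 1.0, 0.0])
            ext_cursor += phys_len
        else:
            ext_len = phys_len * r / rho0
            # real sequence first (identity scale), excess masked after it
            segments.append([s, ext_cursor, phys_len, 1.0, 0.0])
            ext_cursor += phys_len
            excess = ext_len - phys_len
            if excess > 0:
                segments.append([e, ext_cursor, excess, 0.0, 1.0])
                masked.append([ext_cursor, ext_cursor + excess])
                ext_cursor += excess
    return ExtendedMap(float(L), ext_cursor, rho0, np.array(segments),
                       np.array(masked) if masked else np.empty((0, 2)))


# ---------------------------------------------------------------------------
# Rescaled, trajectory-conditioned forward engine
# ---------------------------------------------------------------------------

def _rescaled_sizes(demography: Demography, t_gens: float, Q: float):
    na = demography.size_nonafr(t_gens)
    n_af = max(int(round(2 * demography.size_afr(t_gens) / Q)), 4)
    n_na = 0 if na is None else max(int(round(2 * na / Q)), 4)
    return n_af, n_na


def _msprime_init(demography: Demography, t_start: float, Q: float,
                  ext: ExtendedMap, mu: float, seed: int):
    """Whole-population standing variation at the start of the conditioned phase.

    Builds the rescaled demography as seen from t_start backwards and samples
    every (rescaled) chromosome in each existing deme.
    """
    n_af, n_na = _rescaled_sizes(demography, t_start, Q)
    dem = msprime.Demography()
    dem.add_population(name="AFR", initial_size=n_af / 2)
    t_anc = max((demography.t_af - t_start) / Q, 1e-9)
    dem.add_population_parameters_change(time=t_anc, population="AFR",
                                         initial_size=max(demography.N_anc / Q, 2))
    samples = [msprime.SampleSet(n_af // 2, population="AFR", time=0)]
    if n_na > 0:
        growth = 0.0
        if t_start < demography.t_split:
            growth = demography.growth_rate * Q
        dem.add_population(name="NA", initial_size=n_na / 2, growth_rate=growth)
        dem.set_symmetric_migration_rate(
            ["AFR", "NA"], demography.migration(t_start) * Q)
        if t_start < demography.t_split:
            t_sp = (demography.t_split - t_start) / Q
            dem.add_population_parameters_change(
                time=t_sp, population="NA",
                initial_size=max(demography.N_b / Q, 2), growth_rate=0.0)
            dem.add_migration_rate_change(time=t_sp, rate=demography.m_ooa * Q,
                                          source="AFR", dest="NA")
            dem.add_migration_rate_change(time=t_sp, rate=demography.m_ooa * Q,
                                          source="NA", dest="AFR")
        t_merge = (demography.t_ooa - t_start) / Q
        dem.add_population_split(time=max(t_merge, t_anc / 1e3), derived=["NA"],
                                 ancestral="AFR")
        dem["AFR"].initially_active = True
        samples.append(msprime.SampleSet(n_na // 2, population="NA", time=0))
    dem.sort_events()
    r_per_bp = ext.rho0 * 1e-8  # cM/Mb -> Morgan/bp
    ts = msprime.sim_ancestry(
        samples=samples, demography=dem, sequence_length=ext.L_ext,
        recombination_rate=r_per_bp * Q, discrete_genome=False,
        ploidy=2, random_seed=(seed % (2 ** 31 - 2)) + 1,
    )
    if ext.masked.shape[0]:
        edges = [0.0]
        rates = []
        cursor = 0.0
        for s, e in ext.masked:
            if s > cursor:
                edges.append(s)
                rates.append(mu * Q)
            edges.append(e)
            rates.append(0.0)
            cursor = e
        if cursor < ext.L_ext:
            edges.append(ext.L_ext)
            rates.append(mu * Q)
        rate_map = msprime.RateMap(position=edges, rate=rates)
    else:
        rate_map = mu * Q
    mts = msprime.sim_mutations(ts, rate=rate_map,
                                model=msprime.BinaryMutationModel(),
                                discrete_genome=False,
                                random_seed=(seed % (2 ** 31 - 2)) + 1)
    G = mts.genotype_matrix().T.astype(np.int8)  # haplotypes x sites
    positions = mts.tables.sites.position.copy()
    deme = np.zeros(G.shape[0], dtype=np.int8)
    deme[n_af:] = 1
    return np.ascontiguousarray(G), positions, deme


def _choose_parents(rng, k, pool_same, pool_other, m):
    """Parent rows for k offspring of one (deme, allelic class) group."""
    if k == 0:
        return np.empty(0, dtype=np.int64)
    if len(pool_same) == 0 and len(pool_other) == 0:
        raise RuntimeError("no parents available for required allelic class")
    if len(pool_same) == 0:
        return pool_other[rng.integers(0, len(pool_other), k)]
    out = pool_same[rng.integers(0, len(pool_same), k)]
    if m > 0 and len(pool_other) > 0:
        mig = rng.random(k) < m
        nm = int(mig.sum())
        if nm:
            out[mig] = pool_other[rng.integers(0, len(pool_other), nm)]
    return out


def simulate_locus(spec: SelectionModelSpec, demography: Demography,
                   gmap: Optional[GeneticMap] = None, L: float = 185_000.0,
                   n_hap=(122, 122), mu: float = 1.25e-8,
                   rng: Optional[np.random.Generator] = None,
                   rescale_q: float = 20.0,
                   focal_pos: Optional[float] = None,
                   hotspot_threshold: float = 5.0,
                   trajectory: Optional[Trajectory] = None):
    """Simulate haplotypes at the locus under the model; returns (matrix, focal_pos).

    Populations are labelled ``AFR`` and ``NONAFR`` with ``n_hap`` sampled
    chromosomes each (the non-African sample is empty for a single-deme
    demography).  The focal site sits at ``focal_pos`` (default the locus
    midpoint) and its per-deme frequency follows the conditioning trajectory.
    """
    rng = rng or np.random.default_rng()
    Q = float(rescale_q)
    ext = apply_hotspot_extension(gmap, L, hotspot_threshold)
    if focal_pos is None:
        focal_pos = L / 2
    focal_ext = float(ext.lift(focal_pos)[0])
    traj = trajectory or simulate_trajectory(spec, demography, rng)

    # conditioned phase starts at allele birth (SDN/NTR) or selection onset (SSV)
    t_start_unscaled = traj.birth_gen if spec.base_model != "SSV" else traj.onset_gen
    G_steps = max(int(math.ceil(t_start_unscaled / Q)), 1)
    t_start = G_steps * Q

    A, positions, deme = _msprime_init(
        demography, t_start, Q, ext, mu,
        seed=int(rng.integers(1, 2 ** 31 - 3)),
    )

    # install the focal column
    if spec.base_model == "SSV":
        focal_col, positions, A = _install_standing_variant(
            A, positions, deme, focal_ext, spec.f_sel, ext, rng,
            standing=spec.ssv_standing)
    else:
        col = np.zeros((A.shape[0], 1), dtype=np.int8)
        f_na = traj.freq[1, traj.birth_gen]
        birth_deme = 1 if (np.isfinite(f_na) and f_na > 0) else 0
        rows_pool = np.flatnonzero(deme == birth_deme)
        if len(rows_pool) == 0:
            rows_pool = np.arange(A.shape[0])
        col[rng.choice(rows_pool), 0] = 1
        ins = int(np.searchsorted(positions, focal_ext))
        positions = np.insert(positions, ins, focal_ext)
        A = np.ascontiguousarray(np.concatenate(
            [A[:, :ins], col, A[:, ins:]], axis=1))
        focal_col = ins

    lam_x = (ext.genetic_length_cm / 100.0) * Q           # crossovers per meiosis
    mu_tot = mu * Q * ext.unmasked_length                  # new mutations per haplotype

    for g in range(G_steps - 1, -1, -1):
        t = g * Q
        n_af, n_na = _rescaled_sizes(demography, t, Q)
        m_resc = min(demography.migration(t) * Q, 0.5)
        x_af = traj.at(0, t)
        x_na = traj.at(1, t) if n_na > 0 else 0.0
        if not np.isfinite(x_na):
            x_na = 0.0
        k_af = int(round(x_af * n_af))
        if x_af > 0:
            k_af = min(max(k_af, 1), n_af)
        k_na = int(round(x_na * n_na))
        if x_na > 0 and n_na > 0:
            k_na = min(max(k_na, 1), n_na)

        focal = A[:, focal_col]
        pools = {(d, c): np.flatnonzero((deme == d) & (focal == c))
                 for d in (0, 1) for c in (0, 1)}
        parent_rows = []
        child_deme = []
        for d, n_d, k_d in ((0, n_af, k_af), (1, n_na, k_na)):
            if n_d == 0:
                continue
            for c, k in ((1, k_d), (0, n_d - k_d)):
                other = 1 - d
                rows = _choose_parents(rng, k, pools[(d, c)], pools[(other, c)], m_resc)
                parent_rows.append(rows)
                child_deme.append(np.full(k, d, dtype=np.int8))
        parent_rows = np.concatenate(parent_rows)
        child_deme = np.concatenate(child_deme)
        n_children = len(parent_rows)
        child = A[parent_rows]
        # the child's focal allele is fixed by the conditioning class
        # (crossovers below never move the focal-containing segment)

        # crossovers: mosaic with a random partner from the parent's deme
        n_x = rng.poisson(lam_x, n_children)
        for i in np.flatnonzero(n_x):
            d = child_deme[i]
            pool = np.flatnonzero(deme == d)
            if len(pool) == 0:
                pool = np.arange(A.shape[0])
            partner = int(pool[rng.integers(0, len(pool))])
            cuts = np.sort(rng.random(n_x[i]) * ext.L_ext)
            bounds = np.concatenate([[0.0], cuts, [ext.L_ext]])
            col_bounds = np.searchsorted(positions, bounds)
            focal_seg = int(np.searchsorted(cuts, focal_ext))
            for seg in range(len(bounds) - 1):
                if seg % 2 != focal_seg % 2:
                    lo, hi = col_bounds[seg], col_bounds[seg + 1]
                    child[i, lo:hi] = A[partner, lo:hi]

        # new mutations
        n_new = rng.poisson(n_children * mu_tot)
        if n_new:
            rows = rng.integers(0, n_children, n_new)
            new_pos = ext.sample_unmasked(rng, n_new)
            block = np.zeros((n_children, n_new), dtype=np.int8)
            block[rows, np.arange(n_new)] = 1
            child = np.concatenate([child, block], axis=1)
            positions = np.concatenate([positions, new_pos])
            order = np.argsort(positions, kind="stable")
            positions = positions[order]
            child = child[:, order]
        else:
            order = None

        # drop columns lost or globally fixed (never the focal column)
        counts = child.sum(axis=0)
        focal_col = int(np.searchsorted(positions, focal_ext))
        keep = (counts > 0) & (counts < n_children)
        keep[focal_col] = True
        if not keep.all():
            child = child[:, keep]
            positions = positions[keep]
            focal_col = int(np.searchsorted(positions, focal_ext))
        A = np.ascontiguousarray(child)
        deme = child_deme

    return _finalize_sample(A, positions, deme, focal_ext, ext, n_hap, rng,
                            traj, spec)


def _install_standing_variant(A, positions, deme, focal_ext, f_sel, ext, rng,
                              standing: str = "both"):
    """Relabel a standing neutral variant as the focal allele at the focal position.

    Chooses the segregating column whose global frequency is nearest f_sel
    (preferring sites close to the focal position) and moves it there, giving
    the standing allele a coalescent-consistent haplotype background.
    """
    freq = A.mean(axis=0)
    seg = np.flatnonzero((freq > 0) & (freq < 1))
    if len(seg) == 0:
        raise RuntimeError("no standing variation available for the SSV start")
    # score by the frequency in the deme where selection will act, so the
    # onset adjustment stays within-deme and the bottleneck's pruning of
    # standing lineages is preserved; fall back to global frequency when the
    # non-African deme does not exist yet
    pos_pen = 0.05 * np.abs(positions[seg] - focal_ext) / max(ext.L_ext, 1.0)
    if standing == "both" and (deme == 1).any():
        f_na = A[deme == 1].mean(axis=0)
        f_af = A[deme == 0].mean(axis=0)
        score = np.abs(f_na[seg] - f_sel) + 0.25 * np.abs(f_af[seg] - f_sel) + pos_pen
    elif standing == "africa" and (deme == 1).any():
        f_na = A[deme == 1].mean(axis=0)
        f_af = A[deme == 0].mean(axis=0)
        # standing in Africa only: prefer variants absent outside Africa
        score = np.abs(f_af[seg] - f_sel) + 0.5 * f_na[seg] + pos_pen
    else:
        score = np.abs(freq[seg] - f_sel) + pos_pen
    j = int(seg[np.argmin(score)])
    col = A[:, j].copy()
    A = np.delete(A, j, axis=1)
    positions = np.delete(positions, j)
    ins = int(np.searchsorted(positions, focal_ext))
    positions = np.insert(positions, ins, focal_ext)
    A = np.ascontiguousarray(np.concatenate(
        [A[:, :ins], col[:, None], A[:, ins:]], axis=1))
    return ins, positions, A


def _finalize_sample(A, positions, deme, focal_ext, ext: ExtendedMap, n_hap,
                     rng, traj, spec):
    rows = []
    pops = []
    for d, (label, n_d) in enumerate(zip(("AFR", "NONAFR"), n_hap)):
        pool = np.flatnonzero(deme == d)
        if n_d == 0 or len(pool) == 0:
            continue
        if len(pool) < n_d:
            raise RuntimeError(f"deme {label} smaller than requested sample")
        rows.append(rng.choice(pool, size=n_d, replace=False))
        pops.extend([label] * n_d)
    rows = np.concatenate(rows)
    S = A[rows]
    # project to physical coordinates; masked columns carry no mutations
    phys = ext.project(positions)
    ok = np.isfinite(phys)
    S, phys = S[:, ok], phys[ok]
    # keep sample-polymorphic columns plus the focal site
    focal_idx = int(np.argmin(np.abs(positions[ok] - focal_ext)))
    counts = S.sum(axis=0)
    keep = (counts > 0) & (counts < S.shape[0])
    keep[focal_idx] = True
    S, phys = S[:, keep], phys[keep]
    focal_idx = int(keep[:focal_idx].sum())
    # integer, strictly increasing positions (1-based)
    pos_int = np.round(phys).astype(np.int64) + 1
    for i in range(1, len(pos_int)):
        if pos_int[i] <= pos_int[i - 1]:
            pos_int[i] = pos_int[i - 1] + 1
    focal_pos = int(pos_int[focal_idx])
    ids = np.array([f"sim{i // 2}" for i in range(S.shape[0])], dtype=object)
    hm = HaplotypeMatrix(S, pos_int, ids, np.array(pops, dtype=object))
    hm.focal_site = focal_pos
    hm.trajectory = traj
    hm.model_spec = spec
    return hm, focal_pos
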