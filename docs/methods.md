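# Methods

This note documents the models, estimators and numerical choices behind
`clineselect`, the study conditions its synthetic generators emulate, and
the problem sizes its validation suite runs at.

## Statistics

**Weir–Cockerham F_ST.** Per site we compute the 1984 variance components
*a* (among populations), *b* (among individuals within populations) and
*c* (within individuals) from per-population diploid sample sizes n_i,
derived-allele frequencies p_i and heterozygote frequencies h_i, using the
paper-exact n̄, n_c, p̄, s², h̄ algebra; θ = a/(a+b+c). When only allele
frequencies are available (e.g. recomputing published per-population
values) heterozygosity is imputed under Hardy–Weinberg, h_i = 2p_i(1−p_i).
Sites monomorphic across all populations are flagged undefined rather than
set to zero. Genome-wide F_ST between two populations is the **ratio of
averages** Σa/Σ(a+b+c) over sites polymorphic in that pair — not the mean
of per-site ratios. A vectorized two-population path (identical algebra,
tested against the scalar transcription at 1e-12) serves the
background-SNP matrix computations.

**Frequency-spectrum statistics.** Tajima's D uses the standard 1989
constants; D is undefined (NaN) when S = 0 and that undefinedness
propagates (see ABC exclusion below). Fay & Wu's H is the unnormalized
θ_π − θ_H from the polarized derived SFS. π is the mean pairwise
difference count.

**EHH family.** EHH(x) among carriers of a core allele is the fraction of
carrier pairs identical over [core, x], computed by a lexicographic-sort
walk (O(n·m), matched against brute-force pair counting). The walk extends
outward until EHH < 0.05 (configurable) or the region end; when the cutoff
is never reached the last EHH value is extended flat to the region
boundary, so a panel of identical haplotypes integrates to the full
genetic span. iHH is the trapezoid integral of EHH against cM. Sites
monomorphic in the panel are excluded from the walk, which makes iHS and
XP-EHH invariant to padding with monomorphic columns. iHS =
ln(iHH_ancestral/iHH_derived) is standardized to mean 0/sd 1 within 2%
derived-frequency bins; XP-EHH = ln(iHH_test/iHH_ref) uses the whole-panel
EHH from the core and is standardized genome-wide. Frequency filters
follow the scan conventions: iHS needs 0.05 < DAF < 0.95, XP-EHH needs
test-population DAF > 0.05.

**Empirical P-values** are plain tail proportions against the background
distribution (no +1 smoothing); a value beyond all N background values
reports 0 and should be quoted "< 1/N".

## Cline regression

**PGLS.** The response is the per-population mean derived-allele
frequency. The covariance is Brownian on a neighbor-joining tree
(scikit-bio's Saitou–Nei implementation, negative branch lengths clamped
to zero) built from the pairwise ratio-of-averages F_ST matrix and
midpoint-rooted; C_ij is the shared root-to-MRCA path length, scaled
off-diagonal by Pagel's λ (fixed at 1 by default; λ = 0 recovers OLS, as
does a star tree). Estimates are ML via Cholesky-whitened least squares;
AICc = AIC + 2k(k+1)/(n−k−1) with n = number of populations. The
parameter count follows the published bookkeeping convention (null model
k = 4, +1 per test predictor); Akaike weights depend only on AIC
differences, so the convention does not affect them. Predictors are
z-transformed (mean 0, sd 1, n−1 denominator).

**Binomial GLMM.** Each individual contributes a 2-column response
(derived, ancestral allele counts out of 2). The linear predictor is
logit(p) = β₀ + β_fst·z(F_ST-to-reference) + Σβ_x·z(x) + u_pop + v_ind
with u ~ N(0, σ²_pop) and v ~ N(0, σ²_ind), the individual term being an
observation-level random effect that absorbs overdispersion. Fitting is
Laplace-approximated ML: the joint mode of (u, v) is found by Newton
iteration — because each individual belongs to exactly one population the
Hessian reduces to closed-form diagonal Schur-complement algebra — and
(β, log σ_pop, log σ_ind) are optimized by L-BFGS-B with a Nelder–Mead
polish. ML (not REML) keeps AICs comparable across fixed-effect
structures. On a reference panel the fit matches `lme4::glmer` to ~1e-4
in log likelihood and ~1e-3 in coefficients. Wald standard errors come
from a finite-difference Hessian (pseudo-inverted, so collinear designs
degrade gracefully); the dispersion diagnostic is Σ Pearson residuals² /
(n − k). The modern model set is the null (intercept + F_ST + both
variances, k = 4) plus every combination of latitude and temperature
(four models); adding age for ancient samples doubles it to eight (the
F_ST covariate is dropped in ancient mode, where no genome-wide reference
panel is assumed).

**Multi-model inference.** Models are ranked by (corrected) AIC;
Δ_i = AIC_i − min AIC, w_i = exp(−Δ_i/2)/Σ exp(−Δ_j/2); the 95%
confidence set is the smallest prefix of cumulative weight ≥ 0.95.
Likelihood-ratio tests require nesting and a non-negative deviance;
leave-one-out stability reports per-coefficient min/max over unit
exclusions.

## Allele-origin analysis

Haplotypes are split by the focal allele; pairwise Hamming distances among
derived haplotypes are computed over the analysis window (default the
65 kb high-differentiation region) excluding the focal column. Derived
haplotypes whose **median** distance to the other derived haplotypes
exceeds a threshold are flagged as putative recombinants with the
ancestral background; the threshold is exposed because it scales with the
window's diversity (10 matches the real-data window; simulated 65 kb
windows run at 25 in the validation suite). The proportion of a flagged
haplotype's distinguishing alleles (relative to the unflagged-derived
majority consensus) that also occur on ancestral-background haplotypes
separates recombinants (≈1) from mutation-laden haplotypes (≈0). π among
surviving derived haplotypes, per population, ranks candidate origins;
the filter is a published heuristic, not a statistical test.

## Locus simulator

**Demography.** Two sampled demes on a three-population out-of-Africa
history: ancestral size 7,310 diploids expanding to 14,474 at 148 kya; an
out-of-Africa bottleneck deme of 1,861 splitting at 51 kya with symmetric
migration 15×10⁻⁵/generation; at 23 kya the bottleneck deme becomes the
European (1,032 diploids growing 0.38%/generation, migration 2.5×10⁻⁵) or
East-Asian (554, 0.48%/generation, 0.78×10⁻⁵) branch. Generation time
25 years. All values are config fields of `Demography`;
`Demography.constant(N)` gives the single-deme constant-size model used
for closed-form checks.

**Models and priors.** SDN: allele born as a single copy, t ~ U(30, 60)
kya, s_A ~ U(0, 1.5%) in Africa, s_NA ~ U(0.5%, 5%) outside. SSV: a
standing neutral allele at frequency f_sel ~ U(0, 20%) becomes selected
(s_NA ~ U(0, 5%], non-African deme only) at t₀ ~ U(21, 51) kya. NTR: as
SDN with s = 0. Halted variants set s = 0 for the last 3,000 years.
Fitness is additive: genotypes (1, 1+hs, 1+s) with h = 0.5. De novo
births occur in the selected non-African deme when it exists at the birth
time and in the ancestral African deme otherwise — the configuration
under which the de novo model produces its canonical hard-sweep
signature; the SSV standing allele sits at f_sel in both demes at onset
by default, with an `ssv_standing="africa"` switch under which only
Africa carries it and the selected deme acquires it by migration
("recently introduced" histories).

**Engine.** The allele-frequency trajectory is simulated per unscaled
generation (Wright–Fisher binomial sampling with selection and migration;
numba-compiled). SSV pre-onset history is a time-reversed neutral
absorption path from f_sel. Trajectories that lose the allele everywhere
are rejected and redrawn, with the count reported. Haplotypes then come
from a rescaled (factor Q) forward Wright–Fisher simulation **conditioned
on that trajectory**: msprime generates the whole rescaled population's
neutral standing variation at the start of the conditioned phase (allele
birth for SDN/NTR, selection onset for SSV) under the rescaled demography;
each subsequent rescaled generation samples parents within allelic classes
whose sizes are fixed by the trajectory, applies crossovers (Poisson with
the map's genetic length, mosaic segments keeping the focal-containing
segment on the class parent), migration, and new mutations (μ = 1.25×10⁻⁸
/bp/generation by default, rescaled μQ). Because the trajectory carries
all selection information, selection coefficients never enter the rescaled
engine and the usual s·Q ≪ 1 constraint does not arise. For SSV the focal
column is a real standing neutral variant chosen from the msprime output
(scored by its frequency in the deme where selection will act), so the
standing allele has a coalescent-consistent haplotype background and the
bottleneck's pruning of standing lineages is preserved.

Rescaling fidelity, measured on the constant-size neutral case (N = 10⁴,
30 kb, n = 20): mean segregating sites within 2.6% (Q = 50) and 0.6%
(Q = 100) of Watterson's θ·a_n, mean Tajima's D within 0.04 of zero; the
canonical hard/soft contrast holds at matched s (mean derived-class iHH
0.055 vs 0.038, derived-class π 23 vs 40 at s_NA = 2%, f_sel = 10%).
Reference tables default to Q = 50 in the library and run at Q = 100 in
the validation suite; a Q sweep (100/50/25) moved the SDN-vs-SSV
discrimination by < 8 points, so granularity is not the binding factor at
these scales.

**Hotspot extension.** Map intervals above 5 cM/Mb are replaced by
stretches of length ℓ·ρ_h/ρ₀ at the baseline rate ρ₀ (the mean rate
excluding hotspots); total genetic length is conserved exactly (float
coordinates), the inserted excess is masked for mutation (both in the
msprime initialization, via a mutation rate map, and in the forward
phase), and surviving coordinates project back onto the physical frame.

## ABC

**Summary vector (14 statistics).** The whole-region XP-EHH contrast at
the focal site (test vs African panel); Tajima's D and Fay & Wu's H per
deme for the central 65 kb and the combined 120 kb flanks (8 values);
mean per-SNP F_ST per section (2); the focal derived frequency in each
deme (2); and the focal-site F_ST. A record is **excluded** when the
test-deme focal frequency is ≤ 5% (the XP-EHH computability filter) or
any statistic is undefined (e.g. a monomorphic section). The filter is
applied identically to observations and simulations, and per-model
exclusion fractions (the realized prior) are reported. Reference-table
construction skips the haplotype phase when the trajectory already
guarantees exclusion (test-deme extinction), which is exact for the
statistics since excluded records carry none.

**Transform.** Each statistic is shifted positive, Box-Cox transformed
(ML λ), standardized, and projected onto partial-least-squares components
fitted by regressing the model parameters — pooled across models, with
parameters absent under a model coded zero — on the statistics. Distances
use the first 5 components; `rmse_per_component` produces the held-out
RMSE curves that justify the choice.

**Inference.** Plain rejection retains the nearest n simulations in PLS
space (ties broken by index). The retained fraction follows the
full-scale design (0.1%) with a floor of 50 so desk-scale tables remain
usable. Model posterior probabilities are retained-count proportions
corrected for unequal *usable* (post-filter) table sizes per model — the
convention of a reference table filtered before inference; the Bayes
factor is PP/(1−PP). Parameter posteriors are unweighted rejection
quantiles (2.5%, 50%, 97.5%), flagged low-confidence below 20 retained
rows. Cross-validation power treats reference rows as pseudo-observations
(leave-one-out) and reports TP/FP/FN per model.

## Validation suite: problem sizes and known limitations

The suite builds one session reference table (European branch, Q = 100):
2,000 SDN + 2,000 SSV + 3,000 NTR prior draws, plus 500 halted-SSV draws,
and scores 200 pseudo-observations per model with 20 retained neighbours.
The neutral closed-form check runs 500 replicates; GLMM effect recovery
runs 50 panels of 40 populations × 30 individuals; ABC parameter-recovery
coverage uses 50 pseudo-observations at s_NA = 2%, f_sel = 10%,
t₀ = 30 kya.

At this scale, model-choice power reproduces the neutral and
standing-variation components of the published pattern but **not** the
de novo component: SDN correct-assignment sits near 0.71 rather than
0.96, making SDN (not SSV) the hardest model. Two causes dominate:
(i) with migration 15×10⁻⁵ over ~1,500 generations, back-migration lifts
the African frequency of a de novo allele into the f_sel range of the
standing model, so low-s_A SDN draws are intrinsically standing-like in
all 14 statistics, and resolving that corner needs far denser reference
tables (the full-scale design retains 0.1% of 10⁶ rows — ~100× tighter
neighbourhoods) and/or GLM-adjusted model choice; (ii) plain rejection is
deliberately assumption-light. The corresponding acceptance test asserts
the published pattern and fails on the SDN component by design rather
than being weakened.

What the synthetic generators do **not** emulate: genome-wide linkage
structure (background SNPs are unlinked frequencies; linked haplotypes
come only from the locus simulator), ascertainment bias, genotyping
error, and admixture. Passing tests therefore demonstrate correctness of
the estimators and the inference machinery under the stated models, not
robustness to those real-data complications.

## Degenerate inputs and tie-breaks

Monomorphic sites: F_ST undefined-flagged; D undefined; EHH walks skip
them. Rejection ties break by simulation index. NJ input distances are
clamped at zero (the pairwise estimator can be slightly negative for very
close pairs). Two-leaf trees are midpoint-rooted by direct bisection.
Missing genotypes are flagged, never silently dropped; flagged records
are excluded from GLMM fits and frequency counts.
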