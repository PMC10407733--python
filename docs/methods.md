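# Methods

This note documents the models and procedures implemented in `otskit`, the
defaults and why they were chosen, what the synthetic-data generators emulate,
the numerical conventions, and the known limitations.

## Growth-curve kinetics

**Model of the data.** A plate-reader OD600 trajectory sampled every 10 min
for 16 h (97 points).  The synthetic generator uses a flat lag at the
inoculation density `od0` followed by a logistic rise,

    OD(t) = K·od0 / (od0 + (K − od0)·exp(−μ·(t − lag))),   t ≥ lag,

with carrying capacity `K` and intrinsic rate `μ` (the early-exponential
ln-OD slope), plus additive Gaussian noise clipped at a 10⁻⁴ OD floor.  The
flat-lag + logistic form is the simplest model that exposes all three
extracted parameters distinctly; Gompertz/Baranyi fits are out of scope.

**Extraction procedure.** Natural-log-transformed OD (blank-subtracted if a
blank is given, floored at 10⁻⁴) is regressed by OLS in a moving window of
three consecutive points, excluding the first 3 h.  The window slopes are
rank-ordered; the two highest are dropped and the next five averaged to give
μ.  Growth efficiency is the mean of the six highest raw readings minus the
mean of the two lowest (OD_Max − OD_Min), a multiset statistic independent of
time order.  The lag endpoint is the intersection of the line of slope μ
anchored at the centroid (mean time, mean ln OD) of the five μ-contributing
windows with the horizontal line at the log initial density, taken as the
mean of the two lowest readings (the OD_Min convention); the crossing time is
clamped to [0, t_end].  Curves with μ below 10⁻³ h⁻¹ report the lag as
undefined — a phenotype flag, not an error.

Defaults (all in `GrowthConfig`): window 3, exclusion 3 h, natural log, drop
2 / average 5, 2 lowest / 6 highest readings, μ tolerance 10⁻³ h⁻¹.  The
published description of this procedure leaves the log base, the slope
regression form and the anchor point open; the choices above are this
package's documented defaults, not claims about any external tool's
internals.

**Noise sensitivity (known limitation).** The ranked-window estimator selects
the windows with the steepest slopes, which on a growth curve are exactly the
windows at the lowest densities — where an *absolute* OD noise of σ translates
into a per-point ln-noise of σ/OD and a 3-point window slope SD of
≈ 4.24·σ/OD at 10-min spacing.  The rank-max selection then adds a
systematic +1.5–2 SD bias.  Consequences, measured on the synthetic
generator: noiseless recovery is excellent (median μ error 2.8 %, median lag
error ~1 min over μ ∈ [0.2, 1.2] h⁻¹, lag ∈ [0.5, 4] h, inoculum 0.01,
capacity 1.0), but with σ = 0.005 OD the median μ error rises to ~40 % and no
amount of model-agnostic denoising (median/boxcar/Savitzky–Golay filters,
isotonic regression, low-density window exclusion) brings it below ~6 %.
Users with noisy low-inoculum data should average replicate curves, start
cultures at higher density, or use instruments with ≤ 0.002 OD repeatability;
the estimator is reliable when per-reading noise is ≲ 1 % of the densities at
which growth is fastest.  A related caveat: because slopes before 3 h are
excluded, fast growers that leave early exponential phase by then have μ
underestimated by the logistic deceleration (≈ 3 % at μ = 0.6 h⁻¹, inoculum
0.01, capacity 1.0; worse for μ ≳ 1 h⁻¹ with short lags).

## Cell-size summaries

Forward scatter (FSC) is a proxy for cell size.  A sample is summarised by
the arithmetic mean and SD, the median, and the mode taken as the centre of
the maximal-count bin of an equal-width histogram over [min, max] (256 bins
by default; ties resolve to the lowest-valued bin) — matching the binned
display from which cytometry software reads the mode.  The exact mode and
mode-SD algorithms of commercial packages are not public; here "median SD"
and "mode SD" are the SDs of those statistics over 200 seeded bootstrap
resamples, reported only for samples of ≥ 10 events.  The synthetic
generator draws events log-normally, parameterised by arithmetic mean and CV
(strictly positive and right-skewed like real scatter data); it does not
emulate gating, doublets, debris, or instrument saturation.

## Composite relative fitness

Four phenotype parameters are turned into background-normalised ratios
oriented so larger = fitter: r_μ = μ_c/μ_bg, r_eff = E_c/E_bg,
r_lag = lag_bg/lag_c (inverted — longer lag is less fit), and
r_size = FSC_c/FSC_bg (size reduction accompanies stress).  A condition lag
of zero caps r_lag at 10.  The composite is the weighted geometric mean
∏ r_i^{w_i} with uniform weights by default.  The geometric mean was chosen
because it gives the identity property (condition ≡ background ⇒ exactly 1),
unit-free composition, strict monotonicity in every ratio, and the symmetry
composite(A vs B)·composite(B vs A) = 1.  The exact synthesis formula behind
published relative-fitness heat maps is not stated anywhere; this aggregation
is a documented stand-in, and the per-parameter ratios are always reported
alongside the composite.  Non-viable conditions (strain could not be
established, or no growth) score 0 and render as "N.V.".  Parameters missing
on both sides (e.g. no cytometry data) are omitted from the mapping rather
than poisoning the composite.

## Differential protein abundance

Input is a protein × sample table of positive LFQ intensities (missing cells
allowed), analysed on the log2 scale.  Per protein with ≥ 2 valid values per
group (others excluded and listed): a two-sided equal-variance t-test
(Welch by config) gives the reported p-value, and the softened statistic

    d = Δ / (s + s0),   Δ = mean_B − mean_A,   s = pooled standard error,

with s0 = 0.1 damps the small-variance artefacts of triplicate data.  The
significance cutoff on |d| is calibrated by label permutations: the observed
|d| values are scanned as candidate thresholds, the expected false-positive
count at each is the mean over permutations of permuted |d| values at or
above it, and the smallest threshold whose estimated FDR is ≤ 0.1 becomes
the cutoff (the curved "asymptotic lines" of the volcano plot).  A protein
is called dysregulated only when p < 0.05 **and** |d| ≥ cutoff, the
conjunction rule.  When the number of distinct label assignments is at most
`n_permutations` (e.g. C(6,3) = 20 for 3 v 3), the enumeration is exhaustive
and the per-protein permutation p-value is exact; otherwise 250 random
assignments are drawn (seeded) and the p-value uses the (hits+1)/(B+1)
convention.  No imputation is performed — exclusion is the conservative
choice for permutation calibration.  s0 = 0.1 and 250 permutations are the
conventional defaults of this analysis family; both are exposed in
`DEConfig`.

iBAQ abundance ranks: within each replicate, proteins are ranked by iBAQ
descending (1 = most abundant, ties share the minimal rank — deterministic
and order-independent); a protein's abundance is reported as mean ± SD of
its per-replicate ranks.  Ranks are invariant under any strictly monotone
transform of the iBAQ scale.

Dysregulated-set algebra (`overlap_sets`, `remove_common_core`) is exact set
arithmetic emitting full membership for every Venn region, separately for
up, down, or either direction; common-core removal preserves per-protein
statistics.

## Over-representation

For a query of n proteins from a universe of N containing a K-member
category with k overlapping, p = P[X ≥ k] for X ~ Hypergeometric(N, K, n);
Benjamini–Hochberg across all tested categories.  Only over-representation
is tested.  The default universe should be the quantified proteins, not the
whole proteome — detection bias otherwise inflates every category.  Network
retrieval, clustering and database-specific FDRs are out of scope.

## MS1 incorporation ratios

Each reporter-peptide variant (one amino acid at the readout position)
elutes as its own peak; the generator produces one Gaussian peak per
variant × replicate with area `base_area × ratio`, optional multiplicative
log-normal replicate area variation (`area_cv`, the dominant noise mode of
label-free areas), optional additive trace noise, and ±4σ peak boundaries.
Quantification: trapezoidal integral of (intensity − baseline)⁺ inside the
boundaries, baseline = in-window minimum by default ('none' available).
Ratios are formed within each replicate as AUC_variant / AUC_pSer — the
within-sample normalisation that cancels injection and ionisation scale —
then averaged across replicates (mean ± SD).  Replicates with zero reference
area are excluded with a diagnostic.  A variant is below the limit of
detection when its in-window peak height is < 3× the robust noise of its
trace outside the window (1.4826 × MAD); below-LOD variants report ratio 0
with a flag so ratio tables stay rectangular.  Peak picking, mzML parsing
and isotope envelopes are out of scope — boundaries are inputs.

## Gel-based reporter yield

Band intensity is modelled linear in loaded protein mass.  An OLS standard
curve (intensity = slope·ng + intercept) over ≥ 2 distinct GFP standards is
inverted for the sample band; dividing the lane mass [ng] by the loaded
culture-equivalent volume [µl] gives mg/l.  Phosphoprotein yield is the
total yield × upper/(upper + lower) from the PhosTag band pair.  Saturation
and nonlinear film response are not modelled.

## tRNA identity elements

tRNAs are keyed by Sprinzl position ('1'–'76' plus lettered insertions);
the seven acceptor-stem pairs (1:72 … 7:66) must be Watson–Crick
complementary (G:U tolerated with a warning).  Identity elements are bases,
base pairs, or structural predicates (currently variable-loop length ≥
threshold).  An aaRS is flagged as a mis-recognition risk when its matched-
element count reaches its threshold (default 3 — the number of elements the
suppressor tRNA shares with the host Gly/Thr systems) *and* no structural
element is unmet; the structural veto always applies, which is what keeps
SerRS unflagged at any threshold (the suppressor lacks the extended variable
loop).  No quantitative flagging rule exists in the source literature; this
count-plus-veto formalisation reproduces the documented Gly/Thr-yes, Ser-no
outcome and is fully configurable in the catalog TSV.  Mutation design
enumerates single acceptor-stem flips and discriminator substitutions,
keeps candidates that leave every cognate element matched while strictly
reducing summed host matches, and ranks by that reduction — recovering the
C2:G71 → G2:C71 flip as the top (and only) candidate on the shipped catalog.
The shipped suppressor-tRNA fixture is synthetic filler outside its
documented identity positions, and the element catalog marks which rows are
primary-source versus literature-supplemented.  Secondary-structure
prediction and aminoacylation kinetics are out of scope.

## Synthetic data and what passing tests show

Every generator is seeded (one `numpy.random.Generator` per call, no global
state), byte-reproducible, and attaches a `TruthRecord`.  Defaults mirror
the study design they emulate: 10-min/16-h OD sampling, three biological
replicates, triplicate label-free proteomes of ~2000 proteins with N(25, 2.5)
log2 baselines and a per-protein size factor for the iBAQ channel, 4-fold
spiked effects at 5 % prevalence, 0.25 log2 replicate noise, Gaussian MS1
peaks with 5 % replicate area CV.  Missingness is uniform at random, not
intensity-dependent — real label-free data are left-censored, so recovery
results here are optimistic about missing-not-at-random regimes.  The
generators do not emulate batch effects, drift, carry-over, saturation, or
peptide-level inference; a pass on synthetic data validates the statistics
and bookkeeping, not instrument physics.

## Problem sizes used in validation

The test suite validates: the ranked-slope rule against brute-force
enumeration (1000 random slope vectors) and parameter recovery on 50 seeded
curves; exhaustive-permutation equality on 3 v 3 tables; null behaviour over
100 seeded 2000-protein proteomes (pooled raw p < 0.05 rate vs the binomial
band) and spike-in recovery over 10 seeds; hypergeometric p against full
enumeration for universes up to 25; incorporation-ratio recovery over 50
seeded chromatogram sets; and exact inversion of noiseless densitometry.
These sizes keep the full suite under a minute on a laptop while leaving the
Monte-Carlo bands tight.
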