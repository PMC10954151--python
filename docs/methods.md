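# Methods

This note documents the models and procedures implemented in
`pm25elements`, the assumptions behind them, the defaults that matter, and
what the synthetic validation does and does not show.

## Data model and units

The central object is a per-sample table of 25 element concentrations
(Na, Mg, Al, Si, S, Cl, K, Ca, Sc, Ti, V, Cr, Mn, Fe, Co, Ni, Cu, Zn, Ga,
As, Se, Br, Sr, Ba, Pb) with a site label and a sampling start date.  The
campaign it models collected 72-hour PM2.5 samples at three Thai
observatories — Chiang-Mai (COS, n=82), Bangkok (BOS, n=48) and Phuket
(POS, n=61) — between July 2020 and June 2021.  Major elements are
reported in µg/m³ and trace elements in ng/m³; everything is harmonised
to ng/m³ on ingest (×1000 for µg/m³ columns) and converted back on
output, so round trips are lossless.

Below-detection-limit cells ("N.D.") carry a `not_detected` flag and no
numeric value.  The default policy excludes them from means, standard
deviations and per-sample panel sums, because the campaign's published
statistics print "N.D." as a *minimum* — which implies exclusion rather
than substitution.  Zero- and half-minimum-substitution are available as
config alternatives.  Standard deviations use the n−1 (sample) form.
A 72-h sample is assigned to the season of its start date.

## Synthetic data generator

No raw per-sample data accompany the published campaign, so the package
ships a generator with the statistical structure the analysis assumes,
in two flavours.

**Known-truth mixtures.**  Concentrations follow a low-rank mixture

    x[i, j] = (Σ_k g[i, k] · f[k, j]) · exp(ε[i, j]) · exp(−β · z(RH_i))

with k nonnegative source profiles `f` (rows sum to one; a qualitative
k=3 preset mimics a traffic+biomass source loaded on S/K/Zn/Br/Pb/As/Se/Cu,
a crustal+marine source on Na/Mg/Al/Si/Cl, and a construction source on
Ca/Ti/Mn/Fe/Sr/Ba/Sc/Si, plus a 0.2% background on every element so no
column is degenerate).  Per-sample contributions `g` are lognormal
(median 1.2e5/2.0e5/1.0e5 ng/m³, log-sd 0.4 — comparable scales so no
source swamps the others through the background).  Noise is
multiplicative lognormal with CV 10% by default: concentrations are
positive and right-skewed, and a 10% measurement CV is realistic for
energy-dispersive XRF trace work.  Two optional meteorological couplings
inject known ground truth: a relative-humidity depletion `exp(−β·z(RH))`
acting on *all* elements (wet scavenging), and a hotspot coupling
multiplying the biomass-source contribution by `(1 + γ·z(HS300))`
(fire-driven burning activity).  The default config is the plain mixture
(β=γ=0); the `met_coupled` scenario (β=0.4, γ=0.5) is used wherever the
meteorological structure matters.  The met table itself draws from
plausible tropical ranges (RH 40–95%, Temp 15–35 °C, nested Poisson
hotspot counts with HS100 ≤ HS200 ≤ HS300); these distributions are
configuration, not contract.  True contributions are returned so
recovery can be scored.

**Calibrated fixture.**  A second generator reproduces the published
site-level statistics exactly: for each site and element it takes n
quantiles of the moment-matched lognormal (positive, right-skewed) and
applies an affine correction so the sample mean and sample sd equal the
published values to machine precision; extreme-CV cells fall back to a
clip-and-recentre loop that preserves the mean exactly and the sd to
within 5%.  Four As samples per site are marked not-detected, mirroring
the printed N.D. minima.  Sampling dates honour the published per-season
counts (Bangkok has no July–October samples).

What this does **not** emulate: real inter-element correlation beyond the
mixture structure, true seasonality of concentrations, autocorrelation in
time, matrix effects, or real meteorology.  Tests passing on these data
show the *machinery* is correct and that effects of the injected kind are
recoverable — not that the field conclusions would replicate on new
measurements.

## Site summaries and between-site ratios

Per site and element: mean, sample sd, min, max, n.  The between-site
comparison divides per-element means and, for the panel total, the sums
of the 25 per-element means in ng/m³.  Display rounding is two decimals,
matching the published table.

## Enrichment factors

EF(E) = (C_E/C_R)_air ÷ (a_E/a_R)_crust with Fe the reference element and
site-mean concentrations in the numerator (computing EF from means, not
the mean of per-sample EFs, reproduces the published Al anchors 1.17,
1.02, 1.32 exactly).  The default crustal table carries CRC-handbook
abundances with the Fe/Al mass ratio set to 0.33 — the value the Thai
source-apportionment literature adopts, and the only one consistent with
those anchors; the pure CRC table (Fe/Al = 0.68) is selectable, and the
table is an editable YAML config.  Classification on log₁₀EF: <1 not
enriched, [1,3) slightly, [3,4] moderately, >4 strongly.  The published
banding leaves [3,4] unnamed in one passage; we call it "moderately" and
make the edges configurable.  Note that only the Al/Fe pair of the
crustal table is pinned by published numbers; per-element EF magnitudes
for the other 16 elements depend on which crustal compilation is chosen.

## Receptor model (PCA / varimax / APCS-MLR)

1. **Standardise** each element column (mean 0, sd 1, n−1 denominator);
   complete-case over the panel.
2. **PCA** by eigendecomposition of the p×p correlation matrix; loadings
   are eigenvector·√eigenvalue; explained variance is eigenvalue/p.
3. **Retention**: components with eigenvalue strictly greater than 1.
4. **Varimax** rotation of the retained loadings with Kaiser row
   normalisation (undone afterwards), tolerance 1e-6 on the criterion,
   200 iterations maximum.  The rotation is orthogonal, preserves
   per-variable communalities, and never decreases the varimax criterion.
   Component signs are fixed so each component's largest-magnitude
   loading is positive; components are ordered by rotated variance.
5. **Scores**: regression (Thomson) factor scores W = S⁻¹Λ.  When the
   correlation matrix is exactly singular (noise-free low-rank data) the
   minimum-norm pseudo-inverse solution is used; the loadings lie in the
   span of S, so this is the consistent choice.
6. **Absolute scores (APCS)**: the score of an artificial
   zero-concentration sample, whose z-profile is z0_j = −mean_j/sd_j, is
   subtracted from every sample's score.  A zero sample then has APCS
   exactly 0, which makes scores interpretable as absolute source
   activities.
7. **Regression**: each species' concentration is regressed (OLS) on the
   k APCS columns; b_kj·APCS_ik is the contribution of source k to
   species j in sample i.  We regress each species, following the
   published procedure's description; classical APCS-MLR on total PM2.5
   mass is the textbook alternative and would need the (unavailable)
   gravimetric mass.
8. **Validation**: per-sample M/P = Σ_j measured / Σ_j predicted over the
   25-element panel; samples with non-positive predicted sums are flagged
   and excluded from site means.

Recovery is scored against the model-implied loading pattern
corr(x_j, g_k) — the profile expressed in the standardised metric, which
is what correlation-matrix PCA can see — and against the true per-sample
contributions, with greedy |r| matching to resolve component order and
sign indeterminacy.  At the validation scale used throughout (k=3,
n=200, CV 10%, fixed seed) the model retains exactly 3 components,
matched loading patterns and contributions correlate above 0.9, and
site-mean M/P stays within 1.00 ± 0.05.  The published loadings table
itself mixes in twelve auxiliary species (TC, OC, EC and ionic species)
whose raw values are not available, so it serves as interpretive
reference only.

## Seasonal diagnostic ratios

Ten ratio pairs (Ca/Al, Ca/Si, Zn/Al, Pb/Al, Fe/Al, Na/Mg, Ni/V, V/Fe,
As/V, Se/V).  Ratios are per sample (the seasonal summaries are means of
per-sample ratios — the form consistent with the published ±sd columns),
season-binned March–June / July–October / November–February.  Sites with
three populated seasons use the classical one-way F with df (k−1, N−k);
two seasons use the pooled two-sample t.  Critical values at p<0.05 come
from the F and t distributions; the t critical is one-tailed by default
because the published critical 1.678 at df≈46 is the one-tailed 95%
point (the two-tailed choice is a config switch).  The published F
critical 3.109 for (2, 79) df sits 0.003 below scipy's 3.112; both round
to 3.11 and we match at that precision.  Welch's correction is available
but off by default to match the printed degrees of freedom.  Pearson
correlation matrices are computed over complete cases; constant columns
yield flagged-undefined (NaN) entries.

## Network-based variable importance

A multilayer perceptron maps nine covariates — fire hotspot counts within
100/200/300 km, albedo, temperature, relative humidity, u/v wind
components and total precipitable water — to one element concentration at
a time.  Architecture: two sigmoid hidden layers, sigmoid output.
Covariates are standardised; the target is min-max scaled into
(0.01, 0.99) so the sigmoid output can attain it, with scalers retained
for inversion.  Hidden sizes default to (4, 3): with 48–82 samples per
site the capacity must stay small.  Training is full-batch gradient
descent on SSE = ½Σ(y−ŷ)² with a bold-driver step size (grow 5% on
success, halve and reject on failure), which makes the recorded training
loss monotone non-increasing; early stopping watches validation SSE with
patience 50 and restores the best state.  The optimiser itself is not
part of the contract — determinism under the seed is: the split
(random partition with round(0.7·n) training rows), the weight
initialisation and the importance permutations all derive from the
configured seed, and repeated runs are bit-identical.

Covariate influence is *permutation importance*: the mean increase in
test-set SSE over R=30 independent shuffles of one covariate column,
clipped at zero and normalised so the largest covariate scores exactly
100 (ties broken by covariate order).  Reported relative error is
SSE/TSS = 1 − R², the convention consistent with values both near zero
and near one in the published model summaries.  On the met-coupled
synthetic scenario the network puts RH at 100.0 with hotspot counts
second and inert covariates near zero — the qualitative structure the
generator injects.  Published SSE/importance numbers are not
reproducible without the raw data and are treated as qualitative
reference only.

## Inhalation risk

Non-carcinogenic: ADD = C·IR·ED·EFreq/(BW·AT_nc) in ng/kg/day and
HQ = ADD/RfD, flagged above 1.  Carcinogenic: LADD uses the same dose
with a lifetime averaging time AT_c = 70·365 d, SF = IUR·BW/IR, and
ELCR = LADD·SF classified against the acceptable band [1e-6, 1e-4].
IURs are declared per (µg/m³); an explicit 1e-3 ng→µg factor keeps
ELCR dimensionless.  Elements: HQ for Co, Ni, Cu, Zn, As, Pb; ELCR for
Ni, As, Pb.  Summaries are computed per sample and aggregated
(mean/sd/min/max); not-detected concentrations propagate as
not-detected, forcing an "N.D." minimum.  Because both metrics are
linear in C, evaluating at site means equals the mean of per-sample
values, which the tests exploit as an oracle.

Exposure-factor provenance: the campaign's exposure and toxicity
supplements are not machine-readable, so the defaults were
*reconstructed* from its published risk tables.  ELCR is independent of
IR and BW (they cancel between LADD and SF), which pins EFreq = 350
d/y, ED = 6 y (adolescents, 12–18) and 24 y (adults), AT_c = 70·365 d,
and the IURs As 4.3e-3, Ni 2.4e-4, Pb 1.2e-5 (µg/m³)⁻¹ — the EPA IRIS
inhalation unit risks, which reproduce the published cancer-risk table
to its printed precision.  The HQ side then fixes the dose factors
IR·EFreq/(BW·365): adult IR/BW = 18/80 with the standard inhalation
RfDs for Zn (3.01e-1), Cu (4.02e-2) and Pb (3.52e-3 mg/kg/day), and
adolescent IR/BW = 18/43.39 with the implied RfDs for As (50.2), Ni
(200.5) and Co (2.01e5 ng/kg/day).  These reproduce the published
hazard quotients to three significant figures (e.g. As at Bangkok:
adolescent 0.225, adult 0.122) but are reconstructions, not quoted
source values; all of them live in one editable YAML config.

## Numerical choices and degenerate inputs

- Constant columns abort standardisation and feature preparation with an
  error naming the column; constant correlation entries are NaN-flagged.
- Eigenvalues are clipped at 0 (they are ≥ 0 in exact arithmetic).
- Varimax with k=1 returns its input unchanged; non-convergence warns
  and returns the best-so-far rotation, flagged.
- OLS uses `lstsq`; rank-deficient APCS designs are rejected.
- Zero pooled variance with equal means yields t = 0.
- Zero target variance makes the network's relative error undefined
  (NaN, with a warning); a zero-variance target still trains (bias-only
  solution).
- The pipeline is a pure function of (inputs, config, seed): outputs are
  byte-identical across reruns, and every TSV carries provenance headers
  (stage, seed, input checksum) plus a JSON manifest.

## Problem sizes

The validation suite runs at desk scale, chosen to exercise every code
path while keeping the full suite near ten seconds: mixtures of n=200
(recovery), n=300–600 (distributional sign checks), the calibrated
three-site fixture at its natural 82/48/61, and networks trained on
191–300 samples for up to 2000 full-batch epochs.

## Known limitations

- PCA-based apportionment cannot separate more than ~8 sources and
  confounds collinear ones; no PMF/CMB/UNMIX alternative is provided.
- No uncertainty propagation on EF, loadings or risk (no bootstrap, no
  Monte-Carlo risk).
- The crustal table, exposure factors and RfD/IUR sets are configs with
  documented defaults; conclusions scale directly with them.
- Only the inhalation pathway is modelled — no dermal or ingestion dose,
  and no population-attributable burden.
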