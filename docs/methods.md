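# Methods

## Isotopomer model

Natural-abundance isotopologue distributions are computed by truncated
polynomial convolution: each element contributes the n-fold convolution of
its single-atom isotope-abundance vector (IUPAC representative terrestrial
values, hard-coded in `isotopomers.ISOTOPE_ABUNDANCES`: ²H 0.000115, ¹³C
0.0107, ¹⁵N 0.00364, ¹⁷O/¹⁸O 0.00038/0.00205, plus F, P, S, Cl, Br), with
mass indexed by nominal shift above monoisotopic. Distributions default to
truncation at M4; EM1 uses only M0/M1 and the truncation error at M4 is
orders of magnitude below GC/MS precision. Tests verify the convolution
against an independent exhaustive per-element multinomial enumeration to
1e-12 per mass.

The analyte defaults to the pentafluorobenzyl ester of alanine
(C₁₀H₈F₅NO₂), matching the NCI-GC/MS derivatization chemistry. The exact
fragment monitored by a given instrument method may differ; the formula is
a config-exposed assumption, and only relative M1 excess enters downstream
results.

**Labeling.** A fully newly synthesized population incorporates deuterium
binomially across `n_sites` = 4 alanine C–H positions. A site exchanges
with body water with probability `site_exchange_fraction × p`; otherwise it
retains natural ²H abundance, i.e. the per-site ²H probability is
`q = c·p + a₂H·(1 − c·p)` — the labeled sites' natural deuterium is
replaced by the labeling term, not double-counted, and `p = 0` reproduces
natural abundance exactly. The remaining atoms convolve in at natural
abundance.

**Calibration.** The observable anchoring the model is the low-enrichment
amplification A = lim EM1max(p)/p = 2.7, the empirical body-water→alanine
correlation. Analytically A = n·c·(1 − a₂H)·(R₀ − R₁ + …) where R are the
natural fractions of the remaining atoms, so A is *not* simply n·c; the
package therefore calibrates c numerically (linear solve from one probe
evaluation at p = 1e-6) so that the computed limit equals 2.7 for the
default analyte, giving c ≈ 0.856. `LabelingModel.amplification()` always
reports the computed limit rather than n·c.

EM1max(p) is strictly increasing only while the site-binomial M1 term rises
(q < 1/n, i.e. p below ≈ 0.29 for the calibrated model); study enrichments
are 1–2%, far inside the monotone regime, and the property is tested on
[0, 0.25]. EM1 is not clamped at the isotopomer layer — noisy measurements
may legitimately be slightly negative; clamping is a kinetics-layer
decision.

## Body-water enrichment

The dosing protocol (50 mL × 70% ²H₂O twice daily at 08:00 and 20:00,
Monday–Friday, study start on a Monday by default) expands to explicit
impulse doses. The forward model is a one-compartment superposition: each
dose raises enrichment by volume × purity / body-water volume and decays
first-order at the water turnover rate. Defaults — 42 L total body water,
0.10/day turnover (water half-life about a week) — are textbook adult
values and config-exposed; the model exists to generate realistic curves
and is verified against numerical ODE integration to 1e-8. With these
defaults the plateau sits near 1% with weekend sawtooth dips.

When saliva measurements exist they take precedence (as in the study
design): the curve is their piecewise-linear interpolant, held flat outside
the measured span, with (0, 0) prepended since labeling starts unenriched.
Saliva is treated as body water 1:1 with no lag.

The precursor term of the fractional-synthesis ratio is the time-averaged
enrichment p̄(t) = (1/t)∫₀ᵗ p ds, computed by trapezoid on the curve's
native grid (simulated curves are emitted on a 0.05-day grid; the
integration error is far below EM1 noise). Extrapolation beyond the curve
span carries the last value and warns.

## Conveyor kinetics

f(t) = EM1(t)/EM1max(p̄(t)) per tape-strip day; raw and clamped-to-[0,1]
values are both reported and fitting uses the clamped values (noise pushes
near-plateau ratios above 1). Day-0 or zero-precursor points are excluded
and reported.

The fitted form is the pure-delay conveyor with single-pool replacement,
f(t) = 1 − exp(−k(t − τ)) for t > τ: the simplest model producing the
observed delayed-rise shapes. The study itself reports lag windows rather
than a fitted rate; the exponential-rise k is this package's
operationalization of "turnover rate".

Fitting is profiled least squares: τ on a 0–30-day grid in 0.25-day steps
(tape strips every 2–5 days cannot resolve finer; exact RSS ties resolve to
the smaller, earlier-appearance τ), and for *every* grid τ the optimal k is
found by a coarse 64-point geometric grid on [1e-3, 25]/day refined by a
vectorized golden-section search — refining k at every τ (rather than only
at the coarse winner) is required for the profile minimum to land on the
correct τ. Confidence intervals are percentile bootstrap (default 500
replicates, resampling points with replacement, seeded; intervals are
widened if needed to bracket the point estimate).

Degenerate data are flagged rather than fitted silently: if no point shows
label, τ is reported as a lower bound at the last sampled day
(`non_identifiable`); if every post-lag point is at plateau (f ≥ 0.99), k
is only a lower bound (`k_lower_bound`) — the fast lesional sites often
saturate this way, which is itself the finding that the stratum corneum is
fully replaced between samplings.

`appearance_time` is the first sampled day with clamped f above the
detection threshold (default 0.05, comfortably above the zero-noise floor
at ~1% plateau enrichments). `compare_sites` reports per-group median/range
of τ and k plus within-subject between-site τ spread.

**Estimator calibration.** Monte-Carlo tests (seeded) check that with 5%
relative EM1 noise and ten sampling days at a 2-day cadence through the
rise, τ = 4 d / k = 1/day is recovered within ±1 day in ≥ 90% of
replicates with |bias| < 0.5 day. The cadence matters: with 3-day spacing a
fast rise leaves a single informative point and the τ estimate ridges
against neighbouring sampling days; resolving a lesional lag to ±1 day
requires sampling roughly every 2 days around onset.

## Proteomics summary

Abundance index = total peptide count / molecular weight × 10³ (reported to
2 decimals); tables are ranked descending with ties broken by count then
name. The keratin fraction is the percent of total spectral counts from
records whose name begins with "Keratin" (case-insensitive, with a
config-exposed override list), reported to the whole percent. The bundled
pilot tables give 98% for uninvolved skin. The psoriatic table lists only
the most prominent proteins of the ~66 detected, so its keratin fraction
describes that subset and is flagged `subset_only`; it is not comparable to
a full-isolate figure.

## TEWL

Means and sample SDs of duplicate evaporimeter readings (SD = 0 flagged at
n = 1); per-subject lesional minus non-lesional differences on exactly
shared days (nearest-day matching is not needed for protocol-paired
sampling); cohort sign counts; and per-site day-to-day CVs, since TEWL's
day-to-day noise is the practical limit of the measurement. No hypothesis
test is computed — only descriptive contrasts.

## Synthetic cohorts

The generator reproduces the study conditions: 4 subjects by default, each
with 2 lesional + 2 uninvolved sites, dosing durations uniform on 16–38
days, the Monday–Friday twice-daily protocol, and tape-strip days from the
menu {3, 6, 8, 10, 13, 15, 17, 20, 24, 28, 31, 35, 38} truncated to each
subject's duration (a 2–5-day cadence whose points cover both detection
windows), closing at end of study when ≥ 2 days past the last menu day.

Kinetic truth is anchored on detection, because the study's 3–8-day
(lesional) and 10–20-day (uninvolved) windows describe when label was
*observed* at the surface: each site's first-detection day is drawn
uniformly from the sampling days inside its window, and τ is then drawn on
the 0.25-day lattice between the preceding sampling day and the detection
day (less a margin ensuring f crosses the 0.05 threshold). Lesional lags
may therefore fall below 3 days — consistent with first sampling occurring
only at day 3 — and uninvolved lags always exceed the same subject's
lesional lags. The detection day is also required to precede the final
sampling day: with a single post-onset observation (τ, k) lies on a ridge
and no estimator could recover it, so generated truth is kept observable by
design. Placing τ on the fitter's quarter-day lattice makes zero-noise
truth exactly representable, so closed-loop recovery is exact rather than
merely within a grid step.

Rates: lesional k ~ U(1.0, 1.5)/day, satisfying 1 − exp(−5k) > 0.99 (the
pool fully replaced in under 5 days); uninvolved k ~ U(0.12, 0.18)/day, a
range centred on 0.15/day chosen to plateau over ~2–3 weeks after the lag —
plausible for an ~18-day healthy transit but not anchored to any printed
value. EM1 noise is multiplicative Gaussian (default relative SD 5%,
negative draws clamped to 0), reflecting signal-proportional isotope-ratio
noise; no error model is available from data. EM1 truth is computed through
the same measured-saliva pathway the analyzer uses (saliva sampled from the
simulated curve on tape-strip days, then interpolated), so at zero noise
the pipeline reproduces generating f exactly.

TEWL: lesional site means 25 and non-lesional 8 g·m⁻²·h⁻¹ (±8% per-site
jitter, 15% per-reading noise) — values chosen only to enforce the
lesional > non-lesional ordering, not to match any published magnitudes.
Spectral-count tables are multinomial resamples of the bundled pilot
tables' count proportions at the same totals.

**What the generator does not emulate:** treatment effects, within-site
depth profiles across sequential tape strips, between-day sampling-area
drift, correlated (non-independent) measurement errors, saliva measurement
noise, or per-protein turnover heterogeneity. Passing closed-loop tests
therefore demonstrates the estimator and pipeline are self-consistent under
the stated noise model — not that real tape-strip data meet these
assumptions.

## Problem sizes

Default test and demo runs use 4-subject cohorts (16 sites, ≤ 13 sampling
days each), 100-replicate Monte-Carlo calibrations, and 0–500 bootstrap
replicates per fit; a full analyze run with 100 bootstrap replicates on 16
sites completes in a few seconds on one core.

## Known limitations

- The conveyor model pools all tape-strip protein into one compartment; it
  cannot separate co-isolated non-keratin protein kinetics (substantial in
  plaques) from keratin itself.
- k is reported as a lower bound whenever the rise saturates between
  sampling days — for strongly lesional sites only τ is genuinely
  identified.
- The analyte fragment formula and the site-exchange calibration are tied
  to the 2.7 amplification; a different instrument fragment requires
  re-calibration via the config.
- The one-compartment body-water model ignores isotope fractionation and
  multi-pool water kinetics; it is a stand-in used only when saliva
  measurements are absent.
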