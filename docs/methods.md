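# Methods

## The two-state head-accounting model

A two-headed cardiac myosin population is treated as a mixture of two
kinetic states: an open (disordered-relaxed, DRX) state that turns over
ATP at the basal rate and a sequestered (super-relaxed, SRX) state in
which the heads are folded back against the proximal S2 tail and turn
over ~10-fold slower.  Two independent observables report the mixture:

1. **Single-turnover amplitudes.**  After a cold-ATP chase of bound
   mant-ATP, fluorescence decays as
   `F(t) = a_slow·exp(−k_slow t) + a_fast·exp(−k_fast t) + c`.
   The amplitude fractions are the SRX/DRX head fractions; the nominal
   rates are 0.003 and 0.03 s⁻¹.
2. **kcat ratios.**  A construct with a long (25-heptad) S2 tail can fold
   back; its 2-heptad sibling cannot and serves as the fully-open control
   with the same catalytic head.  If a fraction s of the tailed
   construct's heads is sequestered (and contributes nothing to
   actin-activated turnover), the ratio r of the two kcat values is
   1 − s.

Both observables feed the same bookkeeping: with wild-type ratio `r_wt`
and mutant ratio `r_mut`, the fraction of the wild-type sequestered pool
released by the mutation is `(r_mut − r_wt)/(1 − r_wt)`; with
single-turnover fast fractions, the SRX pool decrease is
`(SRX_wt − SRX_mut)/SRX_wt`.  When ratios equal open-head fractions the
two statistics coincide identically, which the tests verify.  Raw values
outside [0, 100]% are reported clamped **with a flag and the raw value
retained** — a mutant can release slightly "more than" the wild-type
pool through measurement error, and that information is not discarded.
Derived percentages are rounded half-up to integer percent only at the
reporting layer.

## Fitting choices

**Exponential decays** (`srxquant.turnover`).  Bounded nonlinear least
squares (`scipy.optimize.least_squares`), rates constrained to
[1e-5, 1] s⁻¹, amplitudes to [0, 1.5], initialized at the nominal
0.003/0.03 s⁻¹ rates with an even amplitude split, with up to five
log-spaced multi-start restarts if the first attempt fails.  The model
includes a non-negative plateau `c` because real chase traces do not
decay to zero; fixing `c = 0` recovers the strict two-term model.
Two-component fits are canonically ordered slow-first; if the optimizer
converges to two equal rates the amplitude split is unidentified and all
amplitude is assigned to one component.  Model selection between one and
two components uses the small-sample-corrected Akaike criterion with a
parsimony tie-break.  Phases are labelled DRX/SRX by log-space proximity
to the nominal rates; if both fitted rates sit nearer the same nominal
value the summary is flagged ambiguous and falls back to rate order.

**Normalization.**  A raw trace is mapped affinely so its first fitted
point is 1 and its estimated long-time plateau is 0 (time axis shifted to
t = 0).  The plateau is estimated by a preliminary two-exponential-plus-
offset fit on the unit-range-rescaled signal (offset unbounded below at
this stage).  Because that estimate is an affine-equivariant least-squares
functional, normalization is exactly idempotent and invariant to affine
transforms of the raw signal — properties the test suite asserts at
1e-9/1e-6.

**Michaelis–Menten** (`srxquant.atpase`).  Unweighted least squares of
`rate = basal + kcat·[A]/(K_M + [A])`.  When the titration includes
[A] = 0 points the basal rate is fixed to their mean (the titrations
start at zero actin); otherwise it is fitted.  Uncertainties come from
resampling the (concentration, rate) points with replacement — 100
iterations by default — and refitting; the point estimate is always the
full-data fit.  A bootstrap refit whose K_M exceeds the titrated actin
range saw no saturation in its resample, cannot identify kcat, and is
counted as unconverged; more than 20% such failures aborts with the
failure rate.  Ratio errors use first-order propagation (relative errors
in quadrature); a bootstrap-of-ratios alternative can be assembled from
the per-fit bootstrap draws if needed.

**Hill isotherms** (`srxquant.binding`).  Least squares of
`baseline + amplitude·xʰ/(K_Dʰ + xʰ)` with the Hill coefficient bounded
to [0.25, 4] (free by default; fixable, h = 1 giving the Langmuir
isotherm).  K_D uncertainties are across-replicate SEMs, not per-fit
covariances, matching how replicate binding experiments are summarized.
An isotherm whose fitted amplitude is below three residual standard
deviations is returned unconverged with "no binding signal".
Thermophoresis-trace preprocessing (Fnorm extraction) is out of scope:
inputs are already-reduced dose-response points.

**Top-fraction velocity** (`srxquant.motility`).  Mean of the largest
`ceil(0.05·n)` per-filament velocities (floor rounding selectable).
Construct comparisons t-test the per-movie statistics, not individual
filaments.

**Replicate aggregation.**  Hierarchical: technical replicates are
averaged within each biological preparation first; reported means and
SEMs are computed across preparation means (n = number of preparations).
With no replicate design every replicate is its own group (pooled SEM).

**Significance tests.**  Two-sided two-sample t-test, Welch
(unequal-variance) by default with the classical pooled form selectable.
Two zero-variance samples with equal means give p = 1 by convention.

## Synthetic data: what it emulates and what it does not

`srxquant.synthetic` draws each data kind from the closed-form model plus
additive i.i.d. Gaussian noise, with the generating parameters stored in
the output metadata (never read by fitters).  Defaults encode the study
conditions:

| quantity | default | why |
|---|---|---|
| sampling | every 2 s for 16 min (481 points) | plate-reader protocol for the chase |
| nominal rates | 0.03 / 0.003 s⁻¹ | basal (DRX) and SRX turnover |
| trace noise | sd 0.01 (normalized units) | typical plate-reader scatter |
| actin grid | {0, 2.5, 5, 10, 20, 40, 80} µM ×3 | log-ish spacing over the titrated range; three measurements per concentration as in the assay |
| ATPase K_M / basal | 15 µM / 0.03 s⁻¹ | typical half-saturation for these constructs; basal equals the DRX turnover rate |
| rate noise | sd 0.05 s⁻¹ | a few percent of kcat |
| titrant grid | 16 points, ~1.6-fold dilution, 1–1000 µM | 16-capillary instrument; brackets double-digit-µM affinities; each K_D determination pools triplicate isotherms |
| isotherm noise | sd 0.1 (10% of unit amplitude) | conservative MST scatter |
| velocities | truncated normal, CV 0.15 | non-negative, unimodal |

Per-construct presets (`CONSTRUCT_PRESETS`) carry the measured fast
fractions, kcat values (2-hep kcat 2.4 s⁻¹, 4.2 s⁻¹ for I457T; 25-hep
kcat = ratio × control), K_D values (37/45/58 µM) and top-5% velocities
(700/1700 nm/s).  Because a printed gliding velocity *is* the top-5%
statistic, `velocity_normal_from_top_fraction` inverts the normal
upper-tail mean to find the per-filament distribution whose top-5% mean
reproduces it.

The generator does **not** emulate: pre-chase dead time (the time axis
starts at the chase), photobleaching or baseline drift, correlated or
signal-proportional noise, stuck-filament contamination of velocity
tables, or inner-filter/depletion effects in the isotherms.  Passing
recovery tests therefore demonstrate that the estimators are correct and
well-calibrated under the stated noise model — not that they are robust
to every artifact of real instrument data.

## Problem sizes

The recovery ensembles are sized to estimate the relevant error
statistics stably: 200 traces for the fast-fraction ensemble (SEM of the
mean ≈ 0.1 points), 100 bootstrap iterations per titration and 200
Monte-Carlo regenerations for the bootstrap-calibration check, 100
isotherms for the median K_D error.  These match the conditions under
which the package's accuracy claims are made.

## Known limitations

* The two-component decay model cannot resolve rate separations below
  ~3-fold at realistic noise; the classifier flags such fits ambiguous
  rather than guessing.
* Case bootstrap on sparse titrations (one measurement per concentration)
  over-disperses kcat errors because resamples can lose the saturating
  anchor points; with the triplicate design used here it is calibrated to
  the Monte-Carlo truth within 2-fold.
* The kcat-ratio accounting assumes sequestered heads contribute zero
  actin-activated turnover and that the 2-hep control is fully open; any
  partial activity of folded heads biases the sequestered fraction
  downward.
* Percent-sequestered and conversion statistics are ratios of noisy
  estimates; their first-order propagated errors understate uncertainty
  when the wild-type ratio approaches 1.
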