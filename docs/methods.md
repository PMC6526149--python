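# Methods

`flownmr` re-creates, end to end, a quality-monitoring and control stack
for a continuous lithiation reaction: aniline and 1-fluoro-2-nitrobenzene
(o-FNB) are coupled with lithium hexamethyldisilazane (LiHMDS, fed in at
least 2:1 molar excess) in THF, producing lithium 2-nitrodiphenylamine
(Li-NDPA).  The stack has five layers — benchtop-NMR spectrum
preparation, Indirect Hard Modeling (IHM) quantification, steady-state
gating, NIR calibration transfer by PLSR, and modifier-adaptation
real-time optimization (MAWQA) — plus a virtual plant that generates
every input the other layers consume, so the whole package is testable
without instrument data.

## NMR spectrum preparation (`nmr_processing`)

FIDs are zero-filled (default 64 k points), apodized with
`exp(-pi * LB * t)` (LB = 0.5 Hz, adding exactly LB of Lorentzian
width), Fourier-transformed, and mapped to a ppm axis through the
43.32 MHz proton frequency.  The preparation chain then runs

1. **Baseline**: a low-order polynomial (default order 2) fitted to
   signal-free points found by iterative clipping.  The noise scale is
   the MAD of the residuals (robust while most points still sit on
   peaks); clipping is two-sided, because deep negative excursions are
   misphased dispersion, not baseline; the signal mask is dilated by 1%
   of the axis so Lorentzian wings do not drag the polynomial into the
   lineshape.
2. **Phasing**: zero- and first-order phase by minimizing the squared
   negative intensity of the rotated real channel.  Squaring weights
   the deep dispersion lobes of genuine misphasing far more than the
   shallow dips an imperfect baseline leaves.  Because rotation
   re-bends whatever baseline was already subtracted, every score
   detrends against an order-2 polynomial through the quiet points
   (lowest three quarters of the rotated channel, reselected per
   evaluation).  A 5-degree coarse scan of the zero-order term seeds a
   Nelder-Mead refinement; the objective is evaluated on a 2x-decimated
   grid since phase varies far more slowly than the axis.
   Baseline and phasing are interdependent, so the chain applies the
   pair twice; two passes settle in practice.
3. **Alignment**: icoshift-style interval alignment to a reference
   spectrum — per ppm interval, the integer lag maximizing the
   cross-correlation, clamped to a configured maximum, vacated points
   filled with edge values.

Accuracy on synthetic lines: a known zero-order rotation is recovered
within ~1 degree; a noiseless decaying sinusoid transforms to a
Lorentzian whose width matches `LB + 1/(pi*T2*)` within 2%.

## Indirect Hard Modeling (`ihm`)

At 43 MHz the aromatic multiplets overlap, so per-peak integration is
not possible.  Each analyte is a frozen *pure-component model*: a sum
of pseudo-Voigt peaks (`eta*Gaussian + (1-eta)*Lorentzian`, shared
position and FWHM, areas computed analytically).  The mixture fit
minimizes the squared residual over, per component: a non-negative
intensity weight, a bounded global shift (±0.05 ppm), a bounded common
width-scale factor ([0.8, 1.25]), and optionally a small per-peak shift
(±0.01 ppm); a polynomial baseline (order 2) is fitted jointly.
Because every peak of a component shares one width scale, the
intra-component area ratios are preserved *exactly* — the constraint
that makes component areas physically meaningful.  Gaussian fractions
are frozen at the pure-component fit.  The optimizer is bounded
trust-region least squares; single-spectrum fits use up to three
jittered starts (seeded), while series quantification warm-starts each
spectrum from the previous solution.

Concentrations follow the one-point calibration

    c_i = xi * A_i / nu_i

with `A_i` the fitted absolute integral, `nu_i` the proton count, and
`xi` fixed once per production day from the pure o-FNB stream of known
concentration (0.63 mol/L at start-up).  The calibration/quantification
round trip on the calibration stream is exact by construction.

## Steady-state gating (`steady_state`)

A centred 11-point ordinary least-squares line runs over each analyte's
concentration series (15-s spacing).  A point is steady only if, for
*every* analyte, |slope| < 0.1 mol L⁻¹ h⁻¹ and the SD of the fit
residuals (n−2 denominator) < 0.01 mol/L.  The printed slope threshold
is dimensionally ambiguous ("mol h⁻¹"); it is read as a concentration
trend because the fitted values are concentrations.  Residual SD rather
than raw SD avoids double-counting the slope.  Steady stretches are
smoothed with a trailing 6-point moving average over steady points
only.  NMR references pair with NIR spectra after compensating the
120-s inter-sensor delay; a NIR spectrum is excluded from calibration
unless the nearest delay-shifted NMR point is steady and within 15 s
(nearest-neighbour, ties to the earlier point).

## NIR chemometrics (`nir_chemometrics`)

The FT-NIR spectra span 4000–12000 cm⁻¹ (2074 points); the regions
above 8975 and below 4611 cm⁻¹ are noise-dominated, so quantitative
work uses the central window.  Preprocessing is an ordered per-analyte
pipeline: range selection, SNV (sample SD), and polynomial or offset
baselines fitted to window-endpoint support regions (outer 15% per
side, so the analyte band in the middle is untouched).  The order is
fixed: select the range, then SNV — normalizing first would leak
edge-noise statistics into the working region.  Default factor counts
are 1 (aniline), 3 (o-FNB), 5 (Li-NDPA), 4 (Li-aniline); Li-NDPA uses
the whole working window.  The aniline/Li-aniline feature windows are
configuration values (their reference values live in supplementary
material not reproduced here); the defaults cover the synthetic band
positions.

PLSR is NIPALS (via scikit-learn) with mean centring; factor counts
exceeding the data rank are truncated with a warning.  Validation
follows the three-way scheme: cross-validation over 20 random segments
(seeded Fisher–Yates shuffle, near-equal segments, default seed
20171017), systematic leave-one-run-out cross-validation, and
prediction of a held-out run.  Models work in mol/L; reports are in
mmol/L.

## Virtual plant (`plant_simulator`)

The reactor model is steady-state stoichiometry plus a smooth
saturating conversion law — deliberately simple, because the stack
above it is the object of study:

- molar feed flows from mass flow, density (0.90 kg/L per stream,
  consistent with the 900 kg/m³ mixture density) and concentration
  (start-up: o-FNB 5.60 kg/h at 0.63 mol/L, aniline 3.68 at 0.96,
  LiHMDS 6.89 at 1.10 — LiHMDS excess factor 2.14);
- a moisture sink removes `moisture_sink` mol/h of LiHMDS (residual
  water in technical-grade solvent);
- reaction extent = smooth-min(n_aniline, n_oFNB, n_LiHMDS_eff / 2) ×
  eta, with eta = excess / (excess + k_sat) and excess the effective
  LiHMDS over twice the limiting aryl flow.  The min() switches are
  blended over a 0.25 mol/h scale: a real tubular reactor transitions
  smoothly between limiting regimes, and the blending keeps the profit
  surface differentiable for the optimizer;
- a fixed fraction (0.30) of unreacted aniline leaves as the lithiated
  intermediate, consuming one LiHMDS each;
- outlet concentration = molar flow / volumetric flow (sum of mass
  flows over the mixture density).  Aryl and fluoroarene balances close
  to 1e-9 relative by construction.

The "true" plant re-uses this structure with different parameters
(k_sat 0.12 vs 0.05, moisture sink 0.6 vs 0.3 mol/h, mixing efficiency
0.95 vs 1.0), so the nominal model has both parametric and structural
bias — its profit surface peaks at a different place and grossly
overestimates the achievable profit.

**NMR forward model.**  Spectra are synthesized on a 2048-point 0–11 ppm
grid as superpositions of the pseudo-Voigt component models, scaled so
`area/nu` is proportional to concentration with a fixed ground-truth
conversion factor; the imaginary channel comes from the Hilbert
transform so phase errors can be applied and corrected.  Per-spectrum
perturbations: white noise (sd 0.012 intensity units), global ppm
jitter (sd 0.002 ppm) and zero-order phase jitter (sd 0.5°).  These
magnitudes were fixed by a consistency argument: the steady-state
thresholds (residual SD < 0.01 mol/L over 11 points) only admit steady
states if the point-to-point scatter of quantified concentrations is a
few mmol/L, so the published RMSE range of 5–16 mmol/L for this kind of
sensor must be bias-dominated; the defaults give ~1–3 mmol/L scatter
and 4–12 mmol/L RMSE over the full 0–1.2 mol/L range, both inside the
published envelope.

**NIR forward model.**  Absorbance on the instrument's 2074-point grid
as concentration-linear Gaussian bands (all quantitative bands inside
the working window, overlaps intentional) over a fixed solvent
background, with multiplicative scatter (gain sd 5%, offset sd 0.01 —
both SNV-removable) and heteroscedastic noise amplified 20x in the two
edge regions.

**Campaigns.**  A schedule of feed set-points (default: ~10-min holds,
set-points within ±30% of start-up) drives first-order outlet
relaxation (tau = 120 s); NMR spectra are emitted every 15 s and NIR
spectra every 160 s, reflecting the outlet 30 s and 150 s earlier
(120-s inter-sensor offset).  All randomness flows through one seeded
generator; identical seeds give byte-identical bundles.

What the generator does *not* emulate: temperature excursions,
particle/fouling drift in the optical path, slow spectrometer drift
between runs, non-linear NIR response at high absorbance, and kinetic
transients faster than the first-order relaxation.  Passing tests
therefore demonstrate the correctness and internal consistency of the
algorithms under representative noise, not instrument-grade validation.

## Real-time optimization (`rto_mawqa`)

The profit of an operating point is

    Profit = w4 * M_LiNDPA * c_LiNDPA / rho_mix * (u1+u2+u3) - sum(w_i * u_i)

with weights (10000, 25000, 12000, 450000) per kg, M = 0.2202 kg/mol
(computed from C12H9LiN2O2), rho = 900 kg/m³, and c the *measured*
product concentration in mol/m³ (the NMR pipeline's mol/L × 1000).

Modifier adaptation corrects the optimization problem instead of the
model: at each iterate the modified objective
`J_model(u) + epsilon + lambda . (u - u_k)` is maximized inside a trust
region subject to box bounds and the stoichiometric constraint
n_LiHMDS ≥ 2 n_aniline (linear in u under the configured feed
concentrations).  `epsilon` is the plant–model profit bias at u_k;
`lambda` is the gap between the estimated plant gradient and the model
gradient.  Plant gradients come from a full quadratic surrogate
regressed over history points within a radius (3× the trust radius),
screened for geometry: at least 10 points, de-duplicated, design matrix
condition below 1e8 — otherwise the loop performs axis/diagonal probing
moves scaled to the current radius.  Start-up performs one probing star
(step 5% of ||u0||).

Trust-region management: start at 10% of ||u0||, grow ×1.3 on strict
improvement (capped at 50% of ||u0||), shrink ×0.5 on a losing or null
move (the incumbent is kept; the loop moves back to it before handing
over).  A measurement far off the modifier-corrected prediction is
disambiguated by re-measuring the incumbent: only a true disturbance
changes the profit at an unchanged operating point, and then the
surrogate history is flushed, the trust radius reset, and probing
restarted — this is what re-converges the loop after an unannounced
feed-batch change.  Convergence: the modified problem stationary within
tolerance (1e-3 kg/h) once the trust region is refined.

The start-up point (3.58 kg/h each) violates the stoichiometric
constraint — the plant is commissioned far from the optimum — so the
optimizer includes a restoration step: when the feasible set does not
intersect the trust ball, it steps toward the closest feasible point
instead of optimizing.  The constraint is therefore guaranteed at
convergence, not along the whole path, and the converged ratio ends
just above 2 (the economic optimum pushes LiHMDS down onto the
stoichiometric boundary while throughput rides the box bound).

With noiseless measurements the loop reaches the true plant's
brute-force grid optimum (51³ points over the feasible box) within 1%
in ~25 iterations.  With NMR-scale measurement noise (a few mol/m³ on
~200 mol/m³) the profit still improves dramatically over start-up, but
the surrogate gradients are noisy enough that the final gap can exceed
1%; the noiseless mode is the oracle configuration for convergence
checks, matching how the loop's fixed-point property is defined.

## Problem sizes and numerical choices

- NMR grid 2048 points over 0–11 ppm for synthesis and fitting; 64 k
  zero-filling is exercised in the FID-processing tests.
- Quantification studies: 200 spectra for error statistics; campaigns
  of 5 holds × 10 min per run, 4 runs for the transfer study (~200 NMR
  and ~18 NIR spectra per run).  These sizes give stable statistics
  while keeping a full study in minutes on one core.
- Mixture fits: `scipy.optimize.least_squares` (trf), 2-point
  Jacobians; warm starts make series quantification ~10x faster than
  cold fits and deterministic.
- The brute-force profit oracle enumerates a 51³ grid with the
  stoichiometric constraint applied before evaluation.
- Degenerate inputs fail loudly: zero/flat spectra, zero-variance SNV
  input, empty test sets, unknown run ids, non-positive calibration
  inputs all raise.

## Known limitations

- The pure-component models are synthetic (representative positions and
  linewidths, areas normalized to proton counts); real 43-MHz models
  would come from measured pure-component spectra via
  `fit_pure_component`.
- JCAMP-DX support covers AFFN `##XYDATA` tables (plus a basic NTUPLES
  page reader) — not the compressed DIFDUP encodings.
- The steady-state classifier is a batch recomputation, not a streaming
  implementation; identical flags, different plumbing from a live
  plant.
- MAWQA's convergence guarantee is empirical here; no global-convergence
  claim is made, and heavy measurement noise degrades the final gap as
  described above.
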