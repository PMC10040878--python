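# Methods

## Model and assumptions

The abdominal aorta is treated as an incompressible thin-walled cylinder.
Under the membrane assumption the stress is uniform across the wall,
radial stress is negligible, and the circumferential and longitudinal
membrane stresses follow from equilibrium alone (Laplace's law) given the
lumen pressure P, the inner radius r0 and the wall cross-sectional area A:

    sigma_theta_lp = (4 pi r0^2 + A) P / (2A)
    sigma_z_lp     = (pi r0^2 P + F) / A

A is not measurable in the recordings the pipeline targets, so it comes
from published age regressions (A = 19.60 + 0.80 age mm^2 in males,
A = 20.52 + 0.56 age mm^2 in females).  The in-situ axial force F is
assumed pressure-independent and fixed by assuming a known stress ratio
gamma = sigma_z/sigma_theta = 0.59 at the reference pressure 13.3 kPa;
the subject's reference radius is read off the averaged loop by linear
interpolation at that pressure (both limbs averaged).  Both gamma and the
reference pressure are configurable; 0.59/13.3 kPa are the published
population values.

The wall material is the standard two-fiber-family HGO solid,

    psi = c (I1 - 3) + (k1/k2) (exp(k2 (I - 1)^2) - 1),

with mid-wall circumferential stretch
lambda_theta = (R0/r0)(4 pi r0^2 + A)/(4 pi R0^2 + lambda_z A) and the
incompressibility multiplier p = 2 c (lambda_theta lambda_z)^-2 obtained
from a vanishing transmural stress.  The resulting stresses split exactly
into isotropic and anisotropic parts; the package never re-merges them,
so additivity (tot = iso + aniso) holds to machine precision everywhere.

Two modelling choices deserve emphasis:

* **No tension-only switch.**  The fiber term is evaluated as written even
  when I < 1 (fibers shorter than their unloaded length); a runtime
  warning flags such states.  With lambda_z >= 1 and physiological
  circumferential stretches they are rare in practice, but random
  multistart points do visit them.
* **Single mean fiber angle.**  The two fiber families are symmetric about
  the circumferential direction, so one invariant I with one angle beta
  represents both.

## Parameter identification

The six parameters kappa = (c, k1, k2, beta, R0, lambda_z) minimise the
summed squared mismatch between constitutive and Laplace stresses over the
averaged loop, subject to box bounds (c, k1 in [1e-4, 5e5] kPa, k2 in
[1e-4, 1e3], beta in [1e-6, 90] deg, R0 in [1, 20] mm, lambda_z in [1, 5];
the unit lower bound on lambda_z precludes buckling).  Implementation
choices:

* The residual **vector** (one entry per sample per direction, equal
  weights) is minimised by bounded trust-region-reflective least squares
  with a numerical Jacobian, not the scalar error; the residual structure
  speeds convergence substantially.
* c, k1 and k2 are optimised in log10 because their admissible ranges span
  nine to ten decades; beta stays in degrees (bounds are stated in
  degrees) and is converted to radians only inside trigonometric calls.
  R0 is scaled to millimetres inside the optimiser so all coordinates are
  O(1..100).
* The error surface is multimodal (the identified stiffness parameters of
  a population scatter over decades, a known identifiability limit of
  single-loop data).  A seeded multistart with 8 starts is the default:
  start one at the bound midpoints (log-midpoints for the stiffnesses),
  the rest uniform (log-uniform for stiffnesses) in the box.  The best
  residual wins; ties keep the earlier finisher.  Results are bitwise
  reproducible for a fixed seed.
* Convergence per start is a relative residual change below 1e-5 (the
  conventional tolerance for this identification); the step and gradient
  tolerances are set tight (1e-12) so the residual criterion governs.
* Residuals are soft-clipped through cap*tanh(res/cap) with cap = 1e9 Pa.
  Physical stresses are ~1e5 Pa, so the clip is the identity wherever the
  model is remotely plausible; its only role is to keep the fiber
  exponential's overflow (k2 (I-1)^2 > 700 at absurd trial points) from
  aborting the optimiser.  Multistart draws whose residuals are already
  non-finite are rejected and redrawn.
* Degenerate boxes (equal lower and upper bound for some or all
  components) fix those components exactly and optimise the rest.

Fit quality is reported per direction as R^2 between the Laplace reference
and the model stresses.  Because identifiability from a single loop is
limited, recovery claims are made on stress curves, never on kappa itself.

## Signal preprocessing

Raw recordings (pressure and echo-tracked inner radius, both at 870 Hz,
8-10 beats) pass through:

1. **Zero-phase low-pass filtering**: 4th-order Butterworth, 15 Hz cut-off,
   applied forward-backward to both channels identically.  A causal filter
   would add phase lag and distort the pressure-radius loop; the price is
   that the effective magnitude response is the Butterworth response
   squared, which the tests' analytic oracle accounts for.
2. **Delay alignment**: the integer-sample lag maximising the pressure-
   radius cross-correlation over +-0.1 s (configurable; keep below one
   cardiac period) is removed from the pressure channel.  Ties go to the
   smallest |lag|, then the earlier lag.  Constant channels yield zero lag
   with a warning.
3. **Beat averaging**: diastolic feet are detected on the pressure channel
   only (pressure feet are sharper than radius minima) as local minima
   below the 25th pressure percentile separated by at least 0.4 s.  Each
   complete foot-to-foot beat is resampled to 100 points by linear
   interpolation on normalised phase and the beats are averaged pointwise;
   partial first/last beats are implicitly discarded.  At least three
   complete beats are required.

The delay-estimation and beat-detection rules are not prescribed by the
measurement protocol this emulates; both are implemented as stated above
and exposed as configuration.

## Derived metrics

SBP/DBP are the extrema of the averaged loop; MAP = DBP + (SBP - DBP)/3;
PP = SBP - DBP.  1 mmHg = 133.32 Pa exactly at all I/O boundaries; SI
units internally (a deliberate guard against the mm^2/kPa unit mixing the
printed formulas invite).  Stresses at SBP and DBP are evaluated at the
loop's extremal-sample radii by default ("loop_radii"); stress at MAP
inverts the fitted model's pressure-radius relation by bracketed root
finding (tolerance 1e-12 m) over the loop's radius range with a small
outward expansion allowance.  A "model_inversion" mode evaluates SBP/DBP
stresses by inversion as well, since which convention the original
analysis used is not documented.  "Peak wall stress" means total stress at
SBP; a membrane has no transmural stress variation to take a spatial peak
over.  Pulsatile stress is the componentwise systolic-diastolic
difference; load-bearing fractions are component/total per direction, and
pulsatile fractions delta-component/delta-total.  Vanishing totals make a
fraction undefined: it is stored as NaN *and* listed in an `undefined`
field with a warning, never silently.

## Sensitivity test

Each identified parameter is increased by 1%, one at a time; stresses are
recomputed over the same loop radii and compared to the unchanged Laplace
reference through a new R^2 per direction (12 perturbed R^2 in total).
The reported statistic is 100 |R2_base - R2_pert| / R2_base.  Perturbed
parameters may leave the fitting box; the evaluation proceeds (the test is
diagnostic) with a flag.  On the representative subject the geometry
parameters R0 and lambda_z dominate by two to three orders of magnitude
and lambda_z moves the longitudinal direction far more than the
circumferential one, because both enter the fiber invariant squared and
the invariant is squared again in the energy; perturbing R0 translates
the stress-radius curve without changing its slope sign pattern.

## Synthetic data generator

The generator emulates the acquisition the analysis was designed for:
870 Hz sampling, 9 beats by default, radius quantised to 7.8 um, an
integer-sample instrument delay on the pressure channel, and
multiplicative Gaussian noise per channel (1% default).  The beat shape is
a raised-cosine upstroke over the first 30% of the cycle followed by a
Gaussian-like relaxation, C1 at the peak and continuous across beats; the
exact shape is immaterial downstream because the analysis uses only the
(P, r) relation after phase averaging.  Pressure is produced from the
radius waveform through the forward model, so with zero noise the
circumferential Laplace/constitutive equality holds at every sample by
construction.

**Why subjects are calibrated.**  Published per-sex parameter means and
per-group hemodynamic means are not a jointly consistent subject: the
stiffness parameters are non-identifiable from single loops and scatter
over decades (SD >> mean), and plugging all the means into the forward
model at tabulated radii produces fiber exponents near e^20.  The cohort
sampler therefore draws ages, pressures and diameters from the tabulated
group distributions (truncated to physiological order), draws the shape
parameters (k2 log-normal, beta and lambda_z truncated normal) from the
tabulated per-sex statistics, and then solves for the remaining three
parameters: for a trial R0, (c, k1) follow from a 2x2 linear system so
the model reproduces the drawn pressures exactly at the drawn radii, and
R0 is root-found so the anisotropic share of circumferential stress at
systole matches a drawn target (uniform on 0.15-0.35, within the range
the load-fraction analysis reports).  Pressures and ages are drawn once
per subject and never resampled, so group SBP/DBP marginals stay
unbiased; only diameters and shape parameters are renegotiated when a
draw is mechanically infeasible.  Elderly-male draws typically calibrate
to c near 130 kPa - i.e. the calibration lands near the published means
where the published means are meaningful.

The **representative subject** (used for the sensitivity test and the
baseline fit-quality figure) instead takes all six per-sex mean
parameters exactly and the elderly-group mean SBP/DBP, and derives its
diastolic/systolic radii by inverting the forward model; the resulting
diameters (16.4-17.1 mm for males) are plausible though ~1.5 SD below the
tabulated elderly diameters - the over-determination is resolved in
favour of the pressures.

**Longitudinal inconsistency, by design.**  The generator computes F from
the gamma = 0.59 construction, but a generating parameter vector
generally implies a different (and pressure-dependent) axial force, so
synthetic longitudinal Laplace stresses carry an irreducible model error
- exactly as real data do under this framework.  Recovery experiments
that need an attainable ground truth use a *self-consistent* subject: the
representative subject is fitted once and the fitted parameters (whose
longitudinal stresses track a constant-force reference by construction)
generate a fresh loop.  On it, identification recovers all four iso/aniso
stress-component curves to < 1% RMS and total-stress curves at
R^2 > 0.999.

What the generator does **not** emulate: beat-to-beat hemodynamic
variability, ectopic beats and motion artifacts, pulse-wave propagation
(no Windkessel), measurement drift, and any pathology (aneurysm
geometry).  Passing tests therefore certify the pipeline's correctness
and robustness to stationary noise, delay and quantisation - not
performance on arrhythmic or pathological recordings.

## Problem sizes and numerical defaults

Tests and the acceptance script run the full pipeline on loops of 100
phase samples averaged from 7 complete beats per subject, with 10-subject
noisy cohorts for the fit-quality figures and a 1000-draw sampling check
for the cohort statistics; these sizes make every quantity stable to well
inside its tolerance while keeping a full run in tens of seconds.  Root
finding uses Brent's method (xtol 1e-12 m on radii); optimisation
tolerances are as above; all randomness flows from explicit seeds
(NumPy Generator / SeedSequence), making every artifact byte-reproducible.

## Known limitations

* Membrane model: wall thickness-to-radius is ~0.1-0.2 in the abdominal
  aorta, so the membrane parameters are effective through-thickness
  averages; residual stress and the three-layer wall structure are out of
  scope.
* A from age regressions adds population-level error to per-subject
  stresses.
* kappa from one loop is not unique; per-parameter values (especially
  c, k1, k2) should be read as one representative of a near-equivalent
  family.  Stress curves and fractions are the robust outputs.
* The statistical summary is descriptive (means, SDs, OLS slopes, r^2);
  hypothesis testing (ANOVA, multiple-comparison correction) is
  intentionally out of scope.
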