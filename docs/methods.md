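# Methods

## Model and scope

The package treats the irreversible, uninhibited single-substrate
Michaelis–Menten system under the reactant-stationary assumptions
([E]₀ ≪ [S]₀, no product or excess-substrate inhibition, no enzyme
inactivation, no non-enzymatic substrate loss). Under these assumptions the
progress curve satisfies the separable ODE d[P]/dt = V([S]₀−[P])/(Km+[S]₀−[P]),
whose implicit solution is the integrated equation

    t = [P]/V + (Km/V)·ln([S]₀/([S]₀−[P]))

and whose explicit solution is the Lambert-W substrate-depletion form
[S](t) = Km·W((S₀/Km)·exp((S₀−Vt)/Km)). Reversible, multi-substrate,
cooperative, hysteretic and inhibited systems are out of scope; the
consistency diagnostic (below) exists precisely to detect when data depart
from this model.

Units are arbitrary and self-consistent; `KineticParameters` carries unit
strings as labels only and performs no conversion. The reference simulation
conditions used throughout the tests set V = Km = 1 with the seven-point
grid [S]₀ = 0.35, 0.70, …, 2.45 (i.e. 0.35–2.45 Km), plus an all-below-Km
grid (0.07–0.35, step 0.07) and an all-above-Km grid (1.4–8.4, step 1.4).

## Numerical choices

* **Inverse solver.** The Lambert-W closed form is the default inversion of
  the integrated equation. It is evaluated through the Wright omega
  function, ω(z) = W(e^z) with z = ln(S₀/Km) + (S₀−Vt)/Km, which avoids
  overflow of the naked exponential when S₀ ≫ Km or Vt is large. A
  bracketing bisection of the forward map on [0, S₀(1−10⁻¹⁵)] is retained as
  an independent oracle; the two agree to better than 10⁻⁹ relative on
  randomised parameter grids (asserted in the tests).
* **Degenerate inputs.** p = 0 measurements carry no information for the
  integrated regression (the ln term vanishes with the chord); they are
  dropped with a warning, not an error. p ≥ s0 is rejected everywhere as
  unphysical. Perturbed product readings are clipped back into (0, s0) and
  clipping events are logged.
* **Tie-breaks.** The constant-time plan is anchored at the lowest [S]₀ of
  the grid; grids are strictly ascending by construction, so the anchor is
  unique.
* **Significant-digit emulation.** `bias_table(..., round_rates=3)` rounds
  chord rates to 3 significant digits before fitting. Hand-tabulated
  reference values for the apparent parameters were carried at that
  precision, and the rounding moves fitted values by a few units in the
  third decimal; the package default is full precision (`round_rates=None`).

## Estimators

* **Hanes–Woolf**: OLS of s0/v on s0; V = 1/slope, Km = intercept/slope.
  Standard errors by the delta method including the slope–intercept
  covariance. All fits are unweighted in their native space — no weighting
  scheme is assumed anywhere, which is the simplest defensible convention
  for single-point data and reproduces the reference apparent-parameter
  values; SE conventions beyond this are deliberately not asserted against
  external tabulations.
* **Hyperbolic**: unweighted Levenberg–Marquardt fit of v = V·s0/(Km+s0),
  initialised from the Hanes–Woolf solution (fallback: V₀ = max v,
  Km₀ = median s0), SEs from the local-linearisation covariance. On
  noiseless constant-time data it agrees with Hanes–Woolf to < 5% up to 70%
  conversion and exactly on exact hyperbolic rates.
* **Integrated**: OLS of [P]/t on (1/t)·ln(s0/(s0−p)); V is the intercept,
  Km the negative slope. A non-negative slope is reported as a fit failure
  because it cannot arise from the model — it is the primary signal of
  inhibition or inactivation.
* **Single-point specificity**: (p/t)/s0 estimates V/Km from one point when
  s0 < Km; both the finite s0 and the finite conversion bias it downward
  (to ~71% of truth at s0 = 0.35 Km and 10% conversion, ~53% at 60%), and
  the bias map corrects it the same way as the other apparent parameters.
* **Bias correction** (`correct_apparent`): the forward map
  (V, Km) → (V_app, Km_app) is re-simulated for the *actual* grid and target
  conversion at every candidate and inverted in log-parameters by
  trust-region least squares (convergence to 10⁻⁶ relative). The bias
  surface is regenerated rather than interpolated from a fixed table because
  it depends on where the grid sits relative to Km.
* **Consistency diagnostic**: observed V_app/V and (Km)_app/Km (apparent
  over integrated) are compared with the ratios predicted by simulating the
  matched design at the integrated-fit parameters. Flags fire when an
  observed ratio drops below 1 by more than a 5% noise margin or deviates
  from its prediction by more than a configurable fraction (default 25%).

## Error models and replicate studies

"Errors of up to m" describes a hard bound, so errors are uniform on
[−m, +m]: relative (default magnitudes 5% and 10%) multiplying each product
reading, or absolute with half-width m = 20% of the noiseless reading at the
lowest [S]₀. Errors perturb the product readings p — the observable of a
single-point assay; because t is shared within a constant-time run, relative
errors on p and on p/t are equivalent, and p is the natural target for the
absolute model. A `target="rate"` mode applies the same perturbations to
true hyperbolic rates for the "real v" control, which isolates the spread
contributed by the error model itself; for the integrated estimator the
control uses a plate sampled at a very short shared time (10⁻³ Km/V), where
the chord coincides with the initial rate.

Studies default to 18 replicates per condition (conversion × error model),
the same perturbed plate being analysed by every estimator so contrasts are
paired. Summaries report ranges, the largest per-run SE as a percent of the
estimate, and mean ± sample SD (n−1). Seeding: one root `SeedSequence`
spawns one substream per (condition, run), so results are byte-reproducible
and adding estimators does not reshuffle the noise. Ordering properties of
the replicate *means* (integrated closer to truth than Hanes–Woolf at ≥ 30%
conversion for every error model) are tested at 200 replicates, where the
means are settled; 18-replicate cells are compared only against their own
sampling spread.

## The synthetic experimental fixture

`generate_fixture` emulates a chromogenic β-lactamase assay: progress curves
for nitrocefin-like hydrolysis at V = 33 µM/min, Km = 29 µM, substrate
11–64 µM, photometric readings 2/s, a mixing dead time of 7.5 s (product
formed during the dead time is present in the first reading), and additive
Gaussian signal noise (default SD 0.15 µM-equivalent, a realistic photometric
noise floor for a ~10–60 µM signal). Recording extends to ≥ 99.9% conversion
by default so that the plateau required by dead-time preprocessing exists;
a fixed shorter `duration` reproduces an instrument-limited window and is
rejected by the plateau check, by design.

Preprocessing follows the dead-time correction: effective
[S]₀ = final reading − first reading; p and t measured relative to the first
reading; one point selected at the target fraction (or shared time). Because
the kinetics are autonomous, the post-dead-time segment is itself an exact
progress curve with the effective [S]₀, so noiseless round-trips recover the
generating parameters to < 0.5%. The plateau check is a trend test (the two
halves of the final ~10% of readings must agree within 2% of the effective
amplitude) so that point noise does not mask a genuine plateau.

What the fixture does *not* emulate: instrument drift and baseline offsets,
signal-to-concentration calibration error, enzyme inactivation over the
recording, pipetting error on nominal [S]₀ beyond what the dead-time
correction absorbs, and correlated (non-white) photometric noise. Passing
the end-to-end tests therefore shows the estimation pipeline is correct and
well-conditioned under bounded white noise, not that every laboratory
systematic is handled.

## Known limitations and observed numerical facts

* The apparent-parameter bias depends on the grid's position relative to Km:
  at matched conversion, an all-below-Km grid is *more* biased and an
  all-above-Km grid *less* biased than the straddling reference grid (both V
  and Km). The correction must therefore be computed for the actual design.
* The integrated estimator is exactly unbiased on noiseless data but
  acquires a small downward bias (a few percent) under strong noise, because
  noise enters the ln term nonlinearly; at ≥ 30% conversion it still
  dominates the Hanes–Woolf route on both parameters in replicate means.
* Full progress-curve fitting with t as the independent variable is
  deliberately not provided: it is highly sensitive to small errors in
  [S]₀, whereas the single-point use of the same equation (with [P] and
  [S]₀ as variables) is well-conditioned.
* Exact shared times for the reference designs are t* = 0.14036 (10%
  conversion at [S]₀ = 0.35 Km), 0.29314 (20%), 0.86815 (50%), 1.44897
  (70%) in Km/V units; some reference tabulations carry the 20% and 70%
  entries as 0.2941 and 1.450, which differ from the exact values in the
  fourth digit. Tests assert the exact values at 4 significant digits where
  the tabulated and exact values agree, and the exact values otherwise.
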