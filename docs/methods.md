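# Methods

## Model

The photocurrent of an expressed opsin is modeled with two independent
two-state gating pairs,

    i(t) = g · G(V) · O(t) · R(t) · (V − E),

where `O ∈ [0,1]` is the open fraction (closed ↔ open transition) and
`R ∈ [0,1]` is a conductance factor describing dark–light adaptation:
channels that have cycled under light conduct less than dark-adapted
ones, and `R` is the linear blend `(g·DA + g_LA·LA)/g` of the two
molecular populations, so the light-adapted conductance never needs to be
measured separately.  Both gates relax first-order toward
irradiance-dependent steady states with irradiance- and
voltage-dependent time constants.  Fully dark-adapted rest is
`O = 0, R = 1`.

Rate-function forms (`I` in W/m², `V` in mV, times in seconds;
`x = log10 I`):

- `τ_O(I) = p3 / (1 + exp((p1 + x)/p2))` — dark limit `p3`, accelerating
  with light;
- `τ_R(I) = p1 (1 − p2·L(p3,p4) − (1−p2)·L(p5,p6))` with
  `L(a,b) = 1/(1 + exp((a − x)/b))` — a biphasic decay from the
  seconds-scale dark limit `p1`, reflecting two light-driven pathways out
  of the adapted state;
- `τ_X(V) = p1 / (1 + exp(−(V − p2)/p3))`;
- intensity and voltage parts combine either by product or by reciprocal
  addition (`1/τ = 1/τ_I + 1/τ_V`); the bundled RSRS sets use reciprocal
  addition, the PP and MerMAID sets the product;
- `O∞(I) = 1/(1 + exp((p1 − x)/p2))`, rising from 0 in darkness;
- `R∞(I) = 1 − p3/(1 + exp((p1 − x)/p2))`, falling from 1 to `1 − p3`;
- `G(V) = p1 (1 − p2 exp(−(V − E)/p3)) / (V − E)` — an empirical inward
  rectifier.  The current is always evaluated through the cancelled
  product `D(V) = G(V)(V − E)`, which is finite everywhere; note the
  current therefore crosses zero at `V = E + p3 ln p2` (≈ +9.9 mV for the
  RSRS-final set), not at `E` itself.  Without a rectification block
  (MerMAID), `D(V) = V − E`.

At `I = 0` every power of `I` is taken at its limit: `τ_O(0) = p3`,
`τ_R(0) = p1`, `O∞(0) = 0`, `R∞(0) = 1`.  Logistic terms are computed
with `scipy.special.expit`, which is overflow-safe for any argument.

Under voltage clamp and a rectangular pulse both gates are
mono-exponential, giving a closed-form current on each phase; the
on-branch is evaluated on the closed interval up to the pulse offset, so
the plateau read-out equals the on-branch value at `t_off` exactly.
After the pulse, `O` decays to 0 with `τ_O(0,V)` and `R` recovers to 1
with `τ_R(0,V)`.  The current decays monotonically back to baseline
whenever `R∞(I,V) > 1 − τ_R(0,V)/(τ_R(0,V) + τ_O(0,V))`
(`check_decay_constraint`); this is enforced during fitting on the
experimental stimulus grid.  The MerMAID-final set violates the
inequality in the `I → ∞` limit but satisfies it on its experimental
irradiance range (≤ 3734 W/m²) — one reason the constraint is evaluated
on grids, not as a continuum condition.

An ODE route (`simulate_clamp_ode`, LSODA, rtol 1e-8/atol 1e-10 by
default) exists for arbitrary light waveforms and serves as the
independent cross-check of the closed form (agreement to 1e-4 of the
trace maximum over random parameter draws is part of the test suite).

Units: seconds, mV, W/m²; conductance either mS/cm² ("density" mode, for
coupling into a membrane patch) or µS ("absolute", whole-cell), an
explicit flag on the parameter set.  Currents keep their physical sign
(negative = inward).  Because the current depends on the product
`g · G.p1`, fitted scale is reported with `g = 1` by convention;
`normalize_conductance` moves scale between the two fields without
changing the current.

## Feature extraction

Seven features per stimulus condition: `I_peak` (maximal absolute
deflection from the pre-pulse baseline), `I_ss` (plateau), `I_ratio`,
and mono-exponential time constants `τ_on` (onset → peak), `τ_inact`
(peak → offset), `τ_off` (offset → end), plus `τ_recov` from two-pulse
series (the dark gap at which the probe peak reaches 1 − 1/e of the
conditioning peak, located on a monotone piecewise-cubic interpolant of
the measured gap–ratio points).  Peak ratios use raw peak magnitudes.

Choices not fixed by the feature definitions:

- one guard sample is dropped after each pulse edge before the
  exponential fits (edge samples sit on the stimulus discontinuity);
- the plateau estimate is the mean of the last 5% of the on-phase, which
  coincides with the end sample on noise-free data and is robust on
  noisy data;
- mono-exponential fits are bounded trust-region least squares
  (tolerances 1e-12) with multistart: deterministic initial guesses from
  a log-linear regression plus a geometric τ sweep, topped up with
  seeded random draws; ties resolve to the lexicographically smallest
  parameter vector, so a fixed seed gives identical output.

Validity domain: the feature ↔ time-constant correspondences hold when
`τ_O ≪ τ_R` and the pulse outlasts `τ_R(I,V)`.  Two systematic effects
are worth knowing about even on noise-free data: `τ_off` carries a ~2%
bias from the slow dark re-adaptation of `R` leaking into the off-decay
window, and extracted `τ_on` departs from `τ_O(I,V)` progressively as
`τ_O` approaches the 0.15 ms sample step (27% at 1e4 W/m²).  These are
properties of the feature definitions, not extraction defects; the
fitting procedure is immune to them because model features are extracted
from simulated traces by the same operations.

## Fitting procedure

Four steps, all operating on the closed form (no ODE solves):

1. **Feature extraction** as above (skipped when a feature table is
   supplied directly).
2. **Time-constant fits.**  Targets: `τ_on → τ_O(I,V)`,
   `τ_off → τ_O(0,V)`, `τ_inact → τ_R(I,V)`, and
   `τ_recov/(1 − ln(1/(1 − I_ratio))) → τ_R(0,V)` (undefined once
   `I_ratio ≥ 1 − 1/e`, which raises a scaling error).  Each gate's
   nine (or six) parameters are fit by bounded multistart least squares.
   Residuals are *relative* (per-target normalized): targets span
   0.1 ms to 10 s, and absolute residuals would fit only the seconds-
   scale dark constants.  This is this package's choice; the final
   refinement step makes the result insensitive to it.
3. **Equilibria and rectification.**  With the τ surfaces frozen,
   `(O∞, R∞, G)` — or `(O∞, R∞, g, E)` in absolute mode — minimize the
   weighted RMS of the current-feature errors.  Default weights
   (peak 10, plateau 20, ratio 50, τs 1000/1000/1000, recovery 20) level
   the features to a common magnitude.  Constraints: configured `O∞`
   saturation (default `O∞(5500 W/m²) ≥ 0.6`), `G(V) ≥ 0` on the
   experimental voltages (excluding ±1 mV around `E`, where the bare
   rectification factor is singular), and the decay constraint; all are
   folded in as exact penalties and the returned point must be feasible
   to 1e-6, else a constraint-infeasibility error is raised.  The
   multistart screens random starts cheaply and refines the most
   promising ones, and always fully refines a small deterministic grid
   of starts spanning desensitization depth, current scale and —
   critically — rectification shapes that are feasible on the voltage
   grid (the nominal start `p2 = 10, p3 = 50` violates `G ≥ 0` at
   positive voltages, and starts born inside the penalty wall converge
   badly).  The closed-form on-phase exponentials are precomputed once
   per step-3 problem, so a cost evaluation is two scaled additions.
4. **Global refinement.**  A search box of 10% of the full parameter
   space, centered on the intermediate fit and clipped to the global
   bounds, is explored by global-best particle-swarm optimization
   (inertia 0.7298, cognitive = social = 1.49618, reflecting walls,
   seeded; the published-scale budget is 1000 particles with a 24 h
   wall clock, the test preset 60 particles / 2 min).  The cost extends
   the step-3 RMS with weighted τ-error terms, with model features
   extracted from simulated traces (0.15 ms step single pulse, 1 ms
   two-pulse) by the same extraction operations used on data; squared
   errors are summed across features per condition before averaging.
   The swarm always contains the intermediate point, so the result is
   never worse.  After the swarm, a bounded local least-squares polish
   of the best particle runs inside the same box (default on,
   ~12 trust-region iterations).  The polish minimizes *fractional*
   feature errors — the same "level the features" principle applied
   condition-wise — and is kept only if it improves the step-4 cost and
   stays feasible.  On desk-scale budgets the polish, not the swarm,
   does most of the refinement work.

Success criterion: feature recovery, not parameter identity — the
`g·G.p1` product and the voltage-part amplitudes are intentionally
redundant, so distinct parameter vectors can be feature-equivalent.  On
noise-free synthetic data from the RSRS-final set (5 irradiances ×
7 voltages, recovery at the 3 highest irradiances × all voltages) the
test-budget pipeline reproduces every feature to well under 1% in about
six minutes on one CPU.

## Goodness-of-fit metrics

Four RMS flavors differing only in weights: RMSE (1), RMSNE (1/target),
RMSWE (training weights), RMSZE (1/σ of the target; undefined where no
σ exists, e.g. recovery constants).  Besides per-feature values, grouped
scopes (`all`, the four τs, the three current features) sum squared
errors across the group per condition before the mean over conditions
and the root; the mean is over conditions, not condition–feature pairs.
Conditions with zero targets (RMSNE) or missing σ (RMSZE) are excluded
with a warning.

## Synthetic data

The generator emulates a standard opsin characterization: single 0.5 s
pulses on a grid of 5 log-spaced irradiances (1e2–1e4 W/m²) × 7 holding
potentials (−80…+40 mV, 20 mV steps), 0.15 ms sampling, 50 ms pre-pulse
baseline and 0.4 s post-pulse window; plus two-pulse recovery series
(0.5 s pulses, 12 log-spaced gaps 0.3–25 s, 1 ms sampling) at the three
highest irradiances across all voltages — recovery is measured at a few
irradiance levels in practice, and its voltage dependence is the reason
the reciprocal-sum combination exists.  Noise is additive white Gaussian
with σ defaulting to 1% of the grid-maximum peak.  Ground truth contains
the generating model's feature values (exact closed-form currents, model
τs, and the root-solved exact recovery time); conditions where the
driving force vanishes are omitted.  Not emulated: series resistance,
capacitive transients, colored noise, junction potentials — so passing
tests validate numerics, not robustness to instrumentation artifacts.

## Regular-spiking neuron

Single-compartment cortical regular-spiking model: leak
(0.0205 mS/cm², −70.3 mV), transient Na⁺ (56 mS/cm², +50 mV),
delayed-rectifier K⁺ (6 mS/cm², −90 mV) and slow non-inactivating
M-type K⁺ (0.075 mS/cm², τ_max 608 ms), Traub-style kinetics shifted by
the threshold parameter V_T = −56.2 mV, C_m = 1 µF/cm²; the set ships as
a versioned JSON fixture, and the simulation starts from the computed
stable rest (−71.9 mV) with gates at steady state and the opsin fully
dark-adapted.  The opsin (density mode) adds its signed current to the
membrane equation and its two gating ODEs to the state.  Integration:
LSODA with maximum step 100 µs, rtol 1e-3, atol 1e-6 (defaults), split
at light edges where the irradiance is discontinuous; 0.1 ms output
sampling.  Spikes are upward 0 mV crossings with 1 ms minimum
separation.  Firing rates are reported as on-phase counts over total
on-time by default (whole-window normalization is available), and the
calibration protocol — 3162 W/m², 2 s train, 1 Hz repetition, 50%
duty — elicits 102 Hz.

## Strength-duration analysis

Per pulse duration (PD), the threshold irradiance is the minimal
irradiance eliciting at least one spike within the pulse plus a 0.4 s
observation window (near threshold, spikes ride the deactivation tail
and can trail short pulses), found by a decade scan and bisection on
log10 irradiance to 1% (search bounds 0.1–1e6 W/m²).  Because the
Hill–Lapicque relationship assumes a rectangular stimulating current, it
is fit not to irradiance but to the temporal average current,
`TAC = |∫ i dt| / PD` over the pulse plus one second.  The form used is

    TAC(PD) = I_rheo / (1 − exp(−PD ln2 / τ_chron)),

the only reading with the correct limits (threshold → ∞ as PD → 0 and
→ rheobase as PD → ∞) and consistent with the chronaxie definition
(threshold = 2 × rheobase at PD = chronaxie).  An empirical power series
`irradiance = a·TAC^b + c` maps the fit to the irradiance domain:

    I_rheo^irr = a·I_rheo^b + c
    τ_chron^irr = −(τ_chron/ln2)·ln(1 − I_rheo/((2·I_rheo^irr − c)/a)^(1/b)),

which inverts the composition exactly (verified against direct search in
the tests).  Fit quality is the adjusted R², with p = 2 (Hill–Lapicque)
and p = 3 (mapping, and the composite irradiance–PD curve, which is
scored against the bisection thresholds).

The default PD grid is 15 log-spaced points over 10 ms – 1 s.  The lower
edge is set by the opsin kinetics: below ~10 ms the injected charge is
dominated by the ~20 ms deactivation tail, whose duration is fixed by
the channel rather than the pulse, so threshold TAC grows as 1/PD and
the absolute least-squares Hill–Lapicque fit degenerates (the head of
the curve overwhelms the knee that defines rheobase and chronaxie).
Restricting the grid to the Lapicque validity domain (PD at least of the
order of the deactivation time) keeps the fitted pair meaningful.  With
these defaults the RSRS-final opsin in the RS neuron gives a TAC
rheobase of 0.504 µA/cm², chronaxie 45.6 ms, Hill–Lapicque adjusted R²
0.9961 and irradiance rheobase 4.69 W/m² (all computed by
`scripts/acceptance.py` and asserted in the test suite).  The mapping
exponent is sensitive to the exact short-PD thresholds and the (a, b, c)
triple is strongly covariant — a ridge in parameter space along which
the mapped rheobase and chronaxie barely move — so the individual
coefficients are less reproducible than any mapped quantity.

## Numerical choices and limitations

- Strictly positive parameters carry an effective lower bound of 1e-6
  inside the optimizers; voltage-slope parameters may be negative.
- Degenerate inputs raise typed errors (constant traces, unbracketed
  recovery grids, infeasible constraints, out-of-range thresholds)
  rather than returning silent NaNs; the SDC sweep records per-PD
  failures and continues.
- The model responds instantaneously to light: responses to pulses
  shorter than the activation time constant are overestimated.  There is
  no pH or ionic-concentration dependence; for anion channels like
  MerMAID the reversal potential must be adjusted to the recording
  conditions.  `O∞` and `R∞` carry no voltage dependence (the
  rectification function absorbs most of it).
- Fitted parameters extrapolate poorly outside the fitted irradiance
  range; quantities that depend on sub-threshold extrapolation (e.g. the
  irradiance rheobase) inherit that uncertainty.
- Desk-scale problem sizes used throughout the tests: the 5 × 7 stimulus
  grid with 3 × 7 recovery conditions for fitting; 100 random draws for
  the closed-form/ODE equivalence; 15 pulse durations with 1%-resolution
  bisection for the strength-duration analysis.  The published-scale
  budgets (2000/3000 multistarts, 1000-particle day-long swarm) remain
  the `published`-mode defaults.
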