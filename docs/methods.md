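# Methods

## The oscillator and its control

The unit model is the Berry bienzymatic description of extracellular-matrix
remodelling: matrix `m`, soluble filament `f`, proteinase `p` (matrix →
filament) and transglutaminase `g` (filament → matrix), with matrix
supplied at rate `r_im` and all species degraded in `p`-dependent catalytic
steps.  Kinetic constants (package defaults): γ = 0.026, β = 0.00075,
K_R = 4.5, K_S = 1, K_G = 0.1, K_deg = 1.1, k_g = k_deg = 0.05,
k_a = k_deg/K_deg (the exact quotient, ≈ 0.04545; the commonly quoted
0.0455 is this quotient rounded), Hill exponents n = l = 4.  Both enzyme
production terms are fourth-order Hill functions of `f`, which matters
below: at low filament levels enzyme production shuts off entirely.

Rate Control of Chaos multiplies the two production terms by
σ(q) = f_s·exp(ξ·q) with q = f/(f+μ_f) ∈ [0, 1); defaults μ_f = 2,
ξ_p = ξ_g = −1, f_p = f_g = 1 (the "enhanced" variant ξ = −3 is used by the
global-feedback experiments).  With ξ < 0 the control slows enzyme
production when filament accumulates; it uses only the unit's own
instantaneous state.

**Chaotic supply rate.**  The supply rate at which the uncontrolled unit is
chaotic is not a published constant; we located it by scanning the largest
Lyapunov exponent (two-trajectory and tangent-space estimates agree) over
r_im ∈ [0.002, 0.1].  Weak chaos (LE ≈ +3·10⁻⁴ per time unit) appears for
r_im ≈ 0.012–0.025.  At the preset value `CHAOTIC_R_IM = 0.012` the chaos
is a *long chaotic transient*: from attractor-adjacent states it lasts of
order 5·10⁴ time units before locking onto a period-2 orbit, while the
perturbed coupled network re-excites it continually.  Persistent
single-unit chaos lives near r_im ≈ 0.014–0.015, where however the
controlled orbit is period-1; the period-2 stabilisation showcase therefore
runs at 0.012 inside the transient window.  Enabling the control mid-run
there yields the bounded two-orbit (alternating peak levels ≈ 7.24 / 8.18
in `m`).

## Network construction

Unit `i` receives the supply rate

    r_im,i = max(0, r₀ + C_i(m) + ε_i ± v·M),

with the terms calibrated as follows.  Every choice below concerns a
quantity the protocol needs but no published constant fixes; each was set
once, for the stated reason, and not revisited per experiment.

* **Base supply r₀ = 0.012.**  Matrix is produced by *unmodelled*
  neighbouring cells at a constant rate kept inside the chaotic domain.
  Without this floor the network's only drive is its own summed output; it
  then possesses an absorbing collapsed state (all mass digested → supply
  → 0) into which synchronised troughs eventually fall, followed either by
  negative concentrations (under negative perturbations) or by an
  unbounded regrowth runaway.  No such behaviour is part of the modelled
  phenomenology; the base supply removes it.
* **Supply floor (clamp).**  A production rate cannot be negative, so the
  total supply is floored at zero.  The floor only engages for strongly
  negative perturbations, where it converts an unphysical negative supply
  into starvation of the unit — the suppression branch of the
  perturbation response.
* **Coupling C_i.**  All-to-all mode implements the weighted sum over all
  other units with *source-indexed* weights, drawn per unit from
  {1.1, 1.2, 2.5}·10⁻⁴ and normalised by the number of incoming
  connections relative to the 16-unit reference (w_eff = w·15/(n−1)).
  The normalisation keeps the total coupling input size-independent:
  unnormalised 32-unit networks diverge unconditionally (checked up to an
  amplitude ceiling of 10¹²), and the 64-unit experiment's own per-unit
  weights (unique values 1–10, read as ×10⁻⁵) have almost exactly the same
  total as the 16-unit reference.  The grid-local "finite-difference"
  stencil mode sums over the orthogonal grid neighbours with the printed
  weights as-is; the Crank–Nicholson mode additionally averages current
  and previous-step neighbour values with equal temporal weights (the
  linearising negative control).  The connectivity-ramp and
  global-feedback experiments use the stencil mode: under all-to-all
  coupling the amplitudes they reach (mean m ≈ 25 per unit with ξ = −3)
  would require a supply beyond the maximum proteolytic digestion rate,
  i.e. certain divergence.
* **Perturbations ε.**  Uniform mode: one shared draw u ~ U[−1, 1] per
  epoch, scaled per unit by its column multiplier (columns use
  [7.5, 1, 8, 3.25]) and by its *aggregate nominal connectivity*
  ε_unit = w_nom·(n−1)·eps_gain with eps_gain = 2.  For 16 units the
  strongest perturbations then span the same order as the supply rate
  itself, so they can suppress a unit's oscillation rather than merely
  nudge it — the regime in which the perturbation-response exponents and
  their growth with network size reproduce; per-link scaling alone yields
  a flat response at every operating point we scanned.  Gaussian mode
  (64-unit experiment): independent per-unit draws from N(5·10⁻⁵, 10)
  divided by the documented normalisation constant (preset: 30), with
  per-unit scales = unique reals on [1, 10].  The per-epoch perturbation
  scalar used on response plots is |Σ_i ε_i| (identical to Σ|ε_i| in
  uniform mode).
* **Global feedback.**  ±v·M with v = 10⁻⁵ (|v| < every w_k), where M is
  the *instantaneous* summed matrix recomputed at every Runge-Kutta stage,
  not the previous step's value; a regression test asserts the two differ.

**Initial conditions.**  Unstated in the source material.  Raw uniform
(0, 1] starts are outside the attractor basin: at low `f` the fourth-order
Hill production of `p` is off, digestion collapses, and the coupled supply
runs away through a very long large-amplitude excursion.  Units therefore
start from a numerically located attractor point (3.8, 0.85, 0.03, 0.27)
with ±50 % multiplicative seeded jitter and relax *uncoupled* for 20000
steps at the chaotic supply rate, which settles and decorrelates them (the
chaotic flow amplifies the jitter).

## Integration

Fixed-step explicit Runge–Kutta: classical RK4 (default), and the 5th-order
solutions of the Fehlberg 4(5) and Dormand–Prince 5(4) pairs run in
fixed-step mode.  The compiled kernel evaluates coupling, perturbation and
the instantaneous M at every stage.  Default dt = 0.1 time units: kinetic
rates are ≤ 0.05, the controlled oscillation period is ≈ 1.9·10³ time
units, and with dt = 0.1 one 20000-step perturbation epoch spans about one
collective oscillation — matching protocols in which the number of epochs
equals the number of stable oscillations observed.  RK4 and fixed-step
Dormand–Prince agree on per-epoch peaks to 0.1 % over short horizons; weak
chaos (LE ≈ 3·10⁻⁴) precludes long-horizon trajectory agreement for any
pair of methods, so method-agreement and step-halving checks use few-epoch
horizons.  Divergence (non-finite state or |y| above a configurable
ceiling, default 10⁶) truncates the run and flags the offending epoch;
negative concentrations raise a warning and are never clamped.

## Analysis pipeline

* **Transient removal** drops the leading 25 % of each epoch (the
  protocols describe "very short transients"); per-epoch peaks are maxima
  of the post-transient recorded M (stride 10 steps).
* **Orbit classification** clusters the last ≤ 12 post-transient peak
  heights with 1 % relative tolerance and checks the cluster-label
  sequence for periodicity; non-repeating structure is flagged aperiodic,
  fewer than 4 maxima is "undetermined" (such epochs keep their stability
  flag).  An epoch is *stable* when finite, non-divergent and not
  classified aperiodic.  Ramp epochs rarely contain enough repeated peaks
  to classify, so ramp analyses use every completed epoch.
* **Local Lyapunov estimates** propagate a tangent vector (directional
  derivative by state-scaled central differences) with renormalisation
  every window, giving window-resolved exponents rather than one global
  number.
* **Power-law tail fit**: for every candidate cutoff among the observed
  values, the continuous maximum-likelihood exponent
  α̂ = 1 + n/Σ ln(x_i/x_min) (discrete variant: numerical maximisation of
  the Hurwitz-zeta likelihood) and the Kolmogorov–Smirnov distance between
  empirical and fitted tail CDFs; the fit minimising the KS distance wins.
  Experiment reports constrain the scan to cutoffs keeping ≥ 20 % of the
  sample, guarding against a tiny-tail overfit.  Because figure captions
  mix sign conventions, the positive tail exponent α and the signed
  log-log slope of the fitted survival function, −(α−1), are both
  reported.
* **Curve fits** y = a·x^b and y = a·e^{bx} are seeded by linear
  regression on the appropriate log scale; by default they are polished by
  nonlinear least squares on the original scale, but the experiment
  pipeline keeps the log-scale regression (`refine=False`): per-epoch peak
  scatter spans decades, the original-scale polish is dominated by the
  largest peaks and is seed-unstable, and the log-log regression is what
  the response plots display.  MSE is evaluated on the original scale and
  enters the information criteria as aic = −n·ln(mse) + 2k,
  bic = −n·ln(mse) + k·ln(n) — note the sign of the mse term is opposite
  to the textbook form; the conventional form is available behind a flag
  and the two are exact negations in that term.
* **Changepoint detection** for the two-domain Gaussian experiment scans
  splits of log x minimising the total squared residual of two log-log
  lines (≥ 15 % of points per side).

## What the experiments show — and what they do not

The preset experiments reproduce, at the documented sizes (100 epochs of
20000 steps; 8–64 units; 3 seeds per quantity): the mid-run stabilisation
of a chaotic unit into a two-orbit; seven distinct stable collective
orbits under seven random perturbations; negative perturbation-response
exponents whose magnitude grows with network size (medians ≈ −0.08 / −0.23
/ −0.41 for 8/16/32 units); boundedness of the connectivity ramp with an
explicit singularity outcome once connectivity grows too large; and the
amplifying/compressing effect of positive/negative global feedback on the
ramp's excursions.

Known limitations of the reconstruction, reported as measured:

* The per-epoch peak distribution has a heavier tail (α ≈ 2–3) than the
  published tail exponents (≈ 5–7): strong negative perturbations produce
  drain-rebound overshoots up to ~10× the median peak.  Removing them
  would remove the same suppression dynamics that produces the response
  exponents.
* The Crank–Nicholson negative control is stable and analysable, but its
  KS distance does not order strictly above the default coupling's: in
  this reconstruction the peak-distribution tail is driven mostly by
  per-unit drain-rebound dynamics, which the coupling interpolation barely
  touches.
* The 64-unit Gaussian run is stable with a wide perturbation range, but
  shows no sharp two-domain structure in (ε, max M); the changepoint
  detector returns a split, the lower-domain exponent is ≈ 0 rather than
  ≈ −0.33.
* The synthetic perturbation schedules emulate the *protocol* (epoch-wise
  redraws from stated distributions), not biological noise: real systems
  would see continuous, correlated fluctuations, so passing tests support
  the mechanism's internal consistency, not its fit to any dataset.
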