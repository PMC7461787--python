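# Methods

## Problem and model

A sprinter runs a straight 30–60 m test wearing a trunk unit that samples a
tri-axial accelerometer and gyroscope at 200 Hz and GNSS ground speed at
10 Hz.  The quantity of interest is the instantaneous horizontal velocity
v(t), from which the sprint duration, the maximum velocity and the
mechanical profile (v₀, f₀, p_max, F–V and P–V curves) follow.  The motion
is assumed to stay in the sagittal plane along a straight line, so a single
global horizontal axis X (defined anew per sprint by the mounting
convention; there is no magnetometer and hence no absolute heading)
carries all the relevant dynamics, and the estimation problem is
one-dimensional and linear.

### Orientation

Quaternions are Hamilton, scalar-first, passive sensor→global.  The
attitude is propagated by the quaternion exponential of the midpoint
angular rate (exact for piecewise-constant rate; plain Euler integration
loses ~10⁻³ rad over a sprint, which matters because 1 mrad of tilt leaks
~0.01 m/s² of gravity into the horizontal channel).  A gradient-descent
step of size β·dt (β = 0.1 rad/s by default) corrects the attitude toward
agreement between the predicted gravity direction R(q)ᵀ(0,1,0) and the
normalised accelerometer reading.

The accelerometer also measures motion acceleration, which during a sprint
start reaches ~0.85 g — treating it as gravity would tilt the estimate by
tens of degrees.  The correction is therefore *gated* to quasi-static
samples: it runs only where the moving maximum (0.25 s window) of the
gyroscope norm is ≤ 0.25 rad/s and the accelerometer norm is within
0.5 m/s² of g.  During the sprint the step-frequency trunk oscillation
keeps the gyroscope envelope far above the gate, so the attitude evolves by
pure gyroscopic integration from its statically initialised value; between
sprints the correction re-converges the estimate.  This conditional
(quasi-static-update) correction is standard practice in pedestrian and
sports inertial navigation.

The initial attitude is the minimal rotation mapping the mean specific
force of a still-standing window onto (0, g, 0).  Because the GNSS-derived
start time trails the true motion onset (the receiver responds late), a
window ending exactly at the detected start may already contain early
acceleration; the implementation therefore scans window ends over
[t_s − 0.8 s, t_s] in 0.05 s steps and uses the window with the smallest
variance of the specific-force norm — the usual stillness statistic.  The
same window yields the mean angular rate, available as a zero-rate gyro
bias estimate (`select_static_window`), though the default pipeline leaves
the bias in: the fusion filter's GNSS updates bound the resulting drift,
and the IMU-only baseline is meant to exhibit it.

### Kalman filtering

Both passes use the same scalar filter.  State: velocity.  Prediction
integrates the global forward acceleration over Δt = 5 ms and inflates the
variance by μΔt² (μ is an accelerometer noise *variance*, (m/s²)²; read as
an additive constant, the printed "+ μ" term would inject an absurd
80 m/s² of bias per step).  Update: gain K = p/(p+η) against the GNSS
speed.  Defaults μ = 0.4, η = 0.01; p₀ = η and v₀ = 0 (the athlete starts
at rest with about one measurement's worth of uncertainty).

The 10 Hz GNSS series is placed on the 200 Hz grid by zero-padding —
each sample at its nearest grid instant, zeros elsewhere — and a zero
value means "no update".  A consequence worth stating: a genuine
standstill reading can never correct the filter.

Both filter passes *free-run from inside the static window* (one
static-window length before t_s) rather than cold-starting at t_s.  The
rest initialisation is exact there, the GNSS zeros produce no updates, and
the integration picks up the true motion onset even though the detected
t_s trails it; a filter started from rest at t_s would permanently miss
the 1–2 m/s already built by the time the receiver reports motion,
which both degrades the velocity estimate and biases the duration long.
Distance is nevertheless integrated from t_s only, per the method's
definition of the sprint window.

η tuning: over the candidate sprint the GNSS speed is checked against the
first-order rise by fitting v_max_obs·e^(−t/τ) to v_max_obs − v(t) (single
bounded parameter, τ ∈ [0.05, 30] s, start 1 s).  R² > 0.91 keeps
η = 0.01; otherwise η escalates to 0.1 (trust the GNSS less).  The check
runs on the coarse segment for pass 1 and is re-run on the precise segment
for pass 2.  Segments with fewer than five moving samples escalate
conservatively.

Start/end: t_s is the last GNSS sample at/below 0.3 m/s before the first
sample above it; t_e is the sub-sample (linearly interpolated) instant
where the integrated distance reaches the sprint distance D.  T_est is the
pass-2 distance crossing minus t_s.

### Velocity models and mechanics

First-order fits fix the amplitude (at max(v_est), or at the mean of the
last 0.1 s for the end-anchored variant — one sample would be noise-brittle)
and fit τ by bounded least squares.  The second-order model
a·e^(τ₁t) − a·e^(τ₂t) (a > 0, τ₂ < τ₁ ≤ 0) is fitted with scipy's
trust-region-reflective least squares; since the problem is multimodal the
fit starts from (max v, −0.01, −1/τ̂₁) plus four deterministic jittered
restarts and keeps the best sum of squares (ties → smaller |τ₁|).  τ₁ = 0
is allowed so the model nests the first-order curve.

Mechanics: F = M·a_mdl, P = F·v_mdl (power is force times velocity; a
`power_from="acceleration"` flag evaluates F·a instead for comparison with
that convention).  Closed forms: f₀ = a_mdl(0) (= a(τ₁−τ₂) for order 2,
v_max/τ for order 1); v₀ = v at zero acceleration (t* = ln(τ₁/τ₂)/(τ₂−τ₁)
for order 2; the anchor for order 1; the supremum a in the τ₁ = 0 edge
case); p_max = apex of P/M, located on a 2000-point grid and refined by
bounded golden-section (for order 1 the closed form v_max²/4τ is used).
F–V/P–V curves are the parametric elimination of t restricted to the
monotone-velocity portion (t ≤ t*).

### Validation statistics

Velocity error: ε_v(t) = (v_ref − v_test)/max(v_ref)·100, RMS over the
sprint; the 200 Hz estimate is decimated by 4 onto the 50 Hz radar grid
and the two series are aligned at their respective sprint starts (radar
trigger vs detected t_s) and truncated to the shorter.  Fit error is the
unnormalised RMS in m/s; duration error is (T_ref − T_est)/T_ref·100
(negative = overestimated duration).  Cohort summaries are medians with
linear-interpolation quartiles.  Bland–Altman uses 1.96 sample-sd limits;
Lin's ccc uses population (1/n) moments with a Fisher-z 95% CI (clipped so
the interval always brackets the estimate in the saturated |ccc| = 1
case).

## Synthetic data: what it emulates, and what it does not

Ground truth is analytic (first- or second-order exponential velocity; the
default is the second-order profile a = 10.5 m/s, τ₁ = −0.005 /s,
τ₂ = −0.8 /s, peaking at 10.11 m/s with f₀ = 8.35 N/kg and
p_max ≈ 21.6 W/kg — elite-range values), preceded by a 2 s static period.
Trunk pitch leans forward 45°→5° linearly with distance over the first
20 m plus a 5°, 4 Hz step oscillation whose amplitude ramps in over 0.5 s
so the angular rate is continuous at the onset; the horizontal
acceleration is right-continuous there (the initial push is present at the
onset sample).

Sensor imperfections (defaults): accelerometer noise 0.3 m/s²/axis,
gyroscope noise 0.01 rad/s/axis plus a 0.005 rad/s constant bias on every
axis; GNSS under-responsiveness as a 0.3 s lag plus a 0.4 s centred moving
average, 0.15 m/s noise, standstill clamped to exactly zero; radar noise
0.05 m/s on a 50 Hz grid triggered at motion onset; photocells fire exactly
at onset and at the true distance crossing.  All streams derive from
independent substreams of one seed and are bit-reproducible.

Not emulated: accelerometer bias and scale error, soft-tissue/garment
artefacts, non-sagittal motion, GNSS multipath or satellite geometry,
radar cosine error, reaction-time offsets between gates.  Passing tests on
this generator therefore demonstrate correctness of the algorithms under
the stated error model, not field accuracy; in particular the IMU-only
(strapdown) baseline is cleaner here than trunk IMUs are in practice.

## Evaluation cohort and observed behaviour

The evaluation cohort is 30 sessions (10 per distance at 30/40/60 m,
consecutive seeds, default noise) — small enough to run in seconds yet
wide enough for stable medians.  On it the fused estimate attains
per-distance median velocity RMS errors of ≈ 4.5–6.5% and a pooled median
duration error of ≈ −4% (overestimated durations, consistent with a start
detected slightly late), and improves on the IMU-only strapdown baseline
by roughly a factor of three.

One behaviour deserves honesty: under this error model the raw GNSS,
compared with the same start-anchored protocol, scores a *lower* median
RMS (≈ 3%) than the fusion.  Anchoring at the GNSS-detected start absorbs
most of the GNSS's own lag, while the fusion filter — blind to that lag —
tracks slightly below the delayed measurement whenever the acceleration is
decaying (equilibrium offset ≈ (ż − a)·Δt_update·(1−K)/K).  The fusion's
advantages are responsiveness at the start, robustness when the GNSS
degrades (the η escalation path), and drift-free IMU integration — not a
uniformly lower median error than a well-behaved GNSS.

## Numerical choices and degenerate inputs

Root-finding for the ground-truth duration uses brentq to 1e-9 s;
integration is trapezoidal; the distance crossing is linearly
interpolated between bracketing samples (5 ms quantisation would otherwise
bound duration accuracy).  Empty series, non-monotone timestamps, negative
GNSS speeds, non-positive fit anchors, unreachable sprint distances and
non-static initialisation windows all raise typed exceptions
(`sprintfusion.errors`).  Measurement times are attached to the nearest
acceleration sample; ties resolve to the later sample.

## Known limitations

Straight-line sprints only; heading is conventional, so lateral dynamics
are computed but unused.  Zero GNSS readings can never correct the filter.
The η escalation is binary (0.01/0.1) as designed, not continuous.  The
start threshold inherits the GNSS's response delay; durations are
consequently biased long by a few percent, as reflected in the cohort
numbers.
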