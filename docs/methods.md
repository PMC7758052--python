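# Methods

This note documents the model, the numerical choices, and the design
decisions behind `watermaze`, including the points where the design was
genuinely open and what the synthetic-data tests do and do not establish.

## Dynamics

The swimming animal is a point mass in the plane with state
x = [q_x, q_y, p_x, p_y] (cm, cm/s) obeying a linear stochastic differential
equation dx/dt = A x + B u + ξ. The drift

    A = [[0, 0, 1, 0],
         [0, 0, 0, 1],
         [-k/m, 0, -γ/m, 0],
         [0, -k/m, 0, -γ/m]]

combines a central restoring force (constant k) with viscous damping
(constant γ) at fixed body mass m = 20 g. With the reference estimates
(k = 3.7, γ = 0.47) the oscillator is strongly underdamped
(ζ = γ/(2√(mk)) ≈ 0.027) with damped angular frequency
ω = √(k/m)·√(1−ζ²) ≈ 0.43 rad/s, so a naive animal orbits near the wall at
ω·r ≈ 26 cm/s — the empirically typical mouse swimming speed. The process
noise ξ is white and isotropic with covariance
Σ_ξ = diag(σ_q², σ_q², σ_p², σ_p²); defaults σ_q = 1.1 cm/s, σ_p = 4.5 cm/s².

**Units of the control.** The control channel is defined as a *specific
force* (steering acceleration, cm/s²): B has unit entries in the velocity
rows. This is a deliberate unit choice for the package: it makes the
reference feedback-gain estimates (K_r = 0.20, K_t = 0.38, K_α = 0.89)
produce the behavior they are meant to describe. We verified numerically
that if the same gain values are instead applied through a force-per-mass
channel (entries 1/m with m = 20 g), the resulting control is ~5% of the
oscillator's intrinsic forces: the noiseless closed loop never reaches the
platform and controlled trials are statistically indistinguishable from free
swimming. Under the acceleration convention the noiseless closed loop
reaches the platform from every release point in 3–8 s and noisy LQR trials
average ~16 s latency versus ~37 s for free swimming. The choice also places
the β-sensitive region of the constrained controller in a usable range (see
below). Gains fitted by this package are therefore in units of cm/s² per
state unit.

## Discretization

Tracking is sampled at Δt = 0.2 s (5 Hz). All discrete quantities are exact
under a zero-order hold, computed with augmented matrix exponentials (Van
Loan blocks) so that singular drift matrices (k = 0 or γ = 0) need no
special-casing:

* A_Δt = exp(A Δt); B_Δt = (∫₀^Δt e^{As} ds) B;
* Σ_Δt = ∫₀^Δt e^{As} Σ_ξ e^{Aᵀs} ds, equivalently the solution of
  A Σ_Δt + Σ_Δt Aᵀ = A_Δt Σ_ξ A_Δtᵀ − Σ_ξ;
* the quadratic cost weights (Q, R, N) integrate to (Q_Δt, R_Δt, N_Δt) via
  the block exponential of [[−Cᵀ, W], [0, C]]Δt with C = [[A, B], [0, 0]]
  and W = [[Q, N], [Nᵀ, R]].

Each of these is unit-tested against direct numerical quadrature (1e-8) and
closed forms.

## Control

Gain convention: a stored gain K acts as u = −K(x − x̄), where
x̄ = [platform, 0, 0] is the rest state on the platform. Continuous gains
are K = R⁻¹(BᵀS + Nᵀ) with S the stabilizing solution of the algebraic
Riccati equation; discrete gains are (BᵀSB + R)⁻¹(BᵀSA + Nᵀ). Riccati
equations are solved with SciPy's structured solvers (cross-term aware); the
discrete path falls back to fixed-point iteration from S = 0 (tolerance
1e-10, capped at 1e5 iterations) and every returned solution is residual-
checked at 1e-8.

**Inverse optimal control.** Given an observed stabilizing gain K, the
weights Q = KᵀK, R = I, N = Kᵀ make the running cost the perfect square
|K e + u|², minimized pointwise by u = −K e. Consequently S = 0 solves both
Riccati equations, the recovered gain is exactly K, and the accumulated cost
vanishes identically along the noiseless closed loop. (With the opposite
cross-term sign, N = −Kᵀ, the same functional is minimized by u = +K e,
which pushes *away* from the target; we standardized on the sign that makes
the feedback law, the cost minimum, and the recovery identity mutually
consistent.) The zero-cost identity holds at machine precision only when
(Q, R, N) are applied as the discrete weights directly: the zero-order-hold
discretization of the perfect-square cost has a strictly positive minimum
(the control is held while the state moves within a step), so tests of the
J = 0 identity use the discrete-native construction, while the Van Loan
cost discretization is used everywhere a continuous cost must be sampled.

Note the closed loop u = −K(x − x̄) carries no feedforward term to cancel
A x̄ ≠ 0, so its noiseless fixed point sits slightly short of the platform
center; with the reference parameters the trajectory still enters the 5 cm
platform disc from every release point.

**Complexity-constrained control.** The per-step policy complexity is the
KL divergence between controlled and free transition laws; with shared
Gaussian noise it reduces to ½ uᵀ B_Δtᵀ Σ_Δt⁻¹ B_Δt u. Minimizing the free
energy F = I − βV is a standard LQR with inflated control penalty
R_β = R_Δt + (B_Δtᵀ Σ_Δt⁻¹ B_Δt)/β. β = 0 short-circuits to the zero
policy; β ≥ 1e12 is treated as the pure LQR. The optimality of the
β-controller is an infinite-horizon statement: in trial semantics (stop at
the platform) an over-aggressive gain can truncate complexity accumulation
early, so optimality tests use a fixed horizon with common random numbers.

**The usable range of β.** With the reference parameters the β-controller's
gain transitions from ~0 to the LQR gain over roughly β ∈ [5e-4, 5]; above
β ≈ 5 the gain is within ~1% of the LQR and policies become numerically
indistinguishable. The cohort generator's default day-mean schedule
(0.22, 4.5, 36.8, 475) — the study conditions it emulates — therefore
produces a clear naive-versus-trained contrast and a day-1 policy measurably
short of the LQR, but days 2–4 differ from one another by less than the
likelihood can resolve at realistic data sizes (per mouse-day Fisher
information resolves relative gain deviations of ≳9%, while the day-to-day
deviations are ≤1%). Estimator-recovery tests consequently place their
generating β values inside the identifiable window; a day-monotone recovery
of the *default* schedule beyond day 1 is not a statistically attainable
check and is not asserted.

## Estimation

Three maximum-likelihood stages, all operating on one-step residuals with
the Gaussian transition likelihood (log-likelihoods are reported per
transition so they are comparable across data sizes):

1. **Free model** (first trial of each animal): residuals
   ε_t = x_{t+1} − A_Δt x_t; the likelihood is maximized over
   (k, γ, σ_q, σ_p) in log space by Nelder–Mead from 8 coarse-grid starts
   (k ∈ {1,3,6,12} × γ ∈ {0.15,1.0}, noise scales moment-matched per
   start), tolerance 1e-8. Note the weak identifiability of γ: at ζ ≈ 0.03
   damping is a percent-level effect, and its MLE sampling spread is ≈25%
   (relative) in a 51-trial cohort — close to the 15% recovery tolerance the
   test suite uses, which is why recovery tests fix their seed. A subtlety
   worth recording: on noiseless data with σ fixed, the *full* likelihood is
   not maximized exactly at the true (k, γ) because log det Σ_Δt also
   depends on them; what vanishes at truth is the residual sum of squares,
   and that is what the corresponding test asserts.
2. **Feedback gain** (last trial of each animal), dynamics and noise frozen
   at stage 1: the controlled residual is linear in K, so the unconstrained
   2×4 MLE is solved in closed form by generalized least squares; the
   structured (K_r, K_t, K_α) form is fitted by multi-start Nelder–Mead
   seeded from the projection of the closed-form estimate.
3. **β schedules** (all remaining trials, grouped per animal and day): the
   profile likelihood of β is scanned on a log₁₀ grid over [−3, 4] in steps
   of 0.1 (gains cached across animals) and refined by bounded scalar
   minimization; log β(day) = b₀ + b₁·day + b₂·day² is then fitted by least
   squares on the per-day optima and, in the default joint mode, polished
   against the summed likelihood. Animals with fewer than 3 usable days
   fall back to a linear (or constant) schedule with a warning.

Velocities: simulator-produced trajectories carry exact velocities;
trajectories read from CSV (positions only) get velocities from central
differences smoothed with a 3-sample moving average. Numerical
differentiation correlates the derived velocity with the position noise and
biases σ̂_q downward by roughly 15–20% on synthetic data; parameter-recovery
tests therefore use velocity-bearing trajectories, and fits of tracked data
should be read with that bias in mind.

## Synthetic cohorts

The generator emulates the study design the analysis assumes: 51 mice
(WT 11 M / 13 F, HET 12 M / 15 F), 4 days × 4 release points (E, S, NE, SW
at 55 cm radius; platform of 5 cm radius at polar (30 cm, 135°)), 60 s cap,
Δt = 0.2 s — 816 trials. Per animal and day, β is drawn lognormally around
the day mean (sd 0.5 on the log₁₀ scale; the emulated design reports only
means, so the dispersion is a package choice). Each animal's very first
trial is generated from the free model (a mouse that has never seen the
maze is naive by definition, and the first-trial estimation stage assumes
exactly that). Flotation episodes are injected per group as 1–3 s intervals
of zero control *plus* a strong velocity brake (×0.2 per step): zero control
alone would not slow the animal, since the swimming-fitted damping is far
weaker than the drag on a passively floating body; onsets are drawn within
the first ~12 s so they land inside the active trial. The exclusion filter
operationalizes "missing samples or measurement errors" as: fully-missing
samples tolerated up to 5% of the trial, any other non-finite coordinate
excluded outright; a corruption injector exists solely to test the filter
(e.g. corrupting 49 of 816 trials leaves the 767 analyzed trials of the
emulated study).

Everything is deterministic given the master seed, with per-(mouse, day) and
per-(β, repetition) child streams so any single trial or frontier point is
reproducible in isolation.

What passing on synthetic cohorts does *not* show: the generator produces
exactly the linear-Gaussian dynamics the estimators assume, with no
measurement noise, no tracking dropouts beyond the injected ones, no wall
interactions (the free model is unbounded; the hard-wall clamp is a
visualization device only) and no within-day ordering effects. Real tracking
data violate all of these to some degree; the tests establish correctness of
the machinery, not robustness to misspecification.

## Frontier computation

The value–complexity curve is computed per release point at 50
logarithmically spaced β between 1e-5 and 1e5 (linear spacing is available
as a config option), averaging value and complexity over 1000 repetitions
by default (tests and the CLI can lower this). Trials start at the release
point with zero velocity and stop at the platform or at 300 steps. Solver
failures at a grid point are recorded as missing, not fatal. Monotonicity
checks allow up to 2 violations beyond 3 Monte-Carlo standard errors. At the
β = 1e-5 end the mean complexity is ~2e-3 nats — four orders below the
LQR end (~15–20 nats), i.e. numerically the naive policy.

## Problem sizes in the test suite

The suite favors the smallest sizes that make each statistical check stable:
recovery experiments use the study-scale counts (51 first trials, 26 last
trials), frontier checks use 50 β × 100 repetitions, Monte-Carlo KL checks
use 1e6 draws, and the end-to-end pipeline runs on an 6–8 mouse cohort. The
full suite completes in well under a minute on one CPU.

## Known limitations

* Steady-state gains only: the finite-horizon transient of the Riccati
  differential equation vanishes identically for the inverse-optimal cost
  and decays rapidly otherwise; the differential equation exists only as a
  test oracle.
* No state-estimation layer: the animal is assumed to know x exactly (the
  Kalman-filter/certainty-equivalence extension is out of scope).
* No feedforward in the controller, so the noiseless closed loop
  equilibrates slightly short of the platform center (inside the platform
  disc for the reference parameters).
* γ (and through it ζ) is estimated near its information limit at cohort
  scale; report it with that caveat.
* β values above ~5 are reported as fitted but are not mutually
  distinguishable (gain saturation); treat large fitted β as "at the LQR
  limit" rather than as a precise number.
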