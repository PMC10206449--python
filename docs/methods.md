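# Methods

## Model

Two contestants move in the plane as overdamped Brownian particles.
Contestant *i* experiences a directed effective interaction potential
from its rival *j*,

    V_{j→i}(x) = −α_{j→i} exp(−β x²) − δ_{j→i} ln x,      x = |r_i − r_j| / x₀,

combining a short-range attractive Gaussian well (motivation to escalate)
with a logarithmic repulsion (avoidance / how intimidating the rival is).
These potentials are *behavioural* constructs — analogies to physical
pair potentials — not fighting abilities.  A localized resource adds
V_res(r) = p·ln(r + ε), a radially symmetric trap at the resource
location.

The relative motion along the inter-contestant axis is governed by the
contest potential V_contest = V_{j→i} + V_{i→j}, with coefficient sums
A = α_{j→i} + α_{i→j} and Δ = δ_{j→i} + δ_{i→j}.  Its stationary points
solve u·e^(−u) = Δ/(2A) with u = βx², i.e. the two real Lambert-W
branches; they exist iff A/Δ ≥ e/2 ≈ 1.35914.  The local maximum x∩ is
the contest-onset distance, the minimum x∪ the bound fighting state.  A
pair is *in contest* while x < x∩; the attention switch disables the
resource force for both contestants during that time.

Euler–Maruyama integration: each step displaces a contestant by
η·F·dt plus isotropic Gaussian noise of per-coordinate variance 2·D·dt.
The separation coordinate then has diffusion D_rel = 2D and drift
η·F_contest, giving the effective temperature T_eff = 2·D·η used in the
duration theory (1 at the canonical η = 1, D = 0.5).

## Assessment and costs

Effective sizes m (RHP relative to a population reference) enter through
the assessment function

    α_{j→i} = α₀ · m_i^s · (m_i/m_j)^s_Q,      δ_{j→i} = δ₀ · m_j^r · (m_j/m_i)^r_Q.

Presets follow the field's two archetypes: pure self-assessment (s = 1,
others 0) and pure mutual assessment (s_Q = 1, r_Q = 2, others 0).
Mutual assessment is scale-invariant (only the ratio matters); all
strategies coincide at m_i = m_j = 1.  Any non-negative exponent
combination is accepted; the sanity of mixed strategies is the caller's
responsibility.

Fighting costs shrink sizes with accumulated contest time t_σ:
m_i(t_σ) = μ_i / (1 + (K_self + K_ij·μ_j/μ_i)·t_σ), so the larger
contestant inflicts costs faster but incurs them slower.  t_σ advances
only while in contest and persists across episodes.  The cost-driven
duration is the smallest t_σ at which A/Δ of the assessed coefficients
reaches e/2 (the well vanishes); it is found by geometric bracketing and
Brent root-finding on the monotone ratio, with the bracket abandoned
(duration "absent") once the ratio stops moving while still above
critical.  The pure-self closed form
t_cost = (α₀(μ_i+μ_j)/(e·δ₀) − 1)/K_self is used as a test oracle only.

## Simulation conventions

* Default parameters are the canonical set used throughout: α₀ = 7,
  δ₀ = 3, β = x₀ = 1, p = 4, ε = 1, η = 1, D = 0.5, dt = 10⁻³,
  horizon 500 time units, capture radius 0.2.
* Episodes begin/end at x∩ with no hysteresis; an episode ending because
  the extrema vanished mid-fight is labelled `cost_driven`, an upward
  crossing `noise_escape`, the horizon `horizon`.
* The winner is the first contestant within the capture radius of the
  resource *while not in contest* and only after at least one completed
  episode; simultaneous captures break ties by smaller distance.
* Separations are clamped at 10⁻⁴ before force evaluation (the
  logarithmic repulsion already dominates at contact); the resource
  force is the zero vector exactly at the center.
* A drift displacement above 0.1 per step warns; above 1.0 the
  integration aborts — the error names the offending time.
* Duration experiments initialize the pair *in the bound state*
  (fair-start geometry with separation x∪, both equidistant from the
  resource), so the first episode's length is the first-passage time out
  of the well — the model's contest duration.  Later episodes are
  retained in single-run output but duration statistics use the first
  episode only.  Fair-start *outcome* experiments instead start at
  separation x∩ (contest onset), the configuration in which neither
  contestant holds a positional advantage.
* The end angle θ is the signed angle between the j→i axis and the
  midpoint-to-resource direction; |θ| < 90° is algebraically equivalent
  to contestant i being strictly closer to the resource.
* The chase axis points from the larger contestant toward the smaller,
  so perfect pursuit yields a correlator of +1; midpoint displacements
  are taken over windows of 10 integration steps because single-step
  displacements are noise-dominated at D = 0.5.

Two stepping engines share these semantics: a vectorized numpy loop
(reference; the only one that records trajectories) and a numba kernel
for large unrecorded ensembles.  With noise disabled they produce
identical results; with noise they draw from different streams but the
same distribution.

## Potential extraction

The empirical-measurement pipeline recovers V_contest from trajectories:

1. **Velocity profile.**  Consecutive frame pairs contribute Δx/Δt to
   the bin (width 0.05) containing the separation at the *first* frame
   of the pair.  Start-point binning is essential: the binned mean is
   then the unbiased Itô drift, whereas midpoint binning adds a
   density-gradient term that exactly cancels the drift wherever the
   bound state is quasi-equilibrated (the stationary zero-flux
   condition), flattening the profile to zero.
2. **Geometric drift correction.**  The radial separation of a planar
   pair drifts outward by D_rel/x even with no force (the Bessel term);
   left in, it masquerades as extra logarithmic repulsion and inflates
   the recovered δ by D_rel/η (+1 at canonical parameters — an 11%
   relative error on Δ = 6 and 17% after splitting).  D_rel is estimated
   from the within-bin velocity variance, Var(v|bin) ≈ 2·D_rel/Δt, of
   the same data — no knowledge of the generating parameters is used.
   Profiles built by hand (without variance information) integrate
   literally.
3. **Integration.**  V_rel = −cumulative trapezoid of the (corrected)
   profile from the first populated bin, evaluated at each bin's
   occupancy-weighted mean separation (assigning a binned drift to the
   geometric center under-measures the steep repulsive wall); interior
   gaps are bridged by linear interpolation and flagged; the additive
   constant is arbitrary and the mobility η is absorbed.  Per-bin
   sampling variances (2·D̂_rel/Δt divided by the bin count) are
   propagated through the trapezoid sums into point-wise uncertainties.
4. **Fit.**  Bounded least squares of −A·e^(−βx²) − Δ·ln x + offset on
   the default window [0.3, 1.4] (β fixed at 1 unless freed), weighted
   by the propagated uncertainties so the sparsely sampled barrier tail
   does not dominate.  The window must avoid the long-range region where
   the residual resource attraction contaminates V_rel — a regression
   test documents the biased Δ obtained from a long-range window.  An
   automatic window heuristic runs from the first populated bin to 90%
   of the first upward zero-crossing of v_rel.  For RHP-matched pools
   the fitted sums split evenly between the two directed potentials.

Recording for the canonical extraction experiment uses every 2nd
integration step (frame spacing 0.002), emulating high-speed tracking.
The frame spacing matters: a binned drift estimate relaxes toward zero
as ≈ κ·Δt_frame/2 with κ the local force gradient (≈ 30 at the well
bottom here), so spacing 0.01 already attenuates the recovered
coefficients by ~10–15%.  With the conventions above, the 30-contest
experiment recovers (α, δ) = (7, 3) with a mean error of about −2% and
a seed-to-seed spread of ±5–15% — the honest sampling variance of an
experiment of that size.

## Observables

* Bounding energy U = V_contest(x∩) − V_contest(x∪); 0 when no well
  exists.  Noise-driven mean duration t_c = Π·exp(U/T_eff) with Π = 1 by
  default; relative durations divide by the reference (m_i = m_j = 1)
  value.
* Force asymmetry ΔF(x) = F_{i→j} − F_{j→i}; its value at x∪ predicts
  the extent of chase dynamics.
* Win probabilities come with exact Clopper–Pearson intervals; the
  positional-advantage probability is P(|θ_end| < 90°) over the final
  episode's end configurations.

## Problem sizes

Ensemble experiments use n = 30 recorded contests for extraction,
n = 500 escapes per point for Kramers scaling, n = 300 contests per grid
point for duration trends, n = 200 for chase sweeps and n = 500 per
ratio for fair-start outcomes — large enough that the trend statistics
(Spearman ranks, slope intervals, binomial tests) are stable across
seeds, while a full analysis run stays in the minutes range on one core.

## What the synthetic data does and does not show

All tests run on trajectories generated by the package's own simulator,
so they validate the internal consistency of the model, the integrator
and the inference pipeline — including full parameter recovery from
trajectories alone.  They do not validate the behavioural assumptions
against real animals: real tracking data carries measurement noise,
finite arenas, non-radial resources and individual variability that the
generator does not emulate.  The extraction layer accepts any CSV of
time-stamped positions, but arena-boundary masking and fragment
selection are left to the caller.

## Known limitations

* Two contestants, one fixed non-consumable resource, planar geometry.
* The Kramers relation t_c = Π·exp(U/T_eff) treats the escape as
  one-dimensional with a constant prefactor.  The simulated escape runs
  through the planar radial coordinate, whose effective potential
  carries an extra −T_eff·ln x term; the realized barrier is
  U − T_eff·ln(x∩/x∪) and the curvature prefactor varies with the well
  shape.  Measured ln(mean duration) is therefore highly linear in U
  (r > 0.99) but with slope ≈ 0.72–0.75 rather than 1/T_eff = 1 at the
  canonical parameters; the duration *trends* across assessment
  strategies are unaffected.
* Under the winner rule (capture only while not in contest), the
  asymmetric interaction keeps acting between the final episode and
  capture, so the larger contestant's win probability systematically
  exceeds its end-of-contest positional-advantage probability by ≈ 0.06
  at size ratio 1.2 — the two match more loosely than the end
  configuration alone would suggest.
* Winner/loser carry-over effects, cumulative assessment, stochastic
  injury events and multi-contestant scenarios are out of scope.
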