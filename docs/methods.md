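# Methods

## Model

The package studies recurrent random networks of binary neurons under a
global sinusoidal drive.  Each neuron is a two-state unit `n_i ∈ {0, 1}`
updated asynchronously (Glauber dynamics): update events form a Poisson
process of rate `N/τ`, each event picks one neuron uniformly and sets it
active iff its summed input exceeds its threshold,

    n_i ← H( Σ_k J_ik n_k + h_ext sin(ωt) + ξ_i − θ_i ),

with fresh Gaussian noise `ξ_i ~ N(0, σ_noise²)` per update.  `τ` is both
the mean inter-update interval and the time a unit's state persists, i.e.
the synaptic/membrane time scale of the model.  Connectivity is random
with *fixed in-degree*: every neuron of population α receives exactly
`K_αβ = round(p_αβ N_β)` inputs of weight `J_αβ` from population β
(uniform choice without replacement, no self-connections — an O(1/N)
choice the model leaves open).  Populations flagged *clamped* (an external
population X) have fixed mean activity, no incoming connections and no
threshold; they contribute shared-input covariance but receive no
feedback.

## Moment equations and Gaussian closure

Because each neuron receives many weakly correlated inputs, the summed
input is treated as Gaussian with population-level moments

    μ_α = Σ_β K_αβ J_αβ m_β + h_ext sin(ωt)
    σ_α² = [ (K⊛J) c (K⊛J)ᵀ ]_αα + Σ_β K_αβ J_αβ² m_β(1−m_β) + σ_noise,α² ,

which closes the moment hierarchy at second order.  The expected
activation is then the erfc gain `φ(μ,σ,θ) = ½ erfc((θ−μ)/(√2σ))`, its
μ-derivative is the susceptibility `S` (a Gaussian bump of height
`1/(√2π σ)` at threshold) and the means/covariances obey

    τ dm/dt = −m + φ(μ, σ)
    τ dc/dt = −2c + W(t) (c + diag(a/N)) + [W(t) (c + diag(a/N))]ᵀ ,

with `a = m(1−m)` (binary units: the variance is slaved to the mean) and
the effective connectivity `W = diag(S) (K⊛J)`.

Two conventions worth noting:

* `sigma_network` denotes the full network-generated part of σ (pairwise
  covariances plus sender variances); `sigma_independent` keeps only the
  sender-variance (convolved-binomial) part `Σ K J² m(1−m)`.  The latter
  is the conventional headline number for the network noise level — for
  the biological preset 2.79 (E) and 4.56 (I) input units — while the
  covariance term reduces the full value by a few percent.
* Rates are reported as `ν = m/τ` with explicit ms→s conversion.

## Stationary state and calibration

The undriven fixed point solves `m̄ = φ(μ̄, σ̄)` jointly with the linear
covariance relation `2c̄ = W̄ c̄_tot + (W̄ c̄_tot)ᵀ`, `c̄_tot = c̄ +
diag(ā/N)`.  The covariance equation is solved exactly in the eigenbasis
of `W̄` (componentwise division by `2 − λ_i − λ_j`; a Schur/Sylvester
fallback covers ill-conditioned eigenvector matrices).  The means are
iterated with an *adaptively damped* fixed-point map: the update
`m ← m + α(φ−m)` has linearization factor `1 + α(λ−1)`, so α is capped at
`0.9·min_λ 2(1−ℜλ)/|1−λ|²` (≤ 0.5); strong negative feedback (λ ≈ −12 for
the single-inhibitory preset) otherwise makes any fixed damping diverge.
If the damped map cycles (far initializations), a hybrid-Newton root solve
finishes the job.  Convergence demands residuals below 1e-12; the
invariants `|φ(m̄)−m̄| < 1e-10` and the covariance relation residual
< 1e-10 are asserted in tests.  Stability requires `max ℜλ(W̄) < 1`;
unstable solutions are returned with a warning.

Threshold calibration inverts the stationarity condition:
`θ_α = μ̄_α + √2 σ̄_α erfc⁻¹(2 m_α*)` for target means `m*`.  At fixed
targets the susceptibility `S̄ = exp(−erfc⁻¹(2m*)²)/(√2π σ̄)` does not
depend on θ, so the joint (θ, m̄, c̄) problem reduces to a damped iteration
over c̄ alone; the calibrated network reproduces its targets to 1e-8 by
construction (verified on random networks in the suite).

## Linear response and the three-term decomposition

For weak drive, `δm(t) = ℑ(M¹ e^{iωt})` with

    M¹ = U diag( 1 / (1 − λ + iτω) ) U⁻¹ S̄ h_ext :

every eigenmode of `W̄` is a first-order low-pass filter, so the mean
modulation lags the drive and decays like 1/ω.  Complex eigenvalue pairs
(possible only with population-specific weights) put the filter corner at
`τω ≈ ℑλ`, producing a resonance at `f_res = ℑλ/(2πτ)` — 158 Hz for the
biological preset.

The covariance deviation `δc(t) = ℑ(C¹ e^{iωt})` solves the linearized
equation `(iτω + 2)C¹ − W̄C¹ − C¹W̄ᵀ = R + Rᵀ` in the same eigenbasis
(denominators `2 − λ_i − λ_j + iτω`).  The inhomogeneity R splits into
three mechanistic parts, each returned separately and summing exactly to
C¹:

* **direct drive (S_h):** `h_ext · V c̄_tot` — the external input shifts
  the operating point of the gain, modulating the susceptibility;
  once-filtered, frequency-independent drive.
* **recurrent drive (S_m):** `diag((K⊛J) M¹) V c̄_tot` — the fed-back rate
  oscillation does the same through the network; carries the already
  low-pass-filtered M¹, hence twice filtered.  In balanced (effectively
  inhibitory) networks it opposes the direct drive at low ω, and their sum
  peaks at an intermediate frequency.
* **modulated autocovariances (a):** `W̄ diag((1−2m̄)/N ⊛ M¹)` — the
  time-varying unit variances `a(t)` drive pair covariances; twice
  filtered, and dominant in the purely inhibitory network, where `c̄` and
  `ā/N` nearly cancel in `c̄_tot` and suppress the S-terms.  There the
  total |C¹(ω)| decays monotonically (no visible resonance); the S-term
  dominance regime requires positive covariances, as in EI networks.

Here `V = diag(∂S/∂μ) (K⊛J)` with `∂S/∂μ = ((θ−μ̄)/σ̄²) S̄`.

The analytic layer neglects the modulation of the input *width* σ.  The
package monitors the justifying ratio `√2 erfc⁻¹(2m̄)/S̄` (184 and 20 for
the biological preset; a warning is emitted below 3) and the moment-ODE
integrator exposes both treatments via `sigma_dynamics={"full","frozen"}`:
frozen mode reproduces the analytic assumption (agreement with the closed
forms to <0.1% at h_ext = 0.1), full mode quantifies the neglected effect
(3–9% on first harmonics at low frequency for the biological preset).

Phase convention throughout: `x(t) = X⁰ + Σ_k ℑ(X^k e^{ikωt})`, so a pure
input-following signal `β sin ωt` has `X¹ = β` with phase 0.  The
*two-sided* Fourier coefficient conventionally quoted for spectra is half
the sine amplitude; peak rate-modulation numbers are reported in that
convention (0.78 Hz excitatory / 4.86 Hz inhibitory for the biological
preset at h_ext = 1).

## Numerical integration and harmonic extraction

The moment ODEs are integrated with LSODA (rtol 1e-8, atol 1e-10) on a
state vector packing the dynamic means and the upper triangle of c —
symmetry is structural, not left to the integrator.  Output is sampled
uniformly (64 points per drive period by default).  Harmonics 0–2 are
obtained by rectangle-rule projection onto `e^{−ikωt}` over an integer
number of periods after discarding a transient of `max(20τ, 2 periods)`;
at least five usable periods are required.  On a uniform grid over whole
periods the rectangle rule is spectrally accurate (validated to 1e-10 on
synthetic signals).  Halving rtol moves extracted first harmonics by
< 1e-6 relative.

## Stochastic simulation and estimators

The simulator is event-driven: exponential waiting times of rate `N/τ`
realize the infinitesimal-update prescription without discretization bias
(a fixed-step mode `dt = τ/N` exists for cross-checks).  A running input
vector is updated through a sender-major CSR adjacency whenever a neuron
flips, so each event costs O(out-degree) only on actual state changes.
Noise is redrawn independently at every update (white across updates).
Kernels compile with numba when available; a pure-NumPy fallback keeps the
package functional without it (determinism is per-backend).

Cyclostationary statistics fold time onto the drive phase after the same
`max(20τ, 2 periods)` transient.  Means pool neurons, cycles and trials
per bin.  Variances and pair covariances are estimated *across
realizations*, where a realization is one (trial, cycle) pair at matched
phase: cycles are at least one period apart — far beyond the network
correlation time `τ/(1−ℜλ)` — so they count as independent ensemble
members, whereas averaging cycles before covariancing would shrink the
covariance by 1/n_cycles.  Pair covariances average a fixed random
subsample of ordered pairs per population block (default 2000; tests use
up to 20000).  Standard errors come from the across-trial spread of
per-trial estimates.  The population error ellipse at a phase bin
diagonalizes `c_pop = ĉ + diag(â/N)` restricted to the dynamic
populations; its half-lengths are the square roots of the eigenvalues and
a nonzero EI covariance tilts its axes.

The Gaussian-input assumption itself is checked empirically: with
external noise matched to the network-generated SD, recorded per-update
inputs pass a KS comparison against the theoretical normal at the 1%
level on 1e5 samples.

## Presets (the study conditions)

* `single_inhibitory`: N = 5000, p = 0.1, J = −1, target m = 0.3,
  σ_noise = σ_network = √105 ≈ 10.25.  τ is not fixed by the source
  setting; 10 ms, the conventional binary-network value, is used.
* `homogeneous_ei`: E, I, X with N = 8192 each, p = 0.2, targets
  m_E = m_I = 0.11, m_X = 0.25 (clamped).  The synaptic weights
  (0.1/−0.5/0.1) are *placeholders* — the canonical source for this
  setting does not print them — chosen to give an inhibition-dominated
  balanced state; quantitative output of this preset is illustrative only.
* `biological_ei`: layer-2/3-like EI network (N = 1691/230; p = 0.168,
  0.5; 0.327, 0.36; J = 0.37, −0.52; 0.82, −0.54 input units; τ = 2.5 ms;
  σ_noise = 10), thresholds calibrated to m = τν with ν = 18/108 Hz.  Any
  constant external drive is absorbed into the calibrated thresholds, so
  no explicit X population is carried (the network-generated input SDs
  are reproduced without one).

## What the tests do and do not show

The suite validates the analytic layers against each other (closed form vs
integrated ODE), the simulator against the theory at quarter network sizes
(4-SE agreement of means, variances and covariances; matching sign and
magnitude of c̄), and the estimators on independent-neuron controls.  All
of this operates on the model's own synthetic networks: homogeneous
populations, fixed in-degree, single shared weight per population pair,
white Gaussian noise.  Passing tests therefore demonstrate the internal
correctness and self-consistency of the theory and its implementation —
not that real cortical networks, with distributed (possibly heavy-tailed)
weights, structured connectivity or colored noise, obey the same
quantitative laws.  Heavy-tailed weight distributions in particular break
the Gaussian closure and are explicitly out of scope.

## Known limitations and problem sizes

* Second harmonics are available numerically (moment ODE) only; no
  analytic second-order expressions.
* Arbitrary (non-sinusoidal) drive waveforms are not supported; the linear
  layer could superpose Fourier components, but the API does not expose
  it.
* The linear-response formulas require a diagonalizable effective
  connectivity; a defective `W̄` raises an explicit error.
* Simulation-based tests run at quarter network size (e.g. N = 1250 for
  the single-inhibitory preset, 20 trials of ~2.4 s biological time;
  N = 481 for the biological preset, 30 driven trials) — sizes chosen so
  the ensemble statistics resolve the O(1/N) covariances while the whole
  suite stays comfortably interactive.  Scaling N changes K = pN and
  therefore the operating point; size comparisons in the tests normalize
  accordingly.
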