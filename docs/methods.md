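# Methods

## The model

`sparsebalance` simulates and analyses recurrent rate networks in the
*sparse balance* regime: networks that receive only an order-1 uniform bias
current (instead of the order-√K feedforward drive of classical balanced
networks) and whose synaptic weights are drawn from high-variance
distributions. The single-population model is a network of N inhibitory
units with currents x_i and rates φ(x_i),

    τ_x dx_i/dt = −x_i − Σ_j J_ij φ(x_j) + I0 ,      J_ij ≥ 0,

with all quantities dimensionless and time measured in units of τ_x = 1.
Each row of J has exactly K structurally nonzero entries ("in-degree" K);
nonzero weights are i.i.d. with

    mean  J0 / √K        (J0 order 1)
    var   g² / K^ν       (g order 1)

ν = 1 is the conventional "low variance" scaling; ν = 1/2 is the
"high variance" scaling in which this package is chiefly interested.
Supported weight families: gamma, lognormal, two-point binary (all
nonnegative) and Gaussian (unconstrained sign, used for mean-field work).
The F-I function φ is rectified: Heaviside, rectified tanh, or rectified
power x^λ; φ(x) = 0 for x ≤ 0 including the threshold point itself, so
"active" (φ > 0) is equivalent to x > 0 everywhere in the package.

Writing η_i = Σ_j J_ij φ(x_j) for the recurrent synaptic input, the
dynamics is a low-pass filter of η. Averaging over units and time gives the
balance relation x̄ = I0 − J0 f √K, where f is the fraction of active
units; keeping x̄ of order 1 forces f ~ 1/√K. For gamma weights and
Heaviside rates, η is a sum of f·K i.i.d. gamma(κ, θ) variables and is
itself gamma(α, θ) with α = f K κ — the *gamma closure* implemented in
`gamma_theory`. At ν = 1/2 with f ∝ 1/√K both α and θ are K-independent,
so the input distribution never becomes Gaussian; at ν = 1, α grows like K
and the central limit theorem applies. The sparsening with K is dynamical:
the decorrelation rate β = τ_x/τ_η of the synaptic input grows ~ log K, the
low-pass filter transmits progressively less of the faster fluctuations,
and the current distribution narrows below threshold.

## Numerical integration

Plain forward Euler (not adaptive), matching the model's definition as a
discrete update; dt defaults to 0.02 with a hard cap of 0.05, and the
scaling studies use dt = 0.05 after verifying that halving dt moves the
measured statistics by less than their across-seed standard error
(`test_halving_dt_leaves_mean_statistics`, and the dt = 0.025 vs 0.05
cross-checks on the E-I network agreed to < 1%). Initial currents are
0.1 × standard normal unless supplied; the attractor statistics are
initial-condition independent (seed-swap test). Burn-in default 100 τ_x.
Recording stride defaults to 0.1 τ_x so autocorrelations are resolved well
below τ_x.

The integrator exploits rectification: only units with x > 0 contribute to
W·φ, so the matrix-vector product gathers the active columns (Fortran
layout makes this contiguous) whenever fewer than N/3 units are active.
This is exact, not an approximation, and makes the high-variance sweeps
(f ~ few %) cheap at K = N = 4000. A nonfinite state aborts with
`SimulationDiverged` naming the step; rectified-power λ > 1 dynamics can
genuinely diverge and is reported, never clipped. Large simulations run in
float32; statistics are accumulated in float64.

## Summary statistics

All variance estimators use the population (1/n) convention so that the
decomposition var_total = var_temporal + var_quenched is an identity, with
var_quenched the variance across units of per-unit time means and
var_temporal the population mean of per-unit temporal variances. φ̄ = f·μ
holds exactly by construction (μ := φ̄/f, zero when silent). The
population-averaged autocovariance R(τ) subtracts per-unit means and uses
divisor T − lag, so R(0) equals the temporal variance; the correlation time
τ_η integrates R by trapezoid from 0 to its first zero crossing (the
infinite upper limit of the defining integral is unreachable on a finite
window, and chaotic-network estimates decay into a noise floor), else to
max_lag; β = 1/τ_η.

The synchrony index is the Golomb-style χ² measure: the temporal variance
of the population-averaged signal divided by the mean per-unit temporal
variance (1 for identical units, ~1/N for independent ones). The package
applies it to the *rates*: at K = N = 1000, g = J0 = I0 = 2 the rate-based
index is ≈ 1.4 × 10⁻⁴, in line with the asynchronous-chaos scale reported
for this regime, whereas the current-based variant is ≈ 4 × 10⁻³ because
current fluctuations retain a weak common component. ψ is the second-to-
first rate moment ratio mean(φ²)/mean(φ) (1 for binary rates, c for a
uniform constant rate c). Normality diagnostics (D'Agostino K², skewness,
excess kurtosis) accept a matched subsample size so low- and high-variance
networks can be compared at equal power.

## The E-I network

The two-population network (N_E = N_I units, in-degree K from each
population) uses signed block connectivity: excitatory columns enter with
+, inhibitory with −, biases I_E and I_I per population. Block ab has
weight mean J_ab/√K. The per-block variance rule is not uniquely determined
by the block scales J_ab and the single fluctuation parameter g; this
package defaults to variance g²·J_ab/K^ν, i.e. for the gamma family a
*shared scale parameter* θ = g² K^(1/2−ν) across all blocks with block
shape ∝ J_ab (a coupling twice as strong contributes proportionally more
synaptic "quanta" of the same unit size, and the summed input from each
presynaptic population keeps a single gamma scale). At the reference
parameter point (g = 1, J_EE = J_IE = 1, J_EI = 2, J_II = 1.2, I_E = 2,
I_I = 1, N_E = N_I = 3000, K = 600, rectified tanh) this convention
reproduces the regime's reported population statistics — about 9% of E and
22% of I units active at a time, with only ~1% of E and ~9% of I units
above threshold more than half the time and none always on — whereas a
flat g²/K^ν variance under-activates the E population and a (g·J_ab)²/K^ν
variance over-activates it. The flat rule remains available via
`block_variance="shared"`.

## Dynamic mean-field theory

For Gaussian weights the package solves the standard self-consistent
single-site theory (dmft module): the current decomposes into a mean u, a
static Gaussian of variance g²√K·q (q = [⟨φ⟩²], the quenched rate moment)
and a temporal Gaussian of variance σ0 − g²√K·q, with

    u  = I0 − J0 √K ∫Dz′ φ(u + √σ0 z′)
    q  = ∫Dz ( ∫Dξ φ(u + g K^{1/4} √q z + √(σ0 − g²√K q) ξ) )²
    σ̈ = σ − g²√K [⟨φ(x(t)) φ(x(t+τ))⟩],  σ(0) = σ0, σ̇(0) = 0,

and derived quantities m = (I0 − u)/(J0√K), f = Φ(u/√σ0),
R_η(τ) = g²√K([⟨φφ⟩](τ) − q), β = R_η(0)/∫R_η.

Numerical choices:

* **Quadrature.** Rectified φ is kinked at threshold, where fixed
  Gauss–Hermite rules converge slowly and non-monotonically. Inner
  (and kink-carrying outer) Gaussian integrals are therefore restricted to
  the active region and evaluated by Gauss–Legendre (default order 64) with
  the Gaussian weight carried explicitly, truncated at 8 sd (mass ~6e−16);
  φ vanishes at the integration boundary, so the remaining outer integrals
  are smooth and plain Gauss–Hermite applies. Doubling the order moves u
  and q by < 1e−12. For the Heaviside the inner integral is the normal CDF
  in closed form.
* **u and q.** The u-equation depends only on σ0 and is solved by a
  bracketed Brent root find (its right side is monotone in u, so the root
  is unique; a damped fixed-point iteration would diverge here because the
  fixed-point slope is of order J0√K). q is solved by damped fixed-point
  iteration (damping 0.5, tolerance 1e−11, max 1e4 iterations), clamping
  and flagging if σ0 falls below the implied quenched variance.
* **σ(τ).** Adaptive RK45 (rtol 1e−9, atol 1e−11) with terminal events on
  the admissibility conditions σ̇ ≤ 0 and σ ≥ quenched floor g²√K q. σ0 is
  found by bisection between the two failure modes. Because u is re-solved
  at every candidate σ0, a larger σ0 gives a more negative u, smaller
  rates, and a *weaker* downward pull on σ: dropping below the floor marks
  σ0 too small and an upturn of σ̇ marks it too large (the opposite of the
  fixed-landscape intuition). The coarse bracket scans [1e−3, 3]·g²√K
  geometrically; bisection stops at relative width 1e−8.
* **Admissible solution.** σ(τ) is clamped to the quenched floor beyond the
  event time when tabulating R_η; β integrates R_η to its first zero
  crossing (same convention as the simulation estimator). Energy
  E = σ̇²/2 − V(σ) (V the path antiderivative of the right side) is
  conserved along the reported trajectories to a few 1e−3 of the potential
  scale, the residual coming from the trapezoidal path integral rather
  than the ODE solve.
* The theory is solved only for the Gaussian-weight model (its currents are
  Gaussian, making the closure exact); gamma/lognormal weights have no
  printed mean-field closure and are out of scope. A `scaling="conventional"`
  regression configuration (weight variance g²/K, bias √K·I0) recovers the
  standard balanced state (m → I0/J0) and guards against sign/scale
  regressions in the sparse equations.

Verified against matched Gaussian-weight simulations at J0 = 3, g = 2,
I0 = 1: m and f agree to 1–4% at K = 400 and 1600 (tested at a 15%
tolerance over 5 realizations), and β to ~1–12%.

## Synthetic-data / problem sizes

All data is generated internally; nothing is read from disk. The scaling
studies use K ∈ {250, 500, 1000, 2000, 4000} with N = K, three
connectivity realizations per point, dt = 0.05, and 400–500 τ_x of
measurement after a 100 τ_x burn-in; the E-I study uses the full
N_E = N_I = 3000, K = 600 network with the same windows. These sizes were
chosen as the desk-scale point where the across-seed scatter of the fitted
exponents (±0.01–0.02) is well inside the tolerance of interest (±0.05);
the measured high-variance exponent is ~0.48 and the low-variance one
~0.51 against the reference 0.503/0.513. What these tests do *not* probe:
asymptotics beyond K ~ 4e3, spiking dynamics, structured connectivity, or
any fit to experimental data — the generator emulates the model's own
assumptions (i.i.d. weights, uniform bias, no noise injection), so passing
tests certify the implementation and the regime's internal consistency,
not biological fidelity.

## Known limitations

* β estimates from finite windows carry an O(τ_η/T) downward bias in R via
  per-unit mean subtraction; β comparisons are made at matched windows.
* The low-variance comparison network's β drifts slowly downward with K at
  desk scale (slope ≈ −0.04 per ln K) rather than being exactly flat; it is
  clearly separated from the high-variance growth (+0.10 per ln K).
* `find_sigma0` assumes the chaotic regime; outside it (no admissible
  bracket) it raises rather than returning a fixed-point solution.
* The E-I block-variance convention is an interpretation (see above);
  both conventions are implemented and the choice is documented.
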