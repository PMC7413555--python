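# Methods

## Scope and assumptions

`viscocurve` solves the displacement-controlled indentation of a
linear, isotropic, non-aging viscoelastic half-space by a rigid,
smooth, axisymmetric probe, for depth histories with a single
contact-radius maximum. The approach force is the Lee–Radok
hereditary integral (the Hertz law with the modulus replaced by a
convolution against the depth-history rate); the retraction force uses
Ting's construction with the auxiliary time map `t1(t)`. Assumptions
inherited from that theory:

* linear viscoelasticity — force scales linearly with `δⁿ`, so curves
  are shape-invariant under depth rescaling (tested);
* time-independent Poisson's ratio;
* the probe displacement is the indentation depth, `δ(t) = z(t)`
  (stiff force sensor; the cantilever-deflection coupling is outside
  scope);
* no adhesion, no plasticity, single contact maximum;
* half-space geometry. A bottom-effect correction for finite sample
  thickness is exposed only as a user-supplied multiplicative hook
  `f_bec(δ)` (default 1, valid when the sample is much thicker than
  the contact).

## Relaxation-function catalogue

Every model is stored as a sum of primitive regular terms — constant,
exponential, power law `E_α1 t^−α`, and Mittag-Leffler kernels
`pref · t^(μ−1) E_{a,μ}(−c tᵃ)` — plus the coefficient `η` of a
Dirac-delta term contributed by a free dashpot in parallel. Each term
carries its exact running integral `∫₀ᵘ E_reg`, which is what the
solver consumes:

* constant `E`: `E u`
* exponential `E e^{−u/τ}`: `E τ (1 − e^{−u/τ})`
* power `E u^{−α}`: `E u^{1−α}/(1−α)` (the t→0 singularity is
  integrable and handled exactly)
* ML term: `pref · u^μ E_{a,μ+1}(−c uᵃ)` (index-shift identity)

Springpot moduli use the reference-time-1-s parameterisation: `E_α1`
[Pa] is the value of the kernel at t = 1 s and time enters as a
numerically unitless multiple of 1 s; `rescale_springpot_modulus`
converts to other reference times. Characteristic times follow the
standard definitions (`τ_KV = η/E∞`, `τ_MW = η/E0`,
`τ_rel = η/(E0−E∞)`, `τ_creep = E0η/(E∞(E0−E∞))`,
`τ = (E_α1/E∞)^{1/α}` and relatives for the fractional networks). For
the springpot+dashpot serial models the serial-time formula
degenerates at the dashpot limit, so the package uses
`τ = (η/E_β1)^{1/(1−β)}` (the dashpot treated as an α = 1 springpot of
coefficient η).

The fractional SLS reduces to the classical SLS in the *exponential*
limit of its kernel, α = 1 (the Mittag-Leffler function `ML_1` is the
exponential); reductions are asserted there and at β = 0. For the
same reason the NHA-positive region of the fractional SLS *broadens as
α decreases* from 1 toward the power-law regime; the package's
property tests encode that direction.

## Mittag-Leffler numerics

`E_{a,b}(z)` is needed for `0 < a ≤ 1`, `0 < b ≤ 2`, `z ≤ 0` only.
Four stitched branches give ~1e-10 relative accuracy in plain float64:
Taylor series for `|z| ≤ 0.7` (no harmful cancellation there for any
`a`); the Gorenflo–Loutchko–Luchko spectral integral over the
relaxation spectrum for `0.7 < |z| < 1000` and `b ≤ 1`; the downward
recurrence `E_{a,b} = (E_{a,b−a} − 1/Γ(b−a))/z` to reach that range
when `b > 1`; and the Poincaré asymptotic series with optimal
truncation for `|z| ≥ 1000` (the asymptotic branch alone is *not*
1e-8-accurate below |z| ≈ 300, which is why the integral band is this
wide). At `a = 1` the function is evaluated through `exp`/`expm1`/
`hyp1f1` directly. The crossovers were fixed by requiring neighbouring
branches to agree to 1e-10 in overlap bands; the test suite pins the
implementation against frozen arbitrary-precision reference values.

## Contact solver

Product integration on a uniform grid of `n_steps` intervals per phase
(default 1000, minimum 100): within each step the rate of `δⁿ` is
replaced by its exact interval mean `(Δδⁿ)/Δt` while the kernel is
integrated exactly via the running integrals above. Consequences: the
elastic case is reproduced to machine precision at any resolution, and
singular springpot kernels cost nothing extra (no quadrature across
the `t^{−α}` singularity). The Dirac term contributes
`η · d(δⁿ)/dt` at the current time with full weight (causal limit);
this reproduces the finite contact-force jump of a Kelvin–Voigt solid
under a flat punch and the force drop at the triangular turning point,
both of magnitude set by the dashpot.

`t1(t)` is found per retraction sample by bracketed bisection on the
discretized matching integral to an absolute tolerance of `dt/100`,
warm-started from the previous sample (t1 is non-increasing), followed
by one false-position step that sharpens the root by ~3 decimal digits
— this is what brings the cylinder Lee–Radok/Ting equivalence below
1e-8 relative. Detachment is declared at the first sample where the
matching integral is negative even with `t1 = 0`; `t_detach` is
linearly interpolated between the bracketing samples on that
integral's value, the force is exactly zero afterwards, and
`t_ind := t_detach` (the probe–sample contact time, with
`t_m < t_ind ≤ 2 t_m`).

For Mittag-Leffler kernels the running integral is tabulated once per
curve on 480 log-spaced nodes and interpolated monotonically (PCHIP)
in log-log space, with power-law continuation below the tabulated
range; interpolation error is orders of magnitude below the metric
tolerances and the closed-form kernels bypass it entirely.

Closed-form oracle curves (`analytic_curve`) are derived independently
of the solver: spring (any ramp/probe), dashpot (delta-kernel
collapse, any ramp/probe), Kelvin–Voigt triangular (any probe;
`t1 = 2t_m − t − τ_KV`, `t_detach = 2t_m − τ_KV`) and Maxwell
triangular (cylinder and cone, where the convolution is elementary;
`t_detach = t_m + τ ln(2 − e^{−t_m/τ})`). The solver agrees with all
of them to better than 0.5% max relative force error at 400 steps.

## Metrics

* **Apparent YM** — linear least squares of `F = C_geom·YM·δⁿ` on the
  *approach* segment only (the quarter-cycle-average identity below
  presupposes approach-only data; using the full loop would mix in the
  hysteresis).
* **Curve exponent** — nonlinear least squares of `F = A δᵐ` in
  normalized coordinates, initialized at the Hertzian solution;
  samples shallower than 1% of the maximum depth are excluded because
  the power-law fit is unstable against contact-point noise there.
* **NHA** — trapezoidal loop area over approach area in `(δ, F)`
  space. The retraction path is closed at the apex with the
  *retraction-side* force limit (linear-in-time extrapolation of the
  first two retraction samples): kernels with a Dirac term have a
  genuine force discontinuity at the turning point, and closing with
  the approach value would bias the dashpot NHA below its exact value
  of 1. Values are clipped to [0, 1]; clipping beyond numerical
  jitter is logged.

## Sweeps and diagnostics

`sweep_indentation_time` takes the *nominal* cycle time `t_ind = 2t_m`
as its control grid (the realized contact time is an output of the
simulation and is recorded per point); normalized time is
`t̄ = t_ind/τ` with the model's characteristic time, and the
normalized-YM axis can divide by `E0`, `E∞` or `E0 − E∞` to match the
convention appropriate to each model. Per-point failures are logged
and left as gaps.

Two diagnostics link the metrics to the relaxation function:
`eq_average_check` compares the apparent YM with
`<E> = (4/t_ind)∫₀^{t_ind/4} E dt` (computed from the exact running
integrals; the delta term adds `η/(t_ind/4)`), and `nha_slope_check`
pairs the NHA with `−2 d ln<E>/d ln t` (central difference with step
ratio 1.05). Measured behaviour at 300-step resolution: the YM tracks
`<E>` within 8% over 4.5 decades for the SLS, two-time generalized
Maxwell, fractional SLS and fractional-SLS-with-dashpot models (the
package asserts a 15% bound); the NHA–slope pairing is exact at both
anchors (spring: 0/0; dashpot: NHA 1, doubled slope 2) and agrees
within ~0.15 for springpots, degrading toward the dashpot-dominated
regime where the doubled slope saturates at 2 but NHA at 1.

## Synthetic data and noise

`add_noise` adds seeded Gaussian noise to the force channel only — the
piezo (depth) channel of real instruments is far cleaner than the
force channel, which is the dominant noise source in practice. It
emulates neither instrument drift, contact-point offset, hydrodynamic
drag nor adhesion; robustness results obtained with it speak to
fit stability under uncorrelated force noise, not to those systematic
effects. A 1% relative force noise leaves the Hertz-fit modulus
within 1% at 1000 samples per phase (tested).

## Default parameters

Probe dimensions follow common AFM practice: sphere radius 5 µm,
cylinder radius 0.4 µm, cone half-angle 85°; maximum depth 100 nm
(sphere warns when `δ_max > 0.1 R`). Moduli default to the kPa-to-
sub-kPa range typical of cells and soft gels (e.g. `E0 = 1000 Pa`,
`E∞ = 300 Pa`). The geometric constants omit the `1/(1−ν²)` divisor
by default so fitted moduli reproduce quoted reference values
directly; `nu_mode="methods"` applies the divisor for comparison with
experiments. Two-time generalized-Maxwell demonstrations use
τ = 0.01 s and 10 s ("well separated") versus 0.01 s and 0.03 s
("close"). Test and benchmark runs use 200–1000 grid steps per phase;
grid-convergence is verified explicitly (doubling the resolution moves
smooth-model forces by < 0.1%).

## Known limitations

* Histories with more than one contact-radius maximum (general
  Ting/Graham case) are out of scope, as are load-controlled
  protocols, adhesive contact and finite-thickness corrections beyond
  the multiplicative hook.
* Creep compliance, frequency-domain moduli and time–frequency
  interconversion are not provided.
* The `t1` solver assumes the matching integral is monotone in `t1`,
  which holds for non-negative, non-increasing relaxation kernels (all
  catalogued models) but is not checked for user-extended kernels.
* The Mittag-Leffler accuracy statement covers the catalogue's working
  sector (`0 < a ≤ 1`, `0 < b ≤ 2`, `z ≤ 0`); outside it (notably
  `a = 1` with non-integer `b` at very large `|z|`) accuracy degrades.
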