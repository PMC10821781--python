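# Methods

`dcsflow` synthesizes and inverts diffuse correlation spectroscopy (DCS)
measurements of a layered human head. This note records the models, the
numerical choices, and the limits of what the synthetic experiments can
show.

## Physical models

**Correlation diffusion.** The unnormalized field autocorrelation
G1(ρ, τ) of multiply scattered coherent light obeys a diffusion-type
equation whose absorption term grows with lag time τ through the mean
square displacement of the moving scatterers, ⟨Δr²(τ)⟩ = 6·Db·τ for
Brownian dynamics. The blood flow index is BFi = α·Db (α = dynamic-scatterer
fraction, 1 everywhere in this package); the measured quantity is
g2(τ) = 1 + β·g1(τ)², with the coherence factor β set by the collection
optics.

**Semi-infinite solver.** The homogeneous half-space solution uses the
extrapolated-boundary image construction:
G1 ∝ exp(−K r1)/r1 − exp(−K r2)/r2 with
K²(τ) = 3 μa μs′ + α μs′² k0² · 6 Db τ, source depth z0 = 1/(μa+μs′),
extrapolation length zb = 5/(3 μs′), r1/r2 the distances to the source and
to its negative image. Validated against an arbitrary-precision
transcription of the closed form (relative error < 1e-10).

**Three-layer solver.** Scalp/skull/brain slabs are solved in the
transverse Fourier domain: within each layer the transformed Green's
function is a combination of exp(±Θp z) with
Θp²(q, τ) = 3 μa,p μs′,p + 6 k0² μs′,p² Db,p τ + q². The layer coefficients
are eliminated with a bottom-up admittance recursion written in tanh and
exponentials of non-positive arguments, which is algebraically identical to
the usual cosh/sinh numerator/denominator closed form but cannot overflow
at large q (cosh(Θ·Δ) exceeds double range near q = 30 mm⁻¹ for
centimeter-thick layers). Two boundary choices were genuinely open:

* *Top boundary.* We impose the extrapolated (Dirichlet) condition
  G(z = −zb) = 0 with zb = 5/(3 μs′₁) — the same construction the
  semi-infinite image solution uses — rather than a partial-flux mixed
  condition. With a mixed condition the two solvers disagree at the
  4e-3 level in the homogeneous limit; with the extrapolated condition they
  agree to ~5e-6 (the homogeneous-limit equivalence test enforces < 1e-3).
* *Source depth.* One transport mean free path including absorption,
  z′ = 1/(μa,1 + μs′,1), again for exact consistency with the image
  solution in the homogeneous limit.

The deepest layer is treated as semi-infinite. The photon diffusion
coefficient Dp = c/(3 μs′,p) enters numerator and denominator jointly, so
the value chosen for c cannot affect the normalized g1 (asserted by a
test).

**Hankel inversion and its precision floor.** g1(τ) = G(ρ, 0, τ)/G(ρ, 0, 0)
with G obtained from ∫₀³⁰ Ĝ(q, 0, τ) q J0(qρ) dq (Gauss–Legendre,
starting at 300 nodes, doubled until successive g1 estimates agree to 1e-8,
at most 4 doublings; a `QuadratureError` carries diagnostics otherwise).
The oscillatory Bessel kernel cancels an O(1) integrand down to the
attenuation scale exp(−K(0)·ρ); once that falls below ~1e-13 of the
integrand scale (strong absorption at large ρ, e.g. μa ≳ 0.1 mm⁻¹ at
ρ = 30 mm) no double-precision quadrature is meaningful and the solver
raises instead of returning noise. All layered-model work here lives in the
head-tissue regime (μa ≈ 0.011–0.027 mm⁻¹), far from that floor; property
tests that compare the two solvers draw from this physiological domain for
the same reason.

## Correlator noise

The per-lag standard deviation of a measured g2 follows the shot-noise /
speckle model of a linear-bin correlator, parameterized by bin width Tb
(default 1 μs, equal to the smallest lag, with bin index m = round(τ/Tb)),
integration time Tint, detected rate I (default 8.05 kcps at 785 nm) and
the curve's decay rate Γ from an unweighted least-squares fit of
1 + β exp(−Γτ) (re-fitted per curve). σ(τ) scales exactly as Tint^(−1/2).
Noise realizations are i.i.d. zero-mean Gaussians across lags — a
documented simplification; real correlator noise is lag-correlated — and
noisy g2 values are deliberately not clipped to [1, 1+β]. Named presets:
`Tint1`, `Tint10`, `Tint30`, `noiseless`.

Note on Γ: for these non-exponential curves the least-squares rate differs
from the 1/e secant rate by ~50%; σ(τ) is insensitive at that level.

## Monte Carlo transport

A scattering-only layered-slab random walk (Henyey–Greenstein, g = 0.89;
μs = μs′/(1−g); uniform n = 1.37 inside vs 1.0 outside with Fresnel
reflection at the top surface; absorbing bottom/side boundaries; 1 mm flat
source beam; photons killed beyond 10× the slab depth of accumulated path).
Each detected photon records per-layer path length L_i and momentum
transfer Y_i = Σ(1−cosθ). Absorption is applied analytically at
re-weighting time, exp(−Σ μa,i L_i), so one photon set serves arbitrary
(μa, Db) settings — "white" Monte Carlo. The field autocorrelation is

G1(τ) ∝ Σ_s exp(−(k0²/3) Σ_i Y_{s,i}·6 D_i τ) · exp(−Σ_i μa,i L_{s,i}),

normalized to G1(0); the per-event factor matches the diffusing-wave
convention exp(−q²⟨Δr²⟩/6) with q² = 2k0²(1−cosθ).

Detectors are annular rings centered on the source (default half-width
0.5 mm). Rings azimuthally average the discrete fibers a real probe would
use; the fixed half-width raises detection efficiency by orders of
magnitude at desk-scale budgets at the cost of blurring ρ by ±0.5 mm —
an accepted bias well under the statistical noise at the budgets used.
Against diffusion theory (homogeneous slab, ρ = 10 mm, 10⁶ photons) the
reconstructed g1 agrees with the semi-infinite closed form to ~1% wherever
g1 > 0.1.

## Training corpus and label encoding

Curves are synthesized from the semi-infinite model with independent
uniform draws: μa ∈ (0.01, 1] mm⁻¹, μs′ ∈ (0.5, 1.6] mm⁻¹, β ∈ (0, 1],
BFi ∈ [1e-8, 1e-5] mm²/s, ρ ∈ [5, 30] mm. BFi is drawn **log-uniformly**
by default (a linear-uniform switch exists): BFi is a scale parameter
spanning three decades, and under a linear-uniform draw ~90% of the mass
sits in the top decade, so the MSE-optimal regressor answers "a few 1e-6"
almost independently of the curve — we measured its flow sensitivity on
layered test curves at ~2%, i.e. an estimator that cannot even rank flows.
The log-uniform draw restores a monotone flow response. The noise mixture is equal
quarters noiseless / Tint1 / Tint10 / Tint30. Inputs are normalized to
(0, 1] by dividing the whole vector by its maximum — this preserves the
β-dependent far-lag plateau ≈ 1/(1+β), so β stays inferable; for noisy
curves the maximum need not sit at the first lag, and the global maximum is
used regardless. Labels: β encodes to itself; BFi encodes logarithmically,
u = (log10 BFi + 8)/3, because BFi spans three decades and a linear
encoding collapses the gradient signal at the low end. The loss is the
plain squared error on the encoded 2-vector.

Two identifiability facts are documented here because they bound what any
estimator — not just this network — can achieve, and they shape how the
evaluation results must be read:

* **Pointwise BFi is not identifiable from one curve.** The Jacobian of
  the normalized curve with respect to (μa, μs′, β, BFi, ρ) has effective
  rank 3 (singular values ≈ 2.1, 0.97, 0.011, then < 1e-6): directions
  exist along which BFi changes by decades while the curve changes below
  any realistic precision. The held-out median |Δlog10 BFi| therefore has
  a task floor of roughly 0.15–0.2 decades under this sampling (the exact
  value depends on the BFi prior); we verified that an independent
  gradient-boosted regressor and a k-NN posterior-mean estimator land on
  the same floor as the network.
* **Partial volume bounds the network's deep-flow sensitivity.** On
  three-layer test curves at ρ = 30 mm, the curve's overall decay rate
  responds to brain-layer flow with elasticity only ≈ 0.17 (scalp and
  skull contribute most of the measured decorrelation). Any estimator
  that maps semi-infinite curve shape to a single BFi — the network, a
  homogeneous fit, or the Bayes-optimal posterior mean (probed directly
  with k-NN regression over large corpora, under both BFi priors, with
  and without noise, and under alternative input normalizations) —
  exhibits intrinsic deep-flow sensitivity of order 10–30% on such
  curves. Sensitivities near 100% require explicitly modeling the
  layered decomposition, which here only the three-layer fitter does
  (η ≈ 98% with near-correct assumptions). Reported network
  sensitivities must be interpreted against this ceiling.

## Network and training

Input 1×127 normalized g2. Shared trunk: two convolutions (kernel 13,
stride 5; 16 then 32 filters), each followed by batch normalization and a
rectifier. Two independent heads (one per output) mirror the trunk's
conv+BN structure (16 then 12 filters, half-kernel zero padding so the
3-sample trunk output survives the stride) and end in a pointwise
(kernel-1) convolution with a sigmoid, giving scalar outputs in (0, 1).
Counting every module with parameters or an activation
(conv/BN/ReLU/sigmoid) the model has 18 layers and 25,506 trainable
parameters; `find_filter_configs` enumerates the filter-count solutions of
that parameter budget, and both anchors are asserted in tests. Sigmoid as
the *internal* activation was evaluated and rejected: it plateaus an order
of magnitude higher even on a fully identifiable task.

Training: Adam, fixed learning rate 1e-5, batch 128, MSE on encoded
labels, early stopping on validation loss with patience 20 within a
configurable epoch cap, best-validation weights restored. Single-threaded
runs are bit-reproducible for a fixed seed. The trainer is a
self-contained NumPy implementation (im2col convolutions with explicit
backprop) verified against finite differences; the regressor is also
exposed as a scikit-learn estimator (`NeuralG2Regressor`).

## Fitters

Both classical fitters minimize the unweighted sum of squared g2 residuals
over the 127-lag grid with Levenberg–Marquardt, initialized at β = 0.3,
BFi = 2e-7 mm²/s. Internally they optimize logit(β) and log10(BFi) —
positivity and range enforcement by reparameterization rather than bounds,
and conditioning across BFi's three decades. Tolerances 1e-10, at most 500
function evaluations; non-convergence is reported in the result, never
raised. The three-layer fitter frees (β, Db3) with scalp/skull dynamics
fixed (Db1 = 1e-6 mm²/s, Db2 = 0). The assumed optical properties of the
fitting protocol (μs′ = 0.635/0.851/1.099 mm⁻¹) deliberately differ
slightly from the generating head (0.660/0.860/1.110); the protocol is
replicated as specified, not harmonized, and the assumed values are carried
in each fit's provenance.

## Evaluation protocols

* **Relative flow (rBFi).** Brain Db3 swept as [1+0.05(w−1)]·6e-6 mm²/s,
  w = 1..21, at ρ = 30 mm; rBFi is referenced to each estimator's own w=1
  estimate, error = |rBFi − rBFi_GT|/rBFi_GT·100%.
* **Intrinsic sensitivity.** η(ζ) = relative change in recovered BFi per
  relative change in true brain flow, reported for perturbations
  ζ ≥ 20% (the ratio is ill-conditioned as ζ → 0). Both the fine ladder
  (5% steps to +100%) and the coarse one (10% steps, w = 1..11) are
  available; the two ladders coexist as options rather than being silently
  merged.
* **Noise trials.** Repeated estimation of the baseline curve under a
  noise preset (default 100 seeded realizations); non-convergent fits are
  counted and excluded from moments.
* **Robustness.** One head parameter (brain μa, brain μs′, scalp or skull
  thickness) swept ±20%/±40% around baseline; E_BFi compares the fit that
  keeps assuming the baseline against the fit given the true value. The
  network takes no assumed inputs, so its E_BFi is zero by construction
  under this definition (its absolute error is probed by the other
  protocols).
* Test curves come from the `analytic3` generator (three-layer analytical;
  default) or `mc` (reduced-budget Monte Carlo).

## Desk-scale problem sizes

The package's own reproduction runs (scripts/acceptance.py) use an
80,000-curve corpus (reference recipe: 200,000) with an epoch cap of 120
under patience-20 early stopping, 2×10⁶ photons for the ρ = 5 mm Monte
Carlo target (reference-grade runs use 2×10⁹ on GPU hardware), and 100
noise realizations per noise condition. The test suite scales further down
(60,000-curve corpus, 10⁶-photon Monte Carlo check). These sizes are the
package's choices for a single-CPU workflow; all protocol definitions are
size-agnostic.

## Known limitations

* Noise is uncorrelated across lags; real multi-tau correlators produce
  correlated noise, so noise-robustness results here are optimistic about
  effective sample size per curve.
* The Monte Carlo blurs ρ by the ring half-width and uses reduced photon
  budgets; curves at ρ = 30 mm from small runs are statistically noisy,
  which is why analytical three-layer curves are the default ground truth
  for the sweep protocols.
* Training data come from the semi-infinite model only; applying the
  network to layered curves is deliberate domain shift (that is the
  experiment), and its absolute accuracy there depends on that shift, not
  only on optimization quality.
* Timing comparisons between estimators (`dcsflow report`) are provided
  for convenience and are hardware-dependent; nothing asserts them.
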