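# Methods

## Model

Laboratory databases mix physiological and pathological measurements
without labels. refmix treats an analyte value y given a covariate x
(age) as a finite Gaussian mixture

    f(y | x) = Σ_{m=1..M} α_m(x) · N(y; μ_m(x), σ_m(x)),

with M = 2 the validated case: component 1 is the lower, physiological
distribution whose quantile curves Q_p(x) = μ₁(x) + σ₁(x)Φ⁻¹(p) are the
continuous reference intervals; component 2 absorbs pathological values
lying above. The model assumes Gaussian components, a single continuous
covariate, and a pathological component positioned above the
physiological one throughout the covariate range. Asymmetric component
families, several pathological components and multivariate covariates
are out of scope (M > 2 is structurally supported but not validated).

Both input and output are standardized (mean 0, sd 1, n−1 convention)
before fitting; all reported surfaces and quantile tables are mapped
back to the original scale (μ → μ·s_y + ȳ, σ → σ·s_y, α unchanged).

## Estimators

### Mixture density network

A single hidden layer of H tanh units (default H = 5) feeds (K+1)M = 6
output neurons: M softmax units for α_m(x), M identity units for μ_m(x),
M positive-transformed units for σ_m(x) (exponential or softplus
activation). The loss is the mixture negative log-likelihood, always
evaluated through log-sum-exp — the raw product likelihood underflows at
n = 10⁴. Gradients are analytic: with posterior responsibilities
π_m = α_m f_m / Σ_k α_k f_k, the output pre-activation derivatives are
α_m − π_m (weights), π_m(μ_m − y)/σ_m² (means) and
π_m(1 − (y−μ_m)²/σ_m²) for the exponential scale parameterization
(softplus adds a chain-rule factor σ'(a) = logistic(a)); the hidden
layer follows by ordinary backpropagation. Correctness is audited
against central finite differences in the test suite.

Two training regimes:

* **Quasi-Newton ("bfgs" family).** scipy's L-BFGS-B with analytic
  gradients, defaults: relative objective-decrease tolerance 1e-9,
  projected-gradient tolerance 1e-6, iteration cap 500. The
  objective-decrease criterion mirrors the convergence semantics of
  classical BFGS implementations in statistical software; an absolute
  gradient-norm rule alone is unreachable here because the NLL is O(n).
  The cap was fixed after verifying on n = 10⁴ fits that beyond ~500
  iterations the loss changes only in the fourth significant digit and
  component identification never changes; `converged=False` on a
  cap-limited run is therefore expected and benign for interval
  extraction. Default scale activation: exponential.
* **ADAM with early stopping.** Full-batch gradient steps (the network
  has ~35 parameters, so full batches are stable), learning rate 0.01,
  canonical moment parameters (0.9, 0.999, 1e-8), epoch cap 2000. A
  random 20 % validation split is drawn under the run seed; training
  stops when the best validation NLL has not improved for 20 consecutive
  epochs, and the weights from the best validation epoch are restored.
  Default scale activation: softplus. The learning rate, epoch cap and
  batch policy are package choices; patience (20) and the split fraction
  (20 %) are part of the protocol being replicated.

The constant-weight variant (`bfgs_const`) freezes the hidden-to-weight
connections at zero (masking, so the flat parameter vector contract is
uniform) and trains only the weight biases: the softmax weights become
input-independent, a middle ground between EM and the full network.

### Initialization

* **Random:** glorot-uniform matrices, U(±√(6/(fan_in+fan_out))), zero
  biases.
* **Custom (partially customized starting weights):** OLS of the
  standardized outcome on the B = 5 tanh basis; the empirical 10 % and
  90 % residual quantiles (linear-interpolation estimator) are added to
  the OLS intercept; the two shifted curves seed the location heads, the
  basis offsets/slope seed the hidden layer, and scale and weight heads
  stay glorot-random. The initial location gap is the constant
  q90 − q10 ≥ 0, so the starting curves never cross and component 1
  starts below component 2 by construction.

### EM benchmark

Per component, μ_m(x) = d(x)'β_m and log σ_m(x) = d(x)'γ_m on the
intercept-plus-tanh-basis design d(x); weights are constants α_m. The
tanh basis (B functions of common slope B/(max−min) with equally spaced
offsets) replaces the usual cubic B-splines so that both estimators
share one function class. The M-step maximizes the responsibility-
weighted Gaussian likelihood per component by direct L-BFGS-B
optimization with analytic gradients, warm-started at the previous
coefficients (the reference formulation delegates this fit to an
additive-model package; the direct implementation honors the same
likelihood without that dependency), and updates α to the mean
responsibility in closed form. Because the inner step only improves the
weighted likelihood from the warm start, observed-data NLL monotonicity
is preserved even when the inner optimizer is stopped early; the suite
audits this on every iteration path. Initial responsibilities come from
the naive single-Gaussian fit: the upper component receives
Φ((y − μ̂)/σ̂) — a soft assignment increasing in y, so high values lean
pathological. The exact mapping "based on" that CDF is a package
decision and is configurable (`ascending=False` flips it); uniform
Dirichlet rows are available to reproduce the fragility of random
observation weights. Convergence: absolute NLL change < 1e-6 or 500
iterations (loop starts with an M-step, since the initializer supplies
responsibilities).

## Synthetic data

The generator emulates an unlabeled laboratory database: x ~ U(0,1),
component label Bernoulli(α₁(x)), y Gaussian with the labeled
component's curves. Default truth functions — μ₁ = 1 + 1.5·sin(πx),
σ₁ = 0.25 + 0.15x, μ₂ = μ₁ + 2.5 − x, σ₂ = 0.5, α₁ = 0.70 + 0.20·sin(πx)
(dependent) or 0.80 (independent) — are package defaults chosen to give
nonlinear location/scale effects, an upper pathological component over
the whole range, and a healthy fraction inside [0.05, 0.99]; all are
injectable. The study grid is the 2×2 factorial {dependent, independent}
× {n = 5000, 10000}, replicated 100 times by default (400 datasets).

What the generator does *not* emulate about real analyte data: skewed or
heavy-tailed components, age-varying pathological shape, heteroscedastic
measurement error, repeated samples per patient, and covariates beyond a
single uniform input. Passing tests therefore demonstrate correct
recovery *under the stated mixture assumptions*, not robustness to their
violation.

## Evaluation

Fits are relabeled so component 1 minimizes Σ_i μ_m(x_i) (stable
tie-break: order preserved). Failure flags: *location crossing* — a
strict sign change of μ₂ − μ₁ between adjacent points of a 201-point
grid on [0,1] (touching zero is not crossing; the threshold-free
sign-change rule is a package decision); *degeneracy* — any component
with mean mixture weight over the data below 0.05 (the rule is
inclusive: exactly 0.05 passes). Clean runs are scored by
ISE(θ̂) = ∫₀¹ (θ̂ − θ)² dx via trapezoid quadrature on the same grid, on
the original measurement scale, for α̂₁, μ̂₁, σ̂₁ and Q̂_{0.95,1}. ISE
magnitudes depend on the truth functions, so cross-study comparisons are
made on orderings and failure frequencies, not magnitudes.

Multi-restart fitting (the protocol for real analyte data) repeats a fit
over derived seeds, discards degenerate runs, and returns the
minimum-loss solution, retaining all per-restart losses for stability
reporting.

## Numerical choices and degenerate inputs

* σ floor 1e-8 when evaluating densities (guards optimizer excursions);
  log-scale clipping at ±30 inside the EM M-step.
* The network NLL + gradient is evaluated by a compiled (numba) kernel —
  a single fused pass over observations, mathematically identical to the
  pure-numpy reference path kept alongside it (agreement ~1e-12; both are
  audited against finite differences). Full-batch training at n = 10⁴ is
  allocation-bound in plain numpy; the kernel makes the simulation study
  run in minutes rather than hours.
* A non-finite trial NLL during optimization returns a large finite
  penalty (1e12) so line searches can backtrack; a persistent failure
  surfaces as a flagged record in the study harness, never an abort.
* The mixture likelihood is unbounded (a component can spike on one
  observation); the σ floor, the degeneracy flag and min-loss selection
  over non-degenerate restarts are the mitigations.
* Zero-variance input, empty data, rank-deficient basis designs, and
  quantile levels outside (0,1) raise ValueError with a diagnostic.
* Problem sizes in the test suite: the heavy acceptance checks run 100
  EM fits per weight setting at n = 10⁴, and 25-replicate cells for the
  network variants; unit tests use n ≤ 2000.

## Known limitations

* Gaussian components only; real hemoglobin-like analytes often need
  skewed components.
* The ADAM regime can over-regularize near the covariate boundary
  (early stopping), and the quasi-Newton regime can overfit if H is
  raised; no explicit weight penalty is implemented.
* Constant-weight estimators (EM, `bfgs_const`) are structurally
  misspecified when the healthy fraction varies with age — that bias,
  not a numerical flaw, is the phenomenon the study harness measures.
* Per-patient deduplication is out of scope for the two-column input
  contract.
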