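# dcsflow

Forward models, noise synthesis, photon Monte Carlo and curve inversion for
**diffuse correlation spectroscopy (DCS)** — the near-infrared technique
that measures blood flow from the temporal intensity autocorrelation
g2(τ) of multiply scattered coherent light.

DCS quantifies the blood flow index **BFi = α·Db** (mm²/s) by modeling the
field autocorrelation g1(τ), related to the measurement through the Siegert
relation g2(τ) = 1 + β·g1(τ)². For a homogeneous half-space,

    g1(τ) ∝ exp(−K(τ) r1)/r1 − exp(−K(τ) r2)/r2,
    K²(τ) = 3 μa μs′ + α μs′² k0² · 6 Db τ,

while the human head is better described as scalp/skull/brain slabs, solved
here in the transverse Fourier domain and inverted with a Hankel transform.
The package is for researchers in biomedical optics who want to study — on
fully synthetic but physically calibrated data — how three estimators of
(β, BFi) behave on layered heads:

* a small 1-D convolutional network (25,506 parameters, trained on
  semi-infinite curves spanning broad optical-property ranges, implemented
  and trained entirely in NumPy),
* a homogeneous semi-infinite Levenberg–Marquardt fit,
* a three-layer Levenberg–Marquardt fit with assumed layer properties.

It includes the correlator noise model σ(τ) of a photon-counting correlator
(σ ∝ Tint^(−1/2)), a "white" layered-slab photon Monte Carlo whose detected
histories (per-layer path lengths and momentum transfer) can be re-weighted
to arbitrary absorption and layer dynamics without re-simulation, and the
evaluation protocols: relative-flow recovery, intrinsic brain-flow
sensitivity, noise trials, and robustness to wrong assumed head parameters.

## Worked example

```python
import numpy as np
from dcsflow import (AcquisitionSpec, make_tau_grid, siegert_g2,
                     baseline_head, three_layer_g1)
from dcsflow.fitting import fit_semi_infinite, fit_three_layer, \
    protocol_head_assumptions

grid = make_tau_grid()                      # 127 lags, 1 us .. <10,000 us
acq = AcquisitionSpec(rho=30.0, beta=0.5)   # 30 mm source-detector channel
head = baseline_head()                        # scalp/skull/brain baseline

g2 = siegert_g2(three_layer_g1(head, acq, grid), beta=0.5)

semi = fit_semi_infinite(g2, acq)           # homogeneous model
three = fit_three_layer(g2, acq, protocol_head_assumptions())
print(f"true brain BFi 6.0e-06  semi {semi.bfi_hat:.2e}  "
      f"three {three.bfi_hat:.2e}")
```

prints

```
true brain BFi 6.0e-06  semi 3.87e-07  three 7.54e-06
```

The homogeneous fit of a layered-head curve collapses to the scalp-flow
scale (≤ 1e-6 mm²/s) — the classic superficial-contamination artifact —
while the three-layer fit recovers the brain flow's order of magnitude; its
residual +26% bias comes from the protocol's deliberately imperfect assumed
optical properties (μs′ = 1.099 vs the generating 1.110 mm⁻¹, etc.). Training and applying the network is one more step:

```python
from dcsflow.dataset import sample_params, synthesize_batch, ParamRanges
from dcsflow.net import NeuralG2Regressor
rng = np.random.default_rng(0)
p = sample_params(rng, 60_000, ParamRanges())
X, _ = synthesize_batch(p, rng.integers(0, 4, 60_000), rng)
reg = NeuralG2Regressor(max_epochs=100).fit(X, p[:, 2:4])  # beta, BFi
beta_hat, bfi_hat = reg.predict(X[:1])[0]
```

A command-line interface mirrors the library:
`dcsflow generate-data`, `dcsflow train`, `dcsflow predict`, `dcsflow fit`,
`dcsflow simulate-mc`, `dcsflow evaluate {rbfi,sensitivity,noise,robustness}`
and `dcsflow report` (timing). Every run writes a JSON manifest with its
arguments and seeds.

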