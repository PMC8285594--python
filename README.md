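# spherelimits

Detection limits for sphere (soma) radius and signal fraction in
powder-averaged b-tensor diffusion MRI.

Multi-compartment models of brain tissue decompose the diffusion-weighted
MR signal into neurite (stick/cylinder), soma (sphere) and extracellular
(ball) sources. Whether the spherical compartment's *size* and *signal
fraction* are actually recoverable from a human in-vivo acquisition —
linear, planar and spherical tensor encoding (LTE/PTE/STE), powder-averaged
per shell — is a question about noise, model degeneracy and the physics of
restricted diffusion. This package implements the simulation-and-estimation
machinery to answer it:

* **Waveforms & b-tensors** — pulsed LTE and bipolar PTE/STE surrogates,
  q-trajectories, `B = ∫q(t)q(t)ᵀdt`, shape parameter bΔ, and dephasing
  spectra `f(ω)`.
* **Restricted diffusion in the frequency domain** — Lorentzian diffusion
  spectra `λ(ω) = Σᵢ BᵢaᵢD₀ω²/(aᵢ²D₀²+ω²)` for cylinders and spheres
  (Bessel-derivative roots μᵢ), and the attenuation exponent
  `ρ = (1/2π)∫fᵀ(ω)D(ω)f(−ω)dω`, `S = e^(−ρ)`.
* **Powder-averaged signal models** —
  `A = exp(−b·DI(1−bΔDΔ))·g(3b·DI·bΔ·DΔ)` with
  `g(α) = √(π/4α)·erf(√α)`; nested stick+ball, stick+ball+sphere and
  cylinder+ball+sphere models, optional Rician-floor prediction
  `Sₙ = √(S²+σ²)`.
* **Synthetic data** — the 604-measurement LTE/PTE/STE protocol,
  per-direction Gaussian or Rician noise at a chosen SNR = 1/σ, arithmetic
  powder averaging, b0 normalization.
* **Estimation & model selection** — bounded multi-start least squares,
  Jacobian confidence intervals, reduced chi-square
  `χ²_red = [Σnᵢ(Sᵢ−Sᵢ′)²/(n−k)]/σ²`, fixed-fraction goodness-of-fit
  scans, and nested-model F-tests
  `F = (SSR₁−SSR₂)(N−M₂)/(SSR₂(M₂−M₁))` over (f_sphere, R_sphere, SNR)
  detection grids.
* **Power-law analysis** — high-b exponent fits `S/S0 = β·b^(−α)` (α = ½
  for pure sticks) and the empirical sphere-radius lower bound from the α
  surface.

See `docs/methods.md` for the model details, assumptions and numerical
choices.

## Worked example

Simulate one "voxel" with half its signal in 5 μm spheres at SNR 100,
fit the three-compartment model, and test whether the sphere compartment
is statistically warranted:

```python
from spherelimits import (TissueParams, default_protocol, generate_dataset,
                          fit_model, f_test)

protocol = default_protocol()
truth = TissueParams(f_stick=0.25, f_ball=0.25, f_sphere=0.5,
                     d_par=2.0, d_ball=0.6, r_sphere=5.0)
data = generate_dataset(truth, protocol, snr=100.0, scenario="rician", seed=7)

fit = fit_model(data, protocol, "stick_ball_sphere", seed=1)
simple = fit_model(data, protocol, "stick_ball", seed=1)
ft = f_test(simple.ssr, fit.ssr, simple.n_params, fit.n_params, data.n_points)
```

Output:

```
f_sphere = 0.505   (true 0.5)
f_stick  = 0.234   (true 0.25)
R_sphere = 5.02 um  [95% CI 4.92, 5.11]  (true 5)
Din_par  = 1.98 um^2/ms  (true 2.0)
D_ball   = 0.61 um^2/ms  (true 0.6)
F = 5801.6, p = 3.69e-21  -> prefer full model
```

At this favorable operating point (large fraction, mid-size sphere, high
SNR) all parameters are recovered and the F-test overwhelmingly supports
the sphere compartment. The interesting science is where this breaks down:
at SNR 50 the detectable sphere fraction bottoms out near 10%, radii below
~3 μm are indistinguishable from zero-size spheres, Rician noise biases
radius estimates upward, and the high-b power-law exponent only departs
from the stick value ½ for spheres larger than ~7 μm.

## Command line

```bash
spherelimits simulate --seed 1 --out out/sim        # one noisy dataset
spherelimits fit --seed 1 --out out/fit             # simulate + fit + report
spherelimits scan --seed 1 --out out/scan           # fixed-f_sphere χ²red scan
spherelimits ftest-grid --seed 1 --out out/grid     # detection grid (--full for dense axes)
spherelimits alpha-surface --out out/alpha          # α surface + radius bounds
spherelimits reproduce --seed 1 --out out/suite     # the four headline experiments
```

Each run writes its resolved YAML config and a hash next to the outputs;
reruns with the same seed are byte-identical.

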