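# Methods

## Scope and model

`spherelimits` studies when the radius and signal fraction of a spherical
(soma-like) compartment can be recovered from powder-averaged diffusion MRI
acquired with linear (LTE), planar (PTE) and spherical (STE) b-tensor
encoding. The tissue signal is a non-exchanging compartment sum

S/S0 = f_neurite·A_neurite + f_sphere·A_sphere + f_ball·A_ball,  Σf = 1,

with three nested variants: stick+ball (no sphere, no time dependence),
stick+ball+sphere, and cylinder+ball+sphere (a finite neurite radius adds a
second time-dependent term).

**Powder averaging.** For an axisymmetric compartment tensor (isotropic
diffusivity `DI`, anisotropy `DΔ`) under an axisymmetric b-tensor (`b`,
`bΔ`), the direction-averaged attenuation is
`A = exp(−b·DI·(1−bΔ·DΔ)) · g(3b·DI·bΔ·DΔ)` with
`g(α) = ∫₀¹exp(−αx²)dx = √(π/4α)·erf(√α)`. For `α < 0` (planar encoding on
anisotropic compartments) we evaluate the continuation
`g(−β) = e^β·dawsn(√β)/√β`, and a Taylor branch below |α| = 1e−6. The
implementation is validated against direct numerical orientation averaging
to 1e−8.

**Restricted diffusion in the frequency domain.** Spheres and cylinders
carry a diffusion spectrum `λ(ω) = Σᵢ Bᵢaᵢ D0 ω²/(aᵢ²D0² + ω²)` with
`aᵢ = (μᵢ/R)²` and weights from the roots of `J₁′` (cylinder) or `j₁′`
(sphere). The attenuation exponent of an arbitrary waveform is
`ρ = (1/2π)∫ fᵀ(ω)D(ω)f(−ω)dω` with `f(ω)` the Fourier transform of the
dephasing `q(t)`; the compartment signal is `exp(−ρ)`. For cylinders only
the transverse eigen-spectra contribute (`λ₃ ≡ 0`); axial Gaussian
diffusion is composed in the signal models. A cylinder enters the powder
average through a per-shell scalar radial diffusivity `D⊥ = ρ⊥/b` (an
approximation recorded here: the orientation integral uses one effective
`D⊥` per waveform shape rather than the full spectral tensor; it reduces
exactly to the stick model as R→0).

Cross-validation: for rectangular pulsed gradients the spectral route
agrees with an independent van Gelderen time-domain series to better than
0.02% over b ∈ [1, 10.5] ms/μm², R ∈ [1, 10] μm (the test suite asserts
1%).

## Waveforms and units

Internal units are ms, μm, mT/m with γ = 2.6751525×10⁻⁴ rad·ms⁻¹·μm⁻¹
per mT/m, so b-values emerge in ms/μm². Waveforms are zero-order-hold
effective gradients; `q(t)` is then piecewise linear and `B = ∫qqᵀdt` is
integrated exactly per interval.

The in vivo study this emulates used numerically optimized,
Maxwell-compensated waveforms that are not published. We ship analytic
surrogates: a rectangular pulsed pair for LTE (δ = 29.65 ms, Δ = 37.05 ms)
and orthogonal bipolar blocks for PTE (two) and STE (three) with total
duration 71.6 ms and a 7.4 ms pause, the encoding time split equally
between blocks. Traces, shapes (bΔ = 1, −1/2, 0) and total durations match
the study protocol; the exact spectral content does not, so all
spectral-content-dependent quantities (e.g. the `D_app(R)` curves) are
surrogate-specific. Slew limits are not enforced. The spectral ordering
STE > PTE > LTE in sphere attenuation at matched b holds for the
surrogates as it does for the optimized waveforms.

Numerical settings: dt = 0.05 ms; FFT zero-padding ×4 for exported spectra
and ×8 for ρ quadrature (resolves the Lorentzian width of a 10 μm sphere);
30 Lorentzian roots (changing 20→50 moves ρ by <0.1%). Shell-wise sphere
`D_app(R)` and cylinder `D⊥(R)` are tabulated once per waveform shape on
121/81-point radius grids and interpolated with cubic splines; protocol
radii coincide with table nodes, so fitted quantities use exact quadrature
values at those radii.

## Synthetic data

The default protocol has 10 b = 0 images plus 18 shells: LTE
b = 1, 2, 3, 4.5, 6, 7.5, 9, 10.5 ms/μm² with (31, 31, 31, 31, 61, 61, 61,
61) directions, PTE b = 1–6 with (31, 31, 31, 31, 61), STE b = 0.2–4.5 with
(6, 9, 9, 12, 15) — 604 DWIs. Direction sets are generated by antipodal
electrostatic repulsion from a fixed seed (the study's optimized schemes
are unavailable; isotropy, which drives powder-average quality, is matched:
mean outer product within 0.02 of I/3 at n = 61, minimum pairwise angle
> 15°).

Default tissue parameters are the study conditions: Din∥ = 2 μm²/ms,
Dball = 0.6 μm²/ms (1.0 in the power-law experiments), sphere D0 = 3 μm²/ms,
f_ball = f_stick = (1 − f_sphere)/2, SNR = 1/σ = 50 with Rician noise
`Sn = √((S+N_r)² + N_i²)` applied per measurement before averaging.
Powder signals are normalized by the mean of the noisy b = 0 images, as a
per-voxel pipeline would. What the generator does **not** emulate:
scanner artifacts (motion, eddy currents, Gibbs ringing, gradient
nonlinearity), spatially varying noise (parallel imaging gives noncentral-χ
rather than Rician statistics), relaxation weighting, exchange, and
orientation dispersion beyond the powder assumption. Passing tests
therefore demonstrate properties of the estimation problem under ideal
acquisition, not performance on real data.

## Fitting

Bounded multi-start nonlinear least squares (`scipy.optimize.least_squares`,
trf; ftol 1e−10, xtol 1e−8, ≤2000 evaluations/start). Residuals are formed
on the powder table (b0 row plus 18 shells) and weighted by √nᵢ, making
them homoscedastic under independent per-direction noise and consistent
with the nᵢ-weighted reduced chi-square

χ²_red = [Σ nᵢ(Sᵢ−Sᵢ′)²/(n−k)] / (σ²_noise/n_voxel),  n_voxel = 1 here.

The fraction simplex is parameterized as f_sphere ∈ [0,1] plus a stick
share w ∈ [0,1] of the remainder. Bounds: d_par ∈ [0.1, 4],
d_ball ∈ [0.05, 4] μm²/ms, R_sphere ∈ [0.1, 15] μm, R_cyl ∈ [0.1, 10] μm,
σ ∈ [0, 0.2]; these contain every ground truth simulated here. Default 20
Latin-hypercube starts (seeded); SSR ties within 1e−10 relative break
toward the smaller sphere radius. Noise-floor-aware fits predict
√(S²+σ²) with σ pinned or free. When a fraction estimate reaches zero the
associated radius/diffusivity is unidentified; confidence intervals are
linearized (Jacobian-based) and report infinite half-widths along
rank-deficient directions rather than failing. Pinned parameters get
zero-width intervals.

## Model selection and detection grids

Nested models are compared with
`F = (SSR₁−SSR₂)(N−M₂)/(SSR₂(M₂−M₁))`, `p` from the upper F tail, with
N = 19 fitted powder points and M = 3/5/6 free parameters. The larger
model is always warm-started at the smaller model's solution, so
SSR₂ ≤ SSR₁ by construction; residual violations clamp F to 0.

Two nestings answer two questions (they differ sharply at large sphere
fractions):

* **presence** (stick+ball vs stick+ball+sphere): is any isotropic
  restricted compartment present? At f_sphere = 0.4 this succeeds at every
  radius — even a non-attenuating sphere is a constant offset the
  two-compartment model cannot absorb — so presence governs the *fraction*
  limit (smallest f_sphere with majority p < 0.05 at a well-detectable
  radius).
* **size** (radius pinned at the zero-size dot limit vs free): does the
  signal distinguish a sphere of radius R from an unattenuated point?
  This governs the *radius* sensitivity floor; below it sphere attenuation
  is lost in the noise.

Detection cells use 10 noise replicates with majority rule (p < 0.05),
scaled down from study-size grids to desk runtimes; grid axes and
replicate counts are configurable, and `spherelimits ftest-grid --full`
runs the dense axes. Default fits inside detection cells use 8 starts plus
the warm start — the nesting guarantee, not start count, controls the
F-statistic's validity, and the simple models involved converge reliably.

Calibration: under the sphere-free null with independent Gaussian powder
noise the presence test's type-I error is 0.05 (500 replicates). Run end
to end — noise applied per direction and shells divided by the noisy mean
b0 — the rate inflates to ≈0.085, because the shared S0 error correlates
all points and the sphere parameters can partially absorb it. This is a
property of b0-normalized pipelines generally, not of the statistic; the
test suite asserts calibration in the independent-noise regime and this
note records the end-to-end behavior.

## Power-law analysis

`S/S0 = β·b^(−α)` is fitted to the direction-averaged LTE signal over
b = 6–10.5 ms/μm² by ordinary least squares in log–log space (a
nonlinear-domain option differs by <0.02 in α on noise-free input). A pure
stick gives α = 1/2; an attenuating sphere pulls α upward, and the radius
bound is the smallest grid radius whose α column exceeds 1/2 at any sphere
fraction.

The α surface is simulated noise-free over f_sphere ∈ {0.01…0.1, 0.15,
0.2…1} and R ∈ {1, 1.5, …, 10} μm with Din∥ = 2, Dball = 1 μm²/ms and a
pulsed LTE waveform (δ = 29.65, Δ = 37.05 ms). The experiment's premise is
that the extracellular signal has fully decayed in this window
(f_ball·e^(−b·1) ≤ 0.12% of S0); the default therefore omits that residual
from the fitted window, because leaving it in raises even the sphere-free
baseline to α ≈ 0.517 — the same order as the sphere effect at the
detection boundary — so a 0.5 threshold would flag the ball rather than
the sphere (`include_ball_residual=True` restores it). With the default,
the bound is 7.0 μm for D0 = 3 μm²/ms and 6.5 μm for D0 = 2 μm²/ms on the
0.5 μm grid; the D0 = 2 case is a knife edge — the R = 6 column peaks at
α = 0.49995 — so its bound is only determined to one grid step. Fixing
f_stick = 0.7 instead of the equal split moves the bound by at most one
grid step.

## Degenerate and edge inputs

Zero-amplitude waveforms give b = 0 and unit attenuation; radius 0 is the
stick/point limit (ρ = 0) rather than an error; non-refocused waveforms
raise with the residual |q(T)|; fraction vectors must sum to 1 within
1e−6; detection cells with failed fits exclude and count the replicates.

## Known limitations

Surrogate waveform spectra (above); scalar-D⊥ cylinder powder averaging;
no Rician likelihood (the floor is handled by prediction, not by a proper
noncentral-χ likelihood); F-tests assume Gaussian residuals and are used
outside that regime exactly as the emulated analysis does; no exchange,
relaxation or dispersion modeling; voxelwise NIfTI fitting performs no
preprocessing.
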