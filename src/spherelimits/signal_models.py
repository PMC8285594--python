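"""Powder-averaged compartment signals and the composite tissue models.

For an axisymmetric compartment tensor (isotropic diffusivity DI, anisotropy
DΔ) under axisymmetric encoding (b, bΔ), the direction-averaged attenuation
is

    A(b, bΔ, DI, DΔ) = exp(−b DI [1 − bΔ DΔ]) · g(3 b DI bΔ DΔ),
    g(α) = ∫₀¹ exp(−α x²) dx = √(π/4α) erf(√α),

where negative arguments (planar encoding on anisotropic compartments) use
the analytic continuation of g through the Dawson integral.

Three composite models are provided: stick+ball, stick+ball+sphere and
cylinder+ball+sphere.  Sphere attenuation enters as exp(−ρ) with ρ from the
frequency-domain restricted model evaluated for each shell's waveform;
a cylinder contributes through Eq-3-style powder averaging with its radial
diffusivity replaced by the shell-wise restricted apparent diffusivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import special

from .restricted import (
    DEFAULT_N_ROOTS,
    RestrictionGeometry,
    SPHERE_D0_DEFAULT,
    attenuation_exponent,
)
from .waveforms import GradientWaveform, compute_btensor

__all__ = [
    "TissueParams",
    "CompartmentTensorSummary",
    "g_function",
    "powder_attenuation",
    "model_signal",
    "rician_floor_prediction",
    "MODELS",
]

MODELS = ("stick_ball", "stick_ball_sphere", "cylinder_ball_sphere")

_FRACTION_TOL = 1e-8


@dataclass(frozen=True)
class TissueParams:
    """Compartment fractions, diffusivities and radii of the tissue model.

    Fractions refer to signal (not volume) fractions and must sum to one.
    ``r_cylinder = 0`` degenerates the cylinder to a stick; ``f_sphere = 0``
    removes the sphere compartment.  ``sigma_floor`` is an optional Rician
    noise standard deviation in S0 units used by floor-aware prediction.
    """

    f_stick: float
    f_ball: float
    f_sphere: float
    d_par: float  # intra-neurite parallel diffusivity, μm²/ms
    d_ball: float  # extra-cellular diffusivity, μm²/ms
    r_sphere: float = 0.0  # μm
    r_cylinder: float = 0.0  # μm (0 = stick)
    d0_sphere: float = SPHERE_D0_DEFAULT  # μm²/ms
    sigma_floor: float | None = None

    def __post_init__(self):
        fracs = (self.f_stick, self.f_ball, self.f_sphere)
        if min(fracs) < -_FRACTION_TOL:
            raise ValueError(f"signal fractions must be nonnegative: {fracs}")
        if abs(sum(fracs) - 1.0) > 1e-6:
            raise ValueError(f"signal fractions must sum to 1, got {sum(fracs)}")
        if not (0 < self.d_par <= 4.0):
            raise ValueError("d_par must lie in (0, 4] μm²/ms")
        if not (0 <= self.d_ball <= 4.0):
            raise ValueError("d_ball must lie in [0, 4] μm²/ms")
        if self.r_sphere < 0 or self.r_cylinder < 0:
            raise ValueError("radii must be nonnegative")
        if self.sigma_floor is not None and self.sigma_floor < 0:
            raise ValueError("sigma_floor must be nonnegative")


@dataclass(frozen=True)
class CompartmentTensorSummary:
    """Axisymmetric tensor summary: DI = (D∥+2D⊥)/3, DΔ = (D∥−D⊥)/(D∥+2D⊥)."""

    d_iso: float
    d_delta: float

    def __post_init__(self):
        if self.d_iso < 0:
            raise ValueError("d_iso must be nonnegative")
        if not (-0.5 - 1e-12 <= self.d_delta <= 1.0 + 1e-12):
            raise ValueError("d_delta must lie in [-0.5, 1]")

    @classmethod
    def from_axial_radial(cls, d_par: float, d_perp: float):
        d_iso = (d_par + 2.0 * d_perp) / 3.0
        d_delta = 0.0 if d_iso == 0 else (d_par - d_perp) / (3.0 * d_iso)
        return cls(d_iso=d_iso, d_delta=d_delta)


def _g_extended(alpha):
    """g(α) = ∫₀¹ exp(−αx²) dx for real α of either sign (vectorized)."""
    alpha = np.asarray(alpha, dtype=float)
    out = np.empty_like(alpha)
    small = np.abs(alpha) < 1e-6
    pos = (alpha >= 1e-6)
    neg = (alpha <= -1e-6)
    a_s = alpha[small]
    out[small] = 1.0 - a_s / 3.0 + a_s**2 / 10.0 - a_s**3 / 42.0
    a_p = alpha[pos]
    out[pos] = np.sqrt(np.pi / (4.0 * a_p)) * special.erf(np.sqrt(a_p))
    beta = -alpha[neg]
    rb = np.sqrt(beta)
    # ∫₀¹ exp(βx²) dx = e^β · dawsn(√β) / √β
    out[neg] = np.exp(beta) * special.dawsn(rb) / rb
    return out


def g_function(alpha):
    """Orientation-average kernel g(α) of the powder-averaged attenuation.

    Defined for α ≥ 0; continuous at 0 with g(0) = 1 and monotonically
    decreasing.  (Negative arguments arise only internally, via the analytic
    continuation used by :func:`powder_attenuation`.)
    """
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha < 0):
        raise ValueError("g_function requires alpha >= 0")
    res = _g_extended(alpha)
    return float(res) if res.ndim == 0 else res


def powder_attenuation(b, b_delta, summary: CompartmentTensorSummary):
    """Direction-averaged attenuation of one axisymmetric compartment."""
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("b must be nonnegative")
    b_delta = np.asarray(b_delta, dtype=float)
    if np.any(np.abs(b_delta) > 1.0 + 1e-9) or np.any(b_delta < -0.5 - 1e-9):
        raise ValueError("b_delta must lie in [-0.5, 1]")
    di, dd = summary.d_iso, summary.d_delta
    arg = 3.0 * b * di * b_delta * dd
    res = np.exp(-b * di * (1.0 - b_delta * dd)) * _g_extended(arg)
    return float(res) if res.ndim == 0 else res


def rician_floor_prediction(signal, sigma: float):
    """Noise-floor-aware prediction Sₙ = √(S² + σ²) of a magnitude signal."""
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    signal = np.asarray(signal, dtype=float)
    res = np.sqrt(signal**2 + sigma**2)
    return float(res) if res.ndim == 0 else res


# --------------------------------------------------------------------------
# Shell-wise restricted apparent diffusivities, cached per waveform shape.
#
# ρ scales linearly with b at fixed waveform shape, so one apparent
# diffusivity per (shape, geometry) suffices: ρ(b, R) = b · D_app(shape, R).
# For continuous-radius fitting the R-dependence is tabulated once per shape
# on a fine grid and interpolated with a cubic spline (node values are exact
# quadrature results; protocol radii of interest coincide with nodes).
# --------------------------------------------------------------------------

_SPHERE_R_GRID = np.linspace(0.0, 15.0, 121)
_CYL_R_GRID = np.linspace(0.0, 10.0, 81)
_dapp_cache: dict = {}


def _unit_b_waveform(wf: GradientWaveform) -> GradientWaveform:
    from .waveforms import scale_to_b

    return scale_to_b(wf, 1.0)


def sphere_dapp_interpolator(wf: GradientWaveform, d0: float,
                             n_roots: int = DEFAULT_N_ROOTS):
    """Cubic-spline D_app(R) of a sphere for this waveform shape at b = 1."""
    key = ("sphere", wf.shape_key(), round(d0, 12), n_roots)
    if key not in _dapp_cache:
        from scipy.interpolate import CubicSpline

        wf1 = _unit_b_waveform(wf)
        vals = np.array(
            [
                attenuation_exponent(
                    wf1, RestrictionGeometry("sphere", r, d0, n_roots)
                )
                for r in _SPHERE_R_GRID
            ]
        )
        _dapp_cache[key] = CubicSpline(_SPHERE_R_GRID, vals)
    return _dapp_cache[key]


def cylinder_dperp_interpolator(wf: GradientWaveform, d0: float,
                                n_roots: int = DEFAULT_N_ROOTS):
    """Cubic-spline transverse D⊥,app(R_c) of a cylinder for this shape.

    The full dephasing power of the shell waveform is projected onto the
    transverse restriction spectrum, yielding a scalar radial diffusivity
    D⊥ = ρ⊥/b that feeds the axisymmetric powder average.  This reduces to
    the stick model as R_c → 0.
    """
    key = ("cylinder", wf.shape_key(), round(d0, 12), n_roots)
    if key not in _dapp_cache:
        from scipy.interpolate import CubicSpline
        from .restricted import lorentzian_lambda
        from .waveforms import spectrum

        wf1 = _unit_b_waveform(wf)
        spec = spectrum(wf1, zero_pad_factor=8)
        power = spec.power()
        vals = []
        for r in _CYL_R_GRID:
            if r == 0.0:
                vals.append(0.0)
                continue
            lam = lorentzian_lambda(
                RestrictionGeometry("cylinder", r, d0, n_roots), spec.frequencies
            )
            vals.append(float(np.sum(lam * power) * spec.domega / (2 * np.pi)))
        _dapp_cache[key] = CubicSpline(_CYL_R_GRID, np.asarray(vals))
    return _dapp_cache[key]


# d0 axis of the 2D cylinder table: log-spaced over the fitting bounds of
# the intra-neurite parallel diffusivity.
_CYL_D0_GRID = np.geomspace(0.1, 4.0, 25)


def cylinder_dperp_surface(wf: GradientWaveform,
                           n_roots: int = DEFAULT_N_ROOTS):
    """Bivariate spline D⊥,app(d0, R_c) for continuous-parameter fitting.

    The cylinder's intrinsic diffusivity equals the (free) parallel
    diffusivity parameter, so fitting needs D⊥ as a smooth function of both
    d0 and radius; tabulating per-d0 splines would rebuild quadratures at
    every optimizer step.
    """
    key = ("cylinder2d", wf.shape_key(), n_roots)
    if key not in _dapp_cache:
        from scipy.interpolate import RectBivariateSpline
        from .restricted import lorentzian_lambda
        from .waveforms import spectrum

        wf1 = _unit_b_waveform(wf)
        spec = spectrum(wf1, zero_pad_factor=8)
        power = spec.power()
        table = np.zeros((len(_CYL_D0_GRID), len(_CYL_R_GRID)))
        for i, d0 in enumerate(_CYL_D0_GRID):
            for j, r in enumerate(_CYL_R_GRID):
                if r == 0.0:
                    continue
                lam = lorentzian_lambda(
                    RestrictionGeometry("cylinder", float(r), float(d0),
                                        n_roots),
                    spec.frequencies,
                )
                table[i, j] = np.sum(lam * power) * spec.domega / (2 * np.pi)
        _dapp_cache[key] = RectBivariateSpline(
            _CYL_D0_GRID, _CYL_R_GRID, table, kx=3, ky=3
        )
    return _dapp_cache[key]


def _shell_arrays(protocol):
    b = np.array([s.b for s in protocol.shells])
    bdelta = np.array([s.b_delta for s in protocol.shells])
    return b, bdelta


def shell_attenuations(params: TissueParams, protocol, model: str):
    """Per-shell attenuation of each compartment (dict of arrays)."""
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    b, bdelta = _shell_arrays(protocol)
    n = len(protocol.shells)

    if model == "cylinder_ball_sphere" and params.r_cylinder > 0:
        d_perp = np.array(
            [
                cylinder_dperp_interpolator(s.waveform, params.d_par)(
                    params.r_cylinder
                )
                for s in protocol.shells
            ]
        )
    else:
        d_perp = np.zeros(n)
    a_stick = np.array(
        [
            powder_attenuation(
                b[i],
                bdelta[i],
                CompartmentTensorSummary.from_axial_radial(params.d_par, d_perp[i]),
            )
            for i in range(n)
        ]
    )

    if model == "stick_ball" or params.f_sphere == 0 or params.r_sphere == 0:
        a_sphere = np.ones(n)
    else:
        a_sphere = np.exp(
            -b
            * np.array(
                [
                    sphere_dapp_interpolator(s.waveform, params.d0_sphere)(
                        params.r_sphere
                    )
                    for s in protocol.shells
                ]
            )
        )
    a_ball = np.exp(-b * params.d_ball)
    return {"stick": a_stick, "sphere": a_sphere, "ball": a_ball}


def model_signal(params: TissueParams, protocol, model: str):
    """Noise-free powder-averaged S/S0 for every shell of the protocol.

    Returns a :class:`~spherelimits.synthetic_data.PowderSignal`; the b = 0
    entry (value 1 by normalization) is included with the protocol's b0
    count so downstream fits see the same measurement table as synthetic
    noisy data.
    """
    from .synthetic_data import PowderSignal  # deferred: avoids import cycle

    if model == "stick_ball" and params.f_sphere > _FRACTION_TOL:
        raise ValueError("stick_ball requires f_sphere = 0")
    if model != "cylinder_ball_sphere" and params.r_cylinder > 0:
        raise ValueError(f"{model} requires r_cylinder = 0")
    att = shell_attenuations(params, protocol, model)
    shell_signal = (
        params.f_stick * att["stick"]
        + params.f_sphere * att["sphere"]
        + params.f_ball * att["ball"]
    )
    signal = np.concatenate([[1.0], shell_signal])
    if params.sigma_floor:
        signal = rician_floor_prediction(signal, params.sigma_floor)
    b, bdelta = _shell_arrays(protocol)
    return PowderSignal(
        family=np.array(["b0"] + [s.family for s in protocol.shells]),
        b=np.concatenate([[0.0], b]),
        b_delta=np.concatenate([[0.0], bdelta]),
        n_dirs=np.concatenate(
            [[protocol.n_b0], [s.n_dirs for s in protocol.shells]]
        ),
        signal=signal,
        s0=1.0,
    )
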