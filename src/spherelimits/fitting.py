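"""Bounded nonlinear least-squares estimation from powder-averaged signals.

Residuals are formed on the direction-averaged signal and weighted by √nᵢ
(the per-shell direction count), matching the nᵢ-weighted residual sum of
the reduced-chi-square statistic.  The fraction simplex is parameterized
without constraints as f_sphere ∈ [0,1] and a stick share w ∈ [0,1] of the
remainder, so every point inside the box bounds is a valid tissue state.
Flat fitting landscapes are handled with multi-start local optimization
(Latin-hypercube starts within the bounds, best SSR wins).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc

from .signal_models import TissueParams, _g_extended
from .synthetic_data import PowderSignal

__all__ = [
    "FitOptions",
    "FitResult",
    "fit_model",
    "confidence_intervals",
    "reduced_chi_square",
    "fixed_fraction_scan",
]

# Fitting bounds; chosen to contain all tissue states simulated in this
# study with room to spare.
DEFAULT_BOUNDS = {
    "f_sphere": (0.0, 1.0),
    "w_stick": (0.0, 1.0),
    "d_par": (0.1, 4.0),
    "d_ball": (0.05, 4.0),
    "r_sphere": (0.1, 15.0),
    "r_cylinder": (0.1, 10.0),
    "sigma": (0.0, 0.2),
}

_PARAM_NAMES = {
    "stick_ball": ["w_stick", "d_par", "d_ball"],
    "stick_ball_sphere": ["f_sphere", "w_stick", "d_par", "d_ball", "r_sphere"],
    "cylinder_ball_sphere": [
        "f_sphere", "w_stick", "d_par", "d_ball", "r_sphere", "r_cylinder",
    ],
}

FTOL = 1e-10
XTOL = 1e-8
MAX_NFEV = 2000


class _Predictor:
    """Fast powder-signal forward model bound to one protocol."""

    def __init__(self, protocol, model: str, d0_sphere: float):
        from .signal_models import (
            cylinder_dperp_interpolator,
            sphere_dapp_interpolator,
        )

        self.model = model
        self.d0_sphere = d0_sphere
        self.b = np.array([0.0] + [s.b for s in protocol.shells])
        self.bdelta = np.array([0.0] + [s.b_delta for s in protocol.shells])
        self.n_dirs = np.array(
            [protocol.n_b0] + [s.n_dirs for s in protocol.shells]
        )
        fams = [s.family for s in protocol.shells]
        self.families = list(dict.fromkeys(fams))
        # boolean mask per family over the full table (b0 row excluded)
        self.fam_masks = {
            f: np.array([False] + [x == f for x in fams]) for f in self.families
        }
        first = {f: next(s for s in protocol.shells if s.family == f)
                 for f in self.families}
        self.sphere_spline = {
            f: sphere_dapp_interpolator(first[f].waveform, d0_sphere)
            for f in self.families
        }
        self._cyl_surface = None
        if model == "cylinder_ball_sphere":
            from .signal_models import cylinder_dperp_surface

            self._cyl_surface = {
                f: cylinder_dperp_surface(first[f].waveform)
                for f in self.families
            }

    def _cylinder_dperp(self, d_par, r_cylinder):
        return {
            f: float(surf(d_par, r_cylinder, grid=False))
            for f, surf in self._cyl_surface.items()
        }

    def predict(self, p: dict) -> np.ndarray:
        b, bdelta = self.b, self.bdelta
        n = b.shape[0]
        # anisotropic compartment (stick or cylinder)
        d_perp = np.zeros(n)
        if self.model == "cylinder_ball_sphere" and p.get("r_cylinder", 0) > 0:
            per_fam = self._cylinder_dperp(p["d_par"], p["r_cylinder"])
            for f, dp in per_fam.items():
                d_perp[self.fam_masks[f]] = dp
        di = (p["d_par"] + 2.0 * d_perp) / 3.0
        dd = np.where(di > 0, (p["d_par"] - d_perp) / (3.0 * di), 0.0)
        a_aniso = np.exp(-b * di * (1.0 - bdelta * dd)) * _g_extended(
            3.0 * b * di * bdelta * dd
        )
        # sphere
        a_sphere = np.ones(n)
        if self.model != "stick_ball" and p["f_sphere"] > 0:
            for f in self.families:
                m = self.fam_masks[f]
                a_sphere[m] = np.exp(
                    -b[m] * float(self.sphere_spline[f](p["r_sphere"]))
                )
        a_ball = np.exp(-b * p["d_ball"])
        f_sphere = p.get("f_sphere", 0.0)
        f_stick = (1.0 - f_sphere) * p["w_stick"]
        f_ball = (1.0 - f_sphere) * (1.0 - p["w_stick"])
        signal = f_stick * a_aniso + f_sphere * a_sphere + f_ball * a_ball
        sigma = p.get("sigma", 0.0)
        if sigma > 0:
            signal = np.sqrt(signal**2 + sigma**2)
        return signal


@dataclass
class FitResult:
    """Outcome of one multi-start model fit."""

    model: str
    estimates: TissueParams
    ssr: float
    n_points: int
    n_params: int
    free_names: list
    x: np.ndarray
    jacobian: np.ndarray
    ci95: dict
    chi2_red: float | None
    converged: bool
    n_starts_used: int
    sigma_floor_estimate: float | None = None
    pinned: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        est = self.estimates
        # size/diffusivity of a vanished compartment is undefined, not zero
        has_sphere = self.model != "stick_ball" and est.f_sphere > 0
        return {
            "model": self.model,
            "ssr": self.ssr,
            "n_points": self.n_points,
            "n_params": self.n_params,
            "chi2_red": self.chi2_red,
            "converged": self.converged,
            "estimates": {
                "f_stick": est.f_stick,
                "f_ball": est.f_ball,
                "f_sphere": est.f_sphere,
                "d_par": est.d_par if est.f_stick > 0 else None,
                "d_ball": est.d_ball if est.f_ball > 0 else None,
                "r_sphere": est.r_sphere if has_sphere else None,
                "r_cylinder": est.r_cylinder
                if est.r_cylinder > 0 and est.f_stick > 0 else None,
                "sigma_floor": self.sigma_floor_estimate,
            },
            "ci95": {k: list(v) for k, v in self.ci95.items()},
        }


def reduced_chi_square(residuals, n_points: int, n_params: int,
                       sigma_noise: float, n_voxel: int = 1) -> float:
    """Reduced chi-square (normalized residual variance).

    ``residuals`` are the √nᵢ-weighted powder residuals, so their squared
    sum is Σ nᵢ(Sᵢ−Sᵢ′)²; the statistic divides the residual variance by
    the noise variance of an nᵥ-voxel average, σ²/nᵥ.
    """
    if sigma_noise <= 0:
        raise ValueError("sigma_noise must be positive")
    if n_points <= n_params:
        raise ValueError("need more data points than parameters")
    residuals = np.asarray(residuals, dtype=float)
    resid_var = np.sum(residuals**2) / (n_points - n_params)
    return float(resid_var / (sigma_noise**2 / n_voxel))


def _params_from_vector(model, names, x, fixed, d0_sphere):
    p = dict(fixed)
    p.update(zip(names, x))
    p.setdefault("f_sphere", 0.0)
    p.setdefault("r_sphere", 0.0)
    p.setdefault("r_cylinder", 0.0)
    p.setdefault("sigma", 0.0)
    return p


def _tissue_params(p, model, d0_sphere):
    f_sphere = p.get("f_sphere", 0.0)
    return TissueParams(
        f_stick=(1.0 - f_sphere) * p["w_stick"],
        f_ball=(1.0 - f_sphere) * (1.0 - p["w_stick"]),
        f_sphere=f_sphere,
        d_par=p["d_par"],
        d_ball=p["d_ball"],
        r_sphere=p.get("r_sphere", 0.0) if model != "stick_ball" else 0.0,
        r_cylinder=p.get("r_cylinder", 0.0),
        d0_sphere=d0_sphere,
        sigma_floor=p.get("sigma", 0.0) or None,
    )


def fit_model(
    data: PowderSignal,
    protocol,
    model: str,
    rician_floor: bool = False,
    fixed: dict | None = None,
    n_starts: int = 20,
    seed: int = 0,
    bounds: dict | None = None,
    sigma_noise: float | None = None,
    d0_sphere: float = 3.0,
    x0_extra=None,
) -> FitResult:
    """Multi-start bounded least-squares fit of one compartment model.

    ``fixed`` pins parameters by name (e.g. ``{"f_sphere": 0.3}``); when
    ``rician_floor`` is set the prediction passes through √(S²+σ²), with σ
    either pinned via ``fixed["sigma"]`` or estimated as a free parameter.
    ``x0_extra`` supplies additional (full-length) start vectors, e.g. warm
    starts from a nested model.  Raises if the data have fewer points than
    free parameters; if no start converges the best attempt is returned
    with ``converged=False``.
    """
    if model not in _PARAM_NAMES:
        raise ValueError(f"unknown model {model!r}")
    fixed = dict(fixed or {})
    user_pinned = set(fixed)
    names = [n for n in _PARAM_NAMES[model] if n not in fixed]
    if rician_floor and "sigma" not in fixed:
        names = names + ["sigma"]
    if not rician_floor:
        fixed.setdefault("sigma", 0.0)
    bound_map = dict(DEFAULT_BOUNDS)
    bound_map.update(bounds or {})
    lb = np.array([bound_map[n][0] for n in names])
    ub = np.array([bound_map[n][1] for n in names])

    pred = _Predictor(protocol, model, d0_sphere)
    y = np.asarray(data.signal, dtype=float)
    if y.shape[0] != pred.b.shape[0]:
        raise ValueError(
            f"data has {y.shape[0]} points but protocol defines "
            f"{pred.b.shape[0]} (shells + b0)"
        )
    if not np.allclose(np.asarray(data.b), pred.b, atol=1e-9):
        raise ValueError("data and protocol b-values are not aligned")
    w = np.sqrt(pred.n_dirs.astype(float))
    n_free = len(names)
    if y.shape[0] <= n_free:
        raise ValueError("fewer data points than free parameters")

    def residual(x):
        p = _params_from_vector(model, names, x, fixed, d0_sphere)
        return w * (y - pred.predict(p))

    sampler = qmc.LatinHypercube(d=n_free, seed=seed)
    starts = qmc.scale(sampler.random(n_starts), lb, ub)
    extra = []
    for x0 in x0_extra or []:
        extra.append(np.clip(np.asarray(x0, dtype=float), lb, ub))
    all_starts = extra + list(starts)

    best = None
    best_key = None
    any_converged = False
    r_idx = names.index("r_sphere") if "r_sphere" in names else None
    for x0 in all_starts:
        try:
            res = least_squares(
                residual, x0, bounds=(lb, ub), method="trf",
                ftol=FTOL, xtol=XTOL, max_nfev=MAX_NFEV,
            )
        except Exception:
            continue
        any_converged = any_converged or res.success
        ssr = float(2.0 * res.cost)
        # ties (1e-10 relative) break toward the smaller sphere radius
        key = (ssr, res.x[r_idx] if r_idx is not None else 0.0)
        if best is None or key[0] < best_key[0] * (1.0 - 1e-10) or (
            abs(key[0] - best_key[0]) <= 1e-10 * max(best_key[0], 1e-30)
            and key[1] < best_key[1]
        ):
            best, best_key = res, key
    if best is None:
        raise RuntimeError("all optimizer starts failed")

    ssr = float(2.0 * best.cost)
    p_best = _params_from_vector(model, names, best.x, fixed, d0_sphere)
    estimates = _tissue_params(p_best, model, d0_sphere)
    chi2 = None
    if sigma_noise is not None:
        chi2 = reduced_chi_square(
            residual(best.x), y.shape[0], n_free, sigma_noise
        )
    fit = FitResult(
        model=model,
        estimates=estimates,
        ssr=ssr,
        n_points=y.shape[0],
        n_params=n_free,
        free_names=names,
        x=best.x.copy(),
        jacobian=best.jac.copy(),
        ci95={},
        chi2_red=chi2,
        converged=bool(any_converged),
        n_starts_used=len(all_starts),
        sigma_floor_estimate=p_best.get("sigma") if rician_floor else None,
        pinned={
            k: float(v) for k, v in fixed.items()
            if k in user_pinned and (k in _PARAM_NAMES[model] or k == "sigma")
        },
    )
    if fit.converged:
        fit.ci95 = confidence_intervals(fit)
        for name, value in fit.pinned.items():
            fit.ci95[name] = (value, value)  # pinned: zero-width interval
    return fit


def confidence_intervals(fit: FitResult, z: float = 1.959964) -> dict:
    """Linearized (Jacobian-based) symmetric 95% confidence intervals.

    The covariance is s²(JᵀJ)⁻¹ with s² = SSR/(N−M), evaluated by SVD; a
    rank-deficient Jacobian yields infinite half-widths along the
    unidentified directions rather than an error.
    """
    if not fit.converged:
        raise ValueError("confidence intervals require a converged fit")
    dof = fit.n_points - fit.n_params
    s2 = fit.ssr / max(dof, 1)
    u, s, vt = np.linalg.svd(fit.jacobian, full_matrices=False)
    tol = max(fit.jacobian.shape) * np.finfo(float).eps * (s[0] if s.size else 0)
    var = np.zeros(len(fit.free_names))
    for j, sv in enumerate(s):
        direction = vt[j] ** 2
        if sv > tol:
            var += direction * (s2 / sv**2)
        else:
            var[direction > 0] = np.inf
    half = z * np.sqrt(var)
    return {
        name: (float(fit.x[i] - half[i]), float(fit.x[i] + half[i]))
        for i, name in enumerate(fit.free_names)
    }


def fixed_fraction_scan(
    data: PowderSignal,
    protocol,
    model: str = "stick_ball_sphere",
    fraction_grid=None,
    sigma_noise: float = 0.02,
    n_starts: int = 8,
    seed: int = 0,
    rician_floor: bool = False,
    d0_sphere: float = 3.0,
):
    """Goodness-of-fit scan with the sphere signal fraction pinned.

    For each grid value the remaining parameters are re-estimated (warm
    started at the previous grid point's solution) and the reduced
    chi-square recorded.  A sharp valley indicates an identifiable sphere
    fraction; a flat one, degeneracy.  Returns (DataFrame, diagnostics)
    where the diagnostics report the minimum and the width of the valley at
    1.05× the minimum.
    """
    if fraction_grid is None:
        fraction_grid = np.linspace(0.0, 1.0, 41)
    fraction_grid = np.asarray(fraction_grid, dtype=float)
    if np.any((fraction_grid < 0) | (fraction_grid > 1)):
        raise ValueError("fraction grid must lie within [0, 1]")
    rows = []
    warm = None
    for fs in fraction_grid:
        try:
            fit = fit_model(
                data, protocol, model,
                fixed={"f_sphere": float(fs)},
                n_starts=n_starts, seed=seed, sigma_noise=sigma_noise,
                rician_floor=rician_floor, d0_sphere=d0_sphere,
                x0_extra=[warm] if warm is not None else None,
            )
        except Exception as exc:  # noqa: BLE001 - failed points are marked
            rows.append(
                {"f_sphere": fs, "chi2_red": np.nan, "ssr": np.nan,
                 "failed": True, "error": str(exc)}
            )
            continue
        warm = fit.x
        row = {"f_sphere": fs, "chi2_red": fit.chi2_red, "ssr": fit.ssr,
               "failed": False, "error": ""}
        for name, value in zip(fit.free_names, fit.x):
            row[name] = value
        rows.append(row)
    curve = pd.DataFrame(rows)
    ok = curve[~curve["failed"]]
    diagnostics = {}
    if len(ok):
        chi = ok["chi2_red"].to_numpy()
        fs = ok["f_sphere"].to_numpy()
        i_min = int(np.argmin(chi))
        in_valley = chi <= 1.05 * chi[i_min]
        diagnostics = {
            "f_sphere_min": float(fs[i_min]),
            "chi2_red_min": float(chi[i_min]),
            "valley_width": float(fs[in_valley].max() - fs[in_valley].min()),
        }
    return curve, diagnostics
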