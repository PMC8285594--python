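"""Synthetic acquisition protocols and noisy per-direction datasets.

The default protocol mirrors the Connectom-style b-tensor acquisition used
throughout this package's simulation studies: 10 b = 0 images, 8 linear
(LTE) shells at b = 1, 2, 3, 4.5, 6, 7.5, 9, 10.5 ms/μm² with
(10, 31, 31, 31, 31, 61, 61, 61, 61) directions, 5 planar (PTE) shells at
b = 1, 2, 3, 4.5, 6 with (31, 31, 31, 31, 61) directions, and 5 spherical
(STE) shells at b = 0.2, 1, 2, 3, 4.5 with (6, 9, 9, 12, 15) directions —
604 diffusion-weighted measurements in total.

Noise is applied per measurement *before* direction averaging (arithmetic
powder averaging cannot remove the Rician noise floor), and the powder
signal is normalized by the mean of the noisy b = 0 measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .signal_models import TissueParams, shell_attenuations
from .waveforms import (
    GradientWaveform,
    make_lte_pgse,
    make_pte,
    make_ste,
    scale_to_b,
)

__all__ = [
    "Shell",
    "AcquisitionProtocol",
    "PowderSignal",
    "default_protocol",
    "direction_set",
    "add_noise",
    "generate_dataset",
]

# Timing of the waveform surrogates (ms): δ/Δ of the pulsed LTE pair and
# total/pause of the planar and spherical trains.
LTE_DELTA = 29.65
LTE_BIG_DELTA = 37.05
PTE_STE_TOTAL = 71.6
PTE_STE_PAUSE = 7.4

LTE_BVALUES = (1.0, 2.0, 3.0, 4.5, 6.0, 7.5, 9.0, 10.5)
LTE_NDIRS = (31, 31, 31, 31, 61, 61, 61, 61)
PTE_BVALUES = (1.0, 2.0, 3.0, 4.5, 6.0)
PTE_NDIRS = (31, 31, 31, 31, 61)
STE_BVALUES = (0.2, 1.0, 2.0, 3.0, 4.5)
STE_NDIRS = (6, 9, 9, 12, 15)

_DIRECTION_SEED = 20210815  # fixed so the shipped protocol is reproducible


@dataclass(frozen=True)
class Shell:
    family: str  # "lte" | "pte" | "ste"
    b: float  # ms/μm²
    b_delta: float
    directions: np.ndarray  # (n, 3) unit vectors
    waveform: GradientWaveform  # scaled to this shell's b

    @property
    def n_dirs(self) -> int:
        return self.directions.shape[0]


@dataclass(frozen=True)
class AcquisitionProtocol:
    shells: tuple
    n_b0: int = 10

    def __post_init__(self):
        for s in self.shells:
            norms = np.linalg.norm(s.directions, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-9):
                raise ValueError("shell directions must be unit vectors")
            if s.n_dirs < 1:
                raise ValueError("per-shell direction counts must be positive")

    @property
    def n_measurements(self) -> int:
        return sum(s.n_dirs for s in self.shells)

    def families(self):
        seen = []
        for s in self.shells:
            if s.family not in seen:
                seen.append(s.family)
        return seen


@dataclass(frozen=True)
class PowderSignal:
    """Direction-averaged, S0-normalized signal table (b = 0 row first)."""

    family: np.ndarray
    b: np.ndarray
    b_delta: np.ndarray
    n_dirs: np.ndarray
    signal: np.ndarray
    s0: float = 1.0

    def __post_init__(self):
        if np.any(np.asarray(self.signal) < 0):
            raise ValueError("powder signal values must be nonnegative")

    @property
    def n_points(self) -> int:
        return len(self.signal)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "family": self.family,
                "b": self.b,
                "bdelta": self.b_delta,
                "n_dirs": self.n_dirs,
                "signal": self.signal,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PowderSignal":
        df = pd.read_csv(path)
        return cls(
            family=df["family"].to_numpy(),
            b=df["b"].to_numpy(float),
            b_delta=df["bdelta"].to_numpy(float),
            n_dirs=df["n_dirs"].to_numpy(int),
            signal=df["signal"].to_numpy(float),
        )


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform hemisphere spiral (antipodally folded)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    z = 1.0 - i / n  # upper hemisphere
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, 1.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def direction_set(n: int, seed: int = 0, n_iter: int = 400) -> np.ndarray:
    """n unit vectors spread by antipodal electrostatic repulsion.

    Directions are treated as axes (u ≡ −u), as appropriate for diffusion
    encoding; repulsion maximizes the minimum pairwise angle.  Deterministic
    for a fixed seed; small sets (n < 10) use the deterministic spiral
    directly.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n == 1:
        return np.array([[0.0, 0.0, 1.0]])
    if n < 10:
        return _fibonacci_sphere(n)
    rng = np.random.default_rng(seed)
    u = _fibonacci_sphere(n) + 0.05 * rng.standard_normal((n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    step = 0.1
    for it in range(n_iter):
        diff_m = u[:, None, :] - u[None, :, :]
        diff_p = u[:, None, :] + u[None, :, :]
        dm = np.linalg.norm(diff_m, axis=-1)
        dp = np.linalg.norm(diff_p, axis=-1)
        np.fill_diagonal(dm, np.inf)
        np.fill_diagonal(dp, np.inf)
        force = np.sum(diff_m / dm[..., None] ** 3, axis=1) + np.sum(
            diff_p / dp[..., None] ** 3, axis=1
        )
        force -= np.sum(force * u, axis=1, keepdims=True) * u  # tangent part
        fmax = np.max(np.linalg.norm(force, axis=1))
        if fmax == 0:
            break
        u = u + step * force / fmax
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        step *= 0.99
    # canonical hemisphere orientation for reproducible sign conventions
    flip = u[:, 2] < 0
    u[flip] *= -1.0
    return u


def _shell_waveforms(dt: float):
    lte = make_lte_pgse(LTE_DELTA, LTE_BIG_DELTA, amplitude=60.0, dt=dt)
    pte = make_pte(PTE_STE_TOTAL, PTE_STE_PAUSE, amplitude=60.0, dt=dt)
    ste = make_ste(PTE_STE_TOTAL, PTE_STE_PAUSE, amplitude=60.0, dt=dt)
    return {"lte": lte, "pte": pte, "ste": ste}


def default_protocol(dt: float = 0.05, direction_seed: int = _DIRECTION_SEED
                     ) -> AcquisitionProtocol:
    """The 18-shell LTE/PTE/STE protocol with 10 b = 0 images (604 DWIs)."""
    base = _shell_waveforms(dt)
    bdelta = {"lte": 1.0, "pte": -0.5, "ste": 0.0}
    shells = []
    plan = (
        [("lte", b, n) for b, n in zip(LTE_BVALUES, LTE_NDIRS)]
        + [("pte", b, n) for b, n in zip(PTE_BVALUES, PTE_NDIRS)]
        + [("ste", b, n) for b, n in zip(STE_BVALUES, STE_NDIRS)]
    )
    dir_cache: dict = {}
    for k, (family, b, n) in enumerate(plan):
        if n not in dir_cache:
            dir_cache[n] = direction_set(n, seed=direction_seed + n)
        shells.append(
            Shell(
                family=family,
                b=b,
                b_delta=bdelta[family],
                directions=dir_cache[n],
                waveform=scale_to_b(base[family], b),
            )
        )
    return AcquisitionProtocol(shells=tuple(shells), n_b0=10)


def lte_pgse_protocol(bvalues, n_dirs: int = 61, delta: float = LTE_DELTA,
                      Delta: float = LTE_BIG_DELTA, dt: float = 0.05,
                      n_b0: int = 10) -> AcquisitionProtocol:
    """LTE-only pulsed-gradient protocol (used by the power-law experiments)."""
    base = make_lte_pgse(delta, Delta, amplitude=60.0, dt=dt)
    dirs = direction_set(n_dirs, seed=_DIRECTION_SEED + n_dirs)
    shells = tuple(
        Shell(
            family="lte",
            b=float(b),
            b_delta=1.0,
            directions=dirs,
            waveform=scale_to_b(base, float(b)),
        )
        for b in bvalues
    )
    return AcquisitionProtocol(shells=shells, n_b0=n_b0)


def write_scheme(protocol: AcquisitionProtocol, path, waveform_dir=None) -> None:
    """Write the scheme text format: ``family b bdelta n_dirs waveform_or_dash``.

    With ``waveform_dir`` set, per-shell waveforms are written there in the
    waveform text format and referenced by file name; otherwise a dash
    marks the family's built-in surrogate shape.
    """
    from pathlib import Path

    from .waveforms import write_waveform

    lines = []
    for k, s in enumerate(protocol.shells):
        ref = "-"
        if waveform_dir is not None:
            ref = f"shell{k:02d}_{s.family}.txt"
            write_waveform(s.waveform, Path(waveform_dir) / ref)
        lines.append(f"{s.family} {s.b:g} {s.b_delta:g} {s.n_dirs} {ref}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_scheme(path, n_b0: int = 10, dt: float = 0.05,
                direction_seed: int = _DIRECTION_SEED) -> AcquisitionProtocol:
    """Read a scheme file back into a protocol.

    Dash entries rebuild the family surrogate scaled to the line's b-value;
    file entries load the referenced waveform.  Direction sets are
    regenerated deterministically from the per-shell counts.
    """
    from pathlib import Path

    from .waveforms import read_waveform

    base = _shell_waveforms(dt)
    shells = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        family, b, bdelta, n_dirs, ref = line.split()
        b, bdelta, n_dirs = float(b), float(bdelta), int(n_dirs)
        if ref == "-":
            wf = scale_to_b(base[family], b)
        else:
            wf = scale_to_b(
                read_waveform(Path(path).parent / ref, label=family), b
            )
        shells.append(
            Shell(
                family=family, b=b, b_delta=bdelta,
                directions=direction_set(n_dirs, seed=direction_seed + n_dirs),
                waveform=wf,
            )
        )
    return AcquisitionProtocol(shells=tuple(shells), n_b0=n_b0)


def add_noise(signals, sigma: float, scenario: str = "rician", seed=None,
              rng=None):
    """Corrupt noise-free signals with one of the two study noise scenarios.

    ``gaussian_magnitude`` adds a single real Gaussian deviate to the
    magnitude; ``rician`` draws independent Gaussian noise on the real and
    imaginary channels and takes the magnitude,
    Sₙ = √((S + N_r(0,σ))² + N_i(0,σ)²).
    """
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    signals = np.asarray(signals, dtype=float)
    if sigma == 0:
        return signals.copy()
    if rng is None:
        rng = np.random.default_rng(seed)
    if scenario == "gaussian_magnitude":
        return signals + sigma * rng.standard_normal(signals.shape)
    if scenario == "rician":
        real = signals + sigma * rng.standard_normal(signals.shape)
        imag = sigma * rng.standard_normal(signals.shape)
        return np.sqrt(real**2 + imag**2)
    raise ValueError(f"unknown noise scenario {scenario!r}")


def _per_direction_signals(params: TissueParams, protocol, model: str):
    """Noise-free per-direction signals, tissue symmetry axis along z.

    The anisotropic (stick/cylinder) compartment attenuates each direction
    as exp(−tr(B D)) for the axisymmetric shell b-tensor with symmetry axis
    m: tr(B D) = b[(1−bΔ)·DI + bΔ·(D⊥ + (D∥−D⊥) (m·ẑ)²)].  Sphere and ball
    contributions are isotropic per shell.
    """
    from .signal_models import (
        cylinder_dperp_interpolator,
        sphere_dapp_interpolator,
    )

    out = []
    for s in protocol.shells:
        if model == "cylinder_ball_sphere" and params.r_cylinder > 0:
            d_perp = float(
                cylinder_dperp_interpolator(s.waveform, params.d_par)(
                    params.r_cylinder
                )
            )
        else:
            d_perp = 0.0
        d_iso = (params.d_par + 2.0 * d_perp) / 3.0
        cos2 = s.directions[:, 2] ** 2
        trBD = s.b * (
            (1.0 - s.b_delta) * d_iso
            + s.b_delta * (d_perp + (params.d_par - d_perp) * cos2)
        )
        a_aniso = np.exp(-trBD)
        if model != "stick_ball" and params.f_sphere > 0 and params.r_sphere > 0:
            a_sphere = float(
                np.exp(
                    -s.b
                    * sphere_dapp_interpolator(s.waveform, params.d0_sphere)(
                        params.r_sphere
                    )
                )
            )
        else:
            a_sphere = 1.0
        a_ball = np.exp(-s.b * params.d_ball)
        out.append(
            params.f_stick * a_aniso
            + params.f_sphere * a_sphere
            + params.f_ball * a_ball
        )
    return out


def generate_dataset(
    params: TissueParams,
    protocol: AcquisitionProtocol,
    model: str = "stick_ball_sphere",
    snr: float = 50.0,
    scenario: str = "rician",
    seed: int = 0,
    return_directions: bool = False,
):
    """Simulate one noisy acquisition and reduce it to a powder average.

    ``snr`` is defined as 1/σ with S0 = 1 (``np.inf`` for noise-free data).
    Noise is drawn per measurement; each shell is then arithmetically
    averaged and the result divided by the mean of the noisy b = 0 images.
    """
    if not (snr > 0):
        raise ValueError("snr must be positive (np.inf for noise-free)")
    sigma = 0.0 if np.isinf(snr) else 1.0 / snr
    rng = np.random.default_rng(seed)
    clean = _per_direction_signals(params, protocol, model)
    b0 = add_noise(np.ones(protocol.n_b0), sigma, scenario, rng=rng)
    noisy = [add_noise(sig, sigma, scenario, rng=rng) for sig in clean]
    s0 = float(np.mean(b0))
    means = np.array([np.mean(x) for x in noisy]) / s0
    powder = PowderSignal(
        family=np.array(["b0"] + [s.family for s in protocol.shells]),
        b=np.array([0.0] + [s.b for s in protocol.shells]),
        b_delta=np.array([0.0] + [s.b_delta for s in protocol.shells]),
        n_dirs=np.array([protocol.n_b0] + [s.n_dirs for s in protocol.shells]),
        signal=np.concatenate([[np.mean(b0) / s0], means]),
        s0=s0,
    )
    if not return_directions:
        return powder
    rows = []
    for s, sig in zip(protocol.shells, noisy):
        for d, v in zip(s.directions, sig):
            rows.append(
                {
                    "family": s.family,
                    "b": s.b,
                    "bdelta": s.b_delta,
                    "gx": d[0],
                    "gy": d[1],
                    "gz": d[2],
                    "signal": v,
                }
            )
    return powder, pd.DataFrame(rows)
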