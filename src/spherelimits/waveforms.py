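"""Effective gradient waveforms for linear, planar and spherical b-tensor encoding.

Internal unit convention: time in ms, length in μm, gradient amplitude in
mT/m.  With the gyromagnetic ratio expressed in these units the dephasing
trajectory q(t) = γ∫g dt comes out in rad/μm and the b-tensor
B = ∫ q(t) q(t)ᵀ dt in ms/μm², matching the values quoted throughout the
diffusion-MRI literature (b = 1 ms/μm² = 1000 s/mm²).

Waveforms are stored as zero-order-hold samples of the *effective* gradient,
i.e. the sign of every lobe after a refocusing pulse is already flipped, so
that a refocused sequence satisfies ∫g dt = 0 per axis.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GAMMA",
    "GradientWaveform",
    "BTensor",
    "WaveformSpectrum",
    "make_lte_pgse",
    "make_pte",
    "make_ste",
    "compute_btensor",
    "scale_to_b",
    "spectrum",
    "read_waveform",
    "write_waveform",
]

#: Proton gyromagnetic ratio in rad · ms⁻¹ · μm⁻¹ · (mT/m)⁻¹.
#: 267.513 × 10⁶ rad s⁻¹ T⁻¹ → 2.67513 × 10⁻⁴ in the internal unit system.
GAMMA = 2.6751525e-4

#: Default sample spacing (ms); resolves the spectral content of all
#: waveform families used here to well below the quadrature tolerances.
DEFAULT_DT = 0.05

_REFOCUS_RTOL = 1e-6


class WaveformError(ValueError):
    """Invalid waveform parameters or a non-refocused gradient train."""


@dataclass(frozen=True)
class GradientWaveform:
    """Time-sampled effective gradient g(t).

    ``samples[k]`` holds the gradient vector (mT/m) applied over the
    interval [k·dt, (k+1)·dt); the dephasing q(t) is therefore piecewise
    linear and exactly integrable.
    """

    dt: float
    samples: np.ndarray  # (n, 3), mT/m
    label: str = "custom"

    def __post_init__(self):
        samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if samples.ndim != 2 or samples.shape[1] != 3:
            raise WaveformError("samples must be an (n, 3) array")
        if not np.all(np.isfinite(samples)):
            raise WaveformError("waveform samples must be finite")
        if self.dt <= 0:
            raise WaveformError(f"dt must be positive, got {self.dt}")
        object.__setattr__(self, "samples", samples)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples * self.dt

    def q_trajectory(self) -> np.ndarray:
        """q at the n+1 sample nodes (rad/μm); q[0] = 0."""
        q = np.empty((self.n_samples + 1, 3))
        q[0] = 0.0
        np.cumsum(self.samples * (GAMMA * self.dt), axis=0, out=q[1:])
        return q

    def refocusing_residual(self) -> float:
        """|q(T)| relative to max|q| (0 for a refocused sequence)."""
        q = self.q_trajectory()
        qmax = np.max(np.linalg.norm(q, axis=1))
        if qmax == 0:
            return 0.0
        return float(np.linalg.norm(q[-1]) / qmax)

    def rotated(self, rotation: np.ndarray) -> "GradientWaveform":
        rotation = np.asarray(rotation, dtype=float)
        return replace(self, samples=self.samples @ rotation.T)

    def time_reversed(self) -> "GradientWaveform":
        return replace(self, samples=self.samples[::-1].copy())

    def shape_key(self) -> tuple:
        """Hashable key identifying the waveform shape up to amplitude.

        Used to cache shape-dependent quantities (spectra, restricted
        apparent diffusivities) that are invariant under b-value rescaling.
        """
        amp = float(np.max(np.abs(self.samples)))
        if amp == 0.0:
            digest = "zero"
        else:
            digest = hashlib.sha1(
                np.round(self.samples / amp, 12).tobytes()
            ).hexdigest()
        return (self.label, self.n_samples, round(self.dt, 9), digest)


@dataclass(frozen=True)
class BTensor:
    """Symmetric diffusion-encoding tensor with trace b and shape bΔ."""

    matrix: np.ndarray  # (3, 3), ms/μm²
    b: float
    b_delta: float

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if not np.allclose(m, m.T, atol=1e-12):
            raise WaveformError("b-tensor must be symmetric")
        object.__setattr__(self, "matrix", m)


@dataclass(frozen=True)
class WaveformSpectrum:
    """Fourier transform f(ω) of the dephasing q(t) on a discrete grid."""

    frequencies: np.ndarray  # (m,), rad/ms, fftfreq ordering
    q_spectrum: np.ndarray  # (m, 3), complex, rad/μm · ms
    domega: float

    def power(self) -> np.ndarray:
        """Total spectral power |f(ω)|² summed over axes."""
        return np.sum(np.abs(self.q_spectrum) ** 2, axis=1)


def _n_steps(duration: float, dt: float, name: str) -> int:
    n = int(round(duration / dt))
    if abs(n * dt - duration) > 0.5 * dt + 1e-12:
        raise WaveformError(f"dt={dt} does not divide {name}={duration}")
    return max(n, 0)


def make_lte_pgse(
    delta: float,
    Delta: float,
    amplitude: float,
    dt: float = DEFAULT_DT,
    direction=(0.0, 0.0, 1.0),
) -> GradientWaveform:
    """Rectangular pulsed-gradient pair (Stejskal–Tanner) along one axis.

    Parameters are the classic pulse width δ, separation Δ (both ms) and
    plateau amplitude (mT/m).  The second lobe is negated (effective
    gradient after the refocusing pulse), so q(T) = 0 and bΔ = 1.
    """
    if delta <= 0 or Delta <= 0 or Delta < delta:
        raise WaveformError(
            f"need 0 < delta <= Delta, got delta={delta}, Delta={Delta}"
        )
    if amplitude < 0:
        raise WaveformError("amplitude must be nonnegative")
    direction = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(direction)
    if norm == 0:
        raise WaveformError("direction must be a nonzero vector")
    direction = direction / norm

    n_delta = _n_steps(delta, dt, "delta")
    n_gap = _n_steps(Delta - delta, dt, "Delta - delta")
    g = np.zeros((2 * n_delta + n_gap, 3))
    g[:n_delta] = amplitude * direction
    g[n_delta + n_gap:] = -amplitude * direction
    return GradientWaveform(dt=dt, samples=g, label="lte")


def _bipolar_block(n: int, amplitude: float, axis: np.ndarray) -> np.ndarray:
    """Refocused bipolar lobe: +g for the first half, −g for the second."""
    g = np.zeros((n, 3))
    half = n // 2
    g[:half] = amplitude * axis
    g[half: 2 * half] = -amplitude * axis
    return g


def make_pte(
    total_duration: float = 71.6,
    pause: float = 7.4,
    amplitude: float = 60.0,
    dt: float = DEFAULT_DT,
) -> GradientWaveform:
    """Planar encoding surrogate: two orthogonal bipolar blocks (DDE-style).

    The encoding time (total minus pause) is split equally between a
    bipolar lobe along x and one along y, giving an axisymmetric b-tensor
    with two equal eigenvalues and bΔ = −1/2.
    """
    if total_duration <= 0 or pause < 0 or pause >= total_duration:
        raise WaveformError("need 0 <= pause < total_duration")
    if amplitude < 0:
        raise WaveformError("amplitude must be nonnegative")
    n_pause = _n_steps(pause, dt, "pause")
    n_block = _n_steps((total_duration - pause) / 2.0, dt, "encoding block")
    if n_block < 2:
        raise WaveformError("encoding blocks too short for the given dt")
    ex = np.array([1.0, 0.0, 0.0])
    ey = np.array([0.0, 1.0, 0.0])
    g = np.concatenate(
        [
            _bipolar_block(n_block, amplitude, ex),
            np.zeros((n_pause, 3)),
            _bipolar_block(n_block, amplitude, ey),
        ]
    )
    return GradientWaveform(dt=dt, samples=g, label="pte")


def make_ste(
    total_duration: float = 71.6,
    pause: float = 7.4,
    amplitude: float = 60.0,
    dt: float = DEFAULT_DT,
) -> GradientWaveform:
    """Spherical encoding surrogate: three orthogonal bipolar blocks.

    Equal-duration lobes along x, y and z (pause before the final block)
    produce an isotropic b-tensor, bΔ = 0, with exactly zero off-diagonal
    elements because the per-axis dephasings never overlap in time.
    """
    if total_duration <= 0 or pause < 0 or pause >= total_duration:
        raise WaveformError("need 0 <= pause < total_duration")
    if amplitude < 0:
        raise WaveformError("amplitude must be nonnegative")
    n_pause = _n_steps(pause, dt, "pause")
    n_block = _n_steps((total_duration - pause) / 3.0, dt, "encoding block")
    if n_block < 2:
        raise WaveformError("encoding blocks too short for the given dt")
    axes = np.eye(3)
    g = np.concatenate(
        [
            _bipolar_block(n_block, amplitude, axes[0]),
            _bipolar_block(n_block, amplitude, axes[1]),
            np.zeros((n_pause, 3)),
            _bipolar_block(n_block, amplitude, axes[2]),
        ]
    )
    return GradientWaveform(dt=dt, samples=g, label="ste")


def compute_btensor(wf: GradientWaveform) -> BTensor:
    """B = ∫ q(t) q(t)ᵀ dt with q(t) = γ∫g dt, by exact piecewise integration.

    q(t) is piecewise linear between sample nodes, so ∫qqᵀ over each
    interval is evaluated with the (exact) quadratic rule
    (qₐqₐᵀ + qᵦqᵦᵀ + (qₐqᵦᵀ + qᵦqₐᵀ)/2)/3 · dt.
    """
    residual = wf.refocusing_residual()
    if residual > _REFOCUS_RTOL:
        raise WaveformError(
            f"waveform is not refocused: |q(T)|/max|q| = {residual:.3e}"
        )
    q = wf.q_trajectory()
    qa, qb = q[:-1], q[1:]
    outer_aa = np.einsum("ki,kj->ij", qa, qa)
    outer_bb = np.einsum("ki,kj->ij", qb, qb)
    outer_ab = np.einsum("ki,kj->ij", qa, qb)
    matrix = (outer_aa + outer_bb + 0.5 * (outer_ab + outer_ab.T)) / 3.0 * wf.dt
    matrix = 0.5 * (matrix + matrix.T)
    b = float(np.trace(matrix))
    if b <= 0:
        return BTensor(matrix=matrix, b=max(b, 0.0), b_delta=0.0)
    eigs = np.sort(np.linalg.eigvalsh(matrix))
    # Axisymmetric shape parameter: the isolated eigenvalue is the axial one.
    if eigs[1] - eigs[0] <= eigs[2] - eigs[1]:
        b_par, b_perp = eigs[2], 0.5 * (eigs[0] + eigs[1])  # prolate
    else:
        b_par, b_perp = eigs[0], 0.5 * (eigs[1] + eigs[2])  # oblate
    return BTensor(matrix=matrix, b=b, b_delta=float((b_par - b_perp) / b))


def scale_to_b(wf: GradientWaveform, b_target: float) -> GradientWaveform:
    """Rescale the amplitude so that the waveform's b-value equals b_target."""
    if b_target < 0:
        raise WaveformError(f"b_target must be nonnegative, got {b_target}")
    if b_target == 0:
        return replace(wf, samples=np.zeros_like(wf.samples))
    b_now = compute_btensor(wf).b
    if b_now <= 0:
        raise WaveformError("cannot rescale a zero-b waveform to nonzero b")
    return replace(wf, samples=wf.samples * np.sqrt(b_target / b_now))


def spectrum(wf: GradientWaveform, zero_pad_factor: int = 4) -> WaveformSpectrum:
    """Discrete Fourier transform f(ω) = ∫ q(t) e^{−iωt} dt of the dephasing.

    Zero padding refines the frequency grid (the underlying transform of the
    finite-support q is unchanged); the rectangle-rule DFT satisfies the
    Parseval identity (1/2π)Σ|f|²dω = Σ|q|²dt exactly on this grid.
    """
    if zero_pad_factor < 1:
        raise WaveformError("zero_pad_factor must be >= 1")
    q = wf.q_trajectory()[:-1]  # q[n] = q[0] = 0 for refocused trains
    n_fft = int(2 ** np.ceil(np.log2(max(q.shape[0] * zero_pad_factor, 16))))
    f = np.fft.fft(q, n=n_fft, axis=0) * wf.dt
    omega = 2.0 * np.pi * np.fft.fftfreq(n_fft, d=wf.dt)
    domega = 2.0 * np.pi / (n_fft * wf.dt)
    return WaveformSpectrum(frequencies=omega, q_spectrum=f, domega=domega)


def write_waveform(wf: GradientWaveform, path) -> None:
    """Write the text format: header ``dt_ms=<dt>``, one gx gy gz triple per line."""
    with open(path, "w") as fh:
        fh.write(f"dt_ms={wf.dt:.9g}\n")
        for gx, gy, gz in wf.samples:
            fh.write(f"{gx:.9g} {gy:.9g} {gz:.9g}\n")


def read_waveform(path, label: str = "custom") -> GradientWaveform:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("dt_ms="):
            raise WaveformError(f"missing 'dt_ms=' header in {path}")
        dt = float(header.split("=", 1)[1])
        samples = np.loadtxt(fh, ndmin=2)
    return GradientWaveform(dt=dt, samples=samples, label=label)
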