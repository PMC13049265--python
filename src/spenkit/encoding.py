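"""The algebra of spatiotemporal encoding (SPEN).

A SPEN acquisition imprints a quadratic phase ``beta * y**2`` on the
transverse magnetization and reads out under a decoding gradient, so the
total phase at sample i is ``beta*y**2 + k_i*y``.  The stationary point of
that parabola, ``y_stat = -k/(2*beta)``, sweeps across the field of view and
dominates the signal at each instant, giving a direct time-to-position
mapping.

Unit conventions (fixed throughout the package):

- gradients are stored as ``gamma*G/2pi`` in Hz/m,
- k-values are in rad/m with ``k = 2*pi * integral(gamma*G/2pi) dt``,
- the quadratic coefficient ``beta`` is in rad/m^2,
- all phases are in radians.

Under these conventions the chirp-derived coefficient is
``beta = pi * g**2 * T / BW`` (g in Hz/m) and the quadratic-gradient
coefficient is ``beta = 2*pi * gamma_bar * C * tau`` (C in T/m^2).  The two
generation mechanisms yield entrywise-identical forward operators whenever
their beta values match.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .errors import InvalidDesignError, SpenError

GAMMA_BAR = 42.577478518e6
"""Proton gyromagnetic ratio over 2*pi, Hz/T."""


def beta_from_chirp(grad: float, bandwidth: float, duration: float) -> float:
    """Quadratic phase coefficient from a chirp + constant gradient.

    ``beta = pi * grad**2 * duration / bandwidth`` in rad/m^2, with ``grad``
    in Hz/m (gamma*G/2pi).
    """
    if bandwidth <= 0:
        raise InvalidDesignError("bandwidth must be positive")
    if duration < 0 or grad < 0:
        raise InvalidDesignError("gradient and duration must be non-negative")
    return np.pi * grad ** 2 * duration / bandwidth


@dataclass(frozen=True)
class QuadGradientDesign:
    """A quadratic spatial-encoding field ``B(y) = C * y**2`` applied for
    duration ``tau``."""

    coefficient: float    # T/m^2
    duration: float       # s

    def __post_init__(self):
        if self.duration <= 0:
            raise InvalidDesignError("quad gradient duration must be positive")


def beta_from_quadratic_gradient(design: QuadGradientDesign,
                                 gamma_bar: float = GAMMA_BAR) -> float:
    """Quadratic phase coefficient from a quadratic-gradient event.

    ``beta = 2*pi * gamma_bar * C * tau`` in rad/m^2 (radian convention of
    the phase ``gamma * C * y**2 * tau`` with gamma in rad/s/T).
    """
    return 2 * np.pi * gamma_bar * design.coefficient * design.duration


def fov_from_chirp(bandwidth: float, grad: float) -> float:
    """Field of view excited by a swept pulse: ``FOV = BW / grad``."""
    if grad <= 0:
        raise InvalidDesignError("gradient must be positive")
    return bandwidth / grad


def stationary_point(k, beta: float):
    """Stationary phase point ``y = -k / (2*beta)`` of ``beta*y^2 + k*y``."""
    if beta == 0:
        raise SpenError("beta = 0 has no stationary point (pure Fourier mode)")
    return -np.asarray(k) / (2 * beta) if np.ndim(k) else -k / (2 * beta)


def delta_k_coverage(beta: float, fov: float) -> float:
    """Total k-space coverage needed to sweep the stationary point across
    one FOV: ``delta_k = 2 * beta * FOV`` (rad/m)."""
    return 2 * beta * fov


def alias_free_beta(n: int, fov: float) -> float:
    """Largest beta whose n-sample SPEN sweep stays at the FOV Nyquist rate.

    An n-sample sweep of ``delta_k = 2*beta*FOV`` has spacing
    ``delta_k/(n-1)``; keeping it at ``2*pi/FOV`` prevents in-FOV replicas
    in adjoint (matched-filter) reconstruction, which performs no aliasing
    suppression.  Within that constraint the off-resonance robustness
    (proportional to the swept k range) is maximized, giving
    ``beta = pi*(n-1)/FOV**2``.
    """
    if n < 2:
        raise InvalidDesignError("need at least 2 samples")
    return np.pi * (n - 1) / fov ** 2


@dataclass(frozen=True)
class EncodingParams:
    """SPEN encoding parameters: beta, FOV and the implied k coverage."""

    beta: float                 # rad/m^2 (0 -> pure Fourier encoding)
    fov: float                  # m
    gamma_bar: float = GAMMA_BAR

    def __post_init__(self):
        if self.fov <= 0:
            raise InvalidDesignError("fov must be positive")

    @property
    def delta_k(self) -> float:
        return delta_k_coverage(abs(self.beta), self.fov)

    @classmethod
    def from_chirp(cls, grad: float, bandwidth: float,
                   duration: float) -> "EncodingParams":
        return cls(beta=beta_from_chirp(grad, bandwidth, duration),
                   fov=fov_from_chirp(bandwidth, grad))

    @classmethod
    def from_quadratic_gradient(cls, design: QuadGradientDesign,
                                fov: float) -> "EncodingParams":
        return cls(beta=beta_from_quadratic_gradient(design), fov=fov)


@dataclass(frozen=True)
class KTrajectory:
    """Ordered k-space samples of the SPEN (or phase-encode) axis.

    ``samples`` are in rad/m at the acquisition times ``sample_times``;
    ``prephase`` is the initial k offset set by the prephasing gradient and
    ``acq_gradient_area`` the aggregate acquisition gradient area
    ``integral(gamma*G/2pi) dt`` in Hz*s/m, i.e. the swept k range over 2*pi.
    """

    samples: np.ndarray        # rad/m
    sample_times: np.ndarray   # s
    prephase: float            # rad/m
    acq_gradient_area: float   # Hz*s/m

    def __post_init__(self):
        k = np.asarray(self.samples, dtype=float)
        t = np.asarray(self.sample_times, dtype=float)
        object.__setattr__(self, "samples", k)
        object.__setattr__(self, "sample_times", t)
        if k.size < 2:
            raise InvalidDesignError("trajectory needs at least 2 samples")
        if k.shape != t.shape:
            raise InvalidDesignError("samples and sample_times must match")
        if not np.all(np.diff(t) > 0):
            raise InvalidDesignError("sample_times must be strictly increasing")

    @property
    def n(self) -> int:
        return self.samples.size


def spen_trajectory(params: EncodingParams, n: int,
                    esp: float = 5e-4, sign: int = +1) -> KTrajectory:
    """Uniform SPEN trajectory sweeping the stationary point across the FOV.

    With ``sign=+1`` the prephaser sets ``k0 = +beta*FOV`` so the stationary
    point starts at ``-FOV/2`` and sweeps upward; the endpoints map exactly
    onto the FOV edges.  ``esp`` is the time between consecutive samples
    (the echo spacing for an EPI-style readout).
    """
    if params.beta == 0:
        raise SpenError("use dft_trajectory for beta = 0")
    k0 = sign * params.beta * params.fov
    k = np.linspace(k0, -k0, n)
    times = (np.arange(n) + 0.5) * esp
    return KTrajectory(samples=k, sample_times=times, prephase=k0,
                       acq_gradient_area=abs(2 * k0) / (2 * np.pi))


def dft_trajectory(fov: float, n: int, esp: float = 5e-4) -> KTrajectory:
    """Conjugate (Nyquist) k grid for Fourier encoding: spacing 2*pi/FOV."""
    k = 2 * np.pi * (np.arange(n) - n // 2) / fov
    times = (np.arange(n) + 0.5) * esp
    return KTrajectory(samples=k, sample_times=times, prephase=k[0],
                       acq_gradient_area=(k[-1] - k[0]) / (2 * np.pi))


class SpenConditionReport(NamedTuple):
    """Result of the excitation/acquisition gradient-area check."""

    passed: bool
    excitation_area: float   # Hz*s/m
    acquisition_area: float  # Hz*s/m
    relative_difference: float

    def __bool__(self) -> bool:  # truthiness == passed
        return self.passed


def check_spen_condition(exc_area: float, traj: KTrajectory,
                         tolerance: float = 1e-6) -> SpenConditionReport:
    """Check ``|G_exc * T_exc| == integral(G_acq) dt`` to within ``tolerance``.

    This condition guarantees the stationary point sweeps exactly one FOV
    during acquisition.  Areas are in Hz*s/m.
    """
    exc = abs(exc_area)
    acq = abs(traj.acq_gradient_area)
    scale = max(exc, acq, 1e-300)
    rel = abs(exc - acq) / scale
    return SpenConditionReport(passed=rel <= tolerance,
                               excitation_area=exc, acquisition_area=acq,
                               relative_difference=rel)


@dataclass(frozen=True)
class ForwardOperator:
    """Discretized encoding matrix mapping spin density to samples.

    Entries are ``exp(i*(beta*y_j**2 + k_i*y_j)) * dy``; with ``beta = 0``
    this is the (conjugate-convention) DFT operator.  Every entry has
    magnitude ``dy``.
    """

    matrix: np.ndarray       # complex, (n_samples, n_grid)
    grid: np.ndarray         # m
    mode: str                # {"spen", "dft"}
    beta: float = 0.0        # rad/m^2 used to build the matrix

    @property
    def dy(self) -> float:
        return float(self.grid[1] - self.grid[0])


def uniform_grid(fov: float, n: int) -> np.ndarray:
    """Uniform centered grid, half-open ``[-FOV/2, FOV/2)``, 0-based."""
    return (np.arange(n) - n // 2) * (fov / n)


def build_forward_operator(params: EncodingParams, traj: KTrajectory,
                           grid: np.ndarray) -> ForwardOperator:
    """Build the SPEN (or DFT) forward operator on a uniform grid."""
    grid = np.asarray(grid, dtype=float)
    if grid.size < 2:
        raise InvalidDesignError("grid needs at least 2 points")
    d = np.diff(grid)
    if not np.allclose(d, d[0], rtol=1e-9, atol=0):
        raise InvalidDesignError("grid must be uniformly spaced")
    dy = d[0]
    phase = (params.beta * grid[None, :] ** 2
             + traj.samples[:, None] * grid[None, :])
    matrix = np.exp(1j * phase) * dy
    mode = "dft" if params.beta == 0 else "spen"
    return ForwardOperator(matrix=matrix, grid=grid, mode=mode,
                           beta=params.beta)


def kspace_psf(beta: float, k: np.ndarray) -> np.ndarray:
    """k-space point-spread function of SPEN encoding (up to a constant).

    The Fourier transform of the spatial chirp ``exp(i*beta*y**2)`` is again
    a chirp, ``H(k) ~ exp(-i*k**2/(4*beta))``.  The returned array is
    unit-magnitude; the true transform carries an additional constant factor
    ``sqrt(pi/beta) * exp(i*pi/4)`` which cancels in any normalized
    deconvolution.
    """
    if beta == 0:
        raise SpenError("k-space PSF undefined for beta = 0")
    k = np.asarray(k, dtype=float)
    return np.exp(-1j * k ** 2 / (4 * beta))
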