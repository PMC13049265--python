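"""Hard-pulse Bloch simulation of RF and gradient events.

The simulator advances the magnetization by one exact rotation per RF raster
sample about the instantaneous effective field (RF amplitude/phase plus the
off-resonance contribution from gradient and field offsets).  Relaxation is
ignored: the demonstration regime has sequence durations far shorter than T2,
and all profile and phase validations here are relaxation-free.

Conventions: the rotating-frame effective field for a spin at position y with
off-resonance df (Hz) under a gradient g (Hz/m, i.e. gamma*G/2pi) is
``(Re b1, Im b1, g*y + df)`` in Hz; each raster step applies the corresponding
exact axis-angle rotation, so the magnetization norm is preserved to machine
precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidDesignError, SpenError
from .rf import RFPulse


@dataclass(frozen=True)
class SimGrid:
    """Spatial simulation grid along the encoded axis.

    ``gradient`` is the constant companion gradient in Hz/m (gamma*G/2pi);
    ``off_resonance`` is an optional per-position field offset map in Hz.
    """

    positions: np.ndarray                 # m
    gradient: float = 0.0                 # Hz/m
    off_resonance: np.ndarray | None = None   # Hz

    def __post_init__(self):
        pos = np.atleast_1d(np.asarray(self.positions, dtype=float))
        object.__setattr__(self, "positions", pos)
        if pos.size > 1 and not np.all(np.diff(pos) > 0):
            raise InvalidDesignError("positions must be strictly increasing")
        if not np.isfinite(self.gradient):
            raise InvalidDesignError("gradient must be finite")
        if self.off_resonance is not None:
            off = np.asarray(self.off_resonance, dtype=float)
            if off.shape != pos.shape:
                raise InvalidDesignError(
                    "off_resonance must match positions in shape")
            object.__setattr__(self, "off_resonance", off)

    @property
    def offsets(self) -> np.ndarray:
        """Total frequency offset per position (Hz)."""
        off = self.gradient * self.positions
        if self.off_resonance is not None:
            off = off + self.off_resonance
        return off


@dataclass
class MagnetizationState:
    """Per-position magnetization 3-vectors, shape (n, 3) as (Mx, My, Mz)."""

    m: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.m, dtype=float)
        if m.ndim != 2 or m.shape[1] != 3:
            raise InvalidDesignError("magnetization must have shape (n, 3)")
        self.m = m

    @classmethod
    def equilibrium(cls, n: int) -> "MagnetizationState":
        m = np.zeros((n, 3))
        m[:, 2] = 1.0
        return cls(m)

    @property
    def transverse(self) -> np.ndarray:
        """Complex transverse magnetization Mx + i My."""
        return self.m[:, 0] + 1j * self.m[:, 1]

    @property
    def flip_angle(self) -> np.ndarray:
        """Polar angle from +z, in [0, pi]."""
        return np.arctan2(np.abs(self.transverse), self.m[:, 2])


@dataclass(frozen=True)
class ExcitationProfile:
    """Flip-angle and transverse-phase profile over offsets or positions."""

    flip_angle: np.ndarray                  # rad
    transverse_phase: np.ndarray            # rad, unwrapped
    offsets: np.ndarray | None = None       # Hz
    positions: np.ndarray | None = None     # m


def _rotate(m: np.ndarray, wx: np.ndarray, wy: np.ndarray,
            wz: np.ndarray) -> np.ndarray:
    """Rotate rows of ``m`` by the axis-angle vectors (wx, wy, wz) in rad.

    Uses the left-handed precession sense of the Bloch equation
    ``dM/dt = M x (2*pi*b_eff)`` for positive gyromagnetic ratio.
    """
    ang = np.sqrt(wx * wx + wy * wy + wz * wz)
    small = ang < 1e-300
    safe = np.where(small, 1.0, ang)
    ux, uy, uz = wx / safe, wy / safe, wz / safe
    c, s = np.cos(ang), np.sin(ang)
    c1 = 1.0 - c
    mx, my, mz = m[:, 0], m[:, 1], m[:, 2]
    dot = ux * mx + uy * my + uz * mz
    cx = uy * mz - uz * my
    cy = uz * mx - ux * mz
    cz = ux * my - uy * mx
    out = np.empty_like(m)
    out[:, 0] = mx * c - cx * s + ux * dot * c1
    out[:, 1] = my * c - cy * s + uy * dot * c1
    out[:, 2] = mz * c - cz * s + uz * dot * c1
    out[small] = m[small]
    return out


def simulate_pulse(pulse: RFPulse, grid: SimGrid,
                   initial: MagnetizationState | None = None
                   ) -> MagnetizationState:
    """Hard-pulse simulation of an RF pulse over a spatial grid.

    Starts from ``initial`` (equilibrium +z if omitted) and applies one exact
    rotation per RF raster sample.  Relaxation-free.
    """
    n = grid.positions.size
    if initial is None:
        initial = MagnetizationState.equilibrium(n)
    if initial.m.shape[0] != n:
        raise SpenError("initial state does not match grid size")
    m = initial.m.copy()
    dt = pulse.raster
    wz = 2 * np.pi * (grid.offsets - pulse.carrier_offset) * dt
    for b1 in pulse.samples:
        wx = np.full(n, 2 * np.pi * b1.real * dt)
        wy = np.full(n, 2 * np.pi * b1.imag * dt)
        m = _rotate(m, wx, wy, wz)
    return MagnetizationState(m)


def apply_gradient_lobe(state: MagnetizationState, positions: np.ndarray,
                        k: float) -> MagnetizationState:
    """Apply an ideal gradient lobe of area ``k`` (rad/m): Mxy *= exp(i k y)."""
    mxy = state.transverse * np.exp(1j * k * np.asarray(positions))
    m = state.m.copy()
    m[:, 0], m[:, 1] = mxy.real, mxy.imag
    return MagnetizationState(m)


def unwrap_from_center(phase: np.ndarray) -> np.ndarray:
    """1-D phase unwrap proceeding outward from the central sample."""
    c = phase.size // 2
    out = np.empty_like(phase)
    out[c:] = np.unwrap(phase[c:])
    left = np.unwrap(phase[:c + 1][::-1])[::-1]
    out[:c + 1] = left + (out[c] - left[-1])
    return out


def flip_angle_profile(pulse: RFPulse, offsets: np.ndarray
                       ) -> ExcitationProfile:
    """Flip angle and transverse phase versus frequency offset.

    Simulates from equilibrium at each offset; flip is
    ``atan2(|Mxy|, Mz)``.
    """
    offsets = np.asarray(offsets, dtype=float)
    # encode offsets directly: zero gradient, per-position off-resonance
    grid = SimGrid(positions=np.arange(offsets.size, dtype=float),
                   gradient=0.0, off_resonance=offsets)
    state = simulate_pulse(pulse, grid)
    phase = unwrap_from_center(np.angle(state.transverse))
    return ExcitationProfile(flip_angle=state.flip_angle,
                             transverse_phase=phase, offsets=offsets)


def encoded_phase_profile(pulse: RFPulse, grid: SimGrid,
                          linear_refocus: float = 0.0) -> ExcitationProfile:
    """Transverse phase versus position after a swept excitation.

    ``linear_refocus`` is the area (rad/m) of an ideal gradient lobe applied
    after the pulse to remove the linear component of the encoded phase.  The
    returned phase is unwrapped outward from the grid center; positions where
    the flip angle is below 1 degree carry unreliable phase and should be
    excluded from fits (see :func:`fit_encoded_phase`).

    Raises if the grid undersamples the phase (more than ~2.5 rad between
    neighbouring samples), which would make the unwrap ambiguous.
    """
    state = simulate_pulse(pulse, grid)
    if linear_refocus != 0.0:
        state = apply_gradient_lobe(state, grid.positions, linear_refocus)
    raw = np.angle(state.transverse)
    phase = unwrap_from_center(raw)
    flip = state.flip_angle
    good = flip > np.deg2rad(1.0)
    if good.sum() >= 2:
        steps = np.abs(np.diff(phase[good]))
        if steps.size and np.max(steps) > 2.5:
            raise SpenError(
                "phase profile appears undersampled (max step "
                f"{np.max(steps):.2f} rad); use a finer position grid")
    return ExcitationProfile(flip_angle=flip, transverse_phase=phase,
                             positions=grid.positions.copy())


@dataclass(frozen=True)
class QuadraticFit:
    """Quadratic fit of an encoded phase profile."""

    curvature: float        # rad/m^2, signed coefficient of y^2
    vertex: float           # m, stationary point of the fitted parabola
    residual_rms: float     # rad


def fit_encoded_phase(profile: ExcitationProfile,
                      central_fraction: float = 0.8,
                      min_flip: float = np.deg2rad(1.0)) -> QuadraticFit:
    """Fit ``phi(y) = c2 y^2 + c1 y + c0`` over the central portion of a
    position-domain profile.

    The fit window is the central ``central_fraction`` of the position span;
    points with flip angle below ``min_flip`` are excluded (signal there is
    too weak for a meaningful phase).  The central window mirrors the fact
    that swept excitation degrades toward the edges of the band.
    """
    if profile.positions is None:
        raise SpenError("profile must be position-domain")
    y = profile.positions
    span = y[-1] - y[0]
    mid = 0.5 * (y[-1] + y[0])
    sel = (np.abs(y - mid) <= central_fraction * span / 2)
    sel &= profile.flip_angle > min_flip
    if sel.sum() < 3:
        raise SpenError("too few usable points for a quadratic fit")
    coeffs = np.polyfit(y[sel], profile.transverse_phase[sel], 2)
    resid = profile.transverse_phase[sel] - np.polyval(coeffs, y[sel])
    vertex = -coeffs[1] / (2 * coeffs[0]) if coeffs[0] != 0 else np.inf
    return QuadraticFit(curvature=float(coeffs[0]), vertex=float(vertex),
                        residual_rms=float(np.sqrt(np.mean(resid ** 2))))


def profile_fwhm(x: np.ndarray, y: np.ndarray) -> float:
    """Full width at half maximum of a sampled profile.

    Half-maximum crossings are located by linear interpolation between the
    outermost samples straddling half of the profile maximum.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    half = np.max(y) / 2
    above = y >= half
    if not above.any() or above.all():
        raise SpenError("profile has no half-maximum crossings")
    i0 = int(np.argmax(above))
    i1 = int(len(y) - 1 - np.argmax(above[::-1]))
    if i0 == 0 or i1 == len(y) - 1:
        raise SpenError("profile does not fall below half max at both ends")

    def cross(i, j):
        return x[i] + (half - y[i]) * (x[j] - x[i]) / (y[j] - y[i])

    return float(cross(i1, i1 + 1) - cross(i0, i0 - 1))
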