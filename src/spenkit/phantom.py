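"""Digital phantoms and forward signal synthesis.

Phantoms are non-negative spin-density maps on centered uniform grids, with
an optional off-resonance (field inhomogeneity) map in Hz.  Synthesis
evaluates the discretized signal integral directly: a SPEN sample at
``(k_i, t_i)`` is ``sum_j rho_j * exp(i*(beta*y_j^2 + k_i*y_j)) *
exp(i*2*pi*df_j*t_i) * dy`` plus circular complex Gaussian noise.

The 2-D synthesizer produces SPEN-SE-EPI "hybrid k-space": Fourier encoding
along the readout axis (axis 1), SPEN (or, with beta = 0, conventional phase
encoding) along axis 0, with alternate readout lines time-reversed as in any
EPI train.  Per-sample acquisition times are tracked so off-resonance accrues
physically: line i, temporal sample j acquires at
``t = t_line(i) + (j + 1/2) * dwell``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .encoding import EncodingParams, ForwardOperator, KTrajectory
from .errors import InvalidDesignError, SpenError


@dataclass(frozen=True)
class DigitalPhantom:
    """Spin density (and optional off-resonance map) on a centered grid.

    1-D: ``density`` has shape (n,), the axis being the SPEN axis y.
    2-D: shape (ny, nx) with y = SPEN/phase-encode axis, x = readout axis.
    ``fov`` is the field of view in m (scalar: same for all axes).
    """

    density: np.ndarray
    fov: float
    off_resonance: np.ndarray | None = None   # Hz

    def __post_init__(self):
        rho = np.asarray(self.density, dtype=float)
        object.__setattr__(self, "density", rho)
        if not np.all(np.isfinite(rho)) or np.any(rho < 0):
            raise InvalidDesignError("density must be finite and non-negative")
        if self.fov <= 0:
            raise InvalidDesignError("fov must be positive")
        if self.off_resonance is not None:
            off = np.asarray(self.off_resonance, dtype=float)
            if off.shape != rho.shape:
                raise InvalidDesignError(
                    "off_resonance map must match density shape")
            object.__setattr__(self, "off_resonance", off)

    def axis_positions(self, axis: int = 0) -> np.ndarray:
        n = self.density.shape[axis]
        return (np.arange(n) - n // 2) * (self.fov / n)

    def coarsen(self, factor_y: int) -> "DigitalPhantom":
        """Block-average the SPEN axis by ``factor_y`` (ground-truth grid
        for reconstructions of supersampled phantoms)."""
        rho = self.density
        n0 = rho.shape[0]
        if n0 % factor_y:
            raise InvalidDesignError("axis size not divisible by factor")
        new = rho.reshape(n0 // factor_y, factor_y, *rho.shape[1:]).mean(axis=1)
        return DigitalPhantom(density=new, fov=self.fov)


@dataclass(frozen=True)
class AcquiredSignal:
    """Acquired complex samples plus acquisition bookkeeping.

    1-D: ``samples`` has shape (n,) following ``trajectory``.
    2-D hybrid k-space: shape (n_lines, n_readout) in *temporal* sample
    order per line; lines of ``reversed_parity`` ("odd" by default) were
    acquired under a negative readout lobe and run right-to-left.
    """

    samples: np.ndarray
    trajectory: KTrajectory | None = None
    noise_sd: float = 0.0
    esp: float | None = None          # s, line-to-line spacing (2-D)
    dwell: float | None = None        # s per readout sample (2-D)
    readout_fov: float | None = None  # m (2-D)
    reversed_parity: str | None = None  # "odd" / "even" / None

    def __post_init__(self):
        object.__setattr__(self, "samples",
                           np.asarray(self.samples, dtype=complex))
        if not np.all(np.isfinite(self.samples)):
            raise InvalidDesignError("signal samples must be finite")


def make_bottle_1d(grid_n: int, fov: float,
                   width_fraction: float = 0.6,
                   edge_fraction: float = 0.02) -> DigitalPhantom:
    """1-D flat-topped ("water bottle") profile with smoothed edges.

    The density is a difference of error-function edges, so its integral is
    exactly ``width_fraction * fov`` whenever the support is inside the grid.
    ``edge_fraction`` sets the edge width as a fraction of the FOV.
    """
    from scipy.special import erf

    if grid_n < 16:
        raise InvalidDesignError("grid_n must be at least 16")
    y = (np.arange(grid_n) - grid_n // 2) * (fov / grid_n)
    w = width_fraction * fov
    s = max(edge_fraction * fov, fov / grid_n)
    rho = 0.5 * (erf((y + w / 2) / s) - erf((y - w / 2) / s))
    return DigitalPhantom(density=np.clip(rho, 0, None), fov=fov)


def make_rod_phantom(grid_n: int, fov: float,
                     rod_radii=(0.012, 0.008, 0.005),
                     rod_positions=None,
                     disk_radius: float | None = None,
                     smooth_px: float = 0.0,
                     supersample: int = 1) -> DigitalPhantom:
    """Uniform disk with zero-density circular rods (resolution phantom).

    Defaults place the rods on a ring of radius ``0.45 * disk_radius``
    at evenly spaced angles.  Rods must fit inside the disk and must not
    overlap.  ``smooth_px`` optionally blurs the binary map with a Gaussian
    (in grid_n-scale pixels) to soften pixel edges for forward simulation.
    ``supersample`` refines the SPEN axis by an integer factor (shape
    becomes ``(grid_n*supersample, grid_n)``) so that forward synthesis
    approximates the continuous object; ``coarsen`` the result back for
    ground-truth comparison.
    """
    if disk_radius is None:
        disk_radius = 0.35 * fov
    if supersample < 1 or int(supersample) != supersample:
        raise InvalidDesignError("supersample must be a positive integer")
    radii = list(rod_radii)
    if rod_positions is None:
        ring = 0.45 * disk_radius
        angles = np.pi / 2 + 2 * np.pi * np.arange(len(radii)) / max(len(radii), 1)
        rod_positions = [(ring * np.sin(a), ring * np.cos(a)) for a in angles]
    if len(rod_positions) != len(radii):
        raise InvalidDesignError("rod_positions must match rod_radii")
    for (py, px), r in zip(rod_positions, radii):
        if np.hypot(py, px) + r > disk_radius:
            raise InvalidDesignError("rod does not fit inside the disk")
    for a in range(len(radii)):
        for b in range(a + 1, len(radii)):
            da = np.hypot(rod_positions[a][0] - rod_positions[b][0],
                          rod_positions[a][1] - rod_positions[b][1])
            if da < radii[a] + radii[b]:
                raise InvalidDesignError(f"rods {a} and {b} overlap")
    ny = grid_n * supersample
    y = (np.arange(ny) - ny // 2) * (fov / ny)
    x = (np.arange(grid_n) - grid_n // 2) * (fov / grid_n)
    yy, xx = np.meshgrid(y, x, indexing="ij")
    rho = (yy ** 2 + xx ** 2 <= disk_radius ** 2).astype(float)
    for (py, px), r in zip(rod_positions, radii):
        rho[(yy - py) ** 2 + (xx - px) ** 2 <= r ** 2] = 0.0
    if smooth_px > 0:
        rho = ndimage.gaussian_filter(rho, (smooth_px * supersample,
                                            smooth_px))
    return DigitalPhantom(density=rho, fov=fov)


def make_shim_map(shape, fov: float, peak_hz: float,
                  linear_weight: float = 0.6) -> np.ndarray:
    """Smooth off-resonance map emulating an intentionally poor shim.

    A weighted combination of a linear ramp along the SPEN axis and a
    centered quadratic bowl, scaled so the maximum magnitude equals
    ``peak_hz``.
    """
    shape = tuple(np.atleast_1d(shape))
    n0 = shape[0]
    y = (np.arange(n0) - n0 // 2) / (n0 / 2)
    if len(shape) == 1:
        f = linear_weight * y + (1 - linear_weight) * y ** 2
    elif len(shape) == 2:
        x = (np.arange(shape[1]) - shape[1] // 2) / (shape[1] / 2)
        yy, xx = np.meshgrid(y, x, indexing="ij")
        f = linear_weight * yy + (1 - linear_weight) * (yy ** 2 + xx ** 2) / 2
    else:
        raise InvalidDesignError("shim maps support 1-D or 2-D shapes only")
    m = np.max(np.abs(f))
    return peak_hz * f / m if m > 0 else f


def synthesize_spen_signal(phantom: DigitalPhantom, op: ForwardOperator,
                           traj: KTrajectory, noise_sd: float = 0.0,
                           rng: np.random.Generator | int | None = None,
                           encode_gradient: float | None = None,
                           ) -> AcquiredSignal:
    """1-D SPEN signal ``s = A @ rho`` plus off-resonance phase and noise.

    If the phantom has an off-resonance map, each sample i accrues an extra
    phase ``2*pi*df(y)*t_i`` inside the sum.  ``encode_gradient`` (Hz/m)
    additionally models the swept-excitation mechanism: a spin off-resonant
    by df is excited as if sitting at ``y + df/g``, so its quadratic encode
    phase becomes ``beta*(y + df/g)**2``; this is what shifts the SPEN
    signal envelope under field offsets.  Noise is i.i.d. circular complex
    Gaussian with standard deviation ``noise_sd`` per sample.
    """
    rho = phantom.density
    if rho.ndim != 1:
        raise SpenError("synthesize_spen_signal expects a 1-D phantom")
    if rho.size != op.grid.size:
        raise SpenError("phantom grid does not match operator grid")
    if op.matrix.shape[0] != traj.n:
        raise SpenError("operator does not match trajectory length")
    mat = op.matrix
    df = phantom.off_resonance
    if df is not None and encode_gradient:
        # replace the encode phase beta*y^2 by beta*(y + df/g)^2
        beta = op.beta
        shift = df / encode_gradient
        extra = beta * (2 * op.grid * shift + shift ** 2)
        mat = mat * np.exp(1j * extra)[None, :]
    if df is not None:
        offp = np.exp(2j * np.pi * traj.sample_times[:, None] * df[None, :])
        s = (mat * offp) @ rho
    else:
        s = mat @ rho
    if noise_sd > 0:
        gen = np.random.default_rng(rng)
        s = s + noise_sd * (gen.standard_normal(s.shape)
                            + 1j * gen.standard_normal(s.shape))
    return AcquiredSignal(samples=s, trajectory=traj, noise_sd=noise_sd)


def synthesize_epi_hybrid(phantom: DigitalPhantom, params: EncodingParams,
                          traj: KTrajectory, readout_n: int,
                          esp: float, dwell: float | None = None,
                          delay: float = 0.0, noise_sd: float = 0.0,
                          rng: np.random.Generator | int | None = None,
                          te_offset: float = 0.0) -> AcquiredSignal:
    """2-D hybrid k-space of a SPEN-SE-EPI (or, with beta=0, SE-EPI) train.

    Axis 0 of the phantom is SPEN-encoded using ``params.beta`` and the
    per-line k values in ``traj``; axis 1 is Fourier-encoded with
    ``readout_n`` samples per line.  Odd-indexed lines are time-reversed.
    ``delay`` injects a gradient-delay error: the reversed lines' readout
    k positions are offset by ``delay/dwell`` samples, which appears as the
    characteristic saw-tooth inter-parity misalignment in hybrid k-space.
    ``te_offset`` shifts all acquisition times (for off-resonance accrual
    referenced to the spin-echo center, pass the time of line 0 relative to
    the echo).
    """
    rho = phantom.density
    if rho.ndim != 2:
        raise SpenError("synthesize_epi_hybrid expects a 2-D phantom")
    ny, nx = rho.shape
    if dwell is None:
        dwell = esp / readout_n
    n_lines = traj.n
    fov_x = phantom.fov
    x = (np.arange(nx) - nx // 2) * (fov_x / nx)
    y = phantom.axis_positions(0)
    dkx = 2 * np.pi / fov_x
    kx = dkx * (np.arange(readout_n) - readout_n // 2)
    dy = phantom.fov / ny
    dx = fov_x / nx
    df = phantom.off_resonance
    out = np.empty((n_lines, readout_n), dtype=complex)
    enc_y = params.beta * y ** 2
    for i in range(n_lines):
        reversed_line = (i % 2 == 1)
        # temporal sample j -> kx index
        if reversed_line:
            kx_eff = kx[::-1] + (delay / dwell) * dkx
        else:
            kx_eff = kx
        t = te_offset + traj.sample_times[i] - esp / 2 \
            + (np.arange(readout_n) + 0.5) * dwell
        ph_y = enc_y + traj.samples[i] * y               # (ny,)
        base = rho * np.exp(1j * ph_y)[:, None]          # (ny, nx)
        # (n_read, ny, nx) phase from readout encoding and off-resonance
        ph = kx_eff[:, None, None] * x[None, None, :]
        if df is not None:
            ph = ph + 2 * np.pi * t[:, None, None] * df[None, :, :]
        out[i] = np.einsum("yx,jyx->j", base, np.exp(1j * ph)) * dy * dx
    if noise_sd > 0:
        gen = np.random.default_rng(rng)
        out = out + noise_sd * (gen.standard_normal(out.shape)
                                + 1j * gen.standard_normal(out.shape))
    return AcquiredSignal(samples=out, trajectory=traj, noise_sd=noise_sd,
                          esp=esp, dwell=dwell, readout_fov=fov_x,
                          reversed_parity="odd")
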