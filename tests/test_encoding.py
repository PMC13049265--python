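"""SPEN algebra: beta relations, operators, PSF, convolution framework."""

import numpy as np
import pytest

import spenkit as sk
from spenkit.errors import InvalidDesignError, SpenError


def test_beta_from_chirp_reference_value():
    # pi * (250 kHz/m)^2 * 4 ms / 50 kHz
    assert sk.beta_from_chirp(250e3, 50e3, 4e-3) == pytest.approx(
        15707.963, rel=1e-6)


def test_beta_from_chirp_scalings():
    b = sk.beta_from_chirp(250e3, 50e3, 4e-3)
    assert sk.beta_from_chirp(500e3, 100e3, 4e-3) == pytest.approx(2 * b)
    assert sk.beta_from_chirp(500e3, 50e3, 4e-3) == pytest.approx(4 * b)
    assert sk.beta_from_chirp(250e3, 50e3, 0.0) == 0.0
    with pytest.raises(InvalidDesignError):
        sk.beta_from_chirp(250e3, 0.0, 4e-3)


def test_beta_from_quadratic_gradient():
    d = sk.QuadGradientDesign(coefficient=0.313, duration=5e-3)
    b = sk.beta_from_quadratic_gradient(d)
    assert b == pytest.approx(2 * np.pi * sk.GAMMA_BAR * 0.313 * 5e-3,
                              rel=1e-12)
    assert b == pytest.approx(4.187e5, rel=1e-3)
    assert sk.beta_from_quadratic_gradient(
        sk.QuadGradientDesign(0.313, 1e-2)) == pytest.approx(2 * b)


def test_fov_from_chirp():
    assert sk.fov_from_chirp(50e3, 250e3) == pytest.approx(0.2)
    assert sk.fov_from_chirp(100e3, 250e3) == pytest.approx(0.4)
    assert sk.fov_from_chirp(50e3, 500e3) == pytest.approx(0.1)
    with pytest.raises(InvalidDesignError):
        sk.fov_from_chirp(50e3, 0.0)


def test_stationary_point_inversion():
    beta = 15708.0
    assert sk.stationary_point(0.0, beta) == 0.0
    y0 = 0.037
    assert sk.stationary_point(-2 * beta * y0, beta) == pytest.approx(y0)
    with pytest.raises(SpenError):
        sk.stationary_point(1.0, 0.0)


def test_delta_k_and_sweep_consistency():
    beta, fov = 15708.0, 0.2
    dk = sk.delta_k_coverage(beta, fov)
    assert dk == pytest.approx(6283.2, rel=1e-4)
    assert sk.delta_k_coverage(0.0, fov) == 0.0
    # a trajectory spanning dk sweeps the stationary point edge to edge
    traj = sk.spen_trajectory(sk.EncodingParams(beta=beta, fov=fov), 64)
    y = sk.stationary_point(traj.samples, beta)
    assert y[0] == pytest.approx(-fov / 2)
    assert y[-1] == pytest.approx(fov / 2)


def test_spen_condition_report():
    traj = sk.spen_trajectory(sk.EncodingParams(beta=15708.0, fov=0.2), 64)
    good = sk.check_spen_condition(traj.acq_gradient_area, traj, 1e-6)
    assert good and good.relative_difference < 1e-12
    bad = sk.check_spen_condition(traj.acq_gradient_area * 1.01, traj, 5e-3)
    assert not bad.passed
    assert bad.relative_difference == pytest.approx(0.01, rel=0.02)


def test_dft_reduction_and_pure_phase():
    """With beta = 0 the operator is entrywise the DFT matrix; every entry
    of any operator has magnitude dy."""
    n, fov = 32, 0.2
    grid = sk.uniform_grid(fov, n)
    traj = sk.dft_trajectory(fov, n)
    op = sk.build_forward_operator(sk.EncodingParams(beta=0.0, fov=fov),
                                   traj, grid)
    assert op.mode == "dft"
    expected = np.exp(1j * traj.samples[:, None] * grid[None, :]) * op.dy
    assert np.allclose(op.matrix, expected, atol=1e-15)
    spen = sk.build_forward_operator(
        sk.EncodingParams(beta=9000.0, fov=fov),
        sk.spen_trajectory(sk.EncodingParams(beta=9000.0, fov=fov), n), grid)
    rng = np.random.default_rng(0)
    ii = rng.integers(0, n, 100)
    jj = rng.integers(0, n, 100)
    assert np.allclose(np.abs(spen.matrix[ii, jj]), spen.dy, rtol=1e-12)


def test_generation_mechanism_equivalence():
    """Chirp-derived and quadratic-gradient-derived operators are entrywise
    identical at matched beta."""
    fov, n = 0.2, 48
    p_chirp = sk.EncodingParams.from_chirp(250e3, 50e3, 4e-3)
    tau = 5e-3
    coeff = p_chirp.beta / (2 * np.pi * sk.GAMMA_BAR * tau)
    p_quad = sk.EncodingParams.from_quadratic_gradient(
        sk.QuadGradientDesign(coefficient=coeff, duration=tau), fov=p_chirp.fov)
    assert p_quad.beta == pytest.approx(p_chirp.beta, rel=1e-14)
    grid = sk.uniform_grid(p_chirp.fov, n)
    traj = sk.spen_trajectory(p_chirp, n)
    a1 = sk.build_forward_operator(p_chirp, traj, grid)
    a2 = sk.build_forward_operator(p_quad, traj, grid)
    assert np.array_equal(a1.matrix, a2.matrix) or \
        np.max(np.abs(a1.matrix - a2.matrix)) < 1e-12 * a1.dy


def test_nonuniform_grid_rejected():
    traj = sk.dft_trajectory(0.2, 16)
    grid = np.sort(np.random.default_rng(1).uniform(-0.1, 0.1, 16))
    with pytest.raises(InvalidDesignError):
        sk.build_forward_operator(sk.EncodingParams(beta=0.0, fov=0.2),
                                  traj, grid)


def test_row_contribution_peaks_at_stationary_point():
    """|A_i . rho| is maximal where y_stat(i) is nearest the density
    centroid (the moving-lens picture of SPEN)."""
    fov, n = 0.2, 256
    beta = sk.alias_free_beta(n, fov)
    params = sk.EncodingParams(beta=beta, fov=fov)
    traj = sk.spen_trajectory(params, n)
    grid = sk.uniform_grid(fov, n)
    op = sk.build_forward_operator(params, traj, grid)
    y0 = 0.031
    rho = np.exp(-((grid - y0) / 0.01) ** 2)
    s = np.abs(op.matrix @ rho)
    y_stat = sk.stationary_point(traj.samples, beta)
    assert abs(y_stat[np.argmax(s)] - y0) < 2 * fov / n


def test_resolution_improves_with_beta():
    """Larger beta (fixed FOV and sample count) narrows the point response
    of the encoding, A^H A applied to a point source."""
    fov, n = 0.2, 256
    grid = sk.uniform_grid(fov, n)
    e = np.zeros(n)
    e[n // 2] = 1.0
    widths = []
    for beta in (1000.0, 2000.0, 4000.0):
        params = sk.EncodingParams(beta=beta, fov=fov)
        traj = sk.spen_trajectory(params, n)
        op = sk.build_forward_operator(params, traj, grid)
        psf = np.abs(op.matrix.conj().T @ (op.matrix @ e))
        widths.append(sk.profile_fwhm(grid, psf))
    assert widths[0] > widths[1] > widths[2]


def test_kspace_psf_basic_properties():
    beta = 12000.0
    k = np.linspace(-4000, 4000, 257)
    h = sk.kspace_psf(beta, k)
    assert np.allclose(np.abs(h), 1.0)
    assert h[k.size // 2] == pytest.approx(1.0)
    assert np.allclose(h, h[::-1])  # even in k
    with pytest.raises(SpenError):
        sk.kspace_psf(0.0, k)


def test_kspace_psf_matches_fourier_of_chirp():
    """The numeric Fourier transform of exp(i*beta*y^2) over a wide window
    reproduces the stationary-phase PSF phase within 0.05 rad over the
    central half band (beta*fov^2 >= 100)."""
    beta, fov = 20000.0, 0.2
    assert beta * fov ** 2 >= 100
    n = 8192
    y = sk.uniform_grid(3 * fov, n)
    dy = y[1] - y[0]
    k = np.linspace(-0.25 * 2 * beta * fov, 0.25 * 2 * beta * fov, 101)
    ft = np.array([np.sum(np.exp(1j * beta * y ** 2) * np.exp(1j * kk * y))
                   * dy for kk in k])
    expected = sk.kspace_psf(beta, k)
    phase_err = np.angle(ft * np.conj(expected)
                         * np.exp(-1j * np.pi / 4))
    assert np.max(np.abs(phase_err)) < 0.05


def test_convolution_theorem():
    """SPEN samples equal the Fourier-encoded samples circularly convolved
    with the discretized chirp PSF (up to one complex scale) within 1% RMS
    for a well-contained 256-point phantom."""
    n, fov = 256, 0.2
    beta = sk.alias_free_beta(n, fov) * n / (n - 1)  # pi*n/fov^2
    grid = sk.uniform_grid(fov, n)
    k = 2 * np.pi * (np.arange(n) - n // 2) / fov
    rho = sk.make_bottle_1d(n, fov, width_fraction=0.5,
                            edge_fraction=0.05).density
    traj = sk.KTrajectory(samples=k, sample_times=(np.arange(n) + 1.0) * 1e-4,
                          prephase=k[0], acq_gradient_area=(k[-1] - k[0])
                          / (2 * np.pi))
    spen = sk.build_forward_operator(sk.EncodingParams(beta=beta, fov=fov),
                                     traj, grid)
    dft = sk.build_forward_operator(sk.EncodingParams(beta=0.0, fov=fov),
                                    traj, grid)
    s = spen.matrix @ rho
    p = dft.matrix @ rho
    h = sk.kspace_psf(beta, k)
    conv = np.fft.ifftshift(np.fft.ifft(
        np.fft.fft(np.fft.fftshift(p)) * np.fft.fft(np.fft.fftshift(h))))
    a = np.vdot(conv, s) / np.vdot(conv, conv)
    err = np.linalg.norm(s - a * conv) / np.linalg.norm(s)
    assert err < 0.01
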