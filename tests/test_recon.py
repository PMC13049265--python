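"""Reconstruction: reordering, Fresnel/adjoint, Tikhonov, EPI alignment."""

import numpy as np
import pytest

import spenkit as sk
from spenkit.errors import RankDeficientError, SpenError


@pytest.fixture(scope="module")
def setup_1d():
    fov, n = 0.2, 128
    beta = sk.alias_free_beta(n, fov)
    params = sk.EncodingParams(beta=beta, fov=fov)
    traj = sk.spen_trajectory(params, n, esp=5e-4)
    grid = sk.uniform_grid(fov, n)
    op = sk.build_forward_operator(params, traj, grid)
    return params, traj, grid, op


def _point_signal(params, traj, y0, fine_n=1024):
    fine = sk.uniform_grid(params.fov, fine_n)
    rho = np.exp(-((fine - y0) / 0.0004) ** 2)
    op = sk.build_forward_operator(params, traj, fine)
    return sk.synthesize_spen_signal(
        sk.DigitalPhantom(rho, params.fov), op, traj)


def test_reorder_point_source(setup_1d):
    params, traj, grid, _ = setup_1d
    y0 = grid[90]
    sig = _point_signal(params, traj, y0)
    rec = sk.reorder_magnitude(sig, params, traj)
    assert abs(grid[np.argmax(rec.image)] - y0) <= 1.5 * params.fov / grid.size
    # the mapping sample -> position is strictly monotone
    pos = rec.diagnostics["positions"]
    assert np.all(np.diff(pos) < 0) or np.all(np.diff(pos) > 0)


def test_reorder_flat_phantom_interior(setup_1d):
    params, traj, grid, _ = setup_1d
    fine = sk.uniform_grid(params.fov, 1024)
    ph = sk.make_bottle_1d(1024, params.fov, width_fraction=0.7)
    op = sk.build_forward_operator(params, traj, fine)
    sig = sk.synthesize_spen_signal(ph, op, traj)
    rec = sk.reorder_magnitude(sig, params, traj)
    interior = rec.image[np.abs(grid) < 0.25 * params.fov]
    assert np.max(np.abs(interior - np.mean(interior))) / np.mean(interior) \
        < 0.10


def test_reorder_requires_nonzero_beta(setup_1d):
    _, traj, _, _ = setup_1d
    sig = sk.AcquiredSignal(samples=np.ones(traj.n, dtype=complex),
                            trajectory=traj)
    with pytest.raises(SpenError):
        sk.reorder_magnitude(sig, sk.EncodingParams(beta=0.0, fov=0.2), traj)


def test_fresnel_equals_operator_adjoint(setup_1d):
    params, traj, grid, op = setup_1d
    rng = np.random.default_rng(5)
    s = rng.standard_normal(traj.n) + 1j * rng.standard_normal(traj.n)
    sig = sk.AcquiredSignal(samples=s, trajectory=traj)
    rec = sk.fresnel_recon(sig, params, traj, out_grid=grid)
    adjoint = op.matrix.conj().T @ s
    assert np.max(np.abs(rec.image - adjoint)) < 1e-10 * np.max(np.abs(adjoint))


def test_fresnel_point_source_psf(setup_1d):
    """Point response peaks at the true position with FWHM ~ 2*pi/delta_k."""
    params, traj, grid, _ = setup_1d
    y0 = grid[40]
    sig = _point_signal(params, traj, y0)
    fine_out = sk.uniform_grid(params.fov, 2048)
    rec = sk.fresnel_recon(sig, params, traj, out_grid=fine_out)
    mag = np.abs(rec.image)
    assert abs(fine_out[np.argmax(mag)] - y0) < params.fov / traj.n
    fwhm = sk.profile_fwhm(fine_out, mag)
    assert fwhm == pytest.approx(2 * np.pi / params.delta_k, rel=0.30)


def test_fresnel_bottle_interior(setup_1d):
    params, traj, grid, _ = setup_1d
    fine = sk.uniform_grid(params.fov, 1024)
    ph = sk.make_bottle_1d(1024, params.fov, width_fraction=0.6)
    op = sk.build_forward_operator(params, traj, fine)
    sig = sk.synthesize_spen_signal(ph, op, traj)
    rec = sk.fresnel_recon(sig, params, traj)
    truth = ph.density.reshape(traj.n, -1).mean(axis=1)
    img = np.abs(rec.image)
    alpha = np.sum(img * truth) / np.sum(img ** 2)
    sel = truth > 0.5
    err = np.sqrt(np.mean((alpha * img[sel] - truth[sel]) ** 2))
    assert err < 0.10 * np.mean(truth[sel])


def test_inverted_kernel_pairs_with_inverted_parabola(setup_1d):
    """Data encoded with -beta (pre-refocusing placement) reconstructs with
    the inverted kernel to the same magnitude image."""
    params, traj, grid, op = setup_1d
    rho = sk.make_bottle_1d(grid.size, params.fov, 0.5).density
    s_pos = op.matrix @ rho
    neg = sk.EncodingParams(beta=-params.beta, fov=params.fov)
    traj_neg = sk.KTrajectory(samples=-traj.samples,
                              sample_times=traj.sample_times,
                              prephase=-traj.prephase,
                              acq_gradient_area=traj.acq_gradient_area)
    op_neg = sk.build_forward_operator(neg, traj_neg, grid)
    s_neg = op_neg.matrix @ rho
    r_pos = sk.fresnel_recon(sk.AcquiredSignal(s_pos, traj), params, traj)
    r_neg = sk.fresnel_recon(sk.AcquiredSignal(s_neg, traj_neg), params,
                             traj_neg, inverted_kernel=True)
    a, b = np.abs(r_pos.image), np.abs(r_neg.image)
    assert np.linalg.norm(a - b) / np.linalg.norm(a) < 0.01


def test_tikhonov_exact_recovery_and_oracle(setup_1d):
    params, traj, grid, op = setup_1d
    rho = sk.make_bottle_1d(grid.size, params.fov, 0.5).density
    s = op.matrix @ rho
    sig = sk.AcquiredSignal(samples=s, trajectory=traj)
    rec = sk.tikhonov_recon(sig, op, lam=0.0)
    assert np.linalg.norm(rec.image - rho) / np.linalg.norm(rho) < 1e-6
    # dense least-squares oracle
    oracle, *_ = np.linalg.lstsq(op.matrix, s, rcond=None)
    assert np.linalg.norm(rec.image - oracle) / np.linalg.norm(oracle) < 1e-8


def test_tikhonov_norm_monotone_in_lambda(setup_1d):
    params, traj, grid, op = setup_1d
    rng = np.random.default_rng(11)
    s = rng.standard_normal(traj.n) + 1j * rng.standard_normal(traj.n)
    sig = sk.AcquiredSignal(samples=s, trajectory=traj)
    norms = [np.linalg.norm(sk.tikhonov_recon(sig, op, lam).image)
             for lam in (1e-8, 1e-5, 1e-2)]
    assert norms[0] >= norms[1] >= norms[2]


def test_tikhonov_rank_deficient_raises():
    fov, n = 0.2, 32
    grid = sk.uniform_grid(fov, n)
    # duplicated k samples -> rank-deficient operator
    k = np.repeat(2 * np.pi * (np.arange(n // 2) - n // 4) / fov, 2)
    traj = sk.KTrajectory(samples=k, sample_times=np.arange(n) * 1e-4 + 1e-4,
                          prephase=k[0], acq_gradient_area=1.0)
    op = sk.build_forward_operator(sk.EncodingParams(beta=0.0, fov=fov),
                                   traj, grid)
    sig = sk.AcquiredSignal(samples=np.ones(n, dtype=complex),
                            trajectory=traj)
    with pytest.raises(RankDeficientError):
        sk.tikhonov_recon(sig, op, lam=0.0)
    rec = sk.tikhonov_recon(sig, op, lam=1e-3)  # regularized solve works
    assert np.all(np.isfinite(rec.image))


def test_tikhonov_noisy_point_localization(setup_1d):
    """At SNR ~ 20 a point source localizes within one grid step."""
    params, traj, grid, op = setup_1d
    j0 = 77
    rho = np.zeros(grid.size)
    rho[j0] = 1.0
    clean = op.matrix @ rho
    sd = np.max(np.abs(clean)) / 20
    rng = np.random.default_rng(42)
    s = clean + sd * (rng.standard_normal(traj.n)
                      + 1j * rng.standard_normal(traj.n))
    rec = sk.tikhonov_recon(sk.AcquiredSignal(s, traj), op, lam=1e-6)
    assert abs(int(np.argmax(np.abs(rec.image))) - j0) <= 1


@pytest.fixture(scope="module")
def hybrid_2d():
    fov, n = 0.22, 32
    beta = sk.alias_free_beta(n, fov)
    params = sk.EncodingParams(beta=beta, fov=fov)
    traj = sk.spen_trajectory(params, n, esp=5e-4)
    ph = sk.make_rod_phantom(n, fov, rod_radii=(0.014,), smooth_px=0.8,
                             supersample=4)
    return fov, n, params, traj, ph


def test_align_recovers_injected_integer_delay(hybrid_2d):
    fov, n, params, traj, ph = hybrid_2d
    dwell = 5e-4 / n
    h = sk.synthesize_epi_hybrid(ph, params, traj, readout_n=n, esp=5e-4,
                                 dwell=dwell, delay=dwell)
    aligned, diag = sk.align_epi_lines(h)
    assert abs(diag["shift"]) == 1
    rec = sk.spen_epi_recon(aligned, params, traj, align=False)
    m = sk.image_metrics(rec, ph.coarsen(4))
    assert m.ghost_ratio < 0.05


def test_half_sample_delay_leaves_residual_ghost(hybrid_2d):
    """Sub-raster delays cannot be corrected and leave extra ghosting."""
    fov, n, params, traj, ph = hybrid_2d
    dwell = 5e-4 / n
    truth = ph.coarsen(4)

    def ghost(delay):
        h = sk.synthesize_epi_hybrid(ph, params, traj, readout_n=n,
                                     esp=5e-4, dwell=dwell, delay=delay)
        rec = sk.spen_epi_recon(h, params, traj)
        return sk.image_metrics(rec, truth).ghost_ratio

    assert ghost(0.5 * dwell) > 2 * ghost(1.0 * dwell)


def test_align_zero_delay_is_identity(hybrid_2d):
    fov, n, params, traj, ph = hybrid_2d
    h = sk.synthesize_epi_hybrid(ph, params, traj, readout_n=n, esp=5e-4)
    aligned, diag = sk.align_epi_lines(h)
    assert diag["shift"] == 0
    rev = np.arange(n) % 2 == 1
    manual = h.samples.copy()
    manual[rev] = manual[rev, ::-1]
    assert np.allclose(aligned.samples, manual)


def test_align_all_zero_warns():
    h = sk.AcquiredSignal(samples=np.zeros((8, 8), dtype=complex),
                          reversed_parity="odd")
    with pytest.warns(UserWarning):
        _, diag = sk.align_epi_lines(h)
    assert not diag["applied"]


def test_fourier_epi_offres_shift_matches_oracle():
    """Constant off-resonance shifts the EPI image along phase encode by
    df * (total phase-encode duration) pixels."""
    fov, n = 0.22, 32
    esp = 5e-4
    yv = sk.uniform_grid(fov, n)
    yy, xx = np.meshgrid(yv, yv, indexing="ij")
    rho = np.exp(-(yy ** 2 + xx ** 2) / (2 * 0.02 ** 2))
    df = 60.0
    ph = sk.DigitalPhantom(rho, fov, off_resonance=np.full((n, n), df))
    dtraj = sk.dft_trajectory(fov, n, esp=esp)
    h = sk.synthesize_epi_hybrid(ph, sk.EncodingParams(beta=0.0, fov=fov),
                                 dtraj, readout_n=n, esp=esp)
    rec = sk.fourier_epi_recon(h)
    m = sk.image_metrics(rec, sk.DigitalPhantom(rho, fov))
    expected_px = df * (n * esp)
    assert m.centroid_shift_px[0] == pytest.approx(expected_px, rel=0.25)


def test_conjugate_symmetric_kspace_gives_real_image():
    fov, n = 0.2, 16
    rho = np.outer(np.hanning(n), np.hanning(n))
    dtraj = sk.dft_trajectory(fov, n, esp=5e-4)
    h = sk.synthesize_epi_hybrid(sk.DigitalPhantom(rho, fov),
                                 sk.EncodingParams(beta=0.0, fov=fov),
                                 dtraj, readout_n=n, esp=5e-4)
    rec = sk.fourier_epi_recon(h)
    assert np.max(np.abs(rec.image.imag)) < 1e-9 * np.max(np.abs(rec.image))


def test_spen_epi_recon_rod_phantom(hybrid_2d):
    fov, n, params, traj, ph = hybrid_2d
    h = sk.synthesize_epi_hybrid(ph, params, traj, readout_n=n, esp=5e-4)
    rec = sk.spen_epi_recon(h, params, traj)
    m = sk.image_metrics(rec, ph.coarsen(4))
    assert m.rms_error < 0.10
    assert m.ghost_ratio < 0.05


def test_spen_epi_recon_zero_input(hybrid_2d):
    fov, n, params, traj, _ = hybrid_2d
    h = sk.AcquiredSignal(samples=np.zeros((n, n), dtype=complex),
                          trajectory=traj, esp=5e-4, dwell=5e-4 / n,
                          readout_fov=fov, reversed_parity="odd")
    with pytest.warns(UserWarning):
        rec = sk.spen_epi_recon(h, params, traj)
    assert np.all(rec.image == 0)


def test_image_metrics_basics():
    fov, n = 0.2, 32
    rho = np.zeros((n, n))
    rho[10:20, 12:22] = 1.0
    truth = sk.DigitalPhantom(rho, fov)
    same = sk.image_metrics(sk.ReconResult(image=rho.astype(complex)), truth)
    assert same.rms_error == pytest.approx(0.0, abs=1e-12)
    assert same.centroid_shift_px == (0.0, 0.0)
    shifted = sk.image_metrics(
        sk.ReconResult(image=np.roll(rho, 1, axis=0).astype(complex)), truth)
    assert shifted.centroid_shift_px[0] == pytest.approx(1.0)
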