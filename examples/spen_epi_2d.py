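"""2-D SPEN-SE-EPI vs. Fourier SE-EPI under poor shim.

Simulates hybrid k-space of a rod phantom with a gradient-delay error and a
smooth off-resonance map, reconstructs both the SPEN acquisition (inverse
Fourier along readout + Fresnel deconvolution along the SPEN axis) and the
matched Fourier-EPI reference, and prints ghost levels and the geometric
displacement caused by the field offset.  SPEN's direct time-to-position
mapping makes it markedly less distorted.
"""

import numpy as np

import spenkit as sk

fov, n, esp, dwell = 0.22, 64, 5e-4, 5e-6
beta = sk.alias_free_beta(n, fov)
params = sk.EncodingParams(beta=beta, fov=fov)
traj = sk.spen_trajectory(params, n, esp=esp)
dtraj = sk.dft_trajectory(fov, n, esp=esp)

phantom = sk.make_rod_phantom(n, fov, smooth_px=0.8, supersample=4)
truth = phantom.coarsen(4)
shim = sk.make_shim_map(phantom.density.shape, fov, peak_hz=100.0)
ph = sk.DigitalPhantom(phantom.density, fov, off_resonance=shim)

hyb = sk.synthesize_epi_hybrid(ph, params, traj, readout_n=n, esp=esp,
                               dwell=dwell, delay=dwell)  # +1 sample delay
rec, = [sk.spen_epi_recon(hyb, params, traj)]
m = sk.image_metrics(rec, truth)
print(f"SPEN-SE-EPI (delay corrected by line alignment): "
      f"ghost ratio {m.ghost_ratio:.4f}, RMS error {100 * m.rms_error:.1f}%")

for df in (100.0,):
    off = np.full(phantom.density.shape, df)
    p = sk.DigitalPhantom(phantom.density, fov, off_resonance=off)
    h_s = sk.synthesize_epi_hybrid(p, params, traj, readout_n=n, esp=esp,
                                   dwell=dwell)
    h_e = sk.synthesize_epi_hybrid(p, sk.EncodingParams(beta=0.0, fov=fov),
                                   dtraj, readout_n=n, esp=esp, dwell=dwell)
    d_s = sk.image_metrics(sk.spen_epi_recon(h_s, params, traj),
                           truth).centroid_shift_px[0]
    d_e = sk.image_metrics(sk.fourier_epi_recon(h_e),
                           truth).centroid_shift_px[0]
    print(f"{df:.0f} Hz uniform offset: SPEN displaced {abs(d_s):.2f} px, "
          f"Fourier-EPI displaced {abs(d_e):.2f} px along phase encode")
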