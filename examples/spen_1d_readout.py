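"""1-D SPEN spin-density readout of a bottle phantom.

Synthesizes the swept-encoding signal of a flat-topped 1-D profile and
reconstructs it three ways: naive sample reordering (blurred by the
intrinsic PSF), the convolution-based Fresnel/adjoint method, and a
Tikhonov-regularized operator inversion.  Prints interior errors versus the
ground truth.
"""

import numpy as np

import spenkit as sk

fov, n = 0.2, 128
beta = sk.alias_free_beta(n, fov)
params = sk.EncodingParams(beta=beta, fov=fov)
traj = sk.spen_trajectory(params, n, esp=5e-4)

# synthesize from a 8x finer grid (continuous-object approximation)
fine = sk.uniform_grid(fov, 8 * n)
phantom = sk.make_bottle_1d(8 * n, fov, width_fraction=0.6)
op_fine = sk.build_forward_operator(params, traj, fine)
signal = sk.synthesize_spen_signal(phantom, op_fine, traj,
                                   noise_sd=1e-4, rng=0)

truth = phantom.density.reshape(n, 8).mean(axis=1)
sel = truth > 0.5
grid = sk.uniform_grid(fov, n)
op = sk.build_forward_operator(params, traj, grid)

print(f"beta = {beta:.0f} rad/m^2, {n} samples over {fov * 1e3:.0f} mm FOV\n")
for name, image in [
    ("reorder", sk.reorder_magnitude(signal, params, traj).image),
    ("fresnel", np.abs(sk.fresnel_recon(signal, params, traj).image)),
    ("tikhonov", np.abs(sk.tikhonov_recon(signal, op, lam=1e-6).image)),
]:
    alpha = np.sum(image * truth) / np.sum(image ** 2)
    err = np.sqrt(np.mean((alpha * image[sel] - truth[sel]) ** 2)) \
        / np.mean(truth[sel])
    print(f"{name:9s} interior RMS error = {100 * err:5.2f}% of the mean "
          "intensity")
print("\nReordering shows the intrinsic blur; the Fresnel deconvolution "
      "compensates the quadratic phase; Tikhonov inverts the operator.")
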