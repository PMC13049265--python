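# Methods

This note records the models, conventions and design choices behind
spenkit, and what its synthetic studies do and do not demonstrate.

## Units and phase conventions

The literature on swept encoding mixes cyclic and angular quantities
freely, so one radian-consistent convention is fixed package-wide and
validated against the Bloch simulator (which is unambiguous):

- RF amplitudes are nutation frequencies in Hz (γB₁/2π); the small-tip
  flip angle is 2π∫b₁dt.
- Gradients are stored as γG/2π in Hz/m; k-values are in rad/m with
  k = 2π∫(γG/2π)dt; β is in rad/m²; phases in radians.
- Under this convention the chirp-derived coefficient is
  β = π g² T / BW and the quadratic-gradient coefficient is
  β = 2π γ̄ C τ (γ̄ = 42.577 MHz/T for ¹H).
- Spatial grids are uniform, centered, half-open [−FOV/2, FOV/2);
  forward encoding uses exp(+i k y), reconstruction the conjugate.

A Bloch-level check ties this down: simulating the reference chirp
(50 kHz, 4 ms, WURST-40) under its companion 250 kHz/m gradient and
fitting a parabola to the unwrapped transverse phase recovers β within
0.2%, with the parabola vertex at one edge of the excited FOV (it can be
recentered by a linear-refocusing gradient lobe of area β·FOV).

## RF design

**Chirp.** Instantaneous frequency sweeps linearly from −BW/2 to +BW/2;
the sample phase is the exact analytic integral 2π(f₀t + Rt²/2), so the
unwrapped phase is quadratic to machine precision.  The WURST envelope is
A(t) = A₀(1 − |cos(πt/T)|ⁿ) with n = 40 by default.

**Flip calibration.**  Two contracts are offered:

- `analytic` (default): the low-adiabaticity 90° rule
  (2πA₀)²/(2πR) = ½, i.e. A₀ = √(R/4π) ≈ 997 Hz for the reference sweep,
  scaled linearly for other flips.  This is the convention under which
  swept-pulse power figures are normally quoted, and it is the one that
  reproduces the package's reference energy/power table.
- `bloch`: bisection of A₀ until the simulated flip at the sweep-center
  offset equals the target within 0.1°.  A swept passage overshoots the
  small-tip prediction, so this lands ~6% lower (≈940 Hz); both options
  are tested.

**Bandwidth correction.**  The smooth WURST envelope narrows the excited
band (43.9 kHz FWHM instead of 50 kHz for n = 40).  The correction runs a
secant iteration on the swept bandwidth against the Bloch-simulated
flip-profile FWHM (offset spacing ≤250 Hz), converging in ~4 evaluations
to the nominal FWHM within the requested tolerance; the widening factor
(1.136 for the reference design) is reported.  The widening needed
decreases toward 1 as n grows (block-pulse limit).

**Sinc.**  Apodized sinc with TBW zero crossings, amplitude set by the
small-tip condition.  Default apodization is Hann (the convention of the
Pulseq sinc generator); Hamming and none are selectable.

## Bloch simulation

Hard-pulse integration: one exact axis-angle rotation per RF raster sample
(default 1 µs) about the effective field (b₁ real/imag, gradient×position
plus off-resonance).  No relaxation — the sequences simulated here are far
shorter than T₂ and the verification targets (flip profiles, encoded
phase) are relaxation-free quantities.  Magnetization norm is conserved to
<1e−8 over any simulation; in the small-tip regime the profile matches the
Fourier transform of the envelope within 2% RMS.

Phase profiles are unwrapped outward from the grid center; samples with
flip below 1° are excluded from quadratic fits, and fits use the central
80% of the FOV because swept excitation degrades toward the band edges.
The profile grid must resolve the phase (≲2.5 rad/sample) or an error
advises a finer grid; 1024 points over 200 mm suffices for the reference
design.

## Encoding and sampling design

The SPEN trajectory prephases to k₀ = +β·FOV and sweeps linearly to −k₀,
so the stationary point crosses the FOV edge-to-edge; the
excitation/acquisition gradient-area condition (|G_exc T_exc| equals the
integrated acquisition gradient) then holds by construction and is checked
at 1e−6 on every built sequence.

**Alias-free β (an explicit design rule).**  An n-sample sweep of
Δk = 2βFOV has spacing Δk/(n−1).  The convolution-based (adjoint)
reconstruction used here performs no aliasing suppression, so the sampling
must stay at the FOV Nyquist rate, Δk/(n−1) ≤ 2π/FOV; within that
constraint the off-resonance robustness (which grows with the swept k
range) is maximized by β = π(n−1)/FOV² (`alias_free_beta`).  The 2-D
studies use this β.  Larger β — e.g. the β ≈ 1.3×10⁴ rad/m² implied by the
reference chirp over a 220 mm FOV with only 64 samples — produces in-FOV
replicas under the plain adjoint and would require aliasing-suppressing
reconstruction, which is out of scope.  The consequence is documented
rather than hidden: at the alias-free β the SPEN distortion advantage over
EPI is modest (but strict); with aliasing-suppressing reconstruction and
larger β it would grow proportionally to Δk.

**Convolution framework.**  Acquiring under exp(iβy²) convolves the true
k-space with the chirp kernel H(k) ∝ exp(−ik²/(4β)).  On a conjugate
(Nyquist) k grid with β = πn/FOV² the identity "SPEN samples = Fourier
samples ⊛ H" holds to <0.1% RMS for a well-contained smooth phantom; H is
returned unit-magnitude (the constant √(π/β)·e^{iπ/4} of the continuous
transform cancels in any normalized deconvolution).

## Signal synthesis

1-D signals are s = Aρ with optional i.i.d. circular complex Gaussian
noise (explicit seeds everywhere).  Off-resonance enters two ways: during
acquisition as the phase 2πΔf(y)·tᵢ, and — for the swept-excitation
mechanism — as a position remapping y → y + Δf/g of the encoded parabola
(`encode_gradient` option), which is what shifts the signal *envelope*
(verified: 0.46 samples at 200 Hz under 250 kHz/m, linear in Δf and equal
to (Δf/g)/(FOV/(n−1))).

2-D hybrid k-space tracks true per-sample times (line i, temporal sample j
acquires at t_line(i) + (j+½)·dwell; echo spacing and dwell are
configuration values, defaults 500 µs and 5 µs).  Alternate lines are
time-reversed; a gradient-delay error offsets the reversed lines' readout
k positions by delay/dwell samples, producing the characteristic hybrid
k-space saw-tooth.  Because the discrete chirp exp(iβy²) on the coarse
acquisition grid would alias (its local frequency 2βy exceeds the grid
Nyquist), synthesis uses a phantom supersampled 4× along the SPEN axis —
a continuous-object approximation — and reconstruction/ground truth live
on the 64-point acquisition grid.

The intentionally-poor-shim emulation is a linear + quadratic field map
scaled to a chosen peak (default studies use 100 Hz); real shim maps have
higher-order structure that this does not represent.

## Reconstruction

- **Reordering**: sample i → y_stat(i); the pedagogical baseline, blurred
  by the intrinsic PSF (7.8% interior RMS on the bottle study vs 1.9% for
  the deconvolutions).
- **Fresnel / convolution-based**: the adjoint
  ρ̂(y) = Σᵢ sᵢ·exp(−i(βy² + kᵢy))·wᵢ with grid-spacing weights (exactly
  Aᴴs on a matched grid; trapezoid weights selectable for non-uniform
  trajectories).  The point response peaks at the true position with FWHM
  ≈ 2π/Δk.  An inverted-kernel variant handles data whose phase parabola
  was flipped by the refocusing pulse (quadratic event played before the
  180°).
- **Tikhonov**: normal-equations solve of ‖Ax−s‖² + λ‖x‖²; at λ = 0 a
  condition-number guard raises on rank-deficient operators advising
  λ > 0.  Validated against a dense least-squares oracle to 1e−8.
- **EPI line alignment**: reversed lines are flipped; the inter-parity
  shift is estimated by integer-sample cross-correlation of mean line
  magnitudes (capped at ±max_shift) and removed as a linear phase in the
  readout transform domain.  Sub-sample misalignment is deliberately not
  corrected; a half-sample delay demonstrably leaves residual ghosting.
- 2-D: alignment → inverse DFT along readout (explicit conjugate-grid
  matrices, so centering never depends on FFT index conventions) → per
  column Fresnel deconvolution (SPEN) or inverse DFT (Fourier reference).

Image metrics: least-squares-scaled RMS error relative to the mean
interior intensity, per-axis centroid displacement (pixels and meters),
and a ghost ratio (mean magnitude ≥3 px outside the truth support over the
mean inside).

## Sequence assembly

TE is defined excitation-center → ADC-center of the middle readout line
and met exactly (10 µs gradient raster, 1 µs RF raster) or a timing error
reports the minimum feasible TE.  The chirp variant plays the encoding
gradient under the RF, then a linear-refocusing lobe; the
quadratic-gradient variant hides its 5 ms event inside the TE delay
(after the 180° by default, before it with `placement="pre"`, which flips
the reconstruction kernel).  All three modes share an identical readout
train; the defaults give 77.81 ms (chirp) vs 77.31 ms (quadratic-gradient
and Fourier) total duration — the ordering, not the absolute values, is
the meaningful statement, since absolute durations depend on readout
timing choices.  The matched-β default makes the quadratic-gradient
acquisition directly comparable to the chirp variant; the 313 mT/m² / 5 ms
event parameters are carried verbatim into the export regardless.

The `.seq` export is a deterministic, version-stamped Pulseq-style subset
(blocks, RF with magnitude/phase shapes, trapezoids, ADC, plus a `[QUAD]`
extension for the quadratic event, its coefficient duplicated under
`[DEFINITIONS]` since standard Pulseq gradients are linear-channel only).
Import re-validates every timeline invariant and refuses unknown sections
explicitly.

## Problem sizes and runtimes

Reference studies use 4000-sample (4 ms / 1 µs) RF waveforms, 321–1024
point Bloch grids, 128–256 point 1-D phantoms, and 64×64 2-D acquisitions
synthesized from 256×64 supersampled phantoms; the full test suite runs in
under a minute on one core.  These desk-scale sizes were chosen so every
study re-runs from scratch; nothing is precomputed.

## Limitations

- No relaxation, diffusion, flow, or coil-sensitivity modeling; the 180°
  pulses act as ideal refocusing rotations in signal synthesis.
- No aliasing-suppressing or super-resolved SPEN reconstruction: β is
  restricted by the alias-free sampling rule above.
- The Pulseq subset writer targets round-tripping of its own builds, not
  vendor-interpreter compatibility.
- Synthetic phantoms and shim maps are parameterized stand-ins, not
  replicas of any physical phantom; conclusions about real acquisitions
  are limited to the mechanisms actually modeled (quadratic-phase
  encoding, EPI timing errors, smooth off-resonance).
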