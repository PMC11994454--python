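# Methods

## The imaging model

Confocal scanning light-field microscopy (csLFM) couples two mechanisms:

1. **Scanning light-field detection (sLFM).** A microlens array (MLA, pitch
   `d_l`, focal length `f_µlens`) sits at the native image plane of a
   high-NA objective; the camera one microlens focal length behind records
   4-D spatial–angular measurements — the pixel offset `(u, v)` within each
   microlens footprint samples a sub-aperture of the pupil, the microlens
   index samples space.  A piezo drifts the image plane over an `s × s`
   sub-pitch lattice; *pixel realignment* (a lossless permutation) reorders
   the scanned frames into `n_views × n_views` angular views on a fine
   spatial grid of step `d_l / s` (object-referred `d_l / (M s)`).

2. **Line-confocal illumination synchronized with the rolling shutter.**
   An axially elongated illumination line of width `w_s` (conjugate
   image-plane µm) sweeps the field while only a band of sensor rows of
   height `h_r` is active.  Integrating the product of the two rectangular
   windows over the sweep turns the acquisition into a static modulation of
   the spatial–angular PSF:

       hp'(x̄, ȳ, u, v, z) = hp(x̄, ȳ, u, v, z) · g(ȳ)

   with `g = tri(ȳ / w_s)` when `w_s = h_r` (the conjugate design used by
   default; `tri(x) = max(0, 1 − |x|)`) and a trapezoid with plateau
   half-width `|w_s − h_r| / 2` otherwise.  Keeping the view offset `v`
   gives the exact form `g = tri((ȳ + v) / w_s)`; dropping it (valid for
   `|v| ≪ w_s`) gives the simplified form used for reconstruction.
   Out-of-focus emitters image away from `ȳ = 0` — the farther and the more
   oblique the view, the farther out — so the triangle suppresses exactly
   the defocused background while in-focus light passes almost unattenuated.

### PSF computation

The emitter field at the native image plane is the scalar Debye integral of
an aplanatic objective (apodization `√cos θ`, defocus phase
`exp(i k p_z cos θ)`, `k = 2πn/λ` in the immersion medium), evaluated by
Simpson quadrature over ≥257 aperture angles on a radial lookup table and
interpolated onto a 2-D grid.  A vectorial Debye–Wolf model is a documented
extension point, not implemented.

Each microlens aperture (square `rect(x/d_l)`) multiplies the field; the
camera plane one `f_µlens` behind sees the Fourier transform of the
truncated field (the quadratic lens and Fresnel phases cancel in this
focal-plane geometry and vanish under the squared modulus).  The intensity
is sampled at 3 sub-samples per camera pixel and box-integrated over the
pixel aperture.  The MLA→camera relay (0.845× in the inverted instrument)
is folded into an effective pixel of exactly `d_l / n_views` at the MLA
plane, which encodes the "one microlens covers exactly `n_views × n_views`
pixels" design constraint; all slit/shutter sizes are stated in the same
conjugate-plane micrometres.

Normalization: the in-focus sensor pattern of one scan phase sums to 1.
All energies (per-view energy maps, photon efficiency) are referenced to
this.  Scan-phase offsets are realized by integer-sample shifts of the
native field (the grid step divides `d_l / s` exactly), so realignment is a
pure permutation and conserves energy to the bit.

Light that a microlens diffracts beyond its own `n_views × n_views`
footprint is truncated rather than assigned to the neighboring lens's
views.  The consequence is a small (~6% at DOF-scale defocus for the
63×/1.4 configuration) apparent per-view energy loss with defocus, and
aperture-ringing ripple in the rim views at and beyond the segmented pupil
edge (~2% of collected energy), whose normalized energy curves are
therefore not monotone; monotonicity statements in the tests are asserted
over the in-pupil view set (radius ≤ 3.5 view indices, ~80% of energy).
Within ±1 µm of focus the under-lens pattern is the re-imaged pupil disk
and its diffraction rings sweep across pixels as defocus grows, so
per-view energies oscillate at the few-percent level; background-rejection
monotonicity is accordingly evaluated on a DOF-scale depth grid (±7.5 µm in
1.5-µm steps for the 1.4-NA design) rather than at sub-µm spacing.

A useful pair of exact symmetries of the scalar model (verified to machine
precision): within each view, `hp(−z)` is the spatial mirror of `hp(+z)`
(every view's parallax reverses through focus), and each plane is itself
invariant under jointly flipping views and space.

### Confocality design calculators

* Airy unit: `AU = 1.22 λ M / NA` at the conjugate image plane;
  sub-aperture AU divides NA by `n_views` (one pitch subtends `1/n_views`
  of the pupil diameter; the κ prefactor is exposed as a knob).
  For the 63×/1.4 inverted instrument (λ = 525 nm) `AU = 28.8 µm`, so the
  325-µm slit is ~11 AU; for the 25×/1.05 upright instrument
  (`M = 25 × 1.64 = 41`) `AU = 25.0 µm` and the 650-µm slit is ~26 AU.
* Normalized energy map `Ē′(p_z, u, v) = E′(p_z, u, v) / E_0(u, v)`:
  modulated per-view energy over the stored support, normalized by the
  in-focus unmodulated energy.  Support truncation losing >1% of a plane's
  energy triggers a warning.
* Photon efficiency: total modulated / total unmodulated energy for
  emitters spread uniformly over a depth window (default ±2 µm, the
  "fixed cell within the DOF" scenario).  At the 11-AU design point of the
  inverted configuration this evaluates to ≈82%.
* Axial coverage: per-depth total energy with a half-energy (50%) width as
  the operational DOF figure; the threshold is a parameter since no printed
  operational definition exists.

## Forward simulation

`forward_views` applies the linear shift-invariant view-space model
`views[v,u] = Σ_z volume[z] ⊛ hp[z,v,u]` on the fine grid (FFT
convolutions); a modulated PSF yields csLFM data, an unmodulated one sLFM
data.  `simulate_raw_scan` is the raw sensor-level counterpart: an explicit
discretized sweep of the illumination line (default line spacing
`h_r / 32`; rectangle rule) with the shutter window centered on the line's
image position, per scan phase.  Because the piezo drifts the image plane
while the MLA stays registered to the pixel grid, the drift offset enters
both the emitter image position and the shutter center and cancels exactly
in the realigned domain — which is why the realigned sweep reproduces the
exact-offset triangle modulation within 0.3% per view (2% asserted), the
derivation chain as an executable theorem.  The raw path treats nonzero
voxels as point emitters on the fine lattice (sparse objects); dense
volumes go through the view-space model.  The illumination sheet is modeled
as a top-hat in `y` and uniform in `z` over a 15-µm axial extent, per the
instrument's measured uniformity; scattering backgrounds are emulated as
distributed random emitters in a slab (no radiative transfer).

Noise: Poisson photon noise at a configurable photons-per-unit scale plus
Gaussian read noise (default 1.6 e⁻, gain 1 e⁻/count), seeded.

## Reconstruction

Multi-view Richardson–Lucy-type iterative tomography:

    volume ← volume · [Σ_views K_vuᵀ (m_vu / (K_vu volume + ε))]
                       / [Σ_views K_vuᵀ 1]

with `ε = 10⁻⁹ · max(measurement)`, default 30 iterations, uniform-constant
initialization (a backprojection initialization is available), FFT
zero-padded linear convolutions with the `correlate(1)` normalizer as the
edge treatment, and forward/backward operators that are exact adjoints.
The Poisson data fidelity is logged per iteration and is non-increasing in
all tests.  Reconstructing confocal data with an unmodulated PSF is
permitted but flagged: the mismatch misplaces energy into out-of-focus
planes (≈10 dB worse against ground truth on the three-bead test object).

Digital adaptive optics is simplified to per-view rigid disparities:
subpixel phase correlation of each view against the central view,
compensated for the PSF's intrinsic in-focus parallax, applied by shifting
the PSF kernels (not the data) so the forward model stays consistent.
Imposed pupil-tilt ramps up to ~0.5 µm/view are recovered within 10%; the
full Zernike wavefront estimation of the original sLFM framework is an
extension point.  Shift magnitudes are clipped at 2 µm by default.
cLFM frames (one scan phase) are cubic-spline upsampled to the fine grid
before deconvolution.

## Metrics

All printed-formula implementations: SBR `10·log₁₀(max S / mean B)` dB;
SNR `10·log₁₀(‖X‖²/‖X−Y‖²)`; 3-D SSIM with Gaussian windows (σ = 1.5
voxels, constants `(0.01 L)²`, `(0.03 L)²`, inputs max-normalized);
FWHM by linear-interpolated half-maximum crossings or Gaussian fit;
Fourier ring correlation with a 1/7 threshold (the paper-standard fixed
threshold; checkerboard parity splitting provides half-images for single
exposures); Calinski–Harabasz score and intra/inter-class mean pairwise
distances; ΔF/F₀ with `F₀` the per-ROI time mean; spike detection as
strict local maxima above 40% (calcium) or above 2% after subtracting a
130-ms running median (voltage); 8-direction tuning with visual-response
ratio `R` (stimulus mean over pooled blank mean), responsiveness `R > 3`,
`OSI = (R_pref − R_orth)/(R_pref + R_orth)` with `R_orth` the mean of the
two directions orthogonal to the preferred one, and the fraction of
responsive ROIs with OSI > 0.8.

Because `F₀` is the global time mean, ΔF/F₀ averages to zero over the
series; for a stimulus-locked responder the blank-period mean is therefore
slightly negative, and `R` / OSI behave as intended only when blanks carry
small positive activity (as real recordings do).  The synthetic tuning
traces used in tests include that blank-period activity; OSI is guaranteed
in [−1, 1] only for nonnegative direction responses.

## Synthetic data: what it does and does not emulate

Phantoms reproduce the *geometry* of the validation samples — sub-µm beads
(Poisson-count, antialiased spheres) over scattering slabs (uniform random
emitters), neurite-like tangles (smoothed random-walk tubes), stimulus-
locked fluorescence traces — under exactly the instrument forward model
above.  They do not model radiative transfer in tissue, refractive-index
aberrations, sample motion, photobleaching, or camera fixed-pattern
artifacts.  Passing tests therefore demonstrate the self-consistency of
the optical model, the design calculators and the inversion, and the
qualitative behaviors (background suppression growing with slab thickness
and defocus, matched-PSF reconstruction fidelity), not quantitative
agreement with any in vivo figure.

## Problem sizes and numerical choices

The bundled test configurations use 5×5 views on a 32.5-µm pitch so the
full chain runs in seconds; design-point numbers use the real inverted
configuration (13×13 views, 100-µm pitch) with lateral support of 13–21
microlenses and 9–11 depths.  The resolution round-trip uses a 40×
magnification variant whose fine grid (0.27 µm) oversamples the 0.33-µm
diffraction FWHM; with the real 63× geometry the fine grid itself (0.53 µm)
exceeds the diffraction FWHM, so a grid-limited reconstruction cannot
express that width.  Native-plane sampling defaults to `λM/(8 NA)` snapped
to divide the pitch into `s·k` (odd) samples; Simpson quadrature uses 257
aperture nodes; argmax ties break toward the lowest index; scan lattices
are odd (`s ∈ {1, 3, …}`) so the drift offsets are symmetric about zero.
Deep background slabs use a coarse extended-z PSF (±40 µm in 2-µm steps,
unscanned lattice, Nyquist-rate sampling, depth-chunked to bound memory).
Random seeds affect only synthetic data; reconstruction is deterministic
given its inputs.
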