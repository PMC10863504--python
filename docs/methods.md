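# Methods

This note documents the physical model behind `holofiber`, the parameters
that matter, what the synthetic data does and does not emulate, and the
numerical choices made where the design was open.

## Scalar optics and coordinate conventions

All fields are scalar complex amplitudes in the weakly-guiding
approximation; polarization enters only as an integer multiplicity in mode
counts.  Physical coordinates are axis-centered in micrometres (x right,
y up); sampled arrays are row-major with row 0 at the most negative y, and
grids place sample centers so the grid centroid sits on the fiber axis
(half-pixel offsets for even sizes).  Power is the discrete integral
Σ|A|²·pitch².

Free-space propagation uses the angular-spectrum method with a 2× zero-pad
guard band and exact kz = √(k² − k⊥²); evanescent components decay.  For
band-limited, well-localized fields power is conserved to better than
1e-6 relative, and propagation composes additively to 1e-8.

## Fiber model

A fiber is a `FiberSpec`: cladding and pulp diameters, multimode NA,
corelet lattice (rings, pitch), corelet core diameter and NA, wavelength.
Three presets carry the studied designs: the 61-corelet
multimode–multicore fiber (278/232 µm, NA 0.1), a 100 µm NA 0.29
graded-index comparison fiber, and a double-clad fiber (9 µm core, 105 µm
inner cladding, NA 0.20).  Corelet pitch (25 µm), corelet core diameter
(2 µm) and corelet NA (0.13) are design defaults — they place four rings
comfortably inside the 232 µm pulp — and are overridable in the YAML
configuration; the source design does not pin them down.

**Guided modes.**  LP(l,m) modes of the step-index pulp come from the
characteristic equation u·J_{l+1}(u)/J_l(u) = w·K_{l+1}(w)/K_l(w) with
u² + w² = V², solved by bracketed bisection per azimuthal branch with the
poles of J_l masked.  Propagation constants are stored as offsets from the
cladding plane-wave constant (β − k·n_clad with n_clad = 1.45) to avoid
catastrophic cancellation; only these offsets enter the transport phases
e^{iβL}, so the absolute index scale is immaterial.  Degenerate l > 0
branches are returned as cos/sin orientation pairs.

Sampled on a finite Cartesian grid, exact LP modes are only ~1e-3
orthogonal under the discrete inner product.  The sampled set is therefore
Löwdin-orthogonalized (multiplication by G^{-1/2} of the Gram matrix),
the transformation that makes the discrete basis exactly orthonormal while
perturbing each mode minimally.  All transport and calibration algebra
then holds to machine precision on the grid.

**Corelets.**  Each single-mode corelet (V ≤ 2.405 enforced) is modeled by
its Gaussian fundamental-mode approximation with the Marcuse waist
w = a(0.65 + 1.619·V^{-3/2} + 2.879·V^{-6}).  The index profile inside
corelets is not specified by the source design; the Gaussian approximation
is used throughout.

**Scale.**  The full fiber has V ≈ 149 (≈ 11·10³ modes with two
polarizations, by the standard estimate round(2·V²/4) — the printed
"≈ 12 500" exceeds this for the printed geometry; the counting convention
behind it is not stated, and the package reports the standard estimate).
Mode solving at V ≈ 149 is supported but slow and unnecessary: every
quantity studied here — focusing fidelity, enhancement statistics, mating
loss, contrast — is scale-free in V.  Simulations default to scaled
fibers of V = 10–20 (27–105 modes) with the same NA and wavelength, which
is also what the test suite uses so it runs in well under a minute.

## Transport model

* **Multimode regime:** T = U(coupling, seed)·diag(e^{iβ_m L}) on the
  guided-mode basis.  U interpolates from the identity (coupling 0) to a
  Haar-like random unitary (coupling 1) via expm(t·logm(Q)), with Q the
  QR-orthogonalized seeded complex Gaussian matrix with phase-fixed
  diagonal.  No fiber-internal statistics are claimed by the source; any
  unitary ensemble satisfies the contracts, and the QR construction is the
  standard one.
* **Multicore regime:** a diagonal matrix of seeded unit-modulus phases on
  the corelet basis.  Crosstalk between corelets within one fiber is zero
  by default (that is what defines the regime).
* **Deformation:** multimode transport is right-multiplied by
  exp(strength·K), K a seeded skew-Hermitian generator of unit spectral
  norm, so the distance from the identity grows monotonically with
  strength up to saturation; multicore deformation perturbs only the
  diagonal phases.  Per-channel corelet *intensities* are therefore
  exactly invariant — up to one ulp of float arithmetic, since rotating a
  unit-modulus complex number changes its computed |·|² by ≤ 2e-16.  The
  61-pixel corelet image is invariant at that level, and with a seeded
  Poisson detector the integer counts are bit-identical.

## Ferrule mating and reconnection

Mating two fiber segments inside a sleeve is a corelet-to-corelet coupling
matrix C: fiber-1 lattice positions are rotated and laterally offset, and
each pair couples by the closed-form overlap of displaced Gaussian beams,
with the axial air gap entering through the complex beam parameter
(paraxial).  For equal waists and zero gap this reduces to
C = exp(−d²/2w²), i.e. coupled power exp(−d²/w²); the closed form is
cross-checked in the tests against numeric angular-spectrum propagation
(agreement ~1e-4, including the e^{ikz} piston phase).  Entries below
1e-4 are truncated to zero.  A 60° rotation maps the six-fold lattice onto
itself, giving a permutation coupling — the basis of rotational alignment.

**Rotational alignment** simulates turning the ferrule against a hidden
true misalignment: the objective (total coupled power Σ|C|²) is sampled on
a 0.5° grid over [0°, 60°) and refined by golden-section search.  With no
lateral offset the true angle is recovered to < 0.1° (mod 60°); with a
residual offset the best-coupling angle may legitimately deviate slightly.

**Power fractions.**  Launching unit power into corelet j, the reported
fraction is the power arriving inside corelet j's disk (radius = half the
lattice pitch) relative to the *launched* power.  Light that misses the
corelet at the junction continues diffusely in the multimode pulp and
spreads over the facet, so the facet-total normalization of the physical
measurement is approximated by the launched power; normalizing by
transmitted corelet power instead would cancel the junction loss
altogether.  The in-disk capture of a Gaussian mode is 1 − exp(−2ρ²/w²).

**Reconnection statistics.**  The bore clearance (280±3 µm bore around a
278 µm fiber) bounds the worst-case lateral offset at 3 µm, but a snug
precision sleeve centers far better than the bore allows: offsets drawn
uniformly within the full clearance would destroy ≈ 85 % of the coupled
power, which is not what the reconnection protocol achieves in practice.
The default residual lateral error is Rayleigh-distributed with scale
σ = 0.2 µm (truncated at the clearance), with a 0.5 µm axial gap (bonded
end faces are never perfectly flush) — σ inferred from the experimentally
reported few-percent average power drop, i.e. an instrument parameter, not
a prediction of the model.  It is exposed as `mating.lateral_sigma` in the
configuration.  Fresnel reflections at the glass–air–glass junction are
ignored (only relative powers are reported).

For the multimode regime the junction coupling is computed numerically on
the mode basis: C = M₂†·D·M₁ with D the gap-propagation, rotation
(spline interpolation) and lateral shift (exact Fourier shift) of the
sampled fiber-1 modes.  C is sub-unitary; the lost power is what degrades
focusing through a connected fiber.

## Holographic calibration

**Hologram encoding.**  A binary-amplitude (Lee) grating switches a pixel
on iff cos(2π f·x − φ) ≥ cos(πq), q = arcsin(A)/π; the first diffraction
order then carries A·e^{iφ}/π.  The default carrier has magnitude 1/8
cycles/pixel at 19.4° from the column axis: an exactly rational carrier
(axis-aligned period 8, or the exact diagonal) locks the duty-cycle
quantization to the same few levels on every stripe and distorts low
amplitudes by up to ~8×, while an incommensurate direction dithers the
quantization across stripes and restores ~1 % amplitude linearity.  A
−1e-9 bias on the threshold keeps borderline pixels deterministic against
float rounding.  Order isolation demodulates by the carrier, applies a
circular iris in the Fourier plane (default radius 0.6× the carrier
magnitude), and inverse-transforms; the iris must stay below the carrier
magnitude or the orders overlap.  Binarization noise limits point-wise
round-trip fidelity to ~0.03 rad rms phase and ~1–2 % amplitude under
smooth targets — a physical property of binary holograms at this carrier,
not a numerical artifact.

**Interferometry.**  Four-step phase-shift interferometry with reference
phases {0, π/2, π, 3π/2} — the minimal scheme with an exact closed-form
demodulation C = [(I₀ − I_π) + i(I_{π/2} − I_{3π/2})]/4 = S·R*.  The
reference is a uniform tilted plane wave (the external reference arm of
the physical interferometer justifies a field constant across
acquisitions); its conjugate per-pixel factor is divided out using the
known reference model.  That factor is constant along each TM row, so
phase-conjugate focusing works even without removal.  Under Poisson shot
noise the demodulation error scales as 1/√photons (verified over two
decades).

**TM acquisition.**  Input foci live on a square grid spanning a window
10 % wider than the core diameter; inputs whose integrated output
intensity falls below 10 % of the maximum are pruned.  At full scale this
window reproduces the instrument's numbers: of 201² = 40 401 input foci,
the core circle keeps ≈ 26·10³ (geometry: π/4·(1/1.1)² ≈ 0.65), and of
352² output points at 0.7 µm, 86 260 fall inside the 232 µm core
(≈ "87·10³").  At small V the soft mode boundary keeps slightly more than
the geometric fraction; the ratio approaches it as V grows.  The TM output
plane is the calibration-camera plane at the working distance (default
15 µm past the facet), so synthesized foci are diffraction-limited exactly
where the sample sits and the scan integrates the phantom at that plane.

**Focus metrics.**  Power ratio: power inside a disk of radius
2×(0.51·λ/NA) around the target over total output power (the source does
not define its window; this one is stated and fixed).  FWHM: linear
interpolation of the half-maximum crossing of the radially averaged
profile.  Enhancement: peak intensity over the mean intensity across the
core area; by power conservation that mean equals the diffuse speckle
level of an uncontrolled input, which is the reference of the classic
η ≈ (π/4)·N law for phase-only conjugation over N channels.  (Measuring
against the *residual* background outside the focus disk instead would
overstate η by ≈ 1/(1 − π/4) ≈ 2.6×, because focusing depletes that
background.)  The dedicated `phase_only_enhancement` measurement uses the
experimental definition directly: focus intensity over the mean intensity
at the same target under seeded random-phase inputs; it lands within a few
percent of (π/4)·N at N = 100.  Both amplitude-and-phase (matched filter)
and phase-only input synthesis are implemented.

## Image formation

**Raster scanning** (multimode): for each masked scan point, the
phase-conjugate input for that TM row is played through the (possibly
deformed or mated) ground-truth transport, and the pixel value is
Poisson(photons·∫I(r)ρ(r)d²r + dark).  An idealized shift-invariant PSF
kernel may replace the TM path; a brute-force convolution oracle in the
tests pins that path to < 1e-6 relative error.  Out-of-mask pixels are
flagged invalid, not zero-filled; exporters write zeros and record the
packed mask plus the exact masked values in the JSON sidecar, making the
TIFF+JSON round trip bit-exact.

**Corelet imaging** (multicore): corelets are illuminated in spiral order
(center first, each ring walked counter-clockwise from the smallest
non-negative angle; consecutive same-ring steps are nearest neighbours);
the collected value integrates the corelet's propagated intensity profile
against the phantom.  Since the profile depends only on |T|², the image is
deformation-invariant (see above).  Fluorescence collection efficiency is
absorbed into the detector's photons-per-unit-signal scale; the collection
path is not modeled separately.

**Contrast** is Michelson (⟨fg⟩−⟨bg⟩)/(⟨fg⟩+⟨bg⟩) between disjoint pixel
sets inside the core mask.  Comparing a connected fiber against a single
one, the controlled experiment mates the *same* two segments with an ideal
junction (zero offset/gap) vs a misaligned one (1.5 µm offset, 0.5 µm
gap): the junction loss lowers the focusing power ratio in every seeded
draw, while the image contrast ordering holds on the mean over draws —
mild misalignment apodizes the mode spectrum and can slightly sharpen a
single realization.  Comparing two independently drawn random fibers
instead confounds the junction effect with draw-to-draw variability.

## Synthetic phantoms

Phantoms are 2-D fluorophore-density maps at the working-distance plane
(the instrument images near one plane; a thin-slab 3-D extension is out of
scope), generated as pure functions of (parameters, seed):

* **beads** — n non-overlapping 6 µm uniform disks, centers uniform in the
  Ø230 µm field, rejection-sampled with a bounded retry budget;
* **Purkinje-like tissue** — soft-edged somata with diameters U(15, 25) µm
  centered with jitter on a layer curve (default: a gentle arc), optional
  1–2 µm dendrite ribbons extending perpendicular to the layer, a diffuse
  background at 5 % of soma density (nonzero so dark structures are
  measurable), and dark vessels as multiplicative ribbons with exact zeros
  along their centerlines.

Every object is recorded in a label list sufficient to reconstruct the
ground truth, which is what the imaging oracles test against.  Phantom
pitch defaults to the scan pitch (0.7 µm full scale, 2.8 µm test scale) so
the oracle convolution needs no resampling.  What these phantoms do *not*
emulate: 3-D structure and defocus background, motion artifacts
(heartbeat/breathing), photobleaching, labeling variability, and the
corelet-lattice imaging artifacts of the real fiber — so passing tests
validate the optical pipeline, not biological realism.

One master seed fans out to per-stage seeds via
SeedSequence([master, crc32(stage)]) mod 2³¹, so any stage is
independently reproducible.

## Problem sizes and runtime

The test suite and the acceptance script use: V = 10 (27 modes, 96² grid)
for calibration, deformation and contrast studies; V = 16–20 (65–105
modes, 128² grid) for resolution and enhancement; 88² raster grids at
2.8 µm over the full 246 µm extent; the full 61-corelet lattice for all
multicore work; full-scale (201², 352²) grids for the pure counting
results.  These sizes were chosen so the entire suite runs in about a
minute on one core while every claim remains scale-free.

## Known limitations

* Scalar, weakly-guiding; no vector modes, bend-loss, or dispersion.
* No physical bend model (curvature → mode coupling); deformation is an
  abstract seeded unitary with a strength knob.
* Junction loss is the only mating imperfection; Fresnel reflections,
  end-face tilt and contamination are ignored.
* The multicore regime assumes zero intra-fiber corelet crosstalk (an
  optional leakage parameter exists for robustness experiments).
* The hardware batching limit of the micromirror device (≈ 1.7·10⁵
  patterns per calibration) is documented but not enforced.
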