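"""Hologram encoding, phase-shift interferometry and TM calibration.

The calibration chain mirrors a DMD-based holographic endoscope:

1. an input wavefront is encoded as a binary-amplitude (Lee) grating whose
   first diffraction order, isolated by an iris in the Fourier plane,
   carries the desired complex field;
2. a grid of diffraction-limited input foci is played through the fiber and
   the output facet is recorded interferometrically against a reference
   beam, stepping the reference phase through {0, π/2, π, 3π/2};
3. the four-frame demodulation returns the complex output field for each
   input, and the stacked fields form the measured transmission matrix;
4. phase conjugation of a TM row (a matched filter) synthesizes a focus at
   the corresponding output point, quantified by power ratio, enhancement
   over the speckle background, and FWHM.

Inputs whose light misses the fiber aperture are pruned from the grid
before calibration, exactly as the integrated-intensity pre-alignment step
does on the real instrument.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .fiber_geometry import aperture_mask, grid_coords
from .optics_core import ComplexField, ModeSet, propagate

__all__ = [
    "DEFAULT_CARRIER",
    "BinaryPattern",
    "InterferogramSet",
    "MeasuredTM",
    "FocusMetrics",
    "FiberSystem",
    "encode_hologram",
    "simulate_first_order",
    "psi_demodulate",
    "acquire_tm",
    "prune_inputs",
    "synthesize_focus",
    "radial_fwhm",
    "save_measured_tm",
    "load_measured_tm",
]

#: reference phase steps of the four-frame interferometry scheme
PSI_PHASES = (0.0, np.pi / 2, np.pi, 3 * np.pi / 2)


# --------------------------------------------------------------------------
# Binary-amplitude (Lee) holography
# --------------------------------------------------------------------------

@dataclass
class BinaryPattern:
    """One binary micromirror frame plus its off-axis carrier frequency.

    ``carrier`` is (f_row, f_col) in cycles/pixel; its magnitude must stay
    sub-Nyquist (≤ 0.5).
    """

    frame: np.ndarray
    carrier: tuple[float, float]

    def __post_init__(self) -> None:
        mag = float(np.hypot(*self.carrier))
        if not (0 < mag <= 0.5):
            raise ValueError("carrier magnitude must lie in (0, 0.5] cycles/pixel")


#: default off-axis carrier: magnitude 1/8 cycles/pixel at 19.4° from the
#: column axis.  An incommensurate direction dithers the duty-cycle
#: quantization of the binary grating across stripes; an exactly rational
#: carrier (e.g. axis-aligned period 8) locks every stripe to the same few
#: quantization levels and ruins amplitude linearity at low amplitudes.
DEFAULT_CARRIER: tuple[float, float] = (np.sin(np.deg2rad(19.4)) / 8,
                                        np.cos(np.deg2rad(19.4)) / 8)


def encode_hologram(target: ComplexField,
                    carrier: tuple[float, float] = DEFAULT_CARRIER) -> BinaryPattern:
    """Lee-type binary-amplitude encoding of a complex target field.

    A pixel (i, j) is switched on iff

        cos(2π(f_r·i + f_c·j) − φ(i,j)) ≥ cos(π·q(i,j)),
        q = arcsin(A)/π,

    where A ≤ 1 is the target amplitude (normalized to max 1) and φ its
    phase.  The first diffraction order of the resulting grating carries a
    field proportional to A·e^{iφ} (first Fourier coefficient of a binary
    pulse of duty cycle q is sin(πq)/π = A/π).
    """
    mag = float(np.hypot(*carrier))
    if mag > 0.5:
        raise ValueError("carrier at or above Nyquist")
    amp = np.abs(target.amplitude)
    m = amp.max()
    if m > 1 + 1e-9:
        raise ValueError("target amplitude must be normalized to max 1")
    a = np.clip(amp, 0.0, 1.0)
    phi = np.angle(target.amplitude)
    q = np.arcsin(a) / np.pi
    ny, nx = a.shape
    ii, jj = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    grating = np.cos(2 * np.pi * (carrier[0] * ii + carrier[1] * jj) - phi)
    # tiny bias keeps borderline pixels (grating exactly at threshold)
    # deterministic against float rounding of the carrier phase
    frame = grating >= np.cos(np.pi * q) - 1e-9
    # q = 0 (zero amplitude) must yield all-off pixels even where the
    # carrier cosine touches exactly 1
    frame &= q > 0
    return BinaryPattern(frame=frame, carrier=tuple(carrier))


def simulate_first_order(pattern: BinaryPattern, iris_radius: float) -> ComplexField:
    """Isolate the first diffraction order of a binary frame.

    The frame is demodulated by the carrier, Fourier transformed, cropped
    by a circular iris of ``iris_radius`` (cycles/pixel) centered on the
    (recentred) first order, and transformed back.  The operation is linear
    in the frame.  ``iris_radius`` must be smaller than the carrier
    magnitude so the zero order stays outside the iris.
    """
    mag = float(np.hypot(*pattern.carrier))
    if iris_radius >= mag:
        raise ValueError("iris radius must be below the carrier magnitude "
                         "(diffraction orders would overlap)")
    frame = pattern.frame.astype(float)
    ny, nx = frame.shape
    ii, jj = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    # the grating cos(2πf·x − φ) puts the e^{+iφ} component on the −f order;
    # demodulating by e^{+2πi f·x} recentres that order, so the isolated
    # field is proportional to A·e^{+iφ}
    demod = frame * np.exp(2j * np.pi * (pattern.carrier[0] * ii
                                         + pattern.carrier[1] * jj))
    spec = np.fft.fft2(demod)
    fr = np.fft.fftfreq(ny)
    fc = np.fft.fftfreq(nx)
    iris = (fr[:, None] ** 2 + fc[None, :] ** 2) < iris_radius**2
    out = np.fft.ifft2(spec * iris)
    return ComplexField(out, pitch=1.0, wavelength=488.0)


# --------------------------------------------------------------------------
# Phase-shift interferometry
# --------------------------------------------------------------------------

@dataclass
class InterferogramSet:
    """Four intensity frames at reference phases {0, π/2, π, 3π/2}."""

    intensities: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]
    reference_phases: tuple[float, float, float, float] = PSI_PHASES

    def __post_init__(self) -> None:
        shapes = {i.shape for i in self.intensities}
        if len(shapes) != 1:
            raise ValueError("interferogram frames must share one shape")
        if any(np.any(i < 0) for i in self.intensities):
            raise ValueError("intensities must be nonnegative")
        if tuple(self.reference_phases) != PSI_PHASES:
            raise ValueError("four-step scheme requires phases (0, π/2, π, 3π/2)")


def make_interferograms(signal: np.ndarray, reference: np.ndarray,
                        photons: Optional[float] = None,
                        rng: Optional[np.random.Generator] = None,
                        ) -> InterferogramSet:
    """Simulated four-step interferograms |S + R·e^{iθ}|².

    With ``photons`` set, each frame is Poisson-sampled at that mean photon
    number per unit intensity and rescaled back (shot-noise model).
    """
    frames = []
    for theta in PSI_PHASES:
        i = np.abs(signal + reference * np.exp(1j * theta)) ** 2
        if photons is not None:
            if rng is None:
                rng = np.random.default_rng(0)
            i = rng.poisson(i * photons) / photons
        frames.append(i)
    return InterferogramSet(intensities=tuple(frames))


def psi_demodulate(igrams: InterferogramSet) -> np.ndarray:
    """Four-step demodulation: C = [(I₀−I_π) + i(I_{π/2}−I_{3π/2})]/4.

    Exactly equals S·conj(R) for noiseless frames (the demodulated signal
    still carries the conjugate reference as a per-pixel factor).
    """
    i0, i90, i180, i270 = igrams.intensities
    return ((i0 - i180) + 1j * (i90 - i270)) / 4.0


# --------------------------------------------------------------------------
# Ground-truth fiber system (transport + reference model)
# --------------------------------------------------------------------------

class FiberSystem:
    """Pixel-level forward model of one calibrated fiber.

    Wraps a guided-mode basis and a mode-basis transmission matrix into the
    map "input focus grid point → complex field at the imaging plane".
    The imaging plane sits ``working_distance`` µm past the facet (the
    calibration camera images that plane, so synthesized foci are
    diffraction-limited there).  A uniform tilted plane wave serves as the
    interferometric reference.

    ``input_window`` is the side of the square focus grid as a multiple of
    the core diameter covered by the mode basis; inputs outside the fiber
    aperture transmit almost nothing and are pruned during calibration.
    """

    def __init__(self, modes: ModeSet, tm, core_diameter: float, na: float,
                 input_grid_n: int = 16, input_window: float = 1.1,
                 working_distance: float = 0.0,
                 reference_tilt: tuple[float, float] = (0.05, 0.03),
                 reference_amplitude: float = 1.0):
        if tm.regime != "multimode":
            raise ValueError("FiberSystem requires a multimode-regime TM")
        self.modes = modes
        self.tm = tm
        self.core_diameter = float(core_diameter)
        self.na = float(na)
        self.working_distance = float(working_distance)
        self.grid_shape = modes.shape
        self.pitch = modes.pitch
        self.wavelength = modes.wavelength

        ny, nx = self.grid_shape
        y, x = grid_coords(self.grid_shape, self.pitch)
        half = input_window * core_diameter / 2
        sel_y = np.flatnonzero(np.abs(y) <= half)
        sel_x = np.flatnonzero(np.abs(x) <= half)
        step_y = max(1, len(sel_y) // input_grid_n)
        take_y = sel_y[::step_y][:input_grid_n]
        take_x = sel_x[::step_y][:input_grid_n]
        pts = np.array([(iy, ix) for iy in take_y for ix in take_x])
        self.input_points = pts[:, 0] * nx + pts[:, 1]  # flattened indices
        self.input_grid_shape = (len(take_y), len(take_x))

        self.output_mask, _ = aperture_mask(self.grid_shape, self.pitch,
                                            core_diameter)

        # uniform plane wave tilted by (f_row, f_col) cycles/pixel at the camera
        ii, jj = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
        self.reference = reference_amplitude * np.exp(
            2j * np.pi * (reference_tilt[0] * ii + reference_tilt[1] * jj))
        self._pixel_tm: Optional[np.ndarray] = None
        self._mode_pixel_tm: Optional[np.ndarray] = None

    # -- forward maps ------------------------------------------------------

    def mode_pixel_tm(self) -> np.ndarray:
        """(n_pixels, n_modes): mode coefficients → field at imaging plane."""
        if self._mode_pixel_tm is None:
            fields = self.modes.fields
            if self.working_distance != 0.0:
                fields = np.stack([
                    propagate(ComplexField(f.copy(), self.pitch, self.wavelength),
                              self.working_distance).amplitude
                    for f in fields
                ])
            m_out = fields.reshape(len(self.modes), -1).T * self.pitch
            self._mode_pixel_tm = m_out @ self.tm.matrix
        return self._mode_pixel_tm

    def pixel_tm(self) -> np.ndarray:
        """(n_pixels, n_inputs): ground-truth response to each input focus."""
        if self._pixel_tm is None:
            m_in = self.modes.matrix()  # facet-side synthesis matrix
            proj = m_in.conj()[self.input_points, :].T  # delta spots → modes
            self._pixel_tm = self.mode_pixel_tm() @ proj
        return self._pixel_tm

    def output_field(self, input_vector: np.ndarray) -> np.ndarray:
        """Field (2-D) at the imaging plane for a weighted focus input."""
        flat = self.pixel_tm() @ input_vector
        return flat.reshape(self.grid_shape)


# --------------------------------------------------------------------------
# TM acquisition
# --------------------------------------------------------------------------

@dataclass
class MeasuredTM:
    """Calibrated transmission matrix on (masked output pixels × kept inputs).

    ``matrix[p, k]`` relates kept input focus k to masked output pixel p.
    ``kept_inputs`` indexes into the system's input-focus list;
    ``output_mask`` is the boolean core mask on the full grid; ``na`` and
    ``wavelength`` parameterize the diffraction limit for focus metrics.
    Rows may still carry the conjugate-reference pixel factor (see
    ``reference_removed``); that factor is constant along each row and
    therefore irrelevant for phase-conjugate focusing.
    """

    matrix: np.ndarray
    kept_inputs: np.ndarray
    output_mask: np.ndarray
    pitch: float
    wavelength: float
    na: float
    input_grid_shape: tuple[int, int]
    reference_removed: bool = False
    seed: Optional[int] = None

    @property
    def masked_indices(self) -> np.ndarray:
        return np.flatnonzero(self.output_mask.ravel())

    def embed(self, masked_values: np.ndarray) -> np.ndarray:
        """Scatter a masked-pixel vector back onto the full 2-D grid."""
        full = np.zeros(self.output_mask.size, dtype=masked_values.dtype)
        full[self.masked_indices] = masked_values
        return full.reshape(self.output_mask.shape)


def prune_inputs(integrated_intensity: np.ndarray,
                 threshold_fraction: float) -> np.ndarray:
    """Indices of inputs whose integrated output intensity is at least
    ``threshold_fraction`` of the maximum (deterministic)."""
    if not (0 < threshold_fraction < 1):
        raise ValueError("threshold_fraction must lie in (0, 1)")
    v = np.asarray(integrated_intensity, dtype=float).ravel()
    m = v.max(initial=0.0)
    if m <= 0:
        warnings.warn("all-zero intensity map: no inputs kept", stacklevel=2)
        return np.array([], dtype=int)
    return np.flatnonzero(v >= threshold_fraction * m)


def acquire_tm(system: FiberSystem,
               photons: Optional[float] = None,
               noise_seed: int = 0,
               prune_threshold: Optional[float] = 0.1,
               remove_reference: bool = True) -> MeasuredTM:
    """Acquire the transmission matrix by four-step interferometry.

    Each input focus is played through the ground-truth transport; the
    output facet interferes with the reference beam at the four phase
    steps; demodulation gives the complex column.  With ``photons`` set,
    interferograms carry Poisson shot noise.  Inputs are pruned on their
    integrated output intensity (the pre-alignment step); with
    ``remove_reference`` the per-pixel conjugate-reference factor is
    divided out using the known reference model.  Noiseless acquisition
    then equals the ground-truth pixel TM exactly.
    """
    s_true = system.pixel_tm()
    mask_idx = np.flatnonzero(system.output_mask.ravel())
    rng = np.random.default_rng(noise_seed) if photons is not None else None
    ref = system.reference.ravel()

    cols = np.empty((len(mask_idx), s_true.shape[1]), dtype=complex)
    integrated = np.empty(s_true.shape[1])
    for k in range(s_true.shape[1]):
        sig = s_true[:, k]
        ig = make_interferograms(sig, ref, photons=photons, rng=rng)
        c = psi_demodulate(ig)
        cols[:, k] = c[mask_idx]
        integrated[k] = float(np.sum(np.abs(c[mask_idx]) ** 2))

    if prune_threshold is not None:
        kept = prune_inputs(integrated, prune_threshold)
    else:
        kept = np.arange(s_true.shape[1])
    cols = cols[:, kept]

    if remove_reference:
        cols = cols / np.conj(ref[mask_idx])[:, None]

    return MeasuredTM(
        matrix=cols,
        kept_inputs=kept,
        output_mask=system.output_mask,
        pitch=system.pitch,
        wavelength=system.wavelength,
        na=system.na,
        input_grid_shape=system.input_grid_shape,
        reference_removed=remove_reference,
        seed=noise_seed if photons is not None else None,
    )


# --------------------------------------------------------------------------
# Phase-conjugate focus synthesis
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FocusMetrics:
    """Quality of one synthesized focus.

    ``power_ratio``: power inside a disk of radius 2×(0.51·λ/NA) around the
    target over the total output power, in [0, 1].  ``enhancement``: peak
    intensity at the target over the mean intensity across the core area —
    by power conservation that mean equals the diffuse speckle level of an
    uncontrolled input, which is the reference of the classic random-matrix
    expectation η ≈ (π/4)·N for phase-only conjugation over N channels.
    ``fwhm``: full width at half maximum of the radially averaged focal
    spot, µm.
    """

    power_ratio: float
    enhancement: float
    fwhm: float


def radial_fwhm(intensity: np.ndarray, center_yx: tuple[float, float],
                pitch: float, n_bins: int = 200) -> float:
    """FWHM of a radially averaged intensity profile, by linear
    interpolation of the half-maximum crossing.  Warns if the profile
    re-crosses half maximum further out (secondary peak)."""
    ny, nx = intensity.shape
    y, x = grid_coords((ny, nx), pitch)
    r = np.hypot(y[:, None] - center_yx[0], x[None, :] - center_yx[1])
    rmax = r.max() / 2
    bins = np.linspace(0, rmax, n_bins + 1)
    idx = np.clip(np.digitize(r.ravel(), bins) - 1, 0, n_bins - 1)
    sums = np.bincount(idx, weights=intensity.ravel(), minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        prof = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    rc = (bins[:-1] + bins[1:]) / 2
    good = ~np.isnan(prof)
    prof, rc = prof[good], rc[good]
    half = prof[0] / 2.0
    below = np.flatnonzero(prof < half)
    if len(below) == 0:
        raise ValueError("profile never falls below half maximum")
    i = below[0]
    r0, r1 = rc[i - 1] if i > 0 else 0.0, rc[i]
    p0 = prof[i - 1] if i > 0 else prof[0]
    p1 = prof[i]
    r_half = r0 + (p0 - half) / (p0 - p1) * (r1 - r0)
    if np.any(prof[i:] > half):
        warnings.warn("non-unimodal radial profile: secondary peak above half "
                      "maximum beyond the first crossing", stacklevel=2)
    return float(2 * r_half)


def synthesize_focus(mtm: MeasuredTM, target_index: int,
                     forward: Optional[np.ndarray] = None,
                     phase_only: bool = False,
                     ) -> tuple[np.ndarray, FocusMetrics, np.ndarray]:
    """Phase-conjugate (matched-filter) focus at one masked output pixel.

    The input vector is the normalized conjugate of the TM row for the
    target (with ``phase_only``, unit amplitudes carrying only the
    conjugate phases — the DMD-like variant).  The resulting output is
    simulated with ``forward`` (a ground-truth pixel TM restricted to the
    kept inputs; defaults to the measured matrix itself) and scored.

    Returns ``(input_vector, FocusMetrics, output_intensity_2d)``.
    """
    n_masked = mtm.matrix.shape[0]
    if not (0 <= target_index < n_masked):
        raise ValueError("target index outside the core mask")
    row = mtm.matrix[target_index, :]
    if not np.any(row):
        raise ValueError("zero TM row: target receives no light")
    if phase_only:
        v = np.exp(-1j * np.angle(row))
    else:
        v = np.conj(row)
    v = v / np.linalg.norm(v)

    fwd = forward if forward is not None else mtm.matrix
    out_masked = fwd @ v if fwd.shape[0] == n_masked else (fwd @ v)[mtm.masked_indices]
    intensity = np.abs(mtm.embed(out_masked)) ** 2

    ny, nx = mtm.output_mask.shape
    y, x = grid_coords((ny, nx), mtm.pitch)
    flat_idx = mtm.masked_indices[target_index]
    ty, tx = y[flat_idx // nx], x[flat_idx % nx]

    disk_r = 2 * 0.51 * (mtm.wavelength * 1e-3) / mtm.na
    r = np.hypot(y[:, None] - ty, x[None, :] - tx)
    disk = r < disk_r
    total = float(intensity.sum())
    power_ratio = float(intensity[disk].sum() / total) if total > 0 else 0.0
    mean_core = float(intensity[mtm.output_mask].mean())
    peak = float(intensity.ravel()[flat_idx])
    enhancement = peak / mean_core if mean_core > 0 else np.inf
    fwhm = radial_fwhm(intensity, (ty, tx), mtm.pitch)
    return v, FocusMetrics(power_ratio, enhancement, fwhm), intensity


def phase_only_enhancement(matrix: np.ndarray, target_index: int,
                           n_reference: int = 64, seed: int = 0) -> float:
    """Focus enhancement of phase-only conjugation over the columns of
    ``matrix`` (output points × channels).

    Numerator: intensity at the target for the phase-conjugate input with
    unit amplitudes.  Denominator: mean intensity at the same target over
    ``n_reference`` seeded random-phase inputs — the diffuse speckle level
    an uncontrolled wavefront produces there.  For N independent channels
    the random-matrix expectation of this ratio is ≈ (π/4)·N.
    """
    row = matrix[target_index, :]
    n = len(row)
    v = np.exp(-1j * np.angle(row)) / np.sqrt(n)
    peak = np.abs(row @ v) ** 2
    rng = np.random.default_rng(seed)
    ref = 0.0
    for _ in range(n_reference):
        r = np.exp(1j * rng.uniform(0, 2 * np.pi, n)) / np.sqrt(n)
        ref += np.abs(row @ r) ** 2
    return float(peak / (ref / n_reference))


# --------------------------------------------------------------------------
# Persistence
# --------------------------------------------------------------------------

def save_measured_tm(path, mtm: MeasuredTM) -> None:
    import json
    meta = {
        "pitch": mtm.pitch, "wavelength": mtm.wavelength, "na": mtm.na,
        "input_grid_shape": list(mtm.input_grid_shape),
        "reference_removed": bool(mtm.reference_removed),
        "seed": mtm.seed,
    }
    np.savez(path, matrix=mtm.matrix, kept_inputs=mtm.kept_inputs,
             output_mask=mtm.output_mask,
             meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8))


def load_measured_tm(path) -> MeasuredTM:
    import json
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        return MeasuredTM(
            matrix=z["matrix"], kept_inputs=z["kept_inputs"],
            output_mask=z["output_mask"], pitch=float(meta["pitch"]),
            wavelength=float(meta["wavelength"]), na=float(meta["na"]),
            input_grid_shape=tuple(meta["input_grid_shape"]),
            reference_removed=bool(meta["reference_removed"]),
            seed=meta["seed"],
        )
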