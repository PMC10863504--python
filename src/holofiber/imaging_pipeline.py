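"""Raster-scan and corelet-scan fluorescence image formation.

In the multimode regime, imaging raster-scans phase-conjugate foci across
the core aperture at the working-distance plane; each scan point integrates
the focal intensity against the fluorophore density, and a Poisson photon
counter turns that signal into a pixel value.  In the multicore regime the
image has one value per corelet: each corelet is illuminated in spiral
order and the collected fluorescence is integrated the same way.  Because a
corelet's output *intensity* profile is immune to the phase perturbations
that deformation induces, the 61-pixel image is deformation-invariant —
the resilience property of the corelet channels.

Image-quality metrics (Michelson contrast, focal-spot FWHM) live here too.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .fiber_geometry import CoreletLattice, FiberSpec, aperture_mask, grid_coords
from .optics_core import ComplexField, corelet_mode, propagate
from .holography_calibration import FiberSystem, MeasuredTM, synthesize_focus
from .transport_model import TransmissionMatrix

__all__ = [
    "ScanPlan",
    "DetectorModel",
    "RasterImage",
    "raster_scan_image",
    "corelet_scan_image",
    "contrast_metric",
    "psf_fwhm",
]


# --------------------------------------------------------------------------
# Types
# --------------------------------------------------------------------------

@dataclass
class ScanPlan:
    """Raster-scan geometry: output grid, core mask and working distance.

    The full-scale plan is a 352×352 grid at 0.7 µm pitch masked to the
    232 µm core; desk-scale runs use coarser grids over the same physical
    extent.  Scan order is row-major over the masked points only.
    """

    grid_shape: tuple[int, int] = (352, 352)
    pitch: float = 0.7
    core_diameter: float = 232.0
    working_distance: float = 15.0

    def __post_init__(self) -> None:
        self.core_mask, self.n_points = aperture_mask(
            self.grid_shape, self.pitch, self.core_diameter)

    @property
    def scan_indices(self) -> np.ndarray:
        """Flattened indices of scanned (masked) grid points, row-major."""
        return np.flatnonzero(self.core_mask.ravel())


@dataclass(frozen=True)
class DetectorModel:
    """Poisson photon counter: counts ~ Poisson(photons·signal + dark).

    ``photons_per_unit_signal`` scales the integrated fluorescence signal
    to mean detected photons; ``dark_rate`` adds a constant mean count.
    ``photons_per_unit_signal = None`` disables noise (the expectation is
    returned).
    """

    photons_per_unit_signal: Optional[float] = None
    dark_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.photons_per_unit_signal is not None and self.photons_per_unit_signal < 0:
            raise ValueError("photons_per_unit_signal must be >= 0")
        if self.dark_rate < 0:
            raise ValueError("dark_rate must be >= 0")

    def detect(self, signal: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.photons_per_unit_signal is None:
            return np.asarray(signal, dtype=float) + self.dark_rate
        mean = self.photons_per_unit_signal * np.asarray(signal, dtype=float) + self.dark_rate
        return rng.poisson(np.maximum(mean, 0.0)).astype(float)


@dataclass
class RasterImage:
    """Scan image on the output grid plus validity mask and provenance.

    ``pixels`` holds values at scanned points; points outside the core
    mask are *invalid* (flagged by ``mask``), not zero — exporters fill
    them with 0 and record the mask so the round trip is exact.
    """

    pixels: np.ndarray
    mask: np.ndarray
    pitch: float
    metadata: dict = field(default_factory=dict)

    def valid_values(self) -> np.ndarray:
        return self.pixels[self.mask]


# --------------------------------------------------------------------------
# Multimode raster imaging
# --------------------------------------------------------------------------

def _focus_intensities_from_tm(mtm: MeasuredTM, system: Optional[FiberSystem],
                               plan: ScanPlan) -> np.ndarray:
    """(n_scan, n_pixels) focal intensity patterns for every masked point."""
    if not np.array_equal(mtm.output_mask, plan.core_mask):
        raise ValueError("TM output mask and scan plan mask differ")
    fwd = system.pixel_tm()[:, mtm.kept_inputs] if system is not None else None
    n = mtm.matrix.shape[0]
    out = np.empty((n, mtm.output_mask.size))
    for t in range(n):
        row = mtm.matrix[t, :]
        v = np.conj(row)
        v /= np.linalg.norm(v)
        if fwd is not None:
            e = fwd @ v
        else:
            e = mtm.embed(mtm.matrix @ v).ravel()
        out[t] = np.abs(e) ** 2
    return out


def raster_scan_image(
    tm: Union[MeasuredTM, np.ndarray],
    phantom,
    plan: ScanPlan,
    detector: Optional[DetectorModel] = None,
    system: Optional[FiberSystem] = None,
) -> RasterImage:
    """Scan-image a phantom in the multimode regime.

    For every masked scan point a phase-conjugate focus is synthesized from
    the measured TM; its intensity at the working-distance plane (where the
    TM was calibrated, hence where the phantom sits) is integrated against
    the fluorophore density, and the detector converts that signal into the
    pixel value:

        pixel = Poisson(photons · ∫ I_focus(r)·ρ(r) d²r + dark).

    ``tm`` may instead be a 2-D intensity kernel (an idealized
    shift-invariant point-spread function, e.g. a delta for perfect foci);
    the scan then slides that kernel across the masked points.  ``system``
    optionally supplies the ground-truth forward model so measured-TM
    inputs are replayed through the true transport.
    """
    dens = phantom.density
    if dens.shape != plan.core_mask.shape:
        raise ValueError("phantom grid does not match the scan grid")
    if abs(phantom.pitch - plan.pitch) > 1e-12:
        raise ValueError("phantom pitch does not match the scan pitch")

    scan_idx = plan.scan_indices
    signals = np.empty(len(scan_idx))

    if isinstance(tm, np.ndarray):
        # idealized shift-invariant PSF: slide the kernel over the density
        ker = np.asarray(tm, dtype=float)
        ky, kx = ker.shape
        if ky % 2 == 0 or kx % 2 == 0:
            raise ValueError("PSF kernel must have odd dimensions")
        ny, nx = dens.shape
        pad = np.zeros((ny + ky - 1, nx + kx - 1))
        pad[ky // 2:ky // 2 + ny, kx // 2:kx // 2 + nx] = dens
        for s, flat in enumerate(scan_idx):
            iy, ix = divmod(int(flat), nx)
            window = pad[iy:iy + ky, ix:ix + kx]
            signals[s] = float(np.sum(window * ker)) * plan.pitch**2
    else:
        inten = _focus_intensities_from_tm(tm, system, plan)
        masked_rows = np.flatnonzero(plan.core_mask.ravel())
        lookup = {int(f): i for i, f in enumerate(masked_rows)}
        flat_dens = dens.ravel()
        for s, flat in enumerate(scan_idx):
            signals[s] = float(inten[lookup[int(flat)]] @ flat_dens) * plan.pitch**2

    rng = np.random.default_rng(detector.seed if detector else 0)
    values = detector.detect(signals, rng) if detector else signals

    pixels = np.zeros(plan.core_mask.size)
    pixels[scan_idx] = values
    meta = {
        "detector_seed": detector.seed if detector else None,
        "phantom_seed": getattr(phantom, "seed", None),
        "working_distance": plan.working_distance,
    }
    return RasterImage(pixels=pixels.reshape(plan.core_mask.shape),
                       mask=plan.core_mask.copy(), pitch=plan.pitch,
                       metadata=meta)


# --------------------------------------------------------------------------
# Multicore corelet imaging
# --------------------------------------------------------------------------

def corelet_scan_image(
    tm: TransmissionMatrix,
    phantom,
    lattice: CoreletLattice,
    detector: Optional[DetectorModel] = None,
    spec: Optional[FiberSpec] = None,
    working_distance: float = 15.0,
) -> dict:
    """61-pixel image: illuminate corelets in spiral order, collect
    fluorescence.

    value_j = Poisson(photons · ∫ I_j(r)·ρ(r) d²r + dark) where I_j is the
    intensity at the working-distance plane when unit power enters corelet
    j.  The intensity is |Σ_m T[m,j]·ψ_m(r)|² — a diagonal phase
    perturbation of T (deformation) leaves every I_j unchanged, so the
    image is deformation-invariant.

    Returns ``{"values", "positions", "spiral_rank"}`` with values ordered
    by spiral rank.
    """
    if tm.regime != "multicore":
        raise ValueError("corelet imaging requires a multicore-regime TM")
    if lattice.spiral_rank is None:
        from .fiber_geometry import spiral_order
        lattice = spiral_order(lattice)
    n = len(lattice)
    if tm.n_inputs != n:
        raise ValueError("TM dimension does not match the lattice")

    dens = phantom.density
    ny, nx = dens.shape
    pitch = phantom.pitch
    w = tm.output_basis.get("waist")
    if w is None:
        if spec is None:
            raise ValueError("corelet waist unknown: pass spec or a TM built with one")
        w = corelet_mode(spec).waist

    # one propagated unit-power corelet profile, shifted per corelet
    half = 6 * w + working_distance  # generous support for the spread mode
    npx = int(np.ceil(2 * half / pitch)) | 1
    base = ComplexField(
        np.zeros((npx, npx), dtype=complex), pitch, 488.0)
    y0, x0 = grid_coords((npx, npx), pitch)
    r2 = y0[:, None] ** 2 + x0[None, :] ** 2
    base.amplitude[:] = np.sqrt(2 / (np.pi * w**2)) * np.exp(-r2 / w**2)
    if working_distance != 0:
        base = propagate(base, working_distance)
    prof = np.abs(base.amplitude) ** 2
    prof /= prof.sum() * pitch**2  # unit power at the plane

    y, x = grid_coords((ny, nx), pitch)
    order = np.argsort(lattice.spiral_rank)
    signals = np.empty(n)
    for rank, j in enumerate(order):
        col = tm.matrix[:, j]
        # diagonal-in-corelet transport: the only nonzero entries sit on
        # corelet channels; total intensity = Σ_m |T_mj|²·I_m(r) because the
        # corelet modes barely overlap spatially
        sig = 0.0
        for m in np.flatnonzero(np.abs(col) > 0):
            cx, cy = lattice.positions[m]
            iy = int(round((cy - y[0]) / pitch))
            ix = int(round((cx - x[0]) / pitch))
            sig += np.abs(col[m]) ** 2 * _shifted_integral(prof, dens, iy, ix)
        signals[rank] = sig * pitch**2

    rng = np.random.default_rng(detector.seed if detector else 0)
    values = detector.detect(signals, rng) if detector else signals
    return {
        "values": values,
        "positions": lattice.positions[order],
        "spiral_rank": np.arange(n),
    }


def _shifted_integral(kernel: np.ndarray, dens: np.ndarray,
                      iy: int, ix: int) -> float:
    """Σ kernel(centered at pixel (iy, ix)) · dens, with clipping."""
    ky, kx = kernel.shape
    ny, nx = dens.shape
    oy, ox = iy - ky // 2, ix - kx // 2
    y0, y1 = max(0, oy), min(ny, oy + ky)
    x0, x1 = max(0, ox), min(nx, ox + kx)
    if y0 >= y1 or x0 >= x1:
        return 0.0
    sub_d = dens[y0:y1, x0:x1]
    sub_k = kernel[y0 - oy:y1 - oy, x0 - ox:x1 - ox]
    return float(np.sum(sub_d * sub_k))


# --------------------------------------------------------------------------
# Metrics
# --------------------------------------------------------------------------

def contrast_metric(image: RasterImage, fg_mask: np.ndarray,
                    bg_mask: np.ndarray) -> float:
    """Michelson contrast (⟨fg⟩−⟨bg⟩)/(⟨fg⟩+⟨bg⟩) between two pixel sets.

    Masks must be disjoint, nonempty and lie inside the image's core mask.
    """
    fg = np.asarray(fg_mask, dtype=bool)
    bg = np.asarray(bg_mask, dtype=bool)
    if not fg.any() or not bg.any():
        raise ValueError("contrast masks must be nonempty")
    if np.any(fg & bg):
        raise ValueError("contrast masks must be disjoint")
    if np.any(fg & ~image.mask) or np.any(bg & ~image.mask):
        raise ValueError("contrast masks must lie inside the core mask")
    mf = float(image.pixels[fg].mean())
    mb = float(image.pixels[bg].mean())
    if mf + mb == 0:
        return 0.0
    return (mf - mb) / (mf + mb)


def psf_fwhm(mtm: MeasuredTM, plan: ScanPlan, target_index: int,
             system: Optional[FiberSystem] = None) -> float:
    """FWHM (µm) of the synthesized focus at one masked output point.

    The focus is generated by phase conjugation of the measured TM row and
    evaluated at the plane where the TM was calibrated (the working-
    distance plane), via the radially averaged intensity profile.
    """
    fwd = system.pixel_tm()[:, mtm.kept_inputs] if system is not None else None
    _, metrics, _ = synthesize_focus(mtm, target_index, forward=fwd)
    return metrics.fwhm
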