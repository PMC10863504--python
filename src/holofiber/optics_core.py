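"""Scalar fields, guided-mode bases and free-space propagation.

All optics in the simulator is scalar and weakly guiding: polarization is
handled as an integer multiplicity where mode counts are needed, never as a
vector field.  The universal currency is :class:`ComplexField`, a complex
amplitude sampled on a uniform axis-centered grid (µm pitch, row 0 at the
most negative y, see :mod:`holofiber.fiber_geometry`).

Guided modes of the step-index multimode waveguide are LP(l,m) modes from
the weakly-guiding characteristic equation; the single-mode corelets use
the Gaussian fundamental-mode approximation with the Marcuse waist.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.special import jv, kv

from .fiber_geometry import FiberSpec, grid_coords

__all__ = [
    "ComplexField",
    "GaussianMode",
    "ModeSet",
    "solve_lp_modes",
    "lp_cutoff_count",
    "corelet_mode",
    "gaussian_field",
    "overlap",
    "propagate",
    "marcuse_waist",
    "save_modeset",
    "load_modeset",
]

#: background (cladding) refractive index used to convert NA to core index
N_CLAD = 1.45


# --------------------------------------------------------------------------
# Fields
# --------------------------------------------------------------------------

@dataclass
class ComplexField:
    """Complex scalar amplitude on a uniform 2-D grid.

    ``amplitude[i, j]`` lives at physical position
    ``(x, y) = center + (x_j, y_i)`` with axis-centered grid coordinates.
    ``pitch`` in µm, ``wavelength`` in nm.
    """

    amplitude: np.ndarray
    pitch: float
    wavelength: float
    center: tuple[float, float] = (0.0, 0.0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.amplitude.shape

    @property
    def power(self) -> float:
        """Total power Σ|A|²·pitch²."""
        return float(np.sum(np.abs(self.amplitude) ** 2) * self.pitch**2)

    def normalized(self) -> "ComplexField":
        """Unit-power copy (power = 1 within 1e-12 relative)."""
        p = self.power
        if p <= 0:
            raise ValueError("cannot normalize a zero-power field")
        return replace(self, amplitude=self.amplitude / np.sqrt(p))

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical (y, x) coordinate axes including the field center."""
        y, x = grid_coords(self.shape, self.pitch)
        return y + self.center[1], x + self.center[0]


@dataclass(frozen=True)
class GaussianMode:
    """Fundamental corelet mode: field ∝ exp(−r²/w²), unit power.

    ``waist`` is the 1/e field radius w (µm); intensity falls as
    exp(−2r²/w²).
    """

    waist: float
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.waist <= 0:
            raise ValueError("waist must be > 0")

    def field(self, grid_shape: tuple[int, int], pitch: float,
              wavelength: float = 488.0) -> ComplexField:
        """Sample the normalized mode on an axis-centered grid."""
        y, x = grid_coords(grid_shape, pitch)
        r2 = (y[:, None] - self.center[1]) ** 2 + (x[None, :] - self.center[0]) ** 2
        amp = np.sqrt(2.0 / (np.pi * self.waist**2)) * np.exp(-r2 / self.waist**2)
        return ComplexField(amp.astype(complex), pitch, wavelength)


def gaussian_field(waist: float, grid_shape: tuple[int, int], pitch: float,
                   wavelength: float = 488.0,
                   center: tuple[float, float] = (0.0, 0.0)) -> ComplexField:
    """Convenience: sampled unit-power Gaussian."""
    return GaussianMode(waist, center).field(grid_shape, pitch, wavelength)


# --------------------------------------------------------------------------
# LP mode solver
# --------------------------------------------------------------------------

def _lp_dispersion(u: np.ndarray, v: float, l: int) -> np.ndarray:
    """Weakly-guiding characteristic function F(u); roots are guided LP(l,m).

    F(u) = u·J_{l+1}(u)/J_l(u) − w·K_{l+1}(w)/K_l(w),  w = sqrt(V²−u²).
    """
    w = np.sqrt(np.maximum(v**2 - u**2, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        lhs = u * jv(l + 1, u) / jv(l, u)
        rhs = w * kv(l + 1, w) / np.where(w > 0, kv(l, w), 1.0)
        rhs = np.where(w > 0, rhs, 0.0)
    return lhs - rhs


def _lp_roots(v: float, l: int, n_scan: int = 4000) -> list[float]:
    """Guided-mode radial parameters u for azimuthal order l, by bisection."""
    if v <= 0:
        return []
    from scipy.optimize import brentq

    us = np.linspace(1e-9, v * (1 - 1e-12), n_scan)
    f = _lp_dispersion(us, v, l)
    # mask the poles of J_l (sign flips there are not roots)
    jl = jv(l, us)
    roots: list[float] = []
    for a, b, fa, fb, ja, jb in zip(us[:-1], us[1:], f[:-1], f[1:], jl[:-1], jl[1:]):
        if not (np.isfinite(fa) and np.isfinite(fb)):
            continue
        if fa == 0.0:
            roots.append(float(a))
            continue
        if fa * fb < 0 and ja * jb > 0:  # genuine crossing, not a J_l pole
            try:
                r = brentq(lambda u: float(_lp_dispersion(np.array([u]), v, l)[0]), a, b,
                           xtol=1e-12, rtol=1e-14)
            except ValueError as exc:  # pragma: no cover - bracketing guard
                raise RuntimeError(f"root bracketing failed on LP({l}, m) branch") from exc
            roots.append(float(r))
    return sorted(roots)


def lp_cutoff_count(v: float) -> int:
    """Number of scalar LP modes guided at normalized frequency V.

    Counts each (l, m) branch once for l = 0 and twice (cos/sin) for l > 0,
    by direct root counting of the characteristic equation.
    """
    total = 0
    l = 0
    while True:
        roots = _lp_roots(v, l)
        if not roots:
            if l > 0:
                break
            l += 1
            continue
        total += len(roots) * (1 if l == 0 else 2)
        l += 1
    return total


@dataclass
class ModeSet:
    """Orthonormal guided-mode basis sampled on a grid.

    ``fields`` has shape (n_modes, ny, nx); ``beta`` holds propagation
    constants in rad/µm *measured as offsets from the cladding plane-wave
    constant* (β − k·n_clad, in (0, k·NA²/2n] for guided modes) to avoid
    catastrophic cancellation at large k.  ``labels`` are
    ``"LP(l,m)cos"`` / ``"LP(l,m)sin"`` or corelet indices.

    The sampled modes are Löwdin-orthogonalized, so the discrete inner
    product ⟨i|j⟩ = Σ conj(f_i)·f_j·pitch² equals δ_ij to machine precision.
    """

    fields: np.ndarray
    beta: np.ndarray
    labels: list[str]
    pitch: float
    wavelength: float
    truncated: bool = False

    def __len__(self) -> int:
        return len(self.fields)

    @property
    def shape(self) -> tuple[int, int]:
        return self.fields.shape[1:]

    def field(self, i: int) -> ComplexField:
        return ComplexField(self.fields[i].copy(), self.pitch, self.wavelength)

    def matrix(self) -> np.ndarray:
        """(n_pixels, n_modes) synthesis matrix M; coefficients → field.

        Columns are the sampled modes flattened row-major and scaled by
        pitch so that M†M = I (discrete orthonormality absorbed).
        """
        n = len(self)
        return self.fields.reshape(n, -1).T * self.pitch

    def project(self, f: ComplexField) -> np.ndarray:
        """Mode coefficients of a field: a_m = ⟨mode_m | f⟩."""
        if abs(f.pitch - self.pitch) > 1e-12:
            raise ValueError("pitch mismatch")
        flat = f.amplitude.reshape(-1)
        return (self.matrix().conj().T @ flat) * self.pitch

    def synthesize(self, coeffs: np.ndarray) -> ComplexField:
        """Field from mode coefficients."""
        flat = (self.matrix() @ coeffs) / self.pitch
        return ComplexField(flat.reshape(self.shape), self.pitch, self.wavelength)


def _lowdin(fields: np.ndarray, pitch: float) -> np.ndarray:
    """Symmetric (Löwdin) orthogonalization of sampled modes.

    Minimally perturbs the set to make the discrete Gram matrix the
    identity; exact LP modes on an adequate grid are already ~1e-3
    orthogonal, so the correction is small.
    """
    n = fields.shape[0]
    flat = fields.reshape(n, -1) * pitch
    g = flat @ flat.conj().T
    vals, vecs = np.linalg.eigh(g)
    if np.min(vals) < 1e-10:
        raise RuntimeError("sampled modes are numerically degenerate; refine the grid")
    g_inv_sqrt = (vecs * (1.0 / np.sqrt(vals))) @ vecs.conj().T
    out = (g_inv_sqrt @ flat) / pitch
    return out.reshape(fields.shape)


def solve_lp_modes(
    core_diameter: float,
    na: float,
    wavelength: float,
    grid_shape: tuple[int, int] = (256, 256),
    pitch: Optional[float] = None,
    max_modes: int = 2000,
) -> ModeSet:
    """All guided LP(l,m) scalar modes of a step-index core.

    ``core_diameter`` µm, ``wavelength`` nm.  Degenerate l>0 branches are
    returned as cos/sin orientation pairs.  Modes are sorted by decreasing
    propagation constant (fundamental first), sampled on an axis-centered
    grid (default pitch spans 2.2× the core diameter), then Löwdin
    orthogonalized.  ``truncated`` is set when ``max_modes`` cuts the set.
    """
    v = np.pi * core_diameter * na / (wavelength * 1e-3)
    a = core_diameter / 2
    k0 = 2 * np.pi / (wavelength * 1e-3)

    if pitch is None:
        pitch = 2.2 * core_diameter / min(grid_shape)

    y, x = grid_coords(grid_shape, pitch)
    r = np.hypot(y[:, None], x[None, :])
    phi = np.arctan2(y[:, None], x[None, :])

    entries: list[tuple[float, str, np.ndarray]] = []  # (beta_offset, label, field)
    l = 0
    while True:
        roots = _lp_roots(v, l)
        if not roots:
            if l == 0:
                l += 1
                continue
            break
        for m, u in enumerate(roots, start=1):
            w = np.sqrt(max(v**2 - u**2, 0.0))
            # β offset from the cladding constant, exact in weak guidance:
            # β² = k²n_core² − (u/a)², n_core² = n_clad² + NA²
            beta = np.sqrt((k0 * N_CLAD) ** 2 + (k0 * na) ** 2 - (u / a) ** 2)
            beta_off = float(beta - k0 * N_CLAD)
            inside = r < a
            with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
                core_part = jv(l, u * np.minimum(r, a) / a) / jv(l, u)
                if w > 0:
                    clad_part = kv(l, np.maximum(w * r / a, 1e-12)) / kv(l, w)
                    clad_part = np.nan_to_num(clad_part, nan=0.0, posinf=0.0)
                else:
                    clad_part = np.zeros_like(r)
            radial = np.where(inside, core_part, clad_part)
            if l == 0:
                entries.append((beta_off, f"LP(0,{m})", radial.astype(complex)))
            else:
                entries.append((beta_off, f"LP({l},{m})cos", (radial * np.cos(l * phi)).astype(complex)))
                entries.append((beta_off, f"LP({l},{m})sin", (radial * np.sin(l * phi)).astype(complex)))
        l += 1

    entries.sort(key=lambda e: -e[0])
    truncated = len(entries) > max_modes
    entries = entries[:max_modes]

    fields = np.stack([e[2] for e in entries])
    # normalize each before the collective orthogonalization
    norms = np.sqrt(np.sum(np.abs(fields) ** 2, axis=(1, 2)) * pitch**2)
    fields /= norms[:, None, None]
    fields = _lowdin(fields, pitch)

    return ModeSet(
        fields=fields,
        beta=np.array([e[0] for e in entries]),
        labels=[e[1] for e in entries],
        pitch=float(pitch),
        wavelength=float(wavelength),
        truncated=truncated,
    )


# --------------------------------------------------------------------------
# Corelet fundamental mode
# --------------------------------------------------------------------------

def marcuse_waist(core_radius: float, v: float) -> float:
    """Marcuse Gaussian-waist approximation of the LP01 mode.

    w = a·(0.65 + 1.619·V^(−3/2) + 2.879·V^(−6)).
    """
    return core_radius * (0.65 + 1.619 * v**-1.5 + 2.879 * v**-6)


def corelet_mode(spec: FiberSpec, center: tuple[float, float] = (0.0, 0.0)) -> GaussianMode:
    """Gaussian fundamental-mode approximation for one single-mode corelet.

    Raises if the corelet V-number exceeds the LP11 cutoff 2.405 (the
    corelet would not be single-mode, and the Gaussian model would not
    apply).
    """
    v = spec.v_corelet
    if not (0 < v <= 2.405):
        raise ValueError(
            f"corelet V = {v:.3f} is not in the single-mode range (0, 2.405]"
        )
    return GaussianMode(waist=marcuse_waist(spec.corelet_core_diameter / 2, v),
                        center=tuple(center))


# --------------------------------------------------------------------------
# Overlap and propagation
# --------------------------------------------------------------------------

def overlap(f: ComplexField, g: ComplexField) -> complex:
    """Discrete inner product ⟨f|g⟩ = Σ conj(f)·g·pitch².

    For unit-power inputs |⟨f|g⟩|² is the coupled power fraction.  Fields
    must share pitch, wavelength, shape and center.
    """
    if abs(f.pitch - g.pitch) > 1e-12:
        raise ValueError("pitch mismatch")
    if abs(f.wavelength - g.wavelength) > 1e-9:
        raise ValueError("wavelength mismatch")
    if f.shape != g.shape or not np.allclose(f.center, g.center):
        raise ValueError("fields must share grid geometry")
    return complex(np.vdot(f.amplitude, g.amplitude) * f.pitch**2)


def propagate(field: ComplexField, distance: float, n_medium: float = 1.0,
              guard_factor: int = 2) -> ComplexField:
    """Angular-spectrum propagation over ``distance`` (µm).

    The field is zero-padded by ``guard_factor`` against wrap-around,
    transformed, multiplied by exp(i·k_z·z) with
    k_z = sqrt(k² − k_x² − k_y²) (evanescent components decay), and
    cropped back.  Power is conserved to 1e-6 relative for band-limited
    fields; ``distance`` may be negative (back-propagation).
    """
    if distance == 0:
        return replace(field, amplitude=field.amplitude.copy())
    ny, nx = field.shape
    py, px = ny * guard_factor, nx * guard_factor
    pad = np.zeros((py, px), dtype=complex)
    oy, ox = (py - ny) // 2, (px - nx) // 2
    pad[oy:oy + ny, ox:ox + nx] = field.amplitude

    k = 2 * np.pi * n_medium / (field.wavelength * 1e-3)  # rad/µm
    fy = np.fft.fftfreq(py, d=field.pitch) * 2 * np.pi
    fx = np.fft.fftfreq(px, d=field.pitch) * 2 * np.pi
    kz2 = k**2 - fy[:, None] ** 2 - fx[None, :] ** 2
    kz = np.sqrt(np.maximum(kz2, 0.0) + 0j)
    h = np.where(
        kz2 >= 0,
        np.exp(1j * kz * distance),
        np.exp(-np.sqrt(np.maximum(-kz2, 0.0)) * abs(distance)),
    )
    out = np.fft.ifft2(np.fft.fft2(pad) * h)
    return replace(field, amplitude=out[oy:oy + ny, ox:ox + nx].copy())


# --------------------------------------------------------------------------
# Persistence (binary container: .npz with JSON metadata)
# --------------------------------------------------------------------------

def save_modeset(path, modes: ModeSet) -> None:
    meta = {
        "labels": modes.labels,
        "pitch": modes.pitch,
        "wavelength": modes.wavelength,
        "truncated": bool(modes.truncated),
    }
    np.savez(path, fields=modes.fields, beta=modes.beta,
             meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8))


def load_modeset(path) -> ModeSet:
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        return ModeSet(
            fields=z["fields"],
            beta=z["beta"],
            labels=list(meta["labels"]),
            pitch=float(meta["pitch"]),
            wavelength=float(meta["wavelength"]),
            truncated=bool(meta["truncated"]),
        )
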