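"""Ground-truth light transport through single and mated fibers.

Two transport regimes are modeled:

* **multimode** — the step-index pulp waveguide.  Transport is a unitary
  matrix on the guided-mode basis, ``T = U(coupling, seed) ·
  diag(e^{iβL})``, where ``U`` interpolates between the identity (no mode
  coupling) and a Haar-like random unitary (fully mixed).  Deformation acts
  as a further random unitary whose distance from the identity grows with a
  strength parameter — bending scrambles the field, and a transmission
  matrix calibrated before the bend loses focusing fidelity.

* **multicore** — the hexagonal lattice of single-mode corelets.  Transport
  is diagonal in the corelet basis (one phase per corelet); deformation
  perturbs only those phases, so per-channel *intensities* are exactly
  preserved.  This is the deformation-resilience contract of the corelet
  channels.

The module also models mating two fiber segments inside a ferrule sleeve:
a coupling matrix of Gaussian fundamental-mode overlaps under lateral
offset, rotation and an axial air gap, plus the rotational-alignment search
and the marker-image similarity check used in the reconnection protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Optional

import numpy as np
from scipy.linalg import expm, logm, qr

from .fiber_geometry import CoreletLattice, FiberSpec, FIBER_PRESETS
from .optics_core import ComplexField, ModeSet, corelet_mode, propagate

__all__ = [
    "TransmissionMatrix",
    "DeformationState",
    "MatingState",
    "random_unitary",
    "build_mm_tm",
    "build_mc_tm",
    "apply_deformation",
    "gaussian_coupling",
    "mating_coupling_matrix",
    "mate_fibers",
    "mate_multimode",
    "corelet_power_fractions",
    "rotation_search",
    "marker_similarity",
]


# --------------------------------------------------------------------------
# Types
# --------------------------------------------------------------------------

@dataclass
class TransmissionMatrix:
    """Complex linear map from input to output basis coefficients.

    ``regime`` is ``"multimode"`` (mode basis, unitary on the guided
    subspace for a lossless fiber) or ``"multicore"`` (corelet basis,
    diagonal for a single fiber).  ``input_basis``/``output_basis`` carry
    metadata dictionaries (e.g. ``{"kind": "lp_modes", "n": 20}`` or
    ``{"kind": "corelets", "n": 61, "waist": 1.17}``).
    """

    matrix: np.ndarray
    input_basis: dict
    output_basis: dict
    regime: str
    seed: Optional[int] = None

    @property
    def n_outputs(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.matrix.shape[1]


@dataclass(frozen=True)
class DeformationState:
    """Strength ≥ 0 of a seeded fiber deformation; 0 means undeformed."""

    strength: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strength < 0:
            raise ValueError("deformation strength must be >= 0")


@dataclass(frozen=True)
class MatingState:
    """Misalignment of two mated ferrules.

    ``lateral_offset`` (µm) is bounded by the ferrule bore clearance
    (280±3 µm bore around a 278 µm fiber → 3 µm default); ``rotation`` in
    degrees, stored modulo 360; ``axial_gap`` (µm) between the end faces.
    """

    lateral_offset: tuple[float, float] = (0.0, 0.0)
    rotation: float = 0.0
    axial_gap: float = 0.5
    bore_clearance: float = 3.0

    def __post_init__(self) -> None:
        if np.hypot(*self.lateral_offset) > self.bore_clearance + 1e-12:
            raise ValueError("lateral offset exceeds the ferrule bore clearance")
        if self.axial_gap < 0:
            raise ValueError("axial gap must be >= 0")
        object.__setattr__(self, "rotation", float(self.rotation) % 360.0)


# --------------------------------------------------------------------------
# Random unitaries
# --------------------------------------------------------------------------

def random_unitary(n: int, seed: int) -> np.ndarray:
    """Haar-like n×n unitary: QR of a seeded complex Gaussian matrix with
    the phases of R's diagonal folded into Q."""
    rng = np.random.default_rng(seed)
    g = rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n))
    q, r = qr(g)
    d = np.diagonal(r)
    return q * (d / np.abs(d))


def _interpolated_unitary(n: int, seed: int, t: float) -> np.ndarray:
    """U(t) = expm(t·logm(Q)): identity at t=0, the seeded unitary at t=1."""
    if t == 0:
        return np.eye(n, dtype=complex)
    q = random_unitary(n, seed)
    if t == 1:
        return q
    h = logm(q)  # principal log of a unitary: skew-Hermitian
    h = (h - h.conj().T) / 2  # scrub numerical Hermitian residue
    return expm(t * h)


# --------------------------------------------------------------------------
# Single-fiber transmission matrices
# --------------------------------------------------------------------------

def build_mm_tm(modes: ModeSet, length: float, seed: int,
                coupling: float = 1.0) -> TransmissionMatrix:
    """Multimode-regime TM on the guided-mode basis.

    ``T = U(coupling, seed) · diag(e^{iβ_m L})`` with L in µm and β the
    per-mode propagation-constant offsets.  ``coupling`` interpolates the
    mixing unitary from the identity (0) to Haar-like (1); T is unitary to
    1e-8 for any value.
    """
    n = len(modes)
    if n == 0:
        raise ValueError("empty mode set")
    if not (0 <= coupling <= 1):
        raise ValueError("coupling must lie in [0, 1]")
    u = _interpolated_unitary(n, seed, coupling)
    t = u @ np.diag(np.exp(1j * modes.beta * length))
    return TransmissionMatrix(
        matrix=t,
        input_basis={"kind": "lp_modes", "n": n},
        output_basis={"kind": "lp_modes", "n": n},
        regime="multimode",
        seed=seed,
    )


def build_mc_tm(lattice: CoreletLattice, seed: int,
                spec: Optional[FiberSpec] = None,
                crosstalk: float = 0.0) -> TransmissionMatrix:
    """Multicore-regime TM: diagonal over corelet channels, seeded uniform
    phases, unit moduli.  ``spec`` (optional) records the corelet waist in
    the basis metadata for downstream power accounting.

    ``crosstalk`` (amplitude fraction, default 0 — the regime definition)
    adds seeded nearest-neighbour leakage for robustness experiments;
    columns are renormalized to unit power.
    """
    n = len(lattice)
    if n == 0:
        raise ValueError("empty lattice")
    if not (0 <= crosstalk < 1):
        raise ValueError("crosstalk must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    phases = rng.uniform(0, 2 * np.pi, n)
    m = np.diag(np.exp(1j * phases))
    if crosstalk > 0:
        p = lattice.positions
        d = np.hypot(p[:, None, 0] - p[None, :, 0], p[:, None, 1] - p[None, :, 1])
        neighbours = (d > 0) & (d < 1.5 * lattice.pitch)
        leak = crosstalk * np.exp(1j * rng.uniform(0, 2 * np.pi, (n, n)))
        m = m + np.where(neighbours, leak, 0.0)
        m /= np.linalg.norm(m, axis=0, keepdims=True)
    basis = {"kind": "corelets", "n": n}
    if spec is not None:
        basis["waist"] = corelet_mode(spec).waist
    return TransmissionMatrix(
        matrix=m,
        input_basis=dict(basis),
        output_basis=dict(basis),
        regime="multicore",
        seed=seed,
    )


def apply_deformation(tm: TransmissionMatrix, state: DeformationState) -> TransmissionMatrix:
    """Transport after a seeded deformation of given strength.

    Multimode: right-multiplication by exp(strength·K) with K a seeded
    skew-Hermitian generator of unit spectral norm — the distance from the
    identity grows monotonically in strength (up to saturation at π).
    Multicore: the diagonal phases are perturbed, moduli untouched to
    machine precision — per-channel power is exactly preserved.
    """
    if state.strength == 0:
        return replace(tm, matrix=tm.matrix.copy())
    rng = np.random.default_rng(state.seed)
    if tm.regime == "multicore":
        n = tm.n_inputs
        dphi = rng.standard_normal(n)
        return replace(tm, matrix=tm.matrix * np.exp(1j * state.strength * dphi)[:, None])
    n = tm.n_inputs
    a = rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n))
    k = (a - a.conj().T) / 2
    k /= np.linalg.norm(k, 2)
    return replace(tm, matrix=tm.matrix @ expm(state.strength * k))


# --------------------------------------------------------------------------
# Fiber mating (multicore regime)
# --------------------------------------------------------------------------

def gaussian_coupling(d: float, w1: float, w2: float, gap: float,
                      wavelength: float) -> complex:
    """Closed-form coupling of two displaced Gaussian fundamental modes.

    Mode 1 (waist ``w1`` µm) propagates across an axial ``gap`` (µm, paraxial
    complex-beam-parameter form) and is projected on mode 2 (waist ``w2``)
    displaced laterally by ``d`` µm.  ``wavelength`` in nm.  For ``w1 == w2``
    and ``gap == 0`` this reduces to ``exp(−d²/(2w²))``, i.e. coupled power
    ``exp(−d²/w²)``.
    """
    lam = wavelength * 1e-3  # µm
    z_r = np.pi * w1**2 / lam
    zeta = gap / z_r
    alpha = 1.0 / w2**2
    beta = 1.0 / (w1**2 * (1 + 1j * zeta))
    pref = (2.0 / (np.pi * w1 * w2)) / (1 + 1j * zeta) * np.pi / (alpha + beta)
    piston = np.exp(1j * 2 * np.pi / lam * gap)  # plane-wave phase across the gap
    return complex(pref * piston * np.exp(-(alpha * beta / (alpha + beta)) * d**2))


def mating_coupling_matrix(lattice: CoreletLattice, spec: FiberSpec,
                           state: MatingState,
                           truncate: float = 1e-4) -> np.ndarray:
    """Corelet-to-corelet coupling matrix C of a ferrule junction.

    Fiber-1 corelet positions are rotated by ``state.rotation`` and shifted
    by ``state.lateral_offset``; entry C[j, k] is the Gaussian-mode overlap
    of fiber-2 corelet j with the (gap-propagated) fiber-1 corelet k.
    Entries below ``truncate`` in magnitude are zeroed.
    """
    w = corelet_mode(spec).waist
    p2 = lattice.positions
    p1 = lattice.rotated(state.rotation).positions + np.asarray(state.lateral_offset)
    d = np.hypot(p2[:, None, 0] - p1[None, :, 0], p2[:, None, 1] - p1[None, :, 1])
    # radial closed form evaluated on the unique distances actually needed
    c = np.zeros(d.shape, dtype=complex)
    near = d < 8.0 * w  # beyond this the coupling is < 1e-9 anyway
    vals = np.array([gaussian_coupling(x, w, w, state.axial_gap, spec.wavelength)
                     for x in d[near]])
    c[near] = vals
    c[np.abs(c) < truncate] = 0.0
    return c


def mate_fibers(tm1: TransmissionMatrix, tm2: TransmissionMatrix,
                lattice: CoreletLattice, spec: FiberSpec,
                state: MatingState) -> TransmissionMatrix:
    """Transport through fiber 1 → ferrule junction → fiber 2.

    ``T = T₂ · C(state) · T₁`` with C from
    :func:`mating_coupling_matrix`.  Both TMs must be multicore over the
    same lattice.
    """
    if tm1.regime != "multicore" or tm2.regime != "multicore":
        raise ValueError("mate_fibers requires two multicore-regime TMs")
    if tm1.n_inputs != len(lattice) or tm2.n_inputs != len(lattice):
        raise ValueError("TM dimensions do not match the lattice")
    c = mating_coupling_matrix(lattice, spec, state)
    basis = {"kind": "corelets", "n": len(lattice), "waist": corelet_mode(spec).waist}
    return TransmissionMatrix(
        matrix=tm2.matrix @ c @ tm1.matrix,
        input_basis=dict(basis),
        output_basis=dict(basis),
        regime="multicore",
        seed=tm1.seed,
    )


def mate_multimode(tm1: TransmissionMatrix, tm2: TransmissionMatrix,
                   modes: ModeSet, state: MatingState) -> TransmissionMatrix:
    """Transport of two mated fibers in the multimode regime.

    The junction coupling on the guided-mode basis is
    ``C = M₂† · D · M₁`` where D shifts fiber-1 mode fields laterally
    (exact Fourier shift), rotates them about the axis, and propagates them
    across the air gap.  C is sub-unitary: power radiated past the guided
    subspace of fiber 2 is lost, which is what degrades the focusing power
    ratio of a connected fiber relative to a single one.
    """
    if tm1.regime != "multimode" or tm2.regime != "multimode":
        raise ValueError("mate_multimode requires two multimode-regime TMs")
    n = len(modes)
    fields = modes.fields
    out = np.empty_like(fields)
    for i in range(n):
        f = ComplexField(fields[i].copy(), modes.pitch, modes.wavelength)
        if state.axial_gap > 0:
            f = propagate(f, state.axial_gap)
        amp = f.amplitude
        if state.rotation % 360.0 != 0.0:
            from scipy.ndimage import rotate as nd_rotate
            amp = (nd_rotate(amp.real, -state.rotation, reshape=False, order=3)
                   + 1j * nd_rotate(amp.imag, -state.rotation, reshape=False, order=3))
        dx, dy = state.lateral_offset
        if dx != 0.0 or dy != 0.0:
            ny, nx = amp.shape
            fy = np.fft.fftfreq(ny, d=modes.pitch)
            fx = np.fft.fftfreq(nx, d=modes.pitch)
            phase = np.exp(-2j * np.pi * (fy[:, None] * dy + fx[None, :] * dx))
            amp = np.fft.ifft2(np.fft.fft2(amp) * phase)
        out[i] = amp
    flat2 = fields.reshape(n, -1) * modes.pitch
    flat1 = out.reshape(n, -1) * modes.pitch
    c = flat2.conj() @ flat1.T
    return TransmissionMatrix(
        matrix=tm2.matrix @ c @ tm1.matrix,
        input_basis=dict(tm1.input_basis),
        output_basis=dict(tm2.output_basis),
        regime="multimode",
        seed=tm1.seed,
    )


# --------------------------------------------------------------------------
# Power-fraction quality control
# --------------------------------------------------------------------------

def corelet_power_fractions(system: TransmissionMatrix, lattice: CoreletLattice,
                            spec: Optional[FiberSpec] = None,
                            disk_radius: Optional[float] = None,
                            ) -> tuple[np.ndarray, float]:
    """Per-corelet preserved-power fractions and their mean.

    Unit power is launched into corelet j; ``fraction_j`` is the power
    arriving inside corelet j's disk at the output facet, relative to the
    launched power.  (Light lost at a junction continues diffusely in the
    multimode pulp, so normalizing by the launched power mirrors the
    facet-total normalization of the experimental measurement.)  The disk
    radius defaults to half the lattice pitch; the in-disk captured power
    of a Gaussian mode of waist w is ``1 − exp(−2ρ²/w²)``.
    """
    if system.regime != "multicore":
        raise ValueError("corelet power fractions are defined on multicore transport")
    n = len(lattice)
    if system.n_inputs != n:
        raise ValueError("system dimension does not match the lattice")
    if spec is None and "waist" not in system.output_basis:
        spec = FIBER_PRESETS["m3cf"]
    w = system.output_basis.get("waist") or corelet_mode(spec).waist
    rho = disk_radius if disk_radius is not None else lattice.pitch / 2
    capture = 1.0 - np.exp(-2.0 * rho**2 / w**2)
    t = system.matrix
    fractions = np.abs(np.diagonal(t)) ** 2 * capture
    return fractions, float(fractions.mean())


# --------------------------------------------------------------------------
# Rotational alignment
# --------------------------------------------------------------------------

def _golden_section(f: Callable[[float], float], a: float, b: float,
                    tol: float = 1e-4) -> float:
    """Maximize f on [a, b] by golden-section search."""
    invphi = (np.sqrt(5.0) - 1) / 2
    c, d = b - invphi * (b - a), a + invphi * (b - a)
    fc, fd = f(c), f(d)
    while (b - a) > tol:
        if fc < fd:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
        else:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
    return (a + b) / 2


def rotation_search(tm1: TransmissionMatrix, tm2: TransmissionMatrix,
                    lattice: CoreletLattice, spec: FiberSpec,
                    offset: tuple[float, float] = (0.0, 0.0),
                    gap: float = 0.5,
                    objective: Optional[Callable[[np.ndarray], float]] = None,
                    true_state: Optional[MatingState] = None,
                    coarse_step: float = 0.5,
                    ) -> tuple[float, list[tuple[float, float]]]:
    """Recover the ferrule rotation that maximizes corelet-to-corelet coupling.

    ``true_state`` describes the hidden physical misalignment; a candidate
    ferrule angle φ counter-rotates fiber 1, leaving an effective relative
    rotation ``true − φ``.  The default objective is the total coupled
    power Σ|C|².  Coarse grid over [0°, 60°) (six-fold lattice symmetry)
    with ``coarse_step``, then golden-section refinement.  Returns the
    maximizing angle modulo 60° and the coarse-grid trace.
    """
    if len(lattice) == 0:
        raise ValueError("rotation search undefined on an empty lattice")
    if true_state is None:
        true_state = MatingState(lateral_offset=offset, rotation=0.0, axial_gap=gap)
    if objective is None:
        objective = lambda c: float(np.sum(np.abs(c) ** 2))

    def measure(phi: float) -> float:
        eff = MatingState(
            lateral_offset=true_state.lateral_offset,
            rotation=(true_state.rotation - phi) % 360.0,
            axial_gap=true_state.axial_gap,
            bore_clearance=true_state.bore_clearance,
        )
        return objective(mating_coupling_matrix(lattice, spec, eff))

    angles = np.arange(0.0, 60.0, coarse_step)
    trace = [(float(a), measure(float(a))) for a in angles]
    vals = np.array([v for _, v in trace])
    if np.ptp(vals) < 1e-15:
        raise RuntimeError("flat rotation objective: no corelets couple at any angle")
    best = angles[int(np.argmax(vals))]
    refined = _golden_section(measure, best - coarse_step, best + coarse_step)
    # guard: refinement must not fall below the best coarse sample
    if measure(refined) < vals.max():
        refined = float(best)
    return float(refined % 60.0), trace


# --------------------------------------------------------------------------
# Marker-image similarity
# --------------------------------------------------------------------------

def marker_similarity(image_a: np.ndarray, image_b: np.ndarray) -> float:
    """Zero-normalized cross-correlation at zero lag, in [−1, 1].

    1.0 for images identical up to an affine intensity change; raises on a
    constant image (undefined normalization).
    """
    a = np.asarray(image_a, dtype=float).ravel()
    b = np.asarray(image_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("marker images must have identical shapes")
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("similarity undefined for a constant image")
    return float(np.dot(a, b) / (na * nb))
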