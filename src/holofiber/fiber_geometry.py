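"""Fiber specifications, corelet lattices, aperture masks, and mode counting.

The fibers modeled here have a cascaded refractive-index structure: an outer
cladding encloses a "pulp" region that acts as the core of a step-index
multimode waveguide, and embedded in the pulp sits a hexagonal lattice of
small single-mode cores ("corelets").  The multimode waveguide supports
high-resolution holographic focusing; the corelets provide a sparse,
deformation-resilient set of channels.

Coordinate conventions (used throughout the package):

* physical coordinates are axis-centered, in micrometres, x to the right and
  y up;
* sampled fields are row-major 2-D arrays with row 0 at the most negative y;
* one lattice axis of the hexagonal corelet arrangement is aligned with +x.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "FiberSpec",
    "CoreletLattice",
    "FIBER_PRESETS",
    "hex_lattice",
    "spiral_order",
    "aperture_mask",
    "grid_coords",
    "v_number",
    "estimate_mode_count",
    "centered_hex_number",
]


# --------------------------------------------------------------------------
# Specifications
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FiberSpec:
    """Geometry and numerical-aperture constants of one fiber design.

    Lengths are in micrometres except ``wavelength`` (nanometres).  The
    multimode waveguide is formed by ``pulp_diameter`` (its core) inside
    ``cladding_diameter``; ``na_multimode`` is the NA of that step.  The
    corelet lattice is a centered hexagonal arrangement of
    ``3·rings·(rings+1)+1`` single-mode cores.
    """

    cladding_diameter: float
    pulp_diameter: float
    na_multimode: float
    corelet_rings: int
    corelet_pitch: float
    corelet_core_diameter: float
    corelet_na: float
    wavelength: float = 488.0
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 < self.pulp_diameter < self.cladding_diameter):
            raise ValueError(
                "pulp_diameter must be positive and smaller than cladding_diameter"
            )
        for name in ("corelet_pitch", "corelet_core_diameter", "wavelength"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("na_multimode", "corelet_na"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.corelet_rings < 0:
            raise ValueError("corelet_rings must be >= 0")
        # outermost corelet center + core radius must fit in the pulp circle
        extent = self.corelet_rings * self.corelet_pitch + self.corelet_core_diameter / 2
        if extent > self.pulp_diameter / 2:
            raise ValueError("corelet lattice does not fit inside the pulp circle")

    @property
    def n_corelets(self) -> int:
        return centered_hex_number(self.corelet_rings)

    @property
    def v_multimode(self) -> float:
        """V-number of the multimode (pulp) waveguide."""
        return v_number(self.pulp_diameter, self.na_multimode, self.wavelength)

    @property
    def v_corelet(self) -> float:
        return v_number(self.corelet_core_diameter, self.corelet_na, self.wavelength)


#: Shipped fiber presets.  ``m3cf`` is the 61-corelet multimode-multicore
#: fiber (278 µm cladding / 232 µm pulp, NA 0.1); ``gi_na029`` the 100 µm
#: NA 0.29 comparison fiber; ``dcf_na020`` the double-clad fiber whose
#: 105 µm inner cladding (NA 0.20) guides the multimode light around a 9 µm
#: single-mode core.  Corelet pitch / core diameter / NA for the m3cf are
#: design defaults (they fit four rings in the 232 µm pulp with margin) and
#: can be overridden in the run configuration.
FIBER_PRESETS: dict[str, FiberSpec] = {
    "m3cf": FiberSpec(
        cladding_diameter=278.0,
        pulp_diameter=232.0,
        na_multimode=0.1,
        corelet_rings=4,
        corelet_pitch=25.0,
        corelet_core_diameter=2.0,
        corelet_na=0.13,
        wavelength=488.0,
        label="m3cf",
    ),
    "gi_na029": FiberSpec(
        cladding_diameter=125.0,
        pulp_diameter=100.0,
        na_multimode=0.29,
        corelet_rings=0,
        corelet_pitch=25.0,
        corelet_core_diameter=2.0,
        corelet_na=0.13,
        wavelength=488.0,
        label="gi_na029",
    ),
    "dcf_na020": FiberSpec(
        cladding_diameter=125.0,
        pulp_diameter=105.0,
        na_multimode=0.20,
        corelet_rings=0,
        corelet_pitch=25.0,
        corelet_core_diameter=9.0,
        corelet_na=0.12,
        wavelength=488.0,
        label="dcf_na020",
    ),
}


def scaled_test_fiber(
    v_target: float = 12.0,
    na: float = 0.1,
    wavelength: float = 488.0,
    rings: int = 1,
) -> FiberSpec:
    """A reduced-scale fiber with the same NA physics but few guided modes.

    The multimode pulp diameter is chosen so the V-number equals
    ``v_target``; corelet geometry is scaled down proportionally.  Focusing,
    calibration and mating physics are scale-free, so desk-scale simulations
    use this spec instead of the full fiber.
    """
    d = v_target * (wavelength * 1e-3) / (np.pi * na)
    pitch = d / (2 * rings + 1.2) if rings > 0 else d / 3
    return FiberSpec(
        cladding_diameter=1.25 * d,
        pulp_diameter=d,
        na_multimode=na,
        corelet_rings=rings,
        corelet_pitch=pitch,
        corelet_core_diameter=min(2.0, 0.8 * pitch),
        corelet_na=0.13,
        wavelength=wavelength,
        label=f"scaled_v{v_target:g}",
    )


# --------------------------------------------------------------------------
# Hexagonal corelet lattice
# --------------------------------------------------------------------------

def centered_hex_number(rings: int) -> int:
    """Number of sites of a centered hexagonal lattice with ``rings`` rings."""
    return 3 * rings * (rings + 1) + 1


@dataclass
class CoreletLattice:
    """Axis-centered hexagonal corelet lattice.

    ``positions`` is an (N, 2) array in µm; ``ring_index[i]`` the ring each
    site belongs to (0 = center); ``spiral_rank`` the spiral addressing
    order (filled by :func:`spiral_order`), a permutation of 0..N-1 with the
    center ranked 0.
    """

    positions: np.ndarray
    ring_index: np.ndarray
    pitch: float
    spiral_rank: Optional[np.ndarray] = None

    def __len__(self) -> int:
        return len(self.positions)

    def rotated(self, angle_deg: float) -> "CoreletLattice":
        """Lattice rigidly rotated counter-clockwise about the fiber axis."""
        t = np.deg2rad(angle_deg)
        rot = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
        return replace(self, positions=self.positions @ rot.T)


def hex_lattice(rings: int, pitch: float) -> CoreletLattice:
    """Centered hexagonal lattice with one axis along +x.

    Sites are generated ring by ring; ring r contains 6r sites obtained by
    walking r steps along each of the six lattice directions starting from
    the corner on the +x axis.
    """
    if rings < 0:
        raise ValueError("rings must be >= 0")
    if pitch <= 0:
        raise ValueError("pitch must be > 0")

    # six unit steps of the triangular lattice, CCW starting at +x
    angles = np.deg2rad(60.0 * np.arange(6))
    steps = np.stack([np.cos(angles), np.sin(angles)], axis=1) * pitch

    positions = [np.zeros(2)]
    ring_index = [0]
    for r in range(1, rings + 1):
        p = steps[0] * r          # corner on the +x axis
        for k in range(6):
            d = steps[(k + 2) % 6]   # walk direction along the ring edge
            for _ in range(r):
                positions.append(p.copy())
                ring_index.append(r)
                p = p + d
    return CoreletLattice(
        positions=np.asarray(positions, dtype=float),
        ring_index=np.asarray(ring_index, dtype=int),
        pitch=float(pitch),
    )


def spiral_order(lattice: CoreletLattice) -> CoreletLattice:
    """Fill ``spiral_rank``: center first, then each ring walked CCW.

    Within a ring the walk starts at the site with the smallest non-negative
    angle from +x and proceeds counter-clockwise; consecutive same-ring
    ranks are nearest neighbours (separation = pitch).  Raises if the sites
    do not form complete hexagonal rings.
    """
    pos = lattice.positions
    n = len(pos)
    radii = np.hypot(pos[:, 0], pos[:, 1])
    # ring membership from hex distance; verify ring completeness
    rings = int(lattice.ring_index.max()) if n else 0
    if n != centered_hex_number(rings):
        raise ValueError("lattice does not form complete hexagonal rings")

    rank = np.empty(n, dtype=int)
    nxt = 0
    for r in range(rings + 1):
        idx = np.flatnonzero(lattice.ring_index == r)
        if r == 0:
            if len(idx) != 1 or radii[idx[0]] > 1e-9:
                raise ValueError("ring 0 must be a single site at the origin")
            rank[idx[0]] = nxt
            nxt += 1
            continue
        if len(idx) != 6 * r:
            raise ValueError(f"ring {r} is incomplete")
        ang = np.mod(np.arctan2(pos[idx, 1], pos[idx, 0]), 2 * np.pi)
        order = idx[np.argsort(ang, kind="stable")]
        # verify the CCW walk is a nearest-neighbour cycle
        p = pos[order]
        gaps = np.hypot(*(np.roll(p, -1, axis=0) - p).T)
        if not np.allclose(gaps, lattice.pitch, rtol=1e-6):
            raise ValueError(f"ring {r} sites are not a contiguous hexagonal ring")
        for i in order:
            rank[i] = nxt
            nxt += 1
    return replace(lattice, spiral_rank=rank)


# --------------------------------------------------------------------------
# Aperture masks and grids
# --------------------------------------------------------------------------

def grid_coords(shape: tuple[int, int], pitch: float) -> tuple[np.ndarray, np.ndarray]:
    """Axis-centered physical coordinates of a sampling grid.

    Returns ``(y, x)`` 1-D arrays; row 0 is at the most negative y.  The
    grid centroid sits exactly on the fiber axis (half-pixel offsets for
    even sizes).
    """
    ny, nx = shape
    y = (np.arange(ny) - (ny - 1) / 2) * pitch
    x = (np.arange(nx) - (nx - 1) / 2) * pitch
    return y, x


def aperture_mask(
    grid_shape: tuple[int, int], pitch: float, diameter: float
) -> tuple[np.ndarray, int]:
    """Boolean mask of grid points strictly inside a centered circle.

    A point belongs to the aperture iff its center satisfies
    ``x² + y² < (diameter/2)²`` (strict, no area weighting), which makes
    the count a reproducible integer.  Returns ``(mask, count)``.
    """
    if pitch <= 0:
        raise ValueError("pitch must be > 0")
    if diameter < 0:
        raise ValueError("diameter must be >= 0")
    y, x = grid_coords(grid_shape, pitch)
    r2 = y[:, None] ** 2 + x[None, :] ** 2
    mask = r2 < (diameter / 2) ** 2
    return mask, int(mask.sum())


# --------------------------------------------------------------------------
# Mode counting
# --------------------------------------------------------------------------

def v_number(core_diameter: float, na: float, wavelength: float) -> float:
    """Normalized frequency V = π·d·NA/λ of a step-index waveguide.

    ``core_diameter`` in µm, ``wavelength`` in nm.
    """
    if core_diameter <= 0 or na <= 0 or wavelength <= 0:
        raise ValueError("all arguments must be > 0")
    return np.pi * core_diameter * na / (wavelength * 1e-3)


def estimate_mode_count(spec: FiberSpec, polarizations: int = 2) -> int:
    """Standard large-V guided-mode estimate of the multimode waveguide.

    ``round(polarizations · V²/4)`` with V computed from the pulp diameter
    and the multimode NA.
    """
    if polarizations not in (1, 2):
        raise ValueError("polarizations must be 1 or 2")
    v = spec.v_multimode
    return int(round(polarizations * v * v / 4))
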