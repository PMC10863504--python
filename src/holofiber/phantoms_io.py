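"""Synthetic fluorescence phantoms, run configuration, and file I/O.

Phantoms are 2-D fluorophore-density maps at the working-distance plane,
emulating the imaging targets of a fiber endoscope pointed at cerebellar
tissue: 6 µm fluorescent calibration beads, a monolayer of Purkinje-like
somata (15–25 µm) with optional thin dendrites extending perpendicular to
the layer, and dark (zero-density) blood-vessel ribbons crossing a diffuse
background.  Every generator is a pure function of its parameters and a
seed, so identical seeds give bit-identical phantoms and every labelled
object can be reconstructed for test oracles.

The module also hosts the YAML run configuration (with shipped fiber
presets), the seed fan-out rule, and TIFF+JSON image export/import.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile
import yaml

from .fiber_geometry import FIBER_PRESETS, FiberSpec, grid_coords
from .imaging_pipeline import RasterImage

__all__ = [
    "Phantom",
    "make_bead_phantom",
    "make_purkinje_phantom",
    "load_config",
    "ConfigError",
    "child_seed",
    "save_raster_image",
    "load_raster_image",
    "save_phantom",
    "load_phantom",
]

log = logging.getLogger("holofiber")


# --------------------------------------------------------------------------
# Seed fan-out
# --------------------------------------------------------------------------

def child_seed(master: int, stage: str) -> int:
    """Derive a per-stage seed from one master seed.

    The rule is ``SeedSequence([master, crc32(stage)])`` reduced to a
    31-bit integer — documented so any stage can be reproduced on its own.
    """
    ss = np.random.SeedSequence([int(master), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


# --------------------------------------------------------------------------
# Phantoms
# --------------------------------------------------------------------------

@dataclass
class Phantom:
    """Fluorophore density map (arbitrary units ≥ 0) plus object labels.

    ``labels`` records every generated object (kind, center, size, …) with
    enough detail to rebuild the ground truth; ``pitch`` in µm.
    """

    density: np.ndarray
    pitch: float
    labels: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if np.any(self.density < 0):
            raise ValueError("phantom density must be nonnegative")


class PackingError(RuntimeError):
    """Raised when rejection sampling cannot place the requested objects."""


def _disk(density: np.ndarray, y: np.ndarray, x: np.ndarray,
          cx: float, cy: float, radius: float, value: float,
          soft_edge: float = 0.0) -> None:
    r = np.hypot(y[:, None] - cy, x[None, :] - cx)
    if soft_edge > 0:
        profile = value * np.clip((radius - r) / soft_edge + 0.5, 0.0, 1.0)
        np.maximum(density, profile, out=density)
    else:
        density[r < radius] = value


def make_bead_phantom(n: int, diameter: float = 6.0,
                      field_diameter: float = 230.0, seed: int = 0,
                      grid_shape: tuple[int, int] = (88, 88),
                      pitch: float = 2.8,
                      max_tries: int = 10_000) -> Phantom:
    """Non-overlapping fluorescent beads scattered in the field of view.

    ``n`` uniform disks of the given diameter with centers drawn uniformly
    in the field circle, rejection-sampled so beads never overlap (center
    separation > diameter).  Labels record each center.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if diameter > field_diameter:
        raise PackingError("bead does not fit in the field")
    rng = np.random.default_rng(seed)
    rmax = (field_diameter - diameter) / 2
    centers: list[tuple[float, float]] = []
    tries = 0
    while len(centers) < n:
        if tries >= max_tries:
            raise PackingError(
                f"could not place {n} beads of {diameter} µm after {max_tries} draws")
        tries += 1
        r = rmax * np.sqrt(rng.uniform())
        t = rng.uniform(0, 2 * np.pi)
        c = (r * np.cos(t), r * np.sin(t))
        if all(np.hypot(c[0] - a, c[1] - b) > diameter for a, b in centers):
            centers.append(c)

    density = np.zeros(grid_shape)
    y, x = grid_coords(grid_shape, pitch)
    labels = []
    for cx, cy in centers:
        _disk(density, y, x, cx, cy, diameter / 2, 1.0)
        labels.append({"kind": "bead", "center": [cx, cy], "diameter": diameter})
    return Phantom(density=density, pitch=pitch, labels=labels, seed=seed)


def _layer_curve(kind: str, field_diameter: float, t: np.ndarray,
                 params: dict) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample a layer curve; returns (x(t), y(t), normal angle(t))."""
    half = field_diameter / 2
    if kind == "line":
        y0 = params.get("y0", 0.0)
        xs = (2 * t - 1) * half * 0.9
        ys = np.full_like(xs, y0)
        normals = np.full_like(xs, np.pi / 2)
    elif kind == "arc":
        radius = params.get("radius", 0.8 * half)
        span = np.deg2rad(params.get("span_deg", 150.0))
        ang = (t - 0.5) * span + np.pi / 2
        cy = params.get("cy", -0.35 * half)
        xs = radius * np.cos(ang)
        ys = cy + radius * np.sin(ang)
        normals = ang
    else:
        raise ValueError(f"unknown layer-curve kind {kind!r}")
    return xs, ys, normals


def make_purkinje_phantom(n_somata: int,
                          soma_diameter_range: tuple[float, float] = (15.0, 25.0),
                          layer: Optional[dict] = None,
                          dendrites: bool = True,
                          vessels: int = 0,
                          seed: int = 0,
                          field_diameter: float = 230.0,
                          grid_shape: tuple[int, int] = (88, 88),
                          pitch: float = 2.8,
                          background: float = 0.05,
                          max_tries: int = 10_000) -> Phantom:
    """Purkinje-like tissue phantom: a monolayer of soft-edged somata.

    Somata of diameter U(range) are centered on the layer curve (default: a
    gentle arc) with small jitter, non-overlapping.  ``dendrites`` adds
    1–2 µm-wide segments extending perpendicular to the layer from each
    soma.  ``vessels`` dark ribbons multiply the diffuse background
    (default 5 % of soma density) with exact zeros along their centerlines.
    """
    layer = dict(layer or {"kind": "arc"})
    kind = layer.pop("kind", "arc")
    rng = np.random.default_rng(seed)
    y, x = grid_coords(grid_shape, pitch)

    soma = np.zeros(grid_shape)
    labels: list[dict] = []

    # --- somata along the layer curve
    centers: list[tuple[float, float, float]] = []  # (cx, cy, radius)
    tries = 0
    while len(centers) < n_somata:
        if tries >= max_tries:
            raise PackingError(f"could not place {n_somata} somata after {max_tries} draws")
        tries += 1
        t = rng.uniform()
        cx, cy, normal = (v.item() for v in _layer_curve(kind, field_diameter,
                                                         np.array([t]), layer))
        d = rng.uniform(*soma_diameter_range)
        jitter = rng.normal(0, 2.0, size=2)
        cx, cy = cx + jitter[0], cy + jitter[1]
        if np.hypot(cx, cy) + d / 2 > field_diameter / 2:
            continue
        if any(np.hypot(cx - a, cy - b) < (d + dd) / 2 for a, b, dd in
               ((a, b, 2 * r) for a, b, r in centers)):
            continue
        centers.append((cx, cy, d / 2))
        _disk(soma, y, x, cx, cy, d / 2, 1.0, soft_edge=2.0)
        labels.append({"kind": "soma", "center": [cx, cy], "diameter": d})
        if dendrites:
            width = rng.uniform(1.0, 2.0)
            length = rng.uniform(25.0, 50.0)
            ang = normal + rng.normal(0, 0.15)
            _ribbon(soma, y, x, (cx, cy),
                    (cx + length * np.cos(ang), cy + length * np.sin(ang)),
                    width, 0.6)
            labels.append({"kind": "dendrite", "center": [cx, cy],
                           "angle": float(ang), "length": length, "width": width})

    # --- diffuse background restricted to the field circle
    density = soma.copy()
    rr = np.hypot(y[:, None], x[None, :])
    in_field = rr < field_diameter / 2
    density[in_field & (density < background)] = background

    # --- dark vessels: multiplicative ribbons, zero on the centerline
    for _ in range(vessels):
        t0 = rng.uniform(0, 2 * np.pi)
        p0 = (0.9 * field_diameter / 2 * np.cos(t0),
              0.9 * field_diameter / 2 * np.sin(t0))
        p1 = (-p0[0] + rng.normal(0, 20), -p0[1] + rng.normal(0, 20))
        width = rng.uniform(8.0, 15.0)
        att = _ribbon_attenuation(y, x, p0, p1, width)
        density *= att
        labels.append({"kind": "vessel", "p0": list(p0), "p1": list(p1),
                       "width": width})
    return Phantom(density=density, pitch=pitch, labels=labels, seed=seed)


def _segment_distance(y: np.ndarray, x: np.ndarray, p0, p1) -> np.ndarray:
    px = x[None, :] - p0[0]
    py = y[:, None] - p0[1]
    dx, dy = p1[0] - p0[0], p1[1] - p0[1]
    seg2 = dx * dx + dy * dy
    t = np.clip((px * dx + py * dy) / seg2, 0.0, 1.0) if seg2 > 0 else 0.0
    return np.hypot(px - t * dx, py - t * dy)


def _ribbon(density: np.ndarray, y: np.ndarray, x: np.ndarray,
            p0, p1, width: float, value: float) -> None:
    d = _segment_distance(y, x, p0, p1)
    np.maximum(density, np.where(d < width / 2, value, 0.0), out=density)


def _ribbon_attenuation(y: np.ndarray, x: np.ndarray, p0, p1,
                        width: float) -> np.ndarray:
    """Smooth attenuation profile, exactly 0 within half a pixel of the
    centerline and 1 outside the ribbon."""
    d = _segment_distance(y, x, p0, p1)
    att = np.clip((d - width / 4) / (width / 4), 0.0, 1.0)
    att[d < width / 8] = 0.0
    return att


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------

class ConfigError(ValueError):
    """Configuration file violates the documented schema."""


_FIBER_KEYS = {
    "preset", "cladding_diameter", "pulp_diameter", "na_multimode",
    "corelet_rings", "corelet_pitch", "corelet_core_diameter", "corelet_na",
    "wavelength", "label",
}
_SCHEMA = {
    "fiber": _FIBER_KEYS,
    "calibration": {"input_grid_n", "input_window", "carrier", "iris_fraction",
                    "prune_threshold", "photons"},
    "imaging": {"grid_n", "pitch", "working_distance", "photons", "dark_rate"},
    "mating": {"offset", "rotation", "gap", "bore_clearance", "lateral_sigma"},
    "phantom": {"kind", "n", "diameter", "n_somata", "vessels", "dendrites",
                "background"},
    "seed": None,
    "scale": None,
}

_DEFAULTS = {
    "fiber": {"preset": "m3cf"},
    "calibration": {"input_grid_n": 16, "input_window": 1.1,
                    "carrier": 0.125, "iris_fraction": 0.6,
                    "prune_threshold": 0.1, "photons": None},
    "imaging": {"grid_n": 88, "pitch": 2.8, "working_distance": 15.0,
                "photons": None, "dark_rate": 0.0},
    "mating": {"offset": [0.0, 0.0], "rotation": 0.0, "gap": 0.5,
               "bore_clearance": 3.0, "lateral_sigma": 0.2},
    "phantom": {"kind": "beads", "n": 10, "diameter": 6.0,
                "n_somata": 8, "vessels": 0, "dendrites": True,
                "background": 0.05},
    "seed": 0,
    "scale": "test",
}


def _fiber_from_section(section: dict) -> FiberSpec:
    section = dict(section)
    preset = section.pop("preset", None)
    if preset is not None:
        if preset not in FIBER_PRESETS:
            raise ConfigError(f"unknown fiber preset {preset!r}")
        base = FIBER_PRESETS[preset]
        fields = {k: getattr(base, k) for k in (
            "cladding_diameter", "pulp_diameter", "na_multimode",
            "corelet_rings", "corelet_pitch", "corelet_core_diameter",
            "corelet_na", "wavelength", "label")}
        fields.update(section)
    else:
        fields = section
    try:
        return FiberSpec(**fields)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid fiber section: {exc}") from exc


def load_config(path) -> dict:
    """Load and validate a YAML run configuration.

    Unknown keys are rejected by name; defaults are applied for every
    omitted key; the fully resolved configuration (including the
    constructed :class:`FiberSpec` under ``fiber_spec``) is echoed to the
    ``holofiber`` logger and returned.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        try:
            raw = yaml.safe_load(fh) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"config is not valid YAML: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")

    for key, sub in raw.items():
        if key not in _SCHEMA:
            raise ConfigError(f"unknown config key {key!r}")
        allowed = _SCHEMA[key]
        if allowed is not None:
            if not isinstance(sub, dict):
                raise ConfigError(f"section {key!r} must be a mapping")
            for k in sub:
                if k not in allowed:
                    raise ConfigError(f"unknown config key {key}.{k!r}")

    cfg = {}
    for key, default in _DEFAULTS.items():
        if isinstance(default, dict):
            merged = dict(default)
            merged.update(raw.get(key, {}))
            cfg[key] = merged
        else:
            cfg[key] = raw.get(key, default)

    cfg["fiber_spec"] = _fiber_from_section(cfg["fiber"])
    for key in sorted(cfg):
        log.info("config %s=%r", key, cfg[key])
    return cfg


# --------------------------------------------------------------------------
# File export / import
# --------------------------------------------------------------------------

def save_raster_image(path, image: RasterImage) -> None:
    """16-bit grayscale TIFF plus a JSON sidecar.

    Pixel values are scaled to the uint16 range by a factor recorded in the
    sidecar; invalid (out-of-mask) pixels are written as 0 and the mask is
    stored (packed) in the sidecar so the round trip reproduces the image
    bit-exactly.
    """
    path = Path(path)
    vals = np.where(image.mask, image.pixels, 0.0)
    vmax = float(vals.max())
    scale = 65535.0 / vmax if vmax > 0 else 1.0
    raw = np.round(vals * scale).astype(np.uint16)
    tifffile.imwrite(path, raw, photometric="minisblack", compression=None)
    sidecar = {
        "pitch": image.pitch,
        "scale": scale,
        "shape": list(image.pixels.shape),
        "mask_packed": np.packbits(image.mask.ravel()).tolist(),
        "pixels": image.pixels[image.mask].tolist(),  # exact masked values
        "metadata": image.metadata,
    }
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh)


def load_raster_image(path) -> RasterImage:
    path = Path(path)
    with open(path.with_suffix(path.suffix + ".json")) as fh:
        sidecar = json.load(fh)
    shape = tuple(sidecar["shape"])
    mask = np.unpackbits(
        np.array(sidecar["mask_packed"], dtype=np.uint8),
        count=shape[0] * shape[1]).astype(bool).reshape(shape)
    pixels = np.zeros(shape)
    pixels[mask] = np.array(sidecar["pixels"])
    return RasterImage(pixels=pixels, mask=mask, pitch=float(sidecar["pitch"]),
                       metadata=sidecar["metadata"])


def save_phantom(path, phantom: Phantom) -> None:
    """Float64 TIFF plus JSON sidecar with labels; bit-exact round trip."""
    path = Path(path)
    tifffile.imwrite(path, phantom.density.astype(np.float64),
                     photometric="minisblack", compression=None)
    sidecar = {"pitch": phantom.pitch, "seed": phantom.seed,
               "labels": phantom.labels}
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh)


def load_phantom(path) -> Phantom:
    path = Path(path)
    density = np.asarray(tifffile.imread(path), dtype=np.float64)
    with open(path.with_suffix(path.suffix + ".json")) as fh:
        sidecar = json.load(fh)
    return Phantom(density=density, pitch=float(sidecar["pitch"]),
                   labels=sidecar["labels"], seed=int(sidecar["seed"]))
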