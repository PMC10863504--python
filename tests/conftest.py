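"""Shared fixtures: a reduced-scale fiber whose physics matches the full
instrument but whose mode count keeps the suite fast."""

import numpy as np
import pytest

import holofiber as hf


@pytest.fixture(scope="session")
def m3cf_spec():
    return hf.FIBER_PRESETS["m3cf"]


@pytest.fixture(scope="session")
def m3cf_lattice(m3cf_spec):
    return hf.spiral_order(
        hf.hex_lattice(m3cf_spec.corelet_rings, m3cf_spec.corelet_pitch))


@pytest.fixture(scope="session")
def scaled_spec():
    """V ≈ 10 fiber (27 guided scalar modes), NA 0.1 at 488 nm."""
    return hf.scaled_test_fiber(v_target=10.0)


@pytest.fixture(scope="session")
def scaled_modes(scaled_spec):
    return hf.solve_lp_modes(scaled_spec.pulp_diameter,
                             scaled_spec.na_multimode,
                             scaled_spec.wavelength,
                             grid_shape=(96, 96))


@pytest.fixture(scope="session")
def scaled_tm(scaled_modes):
    return hf.build_mm_tm(scaled_modes, length=50_000.0, seed=42)


@pytest.fixture(scope="session")
def scaled_system(scaled_spec, scaled_modes, scaled_tm):
    return hf.FiberSystem(scaled_modes, scaled_tm,
                          scaled_spec.pulp_diameter,
                          scaled_spec.na_multimode,
                          input_grid_n=14)


@pytest.fixture(scope="session")
def scaled_measured_tm(scaled_system):
    return hf.acquire_tm(scaled_system, prune_threshold=0.1)


@pytest.fixture(scope="session")
def scaled_truth(scaled_system, scaled_measured_tm):
    """Ground-truth pixel TM restricted to the measured TM's rows/columns."""
    return (scaled_system.pixel_tm()[scaled_measured_tm.masked_indices]
            [:, scaled_measured_tm.kept_inputs])
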