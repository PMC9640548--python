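from datetime import datetime, timezone

import numpy as np
import pytest

import pollensim as ps


@pytest.fixture(scope="session")
def demo_grid():
    """20x15x4 cells, 36 km spacing, 30 days starting March 1 (oak season)."""
    return ps.build_grid(20, 15, 4, layer_tops=[60.0, 150.0, 400.0, 1000.0],
                         t0=datetime(2004, 3, 1, tzinfo=timezone.utc),
                         n_hours=720)


@pytest.fixture(scope="session")
def synth_cfg():
    return ps.SynthConfig()


@pytest.fixture(scope="session")
def demo_met(demo_grid, synth_cfg):
    return ps.gen_meteorology(demo_grid, synth_cfg, seed=1)


@pytest.fixture(scope="session")
def demo_veg(demo_grid, synth_cfg):
    return ps.gen_vegetation(demo_grid, synth_cfg, seed=2)


@pytest.fixture(scope="session")
def oak():
    return ps.oak_params()


@pytest.fixture(scope="session")
def demo_emission(demo_grid, demo_met, demo_veg, oak):
    tendency, f_e, onset = ps.emission_field(
        demo_grid, demo_met, demo_veg, ps.MetAdjustParams(), oak)
    return tendency, f_e, onset


@pytest.fixture(scope="session")
def demo_run(demo_grid, demo_met, demo_emission, oak):
    """Full 720-hour run with all processes active and per-cell budget."""
    tendency, _, _ = demo_emission
    v_s = ps.settling_velocity(oak.d_p, oak.rho_p)
    return ps.run_simulation(demo_grid, demo_met, tendency, v_s)


@pytest.fixture
def tiny_grid():
    """Single-column sandbox for operator-level tests."""
    return ps.build_grid(1, 1, 3, dx=1000.0, dy=1000.0,
                         layer_tops=[50.0, 120.0, 300.0], n_hours=24)
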