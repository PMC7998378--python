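"""Shared fixtures: synthetic datasets generated once per session."""

import numpy as np
import pytest

from hypoxiq.config import SimulationConfig
from hypoxiq import synthetic


@pytest.fixture(scope="session")
def foci_cfg():
    return SimulationConfig(seed=3, pixel_size_um=0.2)


@pytest.fixture(scope="session")
def foci_dataset(foci_cfg):
    image, truth = synthetic.generate_foci_image(
        n_nuclei=75, foci_mean=10, cfg=foci_cfg
    )
    return image, truth


@pytest.fixture(scope="session")
def reporter_dataset():
    cfg = SimulationConfig(seed=7, pixel_size_um=1.0)
    rng = np.random.default_rng(7)
    ratios = list(rng.uniform(0.1, 2.0, 200))
    image, truth = synthetic.generate_reporter_image(
        ratio=0.5, n_cells=200, cfg=cfg, ratios=ratios
    )
    return image, truth


@pytest.fixture(scope="session")
def trace_dataset():
    cfg = SimulationConfig(seed=5, frame_interval_h=0.5)
    traces, truth = synthetic.generate_fucci_traces(
        n_cells=500, noncycling_fraction=0.3, cfg=cfg, noise_cv=0.1
    )
    return traces, truth, cfg


@pytest.fixture(scope="session")
def section_dataset():
    cfg = SimulationConfig(seed=11, pixel_size_um=1.3)
    brdu, pimo, truth = synthetic.generate_section_image(
        radius_um=250, hypoxia_onset_um=100, proliferation_depth_um=80,
        cfg=cfg, noise_od=0.01,
    )
    return brdu, pimo, truth, cfg


@pytest.fixture(scope="session")
def spheroid_dataset():
    cfg = SimulationConfig(seed=13, pixel_size_um=2.0)
    stack, truth = synthetic.generate_spheroid_stack(
        radius_um=200, green_rim_depth_um=50, z_step_um=10, cfg=cfg
    )
    return stack, truth, cfg
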