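"""Shared fixtures: synthetic bodies are expensive, so build them once."""

import numpy as np
import pytest

from anthroscan import (
    BodyShapeParams,
    SegmentationConfig,
    add_depth_noise,
    generate_body,
    measure_all,
    segment_body,
)


@pytest.fixture(scope="session")
def default_config():
    return SegmentationConfig()


@pytest.fixture(scope="session")
def default_body():
    """Reference noise-free body at default density with its ground truth."""
    cloud, gt = generate_body(BodyShapeParams(seed=0))
    return cloud, gt


@pytest.fixture(scope="session")
def default_scan(default_body, default_config):
    cloud, _ = default_body
    return segment_body(cloud, default_config)


@pytest.fixture(scope="session")
def default_measurements(default_scan, default_config):
    return measure_all(default_scan, default_config)


@pytest.fixture(scope="session")
def noisy_body(default_body):
    """Default body with 2 mm depth noise (fixed seed)."""
    cloud, gt = default_body
    return add_depth_noise(cloud, 0.002, seed=42), gt


@pytest.fixture(scope="session")
def small_body():
    """Reduced-density body for structural (non-recovery) tests."""
    params = BodyShapeParams(density=15_000, seed=1)
    cloud, gt = generate_body(params)
    return cloud, gt, params


@pytest.fixture(scope="session")
def small_scan(small_body, default_config):
    cloud, _, _ = small_body
    return segment_body(cloud, default_config)


def cylinder_cloud(radius=0.1, height=1.0, n=20_000, seed=0, center=(0.0, 0.0)):
    """Dense vertical circular cylinder surface; a reusable test shape."""
    rng = np.random.default_rng(seed)
    y = rng.uniform(0.0, height, n)
    t = rng.uniform(0.0, 2.0 * np.pi, n)
    from anthroscan import PointCloud

    return PointCloud(
        np.c_[center[0] + radius * np.cos(t), y, center[1] + radius * np.sin(t)]
    )
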