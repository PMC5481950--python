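import dataclasses

import numpy as np
import pytest

from pcmrca.flow_data import FlowDataset, normalize_magnitude
from pcmrca.phantom import PhantomConfig, generate_phantom
from pcmrca.preprocess import (
    apply_suppression,
    magnitude_noise_mask,
    velocity_outlier_mask,
)


def small_phantom_config(**overrides) -> PhantomConfig:
    """A 32³ × 8-frame phantom, geometry scaled down from the default."""
    base = dict(
        grid=(32, 32, 32),
        n_frames=8,
        chamber_center=(11.0, 16.0, 16.0),
        chamber_axes=(6.0, 5.0, 5.0),
        vessel_center_xy=(25.0, 16.0),
        vessel_radius_vox=3.0,
        reference_frame=2,
    )
    base.update(overrides)
    return PhantomConfig(**base)


def preprocess(ds: FlowDataset) -> FlowDataset:
    """The standard pipeline front end: normalize then suppress noise."""
    ds = normalize_magnitude(ds)
    return apply_suppression(
        ds, [magnitude_noise_mask(ds), velocity_outlier_mask(ds)]
    )


@pytest.fixture(scope="session")
def small_phantom():
    cfg = small_phantom_config()
    ds, truth = generate_phantom(cfg)
    return cfg, ds, truth


@pytest.fixture(scope="session")
def small_phantom_prepped(small_phantom):
    cfg, ds, truth = small_phantom
    return cfg, preprocess(ds), truth


@pytest.fixture()
def random_dataset():
    """A tiny random but valid FlowDataset (3 frames of 8³)."""
    rng = np.random.default_rng(42)
    return FlowDataset(
        magnitude=rng.uniform(0, 800, size=(3, 8, 8, 8)),
        velocity=rng.uniform(-150, 150, size=(3, 3, 8, 8, 8)),
        venc=120.0,
        spacing=np.full(3, 2.7),
        temporal_resolution=52.8,
    )


def replace_cfg(cfg: PhantomConfig, **kw) -> PhantomConfig:
    return dataclasses.replace(cfg, **kw)
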