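import numpy as np
import pytest

from upunet.simulate import (
    DatasetSpec,
    ParticleField,
    VolumeSpec,
    place_particles,
)


@pytest.fixture(scope="session")
def paper_volume() -> VolumeSpec:
    """The study's 76x76x5 um volume at 128x128 lateral resolution."""
    return VolumeSpec(Dx=76.0, Dy=76.0, Dz=5.0, n=128, nz=20)


@pytest.fixture(scope="session")
def tiny_volume() -> VolumeSpec:
    return VolumeSpec(Dx=19.0, Dy=19.0, Dz=5.0, n=32, nz=8)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_field(paper_volume) -> ParticleField:
    return place_particles(paper_volume, (10, 15), 2.0, seed=42)


def make_tiny_spec(n_images=6, seed=0, **kw) -> DatasetSpec:
    """Small 32x32 dataset spec for fast pipeline tests."""
    defaults = dict(
        n_images=n_images,
        split=(2 / 3, 1 / 6, 1 / 6),
        count_range=(1, 3),
        radius=2.0,
        volume=VolumeSpec(Dx=19.0, Dy=19.0, Dz=5.0, n=32, nz=8),
        seed=seed,
    )
    defaults.update(kw)
    return DatasetSpec(**defaults)
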