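import numpy as np
import pytest

from conemosaiq.synthdata import IntensityParams, MosaicSpec, generate_field


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def small_field_spec(**overrides) -> MosaicSpec:
    """A fast 256x256 px field spec used across the suite."""
    defaults = dict(
        field_size_um=64.0,
        px_per_um=4.0,
        n_red_cells=40,
        n_green_only_cells=0,
        double_positive_fraction=0.2,
        cell_radius_um=2.9,
        min_spacing_um=6.4,
        layout="hex",
        psf_sigma_px=1.0,
        noise_sd=10.0,
        exact_counts=True,
        seed=0,
    )
    defaults.update(overrides)
    return MosaicSpec(**defaults)


def noiseless_field_spec(**overrides) -> MosaicSpec:
    """Noise-free, blur-free spec: intensities render exactly as drawn."""
    defaults = dict(
        psf_sigma_px=0.0,
        noise_sd=0.0,
        background_level=0.0,
        intensity_params=IntensityParams(
            red_mean=3000.0, red_sd=100.0,
            green_only_mean=3000.0, green_only_sd=100.0,
            baseline_mean=100.0, baseline_sd=10.0,
        ),
    )
    defaults.update(overrides)
    return small_field_spec(**defaults)


@pytest.fixture
def small_field():
    return generate_field(small_field_spec())


@pytest.fixture
def noiseless_field():
    return generate_field(noiseless_field_spec())
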