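import numpy as np
import pytest

from haycal.simulate import GeneratorConfig, ScatterParams, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


#: A short wavelength grid (200 channels, 680-1078 nm) for fast unit tests.
SMALL_GRID = 680.0 + 2.0 * np.arange(200)

#: Single-analyte statistics and in-range bands for the small grid.
SMALL_STATS = {"CP": (155.0, 26.3, 85.0, 212.0)}
SMALL_BANDS = {"CP": [(800.0, 30.0, 1.5), (950.0, 40.0, 1.0)]}


def small_config(**overrides) -> GeneratorConfig:
    """A fast single-analyte generator configuration on the short grid."""
    kwargs = dict(
        species="alfalfa",
        n_samples=60,
        analyte_stats=dict(SMALL_STATS),
        band_library={k: list(v) for k, v in SMALL_BANDS.items()},
        wavelengths_nm=SMALL_GRID.copy(),
        seed=7,
    )
    kwargs.update(overrides)
    return GeneratorConfig(**kwargs)


@pytest.fixture
def small_dataset():
    """60 synthetic samples, one analyte (CP), 200 channels, ground scatter."""
    return generate(small_config())


@pytest.fixture
def noise_free_dataset():
    """Same layout with all distortion and noise switched off."""
    silent = ScatterParams(0.0, 0.0, 0.0, 0.0)
    return generate(
        small_config(
            scatter={"ground": silent, "unground": silent},
            noise_sd=0.0,
            n_samples=100,
        )
    )
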