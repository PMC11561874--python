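import numpy as np
import pytest

from atmcorr.simulate import LineComb, SceneConfig
from atmcorr.spectra import InterferentSpec, Region, Spectrum


@pytest.fixture
def small_spectrum():
    wn = np.arange(1000.0, 1011.0)
    return Spectrum(wn, np.linspace(0.1, 0.2, wn.size))


@pytest.fixture
def water_region():
    return Region(1205.0, 2072.0)


def make_comb(seed: int, lo: float = 1300.0, hi: float = 1950.0,
              n_lines: int = 40, fwhm: float = 4.0,
              window: tuple[float, float] | None = (1250.0, 2000.0)) -> LineComb:
    rng = np.random.default_rng(seed)
    centers = np.sort(rng.uniform(lo, hi, n_lines))
    return LineComb(centers, rng.uniform(0.2, 1.0, n_lines), fwhm, window=window)


def make_noiseless_scene(seed: int, c1: float, c2: float,
                         offset: float = 0.2) -> SceneConfig:
    """Two-scan noiseless scene: flat analyte plus one windowed water comb.

    The analyte band sits outside the correction region and the comb has
    compact support inside it, so the closed-form scaling factor is exactly
    recoverable.
    """
    spec = InterferentSpec("H2O-bend", Region(1205.0, 2072.0))
    return SceneConfig(
        axis=(1000.0, 2300.0, 2.0),
        analyte_bands=[(1100.0, 0.4, 30.0)],
        analyte_offset=offset,
        interferents=[(spec, make_comb(seed), np.array([c1, c2]))],
        seed=seed,
    )
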