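from __future__ import annotations

import numpy as np
import pytest

from specscreen import FixtureConfig, SpectralLibrary, Spectrum, generate_library


def make_spectrum(
    sid: str,
    peaks: list[tuple[float, float]],
    resolution_class: str = "low",
) -> Spectrum:
    mz, intensity = zip(*peaks)
    return Spectrum(
        id=sid, mz=np.array(mz), intensity=np.array(intensity),
        resolution_class=resolution_class,
    )


def random_library(
    rng: np.random.Generator,
    size: int,
    *,
    resolution_class: str = "low",
    peak_range: tuple[int, int] = (5, 15),
) -> SpectralLibrary:
    """A small random library without going through FixtureConfig."""
    spectra = []
    for i in range(size):
        count = int(rng.integers(*peak_range))
        if resolution_class == "low":
            mz = np.sort(rng.choice(np.arange(50, 501), size=count, replace=False))
        else:
            mz = np.sort(np.round(rng.uniform(50, 500, size=count), 4))
            mz = np.unique(mz)
        inten = rng.exponential(1.0, size=mz.size) + 1e-6
        spectra.append(
            Spectrum(
                id=f"S{i:04d}", mz=mz.astype(float), intensity=inten,
                resolution_class=resolution_class,
            )
        )
    return SpectralLibrary.from_spectra(spectra, resolution_class)


@pytest.fixture(scope="session")
def small_low_library() -> SpectralLibrary:
    cfg = FixtureConfig.low_resolution(library_size=60, n_queries=0, seed=7)
    return generate_library(cfg)


@pytest.fixture(scope="session")
def small_high_library() -> SpectralLibrary:
    cfg = FixtureConfig.high_resolution(library_size=60, n_queries=0, seed=7)
    return generate_library(cfg)
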