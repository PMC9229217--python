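"""Core spectrum data model: peaks, spectra, and spectral libraries.

A :class:`Spectrum` is an identified peak list — pairs of mass-to-charge
ratio (m/z, in Thomson) and abundance — the unit of library search in
electron-ionization GC-MS. Spectra come in two acquisition regimes:
unit-mass ("low" resolution, integer-like m/z, many fragment peaks) and
accurate-mass ("high" resolution, fractional m/z, fewer peaks).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple

import numpy as np

logger = logging.getLogger(__name__)

RESOLUTION_CLASSES = ("low", "high")


class SpectrumError(ValueError):
    """Raised when a spectrum or library violates its invariants."""


class Peak(NamedTuple):
    """A single fragment peak: m/z in Th and a positive raw abundance."""

    mz: float
    intensity: float


@dataclass
class Spectrum:
    """An EI fragment spectrum: sorted peak arrays plus metadata.

    Parameters
    ----------
    id : str
        Unique identifier within a library.
    mz, intensity : ndarray of float
        Parallel peak arrays; m/z strictly increasing, both positive.
    resolution_class : {"low", "high"}
        Acquisition regime (unit-mass vs accurate-mass).
    name : str, optional
        Compound name or unknown label.
    metadata : dict
        Opaque key-value pairs carried through MSP round trips.
    """

    id: str
    mz: np.ndarray
    intensity: np.ndarray
    resolution_class: str = "low"
    name: str | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.mz.shape != self.intensity.shape:
            raise SpectrumError(
                f"spectrum {self.id!r}: mz and intensity must be parallel 1-d arrays"
            )
        if self.mz.size == 0:
            raise SpectrumError(f"spectrum {self.id!r}: empty peak list")
        if not (self.mz > 0).all():
            raise SpectrumError(f"spectrum {self.id!r}: non-positive m/z")
        if not (self.intensity > 0).all():
            raise SpectrumError(f"spectrum {self.id!r}: non-positive intensity")
        if not (np.diff(self.mz) > 0).all():
            raise SpectrumError(
                f"spectrum {self.id!r}: m/z must be strictly increasing "
                "(merge duplicates with Spectrum.from_raw_peaks)"
            )
        if self.resolution_class not in RESOLUTION_CLASSES:
            raise SpectrumError(
                f"spectrum {self.id!r}: resolution_class must be one of "
                f"{RESOLUTION_CLASSES}, got {self.resolution_class!r}"
            )

    @classmethod
    def from_raw_peaks(
        cls,
        id: str,
        mz: Iterable[float],
        intensity: Iterable[float],
        *,
        resolution_class: str = "low",
        name: str | None = None,
        metadata: dict | None = None,
    ) -> "Spectrum":
        """Build a spectrum from raw peak pairs, cleaning as it goes.

        Zero-intensity peaks are dropped (with a log message) and peaks that
        share an m/z value exactly are merged by summing their intensities —
        scoring assumes one intensity per m/z channel.
        """
        mz = np.asarray(list(mz), dtype=float)
        intensity = np.asarray(list(intensity), dtype=float)
        if mz.shape != intensity.shape:
            raise SpectrumError(f"spectrum {id!r}: ragged peak arrays")
        keep = intensity > 0
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.info(
                "spectrum %r: dropped %d zero/negative-intensity peak(s)",
                id, n_dropped,
            )
        mz, intensity = mz[keep], intensity[keep]
        if mz.size == 0:
            raise SpectrumError(f"spectrum {id!r}: no positive-intensity peaks")
        uniq, inverse = np.unique(mz, return_inverse=True)
        if uniq.size != mz.size:
            logger.info(
                "spectrum %r: merged %d duplicate m/z peak(s) by intensity sum",
                id, mz.size - uniq.size,
            )
            summed = np.zeros_like(uniq)
            np.add.at(summed, inverse, intensity)
            mz, intensity = uniq, summed
        else:
            order = np.argsort(mz)
            mz, intensity = mz[order], intensity[order]
        return cls(
            id=id,
            mz=mz,
            intensity=intensity,
            resolution_class=resolution_class,
            name=name,
            metadata=dict(metadata or {}),
        )

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)

    @property
    def peaks(self) -> list[Peak]:
        return [Peak(float(m), float(i)) for m, i in zip(self.mz, self.intensity)]

    @property
    def base_peak_intensity(self) -> float:
        return float(self.intensity.max())


@dataclass
class SpectralLibrary:
    """A collection of spectra keyed by id, all in one resolution regime."""

    spectra: dict[str, Spectrum]
    resolution_class: str = "low"

    def __post_init__(self) -> None:
        if self.resolution_class not in RESOLUTION_CLASSES:
            raise SpectrumError(
                f"library resolution_class must be one of {RESOLUTION_CLASSES}"
            )
        for sid, spec in self.spectra.items():
            if spec.id != sid:
                raise SpectrumError(f"library key {sid!r} != spectrum id {spec.id!r}")
            if spec.resolution_class != self.resolution_class:
                raise SpectrumError(
                    f"spectrum {sid!r} is {spec.resolution_class}-resolution in a "
                    f"{self.resolution_class}-resolution library"
                )

    @classmethod
    def from_spectra(
        cls, spectra: Iterable[Spectrum], resolution_class: str | None = None
    ) -> "SpectralLibrary":
        spectra = list(spectra)
        if not spectra:
            raise SpectrumError("cannot build a library from zero spectra")
        if resolution_class is None:
            resolution_class = spectra[0].resolution_class
        mapping: dict[str, Spectrum] = {}
        for spec in spectra:
            if spec.id in mapping:
                raise SpectrumError(f"duplicate spectrum id {spec.id!r}")
            mapping[spec.id] = spec
        return cls(spectra=mapping, resolution_class=resolution_class)

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self) -> Iterator[Spectrum]:
        return iter(self.spectra.values())

    def __getitem__(self, spectrum_id: str) -> Spectrum:
        return self.spectra[spectrum_id]

    def __contains__(self, spectrum_id: str) -> bool:
        return spectrum_id in self.spectra

    @property
    def ids(self) -> list[str]:
        return list(self.spectra.keys())
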