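"""Intensity scaling and sqrt-cosine spectral similarity.

Raw EI intensities are first base-peak normalized (the most intense peak
becomes 1) and then weighted by mass so that heavier, more diagnostic
fragments carry more signal:

    A_i = I_i * mz_i / (1 + omega * I_i),     omega = 1 / (I_total - 0.5)

where ``I_total`` is the summed normalized intensity of the spectrum.
The weighting factor ``omega`` damps spectra dominated by a single large
peak: after base-peak normalization ``I_total >= 1`` always, hence
``omega`` lies in (0, 2] and the singularity at ``I_total = 0.5`` cannot
occur.

Two scaled spectra are compared with the sqrt-cosine similarity

    S(U, L) = ( sum_matched sqrt(A^u_i * A^l_i) )^2 / (A^u * A^l)

with the sums over one-to-one matched peak pairs in the numerator and
the *total* scaled intensities ``A^u = sum_i A^u_i`` (over all peaks of
each spectrum) in the denominator. By Cauchy–Schwarz, S is bounded in
[0, 1] and equals 1 exactly for identical spectra.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra import Spectrum, SpectrumError

#: Conventional absolute matching half-widths per acquisition regime:
#: half a unit-mass channel for low resolution, 0.01 Th for accurate mass.
DEFAULT_TOLERANCE = {"low": 0.5, "high": 0.01}


@dataclass(frozen=True)
class MatchTolerance:
    """Absolute m/z matching half-width in Th: peaks match when |Δmz| ≤ value."""

    value: float
    mode: str = "absolute"

    def __post_init__(self) -> None:
        if self.mode != "absolute":
            raise ValueError(f"unsupported tolerance mode {self.mode!r}")
        if not self.value > 0:
            raise ValueError("tolerance must be positive")

    @classmethod
    def for_resolution(cls, resolution_class: str) -> "MatchTolerance":
        return cls(DEFAULT_TOLERANCE[resolution_class])


@dataclass
class ScaledSpectrum:
    """A spectrum after base-peak normalization and mass weighting.

    Attributes
    ----------
    spectrum_id : str
    mz : ndarray
        Peak m/z values, ascending.
    scaled : ndarray
        Scaled intensities ``A_i`` (dimensionless, positive).
    total : float
        ``sum(scaled)``, precomputed for the similarity denominator.
    omega : float
        The dominant-peak correction weight used, in (0, 2].
    """

    spectrum_id: str
    mz: np.ndarray
    scaled: np.ndarray
    total: float
    omega: float

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)


def scale_spectrum(spectrum: Spectrum) -> ScaledSpectrum:
    """Apply base-peak normalization and the mass/dominance weighting."""
    base = spectrum.intensity.max()
    if not base > 0:
        raise SpectrumError(
            f"spectrum {spectrum.id!r}: cannot normalize all-zero intensities"
        )
    rel = spectrum.intensity / base
    total_intensity = float(rel.sum())
    # base peak contributes 1 to the sum, so total_intensity >= 1 > 0.5
    assert total_intensity >= 1.0
    omega = 1.0 / (total_intensity - 0.5)
    scaled = rel * spectrum.mz / (1.0 + omega * rel)
    return ScaledSpectrum(
        spectrum_id=spectrum.id,
        mz=spectrum.mz,
        scaled=scaled,
        total=float(scaled.sum()),
        omega=omega,
    )


def match_peaks(
    query: ScaledSpectrum, library: ScaledSpectrum, tol: MatchTolerance
) -> list[tuple[int, int]]:
    """One-to-one greedy nearest-m/z peak pairing.

    Each query peak is paired with at most one library peak within
    ``tol.value`` Th, and each library peak is used at most once. Pairs are
    chosen globally by smallest absolute m/z difference, ties broken toward
    the lower library m/z; the resulting (query index, library index) pairs
    are returned sorted by query m/z. An empty pairing is a valid result.
    """
    qmz, lmz = query.mz, library.mz
    lo = np.searchsorted(lmz, qmz - tol.value, side="left")
    hi = np.searchsorted(lmz, qmz + tol.value, side="right")
    counts = hi - lo
    if not counts.any():
        return []
    qi = np.repeat(np.arange(qmz.size), counts)
    li = np.concatenate([np.arange(a, b) for a, b in zip(lo, hi) if b > a])
    dist = np.abs(qmz[qi] - lmz[li])
    # primary key: distance; tie-break: lower library m/z (lower index)
    order = np.lexsort((li, dist))

    used_q = np.zeros(qmz.size, dtype=bool)
    used_l = np.zeros(lmz.size, dtype=bool)
    pairs: list[tuple[int, int]] = []
    for k in order:
        a, b = int(qi[k]), int(li[k])
        if used_q[a] or used_l[b]:
            continue
        used_q[a] = used_l[b] = True
        pairs.append((a, b))
    pairs.sort(key=lambda p: qmz[p[0]])
    return pairs


def similarity(
    query: ScaledSpectrum, library: ScaledSpectrum, tol: MatchTolerance
) -> float:
    """Sqrt-cosine similarity between two scaled spectra, in [0, 1]."""
    pairs = match_peaks(query, library, tol)
    if not pairs:
        return 0.0
    qi = np.fromiter((p[0] for p in pairs), dtype=int, count=len(pairs))
    li = np.fromiter((p[1] for p in pairs), dtype=int, count=len(pairs))
    numerator = float(np.sqrt(query.scaled[qi] * library.scaled[li]).sum()) ** 2
    score = numerator / (query.total * library.total)
    # guard against last-ulp overshoot of the Cauchy–Schwarz bound
    return min(max(score, 0.0), 1.0)


def similarity_spectra(
    query: Spectrum, library: Spectrum, tol: MatchTolerance | None = None
) -> float:
    """Convenience: scale two raw spectra and score them."""
    if tol is None:
        tol = MatchTolerance.for_resolution(query.resolution_class)
    return similarity(scale_spectrum(query), scale_spectrum(library), tol)
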