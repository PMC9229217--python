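"""Top-peak prescreening: graduated matching, ranking, tiered selection.

The prescreening stage avoids scoring the whole library. The m/z values
of each library spectrum's ``m`` most intense peaks are pre-extracted
into an index. At query time the ``n`` most intense query peaks are
matched against graduated prefixes of those lists: the largest query
peak looks only at the top ``n`` library peaks, the second largest at a
slightly longer prefix, and so on until the ``n``-th query peak looks at
all ``m``. Library spectra are ranked by how many query peaks found a
within-tolerance m/z, and whole rank tiers are returned until at least
``R`` candidates have accumulated. Only candidates then receive the
expensive similarity score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import groupby

import numpy as np

from .scaling import MatchTolerance
from .spectra import SpectralLibrary, Spectrum


@dataclass(frozen=True)
class PrescreenParams:
    """Prescreening knobs: query depth ``n``, library depth ``m``, tier threshold ``R``.

    ``n`` is the number of top query peaks used, ``m >= n`` the number of top
    library peaks indexed, and ``R`` the candidate-count threshold at which
    tier accumulation stops. Defaults are the recommended operating point
    (n=8, m=15, R=50).
    """

    n: int = 8
    m: int = 15
    r: int = 50

    def __post_init__(self) -> None:
        if not (1 <= self.n <= self.m):
            raise ValueError(f"need 1 <= n <= m, got n={self.n}, m={self.m}")
        if self.r < 1:
            raise ValueError(f"need R >= 1, got R={self.r}")


@dataclass
class PrescreenIndex:
    """Per-library-spectrum top-peak m/z lists, padded into one matrix.

    ``top_mz[i, :lengths[i]]`` holds the m/z of spectrum ``ids[i]``'s most
    intense peaks in descending-intensity order (ties toward higher m/z),
    truncated at ``m``; remaining cells are NaN.
    """

    ids: list[str]
    top_mz: np.ndarray          # (n_spectra, m), NaN-padded
    lengths: np.ndarray         # (n_spectra,), ints
    m: int

    def top_peaks(self, spectrum_id: str) -> list[float]:
        i = self.ids.index(spectrum_id)
        return [float(v) for v in self.top_mz[i, : self.lengths[i]]]


@dataclass
class RankedCandidates:
    """Prescreening output: (spectrum_id, matched_count) sorted by count desc, id asc."""

    entries: list[tuple[str, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def as_dict(self) -> dict[str, int]:
        return dict(self.entries)


def top_peak_mz(spectrum: Spectrum, depth: int) -> np.ndarray:
    """m/z of the ``depth`` most intense peaks, intensity-descending.

    Intensity ties are broken toward the higher m/z (heavier fragments are
    the more diagnostic in EI spectra); the same rule orders query peaks
    and index lists so prescreening is self-consistent.
    """
    order = np.lexsort((-spectrum.mz, -spectrum.intensity))
    return spectrum.mz[order[:depth]]


def build_index(library: SpectralLibrary, m: int) -> PrescreenIndex:
    """Extract every library spectrum's top-``m`` peak m/z list."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if len(library) == 0:
        raise ValueError("cannot index an empty library")
    ids = library.ids
    tops = [top_peak_mz(library[sid], m) for sid in ids]
    lengths = np.array([t.size for t in tops], dtype=int)
    top_mz = np.full((len(ids), m), np.nan)
    for i, t in enumerate(tops):
        top_mz[i, : t.size] = t
    return PrescreenIndex(ids=ids, top_mz=top_mz, lengths=lengths, m=m)


def match_depth(k: int, params: PrescreenParams) -> int:
    """Library prefix length d_k the k-th largest query peak is compared against.

    The schedule interpolates linearly from ``n`` (for k=1) to ``m`` (for
    k=n): d_k = n + round((k-1)(m-n)/(n-1)), rounding half up. This reduces
    to the consecutive schedule d_k = n + k - 1 when m = 2n - 1 and to the
    constant d_k = n when m = n. For n = 1 the single query peak scans all
    ``m`` entries.
    """
    n, m = params.n, params.m
    if not (1 <= k <= n):
        raise ValueError(f"query-peak rank k={k} out of range 1..{n}")
    if n == 1:
        return m
    return n + math.floor((k - 1) * (m - n) / (n - 1) + 0.5)


def prescreen(
    query: Spectrum,
    index: PrescreenIndex,
    params: PrescreenParams,
    tol: MatchTolerance,
) -> RankedCandidates:
    """Rank library spectra by matched top-peak count against a query.

    For k = 1..min(n, query peak count), the k-th largest query peak is
    matched (|Δmz| ≤ tol) against the first d_k index entries of every
    library spectrum; a spectrum's matched_count is the number of query
    peaks that found at least one hit in their prefix. Spectra with zero
    matches are excluded.
    """
    if params.m > index.m:
        raise ValueError(
            f"index was built with m={index.m} < requested m={params.m}"
        )
    qtop = top_peak_mz(query, params.n)
    counts = np.zeros(len(index.ids), dtype=int)
    for k, qmz in enumerate(qtop, start=1):
        d = match_depth(k, params)
        prefix = index.top_mz[:, :d]
        with np.errstate(invalid="ignore"):
            hit = (np.abs(prefix - qmz) <= tol.value).any(axis=1)
        counts += hit
    entries = [
        (index.ids[i], int(c)) for i, c in enumerate(counts) if c > 0
    ]
    entries.sort(key=lambda e: (-e[1], e[0]))
    return RankedCandidates(entries=entries)


def select_candidates(ranked: RankedCandidates, r: int) -> list[str]:
    """Accumulate whole matched-count tiers until at least ``r`` candidates.

    Tiers (equal matched_count, descending) are appended intact — never
    split — so the result may exceed ``r``; if the ranking runs out first,
    every spectrum with at least one matched peak is returned.
    """
    if r < 1:
        raise ValueError("R must be >= 1")
    selected: list[str] = []
    for _, tier in groupby(ranked.entries, key=lambda e: e[1]):
        selected.extend(sid for sid, _ in tier)
        if len(selected) >= r:
            break
    return selected
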