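"""The two-stage library search engine, sklearn-estimator style.

:class:`LibrarySearch` follows the `fit`/query pattern of
``sklearn.neighbors.NearestNeighbors``: fitting scales every library
spectrum and (optionally) builds the top-peak prescreening index; each
query is then either scored against the full library or only against
the prescreened candidates. The prescreen never alters scoring — every
hit it returns is a full-search hit with the identical score — it only
removes candidates, trading a little recall on low-ranked matches for a
large cut in similarity evaluations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .prescreen import (
    PrescreenIndex,
    PrescreenParams,
    RankedCandidates,
    build_index,
    prescreen,
    select_candidates,
)
from .scaling import MatchTolerance, ScaledSpectrum, scale_spectrum, similarity
from .spectra import SpectralLibrary, Spectrum, SpectrumError


class SearchHit(NamedTuple):
    """One scored library match."""

    spectrum_id: str
    score: float


@dataclass
class SearchResult:
    """Ranked hits for one query plus the cost proxy.

    ``n_evaluations`` counts similarity-score computations performed — the
    portable analogue of wall-clock search time. ``matched_counts`` maps
    candidate ids to their prescreening matched-peak count (empty when the
    prescreen is disabled).
    """

    query_id: str
    hits: list[SearchHit]
    n_evaluations: int
    matched_counts: dict[str, int] = field(default_factory=dict)

    @property
    def hit_ids(self) -> list[str]:
        return [h.spectrum_id for h in self.hits]


class LibrarySearch(BaseEstimator):
    """Spectral library search with optional top-peak prescreening.

    Parameters
    ----------
    n, m, r : int
        Prescreening parameters: top query peaks, top library peaks
        (n <= m), and the candidate-tier threshold. Defaults (8, 15, 50)
        are the recommended operating point.
    tolerance : float or None
        Absolute m/z matching half-width in Th; None picks the regime
        default (0.5 low-res, 0.01 high-res) at fit time.
    score_threshold : float
        Hits must score strictly above this (default 0.6).
    top_n : int or None
        Maximum hits returned per query; None = unlimited.
    prescreen : bool
        False gives the exhaustive full-library search.

    Attributes
    ----------
    library_ : SpectralLibrary
    scaled_ : dict of str -> ScaledSpectrum
    index_ : PrescreenIndex or None
    tolerance_ : MatchTolerance
    n_spectra_ : int
    """

    def __init__(
        self,
        *,
        n: int = 8,
        m: int = 15,
        r: int = 50,
        tolerance: float | None = None,
        score_threshold: float = 0.6,
        top_n: int | None = None,
        prescreen: bool = True,
    ):
        self.n = n
        self.m = m
        self.r = r
        self.tolerance = tolerance
        self.score_threshold = score_threshold
        self.top_n = top_n
        self.prescreen = prescreen

    def fit(self, library: SpectralLibrary | Iterable[Spectrum]) -> "LibrarySearch":
        """Scale the library and build the prescreening index."""
        if not isinstance(library, SpectralLibrary):
            library = SpectralLibrary.from_spectra(library)
        if len(library) == 0:
            raise SpectrumError("cannot fit on an empty library")
        if not (0.0 <= self.score_threshold < 1.0):
            raise ValueError("score_threshold must lie in [0, 1)")
        if self.top_n is not None and self.top_n < 1:
            raise ValueError("top_n must be a positive integer or None")
        if self.prescreen:
            self.params_: PrescreenParams | None = PrescreenParams(
                n=self.n, m=self.m, r=self.r
            )
        else:
            self.params_ = None
        self.library_ = library
        self.tolerance_ = (
            MatchTolerance(self.tolerance)
            if self.tolerance is not None
            else MatchTolerance.for_resolution(library.resolution_class)
        )
        self.scaled_ = {spec.id: scale_spectrum(spec) for spec in library}
        self.index_: PrescreenIndex | None = (
            build_index(library, self.m) if self.prescreen else None
        )
        self.n_spectra_ = len(library)
        return self

    def rank_candidates(self, query: Spectrum) -> RankedCandidates:
        """Run only the prescreening stage for one query."""
        check_is_fitted(self, "library_")
        if self.index_ is None or self.params_ is None:
            raise SpectrumError("prescreen is disabled for this searcher")
        return prescreen(query, self.index_, self.params_, self.tolerance_)

    def candidate_ids(self, query: Spectrum) -> list[str]:
        """Ids surviving prescreening + tier selection for one query."""
        return select_candidates(self.rank_candidates(query), self.r)

    def search(self, query: Spectrum) -> SearchResult:
        """Score one query; returns threshold-filtered hits sorted by score.

        Hits with score strictly above ``score_threshold`` are sorted by
        score descending (ties by id ascending) and truncated to ``top_n``.
        """
        check_is_fitted(self, "library_")
        if query.n_peaks == 0:
            raise SpectrumError("empty query spectrum")
        matched_counts: dict[str, int] = {}
        if self.prescreen:
            ranked = self.rank_candidates(query)
            matched_counts = ranked.as_dict()
            ids = select_candidates(ranked, self.r)
        else:
            ids = self.library_.ids

        scaled_query = scale_spectrum(query)
        hits = [
            SearchHit(sid, similarity(scaled_query, self.scaled_[sid], self.tolerance_))
            for sid in ids
        ]
        hits = [h for h in hits if h.score > self.score_threshold]
        hits.sort(key=lambda h: (-h.score, h.spectrum_id))
        if self.top_n is not None:
            hits = hits[: self.top_n]
        return SearchResult(
            query_id=query.id,
            hits=hits,
            n_evaluations=len(ids),
            matched_counts=matched_counts,
        )

    def search_all(self, queries: Iterable[Spectrum]) -> list[SearchResult]:
        return [self.search(q) for q in queries]


def full_search(
    query: Spectrum,
    library: SpectralLibrary,
    *,
    tolerance: float | None = None,
    score_threshold: float = 0.6,
    top_n: int | None = None,
) -> SearchResult:
    """Exhaustive search: score the query against every library spectrum."""
    engine = LibrarySearch(
        prescreen=False,
        tolerance=tolerance,
        score_threshold=score_threshold,
        top_n=top_n,
    ).fit(library)
    return engine.search(query)


def prescreened_search(
    query: Spectrum,
    library: SpectralLibrary,
    *,
    n: int = 8,
    m: int = 15,
    r: int = 50,
    tolerance: float | None = None,
    score_threshold: float = 0.6,
    top_n: int | None = None,
) -> SearchResult:
    """Two-stage search: prescreen candidates, then score only those."""
    engine = LibrarySearch(
        n=n, m=m, r=r,
        tolerance=tolerance,
        score_threshold=score_threshold,
        top_n=top_n,
        prescreen=True,
    ).fit(library)
    return engine.search(query)
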