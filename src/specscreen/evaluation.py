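"""Inclusion-rate evaluation of the prescreened search against the full search.

The inclusion rate measures how much of the exhaustive search the
prescreen retains:

    InclusionRate(N) = M_pre(N) / M_orig(N)

where M_orig(N) is the total number of top-N full-search matches with
similarity above 0.6 across all queries, and M_pre(N) is how many of
those same (query, library-spectrum) matches the prescreened search
also returns. Counts are summed over all queries before the single
division (micro-average); a match counts for M_pre if it appears
anywhere in the prescreened hit list, regardless of rank.

Because the scoring stage is identical in both searches, a full-search
hit is returned by the prescreened search exactly when its library
spectrum survives candidate selection; the evaluator therefore reuses
the full-search scores and tests candidate-set membership rather than
re-scoring, which makes sweeping (n, m, R) grids cheap. A dedicated
test asserts this shortcut agrees with literally re-running
``prescreened_search``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .prescreen import select_candidates
from .search import LibrarySearch, SearchResult
from .spectra import SpectralLibrary, Spectrum

#: Default (n, m) pairs: five equal-peak strategies and three graduated
#: MSSearch-style pairs.
DEFAULT_PAIRS: tuple[tuple[int, int], ...] = (
    (4, 4), (6, 6), (8, 8), (12, 12), (16, 16),
    (4, 7), (6, 11), (8, 15),
)
DEFAULT_RS: tuple[int, ...] = (10, 50, 100, 500)
DEFAULT_NS: tuple[int, ...] = (1, 3, 10, 50)


@dataclass
class InclusionReport:
    """Per-N retained-match counts and rates for one (n, m, R) setting."""

    n: int
    m: int
    r: int
    m_orig: dict[int, int]
    m_pre: dict[int, int]
    rates: dict[int, float | None]
    mean_eval_count: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "N": list(self.m_orig),
                "M_orig": list(self.m_orig.values()),
                "M_pre": list(self.m_pre.values()),
                "inclusion_rate": [self.rates[N] for N in self.m_orig],
            }
        )


def _full_results(
    queries: list[Spectrum],
    library: SpectralLibrary,
    *,
    tolerance: float | None,
    score_threshold: float,
) -> list[SearchResult]:
    engine = LibrarySearch(
        prescreen=False, tolerance=tolerance, score_threshold=score_threshold
    ).fit(library)
    return engine.search_all(queries)


def _report(
    full: list[SearchResult],
    candidate_sets: list[set[str]],
    n: int, m: int, r: int,
    ns: tuple[int, ...],
) -> InclusionReport:
    m_orig = {N: 0 for N in ns}
    m_pre = {N: 0 for N in ns}
    for res, cands in zip(full, candidate_sets):
        top_ids = res.hit_ids
        for N in ns:
            kept = top_ids[:N]
            m_orig[N] += len(kept)
            m_pre[N] += sum(1 for sid in kept if sid in cands)
    rates: dict[int, float | None] = {}
    for N in ns:
        if m_orig[N] == 0:
            warnings.warn(
                f"inclusion rate undefined for N={N}: no full-search matches "
                f"above threshold", stacklevel=3,
            )
            rates[N] = None
        else:
            rates[N] = m_pre[N] / m_orig[N]
    mean_eval = sum(len(c) for c in candidate_sets) / len(candidate_sets)
    return InclusionReport(
        n=n, m=m, r=r, m_orig=m_orig, m_pre=m_pre, rates=rates,
        mean_eval_count=mean_eval,
    )


def inclusion_rate(
    queries: list[Spectrum],
    library: SpectralLibrary,
    *,
    n: int = 8,
    m: int = 15,
    r: int = 50,
    ns: tuple[int, ...] = DEFAULT_NS,
    tolerance: float | None = None,
    score_threshold: float = 0.6,
) -> InclusionReport:
    """Inclusion rates of the prescreened search at one (n, m, R) setting."""
    if not queries:
        raise ValueError("need at least one query spectrum")
    full = _full_results(
        queries, library, tolerance=tolerance, score_threshold=score_threshold
    )
    engine = LibrarySearch(
        n=n, m=m, r=r, tolerance=tolerance, score_threshold=score_threshold
    ).fit(library)
    candidate_sets = [set(engine.candidate_ids(q)) for q in queries]
    return _report(full, candidate_sets, n, m, r, ns)


def parameter_grid(
    queries: list[Spectrum],
    library: SpectralLibrary,
    *,
    pairs: tuple[tuple[int, int], ...] = DEFAULT_PAIRS,
    rs: tuple[int, ...] = DEFAULT_RS,
    ns: tuple[int, ...] = DEFAULT_NS,
    tolerance: float | None = None,
    score_threshold: float = 0.6,
) -> pd.DataFrame:
    """Sweep (n, m) x R; one row per parameter triple.

    Full-search results are computed once and reused for every grid cell.
    Columns: n, m, R, mean_eval_count, and one ``inclusion_rate_top{N}``
    column per requested cutoff N.
    """
    if not queries:
        raise ValueError("need at least one query spectrum")
    if not pairs:
        raise ValueError("need at least one (n, m) pair")
    for n, m in pairs:
        if n > m:
            raise ValueError(f"invalid pair (n={n}, m={m}): need n <= m")

    full = _full_results(
        queries, library, tolerance=tolerance, score_threshold=score_threshold
    )
    rows = []
    for n, m in pairs:
        # one fitted engine per (n, m): the ranking does not depend on R
        engine = LibrarySearch(
            n=n, m=m, r=max(rs), tolerance=tolerance,
            score_threshold=score_threshold,
        ).fit(library)
        ranked = [engine.rank_candidates(q) for q in queries]
        for r in rs:
            candidate_sets = [set(select_candidates(rk, r)) for rk in ranked]
            report = _report(full, candidate_sets, n, m, r, ns)
            row = {"n": n, "m": m, "R": r, "mean_eval_count": report.mean_eval_count}
            for N in ns:
                row[f"inclusion_rate_top{N}"] = report.rates[N]
            rows.append(row)
    return pd.DataFrame(rows)
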