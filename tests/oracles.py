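"""Independent brute-force reference implementations for cross-checking.

Deliberately naive plain-Python code (double loops, no numpy tricks, no
imports from the package's numerical paths) so these stay independent of
the implementations they verify.
"""

from __future__ import annotations

import math


def brute_scale(mz: list[float], intensity: list[float]) -> list[float]:
    """Base-peak normalization followed by the mass/dominance weighting."""
    base = max(intensity)
    rel = [i / base for i in intensity]
    total = sum(rel)
    omega = 1.0 / (total - 0.5)
    return [r * m / (1.0 + omega * r) for r, m in zip(rel, mz)]


def brute_match(qmz: list[float], lmz: list[float], tol: float) -> list[tuple[int, int]]:
    """Greedy one-to-one nearest-m/z pairing by exhaustive enumeration."""
    pairs = [
        (abs(q - l), l, qi, li)
        for qi, q in enumerate(qmz)
        for li, l in enumerate(lmz)
        if abs(q - l) <= tol
    ]
    pairs.sort()
    used_q: set[int] = set()
    used_l: set[int] = set()
    out = []
    for _, _, qi, li in pairs:
        if qi in used_q or li in used_l:
            continue
        used_q.add(qi)
        used_l.add(li)
        out.append((qi, li))
    out.sort(key=lambda p: qmz[p[0]])
    return out


def brute_similarity(
    qmz: list[float], qint: list[float],
    lmz: list[float], lint: list[float],
    tol: float,
) -> float:
    qa = brute_scale(qmz, qint)
    la = brute_scale(lmz, lint)
    num = sum(math.sqrt(qa[i] * la[j]) for i, j in brute_match(qmz, lmz, tol))
    return num * num / (sum(qa) * sum(la))


def brute_similarity_binned(
    qmz: list[float], qint: list[float],
    lmz: list[float], lint: list[float],
) -> float:
    """Exact-m/z binning variant: valid when no two peaks are within 2*tol."""
    qa = dict(zip(qmz, brute_scale(qmz, qint)))
    la = dict(zip(lmz, brute_scale(lmz, lint)))
    num = sum(math.sqrt(qa[m] * la[m]) for m in set(qa) & set(la))
    return num * num / (sum(qa.values()) * sum(la.values()))


def brute_full_search(
    query: tuple[list[float], list[float]],
    library: dict[str, tuple[list[float], list[float]]],
    tol: float,
    score_threshold: float = 0.6,
) -> list[tuple[str, float]]:
    """Double-loop full search: score everything, filter, sort by (-score, id)."""
    hits = []
    for sid, (lmz, lint) in library.items():
        s = brute_similarity(query[0], query[1], lmz, lint, tol)
        if s > score_threshold:
            hits.append((sid, s))
    hits.sort(key=lambda h: (-h[1], h[0]))
    return hits


def brute_top_peaks(mz: list[float], intensity: list[float], depth: int) -> list[float]:
    """Stable sort by (-intensity, -mz), truncated."""
    ranked = sorted(zip(mz, intensity), key=lambda p: (-p[1], -p[0]))
    return [m for m, _ in ranked[:depth]]


def brute_sharing_ids(
    query_mz: list[float],
    library: dict[str, list[float]],
    tol: float,
) -> set[str]:
    """Ids of library spectra sharing >= 1 within-tolerance m/z with the query."""
    out = set()
    for sid, lmz in library.items():
        if any(abs(q - l) <= tol for q in query_mz for l in lmz):
            out.add(sid)
    return out
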