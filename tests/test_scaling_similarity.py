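"""Intensity scaling, peak matching, and sqrt-cosine similarity."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from specscreen import (
    MatchTolerance,
    match_peaks,
    scale_spectrum,
    similarity,
    similarity_spectra,
)

from conftest import make_spectrum, random_library
from oracles import brute_match, brute_scale, brute_similarity, brute_similarity_binned

EXACT = MatchTolerance(1e-9)


@st.composite
def spectra(draw, max_peaks: int = 12):
    """Small random spectra on the unit-mass grid."""
    n = draw(st.integers(1, max_peaks))
    mz = draw(
        st.lists(st.integers(50, 500), min_size=n, max_size=n, unique=True)
    )
    inten = draw(
        st.lists(
            st.floats(1e-3, 1e3, allow_nan=False, allow_infinity=False),
            min_size=n, max_size=n,
        )
    )
    peaks = sorted(zip(mz, inten))
    return make_spectrum("h", peaks)


class TestScaleSpectrum:
    def test_single_dominant_peak(self):
        scaled = scale_spectrum(make_spectrum("s", [(100, 1.0)]))
        # I_total = 1 so omega = 2 and A = 100 / (1 + 2)
        assert scaled.omega == pytest.approx(2.0)
        assert scaled.scaled[0] == pytest.approx(100.0 / 3.0, rel=1e-12)
        assert scaled.total == pytest.approx(100.0 / 3.0, rel=1e-12)

    def test_two_peak_hand_example(self):
        scaled = scale_spectrum(make_spectrum("s", [(50, 1.0), (100, 0.5)]))
        assert scaled.omega == pytest.approx(1.0)
        np.testing.assert_allclose(scaled.scaled, [25.0, 100.0 / 3.0], rtol=1e-12)
        assert scaled.total == pytest.approx(175.0 / 3.0, rel=1e-12)

    def test_normalization_is_intensity_scale_invariant(self):
        a = scale_spectrum(make_spectrum("a", [(50, 200.0), (60, 900.0)]))
        b = scale_spectrum(make_spectrum("b", [(50, 2.0), (60, 9.0)]))
        np.testing.assert_allclose(a.scaled, b.scaled, rtol=1e-12)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(spectra())
    def test_omega_in_unit_to_two_range(self, spectrum):
        scaled = scale_spectrum(spectrum)
        assert 0.0 < scaled.omega <= 2.0
        assert (scaled.scaled > 0).all()
        assert scaled.total == pytest.approx(scaled.scaled.sum(), rel=1e-9)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(spectra())
    def test_matches_brute_force_scaling(self, spectrum):
        scaled = scale_spectrum(spectrum)
        expected = brute_scale(list(spectrum.mz), list(spectrum.intensity))
        np.testing.assert_allclose(scaled.scaled, expected, rtol=1e-12)


class TestMatchPeaks:
    def _scaled(self, peaks):
        return scale_spectrum(make_spectrum("s", peaks))

    def test_exact_coincidence_and_disjoint(self):
        q = self._scaled([(50, 1.0)])
        assert match_peaks(q, self._scaled([(50, 1.0)]), MatchTolerance(0.01)) == [(0, 0)]
        assert match_peaks(q, self._scaled([(60, 1.0)]), MatchTolerance(0.01)) == []

    def test_nearest_of_two_in_tolerance_wins(self):
        q = self._scaled([(100.00, 1.0)])
        lib = self._scaled([(99.995, 1.0), (100.004, 0.5)])
        assert match_peaks(q, lib, MatchTolerance(0.01)) == [(0, 1)]

    def test_one_to_one_no_library_peak_reused(self):
        q = self._scaled([(100.0, 1.0), (100.3, 0.5)])
        lib = self._scaled([(100.1, 1.0)])
        pairs = match_peaks(q, lib, MatchTolerance(0.5))
        assert pairs == [(0, 0)]  # closer query peak claims the only library peak

    def test_distance_tie_prefers_lower_library_mz(self):
        q = self._scaled([(100.0, 1.0)])
        lib = self._scaled([(99.6, 1.0), (100.4, 1.0)])
        assert match_peaks(q, lib, MatchTolerance(0.5)) == [(0, 0)]

    def test_agrees_with_brute_force_assignment(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            nq, nl = rng.integers(1, 10, size=2)
            qmz = np.sort(rng.uniform(50, 80, nq))
            lmz = np.sort(rng.uniform(50, 80, nl))
            q = self._scaled([(m, 1.0) for m in np.unique(qmz)])
            lib = self._scaled([(m, 1.0) for m in np.unique(lmz)])
            got = match_peaks(q, lib, MatchTolerance(0.7))
            want = brute_match(list(q.mz), list(lib.mz), 0.7)
            assert got == want


class TestSimilarity:
    def test_identical_spectra_score_one(self):
        spec = make_spectrum("s", [(50, 0.3), (73, 1.0), (147, 0.6)])
        assert similarity_spectra(spec, spec) == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_spectra_score_zero(self):
        a = make_spectrum("a", [(50, 1.0)])
        b = make_spectrum("b", [(60, 1.0)])
        assert similarity_spectra(a, b) == 0.0

    def test_hand_derived_partial_overlap(self):
        q = make_spectrum("q", [(50, 1.0), (100, 0.5)])
        lib = make_spectrum("l", [(50, 1.0)])
        assert similarity_spectra(q, lib, EXACT) == pytest.approx(3.0 / 7.0, abs=1e-12)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(spectra(), spectra())
    def test_bounded_and_symmetric(self, a, b):
        sa, sb = scale_spectrum(a), scale_spectrum(b)
        tol = MatchTolerance(0.5)
        s_ab = similarity(sa, sb, tol)
        s_ba = similarity(sb, sa, tol)
        assert 0.0 <= s_ab <= 1.0
        assert s_ab == pytest.approx(s_ba, abs=1e-9)

    def test_equals_binning_oracle_on_separated_spectra(self):
        # unit-mass spectra with tol=0.4: every m/z pair differs by > 2*tol,
        # so greedy matching must coincide with exact binning
        rng = np.random.default_rng(17)
        lib = random_library(rng, 30)
        specs = list(lib)
        tol = MatchTolerance(0.4)
        for a, b in zip(specs[:-1], specs[1:]):
            got = similarity(scale_spectrum(a), scale_spectrum(b), tol)
            want = brute_similarity_binned(
                list(a.mz), list(a.intensity), list(b.mz), list(b.intensity)
            )
            assert got == pytest.approx(want, rel=1e-12)

    def test_matches_full_brute_force_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            a = random_library(rng, 1, peak_range=(2, 10))
            b = random_library(rng, 1, peak_range=(2, 10))
            (sa,), (sb,) = list(a), list(b)
            got = similarity_spectra(sa, sb, MatchTolerance(0.5))
            want = brute_similarity(
                list(sa.mz), list(sa.intensity), list(sb.mz), list(sb.intensity), 0.5
            )
            assert got == pytest.approx(want, rel=1e-12)
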