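"""Seeded synthetic spectral libraries and perturbed query sets.

Emulates the two GC-MS acquisition regimes used throughout the package:

* **low resolution** — unit-mass spectra with integer m/z in [50, 500]
  and many fragment peaks (30–150 per spectrum), so top-peak m/z
  collisions between unrelated compounds are common;
* **high resolution** — accurate-mass spectra with 4-decimal m/z and few
  peaks (5–30), where chance collisions are rare.

Peak intensities follow an exponential law (EI fragment abundances are
heavy-tailed) and are base-peak normalized. Queries are perturbed copies
of library spectra: independent peak dropout (never the base peak),
log-normal intensity noise, bounded m/z jitter, and a few spurious
low-intensity peaks — together with the ground-truth source id, so
self-retrieval and inclusion-rate behaviour can be measured without any
external data. Everything is deterministic given (config, seed).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .msp import save_msp
from .scaling import DEFAULT_TOLERANCE
from .spectra import SpectralLibrary, Spectrum


@dataclass(frozen=True)
class FixtureConfig:
    """All knobs of the synthetic benchmark, with per-regime defaults.

    Use :meth:`low_resolution` / :meth:`high_resolution` rather than the
    bare constructor; they fill in the regime-appropriate peak counts,
    m/z grid, and jitter scale.
    """

    resolution_class: str = "low"
    library_size: int = 1000
    peak_count_range: tuple[int, int] = (30, 150)
    mz_range: tuple[float, float] = (50.0, 500.0)
    intensity_rate: float = 1.0          # exponential rate (1/scale)
    n_queries: int = 200
    peak_dropout: float = 0.1
    intensity_noise_sd: float = 0.3      # sd of log-normal multiplier
    mz_jitter_sd: float = 0.0            # Th; clipped at half the match tolerance
    spurious_peak_range: tuple[int, int] = (1, 5)
    spurious_intensity_scale: float = 0.05  # relative to the base peak
    seed: int = 0

    @classmethod
    def low_resolution(cls, **overrides) -> "FixtureConfig":
        """Unit-mass regime: integer m/z in [50, 500], 30–150 peaks."""
        cfg = cls(
            resolution_class="low",
            peak_count_range=(30, 150),
            mz_range=(50.0, 500.0),
            mz_jitter_sd=0.0,
        )
        return replace(cfg, **overrides)

    @classmethod
    def high_resolution(cls, **overrides) -> "FixtureConfig":
        """Accurate-mass regime: 4-decimal m/z, 5–30 peaks."""
        cfg = cls(
            resolution_class="high",
            peak_count_range=(5, 30),
            mz_range=(50.0, 500.0),
            mz_jitter_sd=0.002,
        )
        return replace(cfg, **overrides)

    @property
    def match_tolerance(self) -> float:
        return DEFAULT_TOLERANCE[self.resolution_class]


def _draw_mz(rng: np.random.Generator, config: FixtureConfig, count: int) -> np.ndarray:
    lo, hi = config.mz_range
    if config.resolution_class == "low":
        grid = np.arange(int(np.ceil(lo)), int(np.floor(hi)) + 1)
        if count > grid.size:
            raise ValueError(
                f"peak count {count} exceeds the {grid.size} distinct integer "
                f"m/z values in {config.mz_range}"
            )
        return np.sort(rng.choice(grid, size=count, replace=False)).astype(float)
    # high resolution: 4-decimal m/z, drawn until unique
    mz: np.ndarray = np.empty(0)
    while mz.size < count:
        extra = np.round(rng.uniform(lo, hi, size=count - mz.size), 4)
        mz = np.unique(np.concatenate([mz, extra]))
    return np.sort(mz)


def generate_library(config: FixtureConfig) -> SpectralLibrary:
    """Draw a deterministic synthetic library from the config's seed."""
    lo_count, hi_count = config.peak_count_range
    if not (1 <= lo_count <= hi_count):
        raise ValueError(f"bad peak_count_range {config.peak_count_range}")
    rng = np.random.default_rng(config.seed)
    spectra = []
    width = max(5, len(str(config.library_size)))
    for i in range(config.library_size):
        count = int(rng.integers(lo_count, hi_count + 1))
        mz = _draw_mz(rng, config, count)
        inten = rng.exponential(scale=1.0 / config.intensity_rate, size=count)
        inten = np.maximum(inten, 1e-6)  # exponential draws can underflow to ~0
        inten = inten / inten.max()      # base-peak normalize
        spectra.append(
            Spectrum(
                id=f"LIB{i:0{width}d}",
                mz=mz,
                intensity=inten,
                resolution_class=config.resolution_class,
                name=f"synthetic compound {i}",
            )
        )
    return SpectralLibrary.from_spectra(spectra, config.resolution_class)


def generate_queries(
    library: SpectralLibrary, config: FixtureConfig
) -> list[tuple[Spectrum, str]]:
    """Perturbed copies of library spectra, each with its ground-truth source id.

    The base peak is never dropped and m/z jitter is clipped at half the
    matching tolerance, so every query is guaranteed to share at least one
    within-tolerance peak with its source (re-drawn in the rare case the
    perturbation breaks that).
    """
    if len(library) == 0:
        raise ValueError("empty library")
    # independent stream from the library's: same seed, distinct spawn key
    rng = np.random.default_rng([config.seed, 1])
    ids = library.ids
    source_ids = [ids[int(k)] for k in rng.integers(0, len(ids), size=config.n_queries)]
    tol = config.match_tolerance
    queries: list[tuple[Spectrum, str]] = []
    width = max(5, len(str(config.n_queries)))
    for j, sid in enumerate(source_ids):
        for _ in range(100):
            q = _perturb(library[sid], f"Q{j:0{width}d}", config, rng)
            if _shares_peak(q, library[sid], tol):
                break
        else:  # pragma: no cover - dropout<1 makes this unreachable in practice
            raise RuntimeError("could not generate a query sharing a peak")
        queries.append((q, sid))
    return queries


def _perturb(
    source: Spectrum, query_id: str, config: FixtureConfig, rng: np.random.Generator
) -> Spectrum:
    mz = source.mz.copy()
    inten = source.intensity.copy()
    base_idx = int(np.argmax(inten))
    keep = rng.random(mz.size) >= config.peak_dropout
    keep[base_idx] = True
    mz, inten = mz[keep], inten[keep]
    inten = inten * rng.lognormal(mean=0.0, sigma=config.intensity_noise_sd, size=inten.size)
    if config.mz_jitter_sd > 0:
        half_tol = 0.5 * config.match_tolerance
        jitter = np.clip(
            rng.normal(0.0, config.mz_jitter_sd, size=mz.size), -half_tol, half_tol
        )
        mz = mz + jitter

    s_lo, s_hi = config.spurious_peak_range
    n_spurious = int(rng.integers(s_lo, s_hi + 1))
    if n_spurious > 0:
        extra_mz = _draw_mz(rng, config, n_spurious)
        fresh = ~np.isin(extra_mz, mz)
        extra_mz = extra_mz[fresh]
        extra_int = (
            rng.exponential(scale=config.spurious_intensity_scale, size=extra_mz.size)
            * inten.max()
        )
        extra_int = np.maximum(extra_int, 1e-6 * inten.max())
        mz = np.concatenate([mz, extra_mz])
        inten = np.concatenate([inten, extra_int])

    return Spectrum.from_raw_peaks(
        query_id, mz, inten,
        resolution_class=config.resolution_class,
        name=f"query from {source.id}",
    )


def _shares_peak(query: Spectrum, source: Spectrum, tol: float) -> bool:
    lo = np.searchsorted(source.mz, query.mz - tol, side="left")
    hi = np.searchsorted(source.mz, query.mz + tol, side="right")
    return bool((hi > lo).any())


def write_fixture(config: FixtureConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write library.msp, queries.msp, and truth.csv; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    library = generate_library(config)
    queries = generate_queries(library, config)
    paths = {
        "library": out_dir / "library.msp",
        "queries": out_dir / "queries.msp",
        "truth": out_dir / "truth.csv",
    }
    save_msp(library, paths["library"])
    save_msp(
        SpectralLibrary.from_spectra([q for q, _ in queries], config.resolution_class),
        paths["queries"],
    )
    with open(paths["truth"], "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["query_id", "source_id"])
        for q, sid in queries:
            writer.writerow([q.id, sid])
    return paths
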