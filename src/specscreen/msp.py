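"""Reading and writing NIST MSP text spectral libraries.

MSP is the de-facto plain-text interchange format for EI spectral
libraries: records separated by blank lines, each with ``Name:`` and
``Num Peaks:`` header lines followed by m/z–intensity pairs. Both common
peak-line dialects are accepted — ``mz intensity`` pairs separated by
whitespace and ``mz<tab>intensity;`` pairs terminated by semicolons,
with any number of pairs per line.

The declared ``Num Peaks`` count is validated against the number of
parsed pairs before any cleaning; zero-intensity peaks are then dropped
(logged) and exact-duplicate m/z channels merged by intensity summation.
Metadata lines other than Name/Num Peaks are preserved as opaque
key–value pairs so a read–write cycle is lossless.
"""

from __future__ import annotations

import io
import logging
import re
from typing import Iterable, TextIO

from .spectra import RESOLUTION_CLASSES, SpectralLibrary, Spectrum, SpectrumError

logger = logging.getLogger(__name__)

_ID_KEYS = ("DB#", "ID", "Id")
_NUM_PEAKS_RE = re.compile(r"^num\s*peaks\s*:\s*(\d+)\s*$", re.IGNORECASE)
_HEADER_RE = re.compile(r"^([^:]+):\s?(.*)$")


class MspFormatError(ValueError):
    """A malformed MSP record; names the record index and source line."""

    def __init__(self, message: str, record: int | None = None, line: int | None = None):
        loc = []
        if record is not None:
            loc.append(f"record {record}")
        if line is not None:
            loc.append(f"line {line}")
        super().__init__(f"{message} ({', '.join(loc)})" if loc else message)
        self.record = record
        self.line = line


def read_msp(source: TextIO | str, resolution_class: str = "low") -> SpectralLibrary:
    """Parse an MSP text stream into a :class:`SpectralLibrary`.

    Parameters
    ----------
    source : text stream or str
        Open text file, or the MSP content itself as a string.
    resolution_class : {"low", "high"}
        Regime tag assigned to every parsed spectrum.

    Raises
    ------
    MspFormatError
        On a missing ``Num Peaks`` line, an unparsable peak line, a
        declared-count mismatch, a duplicate record id, or empty input.
    """
    if resolution_class not in RESOLUTION_CLASSES:
        raise SpectrumError(f"resolution_class must be one of {RESOLUTION_CLASSES}")
    if isinstance(source, str):
        source = io.StringIO(source)

    spectra: list[Spectrum] = []
    seen_ids: set[str] = set()
    for rec_index, start_line, lines in _records(source):
        spec = _parse_record(rec_index, start_line, lines, resolution_class)
        if spec.id in seen_ids:
            raise MspFormatError(
                f"duplicate spectrum id {spec.id!r}", record=rec_index
            )
        seen_ids.add(spec.id)
        spectra.append(spec)

    if not spectra:
        raise MspFormatError("no spectra found in MSP source")
    return SpectralLibrary.from_spectra(spectra, resolution_class=resolution_class)


def load_msp(path, resolution_class: str = "low") -> SpectralLibrary:
    """Read an MSP file from disk."""
    with open(path, "r", encoding="utf-8") as fh:
        return read_msp(fh, resolution_class=resolution_class)


def write_msp(library: SpectralLibrary, sink: TextIO) -> None:
    """Write a library as MSP text, one blank-line-separated record per spectrum.

    m/z values are printed with 1 decimal for the low-resolution regime and
    4 decimals for high resolution; the spectrum id is carried on a ``DB#``
    line so round trips preserve identity.
    """
    if len(library) == 0:
        raise SpectrumError("refusing to write an empty library")
    mz_fmt = "{:.1f}" if library.resolution_class == "low" else "{:.4f}"
    for spec in library:
        if spec.n_peaks == 0:  # unreachable for valid Spectrum; guard anyway
            raise SpectrumError(f"spectrum {spec.id!r} has no peaks")
        sink.write(f"Name: {spec.name if spec.name is not None else spec.id}\n")
        sink.write(f"DB#: {spec.id}\n")
        for key, value in spec.metadata.items():
            if key.lower() in ("name", "num peaks") or key in _ID_KEYS:
                continue
            sink.write(f"{key}: {value}\n")
        sink.write(f"Num Peaks: {spec.n_peaks}\n")
        for mz, inten in zip(spec.mz, spec.intensity):
            sink.write(f"{mz_fmt.format(mz)} {inten:.8g}\n")
        sink.write("\n")


def save_msp(library: SpectralLibrary, path) -> None:
    """Write a library to an MSP file on disk."""
    with open(path, "w", encoding="utf-8") as fh:
        write_msp(library, fh)


def _records(source: Iterable[str]):
    """Yield (record_index, first_line_number, lines) for blank-separated records."""
    rec: list[tuple[int, str]] = []
    rec_index = 0
    for lineno, raw in enumerate(source, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if line.strip():
            rec.append((lineno, line))
        elif rec:
            rec_index += 1
            yield rec_index, rec[0][0], rec
            rec = []
    if rec:
        rec_index += 1
        yield rec_index, rec[0][0], rec


def _parse_record(
    rec_index: int, start_line: int, lines: list[tuple[int, str]], resolution_class: str
) -> Spectrum:
    name: str | None = None
    metadata: dict[str, str] = {}
    declared: int | None = None
    peak_lines: list[tuple[int, str]] = []

    in_peaks = False
    for lineno, line in lines:
        if in_peaks:
            peak_lines.append((lineno, line))
            continue
        m = _NUM_PEAKS_RE.match(line)
        if m:
            declared = int(m.group(1))
            in_peaks = True
            continue
        m = _HEADER_RE.match(line)
        if m and not _looks_like_peaks(line):
            key, value = m.group(1).strip(), m.group(2).strip()
            if key.lower() == "name":
                name = value
            else:
                metadata[key] = value
            continue
        raise MspFormatError(
            f"unexpected line before 'Num Peaks': {line!r}",
            record=rec_index, line=lineno,
        )

    if name is None:
        raise MspFormatError("record has no 'Name' line", record=rec_index, line=start_line)
    if declared is None:
        raise MspFormatError(
            "record has no 'Num Peaks' line", record=rec_index, line=start_line
        )

    mzs: list[float] = []
    intens: list[float] = []
    for lineno, line in peak_lines:
        tokens = line.replace(";", " ").replace(",", " ").split()
        if len(tokens) % 2 != 0:
            raise MspFormatError(
                f"odd token count in peak line: {line!r}", record=rec_index, line=lineno
            )
        try:
            values = [float(t) for t in tokens]
        except ValueError:
            raise MspFormatError(
                f"unparsable peak line: {line!r}", record=rec_index, line=lineno
            ) from None
        mzs.extend(values[0::2])
        intens.extend(values[1::2])

    if len(mzs) != declared:
        raise MspFormatError(
            f"'Num Peaks: {declared}' but {len(mzs)} peak pair(s) listed",
            record=rec_index, line=start_line,
        )

    spectrum_id = next(
        (metadata[k] for k in _ID_KEYS if metadata.get(k)), None
    ) or f"record-{rec_index:05d}"
    try:
        return Spectrum.from_raw_peaks(
            spectrum_id, mzs, intens,
            resolution_class=resolution_class, name=name, metadata=metadata,
        )
    except SpectrumError as exc:
        raise MspFormatError(str(exc), record=rec_index, line=start_line) from exc


def _looks_like_peaks(line: str) -> bool:
    """Distinguish a peak line from a 'Key: value' header (m/z never has a colon)."""
    head = line.split(":", 1)[0].strip()
    try:
        float(head)
    except ValueError:
        return False
    return True
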