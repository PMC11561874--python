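"""Core spectral domain types and file I/O.

A :class:`Spectrum` is a wavenumber-indexed absorbance trace; a
:class:`SpectrumSeries` is an ordered set of replicates of one sample on a
single common axis. Spectra are always stored with an ascending wavenumber
axis regardless of file order; the original direction is kept in metadata.

Regions are mapped to index ranges by the *nearest axis point* rule and are
inclusive at both ends: region bounds quoted in the literature (e.g.
1205 cm^-1) rarely coincide with instrument grid points.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    AxisError,
    EmptySeriesError,
    RegionError,
    SpectrumParseError,
    TooShortError,
    UnitError,
    UnsupportedDialectError,
)

__all__ = [
    "Spectrum",
    "SpectrumSeries",
    "Region",
    "InterferentSpec",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_jcampdx",
    "slice_region",
    "assert_common_axis",
]


@dataclass
class Spectrum:
    """One absorbance trace on a strictly monotonic wavenumber axis.

    Parameters
    ----------
    wavenumbers : array-like of float
        Axis in cm^-1, strictly monotonic in either direction. Stored
        ascending.
    absorbance : array-like of float
        Absorbance in AU, same length as ``wavenumbers``, all finite.
    timestamp : float
        Acquisition time in seconds from an arbitrary origin.
    resolution : float, optional
        Nominal instrument resolution in cm^-1.
    label : str
        Free-text identifier.
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    timestamp: float = 0.0
    resolution: float | None = None
    label: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        if wn.ndim != 1 or ab.ndim != 1:
            raise AxisError("wavenumbers and absorbance must be 1-D")
        if wn.size != ab.size:
            raise AxisError(
                f"length mismatch: {wn.size} wavenumbers vs {ab.size} absorbances"
            )
        if wn.size < 2:
            raise TooShortError(f"spectrum needs >= 2 points, got {wn.size}")
        d = np.diff(wn)
        if np.all(d > 0):
            pass
        elif np.all(d < 0):
            wn = wn[::-1].copy()
            ab = ab[::-1].copy()
            self.metadata.setdefault("original_direction", "descending")
        else:
            raise AxisError("wavenumber axis is not strictly monotonic")
        if not np.all(np.isfinite(ab)):
            raise AxisError("absorbance contains non-finite values")
        if not np.all(np.isfinite(wn)):
            raise AxisError("wavenumbers contain non-finite values")
        self.wavenumbers = wn
        self.absorbance = ab

    def __len__(self) -> int:
        return self.wavenumbers.size

    def copy(self, **updates) -> "Spectrum":
        kw = dict(
            wavenumbers=self.wavenumbers.copy(),
            absorbance=self.absorbance.copy(),
            timestamp=self.timestamp,
            resolution=self.resolution,
            label=self.label,
            metadata=dict(self.metadata),
        )
        kw.update(updates)
        return Spectrum(**kw)

    def with_absorbance(self, values: np.ndarray, **meta) -> "Spectrum":
        """Same axis and metadata, new absorbance values."""
        s = self.copy()
        s.absorbance = np.asarray(values, dtype=float)
        if s.absorbance.size != s.wavenumbers.size:
            raise AxisError("replacement absorbance has wrong length")
        s.metadata.update(meta)
        return s


@dataclass
class Region:
    """Inclusive wavenumber interval [lo, hi] in cm^-1."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (self.lo < self.hi):
            raise RegionError(f"region requires lo < hi, got ({self.lo}, {self.hi})")

    def as_tuple(self) -> tuple[float, float]:
        return (self.lo, self.hi)


@dataclass
class InterferentSpec:
    """A named interferent with its correction region and, optionally, a
    separate region used only for estimating the scaling factor.

    When ``gamma_region`` is set it must cover absorption by the *same*
    physical interferent (the caller's responsibility); it is used when sharp
    analyte peaks inside ``correct_region`` would corrupt the estimate.
    """

    name: str
    correct_region: Region
    gamma_region: Region | None = None

    @property
    def gamma_region_used(self) -> Region:
        return self.gamma_region if self.gamma_region is not None else self.correct_region


@dataclass
class SpectrumSeries:
    """Ordered replicate spectra of one sample on an identical axis."""

    spectra: list[Spectrum]
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not self.spectra:
            raise EmptySeriesError("series contains no spectra")
        assert_common_axis_list(self.spectra)
        ts = [s.timestamp for s in self.spectra]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise AxisError("series timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    def __getitem__(self, i):
        return self.spectra[i]

    @property
    def wavenumbers(self) -> np.ndarray:
        return self.spectra[0].wavenumbers

    def stack(self) -> np.ndarray:
        """Replicates as a (n_spectra, n_points) matrix."""
        return np.vstack([s.absorbance for s in self.spectra])


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_FLOAT_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


def read_spectrum_csv(path: str | Path, **spectrum_kwargs) -> Spectrum:
    """Read a two-column CSV (wavenumber cm^-1, absorbance AU).

    One optional header line is tolerated. The returned spectrum is stored
    ascending; a descending file direction is recorded in metadata.
    """
    path = Path(path)
    wn: list[float] = []
    ab: list[float] = []
    with open(path, "r") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = [p.strip() for p in line.split(",")]
            if len(parts) < 2:
                raise SpectrumParseError(
                    f"{path}:{lineno}: expected two comma-separated columns"
                )
            try:
                x, y = float(parts[0]), float(parts[1])
            except ValueError:
                if lineno == 1 and not wn:  # tolerated header
                    continue
                raise SpectrumParseError(
                    f"{path}:{lineno}: non-numeric row {line!r}"
                ) from None
            wn.append(x)
            ab.append(y)
    if len(wn) < 2:
        raise TooShortError(f"{path}: fewer than 2 data rows")
    return Spectrum(np.array(wn), np.array(ab), **spectrum_kwargs)


def write_spectrum_csv(s: Spectrum, path: str | Path) -> None:
    """Write a spectrum as two-column CSV, round-trippable to 1e-12 relative."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("wavenumber_cm-1,absorbance_AU\n")
        for x, y in zip(s.wavenumbers, s.absorbance):
            fh.write(f"{x:.17g},{y:.17g}\n")


def _jcamp_records(text: str) -> list[tuple[str, str]]:
    """Split JCAMP-DX text into (LABEL, content) labelled data records."""
    records: list[tuple[str, str]] = []
    current: list[str] | None = None
    for raw in text.splitlines():
        line = raw.split("$$")[0]  # strip comments
        if line.startswith("##"):
            if current is not None:
                records.append((current[0], "\n".join(current[1:])))
            label, _, rest = line[2:].partition("=")
            current = [label.strip().upper().replace(" ", "").replace("-", "").replace("_", ""), rest.strip()]
        elif current is not None and line.strip():
            current.append(line.strip())
    if current is not None:
        records.append((current[0], "\n".join(current[1:])))
    return records


def read_jcampdx(path: str | Path, **spectrum_kwargs) -> Spectrum:
    """Read a single-block JCAMP-DX 4.24 absorbance spectrum.

    Supports AFFN ``##XYDATA=(X++(Y..Y))`` (axis reconstructed from
    FIRSTX/DELTAX, or evenly spaced between FIRSTX and LASTX) and
    ``##XYPOINTS=(XY..XY)`` dialects. Transmittance files are rejected with
    instructions to convert; multi-block (compound) files are unsupported.
    """
    path = Path(path)
    records = _jcamp_records(path.read_text())
    labels = [lab for lab, _ in records]
    if labels.count("TITLE") > 1 or "BLOCKS" in labels:
        raise UnsupportedDialectError(
            f"{path}: multi-block JCAMP-DX files are not supported"
        )
    fields = {lab: content for lab, content in records}

    yunits = fields.get("YUNITS", "").upper()
    if "TRANSMITTANCE" in yunits:
        raise UnitError(
            f"{path}: YUNITS=TRANSMITTANCE; convert to absorbance "
            "(A = -log10(T)) before reading"
        )

    xfactor = float(fields.get("XFACTOR", "1"))
    yfactor = float(fields.get("YFACTOR", "1"))

    if "XYPOINTS" in fields:
        body = fields["XYPOINTS"]
        # first line is the variable list, e.g. (XY..XY)
        lines = body.split("\n")
        data = " ".join(lines[1:]) if len(lines) > 1 else ""
        nums = [float(t) for t in re.split(r"[,;\s]+", data.strip()) if t]
        if len(nums) % 2:
            raise SpectrumParseError(f"{path}: odd number of XYPOINTS values")
        arr = np.array(nums).reshape(-1, 2)
        wn = arr[:, 0] * xfactor
        ab = arr[:, 1] * yfactor
    elif "XYDATA" in fields:
        body = fields["XYDATA"].split("\n")
        data_lines = body[1:]
        ys: list[float] = []
        xs_first: list[float] = []
        for line in data_lines:
            toks = [t for t in re.split(r"[,;\s]+", line.strip()) if t]
            if not toks:
                continue
            for tok in toks:
                if not _FLOAT_RE.match(tok):
                    raise UnsupportedDialectError(
                        f"{path}: non-AFFN token {tok!r}; compressed (SQZ/DIF) "
                        "XYDATA is not supported"
                    )
            xs_first.append(float(toks[0]) * xfactor)
            ys.extend(float(t) * yfactor for t in toks[1:])
        n = len(ys)
        firstx = float(fields["FIRSTX"]) if "FIRSTX" in fields else xs_first[0]
        if "DELTAX" in fields:
            deltax = float(fields["DELTAX"])
        elif "LASTX" in fields and n > 1:
            deltax = (float(fields["LASTX"]) - firstx) / (n - 1)
        else:
            raise SpectrumParseError(f"{path}: cannot reconstruct X axis")
        wn = firstx + deltax * np.arange(n)
        ab = np.array(ys)
    else:
        raise UnsupportedDialectError(f"{path}: no XYDATA or XYPOINTS block")

    if wn.size < 2:
        raise TooShortError(f"{path}: fewer than 2 data points")
    meta = {"source_format": "jcamp-dx", "title": fields.get("TITLE", "")}
    kw = dict(metadata=meta)
    kw.update(spectrum_kwargs)
    return Spectrum(np.asarray(wn, float), np.asarray(ab, float), **kw)


# ---------------------------------------------------------------------------
# Axis / region arithmetic
# ---------------------------------------------------------------------------


def region_indices(axis: np.ndarray, r: Region) -> tuple[int, int]:
    """Inclusive index range [i_lo, i_hi] of the axis points nearest r.lo/r.hi."""
    if r.hi < axis[0] or r.lo > axis[-1]:
        raise RegionError(
            f"region ({r.lo}, {r.hi}) lies outside axis span "
            f"({axis[0]}, {axis[-1]})"
        )
    i_lo = int(np.argmin(np.abs(axis - r.lo)))
    i_hi = int(np.argmin(np.abs(axis - r.hi)))
    return i_lo, i_hi


def slice_region(s: Spectrum, r: Region) -> tuple[tuple[int, int], Spectrum]:
    """Extract the segment of ``s`` covered by region ``r``.

    Returns the inclusive index range and a copied segment spectrum. The
    segment must contain at least 3 points.
    """
    i_lo, i_hi = region_indices(s.wavenumbers, r)
    n = i_hi - i_lo + 1
    if n < 3:
        raise TooShortError(
            f"region ({r.lo}, {r.hi}) covers only {n} axis point(s); need >= 3"
        )
    seg = Spectrum(
        s.wavenumbers[i_lo : i_hi + 1].copy(),
        s.absorbance[i_lo : i_hi + 1].copy(),
        timestamp=s.timestamp,
        resolution=s.resolution,
        label=s.label,
        metadata=dict(s.metadata),
    )
    return (i_lo, i_hi), seg


def assert_common_axis_list(spectra: Sequence[Spectrum]) -> None:
    if not spectra:
        raise EmptySeriesError("empty spectrum list")
    ref = spectra[0].wavenumbers
    for k, s in enumerate(spectra[1:], start=1):
        if s.wavenumbers.size != ref.size:
            raise AxisError(
                f"spectrum {k} ({s.label or 'unlabelled'}) has {s.wavenumbers.size} "
                f"points, expected {ref.size}"
            )
        neq = np.nonzero(s.wavenumbers != ref)[0]
        if neq.size:
            i = int(neq[0])
            raise AxisError(
                f"spectrum {k} ({s.label or 'unlabelled'}) axis differs first at "
                f"index {i}: {s.wavenumbers[i]!r} != {ref[i]!r}"
            )


def assert_common_axis(series: SpectrumSeries) -> None:
    """Raise AxisError naming the first differing spectrum/index, else no-op."""
    assert_common_axis_list(series.spectra)
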