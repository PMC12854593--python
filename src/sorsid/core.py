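"""Core spectral types and file I/O.

The universal currency of the package is the :class:`Spectrum`: a strictly
increasing Raman-shift axis (cm^-1) with one intensity value per axis point
and a free-form metadata mapping.  A SORS acquisition pairs a "zero" spectrum
(laser and collection co-located, surface/container dominated) with an
"offset" spectrum (collection displaced by a few mm, subsurface/fluid
enriched); the pair is held in :class:`SORSMeasurement` and two to three such
replicates per physical sample are grouped in :class:`SampleRecord`.

File formats are plain text: a two-column CSV dialect with ``# key: value``
header comments, and a minimal JCAMP-DX reader for ``XYDATA=(X++(Y..Y))``
blocks in AFFN (plain numeric) form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpectrumFormatError",
    "AxisError",
    "AlignmentError",
    "DegenerateInputError",
    "WavenumberAxis",
    "Spectrum",
    "SORSMeasurement",
    "SampleRecord",
    "read_spectrum",
    "write_spectrum",
    "resample",
    "truncate",
    "average_replicates",
    "read_manifest",
    "load_cohort",
]

RAW_CHANNELS = ("zero", "offset")


class SpectrumFormatError(ValueError):
    """Malformed spectrum file (wrong column count, non-numeric rows ...)."""


class AxisError(ValueError):
    """Invalid wavenumber axis or out-of-range axis request."""


class AlignmentError(ValueError):
    """Two spectra that must share an axis do not; resample explicitly."""


class DegenerateInputError(ValueError):
    """Input carries no usable signal (e.g. identically-zero spectrum)."""


class WavenumberAxis:
    """Strictly increasing, finite Raman-shift axis in cm^-1 (length >= 2)."""

    __slots__ = ("values",)

    def __init__(self, values: Sequence[float] | np.ndarray):
        arr = np.asarray(values, dtype=float)
        if arr.ndim != 1 or arr.size < 2:
            raise AxisError("axis must be 1-D with at least 2 points")
        if not np.all(np.isfinite(arr)):
            raise AxisError("axis values must be finite")
        if not np.all(np.diff(arr) > 0):
            raise AxisError("axis must be strictly increasing")
        self.values = arr
        self.values.flags.writeable = False

    def __len__(self) -> int:
        return self.values.size

    def __eq__(self, other) -> bool:
        if not isinstance(other, WavenumberAxis):
            return NotImplemented
        return self.values.shape == other.values.shape and bool(
            np.allclose(self.values, other.values, rtol=0.0, atol=1e-9)
        )

    def __repr__(self) -> str:
        v = self.values
        return f"WavenumberAxis({v[0]:g}..{v[-1]:g} cm-1, n={v.size})"


@dataclass
class Spectrum:
    """One spectrum: axis + intensity + metadata.

    ``meta['channel']`` distinguishes raw ``zero``/``offset`` acquisitions
    (which must be non-negative) from derived ``processed`` spectra (which
    may legitimately carry negative values after subtraction or SNV).
    """

    axis: WavenumberAxis
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if not isinstance(self.axis, WavenumberAxis):
            self.axis = WavenumberAxis(self.axis)
        arr = np.asarray(self.intensity, dtype=float)
        if arr.shape != (len(self.axis),):
            raise AlignmentError(
                f"intensity length {arr.shape} does not match axis length "
                f"{len(self.axis)}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValueError("intensities must be finite")
        if self.meta.get("channel") in RAW_CHANNELS and np.any(arr < 0):
            raise ValueError("raw-channel intensities must be non-negative")
        self.intensity = arr

    @property
    def wavenumbers(self) -> np.ndarray:
        return self.axis.values

    def with_intensity(self, intensity: np.ndarray, **meta_updates) -> "Spectrum":
        meta = dict(self.meta)
        meta.update(meta_updates)
        return Spectrum(self.axis, np.asarray(intensity, dtype=float), meta)

    def copy(self) -> "Spectrum":
        return Spectrum(self.axis, self.intensity.copy(), dict(self.meta))


@dataclass
class SORSMeasurement:
    """Paired zero/offset spectra for one replicate of one sample."""

    sample_id: str
    replicate_id: str
    zero: Spectrum
    offset: Spectrum
    offset_distance: float = 5.5  # mm source-collection displacement

    def __post_init__(self):
        if self.offset_distance <= 0:
            raise ValueError("offset_distance must be > 0")
        if self.zero.axis != self.offset.axis:
            raise AlignmentError(
                f"{self.sample_id}/{self.replicate_id}: zero and offset axes "
                "differ; resample onto a common axis first"
            )


@dataclass
class SampleRecord:
    """All replicate measurements of one physical sample."""

    sample_id: str
    expected_label: str = ""
    measurements: list = field(default_factory=list)

    def __post_init__(self):
        if not self.measurements:
            raise ValueError(f"{self.sample_id}: at least one measurement required")
        for m in self.measurements:
            if m.sample_id != self.sample_id:
                raise ValueError(
                    f"measurement {m.sample_id}/{m.replicate_id} does not "
                    f"belong to sample {self.sample_id}"
                )


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _parse_csv2col(lines: Iterable[str], path: str) -> tuple[np.ndarray, np.ndarray, dict]:
    meta: dict = {}
    xs: list[float] = []
    ys: list[float] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise SpectrumFormatError(
                f"{path}:{lineno}: csv2col requires exactly 2 comma-separated "
                f"columns, got {len(parts)}"
            )
        try:
            xs.append(float(parts[0]))
            ys.append(float(parts[1]))
        except ValueError as exc:
            raise SpectrumFormatError(
                f"{path}:{lineno}: non-numeric row {line!r}"
            ) from exc
    if not xs:
        raise SpectrumFormatError(f"{path}: no data rows")
    return np.array(xs), np.array(ys), meta


def _parse_jcampdx(text: str, path: str) -> tuple[np.ndarray, np.ndarray, dict]:
    # Minimal AFFN XYDATA=(X++(Y..Y)) reader; enough for instrument exports
    # saved in the simplest JCAMP-DX form.
    meta: dict = {}
    xs: list[float] = []
    ys: list[float] = []
    in_xy = False
    xfactor = yfactor = 1.0
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            key = key.strip().upper()
            value = value.strip()
            if key == "XYDATA":
                in_xy = True
                continue
            if key == "END":
                in_xy = False
                continue
            if key == "XFACTOR":
                xfactor = float(value)
            elif key == "YFACTOR":
                yfactor = float(value)
            elif value:
                meta[key.lower()] = value
            continue
        if in_xy:
            fields = line.replace(",", " ").split()
            try:
                values = [float(f) for f in fields]
            except ValueError as exc:
                raise SpectrumFormatError(
                    f"{path}:{lineno}: non-numeric JCAMP data line {line!r}"
                ) from exc
            if len(values) < 2:
                raise SpectrumFormatError(
                    f"{path}:{lineno}: XYDATA line needs X followed by >=1 Y"
                )
            x0 = values[0] * xfactor
            yvals = [v * yfactor for v in values[1:]]
            xs.append(x0)
            ys.append(yvals[0])
            if len(yvals) > 1:
                # X++(Y..Y): abscissa increments implicitly; infer step from
                # the previous line spacing once two lines are present.
                raise SpectrumFormatError(
                    f"{path}:{lineno}: multi-Y JCAMP lines require a fixed "
                    "DELTAX; export one XY pair per line"
                )
    if not xs:
        raise SpectrumFormatError(f"{path}: no XYDATA block found")
    return np.array(xs), np.array(ys), meta


def read_spectrum(path: str | Path, dialect: str = "csv2col") -> Spectrum:
    """Read a spectrum file; the axis is sorted ascending if needed."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    if dialect == "csv2col":
        x, y, meta = _parse_csv2col(text.splitlines(), str(path))
    elif dialect == "jcampdx":
        x, y, meta = _parse_jcampdx(text, str(path))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    order = np.argsort(x, kind="stable")
    if not np.all(order == np.arange(x.size)):
        x, y = x[order], y[order]
    return Spectrum(WavenumberAxis(x), y, meta)


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    """Write csv2col: '# key: value' header lines then 'wavenumber,intensity'."""
    path = Path(path)
    lines = [f"# {k}: {v}" for k, v in sorted(spectrum.meta.items())]
    lines += [
        f"{x!r},{y!r}"
        for x, y in zip(spectrum.wavenumbers.tolist(), spectrum.intensity.tolist())
    ]
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Axis operations
# ---------------------------------------------------------------------------

def resample(spectrum: Spectrum, target_axis: WavenumberAxis | np.ndarray) -> Spectrum:
    """Linear interpolation onto ``target_axis`` (no extrapolation)."""
    if not isinstance(target_axis, WavenumberAxis):
        target_axis = WavenumberAxis(target_axis)
    src = spectrum.wavenumbers
    tgt = target_axis.values
    tol = 1e-9 * max(1.0, abs(src[0]), abs(src[-1]))
    if tgt[0] < src[0] - tol or tgt[-1] > src[-1] + tol:
        raise AxisError(
            f"target axis [{tgt[0]:g}, {tgt[-1]:g}] exceeds source span "
            f"[{src[0]:g}, {src[-1]:g}]"
        )
    y = np.interp(tgt, src, spectrum.intensity)
    return Spectrum(target_axis, y, dict(spectrum.meta))


def truncate(spectrum: Spectrum, lo: float = 750.0, hi: float = 1800.0) -> Spectrum:
    """Keep only axis points in the closed interval [lo, hi]."""
    if lo >= hi:
        raise AxisError(f"require lo < hi, got [{lo}, {hi}]")
    x = spectrum.wavenumbers
    mask = (x >= lo) & (x <= hi)
    if mask.sum() < 2:
        raise AxisError(
            f"truncation window [{lo}, {hi}] leaves fewer than 2 of the "
            f"axis points [{x[0]:g}, {x[-1]:g}]"
        )
    return Spectrum(
        WavenumberAxis(x[mask]), spectrum.intensity[mask], dict(spectrum.meta)
    )


def average_replicates(spectra: Sequence[Spectrum]) -> Spectrum:
    """Pointwise arithmetic mean of replicate spectra on a common axis."""
    if not spectra:
        raise ValueError("need at least one spectrum")
    first = spectra[0]
    for s in spectra[1:]:
        if s.axis != first.axis:
            raise AlignmentError("replicates are not on a common axis; resample")
    stack = np.stack([s.intensity for s in spectra])
    meta = dict(first.meta)
    reps = [s.meta.get("replicate_id", "") for s in spectra]
    meta["averaged_replicates"] = ",".join(str(r) for r in reps)
    meta["n_averaged"] = len(spectra)
    return Spectrum(first.axis, stack.mean(axis=0), meta)


# ---------------------------------------------------------------------------
# Cohort manifest
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = [
    "sample_id",
    "replicate_id",
    "zero_path",
    "offset_path",
    "expected_label",
    "offset_mm",
]


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"sample_id": str, "replicate_id": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise SpectrumFormatError(f"{path}: manifest missing columns {missing}")
    return df


def load_cohort(
    manifest_path: str | Path, on_error: str = "raise"
) -> tuple[list[SampleRecord], list[str]]:
    """Load all samples referenced by a manifest CSV.

    ``on_error='skip'`` drops replicates whose spectrum files are missing or
    malformed (and whole samples if no replicate survives), returning the
    problem descriptions alongside the records.
    """
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    df = read_manifest(manifest_path)
    records: list[SampleRecord] = []
    warnings_: list[str] = []
    for sample_id, group in df.groupby("sample_id", sort=False):
        measurements = []
        expected = ""
        for _, row in group.iterrows():
            expected = str(row.get("expected_label", "") or "")
            try:
                zero = read_spectrum(base / str(row["zero_path"]))
                offset = read_spectrum(base / str(row["offset_path"]))
                zero.meta.setdefault("channel", "zero")
                offset.meta.setdefault("channel", "offset")
                measurements.append(
                    SORSMeasurement(
                        sample_id=str(sample_id),
                        replicate_id=str(row["replicate_id"]),
                        zero=zero,
                        offset=offset,
                        offset_distance=float(row["offset_mm"]),
                    )
                )
            except (OSError, ValueError) as exc:
                if on_error == "skip":
                    warnings_.append(
                        f"{sample_id}/{row['replicate_id']}: skipped ({exc})"
                    )
                    continue
                raise
        if measurements:
            records.append(
                SampleRecord(
                    sample_id=str(sample_id),
                    expected_label=expected,
                    measurements=measurements,
                )
            )
        elif on_error == "skip":
            warnings_.append(f"{sample_id}: no usable replicates; sample dropped")
    return records, warnings_
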