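"""Spectrum and manifest I/O.

All spectra travel as two-column delimited text (axis, intensity) with
``# key: value`` header comments carrying metadata; images are single-plane
TIFF (integer labels for nuclei, 0/1 masks for outlines); manifests are CSV.
The dialects are deliberately minimal so every pipeline stage is
file-testable and fixtures stay diffable.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .exceptions import (
    ManifestError,
    SpectrumAxisError,
    SpectrumParseError,
    SpectrumSizeError,
)

#: Experimental conditions used throughout the package.
CONDITIONS = ("control", "rock", "rhoa", "compressed", "flow", "cycle1", "cycle4")

#: Objectives used for acquisition (bulk 20x averages cells + ECM; 60x
#: resolves single cells).
OBJECTIVES = ("20x", "60x")

SPECTRUM_KINDS = ("brillouin", "raman")

#: Minimum number of samples for a spectrum to be considered a real trace.
MIN_POINTS = 16


@dataclass
class Spectrum:
    """A single spectral trace.

    Parameters
    ----------
    kind:
        ``"brillouin"`` (axis in GHz, may span negative to positive
        frequencies around the elastic line) or ``"raman"`` (axis in cm^-1).
    axis:
        Strictly increasing spectral axis.
    intensity:
        Non-negative intensities, same length as ``axis``.
    meta:
        Free-form key/value metadata (sample id, condition, objective, ...).
    """

    kind: str
    axis: np.ndarray
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in SPECTRUM_KINDS:
            raise ValueError(f"unknown spectrum kind {self.kind!r}; expected one of {SPECTRUM_KINDS}")
        self.axis = np.asarray(self.axis, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.axis.ndim != 1 or self.intensity.ndim != 1:
            raise SpectrumAxisError("axis and intensity must be one-dimensional")
        if self.axis.size != self.intensity.size:
            raise SpectrumSizeError(
                f"axis ({self.axis.size}) and intensity ({self.intensity.size}) lengths differ"
            )
        if self.axis.size < 2:
            raise SpectrumSizeError("spectrum needs at least two points")
        d = np.diff(self.axis)
        if np.any(d <= 0):
            raise SpectrumAxisError("axis must be strictly increasing (duplicate or unsorted values)")

    def __len__(self) -> int:
        return self.axis.size

    @property
    def span(self) -> tuple[float, float]:
        return float(self.axis[0]), float(self.axis[-1])

    def copy(self, intensity: np.ndarray | None = None, axis: np.ndarray | None = None) -> "Spectrum":
        return Spectrum(
            kind=self.kind,
            axis=self.axis.copy() if axis is None else np.asarray(axis, float),
            intensity=self.intensity.copy() if intensity is None else np.asarray(intensity, float),
            meta=dict(self.meta),
        )


@dataclass
class SampleRecord:
    """One manifest row: a sample id plus modality file paths."""

    sample_id: str
    condition: str
    objective: str = "20x"
    time_bin_min: str = ""
    brillouin_path: str | None = None
    raman_path: str | None = None
    image_path: str | None = None

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ManifestError(
                f"unknown condition {self.condition!r}; allowed values: {', '.join(CONDITIONS)}"
            )
        if self.objective not in OBJECTIVES:
            raise ManifestError(
                f"unknown objective {self.objective!r}; allowed values: {', '.join(OBJECTIVES)}"
            )


def read_spectrum(path: str | os.PathLike, kind: str, min_points: int = MIN_POINTS) -> Spectrum:
    """Read a two-column text spectrum.

    Whitespace- or comma-delimited numeric rows; ``#`` lines are treated as
    comments and ``# key: value`` pairs are collected into ``meta``. Rows are
    sorted by axis; duplicate axis values are rejected.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    rows: list[tuple[float, float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    meta[key.strip()] = value.strip()
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 2:
                raise SpectrumParseError(f"{path}:{lineno}: expected two columns, got {line!r}")
            try:
                rows.append((float(parts[0]), float(parts[1])))
            except ValueError as exc:
                raise SpectrumParseError(f"{path}:{lineno}: non-numeric row {line!r}") from exc
    if len(rows) < min_points:
        raise SpectrumSizeError(f"{path}: {len(rows)} points, need at least {min_points}")
    arr = np.asarray(rows, dtype=float)
    order = np.argsort(arr[:, 0], kind="stable")
    arr = arr[order]
    if np.any(np.diff(arr[:, 0]) <= 0):
        raise SpectrumAxisError(f"{path}: duplicate axis values after sorting")
    meta.pop("kind", None)
    return Spectrum(kind=kind, axis=arr[:, 0], intensity=arr[:, 1], meta=meta)


def write_spectrum(spectrum: Spectrum, path: str | os.PathLike) -> Path:
    """Write a spectrum as two-column text, metadata in ``#`` header lines.

    Values are written with ``%.17g`` so ``read_spectrum`` round-trips at
    full float precision.
    """
    path = Path(path)
    lines = [f"# kind: {spectrum.kind}"]
    for key, value in spectrum.meta.items():
        lines.append(f"# {key}: {value}")
    for x, y in zip(spectrum.axis, spectrum.intensity):
        lines.append(f"{x:.17g} {y:.17g}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_manifest(path: str | os.PathLike, check_files: bool = True) -> list[SampleRecord]:
    """Read a sample manifest CSV into validated :class:`SampleRecord` rows.

    Relative file paths are resolved against the manifest's directory. Empty
    path cells mean the modality is absent for that sample.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str).fillna("")
    required = {"sample_id", "condition"}
    missing = required - set(df.columns)
    if missing:
        raise ManifestError(f"{path}: missing required columns {sorted(missing)}")
    base = path.parent
    records: list[SampleRecord] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        sid = row["sample_id"]
        if sid in seen:
            raise ManifestError(f"{path}: duplicate sample_id {sid!r}")
        seen.add(sid)
        paths = {}
        for col in ("brillouin_path", "raman_path", "image_path"):
            value = row.get(col, "")
            if value:
                resolved = base / value if not os.path.isabs(value) else Path(value)
                if check_files and not resolved.exists():
                    raise ManifestError(f"{path}: sample {sid!r}: file not found: {resolved}")
                paths[col] = str(resolved)
            else:
                paths[col] = None
        records.append(
            SampleRecord(
                sample_id=sid,
                condition=row["condition"],
                objective=row.get("objective", "20x") or "20x",
                time_bin_min=row.get("time_bin_min", ""),
                **paths,
            )
        )
    return records


def write_manifest(records: Iterable[SampleRecord], path: str | os.PathLike) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "condition": r.condition,
                "objective": r.objective,
                "time_bin_min": r.time_bin_min,
                "brillouin_path": r.brillouin_path or "",
                "raman_path": r.raman_path or "",
                "image_path": r.image_path or "",
            }
            for r in records
        ]
    )
    df.to_csv(path, index=False)
    return path


def read_image(path: str | os.PathLike) -> np.ndarray:
    """Read a single-plane TIFF image (labels, mask, or intensity)."""
    import tifffile

    arr = tifffile.imread(str(path))
    if arr.ndim != 2:
        raise ManifestError(f"{path}: expected a single-plane 2D image, got shape {arr.shape}")
    return arr


def write_image(array: np.ndarray, path: str | os.PathLike) -> Path:
    import tifffile

    tifffile.imwrite(str(path), np.asarray(array))
    return Path(path)
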