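"""Spheroid image morphometry on segmented label/mask images.

Re-implements the confocal quantifications used for mechanically perturbed
spheroids: per-nucleus equivalent-ellipse aspect ratios split into central
vs peripheral zones, the fraction of marker-positive nuclei under a
threshold normalized to secondary-antibody controls, the invasive-to-core
area ratio, and background-subtracted mean intensity over a region (e.g.
interstitial dextran).

Segmentation is out of scope: all operations consume 2D integer label
images (0 = background) or 0/1 masks from any segmenter, taken at the
spheroid's central z-plane.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import distance_transform_edt
from skimage.measure import regionprops

from .exceptions import RegionError, ZoneAssignmentError

__all__ = [
    "NucleusShape",
    "InvasionResult",
    "PositiveFractionResult",
    "nucleus_shapes",
    "classify_zone",
    "positive_fraction",
    "invasion_ratio",
    "region_mean_intensity",
]


@dataclass
class NucleusShape:
    """Moment-equivalent ellipse descriptors of one nucleus."""

    label: int
    centroid: tuple[float, float]  # (row, col) pixels
    major_axis: float
    minor_axis: float
    aspect_ratio: float
    area: float
    zone: str | None = None  # "center" | "periphery"
    mean_intensity: float | None = None


@dataclass
class InvasionResult:
    core_area: float
    invasive_area: float
    ratio: float


@dataclass
class PositiveFractionResult:
    n_total: int
    n_positive: int
    fraction: float
    threshold: float  # in control-normalized intensity units


def nucleus_shapes(
    labels: np.ndarray,
    intensity: np.ndarray | None = None,
    min_area: int = 20,
) -> tuple[list[NucleusShape], int]:
    """Per-label second-moment ellipse axes and aspect ratios.

    Labels smaller than ``min_area`` pixels are dropped; labels whose minor
    axis collapses to zero (collinear pixels) are flagged invalid and
    excluded.  Returns ``(shapes, n_dropped)``.
    """
    labels = np.asarray(labels)
    if labels.ndim != 2:
        raise RegionError("label image must be 2D (central z-plane)")
    props = regionprops(labels, intensity_image=intensity)
    if not props:
        raise RegionError("label image contains no objects")
    shapes: list[NucleusShape] = []
    dropped = 0
    for p in props:
        if p.area < min_area:
            dropped += 1
            continue
        major, minor = float(p.axis_major_length), float(p.axis_minor_length)
        if minor <= 0:
            warnings.warn(f"label {p.label}: degenerate (collinear) shape excluded", RuntimeWarning)
            dropped += 1
            continue
        shapes.append(
            NucleusShape(
                label=int(p.label),
                centroid=(float(p.centroid[0]), float(p.centroid[1])),
                major_axis=major,
                minor_axis=minor,
                aspect_ratio=major / minor,
                area=float(p.area),
                mean_intensity=float(p.intensity_mean) if intensity is not None else None,
            )
        )
    if not shapes:
        raise RegionError(f"no labels with area >= {min_area} pixels")
    return shapes, dropped


def classify_zone(
    shapes: list[NucleusShape],
    spheroid_mask: np.ndarray,
    band: float | None = None,
) -> list[NucleusShape]:
    """Assign each nucleus to the peripheral band or the center.

    A nucleus is peripheral if its centroid lies within ``band`` pixels of
    the spheroid-mask boundary (Euclidean distance transform); otherwise
    central.  ``band`` defaults to the median nucleus major axis of the
    image, a nucleus-sized rim.
    """
    mask = np.asarray(spheroid_mask).astype(bool)
    if band is None:
        band = float(np.median([s.major_axis for s in shapes]))
    dist = distance_transform_edt(mask)
    offenders = []
    out = []
    for s in shapes:
        r = int(round(s.centroid[0]))
        c = int(round(s.centroid[1]))
        if not (0 <= r < mask.shape[0] and 0 <= c < mask.shape[1]) or not mask[r, c]:
            offenders.append(s.label)
            continue
        # distance_transform_edt gives distance to the nearest background
        # pixel; subtract half a pixel so a boundary pixel sits at ~0
        d = float(dist[r, c]) - 0.5
        s.zone = "periphery" if d <= band else "center"
        out.append(s)
    if offenders:
        raise ZoneAssignmentError(f"centroids outside spheroid mask for labels: {offenders}")
    return out


def positive_fraction(
    shapes: list[NucleusShape],
    control_intensities,
    k_sd: float = 2.0,
) -> PositiveFractionResult:
    """Marker-positive nuclear fraction under a control-normalized threshold.

    Each nuclear mean intensity is divided by the mean of the
    secondary-antibody-only control distribution; the threshold is the
    normalized control mean (1 by construction) plus ``k_sd`` normalized
    control SDs.  Nuclei above threshold count as positive.
    """
    control = np.asarray(list(control_intensities), dtype=float)
    if control.size == 0:
        raise RegionError("empty control intensity distribution")
    if any(s.mean_intensity is None for s in shapes):
        raise RegionError("all shapes need mean_intensity for positive_fraction")
    mu = control.mean()
    if mu <= 0:
        raise RegionError("control mean intensity must be positive")
    sd = control.std(ddof=1) / mu if control.size > 1 else 0.0
    threshold = 1.0 + k_sd * sd
    values = np.array([s.mean_intensity for s in shapes], dtype=float) / mu
    n_pos = int(np.sum(values > threshold))
    return PositiveFractionResult(
        n_total=len(shapes),
        n_positive=n_pos,
        fraction=n_pos / len(shapes),
        threshold=float(threshold),
    )


def invasion_ratio(core_mask: np.ndarray, total_mask: np.ndarray) -> InvasionResult:
    """Invasive/core area ratio from the compact-core and total outlines.

    ``ratio = (area(total) - area(core)) / area(core)``; the core is
    intersected with the total outline first, with a consistency warning if
    more than 1% of the core lies outside it.
    """
    core = np.asarray(core_mask).astype(bool)
    total = np.asarray(total_mask).astype(bool)
    if core.shape != total.shape:
        raise RegionError("core and total masks must share a shape")
    core_raw = core.sum()
    if core_raw == 0:
        raise RegionError("empty core mask: invasion ratio undefined")
    outside = np.logical_and(core, ~total).sum()
    if outside > 0.01 * core_raw:
        warnings.warn(
            f"{outside} core pixels ({100 * outside / core_raw:.1f}%) outside the total mask",
            RuntimeWarning,
        )
    core &= total
    core_area = float(core.sum())
    if core_area == 0:
        raise RegionError("core mask disjoint from total mask")
    total_area = float(total.sum())
    invasive = total_area - core_area
    return InvasionResult(core_area=core_area, invasive_area=invasive, ratio=invasive / core_area)


def region_mean_intensity(
    image: np.ndarray,
    mask: np.ndarray,
    background: float | np.ndarray = 0.0,
) -> float:
    """Background-subtracted mean intensity over a mask.

    ``background`` may be a scalar level or an image (e.g. a dye-free
    acquisition), in which case its mean over the same mask is subtracted.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask).astype(bool)
    if mask.sum() == 0:
        raise RegionError("empty mask")
    value = float(image[mask].mean())
    if np.ndim(background) == 0:
        return value - float(background)
    bg = np.asarray(background, dtype=float)
    if bg.shape != image.shape:
        raise RegionError("background image must match the intensity image shape")
    return value - float(bg[mask].mean())
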