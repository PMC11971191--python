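"""Histology particle quantification.

Thresholded connected-component analysis of single-channel fields, with
particles classified into two non-overlapping size windows in square
microns: small "diffuse" dots (tau-PLA signal and dot-like IHC labelling,
1.5-3.5 um^2 by default) and large "perikaryal" lesions (mostly
neurofibrillary tangles, 12.5-100 um^2 by default).  Also provides the
GFAP burden, the percentage of a region of interest covered by
GFAP-immunostained astrocyte signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

__all__ = [
    "ImageGrid",
    "SizeWindows",
    "Particle",
    "ParticleClassCounts",
    "SampleMeanCounts",
    "segment_particles",
    "classify_particles",
    "quantify_image",
    "sample_mean_counts",
    "gfap_burden",
]


@dataclass
class ImageGrid:
    """A single-channel image with its physical pixel size."""

    intensities: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 2 or self.intensities.size == 0:
            raise ValueError("intensities must be a non-empty 2-D array")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")


@dataclass(frozen=True)
class SizeWindows:
    """Closed area intervals (um^2) defining the two particle classes."""

    diffuse_um2: tuple[float, float] = (1.5, 3.5)
    perikaryal_um2: tuple[float, float] = (12.5, 100.0)

    def __post_init__(self) -> None:
        for lo, hi in (self.diffuse_um2, self.perikaryal_um2):
            if lo <= 0 or hi < lo:
                raise ValueError("window bounds must be positive and ordered")
        lo_d, hi_d = self.diffuse_um2
        lo_p, hi_p = self.perikaryal_um2
        if max(lo_d, lo_p) <= min(hi_d, hi_p):
            raise ValueError("diffuse and perikaryal windows must not overlap")


@dataclass(frozen=True)
class Particle:
    pixel_count: int
    area_um2: float
    centroid_px: tuple[float, float]


@dataclass(frozen=True)
class ParticleClassCounts:
    """Diffuse/perikaryal/other particle counts for one image."""

    diffuse_count: int
    perikaryal_count: int
    other_count: int

    @property
    def total(self) -> int:
        return self.diffuse_count + self.perikaryal_count + self.other_count


@dataclass(frozen=True)
class SampleMeanCounts:
    diffuse_mean: float
    perikaryal_mean: float
    other_mean: float
    n_images: int


def segment_particles(
    image: ImageGrid, threshold: float | str = "otsu", connectivity: int = 2
) -> list[Particle]:
    """Threshold and extract connected foreground components.

    Foreground is ``intensity > threshold``; components use 8-connectivity
    by default (``connectivity=2``), matching the behaviour of the usual
    particle-analysis tools, so diagonally touching objects merge.
    ``threshold`` may be a number or ``"otsu"``; Otsu's method needs an
    image with both populations present and raises otherwise, advising an
    explicit threshold.
    """
    img = image.intensities
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise ValueError(f"unknown threshold method {threshold!r}")
        if img.min() == img.max():
            raise ValueError(
                "Otsu thresholding is undefined on a constant image; pass an "
                "explicit intensity threshold"
            )
        thr = threshold_otsu(img)
        mask = img > thr
        if mask.all() or not mask.any():
            raise ValueError(
                "Otsu threshold left the image fully fore- or background; "
                "pass an explicit intensity threshold"
            )
    else:
        mask = img > threshold
    labels = label(mask, connectivity=connectivity)
    pa = image.pixel_size_um**2
    return [
        Particle(
            pixel_count=int(p.area),
            area_um2=float(p.area * pa),
            centroid_px=(float(p.centroid[0]), float(p.centroid[1])),
        )
        for p in regionprops(labels)
    ]


def classify_particles(
    particles: list[Particle], windows: SizeWindows | None = None
) -> ParticleClassCounts:
    """Assign each particle to a size class by its area in square microns.

    Both windows are closed intervals; a particle of exactly 3.5 um^2 is
    diffuse and one of exactly 12.5 um^2 is perikaryal.  Particles outside
    both windows are counted as "other" and excluded from the reported
    pathology counts.
    """
    windows = windows or SizeWindows()
    lo_d, hi_d = windows.diffuse_um2
    lo_p, hi_p = windows.perikaryal_um2
    diffuse = perikaryal = other = 0
    for p in particles:
        if lo_d <= p.area_um2 <= hi_d:
            diffuse += 1
        elif lo_p <= p.area_um2 <= hi_p:
            perikaryal += 1
        else:
            other += 1
    return ParticleClassCounts(diffuse, perikaryal, other)


def quantify_image(
    image: ImageGrid,
    threshold: float | str = "otsu",
    windows: SizeWindows | None = None,
    connectivity: int = 2,
) -> ParticleClassCounts:
    """Segment and classify in one step."""
    return classify_particles(
        segment_particles(image, threshold, connectivity), windows
    )


def sample_mean_counts(per_image_counts: list[ParticleClassCounts]) -> SampleMeanCounts:
    """Arithmetic mean of class counts across a sample's images."""
    if not per_image_counts:
        raise ValueError("no images supplied for this sample")
    n = len(per_image_counts)
    return SampleMeanCounts(
        diffuse_mean=sum(c.diffuse_count for c in per_image_counts) / n,
        perikaryal_mean=sum(c.perikaryal_count for c in per_image_counts) / n,
        other_mean=sum(c.other_count for c in per_image_counts) / n,
        n_images=n,
    )


def gfap_burden(stain_area_um2: float, roi_area_um2: float) -> float:
    """Percent of the region of interest occupied by GFAP staining:
    ``100 * stain_area / roi_area``."""
    if roi_area_um2 <= 0:
        raise ValueError("region-of-interest area must be positive")
    if stain_area_um2 < 0:
        raise ValueError("stain area must be non-negative")
    if stain_area_um2 > roi_area_um2:
        raise ValueError("stain area cannot exceed the region-of-interest area")
    return 100.0 * stain_area_um2 / roi_area_um2
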