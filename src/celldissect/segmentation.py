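"""Label-mask data model and a classical baseline nucleus segmenter.

The deep-learning segmenters used in production microscopy pipelines are
deliberately out of scope here; any external tool can produce a
:class:`LabelMask` and plug into the rest of the pipeline through the
:class:`Segmenter` contract.  The shipped baseline is the classical
adaptive-threshold + distance-transform-watershed recipe.

Coordinate convention (used everywhere in this package): pixel at array
position (row r, col c) has its physical center at
``x = (c + 0.5) * pixel_size_um``, ``y = (r + 0.5) * pixel_size_um``,
origin at the image top-left, x rightward, y downward.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, runtime_checkable

import numpy as np
import tifffile
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_li, threshold_otsu
from skimage.measure import regionprops
from skimage.morphology import remove_small_objects
from skimage.segmentation import watershed

__all__ = [
    "LabelMask",
    "ObjectInfo",
    "Segmenter",
    "baseline_segment",
    "mask_to_objects",
    "read_mask_tiff",
    "write_mask_tiff",
]


@dataclass(frozen=True)
class LabelMask:
    """Integer instance-label image with physical pixel size.

    Label 0 is background; positive labels are objects.  Labels need not be
    contiguous integers, but every positive label present occupies at least
    one pixel by construction.
    """

    labels: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 2:
            raise ValueError("label image must be 2D")
        if not np.issubdtype(labels.dtype, np.integer):
            raise ValueError("label image must have an integer dtype")
        if labels.size and labels.min() < 0:
            raise ValueError("labels must be non-negative")
        if not (self.pixel_size_um > 0):
            raise ValueError("pixel_size_um must be positive")
        object.__setattr__(self, "labels", labels)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def object_labels(self) -> np.ndarray:
        """Sorted array of the positive labels present."""
        u = np.unique(self.labels)
        return u[u > 0]

    @property
    def n_objects(self) -> int:
        return int(self.object_labels.size)


@dataclass(frozen=True)
class ObjectInfo:
    """One labeled object: its pixels, physical centroid and bounding box."""

    label: int
    pixels: np.ndarray  # (n, 2) array of (row, col)
    centroid_um: tuple[float, float]  # (x, y)
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col) inclusive-exclusive


@runtime_checkable
class Segmenter(Protocol):
    """Contract for any instance segmenter usable by the pipeline.

    Implementations must be deterministic for fixed parameters and return a
    mask with the same shape as the input image.
    """

    def __call__(
        self, image: np.ndarray, pixel_size_um: float, second_channel: np.ndarray | None = None
    ) -> LabelMask: ...


_THRESHOLD_METHODS = {"otsu": threshold_otsu, "li": threshold_li}


def baseline_segment(
    image: np.ndarray,
    pixel_size_um: float,
    *,
    blur_sigma_um: float = 1.0,
    threshold_method: str | float = "otsu",
    min_area_um2: float = 10.0,
    split_footprint_um: float = 8.0,
) -> LabelMask:
    """Classical threshold-and-split instance segmentation.

    Gaussian blur, global threshold (Otsu/Li or a fixed value), removal of
    objects below ``min_area_um2``, then distance-transform watershed to
    split touching objects.  Watershed seeds are local maxima of the
    (smoothed) distance transform at least ``split_footprint_um`` apart, so
    elongated nuclei are not over-seeded along their medial ridge.

    Output labels are renumbered 1..n in raster-scan order of object
    centroids.  An all-background result is legal and yields an empty mask.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2D")
    if not np.all(np.isfinite(image)):
        raise ValueError("image must contain finite values")

    px = float(pixel_size_um)
    sigma_px = blur_sigma_um / px
    blurred = gaussian(image, sigma=sigma_px, preserve_range=True) if sigma_px > 0 else image

    if isinstance(threshold_method, str):
        try:
            thresh_fn = _THRESHOLD_METHODS[threshold_method]
        except KeyError:
            raise ValueError(f"unknown threshold method {threshold_method!r}") from None
        if np.ptp(blurred) == 0:  # constant image: nothing to segment
            return LabelMask(np.zeros(image.shape, dtype=np.int32), px)
        thresh = thresh_fn(blurred)
    else:
        thresh = float(threshold_method)
    binary = blurred > thresh

    min_px = max(1, int(round(min_area_um2 / px**2)))
    binary = remove_small_objects(binary, max_size=min_px - 1)
    if not binary.any():
        return LabelMask(np.zeros(image.shape, dtype=np.int32), px)

    dist = ndi.distance_transform_edt(binary)
    dist_smooth = ndi.gaussian_filter(dist, sigma=2.0)
    min_dist_px = max(1, int(round(split_footprint_um / px)))
    coords = peak_local_max(
        dist_smooth,
        min_distance=min_dist_px,
        labels=ndi.label(binary)[0],
        exclude_border=False,
    )
    markers = np.zeros(binary.shape, dtype=np.int32)
    markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
    labels = watershed(-dist, markers, mask=binary)

    # post-split size filter, then stable raster-scan relabeling
    for r in regionprops(labels):
        if r.area < min_px:
            labels[labels == r.label] = 0
    out = np.zeros_like(labels, dtype=np.int32)
    props = sorted(regionprops(labels), key=lambda r: (r.centroid[0], r.centroid[1]))
    for new_label, r in enumerate(props, start=1):
        out[labels == r.label] = new_label
    return LabelMask(out, px)


def mask_to_objects(mask: LabelMask) -> list[ObjectInfo]:
    """Enumerate the objects of a mask with physical centroids.

    Centroid is the mean of pixel centers in µm under the package-wide
    pixel-center convention.
    """
    out: list[ObjectInfo] = []
    px = mask.pixel_size_um
    objects = ndi.find_objects(mask.labels)
    for idx, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        rows, cols = np.nonzero(mask.labels[sl] == idx)
        rows = rows + sl[0].start
        cols = cols + sl[1].start
        cx = float((cols + 0.5).mean() * px)
        cy = float((rows + 0.5).mean() * px)
        out.append(
            ObjectInfo(
                label=idx,
                pixels=np.column_stack([rows, cols]),
                centroid_um=(cx, cy),
                bbox=(sl[0].start, sl[1].start, sl[0].stop, sl[1].stop),
            )
        )
    return out


def write_mask_tiff(path, mask: LabelMask) -> None:
    """Write a mask as 16-bit label TIFF; pixel size stored as resolution tag."""
    labels = mask.labels
    if labels.size and labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("too many labels for 16-bit TIFF")
    tifffile.imwrite(
        path,
        labels.astype(np.uint16),
        resolution=(1.0 / mask.pixel_size_um, 1.0 / mask.pixel_size_um),
        metadata={"unit": "um", "pixel_size_um": mask.pixel_size_um},
    )


def read_mask_tiff(path, pixel_size_um: float | None = None) -> LabelMask:
    """Read a label TIFF; pixel size from the argument or the TIFF tags."""
    with tifffile.TiffFile(path) as tf:
        labels = tf.asarray().astype(np.int32)
        if pixel_size_um is None:
            page = tf.pages[0]
            res = page.tags.get("XResolution")
            if res is None:
                raise ValueError("pixel size not stored in TIFF; pass pixel_size_um")
            num, den = res.value
            pixel_size_um = den / num
    return LabelMask(labels, float(pixel_size_um))
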