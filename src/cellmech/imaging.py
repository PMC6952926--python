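"""Actin-aggregate quantification from phalloidin-channel images.

The readout is the aggregate area as a percentage of total cytoskeleton
area.  Cytoskeleton is segmented by Otsu thresholding of a Gaussian-smoothed
image; aggregates are bright puncta extracted with a white top-hat filter
and an in-mask ``mean + k sigma`` threshold.  Images are assumed pre-cropped
to single cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.filters import threshold_otsu
from skimage.morphology import disk, remove_small_objects, white_tophat

from .errors import EmptyMaskError


def _drop_small(mask: np.ndarray, min_size: int) -> np.ndarray:
    """remove_small_objects across the skimage 0.26 parameter rename."""
    try:
        return remove_small_objects(mask, max_size=min_size - 1)
    except TypeError:  # older scikit-image
        return remove_small_objects(mask, min_size=min_size)


@dataclass
class ImageQuant:
    """Aggregate quantification of one image."""

    cytoskeleton_area_px: int
    aggregate_area_px: int

    @property
    def aggregate_fraction_percent(self) -> float:
        return 100.0 * self.aggregate_area_px / self.cytoskeleton_area_px


def segment_cytoskeleton(image: np.ndarray, sigma_px: float = 2.0) -> np.ndarray:
    """Binary cytoskeleton mask by Otsu thresholding of the smoothed image.

    Connected components smaller than 64 px are discarded.  A blank
    (constant) image or an empty final mask raises :class:`EmptyMaskError`.
    Otsu's criterion is invariant to affine intensity rescaling, so the
    mask does not depend on overall gain.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    smoothed = gaussian_filter(img, sigma_px)
    if np.ptp(smoothed) == 0:
        raise EmptyMaskError("uniform-intensity image: nothing to segment")
    # Clip the brightest 1% before computing the threshold: very bright
    # puncta otherwise pull Otsu's split above the filament intensity and
    # collapse the mask onto the aggregates alone.  Clipping at a quantile
    # preserves invariance to affine intensity rescaling.
    capped = np.minimum(smoothed, np.quantile(smoothed, 0.99))
    mask = smoothed > threshold_otsu(capped)
    mask = _drop_small(mask, 64)
    if not mask.any():
        raise EmptyMaskError("segmentation produced an empty mask")
    return mask


def quantify_aggregates(
    image: np.ndarray,
    mask: np.ndarray,
    tophat_radius_px: int = 5,
    k_sigma: float = 3.0,
    min_area_px: int = 4,
) -> ImageQuant:
    """Quantify bright puncta (aggregates) within the cytoskeleton mask.

    A white top-hat with a disk structuring element isolates features
    smaller than the element; pixels whose response exceeds
    ``mean + k_sigma * SD`` (statistics over the mask) are aggregate
    candidates, intersected with the mask, and components below
    ``min_area_px`` are dropped.
    """
    if not np.any(mask):
        raise EmptyMaskError("cytoskeleton mask is empty")
    img = np.asarray(image, dtype=float)
    th = white_tophat(img, footprint=disk(tophat_radius_px))
    vals = th[mask]
    thr = float(vals.mean() + k_sigma * vals.std())
    agg = (th > thr) & mask
    agg = _drop_small(agg, min_area_px)
    return ImageQuant(
        cytoskeleton_area_px=int(mask.sum()),
        aggregate_area_px=int(agg.sum()),
    )


def quantify_image(image: np.ndarray, sigma_px: float = 2.0, **kwargs) -> ImageQuant:
    """Segment and quantify in one call."""
    mask = segment_cytoskeleton(image, sigma_px=sigma_px)
    return quantify_aggregates(image, mask, **kwargs)


def read_image(path: str | Path) -> np.ndarray:
    """Read a single-channel TIFF or PNG image."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        return tifffile.imread(path)
    from skimage.io import imread

    return imread(path)


def write_image(image: np.ndarray, path: str | Path) -> Path:
    """Write an image; 16-bit TIFF for .tif/.tiff, PNG otherwise."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, np.asarray(image, dtype=np.uint16))
    else:
        from skimage.io import imsave

        imsave(path, image)
    return path


def quantify_directory(images_dir: str | Path, **kwargs):
    """Quantify every TIFF/PNG in a directory; returns a pandas DataFrame."""
    import pandas as pd

    rows = []
    for path in sorted(Path(images_dir).iterdir()):
        if path.suffix.lower() not in (".tif", ".tiff", ".png"):
            continue
        quant = quantify_image(read_image(path), **kwargs)
        rows.append(
            {
                "image": path.name,
                "cytoskeleton_area_px": quant.cytoskeleton_area_px,
                "aggregate_area_px": quant.aggregate_area_px,
                "fraction_percent": quant.aggregate_fraction_percent,
            }
        )
    return pd.DataFrame(rows)
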