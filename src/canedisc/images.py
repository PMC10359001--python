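"""RGB leaf images: segmentation, band attributes and pixel resampling.

Images are plain ``uint8`` arrays of shape (height, width, 3) in (R, G, B)
channel order; masks are boolean arrays of the same height/width.  Attributes
of an image are per-channel mean intensities over the leaf mask — a 3-vector
for ``"RGB"`` or a 1-vector for ``"R"``.

A *pixel-resampling image* is a bootstrap pseudo-image: ``n`` pixels drawn
uniformly with replacement from the masked (leaf) pixels.  Its attribute
vector estimates the image attributes with variance σ²/n per channel, which is
what the Mahalanobis protocol uses as its "within" variability.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = [
    "SegmentationError",
    "AttributeError_",
    "PixelResample",
    "channel_indices",
    "attribute_names",
    "read_image",
    "write_image",
    "segment_leaf",
    "masked_pixel_table",
    "extract_band_means",
    "resample_pixels",
    "resample_mean",
]

_CHANNELS = {"R": 0, "G": 1, "B": 2}


class SegmentationError(RuntimeError):
    """Raised when no leaf foreground can be found."""


class AttributeError_(ValueError):
    """Raised for invalid attribute sets or empty masks."""


def channel_indices(attrs: str) -> tuple[int, ...]:
    """Map an attribute set like ``"RGB"`` or ``"R"`` to channel indices."""
    if not attrs:
        raise AttributeError_("attribute set must be nonempty")
    try:
        return tuple(_CHANNELS[c] for c in attrs)
    except KeyError as exc:
        raise AttributeError_(f"unknown channel {exc} in attrs {attrs!r}") from exc


def attribute_names(attrs: str) -> tuple[str, ...]:
    channel_indices(attrs)  # validate
    return tuple(attrs)


def _check_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise AttributeError_(f"expected (H, W, 3) image, got shape {image.shape}")
    if image.size == 0:
        raise AttributeError_("empty image")
    return image


def read_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit RGB image (PNG/TIFF) as a (H, W, 3) uint8 array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"), dtype=np.uint8)


def write_image(image: np.ndarray, path: str | Path) -> None:
    Image.fromarray(_check_image(image).astype(np.uint8), mode="RGB").save(path)


def segment_leaf(
    image: np.ndarray,
    brightness_threshold: int = 240,
    keep_largest: bool = True,
    min_pixels: int = 1,
) -> np.ndarray:
    """Segment leaf pixels from a bright background.

    A pixel is background when its *minimum* channel intensity exceeds
    ``brightness_threshold`` (white/bright pixels are high in every channel;
    leaf pixels are dark in at least one).  Optionally only the largest
    8-connected foreground component is kept, which discards stray debris.
    """
    image = _check_image(image)
    fg = image.min(axis=2) <= brightness_threshold
    if not fg.any():
        raise SegmentationError(
            f"no pixel below brightness threshold {brightness_threshold}"
        )
    if keep_largest:
        labels, n = ndimage.label(fg, structure=np.ones((3, 3), dtype=int))
        sizes = ndimage.sum_labels(fg, labels, index=np.arange(1, n + 1))
        fg = labels == (1 + int(np.argmax(sizes)))
    if int(fg.sum()) < min_pixels:
        raise SegmentationError(
            f"foreground has {int(fg.sum())} pixels, fewer than min_pixels={min_pixels}"
        )
    return fg


def masked_pixel_table(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """(n_pixels, 3) float table of the masked pixels' channel values."""
    image = _check_image(image)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape[:2]:
        raise AttributeError_("mask shape does not match image")
    if not mask.any():
        raise AttributeError_("empty mask")
    return image[mask].astype(np.float64)


def extract_band_means(image: np.ndarray, mask: np.ndarray, attrs: str = "RGB") -> np.ndarray:
    """Mean intensity per selected channel over the masked pixels."""
    idx = channel_indices(attrs)
    table = masked_pixel_table(image, mask)
    return table[:, list(idx)].mean(axis=0)


@dataclass(frozen=True)
class PixelResample:
    """One bootstrap pseudo-image: ``values`` is an (n, 3) pixel table."""

    n: int
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.n < 1 or self.values.shape != (self.n, 3):
            raise AttributeError_("inconsistent resample table")


def resample_pixels(
    image: np.ndarray,
    mask: np.ndarray,
    n: int,
    rng: np.random.Generator | int | None = None,
) -> PixelResample:
    """Draw ``n`` masked pixels uniformly with replacement.

    ``n`` must be smaller than the number of masked pixels.  Reproducible
    given a seeded generator.
    """
    table = masked_pixel_table(image, mask)
    total = table.shape[0]
    if not 1 <= n < total:
        raise AttributeError_(
            f"resample size n={n} must satisfy 1 <= n < masked pixel count {total}"
        )
    rng = np.random.default_rng(rng)
    idx = rng.integers(0, total, size=n)
    return PixelResample(n=n, values=table[idx])


def resample_mean(resample: PixelResample, attrs: str = "RGB") -> np.ndarray:
    """Attribute vector (per-channel mean) of a pixel-resampling image."""
    idx = channel_indices(attrs)
    return resample.values[:, list(idx)].mean(axis=0)
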