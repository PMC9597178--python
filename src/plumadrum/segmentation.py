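"""Masked-image loading and colour-map construction.

An image is segmented into a small set of discrete colour classes in three
steps: (1) histogram binning in sRGB with a fixed number of bins per channel
(default 3, giving at most 27 bins), (2) agglomerative reclustering of the
bin centroids in CIE Lab space under a ΔE cutoff, and (3) relabelling of
every valid pixel to the nearest merged centroid.  Images are compared at a
common sampling frequency by nearest-neighbour downsampling to a shared
pixel width before segmentation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from PIL import Image

from plumadrum.colorspace import (
    LabColor,
    pairwise_delta_e,
    rgb_array_to_lab,
)

#: Default ΔE cutoff for reclustering (an alternative value of 55 is in
#: use in some workflows; pass ``cutoff=55`` to use it).
DEFAULT_CUTOFF = 45.0

#: Alpha value (8-bit) at and above which a pixel counts as valid plumage.
ALPHA_THRESHOLD = 128


class MissingAlphaError(ValueError):
    """Raised when a PNG has no alpha channel and no explicit override."""


@dataclass
class MaskedImage:
    """A pixel grid of 8-bit sRGB values plus a validity mask.

    ``mask`` is True where the pixel is plumage (valid) and False where it
    is background.
    """

    pixels: np.ndarray  # (H, W, 3) uint8
    mask: np.ndarray  # (H, W) bool

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.uint8)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.pixels.ndim != 3 or self.pixels.shape[-1] != 3:
            raise ValueError("pixels must have shape (H, W, 3)")
        if self.mask.shape != self.pixels.shape[:2]:
            raise ValueError("mask and pixel grids must share dimensions")
        if not self.mask.any():
            raise ValueError("image has no valid (unmasked) pixels")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())


@dataclass
class ColorBin:
    """A non-empty sRGB histogram bin.

    The centroid is the mean sRGB of the member pixels converted to Lab.
    """

    centroid: LabColor
    count: int
    bin_index: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("bin count must be non-negative")


@dataclass
class ColorMap:
    """Per-pixel colour-class labels with a Lab palette and proportions.

    Background pixels carry the sentinel label −1.  ``proportions`` are the
    fractions of valid pixels per class and sum to 1.
    """

    labels: np.ndarray  # (H, W) int, -1 = background
    palette: np.ndarray  # (k, 3) Lab
    proportions: np.ndarray  # (k,)
    palette_delta_e: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.palette = np.asarray(self.palette, dtype=float)
        self.proportions = np.asarray(self.proportions, dtype=float)
        k = len(self.palette)
        if k < 1:
            raise ValueError("colour map must have at least one class")
        if len(self.proportions) != k:
            raise ValueError("palette/proportions length mismatch")
        if not np.isclose(self.proportions.sum(), 1.0, atol=1e-9):
            raise ValueError("proportions must sum to 1 over valid pixels")
        if self.labels.max() >= k:
            raise ValueError("label indexes a missing palette entry")
        if self.palette_delta_e is None:
            self.palette_delta_e = pairwise_delta_e(self.palette)

    @property
    def n_classes(self) -> int:
        return len(self.palette)

    def to_json(self) -> str:
        return json.dumps(
            {
                "palette_lab": self.palette.tolist(),
                "proportions": self.proportions.tolist(),
                "palette_delta_e": self.palette_delta_e.tolist(),
            },
            indent=2,
        )


def load_masked_image(png_path, allow_missing_alpha: bool = False) -> MaskedImage:
    """Load an RGBA PNG into a :class:`MaskedImage`.

    The mask is True where alpha ≥ 128 (i.e. ≥ 0.5 on the unit scale).
    A file without an alpha channel raises :class:`MissingAlphaError`
    unless ``allow_missing_alpha`` is set, in which case the mask is
    all-True.
    """
    with Image.open(png_path) as im:
        has_alpha = "A" in im.getbands()
        if not has_alpha and not allow_missing_alpha:
            raise MissingAlphaError(
                f"{png_path}: no alpha channel; pass allow_missing_alpha=True "
                "to treat every pixel as plumage"
            )
        rgba = np.asarray(im.convert("RGBA"))
    pixels = rgba[..., :3]
    mask = rgba[..., 3] >= ALPHA_THRESHOLD if has_alpha else np.ones(rgba.shape[:2], bool)
    return MaskedImage(pixels=pixels, mask=mask)


def write_masked_image(img: MaskedImage, png_path) -> None:
    """Write a :class:`MaskedImage` as an RGBA PNG (alpha 255/0)."""
    rgba = np.dstack([img.pixels, np.where(img.mask, 255, 0).astype(np.uint8)])
    Image.fromarray(rgba, mode="RGBA").save(png_path)


def resample_to_common_width(img: MaskedImage, target_width: int) -> MaskedImage:
    """Nearest-neighbour downsample to ``target_width`` pixels wide.

    Height scales to preserve aspect ratio; the mask is sampled on the same
    grid, and no new colours are invented.  Requesting a width larger than
    the source passes the image through unchanged with a warning (never
    upsample).
    """
    if target_width < 2:
        raise ValueError("target_width must be at least 2")
    w, h = img.width, img.height
    if target_width > w:
        warnings.warn(
            f"target width {target_width} exceeds source width {w}; "
            "passing image through unchanged",
            stacklevel=2,
        )
        return MaskedImage(pixels=img.pixels.copy(), mask=img.mask.copy())
    if target_width == w:
        return MaskedImage(pixels=img.pixels.copy(), mask=img.mask.copy())
    target_height = max(1, round(h * target_width / w))
    cols = np.minimum((np.arange(target_width) + 0.5) * w / target_width, w - 1).astype(int)
    rows = np.minimum((np.arange(target_height) + 0.5) * h / target_height, h - 1).astype(int)
    return MaskedImage(
        pixels=img.pixels[np.ix_(rows, cols)],
        mask=img.mask[np.ix_(rows, cols)],
    )


def bin_colors(img: MaskedImage, bins_per_channel: int = 3) -> list[ColorBin]:
    """Histogram the valid pixels into ``bins_per_channel``³ sRGB bins.

    A pixel with channels (r, g, b) falls in bin
    (⌊B·r/256⌋, ⌊B·g/256⌋, ⌊B·b/256⌋).  Each non-empty bin carries the mean
    sRGB of its members converted to Lab as centroid; empty bins are
    dropped.
    """
    if bins_per_channel < 1:
        raise ValueError("bins_per_channel must be positive")
    b = bins_per_channel
    valid = img.pixels[img.mask].astype(np.int64)  # (N, 3)
    idx = (valid * b) // 256  # per-channel bin in {0..b-1}
    code = idx[:, 0] * b * b + idx[:, 1] * b + idx[:, 2]
    counts = np.bincount(code, minlength=b**3)
    sums = np.zeros((b**3, 3))
    for ch in range(3):
        sums[:, ch] = np.bincount(code, weights=valid[:, ch], minlength=b**3)
    bins: list[ColorBin] = []
    for flat in np.flatnonzero(counts):
        mean_rgb = sums[flat] / counts[flat]
        lab = rgb_array_to_lab(mean_rgb[None])[0]
        tri = (flat // (b * b), (flat // b) % b, flat % b)
        bins.append(
            ColorBin(
                centroid=LabColor(*map(float, lab)),
                count=int(counts[flat]),
                bin_index=tuple(map(int, tri)),
            )
        )
    return bins


def recluster(
    bins: list[ColorBin] | list[tuple[np.ndarray, int]],
    cutoff: float = DEFAULT_CUTOFF,
) -> list[tuple[np.ndarray, int]]:
    """Agglomeratively merge clusters closer than ``cutoff`` ΔE.

    Repeatedly merges the closest pair with ΔE < cutoff, replacing it by
    the pixel-count-weighted Lab centroid, until no pair is below cutoff.
    Ties break on the lowest pair of cluster indices.  Returns
    ``(centroid Lab array, count)`` pairs; the operation is idempotent.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if not bins:
        raise ValueError("need at least one bin")
    if isinstance(bins[0], ColorBin):
        clusters = [(np.asarray(b.centroid, float), int(b.count)) for b in bins]
    else:
        clusters = [(np.asarray(c, float), int(n)) for c, n in bins]
    while len(clusters) > 1:
        cents = np.array([c for c, _ in clusters])
        d = pairwise_delta_e(cents)
        iu = np.triu_indices(len(clusters), k=1)
        pair_d = d[iu]
        best = np.argmin(pair_d)  # first occurrence = lowest (i, j)
        if pair_d[best] >= cutoff:
            break
        i, j = int(iu[0][best]), int(iu[1][best])
        (ci, ni), (cj, nj) = clusters[i], clusters[j]
        merged = ((ci * ni + cj * nj) / (ni + nj), ni + nj)
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return clusters


def make_color_map(
    img: MaskedImage,
    cutoff: float = DEFAULT_CUTOFF,
    bins_per_channel: int = 3,
) -> ColorMap:
    """Bin, recluster, and relabel every valid pixel to its nearest centroid.

    Composite of :func:`bin_colors` → :func:`recluster` → nearest-ΔE
    relabelling.  Classes left with zero pixels after relabelling are
    dropped; proportions are fractions of valid pixels.
    """
    bins = bin_colors(img, bins_per_channel=bins_per_channel)
    clusters = recluster(bins, cutoff=cutoff)
    palette = np.array([c for c, _ in clusters])
    lab = rgb_array_to_lab(img.pixels.astype(float))
    # squared ΔE to every centroid; argmin is the nearest class
    d2 = ((lab[:, :, None, :] - palette[None, None, :, :]) ** 2).sum(axis=-1)
    labels = np.argmin(d2, axis=-1)
    labels = np.where(img.mask, labels, -1)
    counts = np.bincount(labels[img.mask], minlength=len(palette))
    keep = np.flatnonzero(counts)
    remap = -np.ones(len(palette), dtype=int)
    remap[keep] = np.arange(len(keep))
    labels = np.where(labels >= 0, remap[np.maximum(labels, 0)], -1)
    palette = palette[keep]
    proportions = counts[keep] / counts.sum()
    return ColorMap(labels=labels, palette=palette, proportions=proportions)
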