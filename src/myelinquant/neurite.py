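"""Neurite segmentation.

The default route normalizes local contrast (NLC) before thresholding so
that dim and bright regions of the same field — and fields acquired at
different illumination or exposure — binarize consistently.  For a window
of radius ``r`` centred at pixel ``p`` with local mean ``mu(p)`` and
standard deviation ``s(p)``, and ``M = 2**bit_depth - 1``::

    out(p) = clamp( center_term + (in(p) - mu(p)) * gain(p), 0, M )
    center_term = M/2            if center else mu(p)
    gain(p)     = (M/2) / (k * max(s(p), eps))   if stretch else 1

``eps`` = 1 intensity unit keeps flat regions from exploding.  With center
and stretch on (the default), local structure ``k`` standard deviations
above its surroundings maps to full scale regardless of absolute gain —
which is what makes the derived percent-neurite-density robust to global
intensity changes.

Alternatively a standard automatic histogram threshold (Otsu, mean,
triangle, isodata) can be applied to the raw channel.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Dict, Literal

import numpy as np
from scipy import ndimage
from skimage import filters

from .core_io import BinaryMask, ChannelImage
from .myelin import attribute_filter_area

NLC_SIGMA_FLOOR = 1.0  # intensity units; floor on the local std dev


@dataclasses.dataclass
class NeuriteSegSettings:
    method: Literal["nlc", "auto"] = "nlc"
    nlc_block_radius: int = 40
    nlc_stddevs: float = 3.0
    nlc_center: bool = True
    nlc_stretch: bool = True
    post_nlc_threshold: float | None = None  # None -> 0.7 * M at run time
    auto_method: str = "otsu"
    min_object_area: int = 10

    def validate(self) -> None:
        if self.method not in ("nlc", "auto"):
            raise ValueError(f"unknown neurite segmentation method {self.method!r}")
        if self.nlc_block_radius < 1:
            raise ValueError("nlc_block_radius must be >= 1")
        if self.nlc_stddevs <= 0:
            raise ValueError("nlc_stddevs must be > 0")
        if self.auto_method not in AUTO_THRESHOLD_METHODS:
            raise ValueError(
                f"unknown auto-threshold method {self.auto_method!r}; "
                f"available: {sorted(AUTO_THRESHOLD_METHODS)}"
            )
        if self.min_object_area < 0:
            raise ValueError("min_object_area must be >= 0")


def normalize_local_contrast(
    img: ChannelImage,
    block_radius: int,
    k: float,
    center: bool = True,
    stretch: bool = True,
) -> ChannelImage:
    """Local contrast normalization over (2r+1)x(2r+1) windows.

    Window statistics use edge-replicated borders; output is clamped to the
    native intensity range.
    """
    if block_radius < 1:
        raise ValueError("block_radius must be >= 1")
    if k <= 0:
        raise ValueError("k must be > 0")
    px = img.pixels
    m = img.max_intensity
    size = 2 * int(block_radius) + 1
    mean = ndimage.uniform_filter(px, size=size, mode="nearest")
    mean_sq = ndimage.uniform_filter(px * px, size=size, mode="nearest")
    var = np.maximum(mean_sq - mean * mean, 0.0)
    std = np.sqrt(var)
    center_term = (m / 2.0) if center else mean
    gain = (m / 2.0) / (k * np.maximum(std, NLC_SIGMA_FLOOR)) if stretch else 1.0
    out = center_term + (px - mean) * gain
    return img.with_pixels(np.clip(out, 0.0, m))


def _threshold_mean(pixels: np.ndarray) -> float:
    return float(pixels.mean())


AUTO_THRESHOLD_METHODS: Dict[str, Callable[[np.ndarray], float]] = {
    "otsu": lambda px: float(filters.threshold_otsu(px, nbins=256)),
    "mean": _threshold_mean,
    "triangle": lambda px: float(filters.threshold_triangle(px, nbins=256)),
    "isodata": lambda px: float(filters.threshold_isodata(px, nbins=256)),
}


def register_threshold_method(name: str, func: Callable[[np.ndarray], float]) -> None:
    """Extend the auto-threshold registry with a custom method."""
    AUTO_THRESHOLD_METHODS[name] = func


def auto_threshold(img: ChannelImage, method: str = "otsu") -> float:
    """Automatic histogram threshold, returned in native intensity units.

    Pixels strictly above the returned value are foreground.  Histogram
    methods (otsu, triangle, isodata) reject constant images, whose
    histogram is degenerate.
    """
    if method not in AUTO_THRESHOLD_METHODS:
        raise ValueError(
            f"unknown auto-threshold method {method!r}; available: "
            f"{sorted(AUTO_THRESHOLD_METHODS)}"
        )
    px = img.pixels
    if method in ("otsu", "triangle", "isodata") and px.min() == px.max():
        raise ValueError(f"{method} threshold undefined on a constant image")
    # integer-valued images are thresholded on their integer histogram so
    # the returned cut is an exact intensity level
    if np.all(px == np.rint(px)):
        px = px.astype(np.uint8 if img.bit_depth == 8 else np.uint16)
    return AUTO_THRESHOLD_METHODS[method](px)


def segment_neurites(neurite_img: ChannelImage, settings: NeuriteSegSettings) -> BinaryMask:
    """Neurite-pixel selection: NLC + fixed threshold, or an auto threshold.

    Connected foreground components smaller than ``min_object_area`` are
    removed afterwards.
    """
    settings.validate()
    if settings.method == "nlc":
        nlc = normalize_local_contrast(
            neurite_img,
            settings.nlc_block_radius,
            settings.nlc_stddevs,
            center=settings.nlc_center,
            stretch=settings.nlc_stretch,
        )
        # Default cut at 0.7*M. With center+stretch on, NLC maps the local
        # mean to M/2 and k local SDs to M, so 0.7*M is 0.4*k local SDs
        # above the local mean — low enough to keep blurred neurite edges,
        # while the area filter removes the isolated noise pixels it lets
        # through.  A cut at M/2 itself would mark every pixel above its
        # local mean (half of any noisy background) foreground.
        thr = settings.post_nlc_threshold
        if thr is None:
            thr = 0.7 * neurite_img.max_intensity
        mask = nlc.pixels > thr
    else:
        thr = auto_threshold(neurite_img, settings.auto_method)
        mask = neurite_img.pixels > thr
    if settings.min_object_area > 0:
        mask = attribute_filter_area(mask, settings.min_object_area)
    return BinaryMask(pixels=mask, role="neurite")
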