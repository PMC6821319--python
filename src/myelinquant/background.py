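"""Background subtraction for the myelin channel.

Three modes are supported, selected in :class:`BackgroundSettings`:

``rolling_ball``
    Classic rolling-ball background estimation: the background is the
    grayscale opening of the image by a ball-shaped structuring element of
    the given radius rolled under the intensity surface, and is subtracted
    pointwise.  Flattens uneven illumination while preserving structures
    thinner than the ball.
``neurite_mask``
    Bleed-through correction: fluorescence from the neurite stain that
    leaks into the myelin channel is removed by subtracting a scaled copy
    of the neurite channel inside the binarized neurite mask, followed by
    flooring of all pixels below a user threshold to zero.
``none``
    Identity.

All modes are anti-extensive (output <= input pointwise) and never produce
negative intensities.
"""

from __future__ import annotations

import dataclasses
from typing import Literal, Optional

import numpy as np
from scipy import ndimage

from .core_io import BinaryMask, ChannelImage

BackgroundMode = Literal["rolling_ball", "neurite_mask", "none"]


@dataclasses.dataclass
class BackgroundSettings:
    """Parameters for the background stage.

    Attributes
    ----------
    mode
        One of ``rolling_ball``, ``neurite_mask``, ``none``.
    rolling_ball_radius
        Ball radius in pixels (>= 1); used only in ``rolling_ball`` mode.
        Should exceed the width of the thickest genuine structure.
    bleed_fraction
        Fraction of the neurite-channel intensity subtracted inside the
        neurite mask (>= 0).  Default 1.0: worst-case proportional
        bleed-through.
    floor_threshold
        Intensity floor; after bleed-through removal every pixel strictly
        below this value is set to 0.
    """

    mode: BackgroundMode = "rolling_ball"
    rolling_ball_radius: float = 25.0
    bleed_fraction: float = 1.0
    floor_threshold: float = 0.0

    def validate(self) -> None:
        if self.mode not in ("rolling_ball", "neurite_mask", "none"):
            raise ValueError(f"unknown background mode {self.mode!r}")
        if self.mode == "rolling_ball" and self.rolling_ball_radius < 1:
            raise ValueError("rolling_ball_radius must be >= 1")
        if self.bleed_fraction < 0:
            raise ValueError("bleed_fraction must be >= 0")
        if self.floor_threshold < 0:
            raise ValueError("floor_threshold must be >= 0")


def _ball_structure(radius: float) -> tuple[np.ndarray, np.ndarray]:
    """Footprint and height profile of a ball of the given radius.

    The structuring function is ``b(q) = sqrt(r**2 - |q|**2)`` on the disk
    ``|q| <= r`` — the upper hemisphere of the ball, apex over the origin.
    """
    r = int(np.ceil(radius))
    dr, dc = np.mgrid[-r : r + 1, -r : r + 1]
    d2 = dr * dr + dc * dc
    footprint = d2 <= radius * radius
    heights = np.where(footprint, np.sqrt(np.maximum(radius * radius - d2, 0.0)), 0.0)
    return footprint, heights


def rolling_ball_subtract(img: ChannelImage, radius: float) -> ChannelImage:
    """Subtract the rolling-ball background.

    The background is the grayscale morphological opening of the image by
    the ball structuring element of :func:`_ball_structure` (edge-replicated
    borders) — the surface traced by a ball of the given radius rolled
    under the intensity landscape.  It is pointwise <= the image, so the
    result is pointwise >= 0 and <= the input.
    """
    if radius < 1:
        raise ValueError(f"rolling-ball radius must be >= 1, got {radius}")
    footprint, heights = _ball_structure(radius)
    background = ndimage.grey_opening(
        img.pixels, footprint=footprint, structure=heights, mode="nearest"
    )
    # guard tiny numerical overshoot of the non-flat opening
    background = np.minimum(background, img.pixels)
    return img.with_pixels(img.pixels - background)


def bleedthrough_subtract(
    myelin: ChannelImage,
    neurite_mask: BinaryMask,
    bleed_fraction: float,
    floor_threshold: float,
    neurite: ChannelImage,
) -> ChannelImage:
    """Remove neurite-stain bleed-through from the myelin channel.

    Inside the neurite mask, ``bleed_fraction * neurite`` is subtracted
    (clipped at 0); outside the mask the myelin channel is untouched.
    Afterwards every pixel strictly below ``floor_threshold`` is zeroed.
    """
    if myelin.shape != neurite.shape or myelin.shape != neurite_mask.shape:
        raise ValueError(
            f"dimension mismatch: myelin {myelin.shape}, neurite {neurite.shape}, "
            f"mask {neurite_mask.shape}"
        )
    out = myelin.pixels.copy()
    inside = neurite_mask.pixels
    out[inside] = np.maximum(0.0, out[inside] - bleed_fraction * neurite.pixels[inside])
    out[out < floor_threshold] = 0.0
    return myelin.with_pixels(out)


def subtract_background(
    myelin: ChannelImage,
    settings: BackgroundSettings,
    neurite: Optional[ChannelImage] = None,
    neurite_mask: Optional[BinaryMask] = None,
) -> ChannelImage:
    """Dispatch to the configured background mode.

    ``neurite`` and ``neurite_mask`` are required only for the
    ``neurite_mask`` mode.
    """
    settings.validate()
    if settings.mode == "none":
        return myelin
    if settings.mode == "rolling_ball":
        return rolling_ball_subtract(myelin, settings.rolling_ball_radius)
    if neurite is None or neurite_mask is None:
        raise ValueError("neurite_mask mode requires the neurite channel and its mask")
    return bleedthrough_subtract(
        myelin, neurite_mask, settings.bleed_fraction, settings.floor_threshold, neurite
    )
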