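"""The two per-image quantities and the per-field pipeline.

% myelination  = 100 * myelin foreground pixels / neurite foreground pixels
% neurite density = 100 * neurite foreground pixels / total pixels

% myelination is a ratio of two masks and can in principle exceed 100 when
the sheath mask is larger than the neurite mask; such values are kept but
flagged with a warning.  A field whose neurite mask is empty has no defined
% myelination; it is recorded as missing (NaN), never as 0 or 100, and
excluded from condition means and tests downstream.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

from .background import BackgroundSettings, subtract_background
from .core_io import BinaryMask, FieldPair
from .myelin import MyelinSegSettings, segment_myelin
from .neurite import NeuriteSegSettings, segment_neurites


class UndefinedMetricError(ValueError):
    """The metric is undefined on these masks (empty denominator)."""


@dataclasses.dataclass(frozen=True)
class ImageMeasurement:
    """Pixel counts and percentage metrics for one field."""

    field_id: str
    condition: str
    myelin_pixels: int
    neurite_pixels: int
    total_pixels: int
    pct_myelination: float  # NaN when undefined (empty neurite mask)
    pct_neurite_density: float

    @property
    def myelination_missing(self) -> bool:
        return math.isnan(self.pct_myelination)


def percent_myelination(myelin_mask: BinaryMask, neurite_mask: BinaryMask) -> float:
    """Myelin foreground as a percentage of neurite foreground."""
    if myelin_mask.shape != neurite_mask.shape:
        raise ValueError(
            f"mask dimensions differ: {myelin_mask.shape} vs {neurite_mask.shape}"
        )
    n_neurite = neurite_mask.foreground_count
    if n_neurite == 0:
        raise UndefinedMetricError("percent myelination undefined: neurite mask is empty")
    pct = 100.0 * myelin_mask.foreground_count / n_neurite
    if pct > 100.0:
        warnings.warn(
            f"percent myelination {pct:.1f} exceeds 100: myelin mask larger than neurite mask",
            stacklevel=2,
        )
    return pct


def percent_neurite_density(neurite_mask: BinaryMask) -> float:
    """Neurite foreground as a percentage of all pixels in the field."""
    total = neurite_mask.height * neurite_mask.width
    return 100.0 * neurite_mask.foreground_count / total


def measure_masks(
    field_id: str,
    condition: str,
    myelin_mask: BinaryMask,
    neurite_mask: BinaryMask,
) -> ImageMeasurement:
    """Assemble an :class:`ImageMeasurement` from already-computed masks."""
    try:
        pct_my = percent_myelination(myelin_mask, neurite_mask)
    except UndefinedMetricError:
        pct_my = float("nan")
    return ImageMeasurement(
        field_id=field_id,
        condition=condition,
        myelin_pixels=myelin_mask.foreground_count,
        neurite_pixels=neurite_mask.foreground_count,
        total_pixels=neurite_mask.height * neurite_mask.width,
        pct_myelination=pct_my,
        pct_neurite_density=percent_neurite_density(neurite_mask),
    )


def measure_field(pair: FieldPair, settings: "PipelineSettings") -> ImageMeasurement:
    """Run the full per-field pipeline and compute both metrics.

    Stages: neurite segmentation -> background subtraction on the myelin
    channel (the neurite mask is available for bleed-through mode) ->
    sheath segmentation -> metrics.  Pure function of (images, settings):
    repeated calls are bit-identical.
    """
    neurite_mask = segment_neurites(pair.neurite, settings.neurite)
    myelin_bg = subtract_background(
        pair.myelin, settings.background, neurite=pair.neurite, neurite_mask=neurite_mask
    )
    myelin_mask = segment_myelin(myelin_bg, settings.myelin)
    return measure_masks(pair.field_id, pair.condition, myelin_mask, neurite_mask)


@dataclasses.dataclass
class PipelineSettings:
    """The complete named parameter set for one analysis.

    Serializes to a single YAML profile (see :mod:`myelinquant.settings`)
    so a full analysis is reproducible from the profile alone.
    """

    profile_name: str = "default"
    background: BackgroundSettings = dataclasses.field(default_factory=BackgroundSettings)
    myelin: MyelinSegSettings = dataclasses.field(default_factory=MyelinSegSettings)
    neurite: NeuriteSegSettings = dataclasses.field(default_factory=NeuriteSegSettings)
    neurite_suffix: str = "_neurite"
    myelin_suffix: str = "_myelin"

    def validate(self) -> None:
        self.background.validate()
        self.myelin.validate()
        self.neurite.validate()
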