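"""Image and table I/O plus the canonical in-memory image model.

One micrograph field is two registered single-channel images: a neurite
stain (e.g. NF-H/SMI31 immunoreactivity) and a myelin stain (e.g. PLP
immunoreactivity).  Internally every channel is held as a float64 array in
its native intensity range (0 .. 2**bit_depth - 1); integer conversion
happens only when an image is written back to disk.  Arrays are row-major,
origin top-left, 0-based.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Literal

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

ChannelRole = Literal["neurite", "myelin"]
MaskRole = Literal["neurite", "myelin", "cellbody"]

#: CSV header for per-image measurement tables, fixed so downstream stats
#: and external tooling can rely on it.
MEASUREMENT_COLUMNS = [
    "field_id",
    "condition",
    "myelin_pixels",
    "neurite_pixels",
    "total_pixels",
    "pct_myelination",
    "pct_neurite_density",
]


class FormatError(ValueError):
    """Input image violates the supported-format contract."""


class PairingError(ValueError):
    """Channel files for one field are inconsistent."""


@dataclasses.dataclass(frozen=True)
class ChannelImage:
    """A single registered 2D fluorescence channel.

    Parameters
    ----------
    pixels
        2D float array of intensities in ``[0, 2**bit_depth - 1]``.
    bit_depth
        8 or 16; defines the native intensity range.
    channel_role
        ``"neurite"`` or ``"myelin"``.
    source_id
        Field identifier (usually derived from the file name).
    """

    pixels: np.ndarray
    bit_depth: int
    channel_role: ChannelRole
    source_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError(f"pixels must be a non-empty 2D array, got shape {px.shape}")
        if self.bit_depth not in (8, 16):
            raise FormatError(f"unsupported bit depth {self.bit_depth}; expected 8 or 16")
        if not np.all(np.isfinite(px)):
            raise ValueError("intensities must be finite")
        if px.min() < 0:
            raise ValueError("intensities must be non-negative")
        if px.max() > self.max_intensity:
            raise ValueError(
                f"intensity {px.max()} exceeds native range of a {self.bit_depth}-bit image"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def max_intensity(self) -> float:
        return float(2**self.bit_depth - 1)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray) -> "ChannelImage":
        """Same metadata, new pixel grid (clipped into the native range)."""
        px = np.clip(np.asarray(pixels, dtype=np.float64), 0.0, self.max_intensity)
        return dataclasses.replace(self, pixels=px)


@dataclasses.dataclass(frozen=True)
class BinaryMask:
    """Boolean grid aligned with a :class:`ChannelImage`."""

    pixels: np.ndarray
    role: MaskRole

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.dtype != bool:
            px = px.astype(bool)
        if px.ndim != 2:
            raise ValueError(f"mask must be 2D, got shape {px.shape}")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def foreground_count(self) -> int:
        return int(self.pixels.sum())


@dataclasses.dataclass(frozen=True)
class FieldPair:
    """The two stains of one field, registered and equally sized."""

    neurite: ChannelImage
    myelin: ChannelImage
    field_id: str
    condition: str = ""

    def __post_init__(self) -> None:
        if self.neurite.shape != self.myelin.shape:
            raise PairingError(
                f"field {self.field_id!r}: channel dimensions differ "
                f"({self.neurite.shape} vs {self.myelin.shape})"
            )


def read_image(path: str | Path, channel_role: ChannelRole) -> ChannelImage:
    """Read a grayscale 8/16-bit TIFF or PNG as a :class:`ChannelImage`.

    RGB/multi-channel inputs are rejected: splitting a composite image into
    its stains is the caller's responsibility.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    arr = iio.imread(path)
    if arr.ndim == 3:
        raise FormatError(
            f"{path.name}: expected a single-channel image, got shape {arr.shape} "
            "(RGB/multi-channel input; split channels first)"
        )
    if arr.ndim != 2:
        raise FormatError(f"{path.name}: expected a 2D image, got shape {arr.shape}")
    if arr.dtype == np.uint8:
        bit_depth = 8
    elif arr.dtype == np.uint16:
        bit_depth = 16
    else:
        raise FormatError(
            f"{path.name}: unsupported pixel type {arr.dtype}; expected 8- or 16-bit unsigned"
        )
    return ChannelImage(
        pixels=arr.astype(np.float64),
        bit_depth=bit_depth,
        channel_role=channel_role,
        source_id=path.stem,
    )


def write_image(img: ChannelImage, path: str | Path) -> None:
    """Write a channel back to disk at its native integer depth."""
    path = Path(path)
    dtype = np.uint8 if img.bit_depth == 8 else np.uint16
    data = np.clip(np.rint(img.pixels), 0, img.max_intensity).astype(dtype)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data)
    else:
        iio.imwrite(path, data)


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a mask as an 8-bit image (foreground 255, background 0)."""
    data = np.where(mask.pixels, 255, 0).astype(np.uint8)
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data)
    else:
        iio.imwrite(path, data)


def pair_fields(
    directory: str | Path,
    neurite_suffix: str = "_neurite",
    myelin_suffix: str = "_myelin",
    condition: str = "",
) -> tuple[list[FieldPair], list[str]]:
    """Pair channel files in ``directory`` by filename suffix convention.

    Files named ``<field><neurite_suffix>.<ext>`` and
    ``<field><myelin_suffix>.<ext>`` form one :class:`FieldPair`.  Returns
    the pairs sorted by ``field_id`` (deterministic regardless of directory
    listing order) together with the names of files that could not be
    paired; unmatched files are reported, never silently dropped.

    Raises
    ------
    PairingError
        If the two channels of a field have different dimensions.
    """
    directory = Path(directory)
    exts = (".tif", ".tiff", ".png")
    neurite_files: dict[str, Path] = {}
    myelin_files: dict[str, Path] = {}
    unmatched: list[str] = []
    for f in sorted(directory.iterdir()):
        if not f.is_file() or f.suffix.lower() not in exts:
            continue
        stem = f.stem
        if stem.endswith(neurite_suffix):
            neurite_files[stem[: -len(neurite_suffix)]] = f
        elif stem.endswith(myelin_suffix):
            myelin_files[stem[: -len(myelin_suffix)]] = f
        else:
            unmatched.append(f.name)
    pairs: list[FieldPair] = []
    for field_id in sorted(set(neurite_files) | set(myelin_files)):
        if field_id in neurite_files and field_id in myelin_files:
            neurite = read_image(neurite_files[field_id], "neurite")
            myelin = read_image(myelin_files[field_id], "myelin")
            pairs.append(
                FieldPair(neurite=neurite, myelin=myelin, field_id=field_id, condition=condition)
            )
        elif field_id in neurite_files:
            unmatched.append(neurite_files[field_id].name)
        else:
            unmatched.append(myelin_files[field_id].name)
    return pairs, unmatched


def write_measurements(rows: Iterable, path: str | Path) -> None:
    """Write per-image measurements as an RFC-4180 CSV with a fixed header.

    Counts round-trip bit-exactly; percentages are written with full float
    precision (``repr`` round-trip).  Missing percent-myelination values
    (empty neurite mask) are written as empty cells.
    """
    records = []
    for r in rows:
        records.append(
            {
                "field_id": r.field_id,
                "condition": r.condition,
                "myelin_pixels": r.myelin_pixels,
                "neurite_pixels": r.neurite_pixels,
                "total_pixels": r.total_pixels,
                "pct_myelination": r.pct_myelination,
                "pct_neurite_density": r.pct_neurite_density,
            }
        )
    df = pd.DataFrame.from_records(records, columns=MEASUREMENT_COLUMNS)
    df.to_csv(path, index=False, float_format="%.17g")


def read_measurements(path: str | Path) -> pd.DataFrame:
    """Read a measurement CSV written by :func:`write_measurements`."""
    df = pd.read_csv(
        path,
        dtype={
            "field_id": str,
            "condition": str,
            "myelin_pixels": "int64",
            "neurite_pixels": "int64",
            "total_pixels": "int64",
        },
    )
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"measurement table {path} lacks columns {missing}")
    return df
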