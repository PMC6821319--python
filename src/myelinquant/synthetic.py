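"""Synthetic two-channel myelinating-culture fields with ground truth.

Each phantom field emulates the structures the analysis pipeline assumes:

* neurites — smooth random curves (cubic splines through random waypoints)
  dilated to a fixed width, bright in the neurite channel;
* myelin sheaths — contiguous sub-segments of randomly chosen neurites,
  slightly wider than the neurite, bright in the myelin channel;
* cell bodies — compact near-saturation disks in the myelin channel;
* bleed-through — a fraction of the (clean) neurite channel added to the
  myelin channel;
* debris — small dim speckles in the myelin channel, emulating the
  non-sheath background left behind by demyelination;
* a multiplicative linear illumination gradient along a random direction;
* additive Gaussian read/shot noise, clipped to the native range.

Ground-truth masks are kept before any intensity corruption, and the true
percentage metrics are computed from those masks with the same metrics
code the pipeline uses, so truth and measurement are directly comparable.
All randomness flows from a single generator seeded per field, making
every phantom bit-reproducible.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import interpolate, ndimage
from skimage import morphology

from .core_io import BinaryMask, ChannelImage, FieldPair, write_image
from .metrics import UndefinedMetricError, percent_myelination, percent_neurite_density


@dataclasses.dataclass
class PhantomParams:
    """Geometry, corruption and intensity parameters of one phantom field.

    Intensity amplitudes are in native units of an 8-bit image.  The
    defaults describe a healthy, moderately dense culture; see
    :func:`demyelinated_params` for the post-demyelination scenario.
    """

    width: int = 256
    height: int = 256
    bit_depth: int = 8
    n_neurites: int = 8
    neurite_width: int = 3
    n_sheaths: int = 5
    sheath_width: int = 4
    sheath_coverage: float = 0.25
    n_cellbodies: int = 2
    cellbody_radius: int = 6
    bleed_fraction: float = 0.15
    debris_density: float = 1.0  # speckles per kilopixel
    illumination_gradient: float = 0.2  # relative amplitude, 0..1
    noise_sd: float = 6.0
    neurite_amplitude: float = 120.0
    sheath_amplitude: float = 140.0
    cellbody_amplitude: float = 230.0
    debris_amplitude: float = 80.0
    seed: int = 0

    def validate(self) -> None:
        if self.width < 8 or self.height < 8:
            raise ValueError("phantom must be at least 8x8")
        for name in ("n_neurites", "n_sheaths", "n_cellbodies"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.sheath_coverage <= 1.0:
            raise ValueError("sheath_coverage must be in [0, 1]")
        if not 0.0 <= self.bleed_fraction <= 1.0:
            raise ValueError("bleed_fraction must be in [0, 1]")
        if not 0.0 <= self.illumination_gradient <= 1.0:
            raise ValueError("illumination_gradient must be in [0, 1]")
        if self.debris_density < 0 or self.noise_sd < 0:
            raise ValueError("debris_density and noise_sd must be >= 0")
        if self.sheath_width < self.neurite_width:
            raise ValueError("sheath_width must be >= neurite_width")


def demyelinated_params(**overrides) -> PhantomParams:
    """Preset for the post-demyelination scenario.

    Sparse surviving sheaths, heavy non-sheath debris and extra noise —
    the situation in which naive global thresholding of the myelin channel
    reports mostly debris (or nothing), while ridge filtering still finds
    the surviving sheaths.
    """
    base = dict(
        n_sheaths=2,
        sheath_coverage=0.10,
        debris_density=8.0,
        noise_sd=8.0,
        n_cellbodies=3,
    )
    base.update(overrides)
    return PhantomParams(**base)


@dataclasses.dataclass(frozen=True)
class SyntheticGroundTruth:
    neurite_mask: BinaryMask
    myelin_mask: BinaryMask
    cellbody_mask: BinaryMask
    true_pct_myelination: float  # NaN when the neurite mask is empty
    true_pct_neurite_density: float


def _disk_radius(width: int) -> int:
    return max(0, int(round((width - 1) / 2)))


def _random_curve(rng: np.random.Generator, height: int, width: int) -> np.ndarray:
    """Dense integer sample points of one smooth curve crossing the field.

    Returns an (n, 2) array of ordered (row, col) points, deduplicated but
    order-preserving, clipped to the field.
    """
    n_way = rng.integers(4, 7)
    # waypoints drift across the field along a random principal direction
    t_way = np.linspace(0.0, 1.0, n_way)
    theta = rng.uniform(0, 2 * np.pi)
    length = 1.3 * max(height, width)
    cr, cc = rng.uniform(0.2, 0.8) * height, rng.uniform(0.2, 0.8) * width
    rows = cr + (t_way - 0.5) * length * np.sin(theta) + rng.normal(0, 0.12 * height, n_way)
    cols = cc + (t_way - 0.5) * length * np.cos(theta) + rng.normal(0, 0.12 * width, n_way)
    k = min(3, n_way - 1)
    tck, _ = interpolate.splprep([rows, cols], s=0.0, k=k)
    n_dense = int(4 * length)
    dense = np.stack(interpolate.splev(np.linspace(0, 1, n_dense), tck), axis=1)
    dense = np.rint(dense).astype(int)
    inside = (
        (dense[:, 0] >= 0)
        & (dense[:, 0] < height)
        & (dense[:, 1] >= 0)
        & (dense[:, 1] < width)
    )
    dense = dense[inside]
    if len(dense) == 0:
        return dense.reshape(0, 2)
    keep = np.ones(len(dense), dtype=bool)
    keep[1:] = np.any(dense[1:] != dense[:-1], axis=1)
    return dense[keep]


def _paint(points: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    canvas = np.zeros(shape, dtype=bool)
    if len(points):
        canvas[points[:, 0], points[:, 1]] = True
    return canvas


def generate_field(
    params: PhantomParams, field_id: str = "phantom", condition: str = ""
) -> tuple[FieldPair, SyntheticGroundTruth]:
    """Render one phantom field and its ground truth."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    shape = (params.height, params.width)
    m = float(2**params.bit_depth - 1)

    curves = [_random_curve(rng, params.height, params.width) for _ in range(params.n_neurites)]
    curves = [c for c in curves if len(c) >= 8]
    neurite_line = np.zeros(shape, dtype=bool)
    for c in curves:
        neurite_line |= _paint(c, shape)
    r_n = _disk_radius(params.neurite_width)
    neurite_mask = (
        morphology.dilation(neurite_line, morphology.disk(r_n))
        if r_n > 0
        else neurite_line
    )

    sheath_line = np.zeros(shape, dtype=bool)
    if curves and params.n_sheaths > 0 and params.sheath_coverage > 0:
        for _ in range(params.n_sheaths):
            c = curves[rng.integers(len(curves))]
            seg_len = max(2, int(round(params.sheath_coverage * len(c))))
            start = int(rng.integers(0, max(1, len(c) - seg_len + 1)))
            sheath_line |= _paint(c[start : start + seg_len], shape)
    r_s = _disk_radius(params.sheath_width)
    myelin_mask = (
        morphology.dilation(sheath_line, morphology.disk(r_s))
        if r_s > 0
        else sheath_line
    )

    cellbody = np.zeros(shape, dtype=bool)
    for _ in range(params.n_cellbodies):
        cr = rng.integers(params.cellbody_radius, params.height - params.cellbody_radius)
        cc = rng.integers(params.cellbody_radius, params.width - params.cellbody_radius)
        rr, cc_grid = np.ogrid[: params.height, : params.width]
        cellbody |= (rr - cr) ** 2 + (cc_grid - cc) ** 2 <= params.cellbody_radius**2

    # clean intensity fields (slightly blurred so edges are not razor-sharp)
    neurite_clean = ndimage.gaussian_filter(
        neurite_mask.astype(float) * params.neurite_amplitude, 0.6
    )
    myelin_clean = ndimage.gaussian_filter(
        myelin_mask.astype(float) * params.sheath_amplitude, 0.6
    )
    myelin_clean = np.maximum(myelin_clean, cellbody * params.cellbody_amplitude)
    myelin_clean = myelin_clean + params.bleed_fraction * neurite_clean

    n_debris = rng.poisson(params.debris_density * params.height * params.width / 1000.0)
    if n_debris > 0:
        rr = rng.integers(0, params.height, n_debris)
        cc = rng.integers(0, params.width, n_debris)
        speck = np.zeros(shape, dtype=bool)
        speck[rr, cc] = True
        speck = morphology.dilation(speck, morphology.disk(1))
        amp = params.debris_amplitude * rng.uniform(0.5, 1.0)
        myelin_clean = np.maximum(myelin_clean, speck * amp)

    # multiplicative linear gradient along a random direction, mean ~1
    if params.illumination_gradient > 0:
        phi = rng.uniform(0, 2 * np.pi)
        rr, cc_grid = np.mgrid[: params.height, : params.width]
        u = (rr / max(1, params.height - 1)) * np.sin(phi) + (
            cc_grid / max(1, params.width - 1)
        ) * np.cos(phi)
        u = (u - u.min()) / max(u.max() - u.min(), 1e-12)
        grad = 1.0 - params.illumination_gradient / 2.0 + params.illumination_gradient * u
    else:
        grad = 1.0

    def corrupt(clean: np.ndarray) -> np.ndarray:
        noisy = clean * grad + rng.normal(0.0, params.noise_sd, shape)
        return np.clip(noisy, 0.0, m)

    neurite_img = ChannelImage(
        pixels=corrupt(neurite_clean),
        bit_depth=params.bit_depth,
        channel_role="neurite",
        source_id=field_id,
    )
    myelin_img = ChannelImage(
        pixels=corrupt(myelin_clean),
        bit_depth=params.bit_depth,
        channel_role="myelin",
        source_id=field_id,
    )
    pair = FieldPair(neurite=neurite_img, myelin=myelin_img, field_id=field_id, condition=condition)

    nm = BinaryMask(pixels=neurite_mask, role="neurite")
    mm = BinaryMask(pixels=myelin_mask, role="myelin")
    cm = BinaryMask(pixels=cellbody, role="cellbody")
    try:
        true_my = percent_myelination(mm, nm)
    except UndefinedMetricError:
        true_my = float("nan")
    truth = SyntheticGroundTruth(
        neurite_mask=nm,
        myelin_mask=mm,
        cellbody_mask=cm,
        true_pct_myelination=true_my,
        true_pct_neurite_density=percent_neurite_density(nm),
    )
    return pair, truth


def field_seed(experiment_seed: int, condition_index: int, field_index: int) -> int:
    """Stable per-field seed derived from (experiment seed, indices)."""
    ss = np.random.SeedSequence(entropy=[experiment_seed, condition_index, field_index])
    return int(ss.generate_state(1)[0] % (2**31))


def generate_experiment(
    per_condition: Mapping[str, PhantomParams],
    images_per_condition: int,
    seed: int,
    out_dir: str | Path,
    neurite_suffix: str = "_neurite",
    myelin_suffix: str = "_myelin",
) -> pd.DataFrame:
    """Write a condition-folder tree of phantom image pairs plus truth table.

    Layout: ``out_dir/<condition>/<field><suffix>.tif`` — directly
    consumable by the experiment runner.  Returns (and writes alongside,
    as ``ground_truth.csv``) the per-field true metrics.
    """
    if not per_condition:
        raise ValueError("at least one condition is required")
    out_dir = Path(out_dir)
    rows = []
    for ci, (condition, params) in enumerate(per_condition.items()):
        cond_dir = out_dir / condition
        cond_dir.mkdir(parents=True, exist_ok=True)
        for fi in range(images_per_condition):
            fid = f"{condition}_{fi:03d}"
            p = dataclasses.replace(params, seed=field_seed(seed, ci, fi))
            pair, truth = generate_field(p, field_id=fid, condition=condition)
            write_image(pair.neurite, cond_dir / f"{fid}{neurite_suffix}.tif")
            write_image(pair.myelin, cond_dir / f"{fid}{myelin_suffix}.tif")
            rows.append(
                {
                    "field_id": fid,
                    "condition": condition,
                    "true_pct_myelination": truth.true_pct_myelination,
                    "true_pct_neurite_density": truth.true_pct_neurite_density,
                }
            )
    table = pd.DataFrame(rows)
    table.to_csv(out_dir / "ground_truth.csv", index=False)
    return table
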