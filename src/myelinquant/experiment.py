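"""End-to-end orchestration: single fields and multi-condition experiments.

Outputs are plain files — per-image measurement CSV, per-condition summary
CSV, pairwise statistics CSV, mask/overlay images and a comparison figure.
Every CSV carries a comment line naming the settings profile and a content
hash of the exact parameter values, so results remain traceable to the
parameters that produced them.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .background import subtract_background
from .core_io import FieldPair, pair_fields, read_image, write_mask, write_measurements
from .metrics import ImageMeasurement, PipelineSettings, measure_masks
from .myelin import segment_myelin
from .neurite import segment_neurites
from .settings import settings_hash
from .stats import ExperimentDesign, compare_conditions, plot_comparison, results_table, summarize_conditions

log = logging.getLogger("myelinquant")


def _provenance_line(settings: PipelineSettings) -> str:
    return f"# profile={settings.profile_name} settings_sha={settings_hash(settings)}"


def _write_csv_with_provenance(df: pd.DataFrame, path: Path, settings: PipelineSettings) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(_provenance_line(settings) + "\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def analyse_pair(pair: FieldPair, settings: PipelineSettings):
    """Segment both channels of one field; returns (measurement, masks)."""
    t0 = time.perf_counter()
    neurite_mask = segment_neurites(pair.neurite, settings.neurite)
    myelin_bg = subtract_background(
        pair.myelin, settings.background, neurite=pair.neurite, neurite_mask=neurite_mask
    )
    myelin_mask = segment_myelin(myelin_bg, settings.myelin)
    meas = measure_masks(pair.field_id, pair.condition, myelin_mask, neurite_mask)
    log.info(
        "field %s: neurite_px=%d myelin_px=%d%s (%.2fs)",
        pair.field_id,
        meas.neurite_pixels,
        meas.myelin_pixels,
        " [myelination missing: empty neurite mask]" if meas.myelination_missing else "",
        time.perf_counter() - t0,
    )
    return meas, neurite_mask, myelin_mask


def _overlay_image(pair: FieldPair, myelin_mask, path: Path) -> None:
    """RGB overlay: original myelin channel in green, detected mask in red."""
    import imageio.v3 as iio

    m = pair.myelin.max_intensity
    green = np.clip(pair.myelin.pixels / m * 255, 0, 255).astype(np.uint8)
    red = np.where(myelin_mask.pixels, 255, 0).astype(np.uint8)
    rgb = np.stack([red, green, np.zeros_like(green)], axis=-1)
    iio.imwrite(path, rgb)


def run_single(
    neurite_path: str | Path,
    myelin_path: str | Path,
    settings: PipelineSettings,
    out_dir: str | Path,
) -> ImageMeasurement:
    """Analyse one image pair; writes measurement CSV, masks and an overlay."""
    settings.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    neurite = read_image(neurite_path, "neurite")
    myelin = read_image(myelin_path, "myelin")
    field_id = Path(neurite_path).stem
    for suffix in (settings.neurite_suffix,):
        if field_id.endswith(suffix):
            field_id = field_id[: -len(suffix)]
    pair = FieldPair(neurite=neurite, myelin=myelin, field_id=field_id)
    meas, neurite_mask, myelin_mask = analyse_pair(pair, settings)
    write_mask(neurite_mask, out_dir / f"{field_id}_neurite_mask.tif")
    write_mask(myelin_mask, out_dir / f"{field_id}_myelin_mask.tif")
    _overlay_image(pair, myelin_mask, out_dir / f"{field_id}_overlay.png")
    csv_path = out_dir / f"{field_id}_measurement.csv"
    write_measurements([meas], csv_path)
    with open(csv_path) as fh:
        body = fh.read()
    with open(csv_path, "w") as fh:
        fh.write(_provenance_line(settings) + "\n" + body)
    return meas


class ExperimentError(RuntimeError):
    pass


def run_experiment(
    root_dir: str | Path,
    settings: PipelineSettings,
    design: Optional[ExperimentDesign] = None,
    out_dir: Optional[str | Path] = None,
    plot: bool = True,
) -> dict:
    """Analyse a tree of condition folders and compare conditions.

    ``root_dir`` contains one sub-folder per condition, each holding
    pairable channel images.  Per-field failures are logged and the field
    is excluded; the run aborts only if a condition ends up with fewer
    than two usable fields.  Outputs: ``measurements.csv``,
    ``summary_<metric>.csv``, ``stats_<metric>.csv`` and
    ``comparison_<metric>.png`` for both metrics (or the single metric the
    design names).  Deterministic for fixed inputs and settings.
    """
    settings.validate()
    root_dir = Path(root_dir)
    out_dir = Path(out_dir) if out_dir is not None else root_dir / "results"
    out_dir.mkdir(parents=True, exist_ok=True)

    condition_dirs = sorted(d for d in root_dir.iterdir() if d.is_dir() and d != out_dir)
    if design is not None:
        design.validate()
        wanted = set(design.conditions)
        condition_dirs = [d for d in condition_dirs if d.name in wanted]
        found = {d.name for d in condition_dirs}
        if found != wanted:
            raise ExperimentError(f"missing condition folders: {sorted(wanted - found)}")
    if len(condition_dirs) < 2:
        raise ExperimentError("an experiment needs at least 2 condition folders")

    measurements: list[ImageMeasurement] = []
    failures: list[str] = []
    for cond_dir in condition_dirs:
        pairs, unmatched = pair_fields(
            cond_dir,
            neurite_suffix=settings.neurite_suffix,
            myelin_suffix=settings.myelin_suffix,
            condition=cond_dir.name,
        )
        for name in unmatched:
            log.warning("condition %s: unmatched file %s", cond_dir.name, name)
        usable = 0
        for pair in pairs:
            try:
                meas, _, _ = analyse_pair(pair, settings)
            except Exception as exc:  # per-field failure: log, exclude, continue
                failures.append(f"{cond_dir.name}/{pair.field_id}: {exc}")
                log.error("field %s failed: %s", pair.field_id, exc)
                continue
            measurements.append(meas)
            usable += 1
        if usable < 2:
            raise ExperimentError(
                f"condition {cond_dir.name!r} has only {usable} usable fields (>= 2 required)"
            )

    write_measurements(measurements, out_dir / "measurements.csv")
    with open(out_dir / "measurements.csv") as fh:
        body = fh.read()
    with open(out_dir / "measurements.csv", "w") as fh:
        fh.write(_provenance_line(settings) + "\n" + body)

    if design is None:
        design = ExperimentDesign(conditions=[d.name for d in condition_dirs])
        metrics = ["pct_myelination", "pct_neurite_density"]
    else:
        metrics = [design.metric]

    outputs = {"measurements": out_dir / "measurements.csv", "failures": failures}
    import dataclasses as _dc

    for metric in metrics:
        d = _dc.replace(design, metric=metric)
        summary = summarize_conditions(measurements, d)
        _write_csv_with_provenance(summary, out_dir / f"summary_{metric}.csv", settings)
        results = compare_conditions(measurements, d)
        _write_csv_with_provenance(results_table(results), out_dir / f"stats_{metric}.csv", settings)
        if plot:
            plot_comparison(measurements, d, results, out_dir / f"comparison_{metric}.png")
        outputs[f"summary_{metric}"] = out_dir / f"summary_{metric}.csv"
        outputs[f"stats_{metric}"] = out_dir / f"stats_{metric}.csv"
        outputs[f"results_{metric}"] = results
    if failures:
        log.warning("%d field(s) failed and were excluded: %s", len(failures), failures)
    return outputs
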