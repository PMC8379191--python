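"""Pipeline orchestration: configuration, stage ordering, run artefacts.

A run executes simulate -> normalize -> segment -> ki67-ratio -> hotspot ->
immune -> stats on synthetic fields, writing every product (images, masks,
tables, stats report, manifest) into a run directory.  Identical
(config, seed) re-runs reproduce identical artefacts: every stage derives its
randomness from the root seed and no output embeds timestamps.

Coordinates are 0-based (row, col) pixel indices with the origin at the
top-left; physical quantities are micrometres / mm^2, converted through the
field's pixel size.  The hotspot scale and grid size defaults are expressed
in full-resolution scanner pixels (0.2276 um/px) and rescaled to the pixel
size of the field they are applied to.
"""

from __future__ import annotations

import copy
import dataclasses
import hashlib
import json
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd
import yaml

from . import hotspot as hs
from . import quantify as qt
from . import segment as sg
from . import stats as st
from . import synthetic as syn
from .core import mm2_of, write_image
from .stain import StainModel, estimate_stain_matrix, normalize_to_reference

FULL_SCALE_PIXEL_UM = 0.2276  # pixel size at which d = 250 px is defined

STAGES = ("simulate", "normalize", "segment", "ki67_ratio", "hotspot", "immune", "stats")

DEFAULT_CONFIG = {
    "seed": 0,
    "stages": list(STAGES),
    "simulate": {
        "age_group": "young",
        "field_width_px": 1580,
        "field_height_px": 1145,
        "pixel_size_um": 0.9104,
        "n_lobules": 4,
        "od_noise_sd": 0.02,
    },
    "hotspot": {
        "d_px": 250.0,  # in full-scale scanner pixels
        "d_um": None,  # alternative specification; exact conversion
        "cell_size_px": 50.0,
        "z_threshold": 1.96,
        "n_perm": 0,
    },
    "segment": {
        f.name: f.default for f in dataclasses.fields(sg.SegmentationParams)
    },
    "quantify": {
        "cv_tol": 0.30,
        "cluster_gap_um": 8.0,
        "box_width_um": 400.0,
        "box_height_um": 230.0,
        "n_boxes_per_class": 4,
    },
    "stats": {
        "n_animals_per_group": [7, 6],
    },
    "log_level": "INFO",
}


class ConfigError(ValueError):
    pass


class StageDependencyError(RuntimeError):
    pass


def _merge_with_defaults(defaults: dict, given: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    unknown = []
    for key, value in (given or {}).items():
        if key not in defaults:
            unknown.append(f"{path}{key}")
            continue
        if isinstance(defaults[key], dict) and isinstance(value, dict):
            out[key] = _merge_with_defaults(defaults[key], value, f"{path}{key}.")
        else:
            out[key] = value
    if unknown:
        raise ConfigError(f"unknown configuration keys: {', '.join(unknown)}")
    return out


def validate_config(source=None) -> dict:
    """Load, normalise and validate a pipeline configuration.

    ``source`` may be a path to a YAML file, a dict, or None (full defaults).
    Unknown keys are rejected; micrometre-specified scales are converted to
    pixels through the simulated field's pixel size.
    """
    if source is None:
        given = {}
    elif isinstance(source, dict):
        given = source
    else:
        with open(source) as fh:
            given = yaml.safe_load(fh) or {}
    cfg = _merge_with_defaults(DEFAULT_CONFIG, given)

    sim = cfg["simulate"]
    if sim["field_width_px"] <= 0 or sim["field_height_px"] <= 0:
        raise ConfigError("field dimensions must be positive")
    if sim["pixel_size_um"] <= 0:
        raise ConfigError("pixel_size_um must be positive")
    for stage in cfg["stages"]:
        if stage not in STAGES:
            raise ConfigError(f"unknown stage {stage!r}")
    hp = cfg["hotspot"]
    if hp["d_um"] is not None:
        # exact unit conversion through the field pixel size
        hp["d_actual_px"] = float(hp["d_um"]) / sim["pixel_size_um"]
    else:
        hp["d_actual_px"] = (
            float(hp["d_px"]) * FULL_SCALE_PIXEL_UM / sim["pixel_size_um"]
        )
    hp["cell_actual_px"] = (
        float(hp["cell_size_px"]) * FULL_SCALE_PIXEL_UM / sim["pixel_size_um"]
    )
    qt_cfg = cfg["quantify"]
    if qt_cfg["cv_tol"] <= 0:
        raise ConfigError("cv_tol must be positive")
    st_cfg = cfg["stats"]
    if min(st_cfg["n_animals_per_group"]) < 2:
        raise ConfigError("need at least 2 animals per group")
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.6g")


def run_pipeline(cfg: dict, out_dir) -> Path:
    """Execute the enabled stages in order into ``out_dir``.

    Raises :class:`StageDependencyError` when an enabled stage is missing an
    upstream product.  Returns the run directory.
    """
    cfg = validate_config(cfg) if not cfg.get("_validated") else cfg
    cfg["_validated"] = True
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    enabled = set(cfg["stages"])
    seed = int(cfg["seed"])
    state: dict = {}

    manifest = {
        "config_hash": config_hash(
            {k: v for k, v in cfg.items() if not k.startswith("_")}
        ),
        "seed": seed,
        "stages": [s for s in STAGES if s in enabled],
    }

    if "simulate" in enabled:
        sim = cfg["simulate"]
        config = syn.SimulationConfig(
            seed=seed,
            field_width_px=sim["field_width_px"],
            field_height_px=sim["field_height_px"],
            pixel_size_um=sim["pixel_size_um"],
            n_lobules=sim["n_lobules"],
            od_noise_sd=sim["od_noise_sd"],
        )
        gt = syn.generate_field(config, sim["age_group"])
        field, labels = syn.render_field(gt)
        state.update(gt=gt, field=field, labels=labels)
        write_image(out / "field.tif", field.rgb)
        write_image(out / "epithelium_truth.tif",
                    gt.epithelium_mask.astype(np.uint8) * 255)
        _write_csv(gt.cells, out / "cells.csv")
        with open(out / "truth.yaml", "w") as fh:
            yaml.safe_dump(
                {
                    "seed": seed,
                    "age_group": sim["age_group"],
                    "pixel_size_um": sim["pixel_size_um"],
                    "n_cells": int(len(gt.cells)),
                },
                fh,
            )

    if "normalize" in enabled:
        if "field" not in state:
            raise StageDependencyError("normalize requires the simulate stage output")
        field = state["field"]
        source = estimate_stain_matrix(field.rgb)
        reference = StainModel.default_hdab()
        reference.max_concentrations = source.max_concentrations.copy()
        normalized = normalize_to_reference(field.rgb, source, reference)
        state["normalized"] = normalized
        state["stain"] = reference
        source.to_yaml(out / "stain_model.yaml")
        write_image(out / "field_normalized.tif", normalized)

    if "segment" in enabled:
        if "normalized" not in state:
            raise StageDependencyError("segment requires the normalize stage output")
        params = sg.SegmentationParams(**cfg["segment"])
        masks = sg.segment_field(state["normalized"], state["stain"], params)
        masks = dataclasses.replace(
            masks, pixel_size_um=state["field"].pixel_size_um
        )
        centroids = sg.extract_centroids(masks)
        state.update(masks=masks, centroids=centroids)
        write_image(out / "epithelium_mask.tif",
                    masks.epithelium.astype(np.uint8) * 255)
        write_image(out / "ki67_pos_labels.tif", masks.ki67_pos.astype(np.uint16))
        write_image(out / "ki67_neg_labels.tif", masks.ki67_neg.astype(np.uint16))
        _write_csv(centroids, out / "centroids.csv")

    measurements: List[dict] = []

    if "ki67_ratio" in enabled:
        if "masks" not in state:
            raise StageDependencyError("ki67_ratio requires the segment stage output")
        ratio = qt.ki67_epithelial_ratio(state["masks"])
        measurements.append(
            dict(
                measure="ki67_epithelial_ratio",
                value=ratio.ratio if ratio.defined else float("nan"),
                units="pixel_ratio",
                defined=ratio.defined,
            )
        )

    if "hotspot" in enabled:
        if "centroids" not in state:
            raise StageDependencyError("hotspot requires the segment stage output")
        hp = cfg["hotspot"]
        h, w = state["field"].shape
        grid = hs.grid_discretise(
            state["centroids"], (h, w), hp["cell_actual_px"], phenotype="ki67_pos"
        )
        result = hs.getis_ord(grid, hp["d_actual_px"])
        hotspots = hs.hotspot_mask(result, hp["z_threshold"])
        _write_csv(result.to_frame(), out / "getis_ord.csv")
        np.savetxt(out / "hotspots.csv", hotspots.astype(int), fmt="%d", delimiter=",")
        axis_u = hs.grid_axis_coordinates(grid, state["gt"].lobules)
        try:
            pol = hs.polarisation_index(hotspots, axis_u)
        except ValueError:
            pol = float("nan")
        measurements.append(
            dict(measure="polarisation_index", value=pol, units="fraction",
                 defined=np.isfinite(pol))
        )
        state["hotspots"] = hotspots

    if "immune" in enabled:
        # morphometry runs on the coarser slide-scale support
        slide_cfg = syn.slide_scale_config(seed=seed + 1)
        slide = syn.generate_field(slide_cfg, cfg["simulate"]["age_group"])
        state["slide"] = slide
        parenchyma = slide.epithelium_mask | slide.stroma_mask
        n_per_class = cfg["quantify"]["n_boxes_per_class"]
        boxes = _place_classified_boxes(
            slide, parenchyma, n_per_class, seed=seed + 2
        )
        box_rows = []
        for k, box in enumerate(boxes):
            _fill_box(box, slide)
            for rec in qt.immune_densities(box):
                box_rows.append(
                    dict(
                        box=k,
                        location=box.location_class,
                        measure=rec.name,
                        value=rec.value if rec.defined else float("nan"),
                        units=rec.units,
                        defined=rec.defined,
                    )
                )
        _write_csv(pd.DataFrame(box_rows), out / "count_boxes.csv")
        # macrophage periodicity
        gaps = []
        for trace in slide.ducts:
            runs = qt.detect_periodic_runs(trace, cv_tol=cfg["quantify"]["cv_tol"])
            gaps.extend(qt.inter_macrophage_distances(runs))
        if gaps:
            measurements.append(
                dict(
                    measure="inter_macrophage_distance_um",
                    value=float(np.mean(gaps)),
                    units="um",
                    defined=True,
                )
            )
        # TLS
        b = slide.cells_of("b_cell")[["x_px", "y_px"]].to_numpy()
        t = slide.cells_of("t_cell_stromal", "t_cell_epithelial")[
            ["x_px", "y_px"]
        ].to_numpy()
        tissue_mm2 = mm2_of(parenchyma, slide_cfg.pixel_size_um)
        _, tls_density = qt.detect_tls(
            b, t, tissue_mm2, pixel_size_um=slide_cfg.pixel_size_um
        )
        measurements.append(
            dict(measure="tls_per_mm2", value=tls_density, units="per_mm2",
                 defined=True)
        )

    if measurements:
        _write_csv(pd.DataFrame(measurements), out / "measurements.csv")

    if "stats" in enabled:
        table = syn.emulate_measurement_tables(
            tuple(cfg["stats"]["n_animals_per_group"]), seed=seed + 3
        )
        _write_csv(table, out / "animal_table.csv")
        report = []
        for measure in (
            "ki67_epithelial_ratio",
            "inter_macrophage_distance_um",
            "t_epi_per100",
            "t_stromal_per_mm2",
            "tls_per_mm2",
        ):
            cmpres = st.compare_groups(table, measure)
            report.append(_comparison_row(cmpres))
        paired = st.compare_groups(
            table,
            "stromal_mac_density",
            paired=True,
            paired_measures=(
                "stromal_mac_density_central",
                "stromal_mac_density_peripheral",
            ),
        )
        report.append(_comparison_row(paired))
        _write_csv(pd.DataFrame(report), out / "stats_report.csv")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out


def _comparison_row(c: st.GroupComparison) -> dict:
    row = dict(measure=c.measure, test=c.test, statistic=c.statistic, p=c.p_value)
    for name, summ in c.group_summaries.items():
        row[f"mean_{name}"] = summ["mean"]
        row[f"sd_{name}"] = summ["sd"]
        row[f"n_{name}"] = summ["n"]
    return row


def _place_classified_boxes(
    slide: syn.GroundTruth,
    parenchyma: np.ndarray,
    n_per_class: int,
    seed: int,
    max_rounds: int = 200,
) -> List[qt.CountBox]:
    """Random blinded placement, retained until each location class is filled."""
    px = slide.config.pixel_size_um
    central: List[qt.CountBox] = []
    peripheral: List[qt.CountBox] = []
    for round_id in range(max_rounds):
        batch = qt.place_count_boxes(
            parenchyma, 8, px, seed=seed * 1000 + round_id
        )
        for box in batch:
            cls = qt.classify_box_location(box, parenchyma)
            box.location_class = cls
            if cls == "central" and len(central) < n_per_class:
                central.append(box)
            elif cls == "peripheral" and len(peripheral) < n_per_class:
                peripheral.append(box)
        if len(central) >= n_per_class and len(peripheral) >= n_per_class:
            return central + peripheral
    raise RuntimeError("could not fill both location classes with count boxes")


def _fill_box(box: qt.CountBox, slide: syn.GroundTruth) -> None:
    """Populate a box's counts and normalising areas from the ground truth."""
    px = slide.config.pixel_size_um
    sl = box.pixel_slice()
    box.intralobular_stroma_mm2 = mm2_of(slide.stroma_mask[sl], px)
    # total stroma within the box = everything that is not epithelium
    box.total_stroma_mm2 = mm2_of((~slide.epithelium_mask)[sl], px)
    counts = qt.count_cells_in_box(box, slide.cells)
    box.counts = counts.to_dict()
    box.luminal_count = int(counts.get("luminal", 0))
    lum = slide.cells_of("luminal")
    if box.luminal_count > 0:
        inside = lum[
            (lum.x_px >= box.x0_px)
            & (lum.x_px < box.x0_px + box.width_px)
            & (lum.y_px >= box.y0_px)
            & (lum.y_px < box.y0_px + box.height_px)
        ]
        if len(inside):
            box.mean_luminal_area_um2 = float(inside.area_px.mean()) * px**2
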