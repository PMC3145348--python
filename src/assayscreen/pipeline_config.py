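"""Configured end-to-end run: illumination -> segmentation -> features ->
derived -> aggregation -> screening.

The configuration fans parallel parameter values (dilation distances,
classification thresholds, texture offsets) out into feature-name suffixes
within a single run, so the screening stage compares them all at once.
Per-image failures are logged and skipped; the run aborts only when no
image set processes successfully.  Every stage is a pure function of
(inputs, config), so reruns reproduce outputs bit for bit.
"""

from __future__ import annotations

import copy
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import derived_aggregate as da
from . import features as ft
from . import segmentation as seg
from .illumination import apply_correction, estimate_illumination
from .metadata_io import load_experiment, read_image, write_feature_table, write_report
from .screen import ControlSpec, screen_features

__all__ = ["DEFAULT_CONFIG", "validate_config", "run_pipeline", "measure_image_set"]

log = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "channels": {"dna": "dna", "green": "green"},
    "illumination": {"enabled": True, "filter_size": 151},
    "segmentation": {
        "threshold_method": "otsu_global",
        "min_area": 40,
        "max_area": 5000,
        "declump": True,
        "smoothing_sigma": 1.0,
        "remove_border": True,
    },
    "compartments": {
        "dilation_distances": [5, 10, 15],
        "cell": {"enabled": True, "threshold": "otsu", "regularization": 0.05},
    },
    "speckles": {
        "enabled": True,
        "element_radius": 5,
        "min_area": 2,
        "max_area": 200,
        "per_object": True,
        "min_threshold": 0.1,
    },
    "features": {
        "texture_offsets": [1, 3, 5],
        "texture_levels": 8,
        "radial_bins": 4,
        "radial_wedges": 8,
    },
    "derived": {
        # ratio pairs as [numerator, denominator]; "{d}" expands per dilation
        "ratios": [
            ["Ring{d}_Intensity_Mean_green", "Nucleus_Intensity_Mean_green"],
        ],
        # classification thresholds applied to every derived ratio
        "classified_thresholds": [0.5, 1.0, 2.0],
    },
    "screen": {"score": "auto"},
}


def _merge(defaults: dict, user: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, val in user.items():
        here = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ValueError(f"unknown config key {here!r}")
        if isinstance(defaults[key], dict):
            if not isinstance(val, dict):
                raise ValueError(f"config key {here!r} must be a mapping")
            out[key] = _merge(defaults[key], val, here)
        else:
            out[key] = val
    return out


def validate_config(config: str | Path | dict | None) -> dict:
    """Fill defaults, reject unknown keys, normalize degenerate values.

    ``config`` may be a YAML file path, an already-parsed mapping, or None
    (fully defaulted).  An even illumination filter size is bumped to the
    next odd value with a logged warning.
    """
    if config is None:
        user = {}
    elif isinstance(config, dict):
        user = config
    else:
        with open(config) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError(f"{config}: config must be a mapping")
    cfg = _merge(DEFAULT_CONFIG, user)
    fs = cfg["illumination"]["filter_size"]
    if fs % 2 == 0:
        log.warning("filter_size %d is even; using %d", fs, fs + 1)
        cfg["illumination"]["filter_size"] = fs + 1
    return cfg


def _cell_threshold(green: np.ndarray, spec) -> float:
    if spec == "otsu":
        from skimage.filters import threshold_otsu

        return float(threshold_otsu(green)) if np.ptp(green) > 1e-12 else 1.0
    return float(spec)


def measure_image_set(
    rasters: dict[str, np.ndarray], cfg: dict
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Measure one image set: all compartments, channels and categories.

    Returns the per-object (cell) feature table, indexed by object label
    with full feature names, plus per-image scalars (image-level channel
    correlation, speckle totals, per-compartment object counts).
    """
    dna_name = cfg["channels"]["dna"]
    green_name = cfg["channels"]["green"]
    dna = rasters[dna_name]
    green = rasters[green_name]

    sp = cfg["segmentation"]
    params = seg.SegmentationParams(
        threshold_method=sp["threshold_method"],
        min_area=sp["min_area"],
        max_area=sp["max_area"],
        declump=sp["declump"],
        smoothing_sigma=sp["smoothing_sigma"],
        remove_border=sp["remove_border"],
    )
    nuclei = seg.segment_nuclei(dna, params)

    compartments: dict[str, np.ndarray] = {"Nucleus": nuclei}
    if nuclei.max() > 0:
        dist_map, label_map = seg.nearest_object_maps(nuclei)
        for d in cfg["compartments"]["dilation_distances"]:
            dilated = np.where(dist_map <= d, label_map, 0).astype(np.int32)
            compartments[f"Dilated{d}"] = dilated
            compartments[f"Ring{d}"] = seg.subtract_compartment(dilated, nuclei)
        cell_cfg = cfg["compartments"]["cell"]
        if cell_cfg["enabled"]:
            thr = _cell_threshold(green, cell_cfg["threshold"])
            compartments["Cell"] = seg.propagate_cells(
                nuclei, green, thr, cell_cfg["regularization"]
            )

    image_scalars: dict[str, float] = {}
    blocks: list[pd.DataFrame] = []
    fcfg = cfg["features"]
    for comp_name, comp in compartments.items():
        per_comp: list[pd.DataFrame] = []
        shape_df = ft.measure_shape(comp).add_prefix(f"{comp_name}_Shape_")
        per_comp.append(shape_df)
        for ch_name, raster in ((dna_name, dna), (green_name, green)):
            inten = ft.measure_intensity(comp, raster).add_prefix(
                f"{comp_name}_Intensity_"
            )
            inten.columns = [f"{c}_{ch_name}" for c in inten.columns]
            per_comp.append(inten)
            for off in fcfg["texture_offsets"]:
                tex = ft.measure_texture(comp, raster, off, fcfg["texture_levels"])
                tex.columns = [
                    f"{comp_name}_Texture_{c}_{ch_name}_{off}" for c in tex.columns
                ]
                per_comp.append(tex)
            rad = ft.measure_radial(
                comp, raster, fcfg["radial_bins"], fcfg["radial_wedges"]
            )
            rad.columns = [
                f"{comp_name}_RadialDistribution_{c}_{ch_name}" for c in rad.columns
            ]
            per_comp.append(rad)
        corr, img_corr = ft.measure_correlation(comp, green, dna)
        corr.columns = [
            f"{comp_name}_Correlation_{c}_{green_name}_{dna_name}"
            for c in corr.columns
        ]
        per_comp.append(corr)
        if comp_name == "Nucleus":
            for k, v in img_corr.items():
                image_scalars[f"Image_Correlation_{k}_{green_name}_{dna_name}"] = v
        blocks.append(pd.concat(per_comp, axis=1))
        image_scalars[f"{comp_name}_Count"] = float(int(comp.max()))

    cells = pd.concat(blocks, axis=1) if blocks else pd.DataFrame()

    spk = cfg["speckles"]
    if spk["enabled"] and nuclei.max() > 0:
        parent = compartments.get("Cell", compartments.get("Dilated15", nuclei))
        enhanced = seg.tophat_enhance(green, spk["element_radius"])
        speckles, pmap = seg.detect_speckles(
            enhanced,
            parent,
            spk["min_area"],
            spk["max_area"],
            spk["per_object"],
            spk["min_threshold"],
        )
        child_counts, total = ft.count_children(pmap, parent)
        child_counts.columns = ["Cell_Children_SpeckleCount"]
        cells = pd.concat([cells, child_counts], axis=1)
        image_scalars["Image_Children_SpeckleCount_Count"] = float(total)
        if speckles.max() > 0:
            sp_int = ft.measure_intensity(speckles, green).add_prefix(
                "Speckle_Intensity_"
            )
            sp_int.columns = [f"{c}_{green_name}" for c in sp_int.columns]
            sp_shape = ft.measure_shape(speckles).add_prefix("Speckle_Shape_")
            sp_all = pd.concat([sp_int, sp_shape], axis=1)
            for col in sp_all.columns:
                image_scalars[f"Mean_{col}"] = float(sp_all[col].mean())
    return cells, image_scalars


def _derived_ratio_names(cfg: dict) -> list[tuple[str, str]]:
    pairs = []
    for num, den in cfg["derived"]["ratios"]:
        if "{d}" in num or "{d}" in den:
            for d in cfg["compartments"]["dilation_distances"]:
                pairs.append((num.format(d=d), den.format(d=d)))
        else:
            pairs.append((num, den))
    return pairs


def run_pipeline(
    metadata_path: str | Path,
    config: str | Path | dict | None,
    out_dir: str | Path,
) -> tuple[pd.DataFrame, "object"]:
    """Run the full screen and return (per-image FeatureTable, QualityReport).

    Writes ``features.csv``, ``report.csv`` and ``skipped.csv`` to
    ``out_dir``.  Image sets whose files fail to load or process are
    skipped and listed, not fatal.
    """
    cfg = validate_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    channel_names = list(cfg["channels"].values())
    experiment = load_experiment(metadata_path, channel_names)

    # load once, remembering failures
    loaded: dict[str, dict[str, np.ndarray]] = {}
    skipped: list[tuple[str, str]] = []
    for rec in experiment:
        try:
            loaded[rec.set_id] = {
                ch: read_image(rec.channel_paths[ch]) for ch in channel_names
            }
        except Exception as exc:  # noqa: BLE001 — fault isolation by design
            log.warning("skipping %s: %s", rec.set_id, exc)
            skipped.append((rec.set_id, str(exc)))

    if cfg["illumination"]["enabled"] and loaded:
        shapes = {r.shape for imgs in loaded.values() for r in imgs.values()}
        if len(shapes) == 1:
            for ch in channel_names:
                fn = estimate_illumination(
                    [imgs[ch] for imgs in loaded.values()],
                    cfg["illumination"]["filter_size"],
                    channel=ch,
                )
                for imgs in loaded.values():
                    imgs[ch] = apply_correction(imgs[ch], fn)
        else:
            log.warning("mixed image dimensions; skipping illumination correction")

    perobj_parts, image_rows = [], {}
    for rec in experiment:
        if rec.set_id not in loaded:
            continue
        t0 = time.perf_counter()
        try:
            cells, scalars = measure_image_set(loaded[rec.set_id], cfg)
        except Exception as exc:  # noqa: BLE001
            log.warning("skipping %s during measurement: %s", rec.set_id, exc)
            skipped.append((rec.set_id, str(exc)))
            continue
        image_rows[rec.set_id] = scalars
        if not cells.empty:
            cells.index = pd.MultiIndex.from_product(
                [[rec.set_id], cells.index], names=["set_id", "label"]
            )
            perobj_parts.append(cells)
        log.info(
            "set=%s stage=measure objects=%d elapsed=%.2fs",
            rec.set_id, len(cells), time.perf_counter() - t0,
        )

    if not image_rows:
        raise RuntimeError("no image set processed successfully")

    perobj = pd.concat(perobj_parts) if perobj_parts else pd.DataFrame()

    if not perobj.empty:
        for num, den in _derived_ratio_names(cfg):
            if num in perobj.columns and den in perobj.columns:
                ratio = da.ratio_feature(perobj, num, den)
                perobj[ratio.name] = ratio

    table = da.aggregate_per_image(perobj) if not perobj.empty else pd.DataFrame()
    scalar_df = pd.DataFrame.from_dict(image_rows, orient="index")
    scalar_df.index.name = "set_id"
    table = scalar_df.join(table, how="left") if not table.empty else scalar_df

    if not perobj.empty:
        for col in perobj.columns:
            if col.startswith("Derived_Ratio_"):
                for thr in cfg["derived"]["classified_thresholds"]:
                    frac = da.classify_fraction(perobj, col, thr)
                    table[frac.name] = frac

    survivors = [r for r in experiment if r.set_id in image_rows]
    spec = ControlSpec(
        positive=tuple(r.set_id for r in survivors if r.control == "positive"),
        negative=tuple(r.set_id for r in survivors if r.control == "negative"),
        dose={r.set_id: r.dose for r in survivors},
    )
    report = screen_features(table, spec, cfg["screen"]["score"])

    write_feature_table(table, out_dir / "features.csv")
    write_report(report, out_dir / "report.csv")
    pd.DataFrame(skipped, columns=["set_id", "reason"]).to_csv(
        out_dir / "skipped.csv", index=False
    )
    return table, report
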