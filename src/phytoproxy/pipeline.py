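"""Pipeline orchestration: simulate -> segment -> index -> calibrate -> estimate.

Dataset-on-disk convention (one directory per run):

    manifest.csv                 one row per scene, plus scene geometry
    run_config.yaml              fully resolved configuration + config hash
    <scene_id>_rgb.png           8-bit RGB image
    <scene_id>_cube.hdr/.raw     ENVI reflectance cube
    <scene_id>_f0.csv, _fm.csv   fluorescence maps
    <scene_id>_truth.png         ground-truth plant mask

Mask modes for processing:

    split   RGB-window mask for RGB indices, NDVI-threshold mask for
            NDVI/PRI/Fv/Fm (the study convention; default)
    rgb     RGB-window mask for everything
    ndvi    NDVI-threshold mask for everything
    truth   ground-truth mask (synthetic data only)
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import image_io, indices, segmentation
from .geometry import Rect
from .synthetic import (
    DEFAULT_LAYOUT,
    ExperimentConfig,
    SceneBundle,
    SceneLayout,
    generate_experiment,
)

logger = logging.getLogger(__name__)

MASK_MODES = ("split", "rgb", "ndvi", "truth")

RECORD_COLUMNS = (
    "species", "treatment", "day", "roi",
    "r", "g", "b", "ExG", "VEG", "VARI", "NDVI", "PRI", "FvFm",
)

_CSV_FLOAT_FORMAT = "%.10g"


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of a pipeline run (written to every dataset)."""

    species: tuple[str, ...]
    treatments: tuple[str, ...]
    days: tuple[int, ...]
    seed: int
    mask_mode: str = "split"
    layout: SceneLayout = DEFAULT_LAYOUT

    def experiment_config(self) -> ExperimentConfig:
        return ExperimentConfig(self.species, self.treatments, self.days, self.layout)

    def to_yaml(self) -> str:
        payload = {
            "species": list(self.species),
            "treatments": list(self.treatments),
            "days": list(self.days),
            "seed": self.seed,
            "mask_mode": self.mask_mode,
            "layout": asdict(self.layout),
        }
        return yaml.safe_dump(payload, sort_keys=True)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def _rect_cols(prefix: str, rect: Rect) -> dict[str, int]:
    return {f"{prefix}_{k}": getattr(rect, k) for k in ("r0", "r1", "c0", "c1")}


def simulate_to_dir(config: RunConfig, outdir) -> pd.DataFrame:
    """Render the full experiment and write the dataset directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundles, manifest = generate_experiment(config.experiment_config(), config.seed)
    manifest = manifest.assign(
        config_hash=config.config_hash,
        **_rect_cols("white", config.layout.white_patch),
        **_rect_cols("plant", config.layout.plant_region),
    )
    for bundle in bundles:
        stem = f"{bundle.species}_{bundle.treatment}_d{bundle.day:02d}"
        image_io.write_rgb(outdir / f"{stem}_rgb.png", bundle.rgb)
        image_io.write_cube(outdir / f"{stem}_cube.hdr", bundle.cube, bundle.wavelengths)
        image_io.write_float_map(outdir / f"{stem}_f0.csv", bundle.f0_map)
        image_io.write_float_map(outdir / f"{stem}_fm.csv", bundle.fm_map)
        image_io.write_mask(outdir / f"{stem}_truth.png", bundle.truth_mask)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    (outdir / "run_config.yaml").write_text(
        config.to_yaml() + f"config_hash: {config.config_hash}\n"
    )
    logger.info("simulated %d scenes into %s", len(bundles), outdir)
    return manifest


def load_bundle(datadir, row) -> SceneBundle:
    """Reconstruct a SceneBundle from a manifest row."""
    datadir = Path(datadir)
    stem = row["scene_id"]
    cube, wl = image_io.read_cube(datadir / f"{stem}_cube.hdr")
    return SceneBundle(
        rgb=image_io.read_rgb(datadir / f"{stem}_rgb.png"),
        cube=cube,
        wavelengths=wl,
        f0_map=image_io.read_float_map(datadir / f"{stem}_f0.csv"),
        fm_map=image_io.read_float_map(datadir / f"{stem}_fm.csv"),
        truth_mask=image_io.read_mask(datadir / f"{stem}_truth.png"),
        white_patch=Rect(row["white_r0"], row["white_r1"], row["white_c0"], row["white_c1"]),
        species=row["species"],
        treatment=row["treatment"],
        day=int(row["day"]),
    )


def _masks_for(bundle: SceneBundle, mask_mode: str, ndvi_map: np.ndarray):
    """Return (mask for RGB indices, mask for NDVI/PRI, mask for Fv/Fm).

    In ``split`` mode Fv/Fm uses the ground-truth mask, emulating a
    handheld fluorometer measured directly on plants rather than gated by
    a reflectance threshold.
    """
    if mask_mode not in MASK_MODES:
        raise ValueError(f"unknown mask mode {mask_mode!r}; expected one of {MASK_MODES}")
    rgb_m = segmentation.rgb_plant_mask(bundle.rgb, bundle.species)
    ndvi_m = segmentation.ndvi_plant_mask(ndvi_map, bundle.species)
    truth_m = segmentation.PlantMask(bundle.truth_mask, "truth")
    return {
        "split": (rgb_m, ndvi_m, truth_m),
        "rgb": (rgb_m, rgb_m, rgb_m),
        "ndvi": (ndvi_m, ndvi_m, ndvi_m),
        "truth": (truth_m, truth_m, truth_m),
    }[mask_mode]


def process_bundle(bundle: SceneBundle, mask_mode: str = "split",
                   rois: segmentation.ROISet | None = None) -> pd.DataFrame:
    """Per-ROI averaged index records for one scene (one row per ROI)."""
    if rois is None:
        region = bundle.layout.plant_region if bundle.layout else None
        rois = segmentation.default_rois(bundle.truth_mask.shape, region=region)

    white = image_io.white_stats(bundle.rgb, bundle.white_patch)
    rn, gn, bn = indices.normalize_channels(
        bundle.rgb[..., 0], bundle.rgb[..., 1], bundle.rgb[..., 2], white
    )
    rgb_maps = indices.rgb_indices(rn, gn, bn)
    ndvi_map = indices.ndvi(bundle.cube, bundle.wavelengths)
    pri_map = indices.pri(bundle.cube, bundle.wavelengths)
    fvfm_map = indices.fv_fm(bundle.f0_map, bundle.fm_map)

    rgb_mask, nb_mask, fluo_mask = _masks_for(bundle, mask_mode, ndvi_map)
    logger.info(
        "scene %s_%s_d%02d: %d truth / %d rgb-mask / %d ndvi-mask plant pixels",
        bundle.species, bundle.treatment, bundle.day,
        int(bundle.truth_mask.sum()), int(rgb_mask.mask.sum()), int(nb_mask.mask.sum()),
    )

    columns = {}
    for name, vmap in rgb_maps.items():
        columns[name] = segmentation.roi_average(vmap, rgb_mask, rois)
    columns["NDVI"] = segmentation.roi_average(ndvi_map, nb_mask, rois)
    columns["PRI"] = segmentation.roi_average(pri_map, nb_mask, rois)
    columns["FvFm"] = segmentation.roi_average(fvfm_map, fluo_mask, rois)

    df = pd.DataFrame(columns)
    df.insert(0, "roi", df.index)
    df.insert(0, "day", bundle.day)
    df.insert(0, "treatment", bundle.treatment)
    df.insert(0, "species", bundle.species)
    return df.reset_index(drop=True)


def process_bundles(bundles, mask_mode: str = "split",
                    rois: segmentation.ROISet | None = None) -> pd.DataFrame:
    records = pd.concat(
        [process_bundle(b, mask_mode, rois) for b in bundles], ignore_index=True
    )
    return records[list(RECORD_COLUMNS)]


def process_dataset(datadir, mask_mode: str = "split",
                    roi_file=None) -> pd.DataFrame:
    """Process an on-disk dataset into an IndexRecord table."""
    datadir = Path(datadir)
    manifest = pd.read_csv(datadir / "manifest.csv")
    rois = segmentation.read_roi_csv(roi_file) if roi_file else None
    frames = []
    for _, row in manifest.iterrows():
        bundle = load_bundle(datadir, row)
        if rois is None:
            region = Rect(row["plant_r0"], row["plant_r1"], row["plant_c0"], row["plant_c1"])
            scene_rois = segmentation.default_rois(
                bundle.truth_mask.shape, int(row["n_rois"]), region=region
            )
        else:
            scene_rois = rois
        frames.append(process_bundle(bundle, mask_mode, scene_rois))
    records = pd.concat(frames, ignore_index=True)
    return records[list(RECORD_COLUMNS)]


def write_records(path, records: pd.DataFrame) -> None:
    records.to_csv(Path(path), index=False, float_format=_CSV_FLOAT_FORMAT)


def read_records(path) -> pd.DataFrame:
    return pd.read_csv(Path(path))
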