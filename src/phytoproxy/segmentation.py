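"""Plant-pixel segmentation and ROI averaging.

Two mask families are supported, matching common practice in proximal
sensing of pea and wheat canopies:

* RGB masks from scale-free channel-ratio scores applied to raw 8-bit
  channels (the 5*255 prefactor implies the 8-bit convention):

      score_pea   = 5 * 255 * (0.1 G)      / (0.1 G + 0.1 R + B)
      score_wheat = 5 * 255 * (0.1 G - R)  / (0.1 G + 0.1 R + B)

  A pixel is "plant" when the score falls strictly inside the species
  window: (115.33, 139.3) for pea, (36.39, 140) for wheat.  Because both
  scores are ratios they are invariant under any positive rescaling of
  (R, G, B) — so they are unchanged whether raw or white-normalized
  channels are used.

* NDVI thresholding on hyperspectral cubes: plant iff NDVI strictly
  exceeds 0.5 (pea) or 0.4 (wheat).

Index values are then averaged over plant pixels inside each of (by
default) 10 rectangular regions of interest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import Rect

logger = logging.getLogger(__name__)

SPECIES = ("pea", "wheat")

#: Strict (low, high) score windows defining "plant" pixels.
PEA_WINDOW = (115.33, 139.3)
WHEAT_WINDOW = (36.39, 140.0)

#: Strict NDVI thresholds above which a pixel counts as plant.
NDVI_THRESHOLDS = {"pea": 0.5, "wheat": 0.4}

DEFAULT_N_ROIS = 10


@dataclass(frozen=True)
class PlantMask:
    """Boolean plant/background raster with its provenance."""

    mask: np.ndarray
    method: str  # rgb_mask_pea | rgb_mask_wheat | ndvi_threshold | truth

    def __post_init__(self) -> None:
        if self.mask.dtype != bool or self.mask.ndim != 2:
            raise ValueError("mask must be a 2-D boolean raster")


@dataclass(frozen=True)
class ROISet:
    """Labelled rectangular regions of interest on a raster."""

    rois: tuple[tuple[str, Rect], ...]

    def __post_init__(self) -> None:
        if not self.rois:
            raise ValueError("ROI set is empty")

    def __iter__(self):
        return iter(self.rois)

    def __len__(self) -> int:
        return len(self.rois)

    @property
    def labels(self) -> list[str]:
        return [label for label, _ in self.rois]


def _ratio_score(numerator, r, g, b):
    den = 0.1 * g + 0.1 * r + b
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(den > 0, 5.0 * 255.0 * numerator / den, np.nan)


def mask_score_pea(r, g, b) -> np.ndarray:
    """Pea mask score 5*255*(0.1 G)/(0.1 G + 0.1 R + B); NaN when R=G=B=0."""
    r, g, b = (np.asarray(x, dtype=float) for x in (r, g, b))
    _check_channels(r, g, b)
    return _ratio_score(0.1 * g, r, g, b)


def mask_score_wheat(r, g, b) -> np.ndarray:
    """Wheat mask score 5*255*(0.1 G - R)/(0.1 G + 0.1 R + B)."""
    r, g, b = (np.asarray(x, dtype=float) for x in (r, g, b))
    _check_channels(r, g, b)
    return _ratio_score(0.1 * g - r, r, g, b)


def _check_channels(r, g, b) -> None:
    if np.any(r < 0) or np.any(g < 0) or np.any(b < 0):
        raise ValueError("channel intensities must be nonnegative")
    n_zero = int(np.sum((r + g + b) == 0)) if np.ndim(r) else int(r + g + b == 0)
    if n_zero:
        logger.debug("mask score: %d all-zero pixels classified background", n_zero)


def _window_mask(score: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    with np.errstate(invalid="ignore"):
        return np.asarray((score > lo) & (score < hi))


def mask_pea(r, g, b, window: tuple[float, float] = PEA_WINDOW) -> np.ndarray:
    """Boolean pea plant mask (strict window on the pea score)."""
    return _window_mask(mask_score_pea(r, g, b), window)


def mask_wheat(r, g, b, window: tuple[float, float] = WHEAT_WINDOW) -> np.ndarray:
    """Boolean wheat plant mask (strict window on the wheat score)."""
    return _window_mask(mask_score_wheat(r, g, b), window)


def rgb_plant_mask(image: np.ndarray, species: str,
                   window: tuple[float, float] | None = None) -> PlantMask:
    """Species RGB mask from an (H, W, 3) 8-bit image."""
    _check_species(species)
    image = np.asarray(image)
    r, g, b = image[..., 0], image[..., 1], image[..., 2]
    if species == "pea":
        m = mask_pea(r, g, b, window or PEA_WINDOW)
    else:
        m = mask_wheat(r, g, b, window or WHEAT_WINDOW)
    return PlantMask(m, f"rgb_mask_{species}")


def ndvi_plant_mask(ndvi_map: np.ndarray, species: str) -> PlantMask:
    """Plant mask by strict NDVI threshold: > 0.5 for pea, > 0.4 for wheat."""
    _check_species(species)
    ndvi_map = np.asarray(ndvi_map, dtype=float)
    finite = ndvi_map[np.isfinite(ndvi_map)]
    if finite.size and (finite.min() < -1 - 1e-9 or finite.max() > 1 + 1e-9):
        raise ValueError("NDVI map values must lie in [-1, 1]")
    with np.errstate(invalid="ignore"):
        mask = ndvi_map > NDVI_THRESHOLDS[species]
    return PlantMask(mask, "ndvi_threshold")


def _check_species(species: str) -> None:
    if species not in SPECIES:
        raise ValueError(f"unknown species {species!r}; expected one of {SPECIES}")


def _grid_factors(n: int) -> tuple[int, int]:
    """Largest factor pair (rows, cols) with rows <= cols; 10 -> (2, 5)."""
    rows = int(np.sqrt(n))
    while rows > 1 and n % rows:
        rows -= 1
    return rows, n // rows


def default_rois(shape: tuple[int, int], n: int = DEFAULT_N_ROIS,
                 region: Rect | None = None) -> ROISet:
    """Deterministic grid of ``n`` equal, non-overlapping rectangles.

    The grid covers ``region`` (default: the whole raster); for ``n = 10``
    it is a 2 x 5 grid.  User-supplied ROI files override this default in
    the pipeline.
    """
    if n < 1:
        raise ValueError("need at least one ROI")
    region = region or Rect(0, shape[0], 0, shape[1])
    if not region.within(shape):
        raise ValueError(f"ROI region {region} exceeds raster bounds {shape}")
    rows, cols = _grid_factors(n)
    if region.height < rows or region.width < cols:
        raise ValueError(f"region {region} too small for a {rows}x{cols} ROI grid")
    r_edges = np.linspace(region.r0, region.r1, rows + 1).astype(int)
    c_edges = np.linspace(region.c0, region.c1, cols + 1).astype(int)
    rois = []
    for i in range(rows):
        for j in range(cols):
            label = f"roi{i * cols + j + 1:02d}"
            rois.append((label, Rect(r_edges[i], r_edges[i + 1], c_edges[j], c_edges[j + 1])))
    return ROISet(tuple(rois))


def roi_average(value_map: np.ndarray, mask: PlantMask | np.ndarray,
                rois: ROISet) -> pd.Series:
    """Mean of ``value_map`` over plant pixels inside each ROI.

    An ROI with no (finite-valued) plant pixels yields NaN, never zero;
    missing values propagate to downstream statistics where they are
    dropped pairwise.
    """
    value_map = np.asarray(value_map, dtype=float)
    m = mask.mask if isinstance(mask, PlantMask) else np.asarray(mask, dtype=bool)
    if value_map.shape != m.shape:
        raise ValueError("value map and mask shapes differ")
    out = {}
    for label, rect in rois:
        if not rect.within(value_map.shape):
            raise ValueError(f"ROI {label} {rect} exceeds raster bounds")
        sel = m[rect.slices]
        vals = value_map[rect.slices][sel]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            logger.warning("ROI %s has no plant pixels; value set to missing", label)
            out[label] = np.nan
        else:
            out[label] = float(vals.mean())
    return pd.Series(out, name="mean")


def read_roi_csv(path) -> ROISet:
    """Read ROIs from a CSV with columns label, r0, r1, c0, c1 (half-open)."""
    df = pd.read_csv(Path(path))
    required = {"label", "r0", "r1", "c0", "c1"}
    if not required.issubset(df.columns):
        raise ValueError(f"ROI file must have columns {sorted(required)}")
    rois = tuple(
        (str(row.label), Rect(int(row.r0), int(row.r1), int(row.c0), int(row.c1)))
        for row in df.itertuples()
    )
    return ROISet(rois)


def write_roi_csv(path, rois: ROISet) -> None:
    pd.DataFrame(
        [
            {"label": label, "r0": r.r0, "r1": r.r1, "c0": r.c0, "c1": r.c1}
            for label, r in rois
        ]
    ).to_csv(Path(path), index=False)
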