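"""Vegetation indices: six RGB indices, NDVI, PRI and the PSII quantum yield.

RGB indices are computed from white-normalized channel intensities
``R', G', B'``:

    r = R' / (R' + G' + B')          (normalized red coordinate)
    g = G' / (R' + G' + B')          (normalized green coordinate)
    b = B' / (R' + G' + B')          (normalized blue coordinate)
    ExG  = 2 g - r - b               (excess green; equals 3 g - 1)
    VEG  = G' / (R'^a * B'^(1-a)),   a = 0.667
    VARI = (G' - R') / (G' + R' - B')

Narrow-band reflectance indices use reflectance at fixed wavelengths:

    NDVI = (R780 - R680) / (R780 + R680)
    PRI  = (R531 - R570) / (R531 + R570)

and the potential quantum yield of photosystem II from dark-adapted
PAM fluorometry is Fv/Fm = (Fm - F0) / Fm.

Undefined denominators yield NaN ("missing"), never an exception; missing
pixels are excluded from downstream ROI averages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

#: VEG exponent, stored exactly as the printed constant (not 2/3).
VEG_EXPONENT = 0.667

#: Wavelengths (nm) of the narrow reflectance bands used by NDVI and PRI.
NDVI_BANDS = (780.0, 680.0)
PRI_BANDS = (531.0, 570.0)

#: Maximum distance (nm) between a requested band and the nearest grid band.
BAND_TOLERANCE_NM = 5.0

RGB_INDEX_NAMES = ("r", "g", "b", "ExG", "VEG", "VARI")


@dataclass(frozen=True)
class FluorescencePair:
    """Dark (F0) and maximal (Fm) fluorescence yields for one measurement."""

    f0: float
    fm: float

    def __post_init__(self) -> None:
        if self.f0 < 0 or self.fm < 0:
            raise ValueError("fluorescence yields must be nonnegative")


def normalize_channels(r, g, b, white):
    """Divide raw channel intensities by the white-standard channel means.

    ``white`` is a length-3 sequence (R_w, G_w, B_w); all components must be
    strictly positive (enforced upstream by ``white_stats`` as well).
    """
    white = np.asarray(white, dtype=float)
    if white.shape != (3,):
        raise ValueError("white reference must have exactly three components")
    if np.any(white <= 0):
        raise ValueError("white reference components must be strictly positive")
    return (
        np.asarray(r, dtype=float) / white[0],
        np.asarray(g, dtype=float) / white[1],
        np.asarray(b, dtype=float) / white[2],
    )


def rgb_indices(rp, gp, bp) -> dict[str, np.ndarray]:
    """Compute the six RGB indices from (normalized) channel intensities.

    Accepts scalars or arrays; returns a dict of float arrays keyed by
    ``r, g, b, ExG, VEG, VARI``.  Pixels with an undefined denominator
    (zero channel sum; zero R' or B' for VEG; G'+R'-B' = 0 for VARI) are NaN.
    """
    rp = np.asarray(rp, dtype=float)
    gp = np.asarray(gp, dtype=float)
    bp = np.asarray(bp, dtype=float)
    if np.any(rp < 0) or np.any(gp < 0) or np.any(bp < 0):
        raise ValueError("channel intensities must be nonnegative")

    total = rp + gp + bp
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(total > 0, rp / total, np.nan)
        g = np.where(total > 0, gp / total, np.nan)
        b = np.where(total > 0, bp / total, np.nan)
        exg = 2.0 * g - r - b

        veg_den = rp**VEG_EXPONENT * bp ** (1.0 - VEG_EXPONENT)
        veg = np.where(veg_den > 0, gp / veg_den, np.nan)

        vari_den = gp + rp - bp
        vari = np.where(vari_den != 0, (gp - rp) / vari_den, np.nan)

    n_bad = int(np.sum(~np.isfinite(np.stack([r, veg, vari])))) if r.ndim else 0
    if n_bad:
        logger.debug("rgb_indices: %d undefined index values set to NaN", n_bad)
    return {"r": r, "g": g, "b": b, "ExG": exg, "VEG": veg, "VARI": vari}


def nearest_band(wavelengths, target: float, tolerance: float = BAND_TOLERANCE_NM) -> int:
    """Index of the grid wavelength closest to ``target`` (ties -> lower index).

    Raises if no band lies within ``tolerance`` nm of the target.
    """
    wl = np.asarray(wavelengths, dtype=float)
    if wl.ndim != 1 or wl.size == 0:
        raise ValueError("wavelengths must be a non-empty 1-D vector")
    if np.any(np.diff(wl) <= 0):
        raise ValueError("wavelengths must be strictly increasing")
    dist = np.abs(wl - float(target))
    idx = int(np.argmin(dist))  # argmin returns the first (lower) index on ties
    if dist[idx] > tolerance:
        raise ValueError(
            f"no band within {tolerance} nm of {target} nm "
            f"(closest: {wl[idx]:.2f} nm)"
        )
    return idx


def normalized_difference(cube, wavelengths, band_a: float, band_b: float) -> np.ndarray:
    """Per-pixel (R_a - R_b) / (R_a + R_b) from a (H, W, B) reflectance cube."""
    cube = np.asarray(cube, dtype=float)
    ia = nearest_band(wavelengths, band_a)
    ib = nearest_band(wavelengths, band_b)
    a = cube[..., ia]
    b = cube[..., ib]
    den = a + b
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(den != 0, (a - b) / den, np.nan)


def ndvi(cube, wavelengths) -> np.ndarray:
    """NDVI map: (R780 - R680) / (R780 + R680)."""
    return normalized_difference(cube, wavelengths, *NDVI_BANDS)


def pri(cube, wavelengths) -> np.ndarray:
    """PRI map: (R531 - R570) / (R531 + R570)."""
    return normalized_difference(cube, wavelengths, *PRI_BANDS)


def fv_fm(f0, fm) -> np.ndarray:
    """Potential quantum yield of PSII, (Fm - F0)/Fm.

    Vectorized over maps.  Fm <= 0 yields NaN; F0 > Fm (an invalid
    measurement) also yields NaN and is logged.
    """
    f0 = np.asarray(f0, dtype=float)
    fm = np.asarray(fm, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(fm > 0, (fm - f0) / fm, np.nan)
    invalid = (f0 > fm) & (fm > 0)
    if np.any(invalid):
        logger.warning("fv_fm: %d pixels with F0 > Fm set to NaN", int(np.sum(invalid)))
        ratio = np.where(invalid, np.nan, ratio)
    return ratio


def fv_fm_pair(pair: FluorescencePair) -> float:
    """Scalar Fv/Fm for one (F0, Fm) measurement pair."""
    return float(fv_fm(pair.f0, pair.fm))
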