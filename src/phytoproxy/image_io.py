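"""Raster and tabular I/O: 8-bit RGB images, ENVI reflectance cubes,
fluorescence maps, and white-standard statistics.

Hyperspectral cubes use the ENVI convention: a plain-text ``.hdr`` file with
``key = value`` pairs (including a ``wavelength = { ... }`` list, one entry per
band) next to a flat binary raster.  Cubes are written as band-sequential
(BSQ) float32; ``bil`` and ``bip`` interleaves are accepted on read.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .geometry import Rect

_ENVI_DTYPES = {
    1: np.uint8,
    2: np.int16,
    3: np.int32,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
}
_ENVI_DTYPE_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


@dataclass(frozen=True)
class WhiteReference:
    """Per-channel (or per-band) mean intensity over the white standard."""

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) == 0:
            raise ValueError("white reference is empty")
        if any(v <= 0 for v in self.values):
            raise ValueError("white reference values must be strictly positive")

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.values, dtype=dtype)


def write_rgb(path, image: np.ndarray) -> None:
    """Write an (H, W, 3) uint8 image as PNG or TIFF (by extension)."""
    image = np.asarray(image)
    if image.dtype != np.uint8 or image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) uint8 image")
    iio.imwrite(Path(path), image)


def read_rgb(path) -> np.ndarray:
    """Read an 8-bit 3-channel raster; alpha channels are rejected."""
    image = iio.imread(Path(path))
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"{path}: expected a 3-channel image, got shape {image.shape}")
    if image.dtype != np.uint8:
        raise ValueError(f"{path}: expected 8-bit data, got {image.dtype}")
    return image


def write_cube(hdr_path, cube: np.ndarray, wavelengths) -> None:
    """Write an (H, W, B) reflectance cube as ENVI BSQ float32.

    ``hdr_path`` names the header; the binary goes to the same stem with a
    ``.raw`` suffix.
    """
    hdr_path = Path(hdr_path)
    cube = np.asarray(cube, dtype=np.float32)
    wl = np.asarray(wavelengths, dtype=float)
    if cube.ndim != 3:
        raise ValueError("cube must be (lines, samples, bands)")
    if wl.ndim != 1 or wl.size != cube.shape[2]:
        raise ValueError("wavelength count must equal band count")
    lines, samples, bands = cube.shape
    raw_path = hdr_path.with_suffix(".raw")
    wl_text = ",\n ".join(f"{v:.4f}" for v in wl)
    hdr_path.write_text(
        "ENVI\n"
        f"samples = {samples}\n"
        f"lines = {lines}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_ENVI_DTYPE_CODES[np.dtype(np.float32)]}\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        "wavelength = {\n " + wl_text + "}\n"
    )
    # BSQ: band-major on disk
    np.ascontiguousarray(np.moveaxis(cube, 2, 0)).tofile(raw_path)


def _parse_envi_header(text: str) -> dict[str, str]:
    if not text.lstrip().upper().startswith("ENVI"):
        raise ValueError("not an ENVI header (missing ENVI magic line)")
    body = text.split("\n", 1)[1] if "\n" in text else ""
    fields: dict[str, str] = {}
    # join brace-delimited values across lines
    pattern = re.compile(r"^\s*([^=\n]+?)\s*=\s*(\{[^}]*\}|[^\n]*)", re.M | re.S)
    for m in pattern.finditer(body):
        key = m.group(1).strip().lower()
        val = m.group(2).strip()
        fields[key] = val
    return fields


def _find_raw(hdr_path: Path) -> Path:
    for suffix in (".raw", ".img", ".dat", ".bsq", ""):
        cand = hdr_path.with_suffix(suffix)
        if cand != hdr_path and cand.exists():
            return cand
    raise FileNotFoundError(f"no binary file found next to {hdr_path}")


def read_cube(hdr_path) -> tuple[np.ndarray, np.ndarray]:
    """Read an ENVI cube; returns ``(cube (H, W, B) float32, wavelengths)``.

    Rejects headers without wavelength metadata and binaries whose size does
    not match the declared dimensions.
    """
    hdr_path = Path(hdr_path)
    fields = _parse_envi_header(hdr_path.read_text())
    try:
        samples = int(fields["samples"])
        lines = int(fields["lines"])
        bands = int(fields["bands"])
        dtype_code = int(fields["data type"])
    except KeyError as exc:
        raise ValueError(f"{hdr_path}: missing required ENVI field {exc}") from exc
    if dtype_code not in _ENVI_DTYPES:
        raise ValueError(f"{hdr_path}: unsupported ENVI data type {dtype_code}")
    dtype = np.dtype(_ENVI_DTYPES[dtype_code])
    interleave = fields.get("interleave", "bsq").lower()
    offset = int(fields.get("header offset", 0))

    if "wavelength" not in fields:
        raise ValueError(f"{hdr_path}: missing wavelength metadata")
    wl_text = fields["wavelength"].strip().strip("{}")
    wavelengths = np.array(
        [float(tok) for tok in wl_text.replace("\n", ",").split(",") if tok.strip()]
    )
    if wavelengths.size != bands:
        raise ValueError(
            f"{hdr_path}: wavelength count {wavelengths.size} != band count {bands}"
        )

    raw_path = _find_raw(hdr_path)
    expected = offset + samples * lines * bands * dtype.itemsize
    actual = raw_path.stat().st_size
    if actual != expected:
        raise ValueError(
            f"{raw_path}: file size {actual} does not match header "
            f"({lines}x{samples}x{bands} {dtype.name} = {expected} bytes)"
        )
    flat = np.fromfile(raw_path, dtype=dtype, offset=offset)
    if interleave == "bsq":
        cube = np.moveaxis(flat.reshape(bands, lines, samples), 0, 2)
    elif interleave == "bil":
        cube = np.moveaxis(flat.reshape(lines, bands, samples), 1, 2)
    elif interleave == "bip":
        cube = flat.reshape(lines, samples, bands)
    else:
        raise ValueError(f"{hdr_path}: unknown interleave {interleave!r}")
    return np.ascontiguousarray(cube.astype(np.float32)), wavelengths


def write_float_map(path, array: np.ndarray) -> None:
    """Write a 2-D float map (e.g. F0/Fm) as plain CSV."""
    array = np.asarray(array, dtype=float)
    if array.ndim != 2:
        raise ValueError("expected a 2-D map")
    np.savetxt(Path(path), array, delimiter=",", fmt="%.8g")


def read_float_map(path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(Path(path), delimiter=","))


def write_mask(path, mask: np.ndarray) -> None:
    """Write a boolean mask as a single-channel 0/255 PNG."""
    mask = np.asarray(mask)
    if mask.dtype != bool or mask.ndim != 2:
        raise ValueError("expected a 2-D boolean mask")
    iio.imwrite(Path(path), (mask.astype(np.uint8) * 255))


def read_mask(path) -> np.ndarray:
    arr = iio.imread(Path(path))
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel mask")
    return arr > 127


def white_stats(raster: np.ndarray, patch: Rect) -> WhiteReference:
    """Per-channel (RGB image) or per-band (cube) mean over the white patch.

    The patch must lie within the raster and every channel mean must be
    strictly positive (a black "standard" indicates a measurement error).
    """
    raster = np.asarray(raster)
    if raster.ndim not in (2, 3):
        raise ValueError("raster must be 2-D or 3-D")
    if not patch.within(raster.shape):
        raise ValueError(f"white patch {patch} exceeds raster bounds {raster.shape[:2]}")
    region = raster[patch.slices]
    if region.size == 0:
        raise ValueError("white patch is empty")
    means = region.reshape(-1, 1 if raster.ndim == 2 else raster.shape[2]).mean(axis=0)
    if np.any(means <= 0):
        raise ValueError("white standard has a zero-mean channel (saturated black)")
    return WhiteReference(tuple(float(m) for m in means))
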