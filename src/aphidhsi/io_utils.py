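"""Minimal file IO for hyperspectral cubes and masks.

Cubes are stored as ENVI band-sequential (BSQ) rasters: a plain-text ``.hdr``
carrying the wavelength list in nanometres next to a float32 ``.img`` payload.
Only the small subset of the ENVI header dialect that this package writes is
understood by the reader.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
from PIL import Image

_DTYPE_CODES = {4: np.float32, 5: np.float64, 12: np.uint16, 1: np.uint8}
_CODE_FOR = {np.dtype(np.float32): 4, np.dtype(np.float64): 5,
             np.dtype(np.uint16): 12, np.dtype(np.uint8): 1}


def write_envi(path: str | Path, cube: np.ndarray, wavelengths_nm) -> Path:
    """Write a (bands, rows, cols) cube as ENVI BSQ; returns the ``.img`` path."""
    cube = np.asarray(cube)
    if cube.ndim != 3:
        raise ValueError(f"cube must be 3-D (bands, rows, cols), got {cube.shape}")
    wl = np.asarray(wavelengths_nm, dtype=float)
    if wl.size != cube.shape[0]:
        raise ValueError("wavelength list length must equal the band count")
    path = Path(path)
    img_path = path.with_suffix(".img")
    hdr_path = path.with_suffix(".hdr")
    data = np.ascontiguousarray(cube, dtype=cube.dtype)
    code = _CODE_FOR.get(data.dtype)
    if code is None:
        data = data.astype(np.float32)
        code = 4
    data.tofile(img_path)
    wl_str = ",\n ".join(f"{v:.4f}" for v in wl)
    hdr = (
        "ENVI\n"
        "file type = ENVI Standard\n"
        f"samples = {cube.shape[2]}\n"
        f"lines = {cube.shape[1]}\n"
        f"bands = {cube.shape[0]}\n"
        "header offset = 0\n"
        f"data type = {code}\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        "wavelength = {\n " + wl_str + "}\n"
    )
    hdr_path.write_text(hdr)
    return img_path


def read_envi(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read an ENVI BSQ raster; returns ``(cube, wavelengths_nm)``."""
    path = Path(path)
    hdr_path = path.with_suffix(".hdr")
    img_path = path.with_suffix(".img")
    text = hdr_path.read_text()

    def field(name: str) -> str:
        m = re.search(rf"^{name}\s*=\s*(.+)$", text, re.MULTILINE)
        if m is None:
            raise ValueError(f"missing ENVI header field: {name}")
        return m.group(1).strip()

    samples = int(field("samples"))
    lines = int(field("lines"))
    bands = int(field("bands"))
    dtype = _DTYPE_CODES[int(field("data type"))]
    interleave = field("interleave").lower()
    if interleave != "bsq":
        raise ValueError(f"only BSQ interleave is supported, got {interleave!r}")
    m = re.search(r"wavelength\s*=\s*\{([^}]*)\}", text, re.DOTALL)
    if m is None:
        raise ValueError("header has no wavelength block")
    wl = np.array([float(v) for v in m.group(1).replace("\n", " ").split(",") if v.strip()])
    cube = np.fromfile(img_path, dtype=dtype).reshape(bands, lines, samples)
    return cube, wl


def write_mask_png(path: str | Path, mask: np.ndarray) -> Path:
    """Write a boolean pixel mask as a single-band 8-bit PNG (255 = true)."""
    path = Path(path)
    arr = (np.asarray(mask, dtype=bool) * np.uint8(255))
    Image.fromarray(arr, mode="L").save(path)
    return path


def read_mask_png(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("L")) > 127
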