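"""Hyperspectral cube container, ENVI-style I/O and reflectance calibration.

A :class:`SpectralCube` is the unit of acquisition: a ``lines x samples x
bands`` grid of raw counts or reflectance percent, paired with a strictly
increasing wavelength vector in nm.  Calibration follows the standard
dark/white reference procedure

    R = 100 * (raw - dark) / (white - dark)

so a white-reference pixel maps to 100 % and a dark pixel to 0 %.
Reflectance is stored as float percent on the 0-100 scale; values outside
[0, 120] are clipped (real calibrations overshoot slightly on specular
facets, and the 120 cap preserves those flags for downstream masking).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

log = logging.getLogger(__name__)

REFLECTANCE_CLIP = (0.0, 120.0)

# ENVI numeric "data type" codes for the dtypes this module supports.
_ENVI_DTYPES = {
    1: np.uint8,
    2: np.int16,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
}
_DTYPE_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}

_INTERLEAVES = {
    # axis order of the on-disk array, in terms of (line, sample, band)
    "bil": (0, 2, 1),  # line, band, sample
    "bsq": (2, 0, 1),  # band, line, sample
    "bip": (0, 1, 2),  # line, sample, band
}


@dataclass
class SpectralCube:
    """3-D spectral grid with its wavelength axis.

    ``data`` has shape (lines, samples, bands); ``kind`` is ``"raw"`` for
    sensor counts and ``"reflectance"`` for calibrated percent values.
    """

    data: np.ndarray
    wavelengths: np.ndarray
    kind: str = "raw"
    flagged_bands: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"cube data must be 3-D, got shape {self.data.shape}")
        if self.wavelengths.ndim != 1 or len(self.wavelengths) != self.data.shape[2]:
            raise ValueError(
                f"wavelength vector length {len(self.wavelengths)} does not match "
                f"band dimension {self.data.shape[2]}"
            )
        if len(self.wavelengths) > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.kind not in ("raw", "reflectance"):
            raise ValueError(f"kind must be 'raw' or 'reflectance', got {self.kind!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def band_index(self, nm: float) -> int:
        """Nearest-band lookup for a wavelength in nm (no interpolation)."""
        lo, hi = self.wavelengths[0], self.wavelengths[-1]
        if not (lo <= nm <= hi):
            raise ValueError(f"{nm} nm outside wavelength range [{lo}, {hi}]")
        return int(np.argmin(np.abs(self.wavelengths - nm)))


def calibrate_reflectance(
    raw: SpectralCube, dark: SpectralCube, white: SpectralCube
) -> SpectralCube:
    """Convert raw counts to reflectance percent using dark/white references.

    Bands where the white and dark references coincide anywhere are flagged
    and their values set to NaN (the calibration is undefined there).
    Calibrated values are clipped to [0, 120] %, with the clip count logged.
    """
    for other, name in ((dark, "dark"), (white, "white")):
        if other.shape != raw.shape:
            raise ValueError(f"{name} reference shape {other.shape} != raw {raw.shape}")
        if not np.array_equal(other.wavelengths, raw.wavelengths):
            raise ValueError(f"{name} reference wavelengths differ from raw cube")

    denom = white.data.astype(np.float64) - dark.data.astype(np.float64)
    numer = raw.data.astype(np.float64) - dark.data.astype(np.float64)
    bad = denom == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        refl = 100.0 * numer / denom
    refl[bad] = np.nan
    flagged = sorted(int(b) for b in np.unique(np.nonzero(bad)[2]))
    if flagged:
        log.warning("calibration undefined (white == dark) in %d band(s)", len(flagged))

    lo, hi = REFLECTANCE_CLIP
    n_clipped = int(np.sum((refl < lo) | (refl > hi)))
    if n_clipped:
        log.info("clipped %d reflectance value(s) outside [%g, %g]%%", n_clipped, lo, hi)
    refl = np.clip(refl, lo, hi)
    return SpectralCube(refl, raw.wavelengths.copy(), kind="reflectance", flagged_bands=flagged)


def write_envi(cube: SpectralCube, path: str | Path, interleave: str = "bil") -> Path:
    """Write a cube as an ENVI-style ASCII header + flat little-endian binary.

    ``path`` names the binary file; the header is written next to it as
    ``<path>.hdr``.  Returns the header path.
    """
    interleave = interleave.lower()
    if interleave not in _INTERLEAVES:
        raise ValueError(f"unsupported interleave {interleave!r}; use bil, bsq or bip")
    dtype = np.dtype(cube.data.dtype)
    if dtype not in _DTYPE_CODES:
        dtype = np.dtype(np.float32)
    code = _DTYPE_CODES[dtype]

    path = Path(path)
    lines, samples, bands = cube.shape
    # reorder (line, sample, band) axes into the on-disk layout
    if interleave == "bil":
        disk = np.transpose(cube.data, (0, 2, 1))
    elif interleave == "bsq":
        disk = np.transpose(cube.data, (2, 0, 1))
    else:
        disk = cube.data
    disk.astype(dtype.newbyteorder("<")).tofile(path)

    wl = ",\n".join(f" {w:.17g}" for w in cube.wavelengths)  # full float precision
    header = (
        "ENVI\n"
        "description = {weedspec hyperspectral cube}\n"
        f"samples = {samples}\n"
        f"lines = {lines}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {code}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"cube kind = {cube.kind}\n"
        "wavelength units = Nanometers\n"
        "wavelength = {\n" + wl + "}\n"
    )
    hdr = path.with_name(path.name + ".hdr")
    hdr.write_text(header)
    return hdr


def _parse_envi_header(text: str) -> dict[str, str]:
    fields: dict[str, str] = {}
    body = text
    # join brace-delimited multi-line values
    key = None
    buf: list[str] = []
    in_braces = False
    for line in body.splitlines():
        if in_braces:
            buf.append(line)
            if "}" in line:
                fields[key] = " ".join(buf)
                in_braces = False
            continue
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        key = key.strip().lower()
        value = value.strip()
        if value.startswith("{") and "}" not in value:
            buf = [value]
            in_braces = True
        else:
            fields[key] = value
    return fields


def read_envi(header_path: str | Path) -> SpectralCube:
    """Read an ENVI-style cube given its header path.

    Requires an explicit wavelength list in the header; rejects interleaves
    other than bil/bsq/bip and byte order other than little-endian.
    """
    header_path = Path(header_path)
    fields = _parse_envi_header(header_path.read_text())

    for req in ("samples", "lines", "bands", "data type", "interleave"):
        if req not in fields:
            raise ValueError(f"ENVI header missing required field {req!r}")
    if "wavelength" not in fields:
        raise ValueError(
            "ENVI header has no wavelength list; weedspec requires explicit "
            "per-band wavelengths in nm"
        )
    samples = int(fields["samples"])
    lines = int(fields["lines"])
    bands = int(fields["bands"])
    code = int(fields["data type"])
    if code not in _ENVI_DTYPES:
        raise ValueError(f"unsupported ENVI data type code {code}")
    interleave = fields["interleave"].lower()
    if interleave not in _INTERLEAVES:
        raise ValueError(f"unsupported interleave {fields['interleave']!r}")
    if int(fields.get("byte order", "0")) != 0:
        raise ValueError("only little-endian (byte order = 0) files are supported")

    wl_text = fields["wavelength"].strip().lstrip("{").rstrip("}")
    wavelengths = np.array([float(w) for w in wl_text.replace(",", " ").split()])
    if len(wavelengths) != bands:
        raise ValueError(
            f"header declares {bands} bands but {len(wavelengths)} wavelengths"
        )

    binary = header_path.with_name(header_path.name.removesuffix(".hdr"))
    dtype = np.dtype(_ENVI_DTYPES[code]).newbyteorder("<")
    flat = np.fromfile(binary, dtype=dtype)
    expected = lines * samples * bands
    if flat.size != expected:
        raise ValueError(f"binary has {flat.size} values, expected {expected}")
    if interleave == "bil":
        data = flat.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bsq":
        data = flat.reshape(bands, lines, samples).transpose(1, 2, 0)
    else:
        data = flat.reshape(lines, samples, bands)
    kind = fields.get("cube kind", "raw")
    if kind not in ("raw", "reflectance"):
        kind = "raw"
    return SpectralCube(np.ascontiguousarray(data), wavelengths, kind=kind)


def pseudo_rgb(
    cube: SpectralCube, bands_for_rgb: tuple[float, float, float] = (650.0, 550.0, 470.0)
) -> np.ndarray:
    """Render a (lines, samples, 3) colour image from three wavelengths.

    Each channel is the nearest band, min-max scaled to [0, 1] independently
    so the rendering is usable for both raw and reflectance cubes.
    """
    channels = []
    for nm in bands_for_rgb:
        band = cube.data[:, :, cube.band_index(nm)].astype(float)
        finite = band[np.isfinite(band)]
        lo = finite.min() if finite.size else 0.0
        hi = finite.max() if finite.size else 1.0
        span = hi - lo
        channels.append((band - lo) / span if span > 0 else np.zeros_like(band))
    return np.clip(np.dstack(channels), 0.0, 1.0)


def max_variance_image(cube: SpectralCube) -> tuple[np.ndarray, int]:
    """Return (image, band index) for the band with maximal pixel variance."""
    if cube.n_bands == 1:
        warnings.warn("single-band cube: max-variance image is that band", stacklevel=2)
        return cube.data[:, :, 0].astype(float), 0
    flat = cube.data.reshape(-1, cube.n_bands).astype(float)
    variances = np.nanvar(flat, axis=0)
    idx = int(np.nanargmax(variances))
    return cube.data[:, :, idx].astype(float), idx
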