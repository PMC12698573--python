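"""ENVI cube I/O, empirical-line radiometric correction and ROI extraction.

The ENVI format is a plain-text header (``.hdr``) next to a raw binary array
(``.img``/``.bil``/...), with three interleaves: BSQ (band sequential), BIL
(band interleaved by line) and BIP (band interleaved by pixel).  Pixel
coordinates are 0-based and row-major throughout; ROI masks are same-shape
boolean images.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from hypyield.errors import DataError, DimensionError, FormatError

log = logging.getLogger(__name__)

# ENVI numeric codes for the dtypes this toolkit reads and writes
_ENVI_DTYPES = {2: np.int16, 4: np.float32, 5: np.float64, 12: np.uint16}
_DTYPE_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


@dataclass
class SpectralCube:
    """3-D radiance/reflectance block (rows x cols x channels) with wavelengths.

    ``unit_state`` is "dn" for raw digital numbers and "reflectance" after
    empirical-line correction.
    """

    values: np.ndarray
    wavelengths: np.ndarray
    unit_state: str = "dn"
    out_of_range_count: int | None = None  # set by empirical_line_correct

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.values.ndim != 3:
            raise DimensionError("cube must be 3-D (rows x cols x channels)")
        if self.values.shape[2] != self.wavelengths.size:
            raise DimensionError(
                f"cube has {self.values.shape[2]} channels but "
                f"{self.wavelengths.size} wavelengths"
            )
        if np.any(np.diff(self.wavelengths) <= 0):
            raise FormatError("wavelengths must be strictly increasing")
        if self.unit_state not in ("dn", "reflectance"):
            raise FormatError(f"unknown unit_state {self.unit_state!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class ElmCoefficients:
    """Per-channel gain/offset of the empirical line method (rho = G*DN + O).

    Scalars broadcast to all channels.
    """

    gain: np.ndarray | float
    offset: np.ndarray | float = 0.0

    def resolved(self, n_channels: int) -> tuple[np.ndarray, np.ndarray]:
        gain = np.atleast_1d(np.asarray(self.gain, dtype=float))
        offset = np.atleast_1d(np.asarray(self.offset, dtype=float))
        if gain.size == 1:
            gain = np.full(n_channels, gain.item())
        if offset.size == 1:
            offset = np.full(n_channels, offset.item())
        if gain.size != n_channels or offset.size != n_channels:
            raise DimensionError(
                f"coefficient length ({gain.size}/{offset.size}) does not "
                f"match channel count ({n_channels})"
            )
        if not (np.all(np.isfinite(gain)) and np.all(np.isfinite(offset))):
            raise DataError("ELM coefficients must be finite")
        if np.any(gain == 0):
            raise DataError("ELM gain must be nonzero")
        return gain, offset


@dataclass
class ROPSet:
    """Region-of-interest pixel set: all pixel spectra inside one sample's ROI."""

    sample_id: str
    pixel_spectra: np.ndarray
    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        self.pixel_spectra = np.atleast_2d(np.asarray(self.pixel_spectra, dtype=float))
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.pixel_spectra.shape[0] < 1:
            raise DataError("ROP set must contain at least one pixel")
        if self.pixel_spectra.shape[1] != self.wavelengths.size:
            raise DimensionError("pixel spectra width must match wavelength count")

    @property
    def n_pixels(self) -> int:
        return self.pixel_spectra.shape[0]


# ---------------------------------------------------------------------------
# ENVI read/write


def _parse_header(text: str) -> dict:
    if not text.lstrip().startswith("ENVI"):
        raise FormatError("not an ENVI header (missing 'ENVI' magic line)")
    fields: dict[str, str] = {}
    # join brace-delimited multi-line values first
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    for line in text.splitlines()[1:]:
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        fields[key.strip().lower()] = value.strip()
    return fields


def read_envi_cube(header_path: str | Path, data_path: str | Path | None = None) -> SpectralCube:
    """Read an ENVI header + binary image into a :class:`SpectralCube`.

    ``data_path`` defaults to the header path with its suffix replaced by
    ``.img``.  The cube is returned in (rows, cols, channels) layout
    regardless of the stored interleave; ``unit_state`` is taken from an
    optional ``unit state`` header field, defaulting to "dn".
    """
    header_path = Path(header_path)
    fields = _parse_header(header_path.read_text())
    try:
        samples = int(fields["samples"])
        lines = int(fields["lines"])
        bands = int(fields["bands"])
        dtype_code = int(fields["data type"])
        interleave = fields["interleave"].lower()
    except KeyError as exc:
        raise FormatError(f"header missing required field: {exc}") from exc
    if "wavelength" not in fields:
        raise FormatError("header missing wavelength list")
    wl_text = fields["wavelength"].strip()
    if not (wl_text.startswith("{") and wl_text.endswith("}")):
        raise FormatError("wavelength list must be brace-delimited")
    wavelengths = np.array(
        [float(tok) for tok in wl_text[1:-1].replace(",", " ").split()]
    )
    if wavelengths.size != bands:
        raise FormatError(
            f"header declares {bands} bands but lists {wavelengths.size} wavelengths"
        )
    if dtype_code not in _ENVI_DTYPES:
        raise FormatError(f"unsupported ENVI data type code {dtype_code}")
    if interleave not in ("bsq", "bil", "bip"):
        raise FormatError(f"unknown interleave {interleave!r}")

    if data_path is None:
        data_path = header_path.with_suffix(".img")
    raw = np.fromfile(data_path, dtype=_ENVI_DTYPES[dtype_code])
    expected = samples * lines * bands
    if raw.size != expected:
        raise FormatError(
            f"binary holds {raw.size} values; header implies {expected}"
        )
    if interleave == "bsq":
        values = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        values = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:  # bip
        values = raw.reshape(lines, samples, bands)
    unit_state = fields.get("unit state", "dn")
    return SpectralCube(values=values.copy(), wavelengths=wavelengths, unit_state=unit_state)


def write_envi_cube(
    cube: SpectralCube,
    header_path: str | Path,
    data_path: str | Path | None = None,
    interleave: str = "bil",
) -> None:
    """Write a cube as ENVI header + raw binary in the requested interleave."""
    interleave = interleave.lower()
    if interleave not in ("bsq", "bil", "bip"):
        raise FormatError(f"unknown interleave {interleave!r}")
    header_path = Path(header_path)
    if data_path is None:
        data_path = header_path.with_suffix(".img")
    values = np.asarray(cube.values)
    dtype = values.dtype if values.dtype in _DTYPE_CODES else np.dtype(np.float32)
    values = values.astype(dtype)
    rows, cols, bands = values.shape
    if interleave == "bsq":
        out = values.transpose(2, 0, 1)
    elif interleave == "bil":
        out = values.transpose(0, 2, 1)
    else:
        out = values
    wl = " , ".join(f"{w:.6f}" for w in cube.wavelengths)
    header = (
        "ENVI\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_CODES[dtype]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"unit state = {cube.unit_state}\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    header_path.write_text(header)
    np.ascontiguousarray(out).tofile(data_path)


# ---------------------------------------------------------------------------
# Radiometric correction and ROI handling


def empirical_line_correct(cube: SpectralCube, coeffs: ElmCoefficients) -> SpectralCube:
    """Convert digital numbers to reflectance with the empirical line method.

    Applies ``rho = G * DN + O`` per channel.  Values falling outside
    [0, 1] are retained (clipping would bias downstream statistics) but
    counted; the count is logged and stored on the returned cube as
    ``out_of_range_count``.
    """
    if cube.unit_state != "dn":
        raise DataError("empirical_line_correct expects a cube in DN units")
    gain, offset = coeffs.resolved(cube.shape[2])
    rho = cube.values.astype(float) * gain + offset
    n_bad = int(np.count_nonzero((rho < 0.0) | (rho > 1.0)))
    if n_bad:
        log.warning(
            "empirical line correction: %d of %d values outside [0, 1]",
            n_bad,
            rho.size,
        )
    return SpectralCube(
        values=rho,
        wavelengths=cube.wavelengths.copy(),
        unit_state="reflectance",
        out_of_range_count=n_bad,
    )


def extract_roi(cube: SpectralCube, mask: np.ndarray, sample_id: str = "roi") -> ROPSet:
    """Collect the spectra of all true-mask pixels, row-major order."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != cube.values.shape[:2]:
        raise DimensionError(
            f"mask shape {mask.shape} does not match cube spatial shape "
            f"{cube.values.shape[:2]}"
        )
    if not mask.any():
        raise DataError("empty ROI: mask selects no pixels")
    return ROPSet(
        sample_id=sample_id,
        pixel_spectra=cube.values[mask],  # row-major by numpy advanced indexing
        wavelengths=cube.wavelengths.copy(),
    )


def mean_spectrum(rop: ROPSet) -> np.ndarray:
    """Per-channel arithmetic mean over the ROI pixels (average value method)."""
    return rop.pixel_spectra.mean(axis=0)


def rop_features(rop: ROPSet) -> np.ndarray:
    """Fixed-length summary of an ROI pixel set (the "B" feature block).

    Order: ``[pixel_count, dispersion, brightness, heterogeneity]`` where
    dispersion is the mean over channels of the within-ROI per-channel
    sample standard deviation, brightness the grand mean over pixels and
    channels, and heterogeneity the mean spectral angle (radians) between
    each pixel and the ROI mean spectrum.  Single-pixel ROIs have zero
    dispersion and heterogeneity.
    """
    px = rop.pixel_spectra
    n = px.shape[0]
    brightness = float(px.mean())
    if n == 1:
        return np.array([1.0, 0.0, brightness, 0.0])
    dispersion = float(px.std(axis=0, ddof=1).mean())
    mu = px.mean(axis=0)
    mu_norm = np.linalg.norm(mu)
    px_norm = np.linalg.norm(px, axis=1)
    if mu_norm == 0 or np.any(px_norm == 0):
        angle = 0.0
    else:
        cosine = np.clip(px @ mu / (px_norm * mu_norm), -1.0, 1.0)
        angle = float(np.arccos(cosine).mean())
    return np.array([float(n), dispersion, brightness, angle])


ROP_FEATURE_NAMES = ("pixel_count", "dispersion", "brightness", "heterogeneity")


def wavelength_to_channel(wavelengths: np.ndarray, target_nm: float) -> int:
    """Nearest-channel lookup for a wavelength anchor; ties go to the lower index."""
    wl = np.asarray(wavelengths, dtype=float)
    if not (wl[0] <= target_nm <= wl[-1]):
        raise DataError(
            f"target {target_nm} nm outside grid [{wl[0]}, {wl[-1]}] nm"
        )
    dist = np.abs(wl - target_nm)
    return int(np.argmin(dist))  # argmin returns the first (lower) index on ties


# ---------------------------------------------------------------------------
# ROI mask I/O (PNG or run-length CSV)


def write_mask_png(mask: np.ndarray, path: str | Path) -> None:
    from PIL import Image

    img = Image.fromarray((np.asarray(mask, dtype=bool) * 255).astype(np.uint8))
    img.save(path)


def read_mask_png(path: str | Path) -> np.ndarray:
    from PIL import Image

    return np.asarray(Image.open(path)) > 0


def write_mask_rle(mask: np.ndarray, path: str | Path) -> None:
    """Run-length CSV: header row `rows,cols`, then `row,col_start,length` runs."""
    mask = np.asarray(mask, dtype=bool)
    lines = [f"{mask.shape[0]},{mask.shape[1]}"]
    for r in range(mask.shape[0]):
        row = mask[r]
        edges = np.flatnonzero(np.diff(np.concatenate(([0], row.view(np.int8), [0]))))
        for start, stop in zip(edges[::2], edges[1::2]):
            lines.append(f"{r},{start},{stop - start}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_mask_rle(path: str | Path) -> np.ndarray:
    rows_text = Path(path).read_text().strip().splitlines()
    shape = tuple(int(v) for v in rows_text[0].split(","))
    mask = np.zeros(shape, dtype=bool)
    for line in rows_text[1:]:
        r, start, length = (int(v) for v in line.split(","))
        mask[r, start : start + length] = True
    return mask
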